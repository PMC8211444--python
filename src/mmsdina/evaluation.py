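"""Recovery metrics, classification accuracy, convergence diagnostics and
posterior summaries.

Recovery across simulation replications uses three indices per parameter:
Bias (mean of posterior-mean minus truth), MSE (mean squared deviation) and
SD (mean of posterior standard deviations).  Block aggregates (e.g. "all
strategy-1 slipping parameters") report the mean of |Bias| — written ABias
— and plain means of MSE and SD.

Attribute classification is scored by four criteria: the marginal rate per
attribute (h_k), the proportion of examinees correct on all K attributes
(t), correct on at least K-1 (v), and misclassified on at least K-1 (z).

Convergence uses the Brooks-Gelman corrected potential scale reduction
factor (PSRF) over multiple chains, flagged at a configurable cutoff
(default 1.2; 1.05 available for conservative use).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .model_core import DimensionError, ModelValidationError
from .sampler import PosteriorDraws

logger = logging.getLogger("mmsdina")

__all__ = [
    "RecoveryReport",
    "ClassificationReport",
    "ConvergenceReport",
    "recovery_metrics",
    "classification_metrics",
    "compute_psrf",
    "psrf_report",
    "posterior_summaries",
    "plot_strategy_probabilities",
]


# ---------------------------------------------------------------------------
# parameter recovery
# ---------------------------------------------------------------------------


@dataclass
class RecoveryReport:
    """Per-parameter Bias/MSE/SD and their block averages.

    Arrays share the shape of the truth (e.g. (J, M) for item parameters).
    """

    bias: np.ndarray
    mse: np.ndarray
    sd: np.ndarray
    n_replications: int

    def abias(self, signed: bool = False) -> float:
        """Block-average bias: mean |Bias| by default, plain mean if signed."""
        return float(self.bias.mean() if signed else np.abs(self.bias).mean())

    @property
    def amse(self) -> float:
        return float(self.mse.mean())

    @property
    def asd(self) -> float:
        return float(self.sd.mean())


def recovery_metrics(estimates, truths, posterior_sds=None) -> RecoveryReport:
    """Bias/MSE/SD of posterior-mean estimates across replications.

    Parameters
    ----------
    estimates
        Array of shape ``(n_replications, *param_shape)``: the posterior
        mean of each parameter in each replication.
    truths
        Array of shape ``param_shape`` (or broadcastable to it).
    posterior_sds
        Same shape as ``estimates``: the posterior standard deviation per
        replication.  Optional; SD entries are NaN when absent.
    """
    est = np.asarray(estimates, dtype=float)
    if est.ndim < 1 or est.shape[0] < 1:
        raise ModelValidationError("at least one replication is required")
    truth = np.broadcast_to(np.asarray(truths, dtype=float), est.shape[1:])
    if est.shape[1:] != truth.shape:
        raise DimensionError(
            f"estimates {est.shape[1:]} and truths {truth.shape} do not align"
        )
    err = est - truth
    bias = err.mean(axis=0)
    mse = (err ** 2).mean(axis=0)
    if posterior_sds is not None:
        sds = np.asarray(posterior_sds, dtype=float)
        if sds.shape != est.shape:
            raise DimensionError("posterior SDs must match the estimate array")
        sd = sds.mean(axis=0)
    else:
        sd = np.full(truth.shape, np.nan)
    return RecoveryReport(bias=bias, mse=mse, sd=sd, n_replications=est.shape[0])


# ---------------------------------------------------------------------------
# attribute classification
# ---------------------------------------------------------------------------


@dataclass
class ClassificationReport:
    """Attribute-classification accuracy of estimated profiles."""

    h: np.ndarray  # (K,) marginal rate per attribute
    t: float       # all K correct
    v: float       # >= K-1 correct
    z: float       # >= K-1 incorrect

    def __post_init__(self):
        for val, name in ((self.t, "t"), (self.v, "v"), (self.z, "z")):
            if not 0.0 <= val <= 1.0:
                raise ModelValidationError(f"criterion {name}={val} outside [0, 1]")
        if self.t > self.v + 1e-12:
            raise ModelValidationError("t (all correct) cannot exceed v (>= K-1)")


def classification_metrics(estimated, true) -> ClassificationReport:
    """Score estimated against true attribute profiles (both N x K binary)."""
    est = np.asarray(estimated, dtype=np.int64)
    tru = np.asarray(true, dtype=np.int64)
    if est.shape != tru.shape or est.ndim != 2:
        raise DimensionError(
            f"profile arrays must share (N, K); got {est.shape} vs {tru.shape}"
        )
    N, K = est.shape
    match = est == tru
    n_match = match.sum(axis=1)
    return ClassificationReport(
        h=match.mean(axis=0),
        t=float((n_match == K).mean()),
        v=float((n_match >= K - 1).mean()),
        z=float((n_match <= 1).mean()),  # misclassified on >= K-1 attributes
    )


# ---------------------------------------------------------------------------
# convergence (PSRF)
# ---------------------------------------------------------------------------


@dataclass
class ConvergenceReport:
    """PSRF per scalar parameter with a pass/fail flag at the cutoff."""

    table: pd.DataFrame  # columns: parameter, psrf, converged
    cutoff: float

    @property
    def max_psrf(self) -> float:
        return float(self.table["psrf"].max())

    @property
    def all_converged(self) -> bool:
        return bool(self.table["converged"].all())


def compute_psrf(chains, *, split: bool = False) -> float:
    """Brooks-Gelman corrected PSRF for one scalar parameter.

    ``chains`` is an (C, R) array (or list of equal-length 1-D arrays) of
    draws from C >= 2 chains.  ``split=True`` halves each chain first
    (split R-hat).  Degenerate chains with zero within-variance return 1.
    """
    arr = np.asarray(chains, dtype=float)
    if arr.ndim != 2 or arr.shape[0] < 2:
        raise ModelValidationError("PSRF needs >= 2 chains of equal length")
    if split:
        half = arr.shape[1] // 2
        arr = np.concatenate([arr[:, :half], arr[:, half:2 * half]], axis=0)
    C, R = arr.shape
    chain_means = arr.mean(axis=1)
    W = arr.var(axis=1, ddof=1).mean()
    B_over_R = chain_means.var(ddof=1)  # = B / R
    if W <= 0:
        return 1.0
    sigma2_hat = (R - 1) / R * W + B_over_R
    # Brooks & Gelman's sampling-variability correction
    psrf2 = (C + 1) / C * sigma2_hat / W - (R - 1) / (C * R)
    return float(np.sqrt(max(psrf2, 0.0)))


def _chain_scalars(draws: PosteriorDraws) -> dict[str, np.ndarray]:
    """Flatten one chain's item parameters, mixing proportions and attribute
    means into named scalar traces (1-based labels)."""
    out = {}
    R, J, M = draws.s.shape
    for m in range(M):
        for j in range(J):
            out[f"s[{j + 1},{m + 1}]"] = draws.s[:, j, m]
            out[f"g[{j + 1},{m + 1}]"] = draws.g[:, j, m]
    for m in range(draws.mu.shape[1]):
        out[f"mu[{m + 1}]"] = draws.mu[:, m]
    if draws.pi is not None and draws.pi.shape[1] > 1:
        for m in range(draws.pi.shape[1]):
            out[f"pi[{m + 1}]"] = draws.pi[:, m]
    return out


def _relabel_draws(d: PosteriorDraws, ref_stats) -> PosteriorDraws:
    """Relabel every retained draw of one chain to a reference labelling.

    For each draw the strategy permutation minimizing the squared distance
    of (pi, mu, s, g) to the reference point statistics is applied.
    """
    import itertools
    from dataclasses import replace as _dc_replace

    M = d.pi.shape[1]
    pi_ref, mu_ref, s_ref, g_ref = ref_stats
    perms = [list(p) for p in itertools.permutations(range(M))]
    dists = np.empty((d.R, len(perms)))
    for k, p in enumerate(perms):
        dists[:, k] = (((d.pi[:, p] - pi_ref) ** 2).sum(axis=1)
                       + ((d.mu[:, p] - mu_ref) ** 2).sum(axis=1)
                       + ((d.s[:, :, p] - s_ref) ** 2).sum(axis=(1, 2))
                       + ((d.g[:, :, p] - g_ref) ** 2).sum(axis=(1, 2)))
    choice = dists.argmin(axis=1)
    if (choice == 0).all():
        return d
    pi, mu, s, g = d.pi.copy(), d.mu.copy(), d.s.copy(), d.g.copy()
    c = None if d.c is None else d.c.copy()
    for k, p in enumerate(perms):
        if k == 0:
            continue
        rows = choice == k
        if not rows.any():
            continue
        pi[rows] = d.pi[rows][:, p]
        mu[rows] = d.mu[rows][:, p]
        s[rows] = d.s[rows][:, :, p]
        g[rows] = d.g[rows][:, :, p]
        if c is not None:
            c[rows] = np.argsort(p)[d.c[rows]]
    logger.info("relabelled %d of %d draws", int((choice != 0).sum()), d.R)
    return _dc_replace(d, pi=pi, mu=mu, s=s, g=g, c=c)


def _align_chain_labels(chain_draws: list[PosteriorDraws]) -> list[PosteriorDraws]:
    """Canonicalize strategy labels draw by draw before cross-chain
    comparison.

    In a finite mixture the strategy labels are only identified up to
    permutation through the strategy-specific Q-matrices; chains (and
    stretches within a chain) can visit relabelled copies of the same
    posterior mass, making raw marginal traces of strategy-indexed
    parameters meaningless for variance-based diagnostics.  Following
    standard relabelling practice for mixture MCMC output, every retained
    draw of every chain is mapped to the permutation closest to a common
    reference (the first chain's posterior means, refined once after a
    first alignment pass).  Single-strategy and MS-DINA fits pass through
    unchanged.
    """
    ref = chain_draws[0]
    if ref.pi is None or ref.pi.shape[1] < 2 or ref.s.shape[2] < 2:
        return chain_draws
    ref_stats = (ref.pi.mean(0), ref.mu.mean(0), ref.s.mean(0), ref.g.mean(0))
    aligned = [_relabel_draws(d, ref_stats) for d in chain_draws]
    # refine the reference with the grand mean of the first pass
    ref_stats = tuple(
        np.mean([getattr(d, name).mean(axis=0) for d in aligned], axis=0)
        for name in ("pi", "mu", "s", "g")
    )
    return [_relabel_draws(d, ref_stats) for d in aligned]


def psrf_report(
    chain_draws: list[PosteriorDraws],
    cutoff: float = 1.2,
    *,
    split: bool = False,
    align_labels: bool = True,
) -> ConvergenceReport:
    """PSRF across >= 2 chains for every item parameter, attribute mean and
    mixing proportion.  Parameters at or above the cutoff are flagged.

    By default strategy labels are matched across chains first (see
    :func:`_align_chain_labels`); set ``align_labels=False`` to diagnose
    the raw, unpermuted traces.
    """
    if len(chain_draws) < 2:
        raise ModelValidationError("convergence diagnosis needs >= 2 chains")
    if align_labels:
        chain_draws = _align_chain_labels(chain_draws)
    per_chain = [_chain_scalars(d) for d in chain_draws]
    names = per_chain[0].keys()
    rows = []
    for name in names:
        stacked = np.stack([pc[name] for pc in per_chain], axis=0)
        val = compute_psrf(stacked, split=split)
        rows.append({"parameter": name, "psrf": val, "converged": val < cutoff})
    table = pd.DataFrame(rows)
    n_flag = int((~table["converged"]).sum())
    if n_flag:
        logger.warning("%d parameters have PSRF >= %.3f", n_flag, cutoff)
    return ConvergenceReport(table=table, cutoff=cutoff)


# ---------------------------------------------------------------------------
# posterior summaries
# ---------------------------------------------------------------------------


def posterior_summaries(draws: PosteriorDraws) -> dict:
    """Point summaries of one chain's retained draws.

    Returns a dict with:

    * ``mastery_prob`` (N, K): posterior P(alpha_ik = 1 | u);
    * ``eap_profiles`` (N, K): mastery probability thresholded at 0.5
      (a probability of exactly 0.5 classifies as mastered);
    * ``strategy_prob`` (N, M): retained-draw frequency of each membership
      (None for MS-DINA);
    * ``item_params``: DataFrame of posterior means and SDs of s and g
      (1-based item/strategy labels);
    * ``pi_mean``, ``mu_mean``: posterior means of the mixture block.
    """
    mastery = draws.alpha.mean(axis=0)
    eap = (mastery >= 0.5).astype(np.int8)
    strategy_prob = None
    if draws.c is not None:
        M = draws.pi.shape[1]
        counts = np.stack([(draws.c == m).mean(axis=0) for m in range(M)], axis=1)
        strategy_prob = counts
    R, J, M_items = draws.s.shape
    rows = []
    for j in range(J):
        for m in range(M_items):
            rows.append({
                "item": j + 1,
                "strategy": m + 1,
                "s_mean": draws.s[:, j, m].mean(),
                "s_sd": draws.s[:, j, m].std(ddof=1),
                "g_mean": draws.g[:, j, m].mean(),
                "g_sd": draws.g[:, j, m].std(ddof=1),
            })
    return {
        "mastery_prob": mastery,
        "eap_profiles": eap,
        "strategy_prob": strategy_prob,
        "item_params": pd.DataFrame(rows),
        "pi_mean": None if draws.pi is None else draws.pi.mean(axis=0),
        "mu_mean": draws.mu.mean(axis=0),
    }


def plot_strategy_probabilities(strategy_prob, strategy: int = 0, ax=None):
    """Scatter of per-examinee posterior probability of using one strategy
    (y in [0, 1], x = examinee index)."""
    import matplotlib.pyplot as plt

    probs = np.asarray(strategy_prob)[:, strategy]
    if ax is None:
        _, ax = plt.subplots(figsize=(7, 3.5))
    ax.scatter(np.arange(1, probs.size + 1), probs, s=8)
    ax.set_xlabel("examinee")
    ax.set_ylabel(f"P(strategy {strategy + 1})")
    ax.set_ylim(-0.02, 1.02)
    return ax
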