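"""MH-within-Gibbs estimation of the DINA, MS-DINA and MMS-DINA models.

One sweep of the sampler cycles five full-conditional updates:

1. mixing proportions  ``pi ~ Dirichlet(beta_m + n_m)`` (conjugate),
2. strategy memberships ``c_i`` from their exact M-point conditional,
3. attribute means      ``mu_m ~ Beta(sum alpha + l1, n_m K - sum alpha + l2)``
   (conjugate),
4. attribute profiles   ``alpha_i`` from the exact 2^K-point conditional
   (enumeration; attribute-at-a-time Gibbs fallback for large K),
5. item parameters      ``s_jm, g_jm`` from a Bernoulli-count likelihood
   times a 4-parameter Beta prior on a bounded support — a non-conjugate
   density sampled by inverse-CDF on a fixed grid (default) or by a
   logit-scale random-walk Metropolis step.

The single-strategy DINA model is the M = 1 special case and runs through
the identical code path (bit-identical draws for identical seeds).  The
MS-DINA model shares one (s_j, g_j) pair across strategies and replaces the
per-strategy ideal response by ``eta_ij = max_m eta_ijm``; it has no
mixture side (no pi, no c, a single attribute mean).

All randomness flows through one :class:`numpy.random.Generator`, so a run
is bit-reproducible from its seed.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass

import numpy as np

from .model_core import (
    DimensionError,
    ItemParameters,
    ModelValidationError,
    MultiStrategyQMatrix,
    ResponseMatrix,
    all_profiles,
    eta_table,
    profile_index,
)

logger = logging.getLogger("mmsdina")

__all__ = [
    "PriorSpec",
    "ChainConfig",
    "PosteriorDraws",
    "sample_pi",
    "membership_log_weights",
    "sample_memberships",
    "sample_attribute_mean",
    "sample_profiles",
    "sample_item_params",
    "run_chain",
    "run_chains",
    "four_beta_mean",
]


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PriorSpec:
    """Hyper-parameters of the hierarchical prior.

    Defaults: ``Dirichlet(0.01, ..., 0.01)`` for the mixing proportions,
    ``Beta(0.5, 0.5)`` for each attribute mean, and ``4-Beta(1, 2, 0.1,
    0.5)`` (a Beta(1, 2) rescaled to support (0.1, 0.5)) for every slipping
    and guessing parameter.

    ``literal_mu_update`` switches the second shape parameter of the
    attribute-mean update from the members-only count ``n_m * K`` to the
    literal ``N * K``; the members-only form is the conjugate update for the
    stated hierarchy and is the default.
    """

    beta: float = 0.01
    lambda1: float = 0.5
    lambda2: float = 0.5
    s_shape: tuple = (1.0, 2.0)
    s_support: tuple = (0.1, 0.5)
    g_shape: tuple = (1.0, 2.0)
    g_support: tuple = (0.1, 0.5)
    literal_mu_update: bool = False

    def __post_init__(self):
        for val, name in ((self.beta, "beta"), (self.lambda1, "lambda1"),
                          (self.lambda2, "lambda2")):
            if val <= 0:
                raise ModelValidationError(f"prior concentration {name} must be > 0")
        for shape, support, name in ((self.s_shape, self.s_support, "slipping"),
                                     (self.g_shape, self.g_support, "guessing")):
            if min(shape) <= 0:
                raise ModelValidationError(f"{name} Beta shapes must be > 0")
            if support[0] >= support[1]:
                raise ModelValidationError(f"{name} support must satisfy a < b")
        if self.s_support[0] + self.g_support[1] >= 1.0:
            import warnings

            warnings.warn(
                "prior supports permit 1 - s <= g; the usual monotonicity "
                "condition of the response function is not guaranteed",
                UserWarning,
                stacklevel=2,
            )


@dataclass(frozen=True)
class ChainConfig:
    """Chain-length and sampler-mechanics settings.

    ``iterations`` is the total chain length including burn-in (default
    10,000 with 5,000 burn-in, no thinning).
    """

    iterations: int = 10_000
    burn_in: int = 5_000
    thinning: int = 1
    n_chains: int = 1
    rng_seed: int | None = None
    blocked_membership: bool = True
    label_swap_moves: bool = True
    basin_selection: bool = True
    basin_lookahead: int = 120
    store_cell_logp: bool = True
    criteria_likelihood: str = "conditional"  # "conditional" | "mixture"
    item_param_method: str = "grid"  # "grid" | "mh"
    grid_points: int = 1024
    mh_step: float = 0.4
    max_enum_K: int = 12
    profile_fallback: bool = False  # attribute-at-a-time Gibbs when K > cap
    log_every: int = 0

    def __post_init__(self):
        if not 0 <= self.burn_in < self.iterations:
            raise ModelValidationError("burn_in must satisfy 0 <= burn_in < iterations")
        if self.thinning < 1 or self.n_chains < 1 or self.grid_points < 2:
            raise ModelValidationError("invalid chain configuration")
        if self.item_param_method not in ("grid", "mh"):
            raise ModelValidationError("item_param_method must be 'grid' or 'mh'")
        if self.criteria_likelihood not in ("conditional", "mixture"):
            raise ModelValidationError(
                "criteria_likelihood must be 'conditional' or 'mixture'")

    @property
    def n_retained(self) -> int:
        return len(range(self.burn_in, self.iterations, self.thinning))


@dataclass
class PosteriorDraws:
    """Retained post-burn-in draws of every parameter block.

    ``cell_logp`` holds, for each retained sweep, the (N, J) matrix of
    per-observation mixture log-probabilities ``log sum_m pi_m P(u_ij|.)``
    that DIC and LPML consume; ``loglik`` is its per-sweep sum.
    """

    model: str
    s: np.ndarray                 # (R, J, M_items)
    g: np.ndarray                 # (R, J, M_items)
    mu: np.ndarray                # (R, M) or (R, 1)
    alpha: np.ndarray             # (R, N, K) int8
    loglik: np.ndarray            # (R,)
    pi: np.ndarray | None = None  # (R, M); None for MS-DINA
    c: np.ndarray | None = None   # (R, N) int8; None for MS-DINA
    cell_logp: np.ndarray | None = None  # (R, N, J) float32
    prior: PriorSpec | None = None
    config: ChainConfig | None = None
    data_fingerprint: str | None = None
    mh_acceptance: float | None = None
    swap_acceptance: float | None = None

    @property
    def R(self) -> int:
        return self.s.shape[0]

    def validate(self) -> None:
        """Check every retained draw against the model-type invariants."""
        if self.pi is not None:
            if (self.pi < 0).any() or np.abs(self.pi.sum(axis=1) - 1.0).max() > 1e-8:
                raise ModelValidationError("a retained pi draw is off the simplex")
        prior = self.prior or PriorSpec()
        for arr, (lo, hi), name in ((self.s, prior.s_support, "slipping"),
                                    (self.g, prior.g_support, "guessing")):
            if arr.min() <= lo or arr.max() >= hi:
                raise ModelValidationError(f"a retained {name} draw left its support")
        if not np.isin(self.alpha, (0, 1)).all():
            raise ModelValidationError("a retained profile draw is non-binary")
        if self.c is not None:
            M = self.pi.shape[1]
            if self.c.min() < 0 or self.c.max() >= M:
                raise ModelValidationError("a retained membership draw is out of range")
        if (self.mu <= 0).any() or (self.mu >= 1).any():
            raise ModelValidationError("a retained attribute-mean draw left (0, 1)")
        if self.cell_logp is not None:
            resum = self.cell_logp.sum(axis=(1, 2))
            if np.abs(resum - self.loglik).max() > 1e-3:
                raise ModelValidationError(
                    "stored per-cell terms do not re-sum to the joint log-likelihood"
                )


def four_beta_mean(shape: tuple, support: tuple) -> float:
    """Mean of a Beta(v, t) rescaled to (a, b): ``a + (b - a) v / (v + t)``."""
    v, t = shape
    a, b = support
    return a + (b - a) * v / (v + t)


def _fingerprint(u: np.ndarray) -> str:
    return hashlib.sha1(np.ascontiguousarray(u, dtype=np.int8).tobytes()).hexdigest()


# ---------------------------------------------------------------------------
# full-conditional updates (Steps 1-5)
# ---------------------------------------------------------------------------


def sample_pi(c, M: int, beta, rng: np.random.Generator) -> np.ndarray:
    """Step 1: conjugate Dirichlet update of the mixing proportions.

    Valid (and equal to a prior draw) even when some strategies are empty.
    """
    c = np.asarray(c, dtype=np.int64)
    n = np.bincount(c, minlength=M) if c.size else np.zeros(M)
    conc = np.broadcast_to(np.asarray(beta, dtype=float), (M,)) + n
    return rng.dirichlet(conc)


def _strategy_loglik(u, alpha, s_m, g_m, qmatrix_2d) -> np.ndarray:
    """(N,) log-likelihood of each examinee's responses under one strategy."""
    eta = eta_table(alpha, qmatrix_2d).astype(np.float64)
    ls1, ls0 = np.log(1.0 - s_m), np.log(s_m)
    lg1, lg0 = np.log(g_m), np.log(1.0 - g_m)
    A = np.where(u == 1, ls1, ls0)  # log-prob of u_ij given eta=1
    B = np.where(u == 1, lg1, lg0)  # log-prob of u_ij given eta=0
    return (B + eta * (A - B)).sum(axis=1)


def membership_log_weights(
    responses: ResponseMatrix,
    alpha,
    params: ItemParameters,
    pi,
    mu,
    qmatrix: MultiStrategyQMatrix,
) -> np.ndarray:
    """Unnormalized log-weights of the membership full conditional, (N, M):
    ``log pi_m + log P(u_i | alpha_i, strategy m) + log P(alpha_i | mu_m)``.
    """
    u = responses.u
    alpha = np.asarray(alpha, dtype=np.int64)
    K = alpha.shape[1]
    rowsum = alpha.sum(axis=1)
    with np.errstate(divide="ignore"):
        log_pi = np.log(np.asarray(pi, dtype=float))
    out = np.empty((u.shape[0], qmatrix.M))
    for m in range(qmatrix.M):
        ll = _strategy_loglik(u, alpha, params.s[:, m], params.g[:, m], qmatrix.q[m])
        prior = rowsum * np.log(mu[m]) + (K - rowsum) * np.log(1.0 - mu[m])
        out[:, m] = log_pi[m] + ll + prior
    return out


def _logsumexp_rows(x: np.ndarray) -> np.ndarray:
    hi = x.max(axis=1)
    return hi + np.log(np.exp(x - hi[:, None]).sum(axis=1))


def _categorical_rows(logw: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Draw one index per row from row-wise categorical log-weights."""
    shifted = logw - logw.max(axis=1, keepdims=True)
    if not np.isfinite(shifted).any(axis=1).all():
        raise FloatingPointError(
            "all categorical weights vanished for at least one row; "
            "the conditioning state assigns zero probability everywhere"
        )
    w = np.exp(shifted)
    cdf = np.cumsum(w, axis=1)
    r = rng.random(logw.shape[0]) * cdf[:, -1]
    return np.minimum((cdf < r[:, None]).sum(axis=1), logw.shape[1] - 1)


def sample_memberships(
    responses: ResponseMatrix,
    alpha,
    params: ItemParameters,
    pi,
    mu,
    qmatrix: MultiStrategyQMatrix,
    rng: np.random.Generator,
) -> np.ndarray:
    """Step 2: draw each examinee's strategy membership from its exact
    M-point full conditional (computed in log space, then normalized)."""
    logw = membership_log_weights(responses, alpha, params, pi, mu, qmatrix)
    return _categorical_rows(logw, rng)


def sample_attribute_mean(
    alpha,
    c,
    m: int,
    lambda1: float,
    lambda2: float,
    rng: np.random.Generator,
    *,
    literal_N: int | None = None,
) -> float:
    """Step 3: conjugate Beta update of strategy ``m``'s attribute mean.

    Shape parameters are ``sum alpha (members) + lambda1`` and
    ``n_m K - sum alpha + lambda2``; an empty strategy reduces to a prior
    draw.  Passing ``literal_N`` replaces ``n_m`` by the full sample size
    (the literal reading of the printed update).
    """
    alpha = np.atleast_2d(np.asarray(alpha, dtype=np.int64))
    c = np.asarray(c, dtype=np.int64)
    K = alpha.shape[1]
    members = c == m
    ssum = int(alpha[members].sum())
    total = (literal_N if literal_N is not None else int(members.sum())) * K
    return float(rng.beta(ssum + lambda1, total - ssum + lambda2))


def sample_profiles(
    responses: ResponseMatrix,
    c,
    params: ItemParameters,
    mu,
    qmatrix: MultiStrategyQMatrix,
    rng: np.random.Generator,
    *,
    max_enum_K: int = 12,
    fallback: bool = False,
) -> np.ndarray:
    """Step 4: draw each examinee's attribute profile exactly from the
    2^K-point full conditional under their current strategy.

    Enumeration is exact for ``K <= max_enum_K``; beyond that an
    attribute-at-a-time Gibbs sweep is used if ``fallback`` is enabled.
    """
    K = qmatrix.K
    u = responses.u
    c = np.asarray(c, dtype=np.int64)
    alpha = np.empty((u.shape[0], K), dtype=np.int8)
    if K > max_enum_K:
        if not fallback:
            raise ModelValidationError(
                f"K={K} exceeds the exact-enumeration cap {max_enum_K}; "
                "enable the attribute-at-a-time fallback"
            )
        return _profiles_gibbs_sweep(u, c, params, mu, qmatrix, rng)
    profiles = all_profiles(K)
    prof_sums = profiles.sum(axis=1)
    for m in range(qmatrix.M):
        rows = np.flatnonzero(c == m)
        if rows.size == 0:
            continue
        scores = _profile_scores(u[rows], params.s[:, m], params.g[:, m],
                                 qmatrix.q[m], profiles)
        scores += prof_sums * np.log(mu[m]) + (K - prof_sums) * np.log(1.0 - mu[m])
        idx = _categorical_rows(scores, rng)
        alpha[rows] = profiles[idx]
    return alpha


def _profile_scores(u, s_m, g_m, qmatrix_2d, profiles) -> np.ndarray:
    """(n, P) response log-likelihood of every profile for every row of u."""
    eta_pat = eta_table(profiles, qmatrix_2d).astype(np.float64)  # (P, J)
    ls1, ls0 = np.log(1.0 - s_m), np.log(s_m)
    lg1, lg0 = np.log(g_m), np.log(1.0 - g_m)
    A = np.where(u == 1, ls1, ls0)
    B = np.where(u == 1, lg1, lg0)
    return B.sum(axis=1)[:, None] + (A - B) @ eta_pat.T


def _profiles_gibbs_sweep(u, c, params, mu, qmatrix, rng) -> np.ndarray:
    """One attribute-at-a-time Gibbs sweep over alpha (large-K fallback)."""
    N, K = u.shape[0], qmatrix.K
    alpha = (rng.random((N, K)) < 0.5).astype(np.int8)
    for m in range(qmatrix.M):
        rows = np.flatnonzero(c == m)
        if rows.size == 0:
            continue
        um, am = u[rows], alpha[rows].copy()
        for k in range(K):
            ll = np.empty((rows.size, 2))
            for val in (0, 1):
                am[:, k] = val
                ll[:, val] = _strategy_loglik(um, am, params.s[:, m],
                                              params.g[:, m], qmatrix.q[m])
            ll[:, 0] += np.log(1.0 - mu[m])
            ll[:, 1] += np.log(mu[m])
            am[:, k] = _categorical_rows(ll, rng)
        alpha[rows] = am
    return alpha


class _TruncBetaGrid:
    """Inverse-CDF sampler on a fixed midpoint grid over a 4-Beta support.

    Target density on (a, b): ``x^n1 (1-x)^n0 * 4-Beta(v, t, a, b)``.
    Midpoints keep every draw strictly inside the open support.
    """

    def __init__(self, shape: tuple, support: tuple, n_points: int):
        v, t = shape
        lo, hi = support
        self.x = lo + (hi - lo) * (np.arange(n_points) + 0.5) / n_points
        self.log_x = np.log(self.x)
        self.log_1mx = np.log1p(-self.x)
        self.log_prior = ((v - 1.0) * np.log(self.x - lo)
                          + (t - 1.0) * np.log(hi - self.x))

    def sample(self, n1, n0, rng: np.random.Generator) -> np.ndarray:
        """Vectorized draw, one per row of the count vectors (n1 = exponent
        of x, n0 = exponent of 1-x)."""
        n1 = np.atleast_1d(np.asarray(n1, dtype=np.float64))
        n0 = np.atleast_1d(np.asarray(n0, dtype=np.float64))
        logpdf = (n1[:, None] * self.log_x[None, :]
                  + n0[:, None] * self.log_1mx[None, :]
                  + self.log_prior[None, :])
        logpdf -= logpdf.max(axis=1, keepdims=True)
        cdf = np.cumsum(np.exp(logpdf), axis=1)
        r = rng.random(n1.shape[0]) * cdf[:, -1]
        idx = np.minimum((cdf < r[:, None]).sum(axis=1), self.x.size - 1)
        return self.x[idx]

    def log_density(self, x, n1: float, n0: float, shape, support) -> np.ndarray:
        v, t = shape
        lo, hi = support
        x = np.asarray(x, dtype=float)
        return (n1 * np.log(x) + n0 * np.log1p(-x)
                + (v - 1.0) * np.log(x - lo) + (t - 1.0) * np.log(hi - x))


def _trunc_beta_mh(current, n1, n0, shape, support, step, rng):
    """Logit-scale random-walk Metropolis update of a bounded parameter.

    Works on z = logit((x - a)/(b - a)); the Jacobian term keeps the move
    valid for the density on the original scale.  Returns (new values,
    number accepted).
    """
    v, t = shape
    lo, hi = support
    x = np.atleast_1d(np.asarray(current, dtype=float))
    n1 = np.atleast_1d(np.asarray(n1, dtype=float))
    n0 = np.atleast_1d(np.asarray(n0, dtype=float))
    frac = (x - lo) / (hi - lo)
    z = np.log(frac) - np.log1p(-frac)
    z_new = z + step * rng.standard_normal(x.shape)
    frac_new = 1.0 / (1.0 + np.exp(-z_new))
    x_new = lo + (hi - lo) * frac_new

    def log_target(xx):
        return (n1 * np.log(xx) + n0 * np.log1p(-xx)
                + (v - 1.0) * np.log(xx - lo) + (t - 1.0) * np.log(hi - xx))

    # Jacobian of the logit map: dx/dz = (b-a) frac (1-frac)
    log_ratio = (log_target(x_new) - log_target(x)
                 + np.log(frac_new) + np.log1p(-frac_new)
                 - np.log(frac) - np.log1p(-frac))
    accept = np.log(rng.random(x.shape)) < log_ratio
    out = np.where(accept, x_new, x)
    return out, int(accept.sum())


def sample_item_params(
    responses: ResponseMatrix,
    c,
    alpha,
    qmatrix: MultiStrategyQMatrix,
    prior: PriorSpec,
    rng: np.random.Generator,
    *,
    method: str = "grid",
    grid_points: int = 1024,
    current: ItemParameters | None = None,
    mh_step: float = 0.4,
    shared: bool = False,
):
    """Step 5: update every (s_jm, g_jm) from its truncated full conditional.

    For each item and strategy the likelihood contributes Bernoulli counts
    among that strategy's members: ``s_jm`` sees the eta=1 examinees
    (incorrect answers are the ``s`` exponent), ``g_jm`` the eta=0 examinees
    (correct answers are the ``g`` exponent).  With no relevant examinees
    the update is a prior draw.  ``shared=True`` pools all examinees with
    ``eta = max_m eta_ijm`` (the MS-DINA single-parameter update).
    """
    u = responses.u.astype(np.float64)
    alpha = np.asarray(alpha, dtype=np.int64)
    J, M = qmatrix.J, (1 if shared else qmatrix.M)
    s = np.empty((J, M))
    g = np.empty((J, M))
    s_grid = _TruncBetaGrid(prior.s_shape, prior.s_support, grid_points)
    g_grid = _TruncBetaGrid(prior.g_shape, prior.g_support, grid_points)
    accepted = total = 0
    for m in range(M):
        if shared:
            eta = np.max(
                [eta_table(alpha, qmatrix.q[mm]) for mm in range(qmatrix.M)], axis=0
            ).astype(np.float64)
            um = u
        else:
            rows = np.flatnonzero(np.asarray(c, dtype=np.int64) == m)
            eta = eta_table(alpha[rows], qmatrix.q[m]).astype(np.float64)
            um = u[rows]
        n11 = (eta * um).sum(axis=0)           # eta=1, correct  -> (1-s) exponent
        n10 = (eta * (1.0 - um)).sum(axis=0)   # eta=1, incorrect -> s exponent
        n01 = ((1.0 - eta) * um).sum(axis=0)   # eta=0, correct  -> g exponent
        n00 = ((1.0 - eta) * (1.0 - um)).sum(axis=0)
        if method == "grid":
            s[:, m] = s_grid.sample(n10, n11, rng)
            g[:, m] = g_grid.sample(n01, n00, rng)
        else:
            cur = current if current is not None else None
            s_cur = cur.s[:, m] if cur is not None else np.full(
                J, four_beta_mean(prior.s_shape, prior.s_support))
            g_cur = cur.g[:, m] if cur is not None else np.full(
                J, four_beta_mean(prior.g_shape, prior.g_support))
            s[:, m], acc_s = _trunc_beta_mh(s_cur, n10, n11, prior.s_shape,
                                            prior.s_support, mh_step, rng)
            g[:, m], acc_g = _trunc_beta_mh(g_cur, n01, n00, prior.g_shape,
                                            prior.g_support, mh_step, rng)
            accepted += acc_s + acc_g
            total += 2 * J
    params = ItemParameters(s, g, prior.s_support, prior.g_support)
    return (params, accepted, total)


# ---------------------------------------------------------------------------
# the full chain
# ---------------------------------------------------------------------------


def _normalize_model(model: str) -> str:
    name = model.lower().replace("-", "").replace("_", "")
    if name in ("dina",):
        return "dina"
    if name in ("msdina",):
        return "msdina"
    if name in ("mmsdina",):
        return "mmsdina"
    raise ModelValidationError(f"unknown model {model!r}; use DINA, MS-DINA or MMS-DINA")


def _cell_logp_mixture(u, alpha_idx, eta_pats, s, g, pi) -> np.ndarray:
    """(N, J) log sum_m pi_m P(u_ij | alpha_i, s_jm, g_jm)."""
    M = len(eta_pats)
    with np.errstate(divide="ignore"):
        log_pi = np.log(pi)
    stack = np.empty((M,) + u.shape)
    for m in range(M):
        eta = eta_pats[m][alpha_idx].astype(np.float64)
        A = np.where(u == 1, np.log(1.0 - s[:, m]), np.log(s[:, m]))
        B = np.where(u == 1, np.log(g[:, m]), np.log(1.0 - g[:, m]))
        stack[m] = B + eta * (A - B) + log_pi[m]
    hi = stack.max(axis=0)
    return hi + np.log(np.exp(stack - hi).sum(axis=0))




class _GibbsEngine:
    """Mutable sampling state plus one-sweep and bookkeeping primitives.

    ``run_chain`` drives this; it also powers the burn-in basin selection
    (compare strategy labellings after short re-equilibration runs).
    """

    def __init__(self, responses, qmatrix, prior, config, model, rng, init):
        self.prior = prior
        self.config = config
        self.model = model
        self.rng = rng
        self.mixture = model != "msdina"
        self.N, self.J, self.K = responses.N, qmatrix.J, qmatrix.K
        self.M = qmatrix.M
        self.M_items = self.M if self.mixture else 1
        self.u = responses.u.astype(np.float64)
        self.profiles = all_profiles(self.K)
        self.prof_sums = self.profiles.sum(axis=1).astype(np.float64)
        self.eta_pats = [eta_table(self.profiles, qmatrix.q[m])
                         for m in range(self.M)]
        self.eta_pats_f = [p.astype(np.float64) for p in self.eta_pats]
        if not self.mixture:
            self.eta_max_pat = np.max(self.eta_pats, axis=0)
            self.eta_max_f = self.eta_max_pat.astype(np.float64)
        self.beta_vec = np.broadcast_to(
            np.asarray(prior.beta, dtype=float), (self.M,)).copy()
        self.s_grid = _TruncBetaGrid(prior.s_shape, prior.s_support,
                                     config.grid_points)
        self.g_grid = _TruncBetaGrid(prior.g_shape, prior.g_support,
                                     config.grid_points)
        self.mh_accept = self.mh_total = 0
        self.swap_accept = self.swap_total = 0

        J, M_items, N, K, M = self.J, self.M_items, self.N, self.K, self.M
        if init == "prior":
            sp, gp = prior.s_support, prior.g_support
            self.s = sp[0] + (sp[1] - sp[0]) * rng.beta(*prior.s_shape,
                                                        size=(J, M_items))
            self.g = gp[0] + (gp[1] - gp[0]) * rng.beta(*prior.g_shape,
                                                        size=(J, M_items))
            mu = rng.beta(prior.lambda1, prior.lambda2,
                          size=(M if self.mixture else 1))
            self.mu = np.clip(mu, 1e-6, 1.0 - 1e-6)
        else:
            self.s = np.full((J, M_items), 0.5 * sum(prior.s_support))
            self.g = np.full((J, M_items), 0.5 * sum(prior.g_support))
            self.mu = np.full(M if self.mixture else 1, 0.5)
        self.alpha = (rng.random((N, K)) < 0.5).astype(np.int8)
        self.alpha_idx = profile_index(self.alpha)
        self.c = (rng.integers(0, M, size=N) if self.mixture
                  else np.zeros(N, dtype=np.int64))
        self.pi = np.full(M, 1.0 / M)

    # -- state management ---------------------------------------------------

    def state(self):
        return (self.s.copy(), self.g.copy(), self.mu.copy(), self.pi.copy(),
                self.c.copy(), self.alpha.copy(), self.alpha_idx.copy())

    def restore(self, snap):
        (self.s, self.g, self.mu, self.pi,
         self.c, self.alpha, self.alpha_idx) = [x.copy() for x in snap]

    def swap_labels(self, a: int, b: int) -> None:
        """Exchange two strategy slots of every strategy-indexed quantity."""
        sigma = np.arange(self.M)
        sigma[a], sigma[b] = b, a
        self.pi = self.pi[sigma]
        self.mu = self.mu[sigma]
        self.s = self.s[:, sigma]
        self.g = self.g[:, sigma]
        self.c = sigma[self.c]

    # -- pieces -------------------------------------------------------------

    def _ab_tables(self):
        A_list, B_list, coef_list = [], [], []
        for m in range(self.M_items):
            A = np.where(self.u == 1.0, np.log(1.0 - self.s[:, m]),
                         np.log(self.s[:, m]))
            B = np.where(self.u == 1.0, np.log(self.g[:, m]),
                         np.log(1.0 - self.g[:, m]))
            A_list.append(A)
            B_list.append(B)
            coef_list.append(A - B)
        return A_list, B_list, coef_list

    def _prior_p(self):
        return [self.prof_sums * np.log(self.mu[m])
                + (self.K - self.prof_sums) * np.log(1.0 - self.mu[m])
                for m in range(self.M if self.mixture else 1)]

    @staticmethod
    def _marginal(S_m, prior_m, B_m):
        """(N,) log P(u_i | strategy m) with the profile summed out."""
        return _logsumexp_rows(S_m + prior_m[None, :]) + B_m.sum(axis=1)

    def collapsed_loglik(self) -> float:
        """Joint log-likelihood with both latents (c, alpha) summed out."""
        _, B_list, coef_list = self._ab_tables()
        prior_p = self._prior_p()
        if not self.mixture:
            S = coef_list[0] @ self.eta_max_f.T
            return float(self._marginal(S, prior_p[0], B_list[0]).sum())
        with np.errstate(divide="ignore"):
            log_pi = np.log(self.pi)
        marg = np.stack([
            self._marginal(coef_list[m] @ self.eta_pats_f[m].T,
                           prior_p[m], B_list[m])
            for m in range(self.M)
        ], axis=1)
        return float(_logsumexp_rows(marg + log_pi[None, :]).sum())

    def cell_logp(self) -> np.ndarray:
        """(N, J) per-observation log-probabilities at the current state.

        ``criteria_likelihood="conditional"`` (default) evaluates each cell
        at the sampled latent state — the member strategy's response
        probability, treating both latents (alpha, c) symmetrically, as in
        the conditional DIC for mixtures.  ``"mixture"`` mixes the
        per-strategy probabilities with pi instead (conditioning on alpha
        only).  Identical for single-strategy fits.
        """
        cond = self.config.criteria_likelihood == "conditional"
        if self.mixture and self.M > 1 and not cond:
            return _cell_logp_mixture(self.u, self.alpha_idx, self.eta_pats,
                                      self.s, self.g, self.pi)
        if self.mixture and self.M > 1:
            out = np.empty_like(self.u)
            for m in range(self.M):
                rows = np.flatnonzero(self.c == m)
                if rows.size == 0:
                    continue
                A = np.where(self.u[rows] == 1.0, np.log(1.0 - self.s[:, m]),
                             np.log(self.s[:, m]))
                B = np.where(self.u[rows] == 1.0, np.log(self.g[:, m]),
                             np.log(1.0 - self.g[:, m]))
                eta = self.eta_pats_f[m][self.alpha_idx[rows]]
                out[rows] = B + eta * (A - B)
            return out
        m_eta = (self.eta_max_f if not self.mixture
                 else self.eta_pats_f[0])
        A = np.where(self.u == 1.0, np.log(1.0 - self.s[:, 0]),
                     np.log(self.s[:, 0]))
        B = np.where(self.u == 1.0, np.log(self.g[:, 0]),
                     np.log(1.0 - self.g[:, 0]))
        eta = m_eta[self.alpha_idx]
        return B + eta * (A - B)

    # -- one full sweep -----------------------------------------------------

    def sweep(self) -> None:
        cfg, prior, rng = self.config, self.prior, self.rng
        N, J, K, M = self.N, self.J, self.K, self.M
        mixture = self.mixture
        blocked = cfg.blocked_membership

        # Step 1: mixing proportions (conjugate Dirichlet)
        if mixture:
            n_occ = np.bincount(self.c, minlength=M)
            self.pi = rng.dirichlet(self.beta_vec + n_occ)

        A_list, B_list, coef_list = self._ab_tables()
        prior_p = self._prior_p()
        S_list = None

        # Step 2: strategy memberships.  The blocked variant sums the
        # profile out of the membership weights and redraws it right after,
        # i.e. one exact joint draw of (c_i, alpha_i); the plain variant
        # conditions on the current alpha_i as the update is usually
        # written (ChainConfig.blocked_membership=False).
        if mixture and M > 1:
            with np.errstate(divide="ignore"):
                log_pi = np.log(self.pi)
            if blocked:
                S_list = [coef_list[m] @ self.eta_pats_f[m].T for m in range(M)]
                marg = np.stack([
                    self._marginal(S_list[m], prior_p[m], B_list[m])
                    for m in range(M)
                ], axis=1)
                # permutation Metropolis move: propose exchanging two
                # strategy slots of (pi, mu, s, g); with the latents
                # implicitly redrawn below, the acceptance ratio is the
                # collapsed-posterior ratio.  Lets chains cross relabelled
                # modes that per-examinee updates cannot.
                if cfg.label_swap_moves:
                    a, b = (0, 1) if M == 2 else tuple(
                        rng.choice(M, size=2, replace=False))
                    sigma = np.arange(M)
                    sigma[a], sigma[b] = b, a
                    S_prop_a = coef_list[b] @ self.eta_pats_f[a].T
                    S_prop_b = coef_list[a] @ self.eta_pats_f[b].T
                    marg_prop = marg.copy()
                    marg_prop[:, a] = self._marginal(S_prop_a, prior_p[b],
                                                     B_list[b])
                    marg_prop[:, b] = self._marginal(S_prop_b, prior_p[a],
                                                     B_list[a])
                    cur = _logsumexp_rows(marg + log_pi[None, :]).sum()
                    prop = _logsumexp_rows(marg_prop + log_pi[None, sigma]).sum()
                    log_ratio = prop - cur
                    if self.beta_vec[a] != self.beta_vec[b]:
                        # asymmetric Dirichlet prior is not swap-invariant
                        log_ratio += (self.beta_vec[a] - self.beta_vec[b]) * (
                            np.log(max(self.pi[b], 1e-300))
                            - np.log(max(self.pi[a], 1e-300))
                        )
                    self.swap_total += 1
                    if np.log(rng.random()) < log_ratio:
                        self.swap_accept += 1
                        self.pi = self.pi[sigma]
                        self.mu = self.mu[sigma]
                        self.s = self.s[:, sigma]
                        self.g = self.g[:, sigma]
                        for lst in (A_list, B_list, coef_list):
                            lst[a], lst[b] = lst[b], lst[a]
                        prior_p[a], prior_p[b] = prior_p[b], prior_p[a]
                        S_list[a], S_list[b] = S_prop_a, S_prop_b
                        marg = marg_prop
                        log_pi = log_pi[sigma]
                logw = marg + log_pi[None, :]
            else:
                rowsum = self.alpha.sum(axis=1)
                logw = np.empty((N, M))
                for m in range(M):
                    eta_cur = self.eta_pats_f[m][self.alpha_idx]
                    ll = (B_list[m].sum(axis=1)
                          + (eta_cur * coef_list[m]).sum(axis=1))
                    logw[:, m] = (log_pi[m] + ll
                                  + rowsum * np.log(self.mu[m])
                                  + (K - rowsum) * np.log(1.0 - self.mu[m]))
            self.c = _categorical_rows(logw, rng)

        # Step 3 in the printed order updates mu before the profiles; the
        # blocked kernel updates it afterwards so the (c, alpha) block
        # conditions on a single mu value.
        if not blocked:
            self._update_mu()
            prior_p = self._prior_p()

        # Step 4: attribute profiles (exact 2^K enumeration)
        if mixture:
            for m in range(M):
                rows = np.flatnonzero(self.c == m)
                if rows.size == 0:
                    continue
                if S_list is not None:
                    scores = S_list[m][rows] + prior_p[m][None, :]
                else:
                    scores = coef_list[m][rows] @ self.eta_pats_f[m].T
                    scores = scores + prior_p[m]
                idx = _categorical_rows(scores, rng)
                self.alpha_idx[rows] = idx
                self.alpha[rows] = self.profiles[idx]
        else:
            scores = coef_list[0] @ self.eta_max_f.T + prior_p[0]
            idx = _categorical_rows(scores, rng)
            self.alpha_idx = idx
            self.alpha = self.profiles[idx].copy()

        if blocked:
            self._update_mu()

        # Step 5: item parameters (truncated 4-Beta full conditionals)
        for m in range(self.M_items):
            if mixture:
                rows = np.flatnonzero(self.c == m)
                eta = self.eta_pats_f[m][self.alpha_idx[rows]]
                um = self.u[rows]
            else:
                eta = self.eta_max_f[self.alpha_idx]
                um = self.u
            n11 = (eta * um).sum(axis=0)
            n10 = eta.sum(axis=0) - n11
            n01 = um.sum(axis=0) - n11
            n00 = (1.0 - eta).sum(axis=0) - n01
            if cfg.item_param_method == "grid":
                self.s[:, m] = self.s_grid.sample(n10, n11, rng)
                self.g[:, m] = self.g_grid.sample(n01, n00, rng)
            else:
                self.s[:, m], acc = _trunc_beta_mh(
                    self.s[:, m], n10, n11, prior.s_shape, prior.s_support,
                    cfg.mh_step, rng)
                self.mh_accept += acc
                self.g[:, m], acc = _trunc_beta_mh(
                    self.g[:, m], n01, n00, prior.g_shape, prior.g_support,
                    cfg.mh_step, rng)
                self.mh_accept += acc
                self.mh_total += 2 * J

    def _update_mu(self):
        prior, rng = self.prior, self.rng
        if self.mixture:
            rowsum = self.alpha.sum(axis=1)
            for m in range(self.M):
                members = self.c == m
                ssum = float(rowsum[members].sum())
                n_base = (self.N if prior.literal_mu_update
                          else int(members.sum()))
                self.mu[m] = rng.beta(ssum + prior.lambda1,
                                      n_base * self.K - ssum + prior.lambda2)
        else:
            ssum = float(self.alpha.sum())
            self.mu[0] = rng.beta(ssum + prior.lambda1,
                                  self.N * self.K - ssum + prior.lambda2)
        self.mu = np.clip(self.mu, 1e-12, 1.0 - 1e-12)

    # -- burn-in basin selection ---------------------------------------------

    def basin_select(self, lookahead: int) -> None:
        """Compare strategy labellings after short re-equilibration runs and
        keep the best.

        A relabelled posterior mode cannot be reached by pointwise moves;
        this restarts the chain from each label permutation of the current
        state, lets each branch re-equilibrate for ``lookahead`` sweeps, and
        keeps the branch with the highest average collapsed log-likelihood.
        Used during burn-in only, so the retained kernel stays exact.
        """
        import itertools as _it

        base = self.state()
        tail = max(4, lookahead // 4)

        def _branch():
            lls = []
            for i in range(lookahead):
                self.sweep()
                if i >= lookahead - tail:
                    lls.append(self.collapsed_loglik())
            return float(np.mean(lls)), self.state()

        best_ll, best_state = _branch()
        for a, b in _it.combinations(range(self.M), 2):
            self.restore(base)
            self.swap_labels(a, b)
            ll, st = _branch()
            if ll > best_ll + 1e-9:
                logger.info("burn-in basin selection: adopting labelling "
                            "with strategies %d and %d exchanged "
                            "(%.2f > %.2f)", a + 1, b + 1, ll, best_ll)
                best_ll, best_state = ll, st
        self.restore(best_state)


def run_chain(
    responses: ResponseMatrix,
    qmatrix: MultiStrategyQMatrix,
    prior: PriorSpec | None = None,
    config: ChainConfig | None = None,
    model: str = "mmsdina",
    *,
    rng: np.random.Generator | None = None,
    init: str = "default",
) -> PosteriorDraws:
    """Run one MH-within-Gibbs chain and return the retained draws.

    ``model`` selects the variant: ``"mmsdina"`` (full mixture), ``"dina"``
    (single strategy; a multi-strategy Q-matrix is reduced to its first
    block), or ``"msdina"`` (shared item parameters, eta = max over
    strategies).  ``init="prior"`` draws the starting point from the prior
    (used to disperse multi-chain starts); the default start is attribute
    profiles Bernoulli(0.5), uniform memberships, attribute means 0.5 and
    item parameters at their support midpoints.
    """
    prior = prior or PriorSpec()
    config = config or ChainConfig()
    model = _normalize_model(model)
    if responses.J != qmatrix.J:
        raise DimensionError(
            f"responses have J={responses.J} but Q-matrix has J={qmatrix.J}"
        )
    if model == "dina" and qmatrix.M > 1:
        logger.info("DINA fit: using strategy 1's Q-matrix block")
        qmatrix = qmatrix.single(0)
    if qmatrix.K > config.max_enum_K and not config.profile_fallback:
        raise ModelValidationError(
            f"K={qmatrix.K} exceeds max_enum_K={config.max_enum_K}; enable "
            "profile_fallback to use attribute-at-a-time updates"
        )
    if rng is None:
        rng = np.random.default_rng(config.rng_seed)

    eng = _GibbsEngine(responses, qmatrix, prior, config, model, rng, init)
    mixture = eng.mixture
    N, J, K = eng.N, eng.J, eng.K
    M, M_items = eng.M, eng.M_items

    R = config.n_retained
    draws = PosteriorDraws(
        model=model,
        s=np.empty((R, J, M_items)),
        g=np.empty((R, J, M_items)),
        mu=np.empty((R, M if mixture else 1)),
        alpha=np.empty((R, N, K), dtype=np.int8),
        loglik=np.empty(R),
        pi=np.empty((R, M)) if mixture else None,
        c=np.empty((R, N), dtype=np.int8) if mixture else None,
        cell_logp=(np.empty((R, N, J), dtype=np.float32)
                   if config.store_cell_logp else None),
        prior=prior,
        config=config,
        data_fingerprint=_fingerprint(responses.u),
    )

    look = config.basin_lookahead
    checkpoints: set[int] = set()
    if (mixture and M > 1 and config.basin_selection
            and config.burn_in >= 6 * look):
        checkpoints = {config.burn_in // 3, (2 * config.burn_in) // 3}

    r_out = 0
    for it in range(config.iterations):
        if it in checkpoints:
            eng.basin_select(look)
        eng.sweep()
        if it >= config.burn_in and (it - config.burn_in) % config.thinning == 0:
            cell = eng.cell_logp()
            draws.s[r_out] = eng.s
            draws.g[r_out] = eng.g
            draws.mu[r_out] = eng.mu
            draws.alpha[r_out] = eng.alpha
            draws.loglik[r_out] = cell.sum()
            if mixture:
                draws.pi[r_out] = eng.pi
                draws.c[r_out] = eng.c
            if config.store_cell_logp:
                draws.cell_logp[r_out] = cell.astype(np.float32)
            r_out += 1
        if config.log_every and (it + 1) % config.log_every == 0:
            occ = np.bincount(eng.c, minlength=M) if mixture else [N]
            logger.info("iteration %d/%d: occupancy %s", it + 1,
                        config.iterations, list(occ))

    if config.item_param_method == "mh" and eng.mh_total:
        draws.mh_acceptance = eng.mh_accept / eng.mh_total
        logger.info("random-walk acceptance rate: %.3f", draws.mh_acceptance)
    if eng.swap_total:
        draws.swap_acceptance = eng.swap_accept / eng.swap_total
    return draws


def run_chains(
    responses: ResponseMatrix,
    qmatrix: MultiStrategyQMatrix,
    prior: PriorSpec | None = None,
    config: ChainConfig | None = None,
    model: str = "mmsdina",
) -> list[PosteriorDraws]:
    """Run ``config.n_chains`` independent chains with dispersed (prior-drawn)
    starting points; chain seeds derive deterministically from the config
    seed.  Returns one :class:`PosteriorDraws` per chain."""
    config = config or ChainConfig()
    seeds = np.random.SeedSequence(config.rng_seed).spawn(config.n_chains)
    out = []
    for i, ss in enumerate(seeds):
        rng = np.random.default_rng(ss)
        init = "prior" if config.n_chains > 1 else "default"
        logger.info("starting chain %d/%d", i + 1, config.n_chains)
        out.append(
            run_chain(responses, qmatrix, prior, config, model, rng=rng, init=init)
        )
    return out
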