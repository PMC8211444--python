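"""Response-data generation and replicated simulation studies.

The generator emulates the standard recovery-study conditions for these
models: attributes iid Bernoulli(0.5), true slipping 0.3 and guessing 0.1
for every item and strategy, strategy memberships multinomial with equal
mixing proportions, and responses Bernoulli with the model's item response
probability.  Two built-in two-strategy Q-matrix designs ship with the
package: a 30-item / 5-attribute design (``table2_J30_K5_M2``) and a
40-item / 7-attribute design (``table4_J40_K7_M2``).

Every dataset regenerates bit-exactly from (design, seed, replication
index): the replication RNG is seeded with ``SeedSequence([design_seed,
replication])``, which is stable across runs and platforms.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .evaluation import classification_metrics, posterior_summaries, recovery_metrics
from .model_core import (
    AttributeProfiles,
    ItemParameters,
    ModelValidationError,
    MultiStrategyQMatrix,
    ResponseMatrix,
    eta_table,
    validate_simplex,
)
from .sampler import ChainConfig, PriorSpec, run_chain

logger = logging.getLogger("mmsdina")

__all__ = [
    "SimulationDesign",
    "SimulatedDataset",
    "builtin_qmatrix",
    "simulate_dataset",
    "run_recovery_study",
    "run_study",
    "run_model_comparison_study",
    "BUILTIN_QMATRICES",
]

# --- built-in Q-matrix designs (strategy-A block, then strategy-B block) ---

_Q_J30_K5_M2 = """
1 1 0 0 0  0 1 0 1 1
1 0 1 0 0  0 0 1 1 1
1 0 0 1 0  0 1 1 0 1
1 0 0 0 1  0 1 1 1 0
0 1 1 0 0  1 0 0 1 1
0 1 0 1 0  1 1 0 0 1
0 1 0 0 1  1 1 0 1 0
0 0 1 1 0  1 0 1 0 1
0 0 1 0 1  1 0 1 1 0
0 0 0 1 1  1 1 1 0 0
1 1 1 0 0  0 0 0 1 1
1 1 0 1 0  0 1 0 0 1
1 1 0 0 1  0 1 0 1 0
1 0 1 1 0  0 0 1 0 1
1 0 1 0 1  0 0 1 1 0
1 0 0 1 1  0 1 1 0 0
0 1 1 1 0  1 0 0 0 1
0 1 1 0 1  1 0 0 1 0
0 1 0 1 1  1 1 0 0 0
0 0 1 1 1  1 0 1 0 0
1 1 0 0 0  1 0 0 0 0
1 0 1 0 0  0 1 0 0 0
1 0 0 1 0  0 0 1 0 0
1 0 0 0 1  0 0 0 1 0
0 1 1 0 0  0 0 0 0 1
1 0 0 0 0  0 1 1 0 0
0 1 0 0 0  1 0 0 0 1
0 0 1 0 0  1 0 0 1 0
0 0 0 1 0  1 1 0 0 0
0 0 0 0 1  1 0 1 0 0
"""

_Q_J40_K7_M2 = """
1 1 1 0 0 0 0  1 1 0 0 0 0 0
0 1 0 0 0 0 1  0 1 0 0 0 0 0
0 0 1 0 0 0 0  1 0 0 1 0 0 0
1 0 0 1 0 0 0  1 0 0 0 1 0 0
0 0 1 0 1 0 0  0 0 0 1 0 0 0
0 0 0 0 0 1 0  1 0 0 0 0 0 1
1 0 0 0 0 0 1  0 0 0 1 1 1 0
0 1 0 1 0 0 0  1 0 0 0 0 0 0
1 0 1 0 0 0 0  1 0 1 0 0 0 0
0 0 0 1 0 0 0  0 0 1 0 0 0 0
1 0 0 0 1 0 0  1 0 0 0 0 1 0
0 0 1 0 0 1 0  0 0 0 0 1 0 0
0 0 0 0 0 0 1  0 0 0 0 0 1 0
0 1 1 0 0 0 0  0 0 0 0 0 0 1
1 1 0 0 0 0 0  1 1 1 0 0 0 0
0 1 0 0 1 0 0  1 1 0 1 0 0 0
0 1 0 0 0 0 0  1 1 0 0 1 0 0
0 0 1 1 0 0 0  1 1 0 0 0 1 0
0 0 0 0 1 0 0  0 0 1 0 0 1 1
1 0 0 0 0 1 0  0 1 1 1 0 0 0
0 0 1 0 0 0 1  0 0 1 0 1 0 1
0 0 0 1 1 0 0  1 1 0 0 0 0 1
0 0 0 1 0 1 0  0 1 1 0 0 0 1
0 0 0 1 0 1 0  0 0 1 1 1 0 0
0 0 0 1 0 0 1  0 0 0 1 0 1 1
0 0 0 0 1 1 0  0 1 1 0 0 0 0
0 0 0 0 1 0 1  0 0 1 0 0 1 0
0 0 0 0 0 1 1  0 1 0 0 1 0 0
1 0 0 0 0 0 0  0 1 0 0 0 0 1
1 1 0 1 0 0 0  0 0 1 1 0 0 0
1 1 0 0 1 0 0  0 0 1 0 1 0 0
1 1 0 0 0 1 0  0 1 0 1 0 0 0
1 1 0 0 0 0 1  0 0 0 1 0 1 0
0 1 1 1 0 0 0  0 0 0 1 1 0 0
0 0 1 0 1 0 1  0 0 0 1 0 1 0
0 0 1 0 0 1 1  0 0 1 0 0 0 1
0 1 1 0 0 0 1  0 0 0 1 0 0 1
0 0 1 1 1 0 0  0 0 0 0 1 1 0
0 0 0 1 0 1 1  0 0 0 0 1 0 1
0 0 0 1 1 1 0  0 0 0 0 0 1 1
"""


def _parse_block_matrix(text: str, K: int) -> MultiStrategyQMatrix:
    rows = [[int(tok) for tok in line.split()] for line in text.strip().splitlines()]
    arr = np.asarray(rows, dtype=np.int8)
    M = arr.shape[1] // K
    return MultiStrategyQMatrix.from_strategies(
        [arr[:, m * K:(m + 1) * K] for m in range(M)]
    )


BUILTIN_QMATRICES = {
    "table2_J30_K5_M2": (_Q_J30_K5_M2, 5),
    "table4_J40_K7_M2": (_Q_J40_K7_M2, 7),
}


def builtin_qmatrix(name: str) -> MultiStrategyQMatrix:
    """A named built-in multi-strategy Q-matrix design."""
    try:
        text, K = BUILTIN_QMATRICES[name]
    except KeyError:
        raise ModelValidationError(
            f"unknown built-in Q-matrix {name!r}; available: "
            f"{sorted(BUILTIN_QMATRICES)}"
        ) from None
    return _parse_block_matrix(text, K)


# ---------------------------------------------------------------------------
# design and dataset containers
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SimulationDesign:
    """One cell of a simulation study.

    ``qmatrix`` may be a :class:`MultiStrategyQMatrix` or the name of a
    built-in design.  Defaults are the standard recovery-study conditions:
    s = 0.3 and g = 0.1 for every item/strategy, attributes iid
    Bernoulli(0.5), equal mixing proportions, 50 replications.
    """

    model: str = "mmsdina"
    N: int = 1000
    qmatrix: object = "table2_J30_K5_M2"
    s_true: float = 0.3
    g_true: float = 0.1
    attr_prob: float = 0.5
    pi_true: tuple | None = None
    replications: int = 50
    rng_seed: int = 0

    def resolve_qmatrix(self) -> MultiStrategyQMatrix:
        if isinstance(self.qmatrix, MultiStrategyQMatrix):
            return self.qmatrix
        return builtin_qmatrix(str(self.qmatrix))

    def resolve_pi(self, M: int) -> np.ndarray:
        if self.pi_true is None:
            return np.full(M, 1.0 / M)
        return validate_simplex(np.asarray(self.pi_true, dtype=float))


@dataclass(frozen=True)
class SimulatedDataset:
    """One generated dataset with its ground truth and provenance."""

    responses: ResponseMatrix
    alpha_true: np.ndarray
    c_true: np.ndarray | None
    params_true: ItemParameters
    pi_true: np.ndarray | None
    design: SimulationDesign
    replication: int


def _replication_rng(design_seed: int, replication: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(design_seed),
                                                         int(replication)]))


def simulate_dataset(design: SimulationDesign, replication: int = 0) -> SimulatedDataset:
    """Generate one replication's dataset from the design's true model.

    MMS-DINA: draw memberships from the mixing proportions, then responses
    from the member strategy's DINA probability.  MS-DINA: responses from
    ``eta = max_m eta_ijm`` with the shared (s, g).  DINA: strategy 1's
    Q-matrix alone.
    """
    qmat = design.resolve_qmatrix()
    model = design.model.lower().replace("-", "").replace("_", "")
    if model not in ("dina", "msdina", "mmsdina"):
        raise ModelValidationError(f"unknown model {design.model!r}")
    rng = _replication_rng(design.rng_seed, replication)
    N, J, K, M = design.N, qmat.J, qmat.K, qmat.M
    alpha = (rng.random((N, K)) < design.attr_prob).astype(np.int8)
    s = np.full((J, M), float(design.s_true))
    g = np.full((J, M), float(design.g_true))
    params = ItemParameters(s, g) if (0.0 < design.s_true < 1.0
                                      and 0.0 < design.g_true < 1.0) else None
    c = None
    pi = None
    if model == "mmsdina":
        pi = design.resolve_pi(M)
        c = rng.choice(M, size=N, p=pi)
        eta = np.empty((N, J), dtype=np.int8)
        for m in range(M):
            rows = c == m
            if rows.any():
                eta[rows] = eta_table(alpha[rows], qmat.q[m])
    elif model == "msdina":
        eta = np.max([eta_table(alpha, qmat.q[m]) for m in range(M)], axis=0)
    else:  # dina
        eta = eta_table(alpha, qmat.q[0])
    p = np.where(eta == 1, 1.0 - design.s_true, design.g_true)
    u = (rng.random((N, J)) < p).astype(np.int8)
    if params is None:
        # degenerate truths (e.g. s = g = 0) fall outside the default prior
        # support; carry them without the open-interval validation
        params = object.__new__(ItemParameters)
        object.__setattr__(params, "s", s)
        object.__setattr__(params, "g", g)
        object.__setattr__(params, "s_support", (-np.inf, np.inf))
        object.__setattr__(params, "g_support", (-np.inf, np.inf))
    return SimulatedDataset(
        responses=ResponseMatrix(u),
        alpha_true=alpha,
        c_true=c,
        params_true=params,
        pi_true=pi,
        design=design,
        replication=replication,
    )


# ---------------------------------------------------------------------------
# study harnesses
# ---------------------------------------------------------------------------


def _fit_once(dataset: SimulatedDataset, fit_model, prior, chain_config):
    draws = run_chain(dataset.responses, dataset.design.resolve_qmatrix(),
                      prior, chain_config, fit_model)
    return draws


def run_recovery_study(
    design: SimulationDesign,
    chain_config: ChainConfig | None = None,
    prior: PriorSpec | None = None,
    fit_model: str | None = None,
    *,
    signed_abias: bool = False,
) -> dict:
    """Simulate -> fit -> score, replicated.

    Fits ``fit_model`` (default: the generating model) to each replication,
    computes Bias/MSE/SD of the item-parameter posterior means against the
    design truths, and attribute-classification criteria of the EAP
    profiles.  Returns a dict with per-block :class:`RecoveryReport`
    objects (keys ``("s", m)`` / ``("g", m)``, 0-based strategy), the
    aggregated classification report, an item-parameter summary table
    shaped like the usual recovery tables, and any replication failures
    (recorded, not raised).
    """
    chain_config = chain_config or ChainConfig()
    chain_config = replace(chain_config, store_cell_logp=False)
    prior = prior or PriorSpec()
    fit_model = fit_model or design.model
    s_means, s_sds, g_means, g_sds = [], [], [], []
    h_list, t_list, v_list, z_list = [], [], [], []
    failures = []
    for rep in range(design.replications):
        try:
            data = simulate_dataset(design, rep)
            cfg = replace(chain_config, rng_seed=None)
            rng = np.random.default_rng(
                np.random.SeedSequence([int(design.rng_seed), int(rep), 1])
            )
            draws = run_chain(data.responses, data.design.resolve_qmatrix(),
                              prior, cfg, fit_model, rng=rng)
            s_means.append(draws.s.mean(axis=0))
            s_sds.append(draws.s.std(axis=0, ddof=1))
            g_means.append(draws.g.mean(axis=0))
            g_sds.append(draws.g.std(axis=0, ddof=1))
            summ = posterior_summaries(draws)
            rep_cls = classification_metrics(summ["eap_profiles"], data.alpha_true)
            h_list.append(rep_cls.h)
            t_list.append(rep_cls.t)
            v_list.append(rep_cls.v)
            z_list.append(rep_cls.z)
        except Exception as exc:  # record and continue; partial studies are usable
            logger.error("replication %d failed: %s", rep, exc)
            failures.append((rep, repr(exc)))
    if not s_means:
        raise RuntimeError("every replication failed; nothing to aggregate")
    s_means = np.stack(s_means)
    g_means = np.stack(g_means)
    s_sds = np.stack(s_sds)
    g_sds = np.stack(g_sds)
    M_fit = s_means.shape[2]
    blocks = {}
    rows = []
    for m in range(M_fit):
        rec_s = recovery_metrics(s_means[:, :, m], design.s_true, s_sds[:, :, m])
        rec_g = recovery_metrics(g_means[:, :, m], design.g_true, g_sds[:, :, m])
        blocks[("s", m)] = rec_s
        blocks[("g", m)] = rec_g
        rows.append({
            "strategy": m + 1,
            "s_ABias": rec_s.abias(signed=signed_abias),
            "s_AMSE": rec_s.amse,
            "s_ASD": rec_s.asd,
            "g_ABias": rec_g.abias(signed=signed_abias),
            "g_AMSE": rec_g.amse,
            "g_ASD": rec_g.asd,
        })
    classification = {
        "h": np.mean(h_list, axis=0),
        "t": float(np.mean(t_list)),
        "v": float(np.mean(v_list)),
        "z": float(np.mean(z_list)),
    }
    return {
        "blocks": blocks,
        "table": pd.DataFrame(rows),
        "classification": classification,
        "failures": failures,
        "n_completed": len(s_means),
    }


def run_study(
    designs: list[SimulationDesign],
    chain_config: ChainConfig | None = None,
    prior: PriorSpec | None = None,
    fit_model: str | None = None,
) -> pd.DataFrame:
    """Recovery study over a grid of designs; one table row per design cell
    and strategy, shaped like the standard recovery tables."""
    frames = []
    for design in designs:
        result = run_recovery_study(design, chain_config, prior, fit_model)
        tab = result["table"].copy()
        qmat = design.resolve_qmatrix()
        tab.insert(0, "N", design.N)
        tab.insert(1, "J", qmat.J)
        tab.insert(2, "K", qmat.K)
        tab.insert(3, "model", design.model)
        frames.append(tab)
    return pd.concat(frames, ignore_index=True)


def run_model_comparison_study(
    design: SimulationDesign,
    true_models: tuple = ("dina", "msdina", "mmsdina"),
    fit_models: tuple = ("dina", "msdina", "mmsdina"),
    chain_config: ChainConfig | None = None,
    prior: PriorSpec | None = None,
) -> pd.DataFrame:
    """True-model x fitted-model grid of DIC and LPML, averaged over the
    design's replications (criteria computed per replication, then
    averaged).  Mirrors the usual model-assessment table layout."""
    from .assessment import compute_fit_criteria

    chain_config = chain_config or ChainConfig()
    chain_config = replace(chain_config, store_cell_logp=True)
    prior = prior or PriorSpec()
    records = []
    for true_model in true_models:
        gen = replace(design, model=true_model)
        for rep in range(design.replications):
            data = simulate_dataset(gen, rep)
            for fit_idx, fit_model in enumerate(fit_models):
                rng = np.random.default_rng(np.random.SeedSequence(
                    [int(design.rng_seed), int(rep), 2, fit_idx]
                ))
                draws = run_chain(data.responses, gen.resolve_qmatrix(), prior,
                                  chain_config, fit_model, rng=rng)
                crit = compute_fit_criteria(draws)
                records.append({
                    "true_model": true_model,
                    "fitted_model": fit_model,
                    "replication": rep,
                    "DIC": crit.dic,
                    "LPML": crit.lpml,
                })
    per_rep = pd.DataFrame(records)
    table = (per_rep.groupby(["true_model", "fitted_model"], sort=False)
             [["DIC", "LPML"]].mean().reset_index())
    table.attrs["per_replication"] = per_rep
    return table
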