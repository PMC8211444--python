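"""Bayesian model comparison from MCMC output: DIC and LPML.

Both criteria are functions of the joint log-likelihood evaluated at each
retained draw, which the sampler stores alongside the per-observation
mixture log-probabilities.

DIC uses the posterior-mean deviance ``Dev_bar = -(2/R) sum_r log L_r`` and
the best-draw plug-in ``Dev_hat = -2 max_r log L_r``; the effective number
of parameters is ``P_D = Dev_bar - Dev_hat >= 0`` and
``DIC = Dev_hat + 2 P_D = 2 Dev_bar - Dev_hat``.  Smaller is better.

LPML sums the logs of per-observation conditional predictive ordinates
(CPO), each estimated by the harmonic mean of the per-draw observation
probabilities.  The harmonic mean is computed as a max-shifted
log-mean-exp of negative log-probabilities, so probabilities as small as
1e-300 cannot overflow.  Larger is better.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import logsumexp

from .model_core import ModelValidationError
from .sampler import PosteriorDraws

logger = logging.getLogger("mmsdina")

__all__ = ["FitCriteria", "compute_dic", "compute_lpml", "compute_fit_criteria",
           "compare_models"]


class CriteriaStateError(RuntimeError):
    """Required quantities were not stored during sampling."""


@dataclass
class FitCriteria:
    """Model-fit summary for one fitted model on one dataset."""

    model: str
    dic: float = np.nan
    dev_bar: float = np.nan
    dev_hat: float = np.nan
    p_d: float = np.nan
    lpml: float = np.nan
    log_cpo: np.ndarray | None = None  # (N, J)
    data_fingerprint: str | None = None

    def as_dict(self) -> dict:
        return {
            "model": self.model,
            "DIC": self.dic,
            "Dev_bar": self.dev_bar,
            "Dev_hat": self.dev_hat,
            "P_D": self.p_d,
            "LPML": self.lpml,
        }


def compute_dic(draws: PosteriorDraws, criteria: FitCriteria | None = None) -> FitCriteria:
    """Deviance information criterion from the stored per-draw
    log-likelihoods.  Requires at least two retained draws."""
    if draws.loglik is None or draws.loglik.shape[0] < 2:
        raise CriteriaStateError("DIC needs >= 2 retained draws with log-likelihoods")
    out = criteria or FitCriteria(model=draws.model,
                                  data_fingerprint=draws.data_fingerprint)
    ll = np.asarray(draws.loglik, dtype=np.float64)
    out.dev_bar = float(-2.0 * ll.mean())
    out.dev_hat = float(-2.0 * ll.max())
    out.p_d = out.dev_bar - out.dev_hat
    out.dic = out.dev_hat + 2.0 * out.p_d
    return out


def compute_lpml(draws: PosteriorDraws, criteria: FitCriteria | None = None) -> FitCriteria:
    """LPML via stabilized harmonic-mean CPO estimates.

    ``log CPO_ij = -logmeanexp_r(-log p_r(u_ij))`` computed with the
    per-cell maximum of the negative log-probabilities shifted out of the
    exponentials.  A cell with zero probability in any draw yields
    ``-inf`` with a warning rather than an exception.
    """
    if draws.cell_logp is None:
        raise CriteriaStateError(
            "LPML needs per-observation log-probabilities; rerun the sampler "
            "with store_cell_logp=True"
        )
    out = criteria or FitCriteria(model=draws.model,
                                  data_fingerprint=draws.data_fingerprint)
    neg = -np.asarray(draws.cell_logp, dtype=np.float64)  # (R, N, J)
    R = neg.shape[0]
    if np.isinf(neg).any():
        logger.warning(
            "some stored observation probabilities are exactly zero; the "
            "corresponding CPO estimates are -inf"
        )
    log_cpo = -(logsumexp(neg, axis=0) - np.log(R))
    out.log_cpo = log_cpo
    out.lpml = float(log_cpo.sum())
    return out


def compute_lpml_streaming(
    draws: PosteriorDraws,
    responses,
    qmatrix,
    criteria: FitCriteria | None = None,
) -> FitCriteria:
    """LPML recomputed from the parameter draws in two passes.

    For runs too large to keep the per-observation terms in memory
    (``store_cell_logp=False``), the cell log-probabilities are rebuilt
    from the stored ``(alpha, s, g, pi)`` draws: a first pass finds each
    cell's maximum negative log-probability, a second accumulates the
    shifted exponentials.  Identical to :func:`compute_lpml` up to
    floating-point roundoff.
    """
    from .model_core import ItemParameters, cell_log_likelihood, eta_table

    out = criteria or FitCriteria(model=draws.model,
                                  data_fingerprint=draws.data_fingerprint)
    prior = draws.prior
    supports = ((prior.s_support, prior.g_support) if prior is not None
                else ((0.0, 1.0), (0.0, 1.0)))
    u = responses.u
    conditional = (draws.config is None
                   or draws.config.criteria_likelihood == "conditional")

    def _plain_cells(eta, s, g, rows=slice(None)):
        lp1 = np.where(eta == 1, np.log(1.0 - s), np.log(g))
        lp0 = np.where(eta == 1, np.log(s), np.log(1.0 - g))
        return np.where(u[rows] == 1, lp1, lp0)

    def _cells(r):
        if draws.model == "msdina":
            eta = np.max([eta_table(draws.alpha[r], qmatrix.q[m])
                          for m in range(qmatrix.M)], axis=0)
            return _plain_cells(eta, draws.s[r][:, 0], draws.g[r][:, 0])
        if conditional and qmatrix.M > 1:
            out = np.empty(u.shape)
            for m in range(qmatrix.M):
                rows = np.flatnonzero(draws.c[r] == m)
                if rows.size:
                    eta = eta_table(draws.alpha[r][rows], qmatrix.q[m])
                    out[rows] = _plain_cells(eta, draws.s[r][:, m],
                                             draws.g[r][:, m], rows)
            return out
        params = ItemParameters(draws.s[r], draws.g[r], *supports)
        return cell_log_likelihood(responses, draws.alpha[r], params,
                                   draws.pi[r] if draws.pi is not None
                                   else np.ones(1), qmatrix)

    R = draws.R
    g_max = np.full((responses.N, responses.J), -np.inf)
    for r in range(R):
        np.maximum(g_max, -_cells(r), out=g_max)
    acc = np.zeros_like(g_max)
    for r in range(R):
        acc += np.exp(-_cells(r) - g_max)
    log_cpo = -g_max - np.log(acc / R)
    out.log_cpo = log_cpo
    out.lpml = float(log_cpo.sum())
    return out


def compute_fit_criteria(draws: PosteriorDraws) -> FitCriteria:
    """DIC and LPML together."""
    crit = compute_dic(draws)
    return compute_lpml(draws, crit)


def compare_models(criteria: list[FitCriteria]) -> pd.DataFrame:
    """Rank >= 2 fitted models on the same responses.

    Returns a table with one row per model (DIC ascending = better, LPML
    descending = better), the rank under each criterion, and pairwise
    differences ``DIC_diff_vs_<other>`` / ``LPML_diff_vs_<other>``.
    Ties are reported as equal ranks.
    """
    if len(criteria) < 2:
        raise ModelValidationError("model comparison needs at least two fitted models")
    prints = {c.data_fingerprint for c in criteria if c.data_fingerprint is not None}
    if len(prints) > 1:
        raise ModelValidationError(
            "criteria were computed on different response matrices; DIC/LPML "
            "are only comparable on identical data"
        )
    rows = [c.as_dict() for c in criteria]
    table = pd.DataFrame(rows)
    table["rank_DIC"] = table["DIC"].rank(method="min").astype(int)
    table["rank_LPML"] = table["LPML"].rank(method="min", ascending=False).astype(int)
    for i, j in itertools.permutations(range(len(criteria)), 2):
        table.loc[i, f"DIC_diff_vs_{criteria[j].model}"] = (
            criteria[i].dic - criteria[j].dic
        )
        table.loc[i, f"LPML_diff_vs_{criteria[j].model}"] = (
            criteria[i].lpml - criteria[j].lpml
        )
    return table.sort_values("DIC").reset_index(drop=True)
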