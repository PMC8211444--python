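"""Core model mathematics for multiple-strategy DINA cognitive diagnosis.

The DINA ("deterministic inputs, noisy and-gate") model is a conjunctive
latent-class item response model: an examinee with attribute profile
``alpha`` answers item ``j`` correctly with probability ``1 - s_j`` when
the profile satisfies every attribute the item requires (ideal response
``eta = 1``) and with probability ``g_j`` otherwise.  ``s`` is the slipping
probability, ``g`` the guessing probability.

Its multiple-strategy extensions allow an item to be solvable through
several alternative attribute sets, coded as one Q-matrix per strategy:

* MS-DINA  -- a single (s_j, g_j) pair per item; the ideal response is
  ``eta_ij = max_m eta_ijm`` (satisfying any one strategy suffices).
* MMS-DINA -- a finite mixture: each examinee latently uses one strategy
  ``c_i`` drawn with mixing proportions ``pi``, and every strategy carries
  its own item parameters (s_jm, g_jm), so strategies may differ in
  difficulty.  Marginally,
  ``P(u_ij = 1 | alpha_i) = sum_m pi_m (1 - s_jm)^eta_ijm g_jm^(1-eta_ijm)``.

This module holds the domain containers (Q-matrices, responses, profiles,
item parameters, mixture state) and the deterministic model quantities:
ideal-response indicators, response probabilities for all three model
variants, and the stabilized joint log-likelihood.  All randomness lives in
:mod:`mmsdina.sampler`; all file I/O lives in :mod:`mmsdina.io_cli`.

Indexing convention: user-facing files and reports are 1-based (items,
attributes, strategies); everything in memory is 0-based.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.special import logsumexp

logger = logging.getLogger("mmsdina")

#: models this package can simulate from and fit
MODELS = ("dina", "msdina", "mmsdina")

#: default bounded support of the slipping/guessing parameters, i.e. the
#: support of their 4-parameter Beta prior.  (0.1, 0.5) for both guarantees
#: the monotonicity condition 1 - s > g.
DEFAULT_SUPPORT = (0.1, 0.5)


class DimensionError(ValueError):
    """Shapes of responses, Q-matrices or profiles do not agree."""


class ModelValidationError(ValueError):
    """A value violates a model-type invariant (non-binary entry, probability
    off its support, mixing proportions off the simplex, ...)."""


def _as_binary(arr, name: str) -> np.ndarray:
    out = np.asarray(arr)
    if out.size and not np.isin(out, (0, 1)).all():
        bad = np.argwhere(~np.isin(out, (0, 1)))[0]
        raise ModelValidationError(
            f"{name} must be binary; found {out[tuple(bad)]!r} at index {tuple(bad)}"
        )
    return out.astype(np.int8)


# ---------------------------------------------------------------------------
# domain containers
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class MultiStrategyQMatrix:
    """One binary J x K attribute-requirement matrix per strategy.

    Parameters
    ----------
    q
        Array of shape ``(M, J, K)`` with entries ``q_jkm`` in {0, 1}:
        item ``j`` requires attribute ``k`` under strategy ``m``.
    """

    q: np.ndarray

    def __post_init__(self):
        q = _as_binary(self.q, "Q-matrix")
        if q.ndim != 3:
            raise DimensionError(f"Q-matrix array must be (M, J, K); got shape {q.shape}")
        if q.shape[0] < 1:
            raise ModelValidationError("at least one strategy is required")
        object.__setattr__(self, "q", q)
        if self.M > 1:
            for m in range(self.M):
                for m2 in range(m + 1, self.M):
                    if np.array_equal(q[m], q[m2]):
                        warnings.warn(
                            f"strategies {m + 1} and {m2 + 1} have identical "
                            "Q-matrices; mixture components are then exchangeable "
                            "and strategy labels are not identified",
                            UserWarning,
                            stacklevel=2,
                        )

    @classmethod
    def from_strategies(cls, matrices) -> "MultiStrategyQMatrix":
        """Build from a sequence of J x K arrays, one per strategy."""
        mats = [np.asarray(m) for m in matrices]
        shapes = {m.shape for m in mats}
        if len(shapes) != 1:
            raise DimensionError(f"all strategies must share (J, K); got {sorted(shapes)}")
        return cls(np.stack(mats, axis=0))

    @property
    def M(self) -> int:
        return self.q.shape[0]

    @property
    def J(self) -> int:
        return self.q.shape[1]

    @property
    def K(self) -> int:
        return self.q.shape[2]

    def strategy(self, m: int) -> np.ndarray:
        """The J x K Q-matrix of strategy ``m`` (0-based)."""
        return self.q[m]

    def single(self, m: int = 0) -> "MultiStrategyQMatrix":
        """A single-strategy view (used when fitting the plain DINA model)."""
        return MultiStrategyQMatrix(self.q[m : m + 1])


@dataclass(frozen=True)
class ResponseMatrix:
    """N x J binary observed responses ``u_ij`` (1 = correct)."""

    u: np.ndarray

    def __post_init__(self):
        u = _as_binary(self.u, "response matrix")
        if u.ndim != 2:
            raise DimensionError(f"responses must be (N, J); got shape {u.shape}")
        object.__setattr__(self, "u", u)

    @property
    def N(self) -> int:
        return self.u.shape[0]

    @property
    def J(self) -> int:
        return self.u.shape[1]


@dataclass(frozen=True)
class AttributeProfiles:
    """N x K binary mastery indicators ``alpha_ik``."""

    alpha: np.ndarray

    def __post_init__(self):
        a = _as_binary(self.alpha, "attribute profiles")
        if a.ndim != 2:
            raise DimensionError(f"profiles must be (N, K); got shape {a.shape}")
        object.__setattr__(self, "alpha", a)

    @property
    def N(self) -> int:
        return self.alpha.shape[0]

    @property
    def K(self) -> int:
        return self.alpha.shape[1]


@dataclass(frozen=True)
class ItemParameters:
    """Per-item, per-strategy slipping and guessing probabilities.

    ``s`` and ``g`` have shape ``(J, M)``.  Both live strictly inside their
    supports — (0, 1) for a plain container; posterior draws carry the
    4-Beta prior supports, under whose default (0.1, 0.5) the monotonicity
    condition ``1 - s_jm > g_jm`` holds automatically.
    """

    s: np.ndarray
    g: np.ndarray
    s_support: tuple = (0.0, 1.0)
    g_support: tuple = (0.0, 1.0)

    def __post_init__(self):
        s = np.atleast_2d(np.asarray(self.s, dtype=float))
        g = np.atleast_2d(np.asarray(self.g, dtype=float))
        if s.shape != g.shape:
            raise DimensionError(f"s shape {s.shape} != g shape {g.shape}")
        for arr, (lo, hi), name in ((s, self.s_support, "slipping"),
                                    (g, self.g_support, "guessing")):
            if lo >= hi:
                raise ModelValidationError(f"{name} support must satisfy a < b")
            if arr.size and (arr.min() <= lo or arr.max() >= hi):
                raise ModelValidationError(
                    f"{name} parameters must lie strictly inside ({lo}, {hi})"
                )
        bounded = (self.s_support != (0.0, 1.0) or self.g_support != (0.0, 1.0))
        if bounded and self.s_support[0] + self.g_support[1] >= 1.0:
            warnings.warn(
                "supports allow 1 - s <= g; monotonicity of the response "
                "function is no longer guaranteed",
                UserWarning,
                stacklevel=2,
            )
        object.__setattr__(self, "s", s)
        object.__setattr__(self, "g", g)

    @property
    def J(self) -> int:
        return self.s.shape[0]

    @property
    def M(self) -> int:
        return self.s.shape[1]


@dataclass(frozen=True)
class MixtureState:
    """Mixture side of the MMS-DINA latent state.

    ``pi``: mixing proportions (length M, on the simplex); ``c``: 0-based
    strategy membership per examinee; ``mu``: per-strategy attribute means
    in (0, 1) — ``alpha_ik | c_i = m ~ Bernoulli(mu_m)``.
    """

    pi: np.ndarray
    c: np.ndarray
    mu: np.ndarray

    def __post_init__(self):
        pi = np.asarray(self.pi, dtype=float)
        c = np.asarray(self.c, dtype=np.int64)
        mu = np.asarray(self.mu, dtype=float)
        validate_simplex(pi)
        M = pi.shape[0]
        if mu.shape != (M,):
            raise DimensionError("mu must have one entry per strategy")
        if c.size and (c.min() < 0 or c.max() >= M):
            raise ModelValidationError("memberships must lie in {0..M-1}")
        if mu.size and (mu.min() <= 0 or mu.max() >= 1):
            raise ModelValidationError("attribute means must lie in (0, 1)")
        object.__setattr__(self, "pi", pi)
        object.__setattr__(self, "c", c)
        object.__setattr__(self, "mu", mu)

    @property
    def M(self) -> int:
        return self.pi.shape[0]

    @property
    def n_m(self) -> np.ndarray:
        """Occupancy counts #{i : c_i = m}."""
        return np.bincount(self.c, minlength=self.M)


def validate_simplex(pi, tol: float = 1e-10) -> np.ndarray:
    pi = np.asarray(pi, dtype=float)
    if pi.ndim != 1 or pi.size < 1:
        raise DimensionError("mixing proportions must be a 1-D vector")
    if (pi < 0).any() or abs(pi.sum() - 1.0) > tol:
        raise ModelValidationError(
            f"mixing proportions must be non-negative and sum to 1; got {pi!r}"
        )
    return pi


# ---------------------------------------------------------------------------
# ideal responses
# ---------------------------------------------------------------------------


def compute_eta(profile, q_row) -> int:
    """Ideal response of one profile to one item under one strategy.

    ``eta = prod_k alpha_k ** q_k``: 1 iff every attribute the item requires
    is mastered.  An all-zero requirement row yields 1 (empty product).
    """
    a = np.asarray(profile)
    q = np.asarray(q_row)
    if a.shape != q.shape:
        raise DimensionError(f"profile length {a.shape} != q-row length {q.shape}")
    return int((a >= q).all())


def eta_table(alpha, qmatrix_2d) -> np.ndarray:
    """Vectorized ideal responses: rows of ``alpha`` (n x K) against every
    item of a single-strategy J x K Q-matrix.  Returns an (n, J) 0/1 array."""
    alpha = np.atleast_2d(np.asarray(alpha, dtype=np.int64))
    q = np.asarray(qmatrix_2d, dtype=np.int64)
    if alpha.shape[1] != q.shape[1]:
        raise DimensionError(
            f"profiles have K={alpha.shape[1]} but Q-matrix has K={q.shape[1]}"
        )
    # eta_ij = 1 iff alpha_i . q_j equals the number of required attributes
    return (alpha @ q.T == q.sum(axis=1)[None, :]).astype(np.int8)


def compute_eta_max(profile, qmatrix: MultiStrategyQMatrix, item: int) -> int:
    """``eta_ij = max_m eta_ijm``: 1 iff the profile satisfies the item's
    requirements under at least one strategy (MS-DINA ideal response)."""
    if not 0 <= item < qmatrix.J:
        raise DimensionError(f"item index {item} out of range for J={qmatrix.J}")
    return max(compute_eta(profile, qmatrix.q[m, item]) for m in range(qmatrix.M))


# ---------------------------------------------------------------------------
# response probabilities
# ---------------------------------------------------------------------------


def _check_prob(x, name):
    x = float(x)
    if not 0.0 <= x <= 1.0:
        raise ModelValidationError(f"{name}={x} outside [0, 1]")
    return x


def response_prob_msdina(eta_max: int, s_j: float, g_j: float) -> float:
    """MS-DINA / DINA item response probability: ``(1 - s_j)`` if the ideal
    response is 1, else ``g_j``."""
    s = _check_prob(s_j, "slipping")
    g = _check_prob(g_j, "guessing")
    return 1.0 - s if eta_max else g


def response_prob_conditional(
    profile, item: int, m: int, params: ItemParameters, qmatrix: MultiStrategyQMatrix
) -> float:
    """Correct-response probability given strategy membership ``c_i = m``:
    ``(1 - s_jm)^eta_ijm * g_jm^(1 - eta_ijm)``."""
    if not 0 <= m < qmatrix.M:
        raise DimensionError(f"strategy index {m} out of range for M={qmatrix.M}")
    eta = compute_eta(profile, qmatrix.q[m, item])
    return response_prob_msdina(eta, params.s[item, m], params.g[item, m])


def response_prob_mms(
    profile, item: int, params: ItemParameters, pi, qmatrix: MultiStrategyQMatrix
) -> float:
    """Marginal MMS-DINA probability: convex combination over strategies of
    the conditional DINA probabilities with weights ``pi``.  With M = 1 this
    is exactly the DINA response probability."""
    pi = validate_simplex(pi)
    if pi.shape[0] != qmatrix.M:
        raise DimensionError("pi length must equal the number of strategies")
    return float(
        sum(
            pi[m] * response_prob_conditional(profile, item, m, params, qmatrix)
            for m in range(qmatrix.M)
        )
    )


# ---------------------------------------------------------------------------
# joint likelihood
# ---------------------------------------------------------------------------


def cell_log_likelihood(
    responses: ResponseMatrix,
    alpha,
    params: ItemParameters,
    pi,
    qmatrix: MultiStrategyQMatrix,
) -> np.ndarray:
    """Per-cell mixture log-probabilities ``log sum_m pi_m P(u_ij | ...)``.

    Returns an (N, J) array.  Computed with log-sum-exp over strategies so
    that tiny mixture weights cannot underflow.  These per-cell terms are
    what DIC/LPML consume.
    """
    alpha = np.asarray(alpha, dtype=np.int64)
    u = responses.u
    pi = validate_simplex(pi)
    if alpha.shape[0] != u.shape[0]:
        raise DimensionError("responses and profiles disagree on N")
    if u.shape[1] != qmatrix.J:
        raise DimensionError("responses and Q-matrix disagree on J")
    M = qmatrix.M
    with np.errstate(divide="ignore"):
        log_pi = np.log(pi)
    terms = np.empty((M, u.shape[0], u.shape[1]))
    for m in range(M):
        eta = eta_table(alpha, qmatrix.q[m])
        lp1 = np.where(eta == 1, np.log(1.0 - params.s[:, m]), np.log(params.g[:, m]))
        lp0 = np.where(eta == 1, np.log(params.s[:, m]), np.log(1.0 - params.g[:, m]))
        terms[m] = np.where(u == 1, lp1, lp0) + log_pi[m]
    out = logsumexp(terms, axis=0)
    if np.isneginf(out).any():
        i, j = np.argwhere(np.isneginf(out))[0]
        logger.warning(
            "observation (examinee %d, item %d) has zero probability under "
            "every strategy; joint log-likelihood is -inf",
            i + 1,
            j + 1,
        )
    return out


def joint_loglik(
    responses: ResponseMatrix,
    alpha,
    params: ItemParameters,
    pi,
    qmatrix: MultiStrategyQMatrix,
) -> float:
    """Joint log-likelihood ``sum_ij log sum_m pi_m P(u_ij | alpha_i, s_jm,
    g_jm)`` of the observed responses at one parameter point."""
    return float(cell_log_likelihood(responses, alpha, params, pi, qmatrix).sum())


def all_profiles(K: int) -> np.ndarray:
    """All 2^K binary attribute profiles, ordered by their binary encoding
    ``index = sum_k alpha_k 2^k`` (attribute 0 is the least significant bit)."""
    idx = np.arange(2 ** K)
    return ((idx[:, None] >> np.arange(K)[None, :]) & 1).astype(np.int8)


def profile_index(alpha) -> np.ndarray:
    """Binary encoding of profile rows, the inverse of :func:`all_profiles`."""
    alpha = np.atleast_2d(np.asarray(alpha, dtype=np.int64))
    return alpha @ (1 << np.arange(alpha.shape[1]))
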