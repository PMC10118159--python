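"""Statistical model for three-condition within-subject trials.

A trial compares a placebo (condition 0) against two treatments
(conditions 1 and 2).  In the complete within-subject design every
subject receives all three conditions; in the incomplete design each
subject receives only a pair.  The outcome of subject ``j`` under
condition ``i`` is modelled as

    y_ij = mu_i + e_ij,

where ``mu_i`` is the condition mean and the residual vector ``e_j`` has
a general 3x3 covariance ``D`` with heterogeneous variances ``sigma_i^2``
and covariances ``sigma_ii' = rho_ii' sigma_i sigma_i'``.  Temporal
(period/carryover) effects are deliberately not modelled.

For a subject who receives only a subset of conditions, the rows of the
selector design matrix corresponding to the missing conditions are
dropped, so the subject's response covariance is the matching submatrix
of ``D``.  The GLS estimator of the mean vector then has covariance

    var(mu_hat) = ( sum_j X_j' V_j^{-1} X_j )^{-1},

the inverse of the accumulated information matrix.  The estimands of
interest are the two placebo-treatment contrasts ``mu_0 - mu_1`` and
``mu_0 - mu_2``; their variances are quadratic forms in ``var(mu_hat)``.

Allocations may leave a condition entirely uninformed (e.g. nobody
receives treatment 1).  Estimability is tracked explicitly per condition
rather than masked by pseudo-inverses, because boundary allocations are
legitimate members of the design space.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np

from .errors import NonEstimableContrastError

__all__ = [
    "Combination",
    "CovarianceSpec",
    "MeanCovariance",
    "PLACEBO_T1",
    "PLACEBO_T2",
    "T1_T2",
    "COMPLETE",
    "PAIRS",
    "ALL_COMBINATIONS",
    "CONTRAST_VECTORS",
    "build_covariance_matrix",
    "combination_covariance",
    "combination_information",
    "information_matrix",
    "mean_covariance",
    "contrast_variance",
]

N_CONDITIONS = 3

#: Contrast coefficient vectors for placebo minus treatment i.
CONTRAST_VECTORS = {
    1: np.array([1.0, -1.0, 0.0]),
    2: np.array([1.0, 0.0, -1.0]),
}

# Relative condition-number threshold below which a matrix is treated as
# singular.  Chosen tight because the optimizer evaluates millions of
# small well-scaled matrices and must not confuse noise with rank loss.
_RCOND = 1e-12


@dataclass(frozen=True)
class Combination:
    """An ordered subset of the conditions a subject receives.

    Valid combinations are the three pairs {0,1}, {0,2}, {1,2} and the
    full triple {0,1,2}; conditions are listed in increasing order.
    """

    conditions: tuple[int, ...]

    def __post_init__(self) -> None:
        conds = tuple(int(c) for c in self.conditions)
        object.__setattr__(self, "conditions", conds)
        if any(c not in (0, 1, 2) for c in conds):
            raise ValueError(f"conditions must be in {{0, 1, 2}}, got {conds}")
        if len(set(conds)) != len(conds):
            raise ValueError(f"repeated condition in {conds}")
        if len(conds) not in (2, 3):
            raise ValueError("a combination holds 2 or 3 conditions")
        if conds != tuple(sorted(conds)):
            raise ValueError("conditions must be listed in increasing order")

    def __len__(self) -> int:
        return len(self.conditions)

    def __contains__(self, condition: int) -> bool:
        return condition in self.conditions

    def __iter__(self):
        return iter(self.conditions)

    @property
    def label(self) -> str:
        """Compact string form, e.g. ``'01'`` for placebo + treatment 1."""
        return "".join(str(c) for c in self.conditions)

    def selector(self) -> np.ndarray:
        """|combo| x 3 design matrix: rows of I3 for the received conditions."""
        return np.eye(N_CONDITIONS)[list(self.conditions)]


PLACEBO_T1 = Combination((0, 1))
PLACEBO_T2 = Combination((0, 2))
T1_T2 = Combination((1, 2))
COMPLETE = Combination((0, 1, 2))
PAIRS = (PLACEBO_T1, PLACEBO_T2, T1_T2)
ALL_COMBINATIONS = PAIRS + (COMPLETE,)

_COMBINATION_BY_LABEL = {c.label: c for c in ALL_COMBINATIONS}


def combination_from_label(label: str) -> Combination:
    """Look up a combination by its label, e.g. ``'02'`` or ``'012'``."""
    try:
        return _COMBINATION_BY_LABEL[label]
    except KeyError:
        raise ValueError(f"unknown combination label {label!r}") from None


@dataclass(frozen=True)
class CovarianceSpec:
    """Residual variances and pairwise correlations of the three conditions.

    Parameters
    ----------
    variances
        ``(sigma_0^2, sigma_1^2, sigma_2^2)``, all strictly positive,
        in squared outcome units.
    correlations
        ``(rho_01, rho_02, rho_12)`` in [-1, 1].  The implied covariance
        matrix ``D`` must be positive definite; this is checked at
        construction.
    """

    variances: tuple[float, float, float]
    correlations: tuple[float, float, float]

    def __post_init__(self) -> None:
        variances = tuple(float(v) for v in self.variances)
        correlations = tuple(float(r) for r in self.correlations)
        object.__setattr__(self, "variances", variances)
        object.__setattr__(self, "correlations", correlations)
        if len(variances) != 3 or len(correlations) != 3:
            raise ValueError("need 3 variances and 3 pairwise correlations")
        for i, v in enumerate(variances):
            if not v > 0:
                raise ValueError(f"variance of condition {i} must be > 0, got {v}")
        for pair, r in zip(((0, 1), (0, 2), (1, 2)), correlations):
            if not -1.0 <= r <= 1.0:
                raise ValueError(f"correlation rho_{pair[0]}{pair[1]}={r} outside [-1, 1]")
        # Fails with a named minor if D is not positive definite.
        build_covariance_matrix(self)

    @classmethod
    def from_covariances(
        cls,
        variances: tuple[float, float, float],
        covariances: tuple[float, float, float],
    ) -> "CovarianceSpec":
        """Build a spec from raw covariances (sigma_01, sigma_02, sigma_12)."""
        v = tuple(float(x) for x in variances)
        if len(v) != 3 or any(x <= 0 for x in v):
            raise ValueError("need 3 strictly positive variances")
        s = np.sqrt(v)
        cov = tuple(float(x) for x in covariances)
        correlations = (cov[0] / (s[0] * s[1]), cov[1] / (s[0] * s[2]), cov[2] / (s[1] * s[2]))
        return cls(v, correlations)

    @property
    def covariances(self) -> tuple[float, float, float]:
        """(sigma_01, sigma_02, sigma_12) implied by variances and correlations."""
        s = np.sqrt(self.variances)
        r = self.correlations
        return (r[0] * s[0] * s[1], r[1] * s[0] * s[2], r[2] * s[1] * s[2])

    def matrix(self) -> np.ndarray:
        """The 3x3 residual covariance matrix ``D``."""
        return build_covariance_matrix(self)


def build_covariance_matrix(spec: CovarianceSpec) -> np.ndarray:
    """Assemble and validate the 3x3 residual covariance matrix ``D``.

    ``D[i, i] = sigma_i^2`` and ``D[i, i'] = rho_ii' sigma_i sigma_i'``.
    Positive definiteness is verified through the leading principal
    minors; the first non-positive minor is named in the error message.
    """
    v = np.asarray(spec.variances, dtype=float)
    if np.any(v <= 0):
        raise ValueError("all condition variances must be strictly positive")
    s01, s02, s12 = (
        spec.correlations[0] * np.sqrt(v[0] * v[1]),
        spec.correlations[1] * np.sqrt(v[0] * v[2]),
        spec.correlations[2] * np.sqrt(v[1] * v[2]),
    )
    D = np.array(
        [
            [v[0], s01, s02],
            [s01, v[1], s12],
            [s02, s12, v[2]],
        ]
    )
    for k in (1, 2, 3):
        minor = float(np.linalg.det(D[:k, :k]))
        if minor <= 0:
            raise ValueError(
                f"residual covariance is not positive definite: leading principal "
                f"minor of order {k} is {minor:.6g} <= 0"
            )
    return D


def combination_covariance(D: np.ndarray, combo: Combination) -> np.ndarray:
    """Response covariance ``V_c`` of a subject receiving ``combo``.

    This is the submatrix of ``D`` restricted to the received conditions,
    in combination order; for the full triple it is ``D`` itself.
    """
    idx = list(combo.conditions)
    return np.asarray(D, dtype=float)[np.ix_(idx, idx)]


def combination_information(D: np.ndarray, combo: Combination) -> np.ndarray:
    """Per-subject information matrix ``I_c = X_c' V_c^{-1} X_c`` (3x3).

    Rows and columns of conditions absent from ``combo`` are exactly
    zero; the matrix is positive semidefinite with rank ``|combo|``.
    """
    V = combination_covariance(D, combo)
    if np.linalg.cond(V) > 1.0 / _RCOND:
        raise np.linalg.LinAlgError(
            f"response covariance for combination {combo.label} is singular"
        )
    Vinv = np.linalg.inv(V)
    info = np.zeros((N_CONDITIONS, N_CONDITIONS))
    idx = list(combo.conditions)
    info[np.ix_(idx, idx)] = Vinv
    return info


def _as_counts(allocation) -> Mapping[Combination, int]:
    """Accept either a mapping combo -> count or an object with ``.counts``."""
    if isinstance(allocation, Mapping):
        return allocation
    counts = getattr(allocation, "counts", None)
    if counts is None:
        raise TypeError("expected a mapping Combination -> count or an Allocation")
    return counts


def information_matrix(allocation, D: np.ndarray) -> np.ndarray:
    """Total information ``M = sum_c N_c I_c`` for an allocation.

    Additive in allocations: merging two allocations sums their
    information matrices.
    """
    counts = _as_counts(allocation)
    M = np.zeros((N_CONDITIONS, N_CONDITIONS))
    for combo, n in counts.items():
        n = int(n)
        if n < 0:
            raise ValueError(f"negative count {n} for combination {combo.label}")
        if n:
            M += n * combination_information(D, combo)
    return M


@dataclass(frozen=True)
class MeanCovariance:
    """Covariance of the GLS estimator of the condition means.

    ``matrix`` holds ``var(mu_hat)`` on the estimable block; rows and
    columns of uninformed conditions are NaN, never silently zero.
    ``estimable[i]`` is True iff condition ``i`` received any
    information under the allocation.
    """

    matrix: np.ndarray
    estimable: np.ndarray

    def contrast_variance(self, treatment: int) -> float:
        return contrast_variance(self, treatment)


def mean_covariance(M: np.ndarray) -> MeanCovariance:
    """Invert the information matrix, tracking estimability per condition.

    A condition is uninformed iff its row of ``M`` is entirely zero.  If
    all conditions are informed the full inverse is returned; otherwise
    the inverse is computed on the informed sub-block and the remaining
    rows/columns are flagged NaN.
    """
    M = np.asarray(M, dtype=float)
    informed = np.array([bool(np.any(M[i] != 0.0)) for i in range(N_CONDITIONS)])
    out = np.full((N_CONDITIONS, N_CONDITIONS), np.nan)
    idx = np.flatnonzero(informed)
    if idx.size:
        sub = M[np.ix_(idx, idx)]
        if np.linalg.cond(sub) > 1.0 / _RCOND:
            raise np.linalg.LinAlgError(
                "information matrix is singular on its informed block; "
                "this cannot occur for a positive definite residual covariance"
            )
        out[np.ix_(idx, idx)] = np.linalg.inv(sub)
    return MeanCovariance(matrix=out, estimable=informed)


def contrast_variance(mc: MeanCovariance, treatment: int) -> float:
    """GLS variance of the placebo-treatment contrast ``mu_0 - mu_i``.

    Raises
    ------
    NonEstimableContrastError
        If the placebo or the named treatment carries no information, in
        which case the contrast variance is infinite.
    """
    if treatment not in (1, 2):
        raise ValueError(f"treatment must be 1 or 2, got {treatment}")
    if not (mc.estimable[0] and mc.estimable[treatment]):
        missing = [i for i in (0, treatment) if not mc.estimable[i]]
        raise NonEstimableContrastError(
            f"contrast mu_0 - mu_{treatment} is not estimable: condition(s) "
            f"{missing} carry no information (infinite variance)"
        )
    V = mc.matrix
    return float(V[0, 0] + V[treatment, treatment] - 2.0 * V[0, treatment])
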