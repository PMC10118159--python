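"""Optimality criteria over the two placebo-treatment contrasts.

Two criteria are supported, both functions of ``var(mu_hat)``:

* ``D_A``-optimality minimizes ``det(A' var(mu_hat) A)`` with the 3x2
  contrast matrix ``A`` stacking ``(1,-1,0)`` and ``(1,0,-1)`` — the
  volume of the joint confidence ellipsoid of the two contrasts.
* compound optimality minimizes the weighted sum
  ``lambda1 * Phi_01 + (1 - lambda1) * Phi_02`` of the individual
  contrast variances, where ``lambda1`` expresses the relative
  importance of the placebo vs treatment-1 comparison.

Relative efficiency compares a candidate allocation to the optimum: the
plain criterion ratio for the compound criterion, and the square-rooted
ratio for D_A because two contrasts enter the determinant.  Its
reciprocal is the replication factor the candidate needs to match the
optimum.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .errors import NonEstimableContrastError
from .model import MeanCovariance, contrast_variance

__all__ = [
    "CONTRAST_MATRIX",
    "CriterionSpec",
    "DA",
    "compound",
    "phi_da",
    "phi_compound",
    "criterion_value",
    "relative_efficiency",
]

#: 3x2 matrix of stacked contrast coefficients; columns are
#: a_01 = (1, -1, 0) and a_02 = (1, 0, -1).  Fixed constant.
CONTRAST_MATRIX = np.array(
    [
        [1.0, 1.0],
        [-1.0, 0.0],
        [0.0, -1.0],
    ]
)

#: Relative tolerance used to declare two criterion values tied.
TIE_RTOL = 1e-10


@dataclass(frozen=True)
class CriterionSpec:
    """Choice of optimality criterion.

    ``kind`` is ``"DA"`` or ``"compound"``; ``lambda1`` in [0, 1] is the
    weight of the first contrast and applies to the compound criterion
    only (ignored for D_A).
    """

    kind: str
    lambda1: float | None = None

    def __post_init__(self) -> None:
        kind = str(self.kind)
        object.__setattr__(self, "kind", kind)
        if kind not in ("DA", "compound"):
            raise ValueError(f"criterion kind must be 'DA' or 'compound', got {kind!r}")
        if kind == "compound":
            if self.lambda1 is None:
                raise ValueError("the compound criterion requires lambda1")
            lam = float(self.lambda1)
            if not 0.0 <= lam <= 1.0:
                raise ValueError(f"lambda1 must lie in [0, 1], got {lam}")
            object.__setattr__(self, "lambda1", lam)
        else:
            object.__setattr__(self, "lambda1", None)

    @property
    def name(self) -> str:
        if self.kind == "DA":
            return "DA"
        return f"compound(lambda1={self.lambda1:g})"


def DA() -> CriterionSpec:
    return CriterionSpec("DA")


def compound(lambda1: float) -> CriterionSpec:
    return CriterionSpec("compound", lambda1)


def phi_da(mc: MeanCovariance) -> float:
    """D_A criterion ``det(A' var(mu_hat) A)``; strictly positive.

    Requires every condition to be estimable (both contrasts enter the
    determinant); otherwise the criterion is infinite and a
    :class:`NonEstimableContrastError` is raised.
    """
    if not bool(np.all(mc.estimable)):
        missing = [i for i in range(3) if not mc.estimable[i]]
        raise NonEstimableContrastError(
            f"D_A criterion is infinite: condition(s) {missing} carry no information"
        )
    S = CONTRAST_MATRIX.T @ mc.matrix @ CONTRAST_MATRIX
    return float(S[0, 0] * S[1, 1] - S[0, 1] * S[1, 0])


def phi_compound(mc: MeanCovariance, lambda1: float) -> float:
    """Compound criterion ``lambda1 * Phi_01 + (1 - lambda1) * Phi_02``.

    A contrast with exactly zero weight is never evaluated, so the
    convention 0 x infinity = 0 holds: boundary allocations that drop
    one pair entirely remain admissible at ``lambda1`` of 0 or 1.
    """
    lam = float(lambda1)
    if not 0.0 <= lam <= 1.0:
        raise ValueError(f"lambda1 must lie in [0, 1], got {lam}")
    total = 0.0
    if lam > 0.0:
        total += lam * contrast_variance(mc, 1)
    if lam < 1.0:
        total += (1.0 - lam) * contrast_variance(mc, 2)
    return total


def criterion_value(mc: MeanCovariance, criterion: CriterionSpec) -> float:
    """Evaluate a criterion, mapping non-estimability to ``math.inf``."""
    try:
        if criterion.kind == "DA":
            return phi_da(mc)
        return phi_compound(mc, criterion.lambda1)
    except NonEstimableContrastError:
        return math.inf


def relative_efficiency(
    criterion: CriterionSpec, phi_star: float, phi: float
) -> float:
    """Efficiency of an allocation with criterion value ``phi`` relative
    to the optimum ``phi_star``.

    For D_A the ratio is square-rooted because two contrasts enter the
    determinant; for the compound criterion the plain ratio is used.
    The result lies in (0, 1]; its reciprocal is the number of times the
    candidate trial must be replicated to match the optimal allocation.
    """
    if not (math.isfinite(phi_star) and math.isfinite(phi)):
        raise ValueError("relative efficiency requires finite criterion values")
    if phi_star <= 0 or phi <= 0:
        raise ValueError("criterion values must be strictly positive")
    if phi_star > phi * (1.0 + TIE_RTOL):
        raise ValueError(
            f"reference value {phi_star} exceeds candidate value {phi}: "
            "the reference allocation is not optimal"
        )
    ratio = phi_star / phi
    if criterion.kind == "DA":
        return math.sqrt(ratio)
    return ratio
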