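"""Detectable effect sizes, power, and Cohen's d for a single contrast.

All calculations use the normal approximation for a z-test of one
placebo-treatment contrast with known variance ``var(mu_0 - mu_i)``:

* minimum detectable raw effect at type-I rate ``alpha`` and power
  ``1 - beta``:  ``(z_{1-alpha} + z_{1-beta}) * sqrt(var)`` (with
  ``z_{1-alpha/2}`` for a two-sided test);
* power to detect a raw effect ``delta``:
  ``Phi(delta / sqrt(var) - z_{1-alpha})``.

The two are mutual inverses.  Cohen's d standardizes a raw effect by the
square root of the average of the placebo and treatment variances, so
heteroscedastic conditions contribute symmetrically to the denominator.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from scipy.stats import norm

__all__ = [
    "PowerSpec",
    "detectable_effect_size",
    "power_for_effect",
    "standardized_effect",
    "effect_from_standardized",
]


@dataclass(frozen=True)
class PowerSpec:
    """Settings for a single-contrast power calculation.

    Exactly one of ``power`` (detectable-effect mode) or ``effect``
    (power mode, raw outcome units) should be set per call.  Defaults
    follow common trial-planning practice: one-sided alpha 0.05 and
    target power 0.8.
    """

    alpha: float = 0.05
    sided: int = 1
    power: float | None = 0.8
    effect: float | None = None

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise ValueError(f"alpha must lie in (0, 1), got {self.alpha}")
        if self.sided not in (1, 2):
            raise ValueError(f"sided must be 1 or 2, got {self.sided}")
        if self.power is not None and not 0.0 < self.power < 1.0:
            raise ValueError(f"power must lie in (0, 1), got {self.power}")

    @property
    def z_alpha(self) -> float:
        """Critical value: z_{1-alpha} one-sided, z_{1-alpha/2} two-sided."""
        tail = self.alpha / 2.0 if self.sided == 2 else self.alpha
        return float(norm.ppf(1.0 - tail))


def detectable_effect_size(contrast_var: float, spec: PowerSpec) -> float:
    """Smallest raw effect detectable at the spec's alpha and power.

    ``(z_{1-alpha} + z_{1-beta}) * sqrt(contrast_var)`` in outcome units.
    """
    if not contrast_var > 0:
        raise ValueError(f"contrast variance must be > 0, got {contrast_var}")
    if spec.power is None:
        raise ValueError("PowerSpec must carry a target power for this calculation")
    z_beta = float(norm.ppf(spec.power))
    return (spec.z_alpha + z_beta) * math.sqrt(contrast_var)


def power_for_effect(contrast_var: float, spec: PowerSpec) -> float:
    """Power of the contrast z-test against a raw effect of ``spec.effect``.

    Inverse of :func:`detectable_effect_size`: feeding its output back as
    the effect recovers the target power exactly.
    """
    if not contrast_var > 0:
        raise ValueError(f"contrast variance must be > 0, got {contrast_var}")
    if spec.effect is None:
        raise ValueError("PowerSpec must carry a raw effect for this calculation")
    return float(norm.cdf(spec.effect / math.sqrt(contrast_var) - spec.z_alpha))


def standardized_effect(
    effect: float, var_placebo: float, var_treatment: float
) -> float:
    """Cohen's d: raw effect over sqrt of the mean of the two variances."""
    if not (var_placebo > 0 and var_treatment > 0):
        raise ValueError("condition variances must be > 0")
    return effect / math.sqrt((var_placebo + var_treatment) / 2.0)


def effect_from_standardized(
    d: float, var_placebo: float, var_treatment: float
) -> float:
    """Raw effect in outcome units corresponding to a Cohen's d."""
    if not (var_placebo > 0 and var_treatment > 0):
        raise ValueError("condition variances must be > 0")
    return d * math.sqrt((var_placebo + var_treatment) / 2.0)
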