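"""Exposure-disparity decomposition.

The absolute disparity in exposure experienced by a demographic group —
the difference between that group's population-weighted mean (PWM)
concentration and the total population's — factors exactly into three
independently controllable components:

    D_A = E × XF̄ × D_R

where ``E`` is the emission rate of the source, ``XF̄`` is the
population-average exposure factor (total-population PWM per unit
emission rate, the concentration analogue of an intake fraction), and
``D_R`` is the relative disparity in decimal form,
``(PWM_group − PWM_total) / PWM_total``.  The identity is algebraic:
``E · (PWM_T/E) · ((PWM_g − PWM_T)/PWM_T) = PWM_g − PWM_T``, so it holds
for any consistent unit system; the components carry whatever
emission-rate unit the caller supplies and ``XF̄`` absorbs its
reciprocal.

This module computes PWMs and the four components from gridded
concentration and population rasters, and compares a baseline
decomposition against a policy decomposition as fractional changes in
each component.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import DomainError, ShapeError, ValidationError

__all__ = [
    "DisparityDecomposition",
    "ChangeDecomposition",
    "population_weighted_mean",
    "absolute_disparity",
    "relative_disparity",
    "exposure_factor",
    "decompose",
    "percent_change",
    "change_decomposition",
]


@dataclass(frozen=True)
class DisparityDecomposition:
    """The four framework components for one group at one point in time.

    Attributes
    ----------
    group_label
        Name of the demographic group the disparity refers to.
    emissions
        Source emission rate ``E`` (mass/time, e.g. g/s).
    exposure_factor
        ``XF̄ = PWM_total / E`` — concentration per unit emission rate.
    relative_disparity
        ``D_R = (PWM_group − PWM_total) / PWM_total`` in decimal form
        (0.2 means the group's exposure is 20% above average; negative
        values indicate an under-exposed group).
    absolute_disparity
        ``D_A = PWM_group − PWM_total`` in concentration units.
    pwm_group, pwm_total
        The underlying population-weighted mean concentrations.
    """

    group_label: str
    emissions: float
    exposure_factor: float
    relative_disparity: float
    absolute_disparity: float
    pwm_group: float
    pwm_total: float


@dataclass(frozen=True)
class ChangeDecomposition:
    """Fractional changes in each component between a baseline and a
    policy decomposition, ``(policy − baseline) / baseline``.

    The product identity implies multiplicative consistency:
    ``(1 + ΔE)(1 + ΔXF̄)(1 + ΔD_R) = 1 + ΔD_A``.
    """

    group_label: str
    frac_change_E: float
    frac_change_XF: float
    frac_change_DR: float
    frac_change_DA: float


def _as_array(field) -> np.ndarray:
    values = getattr(field, "values", field)
    return np.asarray(values, dtype=float)


def population_weighted_mean(conc, pop) -> float:
    """Mean concentration over people rather than area.

    ``PWM = Σᵢ Pᵢ Cᵢ / Σᵢ Pᵢ`` with ``Pᵢ`` the resident count and ``Cᵢ``
    the concentration of cell *i*.  ``conc`` may be a
    :class:`~airdisparity.city.ConcentrationField` or a bare array.
    """
    c = _as_array(conc)
    p = _as_array(pop)
    if c.shape != p.shape:
        raise ShapeError(
            f"concentration grid {c.shape} and population grid {p.shape} differ"
        )
    if not np.all(np.isfinite(c)) or not np.all(np.isfinite(p)):
        raise ValidationError("concentration and population must be finite")
    if np.any(p < 0):
        raise ValidationError("population counts must be nonnegative")
    total = p.sum()
    if total <= 0:
        raise DomainError("total population is zero; weighted mean undefined")
    return float((p * c).sum() / total)


def absolute_disparity(pwm_group: float, pwm_total: float) -> float:
    """``D_A = PWM_group − PWM_total``; positive means over-exposed."""
    if not (np.isfinite(pwm_group) and np.isfinite(pwm_total)):
        raise ValidationError("population-weighted means must be finite")
    return float(pwm_group - pwm_total)


def relative_disparity(pwm_group: float, pwm_total: float) -> float:
    """``D_R = (PWM_group − PWM_total) / PWM_total`` in decimal form."""
    if not (np.isfinite(pwm_group) and np.isfinite(pwm_total)):
        raise ValidationError("population-weighted means must be finite")
    if pwm_total <= 0:
        raise DomainError(
            "relative disparity undefined when total exposure is zero"
        )
    return float((pwm_group - pwm_total) / pwm_total)


def exposure_factor(pwm_total: float, emissions: float) -> float:
    """``XF̄ = PWM_total / E`` — average exposure per unit emission rate.

    Invariant under a joint rescaling of the concentration field and the
    emission rate, which makes it a property of source placement and
    dispersion rather than of source strength.
    """
    if not np.isfinite(pwm_total):
        raise ValidationError("pwm_total must be finite")
    if emissions <= 0:
        raise DomainError("exposure factor undefined for emissions <= 0")
    return float(pwm_total / emissions)


def decompose(conc, pop_group, pop_total, emissions: float,
              group_label: str = "group") -> DisparityDecomposition:
    """Compute all framework components from one concentration field.

    The returned record satisfies ``E × XF̄ × D_R == D_A`` to floating
    point, since the components are evaluated from the same pair of
    population-weighted means.
    """
    pwm_g = population_weighted_mean(conc, pop_group)
    pwm_t = population_weighted_mean(conc, pop_total)
    return DisparityDecomposition(
        group_label=group_label,
        emissions=float(emissions),
        exposure_factor=exposure_factor(pwm_t, emissions),
        relative_disparity=relative_disparity(pwm_g, pwm_t),
        absolute_disparity=absolute_disparity(pwm_g, pwm_t),
        pwm_group=pwm_g,
        pwm_total=pwm_t,
    )


def percent_change(value_start: float, value_end: float) -> float:
    """Signed percent change, ``100 (end − start) / start``.

    The sign follows the value, not its magnitude: a relative disparity
    moving from 0.1 to 0.12 is reported as +20% even though a reader may
    describe it as a worsening.  Reports that need the magnitude of the
    change label it separately rather than flipping signs here.
    """
    if value_start == 0:
        raise DomainError("percent change undefined from a zero start value")
    if not (np.isfinite(value_start) and np.isfinite(value_end)):
        raise ValidationError("values must be finite")
    return float(100.0 * (value_end - value_start) / value_start)


def change_decomposition(baseline: DisparityDecomposition,
                         policy: DisparityDecomposition) -> ChangeDecomposition:
    """Fractional change in each component from baseline to policy.

    Both records must describe the same group and every baseline
    component must be nonzero (a fractional change from zero is
    undefined).
    """
    if baseline.group_label != policy.group_label:
        raise ValidationError(
            f"group mismatch: {baseline.group_label!r} vs {policy.group_label!r}"
        )
    pairs = {
        "E": (baseline.emissions, policy.emissions),
        "XF": (baseline.exposure_factor, policy.exposure_factor),
        "DR": (baseline.relative_disparity, policy.relative_disparity),
        "DA": (baseline.absolute_disparity, policy.absolute_disparity),
    }
    changes = {}
    for name, (b, p) in pairs.items():
        if b == 0:
            raise DomainError(f"baseline component {name} is zero; "
                              "fractional change undefined")
        changes[name] = float((p - b) / b)
    return ChangeDecomposition(
        group_label=baseline.group_label,
        frac_change_E=changes["E"],
        frac_change_XF=changes["XF"],
        frac_change_DR=changes["DR"],
        frac_change_DA=changes["DA"],
    )
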