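"""Emission-reduction policy scenarios.

Three archetypal pathways reduce the source's emission rate linearly
from ``E0`` to one increment above zero over ``T`` steps while moving
(or not moving) the source:

``reduce_E``
    The source stays put; only emissions fall.  The spatial pattern of
    concentrations — hence the relative disparity — is frozen, and the
    absolute disparity falls exactly in proportion to emissions.

``reduce_E_XF``
    The source is translated due north, perpendicular to the west–east
    demographic gradient, toward the sparsely populated periphery.  The
    average exposure factor falls, but the east-side spatial bias (and
    with it the relative disparity) is maintained.

``reduce_E_XF_DR``
    Phase 1 moves the source diagonally northwest — away from both the
    overburdened east side and the dense center — until it reaches the
    demographic-equity longitude where the relative disparity for group
    alpha crosses zero (by construction at the trajectory midpoint).
    Phase 2 then continues radially away from the city center, further
    reducing the exposure factor while the disparity stays eliminated.

The per-step displacement magnitudes are model choices: the northward
trajectories end at a radial displacement of ``n/2 − margin`` cells
(default margin 25, which keeps the final source position more than
half a plume standard deviation inside the domain so the field is not
badly truncated at the boundary).

Everything here is deterministic; identical inputs give identical
results.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .city import (ConcentrationField, DispersionParams, EmissionSource,
                   PopulationGrid, concentration_field)
from .errors import DomainError, ValidationError
from .framework import decompose, percent_change, relative_disparity, \
    population_weighted_mean

__all__ = [
    "SCENARIO_KINDS",
    "ScenarioSpec",
    "ScenarioResult",
    "find_equity_longitude",
    "make_scenario",
    "run_scenario",
    "summarize_at_fraction",
    "emission_reduction_at_zero_disparity",
    "compare_scenarios",
    "RESULT_COLUMNS",
]

SCENARIO_KINDS = ("reduce_E", "reduce_E_XF", "reduce_E_XF_DR")

DEFAULT_MARGIN = 25.0

RESULT_COLUMNS = ["step", "group", "E", "XF_bar", "D_R", "D_A",
                  "PWM_group", "PWM_total"]


@dataclass(frozen=True)
class ScenarioSpec:
    """An emission-magnitude and source-location trajectory.

    ``trajectory`` holds the per-step source position as a ``(T, 2)``
    array of ``(x, y)`` cell coordinates.  Results read back from disk
    carry ``trajectory=None`` (positions are not part of the persisted
    record schema).
    """

    name: str
    n_steps: int
    initial_emissions: float
    source_start: tuple[float, float]
    trajectory: np.ndarray | None


@dataclass(frozen=True)
class ScenarioResult:
    """Per-step framework decompositions for both groups.

    ``records`` is a tidy frame with one row per (step, group), columns
    ``step, group, E, XF_bar, D_R, D_A, PWM_group, PWM_total``;
    ``emission_fraction_reduced`` is the per-step fraction ``t/T``.
    """

    spec_ref: ScenarioSpec
    records: pd.DataFrame
    emission_fraction_reduced: np.ndarray

    def group_records(self, group_label: str) -> pd.DataFrame:
        sub = self.records[self.records["group"] == group_label]
        if sub.empty:
            raise ValidationError(f"unknown group label {group_label!r}")
        return sub.sort_values("step").reset_index(drop=True)

    def component_series(self, group_label: str, component: str) -> np.ndarray:
        return self.group_records(group_label)[component].to_numpy()


def find_equity_longitude(city: PopulationGrid, params: DispersionParams,
                          y: float, tol: float = 1e-3, xtol: float = 1e-6,
                          max_iter: int = 200) -> float:
    """Source x-position at which group alpha's relative disparity is zero.

    Bisection on the source longitude at fixed latitude ``y``; requires
    the disparity to change sign across the grid (it is negative with
    the source on the beta-rich west edge and positive on the east
    edge).  The bracket is narrowed to ``xtol`` cells; the result must
    satisfy ``|D_R| ≤ tol``.
    """
    pop_a, pop_t = city.pop_alpha, city.pop_total

    def d_r(x: float) -> float:
        conc = concentration_field(EmissionSource(x, y, 1.0), params)
        pwm_t = population_weighted_mean(conc, pop_t)
        pwm_a = population_weighted_mean(conc, pop_a)
        return relative_disparity(pwm_a, pwm_t)

    lo, hi = 0.0, float(city.n - 1)
    f_lo, f_hi = d_r(lo), d_r(hi)
    if f_lo == 0:
        return lo
    if f_hi == 0:
        return hi
    if f_lo * f_hi > 0:
        raise DomainError("relative disparity does not change sign across "
                          "the grid; no equity longitude exists")
    if f_lo > 0:  # orient so that D_R < 0 at lo
        lo, hi = hi, lo
    mid = 0.5 * (lo + hi)
    for _ in range(max_iter):
        if abs(hi - lo) <= xtol:
            break
        mid = 0.5 * (lo + hi)
        if d_r(mid) < 0:
            lo = mid
        else:
            hi = mid
    mid = 0.5 * (lo + hi)
    if abs(d_r(mid)) > tol:
        raise DomainError("bisection did not reach |D_R| <= tol; the "
                          "disparity is not smooth across the bracket")
    return mid


def _check_inside(x: float, y: float, n: int, what: str) -> None:
    if not (0 <= x <= n - 1 and 0 <= y <= n - 1):
        raise ValidationError(f"{what} ({x}, {y}) outside the {n}x{n} grid")


def make_scenario(kind: str, city: PopulationGrid, params: DispersionParams,
                  n_steps: int = 1000, initial_emissions: float = 10.0,
                  source_start: tuple[float, float] = (150.0, 100.0),
                  margin: float = DEFAULT_MARGIN) -> ScenarioSpec:
    """Build the source trajectory for one of the three scenario kinds."""
    if kind not in SCENARIO_KINDS:
        raise ValidationError(
            f"unknown scenario kind {kind!r}; expected one of {SCENARIO_KINDS}"
        )
    if n_steps < 2:
        raise ValidationError("n_steps must be at least 2")
    if initial_emissions <= 0:
        raise ValidationError("initial_emissions must be positive")
    n = city.n
    x0, y0 = float(source_start[0]), float(source_start[1])
    _check_inside(x0, y0, n, "source_start")

    T = n_steps
    t = np.arange(T, dtype=float)
    if kind == "reduce_E":
        traj = np.column_stack([np.full(T, x0), np.full(T, y0)])
    elif kind == "reduce_E_XF":
        displacement = n / 2.0 - margin
        ys = y0 + displacement * t / (T - 1)
        traj = np.column_stack([np.full(T, x0), ys])
    else:  # reduce_E_XF_DR
        if n_steps < 4:
            raise ValidationError("reduce_E_XF_DR needs at least 4 steps")
        x_eq = find_equity_longitude(city, params, y=y0)
        # Phase 1: straight diagonal to the equity longitude, moving
        # north by the same magnitude it moves in x — away from both the
        # overburdened group and the dense center.  D_R crosses zero at
        # the end of this phase (the trajectory midpoint).
        T1 = T // 2
        y1 = y0 + abs(x0 - x_eq)
        s = t[:T1] / (T1 - 1)
        phase1 = np.column_stack([x0 + (x_eq - x0) * s, y0 + (y1 - y0) * s])
        # Phase 2: radially away from the city center to a final
        # distance of n/2 − margin cells.
        center = (n - 1) / 2.0
        vec = np.array([x_eq - center, y1 - center])
        dist = float(np.hypot(*vec))
        direction = vec / dist if dist > 0 else np.array([0.0, 1.0])
        end = np.array([center, center]) + direction * max(dist, n / 2.0 - margin)
        s2 = np.arange(1, T - T1 + 1, dtype=float) / (T - T1)
        phase2 = phase1[-1] + (end - phase1[-1]) * s2[:, np.newaxis]
        traj = np.vstack([phase1, phase2])
    for xx, yy in (traj[0], traj[-1]):
        _check_inside(float(xx), float(yy), n, "trajectory position")
    return ScenarioSpec(name=kind, n_steps=T,
                        initial_emissions=float(initial_emissions),
                        source_start=(x0, y0), trajectory=traj)


def run_scenario(city: PopulationGrid, spec: ScenarioSpec,
                 params: DispersionParams) -> ScenarioResult:
    """Run the emission-reduction pathway, decomposing at every step.

    Step ``t`` uses ``E_t = E0 (1 − t/T)``, so the final step sits one
    linear increment (``E0/T``) above zero — "approximately zero"
    without the 0/0 that an exactly zero field would create in the
    exposure factor.
    """
    if spec.trajectory is None:
        raise ValidationError("spec has no trajectory (was it read from disk?)")
    if params.n_cells != city.n:
        raise ValidationError(
            f"params.n_cells={params.n_cells} does not match city n={city.n}"
        )
    if len(spec.trajectory) != spec.n_steps:
        raise ValidationError("trajectory length does not match n_steps")
    T = spec.n_steps
    e0 = spec.initial_emissions
    pops = {"alpha": city.pop_alpha, "beta": city.pop_beta}
    pop_t = city.pop_total
    rows = []
    for t in range(T):
        emission = e0 * (1.0 - t / T)
        x, y = spec.trajectory[t]
        conc = concentration_field(
            EmissionSource(float(x), float(y), emission), params)
        for label, pop in pops.items():
            rec = decompose(conc, pop, pop_t, emission, group_label=label)
            rows.append((t, label, rec.emissions, rec.exposure_factor,
                         rec.relative_disparity, rec.absolute_disparity,
                         rec.pwm_group, rec.pwm_total))
    records = pd.DataFrame(rows, columns=RESULT_COLUMNS)
    fractions = np.arange(T, dtype=float) / T
    return ScenarioResult(spec_ref=spec, records=records,
                          emission_fraction_reduced=fractions)


def _step_at_fraction(result: ScenarioResult, fraction: float) -> int:
    fr = result.emission_fraction_reduced
    if not 0 < fraction <= 1:
        raise DomainError("fraction must lie in (0, 1]")
    idx = np.nonzero(fr >= fraction)[0]
    if len(idx) == 0:
        raise DomainError(
            f"fraction {fraction} exceeds the maximum reached ({fr[-1]})"
        )
    return int(idx[0])


def summarize_at_fraction(result: ScenarioResult,
                          fraction: float) -> dict[str, dict[str, float]]:
    """Percent change of each component from step 0 to the first step at
    which at least ``fraction`` of emissions has been removed.

    Returns ``{group: {"E": ..., "XF_bar": ..., "D_R": ..., "D_A": ...}}``
    with signed percent changes (see :func:`~airdisparity.framework.percent_change`
    for the sign convention).
    """
    step = _step_at_fraction(result, fraction)
    out: dict[str, dict[str, float]] = {}
    for group in sorted(result.records["group"].unique()):
        sub = result.group_records(group)
        start, end = sub.iloc[0], sub.iloc[step]
        out[group] = {
            comp: percent_change(float(start[comp]), float(end[comp]))
            for comp in ("E", "XF_bar", "D_R", "D_A")
        }
    return out


def emission_reduction_at_zero_disparity(result: ScenarioResult,
                                         group_label: str,
                                         tolerance: float | None = None
                                         ) -> float:
    """Smallest emission-reduction fraction that eliminates |D_A|.

    Returns the first fraction at which ``|D_A|`` falls to within
    ``tolerance`` of zero (default one part in 10³ of its initial
    magnitude), or 1.0 if that never happens before the final step —
    i.e. if the disparity only vanishes because emissions themselves
    reach (approximately) zero.
    """
    d_a = result.component_series(group_label, "D_A")
    if tolerance is None:
        tolerance = 1e-3 * abs(float(d_a[0]))
    hits = np.nonzero(np.abs(d_a[:-1]) <= tolerance)[0]
    if len(hits) == 0:
        return 1.0
    return float(result.emission_fraction_reduced[hits[0]])


def compare_scenarios(result_a: ScenarioResult, result_b: ScenarioResult,
                      group_label: str,
                      tolerance: float | None = None) -> float:
    """Percent saving in required emission reduction of pathway b over a.

    ``100 (r_a − r_b) / r_a`` with ``r`` each pathway's
    :func:`emission_reduction_at_zero_disparity`; positive when pathway
    b eliminates the group's absolute disparity with less emission
    reduction.
    """
    if result_a.spec_ref.n_steps != result_b.spec_ref.n_steps or \
            result_a.spec_ref.initial_emissions != result_b.spec_ref.initial_emissions:
        raise ValidationError(
            "results were produced under different emission schedules")
    r_a = emission_reduction_at_zero_disparity(result_a, group_label, tolerance)
    r_b = emission_reduction_at_zero_disparity(result_b, group_label, tolerance)
    return float(100.0 * (r_a - r_b) / r_a)
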