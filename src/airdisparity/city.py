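"""Synthetic segregated city and its dispersion model.

The illustrative city is a square grid of cells holding two demographic
groups, alpha and beta.  Total population density peaks at the city
center and decays linearly with radial distance; the alpha share of each
cell rises linearly from west to east, so alpha is concentrated on the
east side while the two groups have exactly equal totals.

A single point (or population-weighted mean) emission source produces a
radially symmetric two-dimensional Gaussian concentration field,

    C(x, y) = E / (n u H) · exp(−[(x − x₀)² + (y − y₀)²] / (2σ²)),

with emission rate ``E``, grid side length ``n``, mean wind speed ``u``
and boundary-layer height ``H``.  An optional first-order loss term
multiplies each cell by ``exp(−k d / u)``, ``d`` the distance from the
source in meters, emulating a shorter-lived reactive pollutant.

Coordinates are 0-based with ``(x, y)`` = (column from west, row from
south); arrays are indexed ``[y, x]``.  Sources may sit at continuous
(non-integer) positions; the Gaussian is evaluated at integer cell
coordinates regardless.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ValidationError

__all__ = [
    "PopulationGrid",
    "EmissionSource",
    "DispersionParams",
    "ConcentrationField",
    "build_city",
    "gaussian_concentration",
    "apply_first_order_decay",
    "concentration_field",
    "default_decay_rate",
]

GROUP_LABELS = ("alpha", "beta")


@dataclass(frozen=True)
class PopulationGrid:
    """Per-cell person counts for the two demographic groups."""

    pop_alpha: np.ndarray
    pop_beta: np.ndarray
    n: int

    @property
    def pop_total(self) -> np.ndarray:
        return self.pop_alpha + self.pop_beta

    def group(self, label: str) -> np.ndarray:
        """Population raster for ``"alpha"``, ``"beta"`` or ``"total"``."""
        if label == "alpha":
            return self.pop_alpha
        if label == "beta":
            return self.pop_beta
        if label == "total":
            return self.pop_total
        raise ValidationError(f"unknown group label {label!r}")


@dataclass(frozen=True)
class EmissionSource:
    """A source at (x0, y0) cell coordinates emitting at ``emission_rate``
    (g/s by convention in the simulator)."""

    x0: float
    y0: float
    emission_rate: float


@dataclass(frozen=True)
class DispersionParams:
    """Parameters of the Gaussian dispersion model.

    Attributes
    ----------
    wind_speed
        Mean wind speed ``u`` in m/s (default 5).
    boundary_height
        Mean boundary-layer height ``H`` in m (default 100).
    sigma
        Plume spread in cell units, identical in x and y (default 40,
        i.e. 20% of the default 200-cell domain: wide enough that both
        groups are measurably exposed, narrow enough that a disparity
        exists).
    n_cells
        Grid side length ``n`` (default 200).
    decay_rate
        First-order rate constant ``k`` in 1/s (default 0 = conserved
        pollutant).
    cell_length
        Physical cell size in m, used only to convert cell distances to
        meters for the decay term (default 100).
    normalization
        ``"side"`` uses the side length ``n`` in the prefactor
        ``E/(n u H)``; ``"cells"`` substitutes the cell count ``n²``.
        The default follows the side-length form.
    """

    wind_speed: float = 5.0
    boundary_height: float = 100.0
    sigma: float = 40.0
    n_cells: int = 200
    decay_rate: float = 0.0
    cell_length: float = 100.0
    normalization: str = "side"

    def __post_init__(self):
        if self.wind_speed <= 0:
            raise ValidationError("wind_speed must be positive")
        if self.boundary_height <= 0:
            raise ValidationError("boundary_height must be positive")
        if self.sigma <= 0:
            raise ValidationError("sigma must be positive")
        if self.n_cells < 3:
            raise ValidationError("n_cells must be at least 3")
        if self.decay_rate < 0:
            raise ValidationError("decay_rate must be nonnegative")
        if self.cell_length <= 0:
            raise ValidationError("cell_length must be positive")
        if self.normalization not in ("side", "cells"):
            raise ValidationError("normalization must be 'side' or 'cells'")

    @property
    def norm_cells(self) -> float:
        n = self.n_cells
        return float(n if self.normalization == "side" else n * n)


@dataclass(frozen=True)
class ConcentrationField:
    """Per-cell concentrations produced by one source configuration."""

    values: np.ndarray
    source_ref: EmissionSource = field(compare=False)

    @property
    def shape(self):
        return self.values.shape


def build_city(n: int = 200, center_peak_density: float = 100.0,
               r_max: float | None = None) -> PopulationGrid:
    """Construct the two-group city grid.

    Total density falls linearly from ``center_peak_density`` at the
    grid center to zero at radius ``r_max`` (default ``n/√2``, so the
    corners are just empty); the alpha share of each column is
    ``x/(n−1)``.  The linear share is antisymmetric about the center
    column while the total density is mirror-symmetric, so the two group
    totals are equal by construction.  Fully deterministic.
    """
    if n < 3:
        raise ValidationError("n must be at least 3")
    if center_peak_density <= 0:
        raise ValidationError("center_peak_density must be positive")
    if r_max is None:
        r_max = n / np.sqrt(2.0)
    if r_max <= 0:
        raise ValidationError("r_max must be positive")
    coords = np.arange(n, dtype=float)
    x = coords[np.newaxis, :]
    y = coords[:, np.newaxis]
    c = (n - 1) / 2.0
    r = np.hypot(x - c, y - c)
    total = center_peak_density * np.maximum(0.0, 1.0 - r / r_max)
    frac_alpha = np.broadcast_to(coords / (n - 1), (n, n))
    return PopulationGrid(pop_alpha=total * frac_alpha,
                          pop_beta=total * (1.0 - frac_alpha),
                          n=n)


def _check_source(source: EmissionSource, params: DispersionParams) -> None:
    n = params.n_cells
    if not (0 <= source.x0 <= n - 1 and 0 <= source.y0 <= n - 1):
        raise ValidationError(
            f"source ({source.x0}, {source.y0}) outside the {n}x{n} grid"
        )
    if source.emission_rate < 0:
        raise ValidationError("emission_rate must be nonnegative")


def gaussian_concentration(source: EmissionSource,
                           params: DispersionParams) -> ConcentrationField:
    """Radial Gaussian concentration field centered on the source.

    Linear in the emission rate, radially symmetric about ``(x0, y0)``
    in cell coordinates, with peak ``E/(n u H)`` at the source.
    """
    _check_source(source, params)
    n = params.n_cells
    coords = np.arange(n, dtype=float)
    dx2 = (coords[np.newaxis, :] - source.x0) ** 2
    dy2 = (coords[:, np.newaxis] - source.y0) ** 2
    prefactor = source.emission_rate / (
        params.norm_cells * params.wind_speed * params.boundary_height
    )
    values = prefactor * np.exp(-(dx2 + dy2) / (2.0 * params.sigma ** 2))
    return ConcentrationField(values=values, source_ref=source)


def apply_first_order_decay(conc: ConcentrationField,
                            source: EmissionSource,
                            params: DispersionParams) -> ConcentrationField:
    """Attenuate a field by ``exp(−k d / u)`` with distance from the source.

    ``d`` is the Euclidean distance in meters (cell distance times
    ``cell_length``).  With ``k = 0`` the field is returned unchanged in
    value; the source cell is always unchanged.
    """
    _check_source(source, params)
    if params.decay_rate == 0:
        return ConcentrationField(values=conc.values.copy(),
                                  source_ref=source)
    n = params.n_cells
    coords = np.arange(n, dtype=float)
    d_cells = np.hypot(coords[np.newaxis, :] - source.x0,
                       coords[:, np.newaxis] - source.y0)
    attenuation = np.exp(-params.decay_rate * d_cells * params.cell_length
                         / params.wind_speed)
    return ConcentrationField(values=conc.values * attenuation,
                              source_ref=source)


def concentration_field(source: EmissionSource,
                        params: DispersionParams) -> ConcentrationField:
    """Gaussian field with the decay term applied when ``decay_rate > 0``."""
    conc = gaussian_concentration(source, params)
    if params.decay_rate > 0:
        conc = apply_first_order_decay(conc, source, params)
    return conc


def default_decay_rate(params: DispersionParams) -> float:
    """A loss rate that competes substantially with dilution: e-folding
    distance of 50 cells (a quarter of the default domain)."""
    return params.wind_speed / (50.0 * params.cell_length)
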