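"""2D lattice substrate: grids, fields, occupancy masks, neighborhoods and diffusion.

Sites are addressed as ``(row, col)`` pairs; arrays are indexed ``values[row, col]``.
Concentrations are arbitrary units per site. The lattice spacing defaults to one
cell diameter (10 µm nominal); only the ratio ``D*dt/spacing**2`` matters to the
diffusion operator.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ConfigurationError, DomainError

__all__ = [
    "Grid",
    "ScalarField",
    "OccupancyMask",
    "neighbors",
    "diffuse",
    "stencil_weight",
]

#: Explicit 5-point stencil stability bound on D*dt/spacing**2.
STABILITY_LIMIT = 0.25


@dataclass(frozen=True)
class Grid:
    """Rectangular lattice geometry.

    Parameters
    ----------
    width, height:
        Number of sites along x (columns) and y (rows). Both must be >= 3.
    spacing:
        Physical length per site. Default 1.0 = one cell diameter.
    """

    width: int
    height: int
    spacing: float = 1.0

    def __post_init__(self) -> None:
        if self.width < 3 or self.height < 3:
            raise ConfigurationError(
                f"grid must be at least 3x3, got {self.width}x{self.height}"
            )
        if not self.spacing > 0:
            raise ConfigurationError(f"spacing must be > 0, got {self.spacing}")

    @property
    def shape(self) -> tuple[int, int]:
        return (self.height, self.width)

    def contains(self, site: tuple[int, int]) -> bool:
        r, c = site
        return 0 <= r < self.height and 0 <= c < self.width

    @property
    def center(self) -> tuple[int, int]:
        return (self.height // 2, self.width // 2)


_VON_NEUMANN = ((-1, 0), (1, 0), (0, -1), (0, 1))
_MOORE = ((-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1))


def neighbors(
    grid: Grid, site: tuple[int, int], scheme: str = "von_neumann"
) -> list[tuple[int, int]]:
    """In-bounds neighbors of ``site`` under the requested scheme.

    ``von_neumann`` returns up to 4 edge-sharing sites, ``moore`` up to 8
    edge-or-corner-sharing sites; sites on grid edges return fewer.
    """
    if not grid.contains(site):
        raise DomainError(f"site {site} outside {grid.height}x{grid.width} grid")
    if scheme == "von_neumann":
        offsets = _VON_NEUMANN
    elif scheme == "moore":
        offsets = _MOORE
    else:
        raise ConfigurationError(f"unknown neighborhood scheme {scheme!r}")
    r, c = site
    out = []
    for dr, dc in offsets:
        s = (r + dr, c + dc)
        if grid.contains(s):
            out.append(s)
    return out


@dataclass
class ScalarField:
    """Non-negative per-site concentration field."""

    grid: Grid
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.shape != self.grid.shape:
            raise ConfigurationError(
                f"field shape {self.values.shape} != grid shape {self.grid.shape}"
            )
        if not np.all(np.isfinite(self.values)):
            raise ConfigurationError("field values must be finite")
        if np.any(self.values < 0):
            raise ConfigurationError("field values must be >= 0")

    @classmethod
    def zeros(cls, grid: Grid) -> "ScalarField":
        return cls(grid, np.zeros(grid.shape))

    def total(self) -> float:
        """Total summed concentration over the grid."""
        return float(self.values.sum())

    def copy(self) -> "ScalarField":
        return ScalarField(self.grid, self.values.copy())


@dataclass
class OccupancyMask:
    """Boolean tumor-occupancy mask; True sites carry a tumor cell."""

    grid: Grid
    occupied: np.ndarray

    def __post_init__(self) -> None:
        self.occupied = np.asarray(self.occupied, dtype=bool)
        if self.occupied.shape != self.grid.shape:
            raise ConfigurationError(
                f"mask shape {self.occupied.shape} != grid shape {self.grid.shape}"
            )

    @classmethod
    def empty(cls, grid: Grid) -> "OccupancyMask":
        return cls(grid, np.zeros(grid.shape, dtype=bool))

    @classmethod
    def single(cls, grid: Grid, site: tuple[int, int] | None = None) -> "OccupancyMask":
        m = cls.empty(grid)
        m.occupied[site if site is not None else grid.center] = True
        return m

    def count(self) -> int:
        return int(self.occupied.sum())

    def copy(self) -> "OccupancyMask":
        return OccupancyMask(self.grid, self.occupied.copy())


def stencil_weight(D: float, dt: float, spacing: float) -> float:
    """The dimensionless stencil weight a = D*dt/spacing**2, validated for stability."""
    a = D * dt / spacing**2
    if a > STABILITY_LIMIT:
        raise ConfigurationError(
            f"diffusion unstable: D*dt/spacing^2 = {a:.6g} exceeds {STABILITY_LIMIT}"
            f" (D={D}, dt={dt}, spacing={spacing})"
        )
    if a < 0:
        raise ConfigurationError(f"D*dt/spacing^2 must be >= 0, got {a}")
    return a


def diffuse(field: ScalarField, D: float, dt: float) -> ScalarField:
    """One explicit forward-Euler step of the 5-point diffusion stencil.

    Zero-flux (reflecting) boundaries: fluxes are exchanged only between
    in-bounds von Neumann neighbor pairs, so total mass is conserved to
    rounding error. With ``a = D*dt/spacing**2 <= 0.25`` the update is a convex
    combination of a site and its neighbors, hence monotone-smoothing.
    """
    a = stencil_weight(D, dt, field.grid.spacing)
    c = field.values
    lap = np.zeros_like(c)
    # pairwise antisymmetric fluxes => exact conservation on the closed grid
    lap[1:, :] += c[:-1, :] - c[1:, :]
    lap[:-1, :] += c[1:, :] - c[:-1, :]
    lap[:, 1:] += c[:, :-1] - c[:, 1:]
    lap[:, :-1] += c[:, 1:] - c[:, :-1]
    out = c + a * lap
    np.maximum(out, 0.0, out=out)  # guard against -0.0 / rounding
    return ScalarField(field.grid, out)
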