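"""Cellular-automata stage: stochastic tumor growth with secretion, diffusion and
deposition of a secreted protein (PAI-1) on the available (cell-free) matrix.

One tick is 1 min nominal. Within a tick the process order is fixed:
grow -> secrete -> diffuse -> deposit -> decay-to-latent. A single seeded RNG
stream drives every stochastic choice, so identical seeds give identical runs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .errors import ConfigurationError, DomainError, RunError
from .lattice import Grid, OccupancyMask, ScalarField, diffuse, stencil_weight

__all__ = [
    "CARates",
    "MatrixGrid",
    "grow_tumor_step",
    "secrete",
    "deposit",
    "decay_to_latent",
    "run_ca",
    "disk_mask_with_count",
    "paired_disk_control",
    "periphery_values",
    "CAResult",
    "CheckpointSnapshot",
]

_CROSS = ndimage.generate_binary_structure(2, 1)  # 4-connectivity
_MOORE_OFFSETS = np.array(
    [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]
)

#: active->latent conversion rate per tick; half-life 30,000 ticks (= 500 h at
#: 1 tick = 1 min), matching the stability horizon of the engineered stable
#: PAI-1 form used experimentally.
DEFAULT_K_LAT = math.log(2) / 30_000


@dataclass(frozen=True)
class CARates:
    """Per-tick rates of the CA stage.

    sigma
        secretion per cell per tick (concentration units).
    D
        diffusivity of soluble PAI-1 (length^2 per tick).
    k_on
        deposition rate per tick: fraction of local soluble PAI-1 binding to
        cell-free matrix each tick, capped by remaining VN capacity.
    k_lat
        active->latent conversion rate per tick.
    p_div
        division probability per peripheral cell per tick.
    """

    sigma: float = 1.0
    D: float = 0.2
    k_on: float = 0.2
    k_lat: float = DEFAULT_K_LAT
    p_div: float = 0.1

    def __post_init__(self) -> None:
        for name in ("sigma", "D", "k_on", "k_lat", "p_div"):
            v = getattr(self, name)
            if v < 0:
                raise ConfigurationError(f"rate {name} must be >= 0, got {v}")
        if self.p_div > 1:
            raise ConfigurationError(f"p_div must be <= 1, got {self.p_div}")


@dataclass
class MatrixGrid:
    """Per-site extracellular matrix state.

    ``bound_active`` and ``bound_latent`` are matrix-bound PAI-1 pools;
    their sum never exceeds ``vn_capacity`` (vitronectin binding capacity).
    ``integrity`` in [0, 1] tracks proteolytic matrix damage (1 = intact).
    """

    grid: Grid
    bound_active: np.ndarray
    bound_latent: np.ndarray
    vn_capacity: np.ndarray
    integrity: np.ndarray

    def __post_init__(self) -> None:
        for name in ("bound_active", "bound_latent", "vn_capacity", "integrity"):
            arr = np.asarray(getattr(self, name), dtype=np.float64)
            if arr.shape != self.grid.shape:
                raise ConfigurationError(f"{name} shape {arr.shape} != grid shape")
            setattr(self, name, arr)
        if np.any(self.bound_active < 0) or np.any(self.bound_latent < 0):
            raise ConfigurationError("bound PAI-1 pools must be >= 0")
        if np.any(self.integrity < 0) or np.any(self.integrity > 1):
            raise ConfigurationError("integrity must lie in [0, 1]")
        if np.any(self.bound_active + self.bound_latent > self.vn_capacity * (1 + 1e-12)):
            raise ConfigurationError("bound PAI-1 exceeds VN capacity")

    @classmethod
    def uniform(
        cls, grid: Grid, capacity: float = np.inf, integrity: float = 1.0
    ) -> "MatrixGrid":
        z = np.zeros(grid.shape)
        return cls(
            grid,
            z.copy(),
            z.copy(),
            np.full(grid.shape, capacity, dtype=np.float64),
            np.full(grid.shape, integrity, dtype=np.float64),
        )

    def total_bound(self) -> float:
        return float(self.bound_active.sum() + self.bound_latent.sum())

    def copy(self) -> "MatrixGrid":
        return MatrixGrid(
            self.grid,
            self.bound_active.copy(),
            self.bound_latent.copy(),
            self.vn_capacity.copy(),
            self.integrity.copy(),
        )


def grow_tumor_step(
    mask: OccupancyMask,
    p_div: float,
    rng: np.random.Generator,
    max_new: int | None = None,
) -> tuple[OccupancyMask, list[tuple[int, int]]]:
    """One Eden-type growth step.

    Each occupied site with at least one empty Moore neighbor divides with
    probability ``p_div`` into one uniformly chosen empty Moore neighbor.
    Divisions are resolved sequentially in RNG-shuffled order so no empty site
    is claimed twice. ``max_new`` caps the number of new cells this step (used
    to land checkpoints exactly). Returns the new mask and the new sites.
    """
    if mask.count() == 0:
        raise DomainError("cannot grow an empty tumor mask")
    if not 0 <= p_div <= 1:
        raise ConfigurationError(f"p_div must be in [0, 1], got {p_div}")
    occ = mask.occupied.copy()
    h, w = occ.shape
    if p_div == 0 or max_new == 0:
        return OccupancyMask(mask.grid, occ), []

    dilated = ndimage.binary_dilation(~occ, structure=np.ones((3, 3), bool))
    frontier = np.argwhere(occ & dilated)  # occupied with >=1 empty Moore neighbor
    order = rng.permutation(len(frontier))
    new_sites: list[tuple[int, int]] = []
    for idx in order:
        if max_new is not None and len(new_sites) >= max_new:
            break
        if rng.random() >= p_div:
            continue
        r, c = frontier[idx]
        cand = []
        for dr, dc in _MOORE_OFFSETS:
            rr, cc = r + dr, c + dc
            if 0 <= rr < h and 0 <= cc < w and not occ[rr, cc]:
                cand.append((rr, cc))
        if not cand:  # neighbors may have filled earlier this step
            continue
        site = cand[rng.integers(len(cand))]
        occ[site] = True
        new_sites.append(site)
    return OccupancyMask(mask.grid, occ), new_sites


def secrete(mask: OccupancyMask, soluble: ScalarField, sigma: float) -> ScalarField:
    """Add ``sigma`` units of soluble PAI-1 at every occupied site."""
    if sigma < 0:
        raise ConfigurationError(f"secretion rate must be >= 0, got {sigma}")
    out = soluble.values.copy()
    out[mask.occupied] += sigma
    return ScalarField(soluble.grid, out)


def deposit(
    soluble: ScalarField,
    matrix: MatrixGrid,
    mask: OccupancyMask,
    k_on: float,
) -> tuple[ScalarField, MatrixGrid, int]:
    """Move soluble PAI-1 into the bound-active pool on available matrix.

    At each cell-free site an amount ``min(k_on * soluble, soluble, remaining
    capacity)`` transfers from the soluble field to ``bound_active``. Matrix
    under an occupied site is unavailable and receives nothing. Returns the new
    field, new matrix, and the number of capacity-saturated cell-free sites.
    """
    if k_on < 0:
        raise ConfigurationError(f"k_on must be >= 0, got {k_on}")
    s = soluble.values
    cap_rem = matrix.vn_capacity - (matrix.bound_active + matrix.bound_latent)
    np.maximum(cap_rem, 0.0, out=cap_rem)
    transfer = np.minimum(np.minimum(k_on * s, s), cap_rem)
    transfer[mask.occupied] = 0.0
    new_m = matrix.copy()
    new_m.bound_active += transfer
    n_sat = int(np.count_nonzero((cap_rem <= 0) & ~mask.occupied & (s > 0)))
    return ScalarField(soluble.grid, s - transfer), new_m, n_sat


def decay_to_latent(matrix: MatrixGrid, k_lat: float, dt: float = 1.0) -> MatrixGrid:
    """Convert a fraction ``k_lat*dt`` of bound-active PAI-1 to the latent pool."""
    f = k_lat * dt
    if f < 0 or f >= 1:
        raise ConfigurationError(f"k_lat*dt must lie in [0, 1), got {f}")
    new_m = matrix.copy()
    moved = f * new_m.bound_active
    new_m.bound_active -= moved
    new_m.bound_latent += moved
    return new_m


def periphery_values(mask: OccupancyMask, field: ScalarField) -> np.ndarray:
    """Field values on the unordered periphery (cell-free sites 4-adjacent to tumor)."""
    halo = ndimage.binary_dilation(mask.occupied, structure=_CROSS) & ~mask.occupied
    return field.values[halo]


def _periphery_stats(mask: OccupancyMask, bound: ScalarField) -> dict:
    v = periphery_values(mask, bound)
    if v.size == 0 or v.mean() == 0:
        return {"periph_mean": 0.0, "periph_max": 0.0, "periph_cv": 0.0}
    return {
        "periph_mean": float(v.mean()),
        "periph_max": float(v.max()),
        "periph_cv": float(v.std() / v.mean()),
    }


def disk_mask_with_count(
    grid: Grid, n: int, center: tuple[int, int] | None = None
) -> OccupancyMask:
    """Deterministic quasi-disk of exactly ``n`` sites around ``center``.

    Sites are added in order of (squared distance, angle, row, col), giving the
    most nearly circular deterministic shape of a given cell count — the
    matched control against stochastic Eden growth.
    """
    if n < 1:
        raise DomainError(f"disk needs >= 1 site, got {n}")
    cr, cc = center if center is not None else grid.center
    rr, cc_ = np.mgrid[0 : grid.height, 0 : grid.width]
    dr, dc = rr - cr, cc_ - cc
    d2 = dr**2 + dc**2
    ang = np.arctan2(dr, dc)
    flat = np.lexsort((cc_.ravel(), rr.ravel(), ang.ravel(), d2.ravel()))
    if n > flat.size:
        raise DomainError(f"grid too small for {n} sites")
    occ = np.zeros(grid.shape, bool)
    occ.ravel()[flat[:n]] = True
    return OccupancyMask(grid, occ)


@dataclass
class CheckpointSnapshot:
    """State captured when the tumor reaches a configured cell count."""

    size: int
    tick: int
    mask: OccupancyMask
    bound: ScalarField  # bound_active + bound_latent surface
    stats: dict


@dataclass
class CAResult:
    checkpoints: list[CheckpointSnapshot]
    mask: OccupancyMask
    soluble: ScalarField
    matrix: MatrixGrid
    summary: dict
    log: list[dict]
    seed: int | None


def run_ca(
    rates: CARates,
    grid: Grid | None = None,
    seed: int | None = 0,
    checkpoints: tuple[int, ...] | None = (10, 100, 500),
    ticks: int | None = None,
    initial_mask: OccupancyMask | None = None,
    matrix: MatrixGrid | None = None,
    growth: str = "stochastic",
    count_trajectory: np.ndarray | None = None,
    step_cap: int = 20_000,
    record_log: bool = True,
) -> CAResult:
    """Run the CA until all checkpoints are reached (or for ``ticks`` ticks).

    ``growth`` is one of:

    - ``"stochastic"``: Eden-type random growth (default);
    - ``"disk"``: deterministic quasi-disk growth replaying ``count_trajectory``
      (cell count per tick), the matched control for heterogeneity comparisons;
    - ``"static"``: no growth (requires ``ticks``), used for deposition on a
      fixed mask such as an invaginated seed shape.

    Checkpoints are hit exactly: within a growth step divisions stop once the
    next checkpoint count is reached. Snapshots capture the bound PAI-1 surface
    (active + latent), the mask, and periphery statistics after the full tick.
    """
    if growth not in ("stochastic", "disk", "static"):
        raise ConfigurationError(f"unknown growth mode {growth!r}")
    if grid is None:
        grid = initial_mask.grid if initial_mask is not None else Grid(64, 64)
    stencil_weight(rates.D, 1.0, grid.spacing)  # validate stability up front
    rng = np.random.default_rng(seed)
    mask = initial_mask.copy() if initial_mask is not None else OccupancyMask.single(grid)
    if mask.count() == 0:
        raise DomainError("initial mask is empty")
    soluble = ScalarField.zeros(grid)
    mat = matrix.copy() if matrix is not None else MatrixGrid.uniform(grid)
    secreted_total = mat.total_bound() + soluble.total()  # pre-loaded mass counts

    cps = sorted(checkpoints) if checkpoints else []
    if growth == "static" and cps:
        cps = []
    if cps and cps[0] < mask.count():
        raise ConfigurationError(
            f"first checkpoint {cps[0]} below initial size {mask.count()}"
        )
    snapshots: list[CheckpointSnapshot] = []
    log: list[dict] = []
    next_cp = 0

    def bound_surface() -> ScalarField:
        return ScalarField(grid, mat.bound_active + mat.bound_latent)

    def take_snapshot(tick: int) -> None:
        b = bound_surface()
        snapshots.append(
            CheckpointSnapshot(
                size=mask.count(),
                tick=tick,
                mask=mask.copy(),
                bound=b,
                stats={
                    "total_secreted": secreted_total,
                    "total_soluble": soluble.total(),
                    "total_bound": mat.total_bound(),
                    **_periphery_stats(mask, b),
                },
            )
        )

    # checkpoint equal to the initial size is captured before any tick
    while next_cp < len(cps) and mask.count() == cps[next_cp]:
        take_snapshot(0)
        next_cp += 1

    tick = 0
    while True:
        if cps:
            if next_cp >= len(cps):
                break
        elif ticks is None:
            raise ConfigurationError("either checkpoints or ticks must be given")
        elif tick >= ticks:
            break
        if tick >= step_cap:
            raise RunError(
                f"step cap {step_cap} reached before checkpoint {cps[next_cp]}"
                f" (current size {mask.count()}, p_div={rates.p_div})"
            )
        tick += 1
        # 1. grow
        if growth == "stochastic":
            cap = cps[next_cp] - mask.count() if next_cp < len(cps) else None
            mask, new_sites = grow_tumor_step(mask, rates.p_div, rng, max_new=cap)
        elif growth == "disk":
            if count_trajectory is None:
                raise ConfigurationError("disk growth requires count_trajectory")
            i = min(tick - 1, len(count_trajectory) - 1)
            mask = disk_mask_with_count(grid, int(count_trajectory[i]))
            new_sites = []
        else:
            new_sites = []
        # 2. secrete
        soluble = secrete(mask, soluble, rates.sigma)
        secreted_total += rates.sigma * mask.count()
        # 3. diffuse
        soluble = diffuse(soluble, rates.D, 1.0)
        # 4. deposit
        soluble, mat, n_sat = deposit(soluble, mat, mask, rates.k_on)
        # 5. latency decay
        mat = decay_to_latent(mat, rates.k_lat, 1.0)
        if record_log:
            log.append(
                {
                    "tick": tick,
                    "n_cells": mask.count(),
                    "n_new": len(new_sites),
                    "n_saturated": n_sat,
                    "secreted_total": secreted_total,
                    "soluble_total": soluble.total(),
                    "bound_total": mat.total_bound(),
                }
            )
        while next_cp < len(cps) and mask.count() >= cps[next_cp]:
            take_snapshot(tick)
            next_cp += 1

    b = bound_surface()
    summary = {
        "seed": seed,
        "ticks": tick,
        "n_cells": mask.count(),
        "total_secreted": secreted_total,
        "total_soluble": soluble.total(),
        "total_bound": mat.total_bound(),
        "mass_balance_rel_error": _mass_balance_rel_error(
            secreted_total, soluble.total() + mat.total_bound()
        ),
        **_periphery_stats(mask, b),
    }
    return CAResult(snapshots, mask, soluble, mat, summary, log, seed)


def _mass_balance_rel_error(secreted: float, accounted: float) -> float:
    if secreted == 0:
        return abs(accounted)
    return abs(secreted - accounted) / secreted


def paired_disk_control(result: CAResult, rates: CARates) -> CAResult:
    """Deterministic quasi-disk control matched tick-for-tick to a stochastic run.

    Replays the stochastic run's cell-count trajectory as deterministic disks,
    with identical secretion/diffusion/deposition, isolating the contribution
    of stochastic boundary history to peripheral heterogeneity.
    """
    if not result.log:
        raise ConfigurationError("stochastic run must carry a per-tick log")
    traj = np.array([row["n_cells"] for row in result.log])
    return run_ca(
        rates,
        grid=result.mask.grid,
        seed=result.seed,
        checkpoints=None,
        ticks=len(traj),
        growth="disk",
        count_trajectory=traj,
        record_log=False,
    )
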