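"""Agent-based stage: tumor cells on the lattice with the full PAI-1 cycle.

Each agent carries the bistable adhesion switch of :mod:`.switch`, driven by
the matrix-bound active PAI-1 at its own site. Per tick, in fixed order:
proliferation (mesenchymal only) -> secretion -> diffusion -> deposition ->
switch update -> movement -> consumption (amoeboid only) -> proteolysis
(mesenchymal only) -> latency decay. Agent iteration order is shuffled each
tick by the seeded RNG; identical seeds give byte-identical event logs.

Amoeboid cells "hive": they flip at a high-PAI-1 spot (MAT), internalize the
bound protein via [uPAR:uPA:PAI-1] complexes until the local concentration
drops below the lower threshold, then revert (AMT).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .ca import (
    CARates,
    MatrixGrid,
    decay_to_latent,
    deposit,
    disk_mask_with_count,
    periphery_values,
    secrete,
)
from .errors import ConfigurationError, ContractViolationError, DomainError
from .lattice import Grid, OccupancyMask, ScalarField, diffuse, stencil_weight
from .switch import SwitchParams, SwitchState, step_switch_arrays

__all__ = [
    "CellAgent",
    "ABMRates",
    "EventLog",
    "World",
    "make_world",
    "consume",
    "proteolyse",
    "move",
    "step_world",
    "run_abm",
    "run_single_cell_spot",
    "ABMResult",
]

_MOORE_OFFSETS = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]

#: Default amoeboid speed in sites per tick: 0.4 µm/min over 10 µm sites at
#: 1-min ticks = 0.04, realized as a per-tick move probability.
DEFAULT_SPEED = 0.04


@dataclass(frozen=True)
class ABMRates(CARates):
    """CA rates plus the agent-level PAI-1 cycle rates.

    k_int
        bound-active PAI-1 internalized ("consumed") per amoeboid cell per
        tick; the internalized mass leaves the system.
    k_prot
        matrix-integrity degradation per mesenchymal cell per tick.
    p_div_mes
        division probability per mesenchymal cell with an empty Moore
        neighbor per tick (amoeboid cells do not divide).
    integrity_threshold
        mesenchymal cells may step only onto matrix with integrity below this
        (proteolytic path-making); 0 disables mesenchymal movement.
    speed_amoeboid
        amoeboid moves per tick; fractional values are move probabilities.
    """

    k_int: float = 0.5
    k_prot: float = 0.005
    p_div_mes: float = 0.1
    integrity_threshold: float = 0.5
    speed_amoeboid: float = DEFAULT_SPEED

    def __post_init__(self) -> None:
        super().__post_init__()
        for name in ("k_int", "k_prot", "speed_amoeboid"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be >= 0")
        if not 0 <= self.p_div_mes <= 1:
            raise ConfigurationError("p_div_mes must be in [0, 1]")
        if not 0 <= self.integrity_threshold <= 1:
            raise ConfigurationError("integrity_threshold must be in [0, 1]")


@dataclass
class CellAgent:
    """One tumor cell: lattice position plus adhesion-switch state."""

    id: int
    r: int
    c: int
    I: float
    P: float
    upar_available: bool = True
    age: int = 0

    @property
    def label(self) -> str:
        return "amoeboid" if self.P > self.I else "mesenchymal"

    @property
    def position(self) -> tuple[int, int]:
        return (self.r, self.c)


class EventLog:
    """Append-only tick-stamped record of divisions, flips, moves, consumption,
    proteolysis and escapes."""

    def __init__(self) -> None:
        self.records: list[dict] = []

    def add(self, tick: int, event: str, agent: int, site: tuple[int, int], amount: float = 0.0) -> None:
        self.records.append(
            {"tick": tick, "event": event, "agent": agent, "r": site[0], "c": site[1], "amount": amount}
        )

    def of_type(self, event: str) -> list[dict]:
        return [r for r in self.records if r["event"] == event]

    def total_amount(self, event: str) -> float:
        return float(sum(r["amount"] for r in self.of_type(event)))

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.records, columns=["tick", "event", "agent", "r", "c", "amount"]
        )

    def __len__(self) -> int:
        return len(self.records)


@dataclass
class World:
    grid: Grid
    mask: OccupancyMask
    soluble: ScalarField
    matrix: MatrixGrid
    agents: list[CellAgent]
    sparams: SwitchParams
    tick: int = 0
    secreted_total: float = 0.0
    consumed_total: float = 0.0
    preloaded_total: float = 0.0
    log: EventLog = field(default_factory=EventLog)
    _next_id: int = 0
    _escaped: set[int] = field(default_factory=set)

    def amoeboid_fraction(self) -> float:
        if not self.agents:
            return 0.0
        return sum(a.label == "amoeboid" for a in self.agents) / len(self.agents)

    def mass_balance_rel_error(self) -> float:
        """Relative error of the full PAI-1 ledger:
        preloaded + secreted = soluble + bound_active + bound_latent + consumed."""
        lhs = self.preloaded_total + self.secreted_total
        rhs = self.soluble.total() + self.matrix.total_bound() + self.consumed_total
        if lhs == 0:
            return abs(rhs)
        return abs(lhs - rhs) / lhs


def make_world(
    initial_mask: OccupancyMask,
    sparams: SwitchParams | None = None,
    matrix: MatrixGrid | None = None,
) -> World:
    """World with one mesenchymal-rest agent per occupied site."""
    if initial_mask.count() == 0:
        raise DomainError("initial mask is empty")
    grid = initial_mask.grid
    sparams = sparams if sparams is not None else SwitchParams()
    rest = SwitchState.mesenchymal_rest(sparams)
    agents = [
        CellAgent(i, int(r), int(c), rest.I, rest.P)
        for i, (r, c) in enumerate(np.argwhere(initial_mask.occupied))
    ]
    mat = matrix.copy() if matrix is not None else MatrixGrid.uniform(grid)
    w = World(
        grid=grid,
        mask=initial_mask.copy(),
        soluble=ScalarField.zeros(grid),
        matrix=mat,
        agents=agents,
        sparams=sparams,
    )
    w.preloaded_total = mat.total_bound()
    w._next_id = len(agents)
    return w


def consume(cell: CellAgent, matrix: MatrixGrid, k_int: float) -> tuple[MatrixGrid, float]:
    """Internalize up to ``k_int`` bound-active PAI-1 at the cell's site.

    Only amoeboid cells with available uPAR form the [uPAR:uPA:PAI-1]
    complexes that drive internalization; the removed mass leaves the system
    (lysosomal degradation). The latent pool is untouched.
    """
    if cell.label != "amoeboid":
        raise ContractViolationError(
            f"consume called on {cell.label} agent {cell.id}; only amoeboid cells consume"
        )
    if not cell.upar_available:
        raise ContractViolationError(f"agent {cell.id} has no available uPAR")
    amount = float(min(k_int, matrix.bound_active[cell.r, cell.c]))
    new_m = matrix.copy()
    new_m.bound_active[cell.r, cell.c] -= amount
    return new_m, amount


def proteolyse(cell: CellAgent, matrix: MatrixGrid, k_prot: float) -> MatrixGrid:
    """Degrade matrix integrity at a mesenchymal cell's site by ``k_prot``.

    Amoeboid migration requires no pericellular proteolysis, so amoeboid
    agents must never call this.
    """
    if cell.label != "mesenchymal":
        raise ContractViolationError(
            f"proteolyse called on {cell.label} agent {cell.id}; only mesenchymal cells proteolyse"
        )
    new_m = matrix.copy()
    new_m.integrity[cell.r, cell.c] = max(0.0, new_m.integrity[cell.r, cell.c] - k_prot)
    return new_m


def _empty_moore(occ: np.ndarray, r: int, c: int) -> list[tuple[int, int]]:
    h, w = occ.shape
    return [
        (r + dr, c + dc)
        for dr, dc in _MOORE_OFFSETS
        if 0 <= r + dr < h and 0 <= c + dc < w and not occ[r + dr, c + dc]
    ]


def move(
    cell: CellAgent,
    world: World,
    rates: ABMRates,
    rng: np.random.Generator,
) -> bool:
    """Attempt one tick's movement for ``cell``; returns True if it moved.

    Amoeboid cells greedily ascend the bound-active field: they step (with
    probability ``speed_amoeboid`` when < 1, else that many steps) onto the
    empty Moore neighbor with the highest bound-active PAI-1, ties uniform.
    Mesenchymal cells step at most once onto an empty neighbor whose matrix
    integrity is below ``integrity_threshold`` (a proteolysed path).
    """
    occ = world.mask.occupied
    moved = False
    if cell.label == "amoeboid":
        speed = rates.speed_amoeboid
        n_moves = int(speed) + (1 if rng.random() < speed - int(speed) else 0)
        for _ in range(n_moves):
            cands = _empty_moore(occ, cell.r, cell.c)
            if not cands:
                break
            vals = np.array([world.matrix.bound_active[s] for s in cands])
            best = np.flatnonzero(vals == vals.max())
            target = cands[best[rng.integers(len(best))]]
            occ[cell.r, cell.c] = False
            cell.r, cell.c = target
            occ[cell.r, cell.c] = True
            moved = True
    else:
        cands = [
            s
            for s in _empty_moore(occ, cell.r, cell.c)
            if world.matrix.integrity[s] < rates.integrity_threshold
        ]
        if cands:
            target = cands[rng.integers(len(cands))]
            occ[cell.r, cell.c] = False
            cell.r, cell.c = target
            occ[cell.r, cell.c] = True
            moved = True
    return moved


def _update_switches(world: World, rng: np.random.Generator, n_sub: int = 5, dt: float = 0.2) -> None:
    """Vectorized switch update for the whole population from local bound_active."""
    if not world.agents:
        return
    I = np.array([a.I for a in world.agents])
    P = np.array([a.P for a in world.agents])
    rows = np.array([a.r for a in world.agents])
    cols = np.array([a.c for a in world.agents])
    C = world.matrix.bound_active[rows, cols]
    before = P > I
    for _ in range(n_sub):
        I, P = step_switch_arrays(I, P, C, world.sparams, dt, rng)
    after = P > I
    for i, a in enumerate(world.agents):
        a.I, a.P = float(I[i]), float(P[i])
        if after[i] and not before[i]:
            world.log.add(world.tick, "flip_MAT", a.id, a.position)
        elif before[i] and not after[i]:
            world.log.add(world.tick, "flip_AMT", a.id, a.position)


def step_world(world: World, rates: ABMRates, rng: np.random.Generator, escape_distance: float = 3.0) -> None:
    """Advance the world by one tick (fixed process order, shuffled agents)."""
    world.tick += 1
    tick = world.tick
    order = rng.permutation(len(world.agents))

    # 1. proliferation: mesenchymal cells with an empty Moore neighbor
    for i in order:
        a = world.agents[i]
        if a.label != "mesenchymal" or rates.p_div_mes == 0:
            continue
        if rng.random() >= rates.p_div_mes:
            continue
        cands = _empty_moore(world.mask.occupied, a.r, a.c)
        if not cands:
            continue
        site = cands[rng.integers(len(cands))]
        child = CellAgent(world._next_id, site[0], site[1], a.I, a.P)
        world._next_id += 1
        world.agents.append(child)
        world.mask.occupied[site] = True
        world.log.add(tick, "divide", a.id, site)

    # 2. secretion (all cells)
    world.soluble = secrete(world.mask, world.soluble, rates.sigma)
    world.secreted_total += rates.sigma * world.mask.count()
    # 3. diffusion
    world.soluble = diffuse(world.soluble, rates.D, 1.0)
    # 4. deposition on cell-free matrix
    world.soluble, world.matrix, _ = deposit(world.soluble, world.matrix, world.mask, rates.k_on)
    # 5. per-cell switch update from local bound_active
    _update_switches(world, rng)
    # 6. movement
    order = rng.permutation(len(world.agents))
    for i in order:
        a = world.agents[i]
        if move(a, world, rates, rng):
            world.log.add(tick, "move", a.id, a.position)
    # 7. consumption (amoeboid only; in-place application of the consume rule)
    if rates.k_int > 0:
        ba = world.matrix.bound_active
        for i in order:
            a = world.agents[i]
            if a.label == "amoeboid" and a.upar_available:
                amount = float(min(rates.k_int, ba[a.r, a.c]))
                if amount > 0:
                    ba[a.r, a.c] -= amount
                    world.consumed_total += amount
                    world.log.add(tick, "consume", a.id, a.position, amount)
    # 8. proteolysis (mesenchymal only; in-place application of the proteolyse rule)
    if rates.k_prot > 0:
        integ = world.matrix.integrity
        for i in order:
            a = world.agents[i]
            if a.label == "mesenchymal":
                delta = float(min(rates.k_prot, integ[a.r, a.c]))
                if delta > 0:
                    integ[a.r, a.c] -= delta
                    world.log.add(tick, "proteolyse", a.id, a.position, delta)
    # 9. latency decay
    world.matrix = decay_to_latent(world.matrix, rates.k_lat, 1.0)

    for a in world.agents:
        a.age += 1

    # escape detection: amoeboid cells far from the mesenchymal tumor body
    _detect_escapes(world, escape_distance)


def _detect_escapes(world: World, escape_distance: float) -> None:
    mes = np.zeros(world.grid.shape, bool)
    any_mes = False
    for a in world.agents:
        if a.label == "mesenchymal":
            mes[a.r, a.c] = True
            any_mes = True
    if not any_mes:
        return
    dist = ndimage.distance_transform_edt(~mes)
    for a in world.agents:
        if a.label == "amoeboid" and a.id not in world._escaped:
            if dist[a.r, a.c] > escape_distance:
                world._escaped.add(a.id)
                world.log.add(world.tick, "escape", a.id, a.position, float(dist[a.r, a.c]))


@dataclass
class ABMResult:
    world: World
    snapshots: list[dict]
    amoeboid_fraction: np.ndarray  # per tick
    population: np.ndarray  # per tick
    summary: dict

    @property
    def log(self) -> EventLog:
        return self.world.log


def run_abm(
    rates: ABMRates | None = None,
    sparams: SwitchParams | None = None,
    grid: Grid | None = None,
    initial_mask: OccupancyMask | None = None,
    matrix: MatrixGrid | None = None,
    ticks: int = 250,
    seed: int | None = 0,
    snapshot_every: int | None = None,
    initial_cells: int = 1,
    escape_distance: float = 3.0,
) -> ABMResult:
    """Run the agent-based model for ``ticks`` ticks.

    The default world is a single mesenchymal cell at the center of a 72x72
    grid, growing into a tumor of a few thousand cells over the default 250
    ticks. Deterministic given ``seed``. Snapshots capture the bound PAI-1
    surface, mask and per-agent states every ``snapshot_every`` ticks (plus
    the initial state).
    """
    rates = rates if rates is not None else ABMRates()
    grid = grid if grid is not None else (initial_mask.grid if initial_mask is not None else Grid(72, 72))
    stencil_weight(rates.D, 1.0, grid.spacing)
    if initial_mask is None:
        initial_mask = disk_mask_with_count(grid, initial_cells)
    world = make_world(initial_mask, sparams, matrix)
    rng = np.random.default_rng(seed)

    snapshots: list[dict] = []

    def snap() -> None:
        snapshots.append(
            {
                "tick": world.tick,
                "mask": world.mask.copy(),
                "bound": ScalarField(grid, world.matrix.bound_active + world.matrix.bound_latent),
                "labels": {a.id: a.label for a in world.agents},
            }
        )

    if snapshot_every is not None:
        snap()
    frac = np.empty(ticks)
    pop = np.empty(ticks, dtype=int)
    for t in range(ticks):
        step_world(world, rates, rng, escape_distance)
        frac[t] = world.amoeboid_fraction()
        pop[t] = len(world.agents)
        if snapshot_every is not None and world.tick % snapshot_every == 0:
            snap()

    periph = periphery_values(
        world.mask, ScalarField(grid, world.matrix.bound_active)
    )
    summary = {
        "seed": seed,
        "ticks": ticks,
        "population": len(world.agents),
        "amoeboid_fraction_final": float(frac[-1]) if ticks else 0.0,
        "amoeboid_fraction_max": float(frac.max()) if ticks else 0.0,
        "total_secreted": world.secreted_total,
        "total_consumed": world.consumed_total,
        "n_escapes": len(world._escaped),
        "mass_balance_rel_error": world.mass_balance_rel_error(),
        "periph_mean": float(periph.mean()) if periph.size else 0.0,
        "periph_max": float(periph.max()) if periph.size else 0.0,
    }
    return ABMResult(world, snapshots, frac, pop, summary)


def run_single_cell_spot(
    preload: float = 20.0,
    spot_radius: int = 1,
    k_int: float = 0.5,
    ticks: int = 400,
    seed: int | None = 0,
    sparams: SwitchParams | None = None,
) -> ABMResult:
    """The hiving-cycle scenario: one cell on a pre-loaded high-PAI-1 spot.

    A single mesenchymal cell sits at the center of a small grid whose matrix
    carries ``preload`` bound-active PAI-1 (well above theta_up for the
    default switch) within ``spot_radius`` of the center. Secretion and
    division are off. With k_int > 0 the expected event sequence is
    flip_MAT -> consume -> flip_AMT; with k_int = 0 the reversal never occurs.
    """
    grid = Grid(21, 21)
    sparams = sparams if sparams is not None else SwitchParams()
    mat = MatrixGrid.uniform(grid)
    rr, cc = np.mgrid[0 : grid.height, 0 : grid.width]
    cr, ccen = grid.center
    spot = (rr - cr) ** 2 + (cc - ccen) ** 2 <= spot_radius**2
    mat.bound_active[spot] = preload
    rates = ABMRates(sigma=0.0, p_div_mes=0.0, k_int=k_int, k_prot=0.0)
    return run_abm(
        rates=rates,
        sparams=sparams,
        grid=grid,
        initial_mask=OccupancyMask.single(grid),
        matrix=mat,
        ticks=ticks,
        seed=seed,
    )
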