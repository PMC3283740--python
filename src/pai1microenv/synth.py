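"""Synthetic-data generators with known ground truth.

Every generator returns its output together with a :class:`GenRecord` that
captures the generator name, parameters, seed and ground-truth summary —
enough to regenerate the dataset bit-exactly and to test the corresponding
pipeline stage against construction truth.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

from .errors import ConfigurationError, DomainError
from .imaging import DEFAULT_BACKGROUND, DEFAULT_THRESHOLD, WORKING_MAX, ChannelImage
from .lattice import Grid, OccupancyMask
from .switch import SwitchParams, SwitchState, step_switch_arrays

__all__ = [
    "ShapeSpec",
    "GenRecord",
    "make_tumor_mask",
    "make_coloc_pair",
    "make_zstack",
    "make_morph_timecourse",
    "triangular_c_path",
]

_MOORE = np.ones((3, 3), bool)


@dataclass(frozen=True)
class ShapeSpec:
    """Specification of a synthetic tumor shape.

    ``kind="disk"`` gives a convex discretized disk; ``kind="lobed"`` modulates
    the radius as ``r(phi) = radius * (1 - lobe_depth*(1 + cos(n_lobes*phi))/2)``,
    carving ``n_lobes`` concave invaginations into the outline.
    """

    kind: str = "disk"
    radius: int = 12
    n_lobes: int = 0
    lobe_depth: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in ("disk", "lobed"):
            raise ConfigurationError(f"kind must be disk|lobed, got {self.kind!r}")
        if self.radius < 3:
            raise ConfigurationError(f"radius must be >= 3, got {self.radius}")
        if not 0 <= self.lobe_depth < 1:
            raise ConfigurationError(f"lobe_depth must be in [0, 1), got {self.lobe_depth}")
        if self.n_lobes < 0:
            raise ConfigurationError(f"n_lobes must be >= 0, got {self.n_lobes}")
        if self.kind == "lobed" and (self.n_lobes == 0 or self.lobe_depth == 0):
            raise ConfigurationError("lobed shape needs n_lobes >= 1 and lobe_depth > 0")


@dataclass
class GenRecord:
    """Provenance record sufficient to regenerate a synthetic dataset."""

    generator: str
    params: dict
    seed: int
    ground_truth: dict

    def to_dict(self) -> dict:
        return {
            "generator": self.generator,
            "params": self.params,
            "seed": self.seed,
            "ground_truth": self.ground_truth,
        }


def make_tumor_mask(
    spec: ShapeSpec, grid: Grid | None = None
) -> tuple[OccupancyMask, GenRecord]:
    """Deterministic tumor occupancy mask for a shape specification.

    The mask is centered on the grid (default grid leaves a 4-site margin).
    Lobed shapes place their invaginations at angles ``2*pi*k/n_lobes``.
    """
    if grid is None:
        side = 2 * spec.radius + 9
        grid = Grid(side, side)
    cr, cc = grid.center
    rr, cc_ = np.mgrid[0 : grid.height, 0 : grid.width]
    dr = rr - cr
    dc = cc_ - cc
    dist = np.hypot(dr, dc)
    if spec.kind == "disk":
        occ = dist <= spec.radius
    else:
        phi = np.arctan2(dr, dc)
        r_phi = spec.radius * (1.0 - spec.lobe_depth * (1.0 + np.cos(spec.n_lobes * phi)) / 2.0)
        occ = dist <= r_phi
    if not occ.any():
        raise DomainError(f"shape spec {spec} produced an empty mask")
    lab, n = ndimage.label(occ, structure=_MOORE)
    if n > 1:  # keep the central component (deep lobes can pinch off slivers)
        occ = lab == lab[cr, cc]
    rec = GenRecord(
        "make_tumor_mask",
        {**asdict(spec), "grid": [grid.width, grid.height]},
        spec.seed,
        {"area": int(occ.sum()), "n_invaginations": spec.n_lobes if spec.kind == "lobed" else 0},
    )
    return OccupancyMask(grid, occ), rec


def make_coloc_pair(
    shape: tuple[int, int] = (160, 160),
    f_coloc: float = 0.3,
    n_pos: int = 10_000,
    threshold: float = DEFAULT_THRESHOLD,
    background: float = DEFAULT_BACKGROUND,
    seed: int = 0,
) -> tuple[ChannelImage, ChannelImage, GenRecord]:
    """Two-channel image pair with a known colocalized pixel fraction.

    Each channel receives ``n_pos`` positive pixels (intensity uniform in
    [threshold, 1000]); ``floor(f_coloc * n_pos)`` of them are shared between
    the channels and the rest are disjoint. All other pixels are background
    (uniform in [0, background)). By construction both colocalization
    percentages equal ``100 * floor(f_coloc*n_pos) / n_pos``.
    """
    if not 0 <= f_coloc <= 1:
        raise ConfigurationError(f"f_coloc must be in [0, 1], got {f_coloc}")
    npix = shape[0] * shape[1]
    n_shared = int(np.floor(f_coloc * n_pos))
    n_only = n_pos - n_shared
    needed = n_shared + 2 * n_only
    if needed > npix:
        raise ConfigurationError(
            f"cannot pack {needed} positive pixels into {npix}-pixel image"
        )
    rng = np.random.default_rng(seed)
    flat = rng.choice(npix, size=needed, replace=False)
    shared = flat[:n_shared]
    only1 = flat[n_shared : n_shared + n_only]
    only2 = flat[n_shared + n_only :]

    def build(pos_idx: np.ndarray) -> ChannelImage:
        img = rng.uniform(0.0, background, size=npix)
        img[pos_idx] = rng.uniform(threshold, WORKING_MAX, size=pos_idx.size)
        return ChannelImage(img.reshape(shape))

    ch1 = build(np.concatenate([shared, only1]))
    ch2 = build(np.concatenate([shared, only2]))
    rec = GenRecord(
        "make_coloc_pair",
        {
            "shape": list(shape),
            "f_coloc": f_coloc,
            "n_pos": n_pos,
            "threshold": threshold,
            "background": background,
        },
        seed,
        {"true_coloc_pct": 100.0 * n_shared / n_pos, "n_shared": n_shared},
    )
    return ch1, ch2, rec


def make_zstack(
    n_slices: int = 6,
    basal_ratio: float = 3.0,
    n_pos: int = 10_000,
    shape: tuple[int, int] = (160, 160),
    threshold: float = DEFAULT_THRESHOLD,
    background: float = DEFAULT_BACKGROUND,
    seed: int = 0,
) -> tuple[list[ChannelImage], GenRecord]:
    """z-stack with positives allocated basal:upper at ``basal_ratio : 1``.

    Each positive pixel lands in the lower or upper half of the stack with
    probability ``basal_ratio / (1 + basal_ratio)``, then uniformly on a free
    pixel of a uniformly chosen slice within that half. The realized basal
    fraction is recorded as ground truth.
    """
    if n_slices < 2 or n_slices % 2:
        raise ConfigurationError(f"n_slices must be even and >= 2, got {n_slices}")
    if basal_ratio <= 0:
        raise ConfigurationError(f"basal_ratio must be > 0, got {basal_ratio}")
    rng = np.random.default_rng(seed)
    npix = shape[0] * shape[1]
    p_basal = basal_ratio / (1.0 + basal_ratio)
    half = n_slices // 2
    basal_draws = rng.random(n_pos) < p_basal
    slice_of = np.where(
        basal_draws,
        rng.integers(0, half, size=n_pos),
        rng.integers(half, n_slices, size=n_pos),
    )
    per_slice = np.bincount(slice_of, minlength=n_slices)
    if per_slice.max() > npix:
        raise ConfigurationError("too many positives for one slice")
    planes = []
    for k in range(n_slices):
        img = rng.uniform(0.0, background, size=npix)
        idx = rng.choice(npix, size=per_slice[k], replace=False)
        img[idx] = rng.uniform(threshold, WORKING_MAX, size=per_slice[k])
        planes.append(ChannelImage(img.reshape(shape)))
    realized_basal = float(per_slice[:half].sum() / n_pos)
    rec = GenRecord(
        "make_zstack",
        {
            "n_slices": n_slices,
            "basal_ratio": basal_ratio,
            "n_pos": n_pos,
            "shape": list(shape),
            "threshold": threshold,
        },
        seed,
        {
            "expected_basal_fraction": p_basal,
            "realized_basal_fraction": realized_basal,
        },
    )
    return planes, rec


def triangular_c_path(
    c_max: float, t_total: float, n_points: int = 120
) -> tuple[np.ndarray, np.ndarray]:
    """Piecewise-linear concentration schedule 0 -> c_max -> 0."""
    t = np.linspace(0.0, t_total, n_points)
    c = np.where(t <= t_total / 2, 2 * c_max * t / t_total, 2 * c_max * (1 - t / t_total))
    return t, np.maximum(c, 0.0)


def make_morph_timecourse(
    params: SwitchParams | None = None,
    times: np.ndarray | None = None,
    c_of_t: np.ndarray | None = None,
    n_cells: int = 500,
    p_b: float = 0.9,
    p_s: float = 0.9,
    seed: int = 0,
    dt: float = 0.05,
    sample: bool = True,
) -> tuple[pd.DataFrame, GenRecord]:
    """Morphology-proportion time-course from the switch model.

    Simulates ``n_cells`` switch trajectories along the concentration schedule
    ``c_of_t`` (default: a slow triangular ramp to 2.5*K), then maps states to
    the three observable morphology classes with emission probabilities:
    amoeboid cells bleb with probability ``p_b``, mesenchymal cells are
    spindle-shaped with probability ``p_s``, the remainder are scored round
    (the ambiguous/transition class). Per time point the class counts are a
    single multinomial-style draw over the cells; ``sample=False`` returns
    the expected (noise-free) proportions instead.
    """
    if n_cells < 10:
        raise ConfigurationError(f"n_cells must be >= 10, got {n_cells}")
    params = params if params is not None else SwitchParams()
    if times is None or c_of_t is None:
        times, c_of_t = triangular_c_path(2.5 * params.K, 400.0 / params.mu)
    times = np.asarray(times, float)
    c_of_t = np.asarray(c_of_t, float)
    rng = np.random.default_rng(seed)
    rest = SwitchState.mesenchymal_rest(params)
    I = np.full(n_cells, rest.I)
    P = np.full(n_cells, rest.P)
    rows = []
    t_now = 0.0
    for t_target, c in zip(times, c_of_t):
        while t_now < t_target - 1e-12:
            step = min(dt, t_target - t_now)
            I, P = step_switch_arrays(I, P, np.full(n_cells, c), params, step, rng)
            t_now += step
        amoe = P > I
        if sample:
            u = rng.random(n_cells)
            blebbing = amoe & (u < p_b)
            spindle = ~amoe & (u < p_s)
            n_b, n_s = int(blebbing.sum()), int(spindle.sum())
        else:
            n_b = int(round(p_b * amoe.sum()))
            n_s = int(round(p_s * (n_cells - amoe.sum())))
        rows.append(
            {
                "time": float(t_target),
                "C": float(c),
                "n_cells": n_cells,
                "n_blebbing": n_b,
                "n_spindle": n_s,
                "n_round": n_cells - n_b - n_s,
                "blebbing": n_b / n_cells,
                "spindle": n_s / n_cells,
                "round": (n_cells - n_b - n_s) / n_cells,
                "amoeboid_true": float(amoe.mean()),
            }
        )
    df = pd.DataFrame(rows)
    rec = GenRecord(
        "make_morph_timecourse",
        {
            "params": asdict(params),
            "n_cells": n_cells,
            "p_b": p_b,
            "p_s": p_s,
            "n_times": len(times),
            "c_max": float(c_of_t.max()),
        },
        seed,
        {"true_K": params.K},
    )
    return df, rec
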