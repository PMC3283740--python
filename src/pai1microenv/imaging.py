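"""Microscopy image statistics: thresholded two-channel colocalization,
line signal-distribution profiles, and z-stack stained-pixel profiles.

Intensities live on a 0-1000 working scale with a significance threshold of
100 and a background level of 25 (grey levels); images of other bit depths
are linearly rescaled onto this scale before thresholding. "Positive" means
intensity >= threshold (inclusive).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ConfigurationError, DomainError

__all__ = [
    "ChannelImage",
    "ColocResult",
    "colocalization_percent",
    "line_profile",
    "z_profile",
]

WORKING_MAX = 1000.0
DEFAULT_THRESHOLD = 100.0
DEFAULT_BACKGROUND = 25.0


@dataclass
class ChannelImage:
    """Single-channel grayscale image on the 0-1000 working scale."""

    pixels: np.ndarray
    provenance: str = "native 0-1000"

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=np.float64)
        if self.pixels.ndim != 2:
            raise ConfigurationError(f"expected 2D image, got shape {self.pixels.shape}")
        if self.pixels.min() < 0 or self.pixels.max() > WORKING_MAX:
            raise ConfigurationError(
                "intensities must lie in [0, 1000]; use ChannelImage.from_raw to rescale"
            )

    @classmethod
    def from_raw(cls, arr: np.ndarray, native_max: float | None = None) -> "ChannelImage":
        """Rescale an image of arbitrary bit depth linearly onto [0, 1000].

        ``native_max`` defaults to the dtype maximum for integer images
        (255 for uint8, 65535 for uint16) and to the data maximum otherwise.
        """
        arr = np.asarray(arr)
        if native_max is None:
            if np.issubdtype(arr.dtype, np.integer):
                native_max = float(np.iinfo(arr.dtype).max)
            else:
                native_max = float(arr.max()) if arr.size and arr.max() > 0 else 1.0
        scaled = arr.astype(np.float64) * (WORKING_MAX / native_max)
        return cls(np.clip(scaled, 0.0, WORKING_MAX), provenance=f"rescaled from max {native_max}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


@dataclass
class ColocResult:
    """Per-channel thresholded colocalization percentages and pixel counts."""

    pct_ch1: float
    pct_ch2: float
    n_pos_ch1: int
    n_pos_ch2: int
    n_coloc: int
    threshold: float
    background: float


def colocalization_percent(
    ch1: ChannelImage,
    ch2: ChannelImage,
    threshold: float = DEFAULT_THRESHOLD,
    background: float = DEFAULT_BACKGROUND,
    roi: np.ndarray | None = None,
) -> ColocResult:
    """Percentage of colocalized pixels relative to each channel's positives.

    Pixels below ``background`` are zeroed; a pixel is positive when its
    intensity is >= ``threshold`` (a common threshold for both channels);
    colocalized pixels are positive in both. ``pct_ch1`` is the percentage of
    channel-1-positive pixels that are also channel-2-positive (and
    symmetrically for ``pct_ch2``). ``roi`` (boolean mask, e.g. a quadrant
    selected around a cell) restricts all counts.
    """
    if ch1.shape != ch2.shape:
        raise DomainError(f"channel shapes differ: {ch1.shape} vs {ch2.shape}")
    if not background < threshold <= WORKING_MAX:
        raise ConfigurationError(
            f"need background < threshold <= {WORKING_MAX}, got "
            f"background={background}, threshold={threshold}"
        )
    a = np.where(ch1.pixels < background, 0.0, ch1.pixels)
    b = np.where(ch2.pixels < background, 0.0, ch2.pixels)
    pos1 = a >= threshold
    pos2 = b >= threshold
    if roi is not None:
        roi = np.asarray(roi, dtype=bool)
        if roi.shape != ch1.shape:
            raise DomainError("roi shape must match image shape")
        pos1 &= roi
        pos2 &= roi
    coloc = pos1 & pos2
    n1, n2, nc = int(pos1.sum()), int(pos2.sum()), int(coloc.sum())
    pct1 = 100.0 * nc / n1 if n1 else 0.0
    pct2 = 100.0 * nc / n2 if n2 else 0.0
    return ColocResult(pct1, pct2, n1, n2, nc, threshold, background)


def line_profile(
    image: ChannelImage,
    start: tuple[float, float],
    end: tuple[float, float],
    width: int = 1,
) -> np.ndarray:
    """Signal distribution along a line: array of (distance, mean intensity).

    Samples the rasterized segment by nearest-pixel stepping (one sample per
    unit of the dominant axis), averaging across ``width`` parallel lines
    offset along the perpendicular. Endpoints are (row, col) and must lie
    inside the image. A zero-length line is an error.
    """
    h, w = image.shape
    r0, c0 = start
    r1, c1 = end
    for r, c in ((r0, c0), (r1, c1)):
        if not (0 <= r <= h - 1 and 0 <= c <= w - 1):
            raise DomainError(f"endpoint ({r}, {c}) outside image {h}x{w}")
    if width < 1:
        raise ConfigurationError("width must be >= 1")
    dr, dc = r1 - r0, c1 - c0
    length = float(np.hypot(dr, dc))
    if length == 0:
        raise DomainError("zero-length line")
    n = int(max(abs(dr), abs(dc))) + 1
    if n < 2:
        n = 2
    t = np.linspace(0.0, 1.0, n)
    rows = r0 + t * dr
    cols = c0 + t * dc
    # unit perpendicular in (row, col) space
    pr, pc = -dc / length, dr / length
    offsets = np.arange(width) - (width - 1) / 2.0
    acc = np.zeros(n)
    for off in offsets:
        rr = np.clip(np.rint(rows + off * pr).astype(int), 0, h - 1)
        cc = np.clip(np.rint(cols + off * pc).astype(int), 0, w - 1)
        acc += image.pixels[rr, cc]
    mean = acc / width
    dist = t * length
    return np.stack([dist, mean], axis=1)


def z_profile(
    stack: list[ChannelImage] | np.ndarray,
    threshold: float = DEFAULT_THRESHOLD,
) -> dict:
    """Stained-pixel counts per optical slice and the basal signal fraction.

    ``stack`` is ordered from the substrate upward. Counts pixels with
    intensity >= ``threshold`` in each slice; ``basal_fraction`` is the share
    of stained pixels in the lower half of the slices (the first ``n//2``
    slices; for odd slice counts the middle slice belongs to the upper half).
    """
    if isinstance(stack, np.ndarray):
        if stack.ndim != 3 or stack.shape[0] < 2:
            raise DomainError("stack must have >= 2 slices")
        planes = [stack[i] for i in range(stack.shape[0])]
    else:
        planes = [im.pixels for im in stack]
    if len(planes) < 2:
        raise DomainError("stack must have >= 2 slices")
    shape = np.shape(planes[0])
    if any(np.shape(p) != shape for p in planes):
        raise DomainError("all slices must share dimensions")
    counts = np.array([int(np.count_nonzero(np.asarray(p) >= threshold)) for p in planes])
    total = int(counts.sum())
    n_basal = len(planes) // 2
    basal = int(counts[:n_basal].sum())
    return {
        "counts": counts,
        "total": total,
        "basal_fraction": (basal / total) if total else 0.0,
        "threshold": threshold,
        "n_slices": len(planes),
    }
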