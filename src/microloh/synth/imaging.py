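"""Two-channel synthetic micrographs of ramified (microglia-like) cells.

Each cell is a small soma disk plus a tree of 1-pixel-wide straight
processes, optionally branched. Channel 1 (pan-myeloid stain analog)
contains every cell; channel 2 (reporter analog) omits a chosen number of
reporter-negative cells. Per-cell ground truth retains the rasterized
skeleton length, terminal endpoint count and the convex-hull area of the
process tips, so morphometry output can be checked against construction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.spatial import ConvexHull, QhullError
from skimage.draw import disk, line


@dataclass
class CellTruth:
    center: tuple[int, int]
    reporter_positive: bool
    n_endpoints: int
    skeleton_length_um: float
    hull_area_um2: float
    tips: list = field(default_factory=list)


@dataclass
class MicrogliaImage:
    channel_iba1: np.ndarray  # uint16, all cells
    channel_reporter: np.ndarray  # uint16, reporter-positive cells only
    pixel_size: float  # um / pixel
    cells: list[CellTruth] = field(default_factory=list)


def _raster_step_length(rr, cc) -> float:
    """Length along a rasterized pixel chain: 1 per orthogonal step, sqrt(2) diagonal."""
    dr = np.abs(np.diff(rr))
    dc = np.abs(np.diff(cc))
    return float(np.sum(np.where((dr == 1) & (dc == 1), math.sqrt(2.0), 1.0)))


def _hull_area(points: np.ndarray) -> float:
    if len(points) < 3:
        return 0.0
    try:
        return float(ConvexHull(points).volume)  # 2-D: volume is area
    except QhullError:
        return 0.0


def render_microglia_image(
    n_cells: int = 10,
    n_reporter_negative: int = 2,
    shape: tuple[int, int] = (640, 640),
    n_arms: tuple[int, int] = (4, 6),
    arm_len: tuple[int, int] = (20, 40),
    branch_prob: float = 0.4,
    soma_radius: int = 5,
    pixel_size: float = 0.5,
    intensity: int = 4_000,
    min_separation: int = 90,
    max_retries: int = 2_000,
    seed: int = 0,
) -> MicrogliaImage:
    """Render non-overlapping cells; raises if placement keeps colliding."""
    if n_reporter_negative > n_cells:
        raise ValueError("n_reporter_negative cannot exceed n_cells")
    rng = np.random.default_rng(seed)
    h, w = shape
    margin = max(arm_len) * 2 + soma_radius + 2

    centers: list[tuple[int, int]] = []
    tries = 0
    while len(centers) < n_cells:
        tries += 1
        if tries > max_retries:
            raise RuntimeError("could not place non-overlapping cells; frame too crowded")
        r = int(rng.integers(margin, h - margin))
        c = int(rng.integers(margin, w - margin))
        if all((r - r0) ** 2 + (c - c0) ** 2 >= min_separation**2 for r0, c0 in centers):
            centers.append((r, c))

    ch1 = np.zeros(shape, dtype=np.uint16)
    ch2 = np.zeros(shape, dtype=np.uint16)
    reporter_neg = set(rng.choice(n_cells, size=n_reporter_negative, replace=False).tolist())

    cells = []
    for i, (r0, c0) in enumerate(centers):
        pos = i not in reporter_neg
        targets = [ch1, ch2] if pos else [ch1]

        # centerlines on a per-cell canvas; rendered processes are the
        # centerlines dilated to ~3 px width so despeckling keeps them
        canvas = np.zeros(shape, dtype=bool)
        total_len = 0.0
        tips: list[tuple[int, int]] = []
        k = int(rng.integers(n_arms[0], n_arms[1] + 1))
        base = rng.uniform(0, 2 * math.pi)
        # evenly spread arms with mild jitter keep tips well separated
        angles = base + np.arange(k) * 2 * math.pi / k + rng.uniform(-0.2, 0.2, size=k)
        for ang in angles:
            length = int(rng.integers(arm_len[0], arm_len[1] + 1))
            r1 = int(round(r0 + length * math.sin(ang)))
            c1 = int(round(c0 + length * math.cos(ang)))
            lrr, lcc = line(r0, c0, r1, c1)
            canvas[lrr, lcc] = True
            total_len += _raster_step_length(lrr, lcc)
            tips.append((r1, c1))
            if rng.random() < branch_prob:
                mid = int(len(lrr) * 0.6)
                bang = ang + rng.choice([-1.0, 1.0]) * rng.uniform(0.5, 0.8)
                blen = max(8, length // 2)
                br1 = int(round(lrr[mid] + blen * math.sin(bang)))
                bc1 = int(round(lcc[mid] + blen * math.cos(bang)))
                brr, bcc = line(int(lrr[mid]), int(lcc[mid]), br1, bc1)
                canvas[brr, bcc] = True
                total_len += _raster_step_length(brr, bcc)
                tips.append((br1, bc1))
        canvas = ndimage.binary_dilation(canvas, structure=np.ones((3, 3)))
        rr, cc = disk((r0, c0), soma_radius, shape=shape)
        canvas[rr, cc] = True
        for t in targets:
            t[canvas] = intensity

        pts = np.array(tips, dtype=float) * pixel_size
        cells.append(
            CellTruth(
                center=(r0, c0),
                reporter_positive=pos,
                n_endpoints=len(tips),
                skeleton_length_um=total_len * pixel_size,
                hull_area_um2=_hull_area(pts),
                tips=tips,
            )
        )
    return MicrogliaImage(
        channel_iba1=ch1, channel_reporter=ch2, pixel_size=pixel_size, cells=cells
    )
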