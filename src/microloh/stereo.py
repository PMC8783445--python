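"""Fractionator stereology: counting frames, total estimate and Schmitz-Hof CE.

The optical-fractionator design samples each section with unbiased counting
frames (default 150 x 150 um) on a systematic-random grid (default
300 x 300 um), giving an area sampling fraction asf = 0.25. The total
estimate is N_hat = sum(q_i) / (asf * ssf * tsf) with ssf the section
sampling fraction and tsf the thickness sampling fraction (1 here: the full
section height is counted). Precision is summarized with the Schmitz-Hof
second coefficient-of-error estimate, which combines the Gundersen-Jensen
systematic-sampling variance of the section counts with a Poisson
counting-noise term:

    CE = sqrt(max(0, (3(A - sQ) - 4B + C) / 12) + sQ) / sQ

with sQ = sum q_i, A = sum q_i^2, B = sum q_i q_{i+1}, C = sum q_i q_{i+2}.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .synth.sections import SectionSeries


@dataclass
class FractionatorDesign:
    frame_w: float = 150.0  # um
    frame_h: float = 150.0
    grid_x: float = 300.0
    grid_y: float = 300.0
    section_interval: int = 36  # every k-th section sampled -> ssf = 1/k
    section_thickness: float = 25.0
    mode: str = "fractionator"  # or "exhaustive"

    def __post_init__(self):
        if self.frame_w > self.grid_x or self.frame_h > self.grid_y:
            raise ValueError("counting frame cannot exceed the sampling grid")
        if self.mode not in ("fractionator", "exhaustive"):
            raise ValueError("mode must be 'fractionator' or 'exhaustive'")

    @property
    def asf(self) -> float:
        if self.mode == "exhaustive":
            return 1.0
        return (self.frame_w * self.frame_h) / (self.grid_x * self.grid_y)

    @property
    def ssf(self) -> float:
        return 1.0 if self.mode == "exhaustive" else 1.0 / self.section_interval

    @property
    def tsf(self) -> float:
        return 1.0  # full section thickness counted


def apply_counting_frames(
    sections: SectionSeries,
    design: FractionatorDesign,
    seed: int = 0,
    offset: tuple[float, float] | None = None,
) -> np.ndarray:
    """Per-section counts q_i under systematic-random frame placement.

    Frames tile the section on the grid with one random offset shared by
    all sections (systematic-random; pass ``offset`` to fix it). Unbiased
    frame rule: a cell is counted if it falls strictly inside the frame or
    on the inclusion edges (top, right); never on the exclusion edges
    (bottom, left).
    """
    if design.mode == "exhaustive":
        return sections.true_counts.to_numpy()
    if offset is None:
        rng = np.random.default_rng(seed)
        off_x = rng.uniform(0, design.grid_x)
        off_y = rng.uniform(0, design.grid_y)
    else:
        off_x, off_y = offset
    q = np.zeros(sections.n_sections, dtype=int)
    for sid, grp in sections.cells.groupby("section_id"):
        # position of each cell inside its grid tile (offset shifts the grid)
        rel_x = (grp["x"].to_numpy() - off_x) % design.grid_x
        rel_y = (grp["y"].to_numpy() - off_y) % design.grid_y
        inside = (
            (rel_x > 0)  # left edge excluded
            & (rel_x <= design.frame_w)  # right edge included
            & (rel_y > 0)  # bottom edge excluded
            & (rel_y <= design.frame_h)  # top edge included
        )
        q[int(sid)] = int(inside.sum())
    return q


@dataclass
class FractionatorEstimate:
    q: np.ndarray
    design: FractionatorDesign

    @property
    def sum_q(self) -> int:
        return int(self.q.sum())

    @property
    def n_hat(self) -> float:
        return self.sum_q / (self.design.asf * self.design.ssf * self.design.tsf)

    @property
    def ce(self) -> float | None:
        """Schmitz-Hof second CE estimate; None when sum_q = 0 (undefined)."""
        return schmitz_hof_ce(self.q)


def schmitz_hof_ce(q) -> float | None:
    q = np.asarray(q, dtype=float)
    sq = q.sum()
    if sq <= 0:
        return None
    a = float((q * q).sum())
    b = float((q[:-1] * q[1:]).sum())
    c = float((q[:-2] * q[2:]).sum())
    var_surs = (3.0 * (a - sq) - 4.0 * b + c) / 12.0
    return float(np.sqrt(max(0.0, var_surs) + sq) / sq)


def fractionator_estimate(q, design: FractionatorDesign) -> FractionatorEstimate:
    return FractionatorEstimate(q=np.asarray(q, dtype=int), design=design)


def relative_number(estimates: dict[str, list[float]], control_group: str) -> dict:
    """Percent-of-control per animal and per group.

    ``estimates`` maps group name -> per-animal totals. Each animal's value
    is its estimate divided by the mean of the control group, x 100.
    """
    control = np.asarray(estimates[control_group], dtype=float)
    if control.size == 0 or control.mean() <= 0:
        raise ValueError("control group must have a positive mean estimate")
    ref = control.mean()
    out = {}
    for group, vals in estimates.items():
        per_animal = [100.0 * v / ref for v in vals]
        out[group] = {"per_animal": per_animal, "mean": float(np.mean(per_animal))}
    return out
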