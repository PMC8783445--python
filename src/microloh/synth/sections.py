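"""Simulated tissue-section cell positions for stereological counting.

Cells are a homogeneous Poisson process in each section's sampled area;
ground-truth per-section counts are retained. Sections stand in for 25 um
sagittal slices through a region of known volume, so the expected total
count is density x volume.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass
class SectionSeries:
    """Cell coordinates per section plus the generating truth."""

    cells: pd.DataFrame  # columns: section_id, x, y (um)
    section_w: float  # um
    section_h: float  # um
    section_thickness: float  # um
    true_density: float  # cells / um^3
    n_sections: int

    @property
    def true_counts(self) -> pd.Series:
        counts = self.cells.groupby("section_id").size()
        return counts.reindex(range(self.n_sections), fill_value=0)

    @property
    def expected_total(self) -> float:
        return (
            self.true_density
            * self.section_w
            * self.section_h
            * self.section_thickness
            * self.n_sections
        )


def simulate_sections(
    true_density: float,
    section_w: float = 3_000.0,
    section_h: float = 3_000.0,
    section_thickness: float = 25.0,
    n_sections: int = 8,
    seed: int = 0,
) -> SectionSeries:
    """Homogeneous Poisson cells in ``n_sections`` sections of w x h um."""
    if true_density < 0:
        raise ValueError("density must be >= 0")
    rng = np.random.default_rng(seed)
    lam = true_density * section_w * section_h * section_thickness
    recs = []
    for s in range(n_sections):
        n = rng.poisson(lam)
        xs = rng.uniform(0, section_w, size=n)
        ys = rng.uniform(0, section_h, size=n)
        recs.append(pd.DataFrame({"section_id": s, "x": xs, "y": ys}))
    cells = (
        pd.concat(recs, ignore_index=True)
        if recs
        else pd.DataFrame(columns=["section_id", "x", "y"])
    )
    return SectionSeries(
        cells=cells,
        section_w=section_w,
        section_h=section_h,
        section_thickness=section_thickness,
        true_density=true_density,
        n_sections=n_sections,
    )
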