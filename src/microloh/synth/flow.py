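"""Synthetic flow-cytometry event tables.

Events are drawn from named ground-truth populations; each channel intensity
is log-normal with population-specific location/scale. Intensities are
emitted already compensated, on a linear scale. The wild-type/wild-type
population's fractalkine-receptor (CX3CR1) channel uses twice the location
(scale parameter) of heterozygous cells, mirroring the two-fold surface
expression that comes with two intact receptor alleles.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

DEFAULT_CHANNELS = (
    "viability", "CD11b", "CD45", "Ly6C", "Ly6G", "EYFP", "CX3CR1", "F4_80",
)

# (median, log-sd) per channel on the linear scale; "hi"/"lo" separations are
# wide (>= 4 sd in log space) so midpoint gates recover labels near-perfectly
_HI = (1000.0, 0.25)
_LO = (10.0, 0.25)


def microglia_channel_models() -> dict:
    """Channel models for the populations in a brain myeloid prep.

    Microglia are CD11b+ CD45+ Ly6C- Ly6G-; the reporter-negative
    (wild-type/wild-type) microglia differ only in EYFP (off) and CX3CR1
    (2x location). Peripheral microglia-like cells are F4/80-high.
    """
    base_microglia = {
        "viability": _HI, "CD11b": _HI, "CD45": _HI,
        "Ly6C": _LO, "Ly6G": _LO, "F4_80": _LO,
    }
    mg_het_cx3cr1 = (800.0, 0.25)
    return {
        "microglia_EYFP_pos": {**base_microglia, "EYFP": _HI, "CX3CR1": mg_het_cx3cr1},
        "microglia_EYFP_neg": {
            **base_microglia,
            "EYFP": _LO,
            # twice the location parameter of the heterozygous population
            "CX3CR1": (2 * mg_het_cx3cr1[0], mg_het_cx3cr1[1]),
        },
        "peripheral_F480_hi": {**base_microglia, "EYFP": _LO, "F4_80": _HI,
                               "CX3CR1": (200.0, 0.3)},
        "monocytes": {
            "viability": _HI, "CD11b": _HI, "CD45": _HI, "Ly6C": _HI,
            "Ly6G": _LO, "EYFP": _LO, "CX3CR1": (100.0, 0.3), "F4_80": _LO,
        },
        "debris": {c: (3.0, 0.5) for c in DEFAULT_CHANNELS},
    }


def simulate_flow_events(
    fractions: dict[str, float],
    channel_models: dict[str, dict] | None = None,
    n_events: int = 50_000,
    seed: int = 0,
) -> pd.DataFrame:
    """Event table with one row per event and a ground-truth ``label`` column.

    ``fractions`` maps population name -> expected share; events are drawn
    multinomially so observed counts fluctuate binomially around them.
    """
    if n_events < 0:
        raise ValueError("n_events must be non-negative")
    if channel_models is None:
        channel_models = microglia_channel_models()
    names = list(fractions)
    probs = np.array([fractions[n] for n in names], dtype=float)
    if probs.min() < 0 or abs(probs.sum() - 1.0) > 1e-9:
        raise ValueError("fractions must be non-negative and sum to 1")
    missing = [n for n in names if n not in channel_models]
    if missing:
        raise KeyError(f"no channel model for populations {missing}")

    rng = np.random.default_rng(seed)
    labels_idx = rng.choice(len(names), size=n_events, p=probs)
    channels = sorted({c for m in channel_models.values() for c in m})
    data = np.empty((n_events, len(channels)))
    for i, name in enumerate(names):
        sel = labels_idx == i
        n_sel = int(sel.sum())
        for j, ch in enumerate(channels):
            median, sigma = channel_models[name][ch]
            data[sel, j] = rng.lognormal(np.log(median), sigma, size=n_sel)
    table = pd.DataFrame(data, columns=channels)
    table["label"] = [names[k] for k in labels_idx]
    return table
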