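"""Branching model of microglial LOH, depletion and repopulation.

A heterozygous knock-in pool undergoes developmental divisions during which
a rare reciprocal mitotic-recombination event converts one heterozygous
division into one wild-type/wild-type and one knock-in/knock-in daughter.
After census, cells proliferate logistically day by day; a depletion event
kills cassette-carrying cells with a given efficiency, after which
peripheral cells may enter at a constant rate. Counts are propagated with
binomial/Poisson sampling per compartment, so populations of millions of
cells simulate in milliseconds.

The expected label-free (wild-type/wild-type) fraction after n developmental
divisions with per-division LOH probability mu is ~ n*mu/2: each LOH event
converts one of the two daughters of a heterozygous division.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ..locus import Genotype

RESIDENT_COMPARTMENTS = ("WT_WT", "KI_WT", "KI_KI")
COMPARTMENTS = RESIDENT_COMPARTMENTS + ("peripheral",)


@dataclass
class PopulationParams:
    mu_loh: float = 1e-3  # reciprocal LOH probability per heterozygous division
    n_divisions: int = 15  # developmental divisions before census
    n_founders: int = 50
    founder_genotype: Genotype = Genotype.KI_WT
    n_days: int = 42
    growth_rate: dict = field(
        default_factory=lambda: {"WT_WT": 0.55, "KI_WT": 0.45, "KI_KI": 0.35, "peripheral": 0.4}
    )
    depletion_day: int | None = 1
    depletion_efficiency: float = 0.9  # kills cassette-carrying residents only
    influx_rate: float = 0.0  # peripheral cells per day post-depletion (Poisson mean)
    carrying_capacity: float = 2e6
    death_rate: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        if not (0.0 <= self.mu_loh <= 1.0):
            raise ValueError("mu_loh must be a probability")
        if not (0.0 <= self.depletion_efficiency <= 1.0):
            raise ValueError("depletion_efficiency must be a probability")
        if self.n_divisions < 0 or self.n_founders < 1 or self.n_days < 0:
            raise ValueError("sizes must be non-negative (founders >= 1)")
        if self.influx_rate < 0 or self.carrying_capacity <= 0:
            raise ValueError("rates must be non-negative, capacity positive")


@dataclass
class PopulationTrajectory:
    """Per-day counts by compartment plus derived fractions."""

    counts: pd.DataFrame  # index day, columns COMPARTMENTS

    @property
    def fractions(self) -> pd.DataFrame:
        tot = self.counts.sum(axis=1)
        fr = self.counts.div(tot.where(tot > 0, 1), axis=0)
        fr[tot == 0] = 0.0
        return fr

    def final_fraction(self, compartment: str) -> float:
        return float(self.fractions.iloc[-1][compartment])


def _developmental_phase(params: PopulationParams, rng: np.random.Generator) -> dict:
    counts = {c: 0 for c in RESIDENT_COMPARTMENTS}
    counts[params.founder_genotype.value] = params.n_founders
    for _ in range(params.n_divisions):
        het = counts["KI_WT"]
        n_loh = rng.binomial(het, params.mu_loh) if het > 0 else 0
        # each dividing cell yields 2 daughters; an LOH division converts a
        # heterozygous pair into one WT_WT + one KI_KI daughter
        counts["WT_WT"] = counts["WT_WT"] * 2 + n_loh
        counts["KI_KI"] = counts["KI_KI"] * 2 + n_loh
        counts["KI_WT"] = (het - n_loh) * 2
    return counts


def simulate_population_dynamics(params: PopulationParams) -> PopulationTrajectory:
    """Run the branching model; day 0 is the census after development."""
    params.validate()
    rng = np.random.default_rng(params.seed)
    state = {c: 0 for c in COMPARTMENTS}
    state.update(_developmental_phase(params, rng))

    rows = [dict(state)]
    for day in range(1, params.n_days + 1):
        n_total = sum(state.values())
        crowd = max(0.0, 1.0 - n_total / params.carrying_capacity)
        for c in COMPARTMENTS:
            if state[c] == 0:
                continue
            p_div = min(1.0, params.growth_rate.get(c, 0.0) * crowd)
            births = rng.binomial(state[c], p_div)
            deaths = rng.binomial(state[c], params.death_rate) if params.death_rate else 0
            if c == "KI_WT" and births > 0 and params.mu_loh > 0:
                # an LOH division replaces (mother + het daughter) with
                # one WT_WT and one KI_KI daughter
                n_loh = rng.binomial(births, params.mu_loh)
                state["WT_WT"] += n_loh
                state["KI_KI"] += n_loh
                births -= 2 * n_loh
            state[c] = max(0, state[c] + births - deaths)
        if params.depletion_day is not None and day == params.depletion_day:
            for c in ("KI_WT", "KI_KI"):  # cassette-carrying residents only
                state[c] -= rng.binomial(state[c], params.depletion_efficiency)
        if (
            params.depletion_day is not None
            and day > params.depletion_day
            and params.influx_rate > 0
        ):
            state["peripheral"] += rng.poisson(params.influx_rate)
        rows.append(dict(state))

    counts = pd.DataFrame(rows, columns=list(COMPARTMENTS)).astype(int)
    counts.index.name = "day"
    return PopulationTrajectory(counts=counts)


def homeostatic_wtwt_fraction(
    mu_loh: float = 1e-3,
    n_divisions: int = 15,
    n_founders: int = 50,
    founder_genotype: Genotype = Genotype.KI_WT,
    n_replicates: int = 200,
    seed: int = 0,
) -> np.ndarray:
    """Label-free fraction at census over replicate developmental runs."""
    rng = np.random.default_rng(seed)
    out = np.empty(n_replicates)
    for i in range(n_replicates):
        params = PopulationParams(
            mu_loh=mu_loh,
            n_divisions=n_divisions,
            n_founders=n_founders,
            founder_genotype=founder_genotype,
            n_days=0,
            depletion_day=None,
            seed=int(rng.integers(0, 2**31)),
        )
        traj = simulate_population_dynamics(params)
        out[i] = traj.fractions.iloc[0]["WT_WT"]
    return out
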