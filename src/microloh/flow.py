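"""Hierarchical gating and subpopulation quantification for event tables.

Gate trees are small rooted hierarchies of 1-D threshold or 2-D rectangle
predicates on named channels; membership is computed top-down so every
event's node set is a root-to-node chain. Fractions, quadrant splits and
mean fluorescence intensity (arithmetic mean on the linear scale by
default) reproduce the conventional read-outs of a myeloid panel.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass
class Gate:
    """One node: predicate on its parent's events."""

    name: str
    parent: str | None  # None for the root
    channel: str | None = None
    low: float = -np.inf
    high: float = np.inf
    channel2: str | None = None  # set for 2-D rectangle gates
    low2: float = -np.inf
    high2: float = np.inf

    def mask(self, events: pd.DataFrame) -> np.ndarray:
        m = np.ones(len(events), dtype=bool)
        if self.channel is not None:
            v = events[self.channel].to_numpy()
            m &= (v >= self.low) & (v < self.high)
        if self.channel2 is not None:
            v = events[self.channel2].to_numpy()
            m &= (v >= self.low2) & (v < self.high2)
        return m


@dataclass
class GateTree:
    gates: dict[str, Gate] = field(default_factory=dict)

    @property
    def root(self) -> str:
        roots = [g.name for g in self.gates.values() if g.parent is None]
        if len(roots) != 1:
            raise ValueError(f"gate tree must have exactly one root, found {roots}")
        return roots[0]

    def add(self, gate: Gate) -> "GateTree":
        if gate.name in self.gates:
            raise ValueError(f"duplicate gate name {gate.name!r}")
        if gate.parent is not None and gate.parent not in self.gates:
            raise ValueError(f"unknown parent {gate.parent!r}")
        self.gates[gate.name] = gate
        return self

    def ancestors(self, name: str) -> list[str]:
        chain = []
        cur = self.gates[name].parent
        while cur is not None:
            chain.append(cur)
            cur = self.gates[cur].parent
        return chain

    @classmethod
    def from_json(cls, text: str) -> "GateTree":
        tree = cls()
        for spec in json.loads(text):
            tree.add(Gate(**spec))
        return tree

    def to_json(self) -> str:
        return json.dumps([vars(g) for g in self.gates.values()], default=float, indent=2)


def apply_gate_tree(events: pd.DataFrame, tree: GateTree) -> pd.DataFrame:
    """Boolean membership per node; children are intersected with parents."""
    member = pd.DataFrame(index=events.index)
    order = _topo_order(tree)
    for name in order:
        gate = tree.gates[name]
        m = gate.mask(events)
        if gate.parent is not None:
            m &= member[gate.parent].to_numpy()
        member[name] = m
    return member


def _topo_order(tree: GateTree) -> list[str]:
    order, seen = [], set()
    pending = [tree.root]
    while pending:
        cur = pending.pop(0)
        order.append(cur)
        seen.add(cur)
        pending.extend(
            g.name for g in tree.gates.values() if g.parent == cur and g.name not in seen
        )
    if len(order) != len(tree.gates):
        raise ValueError("gate tree contains unreachable nodes")
    return order


def population_fraction(
    membership: pd.DataFrame, node: str, denominator_node: str, tree: GateTree | None = None
) -> float:
    """|node| / |denominator|; the denominator must be on the ancestor chain."""
    if tree is not None and denominator_node != node and denominator_node not in tree.ancestors(node):
        raise ValueError(f"{denominator_node!r} is not an ancestor of {node!r}")
    denom = int(membership[denominator_node].sum())
    if denom == 0:
        return 0.0
    return float(membership[node].sum()) / denom


def quadrant_fractions(
    events: pd.DataFrame, x_channel: str, x_threshold: float, y_channel: str, y_threshold: float
) -> dict[str, float]:
    """Four quadrant fractions of the given (already gated) events; sums to 1.

    Keys: '{y}+{x}lo', '{y}+{x}hi', '{y}-{x}lo', '{y}-{x}hi' style tuples
    (y_pos, x_hi) -> fraction.
    """
    if len(events) == 0:
        return {k: 0.0 for k in ("pos_lo", "neg_lo", "pos_hi", "neg_hi")}
    x_hi = events[x_channel].to_numpy() >= x_threshold
    y_pos = events[y_channel].to_numpy() >= y_threshold
    n = len(events)
    return {
        "pos_lo": float((y_pos & ~x_hi).sum()) / n,
        "neg_lo": float((~y_pos & ~x_hi).sum()) / n,
        "pos_hi": float((y_pos & x_hi).sum()) / n,
        "neg_hi": float((~y_pos & x_hi).sum()) / n,
    }


def mfi(events: pd.DataFrame, channel: str, geometric: bool = False) -> float | None:
    """Mean fluorescence intensity; None for an empty population."""
    if len(events) == 0:
        return None
    v = events[channel].to_numpy(dtype=float)
    if geometric:
        return float(np.exp(np.log(np.maximum(v, 1e-12)).mean()))
    return float(v.mean())


def microglia_gate_tree(
    hi_lo_midpoint: float = 100.0, eyfp_threshold: float = 100.0
) -> GateTree:
    """Default hierarchy: live -> CD11b+CD45+ -> Ly6C-Ly6G- (microglia) ->
    EYFP+/- leaves. Thresholds sit at the population-model midpoints."""
    t = hi_lo_midpoint
    tree = GateTree()
    tree.add(Gate("live", None, channel="viability", low=t))
    tree.add(Gate("myeloid", "live", channel="CD11b", low=t, channel2="CD45", low2=t))
    tree.add(Gate("microglia", "myeloid", channel="Ly6C", high=t, channel2="Ly6G", high2=t))
    tree.add(Gate("EYFP_pos", "microglia", channel="EYFP", low=eyfp_threshold))
    tree.add(Gate("EYFP_neg", "microglia", channel="EYFP", high=eyfp_threshold))
    return tree
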