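"""Rate-shift regimes on dated trees and rate extraction.

A diversification history is modelled as a set of *regimes* anchored to
branches of a dated tree at absolute times. Within a regime, speciation
changes exponentially, ``lambda(t) = lambda0 * exp(b * (t - t0))`` with
``t0`` the regime's anchor time, and extinction likewise with parameter
``z`` (``z = 0``, constant extinction per regime, is the default dialect).
Every lineage inherits the nearest upstream regime: among all events
anchored on its root-to-tip path, the one with the latest anchor time.

Tip rates are the instantaneous regime rates evaluated at the present.
Rates through time average the (segment-discretized) instantaneous branch
rates over all lineages of a subtree alive at each grid time; branches
are discretized into segments of ``seg_frac`` times the tree height
(0.02 by default, i.e. piecewise-constant rates on 2%-of-height pieces).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .trees import DatedTree

__all__ = [
    "RateRegime", "ShiftEvent", "EventConfiguration", "TipRateTable",
    "tip_rates", "rate_through_time", "sampling_fractions",
    "parse_event_table", "event_table_frame",
]

#: default branch discretization, as a fraction of tree height
DEFAULT_SEG_FRAC = 0.02


@dataclass(frozen=True)
class RateRegime:
    """Exponential-change diversification regime.

    lambda0, mu0 are events/lineage/Ma at the regime's anchor time; b and
    z are the exponential change parameters (1/Ma) for speciation and
    extinction respectively.
    """
    lambda0: float
    b: float = 0.0
    mu0: float = 0.0
    z: float = 0.0

    def __post_init__(self):
        if not self.lambda0 > 0:
            raise ValueError("lambda0 must be > 0")
        if self.mu0 < 0:
            raise ValueError("mu0 must be >= 0")

    def speciation(self, dt: float) -> float:
        """lambda at time ``dt`` Ma after the regime's anchor."""
        return self.lambda0 * math.exp(self.b * dt)

    def extinction(self, dt: float) -> float:
        return self.mu0 * math.exp(self.z * dt)


@dataclass(frozen=True)
class ShiftEvent:
    """A regime anchored to the branch subtending ``node`` at ``abstime``
    (Ma from the root)."""
    node: object
    abstime: float
    regime: RateRegime


class EventConfiguration:
    """Set of rate regimes on a tree; the root regime (abstime 0) is mandatory."""

    def __init__(self, tree: DatedTree, events: list[ShiftEvent]):
        self.tree = tree
        if not any(ev.node is tree.tree.seed_node and ev.abstime == 0.0
                   for ev in events):
            raise ValueError("event configuration lacks a root regime at abstime 0")
        for ev in events:
            lo = tree.depth(ev.node.parent_node) if ev.node.parent_node else 0.0
            hi = tree.depth(ev.node)
            if not (lo - 1e-9 <= ev.abstime <= hi + 1e-9):
                raise ValueError(
                    f"event at abstime {ev.abstime:g} outside its anchor branch "
                    f"interval [{lo:g}, {hi:g}]"
                )
        self.events = sorted(events, key=lambda ev: ev.abstime)
        # events anchored on or above each node, resolved once per node
        self._by_node: dict = {}
        for ev in self.events:
            self._by_node.setdefault(ev.node, []).append(ev)

    @classmethod
    def single_regime(cls, tree: DatedTree, regime: RateRegime) -> "EventConfiguration":
        return cls(tree, [ShiftEvent(tree.tree.seed_node, 0.0, regime)])

    def governing_event(self, node, abstime: float | None = None) -> ShiftEvent:
        """Nearest upstream event for the branch above ``node``.

        Among events anchored on the root-to-``node`` path (with anchor
        time <= ``abstime`` when given), the latest anchor wins.
        """
        best = None
        nd = node
        while nd is not None:
            for ev in self._by_node.get(nd, ()):
                if abstime is not None and ev.abstime > abstime + 1e-12:
                    continue
                if best is None or ev.abstime > best.abstime:
                    best = ev
            nd = nd.parent_node
        if best is None:
            raise ValueError("no governing regime found (missing root regime)")
        return best


@dataclass
class TipRateTable:
    """Per-tip instantaneous rates at the present plus stem ages."""
    table: pd.DataFrame = field(repr=False)

    def __post_init__(self):
        expected = {"genus", "lambda_tip", "mu_tip", "netdiv_tip", "stem_age"}
        missing = expected - set(self.table.columns)
        if missing:
            raise ValueError(f"tip rate table missing columns {sorted(missing)}")


def tip_rates(tree: DatedTree, events: EventConfiguration) -> pd.DataFrame:
    """Instantaneous speciation/extinction/net-diversification at the present.

    For each tip, the governing regime is the nearest upstream event on
    its root-to-tip path; with ``dt = height - abstime``,
    ``lambda_tip = lambda0 * exp(b*dt)`` and ``mu_tip = mu0 * exp(z*dt)``.
    Returns a frame with columns genus, lambda_tip, mu_tip, netdiv_tip,
    stem_age, indexed by genus.
    """
    rows = []
    h = tree.height
    for label in tree.tip_labels:
        node = tree.tip_node(label)
        ev = events.governing_event(node)
        dt = h - ev.abstime
        lam = ev.regime.speciation(dt)
        mu = ev.regime.extinction(dt)
        rows.append((label, lam, mu, lam - mu, tree.stem_age(label)))
    df = pd.DataFrame(rows, columns=["genus", "lambda_tip", "mu_tip",
                                     "netdiv_tip", "stem_age"])
    return df.set_index("genus", drop=False)


def _segment_midpoint(abstime: float, height: float, seg: float) -> float:
    if abstime >= height - 1e-12:  # the present: evaluate exactly
        return height
    k = math.floor(abstime / seg + 1e-9)
    return min((k + 0.5) * seg, height)


def rate_through_time(tree: DatedTree, events: EventConfiguration,
                      tip_subset, grid, rate: str = "lambda",
                      seg_frac: float = DEFAULT_SEG_FRAC) -> np.ndarray:
    """Mean instantaneous rate over the lineages of a subtree at grid times.

    Parameters
    ----------
    tip_subset
        Nonempty iterable of tip labels; the curve is computed on the
        spanning subtree (union of root-to-tip paths) of these tips.
    grid
        Times in Ma *before present*, within [0, height].
    rate
        "lambda", "mu" or "netdiv".

    Branch rates are discretized into segments of ``seg_frac * height``
    (piecewise constant, evaluated at segment midpoints), mirroring the
    standard event-sampler discretization.
    """
    tips = list(tip_subset)
    if not tips:
        raise ValueError("tip_subset is empty")
    if rate not in ("lambda", "mu", "netdiv"):
        raise ValueError(f"unknown rate kind {rate!r}")
    h = tree.height
    seg = seg_frac * h
    # spanning-subtree edges: nodes on some root-to-tip path
    keep = set()
    for label in tips:
        nd = tree.tip_node(label)
        while nd is not None and nd not in keep:
            keep.add(nd)
            nd = nd.parent_node

    spans = []  # (node, depth_lo, depth_hi)
    for nd in keep:
        if nd.parent_node is None:
            continue
        spans.append((nd, tree.depth(nd.parent_node), tree.depth(nd)))

    out = np.empty(len(list(grid)), dtype=float)
    for gi, t in enumerate(grid):
        tau = h - t  # absolute time from root
        vals = []
        for nd, lo, hi in spans:
            crossing = (lo < tau <= hi) or (tau == 0.0 and lo == 0.0)
            if not crossing:
                continue
            ev = events.governing_event(nd, abstime=tau)
            tm = max(_segment_midpoint(tau, h, seg), ev.abstime)
            dt = tm - ev.abstime
            if rate == "lambda":
                vals.append(ev.regime.speciation(dt))
            elif rate == "mu":
                vals.append(ev.regime.extinction(dt))
            else:
                vals.append(ev.regime.speciation(dt) - ev.regime.extinction(dt))
        out[gi] = float(np.mean(vals)) if vals else np.nan
    return out


def sampling_fractions(richness: dict[str, int], backbone: float) -> tuple[float, pd.DataFrame]:
    """Per-tip species sampling fractions for a genus-level tree.

    Each genus tip stands for one sampled species out of ``richness``
    described species, so its sampling fraction is ``1/richness``;
    ``backbone`` is the completeness fraction of the backbone topology
    (0.725 for a molecular-only tree, 0.97 for a complete genus tree are
    the conventional settings). Returns ``(backbone, frame)`` with
    columns tip, clade, fraction.
    """
    rows = []
    for genus, n in richness.items():
        if not n >= 1:
            raise ValueError(f"species richness for {genus!r} must be >= 1, got {n}")
        rows.append((genus, genus, 1.0 / n))
    return backbone, pd.DataFrame(rows, columns=["tip", "clade", "fraction"])


# -- BAMM-style event table dialect ---------------------------------------

_EVENT_COLUMNS = ["generation", "leftchild", "rightchild", "abstime",
                  "lambdainit", "lambdashift", "muinit", "mushift"]


def parse_event_table(df: pd.DataFrame, tree: DatedTree,
                      generation: int | None = None) -> EventConfiguration:
    """Bind an event table to a tree.

    The table uses the event-data CSV dialect: columns generation,
    leftchild, rightchild, abstime, lambdainit, lambdashift, muinit,
    mushift. Each row is anchored at the branch subtending
    MRCA(leftchild, rightchild); an empty rightchild anchors the
    leftchild's pendant branch. A row with abstime 0 is the root regime.
    """
    missing = [c for c in _EVENT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"event table missing columns {missing}")
    if generation is not None:
        df = df[df["generation"] == generation]
    if df.empty:
        raise ValueError("event table has no rows (after generation selection)")
    events = []
    for row in df.itertuples(index=False):
        left = str(row.leftchild)
        right = "" if pd.isna(row.rightchild) else str(row.rightchild)
        labels = [left] + ([right] if right else [])
        for lab in labels:
            if lab not in tree._tip_index:
                raise ValueError(f"event table references unknown tip {lab!r}")
        node = tree.mrca(labels)
        regime = RateRegime(lambda0=float(row.lambdainit), b=float(row.lambdashift),
                            mu0=float(row.muinit), z=float(row.mushift))
        events.append(ShiftEvent(node, float(row.abstime), regime))
    return EventConfiguration(tree, events)


def _anchor_labels(tree: DatedTree, node) -> tuple[str, str]:
    if node.is_leaf():
        return node.taxon.label, ""
    kids = node.child_nodes()
    left = next(iter(kids[0].leaf_iter())).taxon.label
    right = next(iter(kids[-1].leaf_iter())).taxon.label
    return left, right


def event_table_frame(events: EventConfiguration, generation: int = 0) -> pd.DataFrame:
    """Serialize an EventConfiguration to the event-data CSV dialect."""
    rows = []
    for ev in events.events:
        left, right = _anchor_labels(events.tree, ev.node)
        rows.append((generation, left, right, ev.abstime, ev.regime.lambda0,
                     ev.regime.b, ev.regime.mu0, ev.regime.z))
    return pd.DataFrame(rows, columns=_EVENT_COLUMNS)
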