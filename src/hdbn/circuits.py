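"""Hypothesis-driven circuit comparisons between groups.

A circuit is a named set of composite-ROI nodes and an ordered list of
node pairs to test.  Two circuits are built in: the amygdala-dependent
fear-conditioning pathway (thalamus, somatosensory cortex, isocortex,
hypothalamus, amygdala) and the temporal-lobe-epilepsy pathway
(hippocampus, thalamus, isocortex, amygdala, entorhinal cortex).

For each pair, the per-animal connection strength is the summed
streamline count between the two resolved region sets: ipsilaterally
the mean of the L-L and R-R block sums (both hemispheres combined),
contralaterally the full cross-hemisphere block sum in both crossing
directions.  Pairs are compared with pooled t-tests and BH-adjusted
within the circuit.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence, TYPE_CHECKING

import numpy as np
import pandas as pd

from .groupstats import bh_adjust, pooled_ttest
from .parcellation import CompositeROI, RegionTable, resolve_composite

if TYPE_CHECKING:  # pragma: no cover
    from .simulate import CohortStudy

__all__ = [
    "CircuitDefinition",
    "builtin_circuit",
    "circuit_compare",
    "connection_strength",
]

#: Circuit node labels -> composite ROI member stems.
_LABEL_MEMBERS = {
    "TH": ("TH",),
    "SS": ("SS",),
    "ICTX": ("ICtx",),
    "HY": ("HY",),
    "COA": ("COA",),
    "HIPP": ("CA1", "CA2", "CA3", "DG"),
    "EC": ("EC",),
}


@dataclass(frozen=True)
class CircuitDefinition:
    """A named circuit: node labels and the ordered pairs to test."""

    name: str
    nodes: tuple[str, ...]
    pairs: tuple[tuple[str, str], ...]

    def __post_init__(self) -> None:
        node_set = {n.upper() for n in self.nodes}
        for a, b in self.pairs:
            if a.upper() not in node_set or b.upper() not in node_set:
                raise ValueError(f"pair ({a}, {b}) uses labels outside nodes {self.nodes}")
        keys = [frozenset((a.upper(), b.upper())) for a, b in self.pairs]
        if len(set(keys)) != len(keys):
            raise ValueError("circuit pairs must be unique (pairs are unordered)")


_BUILTINS = {
    "fear": CircuitDefinition(
        name="fear",
        nodes=("TH", "SS", "ICtx", "HY", "CoA"),
        pairs=(("ICtx", "TH"), ("COA", "TH"), ("SS", "TH"),
               ("COA", "HY"), ("COA", "ICtx"), ("SS", "COA")),
    ),
    "tle": CircuitDefinition(
        name="tle",
        nodes=("Hipp", "TH", "ICtx", "CoA", "EC"),
        pairs=(("Hipp", "TH"), ("COA", "ICtx"), ("EC", "ICtx"),
               ("Hipp", "ICtx"), ("EC", "COA"), ("Hipp", "COA"),
               ("Hipp", "EC")),
    ),
}


def builtin_circuit(name: str) -> CircuitDefinition:
    """A built-in circuit definition: ``fear`` or ``tle``."""
    try:
        return _BUILTINS[name.lower()]
    except KeyError:
        raise KeyError(
            f"unknown circuit {name!r}; built-ins: {sorted(_BUILTINS)}"
        ) from None


def _resolve_label(label: str, table: RegionTable, hemisphere: str) -> tuple[int, ...]:
    key = label.upper()
    if key in _LABEL_MEMBERS:
        roi = CompositeROI(label, _LABEL_MEMBERS[key])
    else:
        # fall back on treating the label as a bare abbreviation stem
        roi = CompositeROI(label, (label,))
    return resolve_composite(table, roi, hemisphere)


def connection_strength(counts: np.ndarray, table: RegionTable,
                        label_a: str, label_b: str, side: str) -> float:
    """Summed streamline count between two resolved ROI sets on one side."""
    if side not in ("ipsilateral", "contralateral"):
        raise ValueError("side must be 'ipsilateral' or 'contralateral'")
    a_l = np.array(_resolve_label(label_a, table, "L"))
    a_r = np.array(_resolve_label(label_a, table, "R"))
    b_l = np.array(_resolve_label(label_b, table, "L"))
    b_r = np.array(_resolve_label(label_b, table, "R"))
    if side == "ipsilateral":
        s_l = counts[np.ix_(a_l, b_l)].sum()
        s_r = counts[np.ix_(a_r, b_r)].sum()
        return float((s_l + s_r) / 2.0)
    return float(counts[np.ix_(a_l, b_r)].sum() + counts[np.ix_(a_r, b_l)].sum())


def circuit_compare(cohort: "CohortStudy", circuit: CircuitDefinition | str,
                    side: str = "ipsilateral", q: float = 0.05) -> pd.DataFrame:
    """Compare every circuit pair between groups on one side.

    Returns one row per pair with group means, pooled t, BH-adjusted p
    (across this circuit's pairs only), direction sign, and a label
    mirroring the figures: ``*`` significant, ``nd`` no difference.
    """
    if isinstance(circuit, str):
        circuit = builtin_circuit(circuit)
    table = cohort.table
    wt = [c for c in cohort.connectomes if c.group == "WT"]
    ko = [c for c in cohort.connectomes if c.group == "KO"]
    if len(wt) < 2 or len(ko) < 2:
        raise ValueError("circuit comparison needs at least 2 animals per group")
    rows = []
    p_raws = []
    for a, b in circuit.pairs:
        wt_v = np.array([connection_strength(c.counts, table, a, b, side) for c in wt])
        ko_v = np.array([connection_strength(c.counts, table, a, b, side) for c in ko])
        r = pooled_ttest(wt_v, ko_v)
        rows.append({"circuit": circuit.name, "pair": f"{a}-{b}", "side": side,
                     "mean_WT": float(wt_v.mean()), "mean_KO": float(ko_v.mean()),
                     "t": r.t, "df": r.df, "p_raw": r.p, "sign": r.sign})
        p_raws.append(r.p)
    p_adj, disc = bh_adjust(np.array(p_raws), q)
    out = pd.DataFrame(rows)
    out["p_adj"] = p_adj
    out["significant"] = disc
    out["label"] = np.where(disc, "*", "nd")
    return out
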