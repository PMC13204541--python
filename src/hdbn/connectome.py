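"""Per-animal streamline-count adjacency matrices and their weighted views.

A connectome here is the symmetric nonnegative matrix of tractography
streamline counts between every pair of parcellation regions.  Graph
analysis operates on *views* of it: the whole matrix or a hemisphere
block, normalized so the maximum weight is one and pruned at an
extraction threshold (default 0.001, applied to normalized weights,
strictly-below removed).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .parcellation import CompositeROI, RegionTable, resolve_composite

__all__ = [
    "Connectome",
    "WeightedGraphView",
    "read_count_matrix",
    "normalize",
    "threshold",
    "hemisphere_block",
    "hemisphere_view",
    "merge_rois",
    "export_chord_table",
    "EXTRACTION_THRESHOLD",
]

#: Default graph-theory extraction threshold on normalized weights.
EXTRACTION_THRESHOLD = 0.001

HEMISPHERE_MODES = ("ipsilateral-L", "ipsilateral-R", "contralateral-LR", "contralateral-RL")


def _check_counts(counts: np.ndarray, labels: Sequence[str]) -> np.ndarray:
    counts = np.asarray(counts, dtype=float)
    if counts.ndim != 2 or counts.shape[0] != counts.shape[1]:
        raise ValueError(f"count matrix must be square, got shape {counts.shape}")
    if counts.shape[0] != len(labels):
        raise ValueError(
            f"matrix dimension {counts.shape[0]} does not match {len(labels)} region labels"
        )
    if (counts < 0).any():
        raise ValueError("count matrix has negative entries")
    if not np.array_equal(counts, counts.T):
        raise ValueError("count matrix is not symmetric")
    if np.diag(counts).any():
        raise ValueError("count matrix has nonzero diagonal")
    return counts


@dataclass
class Connectome:
    """One animal's symmetric region-pair streamline-count matrix."""

    animal_id: str
    group: str
    counts: np.ndarray
    labels: list[str]
    table: RegionTable | None = None

    def __post_init__(self) -> None:
        if self.table is not None and not self.labels:
            self.labels = self.table.abbreviations
        self.counts = _check_counts(self.counts, self.labels)

    @property
    def n_regions(self) -> int:
        return len(self.labels)

    def region_totals(self) -> np.ndarray:
        """Per-region total streamline count (row sums)."""
        return self.counts.sum(axis=1)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.labels, columns=self.labels)


@dataclass
class WeightedGraphView:
    """A normalized, thresholded, symmetric weight matrix ready for graph metrics."""

    weights: np.ndarray
    labels: list[str]
    provenance: str = "whole"

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        if w.ndim != 2 or w.shape[0] != w.shape[1]:
            raise ValueError("weight matrix must be square")
        if w.shape[0] != len(self.labels):
            raise ValueError("weight matrix dimension does not match labels")
        if (w < 0).any() or (w > 1).any():
            raise ValueError("weights must lie in [0, 1]")
        if not np.array_equal(w, w.T):
            raise ValueError("weight matrix is not symmetric")
        if np.diag(w).any():
            raise ValueError("weight matrix has nonzero diagonal")
        self.weights = w

    @property
    def n_nodes(self) -> int:
        return len(self.labels)


def read_count_matrix(path, table: RegionTable, animal_id: str = "",
                      group: str = "") -> Connectome:
    """Read a region-by-region count matrix TSV into a :class:`Connectome`.

    Accepts either a labelled matrix (abbreviations in the header row and
    first column, any order — rows are aligned to the table's order) or a
    bare numeric block in table order.  Asymmetric input is symmetrized
    entrywise by the maximum of the two orientations, with a warning:
    counts from A-seeded vs B-seeded tracking differ only by seeding and
    the graphs are treated as undirected.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    try:
        # bare numeric block: header row parsed as numbers
        float(str(df.columns[0]))
        raw = pd.read_csv(path, sep="\t", header=None)
        m = raw.to_numpy(dtype=float)
        labels = table.abbreviations
        if m.shape != (len(labels), len(labels)):
            raise ValueError(
                f"bare matrix shape {m.shape} does not match "
                f"{len(labels)}-region table"
            )
    except ValueError as err:
        if "does not match" in str(err):
            raise
        labels = table.abbreviations
        unknown = sorted(set(df.index) - set(labels)) + sorted(set(df.columns) - set(labels))
        if unknown:
            raise ValueError(f"unknown region labels in matrix: {unknown}")
        if len(df) != len(labels) or len(df.columns) != len(labels):
            raise ValueError(
                f"matrix is {df.shape[0]}x{df.shape[1]} but the region table "
                f"has {len(labels)} regions"
            )
        m = df.loc[labels, labels].to_numpy(dtype=float)
    if (m < 0).any():
        raise ValueError("count matrix has negative entries")
    if not np.array_equal(m, m.T):
        warnings.warn(
            f"asymmetric count matrix {path!r}: symmetrizing by max(a_ij, a_ji)",
            stacklevel=2,
        )
        m = np.maximum(m, m.T)
    if np.diag(m).any():
        warnings.warn(f"nonzero diagonal in {path!r}: self-counts dropped", stacklevel=2)
        np.fill_diagonal(m, 0.0)
    return Connectome(animal_id=animal_id, group=group, counts=m, labels=list(labels),
                      table=table)


def normalize(matrix, labels: Sequence[str] | None = None,
              provenance: str = "whole") -> WeightedGraphView:
    """Divide all entries by the matrix maximum so the largest weight is 1."""
    if isinstance(matrix, WeightedGraphView):
        labels, provenance = matrix.labels, matrix.provenance
        matrix = matrix.weights
    elif isinstance(matrix, Connectome):
        labels = matrix.labels
        matrix = matrix.counts
    m = np.asarray(matrix, dtype=float)
    peak = m.max()
    if peak <= 0:
        raise ValueError("empty graph: all-zero matrix cannot be normalized")
    if labels is None:
        labels = [str(i) for i in range(m.shape[0])]
    return WeightedGraphView(m / peak, list(labels), provenance)


def threshold(view: WeightedGraphView, t: float = EXTRACTION_THRESHOLD) -> WeightedGraphView:
    """Zero out weights strictly below ``t``; ``t=0`` is the identity."""
    if not 0 <= t < 1:
        raise ValueError("threshold must lie in [0, 1)")
    w = view.weights.copy()
    w[w < t] = 0.0
    return WeightedGraphView(w, view.labels, view.provenance)


def hemisphere_block(c: Connectome, table: RegionTable, mode: str) -> tuple[np.ndarray, list[str]]:
    """Extract the raw 36x36 hemisphere block of the count matrix.

    ``ipsilateral-L``/``-R`` are the within-hemisphere blocks;
    ``contralateral-LR``/``-RL`` the cross-hemisphere blocks (transposes
    of one another for symmetric counts).  Row labels are abbreviation
    stems (hemisphere prefix stripped).
    """
    if mode not in HEMISPHERE_MODES:
        raise ValueError(f"mode must be one of {HEMISPHERE_MODES}")
    lids = table.hemisphere_ids("L")
    rids = table.hemisphere_ids("R")
    stems = table.stems
    if mode == "ipsilateral-L":
        block = c.counts[np.ix_(lids, lids)]
    elif mode == "ipsilateral-R":
        block = c.counts[np.ix_(rids, rids)]
    elif mode == "contralateral-LR":
        block = c.counts[np.ix_(lids, rids)]
    else:
        block = c.counts[np.ix_(rids, lids)]
    return block, stems


def hemisphere_view(c: Connectome, table: RegionTable, mode: str,
                    t: float = EXTRACTION_THRESHOLD) -> WeightedGraphView:
    """Normalized, thresholded hemisphere view of a connectome.

    The contralateral cross-block is asymmetric with homolog-to-homolog
    crossings on its diagonal; it is symmetrized by the mean of the two
    orientations and the diagonal is dropped so the result is a valid
    undirected graph over the 36 abbreviation stems.
    """
    block, stems = hemisphere_block(c, table, mode)
    if mode.startswith("contralateral"):
        block = (block + block.T) / 2.0
        block = block.copy()
        np.fill_diagonal(block, 0.0)
    return threshold(normalize(block, stems, provenance=mode), t)


def merge_rois(c: Connectome, rois: Sequence[CompositeROI], table: RegionTable) -> Connectome:
    """Merge composite-ROI members into single nodes, per hemisphere.

    Counts between merged nodes are sums over member-pair counts; counts
    internal to a composite (member-to-member) are dropped to keep the
    diagonal zero.  Off-ROI edge mass is conserved.  ROIs must be
    disjoint.
    """
    n = c.n_regions
    assignment = {}  # region_id -> new label
    for roi in rois:
        for hemi in ("L", "R"):
            ids = resolve_composite(table, roi, hemi)
            for i in ids:
                if i in assignment:
                    raise ValueError(
                        f"overlapping ROIs: region {table.abbreviations[i]!r} "
                        f"claimed by {assignment[i]!r} and {hemi + ':' + roi.label!r}"
                    )
                assignment[i] = f"{hemi}{roi.label}"
    new_labels: list[str] = []
    for i in range(n):
        lab = assignment.get(i, c.labels[i])
        if lab not in new_labels:
            new_labels.append(lab)
    # membership matrix: rows new nodes, cols original regions
    M = np.zeros((len(new_labels), n))
    pos = {lab: k for k, lab in enumerate(new_labels)}
    for i in range(n):
        M[pos[assignment.get(i, c.labels[i])], i] = 1.0
    merged = M @ c.counts @ M.T
    np.fill_diagonal(merged, 0.0)
    return Connectome(animal_id=c.animal_id, group=c.group, counts=merged,
                      labels=new_labels)


def export_chord_table(view: WeightedGraphView | Connectome) -> pd.DataFrame:
    """Edge list for chord-diagram rendering: one row per undirected edge.

    Columns ``region_a``, ``region_b``, ``weight``; upper triangle only,
    positive weights only, so ribbon widths are to scale with connection
    strength.
    """
    if isinstance(view, Connectome):
        w, labels = view.counts, view.labels
    else:
        w, labels = view.weights, view.labels
    iu, ju = np.triu_indices(len(labels), k=1)
    mask = w[iu, ju] > 0
    return pd.DataFrame({
        "region_a": [labels[i] for i in iu[mask]],
        "region_b": [labels[j] for j in ju[mask]],
        "weight": w[iu[mask], ju[mask]],
    })
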