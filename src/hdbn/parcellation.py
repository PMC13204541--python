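"""Bilateral region parcellation: region tables, homolog pairing, composite ROIs.

The analysis operates on a 72-region parcellation of the mouse brain, 36
regions per hemisphere, with every left-hemisphere region paired to its
right-hemisphere homolog.  All downstream mathematics depends only on the
cardinality and labelling of this table, so the packaged default can be
replaced by any user-supplied TSV with the same columns.

Hemisphere is encoded by the leading ``L``/``R`` character of each
abbreviation (``LCC`` / ``RCC``) unless an explicit ``hemisphere`` column
overrides it.  Homolog pairing is built by matching abbreviation stems
across the two prefixes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from importlib import resources
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "RegionTable",
    "CompositeROI",
    "load_region_table",
    "default_region_table",
    "generic_region_table",
    "predetermined_rois",
    "resolve_composite",
]

EXPECTED_REGIONS = 72

_REQUIRED_COLUMNS = ("id", "abbreviation", "name", "hemisphere")


@dataclass(frozen=True)
class CompositeROI:
    """A named region of interest built from one or more atlas regions.

    ``members`` are abbreviation *stems* (hemisphere prefix stripped); the
    ROI is resolved to concrete region ids separately for each hemisphere.
    """

    label: str
    members: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError(f"composite ROI {self.label!r} has no members")
        if len(set(self.members)) != len(self.members):
            raise ValueError(f"composite ROI {self.label!r} has duplicate members")


class RegionTable:
    """The bilateral parcellation table binding region ids to labels.

    Wraps a DataFrame with columns ``id``, ``abbreviation``, ``name``,
    ``hemisphere`` and ``homolog_id`` and validates the bilateral
    invariants: unique abbreviations, equal hemisphere counts, and a
    homolog map that is an involution crossing hemispheres.
    """

    def __init__(self, df: pd.DataFrame, strict: bool = False):
        df = df.reset_index(drop=True).copy()
        missing = [c for c in _REQUIRED_COLUMNS if c not in df.columns and c != "hemisphere"]
        if missing:
            raise ValueError(f"region table missing columns: {missing}")
        if "hemisphere" not in df.columns:
            df["hemisphere"] = [a[0] for a in df["abbreviation"]]
        if df["abbreviation"].duplicated().any():
            dups = sorted(df.loc[df["abbreviation"].duplicated(), "abbreviation"])
            raise ValueError(f"duplicate abbreviations in region table: {dups}")
        bad_hemi = set(df["hemisphere"]) - {"L", "R"}
        if bad_hemi:
            raise ValueError(f"hemisphere values must be L or R, got {sorted(bad_hemi)}")
        n = len(df)
        if n != EXPECTED_REGIONS:
            msg = f"region table has {n} rows, expected {EXPECTED_REGIONS}"
            if strict:
                raise ValueError(msg)
            warnings.warn(msg, stacklevel=3)
        n_l = int((df["hemisphere"] == "L").sum())
        n_r = int((df["hemisphere"] == "R").sum())
        if n_l != n_r:
            raise ValueError(f"unbalanced hemispheres: {n_l} L vs {n_r} R")

        if "homolog_id" not in df.columns or df["homolog_id"].isna().any():
            df["homolog_id"] = self._build_homologs(df)
        df["id"] = df["id"].astype(int)
        df["homolog_id"] = df["homolog_id"].astype(int)
        df = df.sort_values("id").reset_index(drop=True)
        if not np.array_equal(df["id"].to_numpy(), np.arange(n)):
            raise ValueError("region ids must be 0..n-1 with no gaps")
        # involution crossing hemispheres
        hom = df["homolog_id"].to_numpy()
        if not np.array_equal(hom[hom], np.arange(n)):
            raise ValueError("homolog map is not an involution")
        hemi = df["hemisphere"].to_numpy()
        if (hemi[hom] == hemi).any():
            raise ValueError("homolog map does not cross hemispheres")
        self.df = df
        self._id_by_abbrev = dict(zip(df["abbreviation"], df["id"]))

    @staticmethod
    def _build_homologs(df: pd.DataFrame) -> list[int]:
        by_key = {(h, a[1:] if a[0] in "LR" else a): i
                  for i, (a, h) in zip(df["id"], zip(df["abbreviation"], df["hemisphere"]))}
        out = []
        for a, h in zip(df["abbreviation"], df["hemisphere"]):
            stem = a[1:] if a[0] in "LR" else a
            other = "R" if h == "L" else "L"
            try:
                out.append(by_key[(other, stem)])
            except KeyError:
                raise ValueError(
                    f"region {a!r} has no homolog in hemisphere {other}"
                ) from None
        return out

    # -- basic accessors -------------------------------------------------
    @property
    def n_regions(self) -> int:
        return len(self.df)

    @property
    def abbreviations(self) -> list[str]:
        return list(self.df["abbreviation"])

    @property
    def stems(self) -> list[str]:
        """Abbreviation stems in left-hemisphere id order."""
        return [a[1:] if a[0] in "LR" else a
                for a in self.df.loc[self.df["hemisphere"] == "L", "abbreviation"]]

    def hemisphere_ids(self, hemisphere: str) -> np.ndarray:
        if hemisphere not in ("L", "R"):
            raise ValueError("hemisphere must be 'L' or 'R'")
        return self.df.loc[self.df["hemisphere"] == hemisphere, "id"].to_numpy()

    def homolog(self, region_id: int) -> int:
        return int(self.df.loc[region_id, "homolog_id"])

    def id_of(self, abbreviation: str) -> int:
        try:
            return int(self._id_by_abbrev[abbreviation])
        except KeyError:
            raise KeyError(f"unknown region abbreviation {abbreviation!r}") from None

    def __len__(self) -> int:
        return self.n_regions

    def __repr__(self) -> str:
        return f"RegionTable({self.n_regions} regions, {len(self.hemisphere_ids('L'))}/hemisphere)"


def load_region_table(path=None, strict: bool = False) -> RegionTable:
    """Load a region table from TSV, or the packaged default when ``path`` is None.

    The TSV must be tab-separated with a header row and columns ``id``,
    ``abbreviation``, ``name``; ``hemisphere`` and ``homolog_id`` are
    optional (derived from the L/R abbreviation prefix when absent).
    With ``strict=True`` a row count other than 72 is an error rather
    than a warning.
    """
    if path is None:
        ref = resources.files("hdbn.data").joinpath("regions_default.tsv")
        with resources.as_file(ref) as p:
            df = pd.read_csv(p, sep="\t")
    else:
        df = pd.read_csv(path, sep="\t")
    return RegionTable(df, strict=strict)


def default_region_table() -> RegionTable:
    """The packaged 72-region bilateral table."""
    return load_region_table(None)


def generic_region_table(n_regions: int) -> RegionTable:
    """A synthetic balanced parcellation with ``n_regions`` regions.

    Used by the cohort simulator for non-default sizes; abbreviations are
    ``L01..`` / ``R01..``.
    """
    if n_regions % 2 or n_regions < 2:
        raise ValueError("n_regions must be even and >= 2")
    half = n_regions // 2
    rows = [(i, f"L{i + 1:02d}", f"synthetic region {i + 1:02d} left", "L") for i in range(half)]
    rows += [(half + i, f"R{i + 1:02d}", f"synthetic region {i + 1:02d} right", "R")
             for i in range(half)]
    df = pd.DataFrame(rows, columns=["id", "abbreviation", "name", "hemisphere"])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return RegionTable(df)


#: The ten predetermined regions of interest, in their canonical order.
#: The hippocampus is the union of the CA fields and dentate gyrus; the
#: isocortex stands in for the visual cortex.
_PREDETERMINED: tuple[CompositeROI, ...] = (
    CompositeROI("cerebellum", ("CB",)),
    CompositeROI("entorhinal cortex", ("EC",)),
    CompositeROI("hippocampus", ("CA1", "CA2", "CA3", "DG")),
    CompositeROI("hypothalamus", ("HY",)),
    CompositeROI("medulla", ("MED",)),
    CompositeROI("somatomotor cortex", ("MO",)),
    CompositeROI("somatosensory cortex", ("SS",)),
    CompositeROI("superior colliculus", ("SUC",)),
    CompositeROI("thalamus", ("TH",)),
    CompositeROI("visual cortex", ("ICtx",)),
)


def predetermined_rois() -> list[CompositeROI]:
    """The ten predetermined composite ROIs, in canonical order."""
    return list(_PREDETERMINED)


def resolve_roi_label(label: str) -> CompositeROI:
    """Look up a predetermined ROI by (case-insensitive) label."""
    for roi in _PREDETERMINED:
        if roi.label.lower() == label.lower():
            return roi
    raise KeyError(
        f"unknown ROI label {label!r}; known: {[r.label for r in _PREDETERMINED]}"
    )


def resolve_composite(table: RegionTable, roi: CompositeROI | str,
                      hemisphere: str) -> tuple[int, ...]:
    """Resolve a composite ROI to region ids within one hemisphere.

    Returns ids in ascending order.  Raises ``KeyError`` naming any
    member absent from the requested hemisphere.
    """
    if isinstance(roi, str):
        roi = resolve_roi_label(roi)
    if hemisphere not in ("L", "R"):
        raise ValueError("hemisphere must be 'L' or 'R'")
    ids = []
    for stem in roi.members:
        abbrev = hemisphere + stem
        try:
            ids.append(table.id_of(abbrev))
        except KeyError:
            raise KeyError(
                f"ROI {roi.label!r} member {stem!r} not found in hemisphere "
                f"{hemisphere} (no region {abbrev!r})"
            ) from None
    return tuple(sorted(ids))
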