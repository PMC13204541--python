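"""Diffusion-tensor scalars and region-wise group comparison.

From the sorted tensor eigenvalues (lambda1 >= lambda2 >= lambda3, in
mm^2/s) the four standard scalars are derived:

* axial diffusivity      AD = lambda1
* radial diffusivity     RD = (lambda2 + lambda3) / 2
* mean diffusivity       MD = (lambda1 + lambda2 + lambda3) / 3
* fractional anisotropy  FA = sqrt(3/2) * ||lambda - MD|| / ||lambda||

FA is the standard Basser-Pierpaoli fractional anisotropy, ranging from
0 (isotropic) to 1 (totally anisotropic, a single nonzero eigenvalue).

Group comparison runs a pooled-variance two-sample t-test per region on
per-animal region means, corrects across regions (BH by default), and
attaches a direction sign: positive where the KO mean exceeds WT.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, NamedTuple, Sequence

import numpy as np
import pandas as pd

from .groupstats import bh_adjust, pooled_ttest

__all__ = [
    "DiffusivityScalars",
    "DiffusivityRecord",
    "diffusivity_scalars",
    "records_to_frame",
    "compare_regions",
    "SCALARS",
]

SCALARS = ("FA", "MD", "AD", "RD")


class DiffusivityScalars(NamedTuple):
    fa: float
    md: float
    ad: float
    rd: float


def diffusivity_scalars(lambda1: float, lambda2: float, lambda3: float) -> DiffusivityScalars:
    """FA, MD, AD, RD from a sorted nonnegative eigenvalue triple.

    Raises on unsorted or all-zero (degenerate) input.  FA is clipped to
    [0, 1] only against floating-point overshoot.
    """
    lam = np.array([lambda1, lambda2, lambda3], dtype=float)
    if not (lam[0] >= lam[1] >= lam[2]):
        raise ValueError(f"eigenvalues must satisfy lambda1 >= lambda2 >= lambda3, got {lam}")
    if lam[2] < 0:
        raise ValueError("eigenvalues must be nonnegative")
    norm = np.sqrt((lam ** 2).sum())
    if norm == 0:
        raise ValueError("degenerate tensor: all eigenvalues zero")
    md = float(lam.mean())
    fa = float(np.sqrt(1.5) * np.sqrt(((lam - md) ** 2).sum()) / norm)
    fa = min(max(fa, 0.0), 1.0)
    return DiffusivityScalars(fa=fa, md=md, ad=float(lam[0]),
                              rd=float((lam[1] + lam[2]) / 2.0))


@dataclass(frozen=True)
class DiffusivityRecord:
    """Per-animal per-region tensor eigenvalues and derived scalars."""

    animal_id: str
    group: str
    region_id: int
    lambda1: float
    lambda2: float
    lambda3: float

    @property
    def scalars(self) -> DiffusivityScalars:
        return diffusivity_scalars(self.lambda1, self.lambda2, self.lambda3)

    @property
    def fa(self) -> float:
        return self.scalars.fa

    @property
    def md(self) -> float:
        return self.scalars.md

    @property
    def ad(self) -> float:
        return self.scalars.ad

    @property
    def rd(self) -> float:
        return self.scalars.rd


def records_to_frame(records: Iterable[DiffusivityRecord]) -> pd.DataFrame:
    """Flatten records into a tidy frame with eigenvalues and scalars."""
    rows = []
    for r in records:
        s = r.scalars
        rows.append({
            "animal_id": r.animal_id, "group": r.group, "region_id": r.region_id,
            "lambda1": r.lambda1, "lambda2": r.lambda2, "lambda3": r.lambda3,
            "FA": s.fa, "MD": s.md, "AD": s.ad, "RD": s.rd,
        })
    return pd.DataFrame(rows)


def compare_regions(records: Sequence[DiffusivityRecord] | pd.DataFrame,
                    scalar: str = "FA", correction: str = "bh",
                    q: float = 0.05) -> pd.DataFrame:
    """Region-wise group comparison of one diffusivity scalar.

    Returns one row per region: group means, pooled t, raw and adjusted
    p, direction sign (+1 where KO mean > WT), and a flag where
    |adjusted p| < 0.05.  Regions with fewer than two animals per group
    are marked not testable.  ``correction``: ``bh`` (default),
    ``bonferroni``, or ``none``.
    """
    if scalar not in SCALARS:
        raise ValueError(f"scalar must be one of {SCALARS}")
    if correction not in ("bh", "bonferroni", "none"):
        raise ValueError("correction must be 'bh', 'bonferroni' or 'none'")
    df = records if isinstance(records, pd.DataFrame) else records_to_frame(records)
    rows = []
    for region_id, sub in df.groupby("region_id", sort=True):
        wt = sub.loc[sub["group"] == "WT", scalar].to_numpy()
        ko = sub.loc[sub["group"] == "KO", scalar].to_numpy()
        if wt.size < 2 or ko.size < 2:
            rows.append({"region_id": region_id, "scalar": scalar,
                         "mean_WT": np.nan, "mean_KO": np.nan, "t": np.nan,
                         "df": 0, "p_raw": np.nan, "sign": 0, "testable": False})
            continue
        r = pooled_ttest(wt, ko)
        rows.append({"region_id": region_id, "scalar": scalar,
                     "mean_WT": float(wt.mean()), "mean_KO": float(ko.mean()),
                     "t": r.t, "df": r.df, "p_raw": r.p, "sign": r.sign,
                     "testable": True})
    out = pd.DataFrame(rows)
    testable = out["testable"].to_numpy()
    p = out.loc[testable, "p_raw"].to_numpy()
    if correction == "bh":
        p_adj, _ = bh_adjust(p, q)
    elif correction == "bonferroni":
        p_adj = np.minimum(p * p.size, 1.0)
    else:
        p_adj = p
    out["p_adj"] = np.nan
    out.loc[testable, "p_adj"] = p_adj
    out["signed_p_adj"] = out["sign"].replace(0, 1) * out["p_adj"]
    out["flag"] = out["p_adj"] < 0.05
    return out
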