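"""Two-group statistics: edgewise comparison with signed FDR, region totals,
and network-parameter tests.

The edgewise pipeline compares the distribution of streamline counts
between the two groups over all n(n-1)/2 unordered region pairs of a
hemisphere view: pairs where more than half of the observations are
zero are excluded, counts are log-transformed after adding a pseudo
count of 1, each remaining pair gets a pooled-variance two-sample
t-test (df = n_WT + n_KO - 2), and raw p-values are adjusted with the
Benjamini-Hochberg step-up procedure controlling the FDR at 5%.
Adjusted p-values carry an artificial sign: positive where the KO group
mean exceeds the WT mean, negative otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence, TYPE_CHECKING

import numpy as np
import pandas as pd
from scipy import stats as _st

if TYPE_CHECKING:  # pragma: no cover
    from .simulate import CohortStudy

__all__ = [
    "enumerate_pairs",
    "zero_filter",
    "log_transform",
    "edge_ttest",
    "pooled_ttest",
    "bh_adjust",
    "assign_bins",
    "SignedPMatrix",
    "EdgewiseResult",
    "edgewise_compare",
    "pair_observations",
    "region_streamline_compare",
    "compare_network_params",
]

DEFAULT_FDR_Q = 0.05


def enumerate_pairs(n_regions: int) -> list[tuple[int, int]]:
    """All n(n-1)/2 unordered index pairs in lexicographic order."""
    if n_regions < 2:
        raise ValueError("need at least 2 regions to form pairs")
    return [(i, j) for i in range(n_regions) for j in range(i + 1, n_regions)]


def zero_filter(values) -> tuple[bool, float]:
    """Exclusion rule for sparse pairs: drop when >50% of observations are 0.

    Returns ``(included, zero_fraction)``; a fraction of exactly one half
    is kept (0.5 is not greater than 50%).
    """
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("zero_filter needs at least one observation")
    frac = float((v == 0).mean())
    return frac <= 0.5, frac


def log_transform(counts):
    """Natural log of (count + 1), elementwise."""
    c = np.asarray(counts, dtype=float)
    if (c < 0).any():
        raise ValueError("counts must be nonnegative")
    return np.log1p(c)


def _pooled_t_arrays(wt: np.ndarray, ko: np.ndarray):
    """Vectorized pooled-variance t over the last axis being observations.

    ``wt``: (n_wt, m), ``ko``: (n_ko, m).  Returns (t, df, p, sign) with
    sign +1 where mean(ko) > mean(wt), -1 where smaller, 0 on ties.
    Degenerate pairs (both variances zero): equal means give t=0, p=1;
    differing means give an infinite t and the smallest positive float
    as p.
    """
    n1, n2 = wt.shape[0], ko.shape[0]
    if n1 < 2 or n2 < 2:
        raise ValueError("need at least 2 observations per group")
    m1, m2 = wt.mean(axis=0), ko.mean(axis=0)
    v1 = wt.var(axis=0, ddof=1)
    v2 = ko.var(axis=0, ddof=1)
    df = n1 + n2 - 2
    sp2 = ((n1 - 1) * v1 + (n2 - 1) * v2) / df
    se = np.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
    diff = m1 - m2
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, diff / np.where(se > 0, se, 1.0), 0.0)
    p = 2.0 * _st.t.sf(np.abs(t), df)
    sign = np.sign(m2 - m1).astype(int)
    # degenerate: zero pooled variance
    degen = se == 0
    equal = degen & (diff == 0)
    differ = degen & (diff != 0)
    t = np.where(equal, 0.0, t)
    p = np.where(equal, 1.0, p)
    t = np.where(differ, np.where(diff > 0, np.inf, -np.inf), t)
    p = np.where(differ, np.finfo(float).tiny, p)
    p = np.where(sign == 0, 1.0, p)
    return t, df, p, sign


@dataclass(frozen=True)
class TTestResult:
    t: float
    df: int
    p: float
    sign: int
    degenerate: bool = False


def pooled_ttest(wt, ko) -> TTestResult:
    """Pooled-variance (Student) two-sample t-test of WT vs KO samples."""
    wt = np.asarray(wt, dtype=float).reshape(-1, 1)
    ko = np.asarray(ko, dtype=float).reshape(-1, 1)
    t, df, p, sign = _pooled_t_arrays(wt, ko)
    degen = bool(np.isinf(t[0]))
    return TTestResult(float(t[0]), int(df), float(p[0]), int(sign[0]), degen)


def edge_ttest(wt, ko) -> tuple[float, int, float, int]:
    """Pooled t for one edge: returns (t, df, p_raw, sign)."""
    r = pooled_ttest(wt, ko)
    return r.t, r.df, r.p, r.sign


def bh_adjust(p_values, q: float = DEFAULT_FDR_Q) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up adjusted p-values and discovery flags.

    Adjusted values are monotone and capped at 1; a pair is a discovery
    when its adjusted value is <= q.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return np.array([]), np.array([], dtype=bool)
    if (p <= 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in (0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.minimum(adj, 1.0)
    out = np.empty(m)
    out[order] = adj
    return out, out <= q


def assign_bins(p_adj_abs: np.ndarray, convention: str = "text") -> np.ndarray:
    """Display bins for adjusted p magnitudes.

    ``text`` convention: dark for |p| < 0.01, light for 0.01 <= |p| < 0.05,
    none otherwise.  ``legend`` convention labels the dark band as
    0.005-0.01 (values below 0.005 saturate into dark).
    """
    if convention not in ("text", "legend"):
        raise ValueError("convention must be 'text' or 'legend'")
    bins = np.full(p_adj_abs.shape, "none", dtype=object)
    with np.errstate(invalid="ignore"):
        light = (p_adj_abs >= 0.01) & (p_adj_abs < 0.05)
        dark = p_adj_abs < 0.01
    bins[light] = "light"
    bins[dark] = "dark"
    return bins


@dataclass
class SignedPMatrix:
    """Symmetric matrix of signed BH-adjusted p-values.

    Positive entries: KO > WT; negative: WT > KO; NaN where the pair was
    excluded by the zero filter.
    """

    values: pd.DataFrame
    mode: str

    def __post_init__(self) -> None:
        v = self.values.to_numpy()
        if not np.allclose(v, v.T, equal_nan=True):
            raise ValueError("signed p-matrix must be symmetric")

    @property
    def labels(self) -> list[str]:
        return list(self.values.index)


@dataclass
class EdgewiseResult:
    """Full output of the edgewise comparison: tidy table plus signed matrix."""

    table: pd.DataFrame
    matrix: SignedPMatrix
    mode: str
    q: float


def pair_observations(cohort: "CohortStudy", mode: str = "ipsilateral"):
    """Per-animal per-pair streamline observations for one hemisphere mode.

    Ipsilateral: mean of the L-L and R-R entries of each stem pair
    (both hemispheres' within-hemisphere connections combined).
    Contralateral: mean of the L-R and R-L cross-hemisphere entries.

    Returns ``(wt, ko, pairs, stems)`` where ``wt``/``ko`` are arrays of
    shape (n_animals, n_pairs) ordered as :func:`enumerate_pairs`.
    """
    if mode not in ("ipsilateral", "contralateral"):
        raise ValueError("mode must be 'ipsilateral' or 'contralateral'")
    table = cohort.table
    lids = table.hemisphere_ids("L")
    rids = table.hemisphere_ids("R")
    stems = table.stems
    pairs = enumerate_pairs(len(stems))
    ai = np.array([p[0] for p in pairs])
    bj = np.array([p[1] for p in pairs])

    def values_for(c) -> np.ndarray:
        if mode == "ipsilateral":
            v1 = c.counts[lids[ai], lids[bj]]
            v2 = c.counts[rids[ai], rids[bj]]
        else:
            v1 = c.counts[lids[ai], rids[bj]]
            v2 = c.counts[rids[ai], lids[bj]]
        return (v1 + v2) / 2.0

    wt = np.array([values_for(c) for c in cohort.connectomes if c.group == "WT"])
    ko = np.array([values_for(c) for c in cohort.connectomes if c.group == "KO"])
    return wt, ko, pairs, stems


def edgewise_compare(cohort: "CohortStudy", mode: str = "ipsilateral",
                     q: float = DEFAULT_FDR_Q,
                     bin_convention: str = "text") -> EdgewiseResult:
    """The full edgewise pipeline on one cohort and hemisphere mode.

    zero filter -> log(x+1) -> pooled t per pair -> BH across all
    included pairs of this mode jointly -> signed adjusted-p matrix and
    display bins.
    """
    wt, ko, pairs, stems = pair_observations(cohort, mode)
    if wt.shape[0] < 2 or ko.shape[0] < 2:
        raise ValueError("edgewise comparison needs at least 2 animals per group")
    allv = np.vstack([wt, ko])
    zero_frac = (allv == 0).mean(axis=0)
    included = zero_frac <= 0.5
    if not included.any():
        raise ValueError("no testable pairs: all pairs excluded by the zero filter")

    lw = log_transform(wt[:, included])
    lk = log_transform(ko[:, included])
    t, df, p_raw, sign = _pooled_t_arrays(lw, lk)
    p_adj, _ = bh_adjust(p_raw, q)

    n_pairs = len(pairs)
    cols = {
        "region_a": [stems[a] for a, _ in pairs],
        "region_b": [stems[b] for _, b in pairs],
        "n_zero_fraction": zero_frac,
        "included": included,
        "t": np.full(n_pairs, np.nan),
        "df": np.where(included, df, 0).astype(int),
        "p_raw": np.full(n_pairs, np.nan),
        "p_adj": np.full(n_pairs, np.nan),
        "sign": np.zeros(n_pairs, dtype=int),
    }
    tab = pd.DataFrame(cols)
    idx = np.flatnonzero(included)
    tab.loc[idx, "t"] = t
    tab.loc[idx, "p_raw"] = p_raw
    tab.loc[idx, "p_adj"] = p_adj
    tab.loc[idx, "sign"] = sign
    tab["discovery"] = tab["p_adj"] <= q
    tab["bin"] = assign_bins(tab["p_adj"].to_numpy(), bin_convention)
    tab.loc[~tab["included"], "bin"] = "none"

    n = len(stems)
    mat = np.full((n, n), np.nan)
    ai = np.array([p[0] for p in pairs])[idx]
    bj = np.array([p[1] for p in pairs])[idx]
    signed = np.where(sign == 0, p_adj, sign * p_adj)
    mat[ai, bj] = signed
    mat[bj, ai] = signed
    matrix = SignedPMatrix(pd.DataFrame(mat, index=stems, columns=stems), mode)
    return EdgewiseResult(table=tab, matrix=matrix, mode=mode, q=q)


def region_streamline_compare(cohort: "CohortStudy",
                              q: float = DEFAULT_FDR_Q) -> pd.DataFrame:
    """Group comparison of per-region total streamline counts.

    Per animal, a region's value is the row sum of its count matrix;
    groups are compared per region with a pooled t-test and BH-adjusted
    across regions.
    """
    labels = cohort.connectomes[0].labels
    wt = np.array([c.region_totals() for c in cohort.connectomes if c.group == "WT"])
    ko = np.array([c.region_totals() for c in cohort.connectomes if c.group == "KO"])
    if wt.shape[0] < 2 or ko.shape[0] < 2:
        raise ValueError("need at least 2 animals per group")
    t, df, p_raw, sign = _pooled_t_arrays(wt, ko)
    p_adj, disc = bh_adjust(p_raw, q)
    return pd.DataFrame({
        "region": labels,
        "mean_WT": wt.mean(axis=0),
        "mean_KO": ko.mean(axis=0),
        "t": t,
        "df": df,
        "p_raw": p_raw,
        "p_adj": p_adj,
        "sign": sign,
        "discovery": disc,
    })


def compare_network_params(metrics: pd.DataFrame) -> pd.DataFrame:
    """t-tests on network parameters between groups, one per metric.

    ``metrics`` is a tidy frame with columns ``animal_id``, ``group``,
    ``provenance``, ``metric``, ``value``.  Undefined (NaN) values are
    dropped with their count reported; no multiplicity correction is
    applied (noted in the output).  Metrics left with fewer than two
    observations in either group are marked not testable.
    """
    required = {"animal_id", "group", "provenance", "metric", "value"}
    if not required.issubset(metrics.columns):
        raise ValueError(f"metrics frame must have columns {sorted(required)}")
    rows = []
    for (prov, metric), sub in metrics.groupby(["provenance", "metric"], sort=True):
        n_dropped = int(sub["value"].isna().sum())
        sub = sub.dropna(subset=["value"])
        wt = sub.loc[sub["group"] == "WT", "value"].to_numpy()
        ko = sub.loc[sub["group"] == "KO", "value"].to_numpy()
        if wt.size < 2 or ko.size < 2:
            rows.append({"provenance": prov, "metric": metric,
                         "mean_WT": np.nan, "mean_KO": np.nan, "t": np.nan,
                         "df": 0, "p": np.nan, "sign": 0,
                         "n_dropped": n_dropped, "testable": False})
            continue
        r = pooled_ttest(wt, ko)
        rows.append({"provenance": prov, "metric": metric,
                     "mean_WT": float(wt.mean()), "mean_KO": float(ko.mean()),
                     "t": r.t, "df": r.df, "p": r.p, "sign": r.sign,
                     "n_dropped": n_dropped, "testable": True})
    out = pd.DataFrame(rows)
    out.attrs["correction"] = "none"
    return out
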