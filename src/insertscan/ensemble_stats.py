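"""Ensemble-level statistics over per-mutant metric tables.

The substrate is a :class:`MutantEnsemble`: one row per double-insertion
mutant with metric columns (hbc, cce, rop) and annotation columns (elongated
positions, inserted residues, wildtype gaps, helix group, size group).

Analyses: two-sided k-sigma outlier sets, residue / residue-pair / position
frequency tallies over outliers, top-k pair rankings with per-element
breakdowns, Cohen's d with a pooled-variance two-sample t-test, helix-group
comparisons (I_XX / I_XH / I_HH), within-group normalized outlier rates by
amino-acid size class, and the HBC-by-pair grid ordered from the smallest
pair (GG) to the largest (WW).

Conventions: outlier thresholds use the population standard deviation of
the whole ensemble; effect sizes use sample (ddof=1) standard deviations
and the root-mean-square pooled form  d = (M1 - M2) / sqrt((s1^2+s2^2)/2).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations, combinations_with_replacement

import numpy as np
import pandas as pd
from scipy import stats as sps

from .chem import RESIDUE_VOLUME, STANDARD_AA1
from .mutant_space import (HELIX_GROUPS, HOMOGENEOUS_PAIR_LABELS, SIZE_CLASSES,
                           SIZE_ORDER)
from .structure_model import ProteinStructure, gap_in_helix

METRIC_COLUMNS = ("hbc", "cce", "rop")
ANNOTATION_COLUMNS = ("pos1", "pos2", "aa1", "aa2", "gap1", "gap2",
                      "helix_group", "size_group")


@dataclass
class MutantEnsemble:
    """Validated per-mutant metric table keyed by mutant_id."""
    records: pd.DataFrame

    def __post_init__(self):
        df = self.records
        required = {"mutant_id", *METRIC_COLUMNS, *ANNOTATION_COLUMNS}
        missing = required - set(df.columns)
        if missing:
            raise ValueError(f"ensemble missing columns: {sorted(missing)}")
        if df["mutant_id"].duplicated().any():
            raise ValueError("duplicate mutant_id")
        if (df["hbc"] < 0).any():
            raise ValueError("hbc must be non-negative")
        if ((df["cce"] < 0) | (df["cce"] > 1)).any():
            raise ValueError("cce out of [0, 1]")
        if ((df["rop"] <= 0) | (df["rop"] > 1)).any():
            raise ValueError("rop out of (0, 1]")

    def __len__(self) -> int:
        return len(self.records)

    @classmethod
    def from_csv(cls, path, **kwargs) -> "MutantEnsemble":
        return cls(pd.read_csv(path, **kwargs))

    def to_csv(self, path) -> None:
        self.records.to_csv(path, index=False)


@dataclass
class OutlierSet:
    metric: str
    k: float
    mean: float
    sd: float
    member_ids: set

    def __len__(self) -> int:
        return len(self.member_ids)


@dataclass(frozen=True)
class EffectSizeResult:
    """Standardized mean difference between two groups plus a pooled t-test."""
    m1: float
    m2: float
    sd1: float
    sd2: float
    sd_pooled: float
    d: float
    t: float
    p: float
    df: int
    n1: int
    n2: int


def outliers(ensemble: MutantEnsemble, metric: str, k: float = 2.0) -> OutlierSet:
    """Two-sided outlier set: mutants with |x - mean| >= k * sd.

    Mean and (population) standard deviation are taken over the whole
    ensemble.  A zero-variance metric yields an empty set with a warning.
    """
    df = ensemble.records
    if metric not in df.columns:
        raise KeyError(f"no metric column {metric!r}")
    if len(df) < 2:
        raise ValueError("need at least 2 records")
    x = df[metric].to_numpy(float)
    mean = float(x.mean())
    sd = float(x.std(ddof=0))
    if sd == 0.0:
        warnings.warn(f"metric {metric!r} has zero variance; no outliers defined")
        return OutlierSet(metric, k, mean, sd, set())
    mask = np.abs(x - mean) >= k * sd
    return OutlierSet(metric, k, mean, sd, set(df.loc[mask, "mutant_id"]))


def _outlier_rows(ensemble: MutantEnsemble, outlier_set: OutlierSet) -> pd.DataFrame:
    df = ensemble.records
    rows = df[df["mutant_id"].isin(outlier_set.member_ids)]
    if len(rows) != len(outlier_set.member_ids):
        raise ValueError("outlier ids not all present in ensemble")
    return rows


def residue_frequency(ensemble: MutantEnsemble,
                      outlier_set: OutlierSet) -> dict[str, int]:
    """Per-residue insertion counts over the outlier set.

    Each outlier mutant contributes one count per inserted residue
    occurrence, so a homotypic pair contributes 2 to its residue.
    """
    rows = _outlier_rows(ensemble, outlier_set)
    counts = dict.fromkeys(STANDARD_AA1, 0)
    for col in ("aa1", "aa2"):
        for aa, c in rows[col].value_counts().items():
            counts[aa] += int(c)
    return counts


def pair_frequency_matrix(ensemble: MutantEnsemble,
                          outlier_set: OutlierSet) -> pd.DataFrame:
    """Symmetric 20x20 count matrix of inserted pairs among outliers.

    An unordered heterotypic pair increments both (aa1, aa2) and
    (aa2, aa1); a homotypic pair increments its diagonal cell once.
    """
    rows = _outlier_rows(ensemble, outlier_set)
    aas = list(STANDARD_AA1)
    mat = pd.DataFrame(0, index=aas, columns=aas, dtype=int)
    for (a1, a2), c in rows.groupby(["aa1", "aa2"]).size().items():
        mat.loc[a1, a2] += int(c)
        if a1 != a2:
            mat.loc[a2, a1] += int(c)
    return mat


def position_frequency(ensemble: MutantEnsemble, outlier_set: OutlierSet,
                       structure: ProteinStructure) -> pd.DataFrame:
    """Per-gap insertion counts over outliers, with helix membership flags."""
    rows = _outlier_rows(ensemble, outlier_set)
    n = structure.n_residues
    counts = np.zeros(n + 1, dtype=int)
    for col in ("gap1", "gap2"):
        for g, c in rows[col].value_counts().items():
            counts[int(g)] += int(c)
    return pd.DataFrame({
        "gap": np.arange(n + 1),
        "count": counts,
        "in_helix": [gap_in_helix(structure, g) for g in range(n + 1)],
    })


def top_pairs(frequency: dict, k: int = 30) -> tuple[list[tuple], dict]:
    """Top-k pairs by count plus the 5 most frequent elements among them.

    ``frequency`` maps a pair (2-tuple of residues or positions) to a
    count.  Ties break lexicographically.  The element breakdown counts
    occurrences across the selected pairs weighted by each pair's count
    (a homotypic pair contributes twice per count).
    """
    if not frequency:
        raise ValueError("empty frequency tally")
    items = sorted(frequency.items(), key=lambda kv: (-kv[1], kv[0]))
    if k > len(items):
        warnings.warn(f"k={k} exceeds {len(items)} distinct pairs; returning all")
        k = len(items)
    top = items[:k]
    element_counts: dict = {}
    for pair, c in top:
        for el in pair:
            element_counts[el] = element_counts.get(el, 0) + c
    top5 = dict(sorted(element_counts.items(), key=lambda kv: (-kv[1], kv[0]))[:5])
    return [p for p, _ in top], top5


def cohens_d(group1, group2) -> EffectSizeResult:
    """Cohen's d with RMS-pooled sample sds, plus a pooled two-sample t-test.

    d = (M1 - M2) / sqrt((s1^2 + s2^2) / 2), with sample (ddof=1) standard
    deviations; benchmarks 0.2 / 0.5 / 0.8 for small / medium / large.
    """
    x1 = np.asarray(group1, float)
    x2 = np.asarray(group2, float)
    if len(x1) < 2 or len(x2) < 2:
        raise ValueError("each group needs n >= 2")
    m1, m2 = float(x1.mean()), float(x2.mean())
    s1, s2 = float(x1.std(ddof=1)), float(x2.std(ddof=1))
    if s1 == 0.0 and s2 == 0.0:
        raise ValueError("both groups have zero variance")
    pooled = float(np.sqrt((s1 ** 2 + s2 ** 2) / 2.0))
    t, p, dof = two_sample_t(x1, x2)
    return EffectSizeResult(m1=m1, m2=m2, sd1=s1, sd2=s2, sd_pooled=pooled,
                            d=(m1 - m2) / pooled, t=t, p=p, df=dof,
                            n1=len(x1), n2=len(x2))


def two_sample_t(group1, group2, equal_var: bool = True) -> tuple[float, float, int]:
    """Student pooled-variance two-sample t-test (Welch via equal_var=False).

    Returns (t, two-sided p, degrees of freedom).
    """
    x1 = np.asarray(group1, float)
    x2 = np.asarray(group2, float)
    if len(x1) < 2 or len(x2) < 2:
        raise ValueError("each group needs n >= 2")
    res = sps.ttest_ind(x1, x2, equal_var=equal_var)
    dof = int(res.df) if equal_var else res.df
    if equal_var and x1.std(ddof=1) == 0 and x2.std(ddof=1) == 0:
        raise ValueError("zero pooled variance")
    return float(res.statistic), float(res.pvalue), dof


def helix_group_comparison(ensemble: MutantEnsemble, metric: str,
                           ) -> dict[str, dict]:
    """Pairwise effect sizes between helix groups on one metric.

    Compares I_XX vs I_XH, I_XX vs I_HH and I_XH vs I_HH wherever both
    groups have at least two members (proteins without enough helix content
    simply lack the I_HH group).  Each entry carries the EffectSizeResult
    and per-group normal-curve summaries (mean, mean +/- sd) for plotting.
    """
    df = ensemble.records
    groups = {g: df.loc[df["helix_group"] == g, metric].to_numpy(float)
              for g in HELIX_GROUPS}
    out: dict[str, dict] = {}
    for ga, gb in combinations(HELIX_GROUPS, 2):
        xa, xb = groups[ga], groups[gb]
        if len(xa) < 2 or len(xb) < 2:
            if len(xa) or len(xb):
                warnings.warn(f"skipping {ga} vs {gb}: a group has n < 2")
            continue
        result = cohens_d(xa, xb)
        out[f"{ga}_vs_{gb}"] = {
            "effect": result,
            ga: _curve_summary(xa),
            gb: _curve_summary(xb),
        }
    return out


def _curve_summary(x: np.ndarray) -> dict:
    m = float(x.mean())
    s = float(x.std(ddof=1))
    return {"n": len(x), "mean": m, "sd": s, "lo": m - s, "hi": m + s}


def normalized_size_outlier_rates(ensemble: MutantEnsemble, metric: str,
                                  k: float = 2.0,
                                  denominator: str = "group",
                                  ) -> pd.DataFrame:
    """Outlier rates per amino-acid size group, singles and homogeneous pairs.

    A mutant counts toward a single class (VS..VL) when *either* inserted
    residue belongs to it, and toward a pair class (VSVS..VLVL) when both
    do.  With the default ``denominator="group"`` the rate is the fraction
    of that group's mutants that are outliers; ``denominator="ensemble"``
    instead divides by the total ensemble size.  The max- and min-rate
    groups are flagged separately within the singles and pairs blocks.
    """
    if denominator not in ("group", "ensemble"):
        raise ValueError("denominator must be 'group' or 'ensemble'")
    oset = outliers(ensemble, metric, k)
    df = ensemble.records
    is_out = df["mutant_id"].isin(oset.member_ids).to_numpy()

    rows = []
    for label in SIZE_ORDER:
        members = SIZE_CLASSES[label]
        mask = (df["aa1"].isin(members) | df["aa2"].isin(members)).to_numpy()
        rows.append((label, "single", mask))
    for label, cls in zip(HOMOGENEOUS_PAIR_LABELS, SIZE_ORDER):
        members = SIZE_CLASSES[cls]
        mask = (df["aa1"].isin(members) & df["aa2"].isin(members)).to_numpy()
        rows.append((label, "pair", mask))

    out_rows = []
    for label, block, mask in rows:
        n_group = int(mask.sum())
        n_out = int((mask & is_out).sum())
        denom = n_group if denominator == "group" else len(df)
        rate = n_out / denom if denom else np.nan
        out_rows.append({"group": label, "block": block, "n_group": n_group,
                         "n_outliers": n_out, "rate": rate})
    table = pd.DataFrame(out_rows)
    table["flag"] = ""
    for block in ("single", "pair"):
        sub = table[(table["block"] == block) & table["rate"].notna()]
        if len(sub):
            table.loc[sub["rate"].idxmax(), "flag"] = "max"
            table.loc[sub["rate"].idxmin(), "flag"] = "min"
    empty = table["rate"].isna()
    table.loc[empty, "flag"] = "undefined"
    return table


def hbc_by_pair_grid(ensemble: MutantEnsemble,
                     with_counts: bool = False):
    """HBC grid: rows are unordered residue pairs ordered from GG to WW.

    Rows are ordered by summed residue volume (ties lexicographic), columns
    are elongated position pairs.  A cell holds the HBC of the mutant at
    that (pair, positions) point — averaged over the two insertion orders
    for a heterotypic pair — and NaN marks a mutant absent from the
    ensemble.  With ``with_counts`` the companion grid of per-cell mutant
    counts is returned as well.
    """
    df = ensemble.records
    pair_labels = ["".join(sorted((a, b)))
                   for a, b in zip(df["aa1"], df["aa2"])]
    pos_labels = [f"{p1},{p2}" for p1, p2 in zip(df["pos1"], df["pos2"])]
    work = pd.DataFrame({"pair": pair_labels, "pos": pos_labels,
                         "hbc": df["hbc"].to_numpy(float)})
    all_pairs = sorted(
        ("".join(sorted(p)) for p in
         combinations_with_replacement(STANDARD_AA1, 2)),
        key=lambda p: (RESIDUE_VOLUME[p[0]] + RESIDUE_VOLUME[p[1]], p))

    def _pos_key(label: str):
        a, b = label.split(",")
        return int(a), int(b)

    def _ordered(pivot):
        pivot = pivot.reindex(all_pairs)
        return pivot[sorted(pivot.columns, key=_pos_key)]

    grid = _ordered(work.pivot_table(index="pair", columns="pos",
                                     values="hbc", aggfunc="mean"))
    if not with_counts:
        return grid
    counts = _ordered(work.pivot_table(index="pair", columns="pos",
                                       values="hbc", aggfunc="count"))
    return grid, counts.fillna(0).astype(int)
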