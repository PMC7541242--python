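"""Inter- vs intra-TAD interaction comparison across conditions, and
integration of FPKM expression categories with TADs.

Quartiles use linear interpolation between order statistics; the boxplot
notch is median +- 1.58 * IQR / sqrt(n) (the standard 95% rule). FPKM
categories: no (< 1), low (1-10), moderate (10-50], high (> 50).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats as sps

from .tads import TADSet

__all__ = [
    "DistributionSummary",
    "classify_interactions",
    "pool_replicates",
    "summarize_distributions",
    "notch_nonoverlap",
    "rank_sum_test",
    "categorize_expression",
    "fpkm_category",
    "tad_expression_concordance",
    "intersect_de_sets",
]

INTERACTION_COLUMNS = ("chrom1", "start1", "end1", "chrom2", "start2", "end2", "score")


@dataclass
class DistributionSummary:
    condition: str
    interaction_class: str
    n: int
    median: float
    q1: float
    q3: float
    notch_low: float
    notch_high: float
    outlier_low: float
    outlier_high: float

    def __post_init__(self) -> None:
        if not self.q1 <= self.median <= self.q3:
            raise ValueError("quartiles out of order")
        if not self.notch_low <= self.median <= self.notch_high:
            raise ValueError("notch interval must contain the median")


def _tad_arrays(tads: TADSet) -> dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]]:
    out: dict[str, list] = {}
    for k, t in enumerate(tads.tads):
        out.setdefault(t.chrom, []).append((t.start, t.end, k))
    arrays = {}
    for chrom, rows in out.items():
        rows.sort()
        arr = np.array(rows, dtype=np.int64)
        arrays[chrom] = (arr[:, 0], arr[:, 1], arr[:, 2])
    return arrays


def _locate(arrays, chrom: str, pos: int) -> int:
    """TAD index containing pos, or -1."""
    if chrom not in arrays:
        return -1
    starts, ends, idx = arrays[chrom]
    k = int(np.searchsorted(starts, pos, side="right")) - 1
    if k >= 0 and pos < ends[k]:
        return int(idx[k])
    return -1


def classify_interactions(
    table: pd.DataFrame, tads: TADSet, condition: str
) -> pd.DataFrame:
    """Label each interaction intra_tad / inter_tad / unassigned by anchor-
    midpoint containment in the given (consensus) TADs. Anchors in border
    gaps or outside all TADs make the interaction unassigned (tallied but
    excluded from summaries)."""
    missing = set(INTERACTION_COLUMNS) - set(table.columns)
    if missing:
        raise ValueError(f"interaction table missing columns: {sorted(missing)}")
    arrays = _tad_arrays(tads)
    out = table.copy()
    mid1 = (out["start1"].to_numpy() + out["end1"].to_numpy()) // 2
    mid2 = (out["start2"].to_numpy() + out["end2"].to_numpy()) // 2
    t1 = np.array([_locate(arrays, c, int(m)) for c, m in zip(out["chrom1"], mid1)])
    t2 = np.array([_locate(arrays, c, int(m)) for c, m in zip(out["chrom2"], mid2)])
    same_chrom = (out["chrom1"] == out["chrom2"]).to_numpy()
    cls = np.where(
        (t1 >= 0) & (t2 >= 0) & (t1 == t2),
        "intra_tad",
        np.where((t1 >= 0) & (t2 >= 0) & same_chrom, "inter_tad", "unassigned"),
    )
    out["tad1"] = t1
    out["tad2"] = t2
    out["interaction_class"] = cls
    out["condition"] = condition
    return out


def pool_replicates(tables: list[pd.DataFrame]) -> pd.DataFrame:
    """Pool per-replicate interaction tables: per anchor pair, the mean of
    scores over the replicates where the pair is present (presence count
    retained)."""
    if not tables:
        raise ValueError("no tables to pool")
    keys = ["chrom1", "start1", "end1", "chrom2", "start2", "end2"]
    cat = pd.concat(tables, ignore_index=True)
    pooled = cat.groupby(keys, as_index=False).agg(
        score=("score", "mean"), presence=("score", "size")
    )
    return pooled.sort_values(keys, ignore_index=True)


def _summary(values: np.ndarray, condition: str, cls: str) -> DistributionSummary:
    v = np.asarray(values, dtype=float)
    n = len(v)
    q1, med, q3 = np.percentile(v, [25, 50, 75])  # linear interpolation
    iqr = q3 - q1
    half = 1.58 * iqr / np.sqrt(n) if n else np.nan
    return DistributionSummary(
        condition=condition,
        interaction_class=cls,
        n=n,
        median=float(med),
        q1=float(q1),
        q3=float(q3),
        notch_low=float(med - half),
        notch_high=float(med + half),
        outlier_low=float(q1 - 1.5 * iqr),
        outlier_high=float(q3 + 1.5 * iqr),
    )


def summarize_distributions(classified: pd.DataFrame) -> list[DistributionSummary]:
    """Notched-boxplot summaries per (condition, interaction class),
    excluding unassigned interactions."""
    out = []
    kept = classified[classified["interaction_class"] != "unassigned"]
    for (cond, cls), grp in kept.groupby(["condition", "interaction_class"], sort=True):
        if len(grp):
            out.append(_summary(grp["score"].to_numpy(), str(cond), str(cls)))
    return out


def notch_nonoverlap(a: DistributionSummary, b: DistributionSummary) -> bool:
    """True when the two notch intervals are disjoint — the figure-legend
    reading of a median difference at ~95% confidence."""
    return a.notch_low > b.notch_high or b.notch_low > a.notch_high


def rank_sum_test(a, b) -> tuple[float, float]:
    """Optional Wilcoxon rank-sum (Mann-Whitney U) comparison; returns
    (statistic, p). Not the notch criterion — an extra diagnostic."""
    res = sps.mannwhitneyu(a, b, alternative="two-sided")
    return float(res.statistic), float(res.pvalue)


def fpkm_category(mean_fpkm: float) -> str:
    """no (< 1), low (1-10), moderate (10-50], high (> 50)."""
    if mean_fpkm < 0:
        raise ValueError("FPKM must be non-negative")
    if mean_fpkm < 1:
        return "no"
    if mean_fpkm <= 10:
        return "low"
    if mean_fpkm <= 50:
        return "moderate"
    return "high"


def categorize_expression(
    expression: pd.DataFrame, tads: TADSet | None = None
) -> pd.DataFrame:
    """Mean FPKM over replicate columns (``fpkm_*``), expression category
    per the printed thresholds, and gene -> TAD assignment by maximal
    overlap; genes overlapping more than one TAD are flagged as straddlers."""
    fpkm_cols = [c for c in expression.columns if c.startswith("fpkm")]
    if not fpkm_cols:
        raise ValueError("no fpkm_* columns in expression table")
    out = expression.copy()
    out["mean_fpkm"] = out[fpkm_cols].mean(axis=1)
    out["category"] = out["mean_fpkm"].map(fpkm_category)
    if tads is not None:
        assigned, straddle = [], []
        tad_list = list(tads.tads)
        for chrom, gs, ge in zip(out["chrom"], out["start"], out["end"]):
            overlaps = []
            for k, t in enumerate(tad_list):
                if t.chrom != chrom:
                    continue
                ov = min(ge, t.end) - max(gs, t.start)
                if ov > 0:
                    overlaps.append((ov, k))
            if not overlaps:
                assigned.append(-1)
                straddle.append(False)
            else:
                overlaps.sort(reverse=True)
                assigned.append(overlaps[0][1])
                straddle.append(len(overlaps) > 1)
        out["tad_id"] = assigned
        out["straddles_border"] = straddle
    return out


def tad_expression_concordance(
    records: pd.DataFrame, tad_col: str = "tad_id", category_col: str = "category"
) -> tuple[pd.DataFrame, float]:
    """Per-TAD modal expression category and the fraction of member genes
    sharing it; overall concordance is the mean of per-TAD modal fractions.
    Straddlers are excluded (but listed); TADs with zero genes are absent
    from the table."""
    df = records[records[tad_col] >= 0]
    if "straddles_border" in df.columns:
        df = df[~df["straddles_border"]]
    rows = []
    for tad, grp in df.groupby(tad_col, sort=True):
        counts = grp[category_col].value_counts()
        modal = counts.idxmax()
        rows.append(
            {
                "tad_id": int(tad),
                "n_genes": len(grp),
                "modal_category": modal,
                "modal_fraction": counts.max() / len(grp),
            }
        )
    table = pd.DataFrame(rows)
    concordance = float(table["modal_fraction"].mean()) if len(table) else float("nan")
    return table, concordance


def intersect_de_sets(de_lists: dict[str, list[str]]) -> dict:
    """Exact set algebra over differentially-expressed gene-id lists:
    per-exact-subset counts (UpSet-style), pairwise intersections, and the
    union size."""
    sets = {name: set(ids) for name, ids in de_lists.items()}
    universe = set().union(*sets.values()) if sets else set()
    subset_counts: dict[tuple[str, ...], int] = {}
    for gene in universe:
        members = tuple(sorted(name for name, s in sets.items() if gene in s))
        subset_counts[members] = subset_counts.get(members, 0) + 1
    pairwise = {
        (a, b): len(sets[a] & sets[b]) for a, b in combinations(sorted(sets), 2)
    }
    return {
        "set_sizes": {name: len(s) for name, s in sets.items()},
        "subset_counts": subset_counts,
        "pairwise_common": pairwise,
        "union_size": len(universe),
    }
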