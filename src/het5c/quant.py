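"""Raw 5C read pairs -> filtered, normalized, binned contact matrices.

The quantification path is: trim -> quality filter -> primer-pair assignment
(exact junction matching against the forward x reverse primer catalog) ->
total-count normalization -> binning (median) -> distance-decay expected
model and log2 observed/expected validity calls.

Primer-pair assignment uses exact substring matching rather than an external
short-read aligner; ``assign_premapped`` accepts already-mapped pair lists
for real data.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

PHRED_OFFSET = 33

__all__ = [
    "PrimerRecord",
    "ReadPair",
    "InteractionTable",
    "BinnedContactMatrix",
    "ExpectedModel",
    "trim_reads",
    "quality_filter",
    "assign_primer_pairs",
    "assign_premapped",
    "normalize_total",
    "bin_and_smooth",
    "fit_expected_and_log2",
]


@dataclass(frozen=True)
class PrimerRecord:
    """One 5C primer: genomic footprint, orientation, universal tail, sequence.

    Coordinates are 0-based half-open. Forward primers carry the T7 tail,
    reverse primers the T3 tail.
    """

    id: str
    chrom: str
    start: int
    end: int
    orientation: str  # "forward" | "reverse"
    tail: str  # "T7" | "T3"
    sequence: str

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(f"primer {self.id}: end must exceed start")
        if self.orientation not in ("forward", "reverse"):
            raise ValueError(f"primer {self.id}: bad orientation {self.orientation!r}")
        expected_tail = "T7" if self.orientation == "forward" else "T3"
        if self.tail != expected_tail:
            raise ValueError(
                f"primer {self.id}: {self.orientation} primers must carry the "
                f"{expected_tail} tail, got {self.tail}"
            )

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2


def check_primer_set(primers: list[PrimerRecord]) -> None:
    """Validate uniqueness invariants of a primer catalog."""
    seqs = [p.sequence for p in primers]
    if len(set(seqs)) != len(seqs):
        raise ValueError("primer sequences are not unique within the set")
    ids = [p.id for p in primers]
    if len(set(ids)) != len(ids):
        raise ValueError("primer ids are not unique within the set")


@dataclass
class ReadPair:
    """A paired-end read; ``trimmed`` guards against double trimming."""

    id: str
    seq1: str
    qual1: str
    seq2: str
    qual2: str
    trimmed: bool = False


@dataclass
class InteractionTable:
    """Primer-pair raw counts and (optionally) normalized scores.

    ``records`` columns: fwd_id, rev_id, raw_count, norm_score.
    ``tallies`` carries count-conservation bookkeeping from assignment:
    assigned + ambiguous + unmatched + quality_dropped + trim_dropped equals
    the number of input read pairs.
    """

    records: pd.DataFrame
    total_mapped: int = 0
    normalization_factor: float | None = None
    tallies: dict = field(default_factory=dict)
    all_zero: bool = False

    COLUMNS = ("fwd_id", "rev_id", "raw_count", "norm_score")

    def __post_init__(self) -> None:
        missing = set(self.COLUMNS) - set(self.records.columns)
        if missing:
            raise ValueError(f"interaction table missing columns: {sorted(missing)}")
        if (self.records["raw_count"] < 0).any():
            raise ValueError("raw counts must be non-negative")

    @classmethod
    def from_counts(cls, fwd_ids, rev_ids, counts, **kw) -> "InteractionTable":
        df = pd.DataFrame(
            {
                "fwd_id": list(fwd_ids),
                "rev_id": list(rev_ids),
                "raw_count": np.asarray(counts, dtype=np.int64),
                "norm_score": np.nan,
            }
        )
        total = int(df["raw_count"].sum())
        return cls(records=df, total_mapped=total, all_zero=(total == 0), **kw)

    @property
    def normalized(self) -> bool:
        return self.normalization_factor is not None

    def count_lookup(self) -> dict[tuple[str, str], int]:
        return {
            (f, r): int(c)
            for f, r, c in zip(
                self.records["fwd_id"], self.records["rev_id"], self.records["raw_count"]
            )
        }


@dataclass
class ExpectedModel:
    """Distance-stratified expected interaction score (median per stratum)."""

    distance_edges: np.ndarray  # stratum edges in bp, length n+1
    expected: np.ndarray  # expected score per stratum, length n

    def __post_init__(self) -> None:
        edges = np.asarray(self.distance_edges, dtype=float)
        if np.any(np.diff(edges) <= 0):
            raise ValueError("distance edges must be strictly increasing")
        self.distance_edges = edges
        self.expected = np.asarray(self.expected, dtype=float)

    def lookup(self, distance: np.ndarray) -> np.ndarray:
        idx = np.clip(
            np.searchsorted(self.distance_edges, distance, side="right") - 1,
            0,
            len(self.expected) - 1,
        )
        return self.expected[idx]


class BinnedContactMatrix:
    """Symmetric sparse per-chromosome binned contact matrix.

    Values are stored once per unordered bin pair (i <= j); ``get`` is
    symmetric. Absent entries mean "no observation", never zero. For
    ``kind == 'obs_exp_log2'`` an entry is a valid interaction iff its value
    is strictly positive.
    """

    def __init__(self, chrom, bin_size, bin_step, bin_starts, values, kind="raw"):
        if bin_step > bin_size:
            raise ValueError("bin_step must not exceed bin_size")
        self.chrom = chrom
        self.bin_size = int(bin_size)
        self.bin_step = int(bin_step)
        self.bin_starts = np.asarray(bin_starts, dtype=np.int64)
        self.values = {self._canon(i, j): float(v) for (i, j), v in values.items()}
        self.kind = kind

    @staticmethod
    def _canon(i: int, j: int) -> tuple[int, int]:
        return (i, j) if i <= j else (j, i)

    @property
    def n_bins(self) -> int:
        return len(self.bin_starts)

    def get(self, i: int, j: int, default=None):
        return self.values.get(self._canon(i, j), default)

    def items(self):
        return self.values.items()

    def to_dense(self, fill=np.nan) -> np.ndarray:
        m = np.full((self.n_bins, self.n_bins), fill, dtype=float)
        for (i, j), v in self.values.items():
            m[i, j] = v
            m[j, i] = v
        return m

    def valid_fraction(self) -> float:
        """Fraction of present entries that are valid (> 0); obs/exp matrices."""
        if not self.values:
            return float("nan")
        vals = np.fromiter(self.values.values(), dtype=float)
        return float(np.mean(vals > 0))


# ---------------------------------------------------------------------------
# read-level operations


def trim_reads(pair: ReadPair, five_prime_cut: int = 20, three_prime_cut_from: int = 80):
    """Remove the 5' bases 1..``five_prime_cut`` and the 3' bases from
    ``three_prime_cut_from`` onward (both 1-based inclusive) from both mates.

    A 100-base read with the defaults retains bases 21-79 (59 bases).
    Returns the trimmed pair, or ``None`` if either mate retains nothing
    (the pair is dropped). Trimming twice raises.
    """
    if pair.trimmed:
        raise ValueError(f"read pair {pair.id} already trimmed")
    if not 1 <= five_prime_cut <= 20:
        raise ValueError("five_prime_cut must be in 1..20")
    if not 80 <= three_prime_cut_from <= 100:
        raise ValueError("three_prime_cut_from must be in 80..100")
    lo = five_prime_cut  # 0-based start of retained region
    hi = three_prime_cut_from - 1  # 0-based exclusive end
    s1, q1 = pair.seq1[lo:hi], pair.qual1[lo:hi]
    s2, q2 = pair.seq2[lo:hi], pair.qual2[lo:hi]
    if not s1 or not s2:
        return None
    return ReadPair(pair.id, s1, q1, s2, q2, trimmed=True)


def _phred(qual: str) -> np.ndarray:
    return np.frombuffer(qual.encode("ascii"), dtype=np.uint8).astype(np.int32) - PHRED_OFFSET


def quality_filter(pair: ReadPair, min_phred: int = 25, min_fraction: float = 0.80) -> bool:
    """Keep a pair iff, in BOTH mates, the fraction of bases with Phred >=
    ``min_phred`` is >= ``min_fraction`` (boundary inclusive)."""
    for qual in (pair.qual1, pair.qual2):
        if not qual:
            return False
        q = _phred(qual)
        n_ok = int(np.count_nonzero(q >= min_phred))
        # inclusive boundary without float-representation artifacts
        if n_ok < min_fraction * len(q) - 1e-9:
            return False
    return True


def assign_primer_pairs(
    read_pairs,
    primers: list[PrimerRecord],
    *,
    trim: bool = True,
    five_prime_cut: int = 20,
    three_prime_cut_from: int = 80,
    min_phred: int = 25,
    min_fraction: float = 0.80,
) -> InteractionTable:
    """Assign trimmed, quality-filtered read pairs to forward x reverse
    primer combinations by exact substring match; one confident mate
    suffices. Reads matching zero combinations are tallied as unmatched,
    reads compatible with two or more combinations as ambiguous.
    """
    check_primer_set(primers)
    fwd = [(p.sequence, p.id) for p in primers if p.orientation == "forward"]
    rev = [(p.sequence, p.id) for p in primers if p.orientation == "reverse"]

    counts: dict[tuple[str, str], int] = {}
    tallies = {
        "input": 0,
        "assigned": 0,
        "ambiguous": 0,
        "unmatched": 0,
        "quality_dropped": 0,
        "trim_dropped": 0,
    }
    for pair in read_pairs:
        tallies["input"] += 1
        if trim:
            pair = trim_reads(pair, five_prime_cut, three_prime_cut_from)
            if pair is None:
                tallies["trim_dropped"] += 1
                continue
        if not quality_filter(pair, min_phred, min_fraction):
            tallies["quality_dropped"] += 1
            continue
        haystack1, haystack2 = pair.seq1, pair.seq2
        f_hits = {pid for seq, pid in fwd if seq in haystack1 or seq in haystack2}
        r_hits = {pid for seq, pid in rev if seq in haystack1 or seq in haystack2}
        if len(f_hits) == 1 and len(r_hits) == 1:
            key = (next(iter(f_hits)), next(iter(r_hits)))
            counts[key] = counts.get(key, 0) + 1
            tallies["assigned"] += 1
        elif len(f_hits) > 1 or len(r_hits) > 1:
            tallies["ambiguous"] += 1
        else:
            tallies["unmatched"] += 1

    keys = sorted(counts)
    table = InteractionTable.from_counts(
        [k[0] for k in keys], [k[1] for k in keys], [counts[k] for k in keys],
        tallies=tallies,
    )
    return table


def assign_premapped(pairs: pd.DataFrame) -> InteractionTable:
    """Build an InteractionTable from an already-mapped pair list
    (columns fwd_id, rev_id, raw_count) — hook for externally aligned data."""
    grouped = (
        pairs.groupby(["fwd_id", "rev_id"], as_index=False)["raw_count"].sum().sort_values(
            ["fwd_id", "rev_id"], ignore_index=True
        )
    )
    return InteractionTable.from_counts(
        grouped["fwd_id"], grouped["rev_id"], grouped["raw_count"]
    )


# ---------------------------------------------------------------------------
# table-level operations


def normalize_total(table: InteractionTable, normalization_factor: float) -> InteractionTable:
    """norm_score = raw_count / total_mapped * normalization_factor.

    The factor is a per-dataset calibration constant supplied by the caller
    and recorded in the result; it is not re-derived from the data.
    """
    if normalization_factor <= 0:
        raise ValueError("normalization factor must be positive")
    if table.total_mapped <= 0:
        raise ValueError("cannot normalize a table with zero total mapped pairs")
    df = table.records.copy()
    df["norm_score"] = (
        df["raw_count"].to_numpy(dtype=float) / table.total_mapped * normalization_factor
    )
    return replace(
        table, records=df, normalization_factor=float(normalization_factor)
    )


def _agg_func(name: str):
    if name == "median":
        return np.median
    if name == "mean":
        return np.mean
    if name == "sum":
        return np.sum
    raise ValueError(f"unknown aggregation {name!r}")


def bin_and_smooth(
    table: InteractionTable,
    primers: list[PrimerRecord],
    bin_size: int = 10_000,
    bin_step: int | None = None,
    agg: str = "median",
    smooth_span: int = 10_000,
    smooth_agg: str = "median",
    score: str = "norm",
    chrom: str | None = None,
) -> BinnedContactMatrix:
    """Bin primer-pair scores into (possibly overlapping) windows and smooth.

    A pair contributes to every (bin_i, bin_j) whose windows contain its two
    anchor midpoints; the bin value is ``agg`` over contributing scores.
    Smoothing then replaces each present cell by ``smooth_agg`` over present
    cells within +-``smooth_span`` bp on both axes (``smooth_span=0``
    disables it). Empty bins stay absent; the output is symmetric by
    construction.
    """
    if bin_step is None:
        bin_step = bin_size
    if bin_step > bin_size:
        raise ValueError("bin_step must not exceed bin_size")
    by_id = {p.id: p for p in primers}
    col = "norm_score" if score == "norm" else "raw_count"
    if score == "norm" and not table.normalized:
        raise ValueError("table is not normalized; pass score='raw' or normalize first")

    chroms = {by_id[f].chrom for f in table.records["fwd_id"]} | {
        by_id[r].chrom for r in table.records["rev_id"]
    }
    if chrom is None:
        if len(chroms) > 1:
            raise ValueError("table spans multiple chromosomes; pass chrom=")
        chrom = next(iter(chroms)) if chroms else "chr"

    max_mid = 0
    entries = []  # (mid1, mid2, score)
    for f, r, v in zip(
        table.records["fwd_id"], table.records["rev_id"], table.records[col]
    ):
        pf, pr = by_id[f], by_id[r]
        if pf.chrom != chrom or pr.chrom != chrom:
            continue
        entries.append((pf.midpoint, pr.midpoint, float(v)))
        max_mid = max(max_mid, pf.midpoint, pr.midpoint)

    bin_starts = np.arange(0, max_mid + 1, bin_step, dtype=np.int64)
    n = len(bin_starts)

    def covering_bins(mid: int):
        # bins k with bin_starts[k] <= mid < bin_starts[k] + bin_size
        k_hi = mid // bin_step
        k_lo = max(0, (mid - bin_size) // bin_step + 1)
        return range(int(k_lo), int(min(k_hi, n - 1)) + 1)

    cells: dict[tuple[int, int], list[float]] = {}
    for m1, m2, v in entries:
        for i in covering_bins(m1):
            for j in covering_bins(m2):
                cells.setdefault(BinnedContactMatrix._canon(i, j), []).append(v)

    func = _agg_func(agg)
    values = {k: float(func(v)) for k, v in cells.items()}

    if smooth_span and smooth_span > 0 and values:
        k = int(smooth_span // bin_step)
        sfunc = _agg_func(smooth_agg)
        smoothed = {}
        for (i, j), _ in values.items():
            neigh = []
            for di in range(-k, k + 1):
                for dj in range(-k, k + 1):
                    v = values.get(BinnedContactMatrix._canon(i + di, j + dj))
                    if v is not None:
                        neigh.append(v)
            smoothed[(i, j)] = float(sfunc(neigh))
        values = smoothed

    return BinnedContactMatrix(chrom, bin_size, bin_step, bin_starts, values, kind="raw")


def fit_expected_and_log2(
    matrix: BinnedContactMatrix, stratum_width: int | None = None
) -> tuple[BinnedContactMatrix, ExpectedModel]:
    """Fit a distance-decay expected model (per-stratum median of observed
    scores, stratum width = bin_size by default) and return the
    log2(observed/expected) matrix; entries with value > 0 are valid
    interactions. Absent cells stay absent.
    """
    if stratum_width is None:
        stratum_width = matrix.bin_size
    if not matrix.values:
        model = ExpectedModel(np.array([0.0, stratum_width]), np.array([np.nan]))
        return (
            BinnedContactMatrix(
                matrix.chrom, matrix.bin_size, matrix.bin_step, matrix.bin_starts, {},
                kind="obs_exp_log2",
            ),
            model,
        )

    starts = matrix.bin_starts
    dists = {}
    strata: dict[int, list[float]] = {}
    for (i, j), v in matrix.items():
        d = abs(int(starts[j]) - int(starts[i]))
        s = d // stratum_width
        dists[(i, j)] = s
        strata.setdefault(s, []).append(v)
    expected_by_stratum = {s: float(np.median(v)) for s, v in strata.items()}

    max_s = max(expected_by_stratum)
    edges = np.arange(0, (max_s + 2) * stratum_width, stratum_width, dtype=float)
    exp_arr = np.array(
        [expected_by_stratum.get(s, np.nan) for s in range(max_s + 1)], dtype=float
    )
    model = ExpectedModel(edges, exp_arr)

    out = {}
    for (i, j), v in matrix.items():
        e = expected_by_stratum[dists[(i, j)]]
        if e > 0 and v > 0:
            out[(i, j)] = math.log2(v / e)
        elif e > 0:
            # non-positive observation over positive expected: strongly invalid
            out[(i, j)] = float("-inf")
        else:
            logger.debug("stratum with non-positive expected at cell (%d,%d)", i, j)
    return (
        BinnedContactMatrix(
            matrix.chrom, matrix.bin_size, matrix.bin_step, matrix.bin_starts, out,
            kind="obs_exp_log2",
        ),
        model,
    )
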