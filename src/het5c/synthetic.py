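"""Synthetic 5C inputs with planted ground truth.

Everything the pipeline consumes can be generated here: a tiled primer set
over a toy genome, planted-TAD contact counts over a power-law distance
decay with Poisson replicate noise, paired FASTQ with tail + primer +
ligation-junction read structure (plus configurable decoys and quality
floors), feature tracks with tunable border enrichment, and per-gene FPKM
tables tied to TAD activity. Identical (spec, seed) gives byte-identical
outputs.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .overlap import IntervalSet
from .quant import InteractionTable, PrimerRecord

logger = logging.getLogger(__name__)

# universal tails appended to 5C primers: T7 on forward, T3 on reverse
T7_TAIL = "TAATACGACTCACTATAGCC"
T3_TAIL = "TATTAACCCTCACTAAAGGGA"
LIGATION_JUNCTION = "GAATTC"  # EcoRI site at the junction
PRIMER_LEN = 30
BASES = np.array(list("ACGT"))

__all__ = [
    "ToyGenomeSpec",
    "PlantedTADModel",
    "SyntheticTruth",
    "T7_TAIL",
    "T3_TAIL",
    "LIGATION_JUNCTION",
    "generate_primer_set",
    "pair_expectations",
    "simulate_contact_counts",
    "emit_read_pairs",
    "generate_feature_tracks",
    "generate_expression_table",
    "toy_genome",
    "toy_model",
]


@dataclass(frozen=True)
class ToyGenomeSpec:
    chrom_names: tuple[str, ...]
    chrom_lengths: tuple[int, ...]
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.chrom_names) != len(self.chrom_lengths):
            raise ValueError("chrom_names and chrom_lengths differ in length")
        if len(set(self.chrom_names)) != len(self.chrom_names):
            raise ValueError("chromosome names must be unique")
        if any(length <= 0 for length in self.chrom_lengths):
            raise ValueError("chromosome lengths must be positive")

    @property
    def lengths(self) -> dict[str, int]:
        return dict(zip(self.chrom_names, self.chrom_lengths))

    def universe(self) -> dict[str, tuple[int, int]]:
        return {c: (0, l) for c, l in self.lengths.items()}


@dataclass(frozen=True)
class PlantedTADModel:
    """Planted block structure over a power-law distance decay.

    Expected count for a forward x reverse primer pair is proportional to
    distance**(-decay_exponent) times ``within_tad_factor`` when both anchor
    midpoints fall in one planted TAD and ``between_tad_factor`` otherwise;
    counts are Poisson per replicate (optional negative-binomial dispersion,
    off by default). Midpoint distances are floored at ``decay_floor_bp``
    (one bin) to avoid blowup at adjacent primers.
    """

    tads: tuple[tuple[str, int, int, str], ...]  # (chrom, start, end, activity)
    decay_exponent: float = 1.0
    within_tad_factor: float = 5.0
    between_tad_factor: float = 1.0
    read_depth: int = 200_000
    n_replicates: int = 3
    dispersion: float = 0.0  # NB dispersion; 0 -> pure Poisson
    decay_floor_bp: int = 10_000

    def __post_init__(self) -> None:
        if not self.within_tad_factor >= self.between_tad_factor > 0:
            raise ValueError("need within_tad_factor >= between_tad_factor > 0")
        if self.decay_exponent < 0:
            raise ValueError("decay_exponent must be >= 0")
        by_chrom: dict[str, list] = {}
        for chrom, start, end, activity in self.tads:
            if end <= start:
                raise ValueError(f"degenerate TAD {chrom}:{start}-{end}")
            if activity not in ("active", "inactive"):
                raise ValueError(f"bad activity {activity!r}")
            by_chrom.setdefault(chrom, []).append((start, end))
        for chrom, spans in by_chrom.items():
            if spans != sorted(spans):
                raise ValueError(f"TADs on {chrom} must be sorted")
            for (s0, e0), (s1, e1) in zip(spans, spans[1:]):
                if s1 < e0:
                    raise ValueError(f"TADs on {chrom} overlap")

    def boundaries(self) -> dict[str, list[int]]:
        out: dict[str, set[int]] = {}
        for chrom, start, end, _ in self.tads:
            out.setdefault(chrom, set()).update((start, end))
        return {c: sorted(v) for c, v in out.items()}


@dataclass
class SyntheticTruth:
    """Ground truth for a synthetic dataset: planted boundaries, requested
    feature border-fold enrichments, and per-TAD expression parameters."""

    boundaries: list[tuple[str, int]]
    feature_enrichment: dict[str, float] = field(default_factory=dict)
    expression_by_tad: dict[int, dict] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.boundaries = sorted(self.boundaries)
        for name, fold in self.feature_enrichment.items():
            if fold < 1:
                raise ValueError(f"feature {name}: fold enrichment must be >= 1")

    @classmethod
    def from_model(
        cls, model: PlantedTADModel, feature_enrichment: dict[str, float] | None = None
    ) -> "SyntheticTruth":
        bounds = [
            (chrom, pos) for chrom, poss in model.boundaries().items() for pos in poss
        ]
        expr = {
            k: {"activity": act} for k, (_, _, _, act) in enumerate(model.tads)
        }
        return cls(
            boundaries=bounds,
            feature_enrichment=dict(feature_enrichment or {}),
            expression_by_tad=expr,
        )


# ---------------------------------------------------------------------------
# toy defaults: 1 chromosome x 1 Mb, 6 planted TADs of 100-250 kb


def toy_genome(seed: int = 0, length: int = 1_000_000, name: str = "chrT") -> ToyGenomeSpec:
    return ToyGenomeSpec(chrom_names=(name,), chrom_lengths=(length,), seed=seed)


def toy_model(
    genome: ToyGenomeSpec | None = None,
    within_tad_factor: float = 5.0,
    between_tad_factor: float = 1.0,
    read_depth: int = 200_000,
    n_replicates: int = 3,
    decay_exponent: float = 1.0,
) -> PlantedTADModel:
    chrom = (genome or toy_genome()).chrom_names[0]
    spans = [
        (0, 180_000, "active"),
        (180_000, 330_000, "inactive"),
        (330_000, 530_000, "active"),
        (530_000, 650_000, "inactive"),
        (650_000, 800_000, "active"),
        (800_000, 1_000_000, "inactive"),
    ]
    return PlantedTADModel(
        tads=tuple((chrom, s, e, a) for s, e, a in spans),
        decay_exponent=decay_exponent,
        within_tad_factor=within_tad_factor,
        between_tad_factor=between_tad_factor,
        read_depth=read_depth,
        n_replicates=n_replicates,
    )


# ---------------------------------------------------------------------------
# generators


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(BASES[rng.integers(0, 4, size=length)])


def generate_primer_set(genome: ToyGenomeSpec, spacing: int) -> list[PrimerRecord]:
    """Tile alternating forward/reverse primers every ``spacing`` bp.

    Forward primers carry the T7 tail, reverse the T3 tail; each primer is a
    unique random 30-mer drawn reproducibly from the genome seed. Spacing
    larger than a chromosome yields no primers for it (with a warning).
    """
    if spacing < 1_000:
        raise ValueError("spacing must be >= 1 kb")
    rng = np.random.default_rng(genome.seed)
    primers: list[PrimerRecord] = []
    seen: set[str] = set()
    for chrom, length in zip(genome.chrom_names, genome.chrom_lengths):
        if spacing > length:
            warnings.warn(f"spacing {spacing} exceeds {chrom} length {length}; no primers")
            continue
        k = 0
        for start in range(0, length - PRIMER_LEN + 1, spacing):
            seq = _random_seq(rng, PRIMER_LEN)
            while seq in seen:
                seq = _random_seq(rng, PRIMER_LEN)
            seen.add(seq)
            forward = k % 2 == 0
            primers.append(
                PrimerRecord(
                    id=f"{chrom}_{'F' if forward else 'R'}{k:04d}",
                    chrom=chrom,
                    start=start,
                    end=start + PRIMER_LEN,
                    orientation="forward" if forward else "reverse",
                    tail="T7" if forward else "T3",
                    sequence=seq,
                )
            )
            k += 1
    return primers


def _tad_index(model: PlantedTADModel, chrom: str, pos: int) -> int:
    for k, (tc, ts, te, _) in enumerate(model.tads):
        if tc == chrom and ts <= pos < te:
            return k
    return -1


def pair_expectations(
    primers: list[PrimerRecord], model: PlantedTADModel
) -> pd.DataFrame:
    """Expected (unnormalized weight and Poisson rate) for every intra-
    chromosomal forward x reverse primer pair under the planted model."""
    rows = []
    by_chrom: dict[str, list[PrimerRecord]] = {}
    for p in primers:
        by_chrom.setdefault(p.chrom, []).append(p)
    for chrom in sorted(by_chrom):
        ps = by_chrom[chrom]
        fwd = [p for p in ps if p.orientation == "forward"]
        rev = [p for p in ps if p.orientation == "reverse"]
        for f in fwd:
            tf = _tad_index(model, chrom, f.midpoint)
            for r in rev:
                tr = _tad_index(model, chrom, r.midpoint)
                dist = abs(f.midpoint - r.midpoint)
                if dist == 0:
                    continue
                eff = max(dist, model.decay_floor_bp)
                intra = tf >= 0 and tf == tr
                factor = model.within_tad_factor if intra else model.between_tad_factor
                decay = float(eff) ** (-model.decay_exponent) if model.decay_exponent else 1.0
                rows.append(
                    (f.id, r.id, chrom, f.midpoint, r.midpoint, dist, intra, decay * factor)
                )
    df = pd.DataFrame(
        rows,
        columns=["fwd_id", "rev_id", "chrom", "mid1", "mid2", "distance", "intra_tad", "weight"],
    )
    if len(df):
        df["lam"] = df["weight"] / df["weight"].sum() * model.read_depth
    else:
        df["lam"] = pd.Series(dtype=float)
    return df


def simulate_contact_counts(
    primers: list[PrimerRecord], model: PlantedTADModel, seed: int = 0
) -> list[InteractionTable]:
    """Draw per-replicate Poisson counts (optionally gamma-overdispersed)
    from the planted-model expectations; only forward x reverse pairs are
    populated. Zero read depth yields valid all-zero tables, flagged."""
    if sum(1 for p in primers if p.orientation == "forward") < 1 or sum(
        1 for p in primers if p.orientation == "reverse"
    ) < 1:
        raise ValueError("need at least one forward and one reverse primer")
    exp = pair_expectations(primers, model)
    lam = exp["lam"].to_numpy(dtype=float)
    tables = []
    for rep in range(model.n_replicates):
        rng = np.random.default_rng([seed, rep])
        rate = lam
        if model.dispersion > 0:
            shape = 1.0 / model.dispersion
            rate = lam * rng.gamma(shape, 1.0 / shape, size=lam.shape)
        counts = rng.poisson(rate)
        nz = counts > 0
        table = InteractionTable.from_counts(
            exp.loc[nz, "fwd_id"], exp.loc[nz, "rev_id"], counts[nz]
        )
        if table.total_mapped == 0:
            logger.warning("replicate %d: all-zero contact table", rep)
        tables.append(table)
    return tables


def _qual_string(n: int, q: int) -> str:
    return chr(q + 33) * n


def emit_read_pairs(
    table: InteractionTable,
    primers: list[PrimerRecord],
    out_fastq_r1,
    out_fastq_r2,
    seed: int = 0,
    read_length: int = 100,
    decoy_fraction: float = 0.0,
    low_quality_read_fraction: float = 0.0,
    low_quality_base_fraction: float = 0.30,
    high_q: int = 38,
    low_q: int = 2,
) -> dict:
    """Emit paired FASTQ for a count table.

    Each counted (fwd, rev) pair yields that many read pairs: mate 1 is
    T7 tail + forward primer + GAATTC junction + reverse primer (padded to
    ``read_length`` with random bases), mate 2 the T3-tailed mirror. A
    ``decoy_fraction`` of the final reads are decoys (no primer match /
    all-low-quality / ambiguous dual-forward match), interleaved
    deterministically; at 1.0 only decoys are emitted.
    ``low_quality_read_fraction`` of the signal reads get
    ``low_quality_base_fraction`` of their bases set below the Phred floor
    so the quality filter is exercisable.
    """
    if (table.records["raw_count"] < 0).any():
        raise ValueError("counts must be non-negative")
    if not 0.0 <= decoy_fraction <= 1.0:
        raise ValueError("decoy_fraction must be in [0, 1]")
    by_id = {p.id: p for p in primers}
    rng = np.random.default_rng([seed, 997])

    signal = []
    for f, r, c in zip(
        table.records["fwd_id"], table.records["rev_id"], table.records["raw_count"]
    ):
        pf, pr = by_id[f], by_id[r]
        for _ in range(int(c)):
            core1 = T7_TAIL + pf.sequence + LIGATION_JUNCTION + pr.sequence
            core2 = T3_TAIL + pr.sequence + LIGATION_JUNCTION + pf.sequence
            s1 = (core1 + _random_seq(rng, max(0, read_length - len(core1))))[:read_length]
            s2 = (core2 + _random_seq(rng, max(0, read_length - len(core2))))[:read_length]
            signal.append([f"{f}x{r}", s1, s2])

    n_signal = len(signal)
    if decoy_fraction >= 1.0:
        n_decoy = n_signal if n_signal else 0
        signal = []
        n_signal = 0
    elif decoy_fraction > 0:
        n_decoy = int(round(decoy_fraction / (1.0 - decoy_fraction) * n_signal))
    else:
        n_decoy = 0

    fwd_primers = [p for p in primers if p.orientation == "forward"]
    records = []
    for idx, (rid, s1, s2) in enumerate(signal):
        q1 = _qual_string(len(s1), high_q)
        q2 = _qual_string(len(s2), high_q)
        records.append((f"sig{idx}:{rid}", s1, q1, s2, q2))
    # degrade a fraction of signal reads below the Phred floor
    n_low = int(round(low_quality_read_fraction * n_signal))
    low_idx = rng.choice(n_signal, size=n_low, replace=False) if n_low else []
    for i in low_idx:
        rid, s1, q1, s2, q2 = records[i]
        nb = int(round(low_quality_base_fraction * len(s1)))
        pos = rng.choice(len(s1), size=nb, replace=False)
        qa = np.frombuffer(q1.encode(), dtype=np.uint8).copy()
        qa[pos] = low_q + 33
        q1 = qa.tobytes().decode()
        nb2 = int(round(low_quality_base_fraction * len(s2)))
        pos2 = rng.choice(len(s2), size=nb2, replace=False)
        qb = np.frombuffer(q2.encode(), dtype=np.uint8).copy()
        qb[pos2] = low_q + 33
        q2 = qb.tobytes().decode()
        records[i] = (rid, s1, q1, s2, q2)

    for d in range(n_decoy):
        kind = d % 3
        if kind == 1 and not len(table.records):
            kind = 0
        if kind == 2 and len(fwd_primers) < 2:
            kind = 0
        if kind == 0:  # no primer match
            s1 = _random_seq(rng, read_length)
            s2 = _random_seq(rng, read_length)
            q1 = _qual_string(read_length, high_q)
            q2 = q1
            rid = f"decoy{d}:nomatch"
        elif kind == 1:  # all low quality: fails Phred filter
            row = table.records.iloc[int(rng.integers(0, len(table.records)))]
            pf, pr = by_id[row["fwd_id"]], by_id[row["rev_id"]]
            core1 = T7_TAIL + pf.sequence + LIGATION_JUNCTION + pr.sequence
            core2 = T3_TAIL + pr.sequence + LIGATION_JUNCTION + pf.sequence
            s1 = (core1 + _random_seq(rng, max(0, read_length - len(core1))))[:read_length]
            s2 = (core2 + _random_seq(rng, max(0, read_length - len(core2))))[:read_length]
            q1 = _qual_string(len(s1), low_q)
            q2 = _qual_string(len(s2), low_q)
            rid = f"decoy{d}:lowq"
        else:  # ambiguous: a different forward primer in each mate, no reverse
            pa, pb = rng.choice(len(fwd_primers), size=2, replace=False)
            core1 = T7_TAIL + fwd_primers[pa].sequence
            core2 = T7_TAIL + fwd_primers[pb].sequence
            s1 = (core1 + _random_seq(rng, max(0, read_length - len(core1))))[:read_length]
            s2 = (core2 + _random_seq(rng, max(0, read_length - len(core2))))[:read_length]
            q1 = _qual_string(len(s1), high_q)
            q2 = _qual_string(len(s2), high_q)
            rid = f"decoy{d}:ambig"
        records.append((rid, s1, q1, s2, q2))

    order = rng.permutation(len(records))
    try:
        with open(out_fastq_r1, "w") as f1, open(out_fastq_r2, "w") as f2:
            for k in order:
                rid, s1, q1, s2, q2 = records[k]
                f1.write(f"@{rid}/1\n{s1}\n+\n{q1}\n")
                f2.write(f"@{rid}/2\n{s2}\n+\n{q2}\n")
    except OSError as exc:
        raise OSError(f"failed writing FASTQ ({out_fastq_r1}, {out_fastq_r2}): {exc}") from exc
    return {"n_signal": n_signal, "n_decoy": n_decoy, "n_total": len(records)}


def _border_windows(
    truth: SyntheticTruth, genome: ToyGenomeSpec, half_width: int
) -> IntervalSet:
    lengths = genome.lengths
    intervals = []
    for chrom, pos in truth.boundaries:
        lo = max(0, pos - half_width)
        hi = min(lengths[chrom], pos + half_width)
        if hi > lo:
            intervals.append((chrom, lo, hi))
    return IntervalSet("borders", intervals, universe=genome.universe())


def generate_feature_tracks(
    truth: SyntheticTruth,
    genome: ToyGenomeSpec,
    seed: int = 0,
    n_intervals: int = 200,
    interval_length: int = 1_000,
    border_half_width: int = 15_000,
) -> dict[str, IntervalSet]:
    """Generate one interval track per feature in ``truth.feature_enrichment``.

    Fold = 1 places intervals uniformly over the genome; fold > 1 mixes in
    boundary-proximal placements (within +-``border_half_width`` of a planted
    boundary) at the rate required so the border-overlap probability is
    ``fold`` times the uniform rate. Folds above the achievable maximum are
    clamped with a warning.
    """
    if not genome.chrom_names:
        raise ValueError("empty genome")
    if not truth.boundaries and any(f > 1 for f in truth.feature_enrichment.values()):
        raise ValueError("cannot enrich at borders: truth has no boundaries")
    lengths = genome.lengths
    total_len = sum(lengths.values())
    border_set = _border_windows(truth, genome, border_half_width)
    border_bp = sum(
        int((e - s).sum())
        for s, e in (
            (arr[0], arr[1]) for arr in border_set.merged().values()
        )
    ) if truth.boundaries else 0
    rho = border_bp / total_len if total_len else 0.0

    chrom_list = sorted(lengths)
    chrom_weights = np.array([lengths[c] for c in chrom_list], dtype=float)
    chrom_weights /= chrom_weights.sum()
    boundary_list = sorted(truth.boundaries)

    tracks: dict[str, IntervalSet] = {}
    for fi, name in enumerate(sorted(truth.feature_enrichment)):
        fold = truth.feature_enrichment[name]
        rng = np.random.default_rng([seed, 31 + fi])
        if fold > 1 and 0 < rho < 1:
            p_border = rho * (fold - 1) / (1 - rho)
            if p_border > 1:
                warnings.warn(
                    f"feature {name}: fold {fold} unachievable (border fraction "
                    f"{rho:.3f}); clamping"
                )
                p_border = 1.0
        else:
            p_border = 0.0
        intervals = []
        for _ in range(n_intervals):
            if p_border > 0 and rng.random() < p_border:
                chrom, pos = boundary_list[rng.integers(0, len(boundary_list))]
                lo = max(0, pos - border_half_width)
                hi = min(lengths[chrom], pos + border_half_width) - interval_length
                hi = max(hi, lo)
                start = int(rng.integers(lo, hi + 1))
            else:
                chrom = chrom_list[rng.choice(len(chrom_list), p=chrom_weights)]
                start = int(rng.integers(0, lengths[chrom] - interval_length + 1))
            intervals.append((chrom, start, min(start + interval_length, lengths[chrom])))
        tracks[name] = IntervalSet(name, intervals, universe=genome.universe())
    return tracks


def generate_expression_table(
    model: PlantedTADModel,
    genome: ToyGenomeSpec,
    n_replicates: int = 3,
    seed: int = 0,
    genes_per_tad: int = 5,
    active_mean: float = 80.0,
    inactive_mean: float = 0.3,
    gene_log_sigma: float = 0.2,
    replicate_log_sigma: float = 0.1,
    straddle_rate: float = 0.0,
    category_noise: float = 0.0,
) -> pd.DataFrame:
    """Tile genes within planted TADs and draw log-normal FPKM per replicate.

    Active TADs draw around ``active_mean``, inactive around
    ``inactive_mean``. With probability ``category_noise`` a gene draws from
    the opposite activity's distribution (its ``planted_category`` records
    the flip). With probability ``straddle_rate`` a gene is shifted to
    straddle its TAD's downstream boundary. ``replicate_log_sigma = 0``
    makes all replicates identical.
    """
    rng = np.random.default_rng([seed, 71])
    lengths = genome.lengths
    rows = []
    gid = 0
    for k, (chrom, ts, te, activity) in enumerate(model.tads):
        span = te - ts
        slot = span // genes_per_tad
        glen = max(1_000, slot // 2)
        for g in range(genes_per_tad):
            start = ts + g * slot + (slot - glen) // 2
            end = start + glen
            if straddle_rate > 0 and g == genes_per_tad - 1 and rng.random() < straddle_rate:
                # shift the last gene across the TAD's downstream edge
                start = te - glen // 2
                end = min(start + glen, lengths[chrom])
            act = activity
            if category_noise > 0 and rng.random() < category_noise:
                act = "inactive" if act == "active" else "active"
            mean = active_mean if act == "active" else inactive_mean
            gene_mean = mean * float(np.exp(rng.normal(0.0, gene_log_sigma))) if gene_log_sigma else mean
            fpkms = [
                gene_mean * float(np.exp(rng.normal(0.0, replicate_log_sigma)))
                if replicate_log_sigma
                else gene_mean
                for _ in range(n_replicates)
            ]
            rows.append(
                {
                    "gene_id": f"g{gid:04d}",
                    "chrom": chrom,
                    "start": int(start),
                    "end": int(end),
                    "planted_tad": k,
                    "planted_activity": act,
                    **{f"fpkm_rep{i+1}": fpkms[i] for i in range(n_replicates)},
                }
            )
            gid += 1
    return pd.DataFrame(rows)
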