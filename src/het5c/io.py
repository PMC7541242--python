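"""Plain-text I/O: primer TSV, pairwise-interaction TSV, matrix TSV,
BED/bedGraph, FASTQ, and JSON reports."""

from __future__ import annotations

import json

import numpy as np
import pandas as pd
from Bio.SeqIO.QualityIO import FastqGeneralIterator

from .overlap import IntervalSet
from .quant import BinnedContactMatrix, InteractionTable, PrimerRecord, ReadPair
from .tads import TAD, TADSet

PRIMER_COLUMNS = ["id", "chrom", "start", "end", "orientation", "tail", "sequence"]


def write_primer_table(primers: list[PrimerRecord], path, dialect: str = "zero") -> None:
    """Primer TSV; ``dialect='one'`` writes 1-based inclusive coordinates."""
    rows = []
    for p in primers:
        start, end = (p.start + 1, p.end) if dialect == "one" else (p.start, p.end)
        rows.append([p.id, p.chrom, start, end, p.orientation, p.tail, p.sequence])
    pd.DataFrame(rows, columns=PRIMER_COLUMNS).to_csv(path, sep="\t", index=False)


def read_primer_table(path, dialect: str = "zero") -> list[PrimerRecord]:
    df = pd.read_csv(path, sep="\t")
    primers = []
    for row in df.itertuples(index=False):
        start, end = (int(row.start), int(row.end))
        if dialect == "one":
            start -= 1
        primers.append(
            PrimerRecord(
                id=str(row.id),
                chrom=str(row.chrom),
                start=start,
                end=end,
                orientation=str(row.orientation),
                tail=str(row.tail),
                sequence=str(row.sequence),
            )
        )
    return primers


def read_fastq_pairs(path1, path2):
    """Yield ReadPair objects from two synchronized FASTQ files."""
    with open(path1) as f1, open(path2) as f2:
        for (id1, s1, q1), (id2, s2, q2) in zip(
            FastqGeneralIterator(f1), FastqGeneralIterator(f2)
        ):
            yield ReadPair(id=id1.split("/")[0].split()[0], seq1=s1, qual1=q1, seq2=s2, qual2=q2)


def write_interaction_table(
    table: InteractionTable, primers: list[PrimerRecord], path
) -> None:
    """my5C-style pairwise list: both anchors' coordinates plus raw and
    normalized scores."""
    by_id = {p.id: p for p in primers}
    rows = []
    for rec in table.records.itertuples(index=False):
        pf, pr = by_id[rec.fwd_id], by_id[rec.rev_id]
        rows.append(
            [
                rec.fwd_id, pf.chrom, pf.start, pf.end,
                rec.rev_id, pr.chrom, pr.start, pr.end,
                int(rec.raw_count), rec.norm_score,
            ]
        )
    pd.DataFrame(
        rows,
        columns=[
            "fwd_id", "chrom1", "start1", "end1",
            "rev_id", "chrom2", "start2", "end2",
            "raw_count", "norm_score",
        ],
    ).to_csv(path, sep="\t", index=False)


def read_interaction_table(path) -> tuple[InteractionTable, pd.DataFrame]:
    """Read a pairwise TSV back; returns the table and the full coordinate
    frame (for anchor-level analyses)."""
    df = pd.read_csv(path, sep="\t")
    table = InteractionTable.from_counts(df["fwd_id"], df["rev_id"], df["raw_count"])
    if df["norm_score"].notna().any():
        table.records["norm_score"] = df["norm_score"].to_numpy()
    return table, df


def write_matrix(matrix: BinnedContactMatrix, path) -> None:
    with open(path, "w") as fh:
        fh.write(f"# chrom={matrix.chrom}\n")
        fh.write(f"# bin_size={matrix.bin_size}\n")
        fh.write(f"# bin_step={matrix.bin_step}\n")
        fh.write(f"# kind={matrix.kind}\n")
        fh.write(f"# n_bins={matrix.n_bins}\n")
        fh.write("bin_i\tbin_j\tstart_i\tstart_j\tvalue\n")
        for (i, j), v in sorted(matrix.items()):
            fh.write(
                f"{i}\t{j}\t{matrix.bin_starts[i]}\t{matrix.bin_starts[j]}\t{v:.10g}\n"
            )


def read_matrix(path) -> BinnedContactMatrix:
    meta = {}
    with open(path) as fh:
        lines = fh.readlines()
    body_start = 0
    for k, line in enumerate(lines):
        if line.startswith("#"):
            key, _, val = line[1:].strip().partition("=")
            meta[key.strip()] = val.strip()
            body_start = k + 1
        else:
            break
    n_bins = int(meta["n_bins"])
    bin_step = int(meta["bin_step"])
    bin_starts = np.arange(n_bins, dtype=np.int64) * bin_step
    values = {}
    for line in lines[body_start + 1 :]:
        i, j, _, _, v = line.split("\t")
        values[(int(i), int(j))] = float(v)
    return BinnedContactMatrix(
        meta["chrom"], int(meta["bin_size"]), bin_step, bin_starts, values,
        kind=meta.get("kind", "raw"),
    )


def write_bed(intervals, path, names=None) -> None:
    with open(path, "w") as fh:
        for k, (chrom, start, end) in enumerate(intervals):
            name = names[k] if names else f"iv{k}"
            fh.write(f"{chrom}\t{start}\t{end}\t{name}\n")


def read_bed(path, name: str = "bed", universe=None) -> IntervalSet:
    intervals = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split()
            intervals.append((parts[0], int(parts[1]), int(parts[2])))
    return IntervalSet(name, intervals, universe=universe)


def write_tads_bed(tads: TADSet, path) -> None:
    write_bed(
        [(t.chrom, t.start, t.end) for t in tads.tads],
        path,
        names=[t.replicate_id for t in tads.tads],
    )


def read_tads_bed(path, replicate_id: str | None = None) -> TADSet:
    tads = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.split()
            rep = replicate_id or (parts[3] if len(parts) > 3 else "rep")
            tads.append(TAD(parts[0], int(parts[1]), int(parts[2]), rep))
    return TADSet(tads=tads)


def write_bedgraph(chrom, starts, values, span, path) -> None:
    with open(path, "w") as fh:
        for s, v in zip(starts, values):
            fh.write(f"{chrom}\t{int(s)}\t{int(s) + span}\t{v:.6g}\n")


def write_json(obj, path) -> None:
    def default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(f"not JSON serializable: {type(o)}")

    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, default=default)


def read_json(path):
    with open(path) as fh:
        return json.load(fh)
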