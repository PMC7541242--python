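"""End-to-end convenience wrappers tying the stage modules together."""

from __future__ import annotations

import numpy as np

from . import quant, tads
from .quant import InteractionTable, PrimerRecord
from .tads import TADSet


def matrix_from_table(
    table: InteractionTable,
    primers: list[PrimerRecord],
    bin_size: int = 10_000,
    bin_step: int | None = None,
    norm_factor: float = 1.0,
    smooth_span: int = 0,
    score: str = "norm",
):
    """Normalize (if needed) and bin an interaction table."""
    if score == "norm" and not table.normalized:
        table = quant.normalize_total(table, norm_factor)
    return quant.bin_and_smooth(
        table, primers, bin_size=bin_size, bin_step=bin_step,
        smooth_span=smooth_span, score=score,
    )


def call_tads_replicates(
    tables: list[InteractionTable],
    primers: list[PrimerRecord],
    bin_size: int = 10_000,
    window: int = 100_000,
    seed: int = 0,
    norm_factor: float = 1.0,
    min_run: int = 2,
    tolerance: int = 50_000,
    min_support: int = 2,
) -> tuple[TADSet, dict, list[TADSet]]:
    """Per-replicate DI -> HMM -> TAD extraction, then consensus boundaries.

    Returns (consensus TADSet, consensus report, per-replicate TADSets).
    """
    replicate_sets = []
    for k, table in enumerate(tables):
        matrix = matrix_from_table(
            table, primers, bin_size=bin_size, norm_factor=norm_factor
        )
        profile = tads.compute_directionality_index(matrix, window=window)
        _, path = tads.fit_bias_hmm(profile, seed=seed + k)
        ts = tads.extract_tads(
            path, profile.bin_starts, bin_size, profile.chrom,
            replicate_id=f"rep{k + 1}", min_run=min_run,
        )
        replicate_sets.append(ts)
    consensus, report = tads.consensus_boundaries(
        replicate_sets, tolerance=tolerance, min_support=min_support, bin_size=bin_size
    )
    return consensus, report, replicate_sets


def interaction_frame(table: InteractionTable, primers: list[PrimerRecord]):
    """Anchor-coordinate frame (chrom1..end2, score) for condition comparison."""
    import pandas as pd

    by_id = {p.id: p for p in primers}
    rows = []
    score_col = "norm_score" if table.normalized else "raw_count"
    for rec in table.records.itertuples(index=False):
        pf, pr = by_id[rec.fwd_id], by_id[rec.rev_id]
        rows.append(
            (
                pf.chrom, pf.start, pf.end,
                pr.chrom, pr.start, pr.end,
                float(getattr(rec, score_col)),
            )
        )
    return pd.DataFrame(
        rows, columns=["chrom1", "start1", "end1", "chrom2", "start2", "end2", "score"]
    )
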