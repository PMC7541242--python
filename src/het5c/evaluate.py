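"""Self-contained benchmark computations on synthetic data with known truth.

Each function regenerates its inputs from a seed, runs the relevant pipeline
stages, and returns summary metrics. They back both the acceptance test
suite and the standalone acceptance report script.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import compare, overlap, quant, synthetic, tads
from .pipeline import call_tads_replicates, interaction_frame, matrix_from_table
from .quant import BinnedContactMatrix


# --- 1. DI oracle equivalence ------------------------------------------------

def naive_di(dense: np.ndarray, bin_size: int, window: int) -> np.ndarray:
    """Independent double-loop evaluation of the DI formula."""
    nb = window // bin_size
    n = dense.shape[0]
    out = np.zeros(n)
    for i in range(n):
        a = b = 0.0
        for j in range(max(0, i - nb), i):
            if not np.isnan(dense[i, j]):
                a += dense[i, j]
        for j in range(i + 1, min(n, i + nb + 1)):
            if not np.isnan(dense[i, j]):
                b += dense[i, j]
        if a == b:
            continue
        e = (a + b) / 2.0
        sign = 1.0 if b > a else -1.0
        out[i] = sign * ((a - e) ** 2 / e + (b - e) ** 2 / e)
    return out


def di_oracle_check(n_matrices: int = 100, seed: int = 0) -> dict:
    """Exact agreement between the DI implementation and the naive oracle on
    random integer-valued matrices up to 30 bins, plus antisymmetry and the
    A = B -> 0 convention."""
    rng = np.random.default_rng(seed)
    n_equal = 0
    antisym_ok = 0
    for _ in range(n_matrices):
        n = int(rng.integers(3, 31))
        values = {}
        for i in range(n):
            for j in range(i, n):
                if rng.random() < 0.7:
                    values[(i, j)] = float(rng.integers(0, 100))
        m = BinnedContactMatrix("c", 10_000, 10_000, np.arange(n) * 10_000, values)
        di = tads.compute_directionality_index(m, window=100_000).di
        oracle = naive_di(m.to_dense(), 10_000, 100_000)
        if np.array_equal(di, oracle):
            n_equal += 1
        reflected = {(n - 1 - j, n - 1 - i): v for (i, j), v in m.items()}
        mr = BinnedContactMatrix("c", 10_000, 10_000, m.bin_starts, reflected)
        dir_ = tads.compute_directionality_index(mr, window=100_000).di
        if np.array_equal(dir_, -di[::-1]):
            antisym_ok += 1
    # A = B convention
    mm = BinnedContactMatrix(
        "c", 10_000, 10_000, np.arange(3) * 10_000, {(0, 1): 5.0, (1, 2): 5.0}
    )
    ab_zero = tads.compute_directionality_index(mm).di[1] == 0.0
    return {
        "n_matrices": n_matrices,
        "n_equal": n_equal,
        "n_antisymmetric": antisym_ok,
        "a_equals_b_zero": bool(ab_zero),
        "fraction_equal": n_equal / n_matrices,
    }


# --- 2. planted-TAD recovery -------------------------------------------------

def planted_recovery(
    n_seeds: int = 10,
    read_depth: int = 200_000,
    tolerance_bp: int = 20_000,
    seed0: int = 1,
) -> dict:
    """Consensus boundary recovery on the toy 1 Mb / 6-TAD model with 3
    Poisson replicates."""
    recalls, spurious = [], []
    for k in range(n_seeds):
        seed = seed0 + k
        genome = synthetic.toy_genome(seed=seed)
        model = synthetic.toy_model(genome, read_depth=read_depth, n_replicates=3)
        primers = synthetic.generate_primer_set(genome, 10_000)
        tables = synthetic.simulate_contact_counts(primers, model, seed=seed)
        _, report, _ = call_tads_replicates(tables, primers, seed=seed)
        truth = model.boundaries()[genome.chrom_names[0]]
        called = report["chromosomes"][genome.chrom_names[0]]["consensus_boundaries"]
        rec, spur = tads.boundary_match(called, truth, tolerance=tolerance_bp)
        recalls.append(rec / len(truth))
        spurious.append(spur)
    return {
        "n_seeds": n_seeds,
        "recalls": recalls,
        "mean_recall": float(np.mean(recalls)),
        "max_spurious": int(max(spurious)),
        "spurious": spurious,
    }


# --- 3. consensus vs brute-force clustering ---------------------------------

def _brute_force_clusters(positions: list[tuple[int, str]], tolerance: int):
    n = len(positions)
    parent = list(range(n))

    def find(x):
        while parent[x] != x:
            x = parent[x]
        return x

    for i in range(n):
        for j in range(i + 1, n):
            if abs(positions[i][0] - positions[j][0]) <= tolerance:
                parent[find(i)] = find(j)
    groups: dict[int, list] = {}
    for i in range(n):
        groups.setdefault(find(i), []).append(positions[i])
    return [sorted(g) for g in groups.values()]


def consensus_vs_brute_force(
    n_configs: int = 200, tolerance: int = 50_000, seed: int = 0
) -> dict:
    """Consensus clustering must equal O(n^2) single-linkage closure on
    random boundary configurations; identical replicates must be idempotent."""
    rng = np.random.default_rng(seed)
    mismatches = 0
    for _ in range(n_configs):
        n_reps = int(rng.integers(2, 5))
        per_rep = []
        for _ in range(n_reps):
            k = int(rng.integers(1, 5)) * 2
            pos = np.sort(rng.choice(np.arange(0, 3_000_000, 10_000), k, replace=False))
            per_rep.append(pos.tolist())
        sets = []
        for r, bounds in enumerate(per_rep):
            ts = [
                tads.TAD("c", s, e, f"rep{r + 1}")
                for s, e in zip(bounds[::2], bounds[1::2])
            ]
            sets.append(tads.TADSet(tads=ts))
        _, report = tads.consensus_boundaries(sets, tolerance=tolerance, min_support=1)
        got = sorted(report["chromosomes"]["c"]["consensus_boundaries"])
        entries = [(p, f"rep{r + 1}") for r, bs in enumerate(per_rep) for p in bs]
        oracle = sorted(
            int(round(float(np.median([p for p, _ in g]))))
            for g in _brute_force_clusters(entries, tolerance)
        )
        if got != oracle:
            mismatches += 1
    # idempotence on identical replicates with well-separated boundaries
    bounds = [100_000, 400_000, 700_000, 1_200_000]
    sets = [
        tads.TADSet(
            tads=[
                tads.TAD("c", s, e, f"rep{r}")
                for s, e in zip(bounds[::2], bounds[1::2])
            ]
        )
        for r in range(3)
    ]
    _, rep = tads.consensus_boundaries(sets, tolerance=tolerance, min_support=2)
    idempotent = rep["chromosomes"]["c"]["consensus_boundaries"] == bounds
    return {"n_configs": n_configs, "mismatches": mismatches, "idempotent": bool(idempotent)}


# --- 4. permutation-test calibration and power ------------------------------

def permutation_calibration(
    n_runs: int = 200, n_permutations: int = 199, alpha: float = 0.05, seed: int = 0
) -> dict:
    """Type-I error of the overlap permutation test under a uniform null."""
    genome = synthetic.toy_genome(seed=0, length=20_000_000)
    bpos = list(range(100_000, 19_900_000, 100_000))
    query = overlap.IntervalSet(
        "borders",
        [("chrT", p - 5_000, p + 5_000) for p in bpos],
        universe=genome.universe(),
    )
    truth = synthetic.SyntheticTruth(
        boundaries=[("chrT", p) for p in bpos], feature_enrichment={"f": 1.0}
    )
    rejections = 0
    for run in range(n_runs):
        track = synthetic.generate_feature_tracks(
            truth, genome, seed=seed * 100_003 + run, n_intervals=1_000
        )["f"]
        res = overlap.permutation_overlap_test(
            query, track, n_permutations=n_permutations, seed=seed * 7 + run
        )
        rejections += res.p_value <= alpha
    return {"n_runs": n_runs, "rejection_rate": rejections / n_runs}


def permutation_power(
    n_seeds: int = 50, fold: float = 10.0, n_permutations: int = 999, seed: int = 0
) -> dict:
    """Power at planted fold-enrichment of a feature at borders."""
    genome = synthetic.toy_genome(seed=0, length=5_000_000)
    bpos = list(range(400_000, 5_000_000, 500_000))
    query = overlap.IntervalSet(
        "borders",
        [("chrT", p - 5_000, p + 5_000) for p in bpos],
        universe=genome.universe(),
    )
    truth = synthetic.SyntheticTruth(
        boundaries=[("chrT", p) for p in bpos], feature_enrichment={"f": fold}
    )
    hits = 0
    for k in range(n_seeds):
        track = synthetic.generate_feature_tracks(
            truth, genome, seed=seed * 100_003 + k, n_intervals=200
        )["f"]
        res = overlap.permutation_overlap_test(
            query, track, n_permutations=n_permutations, seed=seed * 13 + k
        )
        hits += res.p_value <= 0.01
    return {"n_seeds": n_seeds, "fraction_significant": hits / n_seeds}


# --- 5. quantification round trip -------------------------------------------

def quant_round_trip(tmp_dir, seed: int = 0) -> dict:
    """Noiseless FASTQ must regenerate the simulator's count table exactly;
    conservation must hold on decoy-spiked input."""
    import os

    genome = synthetic.toy_genome(seed=seed, length=400_000)
    model = synthetic.PlantedTADModel(
        tads=(
            ("chrT", 0, 200_000, "active"),
            ("chrT", 200_000, 400_000, "inactive"),
        ),
        read_depth=8_000,
        n_replicates=1,
    )
    primers = synthetic.generate_primer_set(genome, 10_000)
    (table,) = synthetic.simulate_contact_counts(primers, model, seed=seed)
    r1 = os.path.join(tmp_dir, "clean_R1.fastq")
    r2 = os.path.join(tmp_dir, "clean_R2.fastq")
    synthetic.emit_read_pairs(table, primers, r1, r2, seed=seed)
    from .io import read_fastq_pairs

    out = quant.assign_primer_pairs(read_fastq_pairs(r1, r2), primers)
    exact = out.count_lookup() == table.count_lookup()

    d1 = os.path.join(tmp_dir, "decoy_R1.fastq")
    d2 = os.path.join(tmp_dir, "decoy_R2.fastq")
    synthetic.emit_read_pairs(
        table, primers, d1, d2, seed=seed, decoy_fraction=0.3,
        low_quality_read_fraction=0.1,
    )
    spiked = quant.assign_primer_pairs(read_fastq_pairs(d1, d2), primers)
    t = spiked.tallies
    conserved = (
        t["assigned"] + t["ambiguous"] + t["unmatched"]
        + t["quality_dropped"] + t["trim_dropped"]
        == t["input"]
    )
    return {
        "exact_round_trip": bool(exact),
        "count_conservation": bool(conserved),
        "n_pairs": int(table.total_mapped),
        "tallies": t,
    }


# --- 6. obs/exp null ---------------------------------------------------------

def obs_exp_null(n_seeds: int = 50, read_depth: int = 300_000, seed0: int = 0) -> dict:
    """Per-stratum mean log2 obs/exp pooled over null simulations (no
    planted contrast)."""
    pooled: dict[int, list[float]] = {}
    for k in range(n_seeds):
        seed = seed0 + k
        genome = synthetic.toy_genome(seed=seed, length=600_000)
        model = synthetic.PlantedTADModel(
            tads=(
                ("chrT", 0, 300_000, "active"),
                ("chrT", 300_000, 600_000, "inactive"),
            ),
            within_tad_factor=1.0,
            between_tad_factor=1.0,
            read_depth=read_depth,
            n_replicates=1,
        )
        primers = synthetic.generate_primer_set(genome, 10_000)
        (table,) = synthetic.simulate_contact_counts(primers, model, seed=seed)
        matrix = matrix_from_table(table, primers)
        oe, _ = quant.fit_expected_and_log2(matrix)
        for (i, j), v in oe.items():
            if not np.isfinite(v):
                continue
            s = abs(int(oe.bin_starts[j]) - int(oe.bin_starts[i])) // oe.bin_size
            pooled.setdefault(s, []).append(v)
    means = {s: float(np.mean(v)) for s, v in pooled.items()}
    worst = max(abs(m) for m in means.values())
    return {
        "n_seeds": n_seeds,
        "stratum_means": means,
        "worst_abs_stratum_mean": worst,
    }


# --- 7. condition comparison -------------------------------------------------

def _classified(genome, primers, tadset, model, seed, label):
    tables = synthetic.simulate_contact_counts(primers, model, seed=seed)
    frames = [
        interaction_frame(quant.normalize_total(t, 1.0), primers) for t in tables
    ]
    pooled = compare.pool_replicates(frames)
    return compare.classify_interactions(pooled, tadset, label)


def condition_comparison(n_null_seeds: int = 50, seed0: int = 0) -> dict:
    """Knockdown simulation (between-TAD factor raised 3x) must raise the
    inter-TAD median and trip the notch non-overlap flag; null pairs must
    trip it rarely."""
    genome = synthetic.toy_genome(seed=0)
    primers = synthetic.generate_primer_set(genome, 10_000)
    wt_model = synthetic.toy_model(genome, read_depth=200_000, n_replicates=3)
    kd_model = synthetic.toy_model(
        genome, within_tad_factor=5.0, between_tad_factor=3.0,
        read_depth=200_000, n_replicates=2,
    )
    tadset = tads.TADSet(
        tads=[tads.TAD(c, s, e, "consensus") for c, s, e, _ in wt_model.tads]
    )
    wt = _classified(genome, primers, tadset, wt_model, seed0 + 1, "WT")
    kd = _classified(genome, primers, tadset, kd_model, seed0 + 2, "KD")
    summ = compare.summarize_distributions(pd.concat([wt, kd], ignore_index=True))
    by = {(s.condition, s.interaction_class): s for s in summ}
    a, b = by[("WT", "inter_tad")], by[("KD", "inter_tad")]
    kd_effect = {
        "wt_inter_median": a.median,
        "kd_inter_median": b.median,
        "median_increased": bool(b.median > a.median),
        "notch_nonoverlap": compare.notch_nonoverlap(a, b),
    }
    null_flags = 0
    for k in range(n_null_seeds):
        x = _classified(genome, primers, tadset, wt_model, 10_000 + seed0 + 2 * k, "A")
        y = _classified(genome, primers, tadset, wt_model, 20_000 + seed0 + 2 * k, "B")
        sm = compare.summarize_distributions(pd.concat([x, y], ignore_index=True))
        dd = {(s.condition, s.interaction_class): s for s in sm}
        null_flags += compare.notch_nonoverlap(
            dd[("A", "inter_tad")], dd[("B", "inter_tad")]
        )
    kd_effect["null_flag_rate"] = null_flags / n_null_seeds
    kd_effect["n_null_seeds"] = n_null_seeds
    return kd_effect


# --- 8. expression concordance -----------------------------------------------

_ACTIVITY_CATEGORY = {"active": "high", "inactive": "no"}


def expression_concordance(n_seeds: int = 10, category_noise: float = 0.10, seed0: int = 0) -> dict:
    """FPKM categorizer reproduces the printed thresholds at boundary values
    and recovers the planted per-TAD concordance."""
    boundary_ok = (
        compare.fpkm_category(0.5) == "no"
        and compare.fpkm_category(1.0) == "low"
        and compare.fpkm_category(10.0) == "low"
        and compare.fpkm_category(30.0) == "moderate"
        and compare.fpkm_category(50.0) == "moderate"
        and compare.fpkm_category(50.5) == "high"
    )
    errs = []
    genome = synthetic.toy_genome(seed=0)
    model = synthetic.toy_model(genome)
    for k in range(n_seeds):
        df = synthetic.generate_expression_table(
            model, genome, 3, seed=seed0 + k, category_noise=category_noise
        )
        df = compare.categorize_expression(df)
        df["tad_id"] = df["planted_tad"]
        _, recovered = compare.tad_expression_concordance(df)
        planted = df.copy()
        planted["category"] = planted["planted_activity"].map(_ACTIVITY_CATEGORY)
        _, expected = compare.tad_expression_concordance(planted)
        errs.append(abs(recovered - expected))
    return {
        "boundary_categories_ok": bool(boundary_ok),
        "n_seeds": n_seeds,
        "max_abs_concordance_error": float(max(errs)),
        "errors": [float(e) for e in errs],
    }
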