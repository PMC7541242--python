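import numpy as np
import pandas as pd
import pytest

from het5c import io, quant, synthetic
from het5c.synthetic import (
    LIGATION_JUNCTION,
    T3_TAIL,
    T7_TAIL,
    PlantedTADModel,
    SyntheticTruth,
    ToyGenomeSpec,
)


class TestToyGenomeSpec:
    def test_rejects_nonpositive_length(self):
        with pytest.raises(ValueError):
            ToyGenomeSpec(("a",), (0,))

    def test_rejects_duplicate_names(self):
        with pytest.raises(ValueError):
            ToyGenomeSpec(("a", "a"), (10, 10))


class TestPlantedTADModel:
    def test_rejects_overlapping_tads(self):
        with pytest.raises(ValueError):
            PlantedTADModel(
                tads=(("c", 0, 100, "active"), ("c", 50, 200, "inactive"))
            )

    def test_rejects_bad_factors(self):
        with pytest.raises(ValueError):
            PlantedTADModel(
                tads=(("c", 0, 100, "active"),),
                within_tad_factor=1.0,
                between_tad_factor=2.0,
            )

    def test_rejects_negative_decay(self):
        with pytest.raises(ValueError):
            PlantedTADModel(tads=(("c", 0, 100, "active"),), decay_exponent=-1)


class TestGeneratePrimerSet:
    def test_600kb_spacing_10kb_gives_60_alternating(self):
        g = synthetic.toy_genome(seed=1, length=600_000)
        primers = synthetic.generate_primer_set(g, 10_000)
        assert len(primers) == 60
        orientations = [p.orientation for p in primers]
        assert orientations.count("forward") == 30
        assert orientations.count("reverse") == 30
        # strictly alternating, verified by brute-force scan
        for k, p in enumerate(primers):
            assert p.orientation == ("forward" if k % 2 == 0 else "reverse")
            assert p.tail == ("T7" if k % 2 == 0 else "T3")
            assert p.start == k * 10_000
            assert len(p.sequence) == 30

    def test_spacing_equal_length_gives_at_most_one(self):
        g = synthetic.toy_genome(seed=1, length=100_000)
        primers = synthetic.generate_primer_set(g, 100_000)
        assert len(primers) <= 1

    def test_same_seed_identical(self):
        g = synthetic.toy_genome(seed=5, length=200_000)
        a = synthetic.generate_primer_set(g, 10_000)
        b = synthetic.generate_primer_set(g, 10_000)
        assert [p.sequence for p in a] == [p.sequence for p in b]

    def test_different_seed_differs(self):
        a = synthetic.generate_primer_set(synthetic.toy_genome(seed=1, length=200_000), 10_000)
        b = synthetic.generate_primer_set(synthetic.toy_genome(seed=2, length=200_000), 10_000)
        assert [p.sequence for p in a] != [p.sequence for p in b]

    def test_spacing_exceeding_chrom_warns_and_is_empty(self):
        g = synthetic.toy_genome(seed=1, length=50_000)
        with pytest.warns(UserWarning):
            primers = synthetic.generate_primer_set(g, 60_000)
        assert primers == []

    def test_sequences_unique(self):
        g = synthetic.toy_genome(seed=1)
        primers = synthetic.generate_primer_set(g, 10_000)
        seqs = [p.sequence for p in primers]
        assert len(set(seqs)) == len(seqs)

    def test_spacing_below_1kb_rejected(self):
        with pytest.raises(ValueError):
            synthetic.generate_primer_set(synthetic.toy_genome(), 500)


class TestSimulateContactCounts:
    def test_flat_factors_depend_only_on_distance(self, genome, primers):
        m = synthetic.toy_model(genome, within_tad_factor=1.0, between_tad_factor=1.0)
        exp = synthetic.pair_expectations(primers, m)
        # same effective distance -> same rate, regardless of TAD membership
        for _, grp in exp.groupby("distance"):
            assert grp["lam"].nunique() == 1

    def test_intra_exceeds_inter_at_matched_distance(self, genome, primers):
        m = synthetic.toy_model(genome, within_tad_factor=5.0, read_depth=200_000)
        tables = synthetic.simulate_contact_counts(primers, m, seed=11)
        exp = synthetic.pair_expectations(primers, m)
        merged = exp[["fwd_id", "rev_id", "distance", "intra_tad"]].copy()
        means = {True: [], False: []}
        for t in tables:  # brute-force mean over simulated pairs, 3 replicates
            df = merged.merge(t.records, on=["fwd_id", "rev_id"], how="left").fillna(0)
            for dist, grp in df.groupby("distance"):
                if grp["intra_tad"].nunique() == 2:
                    for flag, sub in grp.groupby("intra_tad"):
                        means[bool(flag)].append(sub["raw_count"].mean())
        assert np.mean(means[True]) > np.mean(means[False])

    def test_depth_doubling_doubles_totals(self, genome, primers):
        m1 = synthetic.toy_model(genome, read_depth=100_000, n_replicates=2)
        m2 = synthetic.toy_model(genome, read_depth=200_000, n_replicates=2)
        t1 = synthetic.simulate_contact_counts(primers, m1, seed=4)
        t2 = synthetic.simulate_contact_counts(primers, m2, seed=5)
        for a, b in zip(t1, t2):
            assert abs(b.total_mapped - 2 * a.total_mapped) < 3 * np.sqrt(
                b.total_mapped + 4 * a.total_mapped
            )

    def test_zero_depth_gives_flagged_all_zero(self, genome, primers):
        m = synthetic.toy_model(genome, read_depth=0, n_replicates=1)
        (t,) = synthetic.simulate_contact_counts(primers, m, seed=0)
        assert t.total_mapped == 0
        assert t.all_zero

    def test_deterministic(self, genome, primers, model):
        a = synthetic.simulate_contact_counts(primers, model, seed=9)
        b = synthetic.simulate_contact_counts(primers, model, seed=9)
        for x, y in zip(a, b):
            pd.testing.assert_frame_equal(x.records, y.records)

    def test_requires_both_orientations(self, genome, primers, model):
        fwd_only = [p for p in primers if p.orientation == "forward"]
        with pytest.raises(ValueError):
            synthetic.simulate_contact_counts(fwd_only, model, seed=0)


class TestEmitReadPairs:
    def test_count_seven_round_trip(self, tmp_path):
        g = synthetic.toy_genome(seed=2, length=100_000)
        primers = synthetic.generate_primer_set(g, 10_000)
        f = [p for p in primers if p.orientation == "forward"][3]
        r = [p for p in primers if p.orientation == "reverse"][2]
        table = quant.InteractionTable.from_counts([f.id], [r.id], [7])
        synthetic.emit_read_pairs(
            table, primers, tmp_path / "r1.fq", tmp_path / "r2.fq", seed=0
        )
        out = quant.assign_primer_pairs(
            io.read_fastq_pairs(tmp_path / "r1.fq", tmp_path / "r2.fq"), primers
        )
        assert out.count_lookup() == {(f.id, r.id): 7}

    def test_read_structure(self, tmp_path):
        g = synthetic.toy_genome(seed=2, length=100_000)
        primers = synthetic.generate_primer_set(g, 10_000)
        f = [p for p in primers if p.orientation == "forward"][0]
        r = [p for p in primers if p.orientation == "reverse"][0]
        table = quant.InteractionTable.from_counts([f.id], [r.id], [1])
        synthetic.emit_read_pairs(
            table, primers, tmp_path / "r1.fq", tmp_path / "r2.fq", seed=0
        )
        (pair,) = list(io.read_fastq_pairs(tmp_path / "r1.fq", tmp_path / "r2.fq"))
        assert pair.seq1.startswith(T7_TAIL + f.sequence + LIGATION_JUNCTION + r.sequence)
        assert pair.seq2.startswith(T3_TAIL + r.sequence + LIGATION_JUNCTION + f.sequence)

    def test_decoy_fraction_one_recovers_nothing(self, tmp_path, small_table):
        primers, table = small_table
        synthetic.emit_read_pairs(
            table, primers, tmp_path / "r1.fq", tmp_path / "r2.fq", seed=0,
            decoy_fraction=1.0,
        )
        out = quant.assign_primer_pairs(
            io.read_fastq_pairs(tmp_path / "r1.fq", tmp_path / "r2.fq"), primers
        )
        assert out.total_mapped == 0
        assert out.tallies["assigned"] == 0

    def test_conservation_signal_equals_table_sum(self, tmp_path, small_table):
        primers, table = small_table
        stats = synthetic.emit_read_pairs(
            table, primers, tmp_path / "r1.fq", tmp_path / "r2.fq", seed=0,
            decoy_fraction=0.25,
        )
        assert stats["n_signal"] == table.total_mapped
        assert stats["n_total"] == stats["n_signal"] + stats["n_decoy"]

    def test_quality_floor_fails_filter(self, tmp_path):
        g = synthetic.toy_genome(seed=2, length=100_000)
        primers = synthetic.generate_primer_set(g, 10_000)
        f = [p for p in primers if p.orientation == "forward"][0]
        r = [p for p in primers if p.orientation == "reverse"][0]
        table = quant.InteractionTable.from_counts([f.id], [r.id], [40])
        synthetic.emit_read_pairs(
            table, primers, tmp_path / "r1.fq", tmp_path / "r2.fq", seed=1,
            low_quality_read_fraction=0.5, low_quality_base_fraction=0.30,
        )
        n_fail = 0
        for pair in io.read_fastq_pairs(tmp_path / "r1.fq", tmp_path / "r2.fq"):
            # per-read recount of bases >= Q25
            q = np.frombuffer(pair.qual1.encode(), np.uint8) - 33
            frac = np.mean(q >= 25)
            keeps = quant.quality_filter(pair)
            if frac < 0.8:
                assert not keeps
                n_fail += 1
        assert n_fail == 20

    def test_byte_identical_given_seed(self, tmp_path, small_table):
        primers, table = small_table
        for tag in ("a", "b"):
            synthetic.emit_read_pairs(
                table, primers, tmp_path / f"{tag}1.fq", tmp_path / f"{tag}2.fq",
                seed=42, decoy_fraction=0.1,
            )
        assert (tmp_path / "a1.fq").read_bytes() == (tmp_path / "b1.fq").read_bytes()
        assert (tmp_path / "a2.fq").read_bytes() == (tmp_path / "b2.fq").read_bytes()


class TestFeatureTracks:
    def test_fold_one_uniform_border_rate(self):
        g = synthetic.toy_genome(seed=0, length=5_000_000)
        bpos = list(range(250_000, 5_000_000, 250_000))
        truth = SyntheticTruth(
            boundaries=[("chrT", p) for p in bpos], feature_enrichment={"f": 1.0}
        )
        half = 15_000
        border_bp = len(bpos) * 2 * half
        rho = border_bp / 5_000_000
        hits = total = 0
        for seed in range(50):
            track = synthetic.generate_feature_tracks(
                truth, g, seed=seed, border_half_width=half
            )["f"]
            for chrom, s, e in track.intervals:
                total += 1
                hits += any(abs((s + e) // 2 - p) <= half for p in bpos)
        rate = hits / total
        se = np.sqrt(rho * (1 - rho) / total)
        assert abs(rate - rho) < 3 * se + 2 * (1_000 / 2) / 5_000_000 * len(bpos) * 2

    def test_fold_enrichment_raises_border_rate(self):
        g = synthetic.toy_genome(seed=0, length=5_000_000)
        bpos = list(range(250_000, 5_000_000, 250_000))
        truth = SyntheticTruth(
            boundaries=[("chrT", p) for p in bpos],
            feature_enrichment={"flat": 1.0, "enr": 8.0},
        )
        tracks = synthetic.generate_feature_tracks(truth, g, seed=3)

        def rate(track):
            return np.mean(
                [
                    any(abs((s + e) // 2 - p) <= 15_000 for p in bpos)
                    for _, s, e in track.intervals
                ]
            )

        assert rate(tracks["enr"]) > 4 * rate(tracks["flat"])

    def test_empty_genome_errors(self):
        g = ToyGenomeSpec((), ())
        truth = SyntheticTruth(boundaries=[], feature_enrichment={"f": 1.0})
        with pytest.raises(ValueError):
            synthetic.generate_feature_tracks(truth, g)

    def test_fold_below_one_rejected(self):
        with pytest.raises(ValueError):
            SyntheticTruth(boundaries=[], feature_enrichment={"f": 0.5})

    def test_deterministic(self):
        g = synthetic.toy_genome(seed=0, length=2_000_000)
        truth = SyntheticTruth(
            boundaries=[("chrT", 500_000), ("chrT", 1_500_000)],
            feature_enrichment={"f": 3.0},
        )
        a = synthetic.generate_feature_tracks(truth, g, seed=7)["f"]
        b = synthetic.generate_feature_tracks(truth, g, seed=7)["f"]
        assert a.intervals == b.intervals


class TestExpressionTable:
    def test_category_mode_matches_planted_activity(self, genome, model):
        df = synthetic.generate_expression_table(model, genome, 3, seed=0)
        from het5c.compare import categorize_expression

        cat = categorize_expression(df)
        ok = 0
        for tad, grp in cat.groupby("planted_tad"):
            modal = grp["category"].value_counts().idxmax()
            activity = grp["planted_activity"].iloc[0]
            expected = "high" if activity == "active" else "no"
            ok += modal == expected
        assert ok >= 0.9 * cat["planted_tad"].nunique()

    def test_zero_noise_identical_replicates(self, genome, model):
        df = synthetic.generate_expression_table(
            model, genome, 3, seed=0, replicate_log_sigma=0.0
        )
        assert (df["fpkm_rep1"] == df["fpkm_rep2"]).all()
        assert (df["fpkm_rep1"] == df["fpkm_rep3"]).all()

    def test_straddle_rate_zero_containment(self, genome, model):
        df = synthetic.generate_expression_table(model, genome, 2, seed=0, straddle_rate=0.0)
        spans = {k: (s, e) for k, (_, s, e, _) in enumerate(model.tads)}
        for row in df.itertuples(index=False):  # interval containment scan
            ts, te = spans[row.planted_tad]
            assert ts <= row.start and row.end <= te

    def test_straddlers_cross_boundary(self, genome, model):
        df = synthetic.generate_expression_table(
            model, genome, 2, seed=1, straddle_rate=1.0
        )
        spans = {k: (s, e) for k, (_, s, e, _) in enumerate(model.tads)}
        crossing = sum(
            row.end > spans[row.planted_tad][1] for row in df.itertuples(index=False)
        )
        assert crossing > 0

    def test_deterministic(self, genome, model):
        a = synthetic.generate_expression_table(model, genome, 3, seed=5)
        b = synthetic.generate_expression_table(model, genome, 3, seed=5)
        pd.testing.assert_frame_equal(a, b)
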