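"""Metagene binning, background sampling, enrichment calls, QC, clustering."""

import numpy as np
import pandas as pd
import pytest

from temark.annotation import TETypeCatalog
from temark.coverage import CoverageTrack, read_coverage, write_bigwig
from temark.enrichment import (
    EnrichmentMatrix,
    bin_te_type,
    call_enriched_marks,
    cluster_enrichment_matrix,
    compute_metagene_profile,
    compute_te_enrichment,
    correlate_age_enrichment,
    partition_high_low,
    qc_replicates,
    sample_background_regions,
)
from temark.synthetic import PlantedEffect, generate_coverage_track
from conftest import make_catalog


def naive_max_bin(track_values, copies, bin_bp=500):
    """Per-base oracle: gather every base into its bin by explicit loops,
    reduce with np.sum, average across copies, take the max bin."""
    per_copy = []
    for row in copies.itertuples(index=False):
        positions = range(row.start, row.end)
        if row.strand == "-":
            positions = reversed(list(positions))
        bins = {}
        for offset, pos in enumerate(positions):
            bins.setdefault(offset // bin_bp, []).append(track_values[row.chrom][pos])
        per_copy.append({b: np.sum(v) / len(v) for b, v in bins.items()})
    n_bins = max(max(d) for d in per_copy) + 1
    metagene = []
    for b in range(n_bins):
        col = [d[b] for d in per_copy if b in d]
        metagene.append(np.sum(col) / len(col))
    return max(metagene)


class TestReadCoverage:
    def test_empty_bedgraph_all_zero(self, tmp_path):
        p = tmp_path / "e.bedGraph"
        p.write_text("")
        tr = read_coverage(str(p), {"c": 1000})
        assert (tr.values["c"] == 0).all()

    def test_single_interval_mean(self, tmp_path):
        p = tmp_path / "s.bedGraph"
        p.write_text("c\t0\t100\t2.5\n")
        tr = read_coverage(str(p), {"c": 1000})
        assert tr.mean("c", 0, 100) == 2.5
        assert tr.mean("c", 100, 200) == 0.0

    def test_overlapping_intervals_rejected(self, tmp_path):
        p = tmp_path / "o.bedGraph"
        p.write_text("c\t0\t100\t1.0\nc\t50\t150\t2.0\n")
        with pytest.raises(ValueError, match="overlap"):
            read_coverage(str(p), {"c": 1000})

    def test_out_of_bounds_clipped_with_warning(self, tmp_path):
        p = tmp_path / "c.bedGraph"
        p.write_text("c\t900\t1100\t3.0\n")
        with pytest.warns(UserWarning, match="clipping"):
            tr = read_coverage(str(p), {"c": 1000})
        assert tr.mean("c", 900, 1000) == 3.0

    def test_bigwig_round_trip_matches_bedgraph(self, tmp_path, toy_catalog, toy_sizes):
        track = generate_coverage_track(
            toy_catalog, toy_sizes, [PlantedEffect("alpha", "mark_enrichment", 4.0)],
            "m", noise_sd=0.3, seed=9,
        )
        bg, bw = str(tmp_path / "t.bedGraph"), str(tmp_path / "t.bw")
        track.write_bedgraph(bg)
        write_bigwig(track, bw)
        t1 = read_coverage(bg, toy_sizes)
        t2 = read_coverage(bw, toy_sizes)
        for c in toy_sizes:
            # bigWig stores float32; bedGraph text carries 6 significant digits
            np.testing.assert_allclose(t1.values[c], t2.values[c], rtol=1e-5)


class TestBinning:
    def test_constant_track_constant_bins(self, toy_catalog, toy_sizes):
        tr = CoverageTrack.constant(toy_sizes, 3.25)
        prof = bin_te_type(tr, toy_catalog.copies_of("alpha"))
        assert (prof.values == 3.25).all()

    def test_partial_final_bin_counted(self):
        cat = make_catalog([("c", 0, 1250, "+", "t", "LINE")])
        tr = CoverageTrack.constant({"c": 2000}, 1.0)
        prof = bin_te_type(tr, cat.copies_of("t"))
        assert len(prof.values) == 3  # 500 + 500 + 250

    def test_copy_shorter_than_bin_is_one_bin(self):
        cat = make_catalog([("c", 0, 120, "+", "t", "SINE")])
        tr = CoverageTrack.constant({"c": 2000}, 2.0)
        prof = bin_te_type(tr, cat.copies_of("t"))
        assert len(prof.values) == 1 and prof.values[0] == 2.0

    def test_five_prime_signal_lands_in_bin0_both_strands(self, toy_sizes):
        cat = make_catalog(
            [("chrA", 1000, 2500, "+", "t", "LINE"), ("chrA", 5000, 6500, "-", "t", "LINE")]
        )
        tr = CoverageTrack.constant(toy_sizes, 1.0)
        tr.values["chrA"][1000:1500] = 8.0  # 5' of the + copy
        tr.values["chrA"][6000:6500] = 8.0  # 5' of the - copy
        prof = bin_te_type(tr, cat.copies_of("t"))
        assert prof.values[0] == 8.0
        assert (prof.values[1:] == 1.0).all()

    def test_strand_symmetry_of_bin0(self, toy_spec, toy_sizes):
        from temark.synthetic import generate_te_annotation

        cat = generate_te_annotation(toy_spec)
        eff = [PlantedEffect("alpha", "mark_enrichment", 8.0, profile_bias="5prime")]
        tr = generate_coverage_track(cat, toy_sizes, eff, "m", noise_sd=0.0)
        flipped = TETypeCatalog(
            cat.copies.assign(strand=cat.copies["strand"].map({"+": "-", "-": "+"}))
        )
        tr_flip = generate_coverage_track(flipped, toy_sizes, eff, "m", noise_sd=0.0)
        a = bin_te_type(tr, cat.copies_of("alpha"))
        b = bin_te_type(tr_flip, flipped.copies_of("alpha"))
        assert a.values[0] == b.values[0] == 8.0


class TestBackground:
    def test_length_multiset_matches(self, toy_sizes):
        rows = [("chrA", 0, 300, "+", "t", "LINE"), ("chrA", 1000, 1900, "+", "t", "LINE"),
                ("chrB", 0, 2100, "-", "t", "LINE")]
        copies = make_catalog(rows).copies
        bg = sample_background_regions(copies, toy_sizes, seed=1)
        assert sorted(bg["end"] - bg["start"]) == [300, 900, 2100]
        assert len(bg) == len(copies)

    def test_deterministic_per_seed(self, toy_catalog, toy_sizes):
        copies = toy_catalog.copies_of("beta")
        a = sample_background_regions(copies, toy_sizes, seed=4, te_type="beta")
        b = sample_background_regions(copies, toy_sizes, seed=4, te_type="beta")
        pd.testing.assert_frame_equal(a, b)

    def test_exclusion_respected(self, toy_sizes):
        from intervaltree import IntervalTree

        copies = make_catalog([("chrA", 0, 500, "+", "t", "LINE")] * 30).copies
        exclude = {
            "chrA": IntervalTree.from_tuples([(0, 1_100_000)]),
            "chrB": IntervalTree.from_tuples([(0, 700_000)]),
        }
        bg = sample_background_regions(copies, toy_sizes, seed=2, exclude=exclude)
        assert ((bg["chrom"] == "chrA") & (bg["start"] >= 1_100_000)).sum() + (
            (bg["chrom"] == "chrB") & (bg["start"] >= 700_000)
        ).sum() == len(bg)


class TestEnrichment:
    def test_constant_track_zero_log2fold(self, toy_catalog, toy_sizes):
        tr = CoverageTrack.constant(toy_sizes, 1.0)
        row = compute_te_enrichment(tr, toy_catalog, seed=3)
        assert np.allclose(row["log2fold"], 0.0)

    def test_observed_equals_per_base_oracle_exactly(self, toy_catalog, toy_sizes):
        eff = [PlantedEffect("alpha", "mark_enrichment", 8.0, profile_bias="5prime"),
               PlantedEffect("gamma", "mark_enrichment", 3.0)]
        tr = generate_coverage_track(toy_catalog, toy_sizes, eff, "m", noise_sd=0.25, seed=8)
        row = compute_te_enrichment(tr, toy_catalog, seed=3)
        for te_type in toy_catalog.type_names:
            oracle = naive_max_bin(tr.values, toy_catalog.copies_of(te_type))
            assert row.loc[te_type, "obs"] == oracle  # bit-exact

    def test_planted_uniform_fold_recovered(self, toy_catalog, toy_sizes):
        tr = generate_coverage_track(
            toy_catalog, toy_sizes, [PlantedEffect("beta", "mark_enrichment", 8.0)],
            "m", noise_sd=0.2, seed=5,
        )
        row = compute_te_enrichment(tr, toy_catalog, seed=6)
        assert abs(row.loc["beta", "log2fold"] - 3.0) <= 0.25
        assert abs(row.loc["alpha", "log2fold"]) <= 0.5

    def test_zero_obs_zero_exp_flagged(self, toy_sizes):
        cat = make_catalog([("chrA", 0, 500, "+", "t", "LINE")] * 5)
        tr = CoverageTrack.zeros(toy_sizes)
        row = compute_te_enrichment(tr, cat, seed=1)
        assert row.loc["t", "log2fold"] == 0.0
        assert bool(row.loc["t", "low_information"])


class TestCalls:
    @pytest.fixture
    def matrix(self):
        lf = pd.DataFrame(
            {"teA": [np.log2(3.1)], "teB": [np.log2(1.7)], "teC": [np.log2(0.4)]},
            index=["mark1"],
        )
        return EnrichmentMatrix.from_log2fold(lf)

    def test_known_folds_thresholded(self, matrix):
        calls = call_enriched_marks(matrix, threshold=2.0, relaxed=1.5)
        assert int(calls.calls.loc["mark1"].sum()) == 1
        assert int(calls.relaxed_calls.loc["mark1"].sum()) == 2
        assert calls.per_mark.loc["mark1", "n_te_enriched"] == 1

    def test_exact_threshold_not_enriched_under_strict(self):
        lf = pd.DataFrame({"te": [1.0]}, index=["m"])  # fold exactly 2.0
        m = EnrichmentMatrix.from_log2fold(lf)
        assert not call_enriched_marks(m, threshold=2.0).calls.loc["m", "te"]
        assert call_enriched_marks(m, threshold=2.0, strict=False).calls.loc["m", "te"]

    def test_all_zero_matrix_no_calls(self):
        lf = pd.DataFrame(np.zeros((2, 3)), index=["m1", "m2"], columns=["a", "b", "c"])
        calls = call_enriched_marks(EnrichmentMatrix.from_log2fold(lf))
        assert not calls.calls.values.any()


class TestHighLow:
    def test_figure_rule(self):
        folds = [5, 4, 3, 2.5, 2.1, 1.9, 1.5, 1.2, 0.9, 0.5]
        lf = pd.DataFrame([np.log2(folds)], index=["m"], columns=[f"t{i}" for i in range(10)])
        high, low = partition_high_low(EnrichmentMatrix.from_log2fold(lf), "m")
        assert high == [f"t{i}" for i in range(5)]
        assert low == [f"t{i}" for i in range(5, 10)]

    def test_no_enriched_types_empty_sets(self):
        lf = pd.DataFrame([[0.1, 0.2]], index=["m"], columns=["a", "b"])
        high, low = partition_high_low(EnrichmentMatrix.from_log2fold(lf), "m")
        assert high == [] and low == []

    def test_overlap_condition_errors(self):
        lf = pd.DataFrame([[2.0, 2.1, 2.2]], index=["m"], columns=["a", "b", "c"])
        with pytest.raises(ValueError, match="half"):
            partition_high_low(EnrichmentMatrix.from_log2fold(lf), "m")


class TestClustering:
    def test_identical_columns_merge_first(self):
        rng = np.random.default_rng(0)
        df = pd.DataFrame(rng.normal(size=(6, 4)), columns=["a", "b", "c", "d"])
        df["b"] = df["a"]
        res = cluster_enrichment_matrix(df, axis="cols")
        first = res.linkage_matrix[0]
        assert first[2] == 0.0  # distance of the first merge
        merged = {res.labels[int(first[0])], res.labels[int(first[1])]}
        assert merged == {"a", "b"}

    def test_planted_two_cluster_recovery(self):
        rng = np.random.default_rng(1)
        base1, base2 = rng.normal(size=8), rng.normal(size=8)
        rows = {}
        for i in range(4):
            rows[f"g1_{i}"] = base1 + rng.normal(0, 0.05, 8)
        for i in range(4):
            rows[f"g2_{i}"] = base2 + rng.normal(0, 0.05, 8)
        df = pd.DataFrame(rows).T
        res = cluster_enrichment_matrix(df, axis="rows")
        assign = res.cut(2)
        groups = {}
        for label, k in assign.items():
            groups.setdefault(k, set()).add(label.split("_")[0])
        assert all(len(v) == 1 for v in groups.values())

    def test_row_permutation_leaves_membership_unchanged(self):
        rng = np.random.default_rng(2)
        df = pd.DataFrame(rng.normal(size=(6, 5)), index=[f"r{i}" for i in range(6)])
        res1 = cluster_enrichment_matrix(df).cut(3)
        res2 = cluster_enrichment_matrix(df.iloc[::-1]).cut(3)
        # same partition of labels regardless of input order
        part1 = {frozenset(l for l, k in res1.items() if k == v) for v in set(res1.values())}
        part2 = {frozenset(l for l, k in res2.items() if k == v) for v in set(res2.values())}
        assert part1 == part2

    def test_constant_row_distance_defined(self):
        df = pd.DataFrame([[1.0, 1.0, 1.0], [0.1, 0.5, 0.9]], index=["flat", "var"])
        res = cluster_enrichment_matrix(df)
        assert res.linkage_matrix[0][2] == 1.0  # constant row: 1 - r defined as 1


class TestAgeCorrelation:
    def test_strictly_decreasing_gives_minus_one(self):
        lf = pd.DataFrame([[3.0, 2.0, 1.0, 0.5]], index=["m"], columns=list("abcd"))
        ages = pd.Series([1e6, 2e6, 3e6, 4e6], index=list("abcd"))
        out = correlate_age_enrichment(EnrichmentMatrix.from_log2fold(lf), ages)
        assert out.loc["m", "rho"] == -1.0

    def test_p_calibrated_by_permutation(self):
        rng = np.random.default_rng(3)
        n = 200
        lf = pd.DataFrame([rng.normal(size=n)], index=["m"], columns=[f"t{i}" for i in range(n)])
        ages = pd.Series(rng.uniform(1e6, 5e7, n), index=lf.columns)
        out = correlate_age_enrichment(EnrichmentMatrix.from_log2fold(lf), ages)
        rho, p = out.loc["m", "rho"], out.loc["m", "p"]
        assert abs(rho) < 0.2
        # permutation oracle for the p-value
        from scipy.stats import spearmanr

        perm_rhos = []
        vals = lf.loc["m"].to_numpy()
        for _ in range(1000):
            perm_rhos.append(spearmanr(ages.to_numpy(), rng.permutation(vals))[0])
        p_perm = float(np.mean(np.abs(perm_rhos) >= abs(rho)))
        assert abs(p - p_perm) < 0.1

    def test_constant_enrichment_flagged(self):
        lf = pd.DataFrame([[1.0, 1.0, 1.0]], index=["m"], columns=list("abc"))
        ages = pd.Series([1e6, 2e6, 3e6], index=list("abc"))
        with pytest.warns(UserWarning, match="constant"):
            out = correlate_age_enrichment(EnrichmentMatrix.from_log2fold(lf), ages)
        assert not out.loc["m", "defined"]

    def test_too_few_points_flagged(self):
        lf = pd.DataFrame([[1.0, 2.0]], index=["m"], columns=list("ab"))
        ages = pd.Series([1e6, 2e6], index=list("ab"))
        out = correlate_age_enrichment(EnrichmentMatrix.from_log2fold(lf), ages)
        assert not out.loc["m", "defined"]


class TestMetageneProfile:
    def test_constant_track_flat_profile(self, toy_catalog, toy_sizes):
        tr = CoverageTrack.constant(toy_sizes, 2.0)
        prof = compute_metagene_profile(tr, toy_catalog.copies_of("alpha"), n_body_bins=20)
        finite = prof[np.isfinite(prof)]
        assert np.allclose(finite, 2.0)

    def test_body_only_signal_stays_in_body(self, toy_sizes):
        cat = make_catalog([("chrA", 50_000, 52_000, "+", "t", "LTR")])
        tr = CoverageTrack.constant(toy_sizes, 1.0)
        tr.values["chrA"][50_000:52_000] = 5.0
        prof = compute_metagene_profile(tr, cat.copies_of("t"), flank_bp=5000, n_body_bins=10)
        n_flank = 10  # 5000 / 500
        assert np.allclose(prof[n_flank:n_flank + 10], 5.0)
        assert np.allclose(prof[:n_flank], 1.0) and np.allclose(prof[-n_flank:], 1.0)


class TestReplicateQC:
    def test_identical_tracks_kept_and_merged(self, toy_catalog, toy_sizes):
        tr = generate_coverage_track(toy_catalog, toy_sizes, [], "m", noise_sd=0.3, seed=1)
        qc = qc_replicates({"r1": tr, "r2": tr}, toy_catalog)
        assert qc.kept == ["r1", "r2"] and qc.dropped == []
        assert qc.correlations.loc["r1", "r2"] == pytest.approx(1.0)
        for c in toy_sizes:
            np.testing.assert_allclose(qc.merged.values[c], tr.values[c])

    def test_anticorrelated_replicate_dropped(self, toy_catalog, toy_sizes):
        eff = [PlantedEffect("alpha", "mark_enrichment", 6.0)]
        a = generate_coverage_track(toy_catalog, toy_sizes, eff, "m", noise_sd=0.1, seed=1)
        b = generate_coverage_track(toy_catalog, toy_sizes, eff, "m", noise_sd=0.1, seed=2)
        # anti-correlated over the TE vector: high where a is low
        c = CoverageTrack({k: np.maximum(0.0, 7.0 - v) for k, v in a.values.items()})
        qc = qc_replicates({"a": a, "b": b, "c": c}, toy_catalog)
        assert set(qc.kept) == {"a", "b"} and qc.dropped == ["c"]
        # Pearson by the direct formula on the per-copy vectors
        from temark.enrichment import _per_copy_rpkm_vector

        va, vc = _per_copy_rpkm_vector(a, toy_catalog), _per_copy_rpkm_vector(c, toy_catalog)
        r = np.mean((va - va.mean()) * (vc - vc.mean())) / (va.std() * vc.std())
        assert qc.correlations.loc["a", "c"] == pytest.approx(r, abs=1e-12)
        assert r < 0.6

    def test_all_discordant_keeps_highest_coverage(self, toy_catalog, toy_sizes):
        rng = np.random.default_rng(5)
        tracks = {}
        for i, scale in enumerate([1.0, 2.0]):
            vals = {c: scale * rng.exponential(1.0, n) for c, n in toy_sizes.items()}
            tracks[f"r{i}"] = CoverageTrack(vals)
        with pytest.warns(UserWarning, match="discordant"):
            qc = qc_replicates(tracks, toy_catalog, min_r=0.99)
        assert qc.kept == ["r1"]  # the higher-coverage replicate
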