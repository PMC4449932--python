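"""Panel evaluation statistics: MAF, trios, pairwise rates, distribution."""

import numpy as np
import pandas as pd
import pytest

from maizefp import fingerprint_eval as fe
from maizefp import simdata


def _matrix(rows: dict, loci=None) -> pd.DataFrame:
    n = len(next(iter(rows.values())))
    cols = loci or [f"L{i + 1}" for i in range(n)]
    return pd.DataFrame.from_dict(rows, orient="index", columns=cols)


class TestMaf:
    def test_hand_counted_values(self):
        m = _matrix({f"s{i}": ["AA"] for i in range(6)}
                    | {f"t{i}": ["AB"] for i in range(2)}
                    | {f"u{i}": ["BB"] for i in range(2)})
        maf = fe.compute_maf(m)
        # 6 AA + 2 AB + 2 BB -> B allele count 2*2+2 = 6 of 20
        assert maf["maf"].iloc[0] == pytest.approx(0.3)

    def test_balanced_locus_is_half(self):
        m = _matrix({f"a{i}": ["AA"] for i in range(10)}
                    | {f"b{i}": ["BB"] for i in range(10)})
        assert fe.compute_maf(m)["maf"].iloc[0] == pytest.approx(0.5)

    def test_monomorphic_is_zero_and_all_nc_is_nan(self):
        m = _matrix({"s1": ["AA", "NC"], "s2": ["AA", "NC"]})
        maf = fe.compute_maf(m)
        assert maf["maf"]["L1"] == 0.0
        assert np.isnan(maf["maf"]["L2"])
        assert maf["n_informative"]["L2"] == 0

    def test_invariant_under_allele_relabeling(self, small_run):
        calls = small_run["calls"].iloc[:, :50]
        swapped = calls.replace({"AA": "BB", "BB": "AA"})
        a = fe.compute_maf(calls)["maf"]
        b = fe.compute_maf(swapped)["maf"]
        pd.testing.assert_series_equal(a, b)
        assert a.dropna().between(0, 0.5).all()


class TestPedigree:
    @pytest.mark.parametrize(
        "p1, p2, f1, ok",
        [("AA", "BB", "AB", True), ("AA", "AA", "AA", True),
         ("AA", "AB", "AB", True), ("AB", "AB", "BB", True),
         ("AA", "AA", "AB", False), ("AA", "BB", "AA", False),
         ("AA", "AB", "BB", False)],
    )
    def test_mendelian_expectation_sets(self, p1, p2, f1, ok):
        m = _matrix({"P1": [p1], "P2": [p2], "F1": [f1]})
        res = fe.pedigree_consistency(m, ("P1", "P2", "F1"))
        assert res.n_scorable == 1
        assert (res.n_consistent == 1) is ok

    def test_nc_loci_excluded_from_denominator(self):
        m = _matrix({"P1": ["AA", "NC", "AA"], "P2": ["BB", "AA", "AA"],
                     "F1": ["AB", "AA", "NC"]})
        res = fe.pedigree_consistency(m, ("P1", "P2", "F1"))
        assert res.n_scorable == 1
        assert res.consistency == 1.0

    def test_error_free_simulated_triplet_is_fully_consistent(self):
        uni = simdata.generate_locus_universe(500, defect_fractions={}, seed=31)
        samples, truth = simdata.generate_population(
            uni, n_inbreds_per_group=2, groups=("STPT", "P"),
            n_hybrids=1, n_triplets=1, seed=31)
        trio = simdata.triplets(samples)[0]
        res = fe.pedigree_consistency(truth.true_genotypes, trio)
        assert res.n_scorable == 500
        assert res.consistency == 1.0

    def test_missing_sample_raises_with_name(self):
        m = _matrix({"P1": ["AA"]})
        with pytest.raises(KeyError, match="GHOST"):
            fe.pedigree_consistency(m, ("P1", "GHOST", "P1"))


class TestPairwise:
    @pytest.mark.parametrize("n, expected", [(276, 37_950), (309, 47_586), (2, 1)])
    def test_pair_count_identity(self, n, expected):
        m = _matrix({f"s{i}": ["AA", "BB"] for i in range(n)})
        pairs, hist = fe.pairwise_differences(m)
        assert len(pairs) == expected
        assert hist.sum() == expected

    def test_hand_counted_rate_and_symmetry(self):
        rng = np.random.default_rng(3)
        a = rng.choice(["AA", "AB", "BB"], size=100)
        b = a.copy()
        b[:30] = np.where(b[:30] == "AA", "BB", "AA")
        m = pd.DataFrame([a, b], index=["s1", "s2"],
                         columns=[f"L{i}" for i in range(100)])
        pairs, _ = fe.pairwise_differences(m)
        assert pairs[0].differential_rate == pytest.approx(0.30)
        assert fe.genetic_similarity(m, ("s1", "s2")) == pytest.approx(0.70)
        assert fe.genetic_similarity(m, ("s2", "s1")) == pytest.approx(0.70)

    def test_duplicate_pair_has_zero_rate(self, small_run):
        meta = small_run["meta"]
        dup = meta[meta["duplicate_of"] != ""].iloc[0]
        rate = 1.0 - fe.genetic_similarity(
            small_run["truth"].true_genotypes,
            (dup["sample_id"], dup["duplicate_of"]))
        assert rate == 0.0

    def test_nc_excluded_and_undefined_pair_reported(self):
        m = _matrix({"s1": ["AA", "NC"], "s2": ["NC", "BB"], "s3": ["AA", "BB"]})
        pairs, hist = fe.pairwise_differences(m)
        undefined = [p for p in pairs if p.n_cocalled == 0]
        assert len(undefined) == 1
        assert {undefined[0].sample_a, undefined[0].sample_b} == {"s1", "s2"}
        assert np.isnan(undefined[0].differential_rate)
        assert hist.sum() == 2  # only defined pairs enter the histogram

    def test_backcross_similarity_tracks_generator_truth(self):
        uni = simdata.generate_locus_universe(4000, defect_fractions={}, seed=33)
        samples, truth = simdata.generate_population(
            uni, n_inbreds_per_group=2,
            similar_line_spec=[simdata.SimilarLineSpec(1, 0.02)], seed=33)
        base = samples[0].sample_id
        member = next(s.sample_id for s in samples if s.sample_id.startswith("SIM"))
        sim = fe.genetic_similarity(truth.true_genotypes, (base, member))
        assert abs(sim - 0.98) <= 3 * np.sqrt(0.02 * 0.98 / 4000)


class TestConcordance:
    def test_identical_matrices_fully_concordant(self, small_run):
        calls = small_run["calls"]
        overall, per_locus = fe.platform_concordance(calls, calls)
        assert overall == 1.0
        assert per_locus.dropna().eq(1.0).all()

    def test_single_mismatch_arithmetic(self):
        m = _matrix({f"s{i}": ["AA"] for i in range(100)}, loci=["L1"])
        m2 = m.copy()
        m2.iloc[0, 0] = "BB"
        overall, _ = fe.platform_concordance(m, m2)
        assert overall == pytest.approx(0.99)

    def test_uniform_corruption_matches_expectation(self):
        rng = np.random.default_rng(44)
        calls = pd.DataFrame(
            rng.choice(["AA", "AB", "BB"], size=(92, 400)),
            index=[f"s{i}" for i in range(92)],
            columns=[f"L{i}" for i in range(400)])
        corrupted = calls.copy()
        mask = rng.random(calls.shape) < 0.05
        arr = corrupted.to_numpy()
        arr[mask] = rng.choice(["AA", "AB", "BB"], size=int(mask.sum()))
        overall, _ = fe.platform_concordance(calls, pd.DataFrame(
            arr, index=calls.index, columns=calls.columns))
        expected = 1 - 0.05 * (2 / 3)
        n = calls.size
        assert abs(overall - expected) <= 3 * np.sqrt(expected * (1 - expected) / n)

    def test_empty_intersection_rejected(self):
        a = _matrix({"s1": ["AA"]}, loci=["L1"])
        b = _matrix({"s2": ["AA"]}, loci=["L2"])
        with pytest.raises(ValueError):
            fe.platform_concordance(a, b)


class TestGenomicDistribution:
    def test_window_counts_conserve_panel_size(self, small_run):
        frame = simdata.universe_frame(small_run["universe"])
        panel = list(frame.index[:123])
        counts, props = fe.genomic_distribution(panel, frame)
        assert counts["n_snps"].sum() == 123
        assert props.sum() == pytest.approx(1.0)

    def test_window_boundary_convention(self):
        lmap = pd.DataFrame(
            {"locus_id": ["a", "b"], "chromosome": [1, 1],
             "position": [1_000_000, 1_000_001],
             "genic_category": ["exon", "exon"]}).set_index("locus_id", drop=False)
        counts, _ = fe.genomic_distribution(["a", "b"], lmap)
        assert sorted(counts["window"]) == [1, 2]

    def test_default_genic_proportions_recovered(self):
        uni = simdata.generate_locus_universe(10_000, defect_fractions={}, seed=55)
        frame = simdata.universe_frame(uni)
        _, props = fe.genomic_distribution(list(frame.index), frame)
        for cat, p in simdata.DEFAULT_GENIC_PROPORTIONS.items():
            assert abs(props[cat] - p) <= 3 * np.sqrt(p * (1 - p) / 10_000)

    def test_unmapped_locus_rejected(self, small_run):
        frame = simdata.universe_frame(small_run["universe"])
        with pytest.raises(KeyError, match="GHOST"):
            fe.genomic_distribution(["GHOST"], frame)


class TestComparativeReport:
    def _results(self, run, name, loci):
        return {
            "name": name,
            "qc": run["qc"].loc[loci],
            "maf": run["maf"].loc[loci],
            "matrix": run["calls"][loci],
            "sample_meta": run["meta"],
        }

    def test_panel_against_itself_is_identical(self, small_run):
        loci = list(small_run["calls"].columns[:80])
        res = self._results(small_run, "a", loci)
        res_b = dict(res, name="b")
        table = fe.comparative_report(res, res_b)
        pd.testing.assert_series_equal(table["a"], table["b"], check_names=False)

    def test_curated_panel_raises_average_maf(self, small_run):
        all_loci = list(small_run["calls"].columns)
        curated = small_run["report"].final_panel
        table = fe.comparative_report(
            self._results(small_run, "curated", curated),
            self._results(small_run, "universe", all_loci))
        assert table.at["average_maf", "curated"] >= table.at["average_maf", "universe"]
        assert table.at["marker_success_rate", "curated"] >= table.at[
            "marker_success_rate", "universe"]

    def test_mismatched_sample_sets_rejected(self, small_run):
        loci = list(small_run["calls"].columns[:10])
        res_a = self._results(small_run, "a", loci)
        res_b = self._results(small_run, "b", loci)
        res_b["sample_meta"] = res_b["sample_meta"].iloc[:-1]
        with pytest.raises(ValueError):
            fe.comparative_report(res_a, res_b)
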