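"""Generator tests: layout invariants, Mendelian structure, defect planting."""

import numpy as np
import pandas as pd
import pytest

from maizefp import simdata, signalmodel
from maizefp.simdata import NoiseProfile, SimilarLineSpec


def binom_3sd(p, n):
    return 3 * np.sqrt(p * (1 - p) / n)


class TestLocusUniverse:
    def test_zero_defect_fractions_gives_clean_universe(self):
        uni = simdata.generate_locus_universe(100, defect_fractions={}, seed=1)
        assert len(uni) == 100
        assert all(l.defect_class == "none" for l in uni)
        assert all(l.copy_number == 1 for l in uni)

    def test_positions_strictly_increasing_within_chromosome(self):
        uni = simdata.generate_locus_universe(2000, seed=2)
        df = simdata.universe_frame(uni)
        for _, grp in df.groupby("chromosome"):
            assert grp["position"].is_monotonic_increasing
            assert grp["position"].is_unique
            assert (grp["position"] >= 1).all()

    def test_designability_mixture_matches_configured_mass(self):
        uni = simdata.generate_locus_universe(10_000, defect_fractions={}, seed=3)
        scores = np.array([l.designability for l in uni])
        assert scores.min() >= 0.40 and scores.max() <= 1.0
        frac_high = (scores > 0.80).mean()
        assert abs(frac_high - 0.71) <= binom_3sd(0.71, 10_000)
        frac_mid = ((scores > 0.60) & (scores <= 0.80)).mean()
        assert abs(frac_mid - 0.275) <= binom_3sd(0.275, 10_000)

    def test_defect_fractions_realized_within_3sd(self):
        fractions = {"weak_signal": 0.05, "shifted": 0.10}
        uni = simdata.generate_locus_universe(5000, defect_fractions=fractions, seed=4)
        classes = pd.Series([l.defect_class for l in uni])
        for name, frac in fractions.items():
            realized = (classes == name).mean()
            assert abs(realized - frac) <= binom_3sd(frac, 5000)

    def test_same_seed_reproduces_identical_universe(self):
        a = simdata.generate_locus_universe(300, seed=5)
        b = simdata.generate_locus_universe(300, seed=5)
        assert a == b

    @pytest.mark.parametrize(
        "fractions, message",
        [({"weak_signal": -0.1}, "negative"), ({"weak_signal": 0.7, "shifted": 0.6}, "sum"),
         ({"nonsense": 0.1}, "nonsense")],
    )
    def test_invalid_defect_fractions_rejected(self, fractions, message):
        with pytest.raises(ValueError, match=message):
            simdata.generate_locus_universe(100, defect_fractions=fractions, seed=1)

    def test_genic_region_membership_unique(self):
        uni = simdata.generate_locus_universe(500, seed=6, genic_region_size=3)
        df = simdata.universe_frame(uni)
        # every locus belongs to exactly one region; regions never span chromosomes
        per_region = df.groupby("genic_region_id")["chromosome"].nunique()
        assert (per_region == 1).all()


class TestPopulation:
    def test_f1_is_mendelian_combination_of_homozygous_parents(self, clean_universe):
        samples, truth = simdata.generate_population(
            clean_universe, n_inbreds_per_group=2, groups=("STPT", "P"),
            n_hybrids=1, n_triplets=1, seed=8)
        (p1, p2, f1) = simdata.triplets(samples)[0]
        g = truth.true_genotypes
        distinct = (g.loc[p1] == "AA") & (g.loc[p2] == "BB")
        assert (g.loc[f1][distinct] == "AB").all()
        same = g.loc[p1] == g.loc[p2]
        assert (g.loc[f1][same] == g.loc[p1][same]).all()

    def test_inbreds_fully_homozygous(self, clean_universe):
        samples, truth = simdata.generate_population(
            clean_universe, n_inbreds_per_group=4, seed=9)
        inbred_ids = [s.sample_id for s in samples if s.role == "inbred"]
        assert not (truth.true_genotypes.loc[inbred_ids] == "AB").any().any()

    def test_similar_line_identity_matches_mutation_fraction(self):
        uni = simdata.generate_locus_universe(5000, defect_fractions={}, seed=10)
        samples, truth = simdata.generate_population(
            uni, n_inbreds_per_group=2, n_duplicates=0,
            similar_line_spec=[SimilarLineSpec(n_members=1, mutation_fraction=0.02)],
            seed=10)
        base = samples[0].sample_id
        member = [s for s in samples if s.sample_id.startswith("SIM")][0].sample_id
        identity = (truth.true_genotypes.loc[base] == truth.true_genotypes.loc[member]).mean()
        assert abs(identity - 0.98) <= binom_3sd(0.02, 5000)

    def test_duplicate_truth_identical_to_source(self, clean_universe):
        samples, truth = simdata.generate_population(
            clean_universe, n_inbreds_per_group=2, n_duplicates=1, seed=11)
        dup = next(s for s in samples if s.duplicate_of)
        assert truth.true_genotypes.loc[dup.sample_id].equals(
            truth.true_genotypes.loc[dup.duplicate_of])

    def test_inbred_allele_frequency_converges_to_group_frequency(self):
        uni = simdata.generate_locus_universe(50, defect_fractions={},
                                              divergence=0.0, seed=12)
        samples, truth = simdata.generate_population(
            uni, n_inbreds_per_group=200, groups=("STPT",), seed=12)
        freqs = np.array([l.allele_freq_by_group["STPT"] for l in uni])
        emp = (truth.true_genotypes == "BB").mean(axis=0).to_numpy()
        assert (np.abs(emp - freqs) <= binom_3sd(freqs, 200) + 1e-12).all()

    def test_unknown_group_rejected(self, clean_universe):
        with pytest.raises(ValueError, match="Popcorn"):
            simdata.generate_population(clean_universe, n_inbreds_per_group=2,
                                        groups=("Popcorn",), seed=1)

    def test_study_panel_shape(self, small_run):
        samples = small_run["samples"]
        assert len(samples) == 96
        assert sum(s.role == "inbred" for s in samples) == 56
        assert sum(s.role == "hybrid" for s in samples) == 40
        assert len(simdata.triplets(samples)) == 40  # every hybrid's parents present


class TestIntensities:
    def test_clean_homozygote_theta_and_determinism(self, clean_universe):
        samples, truth = simdata.generate_population(
            clean_universe, n_inbreds_per_group=3, seed=13)
        ints = simdata.generate_intensities(clean_universe, samples, truth, seed=13)
        ints2 = simdata.generate_intensities(clean_universe, samples, truth, seed=13)
        pd.testing.assert_frame_equal(ints, ints2)
        theta, r = signalmodel.to_theta_r(ints["x"].to_numpy(), ints["y"].to_numpy())
        truth_long = truth.true_genotypes.loc[
            [s.sample_id for s in samples], [l.locus_id for l in clean_universe]
        ].to_numpy().ravel()
        assert (theta[truth_long == "AA"] < 0.2).all()
        assert (theta[truth_long == "BB"] > 0.8).all()

    def test_zero_noise_places_theta_exactly_at_center(self, clean_universe):
        samples, truth = simdata.generate_population(
            clean_universe, n_inbreds_per_group=2, seed=14)
        profile = NoiseProfile(theta_sd=0.0, signal_sd=0.0)
        ints = simdata.generate_intensities(clean_universe, samples, truth,
                                            profile, seed=14)
        theta, r = signalmodel.to_theta_r(ints["x"].to_numpy(), ints["y"].to_numpy())
        assert set(np.round(theta, 12)) <= {0.05, 0.50, 0.95}
        np.testing.assert_allclose(r, 1.0)

    def test_weak_signal_locus_has_weak_median(self, small_run):
        ints = small_run["intensities"]
        prof = NoiseProfile()
        weak = [l.locus_id for l in small_run["universe"] if l.defect_class == "weak_signal"]
        assert weak
        sub = ints[ints["locus_id"].isin(weak)]
        med = (sub["x"] + sub["y"]).groupby(sub["locus_id"]).median()
        assert (med < 0.2 * prof.signal_mean).all()

    def test_high_missing_locus_fails_enough_samples(self, small_run):
        ints = small_run["intensities"]
        cf = small_run["cluster_file"]
        bad = [l.locus_id for l in small_run["universe"] if l.defect_class == "high_missing"]
        assert bad
        calls = small_run["calls"]
        frac_nc = (calls[bad] == "NC").mean(axis=0)
        assert (frac_nc > 0.05).all()
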