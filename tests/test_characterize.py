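"""Affiliation posteriors, profile thresholding, descriptives, recovery matching."""

import numpy as np
import pandas as pd
import pytest

from segmint import (
    FitConfig,
    PlsaModel,
    affiliation,
    banding_medians,
    characterize,
    default_codebook,
    descriptive_table,
    encode,
    fit_plsa,
    generate_roster,
    match_clusters,
    median_band,
    roster_from_counts,
    round_half_away,
    segment_accuracy,
    stratify_by_sex,
)

from conftest import small_spec


def model_from(pz, pv_rows, pi_rows, labels=None):
    pv = np.asarray(pv_rows, dtype=float)
    pi = np.asarray(pi_rows, dtype=float)
    return PlsaModel(
        K=len(pz),
        pz=np.asarray(pz, dtype=float),
        pi_z=pi / pi.sum(axis=0, keepdims=True),
        pv_z=pv / pv.sum(axis=0, keepdims=True),
        loglik=0.0,
        column_labels=labels or [f"v{i}:x" for i in range(pv.shape[0])],
        row_ids=[f"r{i}" for i in range(pi.shape[0])],
    )


class TestAffiliation:
    def test_posterior_from_equal_priors(self):
        # P(z)=(.5,.5), P(v|z1)=.3, P(v|z2)=.2 -> A = (.6, .4)
        m = model_from([0.5, 0.5], [[0.3, 0.2], [0.7, 0.8]], [[1, 1], [1, 1]])
        a = affiliation(m)
        assert np.allclose(a.var_affil[0], [0.6, 0.4])

    def test_k1_affiliation_is_one(self):
        m = model_from([1.0], [[0.3], [0.7]], [[0.5], [0.5]])
        a = affiliation(m)
        assert np.allclose(a.var_affil, 1.0)
        assert np.allclose(a.ind_affil, 1.0)

    def test_prior_dominates_equal_likelihoods(self):
        m = model_from([0.8, 0.2], [[0.4, 0.4], [0.6, 0.6]], [[1, 1], [1, 1]])
        a = affiliation(m)
        assert np.allclose(a.var_affil, [[0.8, 0.2], [0.8, 0.2]])

    def test_rows_sum_to_one(self):
        spec = small_spec(k=3, n=100, seed=4)
        roster, _ = generate_roster(spec)
        male, _ = stratify_by_sex(roster)
        mat = encode(male, spec.codebook)
        model = fit_plsa(mat, 3, FitConfig(n_restarts=2, seed=0))
        a = affiliation(model)
        assert np.allclose(a.var_affil.sum(axis=1), 1.0, atol=1e-10)
        assert np.allclose(a.ind_affil.sum(axis=1), 1.0, atol=1e-10)

    def test_zero_mass_level_gets_uniform_with_warning(self):
        m = model_from([0.5, 0.5], [[0.0, 0.0], [1.0, 1.0]], [[1, 1], [1, 1]])
        m.pv_z = np.array([[0.0, 0.0], [1.0, 1.0]])
        with pytest.warns(RuntimeWarning, match="zero total mass"):
            a = affiliation(m)
        assert np.allclose(a.var_affil[0], [0.5, 0.5])


class TestCharacterize:
    def two_cluster_affil(self, a_top):
        m = model_from(
            [0.5, 0.5],
            [[2 * a_top, 2 * (1 - a_top)], [2 * (1 - a_top), 2 * a_top]],
            [[1, 1], [1, 1]],
            labels=["age:young", "age:old"],
        )
        return affiliation(m)

    def test_threshold_is_inclusive_at_tau(self):
        a = self.two_cluster_affil(0.55)
        profiles = characterize(a, tau=0.55)
        assert [lbl for lbl, _ in profiles[0].levels] == ["age:young"]

    def test_just_below_threshold_is_excluded(self):
        a = self.two_cluster_affil(0.549)
        with pytest.warns(RuntimeWarning, match="no variable-level"):
            profiles = characterize(a, tau=0.55)
        assert profiles[0].levels == [] and profiles[1].levels == []

    def test_tau_half_puts_split_level_in_both_profiles(self):
        """At tau=0.5 a 50/50 level characterizes two clusters at once —

        the motivation for the working threshold 0.55."""
        a = self.two_cluster_affil(0.5)
        profiles = characterize(a, tau=0.5)
        assert {lbl for lbl, _ in profiles[0].levels} == {"age:young", "age:old"}
        assert {lbl for lbl, _ in profiles[1].levels} == {"age:young", "age:old"}

    def test_raising_tau_never_adds_levels(self):
        spec = small_spec(k=2, n=80, seed=6)
        roster, _ = generate_roster(spec)
        male, _ = stratify_by_sex(roster)
        model = fit_plsa(encode(male, spec.codebook), 2, FitConfig(n_restarts=2, seed=1))
        a = affiliation(model)
        sizes = []
        for tau in (0.5, 0.6, 0.7, 0.8, 0.9):
            profiles = characterize(a, tau=tau)
            sizes.append([len(p.levels) for p in profiles])
        for lo, hi in zip(sizes, sizes[1:]):
            assert all(h <= l for l, h in zip(lo, hi))

    def test_member_counts_partition_sample(self):
        spec = small_spec(k=2, n=90, seed=8)
        roster, _ = generate_roster(spec)
        male, _ = stratify_by_sex(roster)
        model = fit_plsa(encode(male, spec.codebook), 2, FitConfig(n_restarts=2, seed=2))
        profiles = characterize(affiliation(model), tau=0.55)
        assert sum(p.n_members for p in profiles) == len(male)


class TestDescriptives:
    def test_published_percentages_from_published_counts(self):
        roster = roster_from_counts()
        desc = descriptive_table(roster)
        assert desc.percentage("male", "age_group", "age_65_74") == 61.0
        assert desc.percentage("male", "living_alone", "yes") == 73.0
        assert desc.percentage("female", "age_group", "age_85_over") == 14.9
        assert desc.percentage("male", "pension_band", "none") == 67.6
        assert desc.percentage("female", "ltc_status", "long_term_care_need") == 22.9
        assert desc.percentage("male", "working", "yes") == 9.3

    def test_counts_sum_to_stratum_and_percentages_to_100(self):
        roster = roster_from_counts()
        df = descriptive_table(roster).table
        for (sex, var), grp in df.groupby(["sex", "variable"]):
            assert grp["count"].sum() == {"male": 1483, "female": 1682}[sex]
            assert grp["percentage"].sum() == pytest.approx(100.0, abs=0.2)

    def test_zero_count_gives_zero_percent(self, codebook):
        roster = roster_from_counts()
        sub = roster[roster["sex"] == "male"].copy()
        sub["working"] = "no"
        desc = descriptive_table(sub, codebook)
        assert desc.percentage("male", "working", "yes") == 0.0

    def test_rounding_half_away_from_zero(self):
        assert round_half_away(0.25, 1) == 0.3  # bankers' rounding would give 0.2
        assert round_half_away(61.0249 , 1) == 61.0
        assert round_half_away(-0.25, 1) == -0.3
        assert round_half_away(9.305, 1) == 9.3 or round_half_away(9.305, 1) == 9.3


class TestMedianBand:
    def test_even_split(self):
        bands = median_band(pd.Series([10, 20, 30, 40]), pd.Series(["male"] * 4))
        assert list(bands) == ["below_median", "below_median", "above_median", "above_median"]

    def test_all_zero_is_none(self):
        bands = median_band(pd.Series([0.0, 0.0]), pd.Series(["male", "male"]))
        assert list(bands) == ["none", "none"]

    def test_tie_at_median_goes_below(self):
        bands = median_band(pd.Series([10, 20, 30]), pd.Series(["male"] * 3))
        assert list(bands) == ["below_median", "below_median", "above_median"]

    def test_median_over_positive_amounts_only_per_sex(self):
        amounts = pd.Series([0, 0, 10, 30, 0, 100, 300])
        sex = pd.Series(["male"] * 4 + ["female"] * 3)
        bands = median_band(amounts, sex)
        meds = banding_medians(amounts, sex)
        assert meds == {"male": 20.0, "female": 200.0}
        assert list(bands) == [
            "none", "none", "below_median", "above_median",
            "none", "below_median", "above_median",
        ]

    def test_below_count_at_least_above_count(self):
        """The tie rule reproduces the published near-even splits (35 vs 34)."""
        rng = np.random.default_rng(0)
        amounts = pd.Series(np.round(rng.lognormal(10, 0.5, size=69)))
        bands = median_band(amounts, pd.Series(["male"] * 69))
        counts = bands.value_counts()
        assert counts["below_median"] >= counts["above_median"]


class TestMatchClusters:
    @pytest.fixture(scope="class")
    def fitted(self):
        # n large enough that sampling noise sits well inside the 0.05 bound
        spec = small_spec(k=3, n=600, seed=12)
        roster, truth = generate_roster(spec)
        male, _ = stratify_by_sex(roster)
        mat = encode(male, spec.codebook)
        model = fit_plsa(mat, 3, FitConfig(n_restarts=4, seed=3))
        return model, mat, truth

    def test_recovery_error_small_on_separated_data(self, fitted):
        model, mat, truth = fitted
        perm, err = match_clusters(model, mat, truth, sex="male")
        assert sorted(perm) == [0, 1, 2]
        assert err <= 0.05

    def test_label_swap_recovers_swap_permutation(self, fitted):
        model, mat, truth = fitted
        perm0, err0 = match_clusters(model, mat, truth, sex="male")
        swapped = PlsaModel(
            K=3,
            pz=model.pz[[1, 0, 2]],
            pi_z=model.pi_z[:, [1, 0, 2]],
            pv_z=model.pv_z[:, [1, 0, 2]],
            row_ids=model.row_ids,
            column_labels=model.column_labels,
        )
        perm1, err1 = match_clusters(swapped, mat, truth, sex="male")
        assert err1 == pytest.approx(err0, abs=1e-12)
        assert perm1 == (perm0[1], perm0[0], perm0[2])

    def test_k_mismatch_raises(self, fitted):
        model, mat, truth = fitted
        truth.spec.k_true = 4
        try:
            with pytest.raises(ValueError, match="does not match"):
                match_clusters(model, mat, truth, sex="male")
        finally:
            truth.spec.k_true = 3

    def test_segment_accuracy_high_on_separated_data(self, fitted):
        model, mat, truth = fitted
        perm, _ = match_clusters(model, mat, truth, sex="male")
        assert segment_accuracy(model, truth, perm) >= 0.9
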