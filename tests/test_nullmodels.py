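"""Taxa-shuffle null model, SES standardization and the Wilcoxon test."""

from itertools import permutations

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import funcdisp as fd
from funcdisp._errors import NumericalError, ValidationError
from funcdisp.nullmodels import _exact_signflip_pvalue
from conftest import brute_alpha_pw, dist_fn


def _dist(n=4, seed=5) -> fd.TraitDistanceMatrix:
    rng = np.random.default_rng(seed)
    D = rng.random((n, n))
    D = (D + D.T) / 2
    np.fill_diagonal(D, 0.0)
    return fd.TraitDistanceMatrix(D, [f"s{i}" for i in range(n)])


class TestTaxaShuffle:
    def test_distance_multiset_preserved(self):
        dist = _dist(6)
        shuffled = fd.taxa_shuffle(dist, rng=3)
        assert shuffled.labels == dist.labels
        np.testing.assert_allclose(
            np.sort(shuffled.condensed()), np.sort(dist.condensed())
        )

    def test_three_species_shuffles_enumerate_relabelings(self):
        dist = _dist(3, seed=9)
        expected = {
            fd.TraitDistanceMatrix(
                dist.values[np.ix_(p, p)], dist.labels, validate=False
            ).condensed().tobytes()
            for p in permutations(range(3))
        }
        seen = set()
        rng = np.random.default_rng(0)
        for _ in range(200):
            seen.add(fd.taxa_shuffle(dist, rng).condensed().tobytes())
        assert seen == expected  # exactly the 6 relabeled matrices, all reached

    def test_identity_permutation_is_noop(self):
        dist = _dist(4)
        p = np.arange(4)
        same = fd.TraitDistanceMatrix(dist.values[np.ix_(p, p)], dist.labels)
        np.testing.assert_array_equal(same.values, dist.values)


class TestNullDistribution:
    def test_small_pool_matches_exhaustive_enumeration(self):
        dist = _dist(5, seed=7)
        w = {"s0": 0.5, "s2": 0.3, "s4": 0.2}
        exact_vals = np.array(
            [
                fd.alpha_pw(w, fd.TraitDistanceMatrix(
                    dist.values[np.ix_(p, p)], dist.labels, validate=False))
                for p in permutations(range(5))
            ]
        )
        null = fd.null_distribution(fd.alpha_pw, w, dist, n_iter=2000, rng=1)
        se_mean = exact_vals.std() / np.sqrt(null.n_iter)
        se_sd = exact_vals.std() / np.sqrt(2 * (null.n_iter - 1))
        assert abs(null.mean - exact_vals.mean()) < 3 * se_mean
        assert abs(null.sd - exact_vals.std()) < 3 * se_sd

    def test_full_pool_equal_abundance_degenerate(self):
        dist = _dist(4)
        w = {lab: 1.0 for lab in dist.labels}
        null = fd.null_distribution(fd.alpha_pw, w, dist, n_iter=99, rng=2)
        assert null.sd == pytest.approx(0.0)
        assert np.isnan(fd.ses(fd.alpha_pw(w, dist), null.mean, null.sd))

    def test_seed_reproducibility(self):
        dist = _dist(5)
        w = {"s0": 1.0, "s1": 2.0, "s3": 1.0}
        a = fd.null_distribution(fd.alpha_pw, w, dist, n_iter=199, rng=42)
        b = fd.null_distribution(fd.alpha_pw, w, dist, n_iter=199, rng=42)
        assert (a.mean, a.sd) == (b.mean, b.sd)


class TestSes:
    def test_observed_at_null_mean_is_zero(self):
        assert fd.ses(5.0, 5.0, 2.0) == 0.0

    def test_two_sd_below_mean(self):
        assert fd.ses(1.0, 5.0, 2.0) == pytest.approx(-2.0)

    def test_zero_sd_undefined(self):
        assert np.isnan(fd.ses(5.0, 5.0, 0.0))

    def test_scale_invariance_under_distance_rescaling(self):
        dist = _dist(6, seed=11)
        comm = fd.CommunityMatrix(
            pd.DataFrame(
                [[1, 0, 2, 0, 1, 0], [0, 3, 0, 1, 0, 2], [1, 1, 1, 0, 0, 0]],
                index=["p1", "p2", "p3"], columns=dist.labels, dtype=float,
            )
        )
        scaled = fd.TraitDistanceMatrix(dist.values * 7.5, dist.labels)
        a = fd.alpha_ses_table(comm, dist, n_iter=199, rng=4)
        b = fd.alpha_ses_table(comm, scaled, n_iter=199, rng=4)
        np.testing.assert_allclose(a["ses"], b["ses"], rtol=1e-9)


class TestSesTables:
    def test_observed_column_matches_scalar_metrics(self, small_survey):
        coph = fd.build_all_dendrograms(small_survey.traits)[fd.MULTI_TRAIT].cophenetic
        comm = small_survey.community
        tab = fd.alpha_ses_table(comm, coph, n_iter=99, rng=0)
        rel = comm.relative_abundances()
        for _, row in tab[tab.defined].head(20).iterrows():
            fn = fd.alpha_pw if row.metric == "PW" else fd.alpha_nn
            assert row.observed == pytest.approx(fn(rel.loc[row.community], coph), abs=1e-12)

    def test_table_determinism(self, small_survey):
        coph = fd.build_all_dendrograms(small_survey.traits)[fd.MULTI_TRAIT].cophenetic
        a = fd.alpha_ses_table(small_survey.community, coph, n_iter=99, rng=7)
        b = fd.alpha_ses_table(small_survey.community, coph, n_iter=99, rng=7)
        pd.testing.assert_frame_equal(a, b)

    def test_beta_table_observed_matches_direct(self, small_survey):
        comm, hier = small_survey.community, small_survey.hierarchy
        coph = fd.build_all_dendrograms(small_survey.traits)[fd.MULTI_TRAIT].cophenetic
        tab = fd.beta_ses_table(comm, hier, "depth", coph, n_iter=99, rng=0)
        direct = fd.beta_within_group(comm, hier, "depth", coph)
        merged = tab.merge(direct, on=["group", "unit_a", "unit_b", "metric"])
        np.testing.assert_allclose(merged["observed"], merged["value"], atol=1e-12)

    def test_beta_null_matches_exhaustive_small_pool(self):
        # 4-species pool: enumerate all 24 relabelings exactly
        dist = _dist(4, seed=13)
        wa = pd.Series({"s0": 0.6, "s1": 0.4})
        wb = pd.Series({"s2": 0.5, "s3": 0.5})
        exact = np.array(
            [
                fd.beta_dpw(wa, wb, fd.TraitDistanceMatrix(
                    dist.values[np.ix_(p, p)], dist.labels, validate=False))
                for p in permutations(range(4))
            ]
        )
        comm = fd.CommunityMatrix(
            pd.DataFrame([[0.6, 0.4, 0, 0], [0, 0, 0.5, 0.5]],
                         index=["pA", "pB"], columns=dist.labels)
        )
        hier = fd.SpatialHierarchy(
            pd.DataFrame(
                {"plot": ["pA", "pB"], "depth_stratum": ["d", "d"],
                 "water_depth_m": [0.5, 0.5], "lake": ["l", "l"],
                 "region": ["r", "r"], "elevation_m": [1.0, 1.0]}
            )
        )
        tab = fd.beta_ses_table(comm, hier, "plot", dist, n_iter=3000, rng=3)
        row = tab[tab.metric == "Dpw"].iloc[0]
        se_mean = exact.std() / np.sqrt(3000)
        assert abs(row.null_mean - exact.mean()) < 3 * se_mean
        assert abs(row.null_sd - exact.std()) < 3 * exact.std() / np.sqrt(2 * 2999)


class TestWilcoxon:
    def test_symmetric_pairs_give_p_one(self):
        res = fd.wilcoxon_departure([-1, 1, -2, 2, -3, 3])
        assert res.pvalue == 1.0
        assert res.method == "exact"

    def test_six_negative_values_exact_tail(self):
        res = fd.wilcoxon_departure([-0.5, -1.0, -1.5, -2.0, -2.5, -3.0])
        assert res.pvalue == pytest.approx(1 / 32)
        assert res.direction == "negative"

    def test_matches_scipy_exact_without_ties(self):
        rng = np.random.default_rng(8)
        for _ in range(10):
            v = rng.normal(0.3, 1.0, 12)
            ours = fd.wilcoxon_departure(v)
            ref = stats.wilcoxon(v, alternative="two-sided", method="exact")
            assert ours.pvalue == pytest.approx(ref.pvalue, abs=1e-12)

    def test_large_sample_uses_normal_approximation(self):
        rng = np.random.default_rng(9)
        v = rng.normal(-0.5, 1.0, 60)
        res = fd.wilcoxon_departure(v)
        ref = stats.wilcoxon(v, alternative="two-sided", correction=True, method="approx")
        assert res.method == "approx"
        assert res.pvalue == pytest.approx(ref.pvalue)

    def test_too_few_values_rejected(self):
        with pytest.raises(ValidationError):
            fd.wilcoxon_departure([-1.0, 1.0, 2.0])

    def test_all_zero_rejected(self):
        with pytest.raises(NumericalError):
            fd.wilcoxon_departure([0.0] * 10)

    def test_exact_dp_handles_tied_ranks(self):
        # duplicate magnitudes force midranks; DP still sums to 2^n
        v = np.array([1.0, -1.0, 2.0, 2.0, -3.0])
        _, p = _exact_signflip_pvalue(v)
        assert 0.0 < p <= 1.0

    def test_stars_convention(self):
        assert fd.significance_stars(0.2) == ""
        assert fd.significance_stars(0.04) == "*"
        assert fd.significance_stars(0.009) == "**"
        assert fd.significance_stars(0.0009) == "***"


class TestSesSummary:
    def test_summary_groups_and_small_groups_flagged(self, small_survey):
        coph = fd.build_all_dendrograms(small_survey.traits)[fd.MULTI_TRAIT].cophenetic
        tab = fd.alpha_ses_table(small_survey.community, coph, n_iter=99, rng=5)
        tab["scale"] = "plot"
        tab["trait_metric"] = fd.MULTI_TRAIT
        summary = fd.ses_summary(tab)
        assert set(summary["metric"]) == {"PW", "NN"}
        assert (summary["n_defined"] > 0).all()
        assert summary["pvalue"].between(0, 1).all()
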