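import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from conftest import build_cohort, random_cohort
from oracles import wc_fst_single_site
from purgekit import load, outliers
from purgekit.model import CohortError
from purgekit.pipeline import compute_site_stats


def polarized(cohort):
    return load.polarize(cohort)


class TestFst:
    def test_hwe_equal_frequencies_near_zero(self):
        rng = np.random.default_rng(40)
        gt = rng.binomial(2, 0.5, size=(300, 10)).astype(np.int8)
        cohort = polarized(build_cohort(gt))
        out = outliers.fst_per_site(cohort, np.arange(5), np.arange(5, 10))
        assert abs(np.nanmean(out["fst"])) < 0.05

    def test_fixed_difference_is_one(self):
        gt = np.array([[2] * 5 + [0] * 5], dtype=np.int8)
        cohort = polarized(build_cohort(gt))
        out = outliers.fst_per_site(cohort, np.arange(5), np.arange(5, 10))
        assert out.loc[0, "fst"] == pytest.approx(1.0)

    def test_matches_independent_weir_cockerham_oracle(self):
        rng = np.random.default_rng(41)
        gt = rng.integers(0, 3, size=(200, 10)).astype(np.int8)
        cohort = polarized(build_cohort(gt))
        out = outliers.fst_per_site(cohort, np.arange(5), np.arange(5, 10))
        dos = cohort.derived_dosage()
        rows = np.flatnonzero(cohort.polarizable)
        for i, r in enumerate(rows):
            expected = wc_fst_single_site(dos[r, :5], dos[r, 5:])
            got = out.loc[i, "fst"]
            if np.isnan(expected):
                assert np.isnan(got)
            else:
                assert got == pytest.approx(expected, rel=1e-10)

    def test_monomorphic_sites_excluded_as_nan(self):
        gt = np.array([[1, 1, 1, 1]], dtype=np.int8)  # freq 0.5 in both, but defined
        cohort = polarized(build_cohort(gt))
        out = outliers.fst_per_site(cohort, np.array([0, 1]), np.array([2, 3]))
        assert np.isfinite(out.loc[0, "fst"])


class TestPCAScores:
    def test_k_must_be_below_sample_count(self):
        rng = np.random.default_rng(42)
        cohort = polarized(random_cohort(rng, n_sites=50, n_samples=4))
        with pytest.raises(CohortError, match="k="):
            outliers.pca_outlier_scores(cohort, np.arange(4), k=4)

    def test_planted_separating_site_is_top_decile(self, rs_contrast):
        res, cohort = rs_contrast
        cols = np.sort(
            np.r_[cohort.rs_group_columns("high"), cohort.rs_group_columns("low")]
        )
        scores, lam = outliers.pca_outlier_scores(cohort, cols)
        assert lam > 0
        merged = scores.merge(res.truth.candidate_sites, on=["contig", "pos"])
        threshold = np.quantile(scores["pca_score"], 0.9)
        assert (merged["pca_score"] > threshold).mean() >= 0.9

    def test_inflation_factor_unity_on_chi2_distances(self):
        rng = np.random.default_rng(43)
        for k in (1, 2):
            dist = rng.chisquare(k, size=10_000)
            assert outliers.genomic_inflation(dist, k) == pytest.approx(1.0, abs=0.05)


class TestDeltaLoad:
    def _frames(self, q_low, q_high, impact):
        def frame(q):
            return pd.DataFrame(
                {
                    "contig": ["chr1"],
                    "pos": [10],
                    "impact": [impact],
                    "derived_freq": [q],
                    "site_load": [
                        {"MODIFIER": 0.0, "LOW": 0.1, "MODERATE": 0.3, "HIGH": 0.6}[impact] * q
                    ],
                }
            )

        return frame(q_low), frame(q_high)

    def test_hand_value_positive_toward_low_rs(self):
        out = outliers.delta_load(*self._frames(0.8, 0.1, "HIGH"))
        assert out.loc[0, "delta_load"] == pytest.approx(0.42)

    def test_equal_frequencies_zero(self):
        out = outliers.delta_load(*self._frames(0.3, 0.3, "MODERATE"))
        assert out.loc[0, "delta_load"] == 0.0

    def test_modifier_always_zero(self):
        out = outliers.delta_load(*self._frames(0.9, 0.0, "MODIFIER"))
        assert out.loc[0, "delta_load"] == 0.0


class TestIntersection:
    def _stats(self, pca, fst, dl):
        n = len(pca)
        return pd.DataFrame(
            {
                "contig": ["chr1"] * n,
                "pos": np.arange(1, n + 1),
                "pca_score": pca,
                "fst": fst,
                "delta_load": dl,
            }
        )

    def test_planted_joint_outliers_recovered_exactly(self):
        n = 1000
        cols = []
        for s in range(3):
            c = np.zeros(n)
            c[:10] = 10.0  # joint outliers at the first 10 sites
            block = slice(10 + 90 * s, 100 + 90 * s)  # disjoint per-statistic tails
            c[block] = 5.0
            cols.append(c)
        out = outliers.intersect_candidates(self._stats(*cols))
        assert sorted(out["candidates"]["pos"]) == list(range(1, 11))

    def test_disjoint_top_deciles_empty(self):
        n = 30
        base = np.zeros(n)
        pca, fst, dl = base.copy(), base.copy(), base.copy()
        pca[:3], fst[3:6], dl[6:9] = 5, 5, 5
        out = outliers.intersect_candidates(self._stats(pca, fst, dl))
        assert out["n_candidates"] == 0

    def test_nearest_rank_cutoff_keeps_ten_of_hundred(self):
        rng = np.random.default_rng(51)
        vals = rng.permutation(100).astype(float)
        thr = outliers.nearest_rank_threshold(vals, 90)
        assert (vals > thr).sum() == 10

    @settings(max_examples=25, derandomize=True)
    @given(st.integers(min_value=0, max_value=2**31 - 1))
    def test_candidates_invariant_to_monotone_transform(self, seed):
        rng = np.random.default_rng(seed)
        n = 120
        stats = self._stats(rng.normal(size=n), rng.normal(size=n), rng.normal(size=n))
        base = outliers.intersect_candidates(stats)
        warped = stats.copy()
        warped["pca_score"] = np.exp(warped["pca_score"])
        warped["fst"] = 3 * warped["fst"] + 7
        out = outliers.intersect_candidates(warped)
        pd.testing.assert_frame_equal(base["candidates"], out["candidates"])
        assert base["n_candidates"] <= min(base["per_statistic_counts"].values())

    def test_null_three_way_fraction_matches_independence(self):
        rng = np.random.default_rng(52)
        n = 10_000
        out = outliers.intersect_candidates(
            self._stats(rng.normal(size=n), rng.normal(size=n), rng.normal(size=n))
        )
        expected = n * 0.1**3
        sd = np.sqrt(n * 0.1**3 * (1 - 0.1**3))
        assert abs(out["n_candidates"] - expected) <= 3 * sd

    def test_percentile_out_of_range_rejected(self):
        with pytest.raises(CohortError):
            outliers.intersect_candidates(self._stats([1.0], [1.0], [1.0]), percentile=100)


class TestEndToEndContrast:
    def test_planted_candidates_recovered_by_three_way_intersection(self, rs_contrast):
        res, cohort = rs_contrast
        stats = compute_site_stats(cohort)
        out = outliers.intersect_candidates(stats)
        merged = out["stats"].merge(res.truth.candidate_sites, on=["contig", "pos"])
        assert merged["candidate"].sum() >= 9

    def test_carriage_reported_for_outside_populations(self, rs_contrast):
        res, cohort = rs_contrast
        carriage = outliers.candidate_carriage(
            cohort, res.truth.candidate_sites, populations=["srw_like", "bh_like"]
        )
        # planted q_outside = 0.01: candidates nearly absent outside
        assert carriage["carried"].mean() < 0.5
        assert set(carriage["population"]) == {"srw_like", "bh_like"}
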