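import numpy as np
import pytest

from conftest import build_cohort, random_cohort
from oracles import sfs_tally
from purgekit import load
from purgekit.model import CohortError


def polarized(cohort):
    return load.polarize(cohort)


class TestPolarize:
    def test_minor_alt_is_derived(self):
        gt = np.array([[1, 1, 0, 0, 0]], dtype=np.int8)  # alt freq 0.2
        cohort = polarized(build_cohort(gt))
        assert cohort.derived_is_alt[0]

    def test_major_alt_flips_to_ref_derived(self):
        gt = np.array([[2, 2, 2, 1, 0]], dtype=np.int8)  # alt freq 0.7
        cohort = polarized(build_cohort(gt))
        assert not cohort.derived_is_alt[0]

    def test_exact_tie_designates_alt_deterministically(self):
        gt = np.array([[2, 0, 1, 1]], dtype=np.int8)  # alt freq exactly 0.5
        for _ in range(3):
            assert polarized(build_cohort(gt)).derived_is_alt[0]

    def test_invariant_sites_not_polarizable(self):
        gt = np.array([[0, 0], [2, 2], [1, 0]], dtype=np.int8)
        cohort = polarized(build_cohort(gt))
        assert cohort.polarizable.tolist() == [False, False, True]


def four_class_cohort(rng, n_samples=6):
    return polarized(random_cohort(rng, n_sites=240, n_samples=n_samples))


class TestIndividualLoads:
    def test_all_homozygous_derived_individual_scores_exactly_one(self):
        rng = np.random.default_rng(5)
        cohort = four_class_cohort(rng)
        gt = cohort.gt.copy()
        # make s0 homozygous-derived at every segregating site, keeping the
        # site set and polarity fixed
        rows = np.flatnonzero(cohort.polarizable)
        gt[rows, 0] = np.where(cohort.derived_is_alt[rows], 2, 0)
        cohort2 = build_cohort(gt, impacts=cohort.sites["impact"])
        cohort2.derived_is_alt = cohort.derived_is_alt
        cohort2.polarizable = cohort.polarizable
        tab = load.individual_loads(cohort2)
        assert tab.loc[0, "total_load"] == pytest.approx(1.0, abs=1e-12)

    def test_zero_derived_alleles_zero_loads(self):
        gt = np.array([[0, 1, 1], [0, 2, 1], [0, 1, 0]], dtype=np.int8)
        cohort = polarized(build_cohort(gt, impacts=["LOW", "HIGH", "MODERATE"]))
        tab = load.individual_loads(cohort)
        assert tab.loc[0, ["total_load", "hom_load", "het_load"]].tolist() == [0, 0, 0]

    def test_hand_computed_class_dosage_example(self):
        # 2 LOW sites (s0: one het, one hom-ref) + 1 HIGH site (s0 hom-derived)
        gt = np.array([[1, 0, 1], [0, 1, 1], [2, 0, 1]], dtype=np.int8)
        cohort = polarized(build_cohort(gt, impacts=["LOW", "LOW", "HIGH"]))
        tab = load.individual_loads(cohort)
        assert tab.loc[0, "total_load"] == pytest.approx(0.625)
        assert tab.loc[0, "hom_load"] == pytest.approx(0.6)
        assert tab.loc[0, "het_load"] == pytest.approx(0.025)

    def test_total_equals_hom_plus_het_and_bounded(self):
        rng = np.random.default_rng(6)
        cohort = four_class_cohort(rng, n_samples=10)
        tab = load.individual_loads(cohort)
        np.testing.assert_allclose(
            tab["total_load"], tab["hom_load"] + tab["het_load"], atol=1e-12
        )
        assert tab["total_load"].between(0, 1).all()

    def test_adding_derived_allele_never_decreases_load(self):
        rng = np.random.default_rng(8)
        cohort = four_class_cohort(rng)
        base = load.individual_loads(cohort).loc[0, "total_load"]
        dos = cohort.derived_dosage()
        rows = np.flatnonzero(cohort.polarizable & (dos[:, 0] < 2))
        r = rows[0]
        gt = cohort.gt.copy()
        step = 1 if cohort.derived_is_alt[r] else -1
        gt[r, 0] += step
        bumped = build_cohort(gt, impacts=cohort.sites["impact"])
        bumped.derived_is_alt = cohort.derived_is_alt  # same polarity, one extra allele
        bumped.polarizable = cohort.polarizable
        after = load.individual_loads(bumped).loc[0, "total_load"]
        assert after >= base

    def test_allele_label_flip_leaves_loads_unchanged(self):
        # ties at pooled frequency exactly 0.5 are label-dependent by the
        # declared tie rule, so the involution property holds off ties
        rng = np.random.default_rng(9)
        cohort = four_class_cohort(rng)
        ac, an = cohort.allele_counts()
        cohort = polarized(cohort.take_sites(np.flatnonzero(2 * ac != an)))
        tab = load.individual_loads(cohort)
        flipped = polarized(build_cohort(2 - cohort.gt, impacts=cohort.sites["impact"]))
        tab2 = load.individual_loads(flipped)
        np.testing.assert_allclose(tab["total_load"], tab2["total_load"], atol=1e-12)

    def test_unpolarized_cohort_rejected(self):
        cohort = build_cohort(np.array([[1, 0]], dtype=np.int8))
        with pytest.raises(CohortError, match="polarize"):
            load.individual_loads(cohort)


class TestGroupSiteLoad:
    def test_weight_times_frequency(self):
        gt = np.array([[1, 1, 2, 0], [2, 2, 2, 1], [1, 1, 0, 0]], dtype=np.int8)
        cohort = polarized(build_cohort(gt, impacts=["HIGH", "MODIFIER", "LOW"]))
        out = load.group_site_load(cohort, np.array([0, 1]))
        # HIGH site derived freq 0.5 in group -> 0.6 * 0.5
        assert out.loc[0, "site_load"] == pytest.approx(0.30)
        assert out.loc[2, "site_load"] == pytest.approx(0.1 * 0.5)

    def test_modifier_sites_always_zero(self):
        gt = np.array([[2, 2, 1, 0]], dtype=np.int8)
        cohort = polarized(build_cohort(gt, impacts=["MODIFIER"]))
        out = load.group_site_load(cohort, np.array([0, 1]))
        assert out.loc[0, "site_load"] == 0.0

    def test_fixed_derived_in_group_equals_weight(self):
        gt = np.array([[2, 2, 0, 0, 0, 1]], dtype=np.int8)
        cohort = polarized(build_cohort(gt, impacts=["MODERATE"]))
        out = load.group_site_load(cohort, np.array([0, 1]))
        assert out.loc[0, "site_load"] == pytest.approx(0.3)


class TestSFS:
    def test_monomorphic_population_empty_spectrum(self):
        gt = np.array([[0, 0, 1, 1], [2, 2, 0, 1]], dtype=np.int8)
        cohort = polarized(
            build_cohort(gt, populations=["a", "a", "b", "b"])
        )
        res = load.sfs_and_site_classes(cohort, "a")
        assert res["sfs"].sum() == 0
        assert res["polymorphic"] == 0

    def test_specific_copy_number_bin(self):
        gt = np.zeros((1, 10), dtype=np.int8)
        gt[0, :3] = [2, 1, 0]  # 3 derived copies among 5 diploids of pop a
        cohort = polarized(
            build_cohort(gt, populations=["a"] * 5 + ["b"] * 5)
        )
        res = load.sfs_and_site_classes(cohort, "a")
        assert res["sfs"][2] == 1  # index 2 <-> 3 copies

    def test_matches_tally_oracle_and_partition(self):
        rng = np.random.default_rng(13)
        cohort = polarized(random_cohort(rng, n_sites=200, n_samples=10, n_pops=1))
        res = load.sfs_and_site_classes(cohort, "pop0")
        rows = np.flatnonzero(cohort.polarizable)
        dos = cohort.derived_dosage()[rows]
        sfs, fref, fder = sfs_tally(dos, 2 * cohort.n_samples)
        np.testing.assert_array_equal(res["sfs"], sfs)
        assert (res["fixed_ref"], res["fixed_derived"]) == (fref, fder)
        assert res["sfs"].sum() == res["polymorphic"]
        assert res["fixed_ref"] + res["fixed_derived"] + res["polymorphic"] == len(rows)
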