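import numpy as np
import pandas as pd
import pytest

from conftest import build_cohort, random_cohort
from oracles import point_in_intervals
from purgekit import diversity, load, purging, roh
from purgekit.model import CohortError
from purgekit.roh import ROHSet


def polarized(cohort):
    return load.polarize(cohort)


class TestRxy:
    def test_identical_frequencies_give_unity(self):
        gt = np.array([[1, 1, 1, 1], [2, 0, 0, 2], [1, 0, 1, 0]], dtype=np.int8)
        cohort = polarized(build_cohort(gt, populations=["x", "x", "y", "y"], impacts=["LOW"] * 3))
        res = purging.rxy(cohort, "x", "y", "LOW")
        assert res["rxy"] == pytest.approx(1.0)

    def test_single_site_hand_value(self):
        # d_x = 0.4 (5 diploids), d_y = 0.1 -> (0.4*0.9)/(0.1*0.6) = 6
        gt = np.array([[2, 1, 1, 0, 0, 1, 0, 0, 0, 0]], dtype=np.int8)
        pops = ["x"] * 5 + ["y"] * 5
        cohort = polarized(build_cohort(gt, populations=pops, impacts=["HIGH"]))
        res = purging.rxy(cohort, "x", "y", "HIGH")
        assert res["rxy"] == pytest.approx(6.0)

    def test_reciprocality_to_machine_precision(self):
        rng = np.random.default_rng(21)
        cohort = polarized(random_cohort(rng, n_sites=150, n_samples=10))
        for cls in ("MODIFIER", "LOW"):
            a = purging.rxy(cohort, "pop0", "pop1", cls)["rxy"]
            b = purging.rxy(cohort, "pop1", "pop0", cls)["rxy"]
            assert a * b == pytest.approx(1.0, rel=1e-12)

    def test_invariant_to_site_duplication(self):
        rng = np.random.default_rng(22)
        cohort = polarized(random_cohort(rng, n_sites=100, n_samples=10))
        doubled = cohort.take_sites(np.repeat(np.arange(cohort.n_sites), 2))
        # duplicated positions still rank as the same frequencies
        a = purging.rxy(cohort, "pop0", "pop1", "MODIFIER")["rxy"]
        b = purging.rxy(doubled, "pop0", "pop1", "MODIFIER")["rxy"]
        assert a == pytest.approx(b, rel=1e-12)

    def test_zero_denominator_raises_with_diagnostic(self):
        gt = np.array([[1, 1, 0, 0]], dtype=np.int8)
        cohort = polarized(build_cohort(gt, populations=["x", "x", "y", "y"], impacts=["HIGH"]))
        with pytest.raises(CohortError, match="denominator"):
            purging.rxy(cohort, "x", "y", "HIGH")

    def test_purged_class_depressed_neutral_class_near_one(self, three_species):
        _, cohort = three_species
        high = purging.rxy(cohort, "narw_like", "srw_like", "HIGH", region="autosome")
        mod = purging.rxy(cohort, "narw_like", "srw_like", "MODIFIER", region="autosome")
        assert high["rxy"] < 1
        assert mod["rxy"] == pytest.approx(1.0, abs=0.05)
        assert np.isfinite(high["se"]) and high["se"] > 0


class TestRelativeLoad:
    def _tables(self, hom, f):
        lt = pd.DataFrame(
            {"sample_id": ["s"], "population": ["p"], "region": ["autosome"], "hom_load": [hom]}
        )
        ft = pd.DataFrame({"sample_id": ["s"], "region": ["autosome"], "f": [f]})
        return lt, ft

    def test_elementwise_ratio(self):
        out = purging.relative_load(*self._tables(0.30, 0.60))
        assert out.loc[0, "relative_load"] == pytest.approx(0.5)

    def test_zero_hom_load_gives_zero(self):
        out = purging.relative_load(*self._tables(0.0, 0.3))
        assert out.loc[0, "relative_load"] == 0.0

    def test_small_f_flagged_invalid_not_thrown(self):
        out = purging.relative_load(*self._tables(0.2, 0.005))
        assert not out.loc[0, "valid"]
        assert np.isnan(out.loc[0, "relative_load"])


class TestROHEnrichment:
    def test_no_roh_means_zero_proportion(self):
        rng = np.random.default_rng(30)
        cohort = polarized(random_cohort(rng, n_sites=60, n_samples=4))
        out = purging.roh_enrichment(cohort, ROHSet(pd.DataFrame()))
        assert (out["proportion_inside"] == 0).all()

    def test_counted_proportion(self):
        # 10 derived homozygotes for s0, 4 covered by its single ROH
        gt = np.zeros((10, 4), dtype=np.int8)
        gt[:, 0] = 2
        gt[:, 1] = 1  # keeps sites polymorphic, derived = alt
        pos = np.arange(1, 11) * 100
        cohort = polarized(build_cohort(gt, positions=pos, impacts=["LOW"] * 10))
        ivs = pd.DataFrame({"sample_id": ["s0"], "contig": ["chr1"], "start": [0], "end": [400]})
        out = purging.roh_enrichment(cohort, ROHSet(ivs))
        row = out[(out["sample_id"] == "s0") & (out["stratum"] == "all") & (out["impact"] == "LOW")]
        assert row.iloc[0]["proportion_inside"] == pytest.approx(0.4)

    def test_matches_membership_oracle_and_strata_sum(self):
        rng = np.random.default_rng(31)
        cohort = polarized(random_cohort(rng, n_sites=200, n_samples=6))
        starts = np.sort(rng.choice(np.arange(0, 200, 10), size=6, replace=False))
        ivs = pd.DataFrame(
            {
                "sample_id": rng.choice(["s0", "s1"], size=6),
                "contig": "chr1",
                "start": starts,
                "end": starts + rng.integers(3, 9, size=6),
            }
        )
        rohs = ROHSet(ivs)
        out = purging.roh_enrichment(cohort, rohs, strata_bp=(5,))
        dos = cohort.derived_dosage()
        rows = np.flatnonzero(cohort.polarizable)
        for sid in ("s0", "s1"):
            j = cohort.sample_index(sid)
            sample_ivs = [
                (r.contig, r.start, r.end) for r in rohs.for_sample(sid).itertuples()
            ]
            for cls in ("MODIFIER", "LOW", "MODERATE", "HIGH"):
                homs = [
                    r
                    for r in rows
                    if dos[r, j] == 2 and cohort.sites.loc[r, "impact"] == cls
                ]
                inside = sum(
                    point_in_intervals("chr1", int(cohort.sites.loc[r, "pos"]), sample_ivs)
                    for r in homs
                )
                got = out[
                    (out["sample_id"] == sid) & (out["impact"] == cls) & (out["stratum"] == "all")
                ]
                if len(got):
                    assert got.iloc[0]["n_hom_inside"] == inside
                    assert got.iloc[0]["n_hom_total"] == len(homs)
        # strata counts sum to the pooled stratum
        pivot = out.pivot_table(
            index=["sample_id", "impact"], columns="stratum", values="n_hom_inside"
        )
        np.testing.assert_array_equal(pivot["le_5e-06mb"] + pivot["gt_5e-06mb"], pivot["all"])

    def test_purging_orders_inside_proportions_by_impact(self, three_species, three_species_rohs):
        _, cohort = three_species
        enr = purging.roh_enrichment(cohort, three_species_rohs, region="autosome")
        narw = enr[
            enr["sample_id"].str.startswith("narw") & (enr["stratum"] == "all")
        ]
        agg = narw.groupby("impact")[["n_hom_inside", "n_hom_total"]].sum()
        prop = agg["n_hom_inside"] / agg["n_hom_total"]
        assert prop["HIGH"] < prop["MODERATE"] < prop["MODIFIER"]

    def test_relative_load_lower_in_purged_population(self, three_species):
        _, cohort = three_species
        lt = load.individual_loads(cohort, region="autosome")
        ft = diversity.inbreeding_f(cohort, region="autosome")
        rel = purging.relative_load(lt, ft)
        means = rel.groupby("population")["relative_load"].mean()
        assert means["narw_like"] < means["srw_like"]
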