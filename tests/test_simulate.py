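import numpy as np
import pytest

from purgekit import diversity, load, roh, simulate
from purgekit.model import CohortError


class TestDeterminism:
    def test_same_seed_byte_identical_vcf(self, tmp_path):
        cfg = simulate.single_population_config(n_females=6, n_sites=500, seed=99)
        a = simulate.simulate_cohort(cfg, tmp_path / "a")
        b = simulate.simulate_cohort(cfg, tmp_path / "b")
        assert a.vcf.read_bytes() == b.vcf.read_bytes()
        assert a.impact_table.read_bytes() == b.impact_table.read_bytes()

    def test_different_seed_differs(self, tmp_path):
        a = simulate.simulate_cohort(
            simulate.single_population_config(n_females=6, n_sites=500, seed=1), tmp_path / "a"
        )
        b = simulate.simulate_cohort(
            simulate.single_population_config(n_females=6, n_sites=500, seed=2), tmp_path / "b"
        )
        assert a.vcf.read_bytes() != b.vcf.read_bytes()


class TestPlantedTruth:
    def test_no_inbreeding_config_recovers_f_near_zero(self, tmp_path):
        cfg = simulate.single_population_config(target_f=0.0, n_sites=4000, seed=5)
        res = simulate.simulate_cohort(cfg, tmp_path)
        cohort = load.polarize(res.load_cohort())
        f = diversity.inbreeding_f(cohort)
        assert abs(f["f"].mean()) < 0.03
        assert len(res.truth.roh) == 0

    def test_planted_genome_fraction_recovered(self, tmp_path):
        cfg = simulate.single_population_config(target_f=0.4, n_sites=10_000, seed=6)
        res = simulate.simulate_cohort(cfg, tmp_path)
        cohort = load.polarize(res.load_cohort())
        rohs = roh.call_roh_all(cohort)
        summ = roh.summarize_roh(rohs, cohort.genome, "autosome", sample_ids=cohort.sample_ids)
        assert summ["froh"].mean() == pytest.approx(0.40, abs=0.05)
        # truth intervals really cover the planted fraction
        genome_bp = sum(cohort.genome.lengths.values())
        per_sample = res.truth.roh.assign(length=lambda d: d["end"] - d["start"]).groupby("sample_id")["length"].sum()
        np.testing.assert_allclose(per_sample / genome_bp, 0.4, atol=0.01)

    def test_generator_output_passes_cohort_validation(self, three_species):
        res, cohort = three_species
        assert (cohort.gt[cohort.called()] >= 0).all()
        # males masked on X, called on autosomes
        males = np.flatnonzero((cohort.samples["sex"] == "male").to_numpy())
        x_rows = cohort.region_rows("X")
        assert (~cohort.called()[np.ix_(x_rows, males)]).all()
        # invariant records present at the configured density
        n_var = int(cohort.sites["is_variant"].sum())
        assert len(cohort.sites) - n_var >= 8 * n_var

    def test_within_roh_hom_fraction_follows_p_delta_law(self, three_species):
        """Inside tracts hom-derived occurs at ~q*delta, outside at ~q^2."""
        res, cohort = three_species
        truth = res.truth
        sites = truth.sites
        mask = (sites["kind"] == "background") & (sites["impact"] == "MODIFIER")
        sub = cohort.sites.reset_index().merge(
            sites.loc[mask, ["contig", "pos"]], on=["contig", "pos"]
        )
        rows = sub["index"].to_numpy()
        q = sites.loc[mask, "freq_narw_like"].to_numpy()
        j = cohort.sample_index("narw_like_f00")
        ivs = truth.roh[truth.roh["sample_id"] == "narw_like_f00"]
        from purgekit.io import merge_intervals, positions_in_intervals

        inside = positions_in_intervals(
            cohort.sites["contig"].to_numpy()[rows],
            cohort.sites["pos"].to_numpy()[rows],
            merge_intervals(ivs),
        )
        hom = cohort.gt[rows, j] == 2
        # delta(MODIFIER) = 1: inside-rate ~ mean(q), outside-rate ~ mean(q^2)
        inside_rate = hom[inside].mean()
        outside_rate = hom[~inside].mean()
        assert inside_rate == pytest.approx(q[inside].mean(), abs=0.03)
        assert outside_rate == pytest.approx((q[~inside] ** 2).mean(), abs=0.01)

    def test_infeasible_roh_mix_rejected(self, tmp_path):
        cfg = simulate.SimConfig(
            seed=0,
            contigs=(simulate.ContigSpec("chr1", 1_000_000),),
            populations=(
                simulate.PopulationSpec(
                    "p",
                    n_females=2,
                    target_f=0.95,
                    roh_length_ranges=((400_000, 600_000),),
                    roh_length_weights=(1.0,),
                ),
            ),
            class_sites={"MODIFIER": 100},
        )
        with pytest.raises(CohortError, match="infeasible|exceed"):
            simulate.simulate_cohort(cfg, tmp_path)
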