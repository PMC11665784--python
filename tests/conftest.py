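import numpy as np
import pandas as pd
import pytest

from purgekit import load as load_mod
from purgekit import roh as roh_mod
from purgekit import simulate as sim
from purgekit.model import AnnotatedCohort, GenomeSpec


def build_cohort(
    gt,
    impacts=None,
    positions=None,
    contigs=None,
    populations=None,
    sexes=None,
    rs_groups=None,
    is_variant=None,
    genome=None,
    x_contigs=(),
):
    """Hand-build a small AnnotatedCohort from a genotype matrix (sites x samples)."""
    gt = np.asarray(gt, dtype=np.int8)
    n_sites, n_samples = gt.shape
    impacts = list(impacts) if impacts is not None else ["MODIFIER"] * n_sites
    positions = list(positions) if positions is not None else list(range(1, n_sites + 1))
    contigs = list(contigs) if contigs is not None else ["chr1"] * n_sites
    if genome is None:
        lengths = {}
        for c, p in zip(contigs, positions):
            lengths[c] = max(lengths.get(c, 0), p + 1_000_000)
        genome = GenomeSpec(lengths=lengths, x_contigs=frozenset(x_contigs))
    samples = pd.DataFrame(
        {
            "sample_id": [f"s{i}" for i in range(n_samples)],
            "population": populations if populations is not None else ["pop"] * n_samples,
            "sex": sexes if sexes is not None else ["female"] * n_samples,
            "rs_group": rs_groups if rs_groups is not None else ["none"] * n_samples,
        }
    )
    sites = pd.DataFrame(
        {
            "contig": contigs,
            "pos": positions,
            "ref": "A",
            "alt": "C",
            "impact": impacts,
            "region": [genome.region(c) for c in contigs],
            "is_variant": is_variant if is_variant is not None else [True] * n_sites,
        }
    )
    return AnnotatedCohort(sites=sites, gt=gt, samples=samples, genome=genome)


def random_cohort(rng, n_sites=200, n_samples=8, n_pops=2):
    """Random polymorphic-ish cohort across all four impact classes."""
    classes = rng.choice(["MODIFIER", "LOW", "MODERATE", "HIGH"], size=n_sites)
    q = rng.uniform(0.05, 0.45, size=n_sites)
    gt = rng.binomial(2, q[:, None], size=(n_sites, n_samples)).astype(np.int8)
    pops = [f"pop{j % n_pops}" for j in range(n_samples)]
    return build_cohort(gt, impacts=classes, populations=pops)


# --- shared simulated scenarios (session scope: they feed many tests) -----

SEED = 20


@pytest.fixture(scope="session")
def three_species(tmp_path_factory):
    cfg = sim.scenario_presets(seed=SEED)["three_species"]
    res = sim.simulate_cohort(cfg, tmp_path_factory.mktemp("three_species"))
    cohort = load_mod.polarize(res.load_cohort())
    return res, cohort


@pytest.fixture(scope="session")
def three_species_rohs(three_species):
    _, cohort = three_species
    return roh_mod.call_roh_all(cohort)


@pytest.fixture(scope="session")
def rs_contrast(tmp_path_factory):
    cfg = sim.scenario_presets(seed=SEED)["rs_contrast"]
    res = sim.simulate_cohort(cfg, tmp_path_factory.mktemp("rs_contrast"))
    cohort = load_mod.polarize(res.load_cohort())
    return res, cohort


@pytest.fixture(scope="session")
def roh_recovery(tmp_path_factory):
    cfg = sim.scenario_presets(seed=SEED)["roh_recovery"]
    res = sim.simulate_cohort(cfg, tmp_path_factory.mktemp("roh_recovery"))
    cohort = load_mod.polarize(res.load_cohort())
    return res, cohort
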