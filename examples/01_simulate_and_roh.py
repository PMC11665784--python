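"""Simulate a three-population cohort and summarize runs of homozygosity.

One population is small and historically inbred (long autozygous tracts
planted to cover ~35% of its genome); the other two are larger and outbred.
The ROH caller is a two-state Viterbi HMM over hard genotype calls.
"""

import tempfile

from purgekit import (
    call_roh_all,
    polarize,
    population_roh_means,
    scenario_presets,
    simulate_cohort,
    summarize_roh,
)

with tempfile.TemporaryDirectory() as tmp:
    config = scenario_presets(seed=1)["three_species"]
    sim = simulate_cohort(config, tmp)
    cohort = polarize(sim.load_cohort())

print(f"cohort: {cohort.n_sites} sites ({len(cohort.variant_rows())} variants), "
      f"{cohort.n_samples} samples, contigs {list(cohort.genome.lengths)}")

rohs = call_roh_all(cohort)
summary = summarize_roh(rohs, cohort.genome, "autosome", sample_ids=cohort.sample_ids)
means = population_roh_means(summary, cohort.samples)
cols = ["population", "n_lt_1mb", "n_1_to_2.5mb", "n_gt_2.5mb", "nroh", "mean_lroh", "froh"]
print(means[cols].round(2).to_string(index=False))
print(
    "\nThe three length bins always sum to NROH; FROH = summed ROH length /"
    "\nautosome length. The inbred population carries far more of its genome"
    "\nin ROH (planted truth: 0.35 vs 0.05 and 0.18)."
)
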