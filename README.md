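# purgekit

Mutation load, runs of homozygosity, and genetic-purging statistics for
small-cohort conservation genomics.

When a population has collapsed to a few hundred individuals, two forces
race each other: inbreeding exposes recessive deleterious alleles in
homozygous genotypes (inbreeding depression), while that same exposure lets
purifying selection remove them (genetic purging). `purgekit` implements
the statistical toolkit used to tell these apart from a handful of
resequenced genomes per population — the typical situation for endangered
whales, wolves, or island birds — starting from a jointly genotyped,
impact-annotated VCF and a sample sheet.

## What it computes

Given genotypes annotated with SnpEff-style impact classes
(MODIFIER/LOW/MODERATE/HIGH) and weights *w* = (0, 0.1, 0.3, 0.6):

- **Impact-weighted mutation load** per individual:
  total = Σ_c w_c · (Σ_{s∈c} x_s)/n_c with x = 1 for a derived homozygote,
  ½ for a heterozygote — normalized so that an individual
  homozygous-derived at every segregating site scores exactly 1, and split
  into realized (homozygous) and masked (heterozygous) parts. Derived
  alleles are the cohort-wide minor alleles.
- **Diversity and inbreeding**: π in 100 kb windows with invariant sites in
  the denominator; F = (Hom_obs − Hom_exp)/(N − Hom_exp) per individual.
- **ROH**: a two-state Viterbi HMM (emissions ε vs 2p(1−p), distance-decay
  transitions, no genetic map) with NROH/SROH/FROH summaries and length
  bins <1 Mb / 1–2.5 Mb / >2.5 Mb (plus >5 Mb).
- **Purging signatures**: Rxy = Σ d_x(1−d_y)/Σ d_y(1−d_x) per impact class
  with delete-one-contig jackknife SEs; relative mutation load
  (hom load / F); and the proportion of deleterious homozygotes inside vs
  outside ROH (p vs p² expectation), stratified at 2.5 Mb.
- **Candidate-variant scan** for a 5-vs-5 reproductive-success contrast:
  PCA-Mahalanobis outlier scores with genomic-inflation correction,
  per-site Weir–Cockerham FST, per-site Δ total load, and their top-decile
  intersection.
- **Bayesian effect models**: z-standardized responses, normal(0,1) priors,
  a self-contained Gibbs/Metropolis sampler, split-chain R-hat.
- **Synthetic cohorts** with planted truth (inbreeding tracts, purging
  factors, candidate sites) for end-to-end validation — see
  `docs/methods.md` for the model and its limits.

## Worked example

```sh
python examples/03_purging_signatures.py
```

simulates a three-population cohort — one small and inbred with planted
purging (ρ_HIGH = 0.6 on allele frequencies, δ_HIGH = 0.3 inside ROH), two
large and outbred — and prints:

```
Rxy (inbred vs outbred, autosomes):
  MODIFIER  1.007 +- 0.014  (4557 sites)
  LOW       0.979 +- 0.035  (2251 sites)
  MODERATE  0.627 +- 0.017  (1491 sites)
  HIGH      0.391 +- 0.019  (763 sites)

Relative mutation load (hom load / F):
bh_like      0.214
narw_like    0.060
srw_like     0.593

Proportion of derived homozygotes inside ROH (inbred population):
HIGH        0.573
LOW         0.710
MODERATE    0.679
MODIFIER    0.703
```

Read: neutral (MODIFIER) alleles segregate at equal burdens in both
populations (Rxy ≈ 1), but the inbred population carries barely 40% of the
outbred population's HIGH-impact burden (Rxy = 0.39); its homozygous load
is far below what its inbreeding coefficient predicts (0.06 vs 0.59); and
HIGH-impact homozygotes are depleted inside its ROH relative to neutral
ones (0.57 vs 0.70) — the three concordant signatures of purging through
inbreeding, here recovered from planted truth. The other examples cover
ROH summaries, load decomposition, the candidate scan (recovering planted
reproduction-linked variants), and the effect models.

The same workflow runs from a shell:

```sh
purgekit demo --seed 1 --outdir out/          # simulate + full pipeline
purgekit simulate --preset rs_contrast --seed 1 --outdir sim/
purgekit run-all config.yaml --region both
```

producing TSV/BED/JSON outputs and a manifest (config hash, versions, row
counts).

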