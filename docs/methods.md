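# Methods

`purgekit` implements the statistical toolkit used to characterize mutation
load and genetic purging in very small cohorts of endangered species — the
setting where a handful of resequenced genomes per population must carry the
whole inference. This note records the models, the defaults and why they are
what they are, what the synthetic generator does and does not emulate, and
the numerical choices a maintainer would otherwise have to reverse-engineer.

## Cohort model and site filtering

The in-memory substrate is a sites × individuals matrix of hard diploid
genotype calls joined to one SnpEff-style impact class per site
(MODIFIER < LOW < MODERATE < HIGH in severity). Contracts enforced at
construction:

- **No missing calls.** Any site with a missing genotype among the relevant
  columns is dropped at read time. On X-linked contigs, male columns are
  excluded *before* the missingness check and masked in the matrix — males
  are hemizygous there and their diploid calls carry no usable information.
- **Biallelic, normalized sites.** Multiallelic records are rejected by
  default (input is expected pre-normalized); an optional split mode
  decomposes them into per-alt biallelic records.
- **Invariant sites retained** and flagged, so diversity windows have honest
  denominators.
- **Impact per site.** SnpEff emits one annotation per transcript; when the
  impact comes from an ANN INFO field the most severe class wins (a declared
  collapsing rule — upstream pipelines rarely document theirs). A sidecar
  site table is the alternative source.

Depth/quality filtering is an upstream concern: the reader honors
already-filtered input and does not reimplement caller-level filters.
Coordinates are VCF 1-based inclusive on input, and all interval arithmetic
(BED, ROH, masks) is 0-based half-open.

## Diversity and inbreeding

**Windowed π** uses the invariant-sites-aware estimator: within each 100 kb
window (anchored at 0 per contig), π = Σ k(n−k) / Σ C(n,2) over sites with
n ≥ 2 called allele copies, k of them alternate. Windows without valid sites
report NaN, never 0 — "no data" and "no variation" are different findings.

**F** is the excess-homozygosity inbreeding coefficient
(Hom_obs − Hom_exp)/(N − Hom_exp) per individual, against its own
population's allele frequencies. Two conventions are ambiguous in common
usage and are therefore explicit options here (defaults first): expected
heterozygosity uses the 2n/(2n−1) small-sample factor (on), and N counts
only sites polymorphic within the population (on) — monomorphic sites would
inflate both Hom_obs and Hom_exp without adding information.

## ROH calling

A two-state (autozygous / non-autozygous) hidden Markov model decoded by
Viterbi per contig, over hard genotype calls at sites polymorphic in the
frequency source (the individual's population by default):

- emissions: P(het | autozygous) = ε (default 1e-3, the genotype-error
  allowance), P(het | non-autozygous) = 2p(1−p) from the empirical
  frequency p;
- transitions between consecutive sites at distance d bp: 1 − exp(−r·d)
  with r = 1e-8 per bp, no genetic map;
- decoded autozygous runs become half-open intervals from the first to the
  last site of the run; runs shorter than `min_bp` (default 100 kb) are
  dropped.

This parameterization reproduces the procedure class of likelihood-based
ROH callers while being fully specified; using hard calls rather than
genotype likelihoods is a documented simplification (input VCFs often lack
PLs). With sites every ~1 kb, planted 1–5 Mb tracts are recovered with
boundary errors well under 50 kb; detectability falls off below roughly 40
consecutive homozygous sites, so at sparse site densities tracts under a
few hundred kb are under-called — the same resolution limit real pipelines
face, and the reason summary FROH on short-tract genomes is conservative.

Summaries follow the standard reporting convention: counts in three
mutually exclusive length bins (<1 Mb, 1–2.5 Mb, >2.5 Mb; they sum to NROH
by construction) plus the >5 Mb sub-count flagging recent inbreeding, mean
length, SROH, and FROH = SROH / region length, with the region length taken
from the declared genome spec, never from the data extent.

## Polarization and mutation load

Without an outgroup alignment, the derived allele is operationalized as the
cohort-wide **minor** allele: all populations are pooled, the allele with
pooled frequency < 0.5 is derived, and at exactly 0.5 the alternate allele
is designated derived (a deterministic tie rule; note it is label-dependent,
so the ref/alt-flip invariance of the loads holds at all non-tied sites).
Sites invariant in the pooled cohort are non-polarizable and excluded.

Impact weights default to 0 / 0.1 / 0.3 / 0.6, echoing published selection
coefficient distributions, and sum to 1. Loads are normalized **within
class**: for class c with n_c segregating sites, an individual's class
dosage is D_c = Σ x / n_c with x = 1 for a derived homozygote, h = 0.5 for
a heterozygote (additive dominance; h is exposed for sensitivity analyses),
0 otherwise, and total load = Σ_c w_c·D_c. Per-class normalization is the
only convention under which "homozygous-derived everywhere" scores exactly
Σ w_c = 1 regardless of the site composition — that anchor makes loads
comparable across cohorts; a flat per-site normalization is available as an
option. The homozygous (realized) and heterozygous (masked) loads are the
corresponding partial sums, so total = hom + het exactly. The denominator
site set is the pooled cohort's segregating sites, identical for every
individual.

Group-level per-site load is w(impact) × derived frequency in the group;
the unfolded SFS and fixed/polymorphic classification are computed per
population from derived-allele copy counts.

## Purging signatures

- **Rxy** per impact class: Σ d_x(1−d_y) / Σ d_y(1−d_x) over class sites;
  < 1 is a deficit of derived alleles in x. Its standard error is a
  delete-one-contig jackknife — blocks respect linkage; with i.i.d.
  simulated sites this SE is optimistic relative to real genomes.
- **Relative mutation load** = homozygous load / F. Individuals with
  F ≤ 0.01 (configurable) are flagged invalid rather than divided by
  near-zero.
- **ROH enrichment**: derived-homozygote positions are intersected with the
  individual's ROH, stratified by tract length at 2.5 Mb (configurable).
  Autozygosity raises homozygote frequency from ~p² outside to ~p inside a
  tract, so purging *within* ROH appears as a depressed inside proportion
  for damaging classes relative to MODIFIER, the neutral comparator.
  Because the inside/outside contrast scales as p vs p², rarer alleles are
  *more* ROH-concentrated at equal δ; class comparisons are therefore only
  clean when class frequency spectra are comparable, which the generator
  guarantees by design (below).

## Candidate-variant scan

The contrast is two small groups (five high-reproductive-success vs five
nulliparous females). Three per-site statistics:

1. **PCA outlier score**: genotypes of the contrast samples are centered
   and scaled by √(2p(1−p)); K principal components (default K = 1 — a 5v5
   contrast has one dominant axis) are extracted across samples; each site
   is regressed on them. The per-component t statistics are mapped through
   the exact t CDF to normal scores before the Mahalanobis/χ² step: with
   n = 10 the raw t has 8 degrees of freedom and heavy tails that would
   bias the genome-wide median upward by construction. The Mahalanobis
   distance is divided by the genomic inflation factor
   λ = median(D)/median(χ²_K) and −log10 p-values from χ²_K are reported.
   λ is exactly calibrated (→1) on χ²-distributed distances; on real
   10-sample genotype data it deviates from 1 because the leading PC aligns
   with discrete rare-variant patterns — that deviation is precisely what
   dividing by λ corrects, and the reported score is rank-preserving either
   way.
2. **Per-site FST**: the Weir–Cockerham (1984) two-population estimator;
   negative estimates are retained, sites monomorphic across both groups
   are undefined and excluded from ranking.
3. **Δ total load**: group site load of the low-RS minus the high-RS group;
   positive = heavier weighted derived burden in nulliparous females.

Candidates are sites strictly above the nearest-rank 90th-percentile
threshold of **all three** statistics (rank-based, hence invariant to
monotone transforms; a site must have all three defined). Venn cell counts
are emitted. With three *independent* rankings the expected candidate
fraction is 0.1³; the three pipeline statistics share the same group
genotype frequencies, so their joint null rate exceeds that independence
baseline — the intersection is a screening heuristic, not a calibrated
test, and downstream interpretation should treat it as such. A carriage
report tallies derived-allele presence of candidates in named outside
populations.

## Effect models

Cohort-level responses (π, F, loads) are z-standardized and modeled as
y = Xβ + ε with treatment-coded categorical predictors, β ~ N(0,1) priors,
ε ~ N(0,σ), and σ ~ half-normal(0,1) — the response is standardized, so a
unit-scale prior is weakly informative by construction. Sampling is
blocked: β | σ is conjugate and Gibbs-sampled exactly; log σ moves by
random-walk Metropolis (proposal SD 0.15, acceptance ~50% at typical sizes).
Defaults are 3 chains × 10,000 iterations with 1,000 warmup; each chain's
RNG stream derives from (seed, chain index). Convergence is monitored by
split-chain R-hat (threshold 1.01) on every parameter; a rank-normalizing
R-hat (as in arviz) agrees closely on these well-behaved posteriors and is
used as a cross-check in the test suite. Rank-deficient designs raise an
error naming the aliased columns.

## Synthetic cohorts and what passing tests show

The generator plants known truth for every statistic: per-class site counts
with base derived frequencies drawn from one Beta(1,4)/2 law for all
classes (so class contrasts are attributable to the planted factors, not
the base spectrum); per-population purging factors ρ_c multiplying derived
frequencies; autozygous tracts per individual covering exactly the target
genome fraction, inside which the individual is homozygous with
derived-homozygote probability q·δ_c (δ_c < 1 plants within-ROH purging)
and a 1e-3 heterozygote error; invariant sites interleaved at 9:1 by
default; X contigs with males simulated and masked on read; and an optional
5v5 contrast with ~10 extreme candidate sites plus a 500-site
MODIFIER-class group-shift background. That background is a deliberate
design element: ten outlier sites alone cannot dominate the leading PC of
10 samples against 10⁴ noise sites (their spiked-covariance signal is an
order of magnitude below the noise eigenvalue spread), so the scenario
encodes the premise that the two groups differ genome-wide, while the zero
MODIFIER weight keeps the shift sites out of the Δ-load ranking.

Scenario presets: `three_species` (one inbred, purged population —
target F 0.35, ρ = 0.8/0.6 and δ = 0.9/0.6/0.3 for LOW-to-HIGH-adjacent
classes — beside two outbred ones), `rs_contrast`, `null` (no structure,
for calibration), and `roh_recovery` (a 50 Mb chromosome, ten explicit
1.2–5 Mb tracts, sites at ~1/kb). Problem sizes (10⁴–10⁵ sites, 10–34
samples) are chosen so every recovery experiment runs in seconds while
keeping binomial noise comfortably inside the tested tolerances.

Deliberately not emulated: linkage (sites are i.i.d., so jackknife SEs are
optimistic and LD-aware methods cannot be exercised), mutation-rate
heterogeneity, genotype likelihoods/uncertainty, and real SnpEff annotation
structure. Passing recovery tests therefore demonstrates correctness of the
estimators under the model's own assumptions — not robustness to the
violations real data bring.

## Numerical conventions and edge cases

- Polarization ties (pooled frequency exactly 0.5) go to the alternate
  allele, decided on integer counts, so results are reproducible bit-wise.
- Nearest-rank percentile: the ⌈P/100·N⌉-th smallest defined value; "top"
  means strictly above it.
- Undefined statistics propagate as NaN and are excluded from ranking and
  averaging, never silently zeroed (π in empty windows, FST at monomorphic
  sites, mean ROH length with zero tracts, relative load at F ≤ F_min).
- Viterbi runs in log space; ROH emission probabilities are clamped away
  from 0/1 (1e-12) to keep degenerate frequencies finite.
- All simulation and sampling is driven by numpy Generators seeded
  explicitly; identical configs and seeds reproduce outputs byte-for-byte.

## Known limitations

- The load normalization anchors the *scale*, not the biology: weights are
  heuristic stand-ins for selection coefficient distributions.
- Minor-allele polarization misorients sites where the derived allele has
  drifted above 0.5, attenuating Rxy contrasts slightly; with an outgroup
  the polarization step is the single place to substitute.
- ROH calling on hard calls cannot separate genotyping error from true
  heterozygosity inside tracts; ε absorbs both.
- The candidate intersection inherits the multiple-testing character of its
  inputs; it nominates variants for follow-up rather than testing them.
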