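"""Mutation-load scoring from impact-annotated genotypes.

Alleles are polarized by the pooled-cohort minor-allele rule: the rarer allele
across all populations together is taken as derived. Loads weight each impact
class (MODIFIER/LOW/MODERATE/HIGH) by a selection-coefficient-motivated weight
(defaults 0, 0.1, 0.3, 0.6) and normalize within class, so an individual
homozygous for the derived allele at every segregating site scores a total
load of exactly the weight sum — 1.0 at the defaults. Heterozygotes accrue
half the impact of homozygotes (dominance 0.5, configurable).
"""

from __future__ import annotations

from dataclasses import dataclass, replace as _dc_replace

import numpy as np
import pandas as pd

from .model import IMPACT_CLASSES, AnnotatedCohort, CohortError


@dataclass(frozen=True)
class ImpactWeights:
    modifier: float = 0.0
    low: float = 0.1
    moderate: float = 0.3
    high: float = 0.6

    def __post_init__(self) -> None:
        for cls in IMPACT_CLASSES:
            w = self[cls]
            if not 0.0 <= w <= 1.0:
                raise CohortError(f"weight for {cls} must be in [0,1], got {w}")

    def __getitem__(self, impact: str) -> float:
        return getattr(self, impact.lower())

    def as_array(self) -> np.ndarray:
        return np.array([self[c] for c in IMPACT_CLASSES])

    @property
    def total(self) -> float:
        return float(self.as_array().sum())


def polarize(cohort: AnnotatedCohort) -> AnnotatedCohort:
    """Designate the derived allele at each site by the pooled minor-allele rule.

    All populations are pooled for the frequency computation. The allele with
    pooled frequency < 0.5 is derived; at exactly 0.5 the alt allele is
    designated derived (deterministic tie rule). Sites where the minor allele
    is absent (invariant in the pooled cohort) are marked non-polarizable and
    take no part in load, SFS or Rxy computations.
    """
    ac, an = cohort.allele_counts()
    variant = cohort.sites["is_variant"].to_numpy()
    polarizable = variant & (ac > 0) & (ac < an)
    # alt derived iff pooled alt frequency <= 0.5, decided on integer counts
    derived_is_alt = 2 * ac <= an
    return _dc_replace(cohort, derived_is_alt=derived_is_alt, polarizable=polarizable)


def _class_rows(cohort: AnnotatedCohort, region: str | None) -> dict[str, np.ndarray]:
    rows = cohort.region_rows(region)
    ok = cohort.polarizable[rows]
    rows = rows[ok]
    impacts = cohort.sites["impact"].to_numpy()[rows]
    return {c: rows[impacts == c] for c in IMPACT_CLASSES}


def individual_loads(
    cohort: AnnotatedCohort,
    weights: ImpactWeights = ImpactWeights(),
    region: str | None = None,
    dominance_h: float = 0.5,
    normalize: str = "class",
) -> pd.DataFrame:
    """Per-individual total, homozygous and heterozygous mutation load.

    For impact class c with n_c segregating (polarizable) sites, the class
    dosage of individual i is D_c(i) = Σ_s x_s(i) / n_c with x = 1 for a
    derived homozygote, ``dominance_h`` for a heterozygote, 0 otherwise, and
    total_load(i) = Σ_c w_c · D_c(i). The homozygous load keeps only the
    x = 1 terms and the heterozygous load only the heterozygote terms, so
    total = hom + het exactly. ``normalize='none'`` divides every class by
    the total segregating site count instead (flat per-site weighting).

    Also reports the individual's mean derived-allele frequency over
    segregating sites and per-class site counts. Masked calls (males on X)
    are excluded site-wise; a sample with no called sites reports NaN loads.
    """
    cohort.require_polarized()
    if normalize not in ("class", "none"):
        raise CohortError(f"normalize must be class|none, got {normalize!r}")
    by_class = _class_rows(cohort, region)
    n_total_sites = sum(len(r) for r in by_class.values())
    dos = cohort.derived_dosage()

    n = cohort.n_samples
    hom = np.zeros(n)
    het = np.zeros(n)
    dose_sum = np.zeros(n)
    called_sum = np.zeros(n, dtype=np.int64)
    class_counts = {}
    for cls in IMPACT_CLASSES:
        rows = by_class[cls]
        class_counts[cls] = len(rows)
        if len(rows) == 0:
            continue
        d = dos[rows]
        called = d >= 0
        is_hom = (d == 2) & called
        is_het = (d == 1) & called
        denom = len(rows) if normalize == "class" else n_total_sites
        w = weights[cls]
        hom += w * is_hom.sum(axis=0) / denom
        het += w * dominance_h * is_het.sum(axis=0) / denom
        dose_sum += np.where(called, d, 0).sum(axis=0) / 2.0
        called_sum += called.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        mean_freq = np.where(called_sum > 0, dose_sum / called_sum, np.nan)

    out = pd.DataFrame(
        {
            "sample_id": cohort.sample_ids,
            "population": cohort.samples["population"],
            "region": region if region is not None else "all",
            "total_load": hom + het,
            "hom_load": hom,
            "het_load": het,
            "mean_derived_freq": mean_freq,
        }
    )
    for cls in IMPACT_CLASSES:
        out[f"n_{cls.lower()}"] = class_counts[cls]
    no_calls = called_sum == 0
    out.loc[no_calls, ["total_load", "hom_load", "het_load"]] = np.nan
    return out


def group_site_load(
    cohort: AnnotatedCohort,
    columns: np.ndarray,
    weights: ImpactWeights = ImpactWeights(),
    region: str | None = None,
) -> pd.DataFrame:
    """Group-level per-site total load: w(impact) × derived frequency in the group.

    ``columns`` indexes the genotype columns forming the group (e.g. from
    ``cohort.rs_group_columns``). Returns one row per polarizable site in the
    region with the site key, derived frequency and load.
    """
    cohort.require_polarized()
    if len(columns) == 0:
        raise CohortError("empty group")
    rows = cohort.region_rows(region)
    rows = rows[cohort.polarizable[rows]]
    dos = cohort.derived_dosage()[np.ix_(rows, np.asarray(columns))]
    called = dos >= 0
    with np.errstate(invalid="ignore", divide="ignore"):
        q = np.where(called, dos, 0).sum(axis=1) / (2 * called.sum(axis=1))
    w = np.array([weights[i] for i in cohort.sites["impact"].to_numpy()[rows]])
    return pd.DataFrame(
        {
            "contig": cohort.sites["contig"].to_numpy()[rows],
            "pos": cohort.sites["pos"].to_numpy()[rows],
            "impact": cohort.sites["impact"].to_numpy()[rows],
            "derived_freq": q,
            "site_load": w * q,
        }
    )


def sfs_and_site_classes(
    cohort: AnnotatedCohort,
    population: str,
    region: str | None = None,
) -> dict:
    """Unfolded SFS and fixed/polymorphic site classification for a population.

    Counts derived-allele copies within the population at every polarizable
    site of the region. Returns ``{'sfs': counts indexed 1..2n-1,
    'fixed_ref': ..., 'fixed_derived': ..., 'polymorphic': ...}`` where
    fixed_ref means fixed for the ancestral (non-derived) allele. On X the
    copy number reflects called (female) chromosomes only; sites whose called
    copy number differs from the autosomal 2n are tallied by their observed
    derived count.
    """
    cohort.require_polarized()
    cols = cohort.population_columns(population)
    rows = cohort.region_rows(region)
    rows = rows[cohort.polarizable[rows]]
    dos = cohort.derived_dosage()[np.ix_(rows, cols)]
    called = dos >= 0
    k = np.where(called, dos, 0).sum(axis=1)
    n_alleles = 2 * called.sum(axis=1)
    k, n_alleles = k[n_alleles > 0], n_alleles[n_alleles > 0]
    max_n = 2 * len(cols)
    fixed_ref = int((k == 0).sum())
    fixed_derived = int((k == n_alleles).sum())
    poly = (k > 0) & (k < n_alleles)
    sfs = np.bincount(k[poly], minlength=max_n)[1:max_n]
    return {
        "population": population,
        "region": region if region is not None else "all",
        "sfs": sfs,
        "fixed_ref": fixed_ref,
        "fixed_derived": fixed_derived,
        "polymorphic": int(poly.sum()),
    }
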