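"""Windowed nucleotide diversity and per-individual inbreeding coefficients.

π follows the invariant-sites-aware convention: every called site, variant or
not, contributes its pairwise-comparison count to the window denominator, so
windows with poor data are distinguishable (π undefined) from truly
monomorphic windows (π = 0).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .model import AnnotatedCohort, CohortError


def pi_windows(
    cohort: AnnotatedCohort,
    window_bp: int = 100_000,
    region: str | None = None,
) -> pd.DataFrame:
    """Nucleotide diversity in non-overlapping windows anchored at 0 per contig.

    For window w, π = Σ_s k_s (n_s − k_s) / Σ_s C(n_s, 2), summing over sites
    with n_s ≥ 2 called allele copies (k_s = alt copies). Windows containing
    no valid site get π = NaN, not zero. Returns a frame with one row per
    window that contains at least one site.
    """
    if window_bp <= 0:
        raise CohortError(f"window_bp must be positive, got {window_bp}")
    rows = cohort.region_rows(region)
    sites = cohort.sites.iloc[rows]
    ac, an = cohort.allele_counts()
    ac, an = ac[rows], an[rows]
    valid = an >= 2
    diffs = np.where(valid, ac * (an - ac), 0).astype(np.float64)
    comps = np.where(valid, an * (an - 1) // 2, 0).astype(np.float64)

    frame = pd.DataFrame(
        {
            "contig": sites["contig"].to_numpy(),
            "window_start": (sites["pos"].to_numpy() - 1) // window_bp * window_bp,
            "diffs": diffs,
            "comps": comps,
            "valid": valid.astype(np.int64),
        }
    )
    grouped = frame.groupby(["contig", "window_start"], sort=False).sum().reset_index()
    with np.errstate(invalid="ignore", divide="ignore"):
        pi = grouped["diffs"] / grouped["comps"]
    out = pd.DataFrame(
        {
            "contig": grouped["contig"],
            "window_start": grouped["window_start"].astype(np.int64),
            "window_end": (grouped["window_start"] + window_bp).astype(np.int64),
            "n_valid_sites": grouped["valid"].astype(np.int64),
            "pi": np.where(grouped["valid"] > 0, pi, np.nan),
        }
    )
    order = np.lexsort((out["window_start"], out["contig"].map({c: i for i, c in enumerate(cohort.genome.lengths)})))
    return out.iloc[order].reset_index(drop=True)


def inbreeding_f(
    cohort: AnnotatedCohort,
    region: str | None = None,
    small_sample_correction: bool = True,
    polymorphic_only: bool = True,
) -> pd.DataFrame:
    """Excess-homozygosity inbreeding coefficient F per individual.

    F = (Hom_obs − Hom_exp) / (N − Hom_exp), computed per individual against
    the allele frequencies of its own population. Expected homozygosity sums
    1 − 2 p q (with the 2n/(2n−1) small-sample factor on the heterozygosity
    by default, as vcftools --het does). Sites monomorphic within the
    population carry no information and are excluded from N by default.

    On X contigs males are masked and receive no X-region estimate.
    """
    results = []
    for population, grp in cohort.samples.groupby("population", sort=False):
        cols = cohort.population_columns(str(population))
        if len(cols) < 2:
            raise CohortError(
                f"population {population!r} has {len(cols)} individual(s); "
                "allele frequencies require at least 2"
            )
        rows = cohort.region_rows(region)
        variant = cohort.sites["is_variant"].to_numpy()[rows]
        ac, an = cohort.allele_counts(cols)
        ac, an = ac[rows], an[rows]
        if polymorphic_only:
            keep = variant & (ac > 0) & (ac < an)
        else:
            keep = variant & (an > 0)
        rws = rows[keep]
        p = ac[keep] / an[keep]
        het_exp = 2 * p * (1 - p)
        if small_sample_correction:
            het_exp = het_exp * an[keep] / (an[keep] - 1)
        gt = cohort.gt[np.ix_(rws, cols)]
        called = gt >= 0
        hom = (gt == 0) | (gt == 2)
        n_i = called.sum(axis=0)
        hom_obs = (hom & called).sum(axis=0)
        hom_exp = ((1 - het_exp)[:, None] * called).sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            f = (hom_obs - hom_exp) / (n_i - hom_exp)
        for j, c in enumerate(cols):
            if n_i[j] == 0:
                continue  # e.g. male on X
            results.append(
                {
                    "sample_id": cohort.samples.loc[c, "sample_id"],
                    "population": population,
                    "region": region if region is not None else "all",
                    "n_sites": int(n_i[j]),
                    "hom_obs": int(hom_obs[j]),
                    "hom_exp": float(hom_exp[j]),
                    "f": float(f[j]),
                }
            )
    return pd.DataFrame(results, columns=["sample_id", "population", "region", "n_sites", "hom_obs", "hom_exp", "f"])
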