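"""Candidate-variant scan: PCA outlier score, per-site FST, Δ total load.

The contrast is two small groups of females differing in reproductive
success. Each statistic ranks every site; candidates are the sites in the top
decile of all three rankings (nearest-rank percentile, rank-based and hence
invariant to monotone transformations of the statistics).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats as sps

from .model import AnnotatedCohort, CohortError


def genomic_inflation(distances: np.ndarray, k: int) -> float:
    """Genomic inflation factor: median distance over the χ²_k median.

    Equals 1 (up to sampling noise) when the distances are χ²_k distributed;
    values above 1 flag genome-wide inflation to be divided out before
    p-values are taken.
    """
    return float(np.median(distances) / sps.chi2.ppf(0.5, k))


def pca_outlier_scores(
    cohort: AnnotatedCohort,
    columns: np.ndarray,
    k: int = 1,
    region: str | None = None,
) -> tuple[pd.DataFrame, float]:
    """Per-site association with the leading genetic axes of the contrast.

    Genotypes of the ``columns`` subset are centered and scaled by the
    binomial standard deviation sqrt(2p(1−p)); the first ``k`` principal
    components across samples are extracted and each site is regressed on
    them. The per-component t statistics are mapped through the exact t CDF
    to normal scores (small contrasts make the raw t heavy-tailed, which
    would inflate the genome-wide median by construction), the Mahalanobis
    distance of the score vector is divided by the genomic inflation factor
    λ = median(D) / median(χ²_k), and −log10 p-values from χ²_k are
    reported.

    Returns (frame with contig/pos/distance/score for each site polymorphic
    within the subset, λ).
    """
    cohort.require_polarized()
    columns = np.asarray(columns)
    n = len(columns)
    if k >= n:
        raise CohortError(f"k={k} must be smaller than the {n}-sample contrast")
    df_resid = n - k - 1
    if df_resid < 1:
        raise CohortError(f"not enough samples ({n}) for k={k} components")
    rows = cohort.region_rows(region)
    rows = rows[cohort.polarizable[rows]]
    dos = cohort.derived_dosage()[np.ix_(rows, columns)].astype(float)
    if (dos < 0).any():
        raise CohortError("masked genotypes in the contrast subset")
    p_hat = dos.mean(axis=1) / 2
    poly = (p_hat > 0) & (p_hat < 1)
    rows, dos, p_hat = rows[poly], dos[poly], p_hat[poly]
    x = (dos - 2 * p_hat[:, None]) / np.sqrt(2 * p_hat * (1 - p_hat))[:, None]

    # principal components in sample space
    _, _, vt = np.linalg.svd(x, full_matrices=False)
    v = vt[:k].T  # (n, k), orthonormal
    beta = x @ v  # (sites, k)
    rss = (x**2).sum(axis=1) - (beta**2).sum(axis=1)
    sigma = np.sqrt(np.maximum(rss, 0) / df_resid)
    with np.errstate(invalid="ignore", divide="ignore"):
        t = beta / sigma[:, None]
    z = sps.norm.ppf(np.clip(sps.t.cdf(t, df_resid), 1e-15, 1 - 1e-15))
    z[~np.isfinite(z)] = 0.0

    if k == 1:
        dist = z[:, 0] ** 2
    else:
        centered = z - z.mean(axis=0)
        cov = np.cov(centered, rowvar=False)
        dist = np.einsum("ij,ij->i", centered @ np.linalg.inv(cov), centered)
    lam = genomic_inflation(dist, k)
    pvals = sps.chi2.sf(dist / lam, k)
    out = pd.DataFrame(
        {
            "contig": cohort.sites["contig"].to_numpy()[rows],
            "pos": cohort.sites["pos"].to_numpy()[rows],
            "mahalanobis": dist,
            "pca_score": -np.log10(np.clip(pvals, 1e-300, None)),
        }
    )
    return out, lam


def fst_per_site(
    cohort: AnnotatedCohort,
    columns_a: np.ndarray,
    columns_b: np.ndarray,
    region: str | None = None,
) -> pd.DataFrame:
    """Weir–Cockerham (1984) per-site FST between two groups.

    Negative estimates are retained. Sites monomorphic across both groups
    have no defined estimator and report NaN (excluded from ranking).
    """
    cohort.require_polarized()
    if len(columns_a) == 0 or len(columns_b) == 0:
        raise CohortError("both groups must be non-empty")
    rows = cohort.region_rows(region)
    rows = rows[cohort.polarizable[rows]]
    dos = cohort.derived_dosage()[rows]

    def group_stats(cols):
        d = dos[:, np.asarray(cols)]
        called = d >= 0
        n = called.sum(axis=1).astype(float)  # diploids
        with np.errstate(invalid="ignore", divide="ignore"):
            p = np.where(called, d, 0).sum(axis=1) / (2 * n)
            h = ((d == 1) & called).sum(axis=1) / n
        return n, p, h

    n1, p1, h1 = group_stats(columns_a)
    n2, p2, h2 = group_stats(columns_b)
    r = 2.0
    nbar = (n1 + n2) / r
    with np.errstate(invalid="ignore", divide="ignore"):
        nc = (r * nbar - (n1**2 + n2**2) / (r * nbar)) / (r - 1)
        pbar = (n1 * p1 + n2 * p2) / (r * nbar)
        s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / ((r - 1) * nbar)
        hbar = (n1 * h1 + n2 * h2) / (r * nbar)
        a = nbar / nc * (s2 - (pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4) / (nbar - 1))
        b = nbar / (nbar - 1) * (pbar * (1 - pbar) - (r - 1) / r * s2 - (2 * nbar - 1) / (4 * nbar) * hbar)
        c = hbar / 2
        denom = a + b + c
        fst = np.where(denom != 0, a / denom, np.nan)
    fst = np.where((pbar > 0) & (pbar < 1), fst, np.nan)
    return pd.DataFrame(
        {
            "contig": cohort.sites["contig"].to_numpy()[rows],
            "pos": cohort.sites["pos"].to_numpy()[rows],
            "fst": fst,
        }
    )


def delta_load(site_loads_low: pd.DataFrame, site_loads_high: pd.DataFrame) -> pd.DataFrame:
    """Per-site difference in group total load, low-RS minus high-RS.

    Positive values mean a greater weighted derived-allele burden in the
    low-RS (nulliparous) group. Both inputs come from
    :func:`purgekit.load.group_site_load` over the same site universe.
    """
    merged = site_loads_low.merge(
        site_loads_high, on=["contig", "pos"], suffixes=("_low", "_high"), validate="one_to_one"
    )
    return pd.DataFrame(
        {
            "contig": merged["contig"],
            "pos": merged["pos"],
            "impact": merged["impact_low"],
            "delta_load": merged["site_load_low"] - merged["site_load_high"],
        }
    )


STAT_COLUMNS = ("pca_score", "fst", "delta_load")


def nearest_rank_threshold(values: np.ndarray, percentile: float) -> float:
    """Nearest-rank percentile over defined values: the ceil(P/100·N)-th smallest."""
    vals = np.sort(values[~np.isnan(values)])
    if len(vals) == 0:
        raise CohortError("no defined values to rank")
    rank = int(np.ceil(percentile / 100 * len(vals)))
    return float(vals[min(max(rank, 1), len(vals)) - 1])


def intersect_candidates(stats: pd.DataFrame, percentile: float = 90.0) -> dict:
    """Top-decile intersection of the three statistics.

    ``stats`` carries one row per site with columns contig, pos and the three
    statistic columns (NaN where undefined). A site is top-ranked for a
    statistic when it lies strictly above the nearest-rank threshold of that
    statistic's defined values; a candidate is top-ranked in all three.
    Returns the annotated frame, per-statistic thresholds and counts, and the
    seven Venn cell counts.
    """
    if not 0 < percentile < 100:
        raise CohortError(f"percentile must be in (0, 100), got {percentile}")
    missing = set(STAT_COLUMNS) - set(stats.columns)
    if missing:
        raise CohortError(f"stats table missing columns: {sorted(missing)}")
    out = stats.copy()
    thresholds = {}
    for col in STAT_COLUMNS:
        vals = out[col].to_numpy(dtype=float)
        thr = nearest_rank_threshold(vals, percentile)
        thresholds[col] = thr
        out[f"top_{col}"] = (vals > thr) & ~np.isnan(vals)
    tp, tf, td = (out[f"top_{c}"].to_numpy() for c in STAT_COLUMNS)
    out["candidate"] = tp & tf & td
    venn = {
        "pca_only": int((tp & ~tf & ~td).sum()),
        "fst_only": int((~tp & tf & ~td).sum()),
        "delta_only": int((~tp & ~tf & td).sum()),
        "pca_fst": int((tp & tf & ~td).sum()),
        "pca_delta": int((tp & ~tf & td).sum()),
        "fst_delta": int((~tp & tf & td).sum()),
        "all_three": int((tp & tf & td).sum()),
    }
    return {
        "stats": out,
        "thresholds": thresholds,
        "per_statistic_counts": {c: int(out[f"top_{c}"].sum()) for c in STAT_COLUMNS},
        "venn": venn,
        "candidates": out.loc[out["candidate"], ["contig", "pos"] + [c for c in ("impact",) if c in out.columns]],
        "n_candidates": int(out["candidate"].sum()),
    }


def candidate_carriage(
    cohort: AnnotatedCohort, candidates: pd.DataFrame, populations: list[str] | None = None
) -> pd.DataFrame:
    """Derived-allele presence of candidate sites in named outside populations.

    Reports, per candidate site and population, the derived-allele count and
    whether the allele is carried at all — the cross-population check that
    candidate variants are private to (or shared beyond) the focal group.
    """
    cohort.require_polarized()
    if populations is None:
        populations = list(pd.unique(cohort.samples["population"]))
    key = cohort.sites.reset_index().merge(candidates[["contig", "pos"]], on=["contig", "pos"])
    rows = key["index"].to_numpy()
    out = []
    for popn in populations:
        cols = cohort.population_columns(popn)
        dos = cohort.derived_dosage()[np.ix_(rows, cols)]
        called = dos >= 0
        count = np.where(called, dos, 0).sum(axis=1)
        an = 2 * called.sum(axis=1)
        for i, r in enumerate(rows):
            out.append(
                {
                    "contig": cohort.sites.loc[r, "contig"],
                    "pos": int(cohort.sites.loc[r, "pos"]),
                    "population": popn,
                    "derived_count": int(count[i]),
                    "called_alleles": int(an[i]),
                    "carried": bool(count[i] > 0),
                }
            )
    return pd.DataFrame(out)
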