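"""Purging-signature statistics: Rxy, relative mutation load, ROH enrichment.

Three complementary lines of evidence for genetic purging in a small, inbred
population: a deficit of derived alleles of high predicted impact relative to
a larger population (Rxy < 1), a homozygous load smaller than the inbreeding
coefficient predicts (low relative load), and a depletion of deleterious
homozygotes inside runs of homozygosity, where autozygosity should otherwise
raise homozygote frequency from p² to p.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .io import merge_intervals, positions_in_intervals
from .model import AnnotatedCohort, CohortError
from .roh import ROHSet


def _derived_freqs(cohort: AnnotatedCohort, cols: np.ndarray, rows: np.ndarray) -> np.ndarray:
    dos = cohort.derived_dosage()[np.ix_(rows, cols)]
    called = dos >= 0
    n = 2 * called.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(n > 0, np.where(called, dos, 0).sum(axis=1) / n, np.nan)


def rxy(
    cohort: AnnotatedCohort,
    pop_x: str,
    pop_y: str,
    impact_class: str,
    region: str | None = None,
) -> dict:
    """Rxy for one impact class: relative derived-allele burden of x vs y.

    Rxy = Σ_s d_s^x (1 − d_s^y) / Σ_s d_s^y (1 − d_s^x) over polarizable
    sites of the class in the region (d = derived-allele frequency). Values
    below 1 indicate a deficit of derived alleles in population x. The
    standard error is a delete-one-contig jackknife (respecting linkage;
    NaN when fewer than 2 contigs carry usable sites).
    """
    cohort.require_polarized()
    rows = cohort.region_rows(region)
    keep = cohort.polarizable[rows] & (cohort.sites["impact"].to_numpy()[rows] == impact_class)
    rows = rows[keep]
    cols_x = cohort.population_columns(pop_x)
    cols_y = cohort.population_columns(pop_y)
    dx = _derived_freqs(cohort, cols_x, rows)
    dy = _derived_freqs(cohort, cols_y, rows)
    ok = ~(np.isnan(dx) | np.isnan(dy))
    rows, dx, dy = rows[ok], dx[ok], dy[ok]
    num_terms = dx * (1 - dy)
    den_terms = dy * (1 - dx)
    if len(rows) == 0 or den_terms.sum() == 0:
        raise CohortError(
            f"Rxy denominator is zero for class {impact_class} "
            f"({len(rows)} usable sites); population y carries no derived alleles"
        )
    estimate = num_terms.sum() / den_terms.sum()

    contigs = cohort.sites["contig"].to_numpy()[rows]
    blocks = pd.unique(contigs)
    se = float("nan")
    if len(blocks) >= 2:
        thetas = []
        for b in blocks:
            m = contigs != b
            den = den_terms[m].sum()
            if den > 0:
                thetas.append(num_terms[m].sum() / den)
        g = len(thetas)
        if g >= 2:
            thetas = np.array(thetas)
            se = float(np.sqrt((g - 1) / g * ((thetas - thetas.mean()) ** 2).sum()))
    return {
        "pop_x": pop_x,
        "pop_y": pop_y,
        "impact": impact_class,
        "region": region if region is not None else "all",
        "rxy": float(estimate),
        "se": se,
        "n_sites": int(len(rows)),
    }


def relative_load(
    load_table: pd.DataFrame,
    f_table: pd.DataFrame,
    f_min: float = 0.01,
) -> pd.DataFrame:
    """Relative mutation load: homozygous load divided by inbreeding F.

    Joins the per-individual load table with the F table on sample and
    region. Individuals with F ≤ ``f_min`` are flagged invalid (the ratio is
    unstable near F = 0) and get no value rather than an error.
    """
    merged = load_table.merge(
        f_table[["sample_id", "region", "f"]], on=["sample_id", "region"], how="inner"
    )
    valid = merged["f"] > f_min
    rel = np.where(valid, merged["hom_load"] / merged["f"].where(valid), np.nan)
    return pd.DataFrame(
        {
            "sample_id": merged["sample_id"],
            "population": merged.get("population"),
            "region": merged["region"],
            "hom_load": merged["hom_load"],
            "f": merged["f"],
            "relative_load": rel,
            "valid": valid,
        }
    )


def roh_enrichment(
    cohort: AnnotatedCohort,
    rohs: ROHSet,
    strata_bp: tuple[float, ...] = (2_500_000,),
    region: str | None = None,
) -> pd.DataFrame:
    """Proportion of derived homozygotes inside ROH, per impact class and stratum.

    For every sample × impact class × ROH-length stratum: the number of
    derived-homozygous genotype positions falling inside ROH of that length
    stratum (half-open point-in-interval), and the proportion of that
    sample's derived homozygotes of the class that lie inside. The 'all'
    stratum pools every ROH, so stratum counts sum to it. MODIFIER
    homozygotes serve as the neutral comparator for the deleterious classes.
    """
    cohort.require_polarized()
    thresholds = sorted(strata_bp)
    labels = []
    bounds = []
    lo = 0.0
    for t in thresholds:
        labels.append(f"le_{_mb(t)}" if lo == 0 else f"{_mb(lo)}_to_{_mb(t)}")
        bounds.append((lo, t))
        lo = t
    labels.append(f"gt_{_mb(lo)}")
    bounds.append((lo, float("inf")))

    rows = cohort.region_rows(region)
    rows = rows[cohort.polarizable[rows]]
    contigs = cohort.sites["contig"].to_numpy()[rows]
    pos = cohort.sites["pos"].to_numpy()[rows]
    impacts = cohort.sites["impact"].to_numpy()[rows]
    dos = cohort.derived_dosage()[rows]

    out = []
    for j, sid in enumerate(cohort.sample_ids):
        hom = dos[:, j] == 2
        ivs = rohs.for_sample(sid)
        ivs = ivs[ivs["contig"].isin(set(np.unique(contigs)))]
        lens = (ivs["end"] - ivs["start"]).to_numpy()
        inside_by = {}
        for label, (lo, hi) in zip(labels, bounds):
            sel = ivs[(lens > lo) & (lens <= hi)] if np.isfinite(hi) else ivs[lens > lo]
            inside_by[label] = (
                positions_in_intervals(contigs, pos, merge_intervals(sel))
                if len(sel)
                else np.zeros(len(pos), dtype=bool)
            )
        inside_by["all"] = np.logical_or.reduce(list(inside_by.values())) if inside_by else np.zeros(len(pos), bool)
        for impact in np.unique(impacts):
            cls = impacts == impact
            n_total = int((hom & cls).sum())
            for label in labels + ["all"]:
                n_inside = int((hom & cls & inside_by[label]).sum())
                out.append(
                    {
                        "sample_id": sid,
                        "impact": impact,
                        "stratum": label,
                        "n_hom_inside": n_inside,
                        "n_hom_total": n_total,
                        "proportion_inside": n_inside / n_total if n_total else 0.0,
                    }
                )
    return pd.DataFrame(out)


def _mb(x: float) -> str:
    v = x / 1e6
    return f"{v:g}mb"
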