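"""Readers and writers: VCF cohorts, impact sidecar tables, BED intervals, TSV tables.

Conventions, fixed package-wide: VCF positions are 1-based inclusive; BED and
all internal interval arithmetic are 0-based half-open. Input VCFs are expected
to be pre-filtered upstream (depth/quality) and pre-normalized; multiallelic
records are rejected by default, with an optional split mode.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd
from cyvcf2 import VCF

from .model import (
    IMPACT_CLASSES,
    IMPACT_SEVERITY,
    MASKED,
    X,
    AnnotatedCohort,
    CohortError,
    GenomeSpec,
    validate_sample_sheet,
)

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# sample sheets and sidecar tables
# ---------------------------------------------------------------------------

def read_sample_sheet(path: str | Path) -> pd.DataFrame:
    """Read a TSV sample sheet (sample_id, population, sex[, rs_group])."""
    return validate_sample_sheet(pd.read_csv(path, sep="\t", dtype=str))


def read_impact_table(path: str | Path) -> pd.DataFrame:
    """Read a sidecar site-impact table: contig, pos, alt, impact (TSV)."""
    tab = pd.read_csv(path, sep="\t", dtype={"contig": str, "pos": int, "alt": str, "impact": str})
    missing = {"contig", "pos", "impact"} - set(tab.columns)
    if missing:
        raise CohortError(f"impact table missing columns: {sorted(missing)}")
    bad = set(tab["impact"]) - set(IMPACT_CLASSES)
    if bad:
        raise CohortError(f"impact table has unknown classes: {sorted(bad)}")
    return tab


def _most_severe_ann_impact(ann: str) -> str | None:
    """Collapse a SnpEff ANN INFO string to the most severe impact class.

    SnpEff emits one comma-separated annotation per transcript; the impact
    class is the third pipe-separated field of each.
    """
    best = None
    for entry in ann.split(","):
        fields = entry.split("|")
        if len(fields) < 3:
            continue
        impact = fields[2].upper()
        if impact in IMPACT_SEVERITY:
            if best is None or IMPACT_SEVERITY[impact] > IMPACT_SEVERITY[best]:
                best = impact
    return best


# ---------------------------------------------------------------------------
# cohort construction
# ---------------------------------------------------------------------------

def read_cohort(
    vcf_path: str | Path,
    sample_sheet: str | Path | pd.DataFrame,
    genome: GenomeSpec,
    impact_source: str = "info_field",
    impact_table: str | Path | pd.DataFrame | None = None,
    multiallelic: str = "error",
    on_missing_impact: str = "drop",
) -> AnnotatedCohort:
    """Read a multi-sample VCF into an :class:`AnnotatedCohort`.

    Sites with any missing genotype call are dropped (on X contigs, calls of
    male samples are excluded before the missingness check and masked in the
    matrix — hemizygous males carry no usable diploid X genotype). Invariant
    records (empty ALT) are retained and flagged, for diversity denominators.

    Parameters
    ----------
    impact_source : 'info_field' (SnpEff ANN / IMPACT INFO key, collapsed to
        the most severe class per site) or 'site_table' (sidecar TSV).
    multiallelic : 'error' (input must be pre-normalized) or 'split' into
        per-alt biallelic records.
    on_missing_impact : 'drop' variant sites lacking an impact annotation
        (with a warning), or 'error'.
    """
    if impact_source not in ("info_field", "site_table"):
        raise CohortError(f"impact_source must be info_field|site_table, got {impact_source!r}")
    if multiallelic not in ("error", "split"):
        raise CohortError(f"multiallelic must be error|split, got {multiallelic!r}")
    if on_missing_impact not in ("drop", "error"):
        raise CohortError(f"on_missing_impact must be drop|error, got {on_missing_impact!r}")

    if isinstance(sample_sheet, (str, Path)):
        samples = read_sample_sheet(sample_sheet)
    else:
        samples = validate_sample_sheet(sample_sheet)

    sidecar = None
    if impact_source == "site_table":
        if impact_table is None:
            raise CohortError("impact_source='site_table' requires impact_table")
        if isinstance(impact_table, (str, Path)):
            impact_table = read_impact_table(impact_table)
        key_cols = ["contig", "pos", "alt"] if "alt" in impact_table.columns else ["contig", "pos"]
        sidecar = {tuple(k): v for *k, v in impact_table[key_cols + ["impact"]].itertuples(index=False)}

    vcf = VCF(str(vcf_path), gts012=True)
    header_samples = list(vcf.samples)
    absent = [s for s in samples["sample_id"] if s not in header_samples]
    if absent:
        raise CohortError(f"samples in sheet but not in VCF header: {absent}")
    vcf.set_samples(samples["sample_id"].tolist())
    # cyvcf2 returns columns in header order; map to sheet order afterwards
    kept_order = [s for s in vcf.samples]
    col_of = np.array([kept_order.index(s) for s in samples["sample_id"]])

    male = (samples["sex"] == "male").to_numpy()

    records: list[tuple] = []
    gt_rows: list[np.ndarray] = []
    n_missing_dropped = 0
    n_no_impact = 0

    for v in vcf:
        if v.CHROM not in genome.lengths:
            raise CohortError(f"contig {v.CHROM!r} absent from genome spec")
        region = genome.region(v.CHROM)
        alts = v.ALT
        gts = np.asarray(v.gt_types)[col_of]  # 0 hom-ref, 1 het, 2 hom-alt, 3 missing

        if len(alts) > 1:
            if multiallelic == "error":
                raise CohortError(
                    f"multiallelic record at {v.CHROM}:{v.POS}; pre-normalize the VCF "
                    "or pass multiallelic='split'"
                )
            geno = np.array(v.genotypes, dtype=object)[col_of]
            sub_rows = []
            for ai, alt in enumerate(alts, start=1):
                row = np.empty(len(samples), dtype=np.int8)
                for j, g in enumerate(geno):
                    a, b = g[0], g[1]
                    row[j] = 3 if (a < 0 or b < 0) else (a == ai) + (b == ai)
                sub_rows.append((alt, row))
        else:
            alt = alts[0] if alts else "."
            sub_rows = [(alt, gts.astype(np.int8))]

        for alt, row in sub_rows:
            is_variant = alt != "."
            relevant = ~male if region == X else np.ones(len(samples), bool)
            if (row[relevant] == 3).any():
                n_missing_dropped += 1
                continue
            if is_variant:
                impact = _lookup_impact(v, alt, impact_source, sidecar)
                if impact is None:
                    if on_missing_impact == "error":
                        raise CohortError(f"no impact annotation at {v.CHROM}:{v.POS}")
                    n_no_impact += 1
                    continue
            else:
                impact = "MODIFIER"  # invariant sites carry no functional call
            row = row.copy()
            if region == X:
                row[male] = MASKED
            records.append((v.CHROM, v.POS, v.REF, alt, impact, region, is_variant))
            gt_rows.append(row)

    sites = pd.DataFrame(
        records, columns=["contig", "pos", "ref", "alt", "impact", "region", "is_variant"]
    )
    gt = np.vstack(gt_rows) if gt_rows else np.empty((0, len(samples)), dtype=np.int8)
    order = _genome_order(sites, genome)
    sites = sites.iloc[order].reset_index(drop=True)
    gt = gt[order]
    logger.info(
        "read %d sites (%d variant); dropped %d with missing calls, %d without impact",
        len(sites), int(sites["is_variant"].sum()), n_missing_dropped, n_no_impact,
    )
    return AnnotatedCohort(sites=sites, gt=gt, samples=samples, genome=genome)


def _lookup_impact(v, alt: str, impact_source: str, sidecar) -> str | None:
    if impact_source == "info_field":
        ann = v.INFO.get("ANN")
        if ann is not None:
            return _most_severe_ann_impact(str(ann))
        direct = v.INFO.get("IMPACT")
        if direct is not None and str(direct).upper() in IMPACT_SEVERITY:
            return str(direct).upper()
        return None
    hit = sidecar.get((v.CHROM, v.POS, alt))
    if hit is None:
        hit = sidecar.get((v.CHROM, v.POS))
    return hit


def _genome_order(sites: pd.DataFrame, genome: GenomeSpec) -> np.ndarray:
    contig_rank = {c: i for i, c in enumerate(genome.lengths)}
    key = sites["contig"].map(contig_rank).to_numpy()
    return np.lexsort((sites["pos"].to_numpy(), key))


# ---------------------------------------------------------------------------
# interval masks
# ---------------------------------------------------------------------------

def read_bed(path: str | Path, names: bool = True) -> pd.DataFrame:
    """Read a BED file into (contig, start, end[, name]) with half-open coords."""
    cols = ["contig", "start", "end", "name"]
    bed = pd.read_csv(path, sep="\t", header=None, comment="#")
    bed = bed.iloc[:, : 4 if names and bed.shape[1] >= 4 else 3]
    bed.columns = cols[: bed.shape[1]]
    return bed


def merge_intervals(intervals: pd.DataFrame) -> dict[str, np.ndarray]:
    """Merge per-contig intervals into sorted non-overlapping (n, 2) arrays."""
    merged: dict[str, np.ndarray] = {}
    for contig, grp in intervals.groupby("contig", sort=False):
        arr = grp[["start", "end"]].to_numpy(dtype=np.int64)
        if (arr[:, 1] <= arr[:, 0]).any():
            bad = arr[arr[:, 1] <= arr[:, 0]][0]
            raise CohortError(f"malformed interval on {contig}: end {bad[1]} <= start {bad[0]}")
        arr = arr[np.argsort(arr[:, 0])]
        out = [arr[0].copy()]
        for s, e in arr[1:]:
            if s <= out[-1][1]:
                out[-1][1] = max(out[-1][1], e)
            else:
                out.append(np.array([s, e]))
        merged[str(contig)] = np.array(out)
    return merged


def positions_in_intervals(contigs: np.ndarray, pos: np.ndarray, merged: dict[str, np.ndarray]) -> np.ndarray:
    """Boolean: does each 1-based position fall inside a half-open interval set?"""
    inside = np.zeros(len(pos), dtype=bool)
    point = pos - 1  # 1-based position occupies [pos-1, pos)
    for contig, arr in merged.items():
        rows = np.flatnonzero(contigs == contig)
        if len(rows) == 0:
            continue
        idx = np.searchsorted(arr[:, 0], point[rows], side="right") - 1
        ok = idx >= 0
        ok[ok] &= point[rows][ok] < arr[idx[ok], 1]
        inside[rows] = ok
    return inside


def apply_region_mask(cohort: AnnotatedCohort, mask: pd.DataFrame) -> AnnotatedCohort:
    """Drop all sites falling inside the masked intervals (e.g. repeat regions).

    ``mask`` is a BED-style frame (contig, start, end), 0-based half-open.
    Site order is preserved.
    """
    if len(mask) == 0:
        return cohort
    merged = merge_intervals(mask)
    inside = positions_in_intervals(
        cohort.sites["contig"].to_numpy(), cohort.sites["pos"].to_numpy(), merged
    )
    logger.info("region mask removed %d of %d sites", int(inside.sum()), cohort.n_sites)
    return cohort.take_sites(np.flatnonzero(~inside))


# ---------------------------------------------------------------------------
# writers
# ---------------------------------------------------------------------------

def write_site_table(stats: pd.DataFrame, path: str | Path) -> None:
    """Write any per-site statistic table as TSV with a header, stable order."""
    stats.to_csv(path, sep="\t", index=False)


def read_site_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_bed(intervals, path: str | Path) -> None:
    """Write intervals as BED (0-based half-open), sample id in the name column.

    Accepts a DataFrame with columns (contig, start, end[, sample_id]) or any
    object exposing such a frame as ``.intervals`` (e.g. a ROHSet).
    """
    frame = getattr(intervals, "intervals", intervals)
    cols = ["contig", "start", "end"] + (["sample_id"] if "sample_id" in frame.columns else [])
    frame[cols].to_csv(path, sep="\t", index=False, header=False)


def read_roh_bed(path: str | Path) -> pd.DataFrame:
    """Read ROH intervals from BED with the sample id in the name column."""
    bed = read_bed(path, names=True)
    if "name" not in bed.columns:
        raise CohortError("ROH BED requires a 4th (sample id) column")
    return bed.rename(columns={"name": "sample_id"})[["sample_id", "contig", "start", "end"]]
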