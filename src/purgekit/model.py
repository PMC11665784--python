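"""Core in-memory containers: genome description, sample sheet, annotated cohort.

The cohort is the substrate of every downstream statistic: a sites-by-samples
diploid genotype matrix joined to per-site functional impact annotations
(SnpEff-style MODIFIER/LOW/MODERATE/HIGH), with invariant sites retained so
that windowed nucleotide diversity has honest denominators, and with male
genotype columns masked out on X-linked contigs (males are hemizygous there,
so their diploid calls are not comparable).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

#: Functional impact classes in increasing severity order.
IMPACT_CLASSES = ("MODIFIER", "LOW", "MODERATE", "HIGH")

#: Severity rank used when collapsing multi-transcript annotations.
IMPACT_SEVERITY = {c: i for i, c in enumerate(IMPACT_CLASSES)}

AUTOSOME = "autosome"
X = "X"
REGIONS = (AUTOSOME, X)

#: Sentinel genotype for calls masked out (male X columns).
MASKED = -1


class CohortError(ValueError):
    """Raised on contract violations while building or using a cohort."""


@dataclass(frozen=True)
class GenomeSpec:
    """Contig lengths and the autosome/X partition of the reference genome.

    FROH and window denominators are always taken from here, never inferred
    from the extent of the data.
    """

    lengths: dict[str, int]
    x_contigs: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        for name, length in self.lengths.items():
            if length <= 0:
                raise CohortError(f"contig {name!r} has non-positive length {length}")
        unknown = set(self.x_contigs) - set(self.lengths)
        if unknown:
            raise CohortError(f"X contigs absent from lengths: {sorted(unknown)}")

    @property
    def contigs(self) -> list[str]:
        return list(self.lengths)

    def region(self, contig: str) -> str:
        if contig not in self.lengths:
            raise CohortError(f"contig {contig!r} not in genome spec")
        return X if contig in self.x_contigs else AUTOSOME

    def region_contigs(self, region: str) -> list[str]:
        _check_region(region)
        return [c for c in self.lengths if self.region(c) == region]

    def region_length(self, region: str) -> int:
        return sum(self.lengths[c] for c in self.region_contigs(region))

    @classmethod
    def from_dict(cls, d: dict) -> "GenomeSpec":
        return cls(lengths=dict(d["lengths"]), x_contigs=frozenset(d.get("x_contigs", ())))


def _check_region(region: str) -> None:
    if region not in REGIONS:
        raise CohortError(f"region must be one of {REGIONS}, got {region!r}")


SAMPLE_COLUMNS = ["sample_id", "population", "sex", "rs_group"]


def validate_sample_sheet(samples: pd.DataFrame) -> pd.DataFrame:
    """Validate and normalize a sample sheet.

    Required columns: sample_id, population, sex ({female, male}); optional
    rs_group ({high, low, none}) marking the reproductive-success contrast.
    """
    samples = samples.copy()
    missing = {"sample_id", "population", "sex"} - set(samples.columns)
    if missing:
        raise CohortError(f"sample sheet missing columns: {sorted(missing)}")
    if "rs_group" not in samples.columns:
        samples["rs_group"] = "none"
    samples["rs_group"] = samples["rs_group"].fillna("none")
    if samples["sample_id"].duplicated().any():
        dupes = samples.loc[samples["sample_id"].duplicated(), "sample_id"].tolist()
        raise CohortError(f"duplicate sample ids: {dupes}")
    bad_sex = set(samples["sex"]) - {"female", "male"}
    if bad_sex:
        raise CohortError(f"sex must be female/male, got {sorted(bad_sex)}")
    bad_rs = set(samples["rs_group"]) - {"high", "low", "none"}
    if bad_rs:
        raise CohortError(f"rs_group must be high/low/none, got {sorted(bad_rs)}")
    return samples.reset_index(drop=True)[SAMPLE_COLUMNS]


SITE_COLUMNS = ["contig", "pos", "ref", "alt", "impact", "region", "is_variant"]


@dataclass
class AnnotatedCohort:
    """Genotype matrix joined to per-site impact annotations.

    Attributes
    ----------
    sites : DataFrame with columns contig, pos (1-based), ref, alt, impact,
        region ('autosome'|'X'), is_variant (False for invariant records kept
        for diversity denominators). Sorted by (contig, pos) in genome order.
    gt : int8 array of shape (n_sites, n_samples); 0 = hom-ref, 1 = het,
        2 = hom-alt, ``MASKED`` (-1) for male calls on X contigs. No missing
        calls survive construction — sites with any missing genotype are
        dropped upstream.
    samples : validated sample sheet, one row per genotype column.
    genome : the :class:`GenomeSpec` the cohort was read against.
    derived_is_alt / polarizable : set by :func:`purgekit.load.polarize`.
    """

    sites: pd.DataFrame
    gt: np.ndarray
    samples: pd.DataFrame
    genome: GenomeSpec
    derived_is_alt: np.ndarray | None = None
    polarizable: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.samples = validate_sample_sheet(self.samples)
        if self.gt.shape != (len(self.sites), len(self.samples)):
            raise CohortError(
                f"genotype matrix shape {self.gt.shape} does not match "
                f"{len(self.sites)} sites x {len(self.samples)} samples"
            )
        self.gt = np.asarray(self.gt, dtype=np.int8)
        valid = np.isin(self.gt, (MASKED, 0, 1, 2))
        if not valid.all():
            raise CohortError("genotypes must be in {-1, 0, 1, 2}")
        self.sites = self.sites.reset_index(drop=True)
        bad_impact = set(self.sites["impact"]) - set(IMPACT_CLASSES)
        if bad_impact:
            raise CohortError(f"unknown impact classes: {sorted(bad_impact)}")
        # male columns must be masked on X, and only there
        male = (self.samples["sex"] == "male").to_numpy()
        on_x = (self.sites["region"] == X).to_numpy()
        expect = np.outer(on_x, male)
        if ((self.gt == MASKED) != expect).any():
            raise CohortError("mask pattern violated: males must be masked on X contigs only")

    # -- basic views -------------------------------------------------------

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def sample_ids(self) -> list[str]:
        return self.samples["sample_id"].tolist()

    def sample_index(self, sample_id: str) -> int:
        idx = self.samples.index[self.samples["sample_id"] == sample_id]
        if len(idx) == 0:
            raise CohortError(f"unknown sample {sample_id!r}")
        return int(idx[0])

    def population_columns(self, population: str) -> np.ndarray:
        cols = (self.samples["population"] == population).to_numpy()
        if not cols.any():
            raise CohortError(f"no samples in population {population!r}")
        return np.flatnonzero(cols)

    def rs_group_columns(self, group: str) -> np.ndarray:
        cols = (self.samples["rs_group"] == group).to_numpy()
        if not cols.any():
            raise CohortError(f"no samples in rs_group {group!r}")
        return np.flatnonzero(cols)

    def region_rows(self, region: str | None) -> np.ndarray:
        if region is None:
            return np.arange(self.n_sites)
        _check_region(region)
        return np.flatnonzero((self.sites["region"] == region).to_numpy())

    # -- allele arithmetic -------------------------------------------------

    def called(self) -> np.ndarray:
        """Boolean (sites, samples): genotype present (not masked)."""
        return self.gt != MASKED

    def allele_counts(self, columns: np.ndarray | None = None) -> tuple[np.ndarray, np.ndarray]:
        """Return (alt allele count, called allele number) per site."""
        gt = self.gt if columns is None else self.gt[:, columns]
        called = gt != MASKED
        ac = np.where(called, gt, 0).sum(axis=1)
        an = 2 * called.sum(axis=1)
        return ac.astype(np.int64), an.astype(np.int64)

    def require_polarized(self) -> None:
        if self.derived_is_alt is None or self.polarizable is None:
            raise CohortError("cohort is not polarized; call purgekit.load.polarize first")

    def derived_dosage(self) -> np.ndarray:
        """Per-site, per-sample count of derived alleles (0/1/2); -1 masked.

        Only meaningful on polarizable sites.
        """
        self.require_polarized()
        flip = ~self.derived_is_alt[:, None]
        dos = np.where(flip, 2 - self.gt, self.gt)
        return np.where(self.gt == MASKED, MASKED, dos).astype(np.int8)

    # -- subsetting --------------------------------------------------------

    def take_sites(self, rows: np.ndarray) -> "AnnotatedCohort":
        rows = np.asarray(rows)
        return replace(
            self,
            sites=self.sites.iloc[rows].reset_index(drop=True),
            gt=self.gt[rows],
            derived_is_alt=None if self.derived_is_alt is None else self.derived_is_alt[rows],
            polarizable=None if self.polarizable is None else self.polarizable[rows],
        )

    def variant_rows(self) -> np.ndarray:
        return np.flatnonzero(self.sites["is_variant"].to_numpy())
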