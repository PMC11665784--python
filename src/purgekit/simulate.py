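"""Synthetic multi-population cohorts with known ground truth.

The generator emulates the data structure of a small-cohort whale-genomics
study: three populations with contrasting histories (one small and inbred
with long runs of homozygosity and purged high-impact alleles; two larger
ones segregating low-frequency deleterious variation), autosome and X
contigs, zero missing genotypes, four SnpEff-style impact classes, and an
optional reproductive-success contrast of two five-female groups differing
at a planted candidate set.

Mechanics per variant site: a base derived-allele frequency is drawn from a
per-class Beta distribution scaled into (0, 0.5) — the derived allele is the
cohort minor allele by construction. Each population multiplies the
frequency of class c by a purging factor ρ_c ≤ 1. Genotypes are sampled at
Hardy–Weinberg except inside planted autozygous tracts, where the individual
is homozygous: derived-homozygous with probability q·δ_c (δ_c < 1 plants
within-ROH purging, the p-vs-p² contract), ancestral-homozygous otherwise,
with a small heterozygote error rate mimicking genotyping noise. Sites are
drawn independently (no linkage). Output is a standards-compliant VCF with
invariant records interleaved, a sidecar impact table, a sample sheet, and
the truth (planted frequencies, tracts, candidate IDs) for recovery tests.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .io import read_cohort
from .model import IMPACT_CLASSES, AnnotatedCohort, CohortError, GenomeSpec


@dataclass(frozen=True)
class ContigSpec:
    name: str
    length: int
    is_x: bool = False


@dataclass(frozen=True)
class PopulationSpec:
    name: str
    n_females: int
    n_males: int = 0
    target_f: float = 0.0  # fraction of each contig planted as autozygous tract
    roh_length_ranges: tuple[tuple[int, int], ...] = (
        (300_000, 1_000_000),
        (1_000_000, 2_500_000),
    )
    roh_length_weights: tuple[float, ...] = (0.7, 0.3)
    rho: dict = field(default_factory=dict)  # impact -> derived-frequency multiplier
    delta: dict = field(default_factory=dict)  # impact -> inside-ROH hom-derived depletion

    @property
    def n(self) -> int:
        return self.n_females + self.n_males


@dataclass(frozen=True)
class CandidatePlan:
    """Planted RS-linked sites: high derived frequency in the low-RS group."""

    n_sites: int = 10
    impact: str = "HIGH"
    q_low: float = 0.85
    q_high: float = 0.05
    q_outside: float = 0.01


@dataclass(frozen=True)
class GroupShiftPlan:
    """Background group-differentiated sites giving the contrast a dominant PC axis."""

    n_sites: int = 500
    impact: str = "MODIFIER"
    q_low: float = 0.5
    q_high: float = 0.15
    q_outside: float = 0.3


#: Default per-class segregating-site counts; deleterious classes are rarer,
#: mirroring the usual SnpEff annotation composition at reduced scale.
DEFAULT_CLASS_SITES = {"MODIFIER": 6000, "LOW": 3000, "MODERATE": 2000, "HIGH": 1000}

#: One Beta(a, b) for every class, scaled into (0, 0.5): most derived alleles
#: segregate at low frequency. Class differences in frequency are produced by
#: the purging factors, not the base draw, so within-ROH depletion (delta)
#: and between-population deficits (rho) are identifiable separately.
DEFAULT_CLASS_BETA = {c: (1.0, 4.0) for c in IMPACT_CLASSES}


@dataclass(frozen=True)
class SimConfig:
    seed: int
    contigs: tuple[ContigSpec, ...]
    populations: tuple[PopulationSpec, ...]
    class_sites: dict = field(default_factory=lambda: dict(DEFAULT_CLASS_SITES))
    class_beta: dict = field(default_factory=lambda: dict(DEFAULT_CLASS_BETA))
    invariant_per_variant: int = 9
    candidates: CandidatePlan | None = None
    shift: GroupShiftPlan | None = None
    rs_population: str | None = None  # population carrying the 5v5 female contrast
    het_error_in_roh: float = 1e-3
    explicit_roh: dict | None = None  # sample_id -> [(contig, start, end), ...]

    def genome(self) -> GenomeSpec:
        return GenomeSpec(
            lengths={c.name: c.length for c in self.contigs},
            x_contigs=frozenset(c.name for c in self.contigs if c.is_x),
        )


@dataclass
class SimTruth:
    samples: pd.DataFrame
    sites: pd.DataFrame  # contig, pos, impact, kind, base_freq, freq_<pop>...
    roh: pd.DataFrame  # planted intervals: sample_id, contig, start, end
    target_f: dict
    rho: dict
    delta: dict

    @property
    def candidate_sites(self) -> pd.DataFrame:
        return self.sites.loc[self.sites["kind"] == "candidate", ["contig", "pos"]]


@dataclass
class SimResult:
    vcf: Path
    impact_table: Path
    sample_sheet: Path
    genome: GenomeSpec
    truth: SimTruth
    config: SimConfig

    def load_cohort(self, impact_source: str = "site_table") -> AnnotatedCohort:
        return read_cohort(
            self.vcf,
            self.sample_sheet,
            self.genome,
            impact_source=impact_source,
            impact_table=self.impact_table if impact_source == "site_table" else None,
        )


# ---------------------------------------------------------------------------
# internals
# ---------------------------------------------------------------------------

def _distinct_positions(rng: np.random.Generator, length: int, n: int) -> np.ndarray:
    if n == 0:
        return np.array([], dtype=np.int64)
    if n > length:
        raise CohortError(f"cannot place {n} sites on a {length} bp contig")
    draws = np.unique(rng.integers(1, length + 1, size=int(n * 1.3) + 16))
    while len(draws) < n:
        draws = np.unique(np.r_[draws, rng.integers(1, length + 1, size=n)])
    sel = rng.permutation(len(draws))[:n]
    return np.sort(draws[sel])


def _place_tracts(
    rng: np.random.Generator, contig_len: int, pop: PopulationSpec
) -> list[tuple[int, int]]:
    target = pop.target_f * contig_len
    if target <= 0:
        return []
    weights = np.asarray(pop.roh_length_weights, dtype=float)
    weights = weights / weights.sum()
    lengths: list[int] = []
    while sum(lengths) < target:
        lo, hi = pop.roh_length_ranges[rng.choice(len(weights), p=weights)]
        lengths.append(int(rng.integers(lo, hi + 1)))
        if len(lengths) > 10_000:
            raise CohortError("ROH mix cannot reach the target coverage")
    # trim the final tract so planted coverage hits the target exactly
    excess = sum(lengths) - int(target)
    if excess > 0:
        lengths[-1] -= excess
        if lengths[-1] < 50_000:
            lengths.pop()
    total = sum(lengths)
    if total > 0.9 * contig_len:
        raise CohortError(
            f"infeasible config: planted ROH ({total} bp) exceed 90% of a "
            f"{contig_len} bp contig"
        )
    gaps = rng.dirichlet(np.ones(len(lengths) + 1)) * (contig_len - total)
    out = []
    cursor = 0.0
    for g, ln in zip(gaps, lengths):
        start = int(cursor + g)
        out.append((start, start + ln))
        cursor = start + ln
    return out


def _sample_ids(pop: PopulationSpec) -> list[tuple[str, str]]:
    ids = [(f"{pop.name}_f{i:02d}", "female") for i in range(pop.n_females)]
    ids += [(f"{pop.name}_m{i:02d}", "male") for i in range(pop.n_males)]
    return ids


def _build_samples(config: SimConfig) -> pd.DataFrame:
    rows = []
    for pop in config.populations:
        for sid, sex in _sample_ids(pop):
            rows.append({"sample_id": sid, "population": pop.name, "sex": sex, "rs_group": "none"})
    samples = pd.DataFrame(rows)
    if config.rs_population is not None:
        females = samples.index[
            (samples["population"] == config.rs_population) & (samples["sex"] == "female")
        ]
        if len(females) < 10:
            raise CohortError(
                f"rs_population {config.rs_population!r} needs >= 10 females for the 5v5 contrast"
            )
        samples.loc[females[:5], "rs_group"] = "high"
        samples.loc[females[5:10], "rs_group"] = "low"
    return samples


def simulate_cohort(config: SimConfig, outdir: str | Path) -> SimResult:
    """Generate the cohort, write VCF + sidecar + sample sheet + truth files.

    Fully deterministic given ``config.seed`` (byte-identical outputs).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)
    genome = config.genome()
    samples = _build_samples(config)
    n_samples = len(samples)

    # --- site layout ------------------------------------------------------
    site_rows = []
    for cls in IMPACT_CLASSES:
        site_rows += [(cls, "background")] * int(config.class_sites.get(cls, 0))
    if config.shift is not None:
        site_rows += [(config.shift.impact, "shift")] * config.shift.n_sites
    if config.candidates is not None:
        site_rows += [(config.candidates.impact, "candidate")] * config.candidates.n_sites
    n_var = len(site_rows)
    labels = pd.DataFrame(site_rows, columns=["impact", "kind"]).iloc[rng.permutation(n_var)]
    labels = labels.reset_index(drop=True)

    lengths = np.array([c.length for c in config.contigs], dtype=float)
    alloc = np.floor(lengths / lengths.sum() * n_var).astype(int)
    for i in range(n_var - alloc.sum()):  # distribute the remainder
        alloc[i % len(alloc)] += 1

    contig_col, pos_col = [], []
    for contig, n_c in zip(config.contigs, alloc):
        pos = _distinct_positions(rng, contig.length, int(n_c))
        contig_col += [contig.name] * len(pos)
        pos_col.append(pos)
    sites = pd.DataFrame(
        {
            "contig": contig_col,
            "pos": np.concatenate(pos_col) if pos_col else np.array([], dtype=np.int64),
            "impact": labels["impact"].to_numpy(),
            "kind": labels["kind"].to_numpy(),
        }
    )

    # --- frequencies ------------------------------------------------------
    base = np.empty(n_var)
    impacts = sites["impact"].to_numpy()
    for cls in IMPACT_CLASSES:
        m = impacts == cls
        a, b = config.class_beta.get(cls, (1.0, 4.0))
        base[m] = 0.5 * rng.beta(a, b, size=int(m.sum()))
    base = np.clip(base, 1e-3, 0.499)
    kind = sites["kind"].to_numpy()
    sites["base_freq"] = base

    pop_freq: dict[str, np.ndarray] = {}
    for pop in config.populations:
        rho = np.array([pop.rho.get(c, 1.0) for c in impacts])
        pop_freq[pop.name] = np.clip(base * rho, 0.0, 0.999)
        sites[f"freq_{pop.name}"] = pop_freq[pop.name]

    # --- planted ROH ------------------------------------------------------
    roh_rows = []
    tracts_by_sample: dict[str, dict[str, np.ndarray]] = {}
    for pop in config.populations:
        for sid, _sex in _sample_ids(pop):
            per_contig: dict[str, np.ndarray] = {}
            if config.explicit_roh is not None and sid in config.explicit_roh:
                for contig, start, end in config.explicit_roh[sid]:
                    per_contig.setdefault(contig, [])
                    per_contig[contig].append((start, end))
                per_contig = {c: np.array(v) for c, v in per_contig.items()}
            else:
                for contig in config.contigs:
                    tracts = _place_tracts(rng, contig.length, pop)
                    if tracts:
                        per_contig[contig.name] = np.array(tracts)
            tracts_by_sample[sid] = per_contig
            for contig_name, arr in per_contig.items():
                for start, end in arr:
                    roh_rows.append({"sample_id": sid, "contig": contig_name, "start": int(start), "end": int(end)})
    roh_truth = pd.DataFrame(roh_rows, columns=["sample_id", "contig", "start", "end"])

    # --- genotypes --------------------------------------------------------
    contigs_arr = sites["contig"].to_numpy()
    pos_arr = sites["pos"].to_numpy()
    gt = np.zeros((n_var, n_samples), dtype=np.int8)
    rs_group = samples["rs_group"].to_numpy()
    sample_pop = samples["population"].to_numpy()

    for j in range(n_samples):
        sid = samples.loc[j, "sample_id"]
        pop = next(p for p in config.populations if p.name == sample_pop[j])
        q = pop_freq[pop.name].copy()
        # planted contrasts override the population frequency column-wise
        for plan, k in ((config.candidates, "candidate"), (config.shift, "shift")):
            if plan is None:
                continue
            m = kind == k
            if sample_pop[j] != config.rs_population:
                q[m] = plan.q_outside
            elif rs_group[j] == "low":
                q[m] = plan.q_low
            elif rs_group[j] == "high":
                q[m] = plan.q_high
            else:
                q[m] = 0.5 * (plan.q_low + plan.q_high)
        dos = rng.binomial(2, q).astype(np.int8)
        # autozygous tracts: homozygous, with delta-depleted derived probability
        inside = np.zeros(n_var, dtype=bool)
        for contig_name, arr in tracts_by_sample[sid].items():
            rows = contigs_arr == contig_name
            point = pos_arr[rows] - 1
            idx = np.searchsorted(arr[:, 0], point, side="right") - 1
            ok = idx >= 0
            ok[ok] &= point[ok] < arr[idx[ok], 1]
            inside[rows] = ok
        if inside.any():
            delta = np.array([pop.delta.get(c, 1.0) for c in impacts[inside]])
            u = rng.random(int(inside.sum()))
            dos[inside] = np.where(u < q[inside] * delta, 2, 0).astype(np.int8)
            err = rng.random(int(inside.sum())) < config.het_error_in_roh
            dos_in = dos[inside]
            dos_in[err] = 1
            dos[inside] = dos_in
        gt[:, j] = dos

    # --- write outputs ----------------------------------------------------
    vcf_path = outdir / "cohort.vcf"
    impact_path = outdir / "impacts.tsv"
    sheet_path = outdir / "samples.tsv"
    _write_vcf(vcf_path, config, sites, gt, samples, rng)
    sites[["contig", "pos", "impact"]].assign(alt="C")[["contig", "pos", "alt", "impact"]].to_csv(
        impact_path, sep="\t", index=False
    )
    samples.to_csv(sheet_path, sep="\t", index=False)

    truth = SimTruth(
        samples=samples,
        sites=sites,
        roh=roh_truth,
        target_f={p.name: p.target_f for p in config.populations},
        rho={p.name: dict(p.rho) for p in config.populations},
        delta={p.name: dict(p.delta) for p in config.populations},
    )
    _write_truth(outdir, truth)
    return SimResult(
        vcf=vcf_path,
        impact_table=impact_path,
        sample_sheet=sheet_path,
        genome=genome,
        truth=truth,
        config=config,
    )


_GT_STR = {0: "0/0", 1: "0/1", 2: "1/1"}


def _write_vcf(
    path: Path,
    config: SimConfig,
    sites: pd.DataFrame,
    gt: np.ndarray,
    samples: pd.DataFrame,
    rng: np.random.Generator,
) -> None:
    lines = ["##fileformat=VCFv4.2", "##source=purgekit-simulate"]
    for c in config.contigs:
        lines.append(f"##contig=<ID={c.name},length={c.length}>")
    lines.append('##INFO=<ID=IMPACT,Number=1,Type=String,Description="Predicted impact class">')
    lines.append('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    lines.append(
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
        + "\t".join(samples["sample_id"])
    )

    n_hom_ref = "\t".join(["0/0"] * len(samples))
    contigs_arr = sites["contig"].to_numpy()
    pos_arr = sites["pos"].to_numpy()
    impacts = sites["impact"].to_numpy()
    for contig in config.contigs:
        rows = np.flatnonzero(contigs_arr == contig.name)
        var_pos = pos_arr[rows]
        n_inv = config.invariant_per_variant * len(rows)
        inv_pos = _distinct_positions(rng, contig.length, min(n_inv, max(contig.length - len(rows), 0)))
        inv_pos = inv_pos[~np.isin(inv_pos, var_pos)]
        records = [(int(p), -1) for p in inv_pos] + [(int(p), int(r)) for p, r in zip(var_pos, rows)]
        records.sort()
        for p, r in records:
            if r < 0:
                lines.append(f"{contig.name}\t{p}\t.\tA\t.\t.\t.\t.\tGT\t{n_hom_ref}")
            else:
                gts = "\t".join(_GT_STR[int(g)] for g in gt[r])
                lines.append(
                    f"{contig.name}\t{p}\t.\tA\tC\t.\t.\tIMPACT={impacts[r]}\tGT\t{gts}"
                )
    path.write_text("\n".join(lines) + "\n")


def _write_truth(outdir: Path, truth: SimTruth) -> None:
    truth.sites.to_csv(outdir / "truth_sites.tsv", sep="\t", index=False)
    truth.roh.to_csv(outdir / "truth_roh.bed", sep="\t", index=False, header=False,
                     columns=["contig", "start", "end", "sample_id"])
    meta = {
        "target_f": truth.target_f,
        "rho": truth.rho,
        "delta": truth.delta,
        "candidate_sites": truth.candidate_sites.to_dict(orient="records"),
    }
    (outdir / "truth.json").write_text(json.dumps(meta, indent=2) + "\n")


# ---------------------------------------------------------------------------
# presets
# ---------------------------------------------------------------------------

def single_population_config(
    name: str = "popA",
    n_females: int = 25,
    n_males: int = 0,
    target_f: float = 0.0,
    n_sites: int = 10_000,
    seed: int = 0,
    contig_bp: int = 20_000_000,
    n_contigs: int = 2,
    invariant_per_variant: int = 0,
) -> SimConfig:
    """One-population cohort for parameter-recovery studies (F, FROH)."""
    return SimConfig(
        seed=seed,
        contigs=tuple(ContigSpec(f"chr{i+1}", contig_bp) for i in range(n_contigs)),
        populations=(
            PopulationSpec(
                name=name,
                n_females=n_females,
                n_males=n_males,
                target_f=target_f,
                roh_length_ranges=((500_000, 2_000_000),),
                roh_length_weights=(1.0,),
            ),
        ),
        class_sites={"MODIFIER": n_sites, "LOW": 0, "MODERATE": 0, "HIGH": 0},
        class_beta={"MODIFIER": (1.0, 3.0)},
        invariant_per_variant=invariant_per_variant,
    )


def scenario_presets(seed: int = 0) -> dict[str, SimConfig]:
    """Named study scenarios with documented expected directions.

    - ``three_species``: one inbred, purged population (``narw_like``,
      high F, long ROH, ρ and δ below one for damaging classes) next to two
      larger outbred ones (``srw_like``, ``bh_like``). Expected: Rxy(HIGH)
      of narw_like vs srw_like below 1 with Rxy(MODIFIER) near 1; inside-ROH
      homozygote proportions ordered MODIFIER > LOW > MODERATE > HIGH in
      narw_like; relative load lower in narw_like than srw_like.
    - ``rs_contrast``: a 5v5 female reproductive-success contrast with 10
      planted candidate sites (plus a modifier-class group-shift background
      giving the contrast a dominant PC axis) and two outside populations
      where the candidates are nearly absent.
    - ``null``: one outbred population, no group structure, for calibration.
    - ``roh_recovery``: a 50 Mb chromosome with 10 explicit tracts of
      1.2–5 Mb in one focal individual, het sites at ~1/kb outside.
    """
    narw_kw = dict(
        target_f=0.35,
        roh_length_ranges=((300_000, 1_000_000), (1_000_000, 2_500_000), (2_500_000, 6_000_000)),
        roh_length_weights=(0.45, 0.45, 0.10),
        rho={"MODERATE": 0.8, "HIGH": 0.6},
        delta={"LOW": 0.9, "MODERATE": 0.6, "HIGH": 0.3},
    )
    outbred_ranges = dict(
        roh_length_ranges=((200_000, 800_000), (800_000, 1_500_000)),
        roh_length_weights=(0.85, 0.15),
    )
    presets = {
        "three_species": SimConfig(
            seed=seed,
            contigs=(
                ContigSpec("chr1", 15_000_000),
                ContigSpec("chr2", 15_000_000),
                ContigSpec("chr3", 15_000_000),
                ContigSpec("chr4", 15_000_000),
                ContigSpec("chrX", 10_000_000, is_x=True),
            ),
            populations=(
                PopulationSpec("narw_like", n_females=10, n_males=2, **narw_kw),
                PopulationSpec("srw_like", n_females=5, n_males=5, target_f=0.05, **outbred_ranges),
                PopulationSpec("bh_like", n_females=4, n_males=8, target_f=0.18, **outbred_ranges),
            ),
        ),
        "rs_contrast": SimConfig(
            seed=seed,
            contigs=(
                ContigSpec("chr1", 10_000_000),
                ContigSpec("chr2", 10_000_000),
                ContigSpec("chr3", 10_000_000),
                ContigSpec("chr4", 10_000_000),
                ContigSpec("chrX", 5_000_000, is_x=True),
            ),
            populations=(
                PopulationSpec("narw_like", n_females=10, n_males=2, **{**narw_kw, "target_f": 0.2}),
                PopulationSpec("srw_like", n_females=3, n_males=3, target_f=0.05, **outbred_ranges),
                PopulationSpec("bh_like", n_females=2, n_males=4, target_f=0.15, **outbred_ranges),
            ),
            class_sites={"MODIFIER": 4500, "LOW": 2000, "MODERATE": 1500, "HIGH": 1000},
            invariant_per_variant=1,
            candidates=CandidatePlan(),
            shift=GroupShiftPlan(),
            rs_population="narw_like",
        ),
        "null": SimConfig(
            seed=seed,
            contigs=(
                ContigSpec("chr1", 10_000_000),
                ContigSpec("chr2", 10_000_000),
                ContigSpec("chrX", 5_000_000, is_x=True),
            ),
            populations=(PopulationSpec("nullpop", n_females=10),),
            class_sites={"MODIFIER": 4000, "LOW": 3000, "MODERATE": 2000, "HIGH": 1000},
            invariant_per_variant=1,
            rs_population="nullpop",
        ),
        "roh_recovery": SimConfig(
            seed=seed,
            contigs=(ContigSpec("chr1", 50_000_000),),
            populations=(PopulationSpec("popA", n_females=10),),
            class_sites={"MODIFIER": 50_000, "LOW": 0, "MODERATE": 0, "HIGH": 0},
            class_beta={"MODIFIER": (3.0, 2.0)},
            invariant_per_variant=0,
            explicit_roh={
                "popA_f00": [
                    ("chr1", 1_000_000, 2_200_000),
                    ("chr1", 3_200_000, 4_700_000),
                    ("chr1", 5_900_000, 7_700_000),
                    ("chr1", 8_900_000, 11_100_000),
                    ("chr1", 12_300_000, 14_900_000),
                    ("chr1", 16_100_000, 19_100_000),
                    ("chr1", 20_400_000, 23_800_000),
                    ("chr1", 25_000_000, 28_900_000),
                    ("chr1", 30_200_000, 34_600_000),
                    ("chr1", 36_000_000, 41_000_000),
                ]
            },
        ),
    }
    for name in ("narw_like", "srw_like", "bh_like"):
        spec3 = presets["three_species"]
        pop = next(p for p in spec3.populations if p.name == name)
        presets[name] = replace(
            spec3,
            contigs=(
                ContigSpec("chr1", 15_000_000),
                ContigSpec("chr2", 15_000_000),
                ContigSpec("chrX", 10_000_000, is_x=True),
            ),
            populations=(pop,),
        )
    return presets
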