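"""Runs of homozygosity: two-state HMM caller and Table-style summaries.

The caller is a self-contained Viterbi decoder over hard genotype calls — the
two hidden states are autozygous and non-autozygous. In the autozygous state a
heterozygote can only arise by genotyping error (probability ``epsilon``); in
the non-autozygous state heterozygotes occur at the Hardy–Weinberg rate
2p(1−p) given the empirical population allele frequency p at the site.
Transitions decay with physical distance, 1 − exp(−rate · d), with no genetic
map. Contiguous autozygous stretches become half-open intervals; short runs
below ``min_bp`` are discarded.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .model import AnnotatedCohort, CohortError, GenomeSpec

ROH_COLUMNS = ["sample_id", "contig", "start", "end"]

#: Length bins of the ROH summary, in bp: <1 Mb, 1–2.5 Mb, >2.5 Mb (with the
#: >5 Mb sub-bin of the last, flagging recent inbreeding).
BIN_SHORT = 1_000_000
BIN_LONG = 2_500_000
BIN_RECENT = 5_000_000


@dataclass
class ROHSet:
    """Per-sample autozygous intervals (0-based half-open)."""

    intervals: pd.DataFrame

    def __post_init__(self) -> None:
        if len(self.intervals) == 0:
            self.intervals = pd.DataFrame(columns=ROH_COLUMNS)
        missing = set(ROH_COLUMNS) - set(self.intervals.columns)
        if missing:
            raise CohortError(f"ROH intervals missing columns: {sorted(missing)}")
        self.intervals = self.intervals[ROH_COLUMNS].reset_index(drop=True)
        if len(self.intervals):
            if (self.intervals["end"] <= self.intervals["start"]).any():
                raise CohortError("ROH interval with end <= start")
            for (sid, contig), grp in self.intervals.groupby(["sample_id", "contig"], sort=False):
                arr = grp[["start", "end"]].sort_values("start").to_numpy()
                if (arr[1:, 0] < arr[:-1, 1]).any():
                    raise CohortError(f"overlapping ROH for sample {sid} on {contig}")

    @property
    def sample_ids(self) -> list[str]:
        return sorted(self.intervals["sample_id"].unique())

    def for_sample(self, sample_id: str) -> pd.DataFrame:
        return self.intervals[self.intervals["sample_id"] == sample_id]

    def lengths(self) -> np.ndarray:
        return (self.intervals["end"] - self.intervals["start"]).to_numpy()

    @staticmethod
    def concat(parts: list["ROHSet"]) -> "ROHSet":
        frames = [p.intervals for p in parts if len(p.intervals)]
        if not frames:
            return ROHSet(pd.DataFrame(columns=ROH_COLUMNS))
        return ROHSet(pd.concat(frames, ignore_index=True))


# ---------------------------------------------------------------------------
# HMM caller
# ---------------------------------------------------------------------------

def _viterbi_autozygosity(
    pos: np.ndarray, het: np.ndarray, p: np.ndarray, epsilon: float, rate: float
) -> np.ndarray:
    """Viterbi path over one contig; returns boolean autozygous state per site."""
    n = len(pos)
    hw_het = np.clip(2 * p * (1 - p), 1e-12, 1 - 1e-12)
    # emission log-probs per site for [non-autozygous, autozygous]
    log_e = np.where(
        het[:, None],
        np.stack([np.log(hw_het), np.full(n, np.log(epsilon))], axis=1),
        np.stack([np.log1p(-hw_het), np.full(n, np.log1p(-epsilon))], axis=1),
    )
    d = np.diff(pos).astype(np.float64)
    log_stay = -rate * d
    log_switch = np.log(-np.expm1(-rate * d))

    back = np.zeros((n, 2), dtype=np.int8)
    v = np.log(0.5) + log_e[0]
    for i in range(1, n):
        stay, sw = log_stay[i - 1], log_switch[i - 1]
        cand0 = (v[0] + stay, v[1] + sw)
        cand1 = (v[0] + sw, v[1] + stay)
        b0 = int(cand0[1] > cand0[0])
        b1 = int(cand1[1] > cand1[0])
        v = np.array([cand0[b0] + log_e[i, 0], cand1[b1] + log_e[i, 1]])
        back[i, 0], back[i, 1] = b0, b1
    state = np.empty(n, dtype=np.int8)
    state[-1] = int(v[1] > v[0])
    for i in range(n - 1, 0, -1):
        state[i - 1] = back[i, state[i]]
    return state.astype(bool)


def call_roh(
    cohort: AnnotatedCohort,
    sample_id: str,
    epsilon: float = 1e-3,
    rate: float = 1e-8,
    min_bp: int = 100_000,
    freq_source: str = "population",
) -> ROHSet:
    """Call ROH for one individual across every contig it has calls on.

    Sites used are variants polymorphic in the frequency source (the sample's
    own population by default, or the pooled cohort) at which the individual
    is called. ``min_bp`` drops short runs after decoding.
    """
    if freq_source not in ("population", "pooled"):
        raise CohortError(f"freq_source must be population|pooled, got {freq_source!r}")
    col = cohort.sample_index(sample_id)
    if freq_source == "population":
        pop = cohort.samples.loc[col, "population"]
        cols = cohort.population_columns(str(pop))
    else:
        cols = None
    ac, an = cohort.allele_counts(cols)
    variant = cohort.sites["is_variant"].to_numpy()
    usable = variant & (ac > 0) & (ac < an) & (cohort.gt[:, col] >= 0)

    contigs = cohort.sites["contig"].to_numpy()
    pos_all = cohort.sites["pos"].to_numpy()
    out = []
    for contig in cohort.genome.contigs:
        rows = np.flatnonzero((contigs == contig) & usable)
        if len(rows) < 2:
            continue
        pos = pos_all[rows]
        het = cohort.gt[rows, col] == 1
        p = ac[rows] / an[rows]
        state = _viterbi_autozygosity(pos, het, p, epsilon, rate)
        for s, e in _runs(state):
            start, end = int(pos[s] - 1), int(pos[e - 1])
            if end - start >= min_bp:
                out.append((sample_id, contig, start, end))
    return ROHSet(pd.DataFrame(out, columns=ROH_COLUMNS))


def call_roh_all(cohort: AnnotatedCohort, **kwargs) -> ROHSet:
    """Call ROH for every sample in the cohort; see :func:`call_roh`."""
    return ROHSet.concat([call_roh(cohort, sid, **kwargs) for sid in cohort.sample_ids])


def _runs(state: np.ndarray):
    """Yield (start, stop) index pairs of True runs (half-open)."""
    edges = np.flatnonzero(np.diff(np.r_[0, state.astype(np.int8), 0]))
    for s, e in zip(edges[::2], edges[1::2]):
        yield int(s), int(e)


# ---------------------------------------------------------------------------
# summaries
# ---------------------------------------------------------------------------

def summarize_roh(
    rohs: ROHSet,
    genome: GenomeSpec,
    region: str,
    sample_ids: list[str] | None = None,
) -> pd.DataFrame:
    """Per-sample ROH summary for one genomic region.

    Columns mirror the usual reporting convention: counts in the three
    mutually exclusive length bins (<1 Mb, 1–2.5 Mb, >2.5 Mb, which sum to
    NROH), the >5 Mb sub-count of the last bin, mean length, SROH and
    FROH = SROH / region length (the region length always comes from the
    genome spec). Samples without any ROH report NROH = 0 and NaN mean length.
    """
    region_contigs = set(genome.region_contigs(region))
    sub = rohs.intervals[rohs.intervals["contig"].isin(region_contigs)]
    length_total = genome.region_length(region)
    if sample_ids is None:
        sample_ids = rohs.sample_ids
    rows = []
    for sid in sample_ids:
        lens = (sub.loc[sub["sample_id"] == sid, "end"] - sub.loc[sub["sample_id"] == sid, "start"]).to_numpy()
        nroh = len(lens)
        sroh = int(lens.sum())
        rows.append(
            {
                "sample_id": sid,
                "region": region,
                "n_lt_1mb": int((lens < BIN_SHORT).sum()),
                "n_1_to_2.5mb": int(((lens >= BIN_SHORT) & (lens <= BIN_LONG)).sum()),
                "n_gt_2.5mb": int((lens > BIN_LONG).sum()),
                "n_gt_5mb": int((lens > BIN_RECENT).sum()),
                "nroh": nroh,
                "mean_lroh": float(lens.mean()) if nroh else float("nan"),
                "sroh": sroh,
                "froh": sroh / length_total,
            }
        )
    return pd.DataFrame(rows)


def population_roh_means(summary: pd.DataFrame, samples: pd.DataFrame) -> pd.DataFrame:
    """Average the per-sample summary within populations (Table-style rows)."""
    merged = summary.merge(samples[["sample_id", "population"]], on="sample_id")
    value_cols = [c for c in summary.columns if c not in ("sample_id", "region")]
    return (
        merged.groupby(["population", "region"], sort=False)[value_cols]
        .mean()
        .reset_index()
    )
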