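"""Bayesian linear effect models for cohort-level summaries.

Estimates the effects of categorical predictors (species/population, genomic
region, impact class) on a z-standardized response (π, F, a load), with
standard-normal priors on all coefficients and a half-normal(0, 1) prior on
the residual standard deviation. Sampling is a blocked scheme: the
coefficient vector is conjugate given σ and is Gibbs-sampled exactly; log σ
moves by random-walk Metropolis. Convergence is monitored with the
split-chain R-hat.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .model import CohortError


@dataclass
class EffectModelSpec:
    response: str
    predictors: list[str]
    reference_levels: dict[str, str] = field(default_factory=dict)
    chains: int = 3
    iterations: int = 10_000
    warmup: int = 1_000
    prior_sd: float = 1.0
    sigma_prior_sd: float = 1.0
    proposal_sd: float = 0.15


def design_matrix(data: pd.DataFrame, spec: EffectModelSpec) -> tuple[np.ndarray, list[str]]:
    """Intercept + treatment-coded dummies, with declared reference levels.

    Raises on a rank-deficient design, naming the aliased columns.
    """
    cols = [np.ones(len(data))]
    names = ["intercept"]
    for pred in spec.predictors:
        if pred not in data.columns:
            raise CohortError(f"predictor {pred!r} not in data")
        levels = list(pd.unique(data[pred].astype(str)))
        ref = spec.reference_levels.get(pred, levels[0])
        if ref not in levels:
            raise CohortError(f"reference level {ref!r} not found for {pred!r}")
        for lvl in levels:
            if lvl == ref:
                continue
            counts = (data[pred].astype(str) == lvl).sum()
            if counts < 2:
                raise CohortError(f"level {pred}={lvl} has {counts} observation(s); need >= 2")
            cols.append((data[pred].astype(str) == lvl).to_numpy(float))
            names.append(f"{pred}[{lvl}]")
    x = np.column_stack(cols)
    rank = np.linalg.matrix_rank(x)
    if rank < x.shape[1]:
        # greedily identify a maximal independent set; the rest are aliased
        keep: list[int] = []
        for j in range(x.shape[1]):
            trial = keep + [j]
            if np.linalg.matrix_rank(x[:, trial]) == len(trial):
                keep.append(j)
        aliased = [names[j] for j in range(x.shape[1]) if j not in keep]
        raise CohortError(f"non-identifiable design; aliased columns: {aliased}")
    return x, names


def _split_rhat(draws: np.ndarray) -> float:
    """Split-chain potential scale reduction for one parameter.

    ``draws`` has shape (chains, iterations); each chain is split in half
    before the classic between/within variance comparison.
    """
    c, n = draws.shape
    half = n // 2
    chains = np.concatenate([draws[:, :half], draws[:, half : 2 * half]], axis=0)
    m, n2 = chains.shape
    means = chains.mean(axis=1)
    w = chains.var(axis=1, ddof=1).mean()
    b = n2 * means.var(ddof=1)
    if w == 0:
        return 1.0
    var_plus = (n2 - 1) / n2 * w + b / n2
    return float(np.sqrt(var_plus / w))


def fit_effect_model(
    spec: EffectModelSpec,
    data: pd.DataFrame,
    seed: int = 0,
    fixed_sigma: float | None = None,
) -> dict:
    """Fit y_z = Xβ + ε, ε ~ N(0, σ²), β ~ N(0, prior_sd²), σ ~ half-N(0,1).

    The response is z-standardized before fitting. Each chain gets an
    independent stream derived from ``seed`` and its chain index. Returns a
    dict with the posterior ``summary`` frame (mean, sd, central 95%
    interval, split R-hat per coefficient and for σ) and the raw ``draws``.

    ``fixed_sigma`` freezes the residual scale (conjugate normal-normal
    case, used for closed-form validation).
    """
    y_raw = data[spec.response].to_numpy(float)
    if np.isnan(y_raw).any():
        raise CohortError(f"response {spec.response!r} contains NaN")
    sd = y_raw.std(ddof=0)
    y = (y_raw - y_raw.mean()) / sd if sd > 0 else y_raw - y_raw.mean()
    x, names = design_matrix(data, spec)
    n, p = x.shape
    xtx = x.T @ x
    xty = x.T @ y
    prior_prec = np.eye(p) / spec.prior_sd**2

    n_keep = spec.iterations - spec.warmup
    if n_keep <= 1:
        raise CohortError("iterations must exceed warmup by at least 2")
    beta_draws = np.empty((spec.chains, n_keep, p))
    sigma_draws = np.empty((spec.chains, n_keep))
    accept = 0
    total = 0

    for chain in range(spec.chains):
        rng = np.random.default_rng((seed, chain))
        beta = np.zeros(p)
        log_sigma = 0.0 if fixed_sigma is None else float(np.log(fixed_sigma))
        for it in range(spec.iterations):
            sigma2 = np.exp(2 * log_sigma)
            prec = xtx / sigma2 + prior_prec
            chol = np.linalg.cholesky(prec)
            mean = np.linalg.solve(prec, xty / sigma2)
            z = rng.standard_normal(p)
            beta = mean + np.linalg.solve(chol.T, z)
            if fixed_sigma is None:
                resid = y - x @ beta
                rss = float(resid @ resid)

                def log_post(ls: float) -> float:
                    s2 = np.exp(2 * ls)
                    # likelihood + half-normal prior on sigma + log-Jacobian
                    return (
                        -n * ls
                        - rss / (2 * s2)
                        - np.exp(2 * ls) / (2 * spec.sigma_prior_sd**2)
                        + ls
                    )

                prop = log_sigma + spec.proposal_sd * rng.standard_normal()
                total += 1
                if np.log(rng.uniform()) < log_post(prop) - log_post(log_sigma):
                    log_sigma = prop
                    accept += 1
            if it >= spec.warmup:
                beta_draws[chain, it - spec.warmup] = beta
                sigma_draws[chain, it - spec.warmup] = np.exp(log_sigma)

    rows = []
    for j, name in enumerate(names):
        d = beta_draws[:, :, j]
        rows.append(_summary_row(name, d))
    rows.append(_summary_row("sigma", sigma_draws))
    summary = pd.DataFrame(rows)
    return {
        "summary": summary,
        "draws": {"beta": beta_draws, "sigma": sigma_draws, "names": names},
        "acceptance_rate": accept / total if total else float("nan"),
        "response_sd": float(sd),
    }


def _summary_row(name: str, draws: np.ndarray) -> dict:
    flat = draws.reshape(-1)
    lo, hi = np.quantile(flat, [0.025, 0.975])
    return {
        "term": name,
        "mean": float(flat.mean()),
        "sd": float(flat.std(ddof=1)),
        "q2.5": float(lo),
        "q97.5": float(hi),
        "rhat": _split_rhat(draws),
    }


def write_trace(result: dict, path) -> None:
    """Export draws as long-format TSV (chain, iteration, term, value)."""
    beta = result["draws"]["beta"]
    sigma = result["draws"]["sigma"]
    names = result["draws"]["names"]
    c, n, p = beta.shape
    frames = []
    for j, name in enumerate(names):
        frames.append(
            pd.DataFrame(
                {
                    "chain": np.repeat(np.arange(c), n),
                    "iteration": np.tile(np.arange(n), c),
                    "term": name,
                    "value": beta[:, :, j].reshape(-1),
                }
            )
        )
    frames.append(
        pd.DataFrame(
            {
                "chain": np.repeat(np.arange(c), n),
                "iteration": np.tile(np.arange(n), c),
                "term": "sigma",
                "value": sigma.reshape(-1),
            }
        )
    )
    pd.concat(frames, ignore_index=True).to_csv(path, sep="\t", index=False)
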