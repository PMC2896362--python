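"""Empirical-Bayes MCMC estimation of a differential-expression ratio.

Densitometry replicates from a western blot are normalized to a loading
control; the per-replicate log10 ratio between conditions,
y_i = log10(x_A,i) - log10(x_B,i), follows the model
log10(X_A) = R + log10(X_B) with Normal(0, sigma^2) replicate noise.
R and log(sigma) are sampled by random-walk Metropolis with flat priors;
the zero-mean Gaussian proposal is scaled during burn-in to a 0.4
acceptance fraction, convergence of three independent chains is judged by
the Gelman-Rubin potential scale reduction factor, and the posterior
summary (mean, median, credible interval, P(R <= 0) and the 10^R fold
estimate) pools the post-burn-in tails of the converged chains.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

TARGET_ACCEPTANCE = 0.4
PSRF_THRESHOLD = 1.1
SIGMA_FLOOR = 1e-6
ADAPT_BLOCK = 100
ADAPT_FACTOR = 1.1


class ConvergenceError(RuntimeError):
    """Raised when chains have not converged (PSRF above threshold)."""

    def __init__(self, psrf: float, threshold: float) -> None:
        super().__init__(f"PSRF {psrf:.4f} exceeds threshold {threshold}")
        self.psrf = psrf


@dataclass
class DensitometrySet:
    """Loading-normalized replicate log-ratios for one target protein."""

    y: np.ndarray               # per-replicate log10(x_A) - log10(x_B)
    x_a: np.ndarray             # target/loading in condition A
    x_b: np.ndarray             # target/loading in condition B

    @property
    def n(self) -> int:
        return len(self.y)


@dataclass
class ChainSet:
    """Three post-burn-in chains of (R, log sigma) with diagnostics."""

    r_chains: np.ndarray        # (n_chains, n_kept)
    log_sigma_chains: np.ndarray
    n_burn: int
    proposal_scales: np.ndarray
    acceptance: float           # pooled post-burn-in acceptance fraction
    psrf_r: float
    psrf_log_sigma: float


@dataclass
class PosteriorSummary:
    mean: float
    median: float
    ci_low: float
    ci_high: float
    ci_level: float
    p_r_le_0: float
    fold: float                 # 10**posterior-mean R
    n_samples: int
    psrf: float


def normalize_blots(raw: pd.DataFrame) -> DensitometrySet:
    """Normalize band densities to the loading control.

    Expects columns ``replicate, condition, target_density,
    loading_density`` with conditions A and B paired by replicate.  Each
    lane's normalized level is target/loading; replicate log-ratios are
    log10(x_A) - log10(x_B).
    """
    for col in ("target_density", "loading_density"):
        bad = raw[raw[col] <= 0]
        if not bad.empty:
            lane = bad.iloc[0]
            raise ValueError(
                f"non-positive {col} in replicate {lane['replicate']} "
                f"condition {lane['condition']}")
    wide = raw.pivot(index="replicate", columns="condition",
                     values=["target_density", "loading_density"])
    if wide.isna().any().any():
        raise ValueError("every replicate needs both conditions A and B")
    x_a = (wide[("target_density", "A")] /
           wide[("loading_density", "A")]).to_numpy(float)
    x_b = (wide[("target_density", "B")] /
           wide[("loading_density", "B")]).to_numpy(float)
    return DensitometrySet(y=np.log10(x_a) - np.log10(x_b), x_a=x_a, x_b=x_b)


def _log_posterior(r: float, log_sigma: float, y: np.ndarray) -> float:
    """Gaussian likelihood, flat priors on R and log sigma."""
    sigma = np.exp(log_sigma)
    return float(-len(y) * log_sigma
                 - np.sum((y - r) ** 2) / (2.0 * sigma ** 2))


def _run_chain(y: np.ndarray, n_iter: int, n_burn: int,
               target_acceptance: float, seed: int,
               start: tuple[float, float], scale0: float
               ) -> tuple[np.ndarray, np.ndarray, int, float]:
    rng = np.random.default_rng(seed)
    r, ls = start
    lp = _log_posterior(r, ls, y)
    scale = scale0
    kept_r = np.empty(n_iter - n_burn)
    kept_ls = np.empty(n_iter - n_burn)
    accepted_post = 0
    block_accepted = 0
    log_floor = np.log(SIGMA_FLOOR)
    for it in range(n_iter):
        pr = r + scale * rng.standard_normal()
        pls = ls + scale * rng.standard_normal()
        if pls < log_floor:
            accept = False
        else:
            plp = _log_posterior(pr, pls, y)
            accept = np.log(rng.random()) < plp - lp
        if accept:
            r, ls, lp = pr, pls, plp
        if it < n_burn:
            block_accepted += accept
            # retune the random-walk scale once per block, burn-in only
            if (it + 1) % ADAPT_BLOCK == 0:
                frac = block_accepted / ADAPT_BLOCK
                if frac > target_acceptance:
                    scale *= ADAPT_FACTOR
                elif frac < target_acceptance:
                    scale /= ADAPT_FACTOR
                block_accepted = 0
        else:
            accepted_post += accept
            kept_r[it - n_burn] = r
            kept_ls[it - n_burn] = ls
    return kept_r, kept_ls, accepted_post, scale


def run_mcmc(data: DensitometrySet | np.ndarray, n_iter: int = 15000,
             n_burn: int = 5000,
             target_acceptance: float = TARGET_ACCEPTANCE,
             seeds: tuple[int, int, int] = (1, 2, 3)) -> ChainSet:
    """Random-walk Metropolis on (R, log sigma) for three chains.

    ``n_iter`` counts total iterations per chain, of which the first
    ``n_burn`` are burn-in.  During burn-in the proposal scale is
    multiplied or divided by 1.1 after every 100-iteration block
    according to whether the block's acceptance exceeded or fell short of
    ``target_acceptance``; the scale is frozen afterwards so the retained
    chain is Markovian.  Chains start overdispersed at the sample mean
    and mean +/- 2 sample standard deviations.
    """
    y = data.y if isinstance(data, DensitometrySet) else \
        np.asarray(data, dtype=float)
    if len(y) < 2:
        raise ValueError("need >= 2 replicates (sigma is unidentifiable)")
    if not 0 <= n_burn < n_iter:
        raise ValueError("require n_iter > n_burn >= 0")
    sd = max(float(np.std(y, ddof=1)), SIGMA_FLOOR)
    start_ls = float(np.log(sd))
    offsets = (-2.0, 0.0, 2.0)
    rs, lss, scales = [], [], []
    accepted = 0
    for seed, off in zip(seeds, offsets):
        start = (float(np.mean(y)) + off * sd, start_ls)
        kr, kls, acc, scale = _run_chain(
            y, n_iter, n_burn, target_acceptance, seed, start, scale0=sd)
        rs.append(kr)
        lss.append(kls)
        scales.append(scale)
        accepted += acc
    r_chains = np.vstack(rs)
    ls_chains = np.vstack(lss)
    n_kept = n_iter - n_burn
    return ChainSet(
        r_chains=r_chains, log_sigma_chains=ls_chains, n_burn=n_burn,
        proposal_scales=np.array(scales),
        acceptance=accepted / (len(seeds) * n_kept),
        psrf_r=gelman_rubin(r_chains),
        psrf_log_sigma=gelman_rubin(ls_chains))


def gelman_rubin(chains: np.ndarray) -> float:
    """Gelman-Rubin potential scale reduction factor for one parameter.

    With m chains of length n: W is the mean within-chain variance, B/n
    the variance of the chain means, var+ = (n-1)/n * W + B/n, and
    PSRF = sqrt(var+ / W).  Identical chains give sqrt((n-1)/n); zero
    within-chain variance with separated chains gives +inf.
    """
    chains = np.asarray(chains, dtype=float)
    if chains.ndim != 2 or chains.shape[0] < 2 or chains.shape[1] < 2:
        raise ValueError("need >= 2 chains of equal length >= 2")
    n = chains.shape[1]
    w = float(np.mean(np.var(chains, axis=1, ddof=1)))
    b_over_n = float(np.var(np.mean(chains, axis=1), ddof=1))
    if w == 0.0:
        return 1.0 if b_over_n == 0.0 else float("inf")
    var_plus = (n - 1) / n * w + b_over_n
    return float(np.sqrt(var_plus / w))


def summarize_posterior(chains: ChainSet,
                        psrf_threshold: float = PSRF_THRESHOLD,
                        ci_level: float = 0.95) -> PosteriorSummary:
    """Posterior summary of R from the pooled post-burn-in tails.

    Refuses to summarize when the R chains have not converged (PSRF at or
    above ``psrf_threshold``).  P(R <= 0) is the empirical posterior tail
    probability reported as the significance measure for an up-in-A
    claim; when no pooled sample falls at or below zero it is bounded
    above by 1/(pooled n).
    """
    if not chains.psrf_r < psrf_threshold:
        raise ConvergenceError(chains.psrf_r, psrf_threshold)
    pooled = chains.r_chains.ravel()
    alpha = 1.0 - ci_level
    lo, hi = np.quantile(pooled, [alpha / 2, 1.0 - alpha / 2])
    mean = float(np.mean(pooled))
    return PosteriorSummary(
        mean=mean, median=float(np.median(pooled)),
        ci_low=float(lo), ci_high=float(hi), ci_level=ci_level,
        p_r_le_0=float(np.mean(pooled <= 0.0)),
        fold=float(10.0 ** mean), n_samples=pooled.size,
        psrf=chains.psrf_r)
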