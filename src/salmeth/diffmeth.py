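"""Smoothed beta-binomial two-group differential methylation testing.

The model: methylated read counts at a CpG are beta-binomial, with a
group-specific mean methylation level mu and dispersion phi capturing
among-individual biological variance on top of binomial sampling.
Per-sample levels are first smoothed by pooling counts in a +/-250 bp
window (500 bp total), dispersion is estimated per site and group by a
weighted moment estimator with shrinkage toward a genome-wide value,
and the two groups are compared by a Wald statistic

    z = (mu1 - mu2) / sqrt(var(mu1) + var(mu2)),

with a two-sided p-value from the standard normal and Benjamini-Hochberg
FDR across all tested sites.

Because smoothing pools counts, the dispersion and variance formulas are
applied to the pooled fractions and pooled totals: phi is then an
effective dispersion of the smoothed estimator, and the Wald variance
tracks the true sampling variance whether CpGs are isolated or dense.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io import MethylationMatrix

__all__ = [
    "SmoothedCounts",
    "GroupEstimates",
    "smooth_methylation",
    "estimate_group_dispersion",
    "dmc_wald_test",
    "bh_fdr",
    "two_group_contrast",
]

MU_CLAMP = 1e-5
PHI_FLOOR = 1e-4
PHI_CEIL = 0.9


@dataclass
class SmoothedCounts:
    """Window-pooled counts per site per sample (smoothing output)."""

    chrom: np.ndarray
    pos: np.ndarray
    samples: list[str]
    meth: np.ndarray   # pooled methylated reads, sites x samples
    total: np.ndarray  # pooled total reads; 0 where a sample has no data

    def fraction(self) -> np.ndarray:
        """Smoothed methylation fraction; NaN where the window is empty."""
        with np.errstate(invalid="ignore", divide="ignore"):
            frac = np.where(self.total > 0, self.meth / np.where(self.total > 0, self.total, 1.0), np.nan)
        return frac


@dataclass
class GroupEstimates:
    """Per-site group-level estimates: mean, dispersion, estimator variance."""

    mu: np.ndarray       # weighted group mean in [0, 1]; NaN if no data
    phi: np.ndarray      # shrunken effective dispersion in [PHI_FLOOR, PHI_CEIL]
    var_mu: np.ndarray   # variance of the group-mean estimator
    n_obs: np.ndarray    # samples with data at the site
    phi_global: float    # genome-wide trimmed-mean dispersion used for shrinkage


def smooth_methylation(m: MethylationMatrix, window_bp: int = 500) -> SmoothedCounts:
    """Pool counts per sample over a centred window of ``window_bp``.

    For each site the window is [pos - window_bp/2, pos + window_bp/2]
    on the same chromosome; missing cells contribute nothing. A site
    whose window contains only itself keeps its raw fraction.
    """
    if window_bp <= 0:
        raise ValueError("window_bp must be positive")
    half = window_bp / 2.0
    meth = np.nan_to_num(m.meth, nan=0.0)
    total = np.nan_to_num(m.total, nan=0.0)
    sm_meth = np.empty_like(meth)
    sm_total = np.empty_like(total)
    # process each chromosome with cumulative sums over position-sorted sites
    chroms = pd.unique(m.chrom)
    for c in chroms:
        idx = np.flatnonzero(m.chrom == c)
        pos = m.pos[idx].astype(float)
        cm = np.vstack([np.zeros(meth.shape[1]), np.cumsum(meth[idx], axis=0)])
        ct = np.vstack([np.zeros(total.shape[1]), np.cumsum(total[idx], axis=0)])
        lo = np.searchsorted(pos, pos - half, side="left")
        hi = np.searchsorted(pos, pos + half, side="right")
        sm_meth[idx] = cm[hi] - cm[lo]
        sm_total[idx] = ct[hi] - ct[lo]
    return SmoothedCounts(m.chrom, m.pos, list(m.samples), sm_meth, sm_total)


def _kleinman_phi(frac: np.ndarray, weights: np.ndarray) -> np.ndarray:
    """Weighted moment estimator of beta-binomial dispersion, per site.

    With weights w_i (pooled read totals), W = sum w_i, weighted mean
    p-bar and S = sum w_i (p_i - p-bar)^2:

        phi = (S / (p-bar(1-p-bar)) - (m-1)) / (W - sum(w_i^2)/W - (m-1))

    Sites with fewer than two observed samples or a degenerate
    denominator yield NaN (resolved by shrinkage to the global value).
    """
    obs = weights > 0
    mcount = obs.sum(axis=1)
    W = weights.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        pbar = np.where(W > 0, (weights * np.nan_to_num(frac)).sum(axis=1) / np.where(W > 0, W, 1), np.nan)
        dev2 = np.where(obs, (np.nan_to_num(frac) - pbar[:, None]) ** 2, 0.0)
        S = (weights * dev2).sum(axis=1)
        pq = np.clip(pbar, MU_CLAMP, 1 - MU_CLAMP)
        pq = pq * (1 - pq)
        denom = W - (weights**2).sum(axis=1) / np.where(W > 0, W, 1) - (mcount - 1)
        phi = (S / pq - (mcount - 1)) / denom
    phi[(mcount < 2) | (denom <= 0)] = np.nan
    return phi


def estimate_group_dispersion(
    smoothed: SmoothedCounts,
    sample_idx: np.ndarray,
    m0: float = 20.0,
    trim: float = 0.1,
) -> GroupEstimates:
    """Estimate mu, phi and var(mu) for one group of sample columns.

    mu is the coverage-weighted mean of smoothed per-sample fractions.
    phi comes from the weighted moment estimator, shrunk toward the
    genome-wide ``trim``-trimmed mean with weight m/(m + m0), then
    clamped to [1e-4, 0.9]. The group-mean variance is

        var(mu) = sum_i N_i mu(1-mu) (1 + (N_i - 1) phi) / (sum_i N_i)^2

    over that group's samples, with mu clamped away from 0/1 so that
    boundary sites keep a nonzero variance.
    """
    w = smoothed.total[:, sample_idx]
    frac = smoothed.fraction()[:, sample_idx]
    n_obs = (w > 0).sum(axis=1)
    W = w.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        mu = (w * np.nan_to_num(frac)).sum(axis=1) / np.where(W > 0, W, 1)
    mu = np.where(W > 0, mu, np.nan)

    phi_raw = _kleinman_phi(frac, w)
    usable = np.isfinite(phi_raw)
    if usable.sum() >= 10:
        phi_global = float(
            stats.trim_mean(np.clip(phi_raw[usable], PHI_FLOOR, PHI_CEIL), trim)
        )
    else:
        phi_global = 0.1  # fall-back prior when almost nothing is estimable
    phi_global = float(np.clip(phi_global, PHI_FLOOR, PHI_CEIL))

    filled = np.where(usable, phi_raw, phi_global)
    phi = (n_obs * filled + m0 * phi_global) / (n_obs + m0)
    phi = np.clip(phi, PHI_FLOOR, PHI_CEIL)

    mu_c = np.clip(mu, MU_CLAMP, 1 - MU_CLAMP)
    with np.errstate(invalid="ignore", divide="ignore"):
        var_terms = w * (mu_c * (1 - mu_c))[:, None] * (1 + (w - 1) * phi[:, None])
        var_mu = np.where(w > 0, var_terms, 0.0).sum(axis=1) / np.where(W > 0, W, 1) ** 2
    var_mu = np.where(W > 0, var_mu, np.nan)
    return GroupEstimates(mu, phi, var_mu, n_obs, phi_global)


def dmc_wald_test(
    est1: GroupEstimates,
    est2: GroupEstimates,
    chrom: np.ndarray,
    pos: np.ndarray,
) -> pd.DataFrame:
    """Per-site Wald test between two groups.

    Returns a frame with one row per site testable in both groups
    (chrom, pos, mu1, mu2, diff, stat, pval); diff = mu1 - mu2 so a
    negative value means hypo-methylation in group 1.
    """
    testable = (est1.n_obs >= 1) & (est2.n_obs >= 1)
    var_sum = est1.var_mu + est2.var_mu
    if np.any(testable & ~(var_sum > 0)):
        raise RuntimeError("zero variance at a testable site despite clamping")
    diff = est1.mu - est2.mu
    with np.errstate(invalid="ignore", divide="ignore"):
        stat = diff / np.sqrt(var_sum)
    pval = 2.0 * stats.norm.sf(np.abs(stat))
    return pd.DataFrame(
        {
            "chrom": chrom[testable],
            "pos": pos[testable],
            "mu1": est1.mu[testable],
            "mu2": est2.mu[testable],
            "diff": diff[testable],
            "stat": stat[testable],
            "pval": pval[testable],
        }
    ).reset_index(drop=True)


def bh_fdr(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, in input order."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if np.any(~np.isfinite(p)) or np.any(p < 0) or np.any(p > 1):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def two_group_contrast(
    m: MethylationMatrix,
    group_of: dict[str, str],
    group1: str,
    group2: str,
    window_bp: int = 500,
    m0: float = 20.0,
) -> pd.DataFrame:
    """Full per-CpG contrast: smooth, estimate, Wald-test, BH-adjust.

    ``group_of`` maps sample id to group label; ``group1`` is the focal
    group (negative diff = hypo-methylated in group1).
    """
    idx1 = np.array([i for i, s in enumerate(m.samples) if group_of.get(s) == group1])
    idx2 = np.array([i for i, s in enumerate(m.samples) if group_of.get(s) == group2])
    if idx1.size == 0 or idx2.size == 0:
        raise ValueError(f"no samples found for groups {group1!r} / {group2!r}")
    sm = smooth_methylation(m, window_bp=window_bp)
    est1 = estimate_group_dispersion(sm, idx1, m0=m0)
    est2 = estimate_group_dispersion(sm, idx2, m0=m0)
    dmc = dmc_wald_test(est1, est2, m.chrom, m.pos)
    dmc["fdr"] = bh_fdr(dmc["pval"].to_numpy())
    return dmc
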