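"""Window-level co-methylation network analysis.

Methylation is summarized in non-overlapping 100-bp windows (pooled
counts over member CpGs), low-information windows are filtered out
(fewer than three CpGs, or among-sample variance at or below 0.05), and
a weighted network is built from the biweight midcorrelation raised to a
soft-threshold power (18 by default, approximating scale-free topology).
Modules of co-varying windows are found by average-linkage hierarchical
clustering of the topological overlap dissimilarity with a static tree
cut plus eigenvector-based module merging; each module is summarized by
its eigenvector (first principal-component sample scores), which is then
correlated with phenotypes. Module cores are tested for enrichment of
DMR-overlapping windows by resampling, and module membership (MM) /
gene significance (GS) are compared between DMR-overlapping and
non-overlapping windows with Welch t-tests.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .dmr import OverlapResult
from .io import GenomicInterval, MethylationMatrix

__all__ = [
    "WindowMatrix",
    "ModuleSet",
    "summarize_windows",
    "bicor",
    "bicor_matrix",
    "adjacency_and_tom",
    "detect_modules",
    "build_network",
    "module_eigenvectors",
    "trait_association",
    "module_dmr_enrichment",
    "mm_gs_comparison",
]

_TINY_P = np.nextafter(0.0, 1.0)


@dataclass
class WindowMatrix:
    """Mean methylation per 100-bp window (rows) per sample (columns)."""

    windows: list[GenomicInterval]
    values: np.ndarray          # fractions in [0, 1]; NaN where no data
    n_cpg: np.ndarray
    samples: list[str]

    @property
    def n_windows(self) -> int:
        return len(self.windows)


@dataclass
class ModuleSet:
    """Module labels, eigenvectors and membership for a window set."""

    labels: np.ndarray                       # 0 = unassigned
    eigenvectors: dict[int, np.ndarray]      # module -> per-sample scores, unit norm
    mm: np.ndarray                           # |cor(window, module eigenvector)|
    samples: list[str]
    merged_from: list[str] = field(default_factory=list)

    def module_ids(self) -> list[int]:
        return sorted(k for k in set(self.labels.tolist()) if k != 0)


def summarize_windows(
    m: MethylationMatrix,
    window_bp: int = 100,
    min_cpg: int = 3,
    min_var: float = 0.05,
) -> WindowMatrix:
    """Pool CpG counts into tiled windows and apply the window filters.

    Window value per sample is sum(meth)/sum(total) over member CpGs.
    Windows with fewer than ``min_cpg`` CpGs, or with among-sample
    variance (ddof=1, NaN-aware) not exceeding ``min_var``, are dropped.
    """
    n = m.n_sites
    if n == 0:
        return WindowMatrix([], np.empty((0, m.n_samples)),
                            np.zeros(0, dtype=int), list(m.samples))
    meth = np.nan_to_num(m.meth, nan=0.0)
    total = np.nan_to_num(m.total, nan=0.0)
    # sites are (chrom, pos)-sorted, so windows are contiguous runs
    bins = m.pos // window_bp
    is_new = np.ones(n, dtype=bool)
    is_new[1:] = (m.chrom[1:] != m.chrom[:-1]) | (bins[1:] != bins[:-1])
    starts = np.flatnonzero(is_new)
    ncpg = np.diff(np.append(starts, n))
    sum_m = np.add.reduceat(meth, starts, axis=0)
    sum_t = np.add.reduceat(total, starts, axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        vals = np.where(sum_t > 0, sum_m / np.where(sum_t > 0, sum_t, 1), np.nan)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        variance = np.nanvar(vals, axis=1, ddof=1)
    keep = (
        (ncpg >= min_cpg)
        & ((~np.isnan(vals)).sum(axis=1) >= 2)
        & (variance > min_var)
    )
    windows: list[GenomicInterval] = []
    for i in np.flatnonzero(keep):
        chrom = str(m.chrom[starts[i]])
        w0 = int(bins[starts[i]]) * window_bp
        windows.append(GenomicInterval(chrom, w0, w0 + window_bp,
                                       name=f"{chrom}:{w0}"))
    return WindowMatrix(windows, vals[keep], ncpg[keep].astype(int),
                        list(m.samples))


def _bicor_transform(x: np.ndarray) -> np.ndarray:
    """Per-row robust standardization for biweight midcorrelation.

    Rows with zero MAD fall back to Pearson-style mean centering
    (the documented WGCNA convention). Returned rows have unit norm.
    """
    x = np.asarray(x, dtype=float)
    med = np.median(x, axis=1, keepdims=True)
    mad = np.median(np.abs(x - med), axis=1, keepdims=True)
    out = np.empty_like(x)
    robust = (mad > 0).ravel()
    if robust.any():
        u = (x[robust] - med[robust]) / (9.0 * mad[robust])
        w = (1 - u**2) ** 2 * (np.abs(u) < 1)
        out[robust] = (x[robust] - med[robust]) * w
    if (~robust).any():
        out[~robust] = x[~robust] - x[~robust].mean(axis=1, keepdims=True)
    norms = np.linalg.norm(out, axis=1, keepdims=True)
    degenerate = (norms == 0).ravel()
    if degenerate.any():
        # constant rows: correlation undefined; return zero contribution
        norms[degenerate] = 1.0
    return out / norms


def bicor(x, y) -> float:
    """Biweight midcorrelation of two vectors (tuning constant 9 MADs)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 3:
        raise ValueError("bicor needs two equal-length vectors of >= 3 samples")
    t = _bicor_transform(np.vstack([x, y]))
    return float(np.clip(t[0] @ t[1], -1.0, 1.0))


def bicor_matrix(values: np.ndarray) -> np.ndarray:
    """All-pairs biweight midcorrelation of the rows of ``values``."""
    values = np.asarray(values, dtype=float)
    if values.ndim != 2 or values.shape[1] < 3:
        raise ValueError("need a 2-D matrix with at least 3 samples")
    t = _bicor_transform(values)
    c = np.clip(t @ t.T, -1.0, 1.0)
    np.fill_diagonal(c, 1.0)
    return c


def adjacency_and_tom(corr: np.ndarray, power: float = 18) -> tuple[np.ndarray, np.ndarray]:
    """Unsigned soft-threshold adjacency and topological overlap.

    a_ij = |corr_ij|^power (diagonal zeroed);
    TOM_ij = (l_ij + a_ij) / (min(k_i, k_j) + 1 - a_ij) with
    l_ij = sum_u a_iu a_uj and k_i the node connectivity; TOM_ii = 1.
    """
    if power <= 0:
        raise ValueError("power must be positive")
    corr = np.asarray(corr, dtype=float)
    if corr.ndim != 2 or corr.shape[0] != corr.shape[1]:
        raise ValueError("correlation matrix must be square")
    a = np.abs(corr) ** power
    np.fill_diagonal(a, 0.0)
    k = a.sum(axis=1)
    l = a @ a
    denom = np.minimum.outer(k, k) + 1.0 - a
    tom = (l + a) / denom
    np.fill_diagonal(tom, 1.0)
    return a, np.clip(tom, 0.0, 1.0)


def _first_pc_scores(x_z: np.ndarray) -> np.ndarray:
    """First right-singular vector (per-sample scores) of z-scored rows."""
    _, _, vt = np.linalg.svd(x_z, full_matrices=False)
    v = vt[0]
    return v / np.linalg.norm(v)


def _zscore_rows(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    sd = x.std(axis=1, ddof=1)
    keep = sd > 0
    z = (x[keep] - x[keep].mean(axis=1, keepdims=True)) / sd[keep, None]
    return z, keep


def _module_eigvec(values: np.ndarray, idx: np.ndarray) -> np.ndarray:
    """Sign-fixed unit eigenvector of one module's windows."""
    x = values[idx]
    z, keep = _zscore_rows(x)
    if not keep.all():
        warnings.warn("zero-variance windows excluded from module PCA")
    if z.shape[0] == 0:
        return np.zeros(values.shape[1])
    v = _first_pc_scores(z)
    avg = x.mean(axis=0)
    if np.std(avg) > 0 and np.corrcoef(v, avg)[0, 1] < 0:
        v = -v
    return v


def detect_modules(
    tom_dissim: np.ndarray,
    values: np.ndarray | None = None,
    min_module_size: int = 10,
    merge_corr: float = 0.75,
    cut_height: float = 0.99,
) -> np.ndarray:
    """Cluster one block of windows into module labels (0 = unassigned).

    Average-linkage hierarchical clustering of the TOM dissimilarity,
    cut at a static height; clusters below ``min_module_size`` are left
    unassigned. When ``values`` is given, modules whose eigenvectors
    correlate at or above ``merge_corr`` are merged iteratively.
    """
    d = np.asarray(tom_dissim, dtype=float)
    if d.ndim != 2 or d.shape[0] != d.shape[1]:
        raise ValueError("dissimilarity must be square")
    n = d.shape[0]
    if n == 1:
        return np.zeros(1, dtype=int)
    z = linkage(squareform(d, checks=False), method="average")
    raw = fcluster(z, t=cut_height, criterion="distance")
    labels = np.zeros(n, dtype=int)
    next_id = 1
    for cl in np.unique(raw):
        members = np.flatnonzero(raw == cl)
        if len(members) >= min_module_size:
            labels[members] = next_id
            next_id += 1
    if values is not None:
        labels = _merge_by_eigenvector(labels, values, merge_corr)
    return _relabel_by_size(labels)


def _merge_by_eigenvector(
    labels: np.ndarray, values: np.ndarray, merge_corr: float
) -> np.ndarray:
    labels = labels.copy()
    while True:
        ids = sorted(k for k in set(labels.tolist()) if k != 0)
        if len(ids) < 2:
            return labels
        eig = {k: _module_eigvec(values, np.flatnonzero(labels == k)) for k in ids}
        best, best_r = None, merge_corr
        for i, ki in enumerate(ids):
            for kj in ids[i + 1:]:
                r = abs(float(np.corrcoef(eig[ki], eig[kj])[0, 1]))
                if r >= best_r:
                    best, best_r = (ki, kj), r
        if best is None:
            return labels
        labels[labels == best[1]] = best[0]


def _relabel_by_size(labels: np.ndarray) -> np.ndarray:
    ids = [k for k in set(labels.tolist()) if k != 0]
    ids.sort(key=lambda k: (-int(np.sum(labels == k)), k))
    out = np.zeros_like(labels)
    for new, old in enumerate(ids, start=1):
        out[labels == old] = new
    return out


def build_network(
    wm: WindowMatrix,
    power: float = 18,
    min_module_size: int = 10,
    merge_corr: float = 0.75,
    cut_height: float = 0.99,
    max_block: int = 30_000,
) -> ModuleSet:
    """Blockwise network construction and module detection.

    Windows beyond ``max_block`` are processed in chromosome-contiguous
    blocks whose modules are then merged across blocks by eigenvector
    correlation. Values are mean-imputed per window for correlation
    purposes (missingness is rare after the coverage filters).
    """
    n = wm.n_windows
    if n == 0:
        return ModuleSet(np.zeros(0, dtype=int), {}, np.zeros(0), list(wm.samples))
    values = wm.values.copy()
    row_mean = np.nanmean(values, axis=1)
    nan_r, nan_c = np.nonzero(np.isnan(values))
    values[nan_r, nan_c] = row_mean[nan_r]

    blocks: list[np.ndarray] = []
    if n <= max_block:
        blocks.append(np.arange(n))
    else:
        start = 0
        chroms = np.array([w.chrom for w in wm.windows], dtype=object)
        while start < n:
            stop = min(start + max_block, n)
            # keep blocks chromosome-contiguous where possible
            if stop < n and chroms[stop - 1] == chroms[stop]:
                back = stop
                while back > start + 1 and chroms[back - 1] == chroms[stop]:
                    back -= 1
                if back > start:
                    stop = back
            blocks.append(np.arange(start, stop))
            start = stop

    labels = np.zeros(n, dtype=int)
    offset = 0
    log: list[str] = []
    for bi, idx in enumerate(blocks):
        corr = bicor_matrix(values[idx])
        _, tom = adjacency_and_tom(corr, power=power)
        bl = detect_modules(
            1.0 - tom, values=values[idx], min_module_size=min_module_size,
            merge_corr=merge_corr, cut_height=cut_height,
        )
        assigned = bl > 0
        labels[idx[assigned]] = bl[assigned] + offset
        offset = labels.max()
        log.append(f"block {bi}: {len(idx)} windows, {bl.max()} modules")
    if len(blocks) > 1:
        labels = _merge_by_eigenvector(labels, values, merge_corr)
    labels = _relabel_by_size(labels)
    modset = module_eigenvectors(wm, labels)
    modset.merged_from = log
    return modset


def module_eigenvectors(wm: WindowMatrix, labels: np.ndarray) -> ModuleSet:
    """Compute per-module eigenvectors and per-window module membership.

    The eigenvector is the first principal-axis sample-score vector of
    the module's z-scored windows, unit norm, signed to correlate
    non-negatively with the module's average methylation. MM is the
    absolute Pearson correlation of each assigned window with its
    module's eigenvector.
    """
    labels = np.asarray(labels, dtype=int)
    values = wm.values.copy()
    row_mean = np.nanmean(values, axis=1) if values.size else np.zeros(0)
    nan_r, nan_c = np.nonzero(np.isnan(values))
    values[nan_r, nan_c] = row_mean[nan_r]

    eig: dict[int, np.ndarray] = {}
    mm = np.zeros(len(labels))
    for k in sorted(set(labels.tolist()) - {0}):
        idx = np.flatnonzero(labels == k)
        v = _module_eigvec(values, idx)
        eig[k] = v
        for i in idx:
            sd = values[i].std()
            mm[i] = abs(float(np.corrcoef(values[i], v)[0, 1])) if sd > 0 else 0.0
    return ModuleSet(labels, eig, mm, list(wm.samples))


def _cor_t_pvalue(r: float, n: int) -> float:
    """Two-sided Student-t p (n-2 df) for a correlation coefficient."""
    if abs(r) >= 1.0:
        return _TINY_P
    t = r * np.sqrt((n - 2) / (1.0 - r * r))
    p = 2.0 * stats.t.sf(abs(t), df=n - 2)
    return float(max(p, _TINY_P))


def trait_association(
    modset: ModuleSet,
    phenotypes: pd.DataFrame,
    wm: WindowMatrix | None = None,
    alpha: float = 0.05,
) -> tuple[pd.DataFrame, pd.DataFrame | None]:
    """Module-trait correlation table and per-window gene significance.

    ``phenotypes`` is a samples x traits frame aligned to the module
    eigenvectors' sample order. r is the biweight midcorrelation of the
    module eigenvector with the trait; p comes from the two-sided
    Student t with n-2 df. When ``wm`` is given, gene significance
    GS = |bicor(window values, trait)| is returned per window x trait.
    """
    phen = phenotypes.loc[modset.samples] if set(modset.samples) <= set(phenotypes.index) else phenotypes
    rows = []
    for trait in phen.columns:
        tvals = phen[trait].to_numpy(dtype=float)
        if np.std(tvals) == 0:
            raise ValueError(f"trait {trait!r} is constant across samples")
        for k, v in modset.eigenvectors.items():
            r = bicor(v, tvals)
            p = _cor_t_pvalue(r, len(tvals))
            rows.append(
                {"module": k, "trait": trait, "r": r, "p": p, "retained": p < alpha}
            )
    stats_df = pd.DataFrame(rows, columns=["module", "trait", "r", "p", "retained"])
    gs = None
    if wm is not None:
        values = wm.values.copy()
        row_mean = np.nanmean(values, axis=1) if values.size else np.zeros(0)
        nan_r, nan_c = np.nonzero(np.isnan(values))
        values[nan_r, nan_c] = row_mean[nan_r]
        gs_cols = {}
        for trait in phen.columns:
            tvals = phen[trait].to_numpy(dtype=float)
            tt = _bicor_transform(tvals[None, :])[0]
            vv = _bicor_transform(values)
            gs_cols[trait] = np.abs(np.clip(vv @ tt, -1, 1))
        gs = pd.DataFrame(gs_cols, index=[w.name for w in wm.windows])
    return stats_df, gs


def module_dmr_enrichment(
    module_idx: np.ndarray,
    dmr_flags: np.ndarray,
    n_perm: int = 1000,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> OverlapResult:
    """Resampling test: are DMR-overlapping windows enriched in a module?

    ``dmr_flags`` marks, for every network window, whether it intersects
    any DMR; the null redraws |module| windows without replacement from
    all network windows and recounts flagged ones.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    module_idx = np.asarray(module_idx, dtype=int)
    dmr_flags = np.asarray(dmr_flags, dtype=bool)
    size = len(module_idx)
    if size == 0:
        raise ValueError("empty module")
    if size > len(dmr_flags):
        raise ValueError("module larger than the window background")
    observed = int(dmr_flags[module_idx].sum())
    null = np.array(
        [
            int(dmr_flags[rng.choice(len(dmr_flags), size=size, replace=False)].sum())
            for _ in range(n_perm)
        ]
    )
    p_emp = (1 + int(np.sum(null >= observed))) / (1 + n_perm)
    return OverlapResult(observed, null, p_emp)


def mm_gs_comparison(
    mm_values: np.ndarray,
    gs_values: np.ndarray,
    dmr_flags: np.ndarray,
) -> pd.DataFrame:
    """Welch t-tests of MM and GS between DMR- and non-DMR windows.

    Returns one row per measure with t, Welch-Satterthwaite df, and
    two-sided p; a stratum with fewer than two windows marks the row
    untestable (NaN statistics).
    """
    dmr_flags = np.asarray(dmr_flags, dtype=bool)
    rows = []
    for name, vals in (("mm", np.asarray(mm_values, float)),
                       ("gs", np.asarray(gs_values, float))):
        a, b = vals[dmr_flags], vals[~dmr_flags]
        if len(a) < 2 or len(b) < 2:
            rows.append({"measure": name, "t": np.nan, "df": np.nan,
                         "p": np.nan, "testable": False})
            continue
        res = stats.ttest_ind(a, b, equal_var=False)
        va, vb = a.var(ddof=1) / len(a), b.var(ddof=1) / len(b)
        df = (va + vb) ** 2 / (va**2 / (len(a) - 1) + vb**2 / (len(b) - 1))
        rows.append({"measure": name, "t": float(res.statistic), "df": float(df),
                     "p": float(res.pvalue), "testable": True})
    return pd.DataFrame(rows)
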