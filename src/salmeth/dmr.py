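"""DMR construction, direction-bias and interval-overlap statistics.

Significant CpGs are aggregated into differentially methylated regions
(DMRs) under three rules: a region must span at least 50 bp, contain at
least four tested CpGs, and have more than half of its CpGs significant
at the per-site p threshold. Direction (hypo/hyper in the focal group)
is the sign of the mean per-CpG difference. The hypo:hyper imbalance is
assessed with an exact two-sided binomial test, and cross-dataset DMR
overlap with a permutation null that re-places regions on the tested-CpG
backbone, preserving each region's CpG span (so CpG clustering does not
inflate significance the way bp-uniform placement would).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "DMRRecord",
    "OverlapResult",
    "call_dmrs",
    "direction_bias_test",
    "overlap_regions",
    "permutation_overlap_test",
    "dmrs_to_frame",
]


@dataclass(eq=False)  # identity hash: records key region->gene maps
class DMRRecord:
    """A called differentially methylated region (0-based half-open)."""

    chrom: str
    start: int
    end: int
    n_cpg: int
    mean_diff: float
    direction: str  # "hypo" or "hyper" with respect to the focal group
    frac_sig: float
    name: str = ""

    @property
    def length_bp(self) -> int:
        return self.end - self.start


@dataclass
class OverlapResult:
    """Observed overlap count against a permutation null."""

    observed: int
    null_counts: np.ndarray = field(repr=False)
    p_emp: float

    def __post_init__(self) -> None:
        n_perm = len(self.null_counts)
        expect = (1 + int(np.sum(self.null_counts >= self.observed))) / (1 + n_perm)
        assert abs(self.p_emp - expect) < 1e-12


def call_dmrs(
    dmcs: pd.DataFrame,
    p_threshold: float = 1e-3,
    min_len: int = 50,
    min_cpg: int = 4,
    pct_sig: float = 0.5,
    merge_gap_bp: int = 100,
) -> list[DMRRecord]:
    """Aggregate per-CpG test results into DMRs.

    ``dmcs`` must hold chrom, pos, diff, pval sorted by (chrom, pos).
    Clusters are maximal runs of significant CpGs with consecutive
    significant sites no more than ``merge_gap_bp`` apart; the region
    spans first to last cluster CpG (+1) and its membership is every
    tested CpG inside that span. A region is emitted when
    length >= ``min_len``, n_cpg >= ``min_cpg`` and the significant
    fraction strictly exceeds ``pct_sig``.
    """
    if dmcs.empty:
        return []
    out: list[DMRRecord] = []
    for chrom, sub in dmcs.groupby("chrom", sort=True):
        pos = sub["pos"].to_numpy()
        if np.any(np.diff(pos) < 0):
            raise ValueError("dmcs must be sorted by (chrom, pos)")
        pval = sub["pval"].to_numpy()
        diff = sub["diff"].to_numpy()
        sig_idx = np.flatnonzero(pval < p_threshold)
        if sig_idx.size == 0:
            continue
        # split runs of significant CpGs at gaps > merge_gap_bp
        breaks = np.flatnonzero(np.diff(pos[sig_idx]) > merge_gap_bp)
        for run in np.split(sig_idx, breaks + 1):
            start = int(pos[run[0]])
            end = int(pos[run[-1]]) + 1
            member = slice(run[0], run[-1] + 1)
            n_cpg = member.stop - member.start
            frac_sig = float((pval[member] < p_threshold).sum() / n_cpg)
            if end - start < min_len or n_cpg < min_cpg or frac_sig <= pct_sig:
                continue
            mean_diff = float(diff[member].mean())
            direction = "hypo" if mean_diff < 0 else "hyper"  # exact 0 -> hyper
            out.append(
                DMRRecord(str(chrom), start, end, n_cpg, mean_diff, direction,
                          frac_sig, name=f"DMR{len(out) + 1}")
            )
    return out


def dmrs_to_frame(dmrs: list[DMRRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "chrom": d.chrom, "start": d.start, "end": d.end,
                "length_bp": d.length_bp, "n_cpg": d.n_cpg,
                "mean_diff": d.mean_diff, "direction": d.direction,
                "frac_sig": d.frac_sig, "name": d.name,
            }
            for d in dmrs
        ],
        columns=["chrom", "start", "end", "length_bp", "n_cpg", "mean_diff",
                 "direction", "frac_sig", "name"],
    )


def direction_bias_test(n_hypo: int, n_total: int) -> float:
    """Exact two-sided binomial p at p0 = 0.5 by doubling the smaller tail."""
    if n_total < 1:
        raise ValueError("n_total must be >= 1")
    if not (0 <= n_hypo <= n_total):
        raise ValueError("need 0 <= n_hypo <= n_total")
    lower = stats.binom.cdf(n_hypo, n_total, 0.5)
    upper = stats.binom.sf(n_hypo - 1, n_total, 0.5)
    return float(min(1.0, 2.0 * min(lower, upper)))


def overlap_regions(a: list, b: list) -> list[tuple]:
    """All intersecting (x, y) pairs between two half-open region lists."""
    by_chrom: dict[str, list] = {}
    for y in b:
        by_chrom.setdefault(y.chrom, []).append(y)
    for ys in by_chrom.values():
        ys.sort(key=lambda r: r.start)
    pairs = []
    for x in a:
        for y in by_chrom.get(x.chrom, ()):
            if y.start >= x.end:
                break
            if y.end > x.start:
                pairs.append((x, y))
    return pairs


class _Backbone:
    """Tested-CpG backbone indexed for span-preserving re-placement."""

    def __init__(self, chrom: np.ndarray, pos: np.ndarray) -> None:
        order = np.lexsort((pos, chrom.astype(str)))
        self.chrom = np.asarray(chrom, dtype=object)[order]
        self.pos = np.asarray(pos, dtype=np.int64)[order]
        if len(self.pos) == 0:
            raise ValueError("empty backbone")
        self.offsets: dict[str, tuple[int, int]] = {}
        for c in pd.unique(self.chrom):
            idx = np.flatnonzero(self.chrom == c)
            self.offsets[str(c)] = (int(idx[0]), int(idx[-1] + 1))

    def count_cpgs(self, region) -> int:
        lo, hi = self.offsets.get(region.chrom, (0, 0))
        sub = self.pos[lo:hi]
        return int(
            np.searchsorted(sub, region.end, "left")
            - np.searchsorted(sub, region.start, "left")
        )

    def valid_starts(self, span: int) -> np.ndarray:
        """Global indices i such that i .. i+span-1 stay on one chromosome."""
        chunks = [
            np.arange(lo, hi - span + 1)
            for lo, hi in self.offsets.values()
            if hi - lo >= span
        ]
        if not chunks:
            raise ValueError(f"no chromosome holds a span of {span} CpGs")
        return np.concatenate(chunks)


def permutation_overlap_test(
    a: list,
    b: list,
    backbone: tuple[np.ndarray, np.ndarray],
    n_perm: int = 1000,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> OverlapResult:
    """Permutation test for the overlap between two DMR sets.

    ``backbone`` is (chrom array, pos array) of all tested CpGs. Each
    permutation re-places every region of ``a`` at a uniformly chosen
    start CpG, extending over the region's own CpG count, and recounts
    intersecting pairs with ``b`` (assumed non-overlapping within the
    set). The empirical p uses the add-one form, so its smallest
    attainable value is 1/(n_perm + 1).
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    if rng is None:
        rng = np.random.default_rng(seed)
    observed = len(overlap_regions(a, b))
    if not a:
        null = np.zeros(n_perm, dtype=int)
        return OverlapResult(0, null, 1.0)

    bb = _Backbone(*backbone)
    spans = np.array([max(1, bb.count_cpgs(x)) for x in a])

    # b interval bounds per chromosome, for bisection counting
    chrom_names = sorted(bb.offsets)
    chrom_code = {c: i for i, c in enumerate(chrom_names)}
    code_of_site = np.empty(len(bb.pos), dtype=int)
    for c, (lo, hi) in bb.offsets.items():
        code_of_site[lo:hi] = chrom_code[c]
    b_starts = {i: np.empty(0, dtype=int) for i in range(len(chrom_names))}
    b_ends = {i: np.empty(0, dtype=int) for i in range(len(chrom_names))}
    for c in {y.chrom for y in b} & set(chrom_code):
        ys = [y for y in b if y.chrom == c]
        b_starts[chrom_code[c]] = np.sort(np.array([y.start for y in ys]))
        b_ends[chrom_code[c]] = np.sort(np.array([y.end for y in ys]))

    null = np.zeros(n_perm, dtype=int)
    for span in np.unique(spans):
        cand = bb.valid_starts(int(span))
        n_reg = int(np.sum(spans == span))
        idx = cand[rng.integers(len(cand), size=(n_perm, n_reg))]
        s_pos = bb.pos[idx]
        e_pos = bb.pos[idx + span - 1] + 1
        codes = code_of_site[idx]
        for ci in np.unique(codes):
            sel = codes == ci
            if b_starts[ci].size == 0:
                continue
            # b is disjoint within itself: #(start < e) - #(end <= s)
            cnt = (np.searchsorted(b_starts[ci], e_pos[sel], "left")
                   - np.searchsorted(b_ends[ci], s_pos[sel], "right"))
            np.add.at(null, np.nonzero(sel)[0], cnt)
    p_emp = (1 + int(np.sum(null >= observed))) / (1 + n_perm)
    return OverlapResult(observed, null, p_emp)
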