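"""Reading, writing and filtering of per-CpG bisulfite count data.

Counts come in as MethylDackel-style bedGraph tables (one per sample),
are assembled into a sites x samples :class:`MethylationMatrix`, and are
then subjected to the standard site-level hygiene filters: removal of
C-T / A-G polymorphic positions (where apparent methylation differences
can be pure genotype), coverage bounds, and a minimum contig length.

Coordinates are 0-based half-open everywhere; a CpG site is represented
by the forward-strand cytosine position only.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from intervaltree import IntervalTree

__all__ = [
    "SiteCounts",
    "SampleMeta",
    "GenomicInterval",
    "MethylationMatrix",
    "read_site_counts",
    "read_metadata",
    "read_bed_intervals",
    "build_matrix",
    "mask_variant_sites",
    "filter_sites",
    "write_regions_bed",
    "write_site_counts",
]


@dataclass(frozen=True)
class SiteCounts:
    """Methylated/total read counts at one CpG cytosine (0-based position)."""

    chrom: str
    pos: int
    n_meth: int
    n_total: int

    def __post_init__(self) -> None:
        if self.pos < 0:
            raise ValueError(f"negative position {self.pos}")
        if self.n_meth < 0:
            raise ValueError(f"negative methylated count {self.n_meth}")
        if self.n_total <= 0:
            raise ValueError(f"non-positive total count {self.n_total}")
        if self.n_meth > self.n_total:
            raise ValueError(
                f"n_meth {self.n_meth} exceeds n_total {self.n_total} at "
                f"{self.chrom}:{self.pos}"
            )

    @property
    def fraction(self) -> float:
        return self.n_meth / self.n_total


@dataclass
class SampleMeta:
    """Per-sample design information (group, tissue, family, phenotypes)."""

    sample_id: str
    group: str
    tissue: str
    family: str | None = None
    phenotypes: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.group or not self.tissue:
            raise ValueError(f"sample {self.sample_id}: group and tissue required")
        for name, value in self.phenotypes.items():
            if value is not None and not math.isfinite(value):
                raise ValueError(f"sample {self.sample_id}: non-finite {name}")


@dataclass(frozen=True)
class GenomicInterval:
    """0-based half-open genomic interval."""

    chrom: str
    start: int
    end: int
    name: str = ""
    strand: str = "."

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(
                f"empty/inverted interval {self.chrom}:{self.start}-{self.end}"
            )

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def gap_to(self, other: "GenomicInterval") -> float:
        """Distance between intervals: 0 when overlapping or abutting."""
        if self.chrom != other.chrom:
            return math.inf
        return max(0, other.start - self.end, self.start - other.end)


class MethylationMatrix:
    """CpG sites x samples matrix of (methylated, total) read counts.

    Missing cells (site unobserved in a sample) carry NaN in both count
    layers and are distinct from zero coverage, which cannot occur
    (bedGraph rows with zero total are rejected at parse time).
    """

    def __init__(
        self,
        chrom: np.ndarray,
        pos: np.ndarray,
        samples: Sequence[str],
        meth: np.ndarray,
        total: np.ndarray,
    ) -> None:
        self.chrom = np.asarray(chrom, dtype=object)
        self.pos = np.asarray(pos, dtype=np.int64)
        self.samples = list(samples)
        self.meth = np.asarray(meth, dtype=float)
        self.total = np.asarray(total, dtype=float)
        n, s = self.meth.shape
        if self.total.shape != (n, s) or len(self.pos) != n or len(self.samples) != s:
            raise ValueError("inconsistent matrix dimensions")
        with np.errstate(invalid="ignore"):
            if np.any(self.meth > self.total):
                raise ValueError("n_meth exceeds n_total in at least one cell")
        order = np.lexsort((self.pos, self.chrom))
        if not np.array_equal(order, np.arange(n)):
            self.chrom = self.chrom[order]
            self.pos = self.pos[order]
            self.meth = self.meth[order]
            self.total = self.total[order]
        key = list(zip(self.chrom, self.pos))
        if len(set(key)) != n:
            raise ValueError("duplicate (chrom, pos) sites")

    @property
    def n_sites(self) -> int:
        return len(self.pos)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def fraction(self) -> np.ndarray:
        """Per-cell methylated fraction; NaN where missing."""
        with np.errstate(invalid="ignore", divide="ignore"):
            return self.meth / self.total

    def subset_sites(self, mask: np.ndarray) -> "MethylationMatrix":
        mask = np.asarray(mask, dtype=bool)
        return MethylationMatrix(
            self.chrom[mask], self.pos[mask], self.samples,
            self.meth[mask], self.total[mask],
        )

    def site_keys(self) -> list[tuple[str, int]]:
        return list(zip(self.chrom, (int(p) for p in self.pos)))


def read_site_counts(path: str | Path, dialect: str = "auto") -> list[SiteCounts]:
    """Read a MethylDackel-style bedGraph of per-CpG counts.

    Two dialects: ``percent+counts`` rows are
    ``chrom start end pct n_meth n_unmeth``; ``counts`` rows are
    ``chrom start end n_meth n_unmeth``. ``auto`` decides per row from
    the column count. Positions come from the (0-based) start column.
    """
    if dialect not in ("auto", "counts", "percent+counts"):
        raise ValueError(f"unknown dialect {dialect!r}")
    out: list[SiteCounts] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split()
            try:
                if dialect == "counts" or (dialect == "auto" and len(fields) == 5):
                    chrom, start, _end, n_meth, n_unmeth = fields[:5]
                elif dialect == "percent+counts" or (
                    dialect == "auto" and len(fields) >= 6
                ):
                    chrom, start, _end, _pct, n_meth, n_unmeth = fields[:6]
                else:
                    raise ValueError(f"expected 5 or 6 columns, got {len(fields)}")
                m, u = int(n_meth), int(n_unmeth)
                if m < 0 or u < 0:
                    raise ValueError("negative count")
                out.append(SiteCounts(chrom, int(start), m, m + u))
            except (ValueError, IndexError) as exc:
                raise ValueError(f"{path}: parse error at line {lineno}: {exc}") from exc
    return out


def read_metadata(path: str | Path) -> list[SampleMeta]:
    """Read the tab-separated sample sheet.

    Header columns: sample_id, group, tissue, family, then any numeric
    phenotype columns (e.g. length_mm, weight_g).
    """
    metas: list[SampleMeta] = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        required = ["sample_id", "group", "tissue"]
        for col in required:
            if col not in header:
                raise ValueError(f"{path}: missing metadata column {col!r}")
        for line in fh:
            if not line.strip():
                continue
            rec = dict(zip(header, line.rstrip("\n").split("\t")))
            phen = {
                k: float(v)
                for k, v in rec.items()
                if k not in ("sample_id", "group", "tissue", "family") and v not in ("", "NA")
            }
            fam = rec.get("family") or None
            metas.append(
                SampleMeta(rec["sample_id"], rec["group"], rec["tissue"], fam, phen)
            )
    return metas


def read_bed_intervals(path: str | Path) -> list[GenomicInterval]:
    """Read BED3+ into intervals (name from column 4, strand from 6)."""
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            name = f[3] if len(f) > 3 else ""
            strand = f[5] if len(f) > 5 else "."
            out.append(GenomicInterval(f[0], int(f[1]), int(f[2]), name, strand))
    return out


def build_matrix(
    tables: Mapping[str, Sequence[SiteCounts]],
    meta: Sequence[SampleMeta],
) -> MethylationMatrix:
    """Assemble per-sample count tables into one matrix over the site union."""
    if not tables:
        raise ValueError("no sample tables supplied")
    meta_ids = [m.sample_id for m in meta]
    missing = set(tables) - set(meta_ids)
    if missing:
        raise ValueError(f"samples without metadata: {sorted(missing)}")
    samples = [sid for sid in meta_ids if sid in tables]

    site_set: set[tuple[str, int]] = set()
    for sid in samples:
        keys = [(sc.chrom, sc.pos) for sc in tables[sid]]
        if len(set(keys)) != len(keys):
            raise ValueError(f"duplicate (chrom, pos) within sample {sid}")
        site_set.update(keys)
    sites = sorted(site_set)
    index = {key: i for i, key in enumerate(sites)}

    n, s = len(sites), len(samples)
    meth = np.full((n, s), np.nan)
    total = np.full((n, s), np.nan)
    for j, sid in enumerate(samples):
        for sc in tables[sid]:
            i = index[(sc.chrom, sc.pos)]
            meth[i, j] = sc.n_meth
            total[i, j] = sc.n_total
    chrom = np.array([c for c, _ in sites], dtype=object)
    pos = np.array([p for _, p in sites], dtype=np.int64)
    return MethylationMatrix(chrom, pos, samples, meth, total)


def mask_variant_sites(
    m: MethylationMatrix, variants: Iterable[GenomicInterval]
) -> MethylationMatrix:
    """Drop every CpG whose position falls inside a variant interval."""
    trees: dict[str, IntervalTree] = {}
    for iv in variants:
        trees.setdefault(iv.chrom, IntervalTree()).addi(iv.start, iv.end)
    if not trees:
        return m.subset_sites(np.ones(m.n_sites, dtype=bool))
    keep = np.ones(m.n_sites, dtype=bool)
    for i in range(m.n_sites):
        tree = trees.get(m.chrom[i])
        if tree is not None and tree.overlaps_point(int(m.pos[i])):
            keep[i] = False
    return m.subset_sites(keep)


def filter_sites(
    m: MethylationMatrix,
    chrom_lengths: Mapping[str, int],
    min_cov: int = 5,
    max_cov: int = 20,
    min_frac_samples: float = 0.75,
    min_contig_len: int = 10_000,
    chrom_whitelist: set[str] | None = None,
) -> MethylationMatrix:
    """Apply the site-level coverage and contig filters.

    A site is retained when (a) its contig has length >= ``min_contig_len``
    (or is whitelisted), (b) every sample has at least one read at it
    (missing counts as zero), and (c) coverage is within
    [``min_cov``, ``max_cov``] in at least
    ``ceil(min_frac_samples * n_samples)`` samples.
    """
    if not (0 < min_frac_samples <= 1):
        raise ValueError(f"min_frac_samples must be in (0, 1], got {min_frac_samples}")
    if not (0 < min_cov <= max_cov):
        raise ValueError(f"need 0 < min_cov <= max_cov, got {min_cov}, {max_cov}")
    for c in set(m.chrom):
        if c not in chrom_lengths:
            raise ValueError(f"chrom_lengths missing contig {c!r}")

    whitelist = chrom_whitelist or set()
    contig_ok = np.array(
        [c in whitelist or chrom_lengths[c] >= min_contig_len for c in m.chrom]
    )
    total = np.nan_to_num(m.total, nan=0.0)
    covered_all = (total >= 1).all(axis=1)
    need = math.ceil(min_frac_samples * m.n_samples)
    in_range = ((total >= min_cov) & (total <= max_cov)).sum(axis=1) >= need
    return m.subset_sites(contig_ok & covered_all & in_range)


def write_regions_bed(
    regions: Sequence,
    path: str | Path,
    scores: Sequence[float] | None = None,
) -> None:
    """Write intervals (or records with .chrom/.start/.end) as sorted BED6."""
    rows = []
    for i, r in enumerate(regions):
        name = getattr(r, "name", "") or getattr(r, "direction", "") or f"region{i + 1}"
        score = scores[i] if scores is not None else getattr(r, "mean_diff", 0.0)
        strand = getattr(r, "strand", ".")
        rows.append((r.chrom, int(r.start), int(r.end), str(name), float(score), strand))
    rows.sort(key=lambda t: (t[0], t[1], t[2]))
    with open(path, "w") as fh:
        for chrom, start, end, name, score, strand in rows:
            fh.write(f"{chrom}\t{start}\t{end}\t{name}\t{score:.6g}\t{strand}\n")


def write_site_counts(records: Sequence[SiteCounts], path: str | Path) -> None:
    """Write counts back out as a MethylDackel-style bedGraph."""
    with open(path, "w") as fh:
        for sc in records:
            pct = 100.0 * sc.n_meth / sc.n_total
            fh.write(
                f"{sc.chrom}\t{sc.pos}\t{sc.pos + 1}\t{pct:.6g}\t"
                f"{sc.n_meth}\t{sc.n_total - sc.n_meth}\n"
            )
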