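"""Seedable synthetic bisulfite-count generator with planted ground truth.

The generator emulates the statistical structure of sperm/liver WGBS
data from a two-group rearing contrast at desk scale: a CpG backbone
with exponential background spacing plus dense CpG-island-like
clusters; a bimodal baseline methylation landscape (a small fraction of
near-unmethylated sites, a large majority above 0.8, block-constant
over ~500 bp); beta-binomial read counts at ~8x coverage with
overdispersion phi; planted DMRs (mean effect ~0.39, 2:1 hypo:hyper);
planted trait-linked co-methylation modules; and family-structured
phenotypes whose condition factor carries the module signal at a
configurable population correlation.

Everything is driven by one integer seed and returns the planted truth
needed for recovery testing.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from .io import GenomicInterval, MethylationMatrix, SampleMeta, SiteCounts
from .phenostats import PhenotypeRecord

__all__ = [
    "SimConfig",
    "SimTruth",
    "SimulatedCounts",
    "simulate_backbone_and_genes",
    "simulate_counts",
    "simulate_phenotypes",
    "simulate_study",
    "write_simulation",
]


@dataclass
class SimConfig:
    """Generator parameters; defaults are the emulated study conditions."""

    n_chrom: int = 3
    chrom_len_bp: int = 2_500_000
    cpg_spacing_mean_bp: float = 150.0
    island_prob: float = 0.01          # chance of a CpG-island cluster per background gap
    n_samples_per_group: int = 8
    n_families_per_group: int = 4
    coverage_mean: float = 8.3
    coverage_max: int = 20
    frac_low: float = 0.05             # near-unmethylated mixture component
    frac_high: float = 0.91            # highly methylated component (>0.8)
    low_shape: tuple[float, float] = (0.4, 12.0)
    mid_shape: tuple[float, float] = (2.0, 2.0)
    high_shape: tuple[float, float] = (45.0, 2.5)
    baseline_block_bp: int = 500       # regional autocorrelation scale
    phi: float = 0.1
    n_dmrs: int = 50
    dmr_effect_mean: float = 0.39
    dmr_effect_range: tuple[float, float] = (0.08, 0.70)
    dmr_min_cpg: int = 6
    dmr_max_cpg: int = 15
    hypo_fraction: float = 2.0 / 3.0
    n_modules: int = 3
    module_size: int = 30
    module_trait_r: float = 0.69
    module_loading_range: tuple[float, float] = (0.25, 0.40)
    length_mean: tuple[float, float] = (65.2, 63.2)   # (group1, group2) mm
    length_sd: float = 6.6
    condition_mean: tuple[float, float] = (1.20, 1.21)
    condition_cv: float = 0.05
    family_var_share: float = 0.4
    group_names: tuple[str, str] = ("SAS", "wild")
    tissue: str = "liver"
    seed: int = 0

    def __post_init__(self) -> None:
        for f in (self.frac_low, self.frac_high, self.hypo_fraction, self.phi):
            if not 0 <= f <= 1:
                raise ValueError("fractions must lie in [0, 1]")
        if self.frac_low + self.frac_high > 1:
            raise ValueError("mixture fractions exceed 1")
        if abs(self.module_trait_r) >= 1:
            raise ValueError("|module_trait_r| must be < 1")
        if min(self.n_chrom, self.chrom_len_bp, self.n_samples_per_group) <= 0:
            raise ValueError("counts must be positive")


@dataclass
class SimTruth:
    """Planted DMRs, module memberships and phenotype effects."""

    dmrs: list[dict] = field(default_factory=list)
    module_windows: dict[int, list[str]] = field(default_factory=dict)
    module_latent: dict[int, list[float]] = field(default_factory=dict)
    module_trait_map: dict[int, str] = field(default_factory=dict)
    families: dict[str, str] = field(default_factory=dict)
    phenotype_effects: dict = field(default_factory=dict)

    def dmr_intervals(self) -> list[GenomicInterval]:
        return [
            GenomicInterval(d["chrom"], d["start"], d["end"],
                            name=f"planted{i + 1}")
            for i, d in enumerate(self.dmrs)
        ]

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1, default=str)


@dataclass
class SimulatedCounts:
    """Count bundle: backbone-aligned count layers plus design metadata."""

    chrom: np.ndarray
    pos: np.ndarray
    samples: list[str]
    meth: np.ndarray
    total: np.ndarray
    meta: list[SampleMeta]
    truth: SimTruth

    def to_matrix(self) -> MethylationMatrix:
        return MethylationMatrix(
            self.chrom, self.pos, self.samples,
            self.meth.astype(float), self.total.astype(float),
        )

    def to_tables(self) -> dict[str, list[SiteCounts]]:
        tables: dict[str, list[SiteCounts]] = {}
        for j, sid in enumerate(self.samples):
            tables[sid] = [
                SiteCounts(str(self.chrom[i]), int(self.pos[i]),
                           int(self.meth[i, j]), int(self.total[i, j]))
                for i in range(len(self.pos))
                if self.total[i, j] > 0
            ]
        return tables


def simulate_backbone_and_genes(
    cfg: SimConfig, rng: np.random.Generator | None = None
):
    """CpG backbone (background + island clusters), genes, and gene terms.

    Background inter-CpG gaps are exponential with the configured mean;
    with probability ``island_prob`` per gap a dense cluster of 8-16
    CpGs at 20-60 bp spacing is inserted (the CpG-island-like habitat
    of regulatory regions, where DMRs and module windows live). Genes
    are tiled with random lengths/gaps and carry 1-5 terms from a toy
    vocabulary.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    chroms, positions = [], []
    for c in range(cfg.n_chrom):
        name = f"chr{c + 1}"
        pos = 100.0
        while pos < cfg.chrom_len_bp:
            chroms.append(name)
            positions.append(int(pos))
            if rng.random() < cfg.island_prob:
                n_island = int(rng.integers(8, 17))
                for _ in range(n_island):
                    pos += float(rng.integers(20, 61))
                    if pos >= cfg.chrom_len_bp:
                        break
                    chroms.append(name)
                    positions.append(int(pos))
            pos += rng.exponential(cfg.cpg_spacing_mean_bp) + 2.0
    chrom_arr = np.array(chroms, dtype=object)
    pos_arr = np.array(positions, dtype=np.int64)

    vocab = [f"GO:{i:07d}" for i in range(1, 31)]
    genes, gene2go = [], {}
    gid = 0
    from .annotate import GeneRecord

    for c in range(cfg.n_chrom):
        name = f"chr{c + 1}"
        cursor = int(rng.integers(500, 3000))
        while cursor < cfg.chrom_len_bp - 6000:
            length = int(rng.integers(1000, 5001))
            gid += 1
            gene_id = f"gene{gid:04d}"
            terms = set(rng.choice(vocab, size=int(rng.integers(1, 6)), replace=False))
            genes.append(
                GeneRecord(gene_id, GenomicInterval(name, cursor, cursor + length,
                                                    gene_id), terms)
            )
            gene2go[gene_id] = terms
            cursor += length + int(rng.integers(2000, 8001))
    return (chrom_arr, pos_arr), genes, gene2go


def _beta_binomial(rng, mu, phi, n):
    """Beta-binomial draws: p ~ Beta with mean mu, dispersion phi."""
    mu = np.clip(mu, 1e-3, 1 - 1e-3)
    s = 1.0 / phi - 1.0  # alpha + beta
    p = rng.beta(mu * s, (1 - mu) * s)
    return rng.binomial(n, p)


def _sample_ids(cfg: SimConfig) -> tuple[list[str], list[SampleMeta]]:
    samples, meta = [], []
    for g, gname in enumerate(cfg.group_names):
        for i in range(cfg.n_samples_per_group):
            sid = f"{gname.lower()}_{i + 1}"
            fam = f"{gname.lower()}F{i % cfg.n_families_per_group + 1}"
            samples.append(sid)
            meta.append(SampleMeta(sid, gname, cfg.tissue, fam))
    return samples, meta


def _find_dense_runs(chrom, pos, max_gap=100, min_cpg=6):
    """Maximal runs of consecutive CpGs with gaps <= max_gap, per chrom."""
    runs = []
    n = len(pos)
    i = 0
    while i < n:
        j = i
        while (
            j + 1 < n
            and chrom[j + 1] == chrom[j]
            and pos[j + 1] - pos[j] <= max_gap
        ):
            j += 1
        if j - i + 1 >= min_cpg:
            runs.append((i, j))
        i = j + 1
    return runs


def simulate_counts(
    backbone, cfg: SimConfig, rng: np.random.Generator | None = None
) -> SimulatedCounts:
    """Beta-binomial counts for two groups with planted DMRs and modules."""
    if rng is None:
        rng = np.random.default_rng(cfg.seed + 1)
    chrom, pos = backbone
    n_sites = len(pos)
    samples, meta = _sample_ids(cfg)
    n_samp = len(samples)
    truth = SimTruth(families={m.sample_id: m.family for m in meta})

    # baseline mu, block-constant over ~baseline_block_bp
    block_key = np.array(
        [f"{c}:{p // cfg.baseline_block_bp}" for c, p in zip(chrom, pos)], dtype=object
    )
    uniq, inverse = np.unique(block_key, return_inverse=True)
    frac_mid = 1.0 - cfg.frac_low - cfg.frac_high
    comp = rng.choice(3, size=len(uniq), p=[cfg.frac_low, frac_mid, cfg.frac_high])
    block_mu = np.empty(len(uniq))
    for ci, shape in enumerate((cfg.low_shape, cfg.mid_shape, cfg.high_shape)):
        sel = comp == ci
        block_mu[sel] = rng.beta(shape[0], shape[1], size=int(sel.sum()))
    base_mu = block_mu[inverse]

    # plant DMRs on dense CpG runs so the caller's gap rule is attainable
    mu_grp = np.tile(base_mu[:, None], (1, 2))  # per-site mu for group 1 / group 2
    if cfg.n_dmrs > 0:
        runs = _find_dense_runs(chrom, pos, max_gap=100, min_cpg=cfg.dmr_min_cpg)
        if len(runs) < cfg.n_dmrs:
            raise ValueError(
                f"genome holds only {len(runs)} dense CpG runs for "
                f"{cfg.n_dmrs} requested DMRs"
            )
        order = rng.permutation(len(runs))
        for ri in order[: cfg.n_dmrs]:
            i0, j0 = runs[ri]
            n_take = min(j0 - i0 + 1, cfg.dmr_max_cpg)
            j0 = i0 + n_take - 1
            effect = float(rng.uniform(*cfg.dmr_effect_range))
            hypo = rng.random() < cfg.hypo_fraction
            if hypo:
                base = float(rng.uniform(effect + 0.02, 0.97))
                mu1 = base - effect
            else:
                base = float(rng.uniform(0.03, 0.98 - effect))
                mu1 = base + effect
            sl = slice(i0, j0 + 1)
            mu_grp[sl, 0] = np.clip(mu1, 0.01, 0.99)
            mu_grp[sl, 1] = base
            truth.dmrs.append(
                {
                    "chrom": str(chrom[i0]), "start": int(pos[i0]),
                    "end": int(pos[j0]) + 1, "n_cpg": int(n_take),
                    "effect": effect,
                    "direction": "hypo" if hypo else "hyper",
                }
            )

    # planted co-methylation modules on >=3-CpG windows (disjoint from DMRs)
    module_site_mu: dict[int, tuple[np.ndarray, np.ndarray]] = {}
    if cfg.n_modules > 0 and cfg.module_size > 0:
        dmr_sites = np.zeros(n_sites, dtype=bool)
        for d in truth.dmrs:
            sel = (chrom == d["chrom"]) & (pos >= d["start"]) & (pos < d["end"])
            dmr_sites |= sel
        # backbone is (chrom, pos)-sorted: windows are contiguous runs
        bins = pos // 100
        is_new = np.ones(n_sites, dtype=bool)
        is_new[1:] = (chrom[1:] != chrom[:-1]) | (bins[1:] != bins[:-1])
        run_starts = np.flatnonzero(is_new)
        run_len = np.diff(np.append(run_starts, n_sites))
        candidates = [
            np.arange(s, s + ln)
            for s, ln in zip(run_starts, run_len)
            if ln >= 3 and not dmr_sites[s:s + ln].any()
        ]
        need = cfg.n_modules * cfg.module_size
        if len(candidates) < need:
            raise ValueError(
                f"only {len(candidates)} eligible windows for {need} module slots"
            )
        pick = rng.permutation(len(candidates))[:need]
        for mi in range(cfg.n_modules):
            mod_id = mi + 1
            z = rng.normal(size=n_samp)
            z = (z - z.mean()) / z.std()
            truth.module_latent[mod_id] = z.tolist()
            members = pick[mi * cfg.module_size:(mi + 1) * cfg.module_size]
            names = []
            for ci in members:
                idx = candidates[ci]
                sign = 1.0 if rng.random() < 0.7 else -1.0
                b = sign * rng.uniform(*cfg.module_loading_range)
                mu_win = np.clip(0.5 + b * z, 0.02, 0.98)
                module_site_mu[mod_id] = module_site_mu.get(mod_id, ([], []))
                module_site_mu[mod_id][0].append(idx)
                module_site_mu[mod_id][1].append(mu_win)
                c0 = str(chrom[idx[0]])
                w0 = (int(pos[idx[0]]) // 100) * 100
                names.append(f"{c0}:{w0}")
            truth.module_windows[mod_id] = names
        truth.module_trait_map = {1: "condition_k"} if cfg.n_modules >= 1 else {}

    # per-site, per-sample mean methylation
    mu = np.empty((n_sites, n_samp))
    mu[:, :cfg.n_samples_per_group] = mu_grp[:, [0]]
    mu[:, cfg.n_samples_per_group:] = mu_grp[:, [1]]
    for mod_id, (idx_lists, mu_wins) in module_site_mu.items():
        for idx, mu_win in zip(idx_lists, mu_wins):
            mu[np.ix_(idx, np.arange(n_samp))] = mu_win[None, :]

    total = 1 + rng.poisson(cfg.coverage_mean - 1.0, size=(n_sites, n_samp))
    total = np.minimum(total, cfg.coverage_max)
    meth = _beta_binomial(rng, mu, cfg.phi, total)
    return SimulatedCounts(chrom, pos, samples, meth, total, meta, truth)


def simulate_phenotypes(
    cfg: SimConfig,
    truth: SimTruth,
    meta: list[SampleMeta],
    rng: np.random.Generator | None = None,
) -> list[PhenotypeRecord]:
    """Family-structured phenotypes carrying the planted module signal.

    Length is Gaussian per group (configured mean/SD) with a family
    intercept; condition factor K = mean_K * (1 + delta) where delta
    mixes the standardized module latent signal and noise so the
    population correlation of K with the module eigen-signal equals
    ``module_trait_r``; weight is then derived as W = K * L_cm^3 / 100,
    keeping the three traits internally consistent.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed + 2)
    n = len(meta)
    fams = sorted({m.family for m in meta})
    fam_eff = {f: rng.normal(0.0, cfg.length_sd * np.sqrt(cfg.family_var_share))
               for f in fams}
    resid_sd = cfg.length_sd * np.sqrt(1.0 - cfg.family_var_share)

    linked = [m for m, t in truth.module_trait_map.items() if t == "condition_k"]
    if linked and truth.module_latent:
        z = np.asarray(truth.module_latent[linked[0]], dtype=float)
    else:
        z = np.zeros(n)
    r = cfg.module_trait_r if linked else 0.0
    eps = rng.normal(size=n)
    eps = (eps - eps.mean()) / (eps.std() or 1.0)
    delta = cfg.condition_cv * (r * z + np.sqrt(1.0 - r * r) * eps)

    records = []
    for i, m in enumerate(meta):
        g = 0 if m.group == cfg.group_names[0] else 1
        length = cfg.length_mean[g] + fam_eff[m.family] + rng.normal(0.0, resid_sd)
        length = max(length, 30.0)
        k = cfg.condition_mean[g] * (1.0 + delta[i])
        weight = k * (length / 10.0) ** 3 / 100.0
        records.append(PhenotypeRecord(m.sample_id, m.family, m.group,
                                       float(length), float(weight)))
        m.phenotypes.update(length_mm=float(length), weight_g=float(weight))
    truth.phenotype_effects = {
        "module_trait_r": r,
        "linked_module": linked[0] if linked else None,
        "trait": "condition_k" if linked else None,
    }
    return records


def simulate_study(cfg: SimConfig):
    """Run the full generator; returns (backbone, genes, gene2go, counts, phenotypes)."""
    rng = np.random.default_rng(cfg.seed)
    backbone, genes, gene2go = simulate_backbone_and_genes(cfg, rng)
    counts = simulate_counts(backbone, cfg, rng)
    phenos = simulate_phenotypes(cfg, counts.truth, counts.meta, rng)
    return backbone, genes, gene2go, counts, phenos


def write_simulation(outdir: str | Path, cfg: SimConfig) -> dict[str, Path]:
    """Emit bedGraphs, metadata, genes BED, gene terms and truth JSON."""
    from .io import write_site_counts

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    _, genes, gene2go, counts, phenos = simulate_study(cfg)
    paths: dict[str, Path] = {}
    for sid, table in counts.to_tables().items():
        p = outdir / f"{sid}.bedGraph"
        write_site_counts(table, p)
        paths[sid] = p
    meta_path = outdir / "samples.tsv"
    with open(meta_path, "w") as fh:
        fh.write("sample_id\tgroup\ttissue\tfamily\tlength_mm\tweight_g\n")
        for m in counts.meta:
            fh.write(
                f"{m.sample_id}\t{m.group}\t{m.tissue}\t{m.family}\t"
                f"{m.phenotypes.get('length_mm', '')}\t"
                f"{m.phenotypes.get('weight_g', '')}\n"
            )
    paths["metadata"] = meta_path
    genes_path = outdir / "genes.bed"
    with open(genes_path, "w") as fh:
        for g in genes:
            iv = g.interval
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{g.gene_id}\t{iv.strand}\n")
    paths["genes"] = genes_path
    go_path = outdir / "gene2go.tsv"
    with open(go_path, "w") as fh:
        for g in genes:
            for term in sorted(g.go_terms):
                fh.write(f"{g.gene_id}\t{term}\n")
    paths["gene2go"] = go_path
    truth_path = outdir / "truth.json"
    counts.truth.to_json(truth_path)
    paths["truth"] = truth_path
    return paths
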