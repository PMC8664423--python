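"""Config-driven orchestration of the full methylation analysis.

One call runs: data loading (or simulation) -> variant masking -> site
filters -> smoothed beta-binomial testing with BH FDR -> DMR calling ->
direction-bias test -> gene assignment and term enrichment -> window
summarization -> co-methylation network, module-trait statistics,
module/DMR enrichment and MM/GS comparisons -> phenotype statistics.
Stage outputs are written as TSV/BED/JSON and a machine-readable
summary is produced; every random step draws from the single run seed.
"""

from __future__ import annotations

import json
import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import annotate, diffmeth, dmr, network, phenostats
from .io import (
    GenomicInterval,
    MethylationMatrix,
    build_matrix,
    filter_sites,
    mask_variant_sites,
    read_bed_intervals,
    read_metadata,
    read_site_counts,
    write_regions_bed,
)
from .simulate import SimConfig, simulate_study

log = logging.getLogger("salmeth")

DEFAULTS: dict[str, dict] = {
    "filter": {"min_cov": 5, "max_cov": 20, "min_frac_samples": 0.75,
               "min_contig_len": 10_000},
    "dmc": {"window_bp": 500, "m0": 20.0},
    "dmr": {"p_threshold": 1e-3, "min_len": 50, "min_cpg": 4, "pct_sig": 0.5,
            "merge_gap_bp": 100},
    "annotate": {"flank_bp": 5000},
    "network": {"window_bp": 100, "min_cpg": 3, "min_var": 0.05, "power": 18,
                "min_module_size": 10, "merge_corr": 0.75, "cut_height": 0.99,
                "max_block": 30_000, "n_perm": 1000},
    "sim": {},
}


@dataclass
class RunConfig:
    """Paths, per-stage parameters and the run seed."""

    outdir: Path
    seed: int = 0
    count_paths: dict[str, Path] = field(default_factory=dict)
    metadata_path: Path | None = None
    variants_path: Path | None = None
    genes_path: Path | None = None
    gene2go_path: Path | None = None
    chrom_lengths: dict[str, int] = field(default_factory=dict)
    group1: str = "SAS"
    group2: str = "wild"
    params: dict[str, dict] = field(default_factory=dict)
    simulate: bool = False

    def stage(self, name: str) -> dict:
        merged = dict(DEFAULTS.get(name, {}))
        merged.update(self.params.get(name, {}))
        return merged

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        raw.update(overrides)
        return cls(
            outdir=Path(raw.get("outdir", "results")),
            seed=int(raw.get("seed", 0)),
            count_paths={k: Path(v) for k, v in (raw.get("counts") or {}).items()},
            metadata_path=Path(raw["metadata"]) if raw.get("metadata") else None,
            variants_path=Path(raw["variants"]) if raw.get("variants") else None,
            genes_path=Path(raw["genes"]) if raw.get("genes") else None,
            gene2go_path=Path(raw["gene2go"]) if raw.get("gene2go") else None,
            chrom_lengths={k: int(v) for k, v in (raw.get("chrom_lengths") or {}).items()},
            group1=raw.get("group1", "SAS"),
            group2=raw.get("group2", "wild"),
            params={k: v for k, v in raw.items()
                    if k in DEFAULTS and isinstance(v, dict)},
            simulate=bool(raw.get("simulate", False)),
        )


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage


def _dmr_sanity(dmrs, p_threshold, min_len, min_cpg, pct_sig) -> None:
    """Post-hoc assertion that every emitted DMR satisfies its rules."""
    for d in dmrs:
        assert d.length_bp >= min_len, d
        assert d.n_cpg >= min_cpg, d
        assert d.frac_sig > pct_sig, d
        assert d.direction in ("hypo", "hyper"), d


def run_all(cfg: RunConfig) -> dict:
    """Execute the full analysis; returns the machine-readable summary."""
    from . import __version__

    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    summary: dict = {"version": __version__, "seed": cfg.seed}
    stage = "setup"
    try:
        stage = "load"
        if cfg.simulate:
            sim_cfg = SimConfig(seed=cfg.seed, **cfg.stage("sim"))
            _, genes, gene2go, counts, phenos = simulate_study(sim_cfg)
            matrix = counts.to_matrix()
            meta = counts.meta
            chrom_lengths = {f"chr{i + 1}": sim_cfg.chrom_len_bp
                             for i in range(sim_cfg.n_chrom)}
            variants: list[GenomicInterval] = []
            truth = counts.truth
        else:
            meta = read_metadata(cfg.metadata_path)
            tables = {sid: read_site_counts(p) for sid, p in cfg.count_paths.items()}
            matrix = build_matrix(tables, meta)
            chrom_lengths = cfg.chrom_lengths
            variants = (read_bed_intervals(cfg.variants_path)
                        if cfg.variants_path else [])
            genes = annotate.read_genes(cfg.genes_path) if cfg.genes_path else []
            gene2go = (annotate.read_gene2go(cfg.gene2go_path)
                       if cfg.gene2go_path else {})
            phenos = [
                phenostats.PhenotypeRecord(
                    m.sample_id, m.family or "none", m.group,
                    m.phenotypes.get("length_mm", np.nan),
                    m.phenotypes.get("weight_g", np.nan),
                )
                for m in meta
                if np.isfinite(m.phenotypes.get("length_mm", np.nan))
                and np.isfinite(m.phenotypes.get("weight_g", np.nan))
            ]
            truth = None
        log.info("loaded %d sites x %d samples", matrix.n_sites, matrix.n_samples)

        stage = "mask"
        matrix = mask_variant_sites(matrix, variants)

        stage = "filter"
        fpar = cfg.stage("filter")
        matrix = filter_sites(matrix, chrom_lengths, **fpar)
        summary["tested_sites"] = matrix.n_sites
        log.info("retained %d sites after filters", matrix.n_sites)

        stage = "dmc"
        group_of = {m.sample_id: m.group for m in meta}
        dmc = diffmeth.two_group_contrast(
            matrix, group_of, cfg.group1, cfg.group2, **cfg.stage("dmc")
        )
        dmc.to_csv(outdir / "dmc.tsv", sep="\t", index=False)
        dpar = cfg.stage("dmr")
        summary["n_dmc"] = int((dmc["pval"] < dpar["p_threshold"]).sum())

        stage = "dmr"
        dmrs = dmr.call_dmrs(dmc, **dpar)
        _dmr_sanity(dmrs, dpar["p_threshold"], dpar["min_len"],
                    dpar["min_cpg"], dpar["pct_sig"])
        dmr.dmrs_to_frame(dmrs).to_csv(outdir / "dmr.tsv", sep="\t", index=False)
        write_regions_bed(dmrs, outdir / "dmr.bed")
        n_hypo = sum(1 for d in dmrs if d.direction == "hypo")
        summary.update(n_dmr=len(dmrs), n_hypo=n_hypo, n_hyper=len(dmrs) - n_hypo)
        summary["binomial_p"] = (
            dmr.direction_bias_test(n_hypo, len(dmrs)) if dmrs else 1.0
        )

        stage = "annotate"
        if genes:
            apar = cfg.stage("annotate")
            assigned = annotate.assign_genes_to_regions(dmrs, genes, **apar)
            study = set().union(*assigned.values()) if assigned else set()
            universe = {g.gene_id for g in genes}
            enrich = annotate.go_fisher_enrichment(study, universe, gene2go)
            enrich.to_csv(outdir / "go_enrichment.tsv", sep="\t", index=False)
            with open(outdir / "dmr_genes.tsv", "w") as fh:
                fh.write("dmr\tgenes\n")
                for d, gs in assigned.items():
                    fh.write(f"{d.name}\t{','.join(sorted(gs))}\n")
            summary["n_dmr_genes"] = len(study)

        stage = "network"
        npar = cfg.stage("network")
        wm = network.summarize_windows(
            matrix, window_bp=npar["window_bp"], min_cpg=npar["min_cpg"],
            min_var=npar["min_var"],
        )
        summary["n_network_windows"] = wm.n_windows
        if wm.n_windows >= 2:
            modset = network.build_network(
                wm, power=npar["power"], min_module_size=npar["min_module_size"],
                merge_corr=npar["merge_corr"], cut_height=npar["cut_height"],
                max_block=npar["max_block"],
            )
            summary["n_modules"] = len(modset.module_ids())
            phen = pd.DataFrame(
                {
                    "length_mm": [p.length_mm for p in phenos],
                    "weight_g": [p.weight_g for p in phenos],
                    "condition_k": [p.condition_k for p in phenos],
                },
                index=[p.sample_id for p in phenos],
            )
            if modset.eigenvectors and set(modset.samples) <= set(phen.index):
                mt, gs = network.trait_association(modset, phen, wm)
                mt.to_csv(outdir / "module_trait.tsv", sep="\t", index=False)
                summary["n_sig_modules"] = int(
                    mt.loc[mt["retained"], "module"].nunique()
                )
                dmr_ivs = [GenomicInterval(d.chrom, d.start, d.end) for d in dmrs]
                flags = np.array(
                    [any(w.overlaps(iv) for iv in dmr_ivs) for w in wm.windows]
                )
                rng = np.random.default_rng(cfg.seed + 10)
                enr_rows, mmgs_frames = [], []
                for k in modset.module_ids():
                    idx = np.flatnonzero(modset.labels == k)
                    res = network.module_dmr_enrichment(
                        idx, flags, n_perm=npar["n_perm"], rng=rng
                    )
                    enr_rows.append({"module": k, "observed": res.observed,
                                     "p_emp": res.p_emp})
                    if gs is not None and flags[idx].any() and (~flags[idx]).any():
                        tr = modset_trait(mt, k)
                        if tr is not None:
                            cmp_df = network.mm_gs_comparison(
                                modset.mm[idx], gs[tr].to_numpy()[idx], flags[idx]
                            )
                            cmp_df.insert(0, "module", k)
                            mmgs_frames.append(cmp_df)
                pd.DataFrame(enr_rows).to_csv(
                    outdir / "module_dmr_enrichment.tsv", sep="\t", index=False
                )
                if mmgs_frames:
                    pd.concat(mmgs_frames).to_csv(
                        outdir / "mm_gs_ttests.tsv", sep="\t", index=False
                    )
            else:
                summary["n_sig_modules"] = 0
        else:
            summary["n_modules"] = 0
            summary["n_sig_modules"] = 0

        stage = "pheno"
        if phenos and len({p.group for p in phenos}) == 2:
            prows = []
            for trait in ("length_mm", "weight_g", "condition_k"):
                try:
                    res = phenostats.family_anova(phenos, trait)
                    prows.append({"trait": trait, "F": res.f_stat, "df1": res.df1,
                                  "df2": res.df2, "p": res.p})
                except ValueError as exc:
                    log.warning("phenotype ANOVA skipped for %s: %s", trait, exc)
            if prows:
                pd.DataFrame(prows).to_csv(
                    outdir / "phenotype_anova.tsv", sep="\t", index=False
                )

        if truth is not None:
            truth.to_json(outdir / "truth.json")
        with open(outdir / "summary.json", "w") as fh:
            json.dump(summary, fh, indent=1)
        log.info("summary: %s", summary)
        return summary
    except Exception as exc:
        # keep whatever was written, flag the failed run
        try:
            with open(outdir / "summary.partial.json", "w") as fh:
                json.dump(summary, fh, indent=1)
        except OSError:
            pass
        if isinstance(exc, StageError):
            raise
        raise StageError(stage, exc) from exc


def modset_trait(mt: pd.DataFrame, module: int) -> str | None:
    """The most significant retained trait for a module, if any."""
    sub = mt[(mt["module"] == module) & mt["retained"]]
    if sub.empty:
        return None
    return str(sub.sort_values("p").iloc[0]["trait"])


def configure_logging(verbose: bool = True) -> None:
    logging.basicConfig(
        stream=sys.stderr,
        level=logging.INFO if verbose else logging.WARNING,
        format="%(asctime)s %(name)s %(levelname)s %(message)s",
    )
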