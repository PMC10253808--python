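"""End-to-end pipeline: assemble -> structure -> gwas -> evolve -> cross.

A flat :class:`RunConfig` (mirrored one-to-one by CLI flags, loadable from
YAML) drives the stages in order; every output TSV carries a ``#``-prefixed
provenance header echoing the parameters and master seed.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .association import RtmGwas
from .cross import derive_genetic_map, enumerate_crosses
from .dynamics import build_gene_allele_matrix, compare_submatrices
from .gasm import build_gasm, map_snps_to_genes, write_gasm
from .io import read_gene_intervals, read_metadata, read_phenotypes, read_vcf
from .structure import compute_gsc, top_eigenvectors, write_structure

logger = logging.getLogger(__name__)


class ConfigError(ValueError):
    """Invalid pipeline configuration."""


@dataclass
class RunConfig:
    vcf: str = ""
    genes: str = ""
    pheno: str = ""
    meta: str = ""
    trait: str = "trait"
    out_dir: str = "results"
    maf: float = 0.01
    q: int = 10
    alpha1: float = 0.05
    alpha2: float = 0.05
    alpha_mode: str = "fixed"
    h2: str | float = "auto"
    gxe: bool = True
    ancestral: str = "O"
    group_column: str = "geo_group"
    n_progeny: int = 2000
    cross_model: str = "linkage"
    cm_per_mb: float = 2.5
    map_file: str | None = None
    seed: int = 1

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def validate(self) -> None:
        for name in ("alpha1", "alpha2"):
            v = getattr(self, name)
            if not (0 < v < 1):
                raise ConfigError(f"{name} = {v} outside (0, 1)")
        if not (0 < self.maf < 0.5):
            raise ConfigError(f"maf = {self.maf} outside (0, 0.5)")
        if self.q < 1:
            raise ConfigError("q must be >= 1")
        if self.h2 != "auto" and not (0 < float(self.h2) <= 1):
            raise ConfigError(f"h2 = {self.h2} outside (0, 1]")
        if self.n_progeny <= 0:
            raise ConfigError("n_progeny must be > 0")
        if self.cm_per_mb <= 0:
            raise ConfigError("cm_per_mb must be > 0")
        if self.alpha_mode not in ("fixed", "bonferroni"):
            raise ConfigError(f"alpha_mode {self.alpha_mode!r} unknown")
        if self.cross_model not in ("linkage", "independent", "both"):
            raise ConfigError(f"cross_model {self.cross_model!r} unknown")
        for name in ("vcf", "genes", "pheno", "meta"):
            p = getattr(self, name)
            if not p or not Path(p).exists():
                raise ConfigError(f"input {name} missing or unreadable: {p!r}")


def _write_tsv(df: pd.DataFrame, path: Path, config: RunConfig, stage: str,
               index: bool = False) -> None:
    with open(path, "w") as fh:
        fh.write(f"# gasmgwas {__version__} stage={stage} seed={config.seed} "
                 f"maf={config.maf} q={config.q} alpha1={config.alpha1} "
                 f"alpha2={config.alpha2} h2={config.h2} trait={config.trait}\n")
        df.to_csv(fh, sep="\t", index=index)


def run_pipeline(config: RunConfig) -> dict[str, Path]:
    """Execute all stages; returns the paths of the stage outputs."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    outputs: dict[str, Path] = {}

    def stage(name):
        logger.info("stage %s", name)

    try:
        stage("assemble")
        snps = read_vcf(config.vcf)
        genes = read_gene_intervals(config.genes)
        mapping = map_snps_to_genes(snps, genes)
        gasm_set = build_gasm(snps, mapping, genes, maf=config.maf)
        write_gasm(gasm_set, out / "gasm_alleles.tsv", out / "gasm_assignment.tsv")
        outputs["gasm"] = out / "gasm_alleles.tsv"
    except Exception as exc:
        raise RuntimeError(f"stage assemble failed: {exc}") from exc

    try:
        stage("structure")
        gsc = compute_gsc(gasm_set)
        cov = top_eigenvectors(gsc, q=config.q)
        write_structure(cov, out / "structure_eigenvectors.tsv")
        outputs["structure"] = out / "structure_eigenvectors.tsv"
    except Exception as exc:
        raise RuntimeError(f"stage structure failed: {exc}") from exc

    try:
        stage("gwas")
        pheno = read_phenotypes(config.pheno)
        model = RtmGwas(pheno, config.trait, gasm_set, cov, h2=config.h2)
        n_env = len(pheno.environments())
        results = model.fit(
            alpha1=config.alpha1,
            alpha2=config.alpha2,
            alpha_mode=config.alpha_mode,
            gxe=config.gxe and n_env > 1,
        )
        _write_tsv(results.stage1.table, out / "stage1_scan.tsv", config, "gwas")
        _write_tsv(results.gene_table(), out / "selected_genes.tsv", config, "gwas")
        _write_tsv(results.allele_table(), out / "allele_effects.tsv", config, "gwas")
        if model.vc is not None:
            vc_df = pd.DataFrame([dataclasses.asdict(model.vc)])
            _write_tsv(vc_df, out / "variance_components.tsv", config, "gwas")
        outputs["gwas"] = out / "selected_genes.tsv"
        logger.info("selected %d genes, genetic R2 %.4f (cap %.4f)",
                    len(results.gene_fits), results.r2_genetic, results.h2_limit)
    except Exception as exc:
        raise RuntimeError(f"stage gwas failed: {exc}") from exc

    meta = read_metadata(config.meta)
    try:
        stage("evolve")
        matrix = build_gene_allele_matrix(results, gasm_set, meta)
        contrasts = []
        labels = sorted(meta.records[config.group_column].unique())
        derived_all = [lab for lab in labels if lab != config.ancestral]
        if results.gene_fits and derived_all:
            for lab in derived_all:
                contrasts.append((config.ancestral, [lab]))
            if len(derived_all) > 1:
                contrasts.append((config.ancestral, derived_all))
            frames = []
            for anc, der in contrasts:
                summary = compare_submatrices(matrix, anc, der, config.group_column)
                tbl = summary.table.copy()
                tbl.insert(0, "contrast", f"{summary.derived_label}_vs_{summary.ancestral_label}")
                frames.append(tbl)
            _write_tsv(pd.concat(frames, ignore_index=True),
                       out / "allele_changes.tsv", config, "evolve")
            outputs["evolve"] = out / "allele_changes.tsv"
    except Exception as exc:
        raise RuntimeError(f"stage evolve failed: {exc}") from exc

    try:
        stage("cross")
        if results.gene_fits:
            gmap = derive_genetic_map(
                results.gene_table().rename(columns={"gene_id": "gene_id"})[
                    ["gene_id", "chrom", "anchor"]
                ],
                cm_per_mb=config.cm_per_mb,
                map_file=config.map_file,
            )
            models = (
                ("linkage", "independent")
                if config.cross_model == "both"
                else (config.cross_model,)
            )
            table = enumerate_crosses(
                matrix, gmap, n=config.n_progeny, models=models, seed=config.seed
            )
            _write_tsv(table, out / "cross_potential.tsv", config, "cross")
            outputs["cross"] = out / "cross_potential.tsv"
    except Exception as exc:
        raise RuntimeError(f"stage cross failed: {exc}") from exc

    return outputs
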