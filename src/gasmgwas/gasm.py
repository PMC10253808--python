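"""Gene-allele sequence marker (GASM) assembly.

A GASM is a multi-allelic marker whose alleles are the haplotypes formed by
all SNPs falling inside one annotated gene.  Assembly proceeds per gene:
missing SNP calls are imputed with the SNP's major allele, accessions are
haplotyped by concatenating their codes over the gene's SNPs, haplotypes
rarer than the minor-allele-frequency threshold (default 0.01) are
superseded by the most frequent haplotype, and genes left with fewer than
two haplotypes are dropped.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .io import MISSING, GeneInterval, SnpMatrix


@dataclass
class GasmMarker:
    """One gene's haplotype marker.

    ``alleles`` are haplotype strings over {0,1} (one character per SNP in
    ``snp_ids``); ``assignment`` holds each accession's allele index;
    ``frequencies`` the post-collapse allele frequencies.
    """

    gene_id: str
    chromosome: str
    anchor_position: int  # gene start, used for sorting and map building
    snp_ids: list[str]
    alleles: list[str]
    assignment: np.ndarray  # int array over accessions
    frequencies: np.ndarray

    def __post_init__(self) -> None:
        self.assignment = np.asarray(self.assignment, dtype=np.int64)
        self.frequencies = np.asarray(self.frequencies, dtype=float)
        if len(self.alleles) < 2:
            raise ValueError(f"{self.gene_id}: a GASM needs >= 2 alleles")
        if len(self.frequencies) != len(self.alleles):
            raise ValueError(f"{self.gene_id}: frequency/allele length mismatch")
        if abs(self.frequencies.sum() - 1.0) > 1e-12:
            raise ValueError(f"{self.gene_id}: frequencies sum to {self.frequencies.sum()}")
        if self.assignment.min() < 0 or self.assignment.max() >= len(self.alleles):
            raise ValueError(f"{self.gene_id}: assignment index out of range")

    @property
    def n_alleles(self) -> int:
        return len(self.alleles)


@dataclass
class GasmSet:
    """Ordered collection of GASMs sharing one accession panel."""

    accession_ids: list[str]
    markers: list[GasmMarker]

    def __post_init__(self) -> None:
        ids = [m.gene_id for m in self.markers]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate gene ids in GasmSet")
        n = len(self.accession_ids)
        for m in self.markers:
            if len(m.assignment) != n:
                raise ValueError(f"{m.gene_id}: assignment length != accession count")
        self.markers = sorted(
            self.markers, key=lambda m: (m.chromosome, m.anchor_position, m.gene_id)
        )

    def __len__(self) -> int:
        return len(self.markers)

    def __iter__(self):
        return iter(self.markers)

    def __getitem__(self, gene_id: str) -> GasmMarker:
        for m in self.markers:
            if m.gene_id == gene_id:
                return m
        raise KeyError(gene_id)

    @property
    def gene_ids(self) -> list[str]:
        return [m.gene_id for m in self.markers]

    def assignment_matrix(self) -> pd.DataFrame:
        """Accessions x genes table of allele indices."""
        data = {m.gene_id: m.assignment for m in self.markers}
        return pd.DataFrame(data, index=self.accession_ids)

    def subset_genes(self, gene_ids: Sequence[str]) -> "GasmSet":
        keep = set(gene_ids)
        return GasmSet(self.accession_ids, [m for m in self.markers if m.gene_id in keep])


def map_snps_to_genes(
    snps: SnpMatrix, genes: Sequence[GeneInterval]
) -> dict[str, list[str]]:
    """Assign SNPs to genes by position (boundary-inclusive).

    A SNP inside two overlapping genes appears in both gene lists; genes
    containing no SNP are omitted.  Raises when the two inputs share no
    chromosome naming.
    """
    snp_chroms = set(snps.snps["chrom"])
    gene_chroms = {g.chromosome for g in genes}
    if snp_chroms and gene_chroms and not (snp_chroms & gene_chroms):
        raise ValueError(
            "chromosome names do not overlap: "
            f"SNPs {sorted(snp_chroms)[:5]} vs genes {sorted(gene_chroms)[:5]}"
        )
    mapping: dict[str, list[str]] = {}
    by_chrom = {chrom: grp for chrom, grp in snps.snps.groupby("chrom", sort=False)}
    for g in genes:
        grp = by_chrom.get(g.chromosome)
        if grp is None:
            continue
        pos = grp["pos"].to_numpy()
        lo = np.searchsorted(pos, g.start, side="left")
        hi = np.searchsorted(pos, g.end, side="right")
        if hi > lo:
            mapping[g.gene_id] = grp["snp_id"].iloc[lo:hi].tolist()
    return mapping


def _impute_major(calls: np.ndarray) -> np.ndarray:
    """Replace MISSING with each SNP's major allele (ties -> reference 0)."""
    out = calls.copy()
    for j in range(calls.shape[1]):
        col = out[:, j]
        miss = col == MISSING
        if not miss.any():
            continue
        obs = col[~miss]
        n1 = int((obs == 1).sum())
        n0 = obs.size - n1
        major = 1 if n1 > n0 else 0
        col[miss] = major
    return out


def build_gasm(
    snps: SnpMatrix,
    mapping: Mapping[str, Sequence[str]],
    genes: Sequence[GeneInterval] | None = None,
    maf: float = 0.01,
) -> GasmSet:
    """Assemble GASMs from a SNP matrix and a gene -> SNP mapping.

    Haplotypes with frequency below ``maf`` are reassigned to the single
    most frequent pre-collapse haplotype (ties broken by lexicographically
    smallest haplotype string); frequencies are then recomputed.  Genes left
    monomorphic are dropped.  The collapse is single-pass and idempotent.
    """
    if not (0 < maf < 0.5):
        raise ValueError(f"maf must be in (0, 0.5), got {maf}")
    if not mapping:
        raise ValueError("empty gene -> SNP mapping")
    gene_meta: dict[str, GeneInterval] = {}
    if genes is not None:
        gene_meta = {g.gene_id: g for g in genes}
    snp_index = {sid: j for j, sid in enumerate(snps.snps["snp_id"])}
    n_acc = snps.n_accessions
    markers: list[GasmMarker] = []
    for gene_id, snp_ids in mapping.items():
        cols = [snp_index[s] for s in snp_ids]
        calls = _impute_major(snps.calls[:, cols])
        haplos = ["".join(str(int(c)) for c in row) for row in calls]
        counts = pd.Series(haplos).value_counts()
        freqs = counts / n_acc
        # single-pass collapse against the pre-collapse modal haplotype
        modal_count = counts.max()
        modal = min(counts.index[counts == modal_count])
        rare = set(freqs.index[freqs < maf])
        rare.discard(modal)
        if rare:
            haplos = [modal if h in rare else h for h in haplos]
            counts = pd.Series(haplos).value_counts()
        if len(counts) < 2:
            continue
        alleles = sorted(counts.index)
        allele_index = {a: k for k, a in enumerate(alleles)}
        assignment = np.array([allele_index[h] for h in haplos], dtype=np.int64)
        frequencies = np.array([counts[a] for a in alleles], dtype=float) / n_acc
        if gene_id in gene_meta:
            chrom = gene_meta[gene_id].chromosome
            anchor = gene_meta[gene_id].start
        else:
            first = snps.snps.iloc[cols[0]]
            chrom, anchor = first["chrom"], int(first["pos"])
        markers.append(
            GasmMarker(gene_id, chrom, anchor, list(snp_ids), alleles, assignment, frequencies)
        )
    return GasmSet(list(snps.accession_ids), markers)


def write_gasm(gasm_set: GasmSet, allele_path: str | Path, assignment_path: str | Path) -> None:
    """Write a GasmSet as two TSVs: per-allele rows and the assignment matrix."""
    if not gasm_set.markers:
        raise ValueError("cannot write an empty GasmSet")
    rows = []
    n_acc = len(gasm_set.accession_ids)
    for m in gasm_set:
        for k, allele in enumerate(m.alleles):
            count = int((m.assignment == k).sum())
            rows.append(
                (m.gene_id, m.chromosome, m.anchor_position, ";".join(m.snp_ids),
                 allele, m.frequencies[k], count)
            )
    pd.DataFrame(
        rows,
        columns=["gene_id", "chrom", "anchor", "snp_ids", "allele", "frequency", "count"],
    ).to_csv(allele_path, sep="\t", index=False)
    assign = gasm_set.assignment_matrix()
    assign.index.name = "accession"
    assign.to_csv(assignment_path, sep="\t")


def read_gasm(allele_path: str | Path, assignment_path: str | Path) -> GasmSet:
    """Read back the two TSVs written by :func:`write_gasm`."""
    alleles = pd.read_csv(
        allele_path, sep="\t", dtype={"allele": str, "gene_id": str, "chrom": str}
    )
    assign = pd.read_csv(assignment_path, sep="\t", index_col="accession")
    accession_ids = [str(a) for a in assign.index]
    markers = []
    for gene_id, grp in alleles.groupby("gene_id", sort=False):
        grp = grp.reset_index(drop=True)
        markers.append(
            GasmMarker(
                gene_id=str(gene_id),
                chromosome=str(grp["chrom"].iloc[0]),
                anchor_position=int(grp["anchor"].iloc[0]),
                snp_ids=str(grp["snp_ids"].iloc[0]).split(";"),
                alleles=[str(a) for a in grp["allele"]],
                assignment=assign[str(gene_id)].to_numpy(dtype=np.int64),
                frequencies=grp["frequency"].to_numpy(dtype=float),
            )
        )
    return GasmSet(accession_ids, markers)
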