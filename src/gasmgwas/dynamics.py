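"""Gene-allele matrix and evolutionary allele-change accounting.

The detected genes' allele assignments over the panel form a gene-allele
matrix.  Splitting it into subpopulation submatrices and comparing a
derived group against an ancestral one classifies every ancestral-or-
derived allele as inherited (present in both; a migration proxy), emerged
(derived only; mutation) or excluded (ancestral only; selection).  The
significance of an exclusion is judged by the binomial probability of
drawing zero carriers, P0 = (1 - p)^n, with p the allele frequency in the
ancestral group and n the derived group size; emergence is tested with the
mirrored quantity (zero ancestral carriers under the derived frequency).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .association import RtmGwasResults
from .gasm import GasmSet
from .io import AccessionMetadata


@dataclass
class GeneAlleleMatrix:
    """Selected genes x accessions allele identities with effects and labels."""

    assignment: pd.DataFrame          # accessions x genes, allele indices
    alleles: dict[str, list[str]]     # gene -> allele strings
    effects: dict[str, np.ndarray]    # gene -> sum-to-zero allele effects
    frequencies: dict[str, np.ndarray]
    meta: AccessionMetadata
    intercept: float = 0.0

    def __post_init__(self) -> None:
        if self.assignment.isna().any().any():
            raise ValueError("gene-allele matrix has unfilled cells")
        known = set(self.meta.records["accession"])
        missing = [a for a in self.assignment.index if a not in known]
        if missing:
            raise ValueError(f"accessions missing metadata: {missing[:5]}")
        for g in self.assignment.columns:
            if g not in self.effects:
                raise ValueError(f"gene {g} missing from the effect lookup")
            if self.assignment[g].max() >= len(self.effects[g]):
                raise ValueError(f"gene {g}: allele index outside effect lookup")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.assignment.columns)

    @property
    def accession_ids(self) -> list[str]:
        return list(self.assignment.index)

    def effect_of(self, gene_id: str, allele_idx: int) -> float:
        return float(self.effects[gene_id][allele_idx])

    def sign_of(self, gene_id: str, allele_idx: int, tol: float = 1e-9) -> str:
        """Effect-sign class; effects within tol of 0 count as positive."""
        e = self.effect_of(gene_id, allele_idx)
        return "negative" if e < -tol else "positive"

    def alleles_present(self, accessions: Sequence[str]) -> set[tuple[str, int]]:
        """Set of (gene, allele index) carried by at least one accession."""
        sub = self.assignment.loc[list(accessions)]
        present: set[tuple[str, int]] = set()
        for g in self.gene_ids:
            for k in np.unique(sub[g].to_numpy()):
                present.add((g, int(k)))
        return present


def build_gene_allele_matrix(
    results: RtmGwasResults, gasm_set: GasmSet, meta: AccessionMetadata
) -> GeneAlleleMatrix:
    """Restrict the panel's assignments to the detected genes."""
    genes = results.selected_genes
    missing = [g for g in genes if g not in gasm_set.gene_ids]
    if missing:
        raise ValueError(f"selected genes not in GasmSet: {missing}")
    assignment = gasm_set.assignment_matrix()[genes]
    alleles = {g: list(gasm_set[g].alleles) for g in genes}
    freqs = {g: gasm_set[g].frequencies.copy() for g in genes}
    return GeneAlleleMatrix(
        assignment=assignment,
        alleles=alleles,
        effects=results.effects_lookup(),
        frequencies=freqs,
        meta=meta,
        intercept=results.intercept,
    )


@dataclass
class AlleleChangeSummary:
    """Inherited / emerged / excluded accounting for one contrast."""

    ancestral_label: str
    derived_label: str
    table: pd.DataFrame  # per allele: gene, allele, class, effect, sign, freqs, p0, significant
    n_ancestral: int
    n_derived: int

    def _count(self, cls: str) -> int:
        return int((self.table["class"] == cls).sum())

    @property
    def n_inherited(self) -> int:
        return self._count("inherited")

    @property
    def n_emerged(self) -> int:
        return self._count("emerged")

    @property
    def n_excluded(self) -> int:
        return self._count("excluded")

    def sign_split(self, cls: str) -> tuple[int, int]:
        """(negative, positive) counts for a class, as in a gene-allele table."""
        sub = self.table[self.table["class"] == cls]
        neg = int((sub["sign"] == "negative").sum())
        return neg, len(sub) - neg

    def genes_involved(self, cls: str) -> int:
        return self.table.loc[self.table["class"] == cls, "gene"].nunique()

    def allele_set(self, cls: str) -> set[tuple[str, str]]:
        sub = self.table[self.table["class"] == cls]
        return set(zip(sub["gene"], sub["allele"]))


def exclusion_probability(p: float, n: int) -> float:
    """P0 = (1 - p)^n: probability that n derived samples all lack an allele
    segregating at ancestral frequency p."""
    if not (0 <= p <= 1):
        raise ValueError(f"allele frequency {p} outside [0, 1]")
    if n < 1:
        raise ValueError("group size must be >= 1")
    return float((1.0 - p) ** n)


def emergence_probability(p_star: float, n_anc: int) -> float:
    """Mirror of the exclusion test: probability of zero ancestral carriers
    had the allele segregated there at the derived frequency p_star."""
    return exclusion_probability(p_star, n_anc)


def compare_submatrices(
    matrix: GeneAlleleMatrix,
    ancestral: str | Sequence[str],
    derived: str | Sequence[str],
    group_column: str = "geo_group",
    alpha: float = 0.05,
) -> AlleleChangeSummary:
    """Classify every allele of the contrast as inherited/emerged/excluded.

    ``ancestral`` and ``derived`` are labels (or unions of labels) in the
    metadata column ``group_column``; presence means at least one carrier.
    """
    anc_groups = [ancestral] if isinstance(ancestral, str) else list(ancestral)
    der_groups = [derived] if isinstance(derived, str) else list(derived)
    anc_acc = matrix.meta.group_members(group_column, anc_groups)
    der_acc = matrix.meta.group_members(group_column, der_groups)
    anc_acc = [a for a in anc_acc if a in matrix.assignment.index]
    der_acc = [a for a in der_acc if a in matrix.assignment.index]
    if not anc_acc:
        raise ValueError(f"ancestral group {anc_groups} is empty")
    if not der_acc:
        raise ValueError(f"derived group {der_groups} is empty")

    anc_sub = matrix.assignment.loc[anc_acc]
    der_sub = matrix.assignment.loc[der_acc]
    n_anc, n_der = len(anc_acc), len(der_acc)
    rows = []
    for g in matrix.gene_ids:
        anc_counts = anc_sub[g].value_counts()
        der_counts = der_sub[g].value_counts()
        union = sorted(set(anc_counts.index) | set(der_counts.index))
        for k in union:
            in_anc = k in anc_counts.index
            in_der = k in der_counts.index
            if in_anc and in_der:
                cls = "inherited"
            elif in_anc:
                cls = "excluded"
            else:
                cls = "emerged"
            freq_anc = float(anc_counts.get(k, 0)) / n_anc
            freq_der = float(der_counts.get(k, 0)) / n_der
            if cls == "excluded":
                p0 = exclusion_probability(freq_anc, n_der)
            elif cls == "emerged":
                p0 = emergence_probability(freq_der, n_anc)
            else:
                p0 = float("nan")
            rows.append(
                {
                    "gene": g,
                    "allele": matrix.alleles[g][int(k)],
                    "allele_idx": int(k),
                    "class": cls,
                    "effect": matrix.effect_of(g, int(k)),
                    "sign": matrix.sign_of(g, int(k)),
                    "freq_ancestral": freq_anc,
                    "freq_derived": freq_der,
                    "p0": p0,
                    "significant": bool(p0 <= alpha) if np.isfinite(p0) else False,
                }
            )
    table = pd.DataFrame(
        rows,
        columns=["gene", "allele", "allele_idx", "class", "effect", "sign",
                 "freq_ancestral", "freq_derived", "p0", "significant"],
    )
    return AlleleChangeSummary(
        ancestral_label="+".join(anc_groups),
        derived_label="+".join(der_groups),
        table=table,
        n_ancestral=n_anc,
        n_derived=n_der,
    )
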