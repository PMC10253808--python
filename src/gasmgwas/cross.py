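"""Cross recombination-potential prediction.

For every parent pair, 2000 fully homozygous progeny are simulated either
under free recombination (independent assortment) or with the original
linkage among the detected genes preserved.  Under linkage, parent-of-
origin along the ordered loci of a chromosome follows a Markov chain whose
adjacent-locus switch probability is the recombinant-inbred-line value
R = 2r / (1 + 2r), with the single-meiosis recombination fraction r taken
from the Haldane map function r = (1 - exp(-2d/100)) / 2 (d in cM).  Each
progeny's genotypic value is the model intercept plus its summed allele
main effects; the 25th/95th percentiles of the progeny distribution give
the low-/high-parent transgression statistics

    LPT = F25 - LPV,   HPT = F95 - HPV,

negative LPT and positive HPT flagging transgressive segregation below the
low parent and above the high parent respectively.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd

from .dynamics import GeneAlleleMatrix


@dataclass
class GeneticMap:
    """Ordered loci per chromosome with adjacent-pair distances in cM."""

    chromosomes: dict[str, list[str]]          # chrom -> ordered gene ids
    distances: dict[str, np.ndarray]           # chrom -> len-1 adjacent distances (cM)

    def __post_init__(self) -> None:
        for chrom, loci in self.chromosomes.items():
            d = np.asarray(self.distances[chrom], dtype=float)
            if len(d) != max(len(loci) - 1, 0):
                raise ValueError(f"{chrom}: {len(loci)} loci but {len(d)} distances")
            if (d < 0).any():
                raise ValueError(f"{chrom}: negative genetic distance")
            self.distances[chrom] = d

    @property
    def gene_ids(self) -> list[str]:
        return [g for loci in self.chromosomes.values() for g in loci]


@dataclass
class CrossPotential:
    parent1: str
    parent2: str
    model: str                    # "linkage" | "independent"
    f25: float
    f95: float
    lpv: float
    hpv: float

    @property
    def lpt(self) -> float:
        return self.f25 - self.lpv

    @property
    def hpt(self) -> float:
        return self.f95 - self.hpv

    @property
    def lower_transgressive(self) -> bool:
        return self.lpt < 0

    @property
    def higher_transgressive(self) -> bool:
        return self.hpt > 0


def haldane_r(d_cm: float | np.ndarray) -> float | np.ndarray:
    """Haldane map function: recombination fraction for a distance in cM."""
    return (1.0 - np.exp(-2.0 * np.asarray(d_cm, dtype=float) / 100.0)) / 2.0


def ril_switch_probability(d_cm: float | np.ndarray, scheme: str = "ril") -> float | np.ndarray:
    """Adjacent-locus parent-of-origin switch probability for fixed lines.

    ``ril`` (selfing to fixation) uses R = 2r/(1+2r); ``dh`` (doubled
    haploids, one meiosis) uses R = r.
    """
    r = haldane_r(d_cm)
    if scheme == "ril":
        return 2.0 * r / (1.0 + 2.0 * r)
    if scheme == "dh":
        return r
    raise ValueError(f"unknown scheme {scheme!r}")


def derive_genetic_map(
    loci: pd.DataFrame,
    cm_per_mb: float = 2.5,
    map_file: str | Path | None = None,
) -> GeneticMap:
    """Genetic map over the detected genes.

    ``loci`` needs columns ``gene_id, chrom, anchor`` (physical bp).  By
    default adjacent distances are the physical gaps converted at
    ``cm_per_mb``; a user map TSV (columns chrom, gene_id, cm) overrides
    the conversion.  Loci on different chromosomes are unlinked.
    """
    if cm_per_mb <= 0:
        raise ValueError("cm_per_mb must be > 0")
    user_cm: dict[str, float] = {}
    if map_file is not None:
        mf = pd.read_csv(map_file, sep="\t", comment="#")
        for col in ("chrom", "gene_id", "cm"):
            if col not in mf.columns:
                raise ValueError(f"map file missing column {col!r}")
        user_cm = dict(zip(mf["gene_id"].astype(str), mf["cm"].astype(float)))
    chromosomes: dict[str, list[str]] = {}
    distances: dict[str, np.ndarray] = {}
    for chrom, grp in loci.groupby("chrom", sort=True):
        grp = grp.sort_values("anchor", kind="stable")
        genes = grp["gene_id"].tolist()
        chromosomes[chrom] = genes
        if user_cm:
            missing = [g for g in genes if g not in user_cm]
            if missing:
                raise ValueError(f"map file lacks positions for {missing[:5]}")
            cm = np.array([user_cm[g] for g in genes])
            if np.any(np.diff(cm) < 0):
                raise ValueError(f"{chrom}: user map positions not monotone")
            distances[chrom] = np.diff(cm)
        else:
            bp = grp["anchor"].to_numpy(dtype=float)
            distances[chrom] = cm_per_mb * np.diff(bp) / 1e6
    return GeneticMap(chromosomes, distances)


def simulate_homozygous_progeny(
    p1: np.ndarray,
    p2: np.ndarray,
    gene_ids: Sequence[str],
    gmap: GeneticMap,
    n: int = 2000,
    model: Literal["linkage", "independent"] = "linkage",
    rng: np.random.Generator | int | None = None,
    scheme: str = "ril",
) -> np.ndarray:
    """Simulate ``n`` homozygous progeny allele vectors for one cross.

    ``p1`` and ``p2`` are the parents' allele indices over ``gene_ids``
    (ordered as in the genetic map).  Under ``independent`` every locus
    inherits from either parent with probability 1/2 independently; under
    ``linkage`` the parent-of-origin per chromosome follows a Markov chain
    with switch probability R between adjacent loci.
    """
    if n <= 0:
        raise ValueError("n must be > 0")
    rng = np.random.default_rng(rng)
    p1 = np.asarray(p1)
    p2 = np.asarray(p2)
    L = len(gene_ids)
    if len(p1) != L or len(p2) != L:
        raise ValueError("parent vectors do not match the locus list")
    gene_pos = {g: i for i, g in enumerate(gene_ids)}
    origin = np.empty((n, L), dtype=bool)  # True -> from parent 2
    if model == "independent":
        origin[:] = rng.random((n, L)) < 0.5
    elif model == "linkage":
        for chrom, loci in gmap.chromosomes.items():
            idx = [gene_pos[g] for g in loci if g in gene_pos]
            if not idx:
                continue
            present = [g for g in loci if g in gene_pos]
            # distances between consecutive *present* loci (sum the gaps)
            d_all = gmap.distances[chrom]
            pos_in_chrom = {g: i for i, g in enumerate(loci)}
            cum = np.concatenate([[0.0], np.cumsum(d_all)])
            d = np.array(
                [cum[pos_in_chrom[present[i + 1]]] - cum[pos_in_chrom[present[i]]]
                 for i in range(len(present) - 1)]
            )
            R = ril_switch_probability(d, scheme=scheme)
            state = rng.random(n) < 0.5
            origin[:, idx[0]] = state
            for j in range(1, len(idx)):
                switch = rng.random(n) < R[j - 1]
                state = state ^ switch
                origin[:, idx[j]] = state
    else:
        raise ValueError(f"unknown model {model!r}")
    return np.where(origin, p2[None, :], p1[None, :])


def genotypic_value(
    progeny: np.ndarray,
    gene_ids: Sequence[str],
    effects: dict[str, np.ndarray],
    intercept: float = 0.0,
) -> np.ndarray:
    """Additive genotypic values: intercept + summed allele main effects."""
    progeny = np.atleast_2d(progeny)
    values = np.full(progeny.shape[0], float(intercept))
    for j, g in enumerate(gene_ids):
        e = effects[g]
        idx = progeny[:, j]
        if idx.max() >= len(e):
            raise KeyError(f"gene {g}: allele index {idx.max()} unknown to the effect lookup")
        values += e[idx]
    return values


def cross_potential(
    values: np.ndarray,
    lpv: float,
    hpv: float,
    parent1: str = "P1",
    parent2: str = "P2",
    model: str = "linkage",
) -> CrossPotential:
    """Percentile transgression statistics from simulated progeny values.

    Percentiles use linear interpolation between order statistics
    (numpy's default, the type-7 convention: h = (n-1) * p).
    """
    values = np.asarray(values, dtype=float)
    if values.size < 2:
        raise ValueError("need at least 2 progeny values")
    if lpv > hpv:
        lpv, hpv = hpv, lpv
    f25, f95 = np.percentile(values, [25, 95])
    return CrossPotential(parent1, parent2, model, float(f25), float(f95), lpv, hpv)


def enumerate_crosses(
    matrix: GeneAlleleMatrix,
    gmap: GeneticMap,
    n: int = 2000,
    models: Sequence[str] = ("linkage",),
    seed: int = 0,
    rank_by: str = "hpt",
    scheme: str = "ril",
) -> pd.DataFrame:
    """Simulate every unordered parent pair and rank by transgression.

    One RNG stream is derived per (cross, model) from the master seed and
    the pair index, so enumeration order never changes the results.
    Returns a table with one row per pair and model, sorted by ``hpt``
    descending (or ``lpt`` ascending), ties broken by the pair label.
    """
    acc = matrix.accession_ids
    if len(acc) < 2:
        raise ValueError("need at least 2 accessions to enumerate crosses")
    gene_ids = [g for g in gmap.gene_ids if g in matrix.gene_ids]
    assign = matrix.assignment[gene_ids].to_numpy()
    effects = matrix.effects
    intercept = matrix.intercept
    parent_values = genotypic_value(assign, gene_ids, effects, intercept)
    rows = []
    pair_index = 0
    for i in range(len(acc)):
        for j in range(i + 1, len(acc)):
            for mi, model in enumerate(models):
                rng = np.random.default_rng(
                    np.random.SeedSequence([int(seed), pair_index, mi])
                )
                progeny = simulate_homozygous_progeny(
                    assign[i], assign[j], gene_ids, gmap, n=n, model=model,
                    rng=rng, scheme=scheme,
                )
                values = genotypic_value(progeny, gene_ids, effects, intercept)
                lpv = float(min(parent_values[i], parent_values[j]))
                hpv = float(max(parent_values[i], parent_values[j]))
                cp = cross_potential(values, lpv, hpv, acc[i], acc[j], model)
                rows.append(
                    {
                        "parent1": acc[i],
                        "parent2": acc[j],
                        "model": model,
                        "f25": cp.f25,
                        "f95": cp.f95,
                        "lpv": cp.lpv,
                        "hpv": cp.hpv,
                        "lpt": cp.lpt,
                        "hpt": cp.hpt,
                        "lower_transgressive": cp.lower_transgressive,
                        "higher_transgressive": cp.higher_transgressive,
                    }
                )
            pair_index += 1
    table = pd.DataFrame(rows)
    ascending = rank_by == "lpt"
    table = table.sort_values(
        [rank_by, "parent1", "parent2"],
        ascending=[ascending, True, True],
        kind="stable",
    ).reset_index(drop=True)
    return table
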