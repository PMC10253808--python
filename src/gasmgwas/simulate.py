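"""Synthetic structured panels, planted QTL architectures and evolution scenarios.

The generator emulates a structured inbred germplasm panel: SNP allele
frequencies follow a two-level Balding-Nichols-style model (an ancestral
frequency per SNP, subpopulation frequencies drawn around it with a
divergence parameter), accessions are fully homozygous draws within their
subpopulation, genes are laid out non-overlapping with known intervals, and
multi-environment phenotypes are built from planted GASM-allele effects
plus a polygenic background, G-by-E deviations, block effects and plot
residuals calibrated so the entry-mean heritability of the generated data
approaches its target.  Evolution scenarios plant known emerged and
excluded alleles by reassigning carriers, giving exact ground truth for
the submatrix comparison.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .gasm import GasmMarker, GasmSet
from .io import GEO_GROUPS, MG_SETS, AccessionMetadata, GeneInterval, PhenotypeTable, SnpMatrix


@dataclass
class SimulationTruth:
    """Everything the generator decided, for checking recovery downstream."""

    seed: int
    subpopulation: dict[str, int] | None = None
    qtl_effects: dict[str, np.ndarray] = field(default_factory=dict)
    qtl_env_effects: dict[str, np.ndarray] = field(default_factory=dict)
    h2_target: float | None = None
    ge_share: float | None = None
    components: dict[str, float] = field(default_factory=dict)
    emerged: list[tuple[str, str]] = field(default_factory=list)
    excluded: list[tuple[str, str]] = field(default_factory=list)


# ---------------------------------------------------------------------------
# Genotypes
# ---------------------------------------------------------------------------

def simulate_genotypes(
    n_acc: int = 354,
    n_subpop: int = 5,
    divergence: float = 0.12,
    n_chrom: int = 4,
    genes_per_chrom: int = 50,
    snps_per_gene_range: tuple[int, int] = (1, 3),
    seed: int = 0,
    gene_length: int = 2_000,
    gene_spacing: int = 2_000_000,
) -> tuple[SnpMatrix, list[GeneInterval], AccessionMetadata]:
    """Structured inbred panel with genes of known intervals.

    Per SNP an ancestral frequency is drawn uniformly in (0.05, 0.95);
    each subpopulation's frequency comes from a Beta with that mean and
    variance F * p * (1 - p) (F = ``divergence``), and inbred accessions
    are homozygous Bernoulli draws at their subpopulation's frequency.
    """
    if not (0 <= divergence < 1):
        raise ValueError("divergence must be in [0, 1)")
    lo, hi = snps_per_gene_range
    if lo < 1 or hi < lo:
        raise ValueError("bad snps_per_gene_range")
    if gene_length >= gene_spacing:
        raise ValueError("genes overflow the chromosome layout (length >= spacing)")
    rng = np.random.default_rng(seed)
    subpop = rng.integers(0, n_subpop, size=n_acc)
    subpop.sort()  # contiguous groups; labels below carry the grouping
    accession_ids = [f"acc{i:04d}" for i in range(n_acc)]

    genes: list[GeneInterval] = []
    snp_rows = []
    call_cols: list[np.ndarray] = []
    for c in range(n_chrom):
        chrom = f"chr{c + 1:02d}"
        for g in range(genes_per_chrom):
            start = g * gene_spacing + 1_000
            end = start + gene_length - 1
            gene_id = f"g{c + 1:02d}_{g + 1:03d}"
            genes.append(GeneInterval(gene_id, chrom, start, end))
            n_snp = int(rng.integers(lo, hi + 1))
            positions = np.sort(
                rng.choice(np.arange(start, end + 1), size=n_snp, replace=False)
            )
            for k, pos in enumerate(positions):
                p_anc = rng.uniform(0.05, 0.95)
                if divergence > 0:
                    a = p_anc * (1 - divergence) / divergence
                    b = (1 - p_anc) * (1 - divergence) / divergence
                    p_sub = rng.beta(a, b, size=n_subpop)
                else:
                    p_sub = np.full(n_subpop, p_anc)
                calls = (rng.random(n_acc) < p_sub[subpop]).astype(np.int8)
                snp_rows.append((f"{gene_id}_s{k + 1}", chrom, int(pos)))
                call_cols.append(calls)
    snps = pd.DataFrame(snp_rows, columns=["snp_id", "chrom", "pos"])
    calls = np.stack(call_cols, axis=1)
    meta = AccessionMetadata(
        pd.DataFrame(
            {
                "accession": accession_ids,
                "geo_group": [GEO_GROUPS[s % len(GEO_GROUPS)] for s in subpop],
                "mg_set": [MG_SETS[s % len(MG_SETS)] for s in subpop],
            }
        )
    )
    matrix = SnpMatrix(accession_ids, snps, calls)
    return matrix, genes, meta


# ---------------------------------------------------------------------------
# Phenotypes
# ---------------------------------------------------------------------------

def _residual_variance(x: np.ndarray, Z: np.ndarray | None) -> float:
    """Variance of x after projecting out the column space of Z (and the mean)."""
    if Z is None:
        return float(np.var(x))
    beta, _, _, _ = np.linalg.lstsq(Z, x, rcond=None)
    r = x - Z @ beta
    return float(r @ r) / len(x)


def choose_qtl_genes(
    gasm_set: GasmSet,
    n: int,
    rng: np.random.Generator | int | None = None,
    cov=None,
    min_within: float = 0.8,
    min_freq: float = 0.05,
    max_alleles: int = 4,
    relax: bool = False,
) -> list[str]:
    """Pick QTL genes whose allelic variation is not swallowed by structure.

    A gene qualifies when it carries at most ``max_alleles`` haplotype
    alleles (matching the typical marker of a real panel, where most genes
    carry 2-4 alleles), every allele reaches frequency ``min_freq`` (so
    each planted effect has enough carriers to be estimable) and at least
    ``min_within`` of a random centered allele-effect's variance survives
    projection on the structure covariates, so the planted signal is
    identifiable after correction.
    """
    rng = np.random.default_rng(rng)
    Z = None
    if cov is not None:
        Z = np.column_stack([np.ones(len(gasm_set.accession_ids)), cov.vectors])
    chosen: list[str] = []
    for gene_id in rng.permutation(gasm_set.gene_ids):
        m = gasm_set[gene_id]
        if m.n_alleles > max_alleles or m.frequencies.min() < min_freq:
            continue
        e = rng.normal(size=m.n_alleles)
        e -= e.mean()
        x = e[m.assignment]
        v_tot = float(np.var(x))
        if v_tot <= 0:
            continue
        if _residual_variance(x, Z) / v_tot >= min_within:
            chosen.append(str(gene_id))
        if len(chosen) == n:
            return chosen
    if relax and (min_within > 0.3 or min_freq > 0.02 or max_alleles < 8):
        # small demo panels may lack strictly qualifying genes
        return choose_qtl_genes(
            gasm_set, n, rng, cov,
            min_within=max(min_within - 0.2, 0.3),
            min_freq=max(min_freq / 2, 0.02),
            max_alleles=min(max_alleles + 2, 8),
            relax=True,
        )
    raise ValueError(f"only {len(chosen)} of {n} requested QTL genes qualify")


def draw_qtl_spec(
    gasm_set: GasmSet,
    gene_r2: Mapping[str, float],
    rng: np.random.Generator | int | None = None,
    env_interaction: Mapping[str, float] | None = None,
    n_env: int = 4,
    cov=None,
) -> dict[str, dict]:
    """Draw calibrated allele effects for chosen QTL genes.

    ``gene_r2`` maps gene ids to their target share of phenotypic variance
    (on a unit phenotypic-variance scale).  Raw effects are standard-normal
    per allele, centered, then scaled so the empirical variance of the
    gene's effect over the panel equals the target.  When structure
    covariates are passed, the calibration uses the structure-adjusted
    variance instead, so the target is the share attributable to the gene
    net of population structure — the estimand the association model
    reports.  ``env_interaction`` optionally adds doubly-centered
    allele-by-environment deviations with the given variance share.
    """
    rng = np.random.default_rng(rng)
    Z = None
    if cov is not None:
        Z = np.column_stack([np.ones(len(gasm_set.accession_ids)), cov.vectors])
    spec: dict[str, dict] = {}
    for gene_id, r2 in gene_r2.items():
        m = gasm_set[gene_id]
        k = m.n_alleles
        e = rng.normal(size=k)
        e -= e.mean()
        v = _residual_variance(e[m.assignment], Z)
        if v <= 0:
            raise ValueError(f"gene {gene_id} is effectively monomorphic in the panel")
        e *= np.sqrt(r2 / v)
        entry: dict = {"effects": e}
        if env_interaction and gene_id in env_interaction:
            ge = rng.normal(size=(k, n_env))
            ge -= ge.mean(axis=0, keepdims=True)
            ge -= ge.mean(axis=1, keepdims=True)
            v_ge = float(np.var(ge[m.assignment], axis=0).mean())
            if v_ge > 0:
                ge *= np.sqrt(env_interaction[gene_id] / v_ge)
            entry["env_effects"] = ge
        spec[gene_id] = entry
    return spec


def simulate_phenotypes(
    gasm_set: GasmSet,
    qtl_spec: Mapping[str, Mapping],
    n_env: int = 4,
    n_rep: int = 2,
    h2_target: float = 0.9,
    ge_share: float = 0.05,
    seed: int = 0,
    trait: str = "trait",
    grand_mean: float = 50.0,
    calibrated: bool = True,
) -> tuple[PhenotypeTable, SimulationTruth]:
    """Multi-environment RCBD phenotypes from planted GASM-allele effects.

    With ``calibrated=True`` the planted effects are taken on a unit
    phenotypic-variance scale (as produced by :func:`draw_qtl_spec`): a
    polygenic background tops the genotypic variance up to
    ``h2_target``, and G-by-E, block and residual variances are set so the
    entry-mean heritability formula evaluated on the generating components
    equals the targets.  With ``calibrated=False`` the planted effects ARE
    the whole genotypic signal and the noise is scaled around them.
    """
    if not (0 < h2_target <= 1):
        raise ValueError("h2_target must be in (0, 1]")
    if not (0 <= ge_share < h2_target):
        raise ValueError("ge_share must be in [0, h2_target)")
    if ge_share > 0 and n_env == 1:
        raise ValueError("G-by-E share requested with a single environment")
    rng = np.random.default_rng(seed)
    acc = gasm_set.accession_ids
    n_acc = len(acc)
    missing = [g for g in qtl_spec if g not in gasm_set.gene_ids]
    if missing:
        raise ValueError(f"QTL genes not in GasmSet: {missing}")

    q = np.zeros(n_acc)
    env_dev = np.zeros((n_acc, n_env))
    truth = SimulationTruth(seed=int(seed), h2_target=h2_target, ge_share=ge_share)
    for gene_id, entry in qtl_spec.items():
        m = gasm_set[gene_id]
        e = np.asarray(entry["effects"], dtype=float)
        if len(e) != m.n_alleles:
            raise ValueError(f"{gene_id}: {len(e)} effects for {m.n_alleles} alleles")
        q += e[m.assignment]
        truth.qtl_effects[gene_id] = e.copy()
        if "env_effects" in entry and entry["env_effects"] is not None:
            ge = np.asarray(entry["env_effects"], dtype=float)
            if ge.shape != (m.n_alleles, n_env):
                raise ValueError(f"{gene_id}: env_effects shape {ge.shape}")
            env_dev += ge[m.assignment]
            truth.qtl_env_effects[gene_id] = ge.copy()

    var_q = float(np.var(q))
    if calibrated:
        D = 1.0  # unit phenotypic variance of entry means
        sigma2_poly = max(h2_target * D - var_q, 0.0)
    else:
        if var_q <= 0:
            raise ValueError("planted effects carry no variance")
        D = var_q / h2_target
        sigma2_poly = 0.0
    g_poly = rng.normal(0.0, np.sqrt(sigma2_poly), size=n_acc) if sigma2_poly > 0 else 0.0
    g_total = q + g_poly

    sigma2_ge_target = n_env * ge_share * D
    v_ge_planted = float(np.var(env_dev)) if np.any(env_dev) else 0.0
    sigma2_ge_rand = max(sigma2_ge_target - v_ge_planted, 0.0)
    sigma2_e = n_rep * n_env * max(1.0 - h2_target - ge_share, 0.0) * D
    sigma2_b = 0.02 * D

    env_main = rng.normal(0.0, np.sqrt(D), size=n_env)
    block_eff = rng.normal(0.0, np.sqrt(sigma2_b), size=(n_env, n_rep))
    ge_rand = (
        rng.normal(0.0, np.sqrt(sigma2_ge_rand), size=(n_acc, n_env))
        if sigma2_ge_rand > 0
        else np.zeros((n_acc, n_env))
    )
    eps = (
        rng.normal(0.0, np.sqrt(sigma2_e), size=(n_acc, n_env, n_rep))
        if sigma2_e > 0
        else np.zeros((n_acc, n_env, n_rep))
    )

    y = (
        grand_mean
        + env_main[None, :, None]
        + block_eff[None, :, :]
        + g_total[:, None, None]
        + (env_dev + ge_rand)[:, :, None]
        + eps
    )
    records = pd.DataFrame(
        {
            "accession": np.repeat(acc, n_env * n_rep),
            "environment": np.tile(np.repeat([f"E{i+1}" for i in range(n_env)], n_rep), n_acc),
            "block": np.tile([f"B{j+1}" for j in range(n_rep)], n_acc * n_env),
            "trait": trait,
            "value": y.ravel(),
        }
    )
    truth.components = {
        "sigma2_g": var_q + (float(sigma2_poly)),
        "sigma2_qtl": var_q,
        "sigma2_poly": float(sigma2_poly),
        "sigma2_ge": sigma2_ge_rand + v_ge_planted,
        "sigma2_e": sigma2_e,
        "sigma2_b": sigma2_b,
        "phenotypic_variance_entry_mean": D,
    }
    return PhenotypeTable(records), truth


# ---------------------------------------------------------------------------
# Evolution scenarios
# ---------------------------------------------------------------------------

def _group_indices(
    gasm_set: GasmSet, meta: AccessionMetadata, group_column: str
) -> dict[str, np.ndarray]:
    labels = meta.records.set_index("accession")[group_column]
    out: dict[str, np.ndarray] = {}
    for lab in sorted(labels.unique()):
        members = set(labels.index[labels == lab])
        out[lab] = np.array([i for i, a in enumerate(gasm_set.accession_ids) if a in members])
    return out


def make_evolution_scenario(
    gasm_set: GasmSet,
    meta: AccessionMetadata,
    n_emerged: int = 5,
    n_excluded: int = 3,
    seed: int = 0,
    group_column: str = "geo_group",
    ancestral: str = "O",
) -> tuple[GasmSet, SimulationTruth]:
    """Plant known emerged and excluded alleles into a GasmSet.

    The base set is first regularised so every allele of every gene is
    carried in every group (reassigning carriers of each group's modal
    allele), which makes the planted sets the exact ground truth of the
    contrast.  Emerged alleles then lose all their ancestral-group carriers;
    excluded alleles lose their carriers in every derived group.  Donors
    always move to the group's modal allele, so no other allele's presence
    changes.
    """
    rng = np.random.default_rng(seed)
    groups = _group_indices(gasm_set, meta, group_column)
    if ancestral not in groups:
        raise ValueError(f"ancestral group {ancestral!r} absent from {group_column}")
    derived_labels = [g for g in groups if g != ancestral]
    assign = {m.gene_id: m.assignment.copy() for m in gasm_set}

    def modal(gene: str, idx: np.ndarray, exclude: int | None = None) -> int:
        vals, counts = np.unique(assign[gene][idx], return_counts=True)
        order = np.argsort(-counts, kind="stable")
        for o in order:
            if exclude is None or vals[o] != exclude:
                return int(vals[o])
        raise ValueError(f"{gene}: no modal allele outside {exclude}")

    # regularise: every allele present in every group
    for m in gasm_set:
        g = m.gene_id
        for lab, idx in groups.items():
            for k in range(m.n_alleles):
                counts = np.bincount(assign[g][idx], minlength=m.n_alleles)
                if counts[k] > 0:
                    continue
                mode = int(np.argmax(counts))
                donors = idx[assign[g][idx] == mode]
                if counts[mode] < 2 or len(donors) == 0:
                    raise ValueError(
                        f"cannot regularise {g} allele {k} in group {lab}: too few donors"
                    )
                assign[g][donors[0]] = k

    # pick disjoint genes for the plantings
    eligible = [m.gene_id for m in gasm_set if m.n_alleles >= 2]
    need = n_emerged + n_excluded
    if need > len(eligible):
        raise ValueError(f"need {need} genes but only {len(eligible)} are eligible")
    chosen = list(rng.choice(eligible, size=need, replace=False)) if need else []
    emerged_genes, excluded_genes = chosen[:n_emerged], chosen[n_emerged:]
    truth = SimulationTruth(seed=int(seed))
    anc_idx = groups[ancestral]

    for g in emerged_genes:
        marker = gasm_set[g]
        k = int(rng.integers(0, marker.n_alleles))
        target = modal(g, anc_idx, exclude=k)
        carriers = anc_idx[assign[g][anc_idx] == k]
        assign[g][carriers] = target
        truth.emerged.append((g, marker.alleles[k]))
    for g in excluded_genes:
        marker = gasm_set[g]
        k = int(rng.integers(0, marker.n_alleles))
        for lab in derived_labels:
            idx = groups[lab]
            target = modal(g, idx, exclude=k)
            carriers = idx[assign[g][idx] == k]
            assign[g][carriers] = target
        truth.excluded.append((g, marker.alleles[k]))

    n_acc = len(gasm_set.accession_ids)
    markers = []
    for m in gasm_set:
        a = assign[m.gene_id]
        freqs = np.bincount(a, minlength=m.n_alleles).astype(float) / n_acc
        markers.append(
            GasmMarker(
                m.gene_id, m.chromosome, m.anchor_position, list(m.snp_ids),
                list(m.alleles), a, freqs,
            )
        )
    return GasmSet(list(gasm_set.accession_ids), markers), truth
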