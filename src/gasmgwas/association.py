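"""Restricted two-stage multi-locus association on GASM markers.

Stage 1 screens every marker with a single-locus partial F-test against a
baseline of intercept plus population-structure eigenvector covariates,
keeping markers with p below ``alpha1`` (default 0.05).  Stage 2 runs
forward selection with backward elimination under the multi-locus model,
with trait heritability as an upper bound on the genetic R-square of the
model: a candidate whose inclusion would push the genetic R-square past the
heritability limit is not added.  The final refit re-expresses each gene's
allele effects under an unweighted sum-to-zero constraint and decomposes
the genetic R-square sequentially in selection order, so the per-gene
contributions sum exactly to the model total.  A gene-by-environment
extension then tests, gene by gene, the allele-by-environment interaction
on environment-stacked means, budgeted by the G-by-E heritability share.

The public surface is the statsmodels-style pair :class:`RtmGwas` (model)
and :class:`RtmGwasResults` (fitted results with ``summary()``).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd
import scipy.stats

from .anova import HeritabilityReport, VarianceComponents, estimate_variance_components, heritability_gcv
from .gasm import GasmMarker, GasmSet
from .io import PhenotypeTable
from .structure import StructureCovariates

logger = logging.getLogger(__name__)

LC_MAJOR_R2 = 0.015  # large-contribution major gene: R2 >= 1.5% of phenotypic variance


# ---------------------------------------------------------------------------
# Linear-algebra helpers
# ---------------------------------------------------------------------------

def _fit_ols(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, float, int]:
    """Least squares fit; returns (beta, rss, rank)."""
    beta, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    return beta, float(resid @ resid), int(rank)


def _marker_dummies(marker: GasmMarker) -> np.ndarray:
    """Treatment-coded allele dummies (n x (k-1)); allele 0 is the baseline."""
    k = marker.n_alleles
    d = np.zeros((len(marker.assignment), k - 1))
    for j in range(1, k):
        d[marker.assignment == j, j - 1] = 1.0
    return d


def partial_f_test(
    y: np.ndarray, X_reduced: np.ndarray, X_full: np.ndarray
) -> tuple[float, int, int, float]:
    """Partial F for the extra columns of X_full over X_reduced.

    Returns (F, df1, df2, p).  df1 uses the rank increase, so collinear
    extra columns do not inflate the test.
    """
    _, rss_r, rank_r = _fit_ols(X_reduced, y)
    _, rss_f, rank_f = _fit_ols(X_full, y)
    df1 = rank_f - rank_r
    df2 = len(y) - rank_f
    if df1 <= 0:
        return np.nan, 0, df2, np.nan
    if df2 <= 0:
        raise ValueError("no residual degrees of freedom for the partial F-test")
    if rss_f <= 0:
        return np.inf, df1, df2, 0.0
    f = ((rss_r - rss_f) / df1) / (rss_f / df2)
    f = max(f, 0.0)
    return float(f), df1, df2, float(scipy.stats.f.sf(f, df1, df2))


# ---------------------------------------------------------------------------
# Stage 1
# ---------------------------------------------------------------------------

@dataclass
class StageOneResult:
    """Per-marker single-locus scan: F, dfs, p and the pre-selection flag."""

    table: pd.DataFrame  # columns: gene_id, f, df1, df2, p, selected
    alpha1: float

    @property
    def selected_genes(self) -> list[str]:
        return self.table.loc[self.table["selected"], "gene_id"].tolist()


def _base_design(n: int, cov: StructureCovariates | None) -> np.ndarray:
    if cov is None:
        return np.ones((n, 1))
    return np.column_stack([np.ones(n), cov.vectors])


def stage1_scan(
    y: np.ndarray | pd.Series,
    gasm_set: GasmSet,
    cov: StructureCovariates | None = None,
    alpha1: float = 0.05,
) -> StageOneResult:
    """Single-locus pre-selection scan on per-accession trait means."""
    y = _align_y(y, gasm_set.accession_ids)
    n = len(y)
    X0 = _base_design(n, cov)
    max_k = max(m.n_alleles for m in gasm_set)
    if n <= X0.shape[1] + max_k:
        raise ValueError(
            f"{n} accessions are too few for {X0.shape[1]} baseline columns "
            f"plus up to {max_k} alleles"
        )
    rows = []
    for m in gasm_set:
        Xm = np.column_stack([X0, _marker_dummies(m)])
        f, df1, df2, p = partial_f_test(y, X0, Xm)
        rows.append((m.gene_id, f, df1, df2, p, bool(p < alpha1)))
    table = pd.DataFrame(rows, columns=["gene_id", "f", "df1", "df2", "p", "selected"])
    return StageOneResult(table, alpha1)


def _align_y(y: np.ndarray | pd.Series, accession_ids: Sequence[str]) -> np.ndarray:
    if isinstance(y, pd.Series):
        missing = [a for a in accession_ids if a not in y.index]
        if missing:
            raise ValueError(f"phenotype missing for accessions {missing[:5]}")
        return y.loc[list(accession_ids)].to_numpy(dtype=float)
    y = np.asarray(y, dtype=float)
    if len(y) != len(accession_ids):
        raise ValueError("y length does not match the accession panel")
    return y


# ---------------------------------------------------------------------------
# The model / results pair
# ---------------------------------------------------------------------------

@dataclass
class _GeneFit:
    gene_id: str
    chromosome: str
    anchor: int
    alleles: list[str]
    effects: np.ndarray            # sum-to-zero main effects, one per allele
    frequencies: np.ndarray
    r2_seq: float                  # sequential R2 in selection order
    r2_partial: float              # partial R2 (drop-one)
    p_final: float                 # partial-F p in the final model
    r2_ge: float = 0.0
    ge_p: float = float("nan")
    ge_retained: bool = False
    env_effects: pd.DataFrame | None = None  # allele x environment deviations


class RtmGwas:
    """Restricted two-stage multi-locus GWAS model.

    Parameters
    ----------
    pheno : PhenotypeTable
        Plot-level observations; the main-effect scan runs on per-accession
        means over environments and blocks.
    trait : str
        Trait name within ``pheno``.
    gasm_set : GasmSet
        Multi-allelic gene markers for the same accession panel.
    cov : StructureCovariates, optional
        Structure eigenvector covariates (typically the top 10 of the GSC).
    h2 : float or "auto"
        Heritability cap for the genetic R-square of the multi-locus model.
        ``"auto"`` estimates it from the phenotype table's variance
        components; a float in (0, 1] fixes it directly.
    """

    def __init__(
        self,
        pheno: PhenotypeTable,
        trait: str,
        gasm_set: GasmSet,
        cov: StructureCovariates | None = None,
        h2: float | str = "auto",
    ) -> None:
        self.pheno = pheno
        self.trait = trait
        self.gasm_set = gasm_set
        self.cov = cov
        if cov is not None and list(cov.accession_ids) != list(gasm_set.accession_ids):
            raise ValueError("covariates and GASM set index different accession panels")
        self.y = _align_y(pheno.accession_means(trait), gasm_set.accession_ids)
        self.herit: HeritabilityReport | None = None
        self.vc: VarianceComponents | None = None
        if h2 == "auto":
            self.vc = estimate_variance_components(pheno, trait)
            self.herit = heritability_gcv(self.vc)
            self.h2_limit = self.herit.h2_g
            self.h2_ge_limit = self.herit.h2_ge
        else:
            h2 = float(h2)
            if not (0 < h2 <= 1):
                raise ValueError(f"h2 must be in (0, 1], got {h2}")
            self.h2_limit = h2
            self.h2_ge_limit = max(1.0 - h2, 0.0)

    @classmethod
    def from_accession_means(
        cls,
        y: pd.Series | np.ndarray,
        gasm_set: GasmSet,
        cov: StructureCovariates | None = None,
        h2: float = 1.0,
    ) -> "RtmGwas":
        """Build the model directly from per-accession means (single trait)."""
        y = _align_y(y, gasm_set.accession_ids)
        records = pd.DataFrame(
            {
                "accession": gasm_set.accession_ids,
                "environment": "E1",
                "block": "B1",
                "trait": "trait",
                "value": y,
            }
        )
        obj = cls.__new__(cls)
        obj.pheno = PhenotypeTable(records)
        obj.trait = "trait"
        obj.gasm_set = gasm_set
        obj.cov = cov
        obj.y = y
        obj.herit = None
        obj.vc = None
        obj.h2_limit = float(h2)
        obj.h2_ge_limit = max(1.0 - float(h2), 0.0)
        return obj

    # -- fitting ----------------------------------------------------------

    def fit(
        self,
        alpha1: float = 0.05,
        alpha2: float = 0.05,
        alpha_mode: Literal["fixed", "bonferroni"] = "fixed",
        gxe: bool = False,
        max_steps: int = 500,
    ) -> "RtmGwasResults":
        """Run stage 1 + restricted stepwise stage 2 (+ optional G-by-E)."""
        stage1 = stage1_scan(self.y, self.gasm_set, self.cov, alpha1)
        preselected = stage1.selected_genes
        selected, path = self._stage2(preselected, alpha2, alpha_mode, max_steps)
        results = self._finalize(selected, stage1, path, alpha2)
        if gxe:
            results = self._gxe_extension(results, alpha2)
        return results

    def _alpha(self, alpha2: float, alpha_mode: str, n_candidates: int) -> float:
        if alpha_mode == "bonferroni":
            return alpha2 / max(n_candidates, 1)
        if alpha_mode != "fixed":
            raise ValueError(f"unknown alpha_mode {alpha_mode!r}")
        return alpha2

    def _stage2(
        self,
        preselected: Sequence[str],
        alpha2: float,
        alpha_mode: str,
        max_steps: int,
    ) -> tuple[list[str], list[dict]]:
        """Forward selection + backward elimination bounded by h2_limit.

        Returns the ordered selection and a step log (for diagnostics).
        """
        if not preselected:
            return [], []
        alpha = self._alpha(alpha2, alpha_mode, len(preselected))
        markers = {m.gene_id: m for m in self.gasm_set}
        order = {m.gene_id: i for i, m in enumerate(self.gasm_set)}
        y = self.y
        n = len(y)
        X0 = _base_design(n, self.cov)
        tss = float(((y - y.mean()) ** 2).sum())
        _, rss0, _ = _fit_ols(X0, y)

        def design(genes: Sequence[str]) -> np.ndarray:
            blocks = [X0] + [_marker_dummies(markers[g]) for g in genes]
            return np.column_stack(blocks)

        selected: list[str] = []
        candidates = [g for g in preselected]
        path: list[dict] = []
        for _step in range(max_steps):
            X_cur = design(selected)
            _, rss_cur, _ = _fit_ols(X_cur, y)
            r2_cur = (rss0 - rss_cur) / tss if tss > 0 else 0.0
            if r2_cur >= self.h2_limit:
                break
            # forward: score every remaining candidate
            scored = []
            for g in candidates:
                X_try = np.column_stack([X_cur, _marker_dummies(markers[g])])
                f, df1, df2, p = partial_f_test(y, X_cur, X_try)
                if df1 <= 0:
                    logger.warning("marker %s collinear with current model; skipped", g)
                    continue
                _, rss_try, _ = _fit_ols(X_try, y)
                r2_try = (rss0 - rss_try) / tss if tss > 0 else 0.0
                scored.append((p, -f, order[g], g, r2_try))
            scored.sort()
            added = None
            for p, negf, _, g, r2_try in scored:
                if not (p < alpha):
                    break  # sorted by p: no further candidate can qualify
                if r2_try > self.h2_limit:
                    continue  # would breach the heritability cap; try next best
                added = g
                path.append({"action": "add", "gene": g, "p": p, "r2": r2_try})
                break
            if added is None:
                break
            selected.append(added)
            candidates.remove(added)
            # backward elimination, largest p first, iterating
            while len(selected) > 1:
                X_all = design(selected)
                worst: tuple[float, str] | None = None
                for g in selected:
                    rest = [h for h in selected if h != g]
                    f, df1, df2, p = partial_f_test(y, design(rest), X_all)
                    if worst is None or p > worst[0]:
                        worst = (p, g)
                if worst is not None and worst[0] >= alpha:
                    selected.remove(worst[1])
                    candidates.append(worst[1])
                    path.append({"action": "drop", "gene": worst[1], "p": worst[0]})
                else:
                    break
        return selected, path

    def _finalize(
        self,
        selected: list[str],
        stage1: StageOneResult,
        path: list[dict],
        alpha2: float,
    ) -> "RtmGwasResults":
        """Final refit: sum-to-zero allele effects and sequential R2."""
        markers = {m.gene_id: m for m in self.gasm_set}
        y = self.y
        n = len(y)
        X0 = _base_design(n, self.cov)
        tss = float(((y - y.mean()) ** 2).sum())
        _, rss0, rank0 = _fit_ols(X0, y)

        blocks = [X0] + [_marker_dummies(markers[g]) for g in selected]
        X_full = np.column_stack(blocks)
        beta, rss_full, rank_full = _fit_ols(X_full, y)
        df_resid = n - rank_full
        resid_var = rss_full / df_resid if df_resid > 0 else 0.0
        r2_genetic = (rss0 - rss_full) / tss if tss > 0 else 0.0

        # sequential R2 in selection order
        seq_r2: dict[str, float] = {}
        rss_prev = rss0
        for i, g in enumerate(selected):
            Xi = np.column_stack([X0] + [_marker_dummies(markers[h]) for h in selected[: i + 1]])
            _, rss_i, _ = _fit_ols(Xi, y)
            seq_r2[g] = (rss_prev - rss_i) / tss if tss > 0 else 0.0
            rss_prev = rss_i

        # per-gene partial stats in the final model
        partial: dict[str, tuple[float, float]] = {}
        for g in selected:
            rest = [h for h in selected if h != g]
            X_rest = np.column_stack([X0] + [_marker_dummies(markers[h]) for h in rest])
            _, rss_rest, _ = _fit_ols(X_rest, y)
            f, df1, df2, p = partial_f_test(y, X_rest, X_full)
            partial[g] = ((rss_rest - rss_full) / tss if tss > 0 else 0.0, p)

        # re-express effects: treatment coding -> unweighted sum-to-zero
        q = X0.shape[1] - 1
        cov_coefs = beta[1 : 1 + q] if q else np.empty(0)
        intercept = float(beta[0])
        if q:
            intercept += float((X0[:, 1:] @ cov_coefs).mean())
        gene_fits: list[_GeneFit] = []
        col = X0.shape[1]
        for g in selected:
            m = markers[g]
            k = m.n_alleles
            t = np.concatenate([[0.0], beta[col : col + k - 1]])
            col += k - 1
            effects = t - t.mean()
            intercept += float(t.mean())
            gene_fits.append(
                _GeneFit(
                    gene_id=g,
                    chromosome=m.chromosome,
                    anchor=m.anchor_position,
                    alleles=list(m.alleles),
                    effects=effects,
                    frequencies=m.frequencies.copy(),
                    r2_seq=seq_r2[g],
                    r2_partial=partial[g][0],
                    p_final=partial[g][1],
                )
            )
        return RtmGwasResults(
            model=self,
            stage1=stage1,
            gene_fits=gene_fits,
            intercept=intercept,
            covariate_coefs=np.asarray(cov_coefs, dtype=float),
            r2_genetic=float(r2_genetic),
            residual_variance=float(resid_var),
            h2_limit=self.h2_limit,
            h2_ge_limit=self.h2_ge_limit,
            alpha2=alpha2,
            path=path,
        )

    # -- G-by-E extension --------------------------------------------------

    def _gxe_extension(self, results: "RtmGwasResults", alpha2: float) -> "RtmGwasResults":
        """Test allele-by-environment interactions over the selected genes.

        Runs on environment-stacked accession-by-environment means.  The
        interaction R2 is reported on the entry-mean phenotypic-variance
        scale (the gene's interaction variance divided by the number of
        environments and the entry-mean phenotypic variance), which makes
        it commensurate with the main-effect R2 and with the G-by-E
        heritability share h2_ge that caps the cumulative interaction R2,
        mirroring the main-model restriction.
        """
        envs = self.pheno.environments()
        if len(envs) < 2:
            raise ValueError("G-by-E extension needs >= 2 environments")
        if not results.gene_fits:
            return results
        em = self.pheno.environment_means(self.trait)
        em = em[em["accession"].isin(self.gasm_set.accession_ids)]
        acc_index = {a: i for i, a in enumerate(self.gasm_set.accession_ids)}
        rows = em["accession"].map(acc_index).to_numpy()
        env_index = {e: i for i, e in enumerate(envs)}
        env_codes = em["environment"].astype(str).map(env_index).to_numpy()
        y = em["value"].to_numpy(dtype=float)
        n = len(y)

        env_dum = np.zeros((n, len(envs) - 1))
        for e in range(1, len(envs)):
            env_dum[env_codes == e, e - 1] = 1.0
        base_cols = [np.ones((n, 1)), env_dum]
        if self.cov is not None:
            base_cols.append(self.cov.vectors[rows])
        markers = {m.gene_id: m for m in self.gasm_set}
        main_blocks = []
        for gf in results.gene_fits:
            d = _marker_dummies(markers[gf.gene_id])[rows]
            main_blocks.append(d)
        X_main = np.column_stack(base_cols + main_blocks)

        # interaction columns per gene: allele dummy x env dummy
        def inter_block(gene_id: str) -> np.ndarray:
            d = _marker_dummies(markers[gene_id])[rows]
            cols = [d[:, [j]] * env_dum[:, [e]] for j in range(d.shape[1])
                    for e in range(env_dum.shape[1])]
            return np.column_stack(cols) if cols else np.empty((n, 0))

        # entry-mean phenotypic variance: the h2 denominator's scale
        d_entry = float(np.var(self.y))

        accepted: list[str] = []
        X_cur = X_main
        _, rss_cur, _ = _fit_ols(X_cur, y)
        budget = self.h2_ge_limit
        used = 0.0
        denom = len(envs) * d_entry * n
        for gf in results.gene_fits:
            block = inter_block(gf.gene_id)
            X_try = np.column_stack([X_cur, block])
            f, df1, df2, p = partial_f_test(y, X_cur, X_try)
            gf.ge_p = p
            if not (p < alpha2) or df1 <= 0:
                continue
            _, rss_try, _ = _fit_ols(X_try, y)
            r2_ge = (rss_cur - rss_try) / denom if denom > 0 else 0.0
            if used + r2_ge > budget + 1e-9:
                continue  # would breach the G-by-E heritability budget
            gf.r2_ge = r2_ge
            gf.ge_retained = True
            used += r2_ge
            accepted.append(gf.gene_id)
            X_cur, rss_cur = X_try, rss_try

        # per-allele-per-environment deviations from the final stacked fit
        if accepted:
            beta_full, _, _ = _fit_ols(X_cur, y)
            offset = X_main.shape[1]
            for gf in results.gene_fits:
                if not gf.ge_retained:
                    continue
                k = len(gf.alleles)
                ncols = (k - 1) * (len(envs) - 1)
                # locate this gene's interaction columns by acceptance order
                idx = accepted.index(gf.gene_id)
                start = offset + sum(
                    (len(results.get_gene(a).alleles) - 1) * (len(envs) - 1)
                    for a in accepted[:idx]
                )
                coefs = beta_full[start : start + ncols].reshape(k - 1, len(envs) - 1)
                full = np.zeros((k, len(envs)))
                full[1:, 1:] = coefs
                # doubly center so deviations sum to zero over alleles and envs
                full -= full.mean(axis=0, keepdims=True)
                full -= full.mean(axis=1, keepdims=True)
                gf.env_effects = pd.DataFrame(full, index=gf.alleles, columns=envs)
        results.gxe_ran = True
        return results


@dataclass
class RtmGwasResults:
    """Fitted multi-locus model: selected genes, allele effects, R2 decomposition."""

    model: RtmGwas
    stage1: StageOneResult
    gene_fits: list[_GeneFit]
    intercept: float
    covariate_coefs: np.ndarray
    r2_genetic: float
    residual_variance: float
    h2_limit: float
    h2_ge_limit: float
    alpha2: float
    path: list[dict] = field(default_factory=list)
    gxe_ran: bool = False

    @property
    def selected_genes(self) -> list[str]:
        return [gf.gene_id for gf in self.gene_fits]

    def get_gene(self, gene_id: str) -> _GeneFit:
        for gf in self.gene_fits:
            if gf.gene_id == gene_id:
                return gf
        raise KeyError(gene_id)

    @property
    def unmapped_r2(self) -> float:
        """Heritability not captured by the selected genes (unmapped minor genes)."""
        return self.h2_limit - self.r2_genetic

    def effects_lookup(self) -> dict[str, np.ndarray]:
        """gene_id -> array of sum-to-zero allele main effects."""
        return {gf.gene_id: gf.effects for gf in self.gene_fits}

    def gene_table(self) -> pd.DataFrame:
        rows = []
        for gf in self.gene_fits:
            rows.append(
                {
                    "gene_id": gf.gene_id,
                    "chrom": gf.chromosome,
                    "anchor": gf.anchor,
                    "n_alleles": len(gf.alleles),
                    "r2_main": gf.r2_seq,
                    "r2_partial": gf.r2_partial,
                    "r2_ge": gf.r2_ge,
                    "p": gf.p_final,
                    "class": "LC" if gf.r2_seq >= LC_MAJOR_R2 else "SC",
                }
            )
        return pd.DataFrame(
            rows,
            columns=["gene_id", "chrom", "anchor", "n_alleles", "r2_main",
                     "r2_partial", "r2_ge", "p", "class"],
        )

    def allele_table(self) -> pd.DataFrame:
        rows = []
        for gf in self.gene_fits:
            for allele, eff, freq in zip(gf.alleles, gf.effects, gf.frequencies):
                rows.append((gf.gene_id, allele, float(eff), float(freq)))
        return pd.DataFrame(rows, columns=["gene_id", "allele", "effect", "frequency"])

    def predict(self, assignment: pd.DataFrame | None = None) -> np.ndarray:
        """Genotypic values (intercept + summed allele main effects).

        ``assignment`` is an accessions x genes table of allele indices;
        defaults to the fitted panel's own assignments.
        """
        if assignment is None:
            assignment = self.model.gasm_set.assignment_matrix()
        values = np.full(len(assignment), self.intercept)
        for gf in self.gene_fits:
            values += gf.effects[assignment[gf.gene_id].to_numpy()]
        return values

    def summary(self) -> str:
        lines = []
        lines.append("Restricted two-stage multi-locus GWAS")
        lines.append("=" * 54)
        lines.append(f"Trait:                {self.model.trait}")
        lines.append(f"Accessions:           {len(self.model.y)}")
        lines.append(f"Markers scanned:      {len(self.stage1.table)}")
        lines.append(f"Stage-1 preselected:  {len(self.stage1.selected_genes)} "
                     f"(alpha1 = {self.stage1.alpha1})")
        lines.append(f"Genes selected:       {len(self.gene_fits)}")
        lines.append(f"Heritability cap:     {self.h2_limit:.4f}")
        lines.append(f"Genetic R2 (model):   {self.r2_genetic:.4f}")
        lines.append(f"Unmapped minor genes: {self.unmapped_r2:.4f}")
        lines.append(f"Residual variance:    {self.residual_variance:.6g}")
        lines.append("")
        if self.gene_fits:
            tbl = self.gene_table()
            lines.append(f"{'gene':<16}{'chrom':<8}{'alleles':>8}{'R2_main':>10}"
                         f"{'R2_GxE':>10}{'p':>12}  class")
            lines.append("-" * 70)
            for _, r in tbl.iterrows():
                lines.append(
                    f"{r.gene_id:<16}{r.chrom:<8}{r.n_alleles:>8d}"
                    f"{r.r2_main:>10.4f}{r.r2_ge:>10.4f}{r.p:>12.3e}  {r['class']}"
                )
        else:
            lines.append("No genes selected.")
        return "\n".join(lines)


def stage2_stepwise(
    y: pd.Series | np.ndarray,
    gasm_set: GasmSet,
    preselected: Sequence[str],
    cov: StructureCovariates | None = None,
    alpha2: float = 0.05,
    h2_limit: float = 1.0,
    alpha_mode: Literal["fixed", "bonferroni"] = "fixed",
) -> RtmGwasResults:
    """Functional wrapper: stepwise stage 2 from a given pre-selection."""
    model = RtmGwas.from_accession_means(y, gasm_set, cov, h2=h2_limit)
    stage1 = stage1_scan(model.y, gasm_set, cov, alpha1=1.0)
    stage1.table["selected"] = stage1.table["gene_id"].isin(list(preselected))
    selected, path = model._stage2(list(preselected), alpha2, alpha_mode, max_steps=500)
    return model._finalize(selected, stage1, path, alpha2)
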