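"""Variance components, heritability and GCV for multi-environment trials.

The underlying linear model for a randomized complete block design repeated
over environments is

    y_ijk = mu + t_i + r_j(i) + g_k + (gt)_ik + e_ijk

with environments t_i, blocks within environments r_j(i), genotypes g_k,
genotype-by-environment interactions (gt)_ik and plot residuals e_ijk.
Components are estimated by the method of moments from the balanced-design
expected mean squares:

    sigma2_g  = (MS_g - MS_gt) / (n * r)
    sigma2_ge = (MS_gt - MS_e) / r
    sigma2_e  = MS_e

(n environments, r blocks per environment); negative moment estimates are
truncated at zero.  Broad-sense heritability on an entry-mean basis is

    h2_g = sigma2_g / (sigma2_g + sigma2_ge / n + sigma2_e / (r n))

with the G-by-E share h2_ge = (sigma2_ge / n) / (same denominator), and the
genetic coefficient of variation is GCV = sigma_g / mean.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import PhenotypeTable


@dataclass
class VarianceComponents:
    sigma2_g: float
    sigma2_ge: float
    sigma2_e: float
    sigma2_b: float
    n_env: int
    n_rep: int
    grand_mean: float

    def __post_init__(self) -> None:
        for name in ("sigma2_g", "sigma2_ge", "sigma2_e", "sigma2_b"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} < 0")
        if self.n_env < 1 or self.n_rep < 1:
            raise ValueError("n_env and n_rep must be >= 1")


@dataclass
class HeritabilityReport:
    h2_g: float
    h2_ge: float
    gcv: float

    def __post_init__(self) -> None:
        if not (0 <= self.h2_g <= 1 and 0 <= self.h2_ge <= 1):
            raise ValueError("heritabilities must lie in [0, 1]")
        if self.h2_g + self.h2_ge > 1 + 1e-9:
            raise ValueError("h2_g + h2_ge > 1")


def estimate_variance_components(
    pheno: PhenotypeTable, trait: str, max_missing: float = 0.02, impute: bool = False
) -> VarianceComponents:
    """Method-of-moments components from a balanced g x n x r layout.

    Cell missingness up to ``max_missing`` is tolerated only with
    ``impute=True``, which fills missing plots with the genotype-by-
    environment cell mean (falling back to the genotype mean).
    """
    sub = pheno.records[pheno.records["trait"] == trait]
    if sub.empty:
        raise KeyError(f"trait {trait!r} not present")
    genos = sorted(sub["accession"].unique())
    envs = sorted(sub["environment"].astype(str).unique())
    blocks = sorted(sub["block"].astype(str).unique())
    g, n, r = len(genos), len(envs), len(blocks)
    if n < 2:
        raise ValueError("variance-component estimation needs >= 2 environments")
    expected = g * n * r
    missing_frac = 1 - len(sub) / expected
    if missing_frac > 0:
        if missing_frac > max_missing:
            raise ValueError(
                f"{missing_frac:.1%} of cells missing (> {max_missing:.0%}); "
                "re-run with impute=True for mean imputation"
            )
        if not impute:
            raise ValueError(
                f"{missing_frac:.1%} of cells missing; pass impute=True to mean-impute"
            )
    cube = (
        sub.assign(environment=sub["environment"].astype(str), block=sub["block"].astype(str))
        .pivot_table(index="accession", columns=["environment", "block"], values="value")
        .reindex(index=genos)
    )
    arr = cube.to_numpy(dtype=float).reshape(g, n, r)  # genotype x env x block
    if np.isnan(arr).any():
        ge_mean = np.nanmean(arr, axis=2, keepdims=True)
        arr = np.where(np.isnan(arr), np.broadcast_to(ge_mean, arr.shape), arr)
        if np.isnan(arr).any():
            g_mean = np.nanmean(arr, axis=(1, 2), keepdims=True)
            arr = np.where(np.isnan(arr), np.broadcast_to(g_mean, arr.shape), arr)
    grand = arr.mean()
    m_g = arr.mean(axis=(1, 2))          # genotype means
    m_e = arr.mean(axis=(0, 2))          # environment means
    m_ge = arr.mean(axis=2)              # genotype x environment means
    m_eb = arr.mean(axis=0)              # environment x block means
    ss_g = n * r * float(((m_g - grand) ** 2).sum())
    ss_gt = r * float(((m_ge - m_g[:, None] - m_e[None, :] + grand) ** 2).sum())
    ss_b = g * float(((m_eb - m_e[:, None]) ** 2).sum())
    ss_tot = float(((arr - grand) ** 2).sum())
    ss_env = g * r * float(((m_e - grand) ** 2).sum())
    ss_e = ss_tot - ss_env - ss_b - ss_g - ss_gt
    df_g = g - 1
    df_gt = (g - 1) * (n - 1)
    df_b = n * (r - 1)
    df_e = n * (r - 1) * (g - 1)
    if df_e <= 0:
        raise ValueError("no residual degrees of freedom (need r >= 2)")
    ms_g = ss_g / df_g
    ms_gt = ss_gt / df_gt
    ms_e = ss_e / df_e
    ms_b = ss_b / df_b if df_b > 0 else ms_e
    return VarianceComponents(
        sigma2_g=max((ms_g - ms_gt) / (n * r), 0.0),
        sigma2_ge=max((ms_gt - ms_e) / r, 0.0),
        sigma2_e=max(ms_e, 0.0),
        sigma2_b=max((ms_b - ms_e) / g, 0.0),
        n_env=n,
        n_rep=r,
        grand_mean=float(grand),
    )


def heritability_gcv(vc: VarianceComponents) -> HeritabilityReport:
    """Entry-mean heritability, G-by-E share and genetic CV."""
    n, r = vc.n_env, vc.n_rep
    denom = vc.sigma2_g + vc.sigma2_ge / n + vc.sigma2_e / (r * n)
    if denom == 0:
        return HeritabilityReport(0.0, 0.0, 0.0)
    if vc.grand_mean == 0:
        raise ValueError("grand mean is 0; GCV undefined")
    return HeritabilityReport(
        h2_g=vc.sigma2_g / denom,
        h2_ge=(vc.sigma2_ge / n) / denom,
        gcv=float(np.sqrt(vc.sigma2_g)) / vc.grand_mean,
    )
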