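"""Restricted two-stage multi-locus association engine."""

import numpy as np
import pandas as pd
import pytest
import scipy.stats

import gasmgwas as gg
from gasmgwas.association import RtmGwas, _marker_dummies, partial_f_test, stage2_stepwise

from conftest import toy_gasm


# ---------------------------------------------------------------------------
# An independent partial-F oracle built on statsmodels residual sums of squares
# ---------------------------------------------------------------------------

def _oracle_partial_f(y, X_reduced, X_full):
    import statsmodels.api as sm

    fit_r = sm.OLS(y, X_reduced).fit()
    fit_f = sm.OLS(y, X_full).fit()
    df1 = np.linalg.matrix_rank(X_full) - np.linalg.matrix_rank(X_reduced)
    df2 = len(y) - np.linalg.matrix_rank(X_full)
    f = ((fit_r.ssr - fit_f.ssr) / df1) / (fit_f.ssr / df2)
    return f, scipy.stats.f.sf(f, df1, df2)


def _random_instance(n_acc=50, n_markers=20, seed=0, planted=None):
    """Small panel of independent multi-allelic markers with optional signal."""
    rng = np.random.default_rng(seed)
    assignments, alleles = {}, {}
    for j in range(n_markers):
        k = int(rng.integers(2, 4))
        gene = f"m{j:02d}"
        assignments[gene] = rng.integers(0, k, size=n_acc).tolist()
        alleles[gene] = [format(i, "b").zfill(2) for i in range(k)]
    gasm = toy_gasm(assignments, alleles)
    y = rng.normal(size=n_acc)
    if planted:
        for gene, scale in planted.items():
            m = gasm[gene]
            eff = rng.normal(size=m.n_alleles)
            eff -= eff.mean()
            eff *= scale / np.std(eff[m.assignment])
            y = y + eff[m.assignment]
    return gasm, y


class TestStageOne:
    def test_matches_independent_two_model_oracle(self):
        gasm, y = _random_instance(seed=3, planted={"m04": 0.8})
        res = gg.stage1_scan(y, gasm)
        X0 = np.ones((len(y), 1))
        for _, row in res.table.iterrows():
            D = _marker_dummies(gasm[row.gene_id])
            f, p = _oracle_partial_f(y, X0, np.column_stack([X0, D]))
            assert row.f == pytest.approx(f, abs=1e-10)
            assert row.p == pytest.approx(p, abs=1e-10)

    def test_with_covariates_matches_oracle(self, small_panel):
        gasm, cov = small_panel["gasm"], small_panel["cov"]
        rng = np.random.default_rng(9)
        y = rng.normal(size=len(gasm.accession_ids))
        res = gg.stage1_scan(y, gasm, cov)
        X0 = np.column_stack([np.ones(len(y)), cov.vectors])
        for _, row in res.table.sample(5, random_state=1).iterrows():
            D = _marker_dummies(gasm[row.gene_id])
            f, p = _oracle_partial_f(y, X0, np.column_stack([X0, D]))
            assert row.f == pytest.approx(f, abs=1e-10)
            assert row.p == pytest.approx(p, abs=1e-10)

    def test_noiseless_group_means_detected(self):
        gasm, _ = _random_instance(seed=5)
        m = gasm["m00"]
        means = np.array([float(i) for i in range(m.n_alleles)])
        y = means[m.assignment]
        res = gg.stage1_scan(y, gasm)
        row = res.table.set_index("gene_id").loc["m00"]
        assert row.p == pytest.approx(0.0, abs=1e-12)
        assert row.selected

    def test_type_one_error_near_alpha(self):
        """Under a global null the per-marker test rejects at ~alpha."""
        gasm, _ = _random_instance(n_acc=80, n_markers=400, seed=7)
        rng = np.random.default_rng(8)
        y = rng.normal(size=80)
        res = gg.stage1_scan(y, gasm, alpha1=0.05)
        frac = res.table["selected"].mean()
        assert 0.02 < frac < 0.08


class TestStageTwo:
    def test_pure_noise_selects_nothing(self):
        gasm, y = _random_instance(seed=11)
        # pre-select everything so stage 2 alone must reject
        res = stage2_stepwise(y, gasm, gasm.gene_ids, alpha2=0.001)
        assert res.selected_genes == []

    def test_planted_gene_selected_first(self):
        gasm, y = _random_instance(seed=13, planted={"m07": 1.0})
        res = stage2_stepwise(y, gasm, gasm.gene_ids)
        assert res.selected_genes[0] == "m07"

    def test_forward_path_matches_exhaustive_refit_oracle(self):
        """Each forward step picks the brute-force minimum-p candidate."""
        gasm, y = _random_instance(seed=17, planted={"m03": 0.9, "m12": 0.6})
        res = stage2_stepwise(y, gasm, gasm.gene_ids, alpha2=0.05, h2_limit=1.0)
        X0 = np.ones((len(y), 1))

        def design(genes):
            return np.column_stack([X0] + [_marker_dummies(gasm[g]) for g in genes])

        selected, pool = [], list(gasm.gene_ids)
        for step in res.path:
            if step["action"] == "drop":
                selected.remove(step["gene"])
                pool.append(step["gene"])
                continue
            X_cur = design(selected)
            ps = {}
            for g in pool:
                _, p = _oracle_partial_f(y, X_cur, design(selected + [g]))
                ps[g] = p
            best = min(ps.values())
            assert ps[step["gene"]] == pytest.approx(best, abs=1e-10)
            assert step["p"] == pytest.approx(ps[step["gene"]], abs=1e-10)
            selected.append(step["gene"])
            pool.remove(step["gene"])
        assert selected == res.selected_genes

    def test_heritability_restriction_binds(self):
        gasm, y = _random_instance(seed=19, planted={"m03": 1.2, "m12": 0.9})
        low = stage2_stepwise(y, gasm, gasm.gene_ids, h2_limit=0.2)
        assert low.r2_genetic <= 0.2 + 1e-12
        full = stage2_stepwise(y, gasm, gasm.gene_ids, h2_limit=1.0)
        assert len(full.selected_genes) >= len(low.selected_genes)

    def test_backward_elimination_keeps_only_significant(self):
        gasm, y = _random_instance(seed=23, planted={"m05": 1.0})
        res = stage2_stepwise(y, gasm, gasm.gene_ids, alpha2=0.05)
        for gf in res.gene_fits:
            assert gf.p_final < 0.05


class TestFinalize:
    def test_allele_effects_sum_to_zero_per_gene(self, small_panel, qtl_scenario):
        res = RtmGwas(qtl_scenario["pheno"], "trait", small_panel["gasm"],
                      small_panel["cov"], h2="auto").fit()
        assert res.selected_genes
        for gf in res.gene_fits:
            assert abs(gf.effects.sum()) < 1e-9

    def test_sequential_r2_sums_to_model_total(self, small_panel, qtl_scenario):
        res = RtmGwas(qtl_scenario["pheno"], "trait", small_panel["gasm"],
                      small_panel["cov"], h2="auto").fit()
        assert sum(gf.r2_seq for gf in res.gene_fits) == pytest.approx(
            res.r2_genetic, abs=1e-9)
        assert res.r2_genetic <= res.h2_limit + 1e-9
        assert res.unmapped_r2 >= -1e-9

    def test_balanced_biallelic_closed_form(self):
        # one balanced 2-allele gene, no covariates: effects are +/- half the
        # difference of the allele-class means
        assign = [0] * 10 + [1] * 10
        gasm = toy_gasm({"g1": assign}, {"g1": ["0", "1"]})
        rng = np.random.default_rng(31)
        y = np.where(np.array(assign) == 1, 2.0, -2.0) + 0.1 * rng.normal(size=20)
        res = stage2_stepwise(y, gasm, ["g1"])
        (gf,) = res.gene_fits
        half_diff = (y[10:].mean() - y[:10].mean()) / 2
        np.testing.assert_allclose(gf.effects, [-half_diff, half_diff], atol=1e-10)
        assert res.intercept == pytest.approx(y.mean(), abs=1e-10)

    def test_lc_sc_classification_threshold(self, small_panel, qtl_scenario):
        res = RtmGwas(qtl_scenario["pheno"], "trait", small_panel["gasm"],
                      small_panel["cov"], h2="auto").fit()
        tbl = res.gene_table()
        for _, row in tbl.iterrows():
            assert row["class"] == ("LC" if row.r2_main >= 0.015 else "SC")

    def test_predict_reproduces_panel_values(self, small_panel, qtl_scenario):
        res = RtmGwas(qtl_scenario["pheno"], "trait", small_panel["gasm"],
                      small_panel["cov"], h2="auto").fit()
        values = res.predict()
        manual = np.full(len(small_panel["gasm"].accession_ids), res.intercept)
        for gf in res.gene_fits:
            manual += gf.effects[small_panel["gasm"][gf.gene_id].assignment]
        np.testing.assert_allclose(values, manual)


class TestGxe:
    def _fit(self, small_panel, spec, seed, ge_share, h2=0.6):
        pheno, truth = gg.simulate.simulate_phenotypes(
            small_panel["gasm"], spec, n_env=4, n_rep=2, h2_target=h2,
            ge_share=ge_share, seed=seed)
        model = RtmGwas(pheno, "trait", small_panel["gasm"], small_panel["cov"],
                        h2="auto")
        return model.fit(gxe=True)

    def test_constant_effects_across_environments_not_retained(self, small_panel):
        cov = small_panel["cov"]
        rng = np.random.default_rng(41)
        genes = gg.simulate.choose_qtl_genes(small_panel["gasm"], 1, rng, cov=cov)
        spec = gg.simulate.draw_qtl_spec(
            small_panel["gasm"], {genes[0]: 0.3}, rng, cov=cov)
        res = self._fit(small_panel, spec, seed=42, ge_share=0.0)
        assert genes[0] in res.selected_genes
        assert not res.get_gene(genes[0]).ge_retained

    def test_crossover_interaction_retained(self, small_panel):
        cov = small_panel["cov"]
        rng = np.random.default_rng(43)
        genes = gg.simulate.choose_qtl_genes(small_panel["gasm"], 1, rng, cov=cov)
        spec = gg.simulate.draw_qtl_spec(
            small_panel["gasm"], {genes[0]: 0.12}, rng, cov=cov,
            env_interaction={genes[0]: 0.9}, n_env=4)
        res = self._fit(small_panel, spec, seed=44, ge_share=0.3, h2=0.6)
        gf = res.get_gene(genes[0])
        assert gf.ge_retained
        assert gf.r2_ge > gf.r2_seq  # interaction dwarfs the main effect
        assert sum(g.r2_ge for g in res.gene_fits) <= res.h2_ge_limit + 1e-9

    def test_single_environment_rejected(self, small_panel):
        gasm = small_panel["gasm"]
        rng = np.random.default_rng(45)
        y = rng.normal(size=len(gasm.accession_ids))
        model = RtmGwas.from_accession_means(y, gasm, h2=1.0)
        with pytest.raises(ValueError, match="environments"):
            model._gxe_extension(model.fit(), 0.05)


def test_partial_f_counts_rank_not_columns():
    rng = np.random.default_rng(51)
    y = rng.normal(size=30)
    X0 = np.ones((30, 1))
    x = rng.normal(size=30)
    X_full = np.column_stack([X0, x, x])  # duplicated column: rank adds 1
    f, df1, df2, p = partial_f_test(y, X0, X_full)
    assert df1 == 1
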