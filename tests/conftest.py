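import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

import gasmgwas as gg

settings.register_profile("ci", derandomize=True, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_panel():
    """120-accession structured panel with assembled GASMs and covariates."""
    snps, genes, meta = gg.simulate.simulate_genotypes(
        n_acc=120, n_chrom=2, genes_per_chrom=20, seed=11
    )
    mapping = gg.map_snps_to_genes(snps, genes)
    gasm_set = gg.build_gasm(snps, mapping, genes)
    cov = gg.top_eigenvectors(gg.compute_gsc(gasm_set), q=10)
    return {
        "snps": snps,
        "genes": genes,
        "meta": meta,
        "mapping": mapping,
        "gasm": gasm_set,
        "cov": cov,
    }


@pytest.fixture(scope="session")
def qtl_scenario(small_panel):
    """Planted 3-QTL multi-environment phenotypes on the small panel."""
    gasm_set = small_panel["gasm"]
    cov = small_panel["cov"]
    rng = np.random.default_rng(21)
    qtl_genes = gg.simulate.choose_qtl_genes(gasm_set, 3, rng, cov=cov)
    spec = gg.simulate.draw_qtl_spec(
        gasm_set, dict(zip(qtl_genes, (0.20, 0.12, 0.08))), rng, cov=cov
    )
    pheno, truth = gg.simulate.simulate_phenotypes(gasm_set, spec, seed=22)
    return {"qtl_genes": qtl_genes, "spec": spec, "pheno": pheno, "truth": truth}


def toy_gasm(assignments: dict[str, list[int]], alleles: dict[str, list[str]],
             accession_ids=None):
    """Hand-built GasmSet from explicit assignments (test helper)."""
    first = next(iter(assignments.values()))
    n = len(first)
    if accession_ids is None:
        accession_ids = [f"a{i}" for i in range(n)]
    markers = []
    for pos, (gene, assign) in enumerate(assignments.items()):
        assign = np.asarray(assign)
        freqs = np.bincount(assign, minlength=len(alleles[gene])).astype(float) / n
        markers.append(
            gg.GasmMarker(
                gene_id=gene,
                chromosome="chr01",
                anchor_position=1000 * (pos + 1),
                snp_ids=[f"{gene}_s1"],
                alleles=alleles[gene],
                assignment=assign,
                frequencies=freqs,
            )
        )
    return gg.GasmSet(list(accession_ids), markers)
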