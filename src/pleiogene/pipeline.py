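"""End-to-end driver: gene tests for two traits -> overlap -> Fisher meta."""

from __future__ import annotations

from typing import Iterable, Sequence

import pandas as pd

from .genetest import GeneTestConfig, run_gene_test
from .io import GeneInterval, ReferencePanel, SnpAssociation
from .meta import run_meta


def run_pipeline(
    gwas_a: Iterable[SnpAssociation],
    gwas_b: Iterable[SnpAssociation],
    genes: Sequence[GeneInterval],
    panel: ReferencePanel,
    gene_test_config: GeneTestConfig | None = None,
    alpha: float = 0.05,
    bonferroni_factor: int = 2,
) -> dict:
    """Run the two-trait shared-gene screen.

    Returns a dict with the per-trait gene-test tables (``trait_a``,
    ``trait_b``), the Fisher-combined table over the nominal overlap
    (``combined``) and its significant subset (``significant``).
    """
    cfg = gene_test_config or GeneTestConfig()
    results_a = run_gene_test(gwas_a, genes, panel, cfg)
    results_b = run_gene_test(gwas_b, genes, panel, cfg)
    if results_a.empty or results_b.empty:
        empty = pd.DataFrame(columns=["gene", "chrom", "p_a", "p_b",
                                      "fisher_x2", "p_combined", "significant"])
        return {"trait_a": results_a, "trait_b": results_b,
                "combined": empty, "significant": empty.copy()}
    combined, significant = run_meta(results_a, results_b, alpha=alpha,
                                     bonferroni_factor=bonferroni_factor)
    return {"trait_a": results_a, "trait_b": results_b,
            "combined": combined, "significant": significant}
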