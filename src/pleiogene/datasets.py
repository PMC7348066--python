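"""Bundled reference tables from the published MS / ischemic-stroke screen.

Two small TSVs ship with the package:

* ``ms_is_shared_genes.tsv`` — the 24 genes nominally shared between the
  IMSGC multiple-sclerosis GWAS and the METASTROKE ischemic-stroke GWAS, with
  each trait's gene-based p-value, SNP count and top SNP.  The Fisher combined
  p-values are *not* stored; they are always recomputed.
* ``ms_is_expression_pvalues.tsv`` — differential-expression p-values for
  those 24 genes across four GEO case-control series (GSE21942 and GSE43591
  for MS; GSE16561 and GSE58294 for stroke).
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

#: which disease each bundled expression study belongs to
STUDY_DISEASE = {
    "GSE21942": "MS",
    "GSE43591": "MS",
    "GSE16561": "IS",
    "GSE58294": "IS",
}


def _read(name: str) -> pd.DataFrame:
    with resources.files("pleiogene.data").joinpath(name).open() as fh:
        return pd.read_csv(fh, sep="\t", na_values=["NA"])


def load_shared_gene_table() -> pd.DataFrame:
    """24 shared genes with per-trait gene-based p-values (columns ``p_ms``,
    ``p_is``), SNP counts and top SNPs."""
    return _read("ms_is_shared_genes.tsv")


def load_expression_pvalues() -> pd.DataFrame:
    """Genes x studies DE p-value matrix (index = gene, one column per GEO
    series; NaN where the gene was not measured)."""
    return _read("ms_is_expression_pvalues.tsv").set_index("gene")
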