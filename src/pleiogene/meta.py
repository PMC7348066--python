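"""Cross-trait meta-analysis of gene-based p-values.

Genes nominally significant in both traits (p < alpha in each) are combined
with Fisher's method — x^2 = -2 * sum(ln p_i), referred to chi-square with
2k degrees of freedom — and screened at a layered Bonferroni threshold
alpha / (factor * n), where n is the number of overlapping genes and the
factor (default 2) additionally accounts for the two traits.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)


@dataclass
class CombinedGeneResult:
    gene: str
    p_per_trait: tuple[float, ...]
    fisher_x2: float
    df: int
    p_combined: float


@dataclass(frozen=True)
class SignificanceLayer:
    """One layer of Bonferroni control: threshold = alpha / (factor * n_tests)."""

    n_tests: int
    factor: int = 1
    alpha: float = 0.05

    @property
    def threshold(self) -> float:
        return self.alpha / (self.factor * self.n_tests)

    def passes(self, p: float) -> bool:
        return p < self.threshold  # strict, as in every screen of the pipeline


def fisher_combine(p_values: Sequence[float], gene: str = "") -> CombinedGeneResult:
    """Fisher's combined probability test over k independent p-values.

    For k = 1 this is the identity: the chi-square(2) upper tail at -2 ln p
    is exactly p.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size < 1:
        raise ValueError("fisher_combine requires at least one p-value")
    if np.any(p <= 0) or np.any(p > 1):
        raise ValueError(f"p-values must lie in (0, 1], got {list(p)}")
    x2 = float(-2.0 * np.log(p).sum())
    df = 2 * p.size
    p_comb = float(stats.chi2.sf(x2, df))
    return CombinedGeneResult(gene=gene, p_per_trait=tuple(p), fisher_x2=x2,
                              df=df, p_combined=p_comb)


def bonferroni_layer(n_tests: int, factor: int = 1, alpha: float = 0.05) -> SignificanceLayer:
    if n_tests < 1:
        raise ValueError("n_tests must be >= 1")
    if factor not in (1, 2):
        raise ValueError("factor must be 1 or 2")
    return SignificanceLayer(n_tests=n_tests, factor=factor, alpha=alpha)


def nominal_overlap(results_a: pd.DataFrame, results_b: pd.DataFrame,
                    alpha: float = 0.05, p_column: str = "empirical_p") -> list[str]:
    """Genes with p strictly below alpha in both result tables, sorted by symbol."""
    sig_a = set(results_a.loc[results_a[p_column] < alpha, "gene"])
    sig_b = set(results_b.loc[results_b[p_column] < alpha, "gene"])
    return sorted(sig_a & sig_b)


def run_meta(results_a: pd.DataFrame, results_b: pd.DataFrame,
             alpha: float = 0.05, bonferroni_factor: int = 2,
             p_column: str = "empirical_p") -> tuple[pd.DataFrame, pd.DataFrame]:
    """Overlap -> Fisher combination -> layered Bonferroni filter.

    Returns (combined table over the overlap, significant subset).  The
    threshold is alpha / (bonferroni_factor * n_overlap).
    """
    if results_a.empty or results_b.empty:
        raise ValueError("both per-trait result tables must be non-empty")
    overlap = nominal_overlap(results_a, results_b, alpha=alpha, p_column=p_column)
    cols = ["gene", "chrom", "p_a", "p_b", "fisher_x2", "p_combined", "significant"]
    if not overlap:
        logger.warning("no genes are nominally significant in both traits")
        empty = pd.DataFrame(columns=cols)
        return empty, empty.copy()
    a = results_a.set_index("gene")
    b = results_b.set_index("gene")
    layer = bonferroni_layer(len(overlap), factor=bonferroni_factor, alpha=alpha)
    rows = []
    for gene in overlap:
        pa, pb = float(a.loc[gene, p_column]), float(b.loc[gene, p_column])
        comb = fisher_combine([pa, pb], gene=gene)
        rows.append({
            "gene": gene,
            "chrom": a.loc[gene, "chrom"] if "chrom" in a.columns else "",
            "p_a": pa, "p_b": pb,
            "fisher_x2": comb.fisher_x2,
            "p_combined": comb.p_combined,
            "significant": layer.passes(comb.p_combined),
        })
    combined = pd.DataFrame(rows, columns=cols)
    return combined, combined[combined["significant"]].reset_index(drop=True)
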