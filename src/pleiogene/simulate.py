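"""Synthetic inputs for the whole pipeline: LD-structured reference panels,
GWAS summary statistics under null and planted-association regimes, and
case-control expression matrices with planted log fold-changes.

Genotypes come from an AR(1) Gaussian copula: within each gene block the
latent haplotype values follow an autoregressive correlation ``ld_rho``
between adjacent SNPs, thresholded at allele frequencies drawn from
Uniform(0.05, 0.5) and summed into diploid dosages.  Blocks are independent,
so the implied LD structure is exactly block-diagonal and analytically
checkable.

GWAS z-scores are simulated directly on the summary-statistic scale:
``z ~ MVN(lambda, Sigma_block)`` with Sigma taken from the panel's own dosage
correlations, so the gene test's multivariate-normal null is the generating
model and calibration is exact.  ``lambda`` is 0 for non-causal SNPs and the
configured per-SNP noncentrality for causal ones; p-values are two-sided
normal tails.

Every generator is a pure function of (config, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .genetest import _repair_psd
from .io import ExpressionStudy, GeneInterval, ReferencePanel, SnpAssociation

_GENE_SPACING_BP = 1_000_000  # one gene block per megabase
_SNP_SPACING_BP = 1_000


@dataclass
class StudyDesign:
    """Design of one synthetic case-control expression study."""

    study_id: str
    disease: str
    n_case: int
    n_control: int
    sigma: float = 0.5  # residual SD on the log2 scale
    planted_logfc: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise ValueError("sigma must be > 0")
        if min(self.n_case, self.n_control) < 2:
            raise ValueError("need >= 2 samples per group")


@dataclass
class SimulationConfig:
    seed: int = 0
    n_individuals: int = 400
    n_genes: int = 50
    snps_per_gene: int | tuple[int, int] = (2, 12)  # inclusive range, or a fixed count
    ld_rho: float = 0.6
    causal_genes: dict[str, float] = field(default_factory=dict)  # gene -> per-SNP lambda
    expression_design: list[StudyDesign] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not (0.0 <= self.ld_rho < 1.0):
            raise ValueError("ld_rho must lie in [0, 1)")
        if self.n_individuals < 1 or self.n_genes < 1:
            raise ValueError("counts must be >= 1")


@dataclass
class SyntheticTruth:
    """What was planted: the ground truth the pipeline should recover."""

    causal_genes: dict[str, float]
    planted_de: dict[str, dict[str, float]]  # disease -> gene -> logFC
    config: SimulationConfig

    def truth_table(self) -> pd.DataFrame:
        rows = [{"gene": g, "kind": "causal", "value": lam}
                for g, lam in sorted(self.causal_genes.items())]
        for disease, m in sorted(self.planted_de.items()):
            rows += [{"gene": g, "kind": f"de_{disease}", "value": fc}
                     for g, fc in sorted(m.items())]
        return pd.DataFrame(rows, columns=["gene", "kind", "value"])


def _gene_symbol(i: int) -> str:
    return f"G{i:04d}"


def _block_sizes(config: SimulationConfig, rng: np.random.Generator) -> np.ndarray:
    spg = config.snps_per_gene
    if isinstance(spg, int):
        return np.full(config.n_genes, spg, dtype=int)
    lo, hi = spg
    return rng.integers(lo, hi + 1, size=config.n_genes)


def _ar1_chol(n: int, rho: float) -> np.ndarray:
    if n == 1:
        return np.ones((1, 1))
    idx = np.arange(n)
    corr = rho ** np.abs(idx[:, None] - idx[None, :])
    return np.linalg.cholesky(corr + 1e-12 * np.eye(n))


def ar1_dosage_correlation(rho: float, lag: int, maf_a: float, maf_b: float,
                           n_mc: int = 100_000, seed: int = 0) -> float:
    """Monte-Carlo oracle for the dosage correlation implied by the copula.

    Draws latent pairs at the given lag correlation, thresholds at the two
    allele frequencies, and returns the empirical Pearson r of the resulting
    diploid dosages.  Used by tests as an independent check on ``make_panel``.
    """
    rng = np.random.default_rng(seed)
    r = rho**lag
    cov = np.array([[1.0, r], [r, 1.0]])
    chol = np.linalg.cholesky(cov)
    dosages = np.zeros((n_mc, 2))
    for _ in range(2):  # two haplotypes per individual
        z = rng.standard_normal((n_mc, 2)) @ chol.T
        dosages[:, 0] += z[:, 0] <= stats.norm.ppf(maf_a)
        dosages[:, 1] += z[:, 1] <= stats.norm.ppf(maf_b)
    return float(np.corrcoef(dosages[:, 0], dosages[:, 1])[0, 1])


def make_panel(config: SimulationConfig) -> tuple[ReferencePanel, list[GeneInterval]]:
    """Generate the reference panel and the matching gene annotation.

    Each gene occupies one contiguous block on chromosome "1"; blocks are
    mutually independent.  Deterministic per ``config.seed``.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0]))
    sizes = _block_sizes(config, rng)
    snp_rows = []
    genes = []
    blocks = []
    rs_counter = 1
    for gi, nsnp in enumerate(sizes):
        start = gi * _GENE_SPACING_BP + 1
        end = start + nsnp * _SNP_SPACING_BP
        genes.append(GeneInterval(gene=_gene_symbol(gi), chrom="1", start=start, end=end))
        maf = rng.uniform(0.05, 0.5, size=nsnp)
        chol = _ar1_chol(nsnp, config.ld_rho)
        thresh = stats.norm.ppf(maf)
        dosage = np.zeros((config.n_individuals, nsnp))
        for _ in range(2):
            z = rng.standard_normal((config.n_individuals, nsnp)) @ chol.T
            dosage += z <= thresh
        blocks.append(dosage)
        for j in range(nsnp):
            snp_rows.append({"rsid": f"rs{rs_counter}", "chrom": "1",
                             "pos": start + j * _SNP_SPACING_BP})
            rs_counter += 1
    snps = pd.DataFrame(snp_rows)
    return ReferencePanel(snps=snps, dosages=np.hstack(blocks)), genes


def _block_slices(panel: ReferencePanel, genes: Sequence[GeneInterval]) -> dict[str, slice]:
    out = {}
    pos = panel.snps["pos"].to_numpy()
    for g in genes:
        idx = np.where((pos >= g.start) & (pos <= g.end))[0]
        out[g.gene] = slice(int(idx[0]), int(idx[-1]) + 1)
    return out


def make_gwas(panel: ReferencePanel, genes: Sequence[GeneInterval],
              causal_genes: Mapping[str, float], seed: int = 0) -> list[SnpAssociation]:
    """Simulate one trait's GWAS summary statistics over the panel's SNPs.

    Within each gene block, z-scores are drawn from MVN(lambda, Sigma) with
    Sigma the block's (PSD-repaired) dosage correlation matrix; p-values are
    two-sided normal tail probabilities of z.
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed, 1]))
    slices = _block_slices(panel, genes)
    pvals = np.empty(panel.n_snps)
    for g in genes:
        sl = slices[g.gene]
        x = panel.dosages[:, sl]
        n = x.shape[1]
        if n == 1:
            sigma_chol = np.ones((1, 1))
        else:
            sigma = _repair_psd(np.corrcoef(x, rowvar=False))
            sigma_chol = np.linalg.cholesky(sigma + 1e-10 * np.eye(n))
        lam = np.full(n, causal_genes.get(g.gene, 0.0))
        z = lam + sigma_chol @ rng.standard_normal(n)
        pvals[sl] = 2.0 * stats.norm.sf(np.abs(z))
    pvals = np.clip(pvals, 1e-300, 1.0)
    return [SnpAssociation(rsid=r, pvalue=float(p), chrom=c, pos=int(q))
            for r, c, q, p in zip(panel.snps["rsid"], panel.snps["chrom"],
                                  panel.snps["pos"], pvals)]


def make_expression(truth_genes: Sequence[str], designs: Sequence[StudyDesign],
                    seed: int = 0) -> list[ExpressionStudy]:
    """Generate log2 expression matrices with planted case-control shifts.

    Baseline per-gene means are N(8, 1) — typical of log2 microarray
    intensities — with independent N(0, sigma^2) noise per study and sample;
    case means are shifted by the planted logFC.
    """
    studies = []
    for k, design in enumerate(designs):
        rng = np.random.default_rng(np.random.SeedSequence([seed, 2, k]))
        genes = list(truth_genes)
        mu = rng.normal(8.0, 1.0, size=len(genes))
        n = design.n_case + design.n_control
        mat = mu[:, None] + rng.normal(0.0, design.sigma, size=(len(genes), n))
        for i, g in enumerate(genes):
            fc = design.planted_logfc.get(g, 0.0)
            mat[i, : design.n_case] += fc
        samples = [f"{design.study_id}_case{i+1}" for i in range(design.n_case)] + \
                  [f"{design.study_id}_ctrl{i+1}" for i in range(design.n_control)]
        groups = pd.Series(["case"] * design.n_case + ["control"] * design.n_control,
                           index=samples)
        studies.append(ExpressionStudy(
            study_id=design.study_id, disease=design.disease,
            matrix=pd.DataFrame(mat, index=genes, columns=samples), groups=groups))
    return studies


def generate_all(config: SimulationConfig) -> dict:
    """Generate every pipeline input from one config: panel + annotation, two
    traits' GWAS summaries, expression studies, and the planted truth."""
    panel, genes = make_panel(config)
    gwas_a = make_gwas(panel, genes, config.causal_genes, seed=config.seed * 2 + 1)
    gwas_b = make_gwas(panel, genes, config.causal_genes, seed=config.seed * 2 + 2)
    expression = make_expression([g.gene for g in genes], config.expression_design,
                                 seed=config.seed)
    planted_de: dict[str, dict[str, float]] = {}
    for d in config.expression_design:
        planted_de.setdefault(d.disease, {}).update(d.planted_logfc)
    truth = SyntheticTruth(causal_genes=dict(config.causal_genes),
                           planted_de=planted_de, config=config)
    return {"panel": panel, "genes": genes, "gwas_a": gwas_a, "gwas_b": gwas_b,
            "expression": expression, "truth": truth}
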