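import numpy as np
import pandas as pd
import pytest

from pleiogene.io import ExpressionStudy, GeneInterval, ReferencePanel


@pytest.fixture
def tiny_panel() -> ReferencePanel:
    """Five SNPs, hand-built LD: rs1 and rs2 identical (r = 1), rs3 noisy copy
    of rs1, rs4 independent, rs5 monomorphic."""
    rng = np.random.default_rng(11)
    n = 200
    a = rng.integers(0, 3, size=n).astype(float)
    noisy = a.copy()
    flip = rng.random(n) < 0.05
    noisy[flip] = rng.integers(0, 3, size=flip.sum())
    dosages = np.column_stack([
        a, a, noisy, rng.integers(0, 3, size=n).astype(float), np.ones(n)
    ])
    snps = pd.DataFrame({
        "rsid": ["rs1", "rs2", "rs3", "rs4", "rs5"],
        "chrom": ["1"] * 5,
        "pos": [100, 150, 5150, 9000, 180],
    })
    return ReferencePanel(snps=snps, dosages=dosages)


@pytest.fixture
def gene_100_200() -> GeneInterval:
    return GeneInterval(gene="GENE1", chrom="1", start=100, end=200)


def make_study(case: np.ndarray, ctrl: np.ndarray, gene: str = "G1",
               study_id: str = "S", disease: str = "D") -> ExpressionStudy:
    """One-gene expression study from explicit case/control vectors."""
    values = np.concatenate([case, ctrl])[None, :]
    samples = [f"c{i}" for i in range(len(case))] + [f"n{i}" for i in range(len(ctrl))]
    groups = pd.Series(["case"] * len(case) + ["control"] * len(ctrl), index=samples)
    return ExpressionStudy(study_id=study_id, disease=disease,
                           matrix=pd.DataFrame(values, index=[gene], columns=samples),
                           groups=groups)
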