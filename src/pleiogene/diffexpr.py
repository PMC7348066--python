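"""Case-control differential expression and cross-disease concordance.

For each study the per-gene statistic is a two-sample t-test on log2
expression; logFC is mean(case) - mean(control).  The default is the
pooled-variance t (the unmoderated limit of the limma linear model behind
GEO2R); Welch's t and a limma-style moderated t with empirical-Bayes variance
shrinkage are available as options.

A gene is called *shared* across two diseases when it is Bonferroni-significant
(p < alpha / G, strict) in at least one study of each disease.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import special, stats

from .io import ExpressionStudy

logger = logging.getLogger(__name__)

_TINY_P = 1e-300  # p-values must stay in (0, 1] even for degenerate zero-variance rows


@dataclass
class DeResult:
    gene: str
    study_id: str
    logfc: float
    t_stat: float
    pvalue: float
    df: float
    tested: bool = True


@dataclass
class SharedGeneCall:
    gene: str
    min_p: float
    any_significant: bool
    shared_significant: bool
    per_disease_min_p: dict[str, float]


# ---------------------------------------------------------------------------
# two-sample tests
# ---------------------------------------------------------------------------

def _group_values(study: ExpressionStudy, gene: str) -> tuple[np.ndarray, np.ndarray]:
    row = study.matrix.loc[gene]
    case = row[study.group_samples("case")].to_numpy(dtype=float)
    ctrl = row[study.group_samples("control")].to_numpy(dtype=float)
    return case[np.isfinite(case)], ctrl[np.isfinite(ctrl)]  # complete-case per group


def _t_from_summary(d: float, se: float, df: float) -> tuple[float, float]:
    if se == 0.0:
        if d == 0.0:
            return 0.0, 1.0
        return math.copysign(math.inf, d), _TINY_P
    t = d / se
    return t, float(2.0 * stats.t.sf(abs(t), df))


def de_test(study: ExpressionStudy, gene: str, method: str = "pooled_t") -> DeResult:
    """Two-sided two-sample test of case vs control log2 expression.

    ``pooled_t`` assumes equal group variances; ``welch_t`` does not;
    ``moderated_t`` shrinks the per-gene variance toward the study-wide prior
    (computed from all genes in the study) before forming the statistic.
    """
    if method == "moderated_t":
        table = de_table(study, method="moderated_t")
        row = table.loc[table["gene"] == gene]
        if row.empty:
            raise KeyError(f"gene {gene!r} not in study {study.study_id}")
        r = row.iloc[0]
        return DeResult(gene=gene, study_id=study.study_id, logfc=r["logfc"],
                        t_stat=r["t_stat"], pvalue=r["pvalue"], df=r["df"],
                        tested=bool(r["tested"]))
    if method not in ("pooled_t", "welch_t"):
        raise ValueError(f"unknown method {method!r}")
    case, ctrl = _group_values(study, gene)
    n1, n2 = len(case), len(ctrl)
    if n1 < 2 or n2 < 2:
        return DeResult(gene=gene, study_id=study.study_id, logfc=np.nan,
                        t_stat=np.nan, pvalue=np.nan, df=np.nan, tested=False)
    d = float(case.mean() - ctrl.mean())
    v1, v2 = case.var(ddof=1), ctrl.var(ddof=1)
    if method == "pooled_t":
        df = n1 + n2 - 2
        s2 = ((n1 - 1) * v1 + (n2 - 1) * v2) / df
        se = math.sqrt(s2 * (1 / n1 + 1 / n2))
    else:
        se2 = v1 / n1 + v2 / n2
        se = math.sqrt(se2)
        if se2 > 0:
            df = se2**2 / ((v1 / n1) ** 2 / (n1 - 1) + (v2 / n2) ** 2 / (n2 - 1))
        else:
            df = n1 + n2 - 2
    t, p = _t_from_summary(d, se, df)
    return DeResult(gene=gene, study_id=study.study_id, logfc=d, t_stat=t,
                    pvalue=p, df=df)


def de_table(study: ExpressionStudy, method: str = "pooled_t") -> pd.DataFrame:
    """Per-gene DE results for one study (gene, logfc, t_stat, pvalue, df, tested)."""
    if method in ("pooled_t", "welch_t"):
        rows = [de_test(study, g, method) for g in study.matrix.index]
        return pd.DataFrame([{"gene": r.gene, "logfc": r.logfc, "t_stat": r.t_stat,
                              "pvalue": r.pvalue, "df": r.df, "tested": r.tested}
                             for r in rows])
    if method != "moderated_t":
        raise ValueError(f"unknown method {method!r}")
    return _moderated_table(study)


# --- empirical-Bayes variance moderation (limma-style squeezeVar) ----------

def _trigamma_inverse(x: float) -> float:
    """Solve trigamma(y) = x for y > 0 by Newton iteration."""
    if x > 1e7:
        return 1.0 / math.sqrt(x)
    if x < 1e-6:
        return 1.0 / x
    y = 0.5 + 1.0 / x
    for _ in range(50):
        tri = float(special.polygamma(1, y))
        dif = tri * (1.0 - tri / x) / float(special.polygamma(2, y))
        y = y + dif
        if abs(dif) / y < 1e-8:
            break
    return y


def _fit_f_dist(s2: np.ndarray, df: float) -> tuple[float, float]:
    """Moment-match a scaled F prior to the observed sample variances.

    Returns (d0, s0^2): prior degrees of freedom (may be inf) and prior
    variance.  Works on the log scale, where log s^2 is a shifted log-F.
    """
    ok = np.isfinite(s2) & (s2 > 0)
    if ok.sum() < 2:
        return math.inf, float(np.nanmedian(s2[ok])) if ok.any() else 1.0
    z = np.log(s2[ok])
    e = z - special.digamma(df / 2.0) + math.log(df / 2.0)
    emean = float(e.mean())
    evar = float(e.var(ddof=1)) - float(special.polygamma(1, df / 2.0))
    if evar > 0:
        d0 = 2.0 * _trigamma_inverse(evar)
        s0_sq = math.exp(emean + float(special.digamma(d0 / 2.0)) - math.log(d0 / 2.0))
    else:
        d0 = math.inf
        s0_sq = math.exp(emean)
    return d0, s0_sq


def _moderated_table(study: ExpressionStudy) -> pd.DataFrame:
    genes = list(study.matrix.index)
    n = len(genes)
    logfc = np.full(n, np.nan)
    s2 = np.full(n, np.nan)
    dfs = np.full(n, np.nan)
    ses_scale = np.full(n, np.nan)  # 1/n1 + 1/n2 per gene (complete-case)
    tested = np.zeros(n, dtype=bool)
    for i, g in enumerate(genes):
        case, ctrl = _group_values(study, g)
        n1, n2 = len(case), len(ctrl)
        if n1 < 2 or n2 < 2:
            continue
        tested[i] = True
        logfc[i] = case.mean() - ctrl.mean()
        dfs[i] = n1 + n2 - 2
        s2[i] = ((n1 - 1) * case.var(ddof=1) + (n2 - 1) * ctrl.var(ddof=1)) / dfs[i]
        ses_scale[i] = 1 / n1 + 1 / n2
    # prior fitted on genes sharing the modal residual df (complete data)
    df_mode = float(pd.Series(dfs[tested]).mode().iloc[0])
    d0, s0_sq = _fit_f_dist(s2[tested & (dfs == df_mode)], df_mode)
    rows = []
    for i, g in enumerate(genes):
        if not tested[i]:
            rows.append({"gene": g, "logfc": np.nan, "t_stat": np.nan,
                         "pvalue": np.nan, "df": np.nan, "tested": False})
            continue
        if math.isinf(d0):
            s2_post, df_total = s0_sq, math.inf
        else:
            s2_post = (d0 * s0_sq + dfs[i] * s2[i]) / (d0 + dfs[i])
            df_total = dfs[i] + d0
        se = math.sqrt(s2_post * ses_scale[i])
        t, p = _t_from_summary(float(logfc[i]), se, df_total)
        rows.append({"gene": g, "logfc": float(logfc[i]), "t_stat": t,
                     "pvalue": p, "df": df_total, "tested": True})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# cross-disease classification
# ---------------------------------------------------------------------------

def classify_shared(pmat: pd.DataFrame, disease_of_study: Mapping[str, str],
                    n_genes: int | None = None, alpha: float = 0.05) -> pd.DataFrame:
    """Classify genes by cross-disease DE significance.

    ``pmat`` is genes x studies of raw p-values (NaN = gene absent from that
    study).  The threshold is alpha / G with G = ``n_genes`` (defaults to the
    number of rows).  ``any_significant`` requires one study below threshold;
    ``shared_significant`` requires at least one per disease.  NaNs are
    ignored in the minima; a gene missing from every study of a disease can
    never be shared-significant.
    """
    diseases = sorted(set(disease_of_study.values()))
    if len(diseases) != 2:
        raise ValueError(f"expected exactly 2 diseases, got {diseases}")
    unknown = [c for c in pmat.columns if c not in disease_of_study]
    if unknown:
        raise ValueError(f"studies without a disease mapping: {unknown}")
    G = n_genes if n_genes is not None else len(pmat)
    thr = alpha / G
    rows = []
    for gene, p in pmat.iterrows():
        per_dis = {}
        for d in diseases:
            cols = [c for c in pmat.columns if disease_of_study[c] == d]
            vals = p[cols].dropna()
            per_dis[d] = float(vals.min()) if len(vals) else np.nan
        mins = [v for v in per_dis.values() if np.isfinite(v)]
        min_p = min(mins) if mins else np.nan
        any_sig = bool(np.isfinite(min_p) and min_p < thr)
        shared = all(np.isfinite(v) and v < thr for v in per_dis.values())
        rows.append({"gene": gene, "min_p": min_p, "any_significant": any_sig,
                     "shared_significant": shared,
                     **{f"min_p_{d}": per_dis[d] for d in diseases}})
    return pd.DataFrame(rows)


def run_de(studies: Sequence[ExpressionStudy], genes: Sequence[str],
           method: str = "pooled_t", alpha: float = 0.05,
           n_genes: int | None = None) -> dict:
    """Run DE for every (gene, study), classify shared genes, and report the
    best (smallest-p) study per gene and disease.

    Returns a dict with keys ``tables`` (study_id -> DE DataFrame over
    ``genes``), ``pmat`` (genes x studies p-value matrix), ``calls`` (the
    classification table) and ``best_study`` (gene x disease -> study_id).
    """
    diseases = sorted({s.disease for s in studies})
    if len(diseases) != 2:
        raise ValueError("run_de needs studies from exactly two diseases")
    tables: dict[str, pd.DataFrame] = {}
    pmat = pd.DataFrame(index=list(genes), columns=[s.study_id for s in studies],
                        dtype=float)
    for study in studies:
        present = [g for g in genes if g in study.matrix.index]
        sub = de_table(
            ExpressionStudy(study_id=study.study_id, disease=study.disease,
                            matrix=study.matrix.loc[present], groups=study.groups),
            method=method)
        tables[study.study_id] = sub
        for _, r in sub.iterrows():
            if r["tested"]:
                pmat.loc[r["gene"], study.study_id] = r["pvalue"]
    disease_of_study = {s.study_id: s.disease for s in studies}
    calls = classify_shared(pmat, disease_of_study, n_genes=n_genes, alpha=alpha)
    best: dict[tuple[str, str], str | None] = {}
    for gene in genes:
        for d in diseases:
            cols = [s.study_id for s in studies if s.disease == d]
            vals = pmat.loc[gene, cols].dropna()
            best[(gene, d)] = vals.idxmin() if len(vals) else None
    return {"tables": tables, "pmat": pmat, "calls": calls, "best_study": best}
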