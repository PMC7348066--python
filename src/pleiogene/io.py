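"""Readers and writers for the tables the pipeline touches.

All genomic coordinates are stored 1-based inclusive internally.  P-values in
results tables are written in scientific notation with 3 significant digits
(``1.70E-05``); comparisons are always done at full precision and rounding
happens only at output.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: floor applied to p-values of exactly zero (the chi-square quantile diverges
#: as p -> 0, so a literal zero cannot enter the gene statistic)
P_FLOOR = 1e-300


@dataclass(frozen=True)
class SnpAssociation:
    """One GWAS summary record: rsID plus association p-value.

    ``chrom``/``pos`` may be absent (None/0) when the summary file carries only
    rsID and p; positions are then taken from the reference panel.
    """

    rsid: str
    pvalue: float
    chrom: str | None = None
    pos: int | None = None

    def __post_init__(self) -> None:
        if not self.rsid:
            raise ValueError("rsid must be non-empty")
        if not (0.0 < self.pvalue <= 1.0):
            raise ValueError(f"p-value for {self.rsid} outside (0, 1]: {self.pvalue}")
        if self.pos is not None and self.pos < 1:
            raise ValueError(f"position for {self.rsid} must be >= 1")


@dataclass(frozen=True)
class GeneInterval:
    """A gene as a 1-based inclusive interval on a chromosome."""

    gene: str
    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"{self.gene}: start {self.start} > end {self.end}")
        if self.start < 1:
            raise ValueError(f"{self.gene}: start must be >= 1")


class ReferencePanel:
    """Genotype dosages (individuals x SNPs) used solely to estimate LD.

    Parameters
    ----------
    snps : DataFrame with columns ``rsid``, ``chrom``, ``pos`` (one row per SNP,
        in column order of ``dosages``).
    dosages : float array, shape (n_individuals, n_snps), values in [0, 2];
        NaN marks missing genotypes.
    """

    def __init__(self, snps: pd.DataFrame, dosages: np.ndarray):
        snps = snps.reset_index(drop=True)
        dosages = np.asarray(dosages, dtype=float)
        if dosages.ndim != 2 or dosages.shape[1] != len(snps):
            raise ValueError(
                f"dosage matrix has {dosages.shape[1] if dosages.ndim == 2 else '?'} "
                f"columns but SNP map has {len(snps)} rows"
            )
        with np.errstate(invalid="ignore"):
            if np.nanmin(dosages, initial=0.0) < 0 or np.nanmax(dosages, initial=0.0) > 2:
                raise ValueError("dosages must lie in [0, 2]")
        if snps["rsid"].duplicated().any():
            dups = snps.loc[snps["rsid"].duplicated(), "rsid"].tolist()
            raise ValueError(f"duplicate rsIDs in panel: {dups[:5]}")
        self.snps = snps
        self.dosages = dosages
        self._index: dict[str, int] = {r: i for i, r in enumerate(snps["rsid"])}

    @property
    def n_individuals(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_snps(self) -> int:
        return self.dosages.shape[1]

    def __contains__(self, rsid: str) -> bool:
        return rsid in self._index

    def column(self, rsid: str) -> np.ndarray:
        return self.dosages[:, self._index[rsid]]

    def columns(self, rsids: Sequence[str]) -> np.ndarray:
        idx = [self._index[r] for r in rsids]
        return self.dosages[:, idx]

    def position(self, rsid: str) -> tuple[str, int]:
        row = self.snps.iloc[self._index[rsid]]
        return str(row["chrom"]), int(row["pos"])

    def imputed_columns(self, rsids: Sequence[str]) -> np.ndarray:
        """Dosage columns with missing values replaced by the per-SNP mean."""
        x = self.columns(rsids).copy()
        for j in range(x.shape[1]):
            col = x[:, j]
            miss = np.isnan(col)
            if miss.any():
                col[miss] = np.nanmean(col)
        return x

    def is_monomorphic(self, rsid: str) -> bool:
        col = self.column(rsid)
        vals = np.unique(col[~np.isnan(col)])
        return len(vals) < 2


@dataclass
class ExpressionStudy:
    """A labelled genes x samples log2-expression matrix for one case-control study."""

    study_id: str
    disease: str
    matrix: pd.DataFrame  # index = gene symbols, columns = sample ids
    groups: pd.Series  # per-sample "case"/"control", indexed by sample id
    flagged_genes: list[str] = field(default_factory=list)  # rows with missing values

    def __post_init__(self) -> None:
        if not self.matrix.index.is_unique:
            raise ValueError(f"{self.study_id}: gene identifiers must be unique")
        counts = self.groups.value_counts()
        for grp in ("case", "control"):
            if counts.get(grp, 0) < 2:
                raise ValueError(f"{self.study_id}: fewer than 2 '{grp}' samples")
        if self.matrix.isna().all(axis=1).any():
            raise ValueError(f"{self.study_id}: all-missing gene rows are not allowed")

    def group_samples(self, group: str) -> list[str]:
        return list(self.groups.index[self.groups == group])


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------

def _looks_numeric(token: str) -> bool:
    try:
        float(token)
        return True
    except ValueError:
        return False


def read_gwas_summary(path: str | Path, p_floor: float = P_FLOOR) -> list[SnpAssociation]:
    """Read a GWAS summary table: whitespace/tab-delimited rsID, p [, chrom, pos].

    A header line is auto-detected by a non-numeric second column.  Duplicate
    rsIDs keep the first occurrence (count logged); p-values of exactly 0 are
    clamped to ``p_floor`` with a warning.
    """
    path = Path(path)
    records: list[SnpAssociation] = []
    seen: set[str] = set()
    n_dup = 0
    n_clamped = 0
    with open(path) as fh:
        lines = [(i + 1, ln.strip()) for i, ln in enumerate(fh) if ln.strip()]
    if not lines:
        raise ValueError(f"{path}: empty GWAS summary file")
    start = 0
    first_fields = lines[0][1].split()
    if len(first_fields) >= 2 and not _looks_numeric(first_fields[1]):
        start = 1  # header
    if start == len(lines):
        raise ValueError(f"{path}: no data rows after header")
    for lineno, line in lines[start:]:
        fields = line.split()
        if len(fields) < 2:
            raise ValueError(f"{path}, line {lineno}: expected at least 2 columns")
        rsid = fields[0]
        try:
            p = float(fields[1])
        except ValueError:
            raise ValueError(
                f"{path}, line {lineno}: unparseable p-value {fields[1]!r}"
            ) from None
        if p == 0.0:
            p = p_floor
            n_clamped += 1
        chrom = fields[2] if len(fields) >= 4 else None
        pos = int(fields[3]) if len(fields) >= 4 else None
        if rsid in seen:
            n_dup += 1
            continue
        seen.add(rsid)
        records.append(SnpAssociation(rsid=rsid, pvalue=p, chrom=chrom, pos=pos))
    if n_dup:
        logger.warning("%s: dropped %d duplicate rsID rows (first kept)", path, n_dup)
    if n_clamped:
        logger.warning("%s: clamped %d zero p-values to %g", path, n_clamped, p_floor)
    return records


def read_gene_annotation(path: str | Path, dialect: str = "bed") -> list[GeneInterval]:
    """Read gene intervals from BED (0-based half-open) or 1-based inclusive TSV.

    Rows are ``chrom start end gene``; everything is stored 1-based inclusive.
    """
    if dialect not in ("bed", "onebased"):
        raise ValueError(f"unknown annotation dialect {dialect!r}")
    path = Path(path)
    out: list[GeneInterval] = []
    seen: set[str] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split()
            if len(fields) < 4:
                raise ValueError(f"{path}, line {lineno}: expected chrom start end gene")
            chrom, start_s, end_s, gene = fields[:4]
            start, end = int(start_s), int(end_s)
            if dialect == "bed":
                start += 1  # half-open 0-based -> closed 1-based
            if start > end:
                raise ValueError(f"{path}, line {lineno}: start > end for {gene}")
            if gene in seen:
                raise ValueError(f"{path}, line {lineno}: duplicate gene symbol {gene!r}")
            seen.add(gene)
            out.append(GeneInterval(gene=gene, chrom=chrom, start=start, end=end))
    return out


def write_gene_annotation(genes: Iterable[GeneInterval], path: str | Path,
                          dialect: str = "onebased") -> None:
    with open(path, "w") as fh:
        for g in genes:
            start = g.start - 1 if dialect == "bed" else g.start
            fh.write(f"{g.chrom}\t{start}\t{g.end}\t{g.gene}\n")


def read_reference_panel(matrix_path: str | Path, map_path: str | Path) -> ReferencePanel:
    """Read a dosage panel: a TSV matrix (rsID header, one row per individual)
    plus a sidecar SNP map (rsid, chrom, pos)."""
    dos = pd.read_csv(matrix_path, sep="\t")
    snp_map = pd.read_csv(map_path, sep="\t", dtype={"rsid": str, "chrom": str, "pos": int})
    missing = [c for c in ("rsid", "chrom", "pos") if c not in snp_map.columns]
    if missing:
        raise ValueError(f"{map_path}: SNP map lacks columns {missing}")
    order = [c for c in dos.columns]
    snp_map = snp_map.set_index("rsid")
    absent = [r for r in order if r not in snp_map.index]
    if absent:
        raise ValueError(f"{map_path}: SNPs in matrix missing from map: {absent[:5]}")
    snps = snp_map.loc[order].reset_index()[["rsid", "chrom", "pos"]]
    return ReferencePanel(snps=snps, dosages=dos.to_numpy(dtype=float))


def write_reference_panel(panel: ReferencePanel, matrix_path: str | Path,
                          map_path: str | Path) -> None:
    pd.DataFrame(panel.dosages, columns=panel.snps["rsid"]).to_csv(
        matrix_path, sep="\t", index=False, float_format="%g")
    panel.snps.to_csv(map_path, sep="\t", index=False)


def read_expression_matrix(path: str | Path, labels: Mapping[str, str],
                           study_id: str = "", disease: str = "") -> ExpressionStudy:
    """Read a genes x samples TSV (first column = gene identifier).

    ``labels`` maps every sample column to "case" or "control".  Duplicate gene
    rows are disambiguated with a numeric suffix (``GENE.1``) and a warning;
    rows containing missing values are retained but flagged.
    """
    mat = pd.read_csv(path, sep="\t", index_col=0)
    for sample, grp in labels.items():
        if sample not in mat.columns:
            raise ValueError(f"{path}: labelled sample {sample!r} absent from header")
        if grp not in ("case", "control"):
            raise ValueError(f"{path}: group for {sample!r} must be case/control, got {grp!r}")
    mat = mat[list(labels.keys())]
    if not mat.index.is_unique:
        counts: dict[str, int] = {}
        new_index = []
        n_dup = 0
        for g in mat.index:
            k = counts.get(g, 0)
            new_index.append(g if k == 0 else f"{g}.{k}")
            if k:
                n_dup += 1
            counts[g] = k + 1
        mat.index = new_index
        logger.warning("%s: disambiguated %d duplicate gene rows with suffixes", path, n_dup)
    if not np.isfinite(mat.to_numpy(dtype=float)).all():
        flagged = list(mat.index[mat.isna().any(axis=1)])
        inf_rows = mat.index[np.isinf(mat.to_numpy(dtype=float)).any(axis=1)]
        if len(inf_rows):
            raise ValueError(f"{path}: non-finite expression values in {list(inf_rows)[:5]}")
    else:
        flagged = []
    groups = pd.Series({s: g for s, g in labels.items()})
    return ExpressionStudy(study_id=study_id or str(path), disease=disease,
                           matrix=mat, groups=groups, flagged_genes=flagged)


def write_expression_matrix(study: ExpressionStudy, path: str | Path) -> None:
    study.matrix.to_csv(path, sep="\t", index_label="gene")


# ---------------------------------------------------------------------------
# results formatting
# ---------------------------------------------------------------------------

def format_p(p: float) -> str:
    """Scientific notation at 3 significant digits: 1.6999e-05 -> '1.70E-05'."""
    if pd.isna(p):
        return "NA"
    return f"{p:.2E}"


def write_results_table(df: pd.DataFrame, path: str | Path,
                        p_columns: Sequence[str] = ()) -> None:
    """Write a results TSV, formatting the named p-value columns at 3 s.f."""
    out = df.copy()
    for col in p_columns:
        if col in out.columns:
            out[col] = out[col].map(format_p)
    out.to_csv(path, sep="\t", index=False)


def read_results_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", na_values=["NA"])
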