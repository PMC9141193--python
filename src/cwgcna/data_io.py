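"""Reading, cleaning and aligning multi-cohort expression and trait data.

Expression matrices are genes x samples tables of log-scale values, read
either from plain TSV (first column = row identifiers, header = sample
identifiers) or from the GEO series-matrix dialect, whose data block sits
between ``!series_matrix_table_begin`` and ``!series_matrix_table_end``
markers.  Probe-level matrices are collapsed to gene symbols by keeping,
for each gene, the probe with the highest expression; matrices are then
filtered for excessive missingness and near-zero variance, and multiple
cohorts are restricted to their common gene set before network
construction.
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionMatrix",
    "TraitTable",
    "PreprocessReport",
    "load_expression_matrix",
    "read_probe_map",
    "read_trait_table",
    "collapse_probes",
    "filter_missing",
    "align_cohorts",
]

SERIES_MATRIX_BEGIN = "!series_matrix_table_begin"
SERIES_MATRIX_END = "!series_matrix_table_end"

#: tokens treated as missing in expression tables
_NA_TOKENS = {"", "na", "nan", "null", "none", "n/a"}


@dataclass
class ExpressionMatrix:
    """A genes x samples expression table for one cohort.

    ``values`` is a pandas DataFrame indexed by unique row identifiers
    (probe ids before collapsing, gene symbols after) with unique sample
    identifiers as columns.
    """

    values: pd.DataFrame
    cohort_name: str = ""

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        idx = self.values.index
        cols = self.values.columns
        if len(idx) == 0 or len(cols) == 0:
            raise ValueError("expression matrix is empty")
        if idx.duplicated().any():
            dups = idx[idx.duplicated()].unique().tolist()[:5]
            raise ValueError(f"duplicate row identifiers: {dups}")
        if cols.duplicated().any():
            dups = cols[cols.duplicated()].unique().tolist()[:5]
            raise ValueError(f"duplicate sample identifiers: {dups}")
        if any(not str(g) for g in idx):
            raise ValueError("empty row identifier")

    @property
    def gene_ids(self) -> list[str]:
        return [str(g) for g in self.values.index]

    @property
    def sample_ids(self) -> list[str]:
        return [str(s) for s in self.values.columns]

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def to_tsv(self, path) -> None:
        self.values.to_csv(path, sep="\t")


@dataclass
class TraitTable:
    """Per-sample traits: binary phenotype plus FVC and DL_CO (may be missing).

    ``table`` is indexed by sample id with columns ``phenotype`` (1 = case,
    0 = control), ``fvc`` and ``dlco``; absent lung-function columns are
    stored as all-NaN.
    """

    table: pd.DataFrame
    cohort_name: str = ""

    def __post_init__(self) -> None:
        for col in ("fvc", "dlco"):
            if col not in self.table.columns:
                self.table[col] = np.nan
        if "phenotype" not in self.table.columns:
            raise ValueError("trait table needs a 'phenotype' column")
        if self.table.index.duplicated().any():
            raise ValueError("duplicate sample identifiers in trait table")

    def validate_against(self, expr: ExpressionMatrix) -> None:
        missing = set(map(str, self.table.index)) - set(expr.sample_ids)
        if missing:
            raise ValueError(
                f"trait samples absent from expression matrix: {sorted(missing)[:5]}"
            )
        ph = self.phenotype.dropna()
        if not ((ph == 1).any() and (ph == 0).any()):
            raise ValueError("phenotype needs at least one case and one control")

    @property
    def sample_ids(self) -> list[str]:
        return [str(s) for s in self.table.index]

    @property
    def phenotype(self) -> pd.Series:
        return self.table["phenotype"].astype(float)

    def trait(self, name: str) -> pd.Series:
        return self.table[name].astype(float)

    def has_trait(self, name: str) -> bool:
        return name in self.table.columns and self.table[name].notna().sum() >= 3

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index_label="sample_id")


@dataclass
class PreprocessReport:
    """Counts removed at each cleaning step, for the preprocessing report."""

    steps: list[tuple[str, int]] = field(default_factory=list)

    def add(self, step: str, n_removed: int) -> None:
        self.steps.append((step, int(n_removed)))

    def __str__(self) -> str:
        lines = ["preprocessing report:"]
        lines += [f"  {step}: removed {n}" for step, n in self.steps]
        return "\n".join(lines)


def _parse_table(text: str, na_tokens=_NA_TOKENS) -> pd.DataFrame:
    """Parse a TSV block: first column row ids, header sample ids.

    Unparseable cells become NaN; duplicate sample headers raise.
    """
    lines = [l for l in text.splitlines() if l.strip()]
    if len(lines) < 2:
        raise ValueError("empty data block")
    header = [c.strip().strip('"') for c in lines[0].split("\t")[1:]]
    if len(set(header)) != len(header):
        raise ValueError("duplicate sample identifiers in header")
    df = pd.read_csv(
        io.StringIO(text), sep="\t", index_col=0, dtype=str, quotechar='"'
    )
    if df.shape[0] == 0 or df.shape[1] == 0:
        raise ValueError("empty data block")

    def _coerce(col: pd.Series) -> pd.Series:
        cleaned = col.astype(str).str.strip().str.strip('"')
        cleaned = cleaned.mask(cleaned.str.lower().isin(na_tokens))
        return pd.to_numeric(cleaned, errors="coerce")

    out = df.apply(_coerce)
    out.index = df.index.astype(str).str.strip().str.strip('"')
    out.columns = [str(c).strip().strip('"') for c in df.columns]
    return out


def load_expression_matrix(path, format: str = "tsv", cohort_name: str = "") -> ExpressionMatrix:
    """Read an expression matrix from TSV or a GEO series-matrix file."""
    with open(path) as fh:
        text = fh.read()
    if format == "series_matrix":
        lines = text.splitlines()
        try:
            lo = next(i for i, l in enumerate(lines) if l.strip().lower() == SERIES_MATRIX_BEGIN)
            hi = next(i for i, l in enumerate(lines) if l.strip().lower() == SERIES_MATRIX_END)
        except StopIteration:
            raise ValueError("series-matrix table begin/end markers not found") from None
        block = "\n".join(lines[lo + 1 : hi])
        if not block.strip():
            raise ValueError("empty data block")
        df = _parse_table(block)
    elif format == "tsv":
        df = _parse_table(text)
    else:
        raise ValueError(f"unknown format {format!r}")
    if not cohort_name:
        cohort_name = str(path)
    return ExpressionMatrix(df, cohort_name=cohort_name)


def read_probe_map(path) -> pd.Series:
    """Read a 2-column probe_id -> gene_symbol TSV; empty symbol = unmapped."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if df.shape[1] < 2:
        raise ValueError("probe map needs two columns: probe_id, gene_symbol")
    probes = df.iloc[:, 0].astype(str).str.strip()
    genes = df.iloc[:, 1].astype(str).str.strip()
    if probes.duplicated().any():
        raise ValueError("duplicate probe ids in probe map")
    return pd.Series(genes.values, index=probes.values, name="gene_symbol")


def read_trait_table(path, cohort_name: str = "") -> TraitTable:
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    return TraitTable(df, cohort_name=cohort_name or str(path))


def collapse_probes(
    m: ExpressionMatrix,
    probe_map: pd.Series | dict,
    method: str = "mean",
) -> ExpressionMatrix:
    """Collapse probe-level rows to unique gene symbols.

    When several probes map to the same gene, the probe with the highest
    expression is retained -- by default the highest mean across samples
    (missing values ignored); ``method="max"`` uses the highest single value.
    Unmapped probes (absent from the map or mapped to an empty symbol) are
    dropped.  Gene symbols are upper-cased.
    """
    if not isinstance(probe_map, pd.Series):
        probe_map = pd.Series(probe_map)
    genes = m.values.index.to_series().map(probe_map)
    genes = genes.where(genes.astype(str).str.len() > 0).dropna().astype(str).str.upper()
    if genes.empty:
        raise ValueError("no probe maps to any gene")
    sub = m.values.loc[genes.index]
    if method == "mean":
        score = sub.mean(axis=1, skipna=True)
    elif method == "max":
        score = sub.max(axis=1, skipna=True)
    else:
        raise ValueError(f"unknown collapse method {method!r}")
    order = pd.DataFrame({"gene": genes.values, "score": score.values}, index=sub.index)
    order.index.name = None
    best = order.groupby("gene")["score"].idxmax()
    collapsed = sub.loc[best.values]
    collapsed.index = pd.Index(best.index.astype(str), name=None)
    collapsed = collapsed.sort_index()
    return ExpressionMatrix(collapsed, cohort_name=m.cohort_name)


def filter_missing(
    m: ExpressionMatrix,
    max_gene_missing: float = 0.5,
    max_sample_missing: float = 0.5,
    min_variance: float = 1e-10,
    report: PreprocessReport | None = None,
) -> ExpressionMatrix:
    """Drop genes/samples with excessive missingness and near-constant genes.

    One gene pass (missing fraction and variance) followed by one sample
    pass (missing fraction).
    """
    for thr in (max_gene_missing, max_sample_missing):
        if not (0 <= thr < 1):
            raise ValueError("missing-fraction thresholds must be in [0, 1)")
    if min_variance < 0:
        raise ValueError("min_variance must be >= 0")
    df = m.values
    gene_missing = df.isna().mean(axis=1)
    gene_var = df.var(axis=1, skipna=True).fillna(0.0)
    keep_genes = (gene_missing <= max_gene_missing) & (gene_var > min_variance)
    n_gene_removed = int((~keep_genes).sum())
    df = df.loc[keep_genes]
    if df.shape[0] == 0:
        raise ValueError(
            f"all {n_gene_removed} genes removed by missingness/variance filters"
        )
    sample_missing = df.isna().mean(axis=0)
    keep_samples = sample_missing <= max_sample_missing
    n_sample_removed = int((~keep_samples).sum())
    df = df.loc[:, keep_samples]
    if report is not None:
        report.add("genes (missingness/variance)", n_gene_removed)
        report.add("samples (missingness)", n_sample_removed)
    return ExpressionMatrix(df.copy(), cohort_name=m.cohort_name)


def align_cohorts(cohorts: list[ExpressionMatrix]) -> list[ExpressionMatrix]:
    """Restrict every cohort to the shared gene set, identically ordered.

    Gene symbols are compared after upper-casing; rows come back in the
    first cohort's order restricted to the intersection.
    """
    if len(cohorts) < 2:
        raise ValueError("need at least two cohorts to align")
    uppered = []
    for c in cohorts:
        df = c.values.copy()
        df.index = df.index.astype(str).str.upper()
        if df.index.duplicated().any():
            raise ValueError(
                f"cohort {c.cohort_name!r} has case-duplicated gene symbols"
            )
        uppered.append(df)
    common = set(uppered[0].index)
    for df in uppered[1:]:
        common &= set(df.index)
    if not common:
        raise ValueError("no genes shared across cohorts")
    ordered = [g for g in uppered[0].index if g in common]
    out = [
        ExpressionMatrix(df.loc[ordered].copy(), cohort_name=c.cohort_name)
        for df, c in zip(uppered, cohorts)
    ]
    return out
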