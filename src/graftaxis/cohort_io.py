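"""Domain types and delimited-table I/O for the three cohort layers.

A cohort consists of three time-matched tables: a gene × sample expression
matrix (normalized or raw counts), a protein × sample relative-abundance
panel (NPX scale, as produced by proximity-extension assays), and a
per-sample clinical table (kidney function and transplant covariates).
The convention throughout the package is features in rows and samples in
columns, both on disk and in memory; readers accept the transpose via an
``orientation`` flag.

Files are plain delimited text: tab-separated by default, comma-separated
when the filename ends in ``.csv``. All writers emit TSV.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from .errors import (
    AllProteinsRemovedError,
    DuplicateIdentifierError,
    EmptyMatrixError,
    InvalidClinicalValueError,
    MatrixTooSmallError,
    MissingValuesError,
    NoCommonSamplesError,
    NonNumericCellError,
)

logger = logging.getLogger(__name__)

Orientation = Literal["features_in_rows", "features_in_cols"]

#: Recognised clinical column names. ``diagnosis`` is categorical
#: {nonrejection, rejection}; everything else is numeric.
CLINICAL_COLUMNS = (
    "days_posttransplant",
    "creatinine",
    "creatinine_increase",
    "egfr",
    "proteinuria",
    "diagnosis",
    "creatinine_pred_2mo",
    "creatinine_pred_12mo",
)

_NUMERIC_CLINICAL = tuple(c for c in CLINICAL_COLUMNS if c != "diagnosis")


def _check_unique(ids: Sequence[str], what: str) -> None:
    seen: set[str] = set()
    for i in ids:
        if i in seen:
            raise DuplicateIdentifierError(f"duplicate {what} identifier: {i!r}")
        seen.add(i)


@dataclass
class ExpressionMatrix:
    """Gene × sample matrix of nonnegative expression values.

    ``normalized`` records whether values are size-factor-normalized counts
    (the substrate for network calling) or raw counts; ``zscored`` is set by
    the gene-wise standardisation step downstream, after which values may be
    negative.
    """

    data: pd.DataFrame  # genes in rows, samples in columns
    normalized: bool = True
    zscored: bool = False

    def __post_init__(self) -> None:
        _check_unique(list(self.data.index), "gene")
        _check_unique(list(self.data.columns), "sample")
        if self.data.shape[0] < 2 or self.data.shape[1] < 2:
            raise MatrixTooSmallError(
                f"expression matrix needs >=2 genes and >=2 samples, got {self.data.shape}"
            )
        if self.data.isna().any().any():
            bad = self.data.index[self.data.isna().any(axis=1)].tolist()
            raise MissingValuesError(f"missing expression values in genes: {bad[:5]}")
        if not self.zscored and (self.data.to_numpy() < 0).any():
            raise MissingValuesError("negative values in a count-scale expression matrix")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy()

    def subset_samples(self, samples: Sequence[str]) -> "ExpressionMatrix":
        return replace(self, data=self.data.loc[:, list(samples)])


@dataclass
class ProteinPanel:
    """Protein × sample matrix of relative abundances (NPX scale).

    NPX is a log2-like relative unit, so values may be negative; missing
    values are rejected at load because the correlation machinery assumes
    complete protein profiles (clinical gaps, in contrast, are handled
    pairwise downstream).
    """

    data: pd.DataFrame  # proteins in rows, samples in columns

    def __post_init__(self) -> None:
        _check_unique(list(self.data.index), "protein")
        _check_unique(list(self.data.columns), "sample")
        if self.data.shape[0] < 1 or self.data.shape[1] < 2:
            raise MatrixTooSmallError(
                f"protein panel needs >=1 protein and >=2 samples, got {self.data.shape}"
            )
        if self.data.isna().any().any():
            bad = self.data.index[self.data.isna().any(axis=1)].tolist()
            raise MissingValuesError(f"missing protein values in: {bad[:5]}")

    @property
    def protein_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    def subset_samples(self, samples: Sequence[str]) -> "ProteinPanel":
        return ProteinPanel(self.data.loc[:, list(samples)])


@dataclass
class ClinicalTable:
    """Per-sample clinical covariates (samples in rows).

    Missing values are permitted and excluded pairwise in correlations.
    Units: days_posttransplant in days, creatinine and its delta in mg/dL,
    eGFR in mL/min (CKD-EPI), proteinuria in mg/g.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        _check_unique(list(self.data.index), "sample")
        unknown = [c for c in self.data.columns if c not in CLINICAL_COLUMNS]
        if unknown:
            raise InvalidClinicalValueError(f"unknown clinical columns: {unknown}")
        for col in self.data.columns:
            if col == "diagnosis":
                vals = self.data[col].dropna()
                bad = set(vals) - {"nonrejection", "rejection"}
                if bad:
                    raise InvalidClinicalValueError(f"unknown diagnosis labels: {sorted(bad)}")
            else:
                self.data[col] = pd.to_numeric(self.data[col], errors="raise")
        if "egfr" in self.data.columns:
            egfr = self.data["egfr"].dropna()
            if (egfr <= 0).any():
                raise InvalidClinicalValueError("egfr must be positive where present")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    def subset_samples(self, samples: Sequence[str]) -> "ClinicalTable":
        return ClinicalTable(self.data.loc[list(samples)].copy())


@dataclass
class CohortBundle:
    """Time-matched expression, protein and clinical layers of one cohort.

    All three components share one identical, ordered sample id list —
    serum and biopsy were taken at the same visit, so column j means the
    same patient everywhere.
    """

    expression: ExpressionMatrix
    proteins: ProteinPanel
    clinical: ClinicalTable
    provenance: str = ""

    def __post_init__(self) -> None:
        s = self.expression.sample_ids
        if self.proteins.sample_ids != s or self.clinical.sample_ids != s:
            raise NoCommonSamplesError(
                "bundle components must share an identical ordered sample set; "
                "use align_samples() first"
            )

    @property
    def sample_ids(self) -> list[str]:
        return self.expression.sample_ids


# --- readers / writers -------------------------------------------------------


def _sep_for(path: Path) -> str:
    return "," if path.suffix.lower() == ".csv" else "\t"


def _read_table(path: str | Path, orientation: Orientation) -> pd.DataFrame:
    path = Path(path)
    df = pd.read_csv(path, sep=_sep_for(path), index_col=0, dtype=str)
    if df.shape[0] == 0 or df.shape[1] == 0:
        raise EmptyMatrixError(f"{path} parsed to an empty matrix")
    if orientation == "features_in_cols":
        df = df.T
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    _check_unique(list(df.index), "feature")
    _check_unique(list(df.columns), "sample")
    numeric = df.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna() & df.notna()
    if bad.any().any():
        r = bad.any(axis=1).idxmax()
        c = bad.loc[r].idxmax()
        raise NonNumericCellError(str(r), str(c), df.loc[r, c])
    # re-parse with the correctly-rounded converter so write->read is exact
    return df.astype(float).where(df.notna())


def read_matrix(
    path: str | Path,
    orientation: Orientation = "features_in_rows",
    kind: Literal["expression", "protein"] = "expression",
    normalized: bool = True,
) -> ExpressionMatrix | ProteinPanel:
    """Read a delimited feature × sample matrix.

    TSV by default, CSV when the extension is ``.csv``. The first column
    holds feature ids and the header row sample ids (swapped under
    ``orientation="features_in_cols"``).

    Raises
    ------
    DuplicateIdentifierError, NonNumericCellError, EmptyMatrixError,
    MissingValuesError, MatrixTooSmallError
    """
    df = _read_table(path, orientation)
    if kind == "protein":
        return ProteinPanel(df)
    return ExpressionMatrix(df, normalized=normalized)


def write_matrix(matrix: ExpressionMatrix | ProteinPanel, path: str | Path) -> None:
    """Write a matrix as TSV at full float precision (round-trip exact)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    matrix.data.to_csv(path, sep="\t", float_format=lambda v: format(float(v), ".17g"))


def read_clinical(path: str | Path) -> ClinicalTable:
    """Read a clinical TSV/CSV with samples in rows and the fixed header
    vocabulary (:data:`CLINICAL_COLUMNS`); empty cells are missing values."""
    path = Path(path)
    df = pd.read_csv(path, sep=_sep_for(path), index_col=0)
    df.index = df.index.astype(str)
    return ClinicalTable(df)


def write_clinical(clinical: ClinicalTable, path: str | Path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    clinical.data.to_csv(path, sep="\t")


# --- alignment and filtering -------------------------------------------------


def align_samples(
    expression: ExpressionMatrix,
    proteins: ProteinPanel,
    clinical: ClinicalTable,
    provenance: str = "",
) -> CohortBundle:
    """Restrict all three layers to their common samples, in lexicographic
    order, and bundle them.

    Dropped samples are logged per component. Lexicographic rather than
    file order makes the result independent of how the inputs were written.

    Raises
    ------
    NoCommonSamplesError
        If the intersection of the three sample sets is empty.
    """
    sets = {
        "expression": set(expression.sample_ids),
        "proteins": set(proteins.sample_ids),
        "clinical": set(clinical.sample_ids),
    }
    common = sorted(sets["expression"] & sets["proteins"] & sets["clinical"])
    if not common:
        raise NoCommonSamplesError("expression, proteins and clinical share no sample id")
    for name, ids in sets.items():
        dropped = sorted(ids - set(common))
        if dropped:
            logger.info("align_samples: dropped %d sample(s) from %s: %s",
                        len(dropped), name, dropped)
    return CohortBundle(
        expression=expression.subset_samples(common),
        proteins=proteins.subset_samples(common),
        clinical=clinical.subset_samples(common),
        provenance=provenance,
    )


def filter_low_variance_proteins(panel: ProteinPanel, min_sd: float = 0.0) -> ProteinPanel:
    """Drop proteins whose sample standard deviation (ddof=1) is <= min_sd.

    With the default ``min_sd=0`` exactly the constant proteins are removed,
    emulating the removal of analytes under the detection threshold whose
    measured values do not vary. Removed proteins are logged.

    Raises
    ------
    AllProteinsRemovedError
        If no protein survives.
    """
    if min_sd < 0:
        raise ValueError("min_sd must be >= 0")
    sd = panel.data.std(axis=1, ddof=1)
    keep = sd > min_sd
    removed = panel.data.index[~keep].tolist()
    if removed:
        logger.info("filter_low_variance_proteins: removed %d protein(s): %s",
                    len(removed), removed[:10])
    if not keep.any():
        raise AllProteinsRemovedError(
            f"min_sd={min_sd} removes all {panel.data.shape[0]} proteins"
        )
    return ProteinPanel(panel.data.loc[keep].copy())
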