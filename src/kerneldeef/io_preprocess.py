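"""Loading and normalising per-donor expression matrices.

The central type is :class:`DonorProfile`, a cells x features matrix with
identifying metadata.  Cytometry profiles are loaded from FCS files and
asinh-transformed; scRNA-seq count matrices are loaded from MTX/CSV/TSV,
QC-filtered, log-normalised and gene-filtered on the pooled sum.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.io import mmread

from ._fcs import FcsFormatError, read_fcs_raw

__all__ = [
    "DonorProfile",
    "QCThresholds",
    "EmptyProfileError",
    "FcsFormatError",
    "read_fcs",
    "read_expression_matrix",
    "asinh_transform",
    "qc_filter_cells",
    "log_normalize",
    "filter_genes_pooled_sum",
]


class EmptyProfileError(ValueError):
    """Raised when an operation would produce a profile with zero cells."""


@dataclass
class DonorProfile:
    """One donor's (optionally one condition's) cells x features matrix.

    Parameters
    ----------
    donor_id:
        Identifier of the donor.
    expression:
        Array of shape ``(num_cells, num_features)``; must be finite.
    feature_names:
        Column names, unique, length ``num_features``.
    group_label:
        Optional categorical label (e.g. case/control).
    condition:
        Optional stimulation/tube identifier.
    metadata:
        Free-form provenance dict (QC tallies, transform log, ...).
    """

    donor_id: str
    expression: np.ndarray
    feature_names: list[str]
    group_label: str | None = None
    condition: str | None = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.expression = np.asarray(self.expression, dtype=np.float64)
        if self.expression.ndim != 2:
            raise ValueError("expression must be a 2-D cells x features matrix")
        if self.expression.shape[0] < 1:
            raise EmptyProfileError(
                f"donor {self.donor_id!r}: profile must contain at least one cell"
            )
        if not np.all(np.isfinite(self.expression)):
            raise ValueError(
                f"donor {self.donor_id!r}: expression contains missing/non-finite values"
            )
        self.feature_names = [str(f) for f in self.feature_names]
        if len(self.feature_names) != self.expression.shape[1]:
            raise ValueError(
                f"donor {self.donor_id!r}: {len(self.feature_names)} feature names "
                f"for {self.expression.shape[1]} columns"
            )
        if len(set(self.feature_names)) != len(self.feature_names):
            raise ValueError(f"donor {self.donor_id!r}: duplicate feature names")

    @property
    def num_cells(self) -> int:
        return self.expression.shape[0]

    @property
    def num_features(self) -> int:
        return self.expression.shape[1]

    def with_expression(self, expression: np.ndarray, **meta) -> "DonorProfile":
        """Copy with replaced expression matrix; metadata entries merged in."""
        new = replace(self, expression=expression, metadata={**self.metadata, **meta})
        return new


@dataclass(frozen=True)
class QCThresholds:
    """Cell-level QC rules; all four comparisons are strict inequalities."""

    min_features_per_cell: int = 200
    max_features_per_cell: int = 7000
    max_counts_per_cell: float = 70000
    max_mito_percent: float = 10.0

    def __post_init__(self) -> None:
        if self.min_features_per_cell >= self.max_features_per_cell:
            raise ValueError("min_features_per_cell must be < max_features_per_cell")
        if not 0 <= self.max_mito_percent <= 100:
            raise ValueError("max_mito_percent must lie in [0, 100]")


def read_fcs(path: str | Path, prefer_stain_names: bool = True) -> DonorProfile:
    """Read an FCS file into a DonorProfile.

    Channel names come from $PnS (stain) when present, else $PnN (detector);
    set ``prefer_stain_names=False`` to always use $PnN.
    """
    path = Path(path)
    data, kw = read_fcs_raw(path)
    if data.shape[0] == 0:
        raise EmptyProfileError(f"{path}: FCS file contains zero events")
    n_par = data.shape[1]
    names = []
    for i in range(1, n_par + 1):
        pns = kw.get(f"$P{i}S", "").strip()
        pnn = kw.get(f"$P{i}N", "").strip()
        if prefer_stain_names and pns:
            names.append(pns)
        elif pnn:
            names.append(pnn)
        else:
            names.append(f"P{i}")
    # Duplicate stain names fall back to detector-qualified names.
    if len(set(names)) != len(names):
        names = [f"{nm}:{kw.get(f'$P{i + 1}N', i + 1)}" for i, nm in enumerate(names)]
    return DonorProfile(
        donor_id=path.stem,
        expression=data,
        feature_names=names,
        metadata={"source": str(path), "format": "fcs"},
    )


def read_expression_matrix(
    matrix_path: str | Path,
    format: str = "csv",
    genes_path: str | Path | None = None,
    cells_path: str | Path | None = None,
    cells_as_rows: bool | None = None,
    donor_id: str | None = None,
) -> DonorProfile:
    """Read a dense CSV/TSV or sparse MTX count matrix as cells x genes.

    Orientation on disk is declared, never guessed: ``cells_as_rows`` defaults
    to True for csv/tsv and False for mtx (genes-as-rows is the scRNA-seq
    convention for Matrix Market triplets).
    """
    matrix_path = Path(matrix_path)
    fmt = format.lower()
    if fmt not in {"mtx", "csv", "tsv"}:
        raise ValueError(f"unknown format {format!r}; expected mtx, csv or tsv")

    if fmt == "mtx":
        if genes_path is None or cells_path is None:
            raise ValueError("mtx format requires genes_path and cells_path")
        mat = np.asarray(mmread(matrix_path).todense(), dtype=np.float64)
        genes = [ln.split("\t")[0].strip() for ln in Path(genes_path).read_text().splitlines() if ln.strip()]
        cells = [ln.strip() for ln in Path(cells_path).read_text().splitlines() if ln.strip()]
        if cells_as_rows is None:
            cells_as_rows = False
        n_g, n_c = (mat.shape if not cells_as_rows else mat.shape[::-1])
        if len(genes) != n_g or len(cells) != n_c:
            raise ValueError(
                f"{matrix_path}: matrix is {mat.shape[0]} x {mat.shape[1]} but "
                f"{len(genes)} gene names and {len(cells)} cell names were given"
            )
        if not cells_as_rows:
            mat = mat.T
        feature_names = genes
    else:
        sep = "," if fmt == "csv" else "\t"
        df = pd.read_csv(matrix_path, sep=sep, index_col=0)
        if cells_as_rows is None:
            cells_as_rows = True
        if not cells_as_rows:
            df = df.T
        mat = df.to_numpy(dtype=np.float64)
        feature_names = [str(c) for c in df.columns]

    return DonorProfile(
        donor_id=donor_id or matrix_path.stem,
        expression=mat,
        feature_names=feature_names,
        metadata={"source": str(matrix_path), "format": fmt},
    )


def asinh_transform(profile: DonorProfile, cofactor: float = 5.0) -> DonorProfile:
    """Entry-wise ``asinh(x / cofactor)``, the cytometry normalisation."""
    if cofactor <= 0:
        raise ValueError(f"cofactor must be positive, got {cofactor}")
    return profile.with_expression(
        np.arcsinh(profile.expression / cofactor), asinh_cofactor=cofactor
    )


def qc_filter_cells(
    profile: DonorProfile,
    thresholds: QCThresholds | None = None,
    mito_gene_prefix: str = "MT-",
) -> DonorProfile:
    """Remove cells failing any of the four count-based QC criteria.

    A cell is removed when its detected-gene count is below the minimum or
    above the maximum, its total count exceeds the maximum, or its
    mitochondrial-count percentage exceeds the limit.  All comparisons are
    strict, so boundary cells are retained.  Per-criterion removal tallies are
    stored in the returned profile's metadata under ``"qc_removed"``.
    """
    thresholds = thresholds or QCThresholds()
    counts = profile.expression
    if np.any(counts < 0):
        raise ValueError("qc_filter_cells expects raw non-negative counts")
    detected = (counts > 0).sum(axis=1)
    total = counts.sum(axis=1)
    mito_mask = np.array(
        [name.startswith(mito_gene_prefix) for name in profile.feature_names]
    )
    with np.errstate(invalid="ignore", divide="ignore"):
        mito_pct = np.where(
            total > 0, 100.0 * counts[:, mito_mask].sum(axis=1) / np.maximum(total, 1e-300), 0.0
        )
    fail_low = detected < thresholds.min_features_per_cell
    fail_high = detected > thresholds.max_features_per_cell
    fail_counts = total > thresholds.max_counts_per_cell
    fail_mito = mito_pct > thresholds.max_mito_percent
    keep = ~(fail_low | fail_high | fail_counts | fail_mito)
    tally = {
        "low_detected_genes": int(fail_low.sum()),
        "high_detected_genes": int(fail_high.sum()),
        "high_total_counts": int(fail_counts.sum()),
        "high_mito_percent": int(fail_mito.sum()),
    }
    if not keep.any():
        dominant = max(tally, key=tally.get)  # type: ignore[arg-type]
        raise EmptyProfileError(
            f"donor {profile.donor_id!r}: QC removed all {profile.num_cells} cells "
            f"(dominant criterion: {dominant})"
        )
    return profile.with_expression(counts[keep], qc_removed=tally)


def log_normalize(profile: DonorProfile, scale_factor: float = 10000.0) -> DonorProfile:
    """Per-cell library-size log normalisation.

    Entry ``(c, g)`` becomes ``ln(1 + count(c, g) / total(c) * scale_factor)``.
    """
    counts = profile.expression
    total = counts.sum(axis=1, keepdims=True)
    if np.any(total <= 0):
        raise ValueError(
            f"donor {profile.donor_id!r}: cells with zero total count; "
            "run qc_filter_cells first"
        )
    return profile.with_expression(
        np.log1p(counts / total * scale_factor), log_normalized=scale_factor
    )


def filter_genes_pooled_sum(
    profiles: Sequence[DonorProfile], threshold: float = 15000.0
) -> list[str]:
    """Genes whose expression pooled over all cells of all profiles exceeds
    ``threshold`` (strictly); order follows the shared feature_names."""
    if not profiles:
        raise ValueError("at least one profile required")
    names = profiles[0].feature_names
    for prof in profiles[1:]:
        if prof.feature_names != names:
            for a, b in zip(names, prof.feature_names):
                if a != b:
                    raise ValueError(
                        f"feature_names mismatch: {a!r} vs {b!r} "
                        f"(donor {prof.donor_id!r})"
                    )
            raise ValueError(
                f"feature_names length mismatch: {len(names)} vs "
                f"{len(prof.feature_names)} (donor {prof.donor_id!r})"
            )
    pooled = np.zeros(len(names))
    for prof in profiles:
        pooled += prof.expression.sum(axis=0)
    return [name for name, s in zip(names, pooled) if s > threshold]
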