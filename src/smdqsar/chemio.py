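"""Compound records, activity tables, descriptor matrices and scaling.

IC50 values are stored in micromolar throughout; pIC50 is the negative
decadic logarithm of the molar IC50, so the conversion constant between
the two scales is exactly 6.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CompoundRecord",
    "ActivityTable",
    "DescriptorMatrix",
    "ScalingParams",
    "ic50_to_pic50",
    "pic50_to_ic50",
    "read_activity_csv",
    "read_matrix_csv",
    "autoscale",
    "apply_scaling",
    "unscale",
]

#: |pic50 - (6 - log10 ic50)| beyond which a record is flagged inconsistent.
#: Covers half-unit rounding in 2-decimal printed tables plus slack.
PIC50_CONSISTENCY_TOL = 0.005 + 1e-9

ACTIVITY_COLUMNS = (
    "id",
    "name",
    "smiles",
    "ic50_uM",
    "ic50_lo_uM",
    "ic50_hi_uM",
    "pic50",
    "protonation",
)


class FormatError(ValueError):
    """Raised when an input file violates the expected tabular layout."""


def ic50_to_pic50(ic50_um: float) -> float:
    """Convert an IC50 in µM to pIC50 (−log10 of the molar concentration).

    pIC50 = −log10(ic50_µM × 1e−6) = 6 − log10(ic50_µM).
    """
    if not np.isfinite(ic50_um) or ic50_um <= 0:
        raise ValueError(f"IC50 must be positive and finite, got {ic50_um!r}")
    return 6.0 - math.log10(ic50_um)


def pic50_to_ic50(pic50: float) -> float:
    """Inverse of :func:`ic50_to_pic50`; returns µM."""
    if not np.isfinite(pic50):
        raise ValueError(f"pIC50 must be finite, got {pic50!r}")
    return 10.0 ** (6.0 - pic50)


@dataclass
class CompoundRecord:
    id: str
    name: str = ""
    smiles: str | None = None
    ic50: float | None = None
    ic50_ci: tuple[float, float] | None = None
    pic50: float | None = None
    fragments: Mapping[str, str] | None = None
    protonation_tag: str | None = None

    def __post_init__(self) -> None:
        if self.ic50 is None and self.pic50 is None:
            raise ValueError(f"compound {self.id}: need at least one of ic50/pic50")
        if self.ic50 is not None and not (np.isfinite(self.ic50) and self.ic50 > 0):
            raise ValueError(f"compound {self.id}: ic50 must be positive, got {self.ic50}")
        if self.ic50_ci is not None:
            lo, hi = self.ic50_ci
            if self.ic50 is not None and not (lo <= self.ic50 <= hi):
                raise ValueError(
                    f"compound {self.id}: ic50 {self.ic50} outside CI [{lo}, {hi}]"
                )

    @property
    def pic50_effective(self) -> float:
        """Stored pIC50, back-filled from IC50 when absent."""
        if self.pic50 is not None:
            return self.pic50
        assert self.ic50 is not None
        return ic50_to_pic50(self.ic50)

    def consistency_gap(self) -> float | None:
        """|pic50 − (6 − log10 ic50)| when both activities are present."""
        if self.ic50 is None or self.pic50 is None:
            return None
        return abs(self.pic50 - ic50_to_pic50(self.ic50))


@dataclass
class ActivityTable:
    records: list[CompoundRecord]
    role: Literal["train", "test"] = "train"
    set_label: str = ""
    warnings: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [r.id for r in self.records]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise FormatError(f"duplicate compound ids: {dupes}")

    def __len__(self) -> int:
        return len(self.records)

    @property
    def ids(self) -> list[str]:
        return [r.id for r in self.records]

    def pic50(self) -> pd.Series:
        """pIC50 of every record (back-filled from IC50 where needed)."""
        return pd.Series(
            [r.pic50_effective for r in self.records], index=self.ids, name="pic50"
        )

    def get(self, compound_id: str) -> CompoundRecord:
        for r in self.records:
            if r.id == compound_id:
                return r
        raise KeyError(compound_id)


@dataclass
class DescriptorMatrix:
    """Named descriptor table: rows are compounds, columns descriptors.

    ``kind`` distinguishes binary fragment indicators ("conditional") from
    quantitative physicochemical descriptors.  Scope prefixes such as
    ``GLOBAL_`` / ``CAS_`` / ``PAS_`` are carried in the column names.
    """

    values: pd.DataFrame
    kind: Literal["conditional", "quantitative"] = "quantitative"

    def __post_init__(self) -> None:
        if self.values.isna().any().any():
            bad = self.values.columns[self.values.isna().any()].tolist()
            raise ValueError(f"missing cells in descriptor columns {bad}")
        if self.kind == "conditional":
            arr = self.values.to_numpy(dtype=float)
            if not np.isin(arr, (0.0, 1.0)).all():
                raise ValueError("conditional descriptor matrix must be binary (0/1)")

    @property
    def row_ids(self) -> list[str]:
        return [str(i) for i in self.values.index]

    @property
    def column_names(self) -> list[str]:
        return list(self.values.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def to_numpy(self) -> np.ndarray:
        return self.values.to_numpy(dtype=float)

    def subset_columns(self, names: Sequence[str]) -> "DescriptorMatrix":
        missing = [n for n in names if n not in self.values.columns]
        if missing:
            raise KeyError(f"unknown descriptor names: {missing}")
        return DescriptorMatrix(self.values.loc[:, list(names)].copy(), kind=self.kind)


@dataclass
class ScalingParams:
    """Column means and scales frozen on a training matrix.

    ``divisor_mode`` selects the standard-deviation divisor: "population"
    (÷N, making the correlation identity ρ = Σ x₁x₂/N exact) or "sample"
    (÷(N−1), the SIMCA/sklearn convention).
    """

    column_means: np.ndarray
    column_scales: np.ndarray
    divisor_mode: Literal["population", "sample"] = "population"
    column_names: list[str] | None = None

    def __post_init__(self) -> None:
        self.column_means = np.asarray(self.column_means, dtype=float)
        self.column_scales = np.asarray(self.column_scales, dtype=float)
        if not (self.column_scales > 0).all():
            raise ValueError("scales must be strictly positive")


def autoscale(
    matrix: np.ndarray | pd.DataFrame | DescriptorMatrix,
    divisor_mode: Literal["population", "sample"] = "population",
) -> tuple[np.ndarray, ScalingParams]:
    """Center each column to mean 0 and scale to unit variance.

    Constant columns are rejected: scaling them is undefined and silently
    dropping a descriptor would desynchronise downstream column bookkeeping.
    """
    names = None
    if isinstance(matrix, DescriptorMatrix):
        names = matrix.column_names
        X = matrix.to_numpy()
    elif isinstance(matrix, pd.DataFrame):
        names = list(matrix.columns)
        X = matrix.to_numpy(dtype=float)
    else:
        X = np.asarray(matrix, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
    ddof = 0 if divisor_mode == "population" else 1
    means = X.mean(axis=0)
    scales = X.std(axis=0, ddof=ddof)
    if np.any(scales <= 0) or np.any(~np.isfinite(scales)):
        bad = np.flatnonzero(~(scales > 0)).tolist()
        labels = [names[i] for i in bad] if names else bad
        raise ValueError(f"degenerate (constant) columns cannot be scaled: {labels}")
    params = ScalingParams(means, scales, divisor_mode, names)
    return (X - means) / scales, params


def apply_scaling(X_new: np.ndarray | pd.DataFrame, params: ScalingParams) -> np.ndarray:
    """Apply frozen training-set scaling to new rows (never refit on test)."""
    X = np.asarray(X_new, dtype=float) if not isinstance(X_new, pd.DataFrame) else X_new.to_numpy(dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    if X.shape[1] != params.column_means.size:
        raise ValueError(
            f"column mismatch: {X.shape[1]} columns vs {params.column_means.size} scaling params"
        )
    return (X - params.column_means) / params.column_scales


def unscale(X_scaled: np.ndarray, params: ScalingParams) -> np.ndarray:
    return np.asarray(X_scaled, dtype=float) * params.column_scales + params.column_means


def _parse_float(cell, row_index: int, column: str) -> float | None:
    if cell is None or (isinstance(cell, float) and math.isnan(cell)):
        return None
    s = str(cell).strip()
    if s == "":
        return None
    try:
        return float(s)
    except ValueError as exc:
        raise FormatError(f"row {row_index}: unparsable number {s!r} in {column!r}") from exc


def read_activity_csv(path: str | Path, role: Literal["train", "test"] = "train",
                      set_label: str = "") -> ActivityTable:
    """Load an activity CSV into an :class:`ActivityTable`.

    Expected columns: ``id`` plus at least one of ``ic50_uM`` / ``pic50``;
    optional ``name``, ``smiles``, ``ic50_lo_uM``, ``ic50_hi_uM``,
    ``protonation``.  pIC50 is back-filled from IC50 where absent.  Records
    whose printed pIC50 disagrees with their IC50 beyond rounding slack are
    flagged in ``table.warnings`` (never dropped): censored or ambiguous
    potencies are a reporting convention of the source, not a load error.
    """
    path = Path(path)
    df = pd.read_csv(path, dtype=str)
    if "id" not in df.columns:
        raise FormatError(f"{path}: missing required column 'id'")
    if not ({"ic50_uM", "pic50"} & set(df.columns)):
        raise FormatError(f"{path}: need at least one activity column (ic50_uM or pic50)")
    if len(df) == 0:
        raise FormatError(f"{path}: no data rows")

    records: list[CompoundRecord] = []
    warnings: list[str] = []
    for i, row in df.iterrows():
        rid = str(row["id"]).strip()
        ic50 = _parse_float(row.get("ic50_uM"), i, "ic50_uM")
        lo = _parse_float(row.get("ic50_lo_uM"), i, "ic50_lo_uM")
        hi = _parse_float(row.get("ic50_hi_uM"), i, "ic50_hi_uM")
        pic50 = _parse_float(row.get("pic50"), i, "pic50")
        if pic50 is None and ic50 is not None:
            pic50 = ic50_to_pic50(ic50)
        rec = CompoundRecord(
            id=rid,
            name=str(row.get("name", "") or ""),
            smiles=(str(row["smiles"]).strip() or None) if "smiles" in df.columns and pd.notna(row.get("smiles")) else None,
            ic50=ic50,
            ic50_ci=(lo, hi) if lo is not None and hi is not None else None,
            pic50=pic50,
            protonation_tag=(str(row["protonation"]).strip() or None) if "protonation" in df.columns and pd.notna(row.get("protonation")) else None,
        )
        gap = rec.consistency_gap()
        if gap is not None and gap > PIC50_CONSISTENCY_TOL:
            warnings.append(
                f"compound {rid}: stored pic50 {rec.pic50:.3f} differs from "
                f"6-log10(ic50) {ic50_to_pic50(rec.ic50):.3f} by {gap:.3f}"
            )
        records.append(rec)
    return ActivityTable(records, role=role, set_label=set_label, warnings=warnings)


def read_matrix_csv(path: str | Path,
                    kind: Literal["conditional", "quantitative"] = "quantitative",
                    ) -> DescriptorMatrix:
    """Load a descriptor matrix CSV (first column = compound id)."""
    path = Path(path)
    df = pd.read_csv(path, index_col=0)
    if df.shape[1] == 0:
        raise FormatError(f"{path}: no descriptor columns")
    if df.isna().any().any():
        raise FormatError(f"{path}: ragged or missing cells")
    df.index = df.index.astype(str)
    try:
        return DescriptorMatrix(df.astype(float), kind=kind)
    except ValueError as exc:
        raise FormatError(f"{path}: {exc}") from exc


def write_activity_csv(table: ActivityTable, path: str | Path) -> None:
    rows = []
    for r in table.records:
        rows.append({
            "id": r.id,
            "name": r.name,
            "smiles": r.smiles or "",
            "ic50_uM": "" if r.ic50 is None else repr(r.ic50),
            "ic50_lo_uM": "" if r.ic50_ci is None else repr(r.ic50_ci[0]),
            "ic50_hi_uM": "" if r.ic50_ci is None else repr(r.ic50_ci[1]),
            "pic50": "" if r.pic50 is None else repr(r.pic50),
            "protonation": r.protonation_tag or "",
        })
    pd.DataFrame(rows, columns=list(ACTIVITY_COLUMNS)).to_csv(path, index=False)
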