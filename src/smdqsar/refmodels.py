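"""Reference (null) models that any published QSAR should beat.

Seven deliberately simple predictors mirror the benchmarking scheme:
the training-set mean and median, a nearest-neighbour assignment (from a
curated similarity map or a computed descriptor-distance proxy), three
univariate least-squares regressions on single physicochemical descriptors
(logP, TPSA, van der Waals area in the original study), and a small PLS
model on those three descriptors together.  Each is evaluated by RMSEP on
external test sets, including the pooled union set.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Literal, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from . import pls
from .chemio import ActivityTable, DescriptorMatrix, autoscale, apply_scaling
from .pls import rmsep

__all__ = [
    "ReferenceModel",
    "NeighborMap",
    "constant_model",
    "univariate_ols",
    "small_pls_model",
    "nearest_neighbor_model",
    "evaluate_references",
]


@dataclass
class ReferenceModel:
    kind: Literal["mean", "median", "univariate_ols", "small_pls", "nearest_neighbor"]
    name: str
    predict: Callable[[ActivityTable], pd.Series]
    r2: float | None = None  # goodness of fit on the training set, where defined
    parameters: dict = field(default_factory=dict)


@dataclass
class NeighborMap:
    assignments: Mapping[str, str]  # test_id -> train_id
    source: Literal["file", "computed"] = "file"

    @classmethod
    def from_csv(cls, path: str | Path) -> "NeighborMap":
        df = pd.read_csv(path, dtype=str)
        if not {"test_id", "train_id"} <= set(df.columns):
            raise ValueError(f"{path}: need columns test_id,train_id")
        return cls(dict(zip(df["test_id"], df["train_id"])), source="file")


def constant_model(train: ActivityTable, mode: Literal["mean", "median"]) -> ReferenceModel:
    """Predict the training-set mean or median pIC50 for every compound."""
    y = train.pic50().to_numpy()
    if y.size == 0:
        raise ValueError("empty training set")
    value = float(np.mean(y)) if mode == "mean" else float(np.median(y))

    def _predict(table: ActivityTable) -> pd.Series:
        return pd.Series(value, index=table.ids, name="pred")

    return ReferenceModel(kind=mode, name=mode.capitalize(), predict=_predict,
                          parameters={"value": value})


def univariate_ols(descriptor: str, x_train: pd.Series, train: ActivityTable,
                   x_by_id: Mapping[str, float] | pd.Series | None = None) -> ReferenceModel:
    """Least-squares line pIC50 = a·x + b on one descriptor, with its R².

    ``x_train`` must be indexed by training compound id; predictions for a
    test table read the descriptor value per compound from ``x_by_id``
    (falling back to ``x_train`` for ids it covers).
    """
    y = train.pic50()
    x = x_train.loc[y.index].to_numpy(dtype=float)
    if y.size < 3:
        raise ValueError("need at least 3 training compounds")
    if np.ptp(x) == 0:
        raise ValueError(f"constant descriptor {descriptor!r}")
    res = stats.linregress(x, y.to_numpy())
    lookup = pd.Series(x_by_id, dtype=float) if x_by_id is not None else x_train

    def _predict(table: ActivityTable) -> pd.Series:
        missing = [i for i in table.ids if i not in lookup.index]
        if missing:
            raise KeyError(f"no {descriptor!r} value for compounds {missing}")
        xs = lookup.loc[table.ids].to_numpy(dtype=float)
        return pd.Series(res.intercept + res.slope * xs, index=table.ids, name="pred")

    return ReferenceModel(
        kind="univariate_ols", name=descriptor, predict=_predict,
        r2=float(res.rvalue**2),
        parameters={"slope": float(res.slope), "intercept": float(res.intercept)},
    )


def small_pls_model(descriptors: DescriptorMatrix | pd.DataFrame, train: ActivityTable,
                    test_descriptors: pd.DataFrame | None = None,
                    A: int | None = None) -> ReferenceModel:
    """PLS reference model on a handful of descriptors (logP/TPSA/vdW area).

    The component count follows the same incremental-Q² rule as the main
    model unless fixed explicitly.
    """
    frame = descriptors.values if isinstance(descriptors, DescriptorMatrix) else descriptors
    y = train.pic50()
    Xtr = frame.loc[y.index]
    if A is None:
        A = pls.select_components(Xtr, y.to_numpy(), A_max=min(3, Xtr.shape[1]))
    model = pls.fit(Xtr, y.to_numpy(), A)
    pool = frame if test_descriptors is None else pd.concat([frame, test_descriptors])

    def _predict(table: ActivityTable) -> pd.Series:
        missing = [i for i in table.ids if i not in pool.index]
        if missing:
            raise KeyError(f"no descriptor rows for compounds {missing}")
        yhat, _ = pls.predict(model, pool.loc[table.ids])
        return pd.Series(yhat, index=table.ids, name="pred")

    return ReferenceModel(kind="small_pls", name="PLS", predict=_predict,
                          r2=model.adj_r2y, parameters={"A": A, "model": model.to_dict()})


def nearest_neighbor_model(map_or_descriptors: NeighborMap | pd.DataFrame,
                           train: ActivityTable) -> ReferenceModel:
    """Predict each test compound with its nearest training compound's pIC50.

    With a :class:`NeighborMap` the curated (expert-elicited) assignment is
    used directly; with a descriptor table covering both sets the neighbour
    is computed as the arg-min Euclidean distance in autoscaled descriptor
    space (a stated proxy for expert similarity judgement), ties broken
    toward the lexicographically lower training id.
    """
    y = train.pic50()

    if isinstance(map_or_descriptors, NeighborMap):
        nmap = map_or_descriptors
        bad = sorted(set(nmap.assignments.values()) - set(y.index))
        if bad:
            raise ValueError(f"neighbor map points at unknown training ids: {bad}")

        def _predict(table: ActivityTable) -> pd.Series:
            preds, failures = {}, []
            for tid in table.ids:
                if tid in nmap.assignments:
                    preds[tid] = float(y.loc[nmap.assignments[tid]])
                else:
                    failures.append(tid)
            if failures:
                raise KeyError(f"neighbor map does not cover compounds {failures}")
            return pd.Series(preds, name="pred").loc[table.ids]

        source = nmap.source
    else:
        frame = map_or_descriptors
        missing = [i for i in y.index if i not in frame.index]
        if missing:
            raise ValueError(f"descriptor table lacks training compounds {missing}")
        scaled_train, params = autoscale(frame.loc[y.index])

        def _predict(table: ActivityTable) -> pd.Series:
            miss = [i for i in table.ids if i not in frame.index]
            if miss:
                raise KeyError(f"no descriptor rows for compounds {miss}")
            Xq = apply_scaling(frame.loc[table.ids], params)
            preds = {}
            train_ids = list(y.index)
            for row, tid in zip(Xq, table.ids):
                d = np.linalg.norm(scaled_train - row, axis=1)
                # self-matches allowed: on the training set this model is exact
                order = sorted(range(len(train_ids)), key=lambda j: (d[j], train_ids[j]))
                preds[tid] = float(y.iloc[order[0]])
            return pd.Series(preds, name="pred").loc[table.ids]

        source = "computed"

    return ReferenceModel(kind="nearest_neighbor", name="Nearest neighbor",
                          predict=_predict, parameters={"source": source})


def evaluate_references(models: Sequence[ReferenceModel],
                        test_sets: Mapping[str, ActivityTable],
                        union_label: str | None = "Set4") -> pd.DataFrame:
    """RMSEP of every model on every test set, plus the pooled union set.

    Returns a table with rows = models and columns = R² (training fit,
    where defined) followed by per-set RMSEP.  The union set concatenates
    all test sets, so RMSEP(union)² = Σ n_s RMSEP_s² / Σ n_s.
    """
    rows = {}
    for m in models:
        cells: dict[str, float | None] = {"R2": m.r2}
        pooled_pred: list[float] = []
        pooled_meas: list[float] = []
        for label, table in test_sets.items():
            pred = m.predict(table)
            meas = table.pic50()
            cells[label] = rmsep(meas.to_numpy(), pred.to_numpy())
            pooled_pred.extend(pred.tolist())
            pooled_meas.extend(meas.tolist())
        if union_label and len(test_sets) > 1:
            cells[union_label] = rmsep(pooled_meas, pooled_pred)
        rows[m.name] = cells
    return pd.DataFrame(rows).T
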