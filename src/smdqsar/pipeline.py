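"""End-to-end orchestration: design → covariance → fit → validate → predict
→ reference models → statistical comparison.

Every stage consumes and produces plain files (CSV for tables, JSON for
structured results), so any stage can be re-run standalone with identical
results; a manifest records parameters, seeds and input hashes for full
provenance.  Defaults follow the reference workflow: 200 permutations,
|ρ| redundancy threshold 0.7, 90 % coefficient confidence level,
α = 0.05, minimum fragment occurrence 2.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd
import yaml

from . import covariance, pls, refmodels, stattests, synthdata
from .chemio import ActivityTable, DescriptorMatrix, read_activity_csv, read_matrix_csv
from .design import balance_report

__all__ = ["RunConfig", "run_workflow", "descriptor_subset"]


@dataclass
class RunConfig:
    out_dir: str
    seed: int = 7
    # inputs: either file paths …
    activity_csv: str | None = None
    conditional_matrix_csv: str | None = None
    quantitative_matrix_csv: str | None = None
    # … or a synthetic study
    synthetic: bool = True
    library_shape: tuple[int, ...] = synthdata.DEFAULT_LIBRARY_SHAPE
    sigma: float = synthdata.DEFAULT_SIGMA
    n_select: int = 18
    n_test: int = 12
    # stage parameters (defaults = reference workflow values)
    design_starts: int = 20
    min_occurrence: int = 2
    covariance_threshold: float = 0.7
    components: int | Literal["auto"] = "auto"
    a_max: int = 3
    n_perm: int = 200
    ci_level: float = 0.90
    alpha: float = 0.05
    descriptor_subset_names: Sequence[str] | None = None

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)


def descriptor_subset(matrix: DescriptorMatrix, names: Sequence[str]) -> DescriptorMatrix:
    """Column-slice a descriptor matrix to a curated name list."""
    return matrix.subset_columns(names)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write_json(path: Path, obj) -> None:
    def default(o):
        if isinstance(o, (np.floating, np.integer)):
            return o.item()
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(type(o))
    path.write_text(json.dumps(obj, indent=2, default=default) + "\n")


def run_workflow(config: RunConfig) -> dict:
    """Execute the workflow and write per-stage reports under ``out_dir``.

    Returns a summary dict (also written as ``summary.json``) with the key
    model statistics.  Stage failures raise with the stage name attached;
    outputs written before the failure are retained.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"parameters": asdict(config), "inputs": {}, "stages": []}
    summary: dict = {}

    def stage(name):
        manifest["stages"].append(name)
        return name

    try:
        # ---- inputs ------------------------------------------------------
        if config.synthetic:
            stage("simulate")
            study = synthdata.generate_study(
                library_shape=config.library_shape, sigma=config.sigma,
                n_select=config.n_select, seed=config.seed,
                n_starts=config.design_starts,
            )
            activities = study.activities
            indicators = study.indicator_frame
            selection = study.selection
            library = study.library
            _write_json(out / "truth.json", {
                "beta": study.beta, "sigma": study.sigma,
                "intercept": study.intercept,
            })
            # hold-out candidates as an external test set
            rng = np.random.default_rng(np.random.SeedSequence(config.seed).generate_state(1)[0] % 2**31)
            unselected = sorted(set(range(len(study.candidates)))
                                - set(selection.selected_indices if selection else []))
            test_idx = sorted(rng.choice(unselected, size=min(config.n_test, len(unselected)),
                                         replace=False).tolist())
            test_tables, test_indicator = _synthetic_test_sets(study, test_idx)
        else:
            stage("load")
            if not (config.activity_csv and config.conditional_matrix_csv):
                raise FileNotFoundError("file-based run needs activity_csv and conditional_matrix_csv")
            for key in ("activity_csv", "conditional_matrix_csv", "quantitative_matrix_csv"):
                p = getattr(config, key)
                if p:
                    manifest["inputs"][key] = _sha256(Path(p))
            activities = read_activity_csv(config.activity_csv, role="train")
            cond = read_matrix_csv(config.conditional_matrix_csv, kind="conditional")
            indicators = cond.values
            selection, library, test_tables, test_indicator = None, None, {}, None

        y = activities.pic50()
        # reduced encoding for modelling: full indicator blocks are collinear
        X_model = _drop_reference_columns(indicators)
        X_model.to_csv(out / "design_matrix.csv")

        # ---- design diagnostics -----------------------------------------
        if selection is not None and library is not None:
            stage("design")
            _write_json(out / "design_report.json", {
                "selected_indices": selection.selected_indices,
                "log_det": selection.log_det,
                "condition_number": selection.condition_number,
                "balance": balance_report(selection, library, config.min_occurrence),
            })
            summary["condition_number"] = selection.condition_number

        # ---- covariance --------------------------------------------------
        stage("covariance")
        corr = covariance.correlation_matrix(X_model)
        corr.to_frame().to_csv(out / "correlation_matrix.csv")
        red = covariance.redundant_pairs(corr, threshold=config.covariance_threshold)
        n_pairs = corr.rho.shape[0] * (corr.rho.shape[0] - 1) // 2
        _write_json(out / "redundancy_report.json", {
            "threshold": red.threshold,
            "pairs": red.pairs,
            "chance_correlation_risk": covariance.chance_correlation_risk(n_pairs, config.alpha),
        })

        # ---- fit + validate ---------------------------------------------
        stage("fit")
        A = (pls.select_components(X_model, y.to_numpy(), A_max=config.a_max)
             if config.components == "auto" else int(config.components))
        cv = pls.loo_cv(X_model, y.to_numpy(), A)
        model = cv.full_model
        pd.DataFrame({"measured": y, "fitted": model.fitted,
                      "loo_predicted": cv.loo_predictions},
                     index=y.index).to_csv(out / "fitted.csv")

        stage("validate")
        ci = pls.jackknife_ci(cv, level=config.ci_level)
        ci.to_frame().to_csv(out / "coefficients.csv")
        perm = pls.permutation_test(X_model, y.to_numpy(), A,
                                    n_perm=config.n_perm, seed=config.seed)
        pd.DataFrame({"abs_corr": perm.correlations, "r2y": perm.r2y,
                      "q2": perm.q2}).to_csv(out / "permutations.csv", index=False)
        summary.update({
            "A": A, "r2y": model.r2y, "adj_r2y": model.adj_r2y,
            "q2": cv.q2, "rmsee": model.rmsee,
            "permutation_verdict": perm.verdict,
        })

        # ---- predict + applicability domain ------------------------------
        if test_tables:
            stage("predict")
            _, dmod_train = pls.predict(model, X_model, training=True)
            per_set_rmsep = {}
            predictions = {}
            for label, table in test_tables.items():
                Xt = test_indicator.loc[table.ids, X_model.columns]
                yhat, dmod = pls.predict(model, Xt)
                predictions[label] = pd.Series(yhat, index=table.ids)
                per_set_rmsep[label] = pls.rmsep(table.pic50().to_numpy(), yhat)
                pd.DataFrame({"measured": table.pic50(), "predicted": yhat,
                              "dmodx_ps": dmod.dmodx_ps,
                              "outside_ad": dmod.outside_ad},
                             index=table.ids).to_csv(out / f"predictions_{label}.csv")
            pooled_meas = np.concatenate([t.pic50().to_numpy() for t in test_tables.values()])
            pooled_pred = np.concatenate([predictions[k].to_numpy() for k in test_tables])
            summary["rmsep"] = pls.rmsep(pooled_meas, pooled_pred)
            summary["rmsep_per_set"] = per_set_rmsep

            # ---- reference models ---------------------------------------
            stage("reference")
            ref_models = _build_reference_models(activities, indicators, test_indicator)
            table3 = refmodels.evaluate_references(ref_models, test_tables)
            qsar_row = {"R2": model.adj_r2y, **per_set_rmsep,
                        "Set4": summary["rmsep"]} if len(test_tables) > 1 else {
                        "R2": model.adj_r2y, **per_set_rmsep}
            table3 = pd.concat([pd.DataFrame({"QSAR": qsar_row}).T, table3])
            table3.to_csv(out / "model_comparison.csv")
            summary["reference_rmsep"] = {
                name: row.drop("R2").to_dict() for name, row in table3.iterrows()
            }

            # ---- statistical comparison ----------------------------------
            stage("compare")
            grid_pred = {"QSAR": {k: predictions[k].to_numpy() for k in test_tables}}
            for m in ref_models:
                grid_pred[m.name] = {k: m.predict(test_tables[k]).to_numpy()
                                     for k in test_tables}
            measured = {k: t.pic50().to_numpy() for k, t in test_tables.items()}
            grid = stattests.comparison_grid(grid_pred, measured, alpha=config.alpha)
            cells = {
                model_name: {label: {
                    "normality_p": rep.normality_p,
                    "p_values": {t: rep.p(t) for t in ("F", "t", "KS", "MW")},
                    "verdicts": rep.verdicts,
                } for label, rep in per_set.items()}
                for model_name, per_set in grid.items()
            }
            _write_json(out / "statistical_tests.json", cells)
            summary["qsar_t_verdicts"] = {
                label: grid["QSAR"][label].verdicts.get("t")
                for label in test_tables
            }
    except Exception as exc:
        failed = manifest["stages"][-1] if manifest["stages"] else "setup"
        raise RuntimeError(f"workflow stage {failed!r} failed: {exc}") from exc

    _write_json(out / "summary.json", summary)
    _write_json(out / "manifest.json", manifest)
    return summary


def _drop_reference_columns(indicators: pd.DataFrame) -> pd.DataFrame:
    """Drop one reference fragment column per position block ("pos:frag")."""
    seen: dict[str, str] = {}
    drop = []
    for c in indicators.columns:
        pos = str(c).split(":")[0]
        if pos not in seen:
            seen[pos] = c
            drop.append(c)
    if len(drop) == len(indicators.columns):  # unprefixed columns: keep all
        return indicators
    return indicators.drop(columns=drop)


def _synthetic_test_sets(study: synthdata.SyntheticStudy, test_idx: list[int]
                         ) -> tuple[dict[str, ActivityTable], pd.DataFrame]:
    """Carve held-out candidates into two external test sets."""
    from .chemio import CompoundRecord, pic50_to_ic50

    rng = np.random.default_rng(np.random.SeedSequence(study.seed + 1).generate_state(1)[0] % 2**31)
    records = []
    for idx in test_idx:
        cand = study.candidates.candidates[idx]
        mu = study.intercept + sum(
            study.beta.get(f"{p}:{f}", 0.0)
            for p, f in zip(study.library.positions, cand))
        yv = mu + rng.normal(0.0, study.sigma)
        records.append(CompoundRecord(id=str(idx), name="-".join(cand),
                                      ic50=pic50_to_ic50(yv), pic50=yv))
    half = len(records) // 2
    tables = {
        "Set1": ActivityTable(records[:half], role="test", set_label="Set1"),
        "Set2": ActivityTable(records[half:], role="test", set_label="Set2"),
    }
    frame = study.candidates.indicator_matrix.values.iloc[test_idx].copy()
    frame.index = [str(i) for i in test_idx]
    return tables, frame


def _build_reference_models(train: ActivityTable, indicators: pd.DataFrame,
                            test_indicator: pd.DataFrame | None):
    """Mean/median, nearest-neighbour and small-PLS references on indicator space."""
    pool = indicators if test_indicator is None else pd.concat([indicators, test_indicator])
    models = [
        refmodels.constant_model(train, "mean"),
        refmodels.constant_model(train, "median"),
        refmodels.nearest_neighbor_model(pool, train),
    ]
    return models
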