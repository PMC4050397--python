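"""End-to-end experiment: train all models on cohort A, verify on cohort B.

Mirrors the two-hospital design: the training cohort fits every model (the
ICD-9-CM code model and the three rule models need no fitting; the logistic
model is stepwise-selected with a Youden cutoff; the tree is grown and
CV-pruned), then both cohorts are scored and summarized as
training/verification performance tables. Verification labels are used only
at evaluation time, never during fitting.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .claims_model import (
    CriteriaThresholds,
    SecondLineCatalog,
    read_cohort_csv,
    write_cohort_csv,
)
from .synthetic_cohort import CohortSpec, center_a_spec, center_b_spec, generate_cohort
from .rule_classifiers import IcdCodeSets, normalize_icd9
from .regression_classifier import LogisticModel, continuous_design
from .tree_classifier import GrowthParams, select_subtree_cv, CartTree
from .evaluation import (
    PerformanceRow,
    compute_metrics,
    confusion,
    report_tables,
    format_report_text,
)

__all__ = [
    "ExperimentConfig",
    "ExperimentResult",
    "criteria_frame",
    "predict_cohort",
    "run_experiment",
]

ALL_MODELS = ["icd9", "strict", "moderate", "loose", "logistic", "cart"]


def criteria_frame(
    frame: pd.DataFrame,
    thresholds: CriteriaThresholds | None = None,
    catalog: SecondLineCatalog | None = None,
) -> pd.DataFrame:
    """Vectorized six-criteria evaluation for a whole cohort table."""
    thresholds = thresholds or CriteriaThresholds()
    catalog = catalog or SecondLineCatalog()
    sl = frame["atc_codes_used"].fillna("").apply(
        lambda s: any(c in catalog.codes for c in str(s).split(";"))
    )
    out = pd.DataFrame(
        {
            "c1_types": frame["antibiotic_types"].astype(float) > thresholds.types_gt,
            "c2_ddd": frame["antibiotic_ddd_total"].astype(float) > thresholds.ddd_gt,
            "c3_cefazolin": frame["cefazolin_ddd"].astype(float) > thresholds.cefazolin_ddd_gt,
            "c4_second_line": sl,
            "c5_los": frame["los"].astype(float) > thresholds.los_gt,
            "c6_vessels": frame["vessels_obstructed"].astype(float) > thresholds.vessels_gt,
        }
    )
    out["n_satisfied"] = out.sum(axis=1).astype(int)
    return out


def _icd9_predictions(frame: pd.DataFrame, codes: IcdCodeSets) -> np.ndarray:
    def _hit(dx: object, code_set: frozenset[str]) -> bool:
        parts = [p for p in str(dx).split(";") if p]
        return any(normalize_icd9(p) in code_set for p in parts)

    index_hit = frame["index_secondary_dx"].fillna("").apply(lambda s: _hit(s, codes.index_codes))
    post_hit = frame["postdischarge_dx"].fillna("").apply(
        lambda s: _hit(s, codes.postdischarge_codes)
    )
    return (index_hit | post_hit).astype(int).to_numpy()


def predict_cohort(
    frame: pd.DataFrame,
    model: str,
    thresholds: CriteriaThresholds | None = None,
    catalog: SecondLineCatalog | None = None,
    codes: IcdCodeSets | None = None,
    moderate_k: int = 3,
    logistic_model: LogisticModel | None = None,
    tree: CartTree | None = None,
) -> np.ndarray:
    """Binary predictions for one model over a cohort table."""
    if model == "icd9":
        return _icd9_predictions(frame, codes or IcdCodeSets())
    if model in ("strict", "moderate", "loose"):
        crit = criteria_frame(frame, thresholds, catalog)
        if model == "strict":
            return (crit["n_satisfied"] == 6).astype(int).to_numpy()
        if model == "moderate":
            if not 1 <= moderate_k <= 6:
                raise ValueError("moderate_k must be between 1 and 6")
            return (crit["n_satisfied"] >= moderate_k).astype(int).to_numpy()
        return (crit["n_satisfied"] >= 1).astype(int).to_numpy()
    if model == "logistic":
        if logistic_model is None:
            raise ValueError("logistic model not fitted")
        scores = logistic_model.score_frame(continuous_design(frame, catalog))
        return (scores >= logistic_model.cutoff).astype(int)
    if model == "cart":
        if tree is None:
            raise ValueError("tree model not fitted")
        preds, _ = tree.predict_frame(continuous_design(frame, catalog))
        return preds
    raise ValueError(f"unknown model {model!r}")


@dataclass(frozen=True)
class ExperimentConfig:
    """Everything needed to rerun the experiment identically."""

    seed: int = 0
    cohort_a_csv: str | None = None       # load instead of simulate
    cohort_b_csv: str | None = None
    simulate_a: bool = True
    simulate_b: bool = True
    n_a: int = 1017
    n_b: int = 845
    models: tuple[str, ...] = tuple(ALL_MODELS)
    moderate_k: int = 3
    thresholds: CriteriaThresholds = field(default_factory=CriteriaThresholds)
    stepwise_entry_p: float = 0.05
    stepwise_removal_p: float = 0.05
    growth: GrowthParams = field(default_factory=GrowthParams)
    cv_folds: int = 10
    cv_rule: str = "min"
    out_dir: str | None = None

    def __post_init__(self) -> None:
        unknown = [m for m in self.models if m not in ALL_MODELS]
        if unknown:
            raise ValueError(f"unknown models: {unknown}")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["models"] = list(self.models)
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "ExperimentConfig":
        d = dict(d)
        if "thresholds" in d and isinstance(d["thresholds"], Mapping):
            d["thresholds"] = CriteriaThresholds(**d["thresholds"])
        if "growth" in d and isinstance(d["growth"], Mapping):
            d["growth"] = GrowthParams(**d["growth"])
        if "models" in d:
            d["models"] = tuple(d["models"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ExperimentConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    def config_hash(self) -> str:
        payload = yaml.safe_dump(self.to_dict(), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass
class ExperimentResult:
    training_rows: list[PerformanceRow]
    verification_rows: list[PerformanceRow]
    logistic_model: LogisticModel | None
    tree: CartTree | None
    cohort_a: pd.DataFrame
    cohort_b: pd.DataFrame | None
    provenance: dict

    @property
    def tables(self):
        return report_tables(self.training_rows, self.verification_rows or None)


def _load_or_simulate(csv_path: str | None, simulate: bool, spec: CohortSpec) -> pd.DataFrame:
    if csv_path:
        return read_cohort_csv(csv_path)
    if not simulate:
        raise ValueError("no cohort source: provide a CSV path or enable simulation")
    return generate_cohort(spec).frame


def run_experiment(config: ExperimentConfig) -> ExperimentResult:
    """Fit on cohort A, score A and B, assemble reports; optionally persist."""
    seed_a = config.seed
    seed_b = (config.seed + 1_000_003) % (2**31)
    frame_a = _load_or_simulate(
        config.cohort_a_csv, config.simulate_a, center_a_spec(seed=seed_a, n=config.n_a)
    )
    frame_b = None
    if config.cohort_b_csv or config.simulate_b:
        frame_b = _load_or_simulate(
            config.cohort_b_csv, config.simulate_b, center_b_spec(seed=seed_b, n=config.n_b)
        )

    labels_a = np.asarray(frame_a["ssi_label"], dtype=int)
    if labels_a.min() == labels_a.max():
        raise ValueError("training cohort must contain both classes")

    logistic_model = None
    tree = None
    if "logistic" in config.models:
        design_a = continuous_design(frame_a).assign(ssi_label=labels_a)
        logistic_model = LogisticModel.train(
            design_a,
            entry_p=config.stepwise_entry_p,
            removal_p=config.stepwise_removal_p,
        )
    if "cart" in config.models:
        design_a = continuous_design(frame_a).assign(ssi_label=labels_a)
        tree = select_subtree_cv(
            design_a,
            params=config.growth,
            v=config.cv_folds,
            seed=config.seed,
            rule=config.cv_rule,
        )

    def _evaluate(frame: pd.DataFrame) -> list[PerformanceRow]:
        labels = np.asarray(frame["ssi_label"], dtype=int)
        rows = []
        for model in config.models:
            preds = predict_cohort(
                frame,
                model,
                thresholds=config.thresholds,
                moderate_k=config.moderate_k,
                logistic_model=logistic_model,
                tree=tree,
            )
            rows.append(compute_metrics(confusion(preds, labels), model_name=model))
        return rows

    training_rows = _evaluate(frame_a)
    verification_rows = _evaluate(frame_b) if frame_b is not None else []

    provenance = {
        "package_version": __version__,
        "seed": config.seed,
        "config_hash": config.config_hash(),
        "config": config.to_dict(),
        "n_a": int(len(frame_a)),
        "n_b": int(len(frame_b)) if frame_b is not None else None,
    }
    result = ExperimentResult(
        training_rows=training_rows,
        verification_rows=verification_rows,
        logistic_model=logistic_model,
        tree=tree,
        cohort_a=frame_a,
        cohort_b=frame_b,
        provenance=provenance,
    )
    if config.out_dir:
        _persist(result, config)
    return result


def _persist(result: ExperimentResult, config: ExperimentConfig) -> None:
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_cohort_csv(result.cohort_a, out / "cohort_a.csv")
    if result.cohort_b is not None:
        write_cohort_csv(result.cohort_b, out / "cohort_b.csv")
    tables = result.tables
    tables["training"].to_csv(out / "table_training.csv", index=False, lineterminator="\n")
    if tables["verification"] is not None:
        tables["verification"].to_csv(out / "table_verification.csv", index=False, lineterminator="\n")
    (out / "report.txt").write_text(format_report_text(tables) + "\n")
    (out / "report.json").write_text(
        json.dumps(
            {
                "training": [r.as_dict() for r in result.training_rows],
                "verification": [r.as_dict() for r in result.verification_rows],
            },
            indent=2,
        )
        + "\n"
    )
    if result.logistic_model is not None:
        result.logistic_model.to_json(out / "logistic_model.json")
    if result.tree is not None:
        result.tree.to_json(out / "tree.json")
        (out / "tree.txt").write_text(result.tree.to_text() + "\n")
    (out / "provenance.json").write_text(json.dumps(result.provenance, indent=2, sort_keys=True) + "\n")
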