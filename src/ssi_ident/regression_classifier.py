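"""Model 4: stepwise logistic regression with ROC / Youden-index cutoff.

The six surrogate variables enter in continuous form (antibiotic types,
total DDD, cefazolin DDD, second-line use as 0/1, length of stay, vessels
obstructed). Variables are chosen by classical stepwise selection on
likelihood-ratio p-values (entry and removal at 0.05), the fitted
probability of SSI is swept over an ROC curve, and the operating cutoff is
the one maximizing the Youden index J = sensitivity + specificity - 1.

The linear predictor is always oriented toward P(SSI = 1): a positive
coefficient means higher infection risk. A fit produced under the
complementary orientation (as some statistical packages report) is the same
model with all coefficients negated and cutoff c replaced by 1 - c.

The maximum-likelihood fit is Newton-Raphson / IRLS written here directly;
it is cross-checked against an independent GLM implementation in the test
suite only.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .claims_model import PatientEpisode, SecondLineCatalog
from .rule_classifiers import ClassifierResult

__all__ = [
    "DEFAULT_PREDICTORS",
    "LogisticFit",
    "LogisticModel",
    "RocCurve",
    "SeparationWarning",
    "continuous_design",
    "fit_logistic",
    "stepwise_select",
    "roc_and_youden",
    "classify_logistic",
]

#: The six surrogate variables in their continuous form, in canonical order.
DEFAULT_PREDICTORS = [
    "antibiotic_types",
    "antibiotic_ddd_total",
    "cefazolin_ddd",
    "second_line",
    "los",
    "vessels_obstructed",
]


class SeparationWarning(UserWarning):
    """Raised (as a warning) when the likelihood indicates perfect separation."""


def continuous_design(frame: pd.DataFrame, catalog: SecondLineCatalog | None = None) -> pd.DataFrame:
    """Design matrix for models 4 and 5: the cohort's continuous variables
    plus a 0/1 ``second_line`` indicator derived from the ATC codes."""
    catalog = catalog or SecondLineCatalog()
    design = frame[
        ["antibiotic_types", "antibiotic_ddd_total", "cefazolin_ddd", "los", "vessels_obstructed"]
    ].astype(float).copy()
    design["second_line"] = (
        frame["atc_codes_used"]
        .fillna("")
        .apply(lambda s: float(any(c in catalog.codes for c in str(s).split(";"))))
    )
    return design[DEFAULT_PREDICTORS]


@dataclass(frozen=True)
class LogisticFit:
    """Maximum-likelihood coefficients for one predictor set."""

    variables: tuple[str, ...]
    coefficients: np.ndarray  # intercept first
    log_likelihood: float
    converged: bool
    separation: bool
    n_iter: int

    def linear_predictor(self, X: np.ndarray) -> np.ndarray:
        return self.coefficients[0] + X @ self.coefficients[1:]

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        return _expit(self.linear_predictor(X))


def _expit(z: np.ndarray) -> np.ndarray:
    with np.errstate(over="ignore"):
        return 1.0 / (1.0 + np.exp(-z))


def _log_likelihood(y: np.ndarray, p: np.ndarray) -> float:
    eps = 1e-12
    p = np.clip(p, eps, 1 - eps)
    return float(np.sum(y * np.log(p) + (1 - y) * np.log(1 - p)))


def fit_logistic(
    data: pd.DataFrame,
    predictors: Sequence[str],
    outcome: str = "ssi_label",
    tol: float = 1e-8,
    max_iter: int = 100,
) -> LogisticFit:
    """Fit P(SSI=1 | x) by Newton-Raphson IRLS.

    Convergence when the max absolute coefficient change drops below ``tol``
    (or ``max_iter`` sweeps). Perfect separation is reported through the
    ``separation`` flag plus a :class:`SeparationWarning`; a singular
    information matrix (collinear predictors) raises, naming the culprits.
    """
    predictors = list(predictors)
    y = np.asarray(data[outcome], dtype=float)
    classes = np.unique(y)
    if not np.all(np.isin(classes, [0.0, 1.0])) or classes.size < 2:
        raise ValueError("outcome must contain both classes coded 0/1")
    X = np.asarray(data[predictors], dtype=float) if predictors else np.empty((len(y), 0))
    for j, name in enumerate(predictors):
        if np.ptp(X[:, j]) == 0:
            raise ValueError(f"predictor {name!r} is constant")

    n, k = X.shape
    Xd = np.column_stack([np.ones(n), X])
    beta = np.zeros(k + 1)
    beta[0] = np.log(y.mean() / (1 - y.mean()))
    converged = False
    separation = False
    it = 0
    for it in range(1, max_iter + 1):
        eta = Xd @ beta
        p = _expit(eta)
        w = p * (1 - p)
        if not np.all(np.isfinite(w)) or np.max(w) < 1e-10:
            separation = True
            break
        grad = Xd.T @ (y - p)
        info = (Xd * w[:, None]).T @ Xd
        try:
            step = np.linalg.solve(info, grad)
        except np.linalg.LinAlgError:
            culprits = _collinear_predictors(Xd, predictors)
            if culprits:
                raise ValueError(f"singular information matrix; collinear predictors: {culprits}")
            separation = True  # information matrix degenerated numerically
            break
        cond = np.linalg.cond(info)
        if cond > 1e12:
            culprits = _collinear_predictors(Xd, predictors)
            if culprits:
                raise ValueError(f"singular information matrix; collinear predictors: {culprits}")
        prev = beta
        beta = beta + step
        if not np.all(np.isfinite(beta)):
            beta = prev  # diverged past floating range: (quasi-)separation
            separation = True
            break
        if np.max(np.abs(step)) < tol:
            converged = True
            break

    p = _expit(Xd @ beta)
    # diverging coefficients with near-perfect fitted probabilities => separation
    if not separation:
        fitted_extreme = np.all((p > 1 - 1e-6) | (p < 1e-6) | ~np.isfinite(p)) if n else False
        if np.max(np.abs(beta)) > 1e3 or (not converged and fitted_extreme):
            separation = True
    if separation:
        warnings.warn("perfect separation detected; coefficients are unstable", SeparationWarning)
    return LogisticFit(
        variables=tuple(predictors),
        coefficients=beta,
        log_likelihood=_log_likelihood(y, p),
        converged=converged,
        separation=separation,
        n_iter=it,
    )


def _collinear_predictors(Xd: np.ndarray, predictors: list[str]) -> list[str]:
    """Name predictors involved in (near-)exact linear dependence."""
    culprits = []
    rank_full = np.linalg.matrix_rank(Xd)
    if rank_full == Xd.shape[1]:
        return culprits
    for j, name in enumerate(predictors, start=1):
        reduced = np.delete(Xd, j, axis=1)
        if np.linalg.matrix_rank(reduced) == rank_full:
            culprits.append(name)
    return culprits


def stepwise_select(
    data: pd.DataFrame,
    candidates: Sequence[str],
    outcome: str = "ssi_label",
    entry_p: float = 0.05,
    removal_p: float = 0.05,
) -> list[str]:
    """Classical stepwise selection on likelihood-ratio p-values.

    Forward step (best candidate with LR p < ``entry_p``) followed by a
    backward check (drop any included variable whose LR p > ``removal_p``),
    repeated until the model is stable. Deterministic: ties break by
    candidate order.
    """
    if not candidates:
        raise ValueError("candidates must be non-empty")
    candidates = list(candidates)
    selected: list[str] = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", SeparationWarning)
        while True:
            changed = False
            # forward
            current_ll = fit_logistic(data, selected, outcome).log_likelihood
            best_name, best_p = None, np.inf
            for name in candidates:
                if name in selected:
                    continue
                try:
                    ll = fit_logistic(data, selected + [name], outcome).log_likelihood
                except ValueError:
                    continue  # constant or collinear with current model
                lr = max(0.0, 2.0 * (ll - current_ll))
                pval = stats.chi2.sf(lr, df=1)
                if pval < best_p - 1e-15:
                    best_name, best_p = name, pval
            if best_name is not None and best_p < entry_p:
                selected.append(best_name)
                changed = True
            # backward
            while len(selected) > 0:
                full_ll = fit_logistic(data, selected, outcome).log_likelihood
                worst_name, worst_p = None, -np.inf
                for name in selected:
                    reduced = [v for v in selected if v != name]
                    ll = fit_logistic(data, reduced, outcome).log_likelihood
                    lr = max(0.0, 2.0 * (full_ll - ll))
                    pval = stats.chi2.sf(lr, df=1)
                    if pval > worst_p + 1e-15:
                        worst_name, worst_p = name, pval
                if worst_name is not None and worst_p > removal_p:
                    selected.remove(worst_name)
                    changed = True
                else:
                    break
            if not changed:
                return selected


@dataclass(frozen=True)
class RocCurve:
    """ROC sweep over all distinct scores with Youden-index cutoff."""

    points: tuple[tuple[float, float, float], ...]  # (cutoff, sensitivity, specificity)
    auc: float
    youden_cutoff: float
    youden_j: float


def roc_and_youden(scores: Sequence[float], labels: Sequence[int]) -> RocCurve:
    """ROC curve, Mann-Whitney AUC, and the Youden-optimal cutoff.

    The decision rule at cutoff c is "predict positive when score >= c";
    candidate cutoffs are the distinct observed scores plus one cutoff above
    the maximum (nothing flagged). AUC is the probability that a random
    positive outscores a random negative, ties counted half. Youden ties
    break toward the smallest cutoff (maximal sensitivity at equal J).
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=int)
    if s.shape != y.shape or s.ndim != 1:
        raise ValueError("scores and labels must be equal-length 1-d sequences")
    n_pos = int((y == 1).sum())
    n_neg = int((y == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present to build an ROC curve")

    # Mann-Whitney AUC via midranks
    ranks = stats.rankdata(s)
    auc = (ranks[y == 1].sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg)

    cutoffs = np.unique(s)
    cutoffs = np.append(cutoffs, cutoffs[-1] + 1.0)  # sentinel: flag nobody
    points = []
    best_cut, best_j = None, -np.inf
    for c in cutoffs:
        pred = s >= c
        sens = float((pred & (y == 1)).sum()) / n_pos
        spec = float((~pred & (y == 0)).sum()) / n_neg
        points.append((float(c), sens, spec))
        j = sens + spec - 1.0
        if j > best_j + 1e-12:
            best_cut, best_j = float(c), j
    return RocCurve(points=tuple(points), auc=float(auc), youden_cutoff=best_cut, youden_j=float(best_j))


@dataclass(frozen=True)
class LogisticModel:
    """A deployable model-4 artifact: selected variables, coefficients, cutoff."""

    selected_variables: tuple[str, ...]
    coefficients: tuple[float, ...]  # intercept first
    cutoff: float
    orientation: str = "SSI"
    auc: float | None = None

    def __post_init__(self) -> None:
        if len(self.coefficients) != len(self.selected_variables) + 1:
            raise ValueError("need exactly one coefficient per variable plus an intercept")
        if not 0.0 <= self.cutoff <= 1.0:
            raise ValueError("cutoff must lie in [0, 1]")

    @classmethod
    def train(
        cls,
        data: pd.DataFrame,
        candidates: Sequence[str] = tuple(DEFAULT_PREDICTORS),
        outcome: str = "ssi_label",
        entry_p: float = 0.05,
        removal_p: float = 0.05,
    ) -> "LogisticModel":
        """Stepwise-select, fit, and set the Youden cutoff, all on ``data``."""
        selected = stepwise_select(data, candidates, outcome, entry_p, removal_p)
        fit = fit_logistic(data, selected, outcome)
        scores = fit.predict_proba(np.asarray(data[selected], dtype=float))
        roc = roc_and_youden(scores, np.asarray(data[outcome], dtype=int))
        return cls(
            selected_variables=tuple(selected),
            coefficients=tuple(float(b) for b in fit.coefficients),
            cutoff=roc.youden_cutoff,
            auc=roc.auc,
        )

    def score_frame(self, design: pd.DataFrame) -> np.ndarray:
        missing = [v for v in self.selected_variables if v not in design.columns]
        if missing:
            raise ValueError(f"design is missing selected variables: {missing}")
        X = np.asarray(design[list(self.selected_variables)], dtype=float)
        beta = np.asarray(self.coefficients)
        return _expit(beta[0] + X @ beta[1:])

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "selected_variables": list(self.selected_variables),
                    "coefficients": list(self.coefficients),
                    "orientation": self.orientation,
                    "cutoff": self.cutoff,
                    "auc": self.auc,
                },
                indent=2,
            )
            + "\n"
        )

    @classmethod
    def from_json(cls, path: str | Path) -> "LogisticModel":
        d = json.loads(Path(path).read_text())
        return cls(
            selected_variables=tuple(d["selected_variables"]),
            coefficients=tuple(d["coefficients"]),
            cutoff=d["cutoff"],
            orientation=d.get("orientation", "SSI"),
            auc=d.get("auc"),
        )


def classify_logistic(model: LogisticModel, episode: PatientEpisode,
                      catalog: SecondLineCatalog | None = None) -> ClassifierResult:
    """Score one episode with a fitted model; positive when score >= cutoff."""
    catalog = catalog or SecondLineCatalog()
    values = {
        "antibiotic_types": float(episode.antibiotic_types),
        "antibiotic_ddd_total": float(episode.antibiotic_ddd_total),
        "cefazolin_ddd": float(episode.cefazolin_ddd),
        "second_line": float(any(c in catalog.codes for c in episode.atc_codes_used)),
        "los": float(episode.los),
        "vessels_obstructed": float(episode.vessels_obstructed),
    }
    missing = [v for v in model.selected_variables if v not in values]
    if missing:
        raise ValueError(f"episode lacks selected variables: {missing}")
    beta = np.asarray(model.coefficients)
    x = np.array([values[v] for v in model.selected_variables])
    score = float(_expit(beta[0] + x @ beta[1:]))
    return ClassifierResult(episode.patient_id, int(score >= model.cutoff), "logistic", score=score)
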