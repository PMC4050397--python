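"""Rule-based SSI identification: the ICD-9-CM model and criteria-counting models.

The ICD-9-CM model flags an episode when a postoperative-infection code
appears among the secondary diagnoses of the index hospitalization, or a
code from a wider infection list appears among the primary/secondary
diagnoses of post-discharge encounters within one year (the one-year window
is assumed enforced upstream by the cohort builder — aggregated claims carry
no dates).

The three criteria-counting models threshold the number of satisfied
surrogate criteria out of six: *strict* requires all six, *moderate* at
least ``k`` (default 3), *loose* at least one. They are nested — a
strict-positive episode is always moderate-positive, and moderate-positive
implies loose-positive — so sensitivity rises and specificity falls from
strict to loose on any dataset.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

from .claims_model import CriteriaVector, PatientEpisode

__all__ = [
    "IcdCodeSets",
    "ClassifierResult",
    "normalize_icd9",
    "classify_icd9",
    "classify_strict",
    "classify_moderate",
    "classify_loose",
]

_INDEX_CODES = frozenset({"996.03", "996.61", "996.72", "998.5"})
_POSTDISCHARGE_CODES = frozenset(
    {
        "038.0", "038.1", "038.2", "038.3", "038.4", "038.8", "038.9",
        "682.6", "682.9", "780.6", "790.7",
        "875.0", "875.1", "891.0", "891.1",
        "996.03", "996.61", "996.72", "998.3", "998.5",
    }
)

_DOTTED = re.compile(r"^\d{3}\.\d{1,2}$")
_BARE3 = re.compile(r"^\d{3}$")
_UNDOTTED5 = re.compile(r"^\d{5}$")


def normalize_icd9(code: str) -> str:
    """Canonicalize an ICD-9-CM code string to dotted form.

    Accepts dotted forms (``998.5``), bare 3-digit categories, and undotted
    5-digit forms (``99850`` -> ``998.50``). Undotted 4-digit forms are
    rejected as ambiguous (``0385`` could be 038.5 or a truncation), as is
    anything else malformed.
    """
    code = code.strip()
    if _DOTTED.match(code) or _BARE3.match(code):
        return code
    if _UNDOTTED5.match(code):
        return code[:3] + "." + code[3:]
    raise ValueError(f"malformed ICD-9-CM code: {code!r}")


@dataclass(frozen=True)
class IcdCodeSets:
    """Diagnosis-code lists for index and post-discharge SSI events."""

    index_codes: frozenset[str] = _INDEX_CODES
    postdischarge_codes: frozenset[str] = _POSTDISCHARGE_CODES

    def __post_init__(self) -> None:
        object.__setattr__(self, "index_codes", frozenset(normalize_icd9(c) for c in self.index_codes))
        object.__setattr__(
            self, "postdischarge_codes", frozenset(normalize_icd9(c) for c in self.postdischarge_codes)
        )
        missing = self.index_codes - self.postdischarge_codes
        if missing:
            raise ValueError(f"index codes absent from post-discharge list: {sorted(missing)}")


@dataclass(frozen=True)
class ClassifierResult:
    """Per-patient binary prediction, with a score only for probabilistic models."""

    patient_id: str
    prediction: int
    model_name: str
    score: float | None = None

    def __post_init__(self) -> None:
        if self.prediction not in (0, 1):
            raise ValueError("prediction must be 0 or 1")
        if self.score is not None and not 0.0 <= self.score <= 1.0:
            raise ValueError("score must lie in [0, 1]")


def classify_icd9(episode: PatientEpisode, codes: IcdCodeSets | None = None) -> ClassifierResult:
    """ICD-9-CM model: positive iff a listed code is recorded.

    Index-event matching uses secondary diagnoses of the index admission;
    post-discharge matching uses primary/secondary diagnoses of later
    encounters. Matching is exact on normalized dotted code strings.
    """
    codes = codes or IcdCodeSets()
    index_dx = {normalize_icd9(c) for c in episode.index_secondary_dx}
    post_dx = {normalize_icd9(c) for c in episode.postdischarge_dx}
    hit = bool(index_dx & codes.index_codes) or bool(post_dx & codes.postdischarge_codes)
    return ClassifierResult(episode.patient_id, int(hit), "icd9")


def classify_strict(criteria: CriteriaVector, patient_id: str = "") -> ClassifierResult:
    """Model 1: positive only when all six criteria are satisfied."""
    return ClassifierResult(patient_id, int(criteria.n_satisfied == 6), "strict")


def classify_moderate(criteria: CriteriaVector, k: int = 3, patient_id: str = "") -> ClassifierResult:
    """Model 2: positive when at least ``k`` criteria are satisfied.

    The source description ("more than three criteria") is read as >= 3 —
    the literal >= 4 reading nearly collapses onto the strict model; ``k``
    is exposed so both readings are runnable.
    """
    if not 1 <= k <= 6:
        raise ValueError("k must be between 1 and 6")
    return ClassifierResult(patient_id, int(criteria.n_satisfied >= k), "moderate")


def classify_loose(criteria: CriteriaVector, patient_id: str = "") -> ClassifierResult:
    """Model 3: positive when any criterion is satisfied."""
    return ClassifierResult(patient_id, int(criteria.n_satisfied >= 1), "loose")
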