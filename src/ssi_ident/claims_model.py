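"""Domain types for aggregated CABG claims episodes and the six surrogate criteria.

A *patient episode* is one CABG hospitalization as it appears in aggregated
National-Health-Insurance-style claims: demographics, length of stay, number
of obstructed vessels, episode-total antibiotic use in defined daily doses
(DDD), the set of ATC codes administered, and the ICD-9-CM diagnosis codes
recorded on the index admission and on post-discharge encounters within one
year. Treatment items carry no time stamps — every dose field is an episode
total.

The six surrogate criteria for surgical-site infection (SSI) screening are:

1. more than ``types_gt`` distinct antibiotic substances (default 3),
2. more than ``ddd_gt`` DDD of antibiotics in total (default 7),
3. more than ``cefazolin_ddd_gt`` DDD of cefazolin (default 7),
4. any use of a second-line antibiotic (the 19-row reserve-agent catalog),
5. length of stay strictly greater than ``los_gt`` days (default 21),
6. more than ``vessels_gt`` obstructed vessels (default 2).

All comparisons are strict ``>``: boundary equality does not satisfy a
criterion.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

__all__ = [
    "CEFAZOLIN_ATC",
    "PatientEpisode",
    "SecondLineCatalog",
    "CriteriaThresholds",
    "CriteriaVector",
    "is_second_line",
    "compute_criteria",
    "episodes_to_frame",
    "frame_to_episodes",
    "read_cohort_csv",
    "write_cohort_csv",
    "COHORT_COLUMNS",
]

#: WHO ATC code for cefazolin, the standard first-line prophylactic agent in
#: CABG. Configurable on SecondLineCatalog / compute_criteria callers.
CEFAZOLIN_ATC = "J01DB04"

#: Second-line (broad-spectrum / reserve) antibiotics whose use flags
#: possible treatment rather than prophylaxis. One duplicated source row
#: (ticarcillin + enzyme inhibitor) collapses to a single entry.
_SECOND_LINE_ENTRIES: dict[str, str] = {
    "Ceftazidime": "J01DD02",
    "Aztreonam": "J01DF01",
    "Piperacillin": "J01CA12",
    "Piperacillin and enzyme inhibitor": "J01CR05",
    "Tazobactam": "J01CG02",
    "Ticarcillin": "J01CA13",
    "Ticarcillin and enzyme inhibitor": "J01CR03",
    "Amoxicillin and enzyme inhibitor": "J01CR02",
    "Cefepime": "J01DE01",
    "Cefpirome": "J01DE02",
    "Imipenem and enzyme inhibitor": "J01DH51",
    "Meropenem": "J01DH02",
    "Doripenem": "J01DH04",
    "Colistin": "J01XB01",
    "Tigecycline": "J01AA12",
    "Vancomycin": "J01XA01",
    "Teicoplanin": "J01XA02",
    "Daptomycin": "J01XX09",
}

COHORT_COLUMNS = [
    "patient_id",
    "age",
    "sex",
    "los",
    "vessels_obstructed",
    "antibiotic_types",
    "antibiotic_ddd_total",
    "cefazolin_ddd",
    "atc_codes_used",
    "index_secondary_dx",
    "postdischarge_dx",
    "ssi_label",
]


@dataclass(frozen=True)
class SecondLineCatalog:
    """Catalog of second-line antibiotics, name -> ATC code."""

    entries: Mapping[str, str] = field(default_factory=lambda: dict(_SECOND_LINE_ENTRIES))
    cefazolin_code: str = CEFAZOLIN_ATC

    def __post_init__(self) -> None:
        if self.cefazolin_code in self.codes:
            raise ValueError("cefazolin is first-line and may not appear in the second-line catalog")

    @property
    def codes(self) -> frozenset[str]:
        return frozenset(self.entries.values())


@dataclass(frozen=True)
class CriteriaThresholds:
    """Strict '>' thresholds for the six surrogate criteria."""

    types_gt: float = 3
    ddd_gt: float = 7.0
    cefazolin_ddd_gt: float = 7.0
    los_gt: float = 21.0
    vessels_gt: float = 2

    def __post_init__(self) -> None:
        for name in ("types_gt", "ddd_gt", "cefazolin_ddd_gt", "los_gt", "vessels_gt"):
            if getattr(self, name) <= 0:
                raise ValueError(f"threshold {name} must be > 0")


@dataclass(frozen=True)
class PatientEpisode:
    """One CABG admission with aggregated medical-use fields and label."""

    patient_id: str
    age: int
    sex: str  # "male" | "female"
    los: float
    vessels_obstructed: int
    antibiotic_types: int
    antibiotic_ddd_total: float
    cefazolin_ddd: float
    atc_codes_used: frozenset[str] = frozenset()
    index_secondary_dx: frozenset[str] = frozenset()
    postdischarge_dx: frozenset[str] = frozenset()
    ssi_label: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "atc_codes_used", frozenset(self.atc_codes_used))
        object.__setattr__(self, "index_secondary_dx", frozenset(self.index_secondary_dx))
        object.__setattr__(self, "postdischarge_dx", frozenset(self.postdischarge_dx))
        self.validate()

    def validate(self, cefazolin_code: str = CEFAZOLIN_ATC) -> None:
        if self.age < 0:
            raise ValueError(f"episode {self.patient_id}: age must be >= 0")
        if self.sex not in ("male", "female"):
            raise ValueError(f"episode {self.patient_id}: sex must be 'male' or 'female'")
        if self.los <= 0:
            raise ValueError(f"episode {self.patient_id}: los must be positive")
        if self.vessels_obstructed < 1:
            raise ValueError(f"episode {self.patient_id}: vessels_obstructed must be >= 1")
        if self.antibiotic_types < 0:
            raise ValueError(f"episode {self.patient_id}: antibiotic_types must be >= 0")
        if self.antibiotic_ddd_total < 0 or self.cefazolin_ddd < 0:
            raise ValueError(f"episode {self.patient_id}: DDD fields must be >= 0")
        if self.cefazolin_ddd > self.antibiotic_ddd_total + 1e-9:
            raise ValueError(
                f"episode {self.patient_id}: cefazolin_ddd exceeds antibiotic_ddd_total"
            )
        if (self.cefazolin_ddd > 0) != (cefazolin_code in self.atc_codes_used):
            raise ValueError(
                f"episode {self.patient_id}: cefazolin_ddd > 0 must coincide with "
                f"{cefazolin_code} in atc_codes_used"
            )
        if self.antibiotic_types == 0 and self.antibiotic_ddd_total > 0:
            raise ValueError(
                f"episode {self.patient_id}: antibiotic_types = 0 implies antibiotic_ddd_total = 0"
            )
        if self.ssi_label not in (0, 1):
            raise ValueError(f"episode {self.patient_id}: ssi_label must be 0 or 1")


@dataclass(frozen=True)
class CriteriaVector:
    """The six binary surrogate criteria for one episode."""

    c1_types: bool
    c2_ddd: bool
    c3_cefazolin: bool
    c4_second_line: bool
    c5_los: bool
    c6_vessels: bool

    @property
    def n_satisfied(self) -> int:
        return sum(
            (
                self.c1_types,
                self.c2_ddd,
                self.c3_cefazolin,
                self.c4_second_line,
                self.c5_los,
                self.c6_vessels,
            )
        )

    def as_tuple(self) -> tuple[bool, ...]:
        return (
            self.c1_types,
            self.c2_ddd,
            self.c3_cefazolin,
            self.c4_second_line,
            self.c5_los,
            self.c6_vessels,
        )


def is_second_line(atc_code: str, catalog: SecondLineCatalog | None = None) -> bool:
    """True iff ``atc_code`` is in the second-line catalog (exact match)."""
    if not atc_code:
        raise ValueError("atc_code must be a non-empty string")
    catalog = catalog or SecondLineCatalog()
    return atc_code in catalog.codes


def compute_criteria(
    episode: PatientEpisode,
    thresholds: CriteriaThresholds | None = None,
    catalog: SecondLineCatalog | None = None,
) -> CriteriaVector:
    """Evaluate the six surrogate criteria for one episode.

    Every comparison is strict ``>``; the second-line criterion is true when
    any administered ATC code appears in the catalog.
    """
    thresholds = thresholds or CriteriaThresholds()
    catalog = catalog or SecondLineCatalog()
    return CriteriaVector(
        c1_types=episode.antibiotic_types > thresholds.types_gt,
        c2_ddd=episode.antibiotic_ddd_total > thresholds.ddd_gt,
        c3_cefazolin=episode.cefazolin_ddd > thresholds.cefazolin_ddd_gt,
        c4_second_line=any(code in catalog.codes for code in episode.atc_codes_used),
        c5_los=episode.los > thresholds.los_gt,
        c6_vessels=episode.vessels_obstructed > thresholds.vessels_gt,
    )


# ---------------------------------------------------------------------------
# Cohort CSV I/O
# ---------------------------------------------------------------------------

def _join_set(values: Iterable[str]) -> str:
    return ";".join(sorted(values))


def _split_set(value: object) -> frozenset[str]:
    if value is None or (isinstance(value, float) and pd.isna(value)) or value == "":
        return frozenset()
    return frozenset(part for part in str(value).split(";") if part)


def episodes_to_frame(episodes: Iterable[PatientEpisode]) -> pd.DataFrame:
    """Flatten episodes into the canonical cohort table (one row each)."""
    rows = [
        {
            "patient_id": e.patient_id,
            "age": e.age,
            "sex": e.sex,
            "los": e.los,
            "vessels_obstructed": e.vessels_obstructed,
            "antibiotic_types": e.antibiotic_types,
            "antibiotic_ddd_total": e.antibiotic_ddd_total,
            "cefazolin_ddd": e.cefazolin_ddd,
            "atc_codes_used": _join_set(e.atc_codes_used),
            "index_secondary_dx": _join_set(e.index_secondary_dx),
            "postdischarge_dx": _join_set(e.postdischarge_dx),
            "ssi_label": e.ssi_label,
        }
        for e in episodes
    ]
    return pd.DataFrame(rows, columns=COHORT_COLUMNS)


def frame_to_episodes(frame: pd.DataFrame) -> list[PatientEpisode]:
    """Parse cohort-table rows into validated :class:`PatientEpisode` objects."""
    missing = [c for c in COHORT_COLUMNS if c not in frame.columns]
    if missing:
        raise ValueError(f"cohort table is missing required columns: {missing}")
    episodes = []
    for row in frame.itertuples(index=False):
        episodes.append(
            PatientEpisode(
                patient_id=str(row.patient_id),
                age=int(row.age),
                sex=str(row.sex),
                los=float(row.los),
                vessels_obstructed=int(row.vessels_obstructed),
                antibiotic_types=int(row.antibiotic_types),
                antibiotic_ddd_total=float(row.antibiotic_ddd_total),
                cefazolin_ddd=float(row.cefazolin_ddd),
                atc_codes_used=_split_set(row.atc_codes_used),
                index_secondary_dx=_split_set(row.index_secondary_dx),
                postdischarge_dx=_split_set(row.postdischarge_dx),
                ssi_label=int(row.ssi_label),
            )
        )
    return episodes


def read_cohort_csv(path: str | Path | io.IOBase) -> pd.DataFrame:
    """Read a cohort CSV (header required) and check its schema."""
    frame = pd.read_csv(path, dtype={"patient_id": str}, keep_default_na=False, na_values=[])
    missing = [c for c in COHORT_COLUMNS if c not in frame.columns]
    if missing:
        raise ValueError(f"cohort CSV is missing required columns: {missing}")
    frame_to_episodes(frame)  # validates every row
    return frame


def write_cohort_csv(frame: pd.DataFrame, path: str | Path) -> None:
    frame.to_csv(path, index=False, lineterminator="\n")


def with_thresholds(thresholds: CriteriaThresholds, **overrides: float) -> CriteriaThresholds:
    """Return a copy of ``thresholds`` with the given fields replaced."""
    return replace(thresholds, **overrides)
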