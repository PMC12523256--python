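"""Staging/grade consistency validation with descriptive error codes.

Five rule families are evaluated independently on each record; missing
fields silently skip the rules that need them.  Codes form a closed
vocabulary (the Gleason code is parameterized by score sum and reported
grade group).
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd

from .record_model import (
    PathologyRecord,
    TnmCode,
    grade_group_from_patterns,
    is_missing,
)

__all__ = [
    "ConsistencyError",
    "ERROR_CODES",
    "GLEASON_CODE_RE",
    "validate_record",
    "validate_corpus",
    "CorpusValidation",
]

#: Fixed (non-parameterized) error codes, in rule-family order.
ERROR_CODES: tuple[str, ...] = (
    "T2_stage_with_EPE_should_be_T3a",
    "SVI_present_should_be_T3b_or_higher",
    "N0_stage_but_positive_lymph_nodes",
    "N1_stage_but_no_positive_lymph_nodes",
    "T3a_stage_but_no_EPE",
    "T3b_stage_but_no_SVI",
)

GLEASON_CODE_RE = re.compile(r"^Gleason_(\d+)_inconsistent_with_GG([1-5])$")

_T2_FAMILY = frozenset({"T2", "T2a", "T2b", "T2c"})


@dataclass(frozen=True)
class ConsistencyError:
    code: str
    report_id: str
    detail: str


def _t_code(record: PathologyRecord) -> str | None:
    return record.t_stage.code if isinstance(record.t_stage, TnmCode) else None


def _n_code(record: PathologyRecord) -> str | None:
    return record.n_stage.code if isinstance(record.n_stage, TnmCode) else None


def validate_record(record: PathologyRecord) -> list[ConsistencyError]:
    """Evaluate all five rule families; errors follow rule-family order 1-5.

    1. T2-family stage with EPE present.
    2. SVI present in a T2-family or T3a stage.
    3. N0 with positive lymph nodes / N1 without positive nodes.
    4. Gleason sum (primary+secondary) discordant with the reported grade group.
    5. T3a without EPE / T3b without SVI.
    """
    errors: list[ConsistencyError] = []
    rid = record.report_id
    t = _t_code(record)
    n = _n_code(record)

    # 1: T2 stages with EPE present
    if t in _T2_FAMILY and record.epe == "Present":
        errors.append(ConsistencyError(
            "T2_stage_with_EPE_should_be_T3a", rid,
            f"T-stage {t} recorded with EPE present; EPE implies at least T3a",
        ))

    # 2: SVI present in T2 or T3a stages
    if record.svi == "Present" and (t in _T2_FAMILY or t == "T3a"):
        errors.append(ConsistencyError(
            "SVI_present_should_be_T3b_or_higher", rid,
            f"SVI present but T-stage is {t}; SVI implies at least T3b",
        ))

    # 3: N-stage vs lymph-node metastasis counts
    mets = record.nodes_with_metastasis
    if n == "N0" and not is_missing(mets) and mets > 0:
        errors.append(ConsistencyError(
            "N0_stage_but_positive_lymph_nodes", rid,
            f"N0 recorded but {mets} lymph node(s) with metastasis",
        ))
    if n == "N1" and not is_missing(mets) and mets == 0:
        errors.append(ConsistencyError(
            "N1_stage_but_no_positive_lymph_nodes", rid,
            "N1 recorded but no lymph nodes with metastasis",
        ))

    # 4: Gleason sum vs reported grade group (tertiary pattern ignored)
    g = record.gleason
    if (
        not is_missing(g.primary_pattern)
        and not is_missing(g.secondary_pattern)
        and not is_missing(g.reported_grade_group)
    ):
        expected = grade_group_from_patterns(g.primary_pattern, g.secondary_pattern)
        if expected != g.reported_grade_group:
            total = g.primary_pattern + g.secondary_pattern
            errors.append(ConsistencyError(
                f"Gleason_{total}_inconsistent_with_GG{g.reported_grade_group}", rid,
                f"Gleason {g.primary_pattern}+{g.secondary_pattern}={total} maps to "
                f"grade group {expected}, but grade group "
                f"{g.reported_grade_group} was reported",
            ))

    # 5: T3a without EPE / T3b without SVI
    if t == "T3a" and record.epe == "Absent":
        errors.append(ConsistencyError(
            "T3a_stage_but_no_EPE", rid,
            "T-stage T3a recorded but EPE absent",
        ))
    if t == "T3b" and record.svi == "Absent":
        errors.append(ConsistencyError(
            "T3b_stage_but_no_SVI", rid,
            "T-stage T3b recorded but SVI absent",
        ))
    return errors


@dataclass(frozen=True)
class CorpusValidation:
    """Flat error table plus summary counts, mirroring the export sheets."""

    errors: pd.DataFrame  # columns report_id, error_code, detail
    summary: pd.DataFrame  # columns error_code, n, percent (over errors)
    n_records: int
    n_flagged: int

    @property
    def pct_flagged(self) -> float:
        """Flagged cases as a percentage of the corpus."""
        return 100.0 * self.n_flagged / self.n_records if self.n_records else 0.0


def validate_corpus(records: Sequence[PathologyRecord]) -> CorpusValidation:
    rows = []
    flagged: set[str] = set()
    for record in records:
        for err in validate_record(record):
            rows.append((err.report_id, err.code, err.detail))
            flagged.add(record.report_id)
    errors = pd.DataFrame(rows, columns=["report_id", "error_code", "detail"])
    if len(errors):
        counts = errors["error_code"].value_counts()
        summary = pd.DataFrame({
            "error_code": counts.index,
            "n": counts.values,
            "percent": 100.0 * counts.values / counts.values.sum(),
        }).reset_index(drop=True)
    else:
        summary = pd.DataFrame(columns=["error_code", "n", "percent"])
    return CorpusValidation(
        errors=errors,
        summary=summary,
        n_records=len(records),
        n_flagged=len(flagged),
    )
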