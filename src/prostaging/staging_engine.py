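"""Prioritized rule-based AJCC 8th-edition prostate staging.

Nine rules are evaluated in fixed priority order over five staging elements
(T, N, M, grade group, PSA).  A rule fires only when every one of its
conditions is definitely true.  A rule whose outcome cannot be decided
because a needed element is missing *blocks* staging: the final result is
``Unknown`` listing every missing element that blocked a potentially-firing
rule, in the fixed element order T-Stage, N-Stage, M-Stage, Grade Group, PSA.

Missing M-stage is imputed to M0 before rule evaluation (radical
prostatectomy implies localized disease); whether an ``Mx`` x-code also gets
imputed is configurable via ``pmx_blocks``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Optional, Sequence, Union

from .record_model import (
    MissingKind,
    MissingValue,
    NOT_MENTIONED,
    PathologyRecord,
    TnmCode,
    is_missing,
)

__all__ = [
    "STAGES",
    "ELEMENT_ORDER",
    "StagingInput",
    "StagingResult",
    "impute_m",
    "assign_stage",
    "stage_record",
    "UNKNOWN",
]

#: Assignable stages in increasing severity order.
STAGES: tuple[str, ...] = ("I", "IIA", "IIB", "IIC", "IIIA", "IIIB", "IIIC", "IVA", "IVB")
UNKNOWN = "Unknown"

#: Fixed order of element names in Unknown labels.
ELEMENT_ORDER: tuple[str, ...] = ("T-Stage", "N-Stage", "M-Stage", "Grade Group", "PSA")

_T3_T4 = frozenset({"T3", "T3a", "T3b", "T4"})
_T1_T2 = frozenset({"T1", "T1a", "T1b", "T1c", "T2", "T2a", "T2b", "T2c"})
_T1_T2A = frozenset({"T1", "T1a", "T1b", "T1c", "T2", "T2a"})


@dataclass(frozen=True)
class StagingInput:
    """Staging-relevant projection of a record: T/N/M codes, grade group, PSA."""

    t: Union[TnmCode, MissingValue] = NOT_MENTIONED
    n: Union[TnmCode, MissingValue] = NOT_MENTIONED
    m: Union[TnmCode, MissingValue] = NOT_MENTIONED
    grade_group: Union[int, MissingValue] = NOT_MENTIONED
    psa: Union[float, MissingValue] = NOT_MENTIONED


@dataclass(frozen=True)
class StagingResult:
    stage: str
    missing_elements: tuple[str, ...] = ()
    fired_rule: Optional[int] = None
    imputations: tuple[tuple[str, str], ...] = ()
    report_id: Optional[str] = None

    def __post_init__(self) -> None:
        if self.stage == UNKNOWN:
            if not self.missing_elements:
                raise ValueError("Unknown result must list missing elements")
            if self.fired_rule is not None:
                raise ValueError("Unknown result cannot carry a fired rule")
        elif self.missing_elements:
            raise ValueError("assigned stage must not list missing elements")

    @property
    def label(self) -> str:
        """Human-readable stage label, e.g. ``Unknown (Missing N-Stage)``."""
        if self.stage == UNKNOWN:
            return f"Unknown (Missing {', '.join(self.missing_elements)})"
        return self.stage

    def to_dict(self) -> dict:
        return {
            "report_id": self.report_id,
            "stage": self.stage,
            "label": self.label,
            "missing_elements": list(self.missing_elements),
            "fired_rule": self.fired_rule,
            "imputations": [list(p) for p in self.imputations],
        }


def impute_m(
    inp: StagingInput, *, pmx_blocks: bool = False
) -> tuple[StagingInput, tuple[tuple[str, str], ...]]:
    """Impute missing M-stage to M0; returns the input and imputation notes.

    With ``pmx_blocks=True`` an ``x_code`` M value (``pMx``) is left missing,
    so downstream staging reports ``Unknown (Missing M-Stage, ...)`` instead.
    """
    m = inp.m
    if is_missing(m) and not (pmx_blocks and m.kind is MissingKind.X_CODE):
        imputed = replace(inp, m=TnmCode(prefix="", category="M", code="M0"))
        return imputed, (("M-Stage", "M0"),)
    return inp, ()


# Each rule: (number, stage, ((element name, predicate over concrete value), ...)).
# Predicates see the bare code string for T/N/M, the int grade group, the
# float PSA.  Order encodes priority.
_Rule = tuple[int, str, tuple[tuple[str, Callable], ...]]

_RULES: tuple[_Rule, ...] = (
    (1, "IVB", (("M-Stage", lambda m: m == "M1"),)),
    (2, "IVA", (("N-Stage", lambda n: n == "N1"), ("M-Stage", lambda m: m == "M0"))),
    (3, "IIIC", (
        ("Grade Group", lambda g: g == 5),
        ("N-Stage", lambda n: n == "N0"),
        ("M-Stage", lambda m: m == "M0"),
    )),
    (4, "IIIB", (
        ("T-Stage", lambda t: t in _T3_T4),
        ("N-Stage", lambda n: n == "N0"),
        ("M-Stage", lambda m: m == "M0"),
        ("Grade Group", lambda g: g <= 4),
    )),
    (5, "IIIA", (
        ("PSA", lambda p: p >= 20),
        ("T-Stage", lambda t: t in _T1_T2),
        ("N-Stage", lambda n: n == "N0"),
        ("M-Stage", lambda m: m == "M0"),
        ("Grade Group", lambda g: g <= 4),
    )),
    (6, "I", (
        ("T-Stage", lambda t: t in _T1_T2A),
        ("N-Stage", lambda n: n == "N0"),
        ("M-Stage", lambda m: m == "M0"),
        ("Grade Group", lambda g: g == 1),
        ("PSA", lambda p: p < 10),
    )),
    # Sequential evaluation means stage I has already claimed T1-T2a with
    # PSA < 10, so this rule covers the remaining GG1 / PSA < 20 territory
    # (including T2b-T2c below 10, which the range shorthand leaves implicit).
    (7, "IIA", (
        ("T-Stage", lambda t: t in _T1_T2),
        ("N-Stage", lambda n: n == "N0"),
        ("M-Stage", lambda m: m == "M0"),
        ("Grade Group", lambda g: g == 1),
        ("PSA", lambda p: p < 20),
    )),
    (8, "IIB", (
        ("T-Stage", lambda t: t in _T1_T2),
        ("N-Stage", lambda n: n == "N0"),
        ("M-Stage", lambda m: m == "M0"),
        ("Grade Group", lambda g: g == 2),
        ("PSA", lambda p: p < 20),
    )),
    (9, "IIC", (
        ("T-Stage", lambda t: t in _T1_T2),
        ("N-Stage", lambda n: n == "N0"),
        ("M-Stage", lambda m: m == "M0"),
        ("Grade Group", lambda g: g in (3, 4)),
        ("PSA", lambda p: p < 20),
    )),
)


def _element_value(inp: StagingInput, element: str):
    """Concrete value of a staging element, or None when missing."""
    if element == "T-Stage":
        return inp.t.code if isinstance(inp.t, TnmCode) else None
    if element == "N-Stage":
        return inp.n.code if isinstance(inp.n, TnmCode) else None
    if element == "M-Stage":
        return inp.m.code if isinstance(inp.m, TnmCode) else None
    if element == "Grade Group":
        return None if is_missing(inp.grade_group) else inp.grade_group
    if element == "PSA":
        return None if is_missing(inp.psa) else inp.psa
    raise KeyError(element)


def assign_stage(inp: StagingInput) -> StagingResult:
    """Assign an AJCC stage (or Unknown) to an already M-imputed input.

    Total and deterministic: every input yields exactly one result.
    """
    blocked: set[str] = set()
    for number, stage, conditions in _RULES:
        missing_here: list[str] = []
        definitely_false = False
        for element, predicate in conditions:
            value = _element_value(inp, element)
            if value is None:
                missing_here.append(element)
            elif not predicate(value):
                definitely_false = True
                break
        if definitely_false:
            continue
        if not missing_here:
            if blocked:
                # an earlier undecidable rule preempts this one
                continue
            return StagingResult(stage=stage, fired_rule=number)
        blocked.update(missing_here)
    ordered = tuple(e for e in ELEMENT_ORDER if e in blocked)
    if not ordered:
        # unreachable for valid inputs: the rule set is total on complete
        # inputs; guard against silent misuse
        raise AssertionError(f"no rule fired and nothing missing: {inp}")
    return StagingResult(stage=UNKNOWN, missing_elements=ordered)


def stage_record(record: PathologyRecord, *, pmx_blocks: bool = False) -> StagingResult:
    """Project a record to staging elements, impute M, and assign a stage.

    Grade group comes from the reported WHO grade group when present,
    otherwise it is derived from the primary and secondary patterns.
    """
    gg = record.gleason.reported_grade_group
    if is_missing(gg):
        gg = record.gleason.derived_grade_group()
    inp = StagingInput(
        t=record.t_stage,
        n=record.n_stage,
        m=record.m_stage,
        grade_group=gg,
        psa=record.psa_ng_ml,
    )
    inp, imputations = impute_m(inp, pmx_blocks=pmx_blocks)
    result = assign_stage(inp)
    return replace(result, imputations=imputations, report_id=record.report_id)
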