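"""Report-to-record extraction: contract, offline baseline, and JSON parsing.

The extraction contract is a callable from report text to an
:class:`ExtractionResult` holding, for each of the 16 canonical parameters,
a value, a verbatim evidence span and a confidence in [0, 1].  External
model adapters can emit the same JSON schema; :func:`parse_extraction_json`
tolerantly parses it and reports a structured failure for malformed payloads
(so callers can exclude those reports instead of crashing).

:func:`baseline_extract` is a deterministic pattern-based extractor that
understands the report dialects rendered by :mod:`prostaging.synthetic_data`
(narrative prose, synoptic key-value lines, and a tabulated grade grid with
an "X" mark).  When only the primary pattern's percentage is stated it
derives the secondary percentage as the complement.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from typing import Any, Callable, Mapping, Optional, Union

from .record_model import (
    DASH,
    MissingKind,
    MissingValue,
    NOT_MENTIONED,
    PARAMETER_NAMES,
    GleasonInfo,
    PathologyRecord,
    TnmParseError,
    complement_secondary_percentage,
    parse_tnm,
)

__all__ = [
    "FieldExtraction",
    "ExtractionResult",
    "ExtractionFailure",
    "FieldError",
    "ToRecordOutcome",
    "parse_extraction_json",
    "baseline_extract",
    "to_record",
]


@dataclass(frozen=True)
class FieldExtraction:
    """Extracted value for one parameter. ``value=None`` means missing."""

    value: Optional[Union[str, int, float]] = None
    evidence: str = ""
    confidence: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.confidence <= 1.0:
            raise ValueError(f"confidence out of [0,1]: {self.confidence!r}")


_MISSING_FIELD = FieldExtraction()


@dataclass
class ExtractionResult:
    report_id: str
    fields: dict[str, FieldExtraction] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name in PARAMETER_NAMES:
            self.fields.setdefault(name, _MISSING_FIELD)
        unknown = set(self.fields) - set(PARAMETER_NAMES)
        if unknown:
            raise ValueError(f"unknown parameter names: {sorted(unknown)}")

    def to_dict(self) -> dict:
        return {
            "report_id": self.report_id,
            "fields": {
                name: {
                    "value": fe.value,
                    "evidence": fe.evidence,
                    "confidence": fe.confidence,
                }
                for name, fe in self.fields.items()
            },
        }


@dataclass(frozen=True)
class ExtractionFailure:
    """Structured signal that a payload could not be parsed as JSON."""

    report_id: str
    reason: str


_FENCE_RE = re.compile(r"```(?:json)?\s*(.*?)```", re.DOTALL)


def parse_extraction_json(
    text: str, report_id: str = ""
) -> Union[ExtractionResult, ExtractionFailure]:
    """Parse LLM-style JSON output into an :class:`ExtractionResult`.

    Strips code fences and trailing commentary, ignores unknown keys, and
    turns absent keys into missing fields.  Malformed JSON yields an
    :class:`ExtractionFailure` carrying the report id and reason.
    """
    candidate = text.strip()
    m = _FENCE_RE.search(candidate)
    if m:
        candidate = m.group(1).strip()
    # tolerate commentary around the outermost object
    start, end = candidate.find("{"), candidate.rfind("}")
    if start == -1 or end <= start:
        return ExtractionFailure(report_id, "no JSON object found")
    try:
        payload = json.loads(candidate[start : end + 1])
    except json.JSONDecodeError as exc:
        return ExtractionFailure(report_id, f"invalid JSON: {exc.msg}")
    if not isinstance(payload, Mapping):
        return ExtractionFailure(report_id, "top-level JSON value is not an object")

    fields: dict[str, FieldExtraction] = {}
    for name in PARAMETER_NAMES:
        raw = payload.get(name)
        if raw is None:
            continue
        if isinstance(raw, Mapping):
            value = raw.get("value")
            evidence = raw.get("evidence") or ""
            try:
                confidence = float(raw.get("confidence", 0.0))
            except (TypeError, ValueError):
                confidence = 0.0
            confidence = min(max(confidence, 0.0), 1.0)
        else:
            value, evidence, confidence = raw, "", 1.0
        if isinstance(value, str) and value.strip().casefold() in (
            "", "not mentioned", "null", "none",
        ):
            value = None
        fields[name] = FieldExtraction(value=value, evidence=str(evidence), confidence=confidence)
    return ExtractionResult(report_id=report_id, fields=fields)


# ---------------------------------------------------------------------------
# Baseline extractor

def _patterns(*regexes: str) -> tuple[re.Pattern, ...]:
    return tuple(re.compile(r, re.IGNORECASE | re.MULTILINE) for r in regexes)


# Per-parameter pattern lists, first match wins.  Group "v" is the value.
_FIELD_PATTERNS: dict[str, tuple[re.Pattern, ...]] = {
    "Histologic Subtype": _patterns(
        r"^Histologic type:\s*(?P<v>[^\n]+?)\s*$",
        r"Histologic examination demonstrates (?P<v>[^.\n]+)\.",
    ),
    "Primary Gleason Pattern": _patterns(
        r"^Primary Gleason pattern:\s*(?P<v>[3-5])\s*$",
        r"Gleason score (?P<v>[3-5]) \+ [3-5]",
    ),
    "Secondary Gleason Pattern": _patterns(
        r"^Secondary Gleason pattern:\s*(?P<v>[3-5])\s*$",
        r"Gleason score [3-5] \+ (?P<v>[3-5])",
    ),
    "Tertiary Gleason Pattern": _patterns(
        r"^Tertiary Gleason pattern:\s*(?P<v>[3-5])\s*$",
        r"tertiary pattern (?P<v>[3-5])",
    ),
    "WHO Grade Group": _patterns(
        r"^WHO Grade Group:\s*(?P<v>[1-5])\s*$",
        r"^GG(?P<v>[1-5])\s*\|[^|\n]*\|\s*X\s*$",
        r"WHO Grade Group (?P<v>[1-5])",
    ),
    "EPE": _patterns(
        r"Extraprostatic extension(?: is|:)\s*(?P<v>present|absent)",
    ),
    "SVI": _patterns(
        r"Seminal vesicle invasion(?: is|:)\s*(?P<v>present|absent)",
    ),
    "Perineural Invasion": _patterns(
        r"Perineural invasion(?: is|:)\s*(?P<v>present|absent)",
    ),
    "Resection Margins": _patterns(
        r"^Resection margins:\s*(?P<v>[^\n]+?)\s*$",
        r"Resection margins are (?P<v>[^.\n]+)\.",
    ),
    "Number of Lymph Nodes examined": _patterns(
        r"^Number of lymph nodes examined:\s*(?P<v>\d+)\s*$",
        r"(?P<v>\d+) lymph nodes? (?:were|was) examined",
    ),
    "Lymph Nodes with Metastasis": _patterns(
        r"^Number of lymph nodes with metastasis:\s*(?P<v>\d+)\s*$",
        r"examined and (?P<v>\d+) (?:showed|contained) metastatic",
    ),
    "T-Stage": _patterns(
        r"^Pathologic T-stage:\s*(?P<v>[pc]?T[0-9][abc]?)\s*$",
        r"Pathologic stage is [^.\n]*?\b(?P<v>[pc]?T[0-9][abc]?)\b",
    ),
    "N-Stage": _patterns(
        r"^Pathologic N-stage:\s*(?P<v>[pc]?N(?:[01]|x))\s*$",
        r"Pathologic stage is [^.\n]*?\b(?P<v>[pc]?N(?:[01]|x))\b",
    ),
    "M-Stage": _patterns(
        r"^M-stage:\s*(?P<v>[pc]?M(?:[01]|x))\s*$",
        r"Pathologic stage is [^.\n]*?\b(?P<v>[pc]?M(?:[01]|x))\b",
    ),
    "PSA": _patterns(
        r"^Serum PSA:\s*(?P<v>\d+(?:\.\d+)?)\s*ng/mL\s*$",
        r"Serum PSA was (?P<v>\d+(?:\.\d+)?)\s*ng/mL",
    ),
}

_PCT_SECONDARY_DIRECT = _patterns(
    r"^Percentage of secondary pattern:\s*(?P<v>\d+(?:\.\d+)?)%\s*$",
    r"secondary pattern comprising (?P<v>\d+(?:\.\d+)?)%",
)
# "(60% pattern 4)" — percentage attributed to a named pattern.
_PCT_BY_PATTERN = re.compile(
    r"\((?P<pct>\d+(?:\.\d+)?)% pattern (?P<pat>[3-5])\)", re.IGNORECASE
)

_INT_FIELDS = {
    "Primary Gleason Pattern", "Secondary Gleason Pattern",
    "Tertiary Gleason Pattern", "WHO Grade Group",
    "Number of Lymph Nodes examined", "Lymph Nodes with Metastasis",
}


def baseline_extract(report_text: str, report_id: str = "") -> ExtractionResult:
    """Deterministic pattern-based extraction of all 16 parameters.

    Confidence is 1.0 for pattern hits and 0.0 for misses; evidence is the
    matched span.  Never raises on arbitrary text — misses become missing
    fields.
    """
    fields: dict[str, FieldExtraction] = {}
    for name, patterns in _FIELD_PATTERNS.items():
        for pattern in patterns:
            m = pattern.search(report_text)
            if m:
                value: Any = m.group("v")
                if name in _INT_FIELDS:
                    value = int(value)
                elif name == "PSA":
                    value = float(value)
                elif name in ("EPE", "SVI", "Perineural Invasion"):
                    value = value.capitalize()
                fields[name] = FieldExtraction(value, m.group(0), 1.0)
                break

    pct = _extract_pct_secondary(report_text, fields)
    if pct is not None:
        fields["Percentage of Secondary Gleason Pattern"] = pct
    return ExtractionResult(report_id=report_id, fields=fields)


def _extract_pct_secondary(
    text: str, fields: Mapping[str, FieldExtraction]
) -> Optional[FieldExtraction]:
    for pattern in _PCT_SECONDARY_DIRECT:
        m = pattern.search(text)
        if m:
            return FieldExtraction(float(m.group("v")), m.group(0), 1.0)
    m = _PCT_BY_PATTERN.search(text)
    if m:
        pct, pat = float(m.group("pct")), int(m.group("pat"))
        secondary = fields.get("Secondary Gleason Pattern")
        primary = fields.get("Primary Gleason Pattern")
        if secondary is not None and secondary.value == pat and (
            primary is None or primary.value != pat
        ):
            return FieldExtraction(pct, m.group(0), 1.0)
        # percentage belongs to the primary pattern: take the complement
        return FieldExtraction(
            complement_secondary_percentage(pct), m.group(0), 1.0
        )
    return None


# ---------------------------------------------------------------------------
# Typed bridge to PathologyRecord

@dataclass(frozen=True)
class FieldError:
    parameter: str
    raw_value: Any
    reason: str


@dataclass(frozen=True)
class ToRecordOutcome:
    record: PathologyRecord
    errors: tuple[FieldError, ...] = ()


def _as_missing(raw: Any) -> Optional[MissingValue]:
    if raw is None:
        return NOT_MENTIONED
    if isinstance(raw, str):
        s = raw.strip()
        if s.casefold() in ("", "not mentioned", "none", "null", "na", "n/a"):
            return NOT_MENTIONED
        if s == "-":
            return DASH
    return None


def _presence(raw: Any) -> Union[str, MissingValue]:
    s = str(raw).strip().casefold()
    if s in ("present", "positive", "identified", "yes"):
        return "Present"
    if s in ("absent", "negative", "not identified", "no"):
        return "Absent"
    raise ValueError(f"not a presence value: {raw!r}")


def _number(raw: Any, cast, lo=None, hi=None):
    value = cast(str(raw).strip().rstrip("%")) if isinstance(raw, str) else cast(raw)
    if lo is not None and value < lo:
        raise ValueError(f"value below {lo}: {raw!r}")
    if hi is not None and value > hi:
        raise ValueError(f"value above {hi}: {raw!r}")
    return value


def to_record(
    extraction: ExtractionResult, patient_id: str = ""
) -> ToRecordOutcome:
    """Convert an extraction result into a typed :class:`PathologyRecord`.

    Type-invalid values become field-level errors attached to the outcome
    (the field is left missing) rather than exceptions.
    """
    values: dict[str, Any] = {}
    errors: list[FieldError] = []

    converters: dict[str, Callable[[Any], Any]] = {
        "T-Stage": lambda raw: parse_tnm(str(raw), "T"),
        "N-Stage": lambda raw: parse_tnm(str(raw), "N"),
        "M-Stage": lambda raw: parse_tnm(str(raw), "M"),
        "EPE": _presence,
        "SVI": _presence,
        "Perineural Invasion": _presence,
        "Histologic Subtype": lambda raw: str(raw).strip(),
        "Resection Margins": lambda raw: str(raw).strip(),
        "PSA": lambda raw: _number(raw, float, lo=0),
        "Percentage of Secondary Gleason Pattern": lambda raw: _number(raw, float, 0, 100),
        "Primary Gleason Pattern": lambda raw: _number(raw, int, 3, 5),
        "Secondary Gleason Pattern": lambda raw: _number(raw, int, 3, 5),
        "Tertiary Gleason Pattern": lambda raw: _number(raw, int, 3, 5),
        "WHO Grade Group": lambda raw: _number(raw, int, 1, 5),
        "Number of Lymph Nodes examined": lambda raw: _number(raw, int, lo=0),
        "Lymph Nodes with Metastasis": lambda raw: _number(raw, int, lo=0),
    }

    for name in PARAMETER_NAMES:
        raw = extraction.fields[name].value
        missing = _as_missing(raw)
        if missing is not None:
            values[name] = missing
            continue
        try:
            values[name] = converters[name](raw)
        except (ValueError, TnmParseError) as exc:
            errors.append(FieldError(name, raw, str(exc)))
            values[name] = NOT_MENTIONED

    gleason = GleasonInfo(
        primary_pattern=values["Primary Gleason Pattern"],
        secondary_pattern=values["Secondary Gleason Pattern"],
        tertiary_pattern=values["Tertiary Gleason Pattern"],
        pct_secondary=values["Percentage of Secondary Gleason Pattern"],
        reported_grade_group=values["WHO Grade Group"],
    )
    record = PathologyRecord(
        patient_id=patient_id,
        report_id=extraction.report_id,
        t_stage=values["T-Stage"],
        n_stage=values["N-Stage"],
        m_stage=values["M-Stage"],
        gleason=gleason,
        psa_ng_ml=values["PSA"],
        epe=values["EPE"],
        svi=values["SVI"],
        perineural_invasion=values["Perineural Invasion"],
        histologic_subtype=values["Histologic Subtype"],
        resection_margins=values["Resection Margins"],
        nodes_examined=values["Number of Lymph Nodes examined"],
        nodes_with_metastasis=values["Lymph Nodes with Metastasis"],
        allow_incoherent_counts=True,
    )
    return ToRecordOutcome(record=record, errors=tuple(errors))
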