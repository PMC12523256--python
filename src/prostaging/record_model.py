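"""Domain types for structured radical-prostatectomy pathology records.

This module owns the structured representation of a single pathology report:
TNM code parsing, the three-way missing-value distinction (``not mentioned``,
``-``, and recorded-but-uninformative x-codes such as ``pNx``), Gleason
pattern / ISUP grade-group arithmetic, and the value normalization used when
comparing extracted values against ground truth.

The 16 canonical parameter names (:data:`PARAMETER_NAMES`) are the shared
vocabulary between records, extraction results and evaluation tables.
"""

from __future__ import annotations

import enum
import re
from dataclasses import dataclass, field, replace
from typing import Any, Iterable, Mapping, Optional, Union

__all__ = [
    "PARAMETER_NAMES",
    "T_CODES",
    "N_CODES",
    "M_CODES",
    "MissingKind",
    "MissingValue",
    "NOT_MENTIONED",
    "DASH",
    "is_missing",
    "TnmCode",
    "TnmParseError",
    "parse_tnm",
    "render_tnm",
    "GleasonInfo",
    "PathologyRecord",
    "grade_group_from_patterns",
    "complement_secondary_percentage",
    "normalize_for_match",
    "values_match",
    "record_to_dict",
    "record_from_dict",
    "parameter_value",
]

#: Canonical spelling of the 16 per-report parameters, in alphabetical-ish
#: reporting order.  These exact strings are used as JSON keys, extraction
#: field names and evaluation row labels.
PARAMETER_NAMES: tuple[str, ...] = (
    "EPE",
    "Histologic Subtype",
    "Lymph Nodes with Metastasis",
    "M-Stage",
    "N-Stage",
    "Number of Lymph Nodes examined",
    "Percentage of Secondary Gleason Pattern",
    "Perineural Invasion",
    "Primary Gleason Pattern",
    "Resection Margins",
    "Secondary Gleason Pattern",
    "SVI",
    "PSA",
    "T-Stage",
    "Tertiary Gleason Pattern",
    "WHO Grade Group",
)

T_CODES: tuple[str, ...] = (
    "T1", "T1a", "T1b", "T1c",
    "T2", "T2a", "T2b", "T2c",
    "T3", "T3a", "T3b", "T4",
)
N_CODES: tuple[str, ...] = ("N0", "N1")
M_CODES: tuple[str, ...] = ("M0", "M1")

#: Per-category x-codes: recorded in the report but uninformative for staging.
_X_CODES = {"N": "Nx", "M": "Mx"}

_VALID_CODES = {"T": set(T_CODES), "N": set(N_CODES), "M": set(M_CODES)}


class MissingKind(str, enum.Enum):
    """How a value is missing.

    ``not_mentioned``
        The report says nothing about the parameter.
    ``dash``
        The parameter slot exists but holds a dash placeholder.
    ``x_code``
        A TNM x-code (``pNx``/``pMx``): recorded, but it cannot inform
        staging.  The literal token is preserved for value matching.
    """

    NOT_MENTIONED = "not_mentioned"
    DASH = "dash"
    X_CODE = "x_code"


@dataclass(frozen=True)
class MissingValue:
    kind: MissingKind
    literal: Optional[str] = None

    def __post_init__(self) -> None:
        if self.kind is MissingKind.X_CODE and not self.literal:
            raise ValueError("x_code missing values must carry their literal token")


NOT_MENTIONED = MissingValue(MissingKind.NOT_MENTIONED)
DASH = MissingValue(MissingKind.DASH, "-")


def is_missing(value: Any) -> bool:
    return isinstance(value, MissingValue)


class TnmParseError(ValueError):
    """Raised for tokens that are not valid prostate TNM codes."""


@dataclass(frozen=True)
class TnmCode:
    """A single TNM code such as ``pT3a`` or ``cM0``.

    The p/c prefix is metadata only: staging and value comparison ignore it.
    """

    prefix: str  # "p", "c" or ""
    category: str  # "T", "N" or "M"
    code: str  # e.g. "T3a", "N0", "M1"

    def __post_init__(self) -> None:
        if self.prefix not in ("", "p", "c"):
            raise ValueError(f"invalid TNM prefix {self.prefix!r}")
        if self.category not in _VALID_CODES:
            raise ValueError(f"invalid TNM category {self.category!r}")
        if self.code not in _VALID_CODES[self.category]:
            raise ValueError(
                f"code {self.code!r} does not belong to category {self.category!r}"
            )

    def render(self) -> str:
        return f"{self.prefix}{self.code}"


_TNM_RE = re.compile(r"^([pc]?)([tnm])((?:[0-9][abc]?)|x)$", re.IGNORECASE)
_MISSING_TOKENS = {"", "not mentioned", "none", "null", "na", "n/a", "unknown"}


def parse_tnm(text: Optional[str], category: str) -> Union[TnmCode, MissingValue]:
    """Parse a raw TNM token for the given category (``T``/``N``/``M``).

    Case-insensitive; an optional ``p``/``c`` prefix is preserved.  ``Nx`` and
    ``Mx`` map to an :class:`MissingValue` of kind ``x_code`` that retains the
    (case-normalized) literal.  Dash placeholders map to ``dash`` and empty /
    "not mentioned" tokens to ``not_mentioned``.  Any other token raises
    :class:`TnmParseError`.
    """
    if category not in _VALID_CODES:
        raise ValueError(f"invalid TNM category {category!r}")
    if text is None:
        return NOT_MENTIONED
    token = str(text).strip()
    if token.lower() in _MISSING_TOKENS:
        return NOT_MENTIONED
    if token == "-" or set(token) == {"-"}:
        return DASH
    m = _TNM_RE.match(token)
    if not m:
        raise TnmParseError(f"malformed TNM token {token!r} for category {category}")
    prefix = m.group(1).lower()
    letter = m.group(2).upper()
    suffix = m.group(3).lower()
    if letter != category:
        raise TnmParseError(
            f"token {token!r} has category {letter}, expected {category}"
        )
    if suffix == "x":
        if category not in _X_CODES:
            raise TnmParseError(
                f"malformed TNM token {token!r}: x-code is not defined for category {category}"
            )
        literal = f"{prefix}{_X_CODES[category]}"
        return MissingValue(MissingKind.X_CODE, literal)
    code = f"{letter}{suffix}"
    if code not in _VALID_CODES[category]:
        raise TnmParseError(f"malformed TNM token {token!r} for category {category}")
    return TnmCode(prefix=prefix, category=category, code=code)


def render_tnm(value: Union[TnmCode, MissingValue]) -> Optional[str]:
    """Render a TNM code (or x-code missing value) back to its literal form."""
    if isinstance(value, TnmCode):
        return value.render()
    if isinstance(value, MissingValue) and value.kind is MissingKind.X_CODE:
        return value.literal
    return None


def grade_group_from_patterns(primary: int, secondary: int) -> int:
    """ISUP 2014 grade group from primary and secondary Gleason patterns.

    Mapping: score <= 6 -> 1; 3+4 -> 2; 4+3 -> 3; score 8 -> 4; 9-10 -> 5.
    Patterns must be in {3, 4, 5}.
    """
    for name, p in (("primary", primary), ("secondary", secondary)):
        if p not in (3, 4, 5):
            raise ValueError(f"{name} Gleason pattern must be 3, 4 or 5, got {p!r}")
    total = primary + secondary
    if total <= 6:
        return 1
    if total == 7:
        return 2 if primary == 3 else 3
    if total == 8:
        return 4
    return 5


def complement_secondary_percentage(pct_primary: float) -> float:
    """Secondary-pattern percentage as the complement of the primary's."""
    if not 0 <= pct_primary <= 100:
        raise ValueError(f"percentage out of range: {pct_primary!r}")
    return 100 - pct_primary


@dataclass(frozen=True)
class GleasonInfo:
    """Gleason patterns, secondary-pattern percentage and reported grade group."""

    primary_pattern: Union[int, MissingValue] = NOT_MENTIONED
    secondary_pattern: Union[int, MissingValue] = NOT_MENTIONED
    tertiary_pattern: Union[int, MissingValue] = NOT_MENTIONED
    pct_secondary: Union[float, MissingValue] = NOT_MENTIONED
    reported_grade_group: Union[int, MissingValue] = NOT_MENTIONED

    def __post_init__(self) -> None:
        for name in ("primary_pattern", "secondary_pattern", "tertiary_pattern"):
            v = getattr(self, name)
            if not is_missing(v) and v not in (3, 4, 5):
                raise ValueError(f"{name} must be in {{3,4,5}}, got {v!r}")
        if not is_missing(self.pct_secondary) and not 0 <= self.pct_secondary <= 100:
            raise ValueError(f"pct_secondary out of [0,100]: {self.pct_secondary!r}")
        g = self.reported_grade_group
        if not is_missing(g) and g not in (1, 2, 3, 4, 5):
            raise ValueError(f"reported_grade_group must be 1-5, got {g!r}")

    def derived_grade_group(self) -> Union[int, MissingValue]:
        """Grade group computed from the patterns, or missing if patterns are."""
        if is_missing(self.primary_pattern) or is_missing(self.secondary_pattern):
            return NOT_MENTIONED
        return grade_group_from_patterns(self.primary_pattern, self.secondary_pattern)


@dataclass(frozen=True)
class PathologyRecord:
    """One report's structured parameters plus identifiers.

    ``nodes_with_metastasis <= nodes_examined`` is enforced at construction
    unless ``allow_incoherent_counts`` is set; deliberately incoherent records
    (for validator exercises) must opt in.
    """

    patient_id: str
    report_id: str
    t_stage: Union[TnmCode, MissingValue] = NOT_MENTIONED
    n_stage: Union[TnmCode, MissingValue] = NOT_MENTIONED
    m_stage: Union[TnmCode, MissingValue] = NOT_MENTIONED
    gleason: GleasonInfo = field(default_factory=GleasonInfo)
    psa_ng_ml: Union[float, MissingValue] = NOT_MENTIONED
    epe: Union[str, MissingValue] = NOT_MENTIONED
    svi: Union[str, MissingValue] = NOT_MENTIONED
    perineural_invasion: Union[str, MissingValue] = NOT_MENTIONED
    histologic_subtype: Union[str, MissingValue] = NOT_MENTIONED
    resection_margins: Union[str, MissingValue] = NOT_MENTIONED
    nodes_examined: Union[int, MissingValue] = NOT_MENTIONED
    nodes_with_metastasis: Union[int, MissingValue] = NOT_MENTIONED
    allow_incoherent_counts: bool = field(default=False, compare=False)

    def __post_init__(self) -> None:
        for name, cat in (("t_stage", "T"), ("n_stage", "N"), ("m_stage", "M")):
            v = getattr(self, name)
            if isinstance(v, TnmCode) and v.category != cat:
                raise ValueError(f"{name} holds a {v.category} code")
        for name in ("epe", "svi", "perineural_invasion"):
            v = getattr(self, name)
            if not is_missing(v) and v not in ("Absent", "Present"):
                raise ValueError(f"{name} must be 'Absent' or 'Present', got {v!r}")
        if not is_missing(self.psa_ng_ml) and self.psa_ng_ml < 0:
            raise ValueError("PSA must be non-negative")
        for name in ("nodes_examined", "nodes_with_metastasis"):
            v = getattr(self, name)
            if not is_missing(v) and (not isinstance(v, int) or v < 0):
                raise ValueError(f"{name} must be a non-negative integer")
        if (
            not self.allow_incoherent_counts
            and not is_missing(self.nodes_examined)
            and not is_missing(self.nodes_with_metastasis)
            and self.nodes_with_metastasis > self.nodes_examined
        ):
            raise ValueError(
                "nodes_with_metastasis exceeds nodes_examined "
                "(pass allow_incoherent_counts=True to override)"
            )


# Mapping between canonical parameter names and record attribute accessors.
_PARAM_GETTERS = {
    "EPE": lambda r: r.epe,
    "Histologic Subtype": lambda r: r.histologic_subtype,
    "Lymph Nodes with Metastasis": lambda r: r.nodes_with_metastasis,
    "M-Stage": lambda r: r.m_stage,
    "N-Stage": lambda r: r.n_stage,
    "Number of Lymph Nodes examined": lambda r: r.nodes_examined,
    "Percentage of Secondary Gleason Pattern": lambda r: r.gleason.pct_secondary,
    "Perineural Invasion": lambda r: r.perineural_invasion,
    "Primary Gleason Pattern": lambda r: r.gleason.primary_pattern,
    "Resection Margins": lambda r: r.resection_margins,
    "Secondary Gleason Pattern": lambda r: r.gleason.secondary_pattern,
    "SVI": lambda r: r.svi,
    "PSA": lambda r: r.psa_ng_ml,
    "T-Stage": lambda r: r.t_stage,
    "Tertiary Gleason Pattern": lambda r: r.gleason.tertiary_pattern,
    "WHO Grade Group": lambda r: r.gleason.reported_grade_group,
}


def parameter_value(record: PathologyRecord, name: str) -> Any:
    """Raw value (concrete or :class:`MissingValue`) of a canonical parameter."""
    try:
        return _PARAM_GETTERS[name](record)
    except KeyError:
        raise KeyError(f"unknown parameter {name!r}") from None


_ABSENT = ("absent-value",)

_NUMERIC_RE = re.compile(r"^-?\d+(?:\.\d+)?$")
_TNM_TOKEN_RE = re.compile(r"^[pc]?[tnm](?:[0-9][abc]?|x)$", re.IGNORECASE)


def normalize_for_match(field_name: str, value: Any) -> Any:
    """Canonicalize a value for cross-source equality.

    Case-folded strings; TNM prefixes stripped; numerics rounded to 2
    decimals; every missing kind except ``x_code`` collapses to one absent
    token; x-codes keep their (prefix-stripped) literal code.
    """
    if isinstance(value, MissingValue):
        if value.kind is MissingKind.X_CODE:
            return ("value", _strip_tnm_prefix(value.literal.casefold()))
        return _ABSENT
    if isinstance(value, TnmCode):
        return ("value", value.code.casefold())
    if isinstance(value, bool):
        return ("value", value)
    if isinstance(value, (int, float)):
        return ("num", round(float(value), 2))
    if isinstance(value, str):
        s = value.strip()
        if s.casefold() in _MISSING_TOKENS or s == "-":
            return _ABSENT
        if _NUMERIC_RE.match(s):
            return ("num", round(float(s), 2))
        if _TNM_TOKEN_RE.match(s):
            return ("value", _strip_tnm_prefix(s.casefold()))
        return ("value", s.casefold())
    return ("value", value)


def _strip_tnm_prefix(token: str) -> str:
    return token[1:] if token[:1] in ("p", "c") else token


def values_match(field_name: str, a: Any, b: Any) -> bool:
    """Equality under :func:`normalize_for_match`; numerics use abs tol 0.01."""
    na, nb = normalize_for_match(field_name, a), normalize_for_match(field_name, b)
    if na == _ABSENT or nb == _ABSENT:
        return na == nb
    if na[0] == "num" and nb[0] == "num":
        return abs(na[1] - nb[1]) <= 0.01 + 1e-9
    return na == nb


# ---------------------------------------------------------------------------
# JSON (de)serialization — one object per report, 16 parameter keys exactly
# as canonically spelled plus patient_id / report_id.

def _encode_value(value: Any) -> Any:
    if isinstance(value, MissingValue):
        return {"missing": value.kind.value, "literal": value.literal}
    if isinstance(value, TnmCode):
        return value.render()
    return value


def record_to_dict(record: PathologyRecord) -> dict:
    out: dict[str, Any] = {
        "patient_id": record.patient_id,
        "report_id": record.report_id,
    }
    for name in PARAMETER_NAMES:
        out[name] = _encode_value(parameter_value(record, name))
    return out


def _decode_missing(obj: Mapping) -> MissingValue:
    return MissingValue(MissingKind(obj["missing"]), obj.get("literal"))


def _decode_tnm(raw: Any, category: str) -> Union[TnmCode, MissingValue]:
    if raw is None:
        return NOT_MENTIONED
    if isinstance(raw, Mapping):
        return _decode_missing(raw)
    return parse_tnm(raw, category)


def _decode_scalar(raw: Any, cast=None) -> Any:
    if raw is None:
        return NOT_MENTIONED
    if isinstance(raw, Mapping):
        return _decode_missing(raw)
    return cast(raw) if cast is not None else raw


def record_from_dict(obj: Mapping) -> PathologyRecord:
    """Inverse of :func:`record_to_dict`; tolerant of plain-scalar encodings."""
    gleason = GleasonInfo(
        primary_pattern=_decode_scalar(obj.get("Primary Gleason Pattern"), int),
        secondary_pattern=_decode_scalar(obj.get("Secondary Gleason Pattern"), int),
        tertiary_pattern=_decode_scalar(obj.get("Tertiary Gleason Pattern"), int),
        pct_secondary=_decode_scalar(
            obj.get("Percentage of Secondary Gleason Pattern"), float
        ),
        reported_grade_group=_decode_scalar(obj.get("WHO Grade Group"), int),
    )
    return PathologyRecord(
        patient_id=str(obj.get("patient_id", "")),
        report_id=str(obj.get("report_id", "")),
        t_stage=_decode_tnm(obj.get("T-Stage"), "T"),
        n_stage=_decode_tnm(obj.get("N-Stage"), "N"),
        m_stage=_decode_tnm(obj.get("M-Stage"), "M"),
        gleason=gleason,
        psa_ng_ml=_decode_scalar(obj.get("PSA"), float),
        epe=_decode_scalar(obj.get("EPE")),
        svi=_decode_scalar(obj.get("SVI")),
        perineural_invasion=_decode_scalar(obj.get("Perineural Invasion")),
        histologic_subtype=_decode_scalar(obj.get("Histologic Subtype")),
        resection_margins=_decode_scalar(obj.get("Resection Margins")),
        nodes_examined=_decode_scalar(obj.get("Number of Lymph Nodes examined"), int),
        nodes_with_metastasis=_decode_scalar(
            obj.get("Lymph Nodes with Metastasis"), int
        ),
        allow_incoherent_counts=True,
    )
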