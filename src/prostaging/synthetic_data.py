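"""Seeded synthetic corpus: coherent records, report rendering, corruption.

The generator draws T/N/M, grade group and PSA from configurable marginal
distributions (defaults approximate a real radical-prostatectomy cohort) and
then enforces cross-field coherence: EPE present iff T >= T3a, SVI present
iff T = T3b (T4 configurable), positive node counts iff N1, reported grade
group equal to the pattern-derived group, and secondary percentage equal to
the complement of the primary's.  Coherent-mode corpora therefore pass the
consistency validator with zero errors, which is what makes targeted
corruption (:func:`inject_inconsistency`) detectable.

Rendering emits three dialects (narrative prose, synoptic key-value lines,
and a tabulated grade grid marked with an "X"), plus a noise mode that
rewords EPE implicitly (capsular-defect phrasing) and blurs perineural
invasion — failure modes a pattern-based extractor cannot recover from.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field, replace
from typing import Any, Iterable, Mapping, Optional, Sequence

import numpy as np

from .consistency_validator import ERROR_CODES, GLEASON_CODE_RE
from .record_model import (
    DASH,
    MissingKind,
    MissingValue,
    NOT_MENTIONED,
    GleasonInfo,
    PathologyRecord,
    TnmCode,
    grade_group_from_patterns,
    is_missing,
    record_from_dict,
    record_to_dict,
)

__all__ = [
    "GeneratorConfig",
    "CorruptionSpec",
    "InjectionError",
    "DIALECTS",
    "sample_record",
    "render_report",
    "generate_corpus",
    "CorpusBundle",
    "inject_inconsistency",
    "corrupt_corpus",
    "merge_patient_reports",
    "write_corpus_jsonl",
    "read_corpus_jsonl",
]

DIALECTS = ("narrative", "synoptic", "tabulated")


def _default_marginals() -> dict[str, dict[Any, float]]:
    # Concrete-value marginals; missingness is applied separately.
    return {
        "T-Stage": {"T2a": 2, "T2b": 3, "T2c": 72, "T3a": 47, "T3b": 22, "T4": 0},
        "N-Stage": {"N0": 112, "N1": 14},
        "M-Stage": {"M0": 1.0, "M1": 0.0},
        "WHO Grade Group": {1: 2, 2: 70, 3: 48, 4: 4, 5: 20},
        "Perineural Invasion": {"Present": 139, "Absent": 12},
        "Histologic Subtype": {
            "Acinar adenocarcinoma": 0.88,
            "Ductal adenocarcinoma": 0.07,
            "Mucinous adenocarcinoma": 0.05,
        },
        "Resection Margins": {"Negative": 0.72, "Positive": 0.28},
    }


def _default_missing_rates() -> dict[str, float]:
    # Approximate observed per-parameter missingness in report corpora.
    return {
        "T-Stage": 6 / 152,
        "N-Stage": 26 / 152,
        "M-Stage": 149 / 152,
        "WHO Grade Group": 8 / 152,
        "EPE": 2 / 152,
        "Perineural Invasion": 1 / 152,
        "PSA": 0.0,
        "Gleason Patterns": 8 / 152,
        "Tertiary Gleason Pattern": 0.0,
        "Nodes": 0.0,
    }


@dataclass(frozen=True)
class GeneratorConfig:
    """Fully seeded configuration for corpus generation."""

    n_patients: int = 150
    reports_per_patient: int = 1
    marginals: Mapping[str, Mapping[Any, float]] = field(default_factory=_default_marginals)
    missing_rates: Mapping[str, float] = field(default_factory=_default_missing_rates)
    dialect_mix: Mapping[str, float] = field(
        default_factory=lambda: {"narrative": 1 / 3, "synoptic": 1 / 3, "tabulated": 1 / 3}
    )
    noise_rate: float = 0.0
    seed: int = 0
    psa_median: float = 8.0
    psa_sigma: float = 0.8
    n_x_fraction: float = 22 / 26  # missing N drawn as pNx vs not mentioned
    m_x_fraction: float = 0.0  # missing M drawn as pMx vs not mentioned
    svi_in_t4: bool = True
    tertiary_rate: float = 0.15
    loose_coherence: bool = False

    def __post_init__(self) -> None:
        if self.n_patients < 0 or self.reports_per_patient < 1:
            raise ValueError("n_patients must be >= 0 and reports_per_patient >= 1")
        if not 0 <= self.noise_rate <= 1:
            raise ValueError("noise_rate must be in [0,1]")
        for name, dist in self.marginals.items():
            total = sum(dist.values())
            if total <= 0 or any(w < 0 for w in dist.values()):
                raise ValueError(f"invalid marginal for {name!r}")
        for name, rate in self.missing_rates.items():
            if not 0 <= rate <= 1:
                raise ValueError(f"missing rate for {name!r} out of [0,1]")
        if abs(sum(self.dialect_mix.values()) - 1) > 1e-9:
            raise ValueError("dialect_mix weights must sum to 1")
        for d in self.dialect_mix:
            if d not in DIALECTS:
                raise ValueError(f"unknown dialect {d!r}")

    def to_dict(self) -> dict:
        out = dataclasses.asdict(self)
        out["marginals"] = {k: {str(a): b for a, b in v.items()} for k, v in self.marginals.items()}
        return out


@dataclass(frozen=True)
class CorruptionSpec:
    target_code: str
    rate: float = 1.0

    def __post_init__(self) -> None:
        if not 0 <= self.rate <= 1:
            raise ValueError("rate must be in [0,1]")
        if self.target_code not in ERROR_CODES and not GLEASON_CODE_RE.match(self.target_code):
            raise ValueError(f"unknown target error code {self.target_code!r}")


class InjectionError(ValueError):
    """Raised when the target inconsistency cannot be induced on a record."""


def _draw(dist: Mapping[Any, float], rng: np.random.Generator) -> Any:
    keys = list(dist.keys())
    weights = np.asarray([dist[k] for k in keys], dtype=float)
    return keys[int(rng.choice(len(keys), p=weights / weights.sum()))]


def _tnm(category: str, code: str, prefix: str = "p") -> TnmCode:
    return TnmCode(prefix=prefix, category=category, code=code)


def sample_record(
    config: GeneratorConfig,
    rng: np.random.Generator,
    patient_id: str = "P0001",
    report_id: str = "R0001",
) -> PathologyRecord:
    """Draw one coherent record; missingness is applied after coherence."""
    marg = config.marginals
    t_code = _draw(marg["T-Stage"], rng)
    n_code = _draw(marg["N-Stage"], rng)
    m_code = _draw(marg["M-Stage"], rng)
    gg = int(_draw(marg["WHO Grade Group"], rng))

    primary, secondary = _patterns_for_group(gg, rng)
    if primary != secondary:
        pct_secondary = float(rng.integers(5, 50))
    else:
        pct_secondary = float(rng.integers(30, 50))
    tertiary: Any = NOT_MENTIONED
    if rng.random() < config.tertiary_rate:
        choices = [p for p in (3, 4, 5) if p not in (primary, secondary)] or [5]
        tertiary = int(choices[int(rng.integers(len(choices)))])

    psa = float(np.round(rng.lognormal(np.log(config.psa_median), config.psa_sigma), 1))
    psa = max(psa, 0.1)

    if config.loose_coherence:
        epe = _draw({"Present": 67, "Absent": 85}, rng)
        svi = _draw({"Present": 23, "Absent": 129}, rng)
    else:
        epe = "Present" if t_code in ("T3a", "T3b", "T4") else "Absent"
        svi = "Present" if t_code == "T3b" or (t_code == "T4" and config.svi_in_t4) else "Absent"

    if n_code == "N1":
        examined = int(rng.integers(4, 25))
        mets = int(rng.integers(1, min(6, examined + 1)))
    else:
        examined = int(rng.integers(0, 25))
        mets = 0

    pni = _draw(marg["Perineural Invasion"], rng)
    subtype = _draw(marg["Histologic Subtype"], rng)
    margins = _draw(marg["Resection Margins"], rng)

    values: dict[str, Any] = {
        "t_stage": _tnm("T", t_code),
        "n_stage": _tnm("N", n_code),
        "m_stage": _tnm("M", m_code, prefix="c"),
        "psa_ng_ml": psa,
        "epe": epe,
        "svi": svi,
        "perineural_invasion": pni,
        "histologic_subtype": subtype,
        "resection_margins": margins,
        "nodes_examined": examined,
        "nodes_with_metastasis": mets,
    }
    gleason = {
        "primary_pattern": primary,
        "secondary_pattern": secondary,
        "tertiary_pattern": tertiary,
        "pct_secondary": pct_secondary,
        "reported_grade_group": gg,
    }

    _apply_missingness(values, gleason, config, rng)

    return PathologyRecord(
        patient_id=patient_id,
        report_id=report_id,
        gleason=GleasonInfo(**gleason),
        **values,
    )


def _patterns_for_group(gg: int, rng: np.random.Generator) -> tuple[int, int]:
    if gg == 1:
        return 3, 3
    if gg == 2:
        return 3, 4
    if gg == 3:
        return 4, 3
    if gg == 4:
        return [(4, 4), (3, 5), (5, 3)][int(rng.choice(3, p=[0.8, 0.1, 0.1]))]
    return [(4, 5), (5, 4), (5, 5)][int(rng.choice(3, p=[0.5, 0.3, 0.2]))]


def _apply_missingness(
    values: dict[str, Any],
    gleason: dict[str, Any],
    config: GeneratorConfig,
    rng: np.random.Generator,
) -> None:
    rates = config.missing_rates

    if rng.random() < rates.get("T-Stage", 0.0):
        values["t_stage"] = DASH
    if rng.random() < rates.get("N-Stage", 0.0):
        if rng.random() < config.n_x_fraction:
            values["n_stage"] = MissingValue(MissingKind.X_CODE, "pNx")
            values["nodes_examined"] = 0
            values["nodes_with_metastasis"] = 0
        else:
            values["n_stage"] = NOT_MENTIONED
    if rng.random() < rates.get("M-Stage", 0.0):
        if rng.random() < config.m_x_fraction:
            values["m_stage"] = MissingValue(MissingKind.X_CODE, "pMx")
        else:
            values["m_stage"] = NOT_MENTIONED
    if rng.random() < rates.get("WHO Grade Group", 0.0):
        gleason["reported_grade_group"] = DASH if rng.random() < 3 / 8 else NOT_MENTIONED
    if rng.random() < rates.get("Gleason Patterns", 0.0):
        gleason["primary_pattern"] = NOT_MENTIONED
        gleason["secondary_pattern"] = NOT_MENTIONED
        gleason["pct_secondary"] = NOT_MENTIONED
        gleason["tertiary_pattern"] = NOT_MENTIONED  # tertiary needs a score context
    if rng.random() < rates.get("EPE", 0.0):
        values["epe"] = NOT_MENTIONED
    if rng.random() < rates.get("Perineural Invasion", 0.0):
        values["perineural_invasion"] = NOT_MENTIONED
    if rng.random() < rates.get("PSA", 0.0):
        values["psa_ng_ml"] = NOT_MENTIONED
    if rng.random() < rates.get("Nodes", 0.0):
        values["nodes_examined"] = NOT_MENTIONED
        values["nodes_with_metastasis"] = NOT_MENTIONED
    if not is_missing(gleason["tertiary_pattern"]) and rng.random() < rates.get(
        "Tertiary Gleason Pattern", 0.0
    ):
        gleason["tertiary_pattern"] = NOT_MENTIONED


# ---------------------------------------------------------------------------
# Rendering

def _fmt_pct(x: float) -> str:
    return f"{x:g}"


def render_report(
    record: PathologyRecord,
    dialect: str,
    rng: np.random.Generator,
    noise_rate: float = 0.0,
) -> str:
    """Render a record as free text in the given dialect.

    With probability ``noise_rate`` each noise operation is applied: EPE is
    rephrased implicitly as a capsular-defect finding, and the perineural
    line is blurred into an equivocal remark.
    """
    if dialect == "narrative":
        text = _render_narrative(record)
    elif dialect == "synoptic":
        text = _render_synoptic(record)
    elif dialect == "tabulated":
        text = _render_tabulated(record)
    else:
        raise ValueError(f"unknown dialect {dialect!r}")

    if noise_rate > 0:
        text = _apply_noise(text, record, rng, noise_rate)
    return text


def _literal(value: Any) -> Optional[str]:
    if isinstance(value, TnmCode):
        return value.render()
    if isinstance(value, MissingValue):
        return value.literal if value.kind is MissingKind.X_CODE else None
    return None


def _render_synoptic(record: PathologyRecord) -> str:
    g = record.gleason
    lines = ["RADICAL PROSTATECTOMY - SYNOPTIC REPORT"]

    def add(label: str, value: Any, suffix: str = "") -> None:
        if value is None:
            return
        lines.append(f"{label}: {value}{suffix}")

    add("Histologic type", None if is_missing(record.histologic_subtype) else record.histologic_subtype)
    add("Primary Gleason pattern", None if is_missing(g.primary_pattern) else g.primary_pattern)
    add("Secondary Gleason pattern", None if is_missing(g.secondary_pattern) else g.secondary_pattern)
    if not is_missing(g.pct_secondary):
        add("Percentage of secondary pattern", _fmt_pct(g.pct_secondary), "%")
    add("Tertiary Gleason pattern", None if is_missing(g.tertiary_pattern) else g.tertiary_pattern)
    add("WHO Grade Group", None if is_missing(g.reported_grade_group) else g.reported_grade_group)
    add("Extraprostatic extension", None if is_missing(record.epe) else record.epe.lower())
    add("Seminal vesicle invasion", None if is_missing(record.svi) else record.svi.lower())
    add("Perineural invasion", None if is_missing(record.perineural_invasion) else record.perineural_invasion.lower())
    add("Resection margins", None if is_missing(record.resection_margins) else record.resection_margins.lower())
    add("Number of lymph nodes examined", None if is_missing(record.nodes_examined) else record.nodes_examined)
    add("Number of lymph nodes with metastasis", None if is_missing(record.nodes_with_metastasis) else record.nodes_with_metastasis)
    add("Pathologic T-stage", _literal(record.t_stage))
    add("Pathologic N-stage", _literal(record.n_stage))
    add("M-stage", _literal(record.m_stage))
    if not is_missing(record.psa_ng_ml):
        add("Serum PSA", _fmt_pct(record.psa_ng_ml), " ng/mL")
    return "\n".join(lines) + "\n"


def _render_narrative(record: PathologyRecord) -> str:
    g = record.gleason
    sentences = ["The patient underwent radical prostatectomy."]
    if not is_missing(record.histologic_subtype):
        sentences.append(f"Histologic examination demonstrates {record.histologic_subtype.lower()}.")
    if not is_missing(g.primary_pattern) and not is_missing(g.secondary_pattern):
        total = g.primary_pattern + g.secondary_pattern
        s = f"Gleason score {g.primary_pattern} + {g.secondary_pattern} = {total}"
        if not is_missing(g.pct_secondary):
            if g.primary_pattern != g.secondary_pattern:
                pct_primary = _fmt_pct(100 - g.pct_secondary)
                s += f" ({pct_primary}% pattern {g.primary_pattern})"
            else:
                s += f", secondary pattern comprising {_fmt_pct(g.pct_secondary)}%"
        if not is_missing(g.tertiary_pattern):
            s += f", with tertiary pattern {g.tertiary_pattern}"
        if not is_missing(g.reported_grade_group):
            s += f", WHO Grade Group {g.reported_grade_group}"
        sentences.append(s + ".")
    elif not is_missing(g.reported_grade_group):
        sentences.append(f"The tumor corresponds to WHO Grade Group {g.reported_grade_group}.")
    if not is_missing(record.epe):
        sentences.append(f"Extraprostatic extension is {record.epe.lower()}.")
    if not is_missing(record.svi):
        sentences.append(f"Seminal vesicle invasion is {record.svi.lower()}.")
    if not is_missing(record.perineural_invasion):
        sentences.append(f"Perineural invasion is {record.perineural_invasion.lower()}.")
    if not is_missing(record.resection_margins):
        sentences.append(f"Resection margins are {record.resection_margins.lower()}.")
    if not is_missing(record.nodes_examined):
        s = f"{record.nodes_examined} lymph nodes were examined"
        if not is_missing(record.nodes_with_metastasis):
            s += f" and {record.nodes_with_metastasis} showed metastatic carcinoma"
        sentences.append(s + ".")
    stage_tokens = [tok for tok in (
        _literal(record.t_stage), _literal(record.n_stage), _literal(record.m_stage)
    ) if tok]
    if stage_tokens:
        sentences.append(f"Pathologic stage is {' '.join(stage_tokens)}.")
    if not is_missing(record.psa_ng_ml):
        sentences.append(f"Serum PSA was {_fmt_pct(record.psa_ng_ml)} ng/mL.")
    return " ".join(sentences) + "\n"


_GRID_ROWS = (
    (1, "<=6"), (2, "3+4=7"), (3, "4+3=7"), (4, "8"), (5, "9-10"),
)


def _render_tabulated(record: PathologyRecord) -> str:
    text = _render_synoptic(record)
    gg = record.gleason.reported_grade_group
    if is_missing(gg):
        return text
    lines = [ln for ln in text.splitlines() if not ln.startswith("WHO Grade Group:")]
    grid = ["GRADE GROUP ASSIGNMENT:", "Grade Group | Gleason Score | Assigned"]
    for group, score in _GRID_ROWS:
        mark = "X" if group == gg else ""
        grid.append(f"GG{group} | {score} | {mark}")
    return "\n".join(lines + grid) + "\n"


_EPE_IMPLICIT = (
    "A small capsular defect is noted with tumor infiltrates forming margins."
)
_PNI_IMPLICIT = "Nerve-associated tumor involvement is equivocal."

_EPE_PATTERNS = (
    "Extraprostatic extension: present", "Extraprostatic extension: absent",
    "Extraprostatic extension is present.", "Extraprostatic extension is absent.",
)
_PNI_PATTERNS = (
    "Perineural invasion: present", "Perineural invasion: absent",
    "Perineural invasion is present.", "Perineural invasion is absent.",
)


def _apply_noise(
    text: str, record: PathologyRecord, rng: np.random.Generator, noise_rate: float
) -> str:
    if rng.random() < noise_rate:
        for pat in _EPE_PATTERNS:
            if pat in text:
                text = text.replace(pat, _EPE_IMPLICIT)
                break
    if rng.random() < noise_rate:
        for pat in _PNI_PATTERNS:
            if pat in text:
                text = text.replace(pat, _PNI_IMPLICIT)
                break
    return text


# ---------------------------------------------------------------------------
# Corpus generation

@dataclass(frozen=True)
class CorpusBundle:
    """Ground-truth records with parallel rendered texts and a manifest."""

    records: tuple[PathologyRecord, ...]
    texts: tuple[str, ...]
    dialects: tuple[str, ...]
    manifest: dict


def merge_patient_reports(reports: Sequence[PathologyRecord]) -> PathologyRecord:
    """Merge a patient's reports, oldest first: the most recent report is the
    reference and earlier reports only fill fields it is missing."""
    if not reports:
        raise ValueError("no reports to merge")
    final = reports[-1]
    merged = record_to_dict(final)
    for earlier in reversed(reports[:-1]):
        earlier_dict = record_to_dict(earlier)
        for key, value in earlier_dict.items():
            current = merged.get(key)
            if isinstance(current, Mapping) and current.get("missing") in (
                "not_mentioned", "dash",
            ):
                merged[key] = value
    merged["patient_id"] = final.patient_id
    merged["report_id"] = final.report_id
    return record_from_dict(merged)


def generate_corpus(config: GeneratorConfig) -> CorpusBundle:
    """Seed-deterministic corpus of records, rendered texts and a manifest.

    With ``reports_per_patient > 1`` only the most recent report per patient
    enters the corpus (earlier ones exist to exercise the merge rule, which
    is applied before the record is emitted).
    """
    rng = np.random.default_rng(config.seed)
    records: list[PathologyRecord] = []
    texts: list[str] = []
    dialects: list[str] = []
    dialect_names = list(config.dialect_mix.keys())
    dialect_weights = np.asarray(list(config.dialect_mix.values()), dtype=float)
    dialect_weights = dialect_weights / dialect_weights.sum()

    for i in range(config.n_patients):
        patient_id = f"P{i + 1:04d}"
        reports = []
        for j in range(config.reports_per_patient):
            report_id = f"{patient_id}-R{j + 1}"
            reports.append(sample_record(config, rng, patient_id, report_id))
        record = merge_patient_reports(reports) if len(reports) > 1 else reports[0]
        dialect = dialect_names[int(rng.choice(len(dialect_names), p=dialect_weights))]
        text = render_report(record, dialect, rng, config.noise_rate)
        records.append(record)
        texts.append(text)
        dialects.append(dialect)

    manifest = {"generator": "prostaging.synthetic_data", "config": config.to_dict()}
    return CorpusBundle(tuple(records), tuple(texts), tuple(dialects), manifest)


# ---------------------------------------------------------------------------
# Inconsistency injection

def inject_inconsistency(
    record: PathologyRecord,
    spec: CorruptionSpec,
    rng: np.random.Generator,
) -> PathologyRecord:
    """Minimally edit a coherent record so exactly the target code fires.

    Raises :class:`InjectionError` when the record cannot host the target
    (callers resample).  The injected code is recorded by the caller.
    """
    code = spec.target_code
    t = record.t_stage.code if isinstance(record.t_stage, TnmCode) else None
    n = record.n_stage.code if isinstance(record.n_stage, TnmCode) else None

    if code == "T2_stage_with_EPE_should_be_T3a":
        # needs EPE present without SVI so only rule 1 fires after the edit
        if record.epe != "Present" or record.svi == "Present":
            raise InjectionError(code)
        return replace(record, t_stage=_tnm("T", "T2c"))

    if code == "SVI_present_should_be_T3b_or_higher":
        if t != "T3a" or record.epe != "Present":
            raise InjectionError(code)
        return replace(record, svi="Present")

    if code == "N0_stage_but_positive_lymph_nodes":
        if n != "N0":
            raise InjectionError(code)
        examined = record.nodes_examined
        if is_missing(examined) or examined < 1:
            examined = 5
        return replace(record, nodes_examined=examined, nodes_with_metastasis=1)

    if code == "N1_stage_but_no_positive_lymph_nodes":
        if n != "N1":
            raise InjectionError(code)
        return replace(record, nodes_with_metastasis=0)

    if code == "T3a_stage_but_no_EPE":
        if t != "T3a":
            raise InjectionError(code)
        return replace(record, epe="Absent")

    if code == "T3b_stage_but_no_SVI":
        if t != "T3b":
            raise InjectionError(code)
        return replace(record, svi="Absent")

    m = GLEASON_CODE_RE.match(code)
    if m:
        total, target_gg = int(m.group(1)), int(m.group(2))
        g = record.gleason
        if is_missing(g.primary_pattern) or is_missing(g.secondary_pattern):
            raise InjectionError(code)
        if g.primary_pattern + g.secondary_pattern != total:
            raise InjectionError(code)
        if grade_group_from_patterns(g.primary_pattern, g.secondary_pattern) == target_gg:
            raise InjectionError(code)
        return replace(record, gleason=replace(g, reported_grade_group=target_gg))

    raise ValueError(f"unknown target error code {code!r}")


def corrupt_corpus(
    records: Sequence[PathologyRecord],
    spec: CorruptionSpec,
    rng: np.random.Generator,
) -> tuple[list[PathologyRecord], list[tuple[int, str]]]:
    """Corrupt a fraction ``spec.rate`` of eligible records toward one code.

    Returns the new corpus and (index, injected code) annotations.  Records
    the target cannot apply to are left unchanged.
    """
    out = list(records)
    annotations: list[tuple[int, str]] = []
    for i, record in enumerate(records):
        if spec.rate < 1.0 and rng.random() >= spec.rate:
            continue
        try:
            out[i] = inject_inconsistency(record, spec, rng)
        except InjectionError:
            continue
        annotations.append((i, spec.target_code))
    return out, annotations


# ---------------------------------------------------------------------------
# Corpus I/O (JSONL: ground truth + text + dialect per line)

def write_corpus_jsonl(bundle: CorpusBundle, records_path, manifest_path=None) -> None:
    with open(records_path, "w", encoding="utf-8") as fh:
        for record, text, dialect in zip(bundle.records, bundle.texts, bundle.dialects):
            obj = record_to_dict(record)
            obj["text"] = text
            obj["dialect"] = dialect
            fh.write(json.dumps(obj, sort_keys=True) + "\n")
    if manifest_path is not None:
        with open(manifest_path, "w", encoding="utf-8") as fh:
            json.dump(bundle.manifest, fh, indent=2, sort_keys=True)
            fh.write("\n")


def read_corpus_jsonl(records_path) -> CorpusBundle:
    records, texts, dialects = [], [], []
    with open(records_path, encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            obj = json.loads(line)
            records.append(record_from_dict(obj))
            texts.append(obj.get("text", ""))
            dialects.append(obj.get("dialect", ""))
    return CorpusBundle(tuple(records), tuple(texts), tuple(dialects), {})
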