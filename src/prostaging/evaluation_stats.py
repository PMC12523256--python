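"""Extraction and staging evaluation metrics plus inferential statistics.

Field metrics follow the field-document-pair convention: accuracy counts a
both-missing agreement as correct, while precision's denominator is the
non-missing predictions and recall's the non-missing truths (x-codes such
as ``pNx`` count as concrete values).  Staging metrics collapse every
``Unknown (Missing ...)`` label to a unified ``Unknown`` class and use
one-vs-rest counts with unweighted macro averaging.

Inferential pieces: Wilson score intervals for proportions, Fisher's exact
test generalized to r x 2 tables by exact enumeration (seeded Monte Carlo
beyond a state-space bound), and Pearson's chi-squared test.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .record_model import (
    MissingKind,
    MissingValue,
    PARAMETER_NAMES,
    PathologyRecord,
    parameter_value,
    values_match,
)
from .staging_engine import STAGES, UNKNOWN, StagingResult

__all__ = [
    "FieldEvalRow",
    "ClassEvalRow",
    "ProportionCI",
    "FisherResult",
    "ChiSquaredResult",
    "round_half_up",
    "f1_score",
    "evaluate_fields",
    "micro_accuracy_from_counts",
    "evaluate_staging",
    "staging_rows_from_counts",
    "wilson_ci",
    "fisher_exact",
    "chi_squared",
    "write_results_workbook",
]


def round_half_up(x: float, ndigits: int = 3) -> float:
    """Decimal half-up rounding (the display convention for printed tables)."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def f1_score(precision: float, recall: float) -> float:
    """Harmonic mean; defined as 0 when precision + recall == 0."""
    if precision + recall == 0:
        return 0.0
    return 2 * precision * recall / (precision + recall)


# ---------------------------------------------------------------------------
# Field-extraction metrics

@dataclass(frozen=True)
class FieldEvalRow:
    parameter: str
    n_docs: int
    correct: int
    accuracy: float
    precision: float
    recall: float
    f1: float


def _metric_missing(value) -> bool:
    """Missing for metric purposes: x-codes count as extracted values."""
    return isinstance(value, MissingValue) and value.kind is not MissingKind.X_CODE


def evaluate_fields(
    predictions: Sequence[PathologyRecord],
    truths: Sequence[PathologyRecord],
) -> list[FieldEvalRow]:
    """Per-parameter rows plus a pooled ``Overall (micro)`` row.

    Records are aligned by report_id; mismatched report sets are an error.
    """
    pred_by_id = {r.report_id: r for r in predictions}
    truth_by_id = {r.report_id: r for r in truths}
    if set(pred_by_id) != set(truth_by_id):
        raise ValueError("prediction and truth report_id sets differ")
    ids = sorted(truth_by_id)
    n = len(ids)

    rows: list[FieldEvalRow] = []
    pooled = np.zeros(4, dtype=int)  # matches, correct_extracted, n_pred, n_truth
    for name in PARAMETER_NAMES:
        matches = correct_extracted = n_pred = n_truth = 0
        for rid in ids:
            tv = parameter_value(truth_by_id[rid], name)
            pv = parameter_value(pred_by_id[rid], name)
            t_missing, p_missing = _metric_missing(tv), _metric_missing(pv)
            match = values_match(name, pv, tv)
            if match:
                matches += 1
            if not p_missing:
                n_pred += 1
                if match and not t_missing:
                    correct_extracted += 1
            if not t_missing:
                n_truth += 1
        precision = correct_extracted / n_pred if n_pred else 0.0
        recall = correct_extracted / n_truth if n_truth else 0.0
        rows.append(FieldEvalRow(
            parameter=name,
            n_docs=n,
            correct=matches,
            accuracy=matches / n if n else 0.0,
            precision=precision,
            recall=recall,
            f1=f1_score(precision, recall),
        ))
        pooled += (matches, correct_extracted, n_pred, n_truth)

    total_pairs = len(PARAMETER_NAMES) * n
    micro_p = pooled[1] / pooled[2] if pooled[2] else 0.0
    micro_r = pooled[1] / pooled[3] if pooled[3] else 0.0
    rows.append(FieldEvalRow(
        parameter="Overall (micro)",
        n_docs=n,
        correct=int(pooled[0]),
        accuracy=pooled[0] / total_pairs if total_pairs else 0.0,
        precision=micro_p,
        recall=micro_r,
        f1=f1_score(micro_p, micro_r),
    ))
    return rows


def micro_accuracy_from_counts(correct_counts: Sequence[int], n_docs: int) -> float:
    """Pooled accuracy from per-parameter correct counts over ``n_docs`` docs."""
    if len(correct_counts) != len(PARAMETER_NAMES):
        raise ValueError(f"expected {len(PARAMETER_NAMES)} counts")
    return sum(correct_counts) / (len(PARAMETER_NAMES) * n_docs)


# ---------------------------------------------------------------------------
# Staging classification metrics

@dataclass(frozen=True)
class ClassEvalRow:
    class_label: str
    tp: int
    fp: int
    fn: int
    precision: float
    recall: float
    f1: float


def _collapse(result: StagingResult | str) -> str:
    if isinstance(result, StagingResult):
        return UNKNOWN if result.stage == UNKNOWN else result.stage
    return UNKNOWN if str(result).startswith(UNKNOWN) else str(result)


def _class_order(label: str) -> tuple[int, str]:
    try:
        return (STAGES.index(label), label)
    except ValueError:
        return (len(STAGES), label)  # Unknown (and anything else) last


def staging_rows_from_counts(
    counts: Sequence[tuple[str, int, int, int]]
) -> list[ClassEvalRow]:
    """Per-class rows plus an ``Overall (macro)`` row from (label, TP, FP, FN).

    Macro averages are unweighted means of the unrounded per-class values.
    """
    rows: list[ClassEvalRow] = []
    for label, tp, fp, fn in counts:
        precision = tp / (tp + fp) if tp + fp else 0.0
        recall = tp / (tp + fn) if tp + fn else 0.0
        rows.append(ClassEvalRow(label, tp, fp, fn, precision, recall,
                                 f1_score(precision, recall)))
    if rows:
        macro_p = sum(r.precision for r in rows) / len(rows)
        macro_r = sum(r.recall for r in rows) / len(rows)
        macro_f = sum(r.f1 for r in rows) / len(rows)
        rows.append(ClassEvalRow("Overall (macro)", -1, -1, -1, macro_p, macro_r, macro_f))
    return rows


def evaluate_staging(
    predicted: Sequence[StagingResult],
    truth: Sequence[StagingResult],
) -> list[ClassEvalRow]:
    """One-vs-rest rows over classes present in truth or prediction.

    Unknown labels collapse to a single ``Unknown`` class on both sides;
    classes are ordered by stage order with Unknown last.
    """
    pred_by_id = {r.report_id: r for r in predicted}
    truth_by_id = {r.report_id: r for r in truth}
    if set(pred_by_id) != set(truth_by_id):
        raise ValueError("prediction and truth report_id sets differ")
    pairs = [
        (_collapse(pred_by_id[rid]), _collapse(truth_by_id[rid]))
        for rid in sorted(truth_by_id)
    ]
    classes = sorted({p for p, _ in pairs} | {t for _, t in pairs}, key=_class_order)
    counts = []
    for cls in classes:
        tp = sum(1 for p, t in pairs if p == cls and t == cls)
        fp = sum(1 for p, t in pairs if p == cls and t != cls)
        fn = sum(1 for p, t in pairs if p != cls and t == cls)
        counts.append((cls, tp, fp, fn))
    return staging_rows_from_counts(counts)


# ---------------------------------------------------------------------------
# Proportion confidence intervals

@dataclass(frozen=True)
class ProportionCI:
    x: int
    n: int
    level: float
    lower: float
    upper: float


def wilson_ci(x: int, n: int, level: float = 0.95) -> ProportionCI:
    """Wilson score interval for a binomial proportion."""
    if n <= 0:
        raise ValueError("n must be positive")
    if not 0 <= x <= n:
        raise ValueError("x must satisfy 0 <= x <= n")
    z = float(sps.norm.ppf((1 + level) / 2))
    phat = x / n
    denom = 1 + z * z / n
    center = (phat + z * z / (2 * n)) / denom
    half = z * math.sqrt(phat * (1 - phat) / n + z * z / (4 * n * n)) / denom
    lower = 0.0 if x == 0 else max(0.0, center - half)
    upper = 1.0 if x == n else min(1.0, center + half)
    return ProportionCI(x=x, n=n, level=level, lower=lower, upper=upper)


# ---------------------------------------------------------------------------
# Fisher's exact test (r x 2) and Pearson chi-squared

@dataclass(frozen=True)
class FisherResult:
    p_value: float
    method: str  # "exact" or "monte-carlo"
    mc_se: Optional[float] = None


_EXACT_STATE_LIMIT = 10**6
_MC_REPLICATES = 10**5
_P_TOL = 1e-9


def fisher_exact(
    table: Sequence[Sequence[int]], *, seed: int = 0
) -> FisherResult:
    """Two-sided Fisher's exact test for an r x 2 contingency table.

    p is the total null probability of tables (with the observed margins)
    whose probability does not exceed the observed table's.  Exact
    enumeration when the state space is below 10^6 tables, otherwise seeded
    Monte Carlo with 10^5 replicates and a reported standard error.
    """
    t = np.asarray(table, dtype=np.int64)
    if t.ndim != 2 or t.shape[1] != 2 or t.shape[0] < 2:
        raise ValueError("table must be r x 2 with r >= 2")
    if (t < 0).any():
        raise ValueError("counts must be non-negative")
    row_sums = t.sum(axis=1)
    col_sums = t.sum(axis=0)
    if (row_sums == 0).any() or (col_sums == 0).any():
        raise ValueError("empty margin")

    log_fact = _log_factorials(int(t.sum()))

    # log P(table) = sum_i log C(r_i, a_i) - log C(N, c1)
    def table_log_prob(first_col) -> float:
        lp = log_fact[col_sums[0]] + log_fact[col_sums[1]] - log_fact[t.sum()]
        for r_i, a_i in zip(row_sums, first_col):
            lp += log_fact[r_i] - log_fact[a_i] - log_fact[r_i - a_i]
        return float(lp)

    observed_lp = table_log_prob(t[:, 0])
    state_space = int(np.prod(row_sums + 1, dtype=np.float64).clip(max=2 * _EXACT_STATE_LIMIT))

    if state_space < _EXACT_STATE_LIMIT:
        total = 0.0
        threshold = observed_lp + _P_TOL
        for col in _enumerate_first_columns(row_sums.tolist(), int(col_sums[0])):
            lp = table_log_prob(col)
            if lp <= threshold:
                total += math.exp(lp)
        return FisherResult(p_value=min(total, 1.0), method="exact")

    rng = np.random.default_rng(seed)
    draws = rng.multivariate_hypergeometric(
        row_sums.tolist(), int(col_sums[0]), size=_MC_REPLICATES
    )
    threshold = observed_lp + _P_TOL
    hits = sum(1 for col in draws if table_log_prob(col) <= threshold)
    p_hat = hits / _MC_REPLICATES
    se = math.sqrt(p_hat * (1 - p_hat) / _MC_REPLICATES)
    return FisherResult(p_value=p_hat, method="monte-carlo", mc_se=se)


def _log_factorials(n: int) -> np.ndarray:
    return np.concatenate(([0.0], np.cumsum(np.log(np.arange(1, n + 1)))))


def _enumerate_first_columns(row_sums: list[int], c1: int):
    """Yield all first-column vectors consistent with the fixed margins."""
    r = len(row_sums)

    def rec(i: int, remaining: int, prefix: list[int]):
        if i == r - 1:
            if 0 <= remaining <= row_sums[i]:
                yield prefix + [remaining]
            return
        tail_capacity = sum(row_sums[i + 1:])
        lo = max(0, remaining - tail_capacity)
        hi = min(row_sums[i], remaining)
        for a in range(lo, hi + 1):
            yield from rec(i + 1, remaining - a, prefix + [a])

    yield from rec(0, c1, [])


@dataclass(frozen=True)
class ChiSquaredResult:
    statistic: float
    p_value: float
    dof: int


def chi_squared(table: Sequence[Sequence[int]]) -> ChiSquaredResult:
    """Pearson's chi-squared test of independence, no continuity correction."""
    t = np.asarray(table, dtype=float)
    if t.ndim != 2 or min(t.shape) < 2:
        raise ValueError("table must be at least 2 x 2")
    if (t < 0).any():
        raise ValueError("counts must be non-negative")
    if (t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any():
        raise ValueError("zero-margin row or column")
    stat, p, dof, _ = sps.chi2_contingency(t, correction=False)
    return ChiSquaredResult(statistic=float(stat), p_value=float(p), dof=int(dof))


# ---------------------------------------------------------------------------
# Workbook export

def field_rows_to_frame(rows: Iterable[FieldEvalRow]) -> pd.DataFrame:
    return pd.DataFrame([
        {
            "Parameter": r.parameter,
            "Correct": r.correct,
            "Accuracy": round_half_up(r.accuracy),
            "Precision": round_half_up(r.precision),
            "Recall": round_half_up(r.recall),
            "F1-Score": round_half_up(r.f1),
        }
        for r in rows
    ])


def class_rows_to_frame(rows: Iterable[ClassEvalRow]) -> pd.DataFrame:
    return pd.DataFrame([
        {
            "AJCC Stage": r.class_label,
            "TP": r.tp if r.tp >= 0 else "-",
            "FP": r.fp if r.fp >= 0 else "-",
            "FN": r.fn if r.fn >= 0 else "-",
            "Precision": round_half_up(r.precision),
            "Recall": round_half_up(r.recall),
            "F1-Score": round_half_up(r.f1),
        }
        for r in rows
    ])


def write_results_workbook(
    path,
    field_rows: Sequence[FieldEvalRow] | None = None,
    staging_rows: Sequence[ClassEvalRow] | None = None,
    classification: pd.DataFrame | None = None,
    consistency_errors: pd.DataFrame | None = None,
    error_summary: pd.DataFrame | None = None,
    csv_dir=None,
) -> None:
    """Write the results workbook (and optional CSV mirrors of each sheet)."""
    sheets: dict[str, pd.DataFrame] = {}
    if field_rows is not None:
        sheets["field_metrics"] = field_rows_to_frame(field_rows)
    if staging_rows is not None:
        sheets["staging_metrics"] = class_rows_to_frame(staging_rows)
    if classification is not None:
        sheets["classification"] = classification
    if consistency_errors is not None:
        sheets["consistency_errors"] = consistency_errors
    if error_summary is not None:
        sheets["error_summary"] = error_summary
    if not sheets:
        raise ValueError("nothing to write")
    with pd.ExcelWriter(path, engine="openpyxl") as writer:
        for name, frame in sheets.items():
            frame.to_excel(writer, sheet_name=name, index=False)
    if csv_dir is not None:
        import os

        os.makedirs(csv_dir, exist_ok=True)
        for name, frame in sheets.items():
            frame.to_csv(os.path.join(csv_dir, f"{name}.csv"), index=False)
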