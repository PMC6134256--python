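"""Confusion matrices and the 10-metric benchmarking panel.

Predictions are benchmarked against binary in vitro labels (splice-altering
vs not) with a panel of sensitivity, specificity, accuracy, MCC, PPV, NPV,
FNR, FPR, FDR and FOR, stratified by site kind (donor / acceptor / global)
and by whether variants at the invariant GT/AG dinucleotides are included.
Records a tool or rule could not evaluate are excluded from its own counts
and tallied separately — each panel covers the subset the predictor actually
scored.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import pandas as pd

from .delta import NEGATIVE, NOT_EVALUABLE, POSITIVE
from .ensemble import EnsemblePrediction

__all__ = [
    "BenchmarkRecord",
    "ConfusionMatrix",
    "MetricPanel",
    "EvaluationError",
    "build_confusion",
    "metric_panel",
    "confusion_from_rates",
    "stratified_report",
    "position_histogram",
]


class EvaluationError(ValueError):
    pass


@dataclass(frozen=True)
class BenchmarkRecord:
    """One labeled benchmark variant at one splice site."""

    variant_id: str
    site_kind: str  # "donor" | "acceptor"
    offset: int  # signed relative position (no 0)
    label: bool  # True = splice-altering in vitro
    invariant_core: bool = False  # at the intronic +/-1,+/-2 GT/AG core


@dataclass(frozen=True)
class ConfusionMatrix:
    tp: int = 0
    fp: int = 0
    tn: int = 0
    fn: int = 0
    n_not_evaluable: int = 0

    def __post_init__(self):
        if min(self.tp, self.fp, self.tn, self.fn, self.n_not_evaluable) < 0:
            raise EvaluationError("confusion counts must be non-negative")

    @property
    def n_evaluated(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    def __add__(self, other: "ConfusionMatrix") -> "ConfusionMatrix":
        return ConfusionMatrix(
            self.tp + other.tp,
            self.fp + other.fp,
            self.tn + other.tn,
            self.fn + other.fn,
            self.n_not_evaluable + other.n_not_evaluable,
        )


_CALL_ALIASES = {True: POSITIVE, False: NEGATIVE, POSITIVE: POSITIVE, NEGATIVE: NEGATIVE, NOT_EVALUABLE: NOT_EVALUABLE}


def _call_of(prediction) -> str:
    if isinstance(prediction, EnsemblePrediction):
        return prediction.call
    try:
        return _CALL_ALIASES[prediction]
    except (KeyError, TypeError):
        raise EvaluationError(f"uninterpretable prediction {prediction!r}") from None


def build_confusion(
    records: Sequence[BenchmarkRecord],
    predictions: Mapping[str, object],
    missing_policy: str = "exclude",
) -> ConfusionMatrix:
    """Tally predictions against labels.

    ``predictions`` maps variant_id to an :class:`EnsemblePrediction`, a call
    string, or a bool. Not-evaluable predictions are excluded from the counts
    (the only supported policy) and reported in ``n_not_evaluable``; a record
    with no prediction entry at all is an error.
    """
    if missing_policy != "exclude":
        raise EvaluationError(f"unsupported missing_policy {missing_policy!r}")
    tp = fp = tn = fn = skipped = 0
    for rec in records:
        if rec.variant_id not in predictions:
            raise EvaluationError(f"no prediction for record {rec.variant_id!r}")
        call = _call_of(predictions[rec.variant_id])
        if call == NOT_EVALUABLE:
            skipped += 1
        elif call == POSITIVE:
            tp, fp = (tp + 1, fp) if rec.label else (tp, fp + 1)
        else:
            fn, tn = (fn + 1, tn) if rec.label else (fn, tn + 1)
    return ConfusionMatrix(tp, fp, tn, fn, skipped)


def confusion_from_rates(
    n_positive: int, n_negative: int, sensitivity: float, specificity: float
) -> ConfusionMatrix:
    """Reconstruct integer confusion counts from class sizes and printed
    sensitivity/specificity percentages (rounded to the nearest count)."""
    tp = round(sensitivity / 100.0 * n_positive)
    tn = round(specificity / 100.0 * n_negative)
    return ConfusionMatrix(tp=tp, fp=n_negative - tn, tn=tn, fn=n_positive - tp)


@dataclass(frozen=True)
class MetricPanel:
    """The 10 derived performance statistics (percentages except MCC).

    Metrics with a zero denominator are ``None`` (absent), never 0: a silent
    zero would corrupt comparisons.
    """

    sensitivity: float | None
    specificity: float | None
    accuracy: float | None
    mcc: float | None
    ppv: float | None
    npv: float | None
    fnr: float | None
    fpr: float | None
    fdr: float | None
    for_: float | None

    _ORDER = ("sensitivity", "specificity", "accuracy", "mcc", "ppv", "npv", "fnr", "fpr", "fdr", "for_")

    def as_dict(self, ndigits: int | None = None) -> dict[str, float | None]:
        out = {}
        for name in self._ORDER:
            value = getattr(self, name)
            if value is not None and ndigits is not None:
                value = round(value, ndigits)  # banker's rounding, matching table output
            out[name] = value
        return out

    def rounded(self) -> dict[str, float | None]:
        """Table-style formatting: 3 decimals, half-even."""
        return self.as_dict(ndigits=3)


def _ratio(num: int, den: int) -> float | None:
    return 100.0 * num / den if den else None


def metric_panel(c: ConfusionMatrix) -> MetricPanel:
    """Compute the full panel from one confusion matrix.

    MCC = (tp*tn - fp*fn) / sqrt((tp+fp)(tp+fn)(tn+fp)(tn+fn)), on [-1, 1].
    """
    if c.n_evaluated == 0:
        raise EvaluationError("empty confusion matrix")
    tp, fp, tn, fn = c.tp, c.fp, c.tn, c.fn
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    mcc = (tp * tn - fp * fn) / math.sqrt(denom) if denom else None
    sens = _ratio(tp, tp + fn)
    spec = _ratio(tn, tn + fp)
    ppv = _ratio(tp, tp + fp)
    npv = _ratio(tn, tn + fn)
    return MetricPanel(
        sensitivity=sens,
        specificity=spec,
        accuracy=_ratio(tp + tn, c.n_evaluated),
        mcc=mcc,
        ppv=ppv,
        npv=npv,
        fnr=None if sens is None else 100.0 - sens,
        fpr=None if spec is None else 100.0 - spec,
        fdr=None if ppv is None else 100.0 - ppv,
        for_=None if npv is None else 100.0 - npv,
    )


def stratified_report(
    records: Sequence[BenchmarkRecord],
    predictions_by_rule: Mapping[str, Mapping[str, object]],
) -> pd.DataFrame:
    """One metric panel per (rule, stratum).

    Strata are {donor, acceptor, global} crossed with {all, excluding the
    invariant +/-1/+/-2 dinucleotide variants}. Empty strata yield a row with
    the counts only and absent metrics. Row order is deterministic.
    """
    site_strata = (("donor", lambda r: r.site_kind == "donor"),
                   ("acceptor", lambda r: r.site_kind == "acceptor"),
                   ("global", lambda r: True))
    core_strata = (("all", lambda r: True),
                   ("excl_invariant_core", lambda r: not r.invariant_core))
    rows = []
    for rule in sorted(predictions_by_rule):
        predictions = predictions_by_rule[rule]
        for site_name, site_f in site_strata:
            for core_name, core_f in core_strata:
                subset = [r for r in records if site_f(r) and core_f(r)]
                row: dict[str, object] = {
                    "rule": rule,
                    "site_stratum": site_name,
                    "core_stratum": core_name,
                    "n_records": len(subset),
                }
                if subset:
                    c = build_confusion(subset, predictions)
                    row.update(tp=c.tp, fp=c.fp, tn=c.tn, fn=c.fn, n_not_evaluable=c.n_not_evaluable)
                    if c.n_evaluated:
                        row.update(metric_panel(c).rounded())
                rows.append(row)
    return pd.DataFrame(rows)


def position_histogram(records: Sequence[BenchmarkRecord]) -> pd.DataFrame:
    """Counts of splice-altering / non-altering labels per relative offset.

    Indexed by (site_kind, offset) with ``n_positive`` / ``n_negative``
    columns; empty input yields an empty frame.
    """
    counts: dict[tuple[str, int], list[int]] = {}
    for rec in records:
        cell = counts.setdefault((rec.site_kind, rec.offset), [0, 0])
        cell[0 if rec.label else 1] += 1
    rows = [
        {"site_kind": k, "offset": o, "n_positive": c[0], "n_negative": c[1]}
        for (k, o), c in sorted(counts.items())
    ]
    return pd.DataFrame(rows, columns=["site_kind", "offset", "n_positive", "n_negative"])
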