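"""Combination rules over per-tool calls, including the sequential protocol.

Two combined tools predict disruption when at least one of them fires; with
three to six tools, all but one must fire. The sequential protocol runs the
maximum-entropy scorer first (-15% cut-off) and consults SSF-like (-5%) as a
second line; under the default confirmatory policy both must fire, which
trades sensitivity for specificity relative to SSF-like alone.

Tools that are not re-implemented here (NNSplice, SPANR, dbscSNV) are
supported through an external-score table, subject to each tool's published
applicability limits (dbscSNV only covers -3..+8 at donors and -12..+2 at
acceptors; neither dbscSNV nor SPANR scores insertions or deletions).
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from typing import Mapping, Sequence

from .delta import (
    NEGATIVE,
    NOT_EVALUABLE,
    POSITIVE,
    DeltaResult,
    ToolScore,
)
from .genome import RegionPosition
from .variants import Variant

__all__ = [
    "CombinationRule",
    "EnsemblePrediction",
    "RuleConfigError",
    "combine",
    "sequential_mes_ssf",
    "load_external_scores",
    "applicability_filter",
    "recommended_rules",
]

_MODES = ("single", "any_of_two", "all_but_one", "sequential")


class RuleConfigError(ValueError):
    """Raised for malformed combination rules or missing tool results."""


@dataclass(frozen=True)
class CombinationRule:
    name: str
    tools: tuple[str, ...]
    mode: str

    def __post_init__(self):
        object.__setattr__(self, "tools", tuple(self.tools))
        if self.mode not in _MODES:
            raise RuleConfigError(f"{self.name}: unknown mode {self.mode!r}")
        n = len(self.tools)
        if self.mode == "single" and n != 1:
            raise RuleConfigError(f"{self.name}: single rule needs exactly one tool")
        if self.mode == "any_of_two" and n != 2:
            raise RuleConfigError(f"{self.name}: any_of_two needs exactly two tools")
        if self.mode == "all_but_one" and n < 3:
            raise RuleConfigError(f"{self.name}: all_but_one needs at least three tools")
        if self.mode == "sequential" and n != 2:
            raise RuleConfigError(f"{self.name}: sequential needs an ordered pair of tools")

    @property
    def min_evaluable(self) -> int:
        return 2 if self.mode == "all_but_one" else 1


@dataclass(frozen=True)
class EnsemblePrediction:
    rule: str
    call: str  # POSITIVE | NEGATIVE | NOT_EVALUABLE
    evidence: tuple[DeltaResult, ...] = ()
    n_evaluable: int = 0
    note: str = ""


def combine(results: Sequence[DeltaResult], rule: CombinationRule) -> EnsemblePrediction:
    """Apply a combination rule to per-tool calls.

    Tools reported not evaluable are dropped before counting; ``all_but_one``
    recomputes "all but one" over the k tools that were actually evaluable
    (requiring at least two), mirroring how each tool's benchmark panel is
    computed over its scored subset.
    """
    by_tool = {r.tool: r for r in results}
    missing = [t for t in rule.tools if t not in by_tool]
    if missing:
        raise RuleConfigError(f"{rule.name}: no result for tool(s) {missing}")
    picked = [by_tool[t] for t in rule.tools]
    if rule.mode == "sequential":
        return sequential_mes_ssf(picked[0], picked[1], rule_name=rule.name)
    evaluable = [r for r in picked if r.evaluable]
    k = len(evaluable)
    if k < rule.min_evaluable:
        return EnsemblePrediction(rule.name, NOT_EVALUABLE, tuple(picked), k)
    n_pos = sum(r.call == POSITIVE for r in evaluable)
    if rule.mode == "single":
        call = evaluable[0].call
    elif rule.mode == "any_of_two":
        call = POSITIVE if n_pos >= 1 else NEGATIVE
    else:  # all_but_one
        call = POSITIVE if n_pos >= k - 1 else NEGATIVE
    return EnsemblePrediction(rule.name, call, tuple(picked), k)


def sequential_mes_ssf(
    mes: DeltaResult,
    ssf: DeltaResult,
    policy: str = "confirmatory",
    rule_name: str = "sequential_MES_SSF",
) -> EnsemblePrediction:
    """Ordered two-tool protocol: MES first (-15%), then SSF-like (-5%).

    ``confirmatory`` (default): SSF-like is consulted only when MES fires and
    must confirm it — positive iff both fire. ``triage``: MES positives pass
    directly and MES negatives are re-screened by SSF-like — positive iff
    either fires. A not-evaluable MES falls through to SSF-like alone, with
    an annotation.
    """
    if policy not in ("confirmatory", "triage"):
        raise RuleConfigError(f"unknown sequential policy {policy!r}")
    evidence = (mes, ssf)
    if not mes.evaluable:
        if not ssf.evaluable:
            return EnsemblePrediction(rule_name, NOT_EVALUABLE, evidence, 0)
        return EnsemblePrediction(
            rule_name, ssf.call, evidence, 1, note="MES not evaluable; SSF-like alone"
        )
    if not ssf.evaluable:
        return EnsemblePrediction(
            rule_name, mes.call, evidence, 1, note="SSF-like not evaluable; MES alone"
        )
    if policy == "confirmatory":
        call = POSITIVE if (mes.call == POSITIVE and ssf.call == POSITIVE) else NEGATIVE
    else:
        call = POSITIVE if (mes.call == POSITIVE or ssf.call == POSITIVE) else NEGATIVE
    return EnsemblePrediction(rule_name, call, evidence, 2)


def recommended_rules() -> dict[str, CombinationRule]:
    """The combinations recommended by the two-stage benchmark: HSF+SSF-like
    (optionally +MES) for donors, SSF-like alone or the MES->SSF-like
    sequential protocol for acceptors."""
    return {
        "donor_recommended": CombinationRule("donor_recommended", ("HSF", "SSF_like"), "any_of_two"),
        "donor_recommended_3": CombinationRule(
            "donor_recommended_3", ("HSF", "SSF_like", "MES"), "all_but_one"
        ),
        "acceptor_recommended": CombinationRule("acceptor_recommended", ("SSF_like",), "single"),
        "acceptor_sequential": CombinationRule(
            "acceptor_sequential", ("MES", "SSF_like"), "sequential"
        ),
    }


# ---------------------------------------------------------------------------
# external tools


#: signed-offset windows within which dbscSNV provides estimations
DBSCSNV_DONOR_WINDOW = (-3, 8)
DBSCSNV_ACCEPTOR_WINDOW = (-12, 2)
_NO_INDEL_TOOLS = frozenset({"dbscSNV", "SPANR"})


def applicability_filter(v: Variant, pos: RegionPosition, tool: str) -> bool:
    """Whether an external tool can evaluate a variant at this position.

    dbscSNV and SPANR do not analyze insertions or deletions, and dbscSNV
    only scores positions -3..+8 around donors and -12..+2 around acceptors.
    Re-implemented scorers and other tools are unrestricted here.
    """
    if tool in _NO_INDEL_TOOLS and v.is_indel:
        return False
    if tool == "dbscSNV":
        lo, hi = DBSCSNV_DONOR_WINDOW if pos.site_kind == "donor" else DBSCSNV_ACCEPTOR_WINDOW
        return lo <= pos.offset <= hi
    return True


def load_external_scores(path) -> dict[tuple[str, str, str, str], ToolScore]:
    """Load externally computed tool scores.

    TSV columns: ``variant_id, transcript_id, site_kind, tool, wt_score,
    var_score, score_change`` — WT/VAR may be blank when the tool reports
    only a score change (dbscSNV, SPANR). Keys are
    ``(variant_id, transcript_id, site_kind, tool)``; duplicates are an
    error. Variants absent from the table are simply not evaluable.
    """
    out: dict[tuple[str, str, str, str], ToolScore] = {}
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        required = {"variant_id", "transcript_id", "site_kind", "tool"}
        missing = required - set(reader.fieldnames or [])
        if missing:
            raise RuleConfigError(f"{path}: missing columns {sorted(missing)}")
        for lineno, row in enumerate(reader, 2):
            key = (row["variant_id"], row["transcript_id"], row["site_kind"], row["tool"])
            if key in out:
                raise RuleConfigError(f"{path}:{lineno}: duplicate entry for {key}")

            def num(name: str) -> float | None:
                raw = (row.get(name) or "").strip()
                if not raw:
                    return None
                try:
                    return float(raw)
                except ValueError:
                    raise RuleConfigError(
                        f"{path}:{lineno}: malformed {name} value {raw!r}"
                    ) from None

            wt, var, change = num("wt_score"), num("var_score"), num("score_change")
            if change is None and (wt is None or var is None):
                raise RuleConfigError(
                    f"{path}:{lineno}: need either wt_score+var_score or score_change"
                )
            out[key] = ToolScore(
                tool=row["tool"], wt=wt, var=var, source="external", score_change=change
            )
    return out
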