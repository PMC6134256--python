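"""% score variation, per-tool disruption calls, and de novo site scanning.

For each tool the wild-type window score (WT) and the variant window score
(VAR) are compared as

    % score variation = (VAR - WT) / WT * 100

and a variant is called a positive (predicted splicing-disruptive) when the
variation is at or below the tool's threshold: -2% for the HSF-style scorer,
-5% for SSF-like, -15% for the maximum-entropy scorer. Score *increases* at
the natural site never flag disruption; gains elsewhere (new or strengthened
cryptic sites) are a separate analysis handled by :func:`scan_de_novo`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Protocol, Sequence, runtime_checkable

from .genome import SpliceSite
from .pwm import PWMatrix, consensus_value
from .variants import SitePairWindows, Variant, build_site_windows

__all__ = [
    "ToolScore",
    "DeltaResult",
    "ThresholdConfig",
    "ThresholdConfigError",
    "Scorer",
    "PWMScorer",
    "MaxEntScorer",
    "DeNovoCandidate",
    "percent_score_variation",
    "classify_tool",
    "evaluate_variant_at_site",
    "scan_de_novo",
    "POSITIVE",
    "NEGATIVE",
    "NOT_EVALUABLE",
]

POSITIVE = "positive"
NEGATIVE = "negative"
NOT_EVALUABLE = "not_evaluable"

#: tools whose thresholds come from the splice-prediction literature
PAPER_THRESHOLD_TOOLS = frozenset({"HSF", "SSF_like", "MES"})


class ThresholdConfigError(KeyError):
    """Raised when a tool has no configured threshold."""


@dataclass(frozen=True)
class ToolScore:
    """Raw WT/VAR scores for one tool at one site (computed or imported)."""

    tool: str
    wt: float | None
    var: float | None
    source: str = "computed"  # "computed" | "external"
    evaluable: bool = True
    score_change: float | None = None  # for tools reporting a delta directly


@dataclass(frozen=True)
class DeltaResult:
    """A per-tool classification of one variant at one splice site."""

    tool: str
    percent_variation: float | None
    call: str  # POSITIVE | NEGATIVE | NOT_EVALUABLE
    site_lost: bool = False
    threshold_used: float | None = None
    wt: float | None = None
    var: float | None = None

    @property
    def evaluable(self) -> bool:
        return self.call != NOT_EVALUABLE


@dataclass(frozen=True)
class ThresholdConfig:
    """Per-tool % score-variation thresholds (negative = score reduction).

    The literature-established defaults are HSF -2, SSF-like -5 and MES -15;
    the NNSplice entry is a configurable placeholder, not an established
    value. The boundary rule decides whether a variation exactly at the
    threshold fires (inclusive, the default) or not.
    """

    thresholds: Mapping[str, float] = field(
        default_factory=lambda: {"HSF": -2.0, "SSF_like": -5.0, "MES": -15.0, "NNSplice": -5.0}
    )
    inclusive: bool = True

    def __post_init__(self):
        for tool, thr in self.thresholds.items():
            if thr >= 0:
                raise ValueError(
                    f"{tool}: thresholds are score reductions and must be negative, got {thr}"
                )

    def threshold(self, tool: str) -> float:
        try:
            return float(self.thresholds[tool])
        except KeyError:
            raise ThresholdConfigError(f"no threshold configured for tool {tool!r}") from None

    def fires(self, delta: float, tool: str) -> bool:
        thr = self.threshold(tool)
        return delta <= thr if self.inclusive else delta < thr


def percent_score_variation(wt: float, var: float) -> float | None:
    """(VAR - WT) / WT * 100; ``None`` (not evaluable) when WT is 0."""
    if wt == 0:
        return None
    return (var - wt) / wt * 100.0


def classify_tool(
    delta: float | None,
    tool: str,
    cfg: ThresholdConfig | None = None,
    site_lost: bool = False,
    wt: float | None = None,
    var: float | None = None,
) -> DeltaResult:
    """Turn a % score variation into a positive/negative/not-evaluable call.

    A destroyed site (``site_lost``) is encoded as -100% and positive
    regardless of the raw delta; a ``None`` delta is not evaluable.
    """
    cfg = cfg or ThresholdConfig()
    thr = cfg.threshold(tool)
    if site_lost:
        return DeltaResult(tool, -100.0, POSITIVE, site_lost=True, threshold_used=thr, wt=wt, var=var)
    if delta is None:
        return DeltaResult(tool, None, NOT_EVALUABLE, threshold_used=thr, wt=wt, var=var)
    call = POSITIVE if cfg.fires(delta, tool) else NEGATIVE
    return DeltaResult(tool, float(delta), call, threshold_used=thr, wt=wt, var=var)


# ---------------------------------------------------------------------------
# scorer adapters


@runtime_checkable
class Scorer(Protocol):
    """Anything that can score a boundary-anchored window."""

    tool: str
    site_kind: str
    window_spec: tuple[int, ...]

    def score(self, window: str) -> float: ...


@dataclass(frozen=True)
class PWMScorer:
    """Consensus-value scorer bound to one matrix (SSF-like or HSF-style)."""

    tool: str
    matrix: PWMatrix
    detection_floor: float | None = None

    @property
    def site_kind(self) -> str:
        return self.matrix.site_kind

    @property
    def window_spec(self) -> tuple[int, ...]:
        return self.matrix.window_spec

    def score(self, window: str) -> float:
        return consensus_value(window, self.matrix)

    #: CV is bounded in [0,100]; WT scores of planted sites are positive
    requires_positive_wt = False


@dataclass(frozen=True)
class MaxEntScorer:
    """Signal/decoy log-odds scorer (MES-style) for one site kind."""

    tool: str
    signal: object  # MEMModel | FragmentChainModel
    decoy: object
    site_kind: str
    window_spec: tuple[int, ...]
    detection_floor: float | None = None

    #: log-odds can be <= 0, where % variation is ill-defined
    requires_positive_wt = True

    def score(self, window: str) -> float:
        from .maxent import score_log_odds

        return score_log_odds(self.signal, self.decoy, window)


def evaluate_variant_at_site(
    v: Variant,
    site: SpliceSite,
    scorers: Sequence[Scorer],
    ref,
    cfg: ThresholdConfig | None = None,
    external: Mapping[str, ToolScore] | None = None,
    external_tools: Sequence[str] = (),
) -> list[DeltaResult]:
    """One DeltaResult per configured tool for a variant at a splice site.

    ``scorers`` are re-implemented tools evaluated on re-read WT/VAR windows;
    ``external_tools`` name tools whose scores, if present in ``external``,
    are used as supplied (WT/VAR pair or a pre-computed score change) and are
    otherwise reported not evaluable.
    """
    cfg = cfg or ThresholdConfig()
    external = external or {}
    results: list[DeltaResult] = []
    for scorer in scorers:
        if scorer.site_kind != site.kind:
            continue
        pair = build_site_windows(site, v, ref, scorer.window_spec)
        wt = scorer.score(pair.wt_seq)
        var = scorer.score(pair.var_seq)
        if getattr(scorer, "requires_positive_wt", False) and wt <= 0:
            results.append(classify_tool(None, scorer.tool, cfg, wt=wt, var=var))
            continue
        floor = getattr(scorer, "detection_floor", None)
        lost = floor is not None and wt >= floor and var < floor
        delta = percent_score_variation(wt, var)
        results.append(classify_tool(delta, scorer.tool, cfg, site_lost=lost, wt=wt, var=var))
    for tool in external_tools:
        score = external.get(tool)
        if score is None or not score.evaluable:
            results.append(
                DeltaResult(tool, None, NOT_EVALUABLE, threshold_used=cfg.thresholds.get(tool))
            )
            continue
        if score.score_change is not None:
            delta = float(score.score_change)
        else:
            delta = percent_score_variation(score.wt, score.var)
        results.append(classify_tool(delta, tool, cfg, wt=score.wt, var=score.var))
    return results


# ---------------------------------------------------------------------------
# de novo / cryptic site scanning


@dataclass(frozen=True)
class DeNovoCandidate:
    """A window position gaining score under the variant."""

    position: int  # window start within the scanned region (variant sequence)
    wt_score: float
    var_score: float
    outscores_natural: bool = False


def scan_de_novo(
    wt_region: str,
    var_region: str,
    scorer: Scorer,
    floor: float,
    natural_score: float | None = None,
) -> list[DeNovoCandidate]:
    """Report windows whose variant score reaches ``floor`` and exceeds WT.

    Scans every window of the variant region, comparing against the same
    window position in the wild-type region (positions beyond a shifted
    region compare against the aligned prefix; identical regions yield no
    candidates). Candidates at or above ``natural_score`` are flagged as
    outscoring the natural site.
    """
    L = len(scorer.window_spec)
    out: list[DeNovoCandidate] = []
    for start in range(0, len(var_region) - L + 1):
        var_win = var_region[start : start + L]
        var_score = scorer.score(var_win)
        if var_score < floor:
            continue
        wt_win = wt_region[start : start + L] if start + L <= len(wt_region) else None
        wt_score = scorer.score(wt_win) if wt_win else float("-inf")
        if var_score > wt_score:
            flag = natural_score is not None and var_score >= natural_score
            out.append(DeNovoCandidate(start, float(wt_score), float(var_score), flag))
    out.sort(key=lambda c: (-c.var_score, c.position))
    return out
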