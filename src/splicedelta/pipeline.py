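"""End-to-end prediction: variants x splice sites x tools x combination rules."""

from __future__ import annotations

from typing import Mapping, Sequence

import pandas as pd

from .delta import (
    NOT_EVALUABLE,
    DeltaResult,
    Scorer,
    ThresholdConfig,
    ToolScore,
    evaluate_variant_at_site,
)
from .ensemble import CombinationRule, RuleConfigError, applicability_filter, combine
from .genome import RegionConfig, TranscriptModel, extract_splice_sites, nearest_site
from .variants import Variant

__all__ = ["predict_variants"]


def predict_variants(
    ref,
    models: Sequence[TranscriptModel],
    variants: Sequence[Variant],
    scorers: Sequence[Scorer],
    rules: Mapping[str, CombinationRule],
    cfg: ThresholdConfig | None = None,
    region: RegionConfig | None = None,
    external: Mapping[tuple[str, str, str, str], ToolScore] | None = None,
    external_tools: Sequence[str] = (),
) -> pd.DataFrame:
    """One row per (variant, splice site, rule), long format.

    Variants reaching no analysis region are reported with status
    ``out_of_region``. External tools are screened through the applicability
    filter (indels and out-of-coverage positions become not evaluable) before
    their imported scores are used. Rules referencing tools with no result
    for a given site kind are skipped for that site.
    """
    cfg = cfg or ThresholdConfig()
    region = region or RegionConfig()
    external = external or {}
    sites_by_tx = {m.id: extract_splice_sites(m, ref) for m in models}
    rows: list[dict] = []
    for v in variants:
        if v.transcript_id and v.transcript_id in sites_by_tx:
            candidates = sites_by_tx[v.transcript_id]
        else:
            candidates = [
                s for m in models if m.chrom == v.chrom for s in sites_by_tx[m.id]
            ]
        hits = nearest_site(v.pos, candidates, region)
        if not hits:
            rows.append({"variant_id": v.id, "status": "out_of_region"})
            continue
        for site, relpos in hits:
            ext_here: dict[str, ToolScore] = {}
            for tool in external_tools:
                if not applicability_filter(v, relpos, tool):
                    continue  # stays not evaluable
                key = (v.id, site.transcript_id, site.kind, tool)
                if key in external:
                    ext_here[tool] = external[key]
            results = evaluate_variant_at_site(
                v, site, scorers, ref, cfg, ext_here, external_tools
            )
            by_tool = {r.tool: r for r in results}
            base = {
                "variant_id": v.id,
                "transcript_id": site.transcript_id,
                "site_kind": site.kind,
                "offset": relpos.offset,
                "side": relpos.side,
                "invariant_core": relpos.invariant_core,
                "status": "ok",
            }
            for r in results:
                base[f"delta_{r.tool}"] = r.percent_variation
                base[f"call_{r.tool}"] = r.call
            for name, rule in rules.items():
                if not set(rule.tools) <= set(by_tool):
                    continue
                pred = combine(results, rule)
                rows.append({**base, "rule": name, "call": pred.call, "n_evaluable": pred.n_evaluable})
    return pd.DataFrame(rows)
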