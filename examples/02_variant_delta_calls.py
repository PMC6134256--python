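"""Classify a core-disrupting SNV with per-tool thresholds and the
recommended donor combination.

A GT>AT change at donor +1 destroys the invariant core: both consensus-value
scorers drop far past their thresholds (-2% for the HSF-style scorer, -5%
for SSF-like), and the recommended donor rule (either of the two firing)
calls the variant splice-disruptive.
"""

from splicedelta import PWMScorer, evaluate_variant_at_site, extract_splice_sites
from splicedelta.ensemble import recommended_rules, combine
from splicedelta.fixtures import FixtureSpec, generate_reference, fixture_matrix_library
from splicedelta.genome import reverse_complement
from splicedelta.variants import Variant

lib = fixture_matrix_library()
ref, models = generate_reference(FixtureSpec(seed=1, n_genes=1), lib)
donor = extract_splice_sites(models[0], ref)[0]

g = donor.offset_to_genomic(1)  # intronic +1, the G of the GT core
wt = ref[donor.chrom][g]
alt = "A" if donor.strand == "+" else reverse_complement("A")
variant = Variant(donor.chrom, g, wt, alt, id="demo_GT>AT")

matrix = lib.for_kind("donor")[0]
scorers = [PWMScorer("SSF_like", matrix), PWMScorer("HSF", matrix)]
results = evaluate_variant_at_site(variant, donor, scorers, ref)
for r in results:
    print(f"{r.tool:9s} WT={r.wt:6.2f} VAR={r.var:6.2f} "
          f"delta={r.percent_variation:+7.2f}% (threshold {r.threshold_used:+.0f}%) -> {r.call}")

rule = recommended_rules()["donor_recommended"]
pred = combine(results, rule)
print(f"\n{rule.name} ({'+'.join(rule.tools)}, at least one firing): {pred.call}")
print("A % score variation at or below the tool threshold predicts splice disruption.")
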