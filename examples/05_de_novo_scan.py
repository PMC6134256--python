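"""Detect a variant-created (de novo) donor site by scanning window gains.

A natural-site delta of ~0% can hide a genuine splicing defect when the
variant instead *creates* a competing donor nearby. Scanning every window of
the variant region for scores that appear or strengthen reveals it — the
classic example being an exonic SNV that completes a consensus donor
outscoring the natural site (e.g. 96.9 vs 84.5 on the 0-100 scale, a +14.7%
gain).
"""

from splicedelta import PWMScorer, percent_score_variation, scan_de_novo
from splicedelta.pwm import default_library

matrix = default_library()["donor_GT"]
scorer = PWMScorer("SSF_like", matrix)

# an exonic region where one SNV (T>A at the 11th base) completes a donor
cons = matrix.consensus  # CAGGTAAGT
wt_region = "CCTACC" + cons[:4] + "C" + cons[5:] + "CCTACC"
var_region = "CCTACC" + cons + "CCTACC"

natural_score = 84.5  # score of the gene's natural donor site
hits = scan_de_novo(wt_region, var_region, scorer, floor=70.0, natural_score=natural_score)
for h in hits:
    gain = percent_score_variation(natural_score, h.var_score)
    print(f"position {h.position}: WT {h.wt_score:.1f} -> VAR {h.var_score:.1f}"
          f" ({gain:+.1f}% vs natural site){'  ** outscores natural site' if h.outscores_natural else ''}")

print("\nCandidates at or above the natural-site score are the ones most likely")
print("to redirect splicing; they are reported separately from natural-site loss.")
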