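# Methods

## Coordinate model

A splice site is represented as a genomic cut point: the junction sits
between base `boundary − 1` and base `boundary` (0-based, half-open
internally). User-facing offsets are signed and 1-based with no zero, the
standard HGVS-like convention: donor exonic −1 is the last exon base and
intronic +1 the first intron base (the G of GT); acceptor intronic −1 is the
last intron base (the G of AG) and exonic +1 the first exon base. The
analysis region defaults to −10..+20 around donors and −20..+10 around
acceptors. Everything sequence-level is computed on the transcription
strand; minus-strand transcripts are handled by reverse-complementing
fetched windows, so scorer matrices are always applied in their canonical
orientation. A variant within reach of two sites (short exons) is evaluated
at both rather than arbitrated.

## Variant mechanics

Variants are normalized VCF-style: shared prefix/suffix trimmed, pure indels
left-aligned through repeat context (idempotent). Windows are re-read
anchored at the splice boundary: the boundary never moves, and an indel
shifts content only on its own side of the junction, so scorers always see
full-length windows and the natural-site score stays well defined. Edits
spanning the junction are applied with the alternate allele and the
cut-shift assigned to the upstream (genomic-left) side — an arbitrary but
deterministic convention, flagged by the core-overlap indicator.
Ambiguity codes are rejected: all scorer parameterizations are ACGT-only.

## Consensus-value scorer

The CV linearly rescales the sum of observed per-position frequencies
between the argmin and argmax windows, so the per-position consensus scores
exactly 100 and the anti-consensus exactly 0. A pseudo-frequency of 1e-4 is
added to every matrix entry before renormalization to keep unseen bases
finite. Bundled matrices are classic Shapiro–Senapathy-style human donor
(9-mer, −3..+6) and acceptor (15-mer, −14..+1) frequency tables, plus
GC-/AT-core donor and AC-core acceptor variants for non-canonical sites;
windows live in the matrix file, not in code, because the proprietary tools
this scorer emulates do not publish their exact spans. The HSF-style scorer
is deliberately a *configuration* — the same CV machinery with its own
matrix set and the −2 % threshold — not a separate algorithm. Scanning ties
are broken by ascending position for determinism.

## Maximum-entropy scorer

The model is the maximum-entropy distribution over 4^L window k-mers subject
to empirical marginal constraints; the default constraint set is all
single-position plus adjacent-pair marginals. Fitting is iterative
proportional fitting from a uniform start (tolerance 1e-6 on the max
marginal residual, cap 10,000 sweeps; non-convergence raises an error
carrying the residual). Marginal smoothing spreads a configurable total
pseudo-count uniformly over each table (`pseudocount / 4^k` per cell) so
tables of different orders remain marginals of one smoothed distribution and
stay mutually consistent — per-cell pseudo-counts would make singles and
pairs contradict each other and stall the fit. The default pseudo-count is
0, keeping point-mass marginals exact; pipeline training uses a small
positive value so log-odds stay finite.

Windows up to 9 positions use a full joint table. Longer windows (the 23-mer
acceptor) use an overlapping-fragment chain (fragment length 7 by default):
each fragment carries its own full model, and fragments after the first
divide out their own marginal over the positions shared with the previous
coverage. Because every ratio is then a proper conditional of that
fragment's model, the chained probability is exactly normalized regardless
of cross-fragment inconsistencies.

Scores are raw `log₂(P_signal/P_decoy)`; whether the emulated tool
length-normalizes is not documentable from public sources, so the raw ratio
is used and stated here. Log-odds can be ≤ 0, where a percent variation
across zero is ill-defined: such sites are reported not evaluable by this
scorer rather than given a sign-flipped percentage.

## Delta statistic and calls

`% score variation = (VAR − WT)/WT × 100`, with WT = 0 a not-evaluable
signal rather than a division error. Thresholds: HSF-style −2 %, SSF-like
−5 %, maximum-entropy −15 %; the NNSplice −5 % default is a configurable
placeholder, not an established value, and is marked as such. The threshold
boundary is inclusive by default (a variation exactly at the threshold
fires) — the conservative, higher-sensitivity reading of "above the
threshold", and configurable. Score increases at the natural site never
flag disruption; variant-created or strengthened sites are a separate scan
that reports every window whose variant score clears a floor and exceeds its
wild-type score, flagging candidates that outscore the natural site. A site
whose variant-side score falls below a configured detection floor is encoded
as −100 % and positive ("site lost"), a package convention flagged in
output.

## Ensemble semantics

Two tools: positive if at least one fires. Three to six tools: positive if
all but one fire, with k recomputed over the tools actually evaluable for
that variant (minimum two) — mirroring benchmark panels computed over each
tool's scored subset. The sequential protocol defaults to the confirmatory
reading (maximum entropy first, SSF-like consulted only to confirm): the
ordered-AND is the only semantics consistent with the sequential rule
showing lower sensitivity and higher specificity than SSF-like alone, which
an OR cannot produce. The triage reading (either fires) is exposed as an
alternative policy. dbscSNV is only applicable at −3..+8 (donor) and
−12..+2 (acceptor) and, like SPANR, not for insertions/deletions; their
scores, when used, are imported from a score table, never recomputed.

## Benchmarking

The panel reports sensitivity, specificity, accuracy, MCC, PPV, NPV, FNR,
FPR, FDR and FOR, with `MCC = (tp·tn − fp·fn)/√((tp+fp)(tp+fn)(tn+fp)(tn+fn))`.
Zero-denominator metrics are reported absent, never 0. Table output rounds
half-even to 3 decimals; raw values are retained internally, and the
complement identities (Sn+FNR = Sp+FPR = PPV+FDR = NPV+FOR = 100) hold to
1e-9 before rounding. Not-evaluable predictions are excluded from a
predictor's counts and tallied separately. `confusion_from_rates` rebuilds
integer confusion counts from class sizes plus printed
sensitivity/specificity — the reconstruction used to verify the package's
panel arithmetic against published two-stage benchmark tables whose
per-variant data are not redistributable.

## Synthetic fixtures

The generator emulates the *structure* of a curated splice-variant study —
multi-exon genes on both strands, labeled variants concentrated in the
−10..+20 / −20..+10 regions, a discovery-style positive/negative split — with
analytic rather than biological ground truth. Its matrix set carries two
deliberately flat (uninformative) columns per site kind (donor −3/+6,
acceptor −14/−4): substitutions there move the CV by exactly 0 %, giving
guaranteed negatives, while core disruptions and argmin substitutions at
high-information positions give guaranteed positives well past every
threshold. Defaults: 2 genes × 3 exons, exons 60–100 nt, introns 40–70 nt
(≥ 25 enforced so donor and acceptor windows never collide), 20 positives +
20 negatives — sized so every suite and the acceptance script run in seconds
on one CPU. One seeded generator stream pins every byte; seeds are recorded
in output headers. Passing tests on these fixtures demonstrates the
machinery (coordinates, window re-reading, thresholds, combination logic,
metrics) — it does **not** demonstrate predictive accuracy on real variants,
which depends on matrix/model quality and on splicing features (branch
points, polypyrimidine tract, ESE/ESS regulation) that no scorer here
models.

## Known limitations

* Proprietary tool scores (Alamut's SSF-like/HSF variants) are not
  reproduced bit-exactly; matrices are swappable files so published tables
  can be dropped in.
* Branch-point and polypyrimidine-tract effects are invisible to both
  scorers — a documented failure mode for deep 3′ variants.
* ESE/ESS regulatory disruption is out of scope.
* No multi-isoform arbitration: each transcript model is evaluated
  independently, and no clinical (pathogenicity) interpretation is attached
  to any call.
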