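# Methods

## Evidence model

The pipeline treats direct miRNA targeting as a latent property to be
triangulated from independent, individually noisy evidence channels.

**Down-regulation votes.** Each transfection experiment e contributes a
boolean call per gene. For fold-change experiments the call is
`fc_e(g) <= fc_e(calibrator)`: the threshold is not a fixed cutoff but
the fold change of a known target measured in the same experiment,
which absorbs between-experiment differences in transfection efficiency
and platform compression. The comparison is inclusive at equality
("equal or less"), so a gene tied with the calibrator counts as down —
and the calibrator itself always votes down in its own experiment,
which is the intended behaviour (it *is* a target). Binary-list
experiments contribute membership directly. D(g) sums the calls;
a gene absent from an experiment's measured universe contributes no
vote there (absence of evidence, not missing data). Cross-species
harmonization is symbol case-folding only — no orthology mapping —
because the emulated design merges human and mouse results by symbol
identity, and miR-99 family sequences are identical between the two
species. Fold changes are linear ratios throughout; a log2 input column
must be converted explicitly via the reader's `log2=True` flag, never
silently.

**Prediction votes and tiers.** P(g) counts predicting tools out of 12.
The tier rule — high confidence iff (D ≥ 3 and P ≥ 10) or D ≥ 4 — is
deliberately a hard disjunction rather than a weighted score: it is
auditable, monotone in both votes, and reflects that strong expression
evidence (4 of 5 independent experiments) can stand without sequence
support, e.g. for targets bound through non-canonical sites.
"P ≥ 10" is read as at-least (not exactly 10). Thresholds are
configurable (`TierThresholds`); with a matrix of a different width the
absolute P threshold still applies by default.

**Enrichment.** The 2×2 table splits the candidate set (D ≥ 2) by top
membership (D ≥ 3) × predicted (P ≥ 1). The one-sided (greater)
hypergeometric tail is computed with log-factorial (`lgamma`)
arithmetic — no normal approximation — because the interesting p-values
are far in the tail (the printed-counts table gives p ≈ 2.7×10⁻⁸).
Sidedness follows the directional claim being tested (enrichment); the
two-sided p (minimum-likelihood rule, with a 1e-9 relative log-tolerance
against floating-point ties) is reported alongside for transparency.

## Seed sites and duplex energy

**Scanner.** A canonical site is a perfect Watson–Crick reverse
complement of the miRNA seed (nucleotides 2–8) on the transcript sense
strand; G:U is disallowed in the seed (the mutagenesis logic targets
exactly these 7 nt) but allowed in duplex extension. Only the given
strand is scanned — mRNA targeting is single-stranded. Sites are
annotated 8mer vs 7mer-m8 by the target nucleotide facing miRNA
position 1, but the class never gates a call: tool-specific site models
are already represented by the prediction matrix. All coordinates are
1-based inclusive internally; BED-like output converts to 0-based
half-open and says so in its header.

**Energy model.** Intermolecular duplex only: pairs monotone along both
strands (antiparallel), no intramolecular structure in either strand,
per-side gap bound `max_loop` (default 15 nt).

    E = duplex_init + Σ stack(doublet) + Σ loop(a, b)

Stacking applies to adjacent pairs only; a gap of (a, b) unpaired
nucleotides costs `base + 1.08·ln(a+b)` kcal/mol with `base` 3.80 for
bulges and 1.70 for interior loops (non-negative, non-decreasing —
asymmetry and dangling-end terms are deliberately omitted). Parameters
are a Turner-2004-style stacking table shipped as a versioned TSV
(`data/stack_params.tsv`, duplex_init 4.09 kcal/mol), closed under
duplex-reversal symmetry at load; Watson–Crick stacks are validated as
stabilizing. Wobble-containing values are approximate. Absolute
agreement with any particular published hybridization tool is *not*
claimed — different tools ship different parameter generations — and the
correctness surface is exact equivalence of the dynamic program with
exhaustive enumeration of all monotone pairings under the same
parameters, which the test suite checks on 500 seeded cases (combined
length ≤ 16, where enumeration is exact and fast).

A reported duplex must contain at least two consecutive pairs;
otherwise "no stable duplex" (mfe = None). Equal-energy ties break
toward more paired bases, then the lexicographically smallest pairing,
so outputs are reproducible. Each site's context window is the seed
match ±25 nt clipped to the transcript — approximating the 54–57 nt
fragments used in reporter constructs. The DP is O(m·n·max_loop²),
microseconds at miRNA×window scale.

## Quantification and correlation

Relative expression is 2^−ΔΔCt with amplification efficiency fixed at 2
and no efficiency correction; RQ is invariant to adding a constant to
all four Ct values. Correlation screens operate on log2 relative levels
(−ΔCt), the scale on which qPCR noise is additive; the Pearson p is
two-sided via the t transform (r = −0.79 at n = 7 gives p ≈ 0.035,
rounding to 0.03). No multiple-testing correction is applied across the
small gene panels — r is reported per gene, as is conventional for
candidate panels of this size; a Benjamini–Hochberg pass can be applied
downstream if screens grow.

## Synthetic data: what it emulates, and what it does not

The generator's defaults mirror the emulated five-experiment design:
three fold-change experiments carrying the calibrator at fold
differences 0.88 / 0.67 / 0.67, two binary lists (one mouse,
title-case symbols, forcing the harmonization path), a 12-tool matrix,
10 annotated transcripts of 2 400 nt, a 10-cell-line panel and a
7-sample tissue panel (4 embryonic stages + 3 adult tissues). Defaults
chosen where the design itself fixes no value: 300 genes and 20 planted
true targets (plus the calibrator) keep every brute-force test oracle
exact while preserving the top-set/candidate-set contrast; effect_fc
0.5 (a planted target halves its expression — a typical
degradation-mediated miRNA effect, safely below both calibrator
thresholds); log2-noise sd 0.1 (array-scale replicate noise); each true
target planted down in 3 of 5 experiments; down-lists of 80 genes
filled with decoys; per-tool sensitivities 0.50–0.90 and false-positive
rates 0.01–0.06, which reproduce the observed study shape of roughly a
third of non-targets being predicted by at least one of 12 tools;
planted panel correlations −0.4 (cell lines, stochastic construction
with 0.25-cycle Ct noise) and −0.79 (tissue panel, exact Gram–Schmidt
construction so the sample r equals the planted r; reference assays
held near-constant). Background transcript sequence is scrubbed of
accidental seed matches so the planting log is the complete site truth.
All randomness descends from one seed through per-component
`SeedSequence` streams; a fixed seed yields byte-identical files.

What passing on this generator does **not** show: real arrays have
probe-level artifacts, correlated noise across genes, and
platform-specific compression that the independent log-normal noise
model does not produce; real prediction tools are correlated with each
other (shared site models), whereas generated tool columns are
conditionally independent given target status — so real-data
enrichment statistics will be less clean than synthetic ones; and real
transcripts contain chance seed matches, which the scrubbing
deliberately removes from the truth set.

## Numerical and design notes

- Fisher tail sums use `lgamma`; equivalence with rational brute-force
  enumeration is asserted to 1e-12 at small margins.
- Duplex self-consistency: the energy recomputed from the returned
  pairing must reproduce the mfe to 1e-9 kcal/mol.
- Degenerate inputs are refused loudly rather than coerced: missing
  calibrator, duplicate symbols after case-folding (ambiguous fold
  change), constant correlation vectors, n < 3 samples, non-finite Ct,
  non-positive fold changes, windows < 2 nt.
- The pipeline removes partial outputs on failure; the report is fully
  re-derivable from the stage files on disk (no hidden state).
- Suite-scale choices: enumeration oracles run at combined length ≤ 16
  (exhaustive search is exact there); scanner oracles on 50 random
  transcripts; correlation recovery on a 4-point planted-r grid × 50
  seeds. These sizes make the full suite run in seconds while keeping
  every oracle exact.

## Known limitations

- Only canonical 7-nt seed sites are called; seedless/non-canonical
  targeting (suspected for genes down-regulated without any predicted
  site) is out of scope by design.
- The energy model omits dangling ends, loop asymmetry penalties and
  temperature dependence; mfe values are comparable within this
  package, not across tools.
- Case-folding harmonization will conflate distinct cross-species
  symbols in the rare cases where nomenclature diverges.
- Amplification efficiency is fixed at 2; no standard-curve correction.
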