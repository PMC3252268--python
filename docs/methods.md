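# Methods

## The scoring model

The score quantifies three hallmarks of AU-rich elements. Let the input be a
nucleotide string; it is uppercased and T is mapped to U before any matching,
so DNA and RNA input, in any case, score identically. IUPAC ambiguity
letters (including N) never match the pentamer and count as non-AU in window
content — a conservative choice that can only lower a score, never raise it.

**Pentamers.** Every occurrence of AUUUA is counted, including overlapping
occurrences (AUUUAUUUA contains two). Each adds `pentamer_value`
(default 1) to the basal score. The related UUAUUUA(U/A)(U/A) nonamer is not
a separate feature: it is already captured as two overlapping pentamers or a
pentamer inside an AU-rich region.

**Proximity.** Pentamer hits are sorted by position and each *consecutive*
pair contributes once — "distance between neighbouring pentamers", not all
pairs, so a run of three tandem overlapping pentamers earns two overlap
bonuses. The distance measure is the gap: the number of nucleotides strictly
between the two pentamers, `next_start − (prev_start + 5)`. A negative gap
means overlap (+1.5 by default); gaps 0–3, 4–6 and 7–9 add 0.75, 0.4 and
0.2; gaps ≥ 10 add nothing. Reading "0–3 nt apart" as the gap makes the
four bands contiguous and mutually exclusive; this reading is a documented
decision, since start-to-start distance would be an alternative.

**AU-blocks.** A window of `block_word` nt (default 20) slides one position
at a time. A block opens at the start of the first window whose A+U fraction
is ≥ `block_start_au` (default 0.80); while open, the block extends as long
as the window starting at each subsequent position has A+U fraction ≥
`block_end_au` (default 0.55); it closes at the end (start + word) of the
last qualifying window. Overlapping or abutting blocks are merged, so
reported blocks are disjoint and maximal. Sequences shorter than the window
have no blocks. The closing coordinate (end of the last qualifying window,
rather than its start) is a documented decision — the rule needs a boundary
convention and this one is deterministic and maximal. A pentamer earns
`block_bonus` (default 0.3) only when its full 5-nt span lies inside a
block, at most once per pentamer; partial overlap earns nothing.

Consequences worth knowing: the total is 0 exactly when there are no
pentamers (blocks alone never score), the total is non-negative, and with
all bonuses set to 0 the score is the plain pentamer count.

Coordinates are 0-based half-open internally and 1-based in user-facing
detail output. Strand is never considered; input is the mRNA-sense strand.

## Batch scoring and per-gene collapsing

Transcriptome-wide runs score every record with length ≥ `min_len`
(default 10 nt, which discards mis-annotated stub UTRs); shorter records are
reported as skipped. When a table maps several transcripts to one gene, only
the highest-scoring transcript per gene is kept; score ties are broken by
the lexicographically smallest transcript id — the original pipeline's
tie-break is unknown, and this rule is simply reproducible. The length
filter is applied before collapsing.

## Null models

*Composition-matched*: all nucleotides of all input sequences are pooled,
the pool is permuted once with a seeded generator, and the permutation is
cut into pieces whose lengths equal the input lengths in order. Drawing
without replacement is what makes "identical length and base composition"
exact rather than expected; this is a deliberate reading of a procedure that
could also be implemented with i.i.d. draws. *Concatemer*: whole pool
sequences are drawn uniformly with replacement and concatenated until the
target length is reached, the last fragment being tail-truncated — a
stricter null that preserves local sequence structure, used as a
size-matched control group. Both are fully reproducible from one integer
seed, which the CLI requires explicitly.

## Statistics

**Enrichment.** Scores of a real set and a control set are dichotomised at a
threshold (≥ t vs < t; t = 4 or 10 in typical use) into a 2×2 table
[[a, b], [c, d]] with the real set in the first row. Pearson's χ² is used
without Yates continuity correction; Fisher's exact test is two-sided,
summing hypergeometric probabilities ≤ that of the observed table; the
association strength is Φ = (ad − bc)/√((a+b)(c+d)(a+c)(b+d)), positive when
high scores are over-represented in the real set. A zero margin makes χ²
(and Φ) undefined; the code then reports χ² as missing, sets Φ to 0, and
still returns the Fisher p-value.

**ROC.** Every unique observed score is swept as a threshold (predict
"labile" when score ≥ threshold), plus a sentinel above the maximum so the
curve runs from (0,0) to (1,1). The AUC is the trapezoid area, which equals
the Mann–Whitney U statistic with ties counted one half, divided by
n₁·n₂ — the probability that a random positive outscores a random negative.

**Rank correlation with censoring.** Half-lives too slow to measure within
the chase window are recorded as censored (">240 min"). For Spearman
correlation these enter as mutually tied values above every measured one;
average ranks are used throughout and the coefficient is the Pearson
correlation of the rank vectors. This treatment is a documented choice — the
right-censored values carry only the information "larger than the limit",
which is exactly what a top-tied rank encodes — and it is switchable (the
censor flags are an optional argument).

**Half-life fitting.** For a decay time course normalised to t = 0,
ln(abundance) is regressed on time by ordinary least squares and the
half-life is ln 2 / |slope|. A non-negative slope, or a fitted half-life
beyond the censor limit (default 240 min, the practical end of an
actinomycin-D chase), is reported as censored. At the default design
(time points 0/30/60/120 min, 5% multiplicative noise) simulation shows the
mean recovered half-life within a few percent of truth for half-lives of
30–120 min.

**Grouped summaries.** Groups report mean ± SE and a two-sided one-sample
t-test of the group against the pooled mean; singleton groups report the
mean only.

## Reference panel

The built-in panel holds 26 Drosophila SL2-cell mRNAs (12 sensitive to
Tis11 knockdown, 14 controls) with half-lives under control and knockdown
conditions (censored at 240 min), 3′UTR lengths and scores. Its analyses
are deterministic: score-bin counts (<4 / 4–7.99 / ≥8 give 13 / 8 / 5),
stability of score-zero transcripts (9 of 10 censored), censoring-aware
Spearman correlations of score and length against half-life, and ROC
discrimination of labile (measured half-life < 140 min, n = 9) from stable
(censored, n = 13) transcripts; the four transcripts with measured
half-lives between 140 and 240 min are excluded from the ROC. A checksum
test freezes the panel against accidental edits.

## Synthetic transcriptomes

The generator emulates a fly-like 3′UTR population: log-normal lengths
(median 207 nt, σ = 0.7 on the log scale, clipped to [10, 5000]) and i.i.d.
bases at 62% A+U. A chosen fraction of records (default 5%) receives one
class-II-like ARE cassette: 4–7 pentamers, each following its predecessor
either in tandem overlap (probability 0.7) or after an AU-only spacer of
0–3 nt, wrapped in 10 AU-only nucleotides per side so the cassette sits in
an AU-block. The cassette replaces background at a random position; records
whose drawn length cannot hold it are lengthened to cassette + 10 nt (kept
feasible by construction rather than erroring on a random draw; a spec whose
cassette cannot fit the hard length cap does error). A truth table records
which records are planted, where, and with how many pentamers. Output is
byte-identical for a fixed seed.

What the generator does *not* emulate: real codon/UTR base correlations,
dinucleotide structure, repeat content, UTR isoform overlap, and the
long-tailed score distribution of mammalian transcriptomes. Passing the
power analyses therefore shows the pipeline detects planted composition
differences of the modelled kind at n = 2000; it does not certify detection
power on any real transcriptome.

## Problem sizes and numerical choices

The simulation suites run at desk scale, chosen as the sizes where the
checked property is already unambiguous: scorer/oracle equivalence on 1000
random sequences (20–500 nt, AU 0.3–0.9), null conservation over 100 seeds,
enrichment power at n = 2000 genes × 20 seeds with the detection criterion
Φ > 0 and χ² p < 0.05, null-vs-null calibration on 20 seeds, and half-life
recovery over 100 simulations per true value. Scores are compared to the
brute-force oracle for exact equality; component totals are accumulated per
term (count × value) so equality is bitwise, not tolerance-based. Fisher
p-values agree with full hypergeometric enumeration over every 2×2 table of
total ≤ 40. Degenerate inputs are defined, not guessed: empty sequences
score 0, empty score sets and empty groups raise, zero rank variance yields
NaN with the condition stated.
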