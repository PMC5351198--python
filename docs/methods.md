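# Methods

## Problem and model

Given two sets of pre-miRNA hairpin sequences — e.g. one species or clade
per set — the package asks whether a classifier can tell them apart from
sequence alone. Both classes are real sequences, so the usual problem of
arbitrary pseudo-negative data does not arise; separability itself is the
quantity of interest, and it is expected to track evolutionary distance.
Only sequence-composition features are used: hairpin secondary structure is
deliberately excluded because structure is more conserved than sequence and
carries little signal between close relatives.

## Features

**k-mers.** All words over {A,C,G,U} for k = 1..3, ordered by k then
lexicographically: 4 + 16 + 64 = 84 features. The value of word *w* of
length *k* in sequence *s* is count(*w*) / (|*s*| − *k* + 1). When a
sequence contains an ambiguous symbol (N), windows overlapping it are
excluded from both the count and the denominator, so the per-k frequencies
still sum to one whenever any valid window exists — this generalises the
clean-sequence normalisation without changing it.

**Motif scores.** Motifs are position-frequency matrices (w × 4). A
sequence is scored by sliding the profile along it; each offset sums the
profile frequencies of the matching nucleotides and the maximum is the
feature value. If the profile is longer than the sequence, the sequence is
shifted fully inside the profile instead. Scores are raw sums in
[0, min(w, L)] — no length normalisation and no standardisation, since the
downstream random forest is invariant to monotone per-feature rescaling.
Ambiguous residues contribute 0. Motifs are discovered per class (default
100 per class, widths 11–50), giving 200 motif features for two classes;
each column is named `<class>:<motif id>`.

## Built-in motif discovery

The built-in discoverer is a deliberately simple greedy stand-in for an
EM-based tool like MEME, and is not claimed to match it. Per motif:

1. **Seed**: the exact word of length `minw` most over-represented relative
   to the dataset's 0-order background (observed / expected count; ties
   broken lexicographically, so the procedure is deterministic).
2. **Align**: each sequence contributes its best-scoring window against the
   one-hot seed profile.
3. **Extend**: the alignment grows symmetrically (one column each side per
   step, up to `maxw`) while the mean information content of the *newly
   added* columns is at least 0.3 bits; windows that would cross a sequence
   boundary are dropped, and extension stops if fewer than half survive.
   Judging only the new columns prevents a high-information core from
   dragging arbitrary random flanks into the profile.
4. **Profile**: per-column nucleotide counts with add-one pseudocounts.
5. **Mask**: occurrences scoring ≥ 0.8 × width, plus all exact occurrences
   of the seed word, are overwritten with N before the next round. Masking
   the seed word unconditionally guarantees progress: a low-information
   profile that never reaches the score threshold would otherwise leave the
   seed word in place and the search would loop on one motif.

The 0.3-bit extension threshold, 0.8 masking fraction and add-one
pseudocount are engineering choices of this stand-in. External MEME can be
used instead through `run_meme_external` when the executable is installed;
its minimal text output is parsed by the same reader.

## Feature selection

Information gain G = H(C) − Σₜ P(t)·H(C|t) in bits, i.e. the mutual
information between the binned feature and the class label. Continuous
features are discretized by equal-frequency binning at empirical quantiles
(default 10 bins; identical values always share a bin; a constant feature
collapses to one bin and gains 0). Equal-frequency binning is robust to the
strongly skewed k-mer frequency distributions. The top 100 features are
kept; ties are broken by feature name so rankings are reproducible.

Selection runs once per experiment, before cross-validation, on all
non-holdout examples. This mirrors the evaluated workflow and keeps the
computation tractable; the per-fold alternative is available through the
motif re-creation experiment's machinery, and the holdout metrics remain
unaffected by any selection optimism.

## Evaluation protocol

Classes are balanced by uniform downsampling of the majority class (once
per experiment, before the holdout split, so every partition reflects the
balanced task). A stratified 10% holdout is removed once. Each of the
(default 100) Monte Carlo folds draws a fresh stratified 80/20 train/test
split of the remaining 90%, trains a random forest (100 trees,
√n_features candidate splits, no depth limit) and records confusion counts
on the fold's test partition and on the constant holdout. Stratification is
used because small classes would otherwise occasionally vanish from a
partition; a split that still ends single-class is redrawn (up to 10
times). Metrics per fold:

SE = TP/(TP+FN), SP = TN/(TN+FP), precision = TP/(TP+FP),
F = 2·precision·SE/(precision+SE), ACC = (TP+TN)/total,
MCC = (TP·TN − FP·FN)/√((TP+FP)(TP+FN)(TN+FN)(TN+FP)).

Any metric with a zero denominator is defined as 0 so aggregation over
folds stays total. Reported values are means over folds; the full per-fold
accuracy distribution is retained for spread comparisons.

Every random choice derives from one experiment seed via
`numpy.random.SeedSequence` with fixed stage keys, so a rerun with the same
configuration reproduces all artifacts byte-for-byte.

## Motif re-creation control

Discovering motifs on the full dataset before cross-validation could in
principle leak information. The control experiment compares mode A (motifs
discovered once on all data, outer×inner Monte Carlo folds) against mode B
(per outer fold, motifs re-discovered on a random 50% subset, features
rebuilt, inner folds run). Similar mean accuracies across modes indicate
the features are sound; mode B's spread is expected to be at least as large
since its motifs come from half the data. With one outer fold and a 100%
subset, mode B reduces exactly to mode A.

## Synthetic data

The generator emulates hairpin-scale datasets: default 300 sequences per
class, lengths uniform in 60–120 nt (miRBase hairpin scale at desk-scale
runtime), i.i.d. residues from a per-class background, and optionally one
planted motif instance per listed motif (consensus with per-position
mutations) overwriting a uniform random window. The divergence knob d
interpolates class B's background towards its target
((1−d)·bg_A + d·bg_B) and uses class B's motif set with probability d per
sequence, so d = 0 yields two samples of one distribution and d = 1 fully
divergent classes. The bundled `disjoint_motif_spec` plants one 15-nt
motif per class (A/C-rich vs G/U-rich consensus, occurrence probability
0.9, mutation rate 0.05) so that at d = 1 both motif scores and k-mers
carry signal.

What the generator does **not** emulate: hairpin secondary structure,
within-class phylogenetic correlation (sequences are i.i.d., real
pre-miRNAs form families), length/composition coupling, and miRBase
annotation noise. Passing tests therefore demonstrate that the pipeline
recovers controlled composition/motif signal and finds none where none
exists — not that any particular pair of real species is separable.

## Validation scales and numerical choices

The simulation checks run at 300 sequences per class with 20 Monte Carlo
folds and 20 built-in motifs per class (the control experiment at 200 per
class, 5×5 folds, 10 motifs per class) — sizes chosen to exercise the full
pipeline at the generator's native scale while keeping a test run in
minutes. Null-distribution accuracy is accepted within ±0.05 of 0.5;
signal-recovery accuracy at full divergence must reach 0.9.

Degenerate inputs: sequences shorter than k contribute zero k-mer
frequencies for that k; a constant feature gets gain 0; a profile row
summing outside 1 ± 10⁻³ is rejected at parse/construction time;
confusion-metric denominators of zero yield 0. Greedy duplicate filtering
processes records in input order with global-alignment identity
(matches / alignment length; identical strings short-circuit to 1.0), so at
the default threshold 1.0 only exact duplicates are removed — the simplest
rule consistent with removing multiple-identical-sequence bias; lower
thresholds (down to ~0.8) are supported but no published threshold exists
to mirror.

## Known limitations

- The built-in discoverer finds ungapped, roughly position-aligned motifs
  only; it can report a planted motif shifted or with low-information
  flanks when the seed word sits asymmetrically inside it.
- Selection before cross-validation makes fold *test* metrics slightly
  optimistic by construction on null data (the holdout metrics are not);
  the measured null accuracy stays within ±0.05 of chance at the default
  scales.
- Only a random-forest classifier ships; the classifier factory is
  pluggable but alternatives are untested.
- No multi-class assignment: the package answers "are these two pools
  separable", not "which species did this hairpin come from".
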