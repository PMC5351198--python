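# mirclade

Species discrimination for pre-miRNA hairpins from sequence features.

Precursor microRNAs (pre-miRNAs) are ~60–120 nt hairpin sequences. When
deep-sequencing data contains putative xeno-miRNAs — miRNAs apparently
originating from another species — it matters whether the pre-miRNA pools of
two species can be told apart at all: closely related species should be
nearly indistinguishable, distant ones easy to separate. `mirclade` takes
two sets of hairpin sequences (one per species or clade), builds purely
sequence-based features, and measures their separability with a balanced
random-forest classifier under Monte Carlo cross-validation.

## Method

Each sequence *s* is described by:

- **k-mer frequencies** — for every word *w* of length *k* ∈ {1, 2, 3} over
  {A, C, G, U}, the count of *w* divided by the number of windows
  |*s*| − *k* + 1 (84 features);
- **motif-profile scores** — per class, motifs are discovered (built-in
  greedy discoverer, or external MEME) as position-frequency matrices
  *M* ∈ ℝ^(w×4); a sequence's score against *M* is
  max over offsets *o* of Σᵢ *M*[i, s(o+i)], the shift-and-sum best match
  (with the sequence slid inside the profile when the profile is longer).
  With the default 100 motifs per class this adds 200 features.

Features are ranked by information gain
G(f) = H(C) − Σₜ P(t) H(C | t) (bits, over equal-frequency bins *t* of *f*)
and the top 100 are kept. Classes are forced to equal sizes by downsampling;
a stratified 10% holdout is set aside once; then each of 100 Monte Carlo
folds draws a fresh stratified 80/20 train/test split of the remainder,
trains a random forest, and records SE, SP, precision, F-measure, ACC and
MCC on both the fold's test partition and the constant holdout.

A synthetic generator produces paired sequence classes with controlled
background composition, planted motifs, and a divergence knob d ∈ [0, 1]
(d = 0: statistically identical classes; d = 1: fully divergent), so the
whole pipeline can be validated against known ground truth.

## Worked example

```sh
python examples/04_divergence_sweep.py
```

```
divergence   mean test ACC
   0.00         0.544
   0.25         0.600
   0.50         0.687
   1.00         0.980
accuracy tracks divergence: indistinguishable classes sit at ~0.5, fully
divergent ones approach 1.0
```

Two classes drawn from the same distribution (d = 0) sit at chance accuracy
~0.5 — the pipeline finds no spurious signal — while fully divergent classes
(disjoint planted 15-nt motifs, shifted background) are separated almost
perfectly. The other scripts in `examples/` cover motif discovery, feature
building and selection, and the motif re-creation control experiment.

From Python:

```python
from mirclade import generate_dataset, run_pipeline
from mirclade.synthetic import disjoint_motif_spec

pos, neg = generate_dataset(disjoint_motif_spec(n_per_class=300, divergence=1.0, seed=0))
result = run_pipeline(pos, neg, n_motifs=20, n_folds=20, seed=0)
print(result.report.mean_metrics("test").acc)   # ~0.95
```

Real data would enter through `mirclade.read_fasta` / `assemble_group`
(FASTA, DNA or RNA alphabet, with per-species duplicate filtering) instead of
the generator.

There is also a thin CLI (`mirclade simulate|discover|features|select|train|run|recreation-experiment`);
run `mirclade --help`.

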