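"""Generate two divergent synthetic classes and test their separability.

At full divergence (d=1) each class carries its own planted 15-nt motif, so
the combined k-mer + motif-score features make the classes almost perfectly
separable; the printed mean test accuracy should be close to 1.0.
"""

from mirclade import generate_dataset, run_pipeline
from mirclade.synthetic import disjoint_motif_spec

spec = disjoint_motif_spec(n_per_class=100, divergence=1.0, seed=0)
positive, negative = generate_dataset(spec)
print(f"{len(positive)} positive and {len(negative)} negative sequences, "
      f"lengths {positive.records[0].length}.. nt")

result = run_pipeline(
    positive, negative,
    n_motifs=10,      # built-in motifs discovered per class
    n_selected=80,    # top features by information gain
    n_folds=10,       # Monte Carlo folds
    seed=0,
)

test = result.report.mean_metrics("test")
hold = result.report.mean_metrics("holdout")
print(f"mean test    ACC {test.acc:.3f}  MCC {test.mcc:.3f}  F {test.f_measure:.3f}")
print(f"mean holdout ACC {hold.acc:.3f}  MCC {hold.mcc:.3f}")
print("ACC near 1.0 means the two sequence sets are separable; "
      "0.5 would mean they are statistically indistinguishable.")
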