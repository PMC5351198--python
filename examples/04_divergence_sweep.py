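"""Classification accuracy as a function of class divergence.

The divergence knob d interpolates the negative class from a copy of the
positive class (d=0) to a fully distinct background + motif set (d=1),
mimicking increasing evolutionary distance between two species' pre-miRNA
pools.  Accuracy should rise from chance (~0.5) towards ~1.0.
"""

from mirclade import generate_dataset, run_pipeline
from mirclade.synthetic import disjoint_motif_spec

print("divergence   mean test ACC")
for d in (0.0, 0.25, 0.5, 1.0):
    spec = disjoint_motif_spec(n_per_class=150, divergence=d, seed=3)
    positive, negative = generate_dataset(spec)
    result = run_pipeline(
        positive, negative, n_motifs=10, n_selected=80, n_folds=10, seed=3
    )
    acc = result.report.mean_metrics("test").acc
    print(f"   {d:4.2f}         {acc:.3f}")
print("accuracy tracks divergence: indistinguishable classes sit at ~0.5, "
      "fully divergent ones approach 1.0")
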