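"""Train a miniature cascade bundle and predict a contact map.

Generates two proteins per length range, trains the six 1747-5-1
sub-networks and the 9-6-1 cascade briefly, then predicts contacts for
one protein and prints the strongest calls in CASP RR style
(i j 0 8 probability). Sizes here are deliberately tiny — see the
package documentation for realistic settings.
"""

from contactcascade import BundleTrainConfig, TrainConfig, train_bundle
from contactcascade.synthetic_data import SyntheticSpec, synth_dataset

lengths = (55, 64, 75, 86, 100, 120, 140, 180, 210, 270, 300, 400)
samples = synth_dataset(SyntheticSpec(lengths=lengths, msa_rows=10, seed=7))

config = BundleTrainConfig(
    n_train_per_range=2,
    max_pairs_per_subnet=1500,
    subnet_config=TrainConfig(max_epochs=150, seed=7),
    cascade_config=TrainConfig(max_epochs=150, seed=7),
    seed=7,
)
bundle, report = train_bundle(samples, config)
print("per-range optimized thresholds (cascade):",
      [round(t, 2) for t in bundle.cascade_thresholds])

target = samples[4]  # a 100-residue protein, routed to sub-network 3
pm = bundle.predict_map(target.alignment, target.length, name=target.name)
print(f"{target.name}: routed to sub-network {pm.subnet_id}, "
      f"separation >= {pm.separation}, {len(pm.pairs)} pairs scored")
ranked = sorted(zip(pm.pairs, pm.probabilities), key=lambda t: -t[1])[:5]
print("top 5 predicted contacts (i j 0 8 p):")
for (i, j), p in ranked:
    print(f"  {i} {j} 0 8 {p:.3f}")
print(f"{len(pm.calls)} pairs called at threshold {pm.threshold:.2f}")
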