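"""Fixed-seed synthetic benchmark of the full cascade pipeline.

Generates a synthetic corpus spanning all six length ranges, trains the
six sub-networks and the cascade net, then scores both on held-out
proteins with the macro-averaged accuracy/coverage protocol. The two
qualitative findings the architecture is built around are measured:

* the cascade's set-level accuracy versus the mean of the six
  sub-networks' accuracies (combination + balancing should win);
* the per-protein accuracy-vs-length regression slope, whose magnitude
  should shrink under the cascade (robustness to the thin-density
  problem of long chains).

Default problem sizes (6 training / 10 test proteins per range, 40-row
MSAs, 3000 balanced pairs per sub-network, a few hundred epochs) keep a
full run in the minutes range on one CPU.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from . import neural_net as nn
from .cascade_model import (
    BundleTrainConfig,
    CascadeBundle,
    LengthPartition,
    ProteinSample,
    train_bundle,
)
from .evaluation import ProteinScore, aggregate, score_protein
from .synthetic_data import SyntheticSpec, synth_dataset


@dataclass
class BenchmarkConfig:
    """Study conditions for the end-to-end benchmark."""

    n_train_per_range: int = 6
    n_test_per_range: int = 10
    msa_rows: int = 40
    mutation_rate: float = 0.25
    max_pairs_per_subnet: int = 6000
    subnet_epochs: int = 400
    cascade_epochs: int = 500
    seed: int = 0


def _range_lengths(lo: int, hi: int, k: int, rng: np.random.Generator) -> list[int]:
    """k lengths spread evenly across [lo, hi] (deterministic spacing)."""
    return [int(round(v)) for v in np.linspace(lo, hi, k)]


def build_corpus(
    config: BenchmarkConfig, partition: LengthPartition | None = None
) -> tuple[list[ProteinSample], list[ProteinSample]]:
    """(train, test) protein samples spanning all six ranges."""
    partition = partition or LengthPartition()
    rng = np.random.default_rng(config.seed)
    lengths = []
    for lo, hi in partition.ranges:
        lengths.extend(
            _range_lengths(lo, hi, config.n_train_per_range + config.n_test_per_range, rng)
        )
    spec = SyntheticSpec(
        lengths=tuple(lengths),
        msa_rows=config.msa_rows,
        mutation_rate=config.mutation_rate,
        seed=config.seed,
    )
    samples = synth_dataset(spec)
    train, test = [], []
    k = config.n_train_per_range + config.n_test_per_range
    for r in range(len(partition.ranges)):
        block = samples[r * k : (r + 1) * k]
        # interleave so both splits cover the whole range
        order = rng.permutation(k)
        train.extend(block[i] for i in sorted(order[: config.n_train_per_range]))
        test.extend(block[i] for i in sorted(order[config.n_train_per_range :]))
    return train, test


def _score_maps(
    scored: list[tuple[str, int, list, np.ndarray, float, set]]
) -> tuple[list[ProteinScore], list[tuple[int, float]]]:
    per_protein, acc_by_len = [], []
    for name, length, pairs, probs, thr, truth in scored:
        called = {p for p, q in zip(pairs, probs) if q >= thr}
        if not called:
            continue
        sc = score_protein(name, called, truth)
        per_protein.append(sc)
        if sc.accuracy is not None:
            acc_by_len.append((length, sc.accuracy))
    return per_protein, acc_by_len


def run_benchmark(
    config: BenchmarkConfig | None = None,
) -> dict:
    """Train the bundle on the synthetic corpus and score it end to end.

    Returns a dictionary with the cascade's and the sub-networks'
    set-level accuracy/coverage, the per-protein accuracy-vs-length
    regression slopes for both, and bookkeeping counts.
    """
    config = config or BenchmarkConfig()
    partition = LengthPartition()
    train, test = build_corpus(config, partition)

    tc = BundleTrainConfig(
        n_train_per_range=config.n_train_per_range,
        max_pairs_per_subnet=config.max_pairs_per_subnet,
        subnet_config=nn.TrainConfig(max_epochs=config.subnet_epochs,
                                     seed=config.seed),
        cascade_config=nn.TrainConfig(max_epochs=config.cascade_epochs,
                                      seed=config.seed),
        seed=config.seed,
    )
    bundle, train_report = train_bundle(train, tc, partition)

    casc_scored, sub_scored = [], []
    for sample in test:
        pm = bundle.predict_map(sample.alignment, sample.length, name=sample.name)
        truth = {
            (i, j)
            for i, j in sample.contact_map.contact_pairs(pm.separation)
        }
        casc_scored.append(
            (sample.name, sample.length, pm.pairs, pm.probabilities,
             bundle.cascade_thresholds[pm.subnet_id - 1], truth)
        )
        own = pm.subnet_probabilities[pm.subnet_id]
        sub_scored.append(
            (sample.name, sample.length, pm.pairs, own,
             bundle.subnet_thresholds[pm.subnet_id - 1], truth)
        )

    casc_scores, casc_xy = _score_maps(casc_scored)
    sub_scores, sub_xy = _score_maps(sub_scored)
    casc_rep = aggregate(casc_scores)
    sub_rep = aggregate(sub_scores)

    def slope(xy):
        if len(xy) < 3:
            return float("nan")
        x, y = zip(*xy)
        return float(stats.linregress(x, y).slope)

    return {
        "config": config,
        "bundle": bundle,
        "train_report": train_report,
        "cascade_report": casc_rep,
        "subnet_report": sub_rep,
        "cascade_accuracy": casc_rep.mean_accuracy,
        "cascade_coverage": casc_rep.mean_coverage,
        "subnet_accuracy": sub_rep.mean_accuracy,
        "subnet_coverage": sub_rep.mean_coverage,
        "cascade_slope": slope(casc_xy),
        "subnet_slope": slope(sub_xy),
        "n_test_proteins": len(test),
        "n_train_proteins": len(train),
        "n_cascade_scored": len(casc_scores),
        "n_subnet_scored": len(sub_scores),
    }
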