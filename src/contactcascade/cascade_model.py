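"""Length-routed cascade of contact-prediction networks.

Chains of 51-450 residues are partitioned into six length ranges, each
served by its own 1747-5-1 sub-network trained only on chains of that
range. At prediction time a protein consults its own sub-network plus the
left and right neighbours; their per-pair outputs, together with three
balance weights derived from the protein's length, form the 9-element
input of a 9-6-1 cascade network that produces the final contact
probability. Per-range decision thresholds turn probabilities into calls.

The range partition, minimum sequence separations and default thresholds
ship as::

    range        51-70  71-90  91-130  131-190  191-290  291-450
    separation     6      7      10       13       17       21
    threshold     0.1    0.6    0.7      0.7      0.8      0.9
"""

from __future__ import annotations

import hashlib
import json
import os
from dataclasses import dataclass, field

import numpy as np

from . import neural_net as nn
from .pair_encoder import AlignmentFeatures, TOTAL_LENGTH, _as_features, encode_pairs
from .structure_io import ContactMap, separation_mask

BUNDLE_FORMAT_TAG = "contactcascade-bundle-v1"

DEFAULT_RANGES = ((51, 70), (71, 90), (91, 130), (131, 190), (191, 290), (291, 450))
DEFAULT_SEPARATIONS = (6, 7, 10, 13, 17, 21)
DEFAULT_THRESHOLDS = (0.1, 0.6, 0.7, 0.7, 0.8, 0.9)


class CascadeError(ValueError):
    pass


@dataclass(frozen=True)
class LengthPartition:
    """Contiguous length ranges with per-range separation and threshold."""

    ranges: tuple[tuple[int, int], ...] = DEFAULT_RANGES
    separations: tuple[int, ...] = DEFAULT_SEPARATIONS
    thresholds: tuple[float, ...] = DEFAULT_THRESHOLDS

    def __post_init__(self) -> None:
        if not (len(self.ranges) == len(self.separations) == len(self.thresholds)):
            raise CascadeError("partition fields disagree in length")
        for (lo1, hi1), (lo2, _hi2) in zip(self.ranges, self.ranges[1:]):
            if lo1 > hi1 or lo2 != hi1 + 1:
                raise CascadeError("ranges must be contiguous and non-overlapping")
        if any(s <= 0 for s in self.separations):
            raise CascadeError("separations must be positive")
        if any(a > b for a, b in zip(self.separations, self.separations[1:])):
            raise CascadeError("separations must be non-decreasing")

    @property
    def n_ranges(self) -> int:
        return len(self.ranges)

    @property
    def min_length(self) -> int:
        return self.ranges[0][0]

    @property
    def max_length(self) -> int:
        return self.ranges[-1][1]

    def midpoints(self) -> np.ndarray:
        return np.array([(lo + hi) / 2.0 for lo, hi in self.ranges])

    def to_dict(self) -> dict:
        return {
            "ranges": [list(r) for r in self.ranges],
            "separations": list(self.separations),
            "thresholds": list(self.thresholds),
        }

    @classmethod
    def from_dict(cls, obj: dict) -> "LengthPartition":
        return cls(
            ranges=tuple(tuple(r) for r in obj["ranges"]),
            separations=tuple(obj["separations"]),
            thresholds=tuple(obj["thresholds"]),
        )


def route(length: int, partition: LengthPartition | None = None) -> int:
    """Sub-network id (1-based) whose length range contains ``length``."""
    partition = partition or LengthPartition()
    for sid, (lo, hi) in enumerate(partition.ranges, start=1):
        if lo <= length <= hi:
            return sid
    raise CascadeError(
        f"unsupported length: {length} outside "
        f"[{partition.min_length}, {partition.max_length}]"
    )


def corresponding_subnets(
    sid: int, partition: LengthPartition | None = None
) -> tuple[int, ...]:
    """The consulted sub-networks (left-next, own, right-next), clamped at
    the partition edges."""
    partition = partition or LengthPartition()
    if not 1 <= sid <= partition.n_ranges:
        raise CascadeError(f"bad sub-network id: {sid}")
    return tuple(
        s for s in (sid - 1, sid, sid + 1) if 1 <= s <= partition.n_ranges
    )


def balance_weights(
    length: int, partition: LengthPartition | None = None
) -> tuple[float, float, float]:
    """(left, own, right) mixing weights for a protein of ``length``.

    Each consulted sub-network is weighted inversely to the distance from
    the protein length to its range midpoint (1/(1+d)); a missing
    neighbour gets weight 0; weights are renormalised to sum to 1.
    """
    partition = partition or LengthPartition()
    sid = route(length, partition)
    mids = partition.midpoints()
    raw = []
    for s in (sid - 1, sid, sid + 1):
        if 1 <= s <= partition.n_ranges:
            raw.append(1.0 / (1.0 + abs(length - mids[s - 1])))
        else:
            raw.append(0.0)
    total = sum(raw)
    return tuple(w / total for w in raw)


def cascade_input(
    subnet_probs: dict[int, float],
    weights: tuple[float, float, float],
    slotting: str = "id_slots",
    n_subnets: int = 6,
) -> np.ndarray:
    """Assemble one 9-element cascade input vector.

    ``id_slots`` (default): positions 1..6 hold each consulted
    sub-network's output at its own id slot, zeros elsewhere. ``packed``:
    consulted outputs fill the first slots in id order. Positions 7..9
    always hold the (left, own, right) balance weights.
    """
    if not subnet_probs:
        raise CascadeError("empty cascade input: no consulted sub-network")
    vec = np.zeros(n_subnets + 3)
    if slotting == "id_slots":
        for sid, p in subnet_probs.items():
            vec[sid - 1] = p
    elif slotting == "packed":
        for slot, sid in enumerate(sorted(subnet_probs)):
            vec[slot] = subnet_probs[sid]
    else:
        raise CascadeError(f"unknown slotting: {slotting!r}")
    vec[n_subnets:] = weights
    return vec


def quantile_grid(probabilities, n_steps: int = 10) -> np.ndarray:
    """Threshold grid at the inner quantiles of a score sample.

    Each step between consecutive grid points then carries an equal share
    of the predictions, so the coverage-knee search responds to where the
    true contacts concentrate rather than to the absolute score scale.
    """
    probs = np.asarray(probabilities, dtype=float)
    qs = np.quantile(probs, np.linspace(0.0, 1.0, n_steps + 1)[1:-1])
    return np.unique(qs)


def optimize_threshold(
    probabilities, truths, grid=None
) -> float:
    """Pick the decision threshold at the knee of the coverage profile.

    Coverage is computed at every grid threshold (ascending); the chosen
    threshold is the largest one *before* the biggest single-step coverage
    drop, ties broken toward the smaller threshold. This captures the
    observation that coverage collapses once the threshold passes a
    range-specific value.
    """
    probs = np.asarray(probabilities, dtype=float)
    y = np.asarray(truths, dtype=bool)
    if grid is None:
        grid = np.round(np.arange(0.05, 0.96, 0.05), 10)
    grid = np.asarray(grid, dtype=float)
    if np.any(np.diff(grid) <= 0):
        raise CascadeError("grid must be sorted ascending")
    if y.all() or (~y).all():
        raise CascadeError("cannot optimize: degenerate truths")
    n_obs = int(y.sum())
    cov = np.array([(probs[y] >= t).sum() / n_obs for t in grid])
    if len(grid) < 2:
        return float(grid[0])
    drops = cov[:-1] - cov[1:]
    knee = int(np.argmax(drops))  # argmax returns first max -> smaller threshold
    return float(grid[knee])


@dataclass
class PredictionMap:
    """Per-pair contact probabilities for one protein, plus calls.

    ``pairs`` are 1-based (i, j), i < j, restricted to the routed range's
    separation mask; ``calls`` are the pairs with probability >= threshold.
    The map is symmetric by construction (each unordered pair appears once).
    """

    length: int
    pairs: list[tuple[int, int]]
    probabilities: np.ndarray
    threshold: float
    subnet_id: int = 0
    separation: int = 0
    subnet_probabilities: dict[int, np.ndarray] = field(default_factory=dict)
    name: str = ""

    @property
    def calls(self) -> list[tuple[int, int]]:
        return [
            pair
            for pair, p in zip(self.pairs, self.probabilities)
            if p >= self.threshold
        ]

    def to_rr(self, name: str | None = None) -> str:
        """CASP RR-style text: ``i j 0 8 p`` lines under a PFRMAT header."""
        lines = ["PFRMAT RR"]
        lines.append(f"TARGET {name or self.name or 'unknown'}")
        lines.append("MODEL 1")
        order = np.argsort(-self.probabilities, kind="stable")
        for idx in order:
            i, j = self.pairs[idx]
            lines.append(f"{i} {j} 0 8 {self.probabilities[idx]:.6f}")
        lines.append("END")
        return "\n".join(lines) + "\n"

    def calls_tsv(self) -> str:
        return "\n".join(f"{i}\t{j}" for i, j in self.calls) + "\n"


def read_rr(text: str, threshold: float = 0.5, name: str = "") -> PredictionMap:
    """Parse RR-dialect text back into a (model-free) PredictionMap."""
    pairs, probs = [], []
    target = name
    for line in text.splitlines():
        line = line.strip()
        if not line:
            continue
        if line.startswith(("PFRMAT", "MODEL", "END", "REMARK", "AUTHOR", "METHOD")):
            continue
        if line.startswith("TARGET"):
            parts = line.split(maxsplit=1)
            target = parts[1] if len(parts) > 1 else target
            continue
        parts = line.split()
        if len(parts) >= 5:
            i, j = int(parts[0]), int(parts[1])
            pairs.append((min(i, j), max(i, j)))
            probs.append(float(parts[4]))
    n = max((j for _i, j in pairs), default=0)
    return PredictionMap(
        length=n, pairs=pairs, probabilities=np.array(probs),
        threshold=threshold, name=target,
    )


@dataclass
class ProteinSample:
    """One protein of a (training or test) data set."""

    name: str
    alignment: object  # msa_features.Alignment
    contact_map: ContactMap
    chain: object = None  # optional structure_io.ChainRecord

    @property
    def length(self) -> int:
        return self.contact_map.length


@dataclass
class BundleTrainConfig:
    """Orchestration settings for training the six sub-networks + cascade.

    ``n_train_per_range`` mirrors the protocol of training each
    sub-network on a fixed number of randomly selected chains of its
    range. ``max_pairs_per_subnet`` caps the balanced training set, which
    bounds both memory and epoch cost for long chains.
    """

    n_train_per_range: int = 50
    max_pairs_per_subnet: int | None = 6000
    subnet_config: nn.TrainConfig = field(
        default_factory=lambda: nn.TrainConfig(max_epochs=300)
    )
    cascade_config: nn.TrainConfig = field(
        default_factory=lambda: nn.TrainConfig(max_epochs=400)
    )
    balance_factor: float = 1.0
    optimize_thresholds: bool = True
    #: explicit ascending grid, or None for a per-range quantile grid
    threshold_grid: tuple[float, ...] | None = None
    segment_scheme: str = "midpoint_pairs"
    slotting: str = "id_slots"
    chunk_size: int = 20000
    seed: int = 0


@dataclass
class CascadeBundle:
    """Six trained sub-networks plus the cascade net and routing metadata.

    ``subnet_thresholds`` apply when a sub-network's raw output is
    thresholded directly; ``cascade_thresholds`` apply to the cascade
    output of proteins routed to each range. Both default to the shipped
    per-range thresholds.
    """

    subnets: dict[int, nn.NetworkModel]
    cascade: nn.NetworkModel
    partition: LengthPartition = field(default_factory=LengthPartition)
    subnet_thresholds: tuple[float, ...] = DEFAULT_THRESHOLDS
    cascade_thresholds: tuple[float, ...] = DEFAULT_THRESHOLDS
    segment_scheme: str = "midpoint_pairs"
    slotting: str = "id_slots"
    seed: int = 0

    def __post_init__(self) -> None:
        if set(self.subnets) != set(range(1, self.partition.n_ranges + 1)):
            raise CascadeError(
                f"expected sub-networks 1..{self.partition.n_ranges}"
            )
        if self.cascade.layer_sizes[0] != self.partition.n_ranges + 3:
            raise CascadeError("cascade input width must be n_ranges + 3")

    @property
    def trained(self) -> bool:
        return self.cascade.trained and all(m.trained for m in self.subnets.values())

    # -- prediction -----------------------------------------------------

    def predict_map(
        self,
        features,
        n_residues: int | None = None,
        threshold: float | None = None,
        name: str = "",
        require_trained: bool = True,
    ) -> PredictionMap:
        """Final cascade probability for every masked pair of one protein.

        The routed range's separation mask defines the pair set; the
        consulted sub-networks (own, left, right) score that same set.
        Deterministic given a trained bundle.
        """
        if require_trained and not self.trained:
            raise CascadeError("model not trained")
        feat = _as_features(features)
        n = int(n_residues) if n_residues is not None else feat.length
        sid = route(n, self.partition)
        sep = self.partition.separations[sid - 1]
        pairs = separation_mask(n, sep)
        consulted = corresponding_subnets(sid, self.partition)
        weights = balance_weights(n, self.partition)
        thr = (
            float(threshold)
            if threshold is not None
            else self.cascade_thresholds[sid - 1]
        )

        pair_arr = np.asarray(pairs, dtype=np.int64).reshape(-1, 2)
        subnet_probs = {s: np.empty(len(pairs)) for s in consulted}
        final = np.empty(len(pairs))
        chunk = 20000
        for lo in range(0, len(pairs), chunk):
            block = pair_arr[lo : lo + chunk]
            enc = encode_pairs(feat, block, n, segment_scheme=self.segment_scheme)
            casc_in = np.zeros((len(block), self.partition.n_ranges + 3))
            for s in consulted:
                p = nn.forward(self.subnets[s], enc)
                subnet_probs[s][lo : lo + len(block)] = p
                if self.slotting == "id_slots":
                    casc_in[:, s - 1] = p
            if self.slotting == "packed":
                for slot, s in enumerate(sorted(consulted)):
                    casc_in[:, slot] = subnet_probs[s][lo : lo + len(block)]
            casc_in[:, self.partition.n_ranges :] = weights
            final[lo : lo + len(block)] = nn.forward(self.cascade, casc_in)
        return PredictionMap(
            length=n,
            pairs=pairs,
            probabilities=final,
            threshold=thr,
            subnet_id=sid,
            separation=sep,
            subnet_probabilities=subnet_probs,
            name=name,
        )

    # -- persistence ----------------------------------------------------

    def save(self, directory: str) -> None:
        os.makedirs(directory, exist_ok=True)
        for sid, model in self.subnets.items():
            with open(os.path.join(directory, f"subnet_{sid}.json"), "w") as fh:
                fh.write(model.to_json())
        with open(os.path.join(directory, "cascade.json"), "w") as fh:
            fh.write(self.cascade.to_json())
        manifest = {
            "format": BUNDLE_FORMAT_TAG,
            "partition": self.partition.to_dict(),
            "subnet_thresholds": list(self.subnet_thresholds),
            "cascade_thresholds": list(self.cascade_thresholds),
            "segment_scheme": self.segment_scheme,
            "slotting": self.slotting,
            "seed": self.seed,
        }
        blob = json.dumps(manifest, indent=2, sort_keys=True)
        manifest["manifest_sha256"] = hashlib.sha256(blob.encode()).hexdigest()
        with open(os.path.join(directory, "manifest.json"), "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)

    @classmethod
    def load(cls, directory: str) -> "CascadeBundle":
        with open(os.path.join(directory, "manifest.json")) as fh:
            manifest = json.load(fh)
        if manifest.get("format") != BUNDLE_FORMAT_TAG:
            raise CascadeError(f"unknown bundle format: {manifest.get('format')!r}")
        partition = LengthPartition.from_dict(manifest["partition"])
        subnets = {}
        for sid in range(1, partition.n_ranges + 1):
            with open(os.path.join(directory, f"subnet_{sid}.json")) as fh:
                subnets[sid] = nn.NetworkModel.from_json(fh.read())
        with open(os.path.join(directory, "cascade.json")) as fh:
            cascade = nn.NetworkModel.from_json(fh.read())
        return cls(
            subnets=subnets,
            cascade=cascade,
            partition=partition,
            subnet_thresholds=tuple(manifest["subnet_thresholds"]),
            cascade_thresholds=tuple(manifest["cascade_thresholds"]),
            segment_scheme=manifest["segment_scheme"],
            slotting=manifest["slotting"],
            seed=int(manifest["seed"]),
        )


def _protein_labels(sample: ProteinSample, pairs: list[tuple[int, int]]) -> np.ndarray:
    cells = sample.contact_map.cells
    arr = np.asarray(pairs, dtype=np.int64)
    return cells[arr[:, 0] - 1, arr[:, 1] - 1].astype(bool)


def train_bundle(
    dataset: list[ProteinSample],
    config: BundleTrainConfig | None = None,
    partition: LengthPartition | None = None,
) -> tuple[CascadeBundle, dict]:
    """Train the full 6+1 topology on a data set of protein samples.

    Each sub-network trains on up to ``n_train_per_range`` randomly
    selected proteins of its range, on a class-balanced sample of their
    separation-masked pairs. The cascade net then trains on the consulted
    sub-networks' outputs plus balance weights over the same proteins.
    Per-range thresholds are refined at the coverage knee when
    ``optimize_thresholds`` is set. Returns (bundle, training report).
    """
    config = config or BundleTrainConfig()
    partition = partition or LengthPartition()
    rng = np.random.default_rng(config.seed)

    by_range: dict[int, list[ProteinSample]] = {
        sid: [] for sid in range(1, partition.n_ranges + 1)
    }
    for sample in dataset:
        by_range[route(sample.length, partition)].append(sample)
    for sid, group in by_range.items():
        if not group:
            lo, hi = partition.ranges[sid - 1]
            raise CascadeError(f"empty range {sid} ({lo}-{hi}): no training protein")

    report: dict = {"per_range": {}, "seed": config.seed}
    chosen: dict[int, list[ProteinSample]] = {}
    for sid, group in by_range.items():
        k = min(config.n_train_per_range, len(group))
        idx = rng.choice(len(group), size=k, replace=False)
        chosen[sid] = [group[t] for t in sorted(idx)]

    feats_cache: dict[str, AlignmentFeatures] = {}

    def feats(sample: ProteinSample) -> AlignmentFeatures:
        if sample.name not in feats_cache:
            feats_cache[sample.name] = _as_features(sample.alignment)
        return feats_cache[sample.name]

    # 1) train each sub-network on balanced pairs of its own range
    subnets: dict[int, nn.NetworkModel] = {}
    for sid in range(1, partition.n_ranges + 1):
        sep = partition.separations[sid - 1]
        enc_blocks, label_blocks = [], []
        for sample in chosen[sid]:
            pairs = separation_mask(sample.length, sep)
            labels = _protein_labels(sample, pairs)
            if labels.all() or (~labels).all():
                continue  # nothing to balance on this chain
            sel = nn.balanced_sample(
                labels, factor=config.balance_factor,
                seed=int(rng.integers(2**31)),
            )
            arr = np.asarray(pairs, dtype=np.int64)[sel]
            enc_blocks.append(
                encode_pairs(feats(sample), arr, sample.length,
                             segment_scheme=config.segment_scheme)
            )
            label_blocks.append(labels[sel])
        if not enc_blocks:
            raise CascadeError(f"empty range {sid}: no trainable pairs")
        x = np.vstack(enc_blocks)
        y = np.concatenate(label_blocks)
        if config.max_pairs_per_subnet and len(y) > config.max_pairs_per_subnet:
            keep = nn.balanced_sample(
                y, factor=config.max_pairs_per_subnet / len(y),
                seed=int(rng.integers(2**31)),
            )
            x, y = x[keep], y[keep]
        sub_cfg = nn.TrainConfig(**{
            **config.subnet_config.to_dict(), "seed": config.seed * 1000 + sid,
        })
        model = nn.init_network((TOTAL_LENGTH, 5, 1), seed=sub_cfg.seed)
        model, history = nn.train(model, x, y, sub_cfg)
        subnets[sid] = model
        report["per_range"][sid] = {
            "n_train_proteins": len(chosen[sid]),
            "n_train_pairs": int(len(y)),
            "final_loss": history[-1] if history else None,
        }

    # 2) one full prediction pass per training protein (all consulted nets)
    bundle = CascadeBundle(
        subnets=subnets,
        cascade=nn.init_network((partition.n_ranges + 3, 6, 1),
                                seed=config.seed * 1000 + 7),
        partition=partition,
        segment_scheme=config.segment_scheme,
        slotting=config.slotting,
        seed=config.seed,
    )
    passes = []  # (sid, labels, subnet_probs dict, weights)
    for sid in range(1, partition.n_ranges + 1):
        for sample in chosen[sid]:
            pm = bundle.predict_map(
                feats(sample), sample.length, name=sample.name,
                require_trained=False,
            )
            labels = _protein_labels(sample, pm.pairs)
            passes.append((sid, labels, pm.subnet_probabilities,
                           balance_weights(sample.length, partition)))

    # 3) per-range sub-network thresholds at the coverage knee
    subnet_thresholds = list(partition.thresholds)
    if config.optimize_thresholds:
        for sid in range(1, partition.n_ranges + 1):
            probs = np.concatenate(
                [sp[sid] for s, lab, sp, _w in passes if s == sid]
            )
            truths = np.concatenate(
                [lab for s, lab, _sp, _w in passes if s == sid]
            )
            if truths.any() and not truths.all():
                grid = (config.threshold_grid if config.threshold_grid is not None
                        else quantile_grid(probs))
                if len(grid) >= 2:
                    subnet_thresholds[sid - 1] = optimize_threshold(
                        probs, truths, grid
                    )

    # 4) train the cascade on slotted sub-network outputs + balance weights
    casc_x, casc_y, casc_sid = [], [], []
    for sid, labels, sp, weights in passes:
        block = np.zeros((len(labels), partition.n_ranges + 3))
        if config.slotting == "id_slots":
            for s, p in sp.items():
                block[:, s - 1] = p
        else:
            for slot, s in enumerate(sorted(sp)):
                block[:, slot] = sp[s]
        block[:, partition.n_ranges :] = weights
        casc_x.append(block)
        casc_y.append(labels)
        casc_sid.append(np.full(len(labels), sid))
    casc_x = np.vstack(casc_x)
    casc_y = np.concatenate(casc_y)
    casc_sid = np.concatenate(casc_sid)
    sel = nn.balanced_sample(
        casc_y, factor=config.balance_factor, seed=int(rng.integers(2**31))
    )
    casc_cfg = nn.TrainConfig(**{
        **config.cascade_config.to_dict(), "seed": config.seed * 1000 + 8,
    })
    cascade, casc_hist = nn.train(bundle.cascade, casc_x[sel], casc_y[sel], casc_cfg)
    bundle.cascade = cascade
    report["cascade"] = {
        "n_train_pairs": int(len(sel)),
        "final_loss": casc_hist[-1] if casc_hist else None,
    }

    # 5) per-range cascade thresholds at the coverage knee
    cascade_thresholds = list(partition.thresholds)
    if config.optimize_thresholds:
        casc_p = nn.forward(cascade, casc_x)
        for sid in range(1, partition.n_ranges + 1):
            mask = casc_sid == sid
            truths = casc_y[mask]
            if truths.any() and not truths.all():
                grid = (config.threshold_grid if config.threshold_grid is not None
                        else quantile_grid(casc_p[mask]))
                if len(grid) >= 2:
                    cascade_thresholds[sid - 1] = optimize_threshold(
                        casc_p[mask], truths, grid
                    )
    bundle.subnet_thresholds = tuple(subnet_thresholds)
    bundle.cascade_thresholds = tuple(cascade_thresholds)
    report["subnet_thresholds"] = subnet_thresholds
    report["cascade_thresholds"] = cascade_thresholds
    return bundle, report
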