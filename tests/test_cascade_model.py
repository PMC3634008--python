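import numpy as np
import pytest

from contactcascade import neural_net as nn
from contactcascade.cascade_model import (
    BundleTrainConfig,
    CascadeBundle,
    CascadeError,
    DEFAULT_SEPARATIONS,
    DEFAULT_THRESHOLDS,
    LengthPartition,
    balance_weights,
    cascade_input,
    corresponding_subnets,
    optimize_threshold,
    quantile_grid,
    read_rr,
    route,
    train_bundle,
)
from contactcascade.synthetic_data import SyntheticSpec, synth_dataset, synth_msa


class TestRouting:
    def test_every_length_maps_to_exactly_one_range(self):
        part = LengthPartition()
        for length in range(51, 451):
            sid = route(length, part)
            lo, hi = part.ranges[sid - 1]
            assert lo <= length <= hi
            assert sum(1 for a, b in part.ranges if a <= length <= b) == 1

    @pytest.mark.parametrize("length,sid", [(100, 3), (51, 1), (450, 6),
                                            (70, 1), (291, 6)])
    def test_examples(self, length, sid):
        assert route(length) == sid

    @pytest.mark.parametrize("length", [50, 451, 0])
    def test_out_of_range(self, length):
        with pytest.raises(CascadeError, match="unsupported length"):
            route(length)


class TestCorrespondingSubnets:
    @pytest.mark.parametrize("sid,expect", [(3, (2, 3, 4)), (1, (1, 2)),
                                            (6, (5, 6)), (2, (1, 2, 3))])
    def test_neighbours_clamped(self, sid, expect):
        assert corresponding_subnets(sid) == expect


class TestBalanceWeights:
    def test_sum_to_one(self):
        for length in (51, 70, 100, 250, 449):
            assert sum(balance_weights(length)) == pytest.approx(1.0, abs=1e-12)

    def test_own_weight_greatest_at_midpoint(self):
        left, own, right = balance_weights(110)  # midpoint of 91-130
        assert own > left and own > right

    def test_right_neighbour_grows_toward_range_top(self):
        assert balance_weights(70)[2] > balance_weights(51)[2]

    def test_missing_neighbour_gets_zero(self):
        assert balance_weights(60)[0] == 0.0
        assert balance_weights(440)[2] == 0.0


class TestCascadeInput:
    def test_slotted_assembly(self):
        vec = cascade_input({2: 0.4, 3: 0.9, 4: 0.5}, (0.2, 0.6, 0.2))
        np.testing.assert_allclose(vec, [0, 0.4, 0.9, 0.5, 0, 0, 0.2, 0.6, 0.2])

    def test_edge_routing_leaves_far_slots_zero(self):
        vec = cascade_input({1: 0.7, 2: 0.6}, (0.0, 0.8, 0.2))
        assert vec[2:6].sum() == 0
        assert vec[6] == 0.0
        assert len(vec) == 9

    def test_packed_variant(self):
        vec = cascade_input({2: 0.4, 3: 0.9}, (0.5, 0.5, 0.0), slotting="packed")
        np.testing.assert_allclose(vec[:3], [0.4, 0.9, 0.0])

    def test_empty_raises(self):
        with pytest.raises(CascadeError, match="empty cascade input"):
            cascade_input({}, (0, 1, 0))


class TestOptimizeThreshold:
    def _profile_data(self, grid, coverages, n_pos=100):
        """Positive scores realising a given coverage profile over a grid."""
        probs, truths = [], []
        prev = 1.0
        bounds = list(grid) + [1.01]
        # place positives so that fraction cov[m] of them score >= grid[m]
        for m, cov in enumerate(coverages):
            n_here = int(round((prev - cov) * n_pos))
            probs += [grid[m] - 0.01] * n_here
            truths += [1] * n_here
            prev = cov
        n_top = n_pos - len(probs)
        probs += [1.0] * n_top
        truths += [1] * n_top
        probs += [0.0] * 20
        truths += [0] * 20
        return probs, truths

    def test_knee_found_by_brute_force_profile(self):
        grid = (0.1, 0.3, 0.5, 0.7, 0.9)
        probs, truths = self._profile_data(grid, (0.90, 0.88, 0.85, 0.30, 0.05))
        assert optimize_threshold(probs, truths, grid) == pytest.approx(0.5)

    def test_linear_decline_ties_to_smallest(self):
        grid = (0.2, 0.4, 0.6, 0.8)
        probs, truths = self._profile_data(grid, (0.8, 0.6, 0.4, 0.2))
        assert optimize_threshold(probs, truths, grid) == pytest.approx(0.2)

    def test_degenerate_truths_raise(self):
        with pytest.raises(CascadeError, match="cannot optimize"):
            optimize_threshold([0.5, 0.6], [1, 1], (0.1, 0.9))

    def test_quantile_grid_is_ascending_and_inner(self):
        rng = np.random.default_rng(0)
        grid = quantile_grid(rng.uniform(size=1000))
        assert np.all(np.diff(grid) > 0)
        assert len(grid) == 9


class TestShippedConstants:
    def test_partition_defaults_round_trip(self):
        part = LengthPartition()
        assert part.ranges == ((51, 70), (71, 90), (91, 130), (131, 190),
                               (191, 290), (291, 450))
        assert part.separations == (6, 7, 10, 13, 17, 21)
        assert part.thresholds == (0.1, 0.6, 0.7, 0.7, 0.8, 0.9)
        assert LengthPartition.from_dict(part.to_dict()) == part

    def test_bundle_save_load_round_trip(self, stub_bundle, tmp_path):
        stub_bundle.save(str(tmp_path / "bundle"))
        loaded = CascadeBundle.load(str(tmp_path / "bundle"))
        assert loaded.partition == stub_bundle.partition
        assert loaded.subnet_thresholds == DEFAULT_THRESHOLDS
        assert loaded.cascade_thresholds == DEFAULT_THRESHOLDS
        for sid in range(1, 7):
            np.testing.assert_array_equal(
                loaded.subnets[sid].w1, stub_bundle.subnets[sid].w1
            )
        np.testing.assert_array_equal(loaded.cascade.w2, stub_bundle.cascade.w2)


def _msa_for_length(n, seed=0):
    rng = np.random.default_rng(seed)
    target = "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), size=n))
    return synth_msa(target, n_rows=6, mutation_rate=0.2, seed=seed)


class TestPredictMap:
    def test_pairs_respect_routed_separation(self, stub_bundle):
        pm = stub_bundle.predict_map(_msa_for_length(60), 60)
        assert pm.subnet_id == 1 and pm.separation == 6
        assert all(j - i >= 6 for i, j in pm.pairs)
        assert len(pm.pairs) == len(pm.probabilities)
        assert set(pm.subnet_probabilities) == {1, 2}

    def test_constant_stub_propagates_half(self, constant_bundle):
        pm = constant_bundle.predict_map(_msa_for_length(55, seed=1), 55)
        np.testing.assert_allclose(pm.probabilities, 0.5)

    def test_deterministic_rerun(self, stub_bundle):
        a = stub_bundle.predict_map(_msa_for_length(60, seed=2), 60)
        b = stub_bundle.predict_map(_msa_for_length(60, seed=2), 60)
        np.testing.assert_array_equal(a.probabilities, b.probabilities)
        assert a.pairs == b.pairs

    def test_untrained_bundle_raises(self, stub_bundle):
        untrained = CascadeBundle(
            subnets=stub_bundle.subnets,
            cascade=nn.init_network((9, 6, 1), seed=0),  # trained=False
            partition=stub_bundle.partition,
        )
        with pytest.raises(CascadeError, match="model not trained"):
            untrained.predict_map(_msa_for_length(60), 60)

    def test_raising_threshold_never_adds_calls(self, stub_bundle):
        pm = stub_bundle.predict_map(_msa_for_length(64, seed=3), 64)
        counts = []
        for thr in (0.1, 0.3, 0.5, 0.7, 0.9):
            pm.threshold = thr
            counts.append(len(pm.calls))
        assert counts == sorted(counts, reverse=True)

    def test_rr_round_trip(self, stub_bundle):
        pm = stub_bundle.predict_map(_msa_for_length(60, seed=4), 60, name="T1")
        back = read_rr(pm.to_rr())
        assert set(back.pairs) == set(pm.pairs)
        assert back.name == "T1"


class TestTrainBundle:
    def test_empty_range_is_reported(self):
        # lengths covering ranges 1-5 only
        spec = SyntheticSpec(lengths=(55, 80, 100, 150, 250), msa_rows=4,
                             seed=1)
        samples = synth_dataset(spec)
        with pytest.raises(CascadeError, match="empty range 6"):
            train_bundle(samples, BundleTrainConfig(seed=0))

    def test_micro_training_run_produces_trained_bundle(self):
        lengths = (55, 62, 75, 85, 95, 120, 140, 180, 200, 280, 300, 420)
        spec = SyntheticSpec(lengths=lengths, msa_rows=6, seed=3)
        samples = synth_dataset(spec)
        cfg = BundleTrainConfig(
            n_train_per_range=2, max_pairs_per_subnet=400,
            subnet_config=nn.TrainConfig(max_epochs=8, seed=0),
            cascade_config=nn.TrainConfig(max_epochs=8, seed=0),
            seed=0,
        )
        bundle, report = train_bundle(samples, cfg)
        assert bundle.trained
        assert set(report["per_range"]) == set(range(1, 7))
        # thresholds were refined per range on the training pool
        assert len(bundle.subnet_thresholds) == 6
        assert len(bundle.cascade_thresholds) == 6
        pm = bundle.predict_map(samples[0].alignment, samples[0].length)
        assert np.all((pm.probabilities > 0) & (pm.probabilities < 1))
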