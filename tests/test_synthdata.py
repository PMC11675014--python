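"""Synthetic generators: schedules, simulators, degradation, null."""

import numpy as np
import pytest

from neuromapper import (SimulatorConfig, add_noise, g_schedule,
                         modular_connectome, shuffle_blocks, simulate_wc_bold,
                         smooth_downsample, synth_circular_bold, task_paradigm,
                         trefoil_knot)


class TestGSchedule:
    def test_default_duration_samples_segments(self):
        G, labels = g_schedule()
        assert labels.boundaries[-1] + 200.0 == pytest.approx(1200.0)
        assert G.size == 1667
        assert labels.n == 1667
        assert len(labels.boundaries) == 8
        vals, counts = np.unique(labels.labels, return_counts=True)
        assert set(vals) == {"stable-low", "transition-up", "stable-high",
                             "transition-down"}

    def test_two_segments_of_each_type(self):
        _, labels = g_schedule()
        # count maximal runs per state
        runs = []
        for lab, prev in zip(labels.labels, np.roll(labels.labels, 1)):
            if lab != prev:
                runs.append(lab)
        runs[0] = labels.labels[0]
        assert len(runs) == 8
        for state in ("stable-low", "transition-up", "stable-high",
                      "transition-down"):
            assert runs.count(state) == 2

    def test_g_constant_on_stable_monotone_on_transitions(self):
        G, labels = g_schedule()
        for state, seg in (("stable-low", None), ("stable-high", None)):
            vals = G[labels.labels == state]
            assert np.ptp(vals) == 0
        up = G[labels.labels == "transition-up"]
        down = G[labels.labels == "transition-down"]
        half = up.size // 2
        assert np.all(np.diff(up[:half]) > 0)
        assert np.all(np.diff(down[:half]) < 0)

    def test_bad_tr_rejected(self):
        with pytest.raises(ValueError):
            g_schedule(tr=0.0)


class TestTaskParadigm:
    def test_total_duration_25min24s(self):
        labels = task_paradigm()
        total = labels.boundaries[-1] + 180.0   # last segment is a block
        assert total == pytest.approx(1524.0)   # 25 min 24 s
        assert total == 25 * 60 + 24

    def test_eight_blocks_seven_instructions(self):
        labels = task_paradigm()
        states = [labels.labels[0]]
        for lab in labels.labels[1:]:
            if lab != states[-1]:
                states.append(lab)
        assert states.count("instruction") == 7
        assert len([s for s in states if s != "instruction"]) == 8


class TestSimulator:
    def test_output_shape_and_label_rows(self):
        G, labels = g_schedule(stable_s=10, trans_s=20)
        cfg = SimulatorConfig(n_nodes=8, seed=2)
        data = simulate_wc_bold(cfg, G, labels)
        assert data.values.shape == (G.size, 8)
        assert np.array_equal(data.labels, labels.labels)

    def test_seed_determinism(self):
        G, labels = g_schedule(stable_s=10, trans_s=20)
        a = simulate_wc_bold(SimulatorConfig(n_nodes=6, seed=9), G, labels)
        b = simulate_wc_bold(SimulatorConfig(n_nodes=6, seed=9), G, labels)
        assert np.array_equal(a.values, b.values)

    def test_noiseless_constant_g_converges(self):
        G, labels = g_schedule(stable_s=20, trans_s=20, cycles=1)
        Gc = np.full_like(G, 2.0)
        cfg = SimulatorConfig(n_nodes=8, noise_sd=0.0, hrf="none")
        data = simulate_wc_bold(cfg, Gc, labels)
        assert np.linalg.norm(data.values[-1] - data.values[-2]) < 1e-6

    def test_connectome_properties(self):
        C = modular_connectome(20, seed=4)
        assert C.shape == (20, 20)
        assert np.allclose(np.diag(C), 0)
        assert np.all(C >= 0)


class TestCircularGenerator:
    def test_closed_loop_noiseless(self):
        _, labels = g_schedule(tr=2.0)
        data = synth_circular_bold(n_features=10, schedule=labels,
                                   noise_sd=0.0, seed=0)
        step = np.linalg.norm(np.diff(data.values, axis=0), axis=1).max()
        wrap = np.linalg.norm(data.values[0] - data.values[-1])
        assert wrap <= step + 1e-9

    def test_arcs_separated(self):
        _, labels = g_schedule(tr=2.0)
        sep = 1.5
        data = synth_circular_bold(n_features=12, schedule=labels,
                                   arc_separation=sep, noise_sd=0.0, seed=0)
        up = data.values[data.labels == "transition-up"]
        down = data.values[data.labels == "transition-down"]
        mid_up = up[len(up) // 4]       # mid of first up arc (two arcs stacked)
        mid_down = down[len(down) // 4]
        assert np.linalg.norm(mid_up - mid_down) >= sep - 1e-9

    def test_labels_attached(self):
        data = synth_circular_bold(n_features=5, seed=1)
        assert data.labels is not None and len(data.labels) == data.n_timepoints


class TestTrefoil:
    def test_shape_and_exact_parameterization(self):
        data, t = trefoil_knot(n=100, noise_sd=0.0)
        assert data.values.shape == (100, 3)
        x = np.sin(t) + 2 * np.sin(2 * t)
        assert np.allclose(data.values[:, 0], x)
        assert np.allclose(data.values[:, 2], -np.sin(3 * t))

    def test_minimum_points(self):
        with pytest.raises(ValueError):
            trefoil_knot(n=5)


class TestAddNoise:
    def make_signal(self, n=10_000, m=4, seed=0):
        rng = np.random.default_rng(seed)
        t = np.linspace(0, 40 * np.pi, n)
        X = np.column_stack([np.sin(t * (j + 1)) for j in range(m)])
        from neuromapper import DataMatrix
        return DataMatrix(X, tr=1.0)

    def test_snr_half_doubles_amplitude(self):
        data = self.make_signal()
        noisy = add_noise(data, target_snr=0.5, seed=1)
        ratio = (noisy.values - data.values).std(axis=0) / data.values.std(axis=0)
        assert np.all(np.abs(ratio - 2.0) < 0.02)   # within 1%

    @pytest.mark.parametrize("snr", [10.0, 1.0, 0.5])
    def test_measured_ratio_tracks_target(self, snr):
        data = self.make_signal(n=2000)
        noisy = add_noise(data, target_snr=snr, seed=2)
        ratio = (noisy.values - data.values).std(axis=0) / data.values.std(axis=0)
        assert np.all(np.abs(ratio * snr - 1.0) < 0.05)

    def test_infinite_snr_unchanged(self):
        data = self.make_signal(n=100)
        out = add_noise(data, target_snr=np.inf)
        assert np.array_equal(out.values, data.values)

    def test_zero_variance_feature_skipped(self):
        from neuromapper import DataMatrix
        data = DataMatrix(np.column_stack([np.ones(50), np.arange(50.0)]))
        with pytest.warns(UserWarning, match="zero variance"):
            out = add_noise(data, target_snr=1.0, seed=0)
        assert np.array_equal(out.values[:, 0], data.values[:, 0])


class TestSmoothDownsample:
    def test_factor_one_same_length_smoothed(self):
        rng = np.random.default_rng(0)
        from neuromapper import DataMatrix
        data = DataMatrix(rng.standard_normal((60, 2)), tr=0.72)
        out = smooth_downsample(data, factor=1)
        assert out.values.shape == data.values.shape
        assert out.values[:, 0].std() < data.values[:, 0].std()

    def test_counts_and_tr_for_factor_three(self):
        G, labels = g_schedule()
        data = synth_circular_bold(n_features=3, schedule=labels, seed=0)
        out = smooth_downsample(data, factor=3)
        assert out.n_timepoints == 556           # ceil(1667 / 3)
        assert out.tr == pytest.approx(2.16)

    def test_constant_matrix_fixed_point(self):
        from neuromapper import DataMatrix
        data = DataMatrix(np.full((30, 2), 3.5))
        out = smooth_downsample(data, factor=2)
        assert np.allclose(out.values, 3.5)

    def test_factor_bound(self):
        from neuromapper import DataMatrix
        data = DataMatrix(np.zeros((5, 1)))
        with pytest.raises(ValueError):
            smooth_downsample(data, factor=5)


class TestShuffleBlocks:
    def test_rows_are_permutation(self, rng):
        from neuromapper import DataMatrix
        data = DataMatrix(rng.standard_normal((23, 3)))
        out = shuffle_blocks(data, block=7, seed=3)
        a = np.sort(data.values.sum(axis=1))
        b = np.sort(out.values.sum(axis=1))
        assert np.allclose(a, b)

    def test_within_block_order_preserved(self, rng):
        from neuromapper import DataMatrix
        values = np.arange(21.0)[:, None]
        out = shuffle_blocks(DataMatrix(values), block=7, seed=5)
        v = out.values.ravel()
        for start in range(0, 21, 7):
            chunk = v[start:start + 7]
            assert np.all(np.diff(chunk) == 1)

    def test_same_seed_same_permutation_across_matrices(self, rng):
        from neuromapper import DataMatrix
        a = DataMatrix(np.arange(20.0)[:, None])
        b = DataMatrix(np.arange(20.0)[:, None] * 10)
        pa = shuffle_blocks(a, block=4, seed=11).values.ravel()
        pb = shuffle_blocks(b, block=4, seed=11).values.ravel()
        assert np.allclose(pb, pa * 10)
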