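import numpy as np
import pytest

import snncluster as sc
from snncluster.data import Montage
from snncluster.encoding import SpikeRaster
from snncluster.reservoir import LIFParams, ReservoirModel, STDPParams

from conftest import SMALL_GRID


def line_montage():
    return Montage({"a": (0.0, 0.0, 0.0)})


class TestInit:
    def test_zero_radius_no_connections(self):
        model = sc.init_reservoir((3, 3, 3), line_montage(), radius=0.0, seed=0)
        assert not model.connected.any()
        assert not model.w.any()

    def test_collinear_grid_adjacent_pairs_only(self):
        """3 neurons in a line: radius 1.5x spacing connects only adjacent pairs."""
        model = sc.init_reservoir((3, 1, 1), line_montage(), radius=None, seed=0)
        d = np.linalg.norm(model.coords[:, None] - model.coords[None, :], axis=2)
        spacing = np.unique(d[d > 0]).min()
        model = sc.init_reservoir((3, 1, 1), line_montage(), radius=1.5 * spacing, seed=0)
        expected = (d > 0) & (d <= 1.5 * spacing)
        assert np.array_equal(model.connected, expected)
        assert model.connected.sum() == 4  # 2 undirected adjacent pairs

    def test_26_input_neurons_with_default_montage(self):
        model = sc.init_reservoir(SMALL_GRID, seed=0)
        assert model.n_inputs == 26
        assert len(set(model.input_neurons.tolist())) == 26
        F = model.Fsrc
        assert F.shape == (model.n_neurons, 26)
        assert np.array_equal(F.sum(axis=0), np.ones(26))

    def test_colliding_channels_rejected(self):
        # two electrodes much closer than the grid resolution collide
        m = Montage({
            "a": (0.0, 0.0, 0.0), "b": (0.001, 0.0, 0.0), "c": (1.0, 0.0, 0.0),
        })
        with pytest.raises(ValueError):
            sc.init_reservoir((3, 3, 3), m, seed=0)

    def test_deterministic_for_seed(self):
        a = sc.init_reservoir(SMALL_GRID, seed=5)
        b = sc.init_reservoir(SMALL_GRID, seed=5)
        assert np.array_equal(a.w, b.w)

    def test_sign_mix_roughly_80_20(self):
        model = sc.init_reservoir(SMALL_GRID, seed=1)
        w = model.w[model.connected]
        frac_pos = (w > 0).mean()
        assert 0.75 < frac_pos < 0.85

    def test_no_self_connections(self):
        model = sc.init_reservoir(SMALL_GRID, seed=2)
        assert not np.diag(model.connected).any()

    def test_checkpoint_round_trip(self, tmp_path):
        model = sc.init_reservoir(SMALL_GRID, seed=3)
        model.spike_log[1, 2] = 7
        model.save(tmp_path / "m.h5")
        back = ReservoirModel.load(tmp_path / "m.h5")
        assert np.array_equal(back.w, model.w)
        assert np.array_equal(back.spike_log, model.spike_log)
        assert back.channel_names == model.channel_names


class TestLIF:
    def _single(self):
        model = sc.init_reservoir((3, 3, 3), line_montage(), radius=0.0, seed=0)
        return model

    def test_rest_is_fixed_point(self):
        model = self._single()
        p = LIFParams()
        model.reset_state(p.v_rest)
        sc.lif_step(model, np.zeros(model.n_neurons), p)
        assert np.all(model.v_m == p.v_rest)

    def test_hand_euler_step(self):
        """tau=10, dt=1, v_rest=0, R=1, v=0, I=5 -> v' = (1/10)*5 = 0.5."""
        model = self._single()
        p = LIFParams(tau_m=10.0, dt=1.0, v_rest=0.0, R=1.0, theta=1.0, refractory=0)
        model.reset_state(0.0)
        I = np.zeros(model.n_neurons)
        I[0] = 5.0
        sc.lif_step(model, I, p)
        assert model.v_last[0] == pytest.approx(0.5)

    def test_spike_resets_to_rest_and_enters_refractory(self):
        model = self._single()
        p = LIFParams(theta=0.4, refractory=2)
        model.reset_state(0.0)
        I = np.zeros(model.n_neurons)
        I[0] = 10.0
        fired = sc.lif_step(model, I, p)
        assert fired[0] and model.v_m[0] == p.v_rest and model.refrac[0] == 2
        # refractory: does not integrate
        fired = sc.lif_step(model, I, p)
        assert not fired[0] and model.v_m[0] == p.v_rest

    def test_leak_decays_monotonically_to_rest(self):
        model = self._single()
        p = LIFParams(theta=5.0, refractory=0)
        model.reset_state(0.0)
        model.v_m[0] = 2.0
        prev = 2.0
        for _ in range(50):
            sc.lif_step(model, np.zeros(model.n_neurons), p)
            assert model.v_m[0] < prev or model.v_m[0] == pytest.approx(0.0, abs=1e-12)
            assert model.v_m[0] >= 0.0
            prev = model.v_m[0]

    def test_membrane_floor(self):
        model = self._single()
        p = LIFParams(v_min=-0.5, refractory=0)
        model.reset_state(0.0)
        I = np.zeros(model.n_neurons)
        I[0] = -100.0
        sc.lif_step(model, I, p)
        assert model.v_m[0] == -0.5

    def test_non_finite_current_rejected(self):
        model = self._single()
        with pytest.raises(ValueError):
            sc.lif_step(model, np.full(model.n_neurons, np.nan), LIFParams())

    def test_invalid_params(self):
        with pytest.raises(ValueError):
            LIFParams(tau_m=0)
        with pytest.raises(ValueError):
            LIFParams(theta=0.0, v_rest=0.0)


class TestSTDPKernel:
    def test_hand_values(self):
        p = STDPParams(A_plus=0.1, A_minus=0.12, tau_plus=10, tau_minus=10)
        assert sc.stdp_kernel(-10.0, p) == pytest.approx(0.1 * np.exp(-1), abs=1e-12)
        assert sc.stdp_kernel(10.0, p) == pytest.approx(-0.12 * np.exp(-1), abs=1e-12)

    def test_limit_at_zero_minus_is_a_plus(self):
        p = STDPParams(A_plus=0.1, A_minus=0.12)
        assert sc.stdp_kernel(-1e-9, p) == pytest.approx(0.1, rel=1e-6)

    def test_sign_pattern_and_bound(self):
        p = STDPParams(A_plus=0.05, A_minus=0.07)
        dts = np.linspace(-50, 50, 201)
        out = sc.stdp_kernel(dts, p)
        assert np.all(out[dts < 0] > 0)
        assert np.all(out[dts >= 0] <= 0)
        assert np.max(np.abs(out)) <= max(p.A_plus, p.A_minus) + 1e-15

    def test_invalid_params(self):
        with pytest.raises(ValueError):
            STDPParams(A_plus=0)
        with pytest.raises(ValueError):
            STDPParams(w_min=1.0, w_max=-1.0)


class TestTraining:
    def test_zero_rasters_leave_spike_log_untouched(self):
        model = sc.init_reservoir(SMALL_GRID, seed=0)
        raster = SpikeRaster(np.zeros((26, 30), dtype=np.int8), np.zeros(26))
        log = sc.train_unsupervised(model, [raster])
        assert not model.spike_log.any()
        assert log.streamed_points == 30

    def test_streamed_counter_and_bounds(self, trained):
        _, log, rasters, _ = trained
        assert log.streamed_points == sum(r.n_times for r in rasters)
        assert log.sample_bounds[0] == (0, rasters[0].n_times)
        assert log.sample_bounds[-1][1] == log.streamed_points

    def test_weights_stay_within_clip_bounds(self, trained):
        model, _, _, _ = trained
        stdp = STDPParams()
        assert model.w.min() >= stdp.w_min - 1e-12
        assert model.w.max() <= stdp.w_max + 1e-12

    def test_spike_log_diagonal_and_topology(self, trained):
        model, _, _, _ = trained
        assert not np.diag(model.spike_log).any()
        assert np.all(model.spike_log >= 0)
        assert not model.spike_log[~model.connected].any()

    def test_channel_mismatch_rejected(self):
        model = sc.init_reservoir(SMALL_GRID, seed=0)
        raster = SpikeRaster(np.zeros((5, 10), dtype=np.int8), np.zeros(5))
        with pytest.raises(ValueError):
            sc.train_unsupervised(model, [raster])

    def test_training_is_deterministic(self):
        ss = sc.generate_dataset(n_per_class=2, planted=(1,), effect=1.0, seed=9)
        rasters = sc.encode_samples(ss)
        logs = []
        for _ in range(2):
            model = sc.init_reservoir(SMALL_GRID, seed=9)
            logs.append((sc.train_unsupervised(model, rasters), model))
        assert np.array_equal(logs[0][1].w, logs[1][1].w)
        assert np.array_equal(
            logs[0][0].frames[-1].labels, logs[1][0].frames[-1].labels
        )

    def test_replay_does_not_mutate_model(self, trained):
        model, _, rasters, _ = trained
        w0, log0 = model.w.copy(), model.spike_log.copy()
        hist = sc.replay(model, rasters[0])
        assert hist.shape == (rasters[0].n_times, model.n_neurons)
        assert np.array_equal(model.w, w0)
        assert np.array_equal(model.spike_log, log0)
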