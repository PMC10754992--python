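"""bRELU sharpening, detector construction, training and persistence."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import stndetect as sd
from stndetect import sharpnet as sn


class TestBrelu:
    def test_piecewise_branches(self):
        st_ = sn.BRELUState(0.4, 0.6)
        assert sn.brelu(0.7, st_) == 1.0
        assert sn.brelu(0.3, st_) == 0.0
        assert sn.brelu(0.5, st_) == pytest.approx(0.5)

    def test_identity_on_linear_segment(self):
        assert sn.brelu(0.75, sn.BRELUState(0.0, 1.0)) == pytest.approx(0.75)

    def test_step_limit(self):
        step = sn.BRELUState(0.5, 0.5)
        assert sn.brelu(0.49, step) == 0.0
        assert sn.brelu(0.51, step) == 1.0
        assert sn.brelu(0.5, step) == 1.0  # x = threshold maps to 1

    @settings(max_examples=100, derandomize=True)
    @given(w=st.floats(0.0, 0.5),
           xs=st.lists(st.floats(-5, 5), min_size=2, max_size=20))
    def test_monotone_and_bounded(self, w, xs):
        state = sn.BRELUState.from_width(w)
        x = np.sort(np.asarray(xs))
        y = sn.brelu(x, state)
        assert np.all((y >= 0.0) & (y <= 1.0))
        assert np.all(np.diff(y) >= 0.0)

    def test_symmetry_constraint_enforced(self):
        with pytest.raises(ValueError):
            sn.BRELUState(0.1, 0.6)


class TestSharpen:
    def test_single_step(self):
        out = sn.sharpen(sn.BRELUState(0.0, 1.0), 0.1)
        assert (out.alpha, out.beta) == (pytest.approx(0.1), pytest.approx(0.9))

    def test_fixed_point(self):
        step = sn.BRELUState(0.5, 0.5)
        assert sn.sharpen(step, 0.2) == step

    def test_ten_steps_to_full_sharpness(self):
        state = sn.BRELUState.from_width(0.5)
        for _ in range(10):
            state = sn.sharpen(state, 0.05)
        assert state.width == pytest.approx(0.0)


class TestAdaptiveSchedule:
    def test_constant_loss_advances_every_eligible_epoch(self):
        pol = sn.SharpenPolicy(start_epoch=2, delta=0.01)
        deltas = sn.adaptive_schedule([1.0] * 10, pol)
        assert deltas == [0.0, 0.0] + [0.01] * 8

    def test_loss_spike_pauses(self):
        pol = sn.SharpenPolicy(start_epoch=0, delta=0.01, patience=1,
                               loss_tol=0.05)
        deltas = sn.adaptive_schedule([1.0, 1.0, 2.0, 2.0], pol)
        assert deltas[2] == 0.0  # the spike epoch
        assert deltas[1] == 0.01 and deltas[3] == 0.01

    def test_disabled_schedule_leaves_network_unsharpened(self, small_split):
        tr, va = small_split
        spec = sd.build_detector("snn7", width_scale=0.25)
        cfg = sd.TrainConfig(epochs=3, seed=0,
                             policy=sn.SharpenPolicy(start_epoch=3))
        det = sd.train(spec, tr, va, cfg)
        assert det.history["sharpness"] == [0.0, 0.0, 0.0]
        assert all(s.width == 0.5 for s in det.spec.brelu_states)

    def test_cumulative_schedule_monotone(self):
        pol = sn.SharpenPolicy(start_epoch=1, delta=0.02, patience=2,
                               loss_tol=0.01)
        losses = list(np.abs(np.sin(np.arange(30))) + 0.5)
        deltas = sn.adaptive_schedule(losses, pol)
        assert all(d >= 0 for d in deltas)


class TestBuildDetector:
    @pytest.mark.parametrize("arch,n_layers", [("slstm8", 8), ("slstm7", 7),
                                               ("snn7", 7)])
    def test_layer_counts(self, arch, n_layers):
        spec = sd.build_detector(arch)
        assert len(spec.layers) == n_layers
        assert spec.layers[-1].kind == sn.OUTPUT
        assert spec.layers[-1].width == 2

    def test_width_scaling(self):
        spec = sd.build_detector("snn7", width_scale=0.5)
        assert [l.width for l in spec.layers] == [128, 64, 32, 32, 16, 8, 2]

    def test_unknown_arch(self):
        with pytest.raises(ValueError):
            sd.build_detector("mlp3")


class TestTraining:
    def test_gradients_match_numerical(self):
        """BPTT and dense backprop agree with finite differences."""
        spec = sn.DetectorSpec(
            "tiny", [sn.LayerSpec(sn.RECURRENT, 4), sn.LayerSpec(sn.DENSE, 5),
                     sn.LayerSpec(sn.OUTPUT, 2)],
            [sn.BRELUState.from_width(0.5)] * 3)
        rng = np.random.default_rng(0)
        params = sn._init_params(spec, 6, rng)
        X = rng.uniform(0, 1, (4, 6))
        T = np.eye(2)[[0, 1, 0, 1]]

        def loss():
            z, _, _ = sn._forward(spec, params, X, training=True)
            return float(np.mean((sn._softmax(z) - T) ** 2))

        z, y, caches = sn._forward(spec, params, X, want_cache=True,
                                   training=True)
        p = sn._softmax(z)
        dp = 2.0 * (p - T) / T.size
        dz = p * (dp - np.sum(dp * p, axis=1, keepdims=True))
        grads = sn._backward(spec, params, caches, np.zeros_like(dz),
                             dz_out=dz)
        eps = 1e-6
        checked = 0
        for li, g in enumerate(grads):
            for k in g:
                v = params[li][k]
                top = np.argsort(-np.abs(g[k]).ravel())[:6]
                for fi in top:
                    idx = np.unravel_index(fi, v.shape)
                    old = v[idx]
                    v[idx] = old + eps
                    l1 = loss()
                    v[idx] = old - eps
                    l2 = loss()
                    v[idx] = old
                    num = (l1 - l2) / (2 * eps)
                    if abs(num) + abs(g[k][idx]) > 1e-10:
                        assert abs(num - g[k][idx]) <= 1e-4 * (
                            abs(num) + abs(g[k][idx]))
                        checked += 1
        assert checked >= 20

    def test_determinism(self, small_split):
        tr, va = small_split
        spec = sd.build_detector("snn7", width_scale=0.25)
        cfg = sd.TrainConfig(epochs=3, seed=11)
        d1 = sd.train(spec, tr, va, cfg)
        d2 = sd.train(spec, tr, va, cfg)
        for p1, p2 in zip(d1.params, d2.params):
            for k in p1:
                np.testing.assert_array_equal(p1[k], p2[k])
        assert d1.history == d2.history

    def test_history_recorded_per_epoch(self, trained_snn):
        h = trained_snn.history
        assert len(h["loss"]) == len(h["train_acc"]) == len(h["val_acc"]) == 8

    def test_label_shuffle_gives_chance_accuracy(self, small_dataset):
        """Shuffled labels carry no signal: validation ACC ~ 0.5."""
        rng = np.random.default_rng(2)
        perm = rng.permutation(len(small_dataset))
        shuffled = sd.SpikeDataset(
            samples=[
                sd.SpikeTrainSample(s.spike_times,
                                    small_dataset.samples[j].label,
                                    s.sample_id, s.source)
                for s, j in zip(small_dataset.samples, perm)],
            T_max=small_dataset.T_max, L_max=small_dataset.L_max)
        tr, va = sd.split_dataset(shuffled, 0.75, stratified=False, seed=0)
        det = sd.train(sd.build_detector("snn7", width_scale=0.25), tr, va,
                       sd.TrainConfig(epochs=8, seed=0))
        assert abs(det.history["val_acc"][-1] - 0.5) <= 0.1

    def test_mismatched_datasets_rejected(self, small_split, pheno_params):
        tr, _ = small_split
        other = sd.generate_dataset(pheno_params, 2, 2, 2000.0, seed=0)
        with pytest.raises(ValueError):
            sd.train(sd.build_detector("snn7", width_scale=0.25), tr, other,
                     sd.TrainConfig(epochs=1))


class TestPredict:
    def test_empty_sample_gets_a_label(self, trained_snn):
        empty = sd.SpikeDataset(
            samples=[sd.SpikeTrainSample(np.zeros(128), 0, "empty")],
            T_max=2500.0, L_max=128)
        pred = sd.predict(trained_snn, empty, "binary")
        assert pred.shape == (1,) and pred[0] in (0, 1)

    def test_binary_matches_argmax_of_scores(self, trained_snn, small_split):
        _, va = small_split
        binary = sd.predict(trained_snn, va, "binary")
        z = sn._batched_forward(trained_snn, trained_snn.inputs_from(va))
        np.testing.assert_array_equal(binary, (z[:, 1] > z[:, 0]).astype(int))

    def test_round_trip_dataset_predictions_identical(
            self, trained_snn, small_split, tmp_path):
        _, va = small_split
        path = sd.write_dataset(va, tmp_path / "va.csv")
        va2 = sd.read_dataset(path)
        np.testing.assert_array_equal(
            sd.predict(trained_snn, va, "binary"),
            sd.predict(trained_snn, va2, "binary"))

    def test_lmax_mismatch_rejected(self, trained_snn, pheno_params):
        ds = sd.generate_dataset(pheno_params, 2, 2, 2500.0, seed=0, L_max=64)
        with pytest.raises(ValueError):
            sd.predict(trained_snn, ds, "binary")

    def test_time_rescaling_invariance(self, trained_snn, small_split):
        """Scaling spike times and T_max together leaves inputs unchanged."""
        _, va = small_split
        scaled = sd.SpikeDataset(
            samples=[sd.SpikeTrainSample(s.spike_times * 2.0, s.label,
                                         s.sample_id, s.source)
                     for s in va.samples],
            T_max=va.T_max * 2.0, L_max=va.L_max)
        det2 = sn.TrainedDetector(
            spec=trained_snn.spec, params=trained_snn.params,
            history=trained_snn.history, T_max=trained_snn.T_max * 2.0,
            L_max=trained_snn.L_max, seed=trained_snn.seed)
        np.testing.assert_allclose(
            sn._batched_forward(det2, det2.inputs_from(scaled)),
            sn._batched_forward(trained_snn, trained_snn.inputs_from(va)),
            rtol=1e-12)


class TestSharpenedNetwork:
    def test_fully_sharpened_hidden_activations_are_binary(self, trained_snn):
        spec = trained_snn.spec
        sharp = sn.DetectorSpec(
            spec.arch_id, list(spec.layers),
            [sn.BRELUState.from_width(0.0) for _ in spec.layers])
        rng = np.random.default_rng(0)
        X = rng.uniform(0, 1, (16, trained_snn.L_max))
        a = X
        for li, layer in enumerate(sharp.layers):
            p = trained_snn.params[li]
            t = p["_mu_t"][0]
            mu = p["_mu"] / (1 - 0.9 ** t) if t > 0 else 0.0
            z = a @ p["W"] - mu + p["b"]
            a = sn.brelu(z, sharp.brelu_states[li])
            assert set(np.unique(a)) <= {0.0, 1.0}

    def test_sharpness_monotone_during_training(self, small_split):
        tr, va = small_split
        cfg = sd.TrainConfig(
            epochs=10, seed=3,
            policy=sn.SharpenPolicy(start_epoch=2, delta=0.05, patience=1,
                                    loss_tol=1.0))
        det = sd.train(sd.build_detector("snn7", width_scale=0.25), tr, va, cfg)
        s = det.history["sharpness"]
        assert all(b >= a for a, b in zip(s, s[1:]))
        assert s[-1] > 0.0


class TestPersistence:
    def test_export_import_identity(self, trained_snn, tmp_path):
        path = sd.export_weights(trained_snn, tmp_path / "w.h5")
        det2 = sd.import_weights(path)
        assert det2.spec.arch_id == trained_snn.spec.arch_id
        assert det2.spec.layers == trained_snn.spec.layers
        assert det2.spec.brelu_states == trained_snn.spec.brelu_states
        for p1, p2 in zip(trained_snn.params, det2.params):
            assert set(p1) == set(p2)
            for k in p1:
                np.testing.assert_array_equal(p1[k], p2[k])
        for k in trained_snn.history:
            np.testing.assert_allclose(trained_snn.history[k],
                                       det2.history[k])

    def test_imported_detector_predicts_identically(
            self, trained_snn, small_split, tmp_path):
        _, va = small_split
        det2 = sd.import_weights(sd.export_weights(trained_snn,
                                                   tmp_path / "w.h5"))
        np.testing.assert_array_equal(sd.predict(trained_snn, va, "binary"),
                                      sd.predict(det2, va, "binary"))
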