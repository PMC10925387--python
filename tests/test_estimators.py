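"""Network construction/training mechanics and the reference estimators."""

import numpy as np
import pytest

from qmrinet.estimators import (
    MLP,
    Adam,
    NetworkSpec,
    StageConfig,
    TrainingData,
    build_network,
    dictionary_match,
    features,
    nlls_fit,
    predict,
    train_stage,
)


class TestNetworkSpec:
    def test_toy_count_no_batchnorm(self):
        spec = NetworkSpec(input_dim=2, hidden_widths=(3,), output_dim=1,
                           output_caps=(5.0,), batch_norm=False)
        assert spec.n_parameters == (2 * 3 + 3) + (3 * 1 + 1)

    def test_count_matches_per_layer_arithmetic(self, rng):
        """Spec formula vs independent layer-by-layer count on random specs."""
        for _ in range(20):
            widths = tuple(int(w) for w in rng.integers(1, 50, size=rng.integers(1, 4)))
            din, dout = int(rng.integers(1, 30)), int(rng.integers(1, 5))
            bn = bool(rng.integers(0, 2))
            spec = NetworkSpec(input_dim=din, hidden_widths=widths, output_dim=dout,
                               output_caps=(5.0,) * dout, batch_norm=bn)
            dims = [din, *widths, dout]
            expected = 0
            for a, b in zip(dims[:-1], dims[1:]):
                expected += a * b + b
            if bn:
                expected += sum(2 * w for w in widths)
            net, count = build_network(spec, seed=0)
            assert count == expected == spec.n_parameters

    def test_invalid_specs(self):
        with pytest.raises(ValueError):
            NetworkSpec(input_dim=0)
        with pytest.raises(ValueError):
            NetworkSpec(output_dim=2, output_caps=(5.0,))


class TestForward:
    def test_outputs_within_caps(self, rng):
        net, _ = build_network(NetworkSpec(input_dim=6, hidden_widths=(16,),
                                           output_dim=2, output_caps=(5.0, 5.0)), seed=0)
        x = 100.0 * rng.normal(size=(50, 6))
        out = net.forward(x)
        assert np.all(out >= 0) and np.all(out <= 5.0)

    def test_zero_input_finite(self):
        net, _ = build_network(NetworkSpec(input_dim=4, hidden_widths=(8,), output_dim=2,
                                           output_caps=(5.0, 5.0)), seed=1)
        y = np.zeros((1, 2), dtype=complex)
        out = predict(net, y)
        assert np.all(np.isfinite(out)) and np.all((out >= 0) & (out <= 5.0))

    def test_inference_batch_independent_and_deterministic(self, rng):
        net, _ = build_network(NetworkSpec(input_dim=8, hidden_widths=(8, 8), output_dim=2,
                                           output_caps=(5.0, 5.0)), seed=2)
        y = rng.normal(size=(10, 4)) + 1j * rng.normal(size=(10, 4))
        full = predict(net, y)
        single = np.vstack([predict(net, y[i: i + 1]) for i in range(10)])
        assert np.allclose(full, single)  # running statistics, not batch statistics
        assert np.array_equal(full, predict(net, y))

    def test_wrong_input_dim(self):
        net, _ = build_network(NetworkSpec(input_dim=8, hidden_widths=(4,), output_dim=2,
                                           output_caps=(5.0, 5.0)), seed=0)
        with pytest.raises(ValueError):
            predict(net, np.zeros((1, 3), dtype=complex))


class TestBackprop:
    def test_gradients_match_finite_differences(self, rng):
        """Full network backprop (incl. batch norm) vs numerical gradients."""
        spec = NetworkSpec(input_dim=3, hidden_widths=(4,), output_dim=2,
                           output_caps=(5.0, 5.0), batch_norm=True)
        net, _ = build_network(spec, seed=3)
        x = rng.normal(size=(6, 3))
        target = rng.uniform(0.5, 1.5, size=(6, 2))

        def loss_value():
            out = net.forward(x, training=True)
            return 0.5 * np.sum((out - target) ** 2)

        out = net.forward(x, training=True)
        grads = net.backward(out - target)
        params = net.parameters()
        r = np.random.default_rng(0)
        checked = 0
        for p, g in zip(params, grads):
            idx = tuple(r.integers(0, s) for s in p.shape)
            eps = 1e-6
            old = p[idx]
            p[idx] = old + eps
            lp = loss_value()
            p[idx] = old - eps
            lm = loss_value()
            p[idx] = old
            fd = (lp - lm) / (2 * eps)
            assert g[idx] == pytest.approx(fd, rel=1e-4, abs=1e-7)
            checked += 1
        assert checked == len(params)


def toy_training_data(n=200, seed=0):
    """1-parameter toy problem: estimate T2 of a 5-point exponential decay."""
    rng = np.random.default_rng(seed)
    t = np.array([0.002, 0.005, 0.01, 0.02, 0.04])
    t2 = rng.uniform(0.005, 0.05, n)
    y0 = np.exp(-t[None, :] / t2[:, None]).astype(complex)
    # CRB of t2 per sample at sigma=1 (re_m0/im_m0 nuisance)
    from qmrinet.crb import crb, fisher_information

    b = np.empty((n, 1))
    for i in range(n):
        d_t2 = t / t2[i] ** 2 * np.exp(-t / t2[i])
        j = np.stack([d_t2.astype(complex), y0[i], 1j * y0[i]], axis=1)
        b[i] = crb(fisher_information(j, 1.0), np.array([True, False, False]),
                   parameter_order=("t2", "re_m0", "im_m0")).b
    return TrainingData(y0=y0, x_true=t2[:, None], crb_ref=b)


class TestTraining:
    def test_stage0_loss_drops_tenfold(self):
        data = toy_training_data()
        spec = NetworkSpec(input_dim=10, hidden_widths=(16, 16), output_dim=1,
                           output_caps=(0.1,))
        net = MLP(spec, seed=0)
        hist = train_stage(
            net, data, StageConfig(nr=1, lam=0.0, delta=0.0, epochs=200, batch_size=64),
            snr_range=(20.0, 40.0), rng=np.random.default_rng(0), lr=1e-3,
        )
        assert hist[-1] < hist[0] / 10.0

    def test_identical_seeds_identical_histories(self):
        data = toy_training_data(n=60)
        spec = NetworkSpec(input_dim=10, hidden_widths=(8,), output_dim=1, output_caps=(0.1,))

        def run():
            net = MLP(spec, seed=5)
            return train_stage(
                net, data, StageConfig(nr=2, lam=1.0, delta=1.0, epochs=10, batch_size=32),
                snr_range=(10.0, 50.0), rng=np.random.default_rng(17), lr=1e-3,
            )

        assert run() == run()

    @pytest.mark.filterwarnings("ignore:invalid value encountered")
    def test_divergence_aborts(self):
        data = toy_training_data(n=40)
        spec = NetworkSpec(input_dim=10, hidden_widths=(8,), output_dim=1, output_caps=(0.1,))
        net = MLP(spec, seed=0)
        net.weights[0] *= np.inf  # poisoned weights -> non-finite loss
        with pytest.raises(FloatingPointError):
            train_stage(
                net, data, StageConfig(nr=1, lam=0.0, delta=0.0, epochs=1, batch_size=32),
                snr_range=(10.0, 50.0), rng=np.random.default_rng(0),
            )


class TestDictionaryMatch:
    def _dict(self, rng, n=40, r=6):
        d = rng.normal(size=(n, r)) + 1j * rng.normal(size=(n, r))
        params = rng.uniform(0.1, 2.0, (n, 2))
        return d, params

    def test_noiseless_atom_exact(self, rng):
        d, params = self._dict(rng)
        est, m0 = dictionary_match(d, d, params)
        assert np.array_equal(est, params)
        assert np.allclose(m0, 1.0)

    def test_complex_scaling_invariance(self, rng):
        d, params = self._dict(rng)
        c = 1.7 * np.exp(1j * 0.6)
        est, m0 = dictionary_match(c * d[3], d, params)
        assert np.array_equal(est[0], params[3])
        assert m0[0] == pytest.approx(c, rel=1e-12)

    def test_matches_brute_force_oracle(self, rng):
        d, params = self._dict(rng, n=60)
        queries = rng.normal(size=(100, 6)) + 1j * rng.normal(size=(100, 6))
        est, _ = dictionary_match(queries, d, params)
        norms = np.linalg.norm(d, axis=1)
        for q, e in zip(queries, est):
            scores = np.array([abs(np.vdot(d[i], q)) / norms[i] for i in range(60)])
            assert np.array_equal(e, params[int(np.argmax(scores))])

    def test_empty_dictionary(self):
        with pytest.raises(ValueError):
            dictionary_match(np.ones(3, dtype=complex), np.empty((0, 3)), np.empty((0, 2)))


class TestNLLS:
    def _model(self):
        t = np.linspace(0.002, 0.05, 12)

        def model(t1, t2):
            # biexponential-style toy: T1 recovery * T2 decay sampled jointly
            return ((1 - np.exp(-t / t1)) * np.exp(-t / t2)).astype(complex)

        return model

    def test_noiseless_truth_recovery(self):
        model = self._model()
        truth = (0.8, 0.03)
        y = (2.0 - 0.5j) * model(*truth)
        fit = nlls_fit(y, model, init=truth)
        assert fit["t1"] == pytest.approx(truth[0], rel=1e-6)
        assert fit["t2"] == pytest.approx(truth[1], rel=1e-6)
        assert fit["m0"] == pytest.approx(2.0 - 0.5j, rel=1e-6)

    def test_descent_from_perturbed_init(self, rng):
        model = self._model()
        y = model(0.8, 0.03) + 0.01 * (rng.normal(size=12) + 1j * rng.normal(size=12))
        init = (1.2, 0.02)

        def cost(theta):
            g = model(*theta)
            m0 = np.vdot(g, y) / np.vdot(g, g).real
            return np.linalg.norm(y - m0 * g) ** 2

        fit = nlls_fit(y, model, init=init)
        assert 2 * fit["cost"] <= cost(init) + 1e-12


def test_nlls_efficiency_near_crb_on_fisp():
    """At SNR 50 the Monte-Carlo variance of NLLS on the FISP model sits
    within 15% of the CRB at an interior tissue (asymptotic efficiency)."""
    from qmrinet.crb import crb as compute_crb, fisher_information
    from qmrinet.sequence import (
        IsochromatEnsemble, SequenceConfig, TissueParams, make_flip_schedule,
        signal_jacobian, simulate_fisp_batch,
    )

    seq = SequenceConfig(flip_schedule=make_flip_schedule({"kind": "sinusoidal", "length": 400}))
    ens = IsochromatEnsemble.uniform_dephasing(64)
    tis = TissueParams(t1=1.0, t2=0.08)
    snr = 50.0
    sigma = 1.0 / snr
    jac = signal_jacobian(tis, seq, ens)
    b = compute_crb(fisher_information(jac, sigma),
                    np.array([True, True, False, False]), sigma=sigma).b

    y0 = simulate_fisp_batch(tis.t1, tis.t2, seq, ens)[0]
    cache = {}

    def model(t1, t2):
        key = (round(t1, 12), round(t2, 12))
        if key not in cache:
            cache[key] = simulate_fisp_batch(t1, t2, seq, ens)[0]
        return cache[key]

    rng = np.random.default_rng(2)
    n_draws = 300
    est = np.empty((n_draws, 2))
    for i in range(n_draws):
        y = y0 + sigma * (rng.normal(size=y0.size) + 1j * rng.normal(size=y0.size))
        fit = nlls_fit(y, model, init=(tis.t1, tis.t2))
        est[i] = fit["t1"], fit["t2"]
    var = est.var(axis=0)
    assert var[0] == pytest.approx(b[0], rel=0.15)
    assert var[1] == pytest.approx(b[1], rel=0.15)


def test_adam_moves_toward_minimum():
    p = [np.array([5.0])]
    opt = Adam(p, lr=0.1)
    for _ in range(500):
        opt.step(p, [2.0 * p[0]])  # grad of p^2
    assert abs(p[0][0]) < 1e-2


def test_features_split():
    y = np.array([[1 + 2j, 3 - 4j]])
    assert np.allclose(features(y), [[1, 3, 2, -4]])
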