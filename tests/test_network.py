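"""Network core: likelihood terms, BPTT gradients, training loop."""

import numpy as np
import pytest

import pcdraw as pc
from pcdraw.network import (_PARAM_FIELDS, dataset_batch, loss_and_grads,
                            prefix_nll_and_state_grad)


def tiny_problem(noise=False, n_context=4, T=6, n_classes=2, seed=0):
    params = pc.NetworkParameters.init(n_context, n_classes=n_classes,
                                       seed=seed)
    rng = np.random.default_rng(seed + 1)
    X = rng.uniform(-0.6, 0.6, (n_classes, T, 3))
    cls = np.arange(n_classes)
    cfg = pc.PrecisionConfig(1.3, 0.7, 0.05)
    xi = rng.standard_normal((n_classes, T - 1, 3)) if noise else None
    return params, X, cls, cfg, xi


class TestForwardStep:
    def test_zero_parameters_give_zero_mean(self):
        p = pc.NetworkParameters.init(5, n_classes=2)
        for name in ("w_in", "w_rec", "b_h", "w_mu", "b_mu"):
            getattr(p, name)[:] = 0.0
        step = pc.forward_step(p, np.zeros(5), np.array([0.3, -0.2, 1.0]))
        assert np.allclose(step.mu, 0.0)

    def test_variance_respects_positivity_floor(self):
        p = pc.NetworkParameters.init(5, n_classes=2, seed=3)
        p.b_var[:] = -200.0   # drive the exponential head to underflow
        step = pc.forward_step(p, np.zeros(5), np.zeros(3))
        assert np.all(step.var >= p.eps)

    def test_nonfinite_parameter_named_in_error(self):
        p = pc.NetworkParameters.init(5, n_classes=2)
        p.w_rec[0, 0] = np.nan
        with pytest.raises(ValueError, match="w_rec"):
            pc.forward_step(p, np.zeros(5), np.zeros(3))


class TestSequenceNll:
    def test_zero_when_both_terms_vanish(self):
        # mu on target and var = 1/(2*pi) makes the log term vanish too
        t = np.full((4, 3), 0.2)
        assert pc.sequence_nll(t, np.full((4, 3), 1 / (2 * np.pi)), t) == \
            pytest.approx(0.0)

    def test_single_term_worked_example(self):
        val = pc.sequence_nll(np.zeros((1, 1)), np.ones((1, 1)),
                              np.ones((1, 1)))
        assert val == pytest.approx(np.log(2 * np.pi) + 0.5, abs=1e-12)
        assert val == pytest.approx(2.33787, abs=1e-5)

    def test_additive_over_time(self):
        rng = np.random.default_rng(0)
        mu = rng.normal(size=(5, 3))
        var = rng.uniform(0.1, 1, (5, 3))
        t = rng.normal(size=(5, 3))
        one = pc.sequence_nll(mu, var, t)
        double = pc.sequence_nll(np.vstack([mu, mu]), np.vstack([var, var]),
                                 np.vstack([t, t]))
        assert double == pytest.approx(2 * one, rel=1e-12)

    def test_nonpositive_variance_rejected(self):
        with pytest.raises(ValueError):
            pc.sequence_nll(np.zeros((1, 1)), np.zeros((1, 1)),
                            np.zeros((1, 1)))

    def test_decomposes_over_trajectories(self, trained_model, dataset3,
                                          sensor_var):
        from pcdraw.network import _forward_teacher
        X, cls = dataset_batch(dataset3)
        cfg = pc.PrecisionConfig(1.0, 1.0, sensor_var)
        u0 = trained_model.init_states[cls]
        cache = _forward_teacher(trained_model, u0, X, cfg)
        whole = pc.sequence_nll(cache["MU"], cache["VAR"], X[:, 1:])
        parts = 0.0
        for i in range(X.shape[0]):
            ci = _forward_teacher(trained_model, u0[i:i + 1],
                                  X[i:i + 1], cfg)
            parts += pc.sequence_nll(ci["MU"], ci["VAR"], X[i:i + 1, 1:])
        assert whole == pytest.approx(parts, rel=1e-9)


class TestInitialStatePrior:
    def test_degenerate_states_leave_only_log_term(self):
        states = np.full((6, 10), 1.7)
        val = pc.initial_state_prior_nll(states, np.full(10, 1.7), 10.0)
        assert val == pytest.approx(60 * np.log(2 * np.pi * 10.0), rel=1e-12)

    def test_single_unit_worked_example(self):
        val = pc.initial_state_prior_nll(np.array([[2.0]]), np.array([2.0]),
                                         10.0)
        assert val == pytest.approx(np.log(20 * np.pi), abs=1e-12)
        assert val == pytest.approx(4.14046, abs=1e-5)

    def test_quadratic_part_scales_quadratically(self):
        mean = np.zeros(3)
        base = pc.initial_state_prior_nll(np.ones((2, 3)), mean, 10.0)
        doubled = pc.initial_state_prior_nll(2 * np.ones((2, 3)), mean, 10.0)
        log_term = 6 * np.log(2 * np.pi * 10.0)
        assert doubled - log_term == pytest.approx(4 * (base - log_term),
                                                   rel=1e-12)

    def test_dimension_mismatch_rejected(self):
        with pytest.raises(ValueError):
            pc.initial_state_prior_nll(np.ones((2, 3)), np.ones(4), 10.0)


@pytest.mark.parametrize("sampled", [False, True],
                         ids=["mean-input", "sampled-input"])
def test_gradients_match_finite_differences(sampled):
    """Analytic BPTT gradients vs central finite differences on a tiny
    network (N=4, T=6), for every weight array, the initial states, and
    their mean, with and without posterior-sampled inputs."""
    params, X, cls, cfg, xi = tiny_problem(noise=sampled)
    _, _, grads = loss_and_grads(params, X, cls, cfg, 10.0, noise=xi)

    def total(p):
        nll, prior, _ = loss_and_grads(p, X, cls, cfg, 10.0, noise=xi)
        return nll + prior

    h = 1e-5
    for name in _PARAM_FIELDS:
        arr = getattr(params, name)
        it = np.nditer(arr, flags=["multi_index"])
        for _ in it:
            idx = it.multi_index
            orig = arr[idx]
            arr[idx] = orig + h
            fp = total(params)
            arr[idx] = orig - h
            fm = total(params)
            arr[idx] = orig
            fd = (fp - fm) / (2 * h)
            rel = abs(grads[name][idx] - fd) / max(abs(fd), 1e-8)
            assert rel <= 1e-4, f"{name}{idx}: rel err {rel:.2e}"


def test_prefix_state_gradient_matches_finite_differences():
    params, X, cls, cfg, _ = tiny_problem()
    u0 = np.random.default_rng(7).normal(0, 0.5, (2, 4))
    _, grad = prefix_nll_and_state_grad(params, u0, X, cfg)
    h = 1e-5
    for i in np.ndindex(u0.shape):
        orig = u0[i]
        u0[i] = orig + h
        fp = prefix_nll_and_state_grad(params, u0, X, cfg)[0].sum()
        u0[i] = orig - h
        fm = prefix_nll_and_state_grad(params, u0, X, cfg)[0].sum()
        u0[i] = orig
        fd = (fp - fm) / (2 * h)
        assert abs(grad[i] - fd) / max(abs(fd), 1e-8) <= 1e-4


class TestTrain:
    def small_dataset(self):
        return pc.build_dataset(1, n_per_class=4,
                                classes=[pc.ShapeClass.FACE,
                                         pc.ShapeClass.HOUSE])

    def test_best_so_far_total_is_nonincreasing(self):
        ds = self.small_dataset()
        cfg = pc.TrainingConfig(max_epochs=80, patience_epochs=80,
                                n_context=10)
        params = pc.NetworkParameters.init(10, n_classes=2, seed=0)
        _, hist = pc.train(params, ds, cfg, pc.PrecisionConfig(1, 1, 0.02))
        best = np.minimum.accumulate([h.total for h in hist])
        assert np.all(np.diff(best) <= 0)

    def test_no_improvement_stops_exactly_at_patience(self):
        # an improvement tolerance no finite loss can beat acts as a
        # constant-loss optimizer stub: the best epoch stays at 0
        ds = self.small_dataset()
        cfg = pc.TrainingConfig(max_epochs=500, patience_epochs=40,
                                n_context=8, improvement_tolerance=1e18,
                                seed=3)
        params = pc.NetworkParameters.init(8, n_classes=2, seed=3)
        _, hist = pc.train(params, ds, cfg, pc.PrecisionConfig(1, 1, 0.02))
        assert hist[-1].epoch == 40
        assert len(hist) == 41

    def test_seeded_runs_are_bitwise_identical(self):
        ds = self.small_dataset()
        cfg = pc.TrainingConfig(max_epochs=60, patience_epochs=60,
                                n_context=10, seed=5)
        runs = []
        for _ in range(2):
            params = pc.NetworkParameters.init(10, n_classes=2, seed=5)
            best, hist = pc.train(params, ds, cfg,
                                  pc.PrecisionConfig(1, 1, 0.02))
            runs.append((best, [h.total for h in hist]))
        assert runs[0][1] == runs[1][1]
        for name in _PARAM_FIELDS:
            assert np.array_equal(getattr(runs[0][0], name),
                                  getattr(runs[1][0], name))

    def test_loss_report_total_is_sum(self):
        r = pc.LossReport(epoch=3, nll=1.25, init_prior=0.5)
        assert r.total == 1.75

    def test_training_beats_untrained_baseline(self, trained_model,
                                               dataset3, sensor_var):
        """The trained scaled-down network's data NLL is far below an
        untrained network's (well past one fifth of it)."""
        X, cls = dataset_batch(dataset3)
        cfg = pc.PrecisionConfig(1.0, 1.0, sensor_var)
        fresh = pc.NetworkParameters.init(30, n_classes=3, seed=0)
        nll_fresh, _, _ = loss_and_grads(fresh, X, cls, cfg, 10.0)
        nll_trained, _, _ = loss_and_grads(trained_model, X, cls, cfg, 10.0)
        assert nll_trained < nll_fresh / 5

    def test_initial_state_prior_pulls_states_together(self):
        """With the initial-state prior active the per-class states stay
        near their learnable mean; effectively removing the prior (huge
        v_dist) lets them spread further."""
        ds = self.small_dataset()
        dists = {}
        for v_dist in (10.0, 1e9):
            cfg = pc.TrainingConfig(max_epochs=400, patience_epochs=400,
                                    n_context=10, v_dist=v_dist, seed=0)
            params = pc.NetworkParameters.init(10, n_classes=2, seed=0)
            best, _ = pc.train(params, ds, cfg,
                               pc.PrecisionConfig(1, 1, 0.02))
            dists[v_dist] = float(np.mean(np.linalg.norm(
                best.init_states - best.init_mean, axis=1)))
        assert dists[10.0] < dists[1e9]

    def test_divergence_reports_epoch(self):
        ds = self.small_dataset()
        cfg = pc.TrainingConfig(max_epochs=50, patience_epochs=50,
                                n_context=8, learning_rate=1e9)
        params = pc.NetworkParameters.init(8, n_classes=2, seed=0)
        with pytest.raises(RuntimeError, match="epoch"):
            pc.train(params, ds, cfg, pc.PrecisionConfig(1, 1, 0.02))


class TestCheckpoint:
    def test_exact_round_trip(self, tmp_path, trained_model):
        path = tmp_path / "model.ckpt"
        trained_model.save(path, seed=0)
        back = pc.NetworkParameters.load(path)
        for name in _PARAM_FIELDS:
            assert np.array_equal(getattr(trained_model, name),
                                  getattr(back, name))
        assert back.tau == trained_model.tau
        assert back.eps == trained_model.eps
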