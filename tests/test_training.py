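import numpy as np
import pytest

import fishann as fa
from fishann import ActivationKind, TrainerConfig, init_network, train
from fishann.training import train_gda, train_rp, train_seq

from helpers import check_affine_recovery, check_gradient_agreement


def affine_data(n=18, a=2.0, b=0.0):
    cs = np.linspace(0, 1, n)
    return cs, a * cs + b


class TestInit:
    def test_deterministic(self):
        n1 = init_network(5, ActivationKind.TANSIG, seed=3)
        n2 = init_network(5, ActivationKind.TANSIG, seed=3)
        assert n1 == n2

    def test_seed_changes_parameters(self):
        assert init_network(5, seed=3) != init_network(5, seed=4)

    def test_shapes_and_range(self):
        net = init_network(7, seed=0)
        for v in (net.input_weights, net.hidden_biases, net.output_weights):
            assert v.shape == (7,)
            assert np.all(np.abs(v) <= 0.5)
        with pytest.raises(ValueError):
            init_network(0)


class TestGradients:
    def test_zero_residuals_give_zero_gradient(self):
        net = init_network(3, ActivationKind.TANSIG, seed=1)
        cs = np.linspace(0, 1, 6)
        ys = fa.predict_batch(net, cs)
        g = fa.compute_gradients(net, cs, ys)
        assert np.allclose(g.input_weights, 0) and np.allclose(g.hidden_biases, 0)
        assert np.allclose(g.output_weights, 0) and g.output_bias == pytest.approx(0)

    def test_finite_difference_agreement(self):
        check_gradient_agreement(n_instances=100, seed=0)

    def test_purelin_h1_equals_least_squares_gradient(self):
        """For H=1 purelin, the model is y = lw*(w*c + b) + bj; the MSE
        gradient has the ordinary least-squares closed form."""
        net = fa.NetworkParams(
            np.array([0.3]), np.array([0.1]), np.array([0.8]), 0.05,
            ActivationKind.PURELIN,
        )
        cs = np.array([0.0, 0.5, 1.0])
        ys = np.array([0.1, 0.6, 0.9])
        w, b, lw, bj = 0.3, 0.1, 0.8, 0.05
        r = lw * (w * cs + b) + bj - ys
        g = fa.compute_gradients(net, cs, ys)
        assert g.input_weights[0] == pytest.approx(np.mean(2 * r * lw * cs), abs=1e-12)
        assert g.hidden_biases[0] == pytest.approx(np.mean(2 * r * lw), abs=1e-12)
        assert g.output_weights[0] == pytest.approx(
            np.mean(2 * r * (w * cs + b)), abs=1e-12
        )
        assert g.output_bias == pytest.approx(np.mean(2 * r), abs=1e-12)

    def test_length_mismatch(self):
        net = init_network(2, seed=0)
        with pytest.raises(ValueError):
            fa.compute_gradients(net, np.ones(3), np.ones(2))


CONVERGE = dict(max_epochs=2000, goal_mse=1e-7, min_grad=1e-12, patience=2000)


class TestTrainers:
    @pytest.mark.parametrize("alg,fn", [("gda", train_gda), ("rp", train_rp)])
    def test_zero_lr_or_zero_gradient_leaves_parameters(self, alg, fn):
        cs, ys = affine_data()
        net = init_network(3, ActivationKind.PURELIN, seed=2)
        if alg == "gda":
            cfg = TrainerConfig(algorithm="gda", lr0=0.0, max_epochs=5)
            res = fn(net, cs, ys, cfg)
            assert res.net == net
        else:
            # perfect fit at init -> zero gradient -> rp never moves
            ys_fit = fa.predict_batch(net, cs)
            cfg = TrainerConfig(algorithm="rp", max_epochs=5)
            res = fn(net, cs, ys_fit, cfg)
            assert res.net == net

    def test_seq_zero_lr(self):
        cs, ys = affine_data()
        net = init_network(3, ActivationKind.PURELIN, seed=2)
        cfg = TrainerConfig(algorithm="seq", lr0=0.0, max_epochs=5)
        assert train_seq(net, cs, ys, cfg).net == net

    @pytest.mark.parametrize(
        "alg,lr",
        [("gda", 0.05), ("rp", 0.05), ("seq", 0.02)],
    )
    def test_noiseless_affine_convergence(self, alg, lr):
        """y = 2c is exactly representable by a purelin 1-3-1 network, so
        every trainer should drive the MSE to (near) zero."""
        cs, ys = affine_data(a=2.0)
        net = init_network(3, ActivationKind.PURELIN, seed=1)
        cfg = TrainerConfig(algorithm=alg, lr0=lr, **CONVERGE)
        res = train(net, cs, ys, cfg)
        bound = 1e-6 if alg != "seq" else 1e-4
        assert res.final_mse < bound

    def test_gda_accepted_mse_never_jumps_more_than_max_perf_inc(self):
        rng = np.random.default_rng(0)
        cs = rng.uniform(0, 1, 18)
        ys = rng.uniform(0, 1, 18)
        cfg = TrainerConfig(algorithm="gda", lr0=0.5, max_epochs=300)
        res = train_gda(init_network(4, ActivationKind.TANSIG, seed=5), cs, ys, cfg)
        h = res.mse_history
        assert np.all(h[1:] <= cfg.max_perf_inc * h[:-1] + 1e-15)

    def test_seq_single_sample_equals_batch_step(self):
        """With one sample, one seq epoch is exactly one batch gradient step."""
        net = init_network(3, ActivationKind.TANSIG, seed=7)
        cs, ys = np.array([0.4]), np.array([0.9])
        cfg = TrainerConfig(algorithm="seq", lr0=0.1, max_epochs=1, goal_mse=0.0)
        res = train_seq(net, cs, ys, cfg)
        g = fa.compute_gradients(net, cs, ys)
        np.testing.assert_allclose(
            res.net.input_weights, net.input_weights - 0.1 * g.input_weights,
            rtol=1e-12,
        )
        assert res.net.output_bias == pytest.approx(
            net.output_bias - 0.1 * g.output_bias, rel=1e-12
        )

    def test_determinism_bit_identical(self):
        cs, ys = affine_data()
        ys = ys + np.sin(7 * cs) * 0.05
        for alg in ("gda", "rp", "seq"):
            cfg = TrainerConfig(algorithm=alg, max_epochs=200)
            r1 = train(init_network(4, seed=9), cs, ys, cfg)
            r2 = train(init_network(4, seed=9), cs, ys, cfg)
            assert r1.net == r2.net
            assert np.array_equal(r1.mse_history, r2.mse_history)

    @pytest.mark.parametrize("alg", ["gda", "rp", "seq"])
    def test_affine_map_recovery(self, alg):
        check_affine_recovery(alg)

    def test_wrong_algorithm_rejected(self):
        cs, ys = affine_data()
        with pytest.raises(ValueError):
            train_rp(init_network(2, seed=0), cs, ys, TrainerConfig(algorithm="gda"))

    def test_less_noise_means_lower_final_mse(self):
        """Median final MSE over 10 seeds decreases monotonically with the
        generator noise level."""
        medians = []
        for cv in (0.10, 0.05, 0.0):
            finals = []
            for seed in range(10):
                profile = fa.make_profile(
                    fa.Species.COMMON_CARP, noise_cv=cv, seed=seed
                )
                recs = fa.generate_dataset(profile)
                cs = np.array([r.concentration for r in recs])
                ys = np.array([r.IT for r in recs])
                xs = (cs - cs.min()) / (cs.max() - cs.min())
                yn = (ys - ys.min()) / (ys.max() - ys.min())
                cfg = TrainerConfig(algorithm="rp", max_epochs=300)
                res = train(init_network(4, ActivationKind.TANSIG, seed=seed), xs, yn, cfg)
                finals.append(res.final_mse)
            medians.append(float(np.median(finals)))
        assert medians[0] > medians[1] > medians[2]

    def test_rp_divergence_reports_epoch(self):
        # absurd step sizes blow up the loss on purpose
        cs, ys = affine_data()
        cfg = TrainerConfig(algorithm="rp", delta0=1e200, delta_max=1e300, max_epochs=50)
        with pytest.raises(fa.DivergenceError) as err:
            train_rp(init_network(3, ActivationKind.PURELIN, seed=0), cs, ys, cfg)
        assert err.value.epoch >= 0
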