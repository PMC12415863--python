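"""Shared property checks used by both the unit suites and the acceptance
suite: analytic-gradient agreement with finite differences, and recovery of
an affine map from noiseless data by each trainer."""

import numpy as np

import fishann as fa
from fishann.training import TrainerConfig


def check_gradient_agreement(n_instances: int = 100, seed: int = 0) -> None:
    """Analytic gradients match central finite differences (1e-5 relative)
    across random networks of every activation kind."""
    rng = np.random.default_rng(seed)
    kinds = list(fa.ActivationKind)
    for k in range(n_instances):
        H = int(rng.integers(1, 8))
        net = fa.NetworkParams(
            input_weights=rng.uniform(-1, 1, H),
            hidden_biases=rng.uniform(-1, 1, H),
            output_weights=rng.uniform(-1, 1, H),
            output_bias=float(rng.uniform(-1, 1)),
            hidden_activation=kinds[k % len(kinds)],
            output_activation=fa.ActivationKind.PURELIN,
        )
        n = int(rng.integers(1, 12))
        cs = rng.uniform(0, 1, n)
        ys = rng.uniform(0, 1, n)
        g = fa.compute_gradients(net, cs, ys)
        flat_g = np.concatenate(
            [g.input_weights, g.hidden_biases, g.output_weights, [g.output_bias]]
        )

        def mse_at(delta_idx, eps):
            m = net.copy()
            vecs = [m.input_weights, m.hidden_biases, m.output_weights]
            if delta_idx < 3 * H:
                vecs[delta_idx // H][delta_idx % H] += eps
            else:
                m.output_bias += eps
            return float(np.mean((fa.predict_batch(m, cs) - ys) ** 2))

        h = 1e-6
        for idx in range(3 * H + 1):
            fd = (mse_at(idx, h) - mse_at(idx, -h)) / (2 * h)
            tol = 1e-5 * max(1.0, abs(fd))
            assert abs(fd - flat_g[idx]) < tol, (
                f"instance {k}, param {idx}: analytic {flat_g[idx]} vs fd {fd}"
            )


def check_affine_recovery(algorithm: str, a: float = 0.7, b: float = 0.2) -> None:
    """On noiseless y = a*c + b, a purelin-hidden network trained by any of
    the three schemes recovers the effective affine map to 1e-3 (individual
    weights are not identifiable, their contractions are)."""
    cs = np.linspace(0.0, 1.0, 18)
    ys = a * cs + b
    cfg = TrainerConfig(
        algorithm=algorithm,
        lr0=0.05 if algorithm != "seq" else 0.02,
        max_epochs=5000,
        goal_mse=1e-12,
        min_grad=1e-10,
        patience=5000,
    )
    net0 = fa.init_network(3, fa.ActivationKind.PURELIN, seed=11)
    res = fa.train(net0, cs, ys, cfg)
    net = res.net
    slope = float(np.dot(net.input_weights, net.output_weights))
    intercept = float(np.dot(net.hidden_biases, net.output_weights)) + net.output_bias
    assert abs(slope - a) < 1e-3, slope
    assert abs(intercept - b) < 1e-3, intercept
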