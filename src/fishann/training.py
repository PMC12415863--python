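"""From-scratch training of the 1-H-1 network.

Three classical update schemes are implemented over the same closed-form
backpropagation gradients:

* ``gda`` — batch gradient descent with an adaptive learning rate: steps that
  worsen the batch MSE by more than ``max_perf_inc`` are discarded and the
  rate is cut by ``lr_dec``; steps that improve it grow the rate by
  ``lr_inc``.
* ``rp``  — resilient backpropagation (Rprop): each parameter carries its own
  step size, multiplied by ``delta_inc`` while the gradient sign is stable,
  cut by ``delta_dec`` (with retraction of the last step) on a sign flip,
  and clipped at ``delta_max``.  Only the gradient sign is used.
* ``seq`` — sequential (incremental) training: plain per-sample gradient
  steps with a fixed rate, applied in dataset presentation order; one epoch
  is one full ordered pass.

Gradients are exact analytic derivatives of the batch MSE; see
``compute_gradients``.  All training is deterministic given (data, config,
initial network).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .activations import ActivationKind, _apply, _apply_derivative
from .network import NetworkParams

__all__ = [
    "TrainerConfig",
    "TrainResult",
    "DivergenceError",
    "init_network",
    "compute_gradients",
    "train",
    "train_gda",
    "train_rp",
    "train_seq",
]

_ALGORITHMS = ("gda", "rp", "seq")


class DivergenceError(RuntimeError):
    """Training produced a non-finite loss."""

    def __init__(self, epoch: int):
        super().__init__(f"non-finite loss at epoch {epoch}")
        self.epoch = epoch


@dataclass(frozen=True)
class TrainerConfig:
    """Hyperparameters for one training run.

    Defaults follow the canonical published values for these algorithms:
    gda: lr_inc 1.05, lr_dec 0.7, max_perf_inc 1.04; rp: delta0 0.07,
    delta_inc 1.2, delta_dec 0.5, delta_max 50.  ``lr0`` defaults to 0.05,
    sized for inputs and targets scaled to [0, 1].

    Stopping: a run ends at ``goal_mse``, at ``max_epochs``, when the
    infinity norm of the batch gradient falls below ``min_grad`` (the loss
    surface is locally flat), or after ``patience`` consecutive epochs
    without a relative MSE improvement better than 1e-6 (plateau).
    """

    algorithm: str = "gda"
    lr0: float = 0.05
    lr_inc: float = 1.05
    lr_dec: float = 0.7
    max_perf_inc: float = 1.04
    delta0: float = 0.07
    delta_max: float = 50.0
    delta_inc: float = 1.2
    delta_dec: float = 0.5
    max_epochs: int = 1000
    goal_mse: float = 1e-5
    min_grad: float = 1e-6
    patience: int = 50
    seed: int = 0

    def __post_init__(self) -> None:
        if self.algorithm not in _ALGORITHMS:
            raise ValueError(f"unknown algorithm {self.algorithm!r}")
        if self.lr0 < 0:
            raise ValueError("lr0 must be nonnegative")
        if not (self.lr_inc > 1 and 0 < self.lr_dec < 1 and self.max_perf_inc > 1):
            raise ValueError("gda rate factors out of range")
        if not (self.delta0 > 0 and self.delta_max > 0):
            raise ValueError("rp step sizes must be positive")
        if not (self.delta_inc > 1 and 0 < self.delta_dec < 1):
            raise ValueError("rp step factors out of range")
        if self.max_epochs < 1:
            raise ValueError("max_epochs must be positive")
        if self.goal_mse < 0:
            raise ValueError("goal_mse must be nonnegative")
        if self.min_grad < 0:
            raise ValueError("min_grad must be nonnegative")
        if self.patience < 1:
            raise ValueError("patience must be positive")


@dataclass
class TrainResult:
    """Outcome of one training run.

    ``mse_history`` holds the accepted batch MSE after each epoch;
    ``converged`` is true iff ``final_mse <= goal_mse``.
    """

    net: NetworkParams
    epochs_run: int
    final_mse: float
    mse_history: np.ndarray
    converged: bool


def init_network(
    H: int,
    hidden_activation: ActivationKind = ActivationKind.TANSIG,
    seed: int = 0,
) -> NetworkParams:
    """Seeded uniform [-0.5, 0.5] initialization of a 1-H-1 network."""
    if H < 1:
        raise ValueError("H must be >= 1")
    rng = np.random.default_rng(seed)
    draw = rng.uniform(-0.5, 0.5, size=3 * H + 1)
    return NetworkParams(
        input_weights=draw[:H],
        hidden_biases=draw[H : 2 * H],
        output_weights=draw[2 * H : 3 * H],
        output_bias=draw[3 * H],
        hidden_activation=ActivationKind(hidden_activation),
        output_activation=ActivationKind.PURELIN,
    )


# ---------------------------------------------------------------------------
# flat parameter vector <-> NetworkParams

def _pack(net: NetworkParams) -> np.ndarray:
    return np.concatenate(
        [net.input_weights, net.hidden_biases, net.output_weights, [net.output_bias]]
    )


def _unpack(theta: np.ndarray, template: NetworkParams) -> NetworkParams:
    H = template.hidden_size
    return NetworkParams(
        theta[:H].copy(),
        theta[H : 2 * H].copy(),
        theta[2 * H : 3 * H].copy(),
        float(theta[3 * H]),
        template.hidden_activation,
        template.output_activation,
    )


def _mse_flat(theta, template, cs, ys) -> float:
    H = template.hidden_size
    with np.errstate(over="ignore", invalid="ignore"):
        z = cs[:, None] * theta[None, :H] + theta[None, H : 2 * H]
        f = _apply(template.hidden_activation, z)
        pred = _apply(
            template.output_activation, f @ theta[2 * H : 3 * H] + theta[3 * H]
        )
        return float(np.mean((pred - ys) ** 2))


def _grad_flat(theta, template, cs, ys) -> np.ndarray:
    """Analytic gradient of batch MSE w.r.t. the flat parameter vector."""
    H = template.hidden_size
    w1 = theta[:H]
    bh = theta[H : 2 * H]
    lw = theta[2 * H : 3 * H]
    bj = theta[3 * H]
    z = cs[:, None] * w1[None, :] + bh[None, :]  # (N, H)
    f = _apply(template.hidden_activation, z)
    out_pre = f @ lw + bj
    yhat = _apply(template.output_activation, out_pre)
    n = cs.shape[0]
    # residual scaled by d(MSE)/d(yhat) and the output activation derivative
    r = (2.0 / n) * (yhat - ys) * _apply_derivative(
        template.output_activation, out_pre
    )  # (N,)
    g_lw = r @ f
    g_bj = float(np.sum(r))
    fprime = _apply_derivative(template.hidden_activation, z)  # (N, H)
    back = (r[:, None] * lw[None, :]) * fprime  # (N, H)
    g_w1 = cs @ back
    g_bh = back.sum(axis=0)
    return np.concatenate([g_w1, g_bh, g_lw, [g_bj]])


def compute_gradients(net: NetworkParams, cs, ys) -> NetworkParams:
    """Exact analytic gradient of the batch MSE w.r.t. every parameter.

    Returned as a ``NetworkParams``-shaped structure whose fields hold the
    partial derivatives (activation fields carry over from *net*).
    """
    cs, ys = _check_data(cs, ys)
    g = _grad_flat(_pack(net), net, cs, ys)
    H = net.hidden_size
    out = net.copy()
    out.input_weights = g[:H]
    out.hidden_biases = g[H : 2 * H]
    out.output_weights = g[2 * H : 3 * H]
    out.output_bias = float(g[3 * H])
    return out


def _check_data(cs, ys):
    cs = np.asarray(cs, dtype=float)
    ys = np.asarray(ys, dtype=float)
    if cs.ndim != 1 or cs.shape != ys.shape or cs.size < 1:
        raise ValueError("cs and ys must be equal-length nonempty 1-D vectors")
    return cs, ys


def _finish(theta, template, history, config, initial_mse) -> TrainResult:
    final = history[-1] if history else initial_mse
    return TrainResult(
        net=_unpack(theta, template),
        epochs_run=len(history),
        final_mse=float(final),
        mse_history=np.asarray(history),
        converged=bool(final <= config.goal_mse),
    )



class _Plateau:
    """Stop after `patience` epochs without relative improvement > 1e-6."""

    REL = 1e-6

    def __init__(self, patience: int, mse0: float):
        self.patience = patience
        self.best = mse0
        self.wait = 0

    def stalled(self, mse: float) -> bool:
        if mse < self.best * (1.0 - self.REL):
            self.best = mse
            self.wait = 0
        else:
            self.wait += 1
        return self.wait >= self.patience


def train_gda(net: NetworkParams, cs, ys, config: TrainerConfig) -> TrainResult:
    """Batch gradient descent with adaptive learning rate."""
    if config.algorithm != "gda":
        raise ValueError("config.algorithm must be 'gda'")
    cs, ys = _check_data(cs, ys)
    theta = _pack(net)
    lr = config.lr0
    mse0 = mse_prev = _mse_flat(theta, net, cs, ys)
    plateau = _Plateau(config.patience, mse0)
    history: list[float] = []
    for epoch in range(config.max_epochs):
        if mse_prev <= config.goal_mse:
            break
        g = _grad_flat(theta, net, cs, ys)
        if np.max(np.abs(g)) < config.min_grad:
            break
        cand = theta - lr * g
        mse_new = _mse_flat(cand, net, cs, ys)
        if not np.isfinite(mse_new):
            raise DivergenceError(epoch)
        if mse_new > config.max_perf_inc * mse_prev:
            lr *= config.lr_dec  # step discarded
        else:
            if mse_new < mse_prev:
                lr *= config.lr_inc
            theta = cand
            mse_prev = mse_new
        history.append(mse_prev)
        if plateau.stalled(mse_prev):
            break
    return _finish(theta, net, history, config, mse0)


def train_rp(net: NetworkParams, cs, ys, config: TrainerConfig) -> TrainResult:
    """Resilient backpropagation (sign-based per-parameter step sizes)."""
    if config.algorithm != "rp":
        raise ValueError("config.algorithm must be 'rp'")
    cs, ys = _check_data(cs, ys)
    theta = _pack(net)
    delta = np.full(theta.shape, config.delta0)
    g_prev = np.zeros_like(theta)
    step_prev = np.zeros_like(theta)
    history: list[float] = []
    mse0 = mse_prev = _mse_flat(theta, net, cs, ys)
    plateau = _Plateau(config.patience, mse0)
    for epoch in range(config.max_epochs):
        if mse_prev <= config.goal_mse:
            break
        g = _grad_flat(theta, net, cs, ys)
        if np.max(np.abs(g)) < config.min_grad:
            break
        s = g * g_prev
        same = s > 0
        flip = s < 0
        delta = np.where(same, np.minimum(delta * config.delta_inc, config.delta_max), delta)
        delta = np.where(flip, delta * config.delta_dec, delta)
        step = -np.sign(g) * delta
        step[flip] = -step_prev[flip]  # retract the step that overshot
        theta = theta + step
        g = np.where(flip, 0.0, g)  # skip an adaptation round after a flip
        g_prev = g
        step_prev = step
        mse_prev = _mse_flat(theta, net, cs, ys)
        if not np.isfinite(mse_prev):
            raise DivergenceError(epoch)
        history.append(mse_prev)
        if plateau.stalled(mse_prev):
            break
    return _finish(theta, net, history, config, mse0)


def train_seq(net: NetworkParams, cs, ys, config: TrainerConfig) -> TrainResult:
    """Sequential incremental training: per-sample steps in dataset order."""
    if config.algorithm != "seq":
        raise ValueError("config.algorithm must be 'seq'")
    cs, ys = _check_data(cs, ys)
    theta = _pack(net)
    history: list[float] = []
    mse0 = mse_prev = _mse_flat(theta, net, cs, ys)
    plateau = _Plateau(config.patience, mse0)
    H = net.hidden_size
    hidden_act = net.hidden_activation
    lr = config.lr0
    n_samples = cs.shape[0]
    for epoch in range(config.max_epochs):
        if mse_prev <= config.goal_mse:
            break
        if np.max(np.abs(_grad_flat(theta, net, cs, ys))) < config.min_grad:
            break
        w1 = theta[:H]
        bh = theta[H : 2 * H]
        lw = theta[2 * H : 3 * H]
        bj = theta[3 * H]
        with np.errstate(over="ignore", invalid="ignore"):
            for n in range(n_samples):
                c = cs[n]
                z = c * w1 + bh
                f = _apply(hidden_act, z)
                out_pre = float(f @ lw) + bj
                # per-sample MSE gradient (N=1); chain through the output
                # activation where it is not the identity
                if net.output_activation is ActivationKind.PURELIN:
                    r = 2.0 * (out_pre - ys[n])
                else:
                    pre = np.asarray(out_pre)
                    r = (
                        2.0
                        * (float(_apply(net.output_activation, pre)) - ys[n])
                        * float(_apply_derivative(net.output_activation, pre))
                    )
                back = (r * lw) * _apply_derivative(hidden_act, z)
                w1 -= lr * back * c
                bh -= lr * back
                lw -= lr * r * f
                bj -= lr * r
        theta[3 * H] = bj
        mse_prev = _mse_flat(theta, net, cs, ys)
        if not np.isfinite(mse_prev):
            raise DivergenceError(epoch)
        history.append(mse_prev)
        if plateau.stalled(mse_prev):
            break
    return _finish(theta, net, history, config, mse0)


_TRAINERS = {"gda": train_gda, "rp": train_rp, "seq": train_seq}


def train(net: NetworkParams, cs, ys, config: TrainerConfig) -> TrainResult:
    """Dispatch to the trainer named by ``config.algorithm``."""
    return _TRAINERS[config.algorithm](net, cs, ys, config)
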