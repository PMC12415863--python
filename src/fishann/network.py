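"""The 1-H-1 feed-forward network: one input neuron (anesthetic
concentration), H hidden neurons, one output neuron (a single endpoint).

The forward pass is

    F_i = act_hidden(c * W1_i + theta_i)          i = 1..H
    y   = act_output( sum_i F_i * Lw_i + theta_j )

where the output activation of every model considered here is purelin
(identity).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .activations import ActivationKind, activate

__all__ = ["NetworkParams", "InvalidModelError", "forward", "predict_batch"]


class InvalidModelError(ValueError):
    """Network parameter vectors are inconsistent or non-finite."""


@dataclass(eq=False)
class NetworkParams:
    """Parameters of a single-input, single-output, one-hidden-layer network.

    Attributes
    ----------
    input_weights : array (H,)
        Weight from the concentration input to each hidden neuron (W1).
    hidden_biases : array (H,)
        Hidden-layer biases (theta_i).
    output_weights : array (H,)
        Hidden-to-output weights (Lw).
    output_bias : float
        Output-layer bias (theta_j).
    hidden_activation, output_activation : ActivationKind
    """

    input_weights: np.ndarray
    hidden_biases: np.ndarray
    output_weights: np.ndarray
    output_bias: float
    hidden_activation: ActivationKind = ActivationKind.PURELIN
    output_activation: ActivationKind = ActivationKind.PURELIN

    def __post_init__(self) -> None:
        self.input_weights = np.asarray(self.input_weights, dtype=float)
        self.hidden_biases = np.asarray(self.hidden_biases, dtype=float)
        self.output_weights = np.asarray(self.output_weights, dtype=float)
        self.output_bias = float(self.output_bias)
        self.hidden_activation = ActivationKind(self.hidden_activation)
        self.output_activation = ActivationKind(self.output_activation)
        self.validate()

    @property
    def hidden_size(self) -> int:
        return int(self.input_weights.shape[0])

    @property
    def architecture(self) -> str:
        """Architecture string, e.g. ``"1-6-1"``."""
        return f"1-{self.hidden_size}-1"

    def validate(self) -> None:
        H = self.input_weights.shape[0]
        if H < 1:
            raise InvalidModelError("network needs at least one hidden neuron")
        for name, v in (
            ("input_weights", self.input_weights),
            ("hidden_biases", self.hidden_biases),
            ("output_weights", self.output_weights),
        ):
            if v.ndim != 1:
                raise InvalidModelError(f"{name} must be a 1-D vector")
            if v.shape[0] != H:
                raise InvalidModelError(
                    f"{name} has length {v.shape[0]}, expected {H}"
                )
            if not np.all(np.isfinite(v)):
                raise InvalidModelError(f"{name} contains non-finite values")
        if not np.isfinite(self.output_bias):
            raise InvalidModelError("output_bias is non-finite")

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, NetworkParams):
            return NotImplemented
        return (
            np.array_equal(self.input_weights, other.input_weights)
            and np.array_equal(self.hidden_biases, other.hidden_biases)
            and np.array_equal(self.output_weights, other.output_weights)
            and self.output_bias == other.output_bias
            and self.hidden_activation is other.hidden_activation
            and self.output_activation is other.output_activation
        )

    def copy(self) -> "NetworkParams":
        return NetworkParams(
            self.input_weights.copy(),
            self.hidden_biases.copy(),
            self.output_weights.copy(),
            self.output_bias,
            self.hidden_activation,
            self.output_activation,
        )


def forward(net: NetworkParams, c: float) -> float:
    """Evaluate the network at a single concentration *c*."""
    if not np.isfinite(c):
        raise ValueError("concentration must be finite")
    net.validate()
    hidden = activate(net.hidden_activation, c * net.input_weights + net.hidden_biases)
    out = float(np.dot(hidden, net.output_weights)) + net.output_bias
    return float(activate(net.output_activation, out))


def predict_batch(net: NetworkParams, cs) -> np.ndarray:
    """Vectorized forward pass over a sequence of concentrations.

    Order and length are preserved; an empty input yields an empty array.
    """
    cs = np.asarray(cs, dtype=float)
    if cs.size == 0:
        return np.empty(0)
    if not np.all(np.isfinite(cs)):
        raise ValueError("concentrations must be finite")
    net.validate()
    pre = cs[:, None] * net.input_weights[None, :] + net.hidden_biases[None, :]
    hidden = activate(net.hidden_activation, pre)
    out = hidden @ net.output_weights + net.output_bias
    out = activate(net.output_activation, out)
    return np.asarray(out, dtype=float)
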