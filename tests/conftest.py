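import math

import numpy as np
import pytest

import fishann as fa


@pytest.fixture(scope="session")
def carp_records():
    """Default synthetic common-carp dataset, seed 1 (30 fish)."""
    return fa.generate_dataset(fa.make_profile(fa.Species.COMMON_CARP, seed=1))


def oracle_forward(net: fa.NetworkParams, c: float) -> float:
    """Independent per-neuron evaluation with plain Python floats.

    Deliberately avoids numpy and the package's activation code so it can
    serve as a brute-force oracle for the vectorized forward pass.
    """
    total = 0.0
    for i in range(net.hidden_size):
        z = c * float(net.input_weights[i]) + float(net.hidden_biases[i])
        kind = net.hidden_activation.value
        if kind == "purelin":
            f = z
        elif kind == "tansig":
            f = math.tanh(z)
        elif kind == "logsig":
            f = 1.0 / (1.0 + math.exp(-z)) if z > -700 else 0.0
        elif kind == "logsig_scaled":
            f = 2.0 / (1.0 + math.exp(-z)) if z > -700 else 0.0
        else:  # pragma: no cover
            raise AssertionError(kind)
        total += f * float(net.output_weights[i])
    out = total + float(net.output_bias)
    assert net.output_activation.value == "purelin"
    return out


def random_network(rng: np.random.Generator, H=None, kinds=None) -> fa.NetworkParams:
    H = H or int(rng.integers(1, 11))
    kinds = kinds or list(fa.ActivationKind)
    return fa.NetworkParams(
        input_weights=rng.normal(size=H),
        hidden_biases=rng.normal(size=H),
        output_weights=rng.normal(size=H),
        output_bias=float(rng.normal()),
        hidden_activation=kinds[int(rng.integers(len(kinds)))],
        output_activation=fa.ActivationKind.PURELIN,
    )
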