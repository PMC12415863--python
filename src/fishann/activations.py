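"""Neuron transfer functions for the single-hidden-layer networks.

Three transfer functions appear in the transcribed models: ``purelin``
(identity), ``tansig`` (hyperbolic-tangent sigmoid) and a logistic sigmoid.
The logistic sigmoid exists in two dialects:

* ``LOGSIG`` — the canonical 1/(1+e^-x), range (0, 1).
* ``LOGSIG_SCALED`` — 2/(1+e^-x), range (0, 2), i.e. exactly twice the
  canonical logistic.  This is the formula printed alongside the transcribed
  model tables (it shares tansig's 2/(1+e^...) layout with the inner factor
  of 2 dropped), so entries in the model zoo that are tagged "logsig" are
  evaluated with this dialect by default.

Useful identities (tested):
    tansig(x) = 2*logsig(2x) - 1
    logsig_scaled(x) = 2*logsig(x)
"""

from __future__ import annotations

import enum

import numpy as np

__all__ = ["ActivationKind", "activate", "activate_derivative"]


class ActivationKind(str, enum.Enum):
    """Transfer function of a network layer."""

    PURELIN = "purelin"
    TANSIG = "tansig"
    LOGSIG = "logsig"
    LOGSIG_SCALED = "logsig_scaled"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


def _logistic(x):
    # numerically stable logistic; np.exp overflow-safe via clip
    return 1.0 / (1.0 + np.exp(-np.clip(x, -700.0, 700.0)))


def _apply(kind: ActivationKind, x: np.ndarray) -> np.ndarray:
    """Unchecked elementwise transfer function (internal fast path)."""
    if kind is ActivationKind.PURELIN:
        return x.copy()
    if kind is ActivationKind.TANSIG:
        return np.tanh(x)
    if kind is ActivationKind.LOGSIG:
        return _logistic(x)
    return 2.0 * _logistic(x)  # LOGSIG_SCALED


def _apply_derivative(kind: ActivationKind, x: np.ndarray) -> np.ndarray:
    """Unchecked elementwise transfer-function derivative (internal)."""
    if kind is ActivationKind.PURELIN:
        return np.ones_like(x)
    if kind is ActivationKind.TANSIG:
        f = np.tanh(x)
        return 1.0 - f * f
    if kind is ActivationKind.LOGSIG:
        f = _logistic(x)
        return f * (1.0 - f)
    # LOGSIG_SCALED: f = 2*sigma, f' = 2*sigma*(1-sigma) = f*(1-f/2)
    f = 2.0 * _logistic(x)
    return f * (1.0 - f / 2.0)


def activate(kind: ActivationKind, x):
    """Apply the transfer function *kind* elementwise to *x*.

    Parameters
    ----------
    kind
        The transfer function.
    x
        Scalar or array of pre-activations; must be finite.

    Returns
    -------
    Scalar or array of the same shape.  purelin -> x; tansig in (-1, 1);
    logsig in (0, 1); logsig_scaled in (0, 2).
    """
    x = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValueError("activation input must be finite")
    out = _apply(ActivationKind(kind), x)
    return out if out.ndim else float(out)


def activate_derivative(kind: ActivationKind, x):
    """Derivative of the transfer function at pre-activation *x*.

    Expressed through the activation value f = activate(kind, x):
    purelin' = 1; tansig' = 1 - f^2; logsig' = f(1-f);
    logsig_scaled' = f(1 - f/2).
    """
    x = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValueError("activation input must be finite")
    out = _apply_derivative(ActivationKind(kind), x)
    return out if out.ndim else float(out)
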