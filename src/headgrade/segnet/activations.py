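"""Scalar activations of the network.

``lrelu_softplus`` is the piecewise activation used in the adaptive head:
a shifted softplus ``ln(e^x + 1) - ln 2`` for x >= 0 (zero at the origin,
asymptotically linear) and a leaky linear branch ``a*x`` for x < 0 with
slope a = 0.01 by default.  It is continuous at 0 and monotone.
"""

from __future__ import annotations

import numpy as np

__all__ = ["relu", "relu_grad", "lrelu_softplus", "lrelu_softplus_grad"]

LN2 = float(np.log(2.0))


def relu(x):
    """max(0, x), elementwise."""
    return np.maximum(0.0, x)


def relu_grad(x):
    return (np.asarray(x) > 0).astype(float)


def lrelu_softplus(x, a: float = 0.01):
    """Shifted softplus for x >= 0, a*x for x < 0.

    Evaluated in the overflow-safe form ``x + ln(1 + e^-x) - ln 2`` on the
    positive branch, so large inputs do not overflow.
    """
    x = np.asarray(x, dtype=float)
    pos = x >= 0
    out = np.empty_like(x)
    xp = x[pos]
    out[pos] = xp + np.log1p(np.exp(-xp)) - LN2
    out[~pos] = a * x[~pos]
    if out.ndim == 0:
        return float(out)
    return out


def lrelu_softplus_grad(x, a: float = 0.01):
    """Derivative: sigmoid(x) for x >= 0, a for x < 0."""
    x = np.asarray(x, dtype=float)
    pos = x >= 0
    out = np.empty_like(x)
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    out[~pos] = a
    if out.ndim == 0:
        return float(out)
    return out
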