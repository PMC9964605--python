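"""Central-finite-difference gradient checking against the autodiff tape."""

import numpy as np

from sgcsrm.autodiff import Tensor


def numeric_gradient(fn, tensor: Tensor, h: float = 1e-6) -> np.ndarray:
    """Central differences of scalar ``fn()`` w.r.t. ``tensor.data``."""
    grad = np.zeros_like(tensor.data, dtype=float)
    flat = tensor.data.reshape(-1)
    gflat = grad.reshape(-1)
    for i in range(flat.size):
        orig = flat[i]
        flat[i] = orig + h
        up = float(fn())
        flat[i] = orig - h
        down = float(fn())
        flat[i] = orig
        gflat[i] = (up - down) / (2 * h)
    return grad


def assert_gradients_match(build_loss, params: dict[str, Tensor], rtol: float = 1e-4):
    """``build_loss()`` returns a scalar Tensor; compare analytic vs numeric.

    The loss must be rebuilt on every call (the tape is single-use), and must
    be deterministic in the parameter values.
    """
    loss = build_loss()
    for p in params.values():
        p.grad = None
    loss.backward()
    analytic = {name: p.grad.copy() for name, p in params.items()}
    for name, p in params.items():
        numeric = numeric_gradient(lambda: build_loss().data, p)
        scale = max(np.abs(numeric).max(), np.abs(analytic[name]).max(), 1e-8)
        err = np.abs(analytic[name] - numeric).max() / scale
        assert err < rtol, f"gradient mismatch for {name}: rel err {err:.2e}"
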