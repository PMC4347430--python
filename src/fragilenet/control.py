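"""State-feedback gains that cancel the destabilizing row perturbation.

Two designs are provided for a network destabilized by ``W_s + Delta``:

* ``linear_gain``:    K = -B^-1 Delta, derived from the linearized dynamics;
  the closed-loop linear system satisfies A + Delta + B K = A exactly.
* ``nonlinear_gain``: K = -Delta; the control input cancels the perturbation
  inside the synaptic input itself, (W_s + Delta) x + (-Delta x + h)
  = W_s x + h, so the stochastic dynamics revert exactly to the stable mode.

The applied input is ``u = sigma * K x + h`` with the binary state vector x
and the switch signal sigma set by the stability detector.  Only the fragile
node's row of K is non-zero, so control authority is restricted to that node.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np
from numpy.typing import NDArray

from .fragility import InputMatrix, PerturbationMatrix
from .network import DimensionError

__all__ = ["GainMatrix", "ControlError", "linear_gain", "nonlinear_gain", "control_input"]


class ControlError(RuntimeError):
    pass


@dataclass(frozen=True)
class GainMatrix:
    """Feedback gain; only row ``fragile_row`` (1-based) may be non-zero."""

    K: NDArray[np.float64]
    variant: Literal["linear", "nonlinear"]
    fragile_row: int


def linear_gain(B: InputMatrix, delta: PerturbationMatrix) -> GainMatrix:
    """Linear-model gain ``K = -B^-1 Delta``.

    Requires every diagonal entry of B to be non-zero (a node whose response
    is saturated at the fixed point has no input authority); raises
    :class:`ControlError` naming the first offending node otherwise.
    """
    diag = B.diag
    zero = np.nonzero(diag == 0.0)[0]
    if zero.size:
        raise ControlError(
            f"input matrix is singular at node {zero[0] + 1}: response saturated "
            "at the fixed point; linear gain unavailable"
        )
    K = -delta.delta / diag[:, None]
    return GainMatrix(K=K, variant="linear", fragile_row=delta.row_index)


def nonlinear_gain(delta: PerturbationMatrix) -> GainMatrix:
    """Nonlinear-model gain ``K = -Delta`` (exact synaptic cancellation)."""
    return GainMatrix(K=-delta.delta, variant="nonlinear", fragile_row=delta.row_index)


def control_input(K: GainMatrix | NDArray, x, h, sigma: int):
    """Applied input ``u = sigma * K x + h``; equals ``h`` exactly when the
    switch signal is 0."""
    K_mat = K.K if isinstance(K, GainMatrix) else np.asarray(K, dtype=float)
    x = np.asarray(x, dtype=float)
    h = np.asarray(h, dtype=float)
    n = K_mat.shape[0]
    if K_mat.shape != (n, n) or x.shape != (n,) or h.shape != (n,):
        raise DimensionError(
            f"dimension mismatch: K {K_mat.shape}, x {x.shape}, h {h.shape}"
        )
    if sigma == 0:
        return h.copy()
    return sigma * (K_mat @ x) + h
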