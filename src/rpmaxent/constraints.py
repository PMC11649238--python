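"""Synaptic constraint schemes for reshaping.

During reshaping the trainable parameters are an unconstrained weight
matrix ``ã``; the synaptic weights actually used by the model are a
deterministic function ``a = g(ã)`` of it:

- ``none``            a = ã (identity)
- ``bounded``         a_ij = clip(ã_ij, -ω, ω)      (synapse ceiling ω)
- ``homeo_input``     a_ij = φ ã_ij / Σ_k |ã_ik|    (row sums fixed: each
                      projection's incoming synaptic weight totals φ)
- ``homeo_output``    a_ij = φ ã_ij / Σ_k |ã_kj|    (column sums fixed:
                      each neuron's outgoing synaptic weight totals φ)
- ``homeo_circuit``   a_ij = φ ã_ij / Σ_kl |ã_kl|   (whole circuit fixed)

The homeostatic kinds implement synaptic normalization: strengthening
one synapse necessarily weakens the others sharing its budget.
Gradients flow to ``ã`` through g by the chain rule, with sign(0) = 0
as the subgradient of |·| at the origin.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import DegenerateProjectionError, ParameterError

__all__ = ["ConstraintSpec", "apply_constraint", "constraint_vjp"]

_KINDS = ("none", "bounded", "homeo_input", "homeo_output", "homeo_circuit")
_HOMEO = ("homeo_input", "homeo_output", "homeo_circuit")


@dataclass(frozen=True)
class ConstraintSpec:
    """Which synaptic constraint governs reshaping.

    Exactly one of ``omega`` (bounded) or ``phi`` (homeostatic kinds) is
    set, according to ``kind``; ``kind='none'`` takes neither.
    """

    kind: str = "none"
    omega: float | None = None
    phi: float | None = None

    def __post_init__(self) -> None:
        if self.kind not in _KINDS:
            raise ParameterError(f"unknown constraint kind {self.kind!r}")
        if self.kind == "bounded":
            if self.omega is None or not self.omega > 0:
                raise ParameterError("bounded constraint requires omega > 0")
            if self.phi is not None:
                raise ParameterError("bounded constraint takes omega, not phi")
        elif self.kind in _HOMEO:
            if self.phi is None or not self.phi > 0:
                raise ParameterError(f"{self.kind} constraint requires phi > 0")
            if self.omega is not None:
                raise ParameterError(f"{self.kind} constraint takes phi, not omega")
        else:  # none
            if self.omega is not None or self.phi is not None:
                raise ParameterError("kind='none' takes neither omega nor phi")


def _check_mask(A_tilde: np.ndarray, mask: np.ndarray) -> None:
    if A_tilde.shape != mask.shape:
        raise ParameterError("weight matrix and mask shapes differ")
    if np.any(np.asarray(A_tilde)[np.asarray(mask) == 0] != 0.0):
        raise ParameterError("unconstrained weights must be 0 outside the mask")


def apply_constraint(
    A_tilde: np.ndarray, mask: np.ndarray, constraint: ConstraintSpec
) -> np.ndarray:
    """Map unconstrained weights ``ã`` to constrained weights ``a = g(ã)``.

    After the map, homeo_input rows, homeo_output columns (those with at
    least one synapse) and the homeo_circuit total each carry exactly
    their budget φ of absolute weight; bounded entries satisfy |a| <= ω.
    A zero norm where a budget must be distributed raises
    :class:`DegenerateProjectionError`.
    """
    A_tilde = np.asarray(A_tilde, dtype=np.float64)
    mask = np.asarray(mask)
    _check_mask(A_tilde, mask)
    kind = constraint.kind
    if kind == "none":
        return A_tilde.copy()
    if kind == "bounded":
        return np.clip(A_tilde, -constraint.omega, constraint.omega)
    absA = np.abs(A_tilde)
    if kind == "homeo_input":
        norms = absA.sum(axis=1, keepdims=True)
        if np.any(norms == 0.0):
            raise DegenerateProjectionError(
                "a projection's incoming weights all vanished; cannot normalize"
            )
        return constraint.phi * A_tilde / norms
    if kind == "homeo_output":
        norms = absA.sum(axis=0, keepdims=True)
        connected = mask.sum(axis=0, keepdims=True) > 0
        if np.any(connected & (norms == 0.0)):
            raise DegenerateProjectionError(
                "a connected neuron's outgoing weights all vanished; cannot normalize"
            )
        out = np.where(connected, constraint.phi * A_tilde / np.where(norms == 0, 1.0, norms), 0.0)
        return out
    # homeo_circuit
    total = absA.sum()
    if total == 0.0:
        raise DegenerateProjectionError("total circuit weight is zero; cannot normalize")
    return constraint.phi * A_tilde / total


def constraint_vjp(
    grad_a: np.ndarray,
    A_tilde: np.ndarray,
    mask: np.ndarray,
    constraint: ConstraintSpec,
) -> np.ndarray:
    """Pull a gradient w.r.t. ``a`` back to ``ã`` through ``g``.

    Vector–Jacobian product of :func:`apply_constraint`. For the
    normalizing kinds, with s = sign(ã) and S the relevant |ã| norm,

        grad_ã = (φ/S) (grad_a - s * (grad_a · a) / φ)

    taken over the row / column / whole matrix respectively. For the
    bounded kind the clip derivative is 1 on |ã| <= ω and 0 outside.
    """
    grad_a = np.asarray(grad_a, dtype=np.float64)
    A_tilde = np.asarray(A_tilde, dtype=np.float64)
    mask_b = np.asarray(mask) != 0
    kind = constraint.kind
    if kind == "none":
        return np.where(mask_b, grad_a, 0.0)
    if kind == "bounded":
        inside = np.abs(A_tilde) <= constraint.omega
        return np.where(mask_b & inside, grad_a, 0.0)
    s = np.sign(A_tilde)
    a = apply_constraint(A_tilde, mask, constraint)
    phi = constraint.phi
    if kind == "homeo_input":
        S = np.abs(A_tilde).sum(axis=1, keepdims=True)
        dot = (grad_a * a).sum(axis=1, keepdims=True)
    elif kind == "homeo_output":
        S = np.abs(A_tilde).sum(axis=0, keepdims=True)
        S = np.where(S == 0.0, 1.0, S)
        dot = (grad_a * a).sum(axis=0, keepdims=True)
    else:  # homeo_circuit
        S = np.abs(A_tilde).sum()
        dot = (grad_a * a).sum()
    out = (phi / S) * (grad_a - s * dot / phi)
    return np.where(mask_b, out, 0.0)
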