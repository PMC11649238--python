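"""Sparse random projections: the intermediate layer of the RP circuit.

Each projection is a nonlinear read-out ``f_i(x) = sigma(sum_j a_ij x_j - theta_i)``
of the population pattern ``x``. Connectivity is sparse: neuron ``j``
feeds projection ``i`` with probability ``indegree / n``, and nonzero
weights are drawn from N(1, 1). Thresholds default to 1.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.special import expit

from .errors import ParameterError, ShapeError
from .raster import SpikeRaster

__all__ = [
    "Nonlinearity",
    "ProjectionSet",
    "build_sparse_projections",
    "projection_activations",
]


@dataclass(frozen=True)
class Nonlinearity:
    """Projection nonlinearity: Heaviside step or logistic sigmoid.

    The sigmoid ``sigma(u) = 1 / (1 + exp(-beta * u))`` interpolates between
    an independent population model (beta -> 0, all outputs 1/2) and the
    hard-threshold Heaviside model (beta -> inf). The Heaviside boundary
    convention is H(0) = 1, applied consistently everywhere. The default
    is Heaviside (the classic random-projection choice); a sigmoid always
    requires an explicit slope beta.
    """

    kind: str = "heaviside"
    beta: float | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("heaviside", "sigmoid"):
            raise ParameterError(f"unknown nonlinearity kind {self.kind!r}")
        if self.kind == "sigmoid":
            if self.beta is None or not self.beta > 0:
                raise ParameterError("sigmoid nonlinearity requires beta > 0")
        elif self.beta is not None:
            raise ParameterError("heaviside nonlinearity takes no beta")

    def __call__(self, u: np.ndarray) -> np.ndarray:
        u = np.asarray(u, dtype=np.float64)
        if self.kind == "heaviside":
            return (u >= 0).astype(np.float64)
        return expit(self.beta * u)

    def derivative(self, u: np.ndarray) -> np.ndarray:
        """d sigma / d u. Zero almost everywhere for Heaviside."""
        if self.kind == "heaviside":
            return np.zeros_like(np.asarray(u, dtype=np.float64))
        s = self(u)
        return self.beta * s * (1.0 - s)


@dataclass
class ProjectionSet:
    """Connectivity mask, synaptic weights, thresholds and nonlinearity.

    Invariants: ``weights`` is exactly zero wherever ``mask`` is zero, and
    every projection (row) has at least one input synapse.
    """

    mask: np.ndarray
    weights: np.ndarray
    thresholds: np.ndarray
    nonlinearity: Nonlinearity = field(default_factory=Nonlinearity)

    def __post_init__(self) -> None:
        self.mask = np.ascontiguousarray(np.asarray(self.mask), dtype=np.uint8)
        self.weights = np.ascontiguousarray(self.weights, dtype=np.float64)
        self.thresholds = np.ascontiguousarray(
            np.atleast_1d(self.thresholds), dtype=np.float64
        )
        if self.mask.ndim != 2:
            raise ShapeError("mask must be 2-D (n_proj, n_neurons)")
        if self.weights.shape != self.mask.shape:
            raise ShapeError(
                f"weights shape {self.weights.shape} != mask shape {self.mask.shape}"
            )
        if self.thresholds.shape != (self.mask.shape[0],):
            raise ShapeError("thresholds must have length n_proj")
        if not np.isin(self.mask, (0, 1)).all():
            raise ParameterError("mask entries must be 0/1")
        if (self.mask.sum(axis=1) == 0).any():
            raise ParameterError("every projection needs at least one input synapse")
        if np.any(self.weights[self.mask == 0] != 0.0):
            raise ParameterError("weights must be exactly 0 outside the mask")

    @property
    def n_proj(self) -> int:
        return self.mask.shape[0]

    @property
    def n_neurons(self) -> int:
        return self.mask.shape[1]

    def preactivations(self, X: np.ndarray) -> np.ndarray:
        """``u_ti = sum_j a_ij x_tj - theta_i`` for each row of X."""
        X = np.asarray(X, dtype=np.float64)
        if X.ndim == 1:
            X = X[None, :]
        if X.shape[1] != self.n_neurons:
            raise ShapeError(
                f"pattern length {X.shape[1]} != n_neurons {self.n_neurons}"
            )
        return X @ self.weights.T - self.thresholds

    def copy(self) -> "ProjectionSet":
        return replace(
            self,
            mask=self.mask.copy(),
            weights=self.weights.copy(),
            thresholds=self.thresholds.copy(),
        )


def build_sparse_projections(
    n_neurons: int,
    n_proj: int,
    indegree: float,
    nonlinearity: Nonlinearity | None = None,
    seed: int | None = None,
) -> ProjectionSet:
    """Draw a random sparse projection set.

    Each mask entry is an independent Bernoulli(``indegree / n_neurons``)
    draw, so the expected in-degree of every projection is ``indegree``;
    ``indegree = n_neurons`` yields the fully connected mask. Projections
    that come out with no inputs are redrawn (a projection with no inputs
    is a constant and carries no information). Nonzero weights are sampled
    from N(1, 1) signed as drawn; all thresholds are set to 1.
    """
    if n_neurons < 1 or n_proj < 1:
        raise ParameterError("n_neurons and n_proj must be >= 1")
    if not 0.0 < indegree <= n_neurons:
        raise ParameterError(
            f"indegree must be in (0, n_neurons={n_neurons}], got {indegree}"
        )
    rng = np.random.default_rng(seed)
    p = indegree / n_neurons
    mask = (rng.random((n_proj, n_neurons)) < p).astype(np.uint8)
    # redraw empty rows until every projection has at least one input
    empty = np.flatnonzero(mask.sum(axis=1) == 0)
    while empty.size:
        mask[empty] = (rng.random((empty.size, n_neurons)) < p).astype(np.uint8)
        empty = np.flatnonzero(mask.sum(axis=1) == 0)
    weights = np.where(mask == 1, rng.normal(1.0, 1.0, size=mask.shape), 0.0)
    thresholds = np.ones(n_proj)
    return ProjectionSet(
        mask=mask,
        weights=weights,
        thresholds=thresholds,
        nonlinearity=nonlinearity or Nonlinearity(),
    )


def projection_activations(P: ProjectionSet, X: "SpikeRaster | np.ndarray") -> np.ndarray:
    """Projection outputs ``f_i(x_t)``, shape (n_samples, n_proj), in [0, 1]."""
    data = X.data if isinstance(X, SpikeRaster) else np.asarray(X)
    return P.nonlinearity(P.preactivations(data))
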