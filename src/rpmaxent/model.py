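"""The random-projections maximum-entropy distribution.

An :class:`RPModel` assigns every binary population pattern ``x`` the
Gibbs probability

    p(x) = exp(-E(x)) / Z,   E(x) = sum_i lambda_i f_i(x),

where ``f_i`` are the projections and ``lambda_i`` their Lagrange
multipliers. This is the maximum-entropy distribution consistent with the
observed projection means. For populations up to ``ENUMERATION_CAP``
neurons the partition function Z and all expectations are computed by
exact enumeration of the 2^n states; larger populations go through the
sampler module.
"""
from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from scipy.special import logsumexp

from .errors import EnumerationCapError, ShapeError
from .projections import ProjectionSet, projection_activations
from .raster import SpikeRaster

__all__ = [
    "RPModel",
    "ENUMERATION_CAP",
    "all_patterns",
    "energy",
    "enumerate_distribution",
    "log_partition_exact",
    "exact_mean_log_likelihood",
]

#: Largest population for which 2^n enumeration is attempted (2^20 ~ 1.05M states).
ENUMERATION_CAP = 20


@dataclass
class RPModel:
    """Projection set plus coefficients ``lambda_i``; defines pattern energies."""

    projections: ProjectionSet
    lambdas: np.ndarray

    def __post_init__(self) -> None:
        self.lambdas = np.ascontiguousarray(
            np.atleast_1d(self.lambdas), dtype=np.float64
        )
        if self.lambdas.shape != (self.projections.n_proj,):
            raise ShapeError(
                f"lambdas length {self.lambdas.shape} != n_proj "
                f"{self.projections.n_proj}"
            )
        if not np.isfinite(self.lambdas).all():
            raise ShapeError("lambdas must be finite")

    @property
    def n_neurons(self) -> int:
        return self.projections.n_neurons

    @property
    def n_proj(self) -> int:
        return self.projections.n_proj

    def copy(self) -> "RPModel":
        return RPModel(self.projections.copy(), self.lambdas.copy())


@lru_cache(maxsize=4)
def _all_patterns_cached(n: int) -> np.ndarray:
    bits = (np.arange(2**n, dtype=np.uint32)[:, None] >> np.arange(n)) & 1
    bits = bits.astype(np.uint8)
    bits.setflags(write=False)
    return bits

def all_patterns(n_neurons: int) -> np.ndarray:
    """All 2^n binary patterns as a read-only (2^n, n) array.

    Pattern ``k`` holds the binary expansion of ``k``, least-significant
    bit in column 0, so ``pattern_index = x @ 2**arange(n)``.
    """
    if n_neurons > ENUMERATION_CAP:
        raise EnumerationCapError(
            f"n_neurons={n_neurons} exceeds the enumeration cap "
            f"{ENUMERATION_CAP}; use the sampler/AIS path instead"
        )
    return _all_patterns_cached(n_neurons)


def energy(M: RPModel, x: np.ndarray) -> "float | np.ndarray":
    """``E(x) = sum_i lambda_i f_i(x)`` for one pattern or a stack of patterns."""
    x = np.asarray(x)
    single = x.ndim == 1
    F = projection_activations(M.projections, np.atleast_2d(x))
    E = F @ M.lambdas
    return float(E[0]) if single else E


def _all_energies(M: RPModel) -> np.ndarray:
    return energy(M, all_patterns(M.n_neurons))


def log_partition_exact(M: RPModel) -> float:
    """ln Z by exact enumeration (n <= ENUMERATION_CAP)."""
    return float(logsumexp(-_all_energies(M)))


def enumerate_distribution(M: RPModel) -> tuple[float, np.ndarray]:
    """Exact partition function and the full pattern distribution.

    Returns ``(Z, probs)`` where ``probs[k]`` is the probability of the
    pattern whose binary expansion (LSB first) is ``k``. This is the exact
    oracle every sampler and trainer in the package is tested against.
    """
    E = _all_energies(M)
    lnZ = float(logsumexp(-E))
    probs = np.exp(-E - lnZ)
    return float(np.exp(lnZ)), probs


def pattern_index(x: np.ndarray) -> np.ndarray:
    """Index of each pattern row into the ``all_patterns`` ordering."""
    x = np.atleast_2d(np.asarray(x, dtype=np.uint64))
    powers = np.uint64(1) << np.arange(x.shape[1], dtype=np.uint64)
    return (x * powers).sum(axis=1).astype(np.int64)


def exact_mean_log_likelihood(M: RPModel, X: SpikeRaster) -> float:
    """Mean per-sample log-probability of the raster under M, in nats.

    ``(1/T) sum_t [-E(x_t) - ln Z]`` with Z from exact enumeration. Equals
    ``-n ln 2`` for the uniform (no-projection or lambda = 0) model.
    """
    if X.n_neurons != M.n_neurons:
        raise ShapeError(
            f"raster has {X.n_neurons} neurons, model has {M.n_neurons}"
        )
    lnZ = log_partition_exact(M)
    pats, counts = X.unique_patterns()
    E = energy(M, pats)
    return float((counts @ (-E - lnZ)) / counts.sum())


def exact_model_expectations(M: RPModel) -> dict[str, np.ndarray]:
    """Exact expectations used by trainers and metrics (n <= cap).

    Returns projection means ``<f_i>``, neuron means ``<x_j>``, the second
    moments ``<f_i f_j>``, and the weighted activation helpers needed by
    the reshape gradient: ``<sigma'_i x_j>`` and ``<sigma'_i>``.
    """
    X = all_patterns(M.n_neurons).astype(np.float64)
    P = M.projections
    U = P.preactivations(X)
    F = P.nonlinearity(U)
    Fp = P.nonlinearity.derivative(U)
    E = F @ M.lambdas
    lnZ = float(logsumexp(-E))
    w = np.exp(-E - lnZ)
    f_mean = w @ F
    return {
        "lnZ": lnZ,
        "probs": w,
        "f_mean": f_mean,
        "x_mean": w @ X,
        "ff_mean": (F * w[:, None]).T @ F,
        "dsig_x_mean": (Fp * w[:, None]).T @ X,
        "dsig_mean": w @ Fp,
    }


def empirical_expectations(M: RPModel, X: SpikeRaster) -> dict[str, np.ndarray]:
    """Data-side counterparts of :func:`exact_model_expectations`."""
    pats, counts = X.unique_patterns()
    return expectations_from_patterns(M, pats, counts)


def expectations_from_patterns(
    M: RPModel, pats: np.ndarray, counts: np.ndarray
) -> dict[str, np.ndarray]:
    """Empirical expectations from a pre-reduced (patterns, counts) pair.

    Trainers call this with the unique-pattern reduction computed once,
    since the raster never changes across iterations.
    """
    w = counts / counts.sum()
    P = M.projections
    Xf = pats.astype(np.float64)
    U = P.preactivations(Xf)
    F = P.nonlinearity(U)
    Fp = P.nonlinearity.derivative(U)
    return {
        "f_mean": w @ F,
        "x_mean": w @ Xf,
        "dsig_x_mean": (Fp * w[:, None]).T @ Xf,
        "dsig_mean": w @ Fp,
        "n_samples": int(counts.sum()),
    }
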