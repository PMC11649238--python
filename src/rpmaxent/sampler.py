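"""Markov-chain sampling and partition-function estimation.

For populations beyond the exact-enumeration cap the model is sampled by
single-spin-flip Metropolis–Hastings, and ln Z is estimated by annealed
importance sampling (AIS) along a geometric inverse-temperature ladder
from the uniform distribution (lnZ = n ln 2) to the target model.

The inner loops are numba kernels; a chain is fully determined by its
seed, so runs are reproducible.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from numba import njit
from scipy.special import logsumexp

from .errors import ParameterError
from .model import RPModel
from .raster import SpikeRaster

__all__ = ["ChainConfig", "mh_sample", "estimate_log_partition_ais"]

logger = logging.getLogger("rpmaxent")


@dataclass
class ChainConfig:
    """Metropolis–Hastings chain settings.

    ``burn_in`` and ``thin`` are counted in proposed single-neuron flips;
    when left as None they default to ``10 * n_neurons`` and ``n_neurons``
    respectively (one expected update per neuron between retained samples).
    """

    n_samples: int = 10_000
    burn_in: int | None = None
    thin: int | None = None
    seed: int = 0
    init: str = "random"
    init_pattern: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.n_samples < 1:
            raise ParameterError("n_samples must be >= 1")
        if self.burn_in is not None and self.burn_in < 0:
            raise ParameterError("burn_in must be >= 0")
        if self.thin is not None and self.thin < 1:
            raise ParameterError("thin must be >= 1")
        if self.init not in ("random", "data_pattern", "zeros"):
            raise ParameterError(f"unknown init {self.init!r}")
        if self.init == "data_pattern" and self.init_pattern is None:
            raise ParameterError("init='data_pattern' requires init_pattern")


@njit(cache=True)
def _sigma(u: float, beta: float, sigmoid: bool) -> float:
    if sigmoid:
        return 1.0 / (1.0 + np.exp(-beta * u))
    return 1.0 if u >= 0.0 else 0.0


@njit(cache=True)
def _energy_from_u(u, lam, beta, sigmoid):
    E = 0.0
    for i in range(u.size):
        E += lam[i] * _sigma(u[i], beta, sigmoid)
    return E


@njit(cache=True)
def _mh_kernel(W, theta, lam, beta, sigmoid, x0, n_keep, burn_in, thin, seed):
    np.random.seed(seed)
    n_proj, n = W.shape
    x = x0.copy()
    u = np.empty(n_proj)
    for i in range(n_proj):
        s = 0.0
        for j in range(n):
            if x[j]:
                s += W[i, j]
        u[i] = s - theta[i]
    out = np.empty((n_keep, n), dtype=np.uint8)
    kept = 0
    flips = 0
    accepted = 0
    total = burn_in + n_keep * thin
    while flips < total:
        j = np.random.randint(n)
        sgn = -1.0 if x[j] else 1.0
        dE = 0.0
        for i in range(n_proj):
            if W[i, j] != 0.0:
                dE += lam[i] * (
                    _sigma(u[i] + sgn * W[i, j], beta, sigmoid)
                    - _sigma(u[i], beta, sigmoid)
                )
        if dE <= 0.0 or np.random.random() < np.exp(-dE):
            x[j] = 0 if x[j] else 1
            for i in range(n_proj):
                u[i] += sgn * W[i, j]
            accepted += 1
        flips += 1
        if flips > burn_in and (flips - burn_in) % thin == 0:
            out[kept] = x
            kept += 1
    return out, accepted, total


def _model_arrays(M: RPModel) -> tuple[np.ndarray, np.ndarray, np.ndarray, float, bool]:
    P = M.projections
    sigmoid = P.nonlinearity.kind == "sigmoid"
    beta = float(P.nonlinearity.beta) if sigmoid else 1.0
    return P.weights, P.thresholds, M.lambdas, beta, sigmoid


def mh_sample(M: RPModel, cfg: ChainConfig) -> SpikeRaster:
    """Sample a raster from the model by single-flip Metropolis–Hastings.

    Proposals flip one uniformly chosen neuron; acceptance probability is
    ``min(1, exp(E(x) - E(x')))`` for the Gibbs target ``p ∝ exp(-E)``.
    A warning is logged when the acceptance rate falls below 1% (slowly
    mixing chain, typically huge ``|lambda|``).
    """
    n = M.n_neurons
    burn_in = 10 * n if cfg.burn_in is None else cfg.burn_in
    thin = n if cfg.thin is None else cfg.thin
    rng = np.random.default_rng(cfg.seed)
    if cfg.init == "zeros":
        x0 = np.zeros(n, dtype=np.uint8)
    elif cfg.init == "data_pattern":
        x0 = np.asarray(cfg.init_pattern, dtype=np.uint8).ravel()
        if x0.size != n:
            raise ParameterError("init_pattern length != n_neurons")
    else:
        x0 = (rng.random(n) < 0.5).astype(np.uint8)
    W, theta, lam, beta, sigmoid = _model_arrays(M)
    kernel_seed = int(rng.integers(0, 2**31 - 1))
    out, accepted, total = _mh_kernel(
        W, theta, lam, beta, sigmoid, x0, cfg.n_samples, burn_in, thin, kernel_seed
    )
    rate = accepted / total
    if rate < 0.01:
        logger.warning(
            "MH acceptance rate %.4f < 1%%; chain may be mixing poorly", rate
        )
    return SpikeRaster(out)


@njit(cache=True)
def _ais_kernel(W, theta, lam, beta, sigmoid, ladder, n_sweeps, seed):
    np.random.seed(seed)
    n_proj, n = W.shape
    x = np.empty(n, dtype=np.uint8)
    for j in range(n):
        x[j] = 1 if np.random.random() < 0.5 else 0
    u = np.empty(n_proj)
    for i in range(n_proj):
        s = 0.0
        for j in range(n):
            if x[j]:
                s += W[i, j]
        u[i] = s - theta[i]
    lnw = 0.0
    for k in range(1, ladder.size):
        t_prev = ladder[k - 1]
        t = ladder[k]
        E = _energy_from_u(u, lam, beta, sigmoid)
        lnw += (t - t_prev) * (-E)
        # MH sweeps targeting p_t ∝ exp(-t E)
        for _ in range(n_sweeps * n):
            j = np.random.randint(n)
            sgn = -1.0 if x[j] else 1.0
            dE = 0.0
            for i in range(n_proj):
                if W[i, j] != 0.0:
                    dE += lam[i] * (
                        _sigma(u[i] + sgn * W[i, j], beta, sigmoid)
                        - _sigma(u[i], beta, sigmoid)
                    )
            if t * dE <= 0.0 or np.random.random() < np.exp(-t * dE):
                x[j] = 0 if x[j] else 1
                for i in range(n_proj):
                    u[i] += sgn * W[i, j]
    return lnw


def geometric_ladder(n_temps: int, t_min: float = 1e-3) -> np.ndarray:
    """Inverse-temperature ladder: 0, then geometric from ``t_min`` to 1."""
    if n_temps < 2:
        raise ParameterError("n_temps must be >= 2")
    if not 0.0 < t_min < 1.0:
        raise ParameterError("t_min must be in (0, 1)")
    return np.concatenate([[0.0], np.geomspace(t_min, 1.0, n_temps - 1)])


def estimate_log_partition_ais(
    M: RPModel,
    n_chains: int = 64,
    n_temps: int = 100,
    seed: int = 0,
    n_sweeps: int = 2,
    n_bootstrap: int = 200,
) -> tuple[float, float]:
    """Annealed-importance-sampling estimate of ln Z with a bootstrap SE.

    Anneals from the uniform model (lnZ0 = n ln 2) to the target along a
    geometric inverse-temperature ladder, running ``n_sweeps`` MH sweeps
    per rung. Returns ``(lnZ, se)``; the SE is the bootstrap standard
    deviation over per-chain importance weights.
    """
    if n_chains < 2:
        raise ParameterError("n_chains must be >= 2")
    ladder = geometric_ladder(n_temps)
    W, theta, lam, beta, sigmoid = _model_arrays(M)
    rng = np.random.default_rng(seed)
    seeds = rng.integers(0, 2**31 - 1, size=n_chains)
    lnws = np.array(
        [
            _ais_kernel(W, theta, lam, beta, sigmoid, ladder, n_sweeps, int(s))
            for s in seeds
        ]
    )
    lnZ0 = M.n_neurons * np.log(2.0)
    lnZ = lnZ0 + float(logsumexp(lnws)) - np.log(n_chains)
    idx = rng.integers(0, n_chains, size=(n_bootstrap, n_chains))
    boot = lnZ0 + logsumexp(lnws[idx], axis=1) - np.log(n_chains)
    return lnZ, float(boot.std(ddof=1))
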