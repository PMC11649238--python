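"""Evaluation quantities: held-out likelihood, pattern-probability
funnels, projection firing rates and correlations, rotation angles,
synaptic-budget accounting, and firing-rate-change CDFs."""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .constraints import ConstraintSpec
from .errors import DegenerateProjectionError, ParameterError, ShapeError
from .model import (
    RPModel,
    energy,
    exact_model_expectations,
    log_partition_exact,
)
from .projections import ProjectionSet, projection_activations
from .raster import SpikeRaster
from .sampler import ChainConfig, estimate_log_partition_ais, mh_sample
from .training import clopper_pearson_interval

__all__ = [
    "BudgetReport",
    "test_log_likelihood",
    "pattern_probability_comparison",
    "projection_firing_rates",
    "projection_correlations",
    "rotation_angles",
    "synaptic_budget",
    "firing_rate_change_cdf",
]

logger = logging.getLogger("rpmaxent")


@dataclass
class BudgetReport:
    """Synaptic-weight budget accounting.

    ``used`` is the total absolute synaptic weight Σ|a_ij|; ``available``
    is the constraint-implied ceiling (ω per synapse for bounded, φ per
    projection for homeo_input, φ per connected neuron for homeo_output,
    φ total for homeo_circuit; None when unconstrained).
    ``normalized_used`` expresses ``used`` in units where the initial
    projection set's total absolute weight is 1.
    """

    used: float
    available: float | None
    normalized_used: float


def test_log_likelihood(
    M: RPModel,
    X_test: SpikeRaster,
    method: str = "exact",
    n_chains: int = 64,
    n_temps: int = 100,
    seed: int = 0,
) -> tuple[float, float]:
    """Mean held-out log-likelihood in nats/sample, with a standard error.

    ``method='exact'`` enumerates Z (small n); ``method='ais'`` estimates
    ln Z by annealed importance sampling and propagates its uncertainty
    into the returned SE along with the across-sample variability.
    """
    if X_test.n_neurons != M.n_neurons:
        raise ShapeError("raster and model disagree on n_neurons")
    E = energy(M, X_test.data)
    if method == "exact":
        lnZ, lnZ_se = log_partition_exact(M), 0.0
    elif method == "ais":
        lnZ, lnZ_se = estimate_log_partition_ais(
            M, n_chains=n_chains, n_temps=n_temps, seed=seed
        )
    else:
        raise ParameterError(f"unknown method {method!r}")
    ll = -E - lnZ
    se = float(np.sqrt(ll.var(ddof=1) / ll.size + lnZ_se**2))
    return float(ll.mean()), se


def pattern_probability_comparison(
    M: RPModel, X_test: SpikeRaster, ci: float = 0.99
) -> pd.DataFrame:
    """Observed vs. predicted probability of each observed pattern.

    Returns a table (one row per distinct pattern in ``X_test``, sorted by
    empirical probability descending) with the model probability and the
    Clopper–Pearson ``ci`` funnel around the empirical count/T estimate —
    the scatter behind pattern-probability plots.
    """
    pats, counts = X_test.unique_patterns()
    T = counts.sum()
    lnZ = log_partition_exact(M)
    model_p = np.exp(-energy(M, pats) - lnZ)
    bounds = np.array([clopper_pearson_interval(int(k), int(T), ci) for k in counts])
    df = pd.DataFrame(
        {
            "pattern": ["".join(map(str, row)) for row in pats],
            "count": counts,
            "empirical_p": counts / T,
            "model_p": model_p,
            "ci_lo": bounds[:, 0],
            "ci_hi": bounds[:, 1],
        }
    )
    return df.sort_values("empirical_p", ascending=False, ignore_index=True)


def _model_activation_samples(
    M: RPModel, source, chain_config: ChainConfig | None, seed: int
) -> np.ndarray:
    """Projection activations under the requested source (sample matrix)."""
    if isinstance(source, SpikeRaster):
        return projection_activations(M.projections, source)
    if source == "samples":
        cfg = chain_config or ChainConfig(n_samples=50_000, seed=seed)
        return projection_activations(M.projections, mh_sample(M, cfg))
    raise ParameterError(f"unknown source {source!r}")


def projection_firing_rates(
    M: RPModel,
    source="exact",
    chain_config: ChainConfig | None = None,
    seed: int = 0,
) -> np.ndarray:
    """Mean activity ``<f_i>`` of each projection neuron, in [0, 1].

    ``source`` is ``'exact'`` (enumeration), ``'samples'`` (MH draws), or
    a :class:`SpikeRaster` whose empirical activation means are wanted.
    """
    if isinstance(source, str) and source == "exact":
        return exact_model_expectations(M)["f_mean"]
    return _model_activation_samples(M, source, chain_config, seed).mean(axis=0)


def projection_correlations(
    M: RPModel,
    source="exact",
    chain_config: ChainConfig | None = None,
    seed: int = 0,
    var_tol: float = 1e-12,
) -> float:
    """Mean pairwise Pearson correlation between projection outputs.

    Zero-variance projections are excluded (their count is logged); if
    fewer than two projections remain the correlation is undefined and a
    :class:`DegenerateProjectionError` is raised.
    """
    if M.n_proj < 2:
        raise ParameterError("need at least 2 projections for correlations")
    if isinstance(source, str) and source == "exact":
        ex = exact_model_expectations(M)
        m = ex["f_mean"]
        cov = ex["ff_mean"] - np.outer(m, m)
    else:
        F = _model_activation_samples(M, source, chain_config, seed)
        cov = np.cov(F, rowvar=False)
    var = np.diag(cov).copy()
    keep = var > var_tol
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.info("excluding %d zero-variance projections from correlations", n_dropped)
    if keep.sum() < 2:
        raise DegenerateProjectionError(
            "all projections are (near-)constant; correlation undefined"
        )
    cov = cov[np.ix_(keep, keep)]
    sd = np.sqrt(np.diag(cov))
    corr = cov / np.outer(sd, sd)
    iu = np.triu_indices_from(corr, k=1)
    return float(corr[iu].mean())


def rotation_angles(P0: ProjectionSet, P1: ProjectionSet) -> np.ndarray:
    """Angle (degrees, in [0, 180]) between each projection's initial and
    final weight vector — how far reshaping rotated it."""
    if P0.weights.shape != P1.weights.shape:
        raise ShapeError("projection sets must have the same shape")
    if not np.array_equal(P0.mask, P1.mask):
        raise ParameterError("projection sets must share the same mask")
    a0, a1 = P0.weights, P1.weights
    n0 = np.linalg.norm(a0, axis=1)
    n1 = np.linalg.norm(a1, axis=1)
    if np.any(n0 == 0) or np.any(n1 == 0):
        raise DegenerateProjectionError("zero-norm projection row; angle undefined")
    cosines = np.clip((a0 * a1).sum(axis=1) / (n0 * n1), -1.0, 1.0)
    return np.degrees(np.arccos(cosines))


def synaptic_budget(
    P: ProjectionSet, P_initial: ProjectionSet, constraint: ConstraintSpec
) -> BudgetReport:
    """Budget accounting in units of the initial set's total |weight|."""
    used = float(np.abs(P.weights).sum())
    initial_total = float(np.abs(P_initial.weights).sum())
    kind = constraint.kind
    if kind == "bounded":
        available = float(P.mask.sum()) * constraint.omega
    elif kind == "homeo_input":
        available = constraint.phi * P.n_proj
    elif kind == "homeo_output":
        available = constraint.phi * int((P.mask.sum(axis=0) > 0).sum())
    elif kind == "homeo_circuit":
        available = constraint.phi
    else:
        available = None
    return BudgetReport(
        used=used,
        available=available,
        normalized_used=used / initial_total,
    )


def firing_rate_change_cdf(
    rates_initial: np.ndarray, rates_final: np.ndarray
) -> tuple[np.ndarray, callable]:
    """Empirical CDF of the relative firing-rate change
    ``|FR_final - FR_initial| / FR_initial`` across projections.

    Projections with zero initial rate are excluded (count logged).
    Returns the sorted relative changes and a right-continuous step
    function evaluating the CDF.
    """
    ri = np.asarray(rates_initial, dtype=np.float64)
    rf = np.asarray(rates_final, dtype=np.float64)
    if ri.shape != rf.shape:
        raise ShapeError("rate vectors must have the same length")
    keep = ri > 0
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.info("excluding %d projections with zero initial rate", n_dropped)
    if not keep.any():
        raise ParameterError("no projections with positive initial rate")
    rel = np.sort(np.abs(rf[keep] - ri[keep]) / ri[keep])

    def cdf(x):
        return np.searchsorted(rel, np.asarray(x, dtype=np.float64), side="right") / rel.size

    return rel, cdf
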