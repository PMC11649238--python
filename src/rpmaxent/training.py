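"""Learning RP models: λ-training, reshaping, and joint (backprop) training.

Three modes, all maximizing the training log-likelihood
``L = -<E>_data - ln Z`` of the Gibbs model ``p ∝ exp(-E)``,
``E(x) = Σ_i λ_i f_i(x)``:

- ``train_lambdas``  — projections fixed, λ learned. Convex; the unique
  fixed point matches model and data projection means,
  ``<f_i>_model = <f_i>_data``. The ascent gradient is
  ``dL/dλ_i = <f_i>_model - <f_i>_data``.
- ``train_reshape``  — λ fixed, the nonzero synaptic weights a_ij of each
  projection are tuned ("reshaping"); optionally the thresholds too.
  Non-convex; a local optimum is accepted. Synaptic constraints
  (bounded / homeostatic normalization) are enforced exactly at every
  iteration through the reparameterization a = g(ã).
- ``train_backprop`` — both updates applied in the same gradient step.

Convergence follows the Clopper–Pearson criterion: training stops once
every projection's model marginal lies inside the two-sided exact
binomial confidence interval (default level 0.6827, the Gaussian 1-SD
coverage) around its empirical marginal.

Model expectations come either from exact enumeration (small n) or from
a persistent Metropolis–Hastings chain refreshed each iteration
(PCD-style) for larger populations.
"""
from __future__ import annotations

import time
from dataclasses import dataclass, replace

import numpy as np
from scipy.stats import beta as beta_dist

from .constraints import ConstraintSpec, apply_constraint, constraint_vjp
from .errors import (
    ConvergenceError,
    ParameterError,
    ShapeError,
    UnsupportedConfigurationError,
)
from .model import (
    RPModel,
    empirical_expectations,
    exact_model_expectations,
    expectations_from_patterns,
)
from .projections import ProjectionSet
from .raster import SpikeRaster
from .sampler import ChainConfig, mh_sample

__all__ = [
    "OptimizerConfig",
    "FitReport",
    "lambda_gradient",
    "reshape_gradient",
    "clopper_pearson_interval",
    "clopper_pearson_converged",
    "train_lambdas",
    "train_reshape",
    "train_backprop",
]


@dataclass
class OptimizerConfig:
    """Gradient-ascent settings shared by all training modes.

    ``learning_rate`` drives the synaptic-weight (reshape) updates;
    ``lambda_learning_rate`` drives the λ updates and defaults to
    ``learning_rate`` when unset. ``model_expectation_source`` selects
    exact enumeration or a persistent MH chain (``chain`` config).
    """

    algorithm: str = "momentum"
    learning_rate: float = 0.25
    lambda_learning_rate: float | None = None
    momentum: float = 0.9
    adam_beta1: float = 0.9
    adam_beta2: float = 0.999
    adam_eps: float = 1e-8
    max_iters: int = 1000
    model_expectation_source: str = "exact"
    chain: ChainConfig | None = None
    ci_level: float = 0.6827
    tune_thresholds: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.algorithm not in ("momentum", "adam"):
            raise ParameterError(f"unknown algorithm {self.algorithm!r}")
        if self.learning_rate < 0:
            raise ParameterError("learning_rate must be >= 0")
        if not 0.0 < self.ci_level < 1.0:
            raise ParameterError("ci_level must be in (0, 1)")
        if self.model_expectation_source not in ("exact", "mcmc"):
            raise ParameterError(
                f"unknown expectation source {self.model_expectation_source!r}"
            )
        if self.max_iters < 0:
            raise ParameterError("max_iters must be >= 0")

    @property
    def lambda_lr(self) -> float:
        return (
            self.learning_rate
            if self.lambda_learning_rate is None
            else self.lambda_learning_rate
        )


@dataclass
class FitReport:
    """Training trajectory and diagnostics returned alongside the model."""

    ll_trajectory: np.ndarray
    converged: np.ndarray
    final_marginals: np.ndarray
    iterations_used: int
    budget_used: float
    wallclock_s: float

    @property
    def all_converged(self) -> bool:
        return bool(self.converged.all())


class _Momentum:
    def __init__(self, lr: float, mu: float):
        self.lr, self.mu = lr, mu
        self.v: np.ndarray | float = 0.0

    def step(self, grad: np.ndarray) -> np.ndarray:
        self.v = self.mu * self.v + grad
        return self.lr * self.v


class _Adam:
    def __init__(self, lr: float, b1: float, b2: float, eps: float):
        self.lr, self.b1, self.b2, self.eps = lr, b1, b2, eps
        self.m: np.ndarray | float = 0.0
        self.v: np.ndarray | float = 0.0
        self.t = 0

    def step(self, grad: np.ndarray) -> np.ndarray:
        self.t += 1
        self.m = self.b1 * self.m + (1 - self.b1) * grad
        self.v = self.b2 * self.v + (1 - self.b2) * grad**2
        mhat = self.m / (1 - self.b1**self.t)
        vhat = self.v / (1 - self.b2**self.t)
        return self.lr * mhat / (np.sqrt(vhat) + self.eps)


def _make_optimizer(cfg: OptimizerConfig, lr: float):
    if cfg.algorithm == "momentum":
        return _Momentum(lr, cfg.momentum)
    return _Adam(lr, cfg.adam_beta1, cfg.adam_beta2, cfg.adam_eps)


def lambda_gradient(
    M: RPModel, data_marginals: np.ndarray, model_marginals: np.ndarray
) -> np.ndarray:
    """Ascent direction for λ: ``<f_i>_model - <f_i>_data``.

    Zero exactly at the maximum-entropy fixed point where the model
    reproduces the data's projection means; small steps along it increase
    the training likelihood (convex problem).
    """
    data_marginals = np.asarray(data_marginals, dtype=np.float64)
    model_marginals = np.asarray(model_marginals, dtype=np.float64)
    if data_marginals.shape != (M.n_proj,) or model_marginals.shape != (M.n_proj,):
        raise ShapeError("marginal vectors must have length n_proj")
    return model_marginals - data_marginals


def reshape_gradient(
    M: RPModel,
    data_stats: dict,
    model_stats: dict,
    constraint: ConstraintSpec,
    A_tilde: np.ndarray | None = None,
) -> np.ndarray:
    """Ascent direction for the unconstrained weights ã.

    In weight space the likelihood gradient is
    ``dL/da_ij = λ_i (<σ'_i x_j>_model - <σ'_i x_j>_data)`` with
    ``σ'(u) = β σ(u)(1-σ(u))``; it is pulled back to ã through the
    constraint reparameterization and is exactly zero outside the mask
    (only existing synapses are reshaped). Heaviside models cannot be
    reshaped: their weight gradient vanishes almost everywhere.
    """
    if M.projections.nonlinearity.kind != "sigmoid":
        raise UnsupportedConfigurationError(
            "reshaping requires a sigmoid nonlinearity; the Heaviside "
            "weight gradient is zero almost everywhere"
        )
    mask = M.projections.mask
    if A_tilde is None:
        A_tilde = M.projections.weights
    grad_a = M.lambdas[:, None] * (
        model_stats["dsig_x_mean"] - data_stats["dsig_x_mean"]
    )
    grad_a = np.where(mask != 0, grad_a, 0.0)
    return constraint_vjp(grad_a, A_tilde, mask, constraint)


def _threshold_gradient(M: RPModel, data_stats: dict, model_stats: dict) -> np.ndarray:
    # dE/dθ_i = -λ_i σ'(u_i), so dL/dθ_i = -λ_i (<σ'>_model - <σ'>_data)
    return -M.lambdas * (model_stats["dsig_mean"] - data_stats["dsig_mean"])


def clopper_pearson_interval(
    success_count: float, n_obs: int, ci_level: float
) -> tuple[float, float]:
    """Two-sided exact (Clopper–Pearson) binomial confidence interval.

    Computed from Beta quantiles. ``success_count`` may be non-integer:
    sigmoid projection marginals yield fractional "counts"
    ``<f_i>_data * N``, to which the same Beta formula is applied.
    """
    if n_obs <= 0:
        raise ParameterError("n_obs must be positive")
    if not 0 <= success_count <= n_obs:
        raise ParameterError("success_count must be in [0, n_obs]")
    alpha = 1.0 - ci_level
    k, N = float(success_count), float(n_obs)
    lo = 0.0 if k == 0 else float(beta_dist.ppf(alpha / 2, k, N - k + 1))
    hi = 1.0 if k == N else float(beta_dist.ppf(1 - alpha / 2, k + 1, N - k))
    return lo, hi


def clopper_pearson_converged(
    success_count: float,
    n_obs: int,
    model_marginal: float,
    ci_level: float = 0.6827,
) -> bool:
    """True iff the model marginal lies inside the Clopper–Pearson interval
    of the empirical proportion ``success_count / n_obs`` at ``ci_level``."""
    lo, hi = clopper_pearson_interval(success_count, n_obs, ci_level)
    return bool(lo <= model_marginal <= hi)


def _converged_flags(
    data_f: np.ndarray, n_obs: int, model_f: np.ndarray, ci_level: float
) -> np.ndarray:
    """Vectorized Clopper–Pearson acceptance over all projections."""
    alpha = 1.0 - ci_level
    k = np.asarray(data_f, dtype=np.float64) * n_obs
    N = float(n_obs)
    with np.errstate(invalid="ignore"):
        lo = np.where(k <= 0, 0.0, beta_dist.ppf(alpha / 2, np.maximum(k, 1e-12), N - k + 1))
        hi = np.where(k >= N, 1.0, beta_dist.ppf(1 - alpha / 2, k + 1, np.maximum(N - k, 1e-12)))
    return (lo <= model_f) & (model_f <= hi)


class _ModelExpectations:
    """Model-side expectations: exact enumeration or persistent MH chain."""

    def __init__(self, cfg: OptimizerConfig, n_neurons: int):
        self.source = cfg.model_expectation_source
        if self.source == "mcmc":
            self.chain_cfg = cfg.chain or ChainConfig(n_samples=5000, seed=cfg.seed)
            self.state: np.ndarray | None = None
            self.rng = np.random.default_rng(cfg.seed)

    def __call__(self, M: RPModel) -> dict:
        if self.source == "exact":
            return exact_model_expectations(M)
        cfg = self.chain_cfg
        if self.state is not None:
            cfg = replace(
                cfg,
                init="data_pattern",
                init_pattern=self.state,
                burn_in=0,
                seed=int(self.rng.integers(0, 2**31 - 1)),
            )
        else:
            cfg = replace(cfg, seed=int(self.rng.integers(0, 2**31 - 1)))
        raster = mh_sample(M, cfg)
        self.state = raster.data[-1].copy()
        stats = empirical_expectations(M, raster)
        stats["lnZ"] = np.nan
        return stats


def _check_finite(grad: np.ndarray, what: str) -> None:
    if not np.isfinite(grad).all():
        raise ConvergenceError(f"non-finite {what} gradient encountered; aborting")


def _train(
    M: RPModel,
    X: SpikeRaster,
    cfg: OptimizerConfig,
    constraint: ConstraintSpec,
    update_lambdas: bool,
    update_weights: bool,
) -> tuple[RPModel, FitReport]:
    """Shared gradient-ascent loop for all three training modes."""
    if X.n_neurons != M.n_neurons:
        raise ShapeError("raster and model disagree on n_neurons")
    if update_weights and M.projections.nonlinearity.kind != "sigmoid":
        raise UnsupportedConfigurationError(
            "reshaping requires a sigmoid nonlinearity; the Heaviside "
            "weight gradient is zero almost everywhere"
        )
    t0 = time.perf_counter()
    P0 = M.projections
    mask = P0.mask
    n_obs = X.n_samples
    expectations = _ModelExpectations(cfg, M.n_neurons)
    exact_ll = cfg.model_expectation_source == "exact"

    lambdas = M.lambdas.copy()
    A_tilde = P0.weights.copy()
    thresholds = P0.thresholds.copy()
    # initial model obeys the constraint: a = g(ã) from the start
    weights = apply_constraint(A_tilde, mask, constraint)

    opt_lam = _make_optimizer(cfg, cfg.lambda_lr)
    opt_w = _make_optimizer(cfg, cfg.learning_rate)
    opt_th = _make_optimizer(cfg, cfg.learning_rate)

    def current_model() -> RPModel:
        P = ProjectionSet(
            mask=mask, weights=weights, thresholds=thresholds,
            nonlinearity=P0.nonlinearity,
        )
        return RPModel(P, lambdas)

    ll_traj: list[float] = []
    Mc = current_model()
    pats, counts = X.unique_patterns()
    data_stats = expectations_from_patterns(Mc, pats, counts)
    model_stats = expectations(Mc)
    converged = _converged_flags(
        data_stats["f_mean"], n_obs, model_stats["f_mean"], cfg.ci_level
    )
    if exact_ll:
        ll_traj.append(
            float(-(data_stats["f_mean"] @ lambdas) - model_stats["lnZ"])
        )
    iters = 0
    for iters in range(1, cfg.max_iters + 1):
        if converged.all():
            iters -= 1
            break
        if update_lambdas:
            g_lam = lambda_gradient(Mc, data_stats["f_mean"], model_stats["f_mean"])
            _check_finite(g_lam, "lambda")
            lambdas = lambdas + opt_lam.step(g_lam)
        if update_weights:
            g_til = reshape_gradient(Mc, data_stats, model_stats, constraint, A_tilde)
            _check_finite(g_til, "reshape")
            A_tilde = A_tilde + opt_w.step(g_til)
            weights = apply_constraint(A_tilde, mask, constraint)
            if cfg.tune_thresholds:
                g_th = _threshold_gradient(Mc, data_stats, model_stats)
                _check_finite(g_th, "threshold")
                thresholds = thresholds + opt_th.step(g_th)
        Mc = current_model()
        if update_weights or cfg.tune_thresholds:
            data_stats = expectations_from_patterns(Mc, pats, counts)
        model_stats = expectations(Mc)
        converged = _converged_flags(
            data_stats["f_mean"], n_obs, model_stats["f_mean"], cfg.ci_level
        )
        if exact_ll:
            ll_traj.append(
                float(-(data_stats["f_mean"] @ lambdas) - model_stats["lnZ"])
            )
    report = FitReport(
        ll_trajectory=np.array(ll_traj),
        converged=converged,
        final_marginals=np.asarray(model_stats["f_mean"], dtype=np.float64),
        iterations_used=iters,
        budget_used=float(np.abs(weights).sum()),
        wallclock_s=time.perf_counter() - t0,
    )
    return Mc, report


def train_lambdas(
    M: RPModel, X: SpikeRaster, cfg: OptimizerConfig
) -> tuple[RPModel, FitReport]:
    """Learn the Lagrange multipliers λ with the projections fixed.

    The classical maximum-entropy fit: convex, with fixed point
    ``<f_i>_model = <f_i>_data`` for every projection. Stops when all
    projections pass the Clopper–Pearson criterion or at ``max_iters``.
    """
    return _train(M, X, cfg, ConstraintSpec("none"), True, False)


def train_reshape(
    M: RPModel,
    X: SpikeRaster,
    cfg: OptimizerConfig,
    constraint: ConstraintSpec = ConstraintSpec("none"),
) -> tuple[RPModel, FitReport]:
    """Reshape the projections (tune nonzero a_ij) with λ held fixed.

    The connectivity mask never changes — each projection keeps its input
    set, only the relative weights move. Under a bounded or homeostatic
    ``constraint`` the corresponding weight budget holds exactly after
    every iteration. Thresholds are tuned too when ``cfg.tune_thresholds``.
    """
    return _train(M, X, cfg, constraint, False, True)


def train_backprop(
    M: RPModel,
    X: SpikeRaster,
    cfg: OptimizerConfig,
    constraint: ConstraintSpec = ConstraintSpec("none"),
) -> tuple[RPModel, FitReport]:
    """Joint training: λ and weight updates applied in the same step,
    as in backpropagation through the two-layer circuit."""
    return _train(M, X, cfg, constraint, True, True)
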