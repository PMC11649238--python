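"""Model/Results front end over the library.

:class:`ReshapedRP` bundles a spike raster with a projection set and
exposes the three training modes through ``fit``; the returned
:class:`ReshapedRPResults` carries the fitted model, the training
trajectory and convergence diagnostics, and hangs the evaluation metrics
and the sampler off the fit::

    model = ReshapedRP(raster, n_proj=12, indegree=5, seed=0)
    res = model.fit(mode="reshape", constraint=ConstraintSpec("homeo_input", phi=1.0))
    print(res.summary())
    ll, se = res.test_log_likelihood(test_raster)
"""
from __future__ import annotations

import numpy as np
import pandas as pd

from .constraints import ConstraintSpec
from .errors import ParameterError
from .metrics import (
    BudgetReport,
    pattern_probability_comparison,
    projection_correlations,
    projection_firing_rates,
    rotation_angles,
    synaptic_budget,
    test_log_likelihood,
)
from .model import ENUMERATION_CAP, RPModel
from .projections import Nonlinearity, ProjectionSet, build_sparse_projections
from .raster import SpikeRaster
from .sampler import ChainConfig, mh_sample
from .training import (
    FitReport,
    OptimizerConfig,
    train_backprop,
    train_lambdas,
    train_reshape,
)

__all__ = ["ReshapedRP", "ReshapedRPResults"]

_MODES = ("lambdas", "reshape", "backprop")


class ReshapedRP:
    """A random-projections maximum-entropy model bound to training data.

    Parameters
    ----------
    raster : SpikeRaster
        Binary training data, time bins x neurons.
    projections : ProjectionSet, optional
        Initial projections. When omitted, a sparse random set is drawn
        from ``n_proj``, ``indegree``, ``nonlinearity`` and ``seed``.
    n_proj, indegree, nonlinearity, seed
        Parameters of the random draw (ignored when ``projections`` is
        given). Defaults: in-degree 5, sigmoid with slope beta = 2.
    """

    def __init__(
        self,
        raster: SpikeRaster,
        projections: ProjectionSet | None = None,
        *,
        n_proj: int | None = None,
        indegree: float = 5.0,
        nonlinearity: Nonlinearity | None = None,
        seed: int | None = None,
    ):
        self.raster = raster
        if projections is None:
            if n_proj is None:
                raise ParameterError("provide either projections or n_proj")
            projections = build_sparse_projections(
                raster.n_neurons,
                n_proj,
                min(indegree, raster.n_neurons),
                nonlinearity or Nonlinearity("sigmoid", beta=2.0),
                seed=seed,
            )
        elif projections.n_neurons != raster.n_neurons:
            raise ParameterError("projections and raster disagree on n_neurons")
        self.projections = projections

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, bin_width_ms: float = 20.0, **kwargs):
        """Build from a DataFrame of 0/1 activity (rows = time bins)."""
        return cls(SpikeRaster(df.to_numpy(), bin_width_ms), **kwargs)

    def fit(
        self,
        mode: str = "lambdas",
        constraint: ConstraintSpec | None = None,
        lambda_init: float | np.ndarray | None = None,
        optimizer: OptimizerConfig | None = None,
        **optimizer_kwargs,
    ) -> "ReshapedRPResults":
        """Train the model and return a results object.

        ``mode`` is ``'lambdas'`` (maxent fit of λ, projections fixed),
        ``'reshape'`` (synaptic weights tuned, λ fixed — defaults to
        λ = 1) or ``'backprop'`` (both). ``constraint`` selects the
        synaptic constraint for the weight updates. Extra keyword
        arguments populate :class:`OptimizerConfig`.
        """
        if mode not in _MODES:
            raise ParameterError(f"mode must be one of {_MODES}, got {mode!r}")
        constraint = constraint or ConstraintSpec("none")
        cfg = optimizer or OptimizerConfig(**optimizer_kwargs)
        if lambda_init is None:
            lambda_init = 0.0 if mode == "lambdas" else 1.0
        lambdas = np.broadcast_to(
            np.asarray(lambda_init, dtype=np.float64), (self.projections.n_proj,)
        ).copy()
        M0 = RPModel(self.projections.copy(), lambdas)
        trainer = {
            "lambdas": lambda: train_lambdas(M0, self.raster, cfg),
            "reshape": lambda: train_reshape(M0, self.raster, cfg, constraint),
            "backprop": lambda: train_backprop(M0, self.raster, cfg, constraint),
        }[mode]
        fitted, report = trainer()
        return ReshapedRPResults(self, fitted, M0, mode, constraint, cfg, report)


class ReshapedRPResults:
    """Fitted model, uncertainty diagnostics and evaluation methods."""

    def __init__(
        self,
        model: ReshapedRP,
        fitted: RPModel,
        initial: RPModel,
        mode: str,
        constraint: ConstraintSpec,
        config: OptimizerConfig,
        report: FitReport,
    ):
        self.model = model
        self.fitted_model = fitted
        self.initial_model = initial
        self.mode = mode
        self.constraint = constraint
        self.config = config
        self.report = report

    # -- headline quantities -------------------------------------------
    @property
    def llf(self) -> float:
        """Final training mean log-likelihood (nats/sample), when tracked."""
        traj = self.report.ll_trajectory
        return float(traj[-1]) if traj.size else float("nan")

    @property
    def converged(self) -> bool:
        return self.report.all_converged

    @property
    def lambdas(self) -> np.ndarray:
        return self.fitted_model.lambdas

    @property
    def weights(self) -> np.ndarray:
        return self.fitted_model.projections.weights

    # -- evaluation ----------------------------------------------------
    def test_log_likelihood(
        self, X_test: SpikeRaster, method: str | None = None, seed: int = 0
    ) -> tuple[float, float]:
        """Held-out mean log-likelihood (nats/sample) and its SE."""
        if method is None:
            method = "exact" if self.fitted_model.n_neurons <= ENUMERATION_CAP else "ais"
        return test_log_likelihood(self.fitted_model, X_test, method=method, seed=seed)

    def pattern_probabilities(self, X_test: SpikeRaster, ci: float = 0.99) -> pd.DataFrame:
        return pattern_probability_comparison(self.fitted_model, X_test, ci=ci)

    def projection_firing_rates(self, source="exact", **kw) -> np.ndarray:
        return projection_firing_rates(self.fitted_model, source=source, **kw)

    def projection_correlations(self, source="exact", **kw) -> float:
        return projection_correlations(self.fitted_model, source=source, **kw)

    def rotation_angles(self) -> np.ndarray:
        """Degrees each projection rotated from its initialization."""
        return rotation_angles(
            self.initial_model.projections, self.fitted_model.projections
        )

    def synaptic_budget(self) -> BudgetReport:
        return synaptic_budget(
            self.fitted_model.projections,
            self.initial_model.projections,
            self.constraint,
        )

    def sample(self, n_samples: int, seed: int = 0, **chain_kwargs) -> SpikeRaster:
        """Draw a raster from the fitted model by Metropolis–Hastings."""
        return mh_sample(
            self.fitted_model, ChainConfig(n_samples=n_samples, seed=seed, **chain_kwargs)
        )

    # -- reporting -----------------------------------------------------
    def summary(self) -> str:
        M = self.fitted_model
        nl = M.projections.nonlinearity
        nl_s = f"sigmoid(beta={nl.beta:g})" if nl.kind == "sigmoid" else "heaviside"
        c = self.constraint
        if c.kind == "none":
            c_s = "none"
        elif c.kind == "bounded":
            c_s = f"bounded(omega={c.omega:g})"
        else:
            c_s = f"{c.kind}(phi={c.phi:g})"
        budget = self.synaptic_budget()
        rows = [
            ("Mode", self.mode),
            ("Neurons", M.n_neurons),
            ("Projections", M.n_proj),
            ("Training samples", self.model.raster.n_samples),
            ("Nonlinearity", nl_s),
            ("Constraint", c_s),
            ("Optimizer", self.config.algorithm),
            ("Iterations", self.report.iterations_used),
            (
                "Converged (Clopper-Pearson)",
                f"{int(self.report.converged.sum())}/{M.n_proj}",
            ),
            ("Train LL (nats/sample)", f"{self.llf:.4f}"),
            ("Synaptic budget used", f"{budget.used:.4f}"),
            ("Budget (initial-set units)", f"{budget.normalized_used:.4f}"),
            ("Mean |lambda|", f"{np.abs(M.lambdas).mean():.4f}"),
        ]
        width = max(len(k) for k, _ in rows) + 2
        title = "Reshaped Random Projections MaxEnt Results"
        lines = [title, "=" * (width + 24)]
        lines += [f"{k:<{width}}{v}" for k, v in rows]
        lines.append("=" * (width + 24))
        return "\n".join(lines)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"<ReshapedRPResults mode={self.mode} n={self.fitted_model.n_neurons} "
            f"n_proj={self.fitted_model.n_proj} llf={self.llf:.4f}>"
        )
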