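import numpy as np
import pytest

from rpmaxent import (
    ConstraintSpec,
    Nonlinearity,
    OptimizerConfig,
    ProjectionSet,
    RPModel,
    SpikeRaster,
    apply_constraint,
    build_sparse_projections,
    clopper_pearson_converged,
    clopper_pearson_interval,
    exact_mean_log_likelihood,
    lambda_gradient,
    reshape_gradient,
    train_backprop,
    train_lambdas,
    train_reshape,
)
from rpmaxent.errors import ParameterError, UnsupportedConfigurationError
from rpmaxent.model import exact_model_expectations, expectations_from_patterns

ALL_CONSTRAINTS = [
    ConstraintSpec("none"),
    ConstraintSpec("bounded", omega=1.0),
    ConstraintSpec("homeo_input", phi=2.0),
    ConstraintSpec("homeo_output", phi=1.5),
    ConstraintSpec("homeo_circuit", phi=10.0),
]


def _half_rate_raster(n_samples=40_000):
    """Two-neuron data whose single-projection marginal is exactly 1/2."""
    block = np.array([[0, 0], [0, 0], [1, 0], [1, 1]], dtype=np.uint8)
    return SpikeRaster(np.tile(block, (n_samples // 4, 1)))


def _two_neuron_model(lam=0.0):
    P = ProjectionSet(
        mask=np.array([[1, 1]]),
        weights=np.array([[1.0, 1.0]]),
        thresholds=np.array([1.0]),
        nonlinearity=Nonlinearity("heaviside"),
    )
    return RPModel(P, np.array([lam]))


class TestLambdaGradient:
    def test_zero_at_fixed_point(self, small_sigmoid_model):
        m = np.linspace(0.1, 0.6, small_sigmoid_model.n_proj)
        g = lambda_gradient(small_sigmoid_model, m, m)
        assert np.array_equal(g, np.zeros_like(m))

    def test_matches_finite_differences(self, n6_projections, sparse_raster):
        rng = np.random.default_rng(1)
        lam = rng.uniform(0.5, 1.5, n6_projections.n_proj)
        M = RPModel(n6_projections, lam)
        pats, counts = sparse_raster.unique_patterns()
        data = expectations_from_patterns(M, pats, counts)
        g = lambda_gradient(M, data["f_mean"], exact_model_expectations(M)["f_mean"])
        eps = 1e-6
        for i in range(M.n_proj):
            lp, lm = lam.copy(), lam.copy()
            lp[i] += eps
            lm[i] -= eps
            fd = (
                exact_mean_log_likelihood(RPModel(n6_projections, lp), sparse_raster)
                - exact_mean_log_likelihood(RPModel(n6_projections, lm), sparse_raster)
            ) / (2 * eps)
            assert g[i] == pytest.approx(fd, abs=1e-6)


class TestReshapeGradient:
    @pytest.mark.parametrize("spec", ALL_CONSTRAINTS, ids=lambda s: s.kind)
    def test_matches_finite_differences_through_reparameterization(
        self, spec, n6_projections, sparse_raster
    ):
        """d(exact LL)/d a~_ij through a = g(a~), for every constraint kind."""
        rng = np.random.default_rng(2)
        proj = n6_projections
        lam = rng.uniform(0.5, 1.5, proj.n_proj)
        A0 = proj.weights.copy()
        pats, counts = sparse_raster.unique_patterns()

        def ll(At):
            a = apply_constraint(At, proj.mask, spec)
            P = ProjectionSet(proj.mask, a, proj.thresholds, proj.nonlinearity)
            return exact_mean_log_likelihood(RPModel(P, lam), sparse_raster)

        a0 = apply_constraint(A0, proj.mask, spec)
        M0 = RPModel(
            ProjectionSet(proj.mask, a0, proj.thresholds, proj.nonlinearity), lam
        )
        g = reshape_gradient(
            M0,
            expectations_from_patterns(M0, pats, counts),
            exact_model_expectations(M0),
            spec,
            A0,
        )
        eps = 1e-6
        for i, j in zip(*np.nonzero(proj.mask)):
            Ap, Am = A0.copy(), A0.copy()
            Ap[i, j] += eps
            Am[i, j] -= eps
            fd = (ll(Ap) - ll(Am)) / (2 * eps)
            assert g[i, j] == pytest.approx(fd, abs=1e-5)

    def test_zero_lambda_row_gets_zero_update(self, n6_projections, sparse_raster):
        lam = np.ones(n6_projections.n_proj)
        lam[3] = 0.0
        M = RPModel(n6_projections, lam)
        pats, counts = sparse_raster.unique_patterns()
        g = reshape_gradient(
            M,
            expectations_from_patterns(M, pats, counts),
            exact_model_expectations(M),
            ConstraintSpec("none"),
        )
        assert np.array_equal(g[3], np.zeros(6))

    def test_heaviside_reshape_rejected(self, sparse_raster):
        P = build_sparse_projections(6, 4, 3, Nonlinearity("heaviside"), seed=0)
        M = RPModel(P, np.ones(4))
        with pytest.raises(UnsupportedConfigurationError):
            train_reshape(M, sparse_raster, OptimizerConfig(max_iters=5))


class TestClopperPearson:
    def test_point_estimate_always_inside(self):
        assert clopper_pearson_converged(50, 100, 0.5)

    def test_distant_marginal_outside(self):
        assert not clopper_pearson_converged(0, 100, 0.5)

    def test_interval_brackets_proportion(self):
        lo, hi = clopper_pearson_interval(30, 100, 0.95)
        assert lo < 0.3 < hi
        assert 0 <= lo < hi <= 1

    def test_zero_observations_rejected(self):
        with pytest.raises(ParameterError):
            clopper_pearson_converged(0, 0, 0.5)

    def test_coverage_near_nominal(self):
        """For p=0.3, N=1000 the 1-SD interval covers ~68.3% of draws."""
        rng = np.random.default_rng(10)
        ks = rng.binomial(1000, 0.3, size=4000)
        cov = np.mean([clopper_pearson_converged(int(k), 1000, 0.3, 0.6827) for k in ks])
        assert cov == pytest.approx(0.683, abs=0.025)


class TestTrainLambdas:
    def test_closed_form_fixed_point(self):
        M, report = train_lambdas(
            _two_neuron_model(),
            _half_rate_raster(200_000),
            OptimizerConfig(max_iters=3000, learning_rate=1.0),
        )
        assert M.lambdas[0] == pytest.approx(np.log(3.0), abs=0.01)
        assert report.all_converged

    def test_uniform_data_recovers_uniform_model(self):
        rng = np.random.default_rng(3)
        X = SpikeRaster((rng.random((60_000, 6)) < 0.5).astype(int))
        P = build_sparse_projections(6, 5, 3, Nonlinearity("sigmoid", beta=2.0), seed=4)
        M, _ = train_lambdas(RPModel(P, np.zeros(5)), X, OptimizerConfig(max_iters=500))
        assert exact_mean_log_likelihood(M, X) == pytest.approx(-6 * np.log(2), abs=0.01)

    def test_training_ll_increases(self, small_dataset):
        train, _ = small_dataset
        P = build_sparse_projections(8, 10, 3, Nonlinearity("sigmoid", beta=2.0), seed=6)
        _, report = train_lambdas(
            RPModel(P, np.zeros(10)), train, OptimizerConfig(max_iters=200)
        )
        assert report.ll_trajectory[-1] >= report.ll_trajectory[0]

    def test_fitted_marginals_inside_cp_band(self, small_dataset):
        train, _ = small_dataset
        P = build_sparse_projections(8, 10, 3, Nonlinearity("sigmoid", beta=2.0), seed=7)
        M, report = train_lambdas(
            RPModel(P, np.zeros(10)), train, OptimizerConfig(max_iters=2000)
        )
        assert report.all_converged
        data_f = expectations_from_patterns(M, *train.unique_patterns())["f_mean"]
        model_f = exact_model_expectations(M)["f_mean"]
        for df, mf in zip(data_f, model_f):
            assert clopper_pearson_converged(df * train.n_samples, train.n_samples, mf)


class TestTrainReshape:
    def test_improves_on_initial_model(self, small_dataset):
        train, _ = small_dataset
        P = build_sparse_projections(8, 10, 3, Nonlinearity("sigmoid", beta=2.0), seed=8)
        M0 = RPModel(P.copy(), np.ones(10))
        ll0 = exact_mean_log_likelihood(M0, train)
        M, _ = train_reshape(M0, train, OptimizerConfig(max_iters=300))
        assert exact_mean_log_likelihood(M, train) > ll0

    def test_lambda_and_mask_unchanged(self, small_dataset):
        train, _ = small_dataset
        P = build_sparse_projections(8, 10, 3, Nonlinearity("sigmoid", beta=2.0), seed=9)
        M0 = RPModel(P.copy(), np.full(10, 1.0))
        M, _ = train_reshape(M0, train, OptimizerConfig(max_iters=50))
        assert np.array_equal(M.lambdas, M0.lambdas)
        assert np.array_equal(M.projections.mask, P.mask)
        assert np.all(M.projections.weights[P.mask == 0] == 0.0)

    @pytest.mark.parametrize(
        "spec", [c for c in ALL_CONSTRAINTS if c.kind != "none"], ids=lambda s: s.kind
    )
    def test_constraint_holds_after_training(self, spec, small_dataset):
        train, _ = small_dataset
        P = build_sparse_projections(8, 10, 3, Nonlinearity("sigmoid", beta=2.0), seed=10)
        M, _ = train_reshape(
            RPModel(P.copy(), np.ones(10)), train, OptimizerConfig(max_iters=60), spec
        )
        a = M.projections.weights
        if spec.kind == "bounded":
            assert np.abs(a).max() <= spec.omega + 1e-12
        elif spec.kind == "homeo_input":
            assert np.allclose(np.abs(a).sum(axis=1), spec.phi, rtol=1e-10)
        elif spec.kind == "homeo_output":
            connected = P.mask.sum(axis=0) > 0
            assert np.allclose(np.abs(a).sum(axis=0)[connected], spec.phi, rtol=1e-10)
        else:
            assert np.abs(a).sum() == pytest.approx(spec.phi, rel=1e-10)

    def test_zero_iterations_identity(self, small_dataset):
        train, _ = small_dataset
        P = build_sparse_projections(8, 10, 3, Nonlinearity("sigmoid", beta=2.0), seed=11)
        M0 = RPModel(P.copy(), np.ones(10))
        M, report = train_reshape(M0, train, OptimizerConfig(max_iters=0))
        assert report.iterations_used == 0
        assert np.array_equal(M.projections.weights, P.weights)

    def test_threshold_tuning_moves_thresholds(self, small_dataset):
        train, _ = small_dataset
        P = build_sparse_projections(8, 10, 3, Nonlinearity("sigmoid", beta=2.0), seed=12)
        M, _ = train_reshape(
            RPModel(P.copy(), np.ones(10)), train,
            OptimizerConfig(max_iters=50, tune_thresholds=True),
        )
        assert not np.array_equal(M.projections.thresholds, P.thresholds)


class TestTrainBackprop:
    def test_zero_weight_step_degenerates_to_lambda_training(self, small_dataset):
        train, _ = small_dataset
        P = build_sparse_projections(8, 10, 3, Nonlinearity("sigmoid", beta=2.0), seed=13)
        cfg_bp = OptimizerConfig(max_iters=60, learning_rate=0.0, lambda_learning_rate=0.25)
        cfg_lam = OptimizerConfig(max_iters=60, learning_rate=0.25)
        Mb, rb = train_backprop(RPModel(P.copy(), np.zeros(10)), train, cfg_bp)
        Ml, rl = train_lambdas(RPModel(P.copy(), np.zeros(10)), train, cfg_lam)
        assert np.allclose(Mb.lambdas, Ml.lambdas, atol=1e-12)
        assert np.allclose(rb.ll_trajectory, rl.ll_trajectory, atol=1e-12)

    def test_zero_lambda_step_degenerates_to_reshape(self, small_dataset):
        train, _ = small_dataset
        P = build_sparse_projections(8, 10, 3, Nonlinearity("sigmoid", beta=2.0), seed=14)
        cfg_bp = OptimizerConfig(max_iters=60, learning_rate=0.25, lambda_learning_rate=0.0)
        cfg_rs = OptimizerConfig(max_iters=60, learning_rate=0.25)
        Mb, rb = train_backprop(RPModel(P.copy(), np.ones(10)), train, cfg_bp)
        Mr, rr = train_reshape(RPModel(P.copy(), np.ones(10)), train, cfg_rs)
        assert np.allclose(Mb.projections.weights, Mr.projections.weights, atol=1e-12)
        assert np.allclose(rb.ll_trajectory, rr.ll_trajectory, atol=1e-12)


class TestParameterRecovery:
    def test_lambda_training_on_true_projections_recovers_ground_truth(
        self, small_sigmoid_model
    ):
        """Data sampled from a known model, refit on the true projections,
        reaches the ground truth's held-out likelihood within 0.05 nats."""
        from rpmaxent import sample_synthetic_raster

        gt = small_sigmoid_model
        train, test = sample_synthetic_raster(gt, 100_000, 25_000, seed=15)
        M, _ = train_lambdas(
            RPModel(gt.projections.copy(), np.zeros(gt.n_proj)),
            train,
            OptimizerConfig(max_iters=2000),
        )
        ll_fit = exact_mean_log_likelihood(M, test)
        ll_gt = exact_mean_log_likelihood(gt, test)
        assert ll_fit >= ll_gt - 0.05

    def test_mcmc_expectation_source_trains(self, small_dataset):
        """PCD-style training with sampled model expectations reaches a
        likelihood close to the exact-expectation fit."""
        from rpmaxent import ChainConfig

        train, _ = small_dataset
        P = build_sparse_projections(8, 10, 3, Nonlinearity("sigmoid", beta=2.0), seed=16)
        M_ex, _ = train_lambdas(
            RPModel(P.copy(), np.zeros(10)), train, OptimizerConfig(max_iters=300)
        )
        M_mc, _ = train_lambdas(
            RPModel(P.copy(), np.zeros(10)),
            train,
            OptimizerConfig(
                max_iters=300,
                model_expectation_source="mcmc",
                chain=ChainConfig(n_samples=4000),
                seed=17,
            ),
        )
        assert exact_mean_log_likelihood(M_mc, train) >= (
            exact_mean_log_likelihood(M_ex, train) - 0.05
        )
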