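import numpy as np
import pytest

from rpmaxent import (
    ChainConfig,
    ConstraintSpec,
    Nonlinearity,
    ProjectionSet,
    RPModel,
    build_sparse_projections,
    firing_rate_change_cdf,
    mh_sample,
    pattern_probability_comparison,
    projection_correlations,
    projection_firing_rates,
    rotation_angles,
    synaptic_budget,
)
from rpmaxent import test_log_likelihood as held_out_ll
from rpmaxent.errors import DegenerateProjectionError, ParameterError


class TestTestLogLikelihood:
    def test_uniform_model(self):
        P = build_sparse_projections(10, 3, 4, Nonlinearity("sigmoid", beta=2.0), seed=0)
        M = RPModel(P, np.zeros(3))
        X = mh_sample(M, ChainConfig(n_samples=2000, seed=1))
        ll, se = held_out_ll(M, X)
        assert ll == pytest.approx(-10 * np.log(2))
        assert se == pytest.approx(0.0, abs=1e-12)

    def test_exact_and_ais_agree(self, small_sigmoid_model, small_dataset):
        _, test = small_dataset
        ll_e, _ = held_out_ll(small_sigmoid_model, test, method="exact")
        ll_a, se_a = held_out_ll(
            small_sigmoid_model, test, method="ais", n_chains=48, n_temps=80, seed=2
        )
        assert abs(ll_e - ll_a) < 3 * se_a

    def test_ground_truth_beats_mismatched_model(self, small_sigmoid_model, small_dataset):
        """KL >= 0: on its own samples no other model does better."""
        _, test = small_dataset
        other = RPModel(
            small_sigmoid_model.projections, 0.5 * small_sigmoid_model.lambdas
        )
        ll_gt, se1 = held_out_ll(small_sigmoid_model, test)
        ll_other, se2 = held_out_ll(other, test)
        assert ll_gt >= ll_other - 2 * (se1 + se2)


class TestPatternProbabilityComparison:
    def test_funnel_and_sorting(self, small_sigmoid_model, small_dataset):
        _, test = small_dataset
        df = pattern_probability_comparison(small_sigmoid_model, test, ci=0.99)
        assert (df["empirical_p"].diff().dropna() <= 1e-15).all()
        assert ((df["ci_lo"] <= df["empirical_p"]) & (df["empirical_p"] <= df["ci_hi"])).all()

    def test_ground_truth_mostly_inside_funnel(self, small_sigmoid_model):
        X = mh_sample(small_sigmoid_model, ChainConfig(n_samples=200_000, seed=3))
        df = pattern_probability_comparison(small_sigmoid_model, X, ci=0.99)
        seen = df[df["count"] >= 10]
        inside = (seen["ci_lo"] <= seen["model_p"]) & (seen["model_p"] <= seen["ci_hi"])
        assert inside.mean() >= 0.97


class TestProjectionFiringRates:
    def test_uniform_heaviside_closed_form(self):
        # a=(1,1), theta=1, H(0)=1: 3 of 4 equally likely states fire
        P = ProjectionSet(
            mask=np.array([[1, 1]]), weights=np.array([[1.0, 1.0]]),
            thresholds=np.array([1.0]), nonlinearity=Nonlinearity("heaviside"),
        )
        M = RPModel(P, np.array([0.0]))
        assert projection_firing_rates(M)[0] == pytest.approx(0.75)

    def test_flat_sigmoid_rates_half(self):
        P = build_sparse_projections(6, 5, 3, Nonlinearity("sigmoid", beta=1e-7), seed=1)
        M = RPModel(P, np.ones(5))
        assert np.allclose(projection_firing_rates(M), 0.5, atol=1e-6)

    def test_sample_estimate_matches_exact(self, small_sigmoid_model):
        exact = projection_firing_rates(small_sigmoid_model, source="exact")
        sampled = projection_firing_rates(
            small_sigmoid_model, source="samples",
            chain_config=ChainConfig(n_samples=60_000, thin=24, seed=4),
        )
        se = np.sqrt(np.maximum(exact * (1 - exact), 1e-4) / 60_000)
        assert np.all(np.abs(sampled - exact) < 5 * se)


class TestProjectionCorrelations:
    def test_duplicated_projection_fully_correlated(self):
        mask = np.array([[1, 1, 0], [1, 1, 0]])
        w = np.array([[1.0, -0.5, 0.0], [1.0, -0.5, 0.0]])
        P = ProjectionSet(mask, w, np.ones(2), Nonlinearity("sigmoid", beta=2.0))
        M = RPModel(P, np.array([0.3, 0.3]))
        assert projection_correlations(M) == pytest.approx(1.0)

    def test_disjoint_inputs_uncorrelated_under_independence(self):
        # independent neurons (uniform model), projections read disjoint sets
        mask = np.array([[1, 1, 0, 0], [0, 0, 1, 1]])
        w = np.where(mask == 1, 1.3, 0.0)
        P = ProjectionSet(mask, w, np.ones(2), Nonlinearity("sigmoid", beta=2.0))
        M = RPModel(P, np.zeros(2))
        assert projection_correlations(M) == pytest.approx(0.0, abs=1e-12)

    def test_constant_projections_raise(self):
        P = build_sparse_projections(4, 3, 2, Nonlinearity("sigmoid", beta=1e-9), seed=2)
        with pytest.raises(DegenerateProjectionError):
            projection_correlations(RPModel(P, np.ones(3)))


class TestRotationAngles:
    def test_identity_zero_scale_invariant_orthogonal(self):
        mask = np.array([[1, 1]])
        P0 = ProjectionSet(mask, np.array([[1.0, 0.0]]), np.ones(1),
                           Nonlinearity("sigmoid", beta=2.0))
        # weights (1,0) with mask (1,1) is fine: mask marks allowed synapses
        same = ProjectionSet(mask, np.array([[1.0, 0.0]]), np.ones(1),
                             Nonlinearity("sigmoid", beta=2.0))
        scaled = ProjectionSet(mask, np.array([[2.5, 0.0]]), np.ones(1),
                               Nonlinearity("sigmoid", beta=2.0))
        orth = ProjectionSet(mask, np.array([[0.0, 1.0]]), np.ones(1),
                             Nonlinearity("sigmoid", beta=2.0))
        assert rotation_angles(P0, same)[0] == pytest.approx(0.0)
        assert rotation_angles(P0, scaled)[0] == pytest.approx(0.0)
        assert rotation_angles(P0, orth)[0] == pytest.approx(90.0)

    def test_angles_bounded(self, n6_projections):
        rng = np.random.default_rng(5)
        flipped = n6_projections.copy()
        flipped.weights = np.where(
            n6_projections.mask == 1, -n6_projections.weights + rng.normal(0, 0.1,
            n6_projections.weights.shape), 0.0)
        ang = rotation_angles(n6_projections, flipped)
        assert np.all((ang >= 0) & (ang <= 180))
        assert ang.max() > 90  # flipped rows point backwards


class TestSynapticBudget:
    def test_initial_set_normalizes_to_one(self, n6_projections):
        rep = synaptic_budget(n6_projections, n6_projections, ConstraintSpec("none"))
        assert rep.normalized_used == pytest.approx(1.0)
        assert rep.available is None

    def test_homeo_input_available_budget(self, n6_projections):
        rep = synaptic_budget(
            n6_projections, n6_projections, ConstraintSpec("homeo_input", phi=2.0)
        )
        assert rep.available == pytest.approx(2.0 * n6_projections.n_proj)

    def test_bounded_available_counts_synapses(self, n6_projections):
        omega = 0.8
        rep = synaptic_budget(
            n6_projections, n6_projections, ConstraintSpec("bounded", omega=omega)
        )
        assert rep.available == pytest.approx(n6_projections.mask.sum() * omega)


class TestFiringRateChangeCDF:
    def test_unchanged_rates_step_at_zero(self):
        r = np.array([0.1, 0.2, 0.3])
        rel, cdf = firing_rate_change_cdf(r, r)
        assert np.array_equal(rel, np.zeros(3))
        assert cdf(0.0) == 1.0

    def test_single_halved_projection(self):
        rel, cdf = firing_rate_change_cdf(np.array([0.2]), np.array([0.1]))
        assert rel[0] == pytest.approx(0.5)
        assert cdf(0.49) == 0.0 and cdf(0.5) == 1.0

    def test_zero_initial_rates_excluded(self):
        rel, cdf = firing_rate_change_cdf(np.array([0.0, 0.2]), np.array([0.1, 0.4]))
        assert rel.size == 1
        assert cdf(1e9) == 1.0

    def test_all_zero_initial_rates_rejected(self):
        with pytest.raises(ParameterError):
            firing_rate_change_cdf(np.zeros(3), np.ones(3))
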