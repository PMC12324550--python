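import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from bethedge import (
    JointDistribution,
    compute_metrics,
    environment_entropy,
    independent_fitness,
    joint_from_parameters,
    make_dormancy_model,
    make_symmetric_model,
    marginal_information_value,
    max_information,
    max_normalized_fitness,
    mutual_information,
    mutual_information_matrix,
    normalized_fitness,
    symmetric_curve,
    symmetric_gamma_at_information,
    time_averaged_fitness,
)

marginals = st.floats(min_value=0.02, max_value=0.98)


@st.composite
def feasible_triples(draw):
    px1 = draw(marginals)
    py1 = draw(marginals)
    lo = max(px1 * py1, px1 + py1 - 1.0)
    hi = min(px1, py1)
    t = draw(st.floats(min_value=0.0, max_value=1.0))
    return px1, py1, lo + t * (hi - lo)


class TestMutualInformation:
    def test_product_joint_carries_no_information(self):
        joint = JointDistribution(P=np.outer([0.3, 0.7], [0.6, 0.4]))
        assert mutual_information(joint) == pytest.approx(0.0, abs=1e-12)

    def test_diagonal_joint_reaches_environment_entropy(self):
        joint = JointDistribution(P=np.array([[0.5, 0.0], [0.0, 0.5]]))
        assert mutual_information(joint) == pytest.approx(1.0, abs=1e-12)

    def test_direct_evaluation(self):
        joint = JointDistribution(P=np.array([[0.4, 0.1], [0.1, 0.4]]))
        got = mutual_information(joint)
        assert got == pytest.approx(0.2780719051126378, abs=1e-12)
        # coincides with the symmetric master curve at the same corner
        assert got == pytest.approx(symmetric_curve(0.4)[1], abs=1e-12)

    def test_symmetric_in_arguments(self):
        P = np.array([[0.35, 0.05], [0.25, 0.35]])
        assert mutual_information_matrix(P) == pytest.approx(
            mutual_information_matrix(P.T), abs=1e-12
        )

    def test_unnormalized_matrix_rejected(self):
        with pytest.raises(ValueError, match="probability matrix"):
            mutual_information_matrix(np.array([[0.5, 0.2], [0.2, 0.5]]))

    @given(feasible_triples())
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_nonnegative_and_bounded_by_entropy(self, triple):
        px1, py1, p = triple
        joint = joint_from_parameters(px1, py1, p)
        info = mutual_information(joint)
        assert info >= 0.0
        assert info <= environment_entropy(px1) + 1e-9


class TestFitnessMetrics:
    def test_independent_fitness_of_product_joint(self, symmetric_config):
        joint = JointDistribution(P=np.outer([0.5, 0.5], [0.5, 0.5]))
        assert independent_fitness(joint, symmetric_config) == pytest.approx(
            time_averaged_fitness(joint, symmetric_config)
        )

    def test_independent_fitness_ignores_correlation(self, symmetric_config):
        # any joint with balanced marginals gives (mu + rho) / 2
        for p11 in (0.25, 0.35, 0.45):
            joint = joint_from_parameters(0.5, 0.5, p11)
            assert independent_fitness(joint, symmetric_config) == pytest.approx(2.5)

    def test_independent_fitness_dormancy_arithmetic(self, dormancy_config):
        joint = joint_from_parameters(0.5, 0.5, 0.4)
        # 0.25 * (0 - 2 + 0 + 1)
        assert independent_fitness(joint, dormancy_config) == pytest.approx(-0.25)

    def test_product_joint_has_zero_normalized_fitness(self, symmetric_config):
        joint = joint_from_parameters(0.4, 0.3, 0.12)
        assert normalized_fitness(joint, symmetric_config) == pytest.approx(0.0, abs=1e-12)

    def test_perfect_matching_has_unit_normalized_fitness(self, symmetric_config):
        joint = joint_from_parameters(0.4, 0.4, 0.4)
        assert normalized_fitness(joint, symmetric_config) == pytest.approx(1.0, abs=1e-12)

    def test_growth_rate_independence(self):
        """Two models with different growth matrices assign the same
        normalized fitness to the same joint law."""
        joint = joint_from_parameters(0.5, 0.5, 0.4)
        g1 = normalized_fitness(joint, make_symmetric_model(4, 1, 0.1, 1.2, 0.1))
        g2 = normalized_fitness(joint, make_symmetric_model(10, 7, 0.1, 1.2, 0.1))
        g3 = normalized_fitness(joint, make_dormancy_model(2, 1, 0.01, 0.5, 0.5))
        assert g1 == pytest.approx(g2, abs=1e-12)
        assert g1 == pytest.approx(g3, abs=1e-12)

    def test_deterministic_environment_rejected(self, symmetric_config):
        joint = JointDistribution(P=np.array([[0.6, 0.4], [0.0, 0.0]]))
        with pytest.raises(ValueError, match="deterministic"):
            normalized_fitness(joint, symmetric_config)

    def test_zero_relative_growth_rejected(self):
        from bethedge import ModelConfig

        cfg_uniform = ModelConfig(
            growth=np.ones((2, 2)),
            switching=np.full((2, 2), 0.1),
            env_rates=(1.0, 1.0),
        )
        joint = joint_from_parameters(0.5, 0.5, 0.3)
        with pytest.raises(ValueError, match="relative growth"):
            normalized_fitness(joint, cfg_uniform)

    @given(feasible_triples())
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_growth_rate_route_agrees_with_joint_only_route(self, triple):
        """The rate-weighted definition and the growth-rate-free form are
        algebraically identical; the function cross-checks them to 1e-10
        internally for every call with a config."""
        px1, py1, p = triple
        joint = joint_from_parameters(px1, py1, p)
        normalized_fitness(joint, make_symmetric_model(4, 1, 0.1, 1.2, 0.1))


class TestSymmetricCurve:
    @pytest.mark.parametrize(
        "p,expected",
        [
            (0.25, (0.0, 0.0)),
            (0.5, (1.0, 1.0)),
            (0.4, (0.6, 0.2780719051126378)),
        ],
    )
    def test_curve_values(self, p, expected):
        gamma, info = symmetric_curve(p)
        assert gamma == pytest.approx(expected[0], abs=1e-12)
        assert info == pytest.approx(expected[1], abs=1e-12)

    def test_monotone_in_both_coordinates(self):
        ps = np.linspace(0.25, 0.5, 200)
        gammas, infos = zip(*(symmetric_curve(p) for p in ps))
        assert np.all(np.diff(gammas) > 0)
        assert np.all(np.diff(infos) >= 0)

    def test_out_of_interval_rejected(self):
        with pytest.raises(ValueError):
            symmetric_curve(0.2)

    def test_collapse_of_balanced_joints_onto_curve(self):
        """For balanced marginals, (Gamma, I) of the parameterized joint
        lies exactly on the master curve."""
        for p in np.linspace(0.25, 0.5, 11):
            joint = joint_from_parameters(0.5, 0.5, float(p))
            gamma_c, info_c = symmetric_curve(float(p))
            assert normalized_fitness(joint) == pytest.approx(gamma_c, abs=1e-12)
            assert mutual_information(joint) == pytest.approx(info_c, abs=1e-12)

    def test_inversion_round_trip(self):
        for p in (0.26, 0.3, 0.45, 0.499):
            gamma, info = symmetric_curve(p)
            assert symmetric_gamma_at_information(info) == pytest.approx(
                gamma, abs=1e-9
            )


class TestJointFromParameters:
    def test_product_case(self):
        joint = joint_from_parameters(0.5, 0.5, 0.25)
        np.testing.assert_allclose(joint.P, np.full((2, 2), 0.25), atol=1e-14)

    def test_upper_boundary_case(self):
        joint = joint_from_parameters(0.4, 0.2, 0.2)
        np.testing.assert_allclose(
            joint.P, [[0.2, 0.2], [0.0, 0.6]], atol=1e-14
        )

    def test_diagonal_maximal_case(self):
        joint = joint_from_parameters(0.4, 0.4, 0.4)
        assert normalized_fitness(joint) == pytest.approx(1.0, abs=1e-12)

    def test_infeasible_rejected(self):
        with pytest.raises(ValueError, match="infeasible"):
            joint_from_parameters(0.4, 0.2, 0.3)

    def test_anticorrelated_warns(self):
        with pytest.warns(UserWarning, match="anti-correlated"):
            joint = joint_from_parameters(0.5, 0.5, 0.1)
        assert normalized_fitness(joint) < 0.0

    @given(feasible_triples())
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_marginals_recovered_exactly(self, triple):
        px1, py1, p = triple
        joint = joint_from_parameters(px1, py1, p)
        assert np.all(joint.P >= 0)
        assert joint.P.sum() == pytest.approx(1.0, abs=1e-12)
        assert joint.Px1 == pytest.approx(px1, abs=1e-12)
        assert joint.Py1 == pytest.approx(py1, abs=1e-12)


class TestBounds:
    @pytest.mark.parametrize(
        "px1,py1,expected",
        [(0.4, 0.4, 1.0), (0.4, 0.2, 0.5), (0.4, 0.7, 0.5)],
    )
    def test_max_normalized_fitness_branches(self, px1, py1, expected):
        assert max_normalized_fitness(px1, py1) == pytest.approx(expected)

    def test_max_information_examples(self):
        assert max_information(0.5, 0.5) == pytest.approx(1.0, abs=1e-12)
        assert max_information(0.4, 0.2) == pytest.approx(
            0.32192809488736224, abs=1e-12
        )

    @pytest.mark.parametrize("p", [0.2, 0.35, 0.5, 0.7])
    def test_matched_marginals_reach_environment_entropy(self, p):
        assert max_information(p, p) == pytest.approx(environment_entropy(p), abs=1e-12)
        assert max_normalized_fitness(p, p) == pytest.approx(1.0, abs=1e-12)

    def test_first_branch_closed_form(self):
        """For Px1 <= Py1 the bound admits the closed form
        (1-Py1)log2(1/(1-Px1)) + Px1 log2(1/Py1)
        + (Py1-Px1) log2((Py1-Px1)/((1-Px1) Py1))."""
        for px1, py1 in [(0.3, 0.6), (0.4, 0.41), (0.2, 0.9)]:
            d = py1 - px1
            expected = (
                (1 - py1) * math.log2(1 / (1 - px1))
                + px1 * math.log2(1 / py1)
                + d * math.log2(d / ((1 - px1) * py1))
            )
            assert max_information(px1, py1) == pytest.approx(expected, abs=1e-12)

    def test_monotone_in_corner_probability(self):
        """At fixed marginals both Gamma and I are nondecreasing in the
        corner probability on [Px1 Py1, min(Px1, Py1)]."""
        px1, py1 = 0.4, 0.6
        ps = np.linspace(px1 * py1, min(px1, py1), 100)
        gam = [normalized_fitness(joint_from_parameters(px1, py1, float(p)))
               for p in ps]
        inf = [mutual_information(joint_from_parameters(px1, py1, float(p)))
               for p in ps]
        assert np.all(np.diff(gam) > 0)
        assert np.all(np.diff(inf) >= -1e-12)

    def test_brute_force_maxima_on_grid(self):
        """Grid maxima of Gamma and I over the corner probability match
        the closed-form bounds; both bounds peak at matched marginals."""
        px1 = 0.4
        best = {}
        for py1 in np.round(np.arange(0.1, 0.91, 0.1), 10):
            lo, hi = px1 * py1, min(px1, py1)
            ps = np.linspace(lo, hi, 2001)
            gam = (ps - px1 * py1) / (px1 * (1 - px1))
            P = np.stack([ps, px1 - ps, py1 - ps, 1 - px1 - py1 + ps])
            marg = np.outer(
                [px1, px1, 1 - px1, 1 - px1], np.ones_like(ps)
            ) * np.array([py1, 1 - py1, py1, 1 - py1])[:, None]
            with np.errstate(divide="ignore", invalid="ignore"):
                terms = np.where(P > 1e-15, P * np.log2(P / marg), 0.0)
            inf = terms.sum(axis=0)
            assert gam.max() == pytest.approx(max_normalized_fitness(px1, py1), abs=1e-9)
            assert inf.max() == pytest.approx(max_information(px1, py1), abs=1e-9)
            best[py1] = (gam.max(), inf.max())
        peak_gamma = max(best, key=lambda k: best[k][0])
        peak_info = max(best, key=lambda k: best[k][1])
        assert peak_gamma == pytest.approx(px1)
        assert peak_info == pytest.approx(px1)

    def test_boundary_marginals_rejected(self):
        with pytest.raises(ValueError):
            max_normalized_fitness(0.0, 0.5)
        with pytest.raises(ValueError):
            max_information(0.5, 1.0)


class TestMarginalInformationValue:
    def test_matches_finite_differences(self):
        px1, py1 = 0.5, 0.5
        lo, hi = px1 * py1, min(px1, py1)
        eps = 1e-7
        for p in np.linspace(lo, hi, 30)[1:-1]:
            p = float(p)
            def gi(q):
                j = joint_from_parameters(px1, py1, q)
                return normalized_fitness(j), mutual_information(j)
            g_hi, i_hi = gi(p + eps)
            g_lo, i_lo = gi(p - eps)
            fd = (g_hi - g_lo) / (i_hi - i_lo)
            got = marginal_information_value(px1, py1, p)
            assert got == pytest.approx(fd, rel=1e-4)

    def test_diverges_at_independence(self):
        assert marginal_information_value(0.5, 0.5, 0.25) == math.inf
        # approaching from above: grows without bound
        vals = [marginal_information_value(0.5, 0.5, 0.25 + d)
                for d in (1e-2, 1e-4, 1e-6)]
        assert vals[0] < vals[1] < vals[2]

    def test_strictly_positive_and_decreasing_in_information(self):
        px1 = 0.5
        ps = np.linspace(0.25, 0.5, 80)[1:-1]
        infos = [mutual_information(joint_from_parameters(px1, px1, float(p)))
                 for p in ps]
        vals = [marginal_information_value(px1, px1, float(p)) for p in ps]
        assert np.all(np.diff(infos) > 0)
        assert np.all(np.array(vals) > 0)
        assert np.all(np.diff(vals) < 0)


class TestMetricsReport:
    def test_assembly_and_invariants(self, symmetric_config):
        joint = joint_from_parameters(0.5, 0.5, 0.4)
        rep = compute_metrics(joint, symmetric_config)
        assert rep.Gamma == pytest.approx(0.6, abs=1e-12)
        assert rep.I == pytest.approx(0.2780719051126378, abs=1e-12)
        assert rep.gamma_mean == pytest.approx(
            time_averaged_fitness(joint, symmetric_config)
        )
        # gamma_max = gamma_ind + (gx1 + gx2) Px1 (1 - Px1)
        assert rep.gamma_max == pytest.approx(2.5 + 6 * 0.25)
        assert rep.Gamma <= rep.Gamma_max_bound + 1e-9
        assert rep.I <= rep.I_max_bound + 1e-9
        assert rep.I_max_bound <= rep.H_env + 1e-9
        # Gamma is the ratio of the two fitness gaps
        assert rep.Gamma == pytest.approx(
            (rep.gamma_mean - rep.gamma_ind) / (rep.gamma_max - rep.gamma_ind)
        )

    def test_serialization(self, symmetric_config, tmp_path):
        rep = compute_metrics(joint_from_parameters(0.5, 0.5, 0.3), symmetric_config)
        rep.to_json(tmp_path / "r.json")
        df = rep.to_dataframe()
        assert list(df.columns)[:4] == ["gamma_mean", "gamma_ind", "gamma_max", "Gamma"]
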