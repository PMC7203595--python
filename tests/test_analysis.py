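"""Flow analytics: shear, permeability, profiles, sectors, cohorts, stats."""

import itertools

import numpy as np
import pytest
from scipy import stats

import osteoflow as of


def make_solution(net, pressures=None, velocities=None, approach="strain_sources"):
    """Hand-built FlowSolution for analytics that only read fields."""
    n, e = net.n_nodes, net.n_edges
    return of.FlowSolution(
        approach=approach,
        node_pressure=np.asarray(pressures if pressures is not None else np.zeros(n), float),
        edge_flow=np.zeros(e),
        edge_velocity=np.asarray(velocities if velocities is not None else np.zeros(e), float),
        boundary_flux=0.0,
        excluded_nodes=np.array([], dtype=np.int64),
        applied={"delta_p": 13_000.0},
    )


class TestShearStress:
    def test_unit_velocity(self, params):
        assert of.shear_stress(1.0, params) == pytest.approx(0.4929, rel=1e-3)

    def test_zero_and_sign(self, params):
        assert of.shear_stress(0.0, params) == 0.0
        assert of.shear_stress(-2.0, params) == of.shear_stress(2.0, params)

    def test_osteogenic_threshold_velocity(self, params):
        # the 0.4 Pa in-vitro osteogenic threshold corresponds to ~0.81 µm/s
        v = 0.4 / (params.mu * params.shear_constant)
        assert v == pytest.approx(0.8114, rel=1e-3)
        assert of.shear_stress(v, params) == pytest.approx(0.4)


class TestIntrinsicPermeability:
    def test_spoke_limit_equals_canalicular_permeability(self, params, spoke_net):
        sol = of.solve_fixed_pressure(spoke_net, params)
        res = of.intrinsic_permeability(spoke_net, sol, params=params)
        assert res.k_osteon == pytest.approx(params.k_p_eff, rel=1e-9)

    def test_tortuosity_two_halves_permeability(self, params, spoke_net):
        curled = spoke_net.copy()
        curled.lengths = curled.lengths * 2.0  # arc doubles, radial span fixed
        sol = of.solve_fixed_pressure(curled, params)
        res = of.intrinsic_permeability(curled, sol, params=params)
        assert res.k_osteon == pytest.approx(params.k_p_eff / 2.0, rel=1e-9)

    def test_invariant_under_applied_pressure(self, params, ordinary_net):
        a = of.intrinsic_permeability(
            ordinary_net, of.solve_fixed_pressure(ordinary_net, params, 13_000.0), params=params
        )
        b = of.intrinsic_permeability(
            ordinary_net, of.solve_fixed_pressure(ordinary_net, params, 1_300.0), params=params
        )
        assert a.k_osteon == pytest.approx(b.k_osteon, rel=1e-9)
        assert a.k_osteon <= params.k_p_eff * (1 + 1e-9)

    def test_zero_pressure_rejected(self, params, spoke_net):
        sol = of.solve_fixed_pressure(spoke_net, params)
        with pytest.raises(ValueError):
            of.intrinsic_permeability(spoke_net, sol, delta_p=0.0)


class TestPressureProfile:
    def test_exact_on_linear_field(self, params, ordinary_net):
        x = of.normalized_distance(ordinary_net)
        sol = make_solution(ordinary_net, pressures=13_000.0 * x)
        grid, prof = of.pressure_profile(ordinary_net, sol)
        interior = (grid > 0.05) & (grid < 0.95)
        assert np.allclose(prof[interior], 13_000.0 * grid[interior], rtol=1e-6)

    def test_constant_field_stays_constant(self, ordinary_net):
        sol = make_solution(ordinary_net, pressures=np.full(ordinary_net.n_nodes, 5.0))
        _, prof = of.pressure_profile(ordinary_net, sol)
        assert np.allclose(prof, 5.0, atol=1e-9)

    def test_fixed_pressure_spoke_profile_is_linear(self, params, spoke_net):
        # nodes sit at discrete radial stations; evaluate the smoother there
        sol = of.solve_fixed_pressure(spoke_net, params)
        stations = np.unique(np.round(of.normalized_distance(spoke_net), 9))[1:-1]
        _, prof = of.pressure_profile(spoke_net, sol, grid=stations)
        assert np.allclose(prof, 13_000.0 * stations, rtol=1e-6)

    def test_too_few_nodes_rejected(self, params, chain5):
        sol = of.solve_strain_sources(chain5, params)
        with pytest.raises(ValueError, match="at least 10"):
            of.pressure_profile(chain5, sol)


class TestSectorHeterogeneity:
    def ring_net(self):
        angles = (np.arange(36) + 0.5) * 2 * np.pi / 36
        pos = np.column_stack(
            [70 * np.cos(angles), 70 * np.sin(angles), np.full(36, 20.0)]
        )
        return of.OsteonNetwork(
            node_ids=np.arange(36),
            positions=pos,
            kinds=np.array(["branch"] * 36, dtype=object),
            boundary=np.array(["haversian"] * 36, dtype=object),
            edge_ids=np.arange(0),
            edge_nodes=np.zeros((0, 2), dtype=np.int64),
            lengths=np.zeros(0),
            metadata=of.OsteonMetadata(),
        )

    def test_uniform_pressure_gives_zero(self):
        net = self.ring_net()
        sol = make_solution(net, pressures=np.full(36, 3.0))
        assert of.sector_heterogeneity(net, sol).relative_std == 0.0

    def test_single_hot_sector_arithmetic(self):
        net = self.ring_net()
        p = np.ones(36)
        p[7] = 2.0
        sol = make_solution(net, pressures=p)
        stats_ = of.sector_heterogeneity(net, sol)
        assert stats_.relative_std == pytest.approx(0.1599, abs=1e-4)
        assert stats_.n_empty == 0

    def test_strain_loading_more_heterogeneous_than_fixed(self, params, ordinary_net):
        s1 = of.solve_fixed_pressure(ordinary_net, params)
        s2 = of.solve_strain_sources(ordinary_net, params)
        h1 = of.sector_heterogeneity(ordinary_net, s1).relative_std
        h2 = of.sector_heterogeneity(ordinary_net, s2).relative_std
        assert h2 > h1


class TestExceedance:
    def test_identical_shear_is_a_step_function(self, params, spoke_net):
        sol = of.solve_fixed_pressure(spoke_net, params)  # uniform velocity
        tau0 = of.shear_stress(np.abs(sol.edge_velocity[0]), params)
        dist = of.exceedance_distribution(
            [sol], params, thresholds=np.array([0.0, tau0 * 0.999, tau0 * 1.001])
        )
        assert dist.mean.tolist() == [1.0, 1.0, 0.0]

    def test_monotone_and_bounded(self, params, ordinary_net):
        sol = of.solve_strain_sources(ordinary_net, params)
        dist = of.exceedance_distribution([sol], params)
        assert np.all(np.diff(dist.mean) <= 1e-12)
        assert np.all((dist.mean >= 0.0) & (dist.mean <= 1.0))
        assert dist.mean[0] == pytest.approx(1.0, abs=1e-6)

    def test_strain_rate_rescales_curve_exactly(self, params, ordinary_net):
        run = of.solve_strain_sources(ordinary_net, params, 0.015)
        walk = of.solve_strain_sources(ordinary_net, params, 0.0015)
        d_run = of.exceedance_distribution([run], params)
        d_walk = of.exceedance_distribution(
            [walk], params, thresholds=0.1 * d_run.thresholds
        )
        assert np.array_equal(d_run.mean, d_walk.mean)

    def test_length_weighting_option(self, params, ordinary_net):
        sol = of.solve_strain_sources(ordinary_net, params)
        d = of.exceedance_distribution(
            [sol], params, nets=[ordinary_net], weighting="length"
        )
        assert np.all(np.diff(d.mean) <= 1e-12)
        with pytest.raises(ValueError, match="networks"):
            of.exceedance_distribution([sol], params, weighting="length")

    def test_intersection_found_by_bisection(self, params, spoke_net):
        # two single-osteon groups with uniform shear crossing at a known τ
        lo = make_solution(spoke_net, velocities=np.full(spoke_net.n_edges, 1.0))
        steep = make_solution(
            spoke_net,
            velocities=np.linspace(0.0, 4.0, spoke_net.n_edges),
        )
        grid = np.linspace(0.0, of.shear_stress(4.0, params), 400)
        da = of.exceedance_distribution([lo], params, thresholds=grid)
        db = of.exceedance_distribution([steep], params, thresholds=grid)
        tau, frac = of.exceedance_intersection(da, db)
        # oracle: coarse grid scan for the sign change of the difference
        diff = da.mean - db.mean
        sign_change = np.flatnonzero(np.sign(diff[:-1]) != np.sign(diff[1:]))[0]
        assert grid[sign_change] <= tau <= grid[sign_change + 1]
        assert 0.0 < frac < 1.0


class TestVelocityByHalf:
    def test_spoke_halves_equal(self, params, spoke_net):
        sol = of.solve_fixed_pressure(spoke_net, params)
        inner, outer = of.velocity_by_half(spoke_net, sol)
        assert inner == pytest.approx(outer, rel=1e-9)

    def test_strain_flow_accumulates_toward_canal(self, params):
        net = of.generate_chain(10, 10.0)
        sol = of.solve_strain_sources(net, params)
        inner, outer = of.velocity_by_half(net, sol)
        assert inner > outer

    def test_holds_on_synthetic_osteons_both_approaches(self, params, ordinary_net):
        for sol in (
            of.solve_fixed_pressure(ordinary_net, params),
            of.solve_strain_sources(ordinary_net, params),
        ):
            inner, outer = of.velocity_by_half(ordinary_net, sol)
            assert inner > outer


class TestVelocityPathLength:
    def test_inverse_relation_for_fixed_pressure(self, params):
        cohort = []
        for t in (1.0, 1.3, 1.7, 2.2, 3.0):
            net = of.generate_spoke_osteon(30, 4.0)
            net.lengths = net.lengths * t
            sol = of.solve_fixed_pressure(net, params)
            cohort.append(
                (of.structural_summary(net), of.mean_velocity(net, sol))
            )
        fit = of.velocity_pathlength_relation(cohort, "fixed_pressure")
        assert fit.model == "inverse" and fit.a > 0
        assert fit.r_value > 0.999  # v̄ against 1/SPL is essentially exact

    def test_linear_relation_for_strain_sources(self, params):
        cohort = []
        for n in (10, 20, 30, 40):
            net = of.generate_chain(n, 10.0)
            sol = of.solve_strain_sources(net, params, 0.015)
            cohort.append((of.structural_summary(net), of.mean_velocity(net, sol)))
        fit = of.velocity_pathlength_relation(cohort, "strain_sources")
        # closed form: v̄ = ε̇·SPL exactly on sealed chains
        assert fit.a == pytest.approx(0.015, rel=1e-6)
        assert abs(fit.b) < 1e-9
        assert fit.r_value == pytest.approx(1.0, abs=1e-9)

    def test_shuffled_pairing_is_null(self, params):
        rng = np.random.default_rng(5)
        cohort = []
        for n in (10, 15, 20, 25, 30, 35, 40, 45):
            net = of.generate_chain(n, 10.0)
            sol = of.solve_strain_sources(net, params)
            cohort.append((of.structural_summary(net), of.mean_velocity(net, sol)))
        vs = [v for _, v in cohort]
        shuffled = list(rng.permutation(vs))
        null = [(s, v) for (s, _), v in zip(cohort, shuffled)]
        fit = of.velocity_pathlength_relation(null, "strain_sources")
        assert fit.p_value > 0.05

    def test_degenerate_cohort_rejected(self, params):
        net = of.generate_chain(10, 10.0)
        sol = of.solve_strain_sources(net, params)
        item = (of.structural_summary(net), of.mean_velocity(net, sol))
        with pytest.raises(ValueError, match="degenerate"):
            of.velocity_pathlength_relation([item] * 4, "strain_sources")


class TestCompareGroups:
    def test_identical_groups(self):
        c = of.compare_groups([1.0, 1.0, 1.0], [1.0, 1.0])
        assert c.p_value == 1.0

    def test_fully_separated_8_vs_9(self):
        c = of.compare_groups(np.arange(8), np.arange(10, 19))
        assert c.p_value == pytest.approx(2 / 24310, rel=1e-9)
        assert c.significant

    @pytest.mark.parametrize("seed", [3, 17, 42])
    def test_matches_exact_permutation_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.normal(size=4)
        y = rng.normal(0.8, size=4)
        c = of.compare_groups(x, y)
        pooled = np.concatenate([x, y])
        us = []
        for comb in itertools.combinations(range(8), 4):
            xa = pooled[list(comb)]
            yb = pooled[[i for i in range(8) if i not in comb]]
            us.append(sum((xi > yj) for xi in xa for yj in yb))
        us = np.array(us)
        u0 = sum((xi > yj) for xi in x for yj in y)
        p_exact = min(1.0, 2 * min((us <= u0).mean(), (us >= u0).mean()))
        assert c.p_value == pytest.approx(p_exact, rel=1e-12)

    def test_descriptives_and_errors(self):
        c = of.compare_groups([1.0, 2.0, 3.0], [4.0, 6.0])
        assert c.mean_a == pytest.approx(2.0)
        assert c.std_b == pytest.approx(np.sqrt(2.0))
        with pytest.raises(ValueError):
            of.compare_groups([1.0], [2.0, 3.0])


class TestRotationInvariance:
    def test_analyses_invariant_under_rigid_rotation(self, params, ordinary_net):
        angle = np.deg2rad(50.0)
        c, s = np.cos(angle), np.sin(angle)
        rot = ordinary_net.copy()
        x, y = rot.positions[:, 0].copy(), rot.positions[:, 1].copy()
        rot.positions[:, 0] = c * x - s * y
        rot.positions[:, 1] = s * x + c * y
        a = of.solve_fixed_pressure(ordinary_net, params)
        b = of.solve_fixed_pressure(rot, params)
        assert of.mean_velocity(rot, b) == pytest.approx(
            of.mean_velocity(ordinary_net, a), rel=1e-12
        )
        ka = of.intrinsic_permeability(ordinary_net, a, params=params).k_osteon
        kb = of.intrinsic_permeability(rot, b, params=params).k_osteon
        assert kb == pytest.approx(ka, rel=1e-12)
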