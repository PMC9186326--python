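"""SECR conditional likelihood, mesh construction, and derived density."""

import math

import numpy as np
import pytest

import scrpath as sp
from scrpath.core import DetectionParams, ModelSpec, ScrFit, _HistoryStats

from oracles import history_prob, oracle_negloglik, pdot_enumeration, scalar_p
from conftest import random_tiny_config


class TestMakeMesh:
    def test_disc_count_around_single_trap(self):
        traps = sp.TrapArray(ids=["t"], xy=np.array([[0.0, 0.0]]),
                             usage=np.ones((1, 5)))
        mesh = sp.make_mesh(traps, buffer=2000.0, spacing=1000.0)
        # lattice offsets with dx^2 + dy^2 <= 4 (in km): 1 + 4 + 4 + 4
        assert mesh.n_points == 13
        assert mesh.cell_area_km2 == pytest.approx(1.0)

    def test_points_beyond_buffer_excluded(self):
        traps = sp.TrapArray(ids=["t"], xy=np.array([[0.0, 0.0]]),
                             usage=np.ones((1, 5)))
        mesh = sp.make_mesh(traps, buffer=2000.0, spacing=1000.0)
        d = np.hypot(*(mesh.points - traps.xy[0]).T)
        assert (d <= 2000.0 + 1e-9).all()

    def test_water_exclusion(self):
        traps = sp.TrapArray(ids=["t"], xy=np.array([[0.0, 0.0]]),
                             usage=np.ones((1, 5)))
        # water covering the eastern half of the region
        vals = np.zeros((50, 50))
        vals[:, 25:] = 1.0
        water = sp.CostRaster(vals, cellsize=200.0, xll=-5000.0, yll=-5000.0)
        dry = sp.make_mesh(traps, 2000.0, 1000.0)
        wet = sp.make_mesh(traps, 2000.0, 1000.0, water=water)
        assert wet.n_points < dry.n_points
        assert wet.n_water_excluded == dry.n_points - wet.n_points
        for x, y in wet.points:
            r, c = water.index_of(x, y)
            assert water.values[r, c] <= 0.5

    def test_bad_arguments(self):
        traps = sp.TrapArray(ids=["t"], xy=np.array([[0.0, 0.0]]),
                             usage=np.ones((1, 5)))
        with pytest.raises(ValueError):
            sp.make_mesh(traps, buffer=-1.0, spacing=1000.0)
        with pytest.raises(ValueError):
            sp.make_mesh(traps, buffer=2000.0, spacing=0.0)


class TestDetectionPrimitives:
    def test_halfnormal_values(self):
        assert sp.halfnormal_p(0.0, 0.3, 1500.0) == pytest.approx(0.3)
        half_d = 2000.0 * math.sqrt(2 * math.log(2))
        assert sp.halfnormal_p(half_d, 0.3, 2000.0) == pytest.approx(0.15)
        assert sp.halfnormal_p(2000.0, 0.1, 2000.0) == pytest.approx(
            0.1 * math.exp(-0.5), rel=1e-9)
        with pytest.raises(ValueError):
            sp.halfnormal_p(100.0, 0.1, -5.0)

    def test_usage_adjust(self):
        assert sp.usage_adjust(0.7, 0.0) == 0.0
        assert sp.usage_adjust(0.7, 1.0) == pytest.approx(0.7)
        assert sp.usage_adjust(0.2, 0.5) == pytest.approx(1 - 0.8**0.5)
        with pytest.raises(ValueError):
            sp.usage_adjust(0.2, 1.5)

    def test_bk_is_trap_specific(self):
        omega = np.zeros((3, 2), dtype=np.uint8)
        omega[0, 0] = 1     # trap 0, occasion 0
        assert sp.bk_indicator(omega, 0, 0) == 0   # no prior occasions
        assert sp.bk_indicator(omega, 0, 2) == 1
        assert sp.bk_indicator(omega, 1, 2) == 0   # other trap untouched

    def test_encounter_prob_links(self):
        p = DetectionParams(beta0=0.0, gamma0=math.log(1000.0))
        assert sp.encounter_prob(0.0, "F", 1, 0, p, 1.0) == pytest.approx(0.5)
        p_bk = DetectionParams(beta0=0.0, beta_bk=1.0, gamma0=math.log(1000.0))
        assert sp.encounter_prob(500.0, "F", 1, 1, p_bk) > \
            sp.encounter_prob(500.0, "F", 1, 0, p_bk)
        assert sp.encounter_prob(1e6, "F", 1, 0, p) == pytest.approx(0.0)
        assert sp.encounter_prob(np.inf, "F", 1, 0, p) == 0.0


class TestPdot:
    def test_single_trap_single_occasion_equals_p(self):
        params = DetectionParams(beta0=-1.0, gamma0=math.log(1500.0))
        u = np.array([[1.0]])
        p = scalar_p(800.0, params.g0("F"), params.sigma("F"), 1.0)
        enum = pdot_enumeration("F", 1, params, [800.0], u)
        assert enum == pytest.approx(p, rel=1e-12)

    def test_enumeration_matches_complement_product(self):
        # 2 traps x 2 occasions: sum over the 15 non-null histories must
        # equal 1 - prod(1 - p)
        rng = np.random.default_rng(7)
        params = DetectionParams(beta0=-0.8, gamma0=math.log(1200.0))
        usage = rng.choice([0.5, 1.0], size=(2, 2))
        dists = rng.uniform(0, 3000, 2)
        enum = pdot_enumeration("M", 1, params, dists, usage)
        prod = 1.0
        for k in range(2):
            for s in range(2):
                prod *= 1 - scalar_p(dists[k], params.g0("M"),
                                     params.sigma("M"), usage[k, s])
        assert enum == pytest.approx(1 - prod, rel=1e-12)

    def test_history_probabilities_sum_to_one_with_bk_dynamics(self):
        import itertools
        rng = np.random.default_rng(8)
        params = DetectionParams(beta0=-0.5, beta_bk=0.8,
                                 gamma0=math.log(900.0))
        usage = rng.choice([0.3, 1.0], size=(3, 2))   # S*K = 6
        dists = rng.uniform(0, 2500, 3)
        total = 0.0
        nonnull = 0.0
        for bits in itertools.product([0, 1], repeat=6):
            omega = np.array(bits, dtype=np.uint8).reshape(2, 3)
            pr = history_prob(omega, "F", 1, params, dists, usage)
            total += pr
            if omega.any():
                nonnull += pr
        assert total == pytest.approx(1.0, rel=1e-12)
        assert nonnull == pytest.approx(
            pdot_enumeration("F", 1, params, dists, usage, with_bk=True),
            rel=1e-12)


class TestConditionalLikelihood:
    def test_single_point_mesh_closed_form(self):
        traps = sp.TrapArray(ids=["a"], xy=np.array([[0.0, 0.0]]),
                             usage=np.ones((1, 2)))
        mesh = sp.HabitatMesh(np.array([[500.0, 0.0]]), spacing=1000.0)
        omega = np.zeros((1, 2, 1), dtype=np.uint8)
        omega[0, 0, 0] = 1
        data = sp.CaptureHistories(omega, np.array(["F"]))
        params = DetectionParams(beta0=-1.2, beta_bk=0.5,
                                 gamma0=math.log(1000.0))
        p1 = scalar_p(500.0, params.g0("F", 0), params.sigma("F"), 1.0)
        p2 = scalar_p(500.0, params.g0("F", 1), params.sigma("F"), 1.0)
        pr_hist = p1 * (1 - p2)
        pdot = 1 - (1 - p1) ** 2
        expected = -math.log(pr_hist / pdot)
        d = sp.euclidean_distance_matrix(mesh.points, traps.xy).d
        val = sp.conditional_negloglik(data, mesh, traps, params,
                                       ModelSpec(), d)
        assert val == pytest.approx(expected, rel=1e-12)

    def test_mixture_with_null_class_effect_collapses(self, tiny_problem):
        traps, mesh, data = tiny_problem
        d = sp.euclidean_distance_matrix(mesh.points, traps.xy).d
        params = DetectionParams(beta0=-1.0, beta_bk=0.3,
                                 gamma0=math.log(1400.0), gamma_h2=0.0,
                                 logit_pi=0.7)
        plain = sp.conditional_negloglik(data, mesh, traps, params,
                                         ModelSpec(), d)
        mixed = sp.conditional_negloglik(data, mesh, traps, params,
                                         ModelSpec(mixture=True), d)
        assert mixed == pytest.approx(plain, rel=1e-12)

    def test_mixture_class_relabeling_invariance(self, tiny_problem):
        traps, mesh, data = tiny_problem
        d = sp.euclidean_distance_matrix(mesh.points, traps.xy).d
        params = DetectionParams(beta0=-1.0, gamma0=math.log(1000.0),
                                 gamma_h2=0.9, logit_pi=0.4)
        # relabel: class 2 becomes the reference class
        swapped = DetectionParams(beta0=-1.0, gamma0=math.log(1000.0) + 0.9,
                                  gamma_h2=-0.9, logit_pi=-0.4)
        spec = ModelSpec(mixture=True)
        v1 = sp.conditional_negloglik(data, mesh, traps, params, spec, d)
        v2 = sp.conditional_negloglik(data, mesh, traps, swapped, spec, d)
        assert v1 == pytest.approx(v2, rel=1e-12)

    @pytest.mark.parametrize("mixture", [False, True])
    def test_matches_enumeration_oracle(self, mixture):
        rng = np.random.default_rng(42 + mixture)
        for _ in range(8):
            traps, mesh, data, params, spec = random_tiny_config(
                rng, mixture=mixture)
            d = sp.euclidean_distance_matrix(mesh.points, traps.xy).d
            fast = sp.conditional_negloglik(data, mesh, traps, params, spec, d)
            slow = oracle_negloglik(data, mesh, traps, params, spec, d)
            assert fast == pytest.approx(slow, rel=1e-10)

    def test_alpha2_with_euclidean_spec_rejected(self, tiny_problem):
        traps, mesh, data = tiny_problem
        d = sp.euclidean_distance_matrix(mesh.points, traps.xy).d
        params = DetectionParams(beta0=-1.0, alpha2=0.3)
        with pytest.raises(ValueError):
            sp.conditional_negloglik(data, mesh, traps, params, ModelSpec(), d)

    def test_detection_at_zero_usage_rejected(self):
        traps = sp.TrapArray(ids=["a"], xy=np.array([[0.0, 0.0]]),
                             usage=np.array([[0.0, 1.0]]))
        omega = np.zeros((1, 2, 1), dtype=np.uint8)
        omega[0, 0, 0] = 1  # detection on the zero-usage occasion
        data = sp.CaptureHistories(omega, np.array(["F"]))
        with pytest.raises(ValueError):
            _HistoryStats(data, traps)


class TestEsa:
    def test_monotone_in_g0_and_summation_oracle(self):
        rng = np.random.default_rng(9)
        traps = sp.TrapArray(ids=[f"t{i}" for i in range(4)],
                             xy=rng.uniform(-2000, 2000, (4, 2)),
                             usage=np.ones((4, 3)))
        mesh = sp.make_mesh(traps, buffer=8000.0, spacing=500.0)
        assert mesh.n_points > 800
        lo = DetectionParams(beta0=-2.0, gamma0=math.log(1500.0))
        hi = DetectionParams(beta0=-1.0, gamma0=math.log(1500.0))
        d = sp.euclidean_distance_matrix(mesh.points, traps.xy).d
        a_lo = sp.effective_sampling_area(lo, "F", mesh, traps, d)
        a_hi = sp.effective_sampling_area(hi, "F", mesh, traps, d)
        assert 0 < a_lo < a_hi

        # reordered compensated-summation oracle
        total = math.fsum(
            1.0 - math.prod(
                (1 - scalar_p(d[x, k], lo.g0("F"), lo.sigma("F"), 1.0)) ** 3
                for k in range(4))
            for x in reversed(range(mesh.n_points)))
        assert a_lo == pytest.approx(total * mesh.cell_area_km2, rel=1e-9)


class TestDerivedDensity:
    def _manual_fit(self, a_by_sex, vcov, theta_len=5):
        spec = ModelSpec()
        fit = ScrFit(spec=spec, params=DetectionParams(beta0=-1.0),
                     theta=np.zeros(theta_len), loglik=0.0, vcov=vcov,
                     converged=True, n_params=5)
        return fit

    def test_equal_areas_give_n_over_a(self, monkeypatch):
        n, a = 12, 3.5
        fit = self._manual_fit({"F": a, "M": a}, vcov=np.zeros((5, 5)))
        omega = np.zeros((n, 1, 1), dtype=np.uint8)
        omega[:, 0, 0] = 1
        data = sp.CaptureHistories(omega, np.array(["F"] * n))
        monkeypatch.setattr(sp.core, "effective_sampling_area",
                            lambda *args, **kw: a)
        fit._ctx = {"mesh": None, "traps": None, "distances": None}
        D, se, rse = sp.derived_density(fit, data)
        assert D == pytest.approx(n / a)
        # with parameters treated as known, only the Poisson term remains
        assert rse == pytest.approx(1 / math.sqrt(n))

    def test_missing_vcov_yields_no_se(self, monkeypatch):
        fit = self._manual_fit({"F": 2.0, "M": 2.0}, vcov=None)
        omega = np.zeros((3, 1, 1), dtype=np.uint8)
        omega[:, 0, 0] = 1
        data = sp.CaptureHistories(omega, np.array(["F", "M", "F"]))
        monkeypatch.setattr(sp.core, "effective_sampling_area",
                            lambda *args, **kw: 2.0)
        fit._ctx = {"mesh": None, "traps": None, "distances": None}
        D, se, rse = sp.derived_density(fit, data)
        assert D == pytest.approx(1.5)
        assert se is None and rse is None


class TestFitModel:
    def test_fit_recovers_simulation_scale(self, default_survey):
        truth, traps, data = default_survey
        mesh = sp.make_mesh(traps, 15000.0, 1000.0)
        fit = sp.fit_model(ModelSpec(), data, mesh, traps)
        assert fit.converged
        assert fit.density == pytest.approx(truth.density, rel=0.5)
        assert fit.params.sigma("F") == pytest.approx(truth.sigma["F"], rel=0.5)
        assert fit.rse is not None and 0 < fit.rse < 0.5
        assert fit.n_params == 5

    def test_zero_spatial_recaptures_flagged(self):
        traps = sp.TrapArray(ids=["a", "b"],
                             xy=np.array([[0.0, 0.0], [3000.0, 0.0]]),
                             usage=np.ones((2, 3)))
        omega = np.zeros((2, 3, 2), dtype=np.uint8)
        omega[0, 0, 0] = omega[0, 1, 0] = 1
        omega[1, 2, 1] = 1
        data = sp.CaptureHistories(omega, np.array(["F", "M"]))
        mesh = sp.make_mesh(traps, 4000.0, 1000.0)
        fit = sp.fit_model(ModelSpec(), data, mesh, traps, compute_vcov=False)
        assert any("sigma weakly identified" in w for w in fit.warnings)

    def test_lcp_without_surface_errors(self, tiny_problem):
        traps, mesh, data = tiny_problem
        spec = ModelSpec(distance_mode="lcp", covariate="roads",
                         resolution=120)
        with pytest.raises(ValueError):
            sp.fit_model(spec, data, mesh, traps, surfaces={})


class TestModelSpec:
    def test_invariants(self):
        with pytest.raises(ValueError):
            ModelSpec(distance_mode="lcp", covariate="roads",
                      resolution=120, mixture=True)
        with pytest.raises(ValueError):
            ModelSpec(distance_mode="lcp", covariate="lava", resolution=120)
        with pytest.raises(ValueError):
            ModelSpec(covariate="roads")
        assert ModelSpec(mixture=True).n_params == 7
        assert ModelSpec(distance_mode="lcp", covariate="water",
                         resolution=240,
                         alpha2_constraint="positive").n_params == 6

    def test_positive_constraint_round_trip(self):
        spec = ModelSpec(distance_mode="lcp", covariate="water",
                         resolution=240, alpha2_constraint="positive")
        p = DetectionParams(beta0=-1.0, alpha2=0.25)
        theta = p.to_vector(spec)
        back = DetectionParams.from_vector(theta, spec)
        assert back.alpha2 == pytest.approx(0.25, rel=1e-12)
        assert back.alpha2 > 0
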