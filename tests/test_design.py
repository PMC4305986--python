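"""Tracking cost, fitness, GA vs exhaustive search, inducer recommendation."""

import numpy as np
import pytest

import lysisdesign as ld
from lysisdesign.design import FITNESS_EPS, inducer_grid
from lysisdesign.errors import DesignDomainError, TargetRangeError, UsageError


@pytest.fixture(scope="module")
def small_library():
    return ld.generate_library(4, 2, 4, seed=13)


@pytest.fixture(scope="module")
def small_template(small_library):
    return ld.CircuitSpec("activator", small_library.constitutive[0],
                          small_library.activated[0])


class TestCost:
    def test_planted_pair_cost_is_tiny(self, calibrated, template, ref):
        J = ld.cost(calibrated.planted_pair, calibrated.library, template, ref)
        # 2% relative tracking of a response <= 0.7 O.D. bounds the integrand
        bound = (0.02 * 0.7) ** 2 * (10.0 - 0.1)
        assert 0.0 <= J <= bound

    def test_perfect_tracking_costs_zero(self, template, ref):
        """A circuit whose density is analytically flat vs a flat reference."""
        from dataclasses import replace

        flat_ref = ld.ReferenceResponse(base=template.Nmax, amplitude=0.0, scale=1.0)
        lib = ld.ComponentLibrary(
            constitutive=[template.constitutive], activated=[template.regulated],
            repressed=[ld.generate_library(1, 1, 1, seed=0).repressed[0]],
        )
        spec = replace(template, gamma_N=0.0)  # no lysis: N_ss = Nmax exactly
        assert ld.cost((0, 0), lib, spec, flat_ref) == 0.0

    def test_pointwise_dominance_orders_costs(self, calibrated, template, ref):
        ranked = ld.exhaustive_search(calibrated.library, template, ref)
        worst = ranked[-1]
        assert worst.cost > ranked[0].cost

    def test_invalid_indices_rejected(self, small_library, small_template, ref):
        with pytest.raises(DesignDomainError):
            ld.cost((99, 0), small_library, small_template, ref)

    def test_common_random_numbers_make_cost_order_invariant(
        self, small_library, small_template, ref
    ):
        from lysisdesign.steady_state import perturbation_multipliers

        pert = ld.PerturbationSpec(frac=0.05, draws=30, seed=3)
        mults = perturbation_multipliers(pert)
        pairs = [(0, 0), (1, 2), (3, 1)]
        first = [ld.cost(S, small_library, small_template, ref, pert=pert,
                         _multipliers=mults) for S in pairs]
        second = [ld.cost(S, small_library, small_template, ref, pert=pert,
                          _multipliers=mults) for S in reversed(pairs)]
        assert first == list(reversed(second))

    def test_perturbation_never_helps_planted_pair(self, calibrated, template, ref):
        """Parameter noise can only hurt tracking of an already-optimal pair."""
        J0 = ld.cost(calibrated.planted_pair, calibrated.library, template, ref)
        pert = ld.PerturbationSpec(frac=0.05, draws=300, seed=11)
        J_noisy = ld.cost(calibrated.planted_pair, calibrated.library, template,
                          ref, pert=pert)
        assert J_noisy >= J0


class TestFitness:
    def test_reciprocal_with_regularization(self):
        assert ld.fitness(1.0) == pytest.approx(1.0, rel=1e-9)
        assert ld.fitness(0.0) == pytest.approx(1.0 / FITNESS_EPS)

    def test_order_reversal(self):
        assert ld.fitness(0.1) > ld.fitness(0.2)

    def test_negative_cost_rejected(self):
        with pytest.raises(DesignDomainError):
            ld.fitness(-1.0)


class TestSearch:
    def test_single_pair_library(self, template, ref):
        lib = ld.ComponentLibrary(
            constitutive=[template.constitutive],
            activated=[template.regulated],
            repressed=[ld.generate_library(1, 1, 1, seed=0).repressed[0]],
        )
        ga = ld.ga_search(lib, template, ref)
        ex = ld.exhaustive_search(lib, template, ref)
        assert ga[0].S == ex[0].S == (0, 0)

    def test_ga_recovers_planted_pair(self, calibrated, template, ref):
        ranked = ld.ga_search(calibrated.library, template, ref,
                              settings=ld.GASettings(seed=2))
        assert ranked[0].S == calibrated.planted_pair
        assert (ranked[0].constitutive_id, ranked[0].regulated_id) == ("C-cal", "A-cal")

    @pytest.mark.parametrize("seed", range(20))
    def test_ga_matches_exhaustive_optimum(self, ref, seed):
        """Brute-force enumeration is the oracle for the GA's best cost."""
        r = np.random.default_rng(seed)
        lib = ld.generate_library(int(r.integers(3, 11)), 2, int(r.integers(3, 11)),
                                  seed=seed)
        template = ld.CircuitSpec("activator", lib.constitutive[0], lib.activated[0])
        ex = ld.exhaustive_search(lib, template, ref)
        ga = ld.ga_search(lib, template, ref, settings=ld.GASettings(seed=seed))
        assert ga[0].cost == ex[0].cost

    def test_results_sorted_ascending_with_stable_ties(self, calibrated, template, ref):
        ranked = ld.exhaustive_search(calibrated.library, template, ref)
        costs = [c.cost for c in ranked]
        assert costs == sorted(costs)
        assert ranked == sorted(ranked, key=lambda c: (c.cost, c.S))

    def test_seed_reproducibility(self, small_library, small_template, ref):
        a = ld.ga_search(small_library, small_template, ref,
                         settings=ld.GASettings(seed=5))
        b = ld.ga_search(small_library, small_template, ref,
                         settings=ld.GASettings(seed=5))
        assert a == b

    def test_stop_threshold_halts_early(self, calibrated, template, ref):
        settings = ld.GASettings(seed=2, generations=100, stop_cost=1.0)
        ranked = ld.ga_search(calibrated.library, template, ref, settings=settings)
        # a generous threshold stops after few evaluations, well short of all pairs
        n_pairs = len(calibrated.library.constitutive) * len(calibrated.library.activated)
        assert len(ranked) < n_pairs

    def test_exhaustive_guard(self, small_library, small_template, ref):
        with pytest.raises(UsageError):
            ld.exhaustive_search(small_library, small_template, ref, max_pairs=3)

    def test_empty_class_rejected(self, template, ref):
        lib = ld.ComponentLibrary(
            constitutive=[template.constitutive],
            repressed=[ld.generate_library(1, 1, 1, seed=0).repressed[0]],
        )
        with pytest.raises(UsageError):
            ld.ga_search(lib, template, ref)


class TestRecommendInducer:
    @pytest.mark.parametrize("target, expected", [(0.5, 0.5), (0.3, 1.0)])
    def test_demo_worked_values(self, ref, target, expected):
        assert ld.recommend_inducer(ref, target) == pytest.approx(expected)

    def test_intermediate_target(self, ref):
        I = ld.recommend_inducer(ref, 0.4)
        assert I == pytest.approx(np.sqrt(0.5), rel=1e-9)
        assert ref(I) == pytest.approx(0.4, rel=1e-12)

    def test_inversion_identity_on_attainable_interval(self, ref):
        for I in np.geomspace(0.1, 10.0, 25):
            assert ld.recommend_inducer(ref, ref(I)) == pytest.approx(I, rel=1e-9)

    def test_unreachable_target_reports_interval(self, ref):
        with pytest.raises(TargetRangeError) as err:
            ld.recommend_inducer(ref, 0.9)
        lo, hi = err.value.attainable
        assert lo == pytest.approx(ref(10.0)) and hi == pytest.approx(ref(0.1))
        with pytest.raises(TargetRangeError):
            ld.recommend_inducer(ref, 0.01)


def test_inducer_grid_is_log_spaced():
    grid = inducer_grid((0.1, 10.0), points=5)
    assert grid[0] == pytest.approx(0.1) and grid[-1] == pytest.approx(10.0)
    ratios = grid[1:] / grid[:-1]
    assert np.allclose(ratios, ratios[0])
    with pytest.raises(DesignDomainError):
        inducer_grid((0.0, 10.0))
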