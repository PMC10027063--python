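"""Cell population: stochastic division/death, mechanics, confluence, coloring."""

import math

import numpy as np
import pytest

from pkpdsim.cells import (
    CellType,
    Population,
    confluence,
    damage_coloring,
)
from pkpdsim.pd import HillParams, MOAConfig, PDParams


def make_population(ct, n=0, rng=None, domain=(-400, 400, -400, 400), substrates=()):
    pop = Population([ct], substrates=list(substrates), domain=domain)
    if n:
        rng = rng or np.random.default_rng(0)
        pos = rng.uniform(-300, 300, (n, 2))
        pop.add_cells(pos, ct.name, rng)
    return pop


class TestPhenotypeStep:
    def test_zero_rates_population_unchanged(self, rng):
        ct = CellType("t")
        pop = make_population(ct, 50, rng)
        pop.phenotype_step(6.0, rng)
        assert len(pop) == 50

    def test_division_fraction_matches_binomial(self, rng):
        # expected division probability 1 - exp(-rate * dt)
        rate, dt, n = 0.001, 6.0, 10000
        ct = CellType("t", prolif=rate)
        pop = make_population(ct, n, rng)
        births, _, _ = pop.phenotype_step(dt, rng)
        p = 1.0 - math.exp(-rate * dt)
        se = math.sqrt(n * p * (1 - p))
        assert abs(births - n * p) < 3.0 * se

    def test_death_dominates_when_apoptosis_large(self):
        # strongly pro-apoptotic: population shrinks across seeds
        ct = CellType("t", prolif=0.0001, apop=0.05)
        shrunk = 0
        for seed in range(10):
            rng = np.random.default_rng(seed)
            pop = make_population(ct, 200, rng)
            for _ in range(10):
                pop.phenotype_step(6.0, rng)
            shrunk += len(pop) < 200
        assert shrunk == 10

    def test_daughters_placed_one_radius_apart(self, rng):
        ct = CellType("t", radius=10.0, prolif=10.0)  # every cell divides
        pop = make_population(ct, 1, rng)
        parent = pop.positions[0].copy()
        pop.phenotype_step(1.0, rng)
        assert len(pop) == 2
        d = np.linalg.norm(pop.positions[0] - pop.positions[1])
        assert d == pytest.approx(10.0, rel=1e-9)
        assert np.allclose(pop.positions.mean(axis=0), parent, atol=1e-9)

    def test_amount_kind_damage_split_between_daughters(self, rng):
        ct = CellType(
            "t",
            prolif=10.0,
            pd_params={"s": PDParams(0.0, 0.0, 0.0, dt=1.0, damage_model="AUC_amount")},
        )
        pop = make_population(ct, 1, rng, substrates=["s"])
        pop.A["s"][0] = 4.0
        pop.D["s"][0] = 10.0
        pop.phenotype_step(1.0, rng)
        assert len(pop) == 2
        assert np.allclose(sorted(pop.A["s"]), [2.0, 2.0])
        assert np.allclose(sorted(pop.D["s"]), [5.0, 5.0])

    def test_concentration_kind_damage_inherited(self, rng):
        ct = CellType(
            "t", prolif=10.0, pd_params={"s": PDParams(0.0, 0.0, 0.0, dt=1.0)}
        )
        pop = make_population(ct, 1, rng, substrates=["s"])
        pop.D["s"][0] = 10.0
        pop.phenotype_step(1.0, rng)
        assert np.allclose(pop.D["s"], [10.0, 10.0])


class TestMechanics:
    def test_static_nonoverlapping_cells_do_not_move(self, rng):
        ct = CellType("t", radius=5.0, motility=0.0)
        pop = Population([ct], domain=(-100, 100, -100, 100))
        pop.add_cells(np.array([[0.0, 0.0], [50.0, 0.0]]), "t")
        before = pop.positions.copy()
        pop.mechanics_step(0.1, rng)
        assert np.array_equal(pop.positions, before)

    def test_overlapping_pair_pushed_apart(self, rng):
        ct = CellType("t", radius=10.0)
        pop = Population([ct], domain=(-100, 100, -100, 100))
        pop.add_cells(np.array([[0.0, 0.0], [10.0, 0.0]]), "t")  # 0.5 * sum radii
        d0 = 10.0
        pop.mechanics_step(0.1, rng)
        d1 = np.linalg.norm(pop.positions[1] - pop.positions[0])
        assert d1 > d0

    def test_msd_grows_linearly_at_long_times(self):
        # persistent random walk: MSD(t) ~ 2 * v^2 * tau * t for t >> tau
        ct = CellType("t", motility=1.0, persistence_time=5.0)
        dt, n_steps = 0.5, 4000
        disps = []
        for seed in range(40):
            rng = np.random.default_rng(seed)
            pop = Population([ct], domain=(-1e6, 1e6, -1e6, 1e6))
            pop.add_cells(np.array([[0.0, 0.0]]), "t", rng)
            mid = None
            for i in range(n_steps):
                pop.mechanics_step(dt, rng)
                if i == n_steps // 2 - 1:
                    mid = pop.positions[0].copy()
            disps.append((mid.copy(), pop.positions[0].copy()))
        msd_half = np.mean([np.sum(m**2) for m, _ in disps])
        msd_full = np.mean([np.sum(f**2) for _, f in disps])
        # doubling time doubles MSD in the diffusive regime
        assert msd_full / msd_half == pytest.approx(2.0, rel=0.35)

    def test_positions_stay_inside_domain(self, rng):
        ct = CellType("t", motility=50.0, persistence_time=0.1)
        pop = make_population(ct, 100, rng, domain=(-50, 50, -50, 50))
        pop.positions[:] = rng.uniform(-50, 50, (100, 2))
        for _ in range(100):
            pop.mechanics_step(1.0, rng)
        assert (np.abs(pop.positions) <= 50.0).all()


class TestConfluence:
    def test_empty_population(self):
        ct = CellType("t")
        assert confluence(Population([ct])) == 0.0

    def test_single_cell_area_fraction(self):
        ct = CellType("t", radius=10.0)
        pop = Population([ct], domain=(-400, 400, -400, 400))
        pop.add_cells(np.array([[0.0, 0.0]]), "t")
        assert confluence(pop) == pytest.approx(math.pi * 100.0 / 640000.0, rel=1e-12)

    def test_capped_at_one(self, rng):
        ct = CellType("t", radius=50.0)
        pop = make_population(ct, 500, rng, domain=(-100, 100, -100, 100))
        assert confluence(pop) == 1.0


class TestCurrentRates:
    def test_rates_reset_to_base_when_damage_zero(self, rng):
        ct = CellType(
            "t",
            prolif=0.001,
            moa_configs={"s": MOAConfig({"prolif": HillParams(0.0, 10.0, 2.0)})},
            pd_params={"s": PDParams(0.0, 0.0, 0.0, dt=1.0)},
        )
        pop = make_population(ct, 10, rng, substrates=["s"])
        pop.D["s"][:] = 50.0
        pop.update_current_rates()
        assert (pop.rates["prolif"] < 0.001).all()
        pop.D["s"][:] = 0.0
        pop.update_current_rates()
        assert np.array_equal(pop.rates["prolif"], np.full(10, 0.001))

    def test_update_is_idempotent(self, rng):
        ct = CellType(
            "t",
            prolif=0.001,
            moa_configs={"s": MOAConfig({"prolif": HillParams(0.0, 10.0, 2.0)})},
            pd_params={"s": PDParams(0.0, 0.0, 0.0, dt=1.0)},
        )
        pop = make_population(ct, 5, rng, substrates=["s"])
        pop.D["s"][:] = 20.0
        pop.update_current_rates()
        once = pop.rates["prolif"].copy()
        pop.update_current_rates()
        assert np.array_equal(once, pop.rates["prolif"])


class TestDeterminism:
    def test_identical_seeds_identical_trajectories(self):
        ct = CellType("t", prolif=0.002, apop=0.0005, motility=0.3)
        results = []
        for _ in range(2):
            rng = np.random.default_rng(777)
            pop = make_population(ct, 100, np.random.default_rng(1))
            for _ in range(20):
                pop.mechanics_step(0.5, rng)
                pop.phenotype_step(6.0, rng)
            results.append((pop.positions.copy(), pop.ids.copy()))
        assert np.array_equal(results[0][0], results[1][0])
        assert np.array_equal(results[0][1], results[1][1])


class TestDamageColoring:
    def test_zero_damage_gives_base_color(self):
        assert damage_coloring([0.0, 0.0], [10.0, 10.0]) == (0.8, 0.8, 0.8)

    def test_monotone_along_channel_one(self):
        reds = [damage_coloring([d, 0.0], [10.0, 10.0])[0] for d in (0, 5, 20, 100)]
        greens = [damage_coloring([d, 0.0], [10.0, 10.0])[1] for d in (0, 5, 20, 100)]
        assert reds == sorted(reds)
        assert greens == sorted(greens, reverse=True)

    def test_saturated_corner_color(self):
        rgb = damage_coloring([1e12, 1e12], [1.0, 1.0])
        assert rgb == pytest.approx((0.25, 0.0, 0.25), abs=1e-6)

    def test_more_than_two_substrates_rejected(self):
        with pytest.raises(ValueError):
            damage_coloring([1.0, 1.0, 1.0], [1.0, 1.0, 1.0])
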