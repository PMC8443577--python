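"""Expected growth factors, fraction updates and serial propagation."""

import math

import numpy as np
import pytest
from scipy.stats import multinomial as scipy_multinomial

from dropcoop import (
    GrowthFactors,
    OccupancyModel,
    PopulationState,
    cooperator_advantage,
    expected_growth_factors,
    expected_growth_factors_compartment_centric,
    propagate,
    scenario_preset,
    update_fractions,
)
from dropcoop.founder_stats import enumerate_compositions
from dropcoop.growth_rules import Composition, grow_compartment


def brute_force_growth_factors(fractions, lam, consortium, params, t_max):
    """Independent compartment-centric oracle: E[n_i g_i] / E[n_i].

    Plain-Python loops over all compositions up to t_max, Poisson and
    multinomial weights from math/scipy directly.
    """
    k = len(fractions)
    num = np.zeros(k)
    den = np.zeros(k)
    for t in range(1, t_max + 1):
        pois = math.exp(-lam) * lam**t / math.factorial(t)
        for comp in enumerate_compositions(t, k):
            p = pois * scipy_multinomial.pmf(comp.counts, n=t, p=fractions)
            if p == 0:
                continue
            out = grow_compartment(comp, consortium, params)
            for i in range(k):
                if comp.counts[i] >= 1:
                    num[i] += comp.counts[i] * p * out.growth_factors[i]
                    den[i] += comp.counts[i] * p
    return num / den


class TestExpectedGrowthFactors:
    def test_isolation_limit(self, dependent):
        """As lam -> 0 every cell is alone and nobody grows."""
        consortium, params = dependent
        state = PopulationState(np.array([0.4, 0.4, 0.2]))
        gf = expected_growth_factors(
            state, OccupancyModel(lam=1e-6), consortium, params
        )
        np.testing.assert_allclose(gf.per_type, 1.0, atol=1e-3)

    def test_cooperator_symmetry(self, dependent):
        consortium, params = dependent
        state = PopulationState(np.array([0.5, 0.5, 0.0]))
        gf = expected_growth_factors(
            state, OccupancyModel(lam=0.7), consortium, params
        )
        assert gf.per_type[0] == pytest.approx(gf.per_type[1], rel=1e-12)

    @pytest.mark.parametrize("lam", [0.15, 2.0])
    @pytest.mark.parametrize(
        "scenario", ["dependent", "costless_background", "costly_background"]
    )
    def test_against_bruteforce_oracle(self, lam, scenario):
        consortium, params = scenario_preset(scenario)
        f = np.array([0.5, 0.25, 0.25])
        state = PopulationState(f)
        occ = OccupancyModel(lam=lam)
        gf = expected_growth_factors(state, occ, consortium, params)
        oracle = brute_force_growth_factors(f, lam, consortium, params, occ.n_max + 1)
        np.testing.assert_allclose(gf.per_type, oracle, atol=1e-10)

    @pytest.mark.parametrize("lam", [0.15, 1.0, 2.0, 7.0])
    @pytest.mark.parametrize(
        "scenario", ["dependent", "costless_background", "costly_background"]
    )
    def test_dual_route_equivalence(self, lam, scenario):
        """Cell-centric and compartment-centric routes agree to < 1e-10."""
        consortium, params = scenario_preset(scenario)
        state = PopulationState(np.array([0.5, 0.25, 0.25]))
        occ = OccupancyModel(lam=lam)
        g1 = expected_growth_factors(state, occ, consortium, params).per_type
        g2 = expected_growth_factors_compartment_centric(
            state, occ, consortium, params
        ).per_type
        assert np.max(np.abs(g1 - g2)) < 1e-10

    def test_zero_fraction_type_gets_hypothetical_factor(self, dependent):
        """An absent cheater still gets its invasion growth factor."""
        consortium, params = dependent
        state = PopulationState(np.array([0.5, 0.5, 0.0]))
        gf = expected_growth_factors(
            state, OccupancyModel(lam=2.0), consortium, params
        )
        assert np.isfinite(gf.per_type[2])
        assert gf.per_type[2] > 1.0  # invading cheater meets pairs at lam=2

    def test_all_zero_fractions_rejected(self, dependent):
        consortium, params = dependent
        with pytest.raises(ValueError):
            PopulationState(np.array([0.0, 0.0, 0.0]))


class TestUpdateFractions:
    def test_neutral_growth(self):
        state = PopulationState(np.array([0.2, 0.3, 0.5]))
        gf = GrowthFactors(per_type=np.array([5.0, 5.0, 5.0]), cooperator_advantage=0.0)
        new = update_fractions(state, gf)
        np.testing.assert_allclose(new.fractions, state.fractions)
        assert new.propagation_index == 1

    def test_direct_arithmetic(self):
        state = PopulationState(np.array([0.5, 0.5, 0.0]))
        gf = GrowthFactors(per_type=np.array([3.0, 1.0, 9.9]), cooperator_advantage=0.0)
        new = update_fractions(state, gf)
        np.testing.assert_allclose(new.fractions, [0.75, 0.25, 0.0])

    def test_absent_type_stays_absent(self):
        state = PopulationState(np.array([0.5, 0.5, 0.0]))
        gf = GrowthFactors(
            per_type=np.array([1.0, 1.0, 1e6]), cooperator_advantage=0.0
        )
        assert update_fractions(state, gf).fractions[2] == 0.0

    def test_extinction_error(self):
        state = PopulationState(np.array([1.0, 0.0, 0.0]))
        gf = GrowthFactors(per_type=np.array([0.0, 1.0, 1.0]), cooperator_advantage=0.0)
        with pytest.raises(ValueError):
            update_fractions(state, gf)

    def test_fractions_sum_to_one_many_rounds(self, costly):
        consortium, params = costly
        traj = propagate(
            PopulationState(np.array([0.3, 0.3, 0.4])),
            12,
            OccupancyModel(lam=0.5),
            consortium,
            params,
        )
        for s in traj.states:
            assert abs(s.fractions.sum() - 1.0) < 1e-12


class TestPropagate:
    def test_zero_rounds(self, dependent):
        consortium, params = dependent
        state = PopulationState(np.array([0.4, 0.4, 0.2]))
        traj = propagate(state, 0, OccupancyModel(lam=0.15), consortium, params)
        assert len(traj.states) == 1
        np.testing.assert_array_equal(traj.states[0].fractions, state.fractions)

    def test_dependent_cheater_declines(self, dependent):
        """Dependent scenario at lam=0.15: cheater strictly shrinks each round."""
        consortium, params = dependent
        for start in [(1 / 3, 1 / 3, 1 / 3), (0.25, 0.25, 0.5), (0.05, 0.05, 0.9)]:
            traj = propagate(
                PopulationState(np.array(start)),
                3,
                OccupancyModel(lam=0.15),
                consortium,
                params,
            )
            cheater = traj.fractions_matrix()[:, 2]
            assert np.all(np.diff(cheater) < 0)

    def test_costly_background_cheater_wins(self, costly):
        """Costly background at lam=0.15: cheater strictly grows each round."""
        consortium, params = costly
        traj = propagate(
            PopulationState(np.array([0.45, 0.45, 0.1])),
            3,
            OccupancyModel(lam=0.15),
            consortium,
            params,
        )
        cheater = traj.fractions_matrix()[:, 2]
        assert np.all(np.diff(cheater) > 0)

    def test_label_symmetry(self, dependent):
        """Swapping the two (symmetric) cooperators permutes the trajectory."""
        consortium, params = dependent
        occ = OccupancyModel(lam=0.5)
        t1 = propagate(
            PopulationState(np.array([0.6, 0.1, 0.3])), 4, occ, consortium, params
        )
        t2 = propagate(
            PopulationState(np.array([0.1, 0.6, 0.3])), 4, occ, consortium, params
        )
        np.testing.assert_allclose(
            t1.fractions_matrix()[:, [1, 0, 2]], t2.fractions_matrix(), atol=1e-14
        )

    def test_to_frame_layout(self, dependent):
        consortium, params = dependent
        traj = propagate(
            PopulationState(np.array([0.4, 0.4, 0.2])),
            2,
            OccupancyModel(lam=0.15),
            consortium,
            params,
        )
        df = traj.to_frame()
        assert list(df["round"]) == [0, 1, 2]
        assert {"fraction_cheater", "G_cooperator_A", "cooperator_advantage"} <= set(
            df.columns
        )
        assert np.isnan(df["G_cheater"].iloc[-1])


class TestCooperatorAdvantage:
    def test_equal_factors(self, dependent):
        consortium, _ = dependent
        assert cooperator_advantage(np.array([5.0, 5.0, 5.0]), consortium) == 0.0

    def test_single_pair_example(self, dependent):
        consortium, _ = dependent
        assert cooperator_advantage(np.array([375.0, 375.0, 1.0]), consortium) == 374.0

    def test_requires_one_cheater(self):
        from dropcoop.growth_rules import (
            CellTypeSpec,
            ConsortiumSpec,
            ROLE_COOPERATOR_A,
            ROLE_COOPERATOR_B,
        )

        consortium = ConsortiumSpec(
            types=(
                CellTypeSpec("a", ROLE_COOPERATOR_A, 0.0),
                CellTypeSpec("b", ROLE_COOPERATOR_B, 0.0),
            )
        )
        with pytest.raises(ValueError):
            cooperator_advantage(np.array([1.0, 1.0]), consortium)

    def test_three_regime_shape_costly_background(self, costly):
        """Advantage vs lam: negative at tiny lam, peaks at intermediate lam,
        and shrinks in magnitude again at large lam."""
        consortium, params = costly
        state = PopulationState(np.array([1 / 3, 1 / 3, 1 / 3]))
        grid = np.geomspace(0.05, 10.0, 25)
        adv = np.array(
            [
                expected_growth_factors(
                    state, OccupancyModel(lam=lam), consortium, params
                ).cooperator_advantage
                for lam in grid
            ]
        )
        assert adv[0] <= 0
        peak = grid[np.argmax(adv)]
        assert 0.5 <= peak <= 4.0
        assert abs(adv[-1]) < abs(adv[0])  # decays toward 0 relative to lam -> 0
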