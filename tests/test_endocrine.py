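"""HPG-HPA loop: vector field, equilibria, attractors, basin mapping."""

import numpy as np
import pytest

from fmloop import (
    EndocrineParams,
    EndocrineState,
    basin_map,
    endocrine_rhs,
    find_equilibria_endocrine,
    simulate_endocrine,
)
from fmloop.errors import DomainError, ParameterError


def hand_rhs(hpa, hpg, e_x=28.0, h_x=4.2, e_k=25.57, h_k=6.6, alpha=0.48, tau=30.0):
    """Independent direct-arithmetic evaluation of the loop equations."""

    def f(x):
        return 100.0 / (1.0 + (x / e_x) ** h_x)

    def k(x):
        return 1.0 + 4.0 / (1.0 + (alpha * x / e_k) ** h_k)

    return np.array([(f(hpg) - k(hpa) * hpa) / tau, (f(hpa) - k(hpg) * hpg) / tau])


@pytest.fixture(scope="module")
def equilibria(endocrine_defaults):
    return find_equilibria_endocrine(endocrine_defaults)


class TestVectorField:
    def test_origin_drive(self, endocrine_defaults):
        d = endocrine_rhs(EndocrineState(0, 0), endocrine_defaults)
        np.testing.assert_allclose(d, [100 / 30, 100 / 30])

    def test_exchange_symmetry(self, endocrine_defaults):
        d = endocrine_rhs(EndocrineState(37.0, 12.0), endocrine_defaults)
        d_swapped = endocrine_rhs(EndocrineState(12.0, 37.0), endocrine_defaults)
        np.testing.assert_allclose(d, d_swapped[::-1], atol=1e-14)

    def test_matches_hand_evaluation(self, endocrine_defaults):
        got = endocrine_rhs(EndocrineState(50, 50), endocrine_defaults)
        np.testing.assert_allclose(got, hand_rhs(50, 50), atol=1e-12)

    def test_negative_state_rejected(self):
        with pytest.raises(DomainError):
            EndocrineState(-1.0, 5.0)

    def test_alpha_range_enforced(self):
        with pytest.raises(ParameterError):
            EndocrineParams(alpha=1.3)


class TestEquilibria:
    def test_exactly_three_stable(self, equilibria):
        assert sum(e.is_stable for e in equilibria) == 3

    def test_closed_under_exchange(self, equilibria):
        states = [np.array(e.state) for e in equilibria]
        for s in states:
            assert any(np.allclose(s[::-1], t, atol=1e-6) for t in states)

    def test_qualitative_positions(self, equilibria):
        stable = [e.state for e in equilibria if e.is_stable]
        sym = [s for s in stable if abs(s[0] - s[1]) < 1e-6]
        asym = [s for s in stable if abs(s[0] - s[1]) >= 1e-6]
        assert len(sym) == 1 and len(asym) == 2
        assert 10.0 < sym[0][0] < 20.0
        for s in asym:
            assert max(s) > 80.0 and min(s) < 5.0

    def test_residuals_below_tolerance(self, equilibria):
        assert all(e.residual < 1e-8 for e in equilibria)

    def test_counts_stable_under_grid_refinement(self, endocrine_defaults, equilibria):
        refined = find_equilibria_endocrine(
            endocrine_defaults, grid_points=50, diag_points=4001
        )
        by_stab = lambda eqs: sorted(e.stability for e in eqs)
        assert by_stab(refined) == by_stab(equilibria)


class TestAttractors:
    def test_equilibrium_stays_put(self, endocrine_defaults, equilibria):
        eq = next(e for e in equilibria if e.is_stable)
        traj, label = simulate_endocrine(
            EndocrineState(*eq.state), endocrine_defaults, horizon=500.0,
            equilibria=equilibria,
        )
        np.testing.assert_allclose(traj.final_state, eq.state, atol=1e-5)

    @pytest.mark.parametrize(
        "initial, corner",
        [
            ((90.0, 5.0), "high_hpa"),   # stress + withdrawal basin
            ((5.0, 90.0), "high_hpg"),
            ((95.0, 95.0), "low_low"),   # mutual inhibition collapses both
            ((10.0, 10.0), "low_low"),
        ],
    )
    def test_corner_initial_conditions(self, endocrine_defaults, equilibria, initial, corner):
        traj, label = simulate_endocrine(
            EndocrineState(*initial), endocrine_defaults, horizon=3000.0,
            equilibria=equilibria,
        )
        assert label is not None
        hpa, hpg = [e for e in equilibria if e.is_stable][label].state
        if corner == "high_hpa":
            assert hpa > 80.0 and hpg < 5.0
        elif corner == "high_hpg":
            assert hpg > 80.0 and hpa < 5.0
        else:
            assert abs(hpa - hpg) < 1e-6 and hpa < 20.0

    def test_trapping_region(self, endocrine_defaults):
        # f <= 100 and k >= 1 bound activities near 100 from above
        traj, _ = simulate_endocrine(
            EndocrineState(100.0, 100.0), endocrine_defaults, horizon=1000.0
        )
        assert traj.states.max() <= 100.0 + 1e-6


@pytest.fixture(scope="module")
def coarse_map(endocrine_defaults):
    return basin_map(endocrine_defaults, resolution=15, horizon=8000.0)


class TestBasins:
    def test_low_low_basin_is_largest(self, coarse_map):
        sym_idx = next(
            i
            for i, e in enumerate(coarse_map.stable_equilibria)
            if abs(e.state[0] - e.state[1]) < 1e-6
        )
        assert coarse_map.fractions[sym_idx] == max(coarse_map.fractions.values())

    def test_symmetric_under_exchange_with_swapped_labels(self, coarse_map):
        labels = coarse_map.labels
        stable = [np.array(e.state) for e in coarse_map.stable_equilibria]
        # map each stable index to the index of its mirror state
        mirror = {}
        for i, s in enumerate(stable):
            j = next(
                k for k, t in enumerate(stable) if np.allclose(s[::-1], t, atol=1e-6)
            )
            mirror[i] = j
        for i in range(labels.shape[0]):
            for j in range(labels.shape[1]):
                a, b = labels[i, j], labels[j, i]
                if a >= 0 and b >= 0:
                    assert mirror[a] == b

    def test_labels_verified_by_resimulation(self, coarse_map, endocrine_defaults, rng):
        idx = rng.choice(coarse_map.labels.size, size=5, replace=False)
        stable = coarse_map.stable_equilibria
        n = len(coarse_map.hpg_grid)
        for flat in idx:
            i, j = divmod(int(flat), n)
            lab = coarse_map.labels[i, j]
            if lab < 0:
                continue
            traj, relab = simulate_endocrine(
                EndocrineState(coarse_map.hpa_grid[i], coarse_map.hpg_grid[j]),
                endocrine_defaults,
                horizon=8000.0,
                equilibria=stable,
            )
            assert relab == lab

    def test_unresolved_fraction_negligible(self, coarse_map):
        assert coarse_map.unresolved_fraction <= 0.05
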