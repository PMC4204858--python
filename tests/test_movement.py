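import numpy as np
import pytest
from scipy import stats

from cortexsim import ModelParams, apply_genotype
from cortexsim.engine import init_state
from cortexsim.movement import (attempt_move_cp, attempt_move_iz, draw_direction,
                                direction_probabilities, effective_bias)
from cortexsim.params import ConfigurationError
from cortexsim.toys import walker_cp, iz_queue_world
from cortexsim import _kernels as K

WT = apply_genotype(ModelParams()).profile
REELER = apply_genotype(ModelParams(genotype="reeler")).profile


class TestEffectiveBias:
    @pytest.mark.parametrize("rule,dist,expected", [
        ("a", 1, 0.0), ("a", 99, 0.0),
        ("b", 1, +0.6), ("b", 99, +0.6),
        ("c", 10, +0.6), ("c", 11, 0.0),
        ("d", 10, -0.6), ("d", 11, 0.0),
    ])
    def test_wild_type_bias_table(self, rule, dist, expected):
        assert effective_bias(rule, WT, dist, rho_cp=0.6,
                              sensing_distance=10) == expected

    @pytest.mark.parametrize("rule", ["b", "c", "d"])
    def test_reeler_removes_chemotaxis_everywhere(self, rule):
        for dist in range(1, 60):
            assert effective_bias(rule, REELER, dist, rho_cp=0.6,
                                  sensing_distance=10) == 0.0

    def test_unknown_rule_is_a_configuration_error(self):
        with pytest.raises(ConfigurationError, match="rule"):
            effective_bias("e", WT, 1, rho_cp=0.5, sensing_distance=10)


class TestDrawDirection:
    @pytest.mark.parametrize("bias,p_vertical", [
        (0.0, 0.9), (0.5, 0.9), (-0.7, 0.8), (1.0, 0.95), (-1.0, 0.6), (0.3, 1.0),
    ])
    def test_law_is_normalized_and_nonnegative(self, bias, p_vertical):
        probs = direction_probabilities(bias, p_vertical)
        assert all(v >= 0 for v in probs.values())
        assert sum(probs.values()) == pytest.approx(1.0, abs=1e-12)

    def test_full_bias_never_moves_down(self):
        rng = np.random.default_rng(0)
        draws = {draw_direction(1.0, 0.9, rng) for _ in range(2000)}
        assert "down" not in draws

    def test_empirical_frequencies_match_multinomial_law(self):
        # chi-square against the exact law at bias=0.5, p_vertical=0.9
        rng = np.random.default_rng(42)
        n = 100_000
        counts = {"up": 0, "down": 0, "left": 0, "right": 0}
        for _ in range(n):
            counts[draw_direction(0.5, 0.9, rng)] += 1
        expected = direction_probabilities(0.5, 0.9)
        assert expected == pytest.approx(
            {"up": 0.675, "down": 0.225, "left": 0.05, "right": 0.05})
        chi2 = stats.chisquare([counts[d] for d in expected],
                               [expected[d] * n for d in expected])
        assert chi2.pvalue > 1e-4


class TestIzMoves:
    def test_down_from_germinal_boundary_aborts(self, small_state):
        from cortexsim.engine import fill_iz_bottom_row
        fill_iz_bottom_row(small_state)
        aid = int(small_state.iz[0, 0])
        attempt_move_iz(small_state, aid, "down")
        assert small_state.arow[aid] == 0

    def test_move_onto_occupied_site_aborts(self, small_state):
        from cortexsim.engine import fill_iz_bottom_row
        fill_iz_bottom_row(small_state)
        aid = int(small_state.iz[0, 0])
        other = int(small_state.iz[0, 1])
        attempt_move_iz(small_state, aid, "right")
        assert small_state.acol[aid] == 0
        assert small_state.acol[other] == 1

    def test_lateral_off_lattice_aborts(self, small_state):
        from cortexsim.engine import fill_iz_bottom_row
        fill_iz_bottom_row(small_state)
        aid = int(small_state.iz[0, 0])
        attempt_move_iz(small_state, aid, "left")
        assert small_state.acol[aid] == 0

    def test_up_from_top_row_exits_to_queue(self):
        s = iz_queue_world(seed=0)
        aid = int(s.iz[s.params.iz_height - 1, 0])
        attempt_move_iz(s, aid, "up")
        assert s.comp[aid] == K.COMP_QUEUE
        assert s.queue_ids.tolist() == [aid]
        assert s.arow[aid] == -1

    def test_interior_up_is_an_ordinary_move(self):
        s = iz_queue_world(seed=0)
        top = s.params.iz_height - 1
        aid = int(s.iz[top - 1, 0])
        s.iz[top, 0] = -1  # clear the site above
        attempt_move_iz(s, aid, "up")
        assert s.arow[aid] == top
        assert s.queue_length == 0


class TestCpMoves:
    def test_swap_exchanges_exactly_two_agents(self):
        s = walker_cp(seed=0)
        aid = int(np.flatnonzero(s.active == 1)[0])
        r, c = int(s.arow[aid]), int(s.acol[aid])
        other = int(s.cp[r - 1, c])
        before = sorted(s.cp.ravel().tolist())
        attempt_move_cp(s, aid, "up")
        assert s.cp[r - 1, c] == aid
        assert s.cp[r, c] == other
        assert (s.arow[other], s.acol[other]) == (r, c)
        assert sorted(s.cp.ravel().tolist()) == before  # multiset preserved

    @pytest.mark.parametrize("direction", ["up", "down", "left", "right"])
    def test_boundary_moves_abort(self, direction):
        s = walker_cp(seed=0)
        aid = int(np.flatnonzero(s.active == 1)[0])
        # park the walker in the corner that makes the move illegal
        target = {"up": (0, 0), "down": (s.cp_height - 1, 0),
                  "left": (2, 0), "right": (2, s.params.width - 1)}[direction]
        r0, c0 = int(s.arow[aid]), int(s.acol[aid])
        other = int(s.cp[target])
        s.cp[r0, c0], s.cp[target] = other, aid
        s.arow[aid], s.acol[aid] = target
        s.arow[other], s.acol[other] = r0, c0
        attempt_move_cp(s, aid, direction)
        assert (s.arow[aid], s.acol[aid]) == target

    def test_passive_agents_cannot_initiate(self):
        s = walker_cp(seed=0)
        passive = int(np.flatnonzero(s.active == 0)[0])
        with pytest.raises(ValueError, match="passive"):
            attempt_move_cp(s, passive, "up")


class TestSingleWalkerOracle:
    """One active agent in a passive CP under rule (b) is a biased walk."""

    def test_mean_displacement_matches_biased_walk(self):
        # tall periodic-free world, walker far from both boundaries
        size = 41
        bias, p_vertical = 0.3, 0.9
        s = walker_cp(seed=5, size=size, rho_cp=bias, p_vertical=p_vertical,
                      movement_rule="b", sensing_distance=size)
        aid = int(np.flatnonzero(s.active == 1)[0])
        rng = np.random.default_rng(11)
        n_steps = 10_000
        total_dh = 0.0
        for _ in range(n_steps):
            r0 = int(s.arow[aid])
            d = draw_direction(bias, p_vertical, rng)
            attempt_move_cp(s, aid, d)
            total_dh += r0 - int(s.arow[aid])  # + means toward Layer 1
            if s.arow[aid] < 5 or s.arow[aid] > size - 5:
                # re-center to keep the walk boundary-free
                self._teleport(s, aid, size // 2)
        expected = p_vertical * bias  # per-attempt mean displacement
        se = np.sqrt(p_vertical * (1 - (p_vertical * bias) ** 2) / n_steps)
        assert abs(total_dh / n_steps - expected) < 4 * se

    @staticmethod
    def _teleport(s, aid, new_row):
        r, c = int(s.arow[aid]), int(s.acol[aid])
        other = int(s.cp[new_row, c])
        s.cp[new_row, c], s.cp[r, c] = aid, other
        s.arow[aid], s.arow[other] = new_row, r

    def test_below_sensing_band_rules_c_d_match_rule_a(self):
        # vertical-displacement samples far below the band are exchangeable
        # with unbiased ones: two-sample KS on single-attempt displacements
        size = 61
        rng = np.random.default_rng(3)
        samples = {}
        for rule in ["a", "c", "d"]:
            s = walker_cp(seed=9, size=size, rho_cp=0.8, movement_rule=rule,
                          sensing_distance=5)
            aid = int(np.flatnonzero(s.active == 1)[0])
            self._teleport(s, aid, 40)  # well below the 5-row band
            disp = []
            for _ in range(4000):
                r0 = int(s.arow[aid])
                prof = apply_genotype(s.params).profile
                b = effective_bias(rule, prof, r0 + 1, rho_cp=0.8, sensing_distance=5)
                d = draw_direction(b, s.params.p_vertical, rng)
                attempt_move_cp(s, aid, d)
                disp.append(r0 - int(s.arow[aid]))
                if s.arow[aid] < 20 or s.arow[aid] > size - 5:
                    self._teleport(s, aid, 40)
            samples[rule] = np.array(disp)
        for rule in ["c", "d"]:
            ks = stats.ks_2samp(samples["a"], samples[rule])
            assert ks.pvalue > 1e-3
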