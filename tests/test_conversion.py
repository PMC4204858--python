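import numpy as np
import pytest

from cortexsim import ModelParams
from cortexsim.conversion import offer_conversion, sense_neighborhood
from cortexsim.engine import run
from cortexsim.toys import all_active_cp, walker_cp
from cortexsim import _kernels as K


class TestSenseNeighborhood:
    def test_all_active_neighbors_interior(self):
        s = all_active_cp(size=4)
        aid = int(s.cp[2, 2])
        rep = sense_neighborhood(s, aid)
        assert rep.n_passive_neighbors == 0
        assert rep.adjacent_to_layer1 is False

    def test_row1_agent_is_layer1_adjacent(self):
        s = all_active_cp(size=4)
        aid = int(s.cp[0, 1])
        rep = sense_neighborhood(s, aid)
        assert rep.adjacent_to_layer1 is True
        assert rep.n_passive_neighbors == 0

    def test_exact_count_with_one_passive_diagonal(self):
        s = all_active_cp(size=4)
        s.active[int(s.cp[3, 3])] = 0  # diagonal neighbor of (2,2)
        rep = sense_neighborhood(s, int(s.cp[2, 2]))
        assert rep.n_passive_neighbors == 1

    def test_walker_sees_full_passive_moore_neighborhood(self):
        s = walker_cp(size=5)
        aid = int(np.flatnonzero(s.active == 1)[0])
        rep = sense_neighborhood(s, aid)
        assert rep.n_passive_neighbors == 8

    def test_lattice_edges_contribute_nothing(self):
        s = walker_cp(size=5)
        # move the walker into the bottom-left corner: 3 valid neighbors
        aid = int(np.flatnonzero(s.active == 1)[0])
        corner = int(s.cp[4, 0])
        r, c = int(s.arow[aid]), int(s.acol[aid])
        s.cp[4, 0], s.cp[r, c] = aid, corner
        s.arow[aid], s.acol[aid], s.arow[corner], s.acol[corner] = 4, 0, r, c
        assert sense_neighborhood(s, aid).n_passive_neighbors == 3


class TestOfferConversion:
    def test_rule_i_is_unconditional_bernoulli(self):
        s = all_active_cp(size=4, conversion_rule="i", p_convert=1.0)
        assert offer_conversion(s, int(s.cp[2, 2])) is True

    def test_rule_i_zero_probability_never_converts(self):
        s = all_active_cp(size=4, conversion_rule="i", p_convert=0.0)
        for _ in range(50):
            assert offer_conversion(s, int(s.cp[2, 2])) is False

    def test_rule_ii_blocked_without_passive_contact(self):
        # interior agents of an all-active block have conversion probability 0
        s = all_active_cp(size=4, conversion_rule="ii", p_convert=1.0)
        for aid in [int(s.cp[r, c]) for r in (1, 2, 3) for c in range(4)]:
            assert offer_conversion(s, aid) is False

    def test_rule_ii_layer1_sensing_nucleates_top_row(self):
        s = all_active_cp(size=4, conversion_rule="ii", p_convert=1.0)
        aid = int(s.cp[0, 2])
        assert offer_conversion(s, aid) is True
        assert s.active[aid] == 0

    def test_rule_ii_conversion_is_immediately_visible(self):
        s = all_active_cp(size=4, conversion_rule="ii", p_convert=1.0)
        offer_conversion(s, int(s.cp[0, 1]))      # converts via Layer-1 contact
        below = int(s.cp[1, 1])                   # now senses a passive neighbor
        assert offer_conversion(s, below) is True

    def test_rule_iii_deterministic_at_layer1_only(self):
        s = all_active_cp(size=4, conversion_rule="iii", p_convert=0.0)
        assert offer_conversion(s, int(s.cp[1, 1])) is False
        assert offer_conversion(s, int(s.cp[0, 0])) is True

    def test_rule_iii_inert_without_stop_signal(self):
        # reeler cannot receive the Layer-1 stop signal
        s = all_active_cp(size=4, conversion_rule="iii", genotype="reeler")
        for _ in range(20):
            assert offer_conversion(s, int(s.cp[0, 0])) is False

    def test_rule_iv_is_stop_then_local(self):
        s = all_active_cp(size=4, conversion_rule="iv", p_convert=0.0)
        assert offer_conversion(s, int(s.cp[0, 3])) is True   # stop component
        assert offer_conversion(s, int(s.cp[2, 2])) is False  # local, p=0

    def test_passive_agent_cannot_be_offered(self):
        s = walker_cp(size=5)
        passive = int(np.flatnonzero(s.active == 0)[0])
        with pytest.raises(ValueError, match="passive"):
            offer_conversion(s, passive)


def test_rule_i_active_count_monotone_under_conversion_phase():
    """Across full steps of a running world the active CP count never rises
    through the conversion phase (agents only leave the active pool)."""
    p = ModelParams(width=8, iz_height=10, batch_size=24, n_batches=2,
                    conversion_rule="i", p_convert=0.2, max_steps=5000, seed=2)
    from cortexsim.engine import init_state, step
    s = init_state(p)
    prev_passive = 0
    for _ in range(200):
        if s.status != "running":
            break
        step(s)
        n_passive = int((s.active[: s.n_introduced] == 0).sum())
        assert n_passive >= prev_passive
        prev_passive = n_passive


def test_rule_i_expected_conversions_match_binomial_oracle():
    """One conversion phase on a 3x3 all-active toy: the number of conversions
    is distributed as the brute-force enumeration over draw sequences
    predicts.  With p_convert=1 every distinct drawn agent converts, so the
    count equals the number of distinct draws; its mean over many phases
    matches E[# distinct in 9 draws of 9] = 9 (1 - (8/9)^9)."""
    n_runs = 400
    totals = 0
    for seed in range(n_runs):
        s = all_active_cp(seed=seed, size=3, conversion_rule="i", p_convert=1.0)
        K.conversion_phase(s.cp, s.batch, s.active, s.comp, s.arow, s.acol,
                           s.meta, s.ip, s.fp, s.roster, s.rng)
        totals += int((s.active == 0).sum())
    expected = 9 * (1 - (8 / 9) ** 9)  # 6.18...
    se = 1.0 / np.sqrt(n_runs)  # generous: per-phase sd is < 1 conversion
    assert abs(totals / n_runs - expected) < 5 * se
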