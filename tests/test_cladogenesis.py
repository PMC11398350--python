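"""Cladogenetic event enumeration and the probability tensor."""

from itertools import combinations

import numpy as np
import pytest

import biomeshift as bs
from biomeshift.cladogenesis import CladoParams, count_outcomes, enumerate_clado_events

PARAMS = CladoParams(pe=0.5, ps=0.3, pb=0.2)


def brute_force_outcomes(parent_codes):
    """Independent enumeration of all (left, right) daughter outcomes.

    Walks scenario x (which daughter / subset / ordered partition) x
    reduction mode explicitly and builds daughter code vectors from
    scratch.  Returns a list of (scenario, left, right) triples.
    """
    est = [b for b, c in enumerate(parent_codes) if c == 2]

    def reduce_codes(keep, mode):
        out = list(parent_codes)
        for b in est:
            if b not in keep:
                out[b] = mode
        return tuple(out)

    if len(est) == 1:
        return [("equal", tuple(parent_codes), tuple(parent_codes))]
    outcomes = [("equal", tuple(parent_codes), tuple(parent_codes))]
    proper = [
        set(c)
        for r in range(1, len(est))
        for c in combinations(est, r)
    ]
    for sub in proper:
        for mode in (1, 0):
            part = reduce_codes(sub, mode)
            outcomes.append(("subset", tuple(parent_codes), part))
            outcomes.append(("subset", part, tuple(parent_codes)))
            outcomes.append(
                ("split", part, reduce_codes(set(est) - sub, mode))
            )
    return outcomes


class TestCounts:
    @pytest.mark.parametrize("n_est", [1, 2, 3, 4])
    def test_closed_forms_match_brute_force(self, n_est):
        codes = tuple([2] * n_est)
        outcomes = brute_force_outcomes(codes)
        by_scen = {"equal": 0, "subset": 0, "split": 0}
        for scen, _, _ in outcomes:
            by_scen[scen] += 1
        c = count_outcomes(n_est)
        assert by_scen["equal"] == c.n_e == 1
        assert by_scen["subset"] == c.n_s
        assert by_scen["split"] == c.n_b

    def test_closed_form_values(self):
        assert (count_outcomes(2).n_s, count_outcomes(2).n_b) == (8, 4)
        assert (count_outcomes(3).n_s, count_outcomes(3).n_b) == (24, 12)
        c1 = count_outcomes(1)
        assert (c1.n_s, c1.n_b) == (0, 0)

    def test_invalid_rejected(self):
        with pytest.raises(ValueError):
            count_outcomes(0)


class TestEnumerateEvents:
    def test_single_established_identical(self, space2):
        """Parent Hc passes its state to both daughters with probability 1
        regardless of the scenario probabilities."""
        parent = space2.states[space2.index("21")]
        events = enumerate_clado_events(parent, PARAMS)
        assert len(events) == 1
        ev = events[0]
        assert ev.left == ev.right == parent
        assert ev.probability == 1.0

    def test_two_established_full_repertoire(self, space2):
        """Parent HC: 13 events — equal at pe, 8 subset at ps/8, 4 split at
        pb/4, matching the worked two-biome tensor slice."""
        parent = space2.states[space2.index("22")]
        events = enumerate_clado_events(parent, PARAMS)
        assert len(events) == 13
        pairs = {
            (e.left.digits(), e.right.digits()): e.probability for e in events
        }
        ws, wb = PARAMS.ps / 8, PARAMS.pb / 4
        assert pairs[("22", "22")] == pytest.approx(PARAMS.pe)
        for sub in ("20", "21", "02", "12"):
            assert pairs[("22", sub)] == pytest.approx(ws)
            assert pairs[(sub, "22")] == pytest.approx(ws)
        for a, b in (("20", "02"), ("02", "20"), ("21", "12"), ("12", "21")):
            assert pairs[(a, b)] == pytest.approx(wb)

    def test_enabled_biomes_pass_to_both_daughters(self, space3):
        """Split of TWc established biomes keeps the enabled c in both."""
        parent = space3.states[space3.index("221")]
        events = enumerate_clado_events(parent, PARAMS)
        split_nonaff = {
            (e.left.digits(), e.right.digits())
            for e in events
            if e.scenario == "split" and e.reduction == "to_non_affinity"
        }
        assert ("201", "021") in split_nonaff
        for e in events:
            assert e.left.codes[2] == 1 and e.right.codes[2] == 1

    @pytest.mark.parametrize("digits", ["22", "221", "222", "2222"])
    def test_matches_brute_force_oracle(self, digits):
        parent = bs.AffinityState(tuple(int(c) for c in digits))
        events = enumerate_clado_events(parent, PARAMS)
        got = sorted(
            (e.scenario, e.left.codes, e.right.codes) for e in events
        )
        expected = sorted(brute_force_outcomes(parent.codes))
        assert got == expected


class TestTensor:
    @pytest.mark.parametrize("n_biomes", range(1, 5))
    def test_normalization_and_symmetry(self, n_biomes):
        space = bs.enumerate_states(n_biomes)
        tensor = bs.build_clado_tensor(space, PARAMS)
        dense = tensor.dense()
        sums = dense.sum(axis=(1, 2))
        assert np.allclose(sums, 1.0, atol=1e-12)
        assert np.allclose(dense, dense.transpose(0, 2, 1), atol=1e-15)

    def test_daughters_stay_in_space(self, space3):
        tensor = bs.build_clado_tensor(space3, PARAMS)
        assert tensor.left_idx.min() >= 0
        assert tensor.left_idx.max() < space3.n_states
        assert tensor.right_idx.max() < space3.n_states

    def test_worked_two_biome_entries(self, space2):
        tensor = bs.build_clado_tensor(space2, PARAMS)
        hc, h, c = space2.index("22"), space2.index("20"), space2.index("02")
        assert tensor.prob(hc, h, c) == pytest.approx(PARAMS.pb / 4)
        assert tensor.prob(hc, hc, hc) == pytest.approx(PARAMS.pe)

    def test_pure_equal_inheritance_is_identity(self, space3):
        tensor = bs.build_clado_tensor(space3, CladoParams(1.0, 0.0, 0.0))
        dense = tensor.dense()
        for i in range(space3.n_states):
            expected = np.zeros((space3.n_states, space3.n_states))
            expected[i, i] = 1.0
            assert np.allclose(dense[i], expected)

    def test_simplex_violation_rejected(self):
        with pytest.raises(ValueError):
            CladoParams(0.5, 0.5, 0.5)
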