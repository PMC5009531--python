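"""Context counting, mean-force potentials and SCRS scores."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from flexc.chains import PSSM_ALPHABET, STATES3, LabeledChain
from flexc.potentials import (
    ContextCounts,
    EmptyCorpusError,
    MissingStateError,
    PotentialTable,
    combined_pseudo_potential,
    count_contexts,
    derive_potentials,
    offset_pairs,
    scrs_scores,
    window_offsets,
)
from flexc.synthetic import make_tilted_corpus

from _oracles import brute_force_counts

A = {a: i for i, a in enumerate(PSSM_ALPHABET)}
S = {s: i for i, s in enumerate(STATES3)}


def _labeled(seq, states, chain_id="A"):
    return LabeledChain(
        chain_id=chain_id,
        sequence=seq,
        positions=list(range(1, len(seq) + 1)),
        b_norm=np.zeros(len(seq)),
        states=list(states),
    )


class TestCountContexts:
    def test_three_residue_chain_by_hand(self):
        counts = count_contexts([_labeled("ACD", "RIF")])
        assert counts.singlet[S["R"], A["A"]] == 1
        assert counts.singlet[S["I"], A["C"]] == 1
        assert counts.singlet[S["F"], A["D"]] == 1
        assert counts.singlet.sum() == 3
        off = {k: j for j, k in enumerate(counts.offsets)}
        assert counts.doublet[S["I"], off[-1], A["C"], A["A"]] == 1
        assert counts.doublet[S["I"], off[1], A["C"], A["D"]] == 1
        assert counts.doublet.sum(axis=(2, 3))[S["I"]].sum() == 2
        pair = {p: j for j, p in enumerate(counts.pairs)}
        assert counts.triplet[S["I"], pair[(-1, 1)], A["C"], A["A"], A["D"]] == 1
        assert counts.triplet[S["I"]].sum() == 1

    def test_empty_corpus_all_zero(self):
        counts = count_contexts([])
        assert counts.grand_total == 0
        assert counts.singlet.sum() == 0
        assert counts.doublet.sum() == 0
        assert counts.triplet.sum() == 0

    def test_length_one_chain(self):
        counts = count_contexts([_labeled("W", "F")])
        assert counts.singlet[S["F"], A["W"]] == 1
        assert counts.doublet.sum() == 0
        assert counts.triplet.sum() == 0

    def test_undetermined_state_rejected(self):
        with pytest.raises(ValueError, match="undetermined"):
            count_contexts([_labeled("AC", ["R", None])])

    def test_x_residue_contributes_nothing(self):
        counts = count_contexts([_labeled("AXD", "RIF")])
        assert counts.singlet.sum() == 2  # A and D only
        assert counts.doublet.sum() == 2  # A-D at +2 and D-A at -2

    @given(st.data())
    def test_matches_brute_force_recount(self, data):
        n_chains = data.draw(st.integers(1, 5))
        chains = []
        for c in range(n_chains):
            L = data.draw(st.integers(1, 10))
            seq = "".join(
                data.draw(st.sampled_from(PSSM_ALPHABET + "X")) for _ in range(L)
            )
            states = [data.draw(st.sampled_from(STATES3)) for _ in range(L)]
            chains.append(_labeled(seq, states, chain_id=f"C{c}"))
        counts = count_contexts(chains)
        b1, b2, b3 = brute_force_counts([(c.sequence, c.states) for c in chains])
        assert counts.singlet.sum() == sum(b1.values())
        for (s, a), v in b1.items():
            assert counts.singlet[S[s], A[a]] == v
        off = {k: j for j, k in enumerate(counts.offsets)}
        assert counts.doublet.sum() == sum(b2.values())
        for (s, k, x, y), v in b2.items():
            assert counts.doublet[S[s], off[k], A[x], A[y]] == v
        pair = {p: j for j, p in enumerate(counts.pairs)}
        assert counts.triplet.sum() == sum(b3.values())
        for (s, ks, x, y, z), v in b3.items():
            assert counts.triplet[S[s], pair[ks], A[x], A[y], A[z]] == v


def _uniform_counts(per_cell=4):
    """Counts where every singlet cell has equal mass across states."""
    singlet = np.full((3, 20), per_cell, dtype=np.int64)
    h = 3
    counts = ContextCounts(
        window_half=h,
        singlet=singlet,
        doublet=np.zeros((3, 6, 20, 20), dtype=np.int64),
        triplet=np.zeros((3, 15, 20, 20, 20), dtype=np.int64),
        state_totals=singlet.sum(axis=1),
        grand_total=int(singlet.sum()),
    )
    return counts


class TestDerivePotentials:
    def test_uniform_corpus_gives_zero_potentials(self):
        table = derive_potentials(_uniform_counts(), blend_weight=10.0)
        np.testing.assert_allclose(table.u_singlet, 0.0, atol=1e-12)
        np.testing.assert_allclose(table.u_doublet, 0.0, atol=1e-12)
        np.testing.assert_allclose(table.u_triplet, 0.0, atol=1e-12)

    def test_unobserved_cell_is_smoothing_fixed_point(self):
        counts = _uniform_counts()
        counts.singlet[:, A["W"]] = [8, 2, 2]  # skew one cell, keep others
        counts.state_totals = counts.singlet.sum(axis=1)
        counts.grand_total = int(counts.state_totals.sum())
        table = derive_potentials(counts, blend_weight=5.0)
        # triplets were never observed anywhere: all exactly 0
        np.testing.assert_array_equal(table.u_triplet, 0.0)

    def test_worked_singlet_example(self):
        counts = _uniform_counts(per_cell=0)
        # equal state priors: balance the totals with a background cell
        counts.singlet[:, A["G"]] = [100, 107, 107]
        counts.singlet[:, A["A"]] = [8, 1, 1]
        counts.state_totals = counts.singlet.sum(axis=1)
        counts.grand_total = int(counts.state_totals.sum())
        # near-zero smoothing recovers the raw log-ratio -ln(0.8 / (1/3))
        t0 = derive_potentials(counts, blend_weight=1e-9)
        assert t0.u_singlet[S["R"], A["A"]] == pytest.approx(-0.8755, abs=1e-4)
        t3 = derive_potentials(counts, blend_weight=3.0)
        assert t3.u_singlet[S["R"], A["A"]] == pytest.approx(
            -math.log((27 / 13)), abs=1e-9
        )
        assert t3.u_singlet[S["R"], A["A"]] == pytest.approx(-0.7309, abs=1e-4)

    def test_empty_corpus_rejected(self):
        with pytest.raises(EmptyCorpusError):
            derive_potentials(_uniform_counts(per_cell=0))

    def test_missing_state_rejected(self):
        counts = _uniform_counts()
        counts.singlet[S["F"]] = 0
        counts.state_totals = counts.singlet.sum(axis=1)
        counts.grand_total = int(counts.state_totals.sum())
        with pytest.raises(MissingStateError):
            derive_potentials(counts)

    def test_enrichment_monotonically_lowers_potential(self):
        prev = None
        for n_r in (2, 6, 12, 30):
            counts = _uniform_counts()
            counts.singlet[:, A["A"]] = [n_r, 2, 2]
            counts.state_totals = counts.singlet.sum(axis=1)
            counts.grand_total = int(counts.state_totals.sum())
            u = derive_potentials(counts, blend_weight=2.0).u_singlet[S["R"], A["A"]]
            if prev is not None:
                assert u < prev
            prev = u

    def test_large_blend_weight_flattens_potentials(self):
        counts = _uniform_counts()
        counts.singlet[:, A["A"]] = [50, 2, 2]
        counts.state_totals = counts.singlet.sum(axis=1)
        counts.grand_total = int(counts.state_totals.sum())
        u_small = derive_potentials(counts, blend_weight=0.1).u_singlet[S["R"], A["A"]]
        u_big = derive_potentials(counts, blend_weight=1e6).u_singlet[S["R"], A["A"]]
        assert abs(u_big) < 1e-3 < abs(u_small)

    def test_planted_singlet_preference_sign_recovery(self):
        tilt = {"A": {"R": 4.0}, "W": {"F": 4.0}, "G": {"I": 3.0}}
        corpus = make_tilted_corpus(seed=3, n_residues=30000, tilt=tilt)
        table = derive_potentials(count_contexts(corpus), blend_weight=10.0)
        assert table.u_singlet[S["R"], A["A"]] < 0
        assert table.u_singlet[S["F"], A["W"]] < 0
        assert table.u_singlet[S["I"], A["G"]] < 0
        # the un-tilted states of a tilted residue are depleted
        assert table.u_singlet[S["F"], A["A"]] > 0


def _const_table(a=0.0, b=0.0, c=0.0, per_state=None):
    u1 = np.full((3, 20), a)
    u2 = np.full((3, 6, 20, 20), b)
    u3 = np.full((3, 15, 20, 20, 20), c)
    if per_state is not None:
        for s, val in per_state.items():
            u1[S[s]] = val
    return PotentialTable(
        window_half=3,
        blend_weight=10.0,
        priors=np.array([1 / 3] * 3),
        u_singlet=u1,
        u_doublet=u2,
        u_triplet=u3,
    )


class TestCombinedPotential:
    def test_zero_table_gives_zero_everywhere(self):
        table = _const_table()
        seq = "ACDEFGHIKL"
        for i in range(1, len(seq) + 1):
            for s in STATES3:
                assert combined_pseudo_potential(table, seq, i, s) == 0.0

    def test_interior_residue_has_22_terms(self):
        table = _const_table(a=1.0, b=1.0, c=1.0)
        seq = "ACDEFGHIKLMN"
        assert combined_pseudo_potential(table, seq, 6, "R") == pytest.approx(22.0)

    def test_first_position_has_7_terms(self):
        table = _const_table(a=1.0, b=1.0, c=1.0)
        seq = "ACDEFGHIKLMN"
        assert combined_pseudo_potential(table, seq, 1, "R") == pytest.approx(7.0)

    def test_term_weighting_a_6b_15c(self):
        table = _const_table(a=1.5, b=-0.25, c=0.125)
        val = combined_pseudo_potential(table, "ACDEFGHIKLMN", 7, "I")
        assert val == pytest.approx(1.5 + 6 * -0.25 + 15 * 0.125)

    def test_out_of_range_position_rejected(self):
        with pytest.raises(IndexError):
            combined_pseudo_potential(_const_table(), "ACD", 4, "R")


class TestSCRS:
    def test_equal_potentials_give_uniform_scores(self):
        np.testing.assert_allclose(
            scrs_scores(_const_table(a=2.0), "AAAA", 2), [1 / 3] * 3, atol=1e-12
        )

    def test_worked_softmax_example(self):
        table = _const_table(per_state={"R": 0.0, "I": math.log(2), "F": math.log(2)})
        np.testing.assert_allclose(
            scrs_scores(table, "A", 1), [0.5, 0.25, 0.25], atol=1e-12
        )

    @given(st.data())
    def test_scores_are_a_simplex_point(self, data):
        rng = np.random.default_rng(data.draw(st.integers(0, 10**6)))
        table = _const_table()
        table.u_singlet = rng.normal(0, 2, (3, 20))
        table.u_doublet = rng.normal(0, 1, (3, 6, 20, 20))
        L = data.draw(st.integers(1, 12))
        seq = "".join(data.draw(st.sampled_from(PSSM_ALPHABET)) for _ in range(L))
        i = data.draw(st.integers(1, L))
        s = scrs_scores(table, seq, i)
        assert s.sum() == pytest.approx(1.0, abs=1e-9)
        assert (s > 0).all()


def test_window_geometry_helpers():
    assert window_offsets(3) == (-3, -2, -1, 1, 2, 3)
    assert len(offset_pairs(3)) == 15
    assert offset_pairs(1) == ((-1, 1),)


def test_table_serialization_round_trip(tmp_path, small_table):
    p = tmp_path / "table.json"
    small_table.save(p)
    back = PotentialTable.load(p)
    assert back.window_half == small_table.window_half
    assert back.blend_weight == small_table.blend_weight
    np.testing.assert_allclose(back.priors, small_table.priors)
    np.testing.assert_allclose(back.u_singlet, small_table.u_singlet)
    np.testing.assert_allclose(back.u_doublet, small_table.u_doublet)
    np.testing.assert_allclose(back.u_triplet, small_table.u_triplet)
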