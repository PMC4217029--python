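"""PWM construction, scoring and the invariant-core constraint logic."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from ypkscreen import motif
from ypkscreen.motif import (
    AMINO_ACIDS,
    MotifError,
    MotifWindow,
    build_pwm,
    check_constraints,
    score_window,
    uniform_background,
)

OFF3 = (-1, 0, 1)


def win(s, offsets=OFF3):
    return MotifWindow.from_string(s, offsets)


class TestBuildPwm:
    def test_degenerate_counting_no_pseudocount(self):
        """Identical windows with pseudocount 0 give probability 1 to the
        observed residue at every offset."""
        m = build_pwm([win("AST")] * 3, pseudocount=0.0, constrained_offsets={0: frozenset("ST")},
                      preference_offsets={})
        for i, res in enumerate("AST"):
            assert m.probs[i, AMINO_ACIDS.index(res)] == pytest.approx(1.0)
            assert m.probs[i].sum() == pytest.approx(1.0)

    def test_laplace_counting_formula(self):
        """Two windows differing at one offset, pseudocount 1: counts follow
        (count + 1) / (n + 20)."""
        m = build_pwm([win("AST"), win("CST")], pseudocount=1.0,
                      constrained_offsets={0: frozenset("ST")}, preference_offsets={})
        probs_at_minus1 = m.probs[0]
        assert probs_at_minus1[AMINO_ACIDS.index("A")] == pytest.approx(2 / 22)
        assert probs_at_minus1[AMINO_ACIDS.index("C")] == pytest.approx(2 / 22)
        assert probs_at_minus1[AMINO_ACIDS.index("W")] == pytest.approx(1 / 22)

    def test_default_training_argmax_is_arginine_at_core(self, default_matrix):
        """Windows around known-substrate-class sites train a matrix whose
        modal residue at -5 and -3 is Arg."""
        for offset in (-5, -3):
            row = default_matrix.probs[default_matrix.offsets.index(offset)]
            assert AMINO_ACIDS[row.argmax()] == "R"

    def test_errors(self):
        with pytest.raises(MotifError):
            build_pwm([])
        with pytest.raises(MotifError):
            build_pwm([win("AST")], pseudocount=-1)
        with pytest.raises(MotifError):
            build_pwm([win("AST"), win("AST", offsets=(0, 1, 2))])

    @given(st.integers(0, 3), st.floats(0.0, 10.0))
    def test_normalization_any_pseudocount(self, n_extra, pseudocount):
        """Per-offset probability rows sum to one for any pseudocount."""
        windows = [win("AST"), win("CSV"), win("RTI")][: 1 + n_extra % 3]
        m = build_pwm(windows, pseudocount=pseudocount,
                      constrained_offsets={0: frozenset("ST")}, preference_offsets={})
        assert np.allclose(m.probs.sum(axis=1), 1.0, atol=1e-9)

    def test_padding_excluded_from_counts(self):
        m = build_pwm([win("-ST"), win("AST")], pseudocount=0.0,
                      constrained_offsets={0: frozenset("ST")}, preference_offsets={})
        # only one countable residue at offset -1
        assert m.probs[0, AMINO_ACIDS.index("A")] == pytest.approx(1.0)


class TestScoreWindow:
    def toy_matrix(self):
        probs = np.full((3, 20), 1 / 40)  # half mass spread uniformly
        for i, res in enumerate("RSV"):
            probs[i, AMINO_ACIDS.index(res)] += 0.5
        return motif.MotifMatrix(
            offsets=OFF3, probs=probs, background=uniform_background(),
            constrained_offsets={0: frozenset("ST")}, preference_offsets={1: frozenset("VIF")},
        )

    def test_background_equal_probs_scores_zero(self):
        m = motif.MotifMatrix(
            offsets=OFF3, probs=np.tile(uniform_background(), (3, 1)),
            background=uniform_background(),
            constrained_offsets={0: frozenset("ST")}, preference_offsets={},
        )
        assert score_window(m, win("AST")).raw_logodds == pytest.approx(0.0)

    def test_per_position_sum_oracle(self):
        """Raw log-odds equals an independently coded per-position sum."""
        m = self.toy_matrix()
        rng = np.random.default_rng(42)
        for _ in range(1000):
            residues = "".join(rng.choice(list(AMINO_ACIDS), size=3))
            expected = sum(
                math.log(m.probs[i, AMINO_ACIDS.index(r)] / (1 / 20))
                for i, r in enumerate(residues)
            )
            got = score_window(m, win(residues)).raw_logodds
            assert got == pytest.approx(expected, abs=1e-12)

    def test_plus1_hydrophobic_scores_higher(self, default_matrix):
        """With the +1 preference trained in, a consensus window with V at +1
        outscores the same window with N at +1."""
        consensus = list(str(default_matrix.consensus()))
        i_plus1 = default_matrix.offsets.index(1)
        consensus[i_plus1] = "V"
        with_v = MotifWindow(tuple(consensus), default_matrix.offsets)
        consensus[i_plus1] = "N"
        with_n = MotifWindow(tuple(consensus), default_matrix.offsets)
        assert (
            score_window(default_matrix, with_v).raw_logodds
            > score_window(default_matrix, with_n).raw_logodds
        )

    def test_consensus_dominance_exhaustive(self):
        """The per-offset argmax window attains the maximum raw score over
        all 20^3 windows of a 3-offset matrix."""
        m = self.toy_matrix()
        best = max(
            score_window(m, win("".join(r))).raw_logodds
            for r in itertools.product(AMINO_ACIDS, repeat=3)
        )
        assert score_window(m, m.consensus()).raw_logodds == pytest.approx(best)
        assert score_window(m, m.consensus()).likelihood == pytest.approx(1.0)

    def test_likelihood_monotone_in_raw(self):
        m = self.toy_matrix()
        scores = [score_window(m, win("".join(r))) for r in itertools.product("ARSV", repeat=3)]
        by_raw = sorted(scores, key=lambda s: s.raw_logodds)
        liks = [s.likelihood for s in by_raw]
        assert all(a <= b + 1e-12 for a, b in zip(liks, liks[1:]))
        assert all(0.0 <= s.likelihood <= 1.0 for s in scores)

    def test_offset_mismatch_rejected(self, default_matrix):
        with pytest.raises(MotifError):
            score_window(default_matrix, win("AST"))

    def test_padding_contributes_zero(self):
        m = self.toy_matrix()
        padded = win("-SV")
        unpadded_part = score_window(m, padded).raw_logodds
        expected = sum(
            math.log(m.probs[i, AMINO_ACIDS.index(r)] / (1 / 20))
            for i, r in [(1, "S"), (2, "V")]
        )
        assert unpadded_part == pytest.approx(expected)


class TestCheckConstraints:
    @pytest.mark.parametrize(
        "residues, core_ok, plus1",
        [
            ("RPRGQTT", True, False),  # T147-class window: core only
            ("RRRSRSR", True, False),  # S181-class window: core only
            ("RSRATSN", True, False),  # S185-class window: core only
            ("RARAQSV", True, True),
            ("RAKAQSV", False, True),  # K at -3 violates the core
        ],
    )
    def test_examples(self, residues, core_ok, plus1):
        w = MotifWindow.from_string(residues, offsets=range(-5, 2))
        got_core, got_plus1, accepted_core = check_constraints(w, "core")
        _, _, accepted_strict = check_constraints(w, "strict")
        assert got_core is core_ok
        assert got_plus1 is plus1
        assert accepted_core is core_ok
        assert accepted_strict is (core_ok and plus1)

    def test_padded_required_position_fails(self):
        w = MotifWindow.from_string("--RAQSV", offsets=range(-5, 2))
        core_ok, _, accepted = check_constraints(w, "core")
        assert not core_ok and not accepted

    def test_invalid_mode(self):
        with pytest.raises(MotifError):
            check_constraints(win("AST"), "lenient")


class TestWindowInvariants:
    def test_interior_padding_rejected(self):
        with pytest.raises(MotifError):
            MotifWindow(("A", "-", "T"), OFF3)

    def test_offsets_must_increase_and_include_zero(self):
        with pytest.raises(MotifError):
            MotifWindow(("A", "S"), (1, 0))
        with pytest.raises(MotifError):
            MotifWindow(("A", "S"), (1, 2))


def test_matrix_tsv_round_trip(tmp_path, default_matrix):
    path = tmp_path / "matrix.tsv"
    default_matrix.to_tsv(path)
    loaded = motif.MotifMatrix.from_tsv(path)
    assert loaded.offsets == default_matrix.offsets
    assert np.allclose(loaded.probs, default_matrix.probs)
    assert np.allclose(loaded.background, default_matrix.background)
    assert loaded.constrained_offsets == dict(default_matrix.constrained_offsets)
    assert loaded.preference_offsets == dict(default_matrix.preference_offsets)
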