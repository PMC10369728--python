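import itertools
import math

import numpy as np
import pytest

from oracles import viterbi_brute
from pepmine import profile_hmm as ph

AA20 = "ACDEFGHIKLMNPQRSTVWY"


def random_reduced_hmm(M: int, rng) -> ph.ProfileHMM:
    """Random profile concentrated on the reduced alphabet {A, C, D, E}."""
    probs = np.full((M, 20), 1e-12)
    probs[:, :4] = rng.dirichlet(np.ones(4) * 2, size=M)
    probs /= probs.sum(axis=1, keepdims=True)
    uniform = np.full(20, math.log(1 / 20))
    tr = np.empty(7)
    tr[:3] = np.log(rng.dirichlet([8, 1, 1]))
    tr[3:5] = np.log(rng.dirichlet([1, 1]))
    tr[5:] = np.log(rng.dirichlet([1, 1]))
    return ph.ProfileHMM("rand", "", M, np.log(probs),
                         np.tile(uniform, (M, 1)), np.tile(tr, (M + 1, 1)),
                         uniform)


HAND_WRITTEN_2STATE = """HMMER3/f [hand-written fixture]
NAME  toy2
ACC   TOY00002.1
LENG  2
ALPH  amino
HMM          A        C        D        E        F        G        H        I        K        L        M        N        P        Q        R        S        T        V        W        Y
            m->m     m->i     m->d     i->m     i->i     d->m     d->d
  COMPO   2.99573  2.99573  2.99573  2.99573  2.99573  2.99573  2.99573  2.99573  2.99573  2.99573  2.99573  2.99573  2.99573  2.99573  2.99573  2.99573  2.99573  2.99573  2.99573  2.99573
          2.99573  2.99573  2.99573  2.99573  2.99573  2.99573  2.99573  2.99573  2.99573  2.99573  2.99573  2.99573  2.99573  2.99573  2.99573  2.99573  2.99573  2.99573  2.99573  2.99573
          0.16252  2.30259  2.99573  0.69315  0.69315  0.00000        *
      1   0.35667  2.30259  4.49981  4.49981  4.49981  4.49981  4.49981  4.49981  4.49981  4.49981  4.49981  4.49981  4.49981  4.49981  4.49981  4.49981  4.49981  4.49981  4.49981  4.49981
          2.99573  2.99573  2.99573  2.99573  2.99573  2.99573  2.99573  2.99573  2.99573  2.99573  2.99573  2.99573  2.99573  2.99573  2.99573  2.99573  2.99573  2.99573  2.99573  2.99573
          0.16252  2.30259  2.99573  0.69315  0.69315  0.69315  0.69315
      2   2.30259  0.35667  4.49981  4.49981  4.49981  4.49981  4.49981  4.49981  4.49981  4.49981  4.49981  4.49981  4.49981  4.49981  4.49981  4.49981  4.49981  4.49981  4.49981  4.49981
          2.99573  2.99573  2.99573  2.99573  2.99573  2.99573  2.99573  2.99573  2.99573  2.99573  2.99573  2.99573  2.99573  2.99573  2.99573  2.99573  2.99573  2.99573  2.99573  2.99573
          0.10536  2.30259        *  0.69315  0.69315  0.00000        *
//
"""


class TestHmmer3IO:
    def test_hand_written_two_state_profile(self):
        hmm = ph.read_hmmer3(HAND_WRITTEN_2STATE)
        assert hmm.M == 2
        assert hmm.name == "toy2"
        assert hmm.accession == "TOY00002.1"
        # emission values recovered from negative-log space
        assert math.exp(hmm.match_emissions[0, 0]) == pytest.approx(
            math.exp(-0.35667), abs=1e-9)
        assert hmm.transitions[2, ph.MD] == float("-inf")  # '*' parsed

    def test_round_trip_identical_within_tolerance(self, tiny_hmm):
        text = ph.write_hmmer3(tiny_hmm)
        back = ph.read_hmmer3(text)
        assert back.M == tiny_hmm.M
        for a, b in ((back.match_emissions, tiny_hmm.match_emissions),
                     (back.insert_emissions, tiny_hmm.insert_emissions),
                     (back.transitions, tiny_hmm.transitions)):
            fa, fb = np.nan_to_num(a, neginf=-1e9), np.nan_to_num(b, neginf=-1e9)
            assert np.max(np.abs(fa - fb)) < 1e-9

    def test_unnormalised_row_rejected(self):
        bad = HAND_WRITTEN_2STATE.replace("0.35667", "3.35667")
        with pytest.raises(ValueError, match="sums to"):
            ph.read_hmmer3(bad)

    def test_malformed_header_names_line(self):
        with pytest.raises(ValueError, match="line 1"):
            ph.read_hmmer3("NOT A PROFILE\n")

    def test_truncated_model_rejected(self):
        lines = HAND_WRITTEN_2STATE.splitlines()
        with pytest.raises(ValueError):
            ph.read_hmmer3("\n".join(lines[:12]))


class TestBuildFromAlignment:
    def test_identical_ungapped_sequences(self):
        hmm = ph.build_from_alignment(["KKLLA"] * 3)
        assert hmm.M == 5
        for col, res in enumerate("KKLLA"):
            assert AA20[np.argmax(hmm.match_emissions[col])] == res

    def test_laplace_arithmetic(self):
        hmm = ph.build_from_alignment(["K", "K", "K"], pseudocount=1)
        k = AA20.index("K")
        assert math.exp(hmm.match_emissions[0, k]) == pytest.approx(4 / 23)

    def test_majority_gap_column_excluded(self):
        hmm = ph.build_from_alignment(["K-A", "K-A", "KCA"])
        assert hmm.M == 2

    def test_ragged_alignment_rejected(self):
        with pytest.raises(ValueError, match="ragged"):
            ph.build_from_alignment(["KK", "KKK"])


class TestViterbiLocal:
    def test_consensus_alignment_covers_whole_model(self, tiny_hmm):
        consensus = "".join(AA20[int(np.argmax(row))]
                            for row in tiny_hmm.match_emissions)
        hit = ph.viterbi_local(tiny_hmm, consensus)
        assert hit is not None
        assert (hit.hmm_from, hit.hmm_to) == (1, tiny_hmm.M)
        assert (hit.query_start, hit.query_end) == (1, len(consensus))

    def test_partial_query_envelope(self, tiny_hmm):
        consensus = "".join(AA20[int(np.argmax(row))]
                            for row in tiny_hmm.match_emissions)
        padded = "GGG" + consensus + "NN"
        hit = ph.viterbi_local(tiny_hmm, padded)
        assert (hit.query_start, hit.query_end) == (4, 3 + len(consensus))

    def test_matches_exhaustive_enumeration(self):
        """DP equals brute-force max over all local paths (exact, log space)."""
        rng = np.random.default_rng(7)
        alphabet = "ACDE"
        n_cases = 0
        for M in (1, 2, 3, 4):
            for rep in range(2):
                hmm = random_reduced_hmm(M, rng)
                peptides = ["".join(p) for L in (1, 2, 3)
                            for p in itertools.product(alphabet, repeat=L)]
                peptides += ["".join(rng.choice(list(alphabet), size=L))
                             for L in (4, 5, 6) for _ in range(10)]
                for pep in peptides:
                    v = ph.viterbi_local(hmm, pep, threshold_bits=-1e9)
                    b = viterbi_brute(hmm, pep)
                    assert v is not None
                    assert v.score_bits == pytest.approx(b, abs=1e-9)
                    n_cases += 1
        assert n_cases >= 500

    def test_prepending_residues_never_decreases_score(self, tiny_hmm, rng):
        pep = "KKLLA"
        base = ph.viterbi_local(tiny_hmm, pep, threshold_bits=-1e9).score_bits
        for prefix_len in (1, 3, 7):
            prefix = "".join(rng.choice(list(AA20), size=prefix_len))
            s = ph.viterbi_local(tiny_hmm, prefix + pep,
                                 threshold_bits=-1e9).score_bits
            assert s >= base - 1e-12

    def test_hit_coordinate_bounds_on_random_pairs(self, rng):
        for _ in range(200):
            M = int(rng.integers(1, 6))
            hmm = random_reduced_hmm(M, rng)
            pep = "".join(rng.choice(list(AA20), size=int(rng.integers(1, 15))))
            hit = ph.viterbi_local(hmm, pep, threshold_bits=-1e9)
            assert hit is not None
            assert 1 <= hit.query_start <= hit.query_end <= len(pep)
            assert 1 <= hit.hmm_from <= hit.hmm_to <= M

    def test_threshold_suppresses_weak_hits(self, tiny_hmm):
        # a peptide of residues the model never emits scores far below 0 bits
        assert ph.viterbi_local(tiny_hmm, "WWWWW", threshold_bits=0.0) is None

    def test_empty_and_invalid_peptides(self, tiny_hmm):
        with pytest.raises(ValueError):
            ph.viterbi_local(tiny_hmm, "")
        with pytest.raises(ValueError):
            ph.viterbi_local(tiny_hmm, "KXK")


def test_synthetic_homeodomain_envelope_protects_tail():
    """Machinery check on a synthetic stand-in for the homeodomain profile:
    a profile built from N-terminal-conserved variants of a 37-mer aligns to
    residues 1-31 only, leaving the C-terminal tail free for optimisation."""
    rng = np.random.default_rng(3)
    core = "TKEQKEQIAKATGLTTKQVRNWYVQLNASIK"  # residues 1-31
    variants = []
    for _ in range(6):
        seq = list(core)
        for pos in rng.choice(len(core), size=3, replace=False):
            seq[pos] = AA20[int(rng.integers(20))]
        variants.append("".join(seq))
    hmm = ph.build_from_alignment(variants, name="synthetic-homeodomain")
    assert hmm.M == 31
    hit = ph.viterbi_local(hmm, "TKEQKEQIAKATGLTTKQVRNWYVQLNASIKVMLTSI")
    assert hit is not None
    assert (hit.query_start, hit.query_end) == (1, 31)
    assert (hit.hmm_from, hit.hmm_to) == (1, 31)
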