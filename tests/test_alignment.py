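"""Global aligner vs independent oracles; PIDE/KL metrics; roundtrip filtering."""

import numpy as np
import pytest

import pro3di.alignment as alignment_mod
from oracle_alignment import brute_force_score
from pro3di.alignment import (
    generate_with_roundtrip,
    kl_naturalness,
    nw_align,
    aa_frequencies,
)
from pro3di.decoding import DecodeConfig
from pro3di.io import SubstitutionMatrix, default_tdi_matrix


@pytest.fixture(scope="module")
def toy_matrix():
    scores = np.array([[4, -1, -2], [-1, 5, -3], [-2, -3, 6]])
    return SubstitutionMatrix("vdp", scores, gap_open=-5, gap_extend=-1)


class TestNWAlign:
    def test_self_alignment_pide_100_and_diagonal_score(self, toy_matrix):
        res = nw_align("vdpv", "vdpv", toy_matrix)
        assert res.pide == 100.0
        assert res.score == 4 + 5 + 6 + 4

    def test_empty_sequence_gives_gap_columns(self, toy_matrix):
        res = nw_align("vd", "", toy_matrix)
        assert res.aligned_a == "vd" and res.aligned_b == "--"
        assert res.pide == 0.0
        assert res.score == toy_matrix.gap_open + toy_matrix.gap_extend

    def test_gapless_inputs_recoverable(self, toy_matrix):
        res = nw_align("vdpvd", "vpd", toy_matrix)
        assert res.aligned_a.replace("-", "") == "vdpvd"
        assert res.aligned_b.replace("-", "") == "vpd"
        assert len(res.aligned_a) == len(res.aligned_b)

    def test_score_symmetric_under_swap(self, toy_matrix):
        rng = np.random.default_rng(0)
        for _ in range(30):
            a = "".join(rng.choice(list("vdp"), rng.integers(1, 8)))
            b = "".join(rng.choice(list("vdp"), rng.integers(1, 8)))
            assert nw_align(a, b, toy_matrix).score == nw_align(b, a, toy_matrix).score

    def test_matches_exhaustive_enumeration(self, toy_matrix):
        """Dynamic programming equals brute force over all global alignments."""
        rng = np.random.default_rng(1)
        for _ in range(60):
            a = "".join(rng.choice(list("vdp"), rng.integers(0, 6)))
            b = "".join(rng.choice(list("vdp"), rng.integers(0, 6)))
            assert nw_align(a, b, toy_matrix).score == brute_force_score(a, b, toy_matrix)

    def test_matches_biotite_on_3di_matrix(self):
        """Independent library aligner agrees on optimal scores."""
        biotite_align = pytest.importorskip("biotite.sequence.align")
        import biotite.sequence as bseq

        mat = default_tdi_matrix()
        alph = bseq.LetterAlphabet(list(mat.alphabet))
        bmat = biotite_align.SubstitutionMatrix(alph, alph, mat.scores.astype(np.int32))
        rng = np.random.default_rng(2)
        letters = list(mat.alphabet)
        for _ in range(25):
            a = "".join(rng.choice(letters, rng.integers(3, 30)))
            b = "".join(rng.choice(letters, rng.integers(3, 30)))
            ours = nw_align(a, b, mat).score
            ga = bseq.GeneralSequence(alph, list(a))
            gb = bseq.GeneralSequence(alph, list(b))
            theirs = biotite_align.align_optimal(
                ga, gb, bmat, gap_penalty=(mat.gap_open, mat.gap_extend),
                terminal_penalty=True, max_number=1,
            )[0].score
            assert ours == theirs

    def test_pide_denominator_switch(self, toy_matrix):
        res_aln = nw_align("vvd", "vv", toy_matrix, pide_denominator="alignment")
        res_short = nw_align("vvd", "vv", toy_matrix, pide_denominator="shorter")
        assert res_short.pide >= res_aln.pide

    def test_out_of_alphabet_rejected(self, toy_matrix):
        with pytest.raises(Exception, match="alphabet"):
            nw_align("vdz", "vd", toy_matrix)


class TestKLNaturalness:
    def test_matching_composition_gives_zero(self):
        all_letters = "ACDEFGHIKLMNPQRSTVWY"
        ref = np.full(20, 1 / 20)
        assert kl_naturalness([all_letters], ref) == pytest.approx(0.0, abs=1e-12)

    def test_point_mass_vs_uniform_is_log20(self):
        uniform = np.full(20, 1 / 20)
        assert kl_naturalness(["AAAA"], uniform) == pytest.approx(np.log(20))

    def test_monotone_along_interpolation_to_reference(self):
        """KL decreases as the empirical composition approaches the reference."""
        from scipy.stats import entropy

        ref = np.full(20, 1 / 20)
        point = np.zeros(20)
        point[0] = 1.0
        values = [
            entropy((1 - t) * point + t * ref, ref) for t in np.linspace(0, 1, 11)
        ]
        assert all(x >= y - 1e-12 for x, y in zip(values, values[1:]))

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            kl_naturalness([], np.full(20, 1 / 20))

    def test_nonpositive_reference_rejected(self):
        bad = np.full(20, 1 / 20)
        bad[3] = 0.0
        with pytest.raises(ValueError):
            kl_naturalness(["ACD"], bad)


class _ScriptedTranslate:
    """Stand-in for model translation with scripted outputs per direction."""

    def __init__(self, fwd_outputs, back_map):
        self.fwd_outputs = list(fwd_outputs)
        self.back_map = back_map
        self.calls = 0

    def __call__(self, model, seq, direction, cfg, vocab):
        if direction == "fold2AA":
            out = self.fwd_outputs[self.calls % len(self.fwd_outputs)]
            self.calls += 1
            return out
        return self.back_map[seq]


class TestRoundtripFiltering:
    @pytest.fixture
    def matrix(self):
        return default_tdi_matrix()

    def _run(self, monkeypatch, matrix, fwd_outputs, back_map, **kw):
        scripted = _ScriptedTranslate(fwd_outputs, back_map)
        monkeypatch.setattr(alignment_mod, "translate", scripted)
        cfg = DecodeConfig(seed=0)
        return generate_with_roundtrip(
            "vvddpp", None, cfg, cfg, matrix, None, **kw
        )

    def test_perfect_first_candidate_stops_early(self, monkeypatch, matrix):
        res = self._run(
            monkeypatch, matrix, ["MKL"], {"MKL": "vvddpp"}, threshold=70, budget=10
        )
        assert res.n_attempts == 1 and res.accepted == "MKL"
        assert res.candidates[0][1] == 100.0

    def test_threshold_zero_accepts_first(self, monkeypatch, matrix):
        res = self._run(
            monkeypatch, matrix, ["MKL"], {"MKL": "kkkkkk"}, threshold=0, budget=10
        )
        assert res.n_attempts == 1 and res.accepted == "MKL"

    def test_budget_exhausted_reports_best_effort(self, monkeypatch, matrix):
        back = {"AAA": "kkkkkk", "CCC": "vkkkkk"}
        res = self._run(
            monkeypatch, matrix, ["AAA", "CCC"], back, threshold=70, budget=10
        )
        assert res.n_attempts == 10 and res.accepted is None
        assert res.best[0] == "CCC"  # one matching position beats zero

    def test_accepted_is_argmax_of_candidates(self, monkeypatch, matrix):
        back = {"AAA": "vvddpk", "CCC": "vvddpp"}
        res = self._run(
            monkeypatch, matrix, ["AAA", "CCC"], back, threshold=101, budget=4
        )
        assert res.accepted is None
        assert res.best[1] == max(p for _, p in res.candidates)

    def test_budget_below_one_rejected(self, monkeypatch, matrix):
        with pytest.raises(ValueError, match="budget"):
            self._run(monkeypatch, matrix, ["AAA"], {"AAA": "vvddpp"}, budget=0)
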