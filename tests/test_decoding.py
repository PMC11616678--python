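"""Logit-processing pipeline closed forms and generation contracts."""

import re

import numpy as np
import pytest

from pro3di.decoding import DecodeConfig, aa2fold_config, fold2aa_config, process_logits, translate


def _cfg(**kw):
    base = dict(do_sample=True, num_beams=1, temperature=1.0, top_p=1.0,
                top_k=0, repetition_penalty=1.0)
    base.update(kw)
    return DecodeConfig(**base)


class TestProcessLogits:
    def test_neutral_config_is_plain_softmax(self):
        logits = np.array([2.0, 1.0, -1.0])
        probs = process_logits(logits, [], _cfg())
        expected = np.exp(logits) / np.exp(logits).sum()
        assert np.allclose(probs, expected)

    def test_top_k_truncation_closed_form(self):
        probs = process_logits(np.array([2.0, 1.0, 0.0]), [], _cfg(top_k=2))
        e2, e1 = np.exp(2.0), np.exp(1.0)
        assert probs == pytest.approx([e2 / (e2 + e1), e1 / (e2 + e1), 0.0])

    def test_nucleus_keeps_boundary_token(self):
        # probabilities (0.5, 0.3, 0.2) with top_p=0.8 keep the first two
        logits = np.log(np.array([0.5, 0.3, 0.2]))
        probs = process_logits(logits, [], _cfg(top_p=0.8))
        assert probs == pytest.approx([0.625, 0.375, 0.0])

    def test_repetition_penalty_divides_positive_multiplies_negative(self):
        logits = np.array([2.0, -1.0, 0.5])
        probs = process_logits(logits, [0, 1], _cfg(repetition_penalty=1.2))
        adj = np.array([2.0 / 1.2, -1.0 * 1.2, 0.5])
        assert probs == pytest.approx(np.exp(adj) / np.exp(adj).sum())

    def test_temperature_scaling(self):
        logits = np.array([1.0, 0.0])
        probs = process_logits(logits, [], _cfg(temperature=2.0))
        scaled = logits / 2.0
        assert probs == pytest.approx(np.exp(scaled) / np.exp(scaled).sum())

    def test_alphabet_constraint_masks_and_renormalizes(self):
        probs = process_logits(np.zeros(5), [], _cfg(), allowed_ids=[1, 3])
        assert probs == pytest.approx([0.0, 0.5, 0.0, 0.5, 0.0])

    def test_all_masked_raises(self):
        with pytest.raises(ValueError, match="masked"):
            process_logits(np.zeros(4), [], _cfg(), allowed_ids=[])

    def test_non_finite_logits_rejected(self):
        with pytest.raises(ValueError, match="finite"):
            process_logits(np.array([1.0, np.inf]), [], _cfg())

    def test_output_sums_to_one(self):
        rng = np.random.default_rng(0)
        for _ in range(25):
            cfg = _cfg(
                temperature=float(rng.uniform(0.5, 2.0)),
                top_p=float(rng.uniform(0.3, 1.0)),
                top_k=int(rng.integers(0, 8)),
                repetition_penalty=float(rng.uniform(1.0, 2.0)),
            )
            probs = process_logits(rng.normal(0, 2, 8), [1, 2], cfg)
            assert probs.sum() == pytest.approx(1.0)

    def test_raising_penalty_never_raises_repeated_token_probability(self):
        rng = np.random.default_rng(1)
        for _ in range(30):
            logits = rng.normal(0, 2, 6)
            generated = [2]
            p_low = process_logits(logits, generated, _cfg(repetition_penalty=1.0))
            p_high = process_logits(logits, generated, _cfg(repetition_penalty=1.5))
            assert p_high[2] <= p_low[2] + 1e-12


class TestPublishedConfigs:
    def test_aa2fold_defaults(self):
        cfg = aa2fold_config()
        assert (cfg.do_sample, cfg.num_beams, cfg.top_p, cfg.temperature,
                cfg.top_k, cfg.repetition_penalty) == (True, 3, 0.95, 1.2, 6, 1.2)

    def test_fold2aa_defaults(self):
        cfg = fold2aa_config()
        assert (cfg.do_sample, cfg.top_p, cfg.temperature, cfg.top_k,
                cfg.repetition_penalty) == (True, 0.85, 1.0, 3, 1.2)

    def test_validation(self):
        with pytest.raises(ValueError):
            DecodeConfig(temperature=0.0)
        with pytest.raises(ValueError):
            DecodeConfig(top_p=0.0)
        with pytest.raises(ValueError):
            DecodeConfig(num_beams=0)
        with pytest.raises(ValueError):
            DecodeConfig(repetition_penalty=0.5)


class TestTranslate:
    def test_greedy_is_deterministic_across_runs(self, untrained_model, vocab):
        cfg = _cfg(do_sample=False, max_new_tokens=20, seed=0)
        out1 = translate(untrained_model, "ACDEFGHIKL", "AA2fold", cfg, vocab)
        out2 = translate(untrained_model, "ACDEFGHIKL", "AA2fold", cfg, vocab)
        assert out1 == out2

    def test_sampled_generation_deterministic_given_seed(self, untrained_model, vocab):
        cfg = aa2fold_config(seed=7, max_new_tokens=20)
        out1 = translate(untrained_model, "ACDEFGHIKL", "AA2fold", cfg, vocab)
        out2 = translate(untrained_model, "ACDEFGHIKL", "AA2fold", cfg, vocab)
        assert out1 == out2

    def test_alphabet_constraint_yields_lowercase_3di(self, untrained_model, vocab):
        cfg = aa2fold_config(seed=1, max_new_tokens=30)
        out = translate(untrained_model, "ACDEFGHIKLMNPQRSTVWY", "AA2fold", cfg, vocab)
        assert re.fullmatch(r"[a-z]*", out)

    def test_fold2aa_yields_uppercase_aa(self, untrained_model, vocab):
        cfg = fold2aa_config(seed=1, max_new_tokens=30)
        out = translate(untrained_model, "vvdppkail", "fold2AA", cfg, vocab)
        assert re.fullmatch(r"[A-WY]*", out)  # X excluded from generation

    def test_top_k_one_sampling_equals_greedy(self, untrained_model, vocab):
        greedy = translate(
            untrained_model, "ACDEFGHIKL", "AA2fold",
            _cfg(do_sample=False, max_new_tokens=25, seed=0), vocab,
        )
        topk1 = translate(
            untrained_model, "ACDEFGHIKL", "AA2fold",
            _cfg(do_sample=True, top_k=1, max_new_tokens=25, seed=123), vocab,
        )
        assert greedy == topk1

    def test_invalid_direction_rejected(self, untrained_model, vocab):
        with pytest.raises(ValueError, match="direction"):
            translate(untrained_model, "ACD", "sideways", _cfg(), vocab)
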