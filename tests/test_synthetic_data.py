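"""Ground-truthed corpus generation."""

import json

import numpy as np
import pytest

from phonorank import (
    SyntheticCorpusSpec,
    count_phonemes,
    gen_author_profile,
    gen_corpus,
    gen_lexicon,
    gen_text,
    load_lexicon,
    mean_curve,
    normalize_frequencies,
    rank_frequencies,
)
from phonorank.synthetic_data import RP_INVENTORY, default_inventory


class TestAuthorProfile:
    def test_is_probability_vector(self):
        p = gen_author_profile(44, 0.7, seed=0)
        assert p.shape == (44,)
        assert np.all(p >= 0)
        assert p.sum() == pytest.approx(1.0)

    def test_deterministic_under_seed(self):
        assert np.array_equal(gen_author_profile(10, 0.6, 5), gen_author_profile(10, 0.6, 5))

    def test_low_beta_concentrates_mass(self):
        # smaller concentration → larger expected top entry
        tops = {}
        for beta in (0.5, 5.0):
            draws = [np.max(gen_author_profile(20, beta, seed=s)) for s in range(2000)]
            tops[beta] = np.mean(draws)
        assert tops[0.5] > tops[5.0]

    def test_mean_ranked_profile_matches_expected_curve(self):
        # the generative link: averaging sorted profiles over many authors
        # reproduces the model's expected ranked curve
        draws = np.array([
            -np.sort(-gen_author_profile(44, 0.7, seed=s)) for s in range(3000)
        ])
        se = draws.std(axis=0) / np.sqrt(draws.shape[0])
        assert np.all(np.abs(draws.mean(axis=0) - mean_curve(44, 0.7)) < 3 * se + 1e-12)


class TestLexiconGeneration:
    def test_pronunciations_nonempty_and_within_inventory(self):
        spec = SyntheticCorpusSpec(vocab_size=500)
        lex = gen_lexicon(spec, gen_author_profile(44, 0.7, 0), seed=1, n_words=500)
        assert len(lex) == 500
        inv = set(default_inventory(44))
        for pron in lex.entries.values():
            assert pron
            assert set(pron) <= inv

    def test_pooled_phoneme_frequencies_track_profile(self):
        spec = SyntheticCorpusSpec(vocab_size=10_000)
        profile = gen_author_profile(44, 0.7, 3)
        lex = gen_lexicon(spec, profile, seed=4)
        counts = {}
        total = 0
        for pron in lex.entries.values():
            for ph in pron:
                counts[ph] = counts.get(ph, 0) + 1
                total += 1
        inv = default_inventory(44)
        for k, sym in enumerate(inv):
            f = counts.get(sym, 0) / total
            se = np.sqrt(profile[k] * (1 - profile[k]) / total)
            assert abs(f - profile[k]) < 4 * se + 1e-9

    def test_deterministic_under_seed(self):
        spec = SyntheticCorpusSpec(vocab_size=200)
        p = gen_author_profile(44, 0.8, 0)
        assert gen_lexicon(spec, p, 9).entries == gen_lexicon(spec, p, 9).entries


class TestTextGeneration:
    def test_token_count_and_types(self):
        spec = SyntheticCorpusSpec(tokens_per_text=5000, vocab_size=1000)
        words = [f"w{i}" for i in range(1000)]
        seq = gen_text(words, spec, seed=0)
        assert len(seq) == 5000
        assert len(seq.types()) < len(seq)

    def test_deterministic_under_seed(self):
        spec = SyntheticCorpusSpec(tokens_per_text=1000, vocab_size=300)
        words = [f"w{i}" for i in range(300)]
        assert gen_text(words, spec, 3).tokens == gen_text(words, spec, 3).tokens

    def test_rank_frequency_slope_matches_zipf_exponent(self):
        # log-log regression over the top decade of ranks recovers the
        # exponent (shift set to 0 so the law is a pure power law there)
        spec = SyntheticCorpusSpec(
            tokens_per_text=200_000, vocab_size=2000, zipf_exponent=1.0, mandelbrot_shift=0.0
        )
        words = [f"w{i}" for i in range(2000)]
        seq = gen_text(words, spec, seed=8)
        from collections import Counter

        counts = Counter(seq.tokens)
        ranks = np.arange(10, 101)
        freqs = np.array([counts.get(f"w{r-1}", 0) for r in ranks], dtype=float)
        slope = np.polyfit(np.log(ranks), np.log(freqs), 1)[0]
        assert slope == pytest.approx(-1.0, abs=0.1)


class TestCorpus:
    def test_structure_and_files(self, small_corpus, tmp_path):
        assert len(small_corpus.texts) == 9
        assert set(small_corpus.truth.author_beta) == {"A", "B", "C"}
        for profile in small_corpus.truth.author_profile.values():
            assert sum(profile) == pytest.approx(1.0)
        out = tmp_path / "corpus"
        gen_corpus(small_corpus.spec, outdir=out)
        assert len(list(out.glob("*.txt"))) == 9
        lex = load_lexicon(out / "lexicon.tsv")
        assert set(lex.inventory) == set(RP_INVENTORY)
        truth = json.loads((out / "ground_truth.json").read_text())
        assert truth["author_beta"] == {"A": 0.6, "B": 0.7, "C": 0.8}

    def test_pure_function_of_spec_and_seed(self):
        spec = SyntheticCorpusSpec(tokens_per_text=2000, vocab_size=400, seed=5)
        b1, b2 = gen_corpus(spec), gen_corpus(spec)
        assert b1.texts["A1"].tokens == b2.texts["A1"].tokens
        assert b1.lexicon.entries == b2.lexicon.entries

    def test_author_profiles_are_exact_dirichlet_scale(self, small_corpus):
        # profiles live on the 44-simplex and differ between authors
        profs = {a: np.array(p) for a, p in small_corpus.truth.author_profile.items()}
        assert all(abs(p.sum() - 1) < 1e-9 for p in profs.values())
        assert np.abs(profs["A"] - profs["C"]).sum() > 0.1

    def test_disjoint_vocabularies_when_sharing_disabled(self):
        spec = SyntheticCorpusSpec(
            tokens_per_text=3000, vocab_size=400, shared_vocab_fraction=0.0, seed=2
        )
        bundle = gen_corpus(spec)
        types_a = set(t for t in bundle.texts["A1"].tokens)
        types_b = set(t for t in bundle.texts["B1"].tokens)
        assert not (types_a & types_b)

    def test_shared_block_creates_cross_author_overlap(self, small_corpus):
        from phonorank import common_word_fraction

        types = {tid: small_corpus.texts[tid].types() for tid in ("A1", "A2", "B1")}
        p_same = common_word_fraction(types["A1"], types["A2"]).p
        p_cross = common_word_fraction(types["A1"], types["B1"]).p
        assert 0 < p_cross < p_same

    def test_invalid_sharing_raises(self):
        with pytest.raises(ValueError, match="shared_vocab_fraction"):
            gen_corpus(SyntheticCorpusSpec(shared_vocab_fraction=0.95, vocab_size=100,
                                           tokens_per_text=100))

    def test_type_mode_frequencies_converge_to_author_profile(self):
        # longer texts pin the type-mode ranked curve onto the ranked
        # author profile (up to the finite-lexicon floor)
        spec_small = SyntheticCorpusSpec(
            tokens_per_text=10_000, vocab_size=10_000, texts_per_author=1,
            authors=(("A", 0.7),), shared_vocab_fraction=0.0, seed=6,
        )
        spec_big = SyntheticCorpusSpec(
            tokens_per_text=1_000_000, vocab_size=10_000, texts_per_author=1,
            authors=(("A", 0.7),), shared_vocab_fraction=0.0, seed=6,
        )
        errs = {}
        for name, spec in (("small", spec_small), ("big", spec_big)):
            bundle = gen_corpus(spec)
            pc, _ = count_phonemes(bundle.texts["A1"], bundle.lexicon, "different_words")
            lf = normalize_frequencies(pc, bundle.truth.inventory)
            ranked = np.array(rank_frequencies(lf).f)
            target = -np.sort(-np.array(bundle.truth.author_profile["A"]))
            errs[name] = np.max(np.abs(ranked - target))
        assert errs["big"] < errs["small"]
        assert errs["big"] < 0.01
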