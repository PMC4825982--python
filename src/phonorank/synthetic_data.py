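"""Synthetic corpora with the statistical structure the analysis assumes.

The generator emulates the study conditions end to end so that every
pipeline stage is testable without external texts:

- each author has a phoneme profile θ^(a): one draw from a symmetric
  Dirichlet with an author-specific concentration β ∈ (0.5, 1) over an
  inventory of n ≈ 44 phonemes;
- a lexicon of synthetic words whose pronunciations are built by drawing
  each phoneme independently from the relevant profile, with word lengths
  from a truncated geometric distribution (mean ≈ 3.5 phonemes, the
  empirical phonemes-per-word scale of English novels);
- word-token usage follows a Zipf–Mandelbrot law over the author's
  vocabulary, which is a shared global block plus an author-specific block;
- texts of order 10^5 word tokens.

Phonemes within a word are drawn independently from the profile: no
phonotactics.  Independence is the minimal structure under which the
expected ranked phoneme frequencies of a text equal the ranked author
profile, which is exactly the generative link the Dirichlet fit assumes.
All generators are pure functions of (spec, seed).
"""

from __future__ import annotations

import json
import string
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .corpus_phonemizer import Lexicon, TokenSequence

__all__ = [
    "SyntheticCorpusSpec",
    "GroundTruth",
    "CorpusBundle",
    "default_inventory",
    "gen_author_profile",
    "gen_lexicon",
    "gen_text",
    "gen_corpus",
]

# 44-symbol RP-style English phoneme inventory (20 vowels + 24 consonants).
# A repo convention for the default n = 44, not a normative list.
RP_INVENTORY: tuple[str, ...] = (
    "iː", "ɪ", "e", "æ", "ʌ", "ɑː", "ɒ", "ɔː", "ʊ", "uː", "ɜː", "ə",
    "eɪ", "aɪ", "ɔɪ", "aʊ", "əʊ", "ɪə", "eə", "ʊə",
    "p", "b", "t", "d", "k", "g", "tʃ", "dʒ", "f", "v", "θ", "ð",
    "s", "z", "ʃ", "ʒ", "h", "m", "n", "ŋ", "l", "r", "w", "j",
)


def default_inventory(n: int) -> tuple[str, ...]:
    """First ``n`` symbols of the RP-style set, extended as ph45, ph46, …"""
    if n <= len(RP_INVENTORY):
        return RP_INVENTORY[:n]
    return RP_INVENTORY + tuple(f"ph{k}" for k in range(len(RP_INVENTORY) + 1, n + 1))


@dataclass(frozen=True)
class SyntheticCorpusSpec:
    """Study conditions for one synthetic corpus.

    Defaults mirror the benchmark scale: 3 authors × 3 texts, 44 phonemes,
    β values 0.6/0.7/0.8, ~10^5 word tokens per text, vocabularies of a few
    thousand types with roughly a third of the vocabulary shared between
    authors, Zipfian token usage with exponent 1.
    """

    n_phonemes: int = 44
    authors: tuple[tuple[str, float], ...] = (("A", 0.6), ("B", 0.7), ("C", 0.8))
    texts_per_author: int = 3
    tokens_per_text: int = 100_000
    vocab_size: int = 8000
    zipf_exponent: float = 1.0
    mandelbrot_shift: float = 2.7
    shared_vocab_fraction: float = 0.33
    typicality_strength: float = 0.2
    rank_jitter_sigma: float = 0.25
    word_length_mean: float = 3.5
    word_length_max: int = 12
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_phonemes < 1 or self.texts_per_author < 1 or self.tokens_per_text < 1:
            raise ValueError("counts must be positive")
        if self.vocab_size < 2 or self.word_length_max < 1:
            raise ValueError("counts must be positive")
        if not (self.zipf_exponent > 0):
            raise ValueError("zipf_exponent must be > 0")
        if not (0.0 <= self.shared_vocab_fraction <= 1.0):
            raise ValueError("shared_vocab_fraction must be in [0, 1]")
        if not all(b > 0 for _, b in self.authors):
            raise ValueError("author beta values must be > 0")
        if not (1.0 < self.word_length_mean <= self.word_length_max):
            raise ValueError("word_length_mean must lie in (1, word_length_max]")


@dataclass(frozen=True)
class GroundTruth:
    """What the generator actually used: per-author β and profile, and the
    author of every text."""

    author_beta: Mapping[str, float]
    author_profile: Mapping[str, tuple[float, ...]]
    text_author: Mapping[str, str]
    inventory: tuple[str, ...]

    def to_json(self) -> str:
        return json.dumps(
            {
                "author_beta": dict(self.author_beta),
                "author_profile": {a: list(p) for a, p in self.author_profile.items()},
                "text_author": dict(self.text_author),
                "inventory": list(self.inventory),
            },
            indent=2,
        )


@dataclass(frozen=True)
class CorpusBundle:
    spec: SyntheticCorpusSpec
    texts: Mapping[str, TokenSequence]
    lexicon: Lexicon
    truth: GroundTruth


def gen_author_profile(n: int, beta: float, seed: int) -> np.ndarray:
    """One symmetric Dirichlet(β) draw: an author's phoneme profile."""
    if n < 1 or not (beta > 0):
        raise ValueError("need n >= 1 and beta > 0")
    rng = np.random.default_rng(seed)
    g = rng.gamma(beta, size=n)
    return g / g.sum()


def _word_lengths(rng: np.random.Generator, size: int, mean: float, lmax: int) -> np.ndarray:
    # Truncated geometric on 1..lmax with success probability 1/mean.
    q = 1.0 / mean
    lengths = np.arange(1, lmax + 1)
    pmf = (1 - q) ** (lengths - 1) * q
    pmf /= pmf.sum()
    return rng.choice(lengths, size=size, p=pmf)


_LETTERS = string.ascii_lowercase


def _word_key(prefix: str, k: int) -> str:
    # Deterministic unique letter-only orthographic keys (tokenizer-safe).
    digits = []
    k += 1
    while k:
        k, rem = divmod(k - 1, 26)
        digits.append(_LETTERS[rem])
    return prefix + "".join(reversed(digits))


def gen_lexicon(
    spec: SyntheticCorpusSpec,
    profile: np.ndarray,
    seed: int,
    n_words: int | None = None,
    prefix: str = "w",
) -> Lexicon:
    """Synthetic pronunciation lexicon drawn from one phoneme profile.

    Each of the ``n_words`` (default ``spec.vocab_size``) words gets a
    length from the truncated geometric law and that many phonemes drawn
    i.i.d. from ``profile``.
    """
    n_words = spec.vocab_size if n_words is None else n_words
    inventory = default_inventory(spec.n_phonemes)
    profile = np.asarray(profile, dtype=float)
    if profile.shape != (spec.n_phonemes,):
        raise ValueError("profile length must equal n_phonemes")
    rng = np.random.default_rng(seed)
    lengths = _word_lengths(rng, n_words, spec.word_length_mean, spec.word_length_max)
    draws = rng.choice(len(inventory), size=int(lengths.sum()), p=profile)
    entries = {}
    pos = 0
    for k, length in enumerate(lengths):
        entries[_word_key(prefix, k)] = tuple(inventory[i] for i in draws[pos : pos + length])
        pos += length
    return Lexicon(entries=entries, inventory=frozenset(inventory))


def gen_text(
    words_ranked: Sequence[str],
    spec: SyntheticCorpusSpec,
    seed: int,
    source_id: str = "",
) -> TokenSequence:
    """Zipf–Mandelbrot token sampling over a rank-ordered vocabulary.

    P(rank k) ∝ (k + q)^(−a) with a = ``spec.zipf_exponent`` and
    q = ``spec.mandelbrot_shift``; ``words_ranked[0]`` is rank 1.
    """
    ranks = np.arange(1, len(words_ranked) + 1, dtype=float)
    p = (ranks + spec.mandelbrot_shift) ** (-spec.zipf_exponent)
    p /= p.sum()
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(words_ranked), size=spec.tokens_per_text, p=p)
    words = np.asarray(words_ranked, dtype=object)
    return TokenSequence(tokens=tuple(words[idx]), source_id=source_id)


def gen_corpus(spec: SyntheticCorpusSpec, outdir: str | Path | None = None) -> CorpusBundle:
    """Full synthetic corpus: lexicon, texts and ground truth.

    Author profiles are built by gamma additivity so that vocabulary sharing
    does not distort the Dirichlet link: one common gamma vector
    C ~ Gamma(c, 1)^n with c = shared_vocab_fraction · β̄ is shared by all
    authors, each author adds an independent O_a ~ Gamma(β_a − c, 1)^n, and
    the author profile θ^(a) ∝ C + O_a is then *exactly* a symmetric
    Dirichlet(β_a) draw.  The shared vocabulary block (``shared_vocab_fraction
    × vocab_size`` words) is pronounced from C/ΣC and each author-specific
    block from O_a/ΣO_a, so the author's pooled lexicon reproduces θ^(a)
    (up to the fixed word-count split standing in for the realized gamma
    mass split — a small tilt, not a flattening).

    Zipf ranks encode the empirical regularity that frequent words are made
    of frequent phonemes: each author orders the vocabulary by a noisy
    phoneme-typicality score (mean log-probability of the word's phonemes
    under the author profile, weighted by ``typicality_strength``), so token
    weighting systematically amplifies the author's high-frequency phonemes
    — which is what makes token-mode (all-words) fits rougher, hence lower
    in β, than type-mode (different-words) fits.  Each text additionally
    perturbs the author ordering with multiplicative log-normal rank jitter
    (``rank_jitter_sigma``), standing in for text-specific key-words.

    With ``outdir`` set, writes one ``<text_id>.txt`` per text, the merged
    ``lexicon.tsv`` and ``ground_truth.json``.
    """
    root = np.random.SeedSequence(spec.seed)
    n_authors = len(spec.authors)
    seeds = root.spawn(2 + 2 * n_authors + 2 * n_authors * spec.texts_per_author)
    seed_ints = [int(s.generate_state(1)[0] % (2**31)) for s in seeds]
    it = iter(seed_ints)

    betas = np.array([b for _, b in spec.authors], dtype=float)
    shared_conc = spec.shared_vocab_fraction * float(betas.mean())
    if shared_conc >= betas.min():
        raise ValueError(
            "shared_vocab_fraction * mean(beta) must stay below every author "
            f"beta (got common concentration {shared_conc:.3f} vs min beta "
            f"{betas.min():.3f}); lower shared_vocab_fraction"
        )

    n_shared = int(round(spec.shared_vocab_fraction * spec.vocab_size))
    n_own = spec.vocab_size - n_shared
    common_rng = np.random.default_rng(next(it))
    if shared_conc > 0 and n_shared > 0:
        common_gamma = common_rng.gamma(shared_conc, size=spec.n_phonemes)
        shared_lex = gen_lexicon(
            spec, common_gamma / common_gamma.sum(), next(it), n_words=n_shared, prefix="s"
        )
    else:
        common_gamma = np.zeros(spec.n_phonemes)
        next(it)  # keep the seed stream layout independent of this branch
        shared_lex = None

    author_beta: dict[str, float] = {}
    author_profile: dict[str, tuple[float, ...]] = {}
    author_words: dict[str, list[str]] = {}
    entries = dict(shared_lex.entries) if shared_lex is not None else {}
    for name, beta in spec.authors:
        own_rng = np.random.default_rng(next(it))
        own_gamma = own_rng.gamma(beta - shared_conc, size=spec.n_phonemes)
        total = common_gamma + own_gamma
        profile = total / total.sum()
        author_beta[name] = float(beta)
        author_profile[name] = tuple(profile)
        own = gen_lexicon(
            spec, own_gamma / own_gamma.sum(), next(it), n_words=n_own, prefix=f"{name.lower()}x"
        )
        entries.update(own.entries)
        words = (list(shared_lex.entries) if shared_lex else []) + list(own.entries)
        # Frequent words are made of frequent phonemes: rank by noisy
        # phoneme-typicality under the author profile (higher score = lower
        # rank index = more frequent).
        logp = np.log(np.maximum(profile, 1e-300))
        sym_index = {s: k for k, s in enumerate(default_inventory(spec.n_phonemes))}
        score = np.array(
            [np.mean([logp[sym_index[ph]] for ph in entries[w]]) for w in words]
        )
        if score.std() > 0:
            score = (score - score.mean()) / score.std()
        key = spec.typicality_strength * score + own_rng.standard_normal(len(words))
        author_words[name] = [words[i] for i in np.argsort(-key)]

    lexicon = Lexicon(entries=entries, inventory=frozenset(default_inventory(spec.n_phonemes)))

    texts: dict[str, TokenSequence] = {}
    text_author: dict[str, str] = {}
    for name, _ in spec.authors:
        base = np.asarray(author_words[name], dtype=object)
        for t in range(1, spec.texts_per_author + 1):
            text_id = f"{name}{t}"
            jitter_rng = np.random.default_rng(next(it))
            keys = np.arange(1, len(base) + 1) * np.exp(
                spec.rank_jitter_sigma * jitter_rng.standard_normal(len(base))
            )
            ranked = base[np.argsort(keys)]
            texts[text_id] = gen_text(ranked, spec, next(it), source_id=text_id)
            text_author[text_id] = name

    truth = GroundTruth(
        author_beta=author_beta,
        author_profile=author_profile,
        text_author=text_author,
        inventory=default_inventory(spec.n_phonemes),
    )
    bundle = CorpusBundle(spec=spec, texts=texts, lexicon=lexicon, truth=truth)

    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for text_id, seq in texts.items():
            (outdir / f"{text_id}.txt").write_text(" ".join(seq.tokens) + "\n", encoding="utf-8")
        with (outdir / "lexicon.tsv").open("w", encoding="utf-8") as fh:
            for w, pron in sorted(lexicon.entries.items()):
                fh.write(f"{w}\t{' '.join(pron)}\n")
        (outdir / "ground_truth.json").write_text(truth.to_json(), encoding="utf-8")
    return bundle
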