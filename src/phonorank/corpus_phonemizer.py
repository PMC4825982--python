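"""Text → phoneme frequency vectors via a pronunciation lexicon.

Transcription is pure dictionary lookup: a word either is in the lexicon and
contributes its phoneme sequence, or it is out-of-vocabulary (OOV) and is
skipped and reported.  Two word-selection modes are supported:

``all_words``
    every word token contributes its phonemes (token mode);
``different_words``
    each distinct word type contributes once, however often it occurs
    (type mode).

Frequencies are kept as exact count ratios until the distance/fit stages.
"""

from __future__ import annotations

import logging
import re
import unicodedata
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

logger = logging.getLogger(__name__)

__all__ = [
    "TokenizerRules",
    "Lexicon",
    "TokenSequence",
    "PhonemeCounts",
    "CorpusStats",
    "LabeledFrequencies",
    "RankedFrequencyVector",
    "tokenize",
    "load_lexicon",
    "count_phonemes",
    "exclude_common_words",
    "normalize_frequencies",
    "rank_frequencies",
]

_APOSTROPHES = "’ʼ"  # curly / modifier apostrophes → '
_DASHES = "‐‑‒–—―"


@dataclass(frozen=True)
class TokenizerRules:
    """Word normalization: lowercase; letters only, with optional internal
    apostrophes; hyphens/dashes either split words or are kept as joiners."""

    keep_apostrophes: bool = True
    split_hyphens: bool = True


@dataclass(frozen=True)
class TokenSequence:
    tokens: tuple[str, ...]
    source_id: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "tokens", tuple(self.tokens))

    def __len__(self) -> int:
        return len(self.tokens)

    def types(self) -> set[str]:
        return set(self.tokens)


@dataclass(frozen=True)
class Lexicon:
    """Pronunciation dictionary: normalized word → phoneme sequence."""

    entries: Mapping[str, tuple[str, ...]]
    inventory: frozenset[str] = field(default=frozenset())

    def __post_init__(self) -> None:
        entries = {w: tuple(p) for w, p in dict(self.entries).items()}
        for w, pron in entries.items():
            if not pron:
                raise ValueError(f"empty phoneme sequence for word {w!r}")
        derived = frozenset(ph for pron in entries.values() for ph in pron)
        inv = frozenset(self.inventory) | derived if self.inventory else derived
        object.__setattr__(self, "entries", entries)
        object.__setattr__(self, "inventory", inv)

    def __contains__(self, word: str) -> bool:
        return word in self.entries

    def __len__(self) -> int:
        return len(self.entries)

    def __getitem__(self, word: str) -> tuple[str, ...]:
        return self.entries[word]


@dataclass(frozen=True)
class PhonemeCounts:
    counts: Mapping[str, int]
    mode: str
    oov: tuple[tuple[str, int], ...] = ()

    def __post_init__(self) -> None:
        if self.mode not in ("all_words", "different_words"):
            raise ValueError(f"unknown mode {self.mode!r}")
        object.__setattr__(self, "counts", dict(self.counts))
        object.__setattr__(self, "oov", tuple(self.oov))

    @property
    def total(self) -> int:
        return sum(self.counts.values())


@dataclass(frozen=True)
class CorpusStats:
    """Token/type bookkeeping over the in-lexicon part of one text.

    ``n_tw``: word tokens; ``n_pht``: phonemes over all tokens;
    ``n_dw``: distinct word types; ``n_phd``: phonemes over distinct types.
    """

    n_tw: int
    n_pht: int
    n_dw: int
    n_phd: int

    def __post_init__(self) -> None:
        for name in ("n_tw", "n_pht", "n_dw", "n_phd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.n_dw > self.n_tw or self.n_phd > self.n_pht:
            raise ValueError("type-level counts cannot exceed token-level counts")

    def to_dict(self) -> dict[str, int]:
        return {"N_tw": self.n_tw, "N_pht": self.n_pht, "N_dw": self.n_dw, "N_phd": self.n_phd}


@dataclass(frozen=True)
class LabeledFrequencies:
    """Relative phoneme frequencies keyed by symbol; sums to 1."""

    freq: Mapping[str, float]
    source_id: str = ""

    def __post_init__(self) -> None:
        freq = dict(self.freq)
        if any(v < 0 for v in freq.values()):
            raise ValueError("frequencies must be non-negative")
        total = sum(freq.values())
        if abs(total - 1.0) > 1e-12:
            raise ValueError(f"frequencies must sum to 1, got {total!r}")
        object.__setattr__(self, "freq", freq)

    def __getitem__(self, symbol: str) -> float:
        return self.freq.get(symbol, 0.0)


@dataclass(frozen=True)
class RankedFrequencyVector:
    """Descending frequencies f_1 ≥ … ≥ f_n of one text."""

    f: tuple[float, ...]

    def __post_init__(self) -> None:
        f = tuple(float(x) for x in self.f)
        if any(x < 0 for x in f):
            raise ValueError("frequencies must be non-negative")
        if any(f[i] < f[i + 1] for i in range(len(f) - 1)):
            raise ValueError("frequencies must be non-increasing")
        if abs(sum(f) - 1.0) > 1e-12:
            raise ValueError("frequencies must sum to 1")
        object.__setattr__(self, "f", f)

    @property
    def n(self) -> int:
        return len(self.f)

    def as_array(self):
        import numpy as np

        return np.asarray(self.f)


def tokenize(text: str, rules: TokenizerRules = TokenizerRules(), source_id: str = "") -> TokenSequence:
    """Split raw text into normalized lowercase word tokens.

    Digits and punctuation are discarded; internal apostrophes are kept when
    ``rules.keep_apostrophes``; hyphens/dashes split words when
    ``rules.split_hyphens`` and otherwise join their parts.
    """
    text = unicodedata.normalize("NFC", text).lower()
    for ch in _APOSTROPHES:
        text = text.replace(ch, "'")
    if rules.split_hyphens:
        text = re.sub(f"[-{_DASHES}]", " ", text)
    else:
        text = re.sub(f"[{_DASHES}]", "-", text)
    word = r"[^\W\d_]+"
    if rules.keep_apostrophes and not rules.split_hyphens:
        pattern = rf"{word}(?:['-]{word})*"
    elif rules.keep_apostrophes:
        pattern = rf"{word}(?:'{word})*"
    elif not rules.split_hyphens:
        pattern = rf"{word}(?:-{word})*"
    else:
        pattern = word
    tokens = re.findall(pattern, text)
    return TokenSequence(tokens=tuple(tokens), source_id=source_id)


class LexiconParseError(ValueError):
    pass


def load_lexicon(path: str | Path) -> Lexicon:
    """Read a flat-file pronunciation lexicon.

    One entry per line: ``WORD<TAB>PH1 PH2 … PHk`` (whitespace-separated
    phonemes also accepted after the first tab); ``;;;`` starts a comment.
    Duplicate words keep the first pronunciation, with a logged warning.
    """
    path = Path(path)
    entries: dict[str, tuple[str, ...]] = {}
    with path.open(encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith(";;;"):
                continue
            if "\t" in line:
                word, _, pron = line.partition("\t")
            else:
                word, _, pron = line.partition(" ")
            word = word.strip().lower()
            phones = tuple(pron.split())
            if not word or not phones:
                raise LexiconParseError(
                    f"{path.name}:{lineno}: malformed lexicon line (need WORD<TAB>PHONEMES): {line!r}"
                )
            if word in entries:
                logger.warning("%s:%d: duplicate entry for %r; keeping first", path.name, lineno, word)
                continue
            entries[word] = phones
    if not entries:
        raise LexiconParseError(f"{path}: no lexicon entries found")
    return Lexicon(entries=entries)


def count_phonemes(
    tokens: TokenSequence,
    lex: Lexicon,
    mode: str = "all_words",
    oov_warn_fraction: float = 0.05,
) -> tuple[PhonemeCounts, CorpusStats]:
    """Accumulate phoneme counts for one text under the requested word mode.

    OOV words are skipped and reported; if the OOV type fraction exceeds
    ``oov_warn_fraction`` a warning is logged (likely lexicon/corpus
    mismatch).  Raises ``ValueError`` when nothing is transcribable.
    """
    if mode not in ("all_words", "different_words"):
        raise ValueError(f"unknown mode {mode!r}")
    if len(lex) == 0:
        raise ValueError("lexicon is empty")

    token_counts = Counter(tokens.tokens)
    in_lex = {w: c for w, c in token_counts.items() if w in lex}
    oov = {w: c for w, c in token_counts.items() if w not in lex}
    if not in_lex:
        raise ValueError(f"no transcribable content in {tokens.source_id or 'input'}")
    if token_counts and len(oov) / len(token_counts) > oov_warn_fraction:
        logger.warning(
            "%s: %.1f%% of word types are out of lexicon (%d of %d)",
            tokens.source_id or "input",
            100 * len(oov) / len(token_counts),
            len(oov),
            len(token_counts),
        )

    counts: Counter[str] = Counter()
    n_pht = 0
    n_phd = 0
    for w, c in in_lex.items():
        pron = lex[w]
        n_pht += len(pron) * c
        n_phd += len(pron)
        weight = c if mode == "all_words" else 1
        for ph in pron:
            counts[ph] += weight
    stats = CorpusStats(
        n_tw=sum(in_lex.values()), n_pht=n_pht, n_dw=len(in_lex), n_phd=n_phd
    )
    pc = PhonemeCounts(
        counts=dict(counts),
        mode=mode,
        oov=tuple(sorted(oov.items(), key=lambda kv: (-kv[1], kv[0]))),
    )
    return pc, stats


def exclude_common_words(types_i: set[str], types_j: set[str]) -> tuple[set[str], set[str]]:
    """Remove the shared vocabulary from both word-type sets.

    Used for the ablation that asks whether author similarity survives once
    the words two texts have in common are discarded.
    """
    if not types_i or not types_j:
        raise ValueError("word-type sets must be non-empty")
    common = types_i & types_j
    only_i, only_j = types_i - common, types_j - common
    if not only_i or not only_j:
        raise ValueError("texts share entire vocabulary; nothing left after exclusion")
    return only_i, only_j


def normalize_frequencies(
    counts: PhonemeCounts, inventory: Iterable[str], source_id: str = ""
) -> LabeledFrequencies:
    """Counts → relative frequencies over a fixed inventory.

    Inventory symbols absent from the counts get frequency 0; a count for a
    symbol outside the inventory is an error.
    """
    inventory = set(inventory)
    extra = set(counts.counts) - inventory
    if extra:
        raise ValueError(f"counts contain symbols outside inventory: {sorted(extra)}")
    total = counts.total
    if total <= 0:
        raise ValueError("total phoneme count must be positive")
    freq = {sym: counts.counts.get(sym, 0) / total for sym in sorted(inventory)}
    return LabeledFrequencies(freq=freq, source_id=source_id)


def rank_frequencies(lf: LabeledFrequencies) -> RankedFrequencyVector:
    """Sort labeled frequencies into the descending ranked vector.

    Ties are broken by phoneme symbol (lexicographic) so the ranking is
    deterministic; length equals the inventory size.
    """
    ordered = sorted(lf.freq.items(), key=lambda kv: (-kv[1], kv[0]))
    return RankedFrequencyVector(f=tuple(v for _, v in ordered))
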