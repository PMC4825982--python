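"""Phonemize a tiny text with the bundled example lexicon and rank it.

Shows the token-mode vs type-mode distinction on a sentence where one word
repeats, then prints the ranked table the fitting stage consumes.
"""

import importlib.resources

from phonorank import count_phonemes, load_lexicon, normalize_frequencies, rank_frequencies, tokenize

lexicon = load_lexicon(importlib.resources.files("phonorank") / "data" / "example_lexicon.tsv")
text = "Row, row, row! The boy will row; the poor boy can only row."
tokens = tokenize(text)
print("tokens:", list(tokens.tokens))

for mode in ("all_words", "different_words"):
    counts, stats = count_phonemes(tokens, lexicon, mode)
    lf = normalize_frequencies(counts, lexicon.inventory)
    ranked = rank_frequencies(lf)
    top = sorted(lf.freq.items(), key=lambda kv: (-kv[1], kv[0]))[:5]
    print(f"\nmode={mode}: N_tw={stats.n_tw} N_pht={stats.n_pht} "
          f"N_dw={stats.n_dw} N_phd={stats.n_phd}")
    for rank, (sym, freq) in enumerate(top, start=1):
        print(f"  rank {rank}: /{sym}/  {freq:.4f}")
    assert abs(sum(ranked.f) - 1.0) < 1e-12

print("""
Reading: in token mode every occurrence of 'row' feeds /r/ and /əʊ/, so
those phonemes dominate; in type mode 'row' counts once and the profile
flattens — the same contrast the β fits pick up on full novels.""")
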