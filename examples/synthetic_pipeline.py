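"""End-to-end run on a ground-truthed synthetic corpus.

Generates three authors (true β = 0.6, 0.7, 0.8) with three texts each,
phonemizes every text in both word modes, fits β, and checks the author
separation the analysis is built to detect.  Scaled down from the study
defaults for a quick demonstration.
"""

from phonorank import (
    SyntheticCorpusSpec,
    cluster_gap,
    count_phonemes,
    distance_table,
    fit_beta,
    gen_corpus,
    normalize_frequencies,
    rank_frequencies,
)

spec = SyntheticCorpusSpec(tokens_per_text=30_000, vocab_size=3000, seed=0)
bundle = gen_corpus(spec)
print(f"corpus: {len(bundle.texts)} texts, lexicon of {len(bundle.lexicon)} words, "
      f"true beta = {bundle.truth.author_beta}")

betas = {"all_words": {}, "different_words": {}}
labeled = {}
for tid, seq in sorted(bundle.texts.items()):
    for mode in betas:
        counts, _ = count_phonemes(seq, bundle.lexicon, mode)
        lf = normalize_frequencies(counts, bundle.truth.inventory, source_id=tid)
        if mode == "different_words":
            labeled[tid] = lf
        betas[mode][tid] = fit_beta(rank_frequencies(lf)).beta_hat

print(f"\n{'text':>5} {'beta(types)':>12} {'beta(tokens)':>13}")
for tid in sorted(bundle.texts):
    print(f"{tid:>5} {betas['different_words'][tid]:>12.3f} {betas['all_words'][tid]:>13.3f}")

labels = dict(bundle.truth.text_author)
print("\nbeta gaps (type mode):",
      {a: round(cluster_gap(betas["different_words"], labels, a, "beta_gap"), 3)
       for a in bundle.truth.author_beta})

mats = {0: {}, 1: {}}
for rep in distance_table(labeled, mode="different_words"):
    mats[0][rep.pair] = rep.rho0
    mats[1][rep.pair] = rep.rho1
z = {(lam, a): cluster_gap(mats[lam], labels, a, "distance_gap")
     for lam in (0, 1) for a in bundle.truth.author_beta}
print("distance gaps positive:", sum(v > 0 for v in z.values()), "/", len(z),
      " min:", round(min(z.values()), 4))
direction = sum(betas["different_words"][t] > betas["all_words"][t] for t in bundle.texts)
print(f"texts with beta(types) > beta(tokens): {direction}/9")

print("""
Reading: within-author fitted β are tight and authors separate (positive
gaps), distances cluster by author, and token mode always fits a rougher,
lower β than type mode — frequent words over-sample their phonemes.""")
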