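# phonorank

Dirichlet order-statistics modelling of **phoneme rank-frequency relations**,
with author-comparison diagnostics for stylometry.

Word frequencies famously follow Zipf's author-independent power law, but the
ranked frequencies of *phonemes* behave differently: they are well described
by the order statistics of a symmetric Dirichlet density, and the single
concentration parameter β of that density — together with parameter-free
variational distances — carries a reproducible author signal.  `phonorank`
implements that analysis end to end for anyone who wants to profile phoneme
usage in text corpora: phonemization through a pronunciation lexicon, model
fitting, pairwise distances, author-cluster gap statistics, and a
ground-truthed synthetic-corpus generator for validation.

## The model

Treat the n phoneme frequencies of a text as a random probability vector
(θ₁, …, θₙ) with the symmetric Dirichlet density

    D(θ₁,…,θₙ | β) ∝ ∏ₖ θₖ^(β−1) · δ(Σₖ θₖ − 1),   β > 0.

Sorting the components, Θ₍₁₎ ≥ … ≥ Θ₍ₙ₎, gives the model's ranked curve.
Moments of Θ₍᙮₎ follow from the gamma representation: with φ(y) = P(β, y)
the regularized lower incomplete gamma function,

    ⟨θ₍ᵣ₎^m⟩ = Γ(nβ)/Γ(nβ+m) · ∫₀^∞ y^m · n!/((n−r)!(r−1)!) ·
               y^(β−1)e^(−y)/Γ(β) · φ(y)^(n−r) [1−φ(y)]^(r−1) dy.

A text's observed ranked frequencies f₁ ≥ … ≥ fₙ are fitted by minimizing
SS_err(β) = Σₖ (fₖ − f̂ₖ(β))² with f̂ᵣ = ⟨θ₍ᵣ₎⟩; R² between data and curve is
the goodness diagnostic.  Texts are compared by two total-variation
distances — ρ₁ on the sorted vectors (rank-aligned, coarse) and ρ₀ matched
by phoneme label (fine-grained, ρ₀ ≥ ρ₁) — and authors by *cluster gaps*:

    b(a)  = min cross-author |βᵢ − βₖ| − max within-author |βᵢ − βⱼ|
    z_λ(a) = min cross-author ρ_λ     − max within-author ρ_λ

A positive gap means the author's texts form a separated cluster.

## Worked example

Benchmark measurements for nine novels — three each by Austen (texts 1–3),
Dickens (4–6) and Tolkien (7–9) — ship with the package
(`phonorank.refdata`): fitted β per text and word mode, and pairwise
distances ×10⁵.  Running

```bash
python examples/benchmark_author_gaps.py
```

prints, among other lines,

```
beta cluster gaps b(a), token mode:
  b(A) = 0.02
  b(D) = 0.02
  b(T) = 0.00
...
positive gaps: 11/12, min = -0.00207
same-author distances larger in token mode: 17/18
  sole violation: rho0(7, 8), difference -0.00269
gaps still positive after removing each pair's common words: 6/6
```

Reading: each author's β values sit at least as close to one another as to
any other author's (gaps ≥ 0, with Tolkien exactly at the boundary); eleven
of the twelve distance gaps are positive, so the author clustering is
visible without any fitted parameter; and it survives the ablation that
removes the words any two texts share — the signal is not just vocabulary.

Other examples: `expected_curve_demo.py` (the model curve, its closed-form
approximation and per-rank fluctuations), `phonemize_and_fit.py`
(token-mode vs type-mode counting on a toy sentence),
`synthetic_pipeline.py` (full pipeline on a generated corpus with known
author β, recovering positive gaps and the types-above-tokens β direction).

## Command line

```bash
phonorank simulate --out corpus --seed 0            # synthetic corpus
phonorank phonemize corpus/*.txt --lexicon corpus/lexicon.tsv --out freqs
phonorank fit freqs/*.ranked.tsv                    # β, SS_err×10⁷, R² table
phonorank report corpus/*.txt --lexicon corpus/lexicon.tsv \
    --authors authors.yaml --out out                # distances, gaps, report
```

Lexicons are flat files, one `WORD<TAB>PH1 PH2 …` entry per line (`;;;`
comments); a small RP-style example lexicon is bundled under
`phonorank/data/`.  Out-of-lexicon words are skipped and reported.

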