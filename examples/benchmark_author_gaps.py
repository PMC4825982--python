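"""Author-clustering statistics on the published nine-novel measurements.

Feeds the packaged fitted β values and pairwise variational distances
(three novels each by Austen, Dickens and Tolkien) through the cluster-gap
and mode-comparison machinery.
"""

from phonorank import cluster_gap, mode_comparison_report
from phonorank import refdata

labels = dict(refdata.AUTHOR_OF)

print("beta cluster gaps b(a), token mode:")
for author in refdata.CLUSTERS:
    gap = cluster_gap(refdata.BETA_ALL_WORDS, labels, author, "beta_gap")
    print(f"  b({author[0]}) = {gap:.2f}")

print("\ndistance cluster gaps z_lambda(a):")
gaps = {}
for mode, table in (("all words", refdata.RHO_ALL_WORDS_X1E5),
                    ("diff words", refdata.RHO_DIFF_WORDS_X1E5)):
    for lam in (0, 1):
        for author in refdata.CLUSTERS:
            g = cluster_gap(refdata.rho_matrix(table, lam), labels, author, "distance_gap")
            gaps[(mode, lam, author)] = g
            print(f"  z{lam}[{mode}]({author[0]}) = {g:+.5f}")
print(f"positive gaps: {sum(v > 0 for v in gaps.values())}/12, min = {min(gaps.values()):+.5f}")

report = mode_comparison_report(
    refdata.distance_reports(refdata.RHO_ALL_WORDS_X1E5, "all_words"),
    refdata.distance_reports(refdata.RHO_DIFF_WORDS_X1E5, "different_words"),
    refdata.distance_reports(refdata.RHO_NO_COMMON_X1E5, "no_common_words"),
    refdata.BETA_ALL_WORDS, refdata.BETA_DIFF_WORDS, labels,
    same_author_pairs=refdata.SAME_AUTHOR_PAIRS,
)
fam = report["token_mode_same_author_distance_larger"]
print(f"\nsame-author distances larger in token mode: {fam['holding']}/{fam['total']}")
for v in fam["violations"]:
    lam, pair = v.instance
    print(f"  sole violation: rho{lam}{pair}, difference {v.difference:+.5f}")
fam = report["ablation_z_gap_positive"]
print(f"gaps still positive after removing each pair's common words: "
      f"{fam['holding']}/{fam['total']}")

print("""
Reading: positive gaps mean each author's texts sit closer to one another
than to any other author's text under that statistic — the author signal.
It survives the common-word ablation, so shared vocabulary alone does not
explain it.""")
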