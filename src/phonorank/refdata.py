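"""Published reference measurements for a nine-novel benchmark corpus.

The corpus: three novels each by Jane Austen (texts 1–3: *Mansfield Park*,
*Pride and Prejudice*, *Sense and Sensibility*), Charles Dickens (4–6:
*A Tale of Two Cities*, *Great Expectations*, *Oliver Twist*) and J. R. R.
Tolkien (7–9: *The Fellowship of the Ring*, *The Return of the King*,
*The Two Towers*), phonemized over a 44-symbol English inventory.

These are the printed study values — fitted Dirichlet concentrations β per
text and word mode, pairwise variational distances (×10^5, as published),
and shared-vocabulary fractions.  They serve as worked-example inputs for
the gap and mode-comparison statistics: the original novel texts are not
distributed, so the statistics that need only these summary numbers are the
reproducible surface.

Distances are stored as the printed ×10^5 integers; divide by 1e5 (or use
:func:`rho_matrix`) for the dimensionless values.
"""

from __future__ import annotations

__all__ = [
    "TEXTS",
    "AUTHOR_OF",
    "CLUSTERS",
    "CORPUS_STATS",
    "BETA_ALL_WORDS",
    "BETA_DIFF_WORDS",
    "SSERR_X1E7_ALL_WORDS",
    "SSERR_X1E7_DIFF_WORDS",
    "R2_ALL_WORDS",
    "R2_DIFF_WORDS",
    "RHO_ALL_WORDS_X1E5",
    "RHO_DIFF_WORDS_X1E5",
    "RHO_NO_COMMON_X1E5",
    "COMMON_WORD_P_X1E5",
    "SAME_AUTHOR_PAIRS",
    "rho_matrix",
    "distance_reports",
]

TEXTS = {
    1: "MP", 2: "PP", 3: "SS",   # Austen
    4: "TC", 5: "GE", 6: "OT",   # Dickens
    7: "FR", 8: "TT", 9: "RK",   # Tolkien
}

AUTHOR_OF = {i: ("Austen" if i <= 3 else "Dickens" if i <= 6 else "Tolkien") for i in TEXTS}
CLUSTERS = {"Austen": (1, 2, 3), "Dickens": (4, 5, 6), "Tolkien": (7, 8, 9)}
SAME_AUTHOR_PAIRS = tuple(
    (i, j) for ids in CLUSTERS.values() for i in ids for j in ids if i < j
)

# Per text: total word tokens, phonemes over tokens, distinct word types,
# phonemes over distinct types.
CORPUS_STATS = {
    1: {"N_tw": 160473, "N_pht": 567750, "N_dw": 7854, "N_phd": 48747},
    2: {"N_tw": 121763, "N_pht": 435322, "N_dw": 6385, "N_phd": 39767},
    3: {"N_tw": 119394, "N_pht": 425822, "N_dw": 6264, "N_phd": 38668},
    4: {"N_tw": 135420, "N_pht": 468642, "N_dw": 9841, "N_phd": 58760},
    5: {"N_tw": 186683, "N_pht": 623079, "N_dw": 10933, "N_phd": 65364},
    6: {"N_tw": 159103, "N_pht": 555372, "N_dw": 10359, "N_phd": 61072},
    7: {"N_tw": 177227, "N_pht": 617106, "N_dw": 8644, "N_phd": 46509},
    8: {"N_tw": 143436, "N_pht": 502303, "N_dw": 7676, "N_phd": 39823},
    9: {"N_tw": 134462, "N_pht": 431141, "N_dw": 7087, "N_phd": 36494},
}

BETA_ALL_WORDS = {1: 0.61, 2: 0.63, 3: 0.61, 4: 0.67, 5: 0.69, 6: 0.69,
                  7: 0.75, 8: 0.74, 9: 0.79}
BETA_DIFF_WORDS = {1: 0.72, 2: 0.69, 3: 0.69, 4: 0.77, 5: 0.78, 6: 0.79,
                   7: 0.968, 8: 0.979, 9: 0.975}

SSERR_X1E7_ALL_WORDS = {1: 7696, 2: 7574, 3: 6151, 4: 4317, 5: 5287, 6: 3993,
                        7: 4196, 8: 4337, 9: 3580}
SSERR_X1E7_DIFF_WORDS = {1: 5150, 2: 4495, 3: 5003, 4: 6107, 5: 5265, 6: 5220,
                         7: 11296, 8: 12943, 9: 10366}

R2_ALL_WORDS = {1: 0.9768, 2: 0.9765, 3: 0.9816, 4: 0.9859, 5: 0.9820,
                6: 0.9867, 7: 0.9844, 8: 0.9842, 9: 0.9860}
R2_DIFF_WORDS = {1: 0.9818, 2: 0.9847, 3: 0.9829, 4: 0.9771, 5: 0.9800,
                 6: 0.9800, 7: 0.9501, 8: 0.9403, 9: 0.9525}

# Pairwise distances ×10^5: pair -> (rho0, rho1).  Token mode (all words).
RHO_ALL_WORDS_X1E5 = {
    (1, 2): (3045, 2227), (1, 3): (2062, 1602), (2, 3): (2549, 2103),
    (4, 5): (3423, 2100), (4, 6): (2382, 1978), (5, 6): (3448, 2753),
    (7, 8): (2584, 1808), (7, 9): (2066, 1809), (8, 9): (2464, 2037),
    (1, 4): (3583, 2784), (1, 5): (4690, 3044), (1, 6): (4000, 3260),
    (1, 7): (7372, 5149), (1, 8): (7402, 5227), (1, 9): (7322, 5599),
    (2, 4): (3645, 2712), (2, 5): (4762, 3059), (2, 6): (4064, 3110),
    (2, 7): (7653, 4978), (2, 8): (7629, 5052), (2, 9): (7650, 5449),
    (3, 4): (3562, 2546), (3, 5): (4924, 3022), (3, 6): (4358, 3181),
    (3, 7): (7737, 5266), (3, 8): (6950, 5085), (3, 9): (7447, 5654),
    (4, 7): (5174, 3950), (4, 8): (5327, 3568), (4, 9): (5061, 3935),
    (5, 7): (6113, 3894), (5, 8): (6436, 4014), (5, 9): (6217, 4325),
    (6, 7): (5074, 3727), (6, 8): (5706, 3934), (6, 9): (5202, 3770),
}

# Type mode (different words).
RHO_DIFF_WORDS_X1E5 = {
    (1, 2): (1563, 1346), (1, 3): (1317, 1205), (2, 3): (1413, 1346),
    (4, 5): (1568, 1266), (4, 6): (1380, 1126), (5, 6): (1100, 1052),
    (7, 8): (2853, 1653), (7, 9): (1946, 1476), (8, 9): (2025, 1569),
    (1, 4): (2296, 1967), (1, 5): (2703, 2110), (1, 6): (2868, 2470),
    (1, 7): (7430, 6103), (1, 8): (9535, 7200), (1, 9): (8434, 6775),
    (2, 4): (2839, 2252), (2, 5): (3318, 2436), (2, 6): (3458, 2709),
    (2, 7): (8141, 6587), (2, 8): (9999, 7544), (2, 9): (9167, 7136),
    (3, 4): (2718, 2193), (3, 5): (3264, 2486), (3, 6): (3257, 2636),
    (3, 7): (7943, 6539), (3, 8): (9998, 7447), (3, 9): (8997, 7022),
    (4, 7): (5918, 4795), (4, 8): (7875, 5971), (4, 9): (6899, 5368),
    (5, 7): (5521, 4631), (5, 8): (7842, 5566), (5, 9): (6646, 5222),
    (6, 7): (5595, 4486), (6, 8): (7785, 5645), (6, 9): (6786, 5201),
}

# Type mode after removing each pair's shared words (ablation).
RHO_NO_COMMON_X1E5 = {
    (1, 2): (3792, 2832), (1, 3): (3217, 2463), (2, 3): (3734, 2502),
    (4, 5): (3146, 2190), (4, 6): (2930, 2215), (5, 6): (2329, 1610),
    (7, 8): (5918, 3317), (7, 9): (4421, 2773), (8, 9): (4770, 2809),
    (1, 4): (4758, 3912), (1, 5): (5742, 4276), (1, 6): (6087, 4830),
    (1, 7): (12574, 8800), (1, 8): (15119, 9576), (1, 9): (13490, 8895),
    (2, 4): (5708, 4529), (2, 5): (6385, 4991), (2, 6): (6880, 5495),
    (2, 7): (13323, 9469), (2, 8): (15733, 10387), (2, 9): (14113, 9621),
    (3, 4): (5188, 4344), (3, 5): (5887, 4917), (3, 6): (6476, 5285),
    (3, 7): (13391, 9835), (3, 8): (15842, 10637), (3, 9): (14244, 9891),
    (4, 7): (10980, 7025), (4, 8): (13905, 7371), (4, 9): (12109, 6928),
    (5, 7): (10346, 6537), (5, 8): (13003, 7021), (5, 9): (11673, 6673),
    (6, 7): (10413, 6580), (6, 8): (13288, 6667), (6, 9): (11911, 6433),
}

# Shared-vocabulary fraction p ×10^5 per text pair.
COMMON_WORD_P_X1E5 = {
    (1, 2): 47554, (1, 3): 47786, (2, 3): 50655,
    (4, 5): 41146, (4, 6): 42454, (5, 6): 41822,
    (7, 8): 45010, (7, 9): 46948, (8, 9): 48173,
    (1, 4): 35592, (1, 5): 35819, (1, 6): 36660,
    (1, 7): 28978, (1, 8): 25870, (1, 9): 26730,
    (2, 4): 32902, (2, 5): 32499, (2, 6): 33877,
    (2, 7): 26549, (2, 8): 24180, (2, 9): 24643,
    (3, 4): 33463, (3, 5): 32813, (3, 6): 34643,
    (3, 7): 27572, (3, 8): 25340, (3, 9): 25733,
    (4, 7): 33901, (4, 8): 30387, (4, 9): 32005,
    (5, 7): 32069, (5, 8): 27963, (5, 9): 29994,
    (6, 7): 32002, (6, 8): 28649, (6, 9): 30518,
}


def rho_matrix(table: dict, lam: int) -> dict:
    """One distance index of a printed table, as dimensionless values.

    ``lam=0`` selects ρ0 (label-aligned), ``lam=1`` ρ1 (rank-aligned).
    """
    if lam not in (0, 1):
        raise ValueError("lam must be 0 or 1")
    return {pair: v[lam] / 1e5 for pair, v in table.items()}


def distance_reports(table: dict, mode: str = "") -> list:
    """A printed table as a list of :class:`~phonorank.comparison.DistanceReport`."""
    from .comparison import DistanceReport

    return [
        DistanceReport(pair=pair, rho0=v[0] / 1e5, rho1=v[1] / 1e5, mode=mode)
        for pair, v in table.items()
    ]
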