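"""Distances between texts' phoneme frequencies and author-cluster gaps.

Two total-variation (variational) distances are used:

ρ1 — rank-aligned: half the L1 distance between the two *sorted* frequency
vectors.  Coarse-grained: any relabeling of phonemes leaves it unchanged.

ρ0 — label-aligned: half the L1 distance between frequencies matched by
phoneme symbol.  Fine-grained; ρ0 ≥ ρ1 always, because sorting minimizes the
L1 mismatch over label permutations.  ρ0 also equals the largest probability
discrepancy max_Ω |Σ_{α∈Ω}(p_α − q_α)| over composite events Ω.

Author clustering is quantified by gap statistics: for a cluster of texts by
one author, the minimum cross-cluster value minus the maximum within-cluster
value of either the fitted β (``beta_gap``) or a pairwise distance
(``distance_gap``).  A positive gap means the author's texts form a separated
cluster under that statistic.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Hashable, Mapping, Sequence

import numpy as np

from .corpus_phonemizer import LabeledFrequencies, RankedFrequencyVector

__all__ = [
    "DistanceReport",
    "ClusterGapReport",
    "CommonWordStats",
    "InequalityRecord",
    "rho1",
    "rho0",
    "common_word_fraction",
    "cluster_gap",
    "all_cluster_gaps",
    "distance_table",
    "inequality_family",
    "mode_comparison_report",
]

TextId = Hashable


@dataclass(frozen=True)
class DistanceReport:
    pair: tuple
    rho0: float
    rho1: float
    mode: str = ""

    def __post_init__(self) -> None:
        if not (0.0 <= self.rho1 <= self.rho0 + 1e-12 and self.rho0 <= 1.0 + 1e-12):
            raise ValueError("distances must satisfy 0 <= rho1 <= rho0 <= 1")

    def scaled(self) -> dict:
        """Distances ×10^5 rounded to integers (the conventional table form)."""
        return {"rho0_x1e5": round(self.rho0 * 1e5), "rho1_x1e5": round(self.rho1 * 1e5)}


@dataclass(frozen=True)
class ClusterGapReport:
    gaps: Mapping[Hashable, float]
    kind: str  # "beta_gap" or "distance_gap"
    lam: int | None = None  # distance index (0 or 1) for distance gaps
    mode: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "gaps", dict(self.gaps))


@dataclass(frozen=True)
class CommonWordStats:
    """Shared-vocabulary fraction p = n_ij / (n_i + n_j − n_ij)."""

    n_i: int
    n_j: int
    n_ij: int

    @property
    def p(self) -> float:
        return self.n_ij / (self.n_i + self.n_j - self.n_ij)


@dataclass(frozen=True)
class InequalityRecord:
    instance: tuple
    left: float
    right: float

    @property
    def holds(self) -> bool:
        return self.left > self.right

    @property
    def difference(self) -> float:
        return self.left - self.right


def rho1(fi, fj) -> float:
    """Rank-aligned variational distance between two ranked vectors."""
    a = fi.as_array() if isinstance(fi, RankedFrequencyVector) else np.asarray(fi, float)
    b = fj.as_array() if isinstance(fj, RankedFrequencyVector) else np.asarray(fj, float)
    if a.shape != b.shape:
        raise ValueError(f"length mismatch: {a.shape} vs {b.shape}")
    return float(0.5 * np.abs(a - b).sum())


def rho0(fi: LabeledFrequencies, fj: LabeledFrequencies) -> float:
    """Label-aligned variational distance; missing symbols count as 0."""
    symbols = set(fi.freq) | set(fj.freq)
    return 0.5 * sum(abs(fi[s] - fj[s]) for s in symbols)


def common_word_fraction(types_i: set[str], types_j: set[str]) -> CommonWordStats:
    """Shared word-type fraction between two texts' vocabularies."""
    if not types_i or not types_j:
        raise ValueError("word-type sets must be non-empty")
    return CommonWordStats(n_i=len(types_i), n_j=len(types_j), n_ij=len(types_i & types_j))


def _matrix_lookup(matrix):
    """Accept {(i,j): value} dicts (either key order) or pandas DataFrames."""
    if hasattr(matrix, "loc"):  # DataFrame
        return lambda i, j: float(matrix.loc[i, j])

    def get(i, j):
        if (i, j) in matrix:
            return float(matrix[(i, j)])
        if (j, i) in matrix:
            return float(matrix[(j, i)])
        raise KeyError(f"missing pair ({i}, {j})")

    return get


def cluster_gap(
    data,
    cluster_labels: Mapping[TextId, Hashable],
    target_cluster: Hashable,
    kind: str = "beta_gap",
) -> float:
    """Min cross-cluster minus max within-cluster value for one author.

    ``kind="beta_gap"``: ``data`` maps text id → fitted β; values compared
    are |β_i − β_k|.  ``kind="distance_gap"``: ``data`` is a symmetric
    pairwise matrix (dict keyed by pairs, or DataFrame) of ρ_λ values.
    """
    members = [i for i, lab in cluster_labels.items() if lab == target_cluster]
    others = [i for i, lab in cluster_labels.items() if lab != target_cluster]
    if len(members) < 2:
        raise ValueError(f"cluster {target_cluster!r} needs >= 2 members")
    if not others:
        raise ValueError("need at least one text outside the cluster")

    if kind == "beta_gap":
        value = lambda i, j: abs(float(data[i]) - float(data[j]))
    elif kind == "distance_gap":
        value = _matrix_lookup(data)
    else:
        raise ValueError(f"unknown gap kind {kind!r}")

    within = max(value(i, j) for i, j in combinations(members, 2))
    cross = min(value(i, k) for i in members for k in others)
    return cross - within


def all_cluster_gaps(
    data, cluster_labels: Mapping[TextId, Hashable], kind: str = "beta_gap",
    lam: int | None = None, mode: str = "",
) -> ClusterGapReport:
    clusters = sorted(set(cluster_labels.values()), key=repr)
    gaps = {c: cluster_gap(data, cluster_labels, c, kind) for c in clusters}
    return ClusterGapReport(gaps=gaps, kind=kind, lam=lam, mode=mode)


def distance_table(
    labeled: Mapping[TextId, LabeledFrequencies], mode: str = ""
) -> list[DistanceReport]:
    """All pairwise ρ0/ρ1 reports for a set of texts (shared inventory)."""
    from .corpus_phonemizer import rank_frequencies

    ids = list(labeled)
    ranked = {i: rank_frequencies(labeled[i]) for i in ids}
    reports = []
    for i, j in combinations(ids, 2):
        reports.append(
            DistanceReport(
                pair=(i, j),
                rho0=rho0(labeled[i], labeled[j]),
                rho1=rho1(ranked[i], ranked[j]),
                mode=mode,
            )
        )
    return reports


def _reports_as_matrices(reports: Sequence[DistanceReport]) -> dict[int, dict]:
    out: dict[int, dict] = {0: {}, 1: {}}
    for rep in reports:
        out[0][tuple(rep.pair)] = rep.rho0
        out[1][tuple(rep.pair)] = rep.rho1
    return out


def inequality_family(
    left: Mapping[tuple, float], right: Mapping[tuple, float]
) -> list[InequalityRecord]:
    """Per-instance strict comparisons left > right over matching keys."""
    missing = set(left) ^ set(right)
    if missing:
        raise ValueError(f"instance sets differ: {sorted(missing, key=repr)}")
    return [
        InequalityRecord(instance=k if isinstance(k, tuple) else (k,),
                         left=float(left[k]), right=float(right[k]))
        for k in sorted(left, key=repr)
    ]


def _family_summary(records: list[InequalityRecord]) -> dict:
    return {
        "records": records,
        "holding": sum(r.holds for r in records),
        "total": len(records),
        "violations": [r for r in records if not r.holds],
    }


def mode_comparison_report(
    reports_all: Sequence[DistanceReport],
    reports_diff: Sequence[DistanceReport],
    reports_nocommon: Sequence[DistanceReport] | None,
    betas_all: Mapping[TextId, float],
    betas_diff: Mapping[TextId, float],
    cluster_labels: Mapping[TextId, Hashable],
    same_author_pairs: Sequence[tuple] | None = None,
) -> dict:
    """Evaluate the inequality families relating word modes and the ablation.

    Families (left > right per instance):

    - ``type_mode_beta_larger``          β type-mode > β token-mode, per text
    - ``type_mode_beta_gap_larger``      b gaps larger in type mode, per author
    - ``type_mode_z_gap_larger``         z gaps larger in type mode, per (λ, author)
    - ``token_mode_same_author_distance_larger``
                                         ρ_λ token-mode > ρ_λ type-mode for
                                         same-author pairs
    - with the no-common-words ablation also:
      ``ablation_z_gap_positive``, ``ablation_same_author_distance_larger``,
      ``ablation_z_gap_larger``

    Returns {family: {records, holding, total, violations}}.
    """
    mat_all = _reports_as_matrices(reports_all)
    mat_diff = _reports_as_matrices(reports_diff)
    if set(mat_all[0]) != set(mat_diff[0]):
        raise ValueError("text-pair sets differ between modes")
    if set(betas_all) != set(betas_diff):
        raise ValueError("text sets differ between beta maps")

    if same_author_pairs is None:
        same_author_pairs = [
            p for p in mat_all[0]
            if cluster_labels[p[0]] == cluster_labels[p[1]]
        ]
    same_author_pairs = [tuple(p) for p in same_author_pairs]

    out: dict[str, dict] = {}

    out["type_mode_beta_larger"] = _family_summary(
        inequality_family(betas_diff, betas_all)
    )

    b_all = all_cluster_gaps(betas_all, cluster_labels, "beta_gap").gaps
    b_diff = all_cluster_gaps(betas_diff, cluster_labels, "beta_gap").gaps
    out["type_mode_beta_gap_larger"] = _family_summary(
        inequality_family(b_diff, b_all)
    )

    z = {
        mode: {
            lam: all_cluster_gaps(mat[lam], cluster_labels, "distance_gap", lam=lam).gaps
            for lam in (0, 1)
        }
        for mode, mat in (("all", mat_all), ("diff", mat_diff))
    }
    flat = lambda zz: {(lam, a): v for lam in (0, 1) for a, v in zz[lam].items()}
    out["type_mode_z_gap_larger"] = _family_summary(
        inequality_family(flat(z["diff"]), flat(z["all"]))
    )

    pick = lambda mat: {
        (lam, p): mat[lam][p] for lam in (0, 1) for p in same_author_pairs
    }
    out["token_mode_same_author_distance_larger"] = _family_summary(
        inequality_family(pick(mat_all), pick(mat_diff))
    )

    if reports_nocommon is not None:
        mat_nc = _reports_as_matrices(reports_nocommon)
        if set(mat_nc[0]) != set(mat_all[0]):
            raise ValueError("ablation pair set differs from the word modes")
        z_nc = {
            lam: all_cluster_gaps(mat_nc[lam], cluster_labels, "distance_gap", lam=lam).gaps
            for lam in (0, 1)
        }
        zeros = {k: 0.0 for k in flat(z_nc)}
        out["ablation_z_gap_positive"] = _family_summary(
            inequality_family(flat(z_nc), zeros)
        )
        out["ablation_same_author_distance_larger"] = _family_summary(
            inequality_family(pick(mat_nc), pick(mat_diff))
        )
        out["ablation_z_gap_larger"] = _family_summary(
            inequality_family(flat(z_nc), flat(z["diff"]))
        )
    return out
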