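"""Phenotype-based prediction of pathogenic-variant presence.

A class-balanced randomized forest is grown over the phenotype predictor
matrix (16 category flags + sex + number of affected categories).  Each tree
draws, without replacement, ``floor(0.8 * n_minority)`` cases from *each*
class, so out-of-bag (OOB) estimates are defined for every case.  Case
proximities (fraction of trees in which two cases land in the same terminal
leaf) feed a Ward hierarchical clustering used to surface patient subgroups
enriched for diagnosed cases.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform
from sklearn.tree import DecisionTreeClassifier

from .hpo_phenotype import CATEGORIES, PatientPhenotype

__all__ = [
    "PredictorMatrix",
    "ProfilingResult",
    "fit_forest",
    "evaluate",
    "EvalMetrics",
    "prototype_groups",
    "PrototypeResult",
    "mann_whitney_votes",
    "proximity_to_newick",
]

FEATURE_NAMES: tuple[str, ...] = tuple(CATEGORIES) + ("sex_male", "n_categories")


@dataclass
class PredictorMatrix:
    """Encoded per-patient predictors with the binary diagnosed outcome."""

    X: np.ndarray  # (n_patients, 18)
    y: np.ndarray  # (n_patients,) in {0, 1}
    patient_ids: list[str]
    feature_names: tuple[str, ...] = FEATURE_NAMES

    @classmethod
    def from_phenotypes(cls, patients: Sequence[PatientPhenotype]) -> "PredictorMatrix":
        rows = []
        for p in patients:
            row = [float(p.category_flags[c]) for c in CATEGORIES]
            row.append(1.0 if p.sex.value == "M" else 0.0)
            row.append(float(p.n_categories))
            rows.append(row)
        X = np.asarray(rows, dtype=float)
        y = np.asarray([int(p.diagnosed) for p in patients], dtype=int)
        return cls(X, y, [p.patient_id for p in patients])


@dataclass
class ProfilingResult:
    votes: np.ndarray  # OOB vote fraction for class 1, per case
    oob_tree_counts: np.ndarray
    proximity: np.ndarray  # symmetric, unit diagonal, in [0, 1]
    labels: np.ndarray
    patient_ids: list[str]
    n_trees: int
    seed: Optional[int] = None


def fit_forest(
    matrix: PredictorMatrix,
    n_trees: int = 5000,
    seed: Optional[int] = None,
    sample_fraction: float = 0.8,
    max_features: str | int = "sqrt",
    compute_proximity: bool = True,
) -> ProfilingResult:
    """Grow the balanced forest and collect OOB votes and proximities.

    Per tree, ``floor(sample_fraction * n_minority)`` cases are drawn
    without replacement from each class; a case's OOB vote fraction uses
    only the trees that did not sample it.  Proximity between two cases is
    the fraction of all trees in which they share a terminal leaf.
    """
    X, y = matrix.X, matrix.y
    n = len(y)
    classes = np.unique(y)
    if len(classes) < 2:
        raise ValueError("outcome has a single class; cannot fit")
    idx_by_class = [np.flatnonzero(y == c) for c in classes]
    n_minority = min(len(ix) for ix in idx_by_class)
    k = int(sample_fraction * n_minority)
    if k < 1:
        raise ValueError("minority class too small for the sampling fraction")
    if min(len(ix) for ix in idx_by_class) < 2:
        raise ValueError("need >= 2 cases per class")

    rng = np.random.default_rng(seed)
    vote1 = np.zeros(n)
    oob_counts = np.zeros(n)
    prox_counts = np.zeros((n, n)) if compute_proximity else None

    for _ in range(n_trees):
        bag = np.concatenate([rng.choice(ix, size=k, replace=False) for ix in idx_by_class])
        tree = DecisionTreeClassifier(
            max_features=max_features,
            random_state=int(rng.integers(0, 2**31 - 1)),
        )
        tree.fit(X[bag], y[bag])
        in_bag = np.zeros(n, dtype=bool)
        in_bag[bag] = True
        oob = ~in_bag
        if oob.any():
            pred = tree.predict(X[oob])
            vote1[oob] += pred == 1
            oob_counts[oob] += 1
        if compute_proximity:
            leaves = tree.apply(X)
            prox_counts += leaves[:, None] == leaves[None, :]

    with np.errstate(invalid="ignore"):
        votes = np.where(oob_counts > 0, vote1 / np.maximum(oob_counts, 1), np.nan)
    proximity = (
        prox_counts / n_trees if compute_proximity else np.eye(n)
    )
    return ProfilingResult(
        votes=votes,
        oob_tree_counts=oob_counts,
        proximity=proximity,
        labels=y.copy(),
        patient_ids=list(matrix.patient_ids),
        n_trees=n_trees,
        seed=seed,
    )


@dataclass(frozen=True)
class EvalMetrics:
    sensitivity: float
    specificity: float
    accuracy: float
    auc: float
    auc_ci: tuple[float, float]


def auc_from_votes(votes: np.ndarray, labels: np.ndarray) -> float:
    """AUC as the Mann-Whitney rank statistic over vote fractions."""
    ranks = stats.rankdata(votes)
    pos = labels == 1
    n1, n0 = int(pos.sum()), int((~pos).sum())
    if n1 == 0 or n0 == 0:
        raise ValueError("both classes required for AUC")
    return float((ranks[pos].sum() - n1 * (n1 + 1) / 2) / (n1 * n0))


def evaluate(result: ProfilingResult, threshold: float = 0.5) -> EvalMetrics:
    """OOB confusion metrics at the vote threshold plus rank-statistic AUC.

    The AUC confidence interval uses the Hanley-McNeil normal approximation.
    """
    ok = ~np.isnan(result.votes)
    votes, labels = result.votes[ok], result.labels[ok]
    pred = votes >= threshold
    pos, neg = labels == 1, labels == 0
    tp = int((pred & pos).sum())
    tn = int((~pred & neg).sum())
    sens = tp / pos.sum() if pos.any() else float("nan")
    spec = tn / neg.sum() if neg.any() else float("nan")
    acc = (tp + tn) / len(labels)
    auc = auc_from_votes(votes, labels)
    n1, n0 = int(pos.sum()), int(neg.sum())
    q1 = auc / (2 - auc)
    q2 = 2 * auc**2 / (1 + auc)
    var = (auc * (1 - auc) + (n1 - 1) * (q1 - auc**2) + (n0 - 1) * (q2 - auc**2)) / (
        n1 * n0
    )
    se = float(np.sqrt(max(var, 0.0)))
    ci = (max(0.0, auc - 1.96 * se), min(1.0, auc + 1.96 * se))
    return EvalMetrics(float(sens), float(spec), float(acc), auc, ci)


@dataclass
class PrototypeResult:
    linkage: np.ndarray
    #: flat cluster assignment for the requested cut (1-based cluster ids)
    assignments: Optional[np.ndarray]
    #: (member indices, size, diagnosed fraction), enriched clades first
    groups: list[tuple[list[int], int, float]] = field(default_factory=list)
    cohort_yield: float = 0.0


def prototype_groups(
    proximity: np.ndarray,
    labels: Sequence[int],
    n_groups: Optional[int] = None,
    min_size: int = 10,
    margin: float = 0.1,
) -> PrototypeResult:
    """Ward clustering on 1 - proximity and enriched-clade reporting.

    Replaces manual dendrogram inspection with a reproducible rule: every
    clade with >= ``min_size`` members whose diagnosed fraction exceeds the
    cohort fraction by ``margin`` is reported, most enriched first.  When
    ``n_groups`` is given the flat cut at that many clusters is returned too.
    """
    proximity = np.asarray(proximity, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if proximity.ndim != 2 or proximity.shape[0] != proximity.shape[1]:
        raise ValueError("proximity must be square")
    if not np.allclose(proximity, proximity.T, atol=1e-8):
        raise ValueError("proximity must be symmetric")
    dis = 1.0 - proximity
    np.fill_diagonal(dis, 0.0)
    Z = hierarchy.linkage(squareform(dis, checks=False), method="ward")

    assignments = (
        hierarchy.fcluster(Z, t=n_groups, criterion="maxclust")
        if n_groups is not None
        else None
    )

    cohort_yield = float(labels.mean()) if len(labels) else 0.0
    groups: list[tuple[list[int], int, float]] = []
    tree = hierarchy.to_tree(Z)

    def leaves(node) -> list[int]:
        return node.pre_order(lambda x: x.id)

    stack = [tree]
    while stack:
        node = stack.pop()
        if node.is_leaf():
            continue
        members = leaves(node)
        if len(members) >= min_size and len(members) < len(labels):
            frac = float(labels[members].mean())
            if frac >= cohort_yield + margin:
                groups.append((members, len(members), frac))
        stack.extend([node.left, node.right])
    groups.sort(key=lambda g: -g[2])
    return PrototypeResult(Z, assignments, groups, cohort_yield)


def proximity_to_newick(linkage: np.ndarray, names: Sequence[str]) -> str:
    """Serialize the clustering dendrogram as a Newick string."""
    tree = hierarchy.to_tree(linkage)

    def render(node) -> str:
        if node.is_leaf():
            return names[node.id]
        d = node.dist / 2.0
        return (
            f"({render(node.left)}:{d - node.left.dist / 2.0:.6g},"
            f"{render(node.right)}:{d - node.right.dist / 2.0:.6g})"
        )

    return render(tree) + ";"


@dataclass(frozen=True)
class MannWhitneyVotes:
    median_difference: float
    u_statistic: float
    pvalue: float


def mann_whitney_votes(
    votes: Sequence[float], labels: Sequence[int]
) -> MannWhitneyVotes:
    """Two-sided Mann-Whitney U on vote fractions between outcome groups.

    Exact p for small tie-free samples, otherwise the normal approximation
    with midrank tie correction (scipy's "auto" policy).  Also reports the
    difference of group medians (group 1 minus group 0).
    """
    votes = np.asarray(votes, dtype=float)
    labels = np.asarray(labels, dtype=int)
    g1, g0 = votes[labels == 1], votes[labels == 0]
    if len(g1) == 0 or len(g0) == 0:
        raise ValueError("both groups must be non-empty")
    res = stats.mannwhitneyu(g1, g0, alternative="two-sided", method="auto")
    return MannWhitneyVotes(
        median_difference=float(np.median(g1) - np.median(g0)),
        u_statistic=float(res.statistic),
        pvalue=float(res.pvalue),
    )
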