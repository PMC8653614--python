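"""Cluster evaluation: structure, stability and replicability.

Three of the four evaluation measures live here:

* **structure** -- the silhouette coefficient on a dissimilarity matrix;
* **stability** -- clusterwise bootstrap Jaccard: re-cluster 100 bootstrap
  resamples and score each original cluster by its best Jaccard overlap with
  any bootstrap cluster (mean >= 0.75 is conventionally called stable);
* **replicability** -- train a pruned decision tree on the original
  clustering, use it to gold-label an external set, independently re-cluster
  that set, and report the label concordance after optimal alignment.

The fourth measure (clinical utility) lives in :mod:`adsubtypes.outcomes`.
Label alignment uses the Hungarian assignment on the contingency table so all
metrics are invariant to cluster relabeling.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment
from sklearn.model_selection import train_test_split
from sklearn.tree import DecisionTreeClassifier

logger = logging.getLogger(__name__)


# --------------------------------------------------------------------------- #
# Silhouette
# --------------------------------------------------------------------------- #

@dataclass
class SilhouetteResult:
    values: np.ndarray
    mean: float


def silhouette(dissimilarity: np.ndarray, labels) -> SilhouetteResult:
    """Per-point silhouette s(i) = (b - a) / max(a, b) on a distance matrix.

    ``a`` is the mean within-cluster dissimilarity excluding self; ``b`` the
    smallest mean dissimilarity to any other cluster. Points in singleton
    clusters score 0 by convention. Requires at least two clusters.
    """
    D = np.asarray(dissimilarity, dtype=float)
    labels = np.asarray(labels)
    n = len(labels)
    if D.shape != (n, n):
        raise ValueError("dissimilarity shape does not match labels")
    if not np.allclose(D, D.T, atol=1e-10) or not np.allclose(np.diag(D), 0, atol=1e-10):
        raise ValueError("dissimilarity must be symmetric with zero diagonal")
    clusters = np.unique(labels)
    if len(clusters) < 2:
        raise ValueError("silhouette structure undefined for a single cluster")

    onehot = (labels[:, None] == clusters[None, :]).astype(float)
    counts = onehot.sum(axis=0)
    sums = D @ onehot  # n x k: total dissimilarity from i to each cluster

    own = np.array([np.where(clusters == l)[0][0] for l in labels])
    own_count = counts[own]
    values = np.zeros(n)
    multi = own_count > 1
    a = np.where(multi, sums[np.arange(n), own] / np.maximum(own_count - 1, 1), 0.0)
    mean_to = sums / counts[None, :]
    mean_to[np.arange(n), own] = np.inf
    b = mean_to.min(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        s = (b - a) / np.maximum(a, b)
    values = np.where(multi, np.nan_to_num(s), 0.0)
    return SilhouetteResult(values=values, mean=float(values.mean()))


# --------------------------------------------------------------------------- #
# Label alignment
# --------------------------------------------------------------------------- #

def align_labels(reference_labels, candidate_labels) -> tuple[dict, np.ndarray]:
    """Optimal relabeling of ``candidate_labels`` onto the reference.

    Solves the rectangular assignment problem maximising agreement on the
    contingency table; candidate clusters left unmatched keep fresh labels
    beyond the reference range. Returns ``(mapping, aligned_labels)``.
    """
    ref = np.asarray(reference_labels)
    cand = np.asarray(candidate_labels)
    if ref.shape != cand.shape:
        raise ValueError("labelings must cover the same patients")
    ref_vals = np.unique(ref)
    cand_vals = np.unique(cand)
    C = np.zeros((len(cand_vals), len(ref_vals)))
    for i, cv in enumerate(cand_vals):
        for j, rv in enumerate(ref_vals):
            C[i, j] = np.sum((cand == cv) & (ref == rv))
    rows, cols = linear_sum_assignment(-C)
    mapping = {int(cand_vals[r]): int(ref_vals[c]) for r, c in zip(rows, cols)}
    fresh = int(ref_vals.max()) + 1 if len(ref_vals) else 0
    for cv in cand_vals:
        if int(cv) not in mapping:
            mapping[int(cv)] = fresh
            fresh += 1
    aligned = np.array([mapping[int(c)] for c in cand])
    return mapping, aligned


def jaccard(a: set, b: set) -> float:
    if not a and not b:
        return 1.0
    return len(a & b) / len(a | b)


# --------------------------------------------------------------------------- #
# Bootstrap stability
# --------------------------------------------------------------------------- #

@dataclass
class StabilityReport:
    n_bootstraps: int
    per_bootstrap_jaccard: list[float]
    overall_mean_jaccard: float
    per_cluster_mean_jaccard: dict[int, float]
    stable_flag: bool
    threshold: float = 0.75


def bootstrap_stability(
    data,
    cluster_procedure,
    n_bootstraps: int = 100,
    seed: int = 0,
    reference_labels=None,
    matching: str = "max",
) -> StabilityReport:
    """Clusterwise bootstrap Jaccard stability.

    ``cluster_procedure(data_subset)`` must re-run the frozen clustering
    method (fixed hyperparameters, chosen k) on a resampled data set and
    return labels. For each bootstrap resample with replacement the original
    clusters, restricted to the unique resampled points, are scored against
    the bootstrap clusters (mapped back to original indices); by default each
    original cluster takes its best-matching Jaccard ("max"), optionally a
    one-to-one Hungarian matching ("one_to_one").
    """
    if n_bootstraps < 1:
        raise ValueError("n_bootstraps must be >= 1")
    X = data.to_numpy() if isinstance(data, pd.DataFrame) else np.asarray(data)
    n = X.shape[0]
    if reference_labels is None:
        reference_labels = cluster_procedure(X)
    ref = np.asarray(reference_labels)
    ref_clusters = {int(c): set(np.flatnonzero(ref == c)) for c in np.unique(ref)}

    rng = np.random.default_rng(seed)
    per_boot: list[float] = []
    per_cluster: dict[int, list[float]] = {c: [] for c in ref_clusters}
    for _ in range(n_bootstraps):
        idx = rng.integers(0, n, size=n)
        labels_b = np.asarray(cluster_procedure(X[idx]))
        present = set(idx.tolist())
        boot_clusters = [
            set(idx[labels_b == c].tolist()) for c in np.unique(labels_b)
        ]
        if len(boot_clusters) == 1:
            logger.info("bootstrap produced a single cluster")
        scores = {}
        if matching == "max":
            for c, members in ref_clusters.items():
                restricted = members & present
                scores[c] = max(jaccard(restricted, b) for b in boot_clusters)
        elif matching == "one_to_one":
            cs = list(ref_clusters)
            J = np.zeros((len(cs), len(boot_clusters)))
            for i, c in enumerate(cs):
                restricted = ref_clusters[c] & present
                for j, b in enumerate(boot_clusters):
                    J[i, j] = jaccard(restricted, b)
            rows, cols = linear_sum_assignment(-J)
            scores = {cs[i]: 0.0 for i in range(len(cs))}
            for i, j in zip(rows, cols):
                scores[cs[i]] = J[i, j]
        else:
            raise ValueError(f"unknown matching {matching!r}")
        for c, sc in scores.items():
            per_cluster[c].append(sc)
        per_boot.append(float(np.mean(list(scores.values()))))

    overall = float(np.mean(per_boot))
    return StabilityReport(
        n_bootstraps=n_bootstraps,
        per_bootstrap_jaccard=per_boot,
        overall_mean_jaccard=overall,
        per_cluster_mean_jaccard={c: float(np.mean(v)) for c, v in per_cluster.items()},
        stable_flag=overall >= 0.75,
    )


# --------------------------------------------------------------------------- #
# Replicability
# --------------------------------------------------------------------------- #

@dataclass
class ReplicabilityReport:
    concordance_fraction: float
    confusion_table: pd.DataFrame  # gold (rows) x aligned predicted (cols)
    n_test: int
    alignment: dict = field(default_factory=dict)
    tree_validation_accuracy: float | None = None


def _fit_pruned_tree(train_X, train_labels, seed: int, validation_fraction=0.2,
                     **tree_kwargs) -> tuple[DecisionTreeClassifier, float]:
    """Cost-complexity pruned tree with an internal train/validation split."""
    stratify = train_labels if np.min(np.bincount(train_labels)) >= 2 else None
    X_fit, X_val, y_fit, y_val = train_test_split(
        train_X, train_labels, test_size=validation_fraction,
        random_state=seed, stratify=stratify,
    )
    base = DecisionTreeClassifier(random_state=seed, **tree_kwargs)
    path = base.cost_complexity_pruning_path(X_fit, y_fit)
    alphas = np.unique(path.ccp_alphas.clip(min=0))
    best_alpha, best_acc = 0.0, -np.inf
    for alpha in alphas:
        tree = DecisionTreeClassifier(random_state=seed, ccp_alpha=alpha, **tree_kwargs)
        tree.fit(X_fit, y_fit)
        acc = tree.score(X_val, y_val)
        if acc > best_acc + 1e-12 or (abs(acc - best_acc) <= 1e-12 and alpha > best_alpha):
            best_alpha, best_acc = float(alpha), acc
    final = DecisionTreeClassifier(random_state=seed, ccp_alpha=best_alpha, **tree_kwargs)
    final.fit(train_X, train_labels)
    return final, float(best_acc)


def replicability(
    train_features,
    train_labels,
    test_features,
    cluster_procedure,
    seed: int = 0,
    **tree_kwargs,
) -> ReplicabilityReport:
    """Decision-tree replicability protocol.

    A pruned classification tree learned on the original clustering predicts
    gold-standard labels for the external set; the external set is also
    independently clustered by ``cluster_procedure``; concordance is the
    fraction of external patients whose aligned cluster label matches the
    tree's gold label.
    """
    train_X = train_features.to_numpy() if isinstance(train_features, pd.DataFrame) else np.asarray(train_features)
    test_X = test_features.to_numpy() if isinstance(test_features, pd.DataFrame) else np.asarray(test_features)
    train_labels = np.asarray(train_labels)
    if train_X.shape[1] != test_X.shape[1]:
        raise ValueError("train/test feature schemas differ")
    k_train = len(np.unique(train_labels))
    if len(test_X) < k_train:
        logger.warning("test set smaller than the number of training clusters")

    tree, val_acc = _fit_pruned_tree(train_X, train_labels, seed, **tree_kwargs)
    gold = tree.predict(test_X)
    test_labels = np.asarray(cluster_procedure(test_X))
    mapping, aligned = align_labels(gold, test_labels)
    concordance = float(np.mean(aligned == gold))
    confusion = pd.crosstab(
        pd.Series(gold, name="gold"), pd.Series(aligned, name="clustered"),
    )
    return ReplicabilityReport(
        concordance_fraction=concordance,
        confusion_table=confusion,
        n_test=len(test_X),
        alignment=mapping,
        tree_validation_accuracy=val_acc,
    )
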