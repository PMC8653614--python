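"""Cluster characterisation and cross-method consistency analysis.

Clusters are named by the features whose prevalence deviates significantly
from the rest of the cohort (two-proportion test with continuity correction,
Bonferroni-adjusted across clusters x features — conservative on purpose,
since the names are clinical claims). Two special naming rules apply to the
symptom categories: elevated memory with no other elevated symptom category
is "Typical AD"; every category elevated except memory is "Non-typical AD".

Cross-method agreement is summarised by pairwise contingency (flow) tables
in a long format ready for alluvial plotting, and by the "consistent
cluster" search: given a feature signature (e.g. depression + anxiety +
earliest onset band + current smoker), find the matching cluster in each
method and intersect their patient sets.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import chi2_contingency

from .clustering import ClusterSolution
from .features import SYMPTOM_CATEGORIES, FeatureMatrix

logger = logging.getLogger(__name__)


@dataclass
class ClusterCharacterisation:
    table: pd.DataFrame          # cluster, feature, prevalences, direction, p
    names: dict[int, str]
    alpha: float
    n_tests: int                 # Bonferroni family size = clusters x features
    warnings: list[str] = field(default_factory=list)

    def significant(self, cluster: int) -> pd.DataFrame:
        t = self.table
        return t[(t["cluster"] == cluster) & t["significant"]]

    def elevated_features(self, cluster: int) -> set[str]:
        sig = self.significant(cluster)
        return set(sig.loc[sig["direction"] == "higher", "feature"])


def _two_proportion_p(a: int, n1: int, b: int, n2: int) -> float:
    """Two-sided two-proportion test with continuity correction (2x2 chi-square)."""
    table = np.array([[a, n1 - a], [b, n2 - b]], dtype=float)
    if table.sum(axis=0).min() == 0 or table.sum(axis=1).min() == 0:
        return 1.0
    _, p, _, _ = chi2_contingency(table, correction=True)
    return float(p)


def characterize(
    features: FeatureMatrix,
    labels,
    alpha: float = 0.05,
    adjustment: str = "bonferroni",
    min_cluster_size: int = 5,
    max_name_features: int = 3,
) -> ClusterCharacterisation:
    """Per-cluster, per-feature prevalence tests against the rest of the cohort.

    Every binary feature column is tested in every cluster; the Bonferroni
    family size is exactly clusters x features regardless of any skipped
    tests. Clusters smaller than ``min_cluster_size`` are reported with a
    warning and their tests skipped.
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    labels = np.asarray(labels)
    values = features.values
    clusters = sorted(int(c) for c in np.unique(labels))
    feature_cols = list(values.columns)
    n_tests = len(clusters) * len(feature_cols)
    warns: list[str] = []

    col_sums = values.sum(axis=0)
    n_total = len(values)
    rows = []
    for cl in clusters:
        mask = labels == cl
        n1 = int(mask.sum())
        small = n1 < min_cluster_size
        if small:
            msg = f"cluster {cl} has fewer than {min_cluster_size} patients; tests skipped"
            warns.append(msg)
            logger.warning(msg)
        in_sums = values.loc[mask].sum(axis=0)
        for feat in feature_cols:
            a = int(in_sums[feat])
            b = int(col_sums[feat]) - a
            n2 = n_total - n1
            prev_in = a / n1 if n1 else np.nan
            prev_out = b / n2 if n2 else np.nan
            if small or n2 == 0:
                p_adj = np.nan
                sig = False
            else:
                p = _two_proportion_p(a, n1, b, n2)
                if adjustment == "bonferroni":
                    p_adj = min(p * n_tests, 1.0)
                elif adjustment == "none":
                    p_adj = p
                else:
                    raise ValueError(f"unknown adjustment {adjustment!r}")
                sig = p_adj < alpha
            rows.append({
                "cluster": cl, "feature": feat,
                "cluster_prevalence": prev_in, "cohort_prevalence": prev_out,
                "direction": "higher" if prev_in > prev_out else "lower",
                "effect": prev_in - prev_out,
                "adjusted_p": p_adj, "significant": sig,
            })
    table = pd.DataFrame(rows)

    names = {}
    symptom_set = set(SYMPTOM_CATEGORIES)
    for cl in clusters:
        sub = table[(table["cluster"] == cl) & table["significant"]
                    & (table["direction"] == "higher")]
        elevated = set(sub["feature"])
        elevated_sympt = elevated & symptom_set
        base = None
        if elevated_sympt == {"memory"}:
            base = "Typical AD"
        elif elevated_sympt == symptom_set - {"memory"}:
            base = "Non-typical AD"
        others = sub[~sub["feature"].isin(symptom_set)]
        top = list(others.sort_values("effect", ascending=False)["feature"])
        if base is not None:
            parts = [base] + top[: max(0, max_name_features - 1)]
        else:
            top_all = list(sub.sort_values("effect", ascending=False)["feature"])
            parts = top_all[:max_name_features]
        names[cl] = " + ".join(parts) if parts else f"cluster {cl} (no deviating features)"
    return ClusterCharacterisation(
        table=table, names=names, alpha=alpha, n_tests=n_tests, warnings=warns,
    )


# --------------------------------------------------------------------------- #
# Cross-method flow
# --------------------------------------------------------------------------- #

@dataclass
class FlowTable:
    label_matrix: pd.DataFrame   # patients x methods
    pairwise: pd.DataFrame       # method_from, cluster_from, method_to, cluster_to, count


def cross_method_flow(solutions: list[ClusterSolution],
                      patient_index=None) -> FlowTable:
    """Per-patient label matrix plus all ordered pairwise contingency tables."""
    if len(solutions) < 2:
        raise ValueError("need at least two solutions to compare")
    n = len(solutions[0].labels)
    for sol in solutions[1:]:
        if len(sol.labels) != n:
            raise ValueError(
                f"mismatched patient sets: symmetric difference of size "
                f"{abs(len(sol.labels) - n)}"
            )
    index = patient_index if patient_index is not None else pd.RangeIndex(n)
    matrix = pd.DataFrame(
        {sol.method: sol.labels for sol in solutions}, index=index,
    )
    rows = []
    methods = list(matrix.columns)
    for i, ma in enumerate(methods):
        for mb in methods[i + 1:]:
            counts = matrix.groupby([ma, mb]).size()
            for (ca, cb), cnt in counts.items():
                rows.append({"method_from": ma, "cluster_from": int(ca),
                             "method_to": mb, "cluster_to": int(cb),
                             "count": int(cnt)})
    return FlowTable(label_matrix=matrix, pairwise=pd.DataFrame(rows))


def consistent_cluster(
    solutions: list[ClusterSolution],
    characterisations: dict[str, ClusterCharacterisation],
    feature_signature: set[str],
    patient_index=None,
) -> tuple[pd.Index, dict[str, list[int]]]:
    """Patients shared by the signature-matching cluster of every method.

    A cluster matches when its significantly-elevated feature set contains
    the whole signature. Within a method the matching clusters' patients are
    pooled; across methods the pools are intersected. An empty result simply
    means no consistent cluster exists.
    """
    n = len(solutions[0].labels)
    index = patient_index if patient_index is not None else pd.RangeIndex(n)
    per_method: dict[str, list[int]] = {}
    sets = []
    for sol in solutions:
        char = characterisations[sol.method]
        matches = [
            cl for cl in sorted(np.unique(sol.labels))
            if feature_signature <= char.elevated_features(int(cl))
        ]
        per_method[sol.method] = [int(c) for c in matches]
        members = set(np.flatnonzero(np.isin(sol.labels, matches)).tolist())
        sets.append(members)
    common = set.intersection(*sets) if sets else set()
    return index[sorted(common)], per_method
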