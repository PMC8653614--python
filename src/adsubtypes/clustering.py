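"""The four clustering algorithms with their model-selection procedures.

* k-means on MCA row coordinates, best of 100 restarts by total
  within-cluster sum of squares, with k chosen by majority vote of a WSS
  elbow, the mean silhouette and a spherical-Gaussian BIC over k = 2..14.
* kernel k-means on an exponential Hamming-distance kernel built directly
  from the categorical features (no MCA).
* affinity propagation on negative squared Euclidean similarities of MCA
  coordinates, with the preference swept over a grid and the solution chosen
  at the elbow of net similarity versus K.
* latent class analysis: either a diagonal-covariance Gaussian mixture on the
  MCA coordinates (default, matching the study protocol) or a classical
  independent-Bernoulli mixture on the raw one-hot categories; k = 2..8 by
  minimum BIC, patients assigned to the maximum-posterior class.

All methods are deterministic given their seed; ties in assignments break to
the lowest cluster index, and empty clusters during Lloyd iterations are
re-seeded with the point farthest from its centroid.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist, pdist, squareform
from sklearn.cluster import kmeans_plusplus
from sklearn.mixture import GaussianMixture

from .features import FeatureMatrix

_REL_TOL = 1e-9


@dataclass
class ClusterSolution:
    method: str
    labels: np.ndarray
    k: int
    objective: float
    extras: dict = field(default_factory=dict)
    seed: int | None = None
    n_restarts: int | None = None
    converged: bool = True

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        present = np.unique(self.labels)
        if len(present) != self.k or present.min() < 0 or present.max() >= self.k:
            raise ValueError(
                f"labels must cover 0..k-1 with no empty cluster (k={self.k}, "
                f"present={present})"
            )


@dataclass
class KSelectionReport:
    candidate_ks: list[int]
    total_wss: dict[int, float]
    mean_silhouette: dict[int, float]
    bic: dict[int, float]
    chosen_k: int
    rule_choices: dict[str, int | None]
    no_structure: bool = False

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "k": self.candidate_ks,
            "total_wss": [self.total_wss[k] for k in self.candidate_ks],
            "mean_silhouette": [self.mean_silhouette[k] for k in self.candidate_ks],
            "bic": [self.bic[k] for k in self.candidate_ks],
        })


# --------------------------------------------------------------------------- #
# Lloyd's algorithm (shared by plain and kernel k-means logic)
# --------------------------------------------------------------------------- #

def _assign(X: np.ndarray, centers: np.ndarray) -> np.ndarray:
    d2 = cdist(X, centers, metric="sqeuclidean")
    return d2.argmin(axis=1)  # argmin breaks ties to the lowest index


def _wss(X: np.ndarray, centers: np.ndarray, labels: np.ndarray) -> float:
    return float(((X - centers[labels]) ** 2).sum())


def _repair_empty(X, centers, labels, k) -> np.ndarray:
    """Re-seed each empty cluster with the point farthest from its centroid."""
    labels = labels.copy()
    for j in range(k):
        if not (labels == j).any():
            resid = ((X - centers[labels]) ** 2).sum(axis=1)
            far = int(np.argmax(resid))
            labels[far] = j
            centers[j] = X[far]
    return labels


def _lloyd(X: np.ndarray, centers: np.ndarray, max_iter: int = 300):
    """Lloyd iterations to label convergence; asserts the objective never rises."""
    k = centers.shape[0]
    centers = centers.copy()
    labels = _assign(X, centers)
    labels = _repair_empty(X, centers, labels, k)
    history = [_wss(X, centers, labels)]
    for _ in range(max_iter):
        for j in range(k):
            centers[j] = X[labels == j].mean(axis=0)
        new_labels = _assign(X, centers)
        new_labels = _repair_empty(X, centers, new_labels, k)
        obj = _wss(X, centers, new_labels)
        if obj > history[-1] * (1 + _REL_TOL) + 1e-12:
            raise AssertionError("k-means objective increased within a restart")
        converged = bool((new_labels == labels).all())
        labels = new_labels
        history.append(obj)
        if converged:
            break
    # final centroids consistent with final labels
    for j in range(k):
        centers[j] = X[labels == j].mean(axis=0)
    return labels, centers, _wss(X, centers, labels), history


def run_kmeans(
    coords,
    k: int,
    n_restarts: int = 100,
    seed: int = 0,
    init_centers: np.ndarray | None = None,
    max_iter: int = 300,
) -> ClusterSolution:
    """Best-of-restarts Lloyd's k-means (k-means++ initialisation per restart).

    ``init_centers`` replaces the random restarts with a single run from the
    given centers (used for the kernel-equivalence checks).
    """
    X = _coerce_coords(coords)
    n = X.shape[0]
    if not 1 <= k <= n:
        raise ValueError(f"k={k} out of range for n={n}")
    if not np.isfinite(X).all():
        raise ValueError("coordinates must be finite")

    index = coords.index if isinstance(coords, pd.DataFrame) else None

    if init_centers is not None:
        labels, centers, wss, history = _lloyd(X, np.asarray(init_centers, float), max_iter)
        return _kmeans_solution(labels, centers, wss, history, k, seed, 1, index)

    best = None
    rngs = np.random.SeedSequence(seed).spawn(n_restarts)
    for r, ss in enumerate(rngs):
        rs = int(ss.generate_state(1)[0] % (2**31 - 1))
        centers, _ = kmeans_plusplus(X, n_clusters=k, random_state=rs)
        labels, centers, wss, history = _lloyd(X, centers, max_iter)
        if best is None or wss < best[2] * (1 - 1e-12):
            best = (labels, centers, wss, history)
    labels, centers, wss, history = best
    return _kmeans_solution(labels, centers, wss, history, k, seed, n_restarts, index)


def _kmeans_solution(labels, centers, wss, history, k, seed, n_restarts, index):
    labels, order = _canonical_labels(labels, k)
    return ClusterSolution(
        method="kmeans", labels=labels, k=k, objective=wss,
        extras={"centroids": centers[order], "wss_history": history,
                "patient_index": index},
        seed=seed, n_restarts=n_restarts,
    )


def _canonical_labels(labels: np.ndarray, k: int):
    """Relabel clusters by order of first appearance (deterministic output)."""
    order = []
    for lab in labels:
        if lab not in order:
            order.append(int(lab))
        if len(order) == k:
            break
    remap = {old: new for new, old in enumerate(order)}
    return np.array([remap[int(l)] for l in labels]), np.array(order)


def _coerce_coords(coords) -> np.ndarray:
    if isinstance(coords, pd.DataFrame):
        return coords.to_numpy(dtype=float)
    return np.asarray(coords, dtype=float)


# --------------------------------------------------------------------------- #
# k selection for (kernel) k-means
# --------------------------------------------------------------------------- #

def kmeans_bic(wss: float, n: int, d: int, k: int,
               cluster_sizes: np.ndarray | None = None) -> float:
    """BIC under the spherical-Gaussian reading of the k-means objective
    (pooled variance over n - k degrees of freedom, cluster-share entropy
    term included when sizes are given)."""
    if wss <= 0 or n <= k:
        return -np.inf
    sigma2 = wss / ((n - k) * d)
    ll = -0.5 * n * d * np.log(2 * np.pi * sigma2) - 0.5 * (n - k) * d
    if cluster_sizes is not None:
        sizes = np.asarray(cluster_sizes, dtype=float)
        ll += float((sizes * np.log(sizes / n)).sum())
    p = (k - 1) + k * d + 1
    return -2.0 * ll + p * np.log(n)


def _elbow_by_second_difference(ks: list[int], values: list[float]) -> int | None:
    """k at the maximum second difference of a decreasing curve (None if <3 ks)."""
    if len(ks) < 3:
        return None
    v = np.asarray(values, dtype=float)
    second = v[2:] - 2.0 * v[1:-1] + v[:-2]
    return ks[int(np.argmax(second)) + 1]


def select_k(
    coords,
    k_range=range(2, 15),
    n_restarts: int = 100,
    seed: int = 0,
    runner=None,
    dissimilarity: np.ndarray | None = None,
) -> KSelectionReport:
    """Choose k by majority vote of WSS elbow, max silhouette and min BIC.

    ``runner(k) -> ClusterSolution`` may override the default k-means runner
    (used to apply the same selection protocol to kernel k-means);
    ``dissimilarity`` overrides the Euclidean distance matrix used for the
    silhouette (e.g. the kernel-induced distance).
    """
    from .evaluation import silhouette

    X = _coerce_coords(coords)
    n, d = X.shape
    ks = [k for k in k_range]
    if not ks:
        raise ValueError("empty k range")
    if np.allclose(X, X[0]):
        raise ValueError("all points identical: cluster structure undefined (k=1)")

    D = squareform(pdist(X)) if dissimilarity is None else np.asarray(dissimilarity)
    wss_by_k, sil_by_k, bic_by_k = {}, {}, {}
    for k in ks:
        sol = (runner(k) if runner is not None
               else run_kmeans(X, k, n_restarts=n_restarts, seed=seed + k))
        wss_by_k[k] = sol.objective
        sil_by_k[k] = silhouette(D, sol.labels).mean
        bic_by_k[k] = kmeans_bic(sol.objective, n, d, k,
                                 cluster_sizes=np.bincount(sol.labels))

    choices: dict[str, int | None] = {
        "wss_elbow": _elbow_by_second_difference(ks, [wss_by_k[k] for k in ks]),
        "silhouette": max(ks, key=lambda k: sil_by_k[k]),
        "bic": min(ks, key=lambda k: bic_by_k[k]),
    }
    votes = [v for v in choices.values() if v is not None]
    counts = {k: votes.count(k) for k in set(votes)}
    top = max(counts.values())
    winners = sorted(k for k, c in counts.items() if c == top)
    chosen = choices["silhouette"] if len(winners) > 1 else winners[0]

    sils = np.array([sil_by_k[k] for k in ks])
    # structureless data: silhouettes uniformly tiny, or a flat profile that
    # offers no basis for choosing any k over another
    no_structure = bool(
        sils.max() < 0.1 or (sils.max() - sils.min()) < 0.2 * abs(sils.max())
    )
    if no_structure:
        warnings.warn("weak cluster structure: silhouette profile low or flat")
    return KSelectionReport(
        candidate_ks=ks, total_wss=wss_by_k, mean_silhouette=sil_by_k,
        bic=bic_by_k, chosen_k=chosen, rule_choices=choices,
        no_structure=no_structure,
    )


# --------------------------------------------------------------------------- #
# Kernel k-means
# --------------------------------------------------------------------------- #

def hamming_kernel(data, gamma: float | None = None) -> np.ndarray:
    """Exponential Hamming kernel K(x, y) = exp(-gamma * d_H(x, y)).

    ``d_H`` counts parent variables (not one-hot columns) on which two
    patients differ. Accepts a FeatureMatrix (collapsed to parent codes) or an
    integer category-code matrix. ``gamma`` defaults to 1/Q. The kernel is
    symmetric, unit-diagonal and positive semidefinite (the Hamming distance
    is a sum of per-variable conditionally negative definite terms).
    """
    if isinstance(data, FeatureMatrix):
        codes = data.parent_codes().to_numpy()
    else:
        codes = np.asarray(data)
    n, q = codes.shape
    if gamma is None:
        gamma = 1.0 / q
    if gamma <= 0:
        raise ValueError("gamma must be > 0")
    D = np.zeros((n, n), dtype=np.int32)
    for j in range(q):
        col = codes[:, j]
        D += (col[:, None] != col[None, :])
    return np.exp(-gamma * D)


def kernel_induced_distances(K: np.ndarray) -> np.ndarray:
    """Pairwise distances in the kernel feature space:
    d(i, j) = sqrt(K_ii + K_jj - 2 K_ij)."""
    diag = np.diag(K)
    d2 = np.maximum(diag[:, None] + diag[None, :] - 2.0 * K, 0.0)
    np.fill_diagonal(d2, 0.0)
    return np.sqrt(d2)


def _kernel_distances(K: np.ndarray, labels: np.ndarray, k: int) -> np.ndarray:
    """d^2(i, cluster j) = K_ii - 2 mean_{l in j} K_il + mean_{l,m in j} K_lm."""
    n = K.shape[0]
    M = np.zeros((n, k))
    for j in range(k):
        idx = labels == j
        nj = idx.sum()
        Kj = K[:, idx]
        within = K[np.ix_(idx, idx)].sum() / (nj * nj)
        M[:, j] = np.diag(K) - 2.0 * Kj.sum(axis=1) / nj + within
    return M


def kernel_wss(K: np.ndarray, labels: np.ndarray) -> float:
    total = float(np.trace(K))
    for j in np.unique(labels):
        idx = labels == j
        total -= K[np.ix_(idx, idx)].sum() / idx.sum()
    return total


def run_kernel_kmeans(
    kernel: np.ndarray,
    k: int,
    n_restarts: int = 100,
    seed: int = 0,
    init_labels: np.ndarray | None = None,
    max_iter: int = 300,
) -> ClusterSolution:
    """Kernelised Lloyd's algorithm, best of restarts by kernel WSS.

    Restarts initialise from k random seed points (each point assigned to its
    nearest seed in kernel distance). ``init_labels`` runs a single pass from
    the given assignment instead.
    """
    K = np.asarray(kernel, dtype=float)
    n = K.shape[0]
    if K.shape[0] != K.shape[1] or not np.allclose(K, K.T, atol=1e-8):
        raise ValueError("kernel must be square and symmetric")
    if not 1 <= k <= n:
        raise ValueError(f"k={k} out of range for n={n}")

    def one_run(labels0: np.ndarray):
        labels = labels0.copy()
        history = []
        for _ in range(max_iter):
            # repair empty clusters: farthest point from its cluster in
            # kernel distance
            M = _kernel_distances(K, labels, k) if len(np.unique(labels)) == k else None
            if M is None:
                for j in range(k):
                    if not (labels == j).any():
                        resid = np.array([
                            _point_to_cluster(K, labels, i) for i in range(n)
                        ])
                        labels[int(np.argmax(resid))] = j
                M = _kernel_distances(K, labels, k)
            obj = kernel_wss(K, labels)
            if history and obj > history[-1] * (1 + _REL_TOL) + 1e-12:
                raise AssertionError("kernel k-means objective increased")
            history.append(obj)
            new_labels = M.argmin(axis=1)
            if (new_labels == labels).all():
                break
            labels = new_labels
        return labels, kernel_wss(K, labels), history

    if init_labels is not None:
        labels, wss, history = one_run(np.asarray(init_labels).copy())
        labels, _ = _canonical_labels(labels, k)
        return ClusterSolution(
            method="kernel_kmeans", labels=labels, k=k, objective=wss,
            extras={"wss_history": history}, seed=seed, n_restarts=1,
        )

    best = None
    rng = np.random.default_rng(seed)
    for _ in range(n_restarts):
        seeds = rng.choice(n, size=k, replace=False)
        d2 = np.diag(K)[:, None] + np.diag(K)[seeds][None, :] - 2.0 * K[:, seeds]
        labels0 = d2.argmin(axis=1)
        for j in range(k):  # keep every seed point in its own cluster
            labels0[seeds[j]] = j
        labels, wss, history = one_run(labels0)
        if best is None or wss < best[1] * (1 - 1e-12):
            best = (labels, wss, history)
    labels, wss, history = best
    labels, _ = _canonical_labels(labels, k)
    return ClusterSolution(
        method="kernel_kmeans", labels=labels, k=k, objective=wss,
        extras={"wss_history": history}, seed=seed, n_restarts=n_restarts,
    )


def _point_to_cluster(K, labels, i) -> float:
    idx = labels == labels[i]
    nj = idx.sum()
    return K[i, i] - 2.0 * K[i, idx].sum() / nj + K[np.ix_(idx, idx)].sum() / nj**2


# --------------------------------------------------------------------------- #
# Affinity propagation
# --------------------------------------------------------------------------- #

def negative_squared_distances(coords) -> np.ndarray:
    X = _coerce_coords(coords)
    return -squareform(pdist(X, metric="sqeuclidean"))


@dataclass
class PreferenceSweep:
    rows: pd.DataFrame            # preference, k, net_similarity, converged
    chosen: ClusterSolution
    chosen_preference: float


def run_affinity_propagation(
    similarity: np.ndarray,
    preference: float,
    damping: float = 0.9,
    max_iter: int = 1000,
    conv_iter: int = 50,
) -> ClusterSolution:
    """Responsibility/availability message passing with damping.

    Returns exemplar-defined clusters; on non-convergence the current state is
    returned with ``converged=False``. Net similarity (the objective) is the
    sum of each point's similarity to its exemplar; exemplars contribute zero
    (their self-similarity), which makes the objective comparable across
    preference values at a fixed K.
    """
    S = np.array(similarity, dtype=float)
    n = S.shape[0]
    if S.shape[0] != S.shape[1]:
        raise ValueError("similarity must be square")
    if not 0.5 <= damping < 1:
        raise ValueError("damping must be in [0.5, 1)")
    np.fill_diagonal(S, preference)
    # tiny deterministic jitter removes degenerate symmetry ties
    rng = np.random.default_rng(0)
    S = S + 1e-12 * (S.max() - S.min() + 1e-300) * rng.standard_normal((n, n))

    R = np.zeros((n, n))
    A = np.zeros((n, n))
    idx = np.arange(n)
    exemplar_history = np.zeros((n, conv_iter), dtype=bool)
    converged = False
    it = 0
    for it in range(max_iter):
        # responsibilities
        AS = A + S
        first = AS.argmax(axis=1)
        max1 = AS[idx, first]
        AS[idx, first] = -np.inf
        max2 = AS.max(axis=1)
        AS[idx, first] = max1
        Rnew = S - max1[:, None]
        Rnew[idx, first] = S[idx, first] - max2
        R = damping * R + (1 - damping) * Rnew
        # availabilities
        Rp = np.maximum(R, 0)
        Rp[idx, idx] = R[idx, idx]
        Anew = Rp.sum(axis=0)[None, :] - Rp
        dA = Anew[idx, idx].copy()
        Anew = np.minimum(Anew, 0)
        Anew[idx, idx] = dA
        A = damping * A + (1 - damping) * Anew

        E = (A[idx, idx] + R[idx, idx]) > 0
        exemplar_history[:, it % conv_iter] = E
        if it >= conv_iter and E.any():
            if (exemplar_history == exemplar_history[:, [0]]).all():
                converged = True
                break

    E = (A[idx, idx] + R[idx, idx]) > 0
    exemplars = np.flatnonzero(E)
    if len(exemplars) == 0:
        exemplars = np.array([int(np.argmax(A[idx, idx] + R[idx, idx]))])

    labels = np.asarray(S[:, exemplars].argmax(axis=1))
    labels[exemplars] = np.arange(len(exemplars))
    # refine each exemplar to the member maximising within-cluster similarity
    refined = exemplars.copy()
    for j in range(len(exemplars)):
        members = np.flatnonzero(labels == j)
        if len(members):
            within = S[np.ix_(members, members)].sum(axis=0)
            refined[j] = members[int(np.argmax(within))]
    labels = np.asarray(S[:, refined].argmax(axis=1))
    labels[refined] = np.arange(len(refined))

    S0 = np.array(similarity, dtype=float)
    np.fill_diagonal(S0, 0.0)
    net = float(S0[np.arange(n), refined[labels]].sum())
    labels, order = _canonical_labels(labels, len(refined))
    return ClusterSolution(
        method="affinity_propagation", labels=labels, k=len(refined),
        objective=net,
        extras={"exemplars": refined[order], "n_iter": it + 1,
                "preference": preference},
        converged=converged,
    )


def sweep_preference(
    similarity: np.ndarray,
    preference_grid=None,
    n_grid: int = 20,
    damping: float = 0.9,
    max_iter: int = 1000,
    conv_iter: int = 50,
) -> PreferenceSweep:
    """Vary the preference, record (preference, K, net similarity), and pick
    the solution at the elbow of net similarity versus K."""
    S = np.asarray(similarity, dtype=float)
    off = S[~np.eye(S.shape[0], dtype=bool)]
    if preference_grid is None:
        # span from the median similarity (many exemplars) down to far below
        # the minimum (few exemplars): with many points the preference must be
        # much more negative than any single similarity before K gets small
        hi = abs(np.percentile(off, 99))
        lo = 50.0 * abs(off.min())
        preference_grid = -np.geomspace(max(hi, 1e-12), max(lo, 1e-9), n_grid)[::-1]
    grid = list(preference_grid)
    if len(grid) < 2:
        raise ValueError("preference grid must have at least 2 points")

    rows = []
    solutions = {}
    for pref in grid:
        sol = run_affinity_propagation(S, pref, damping, max_iter, conv_iter)
        rows.append({"preference": float(pref), "k": sol.k,
                     "net_similarity": sol.objective,
                     "converged": sol.converged})
        prev = solutions.get(sol.k)
        if prev is None or sol.objective > prev.objective:
            solutions[sol.k] = sol
    frame = pd.DataFrame(rows)

    ks = sorted(solutions)
    if len(ks) == 1:
        warnings.warn("all preferences produced the same K")
        chosen_k = ks[0]
    elif len(ks) == 2:
        warnings.warn("only two distinct K values; elbow undefined, using smaller K")
        chosen_k = ks[0]
    else:
        # net similarity is non-decreasing in K; the elbow is the interior K
        # where the gain per added cluster collapses relative to the gain just
        # before it (scale-invariant, robust to uneven K spacing and to how
        # far into large K the preference grid happens to reach)
        karr = np.asarray(ks, dtype=float)
        v = np.asarray([solutions[k].objective for k in ks])
        slopes = np.diff(v) / np.diff(karr)  # gain per unit K, >= 0
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = slopes[1:] / slopes[:-1]
        ratio = np.where(np.isfinite(ratio), ratio, np.inf)
        chosen_k = ks[int(np.argmin(ratio)) + 1]
    chosen = solutions[chosen_k]
    return PreferenceSweep(rows=frame, chosen=chosen,
                           chosen_preference=chosen.extras["preference"])


# --------------------------------------------------------------------------- #
# Latent class analysis
# --------------------------------------------------------------------------- #

def _bernoulli_em(X: np.ndarray, k: int, rng, tol=1e-6, max_iter=500):
    """EM for a mixture of independent Bernoullis; returns (ll, pi, theta, post)."""
    n, d = X.shape
    resp = rng.dirichlet(np.ones(k), size=n)
    ll_old = -np.inf
    eps = 1e-10
    for _ in range(max_iter):
        nk = resp.sum(axis=0)
        if (nk < 1.0) .any():
            raise FloatingPointError("degenerate component")
        pi = nk / n
        theta = np.clip((resp.T @ X) / nk[:, None], eps, 1 - eps)
        log_p = (
            np.log(pi)[None, :]
            + X @ np.log(theta).T
            + (1 - X) @ np.log(1 - theta).T
        )
        m = log_p.max(axis=1, keepdims=True)
        lse = m[:, 0] + np.log(np.exp(log_p - m).sum(axis=1))
        ll = float(lse.sum())
        resp = np.exp(log_p - lse[:, None])
        if ll - ll_old < tol * max(1.0, abs(ll)) and ll >= ll_old - 1e-8:
            ll_old = ll
            break
        ll_old = ll
    return ll_old, pi, theta, resp


def run_latent_class(
    data,
    k_range=range(2, 9),
    n_starts: int = 5,
    seed: int = 0,
    mode: str = "gaussian",
    tol: float = 1e-6,
    max_iter: int = 500,
) -> ClusterSolution:
    """Finite-mixture latent class model selected by minimum BIC over k.

    ``mode="gaussian"`` fits a diagonal-covariance Gaussian mixture to MCA
    coordinates (the study protocol applies MCA before LCA);
    ``mode="bernoulli"`` fits the classical independent-Bernoulli latent class
    model to the raw one-hot matrix.
    """
    X = _coerce_coords(data)
    n, d = X.shape
    ks = list(k_range)
    bic_by_k: dict[int, float] = {}
    fits: dict[int, tuple] = {}

    if mode == "gaussian":
        for k in ks:
            gm = GaussianMixture(
                n_components=k, covariance_type="diag", n_init=n_starts,
                random_state=seed + k, tol=tol, max_iter=max_iter,
                reg_covar=1e-6,
            ).fit(X)
            bic_by_k[k] = float(gm.bic(X))
            fits[k] = (gm,)
        best_k = min(ks, key=lambda k: bic_by_k[k])
        gm = fits[best_k][0]
        post = gm.predict_proba(X)
        ll = float(gm.score(X) * n)
    elif mode == "bernoulli":
        if not np.isin(X, (0, 1)).all():
            raise ValueError("bernoulli mode requires a binary matrix")
        for k in ks:
            best = None
            rng = np.random.default_rng(seed + k)
            failures = 0
            for _ in range(n_starts):
                try:
                    fit = _bernoulli_em(X, k, rng, tol, max_iter)
                except FloatingPointError:
                    failures += 1
                    continue
                if best is None or fit[0] > best[0]:
                    best = fit
            if best is None:
                raise RuntimeError(f"all EM restarts degenerate at k={k}")
            p = (k - 1) + k * d
            bic_by_k[k] = -2.0 * best[0] + p * np.log(n)
            fits[k] = best
        best_k = min(ks, key=lambda k: bic_by_k[k])
        ll, pi, theta, post = fits[best_k]
    else:
        raise ValueError(f"unknown mode {mode!r}")

    labels = post.argmax(axis=1)
    present = np.unique(labels)
    if len(present) < best_k:
        # posterior assignment may leave a fitted class empty; relabel compactly
        post = post[:, present]
        post = post / post.sum(axis=1, keepdims=True)
        labels = post.argmax(axis=1)
        best_k = len(present)
    labels, order = _canonical_labels(labels, best_k)
    post = post[:, order]
    return ClusterSolution(
        method="lca", labels=labels, k=best_k, objective=ll,
        extras={"posteriors": post, "bic": bic_by_k, "mode": mode},
        seed=seed, n_restarts=n_starts,
    )
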