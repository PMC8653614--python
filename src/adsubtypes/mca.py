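"""Multiple correspondence analysis of the one-hot clinical feature matrix.

Implements indicator-matrix MCA: correspondence analysis of the complete
disjunctive table via the generalized SVD of the doubly-centred,
mass-standardised indicator matrix. Row coordinates are returned in principal
coordinates (scaled by the singular values), so downstream Euclidean
clustering respects chi-square row distances.

Component count is selected by the elbow of the explained-inertia profile
(maximum second difference), mirroring the usual scree-plot judgement.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .features import FeatureMatrix


@dataclass
class MCAResult:
    row_coordinates: pd.DataFrame     # patients x components (principal coords)
    column_coordinates: pd.DataFrame  # categories x components
    eigenvalues: np.ndarray           # principal inertias, non-increasing
    explained_inertia: np.ndarray     # fractions of total inertia
    total_inertia: float
    n_components_retained: int
    dropped_columns: list[str]

    def scree(self) -> pd.DataFrame:
        return pd.DataFrame({
            "component": np.arange(1, len(self.eigenvalues) + 1),
            "inertia": self.eigenvalues,
            "fraction": self.explained_inertia,
        })


def _as_indicator(data) -> pd.DataFrame:
    if isinstance(data, FeatureMatrix):
        return data.indicator(complete=True)
    return pd.DataFrame(data)


def fit_mca(
    data,
    n_components: int | None = None,
    correction: str | None = None,
) -> MCAResult:
    """Fit correspondence analysis to a binary indicator matrix.

    Parameters
    ----------
    data : FeatureMatrix or DataFrame
        A FeatureMatrix is expanded to complete disjunctive coding first; a
        raw DataFrame is analysed as given.
    n_components : int, optional
        Number of components to retain; truncated to the matrix rank with a
        warning if larger. Default: all non-trivial components.
    correction : {"benzecri", None}
        Optional Benzecri inertia correction applied to the explained-inertia
        fractions (eigenvalues below 1/Q are discarded and the rest rescaled).
        Requires the input to be a FeatureMatrix (Q must be known).
    """
    if n_components is not None and n_components < 1:
        raise ValueError("n_components must be >= 1")
    n_parents = data.n_parents if isinstance(data, FeatureMatrix) else None
    X = _as_indicator(data)
    N = X.to_numpy(dtype=float)
    if N.min() < 0:
        raise ValueError("indicator matrix must be non-negative")

    col_totals = N.sum(axis=0)
    dropped = list(X.columns[col_totals == 0])
    if dropped:
        warnings.warn(f"dropping {len(dropped)} zero-mass categories: {dropped}")
        X = X.loc[:, col_totals > 0]
        N = N[:, col_totals > 0]

    total = N.sum()
    if total == 0:
        raise ValueError("indicator matrix is all-zero")
    P = N / total
    r = P.sum(axis=1)
    c = P.sum(axis=0)
    if (r == 0).any():
        raise ValueError("rows with zero mass are undefined in CA")

    S = (P - np.outer(r, c)) / np.sqrt(np.outer(r, c))
    U, s, Vt = np.linalg.svd(S, full_matrices=False)

    # discard numerically-zero singular values (the trivial dimension is
    # already removed by centring)
    tol = max(
        max(S.shape) * np.finfo(float).eps * (s[0] if len(s) else 0.0), 1e-12
    )
    rank = int((s > tol).sum())
    U, s, Vt = U[:, :rank], s[:rank], Vt[:rank]

    eig = s**2
    total_inertia = float((S**2).sum())

    if n_components is not None and n_components > rank:
        warnings.warn(
            f"n_components={n_components} exceeds rank {rank}; truncating"
        )
    keep = rank if n_components is None else min(n_components, rank)

    row_coords = (U * s) / np.sqrt(r)[:, None]
    col_coords = (Vt.T * s) / np.sqrt(c)[:, None]

    # sign convention: first nonzero column loading of each component positive
    for j in range(rank):
        nz = np.nonzero(np.abs(col_coords[:, j]) > 1e-12)[0]
        if len(nz) and col_coords[nz[0], j] < 0:
            col_coords[:, j] *= -1
            row_coords[:, j] *= -1

    if correction == "benzecri":
        if n_parents is None:
            raise ValueError("benzecri correction requires a FeatureMatrix input")
        q = n_parents
        adj = np.where(eig > 1.0 / q, (q / (q - 1.0) * (eig - 1.0 / q)) ** 2, 0.0)
        explained = adj / adj.sum() if adj.sum() > 0 else np.zeros_like(adj)
    elif correction is None:
        explained = eig / total_inertia if total_inertia > 0 else np.zeros_like(eig)
    else:
        raise ValueError(f"unknown correction {correction!r}")

    comp_names = [f"comp{j + 1}" for j in range(keep)]
    return MCAResult(
        row_coordinates=pd.DataFrame(row_coords[:, :keep], index=X.index, columns=comp_names),
        column_coordinates=pd.DataFrame(col_coords[:, :keep], index=X.columns, columns=comp_names),
        eigenvalues=eig,
        explained_inertia=explained,
        total_inertia=total_inertia,
        n_components_retained=keep,
        dropped_columns=dropped,
    )


def select_components(result: MCAResult, min_components: int = 1) -> int:
    """Scree elbow by maximum second difference of explained inertia.

    Returns the component count at which the decrease in explained inertia
    flattens most sharply. A profile with no curvature (all second differences
    ~0) is degenerate: returns ``min_components`` with a warning. With fewer
    than 3 components fitted, all are returned with a warning.
    """
    f = np.asarray(result.explained_inertia, dtype=float)
    m = len(f)
    if m < 3:
        warnings.warn("fewer than 3 components fitted; retaining all")
        return max(m, min_components)
    second = f[2:] - 2.0 * f[1:-1] + f[:-2]  # index i corresponds to keeping i+1
    if np.allclose(second, 0.0, atol=1e-12):
        warnings.warn("explained-inertia profile has no curvature (degenerate elbow)")
        return max(1, min_components)
    k = int(np.argmax(second)) + 1
    return max(k, min_components)
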