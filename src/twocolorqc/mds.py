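"""Classical multidimensional scaling of arrays with P_k dimension selection.

Arrays are embedded from their pairwise Euclidean distance matrix (over all
probes) by classical scaling: double-center −½·J·D²·J, eigendecompose, and
scale eigenvectors by √λ.  For Euclidean input this is mathematically
equivalent to PCA of the centered probe × array matrix.

Dimensionality is chosen by the cumulative eigenvalue-mass statistic

    P_k = Σ_{i≤k} max(λ_i, 0) / Σ_i max(λ_i, 0),

taking the smallest k with P_k ≥ cutoff (0.8 by default).  Double-centering
forces one zero eigenvalue and numerical noise can produce tiny negative
ones, so negative eigenvalues are clamped to zero in P_k and excluded from
the coordinates; the denominator therefore effectively runs over the n−1
informative eigenvalues.

Eigenvector sign is arbitrary; each axis is oriented so that its
largest-magnitude loading is positive, making coordinates deterministic.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from .io_agilent import ExpressionMatrix

__all__ = [
    "MDSResult",
    "distance_matrix",
    "classical_mds",
    "goodness_of_fit",
    "select_dimensions",
]


def distance_matrix(m: ExpressionMatrix) -> pd.DataFrame:
    """Symmetric array × array Euclidean distances over all probes."""
    if m.n_arrays < 2:
        raise ValueError("distance matrix requires at least 2 arrays")
    vals = m.values
    if not np.isfinite(vals).all():
        raise ValueError("non-finite values in expression matrix")
    d = squareform(pdist(vals.T, metric="euclidean"))
    return pd.DataFrame(d, index=m.data.columns, columns=m.data.columns)


@dataclass
class MDSResult:
    eigenvalues: np.ndarray  # full spectrum, descending
    coordinates: pd.DataFrame  # arrays × retained dimensions
    p_k: np.ndarray  # P_k for k = 1 .. n-1
    selected_k: int
    cutoff: float
    annotations: pd.DataFrame | None = None

    @property
    def n_arrays(self) -> int:
        return len(self.coordinates)

    def scores_frame(self) -> pd.DataFrame:
        out = self.coordinates.copy()
        if self.annotations is not None:
            out = out.join(self.annotations, how="left")
        return out


def classical_mds(
    d: pd.DataFrame | np.ndarray,
    k_max: int | None = None,
    cutoff: float = 0.8,
    annotations: pd.DataFrame | None = None,
) -> MDSResult:
    """Classical (Torgerson) scaling of a distance matrix.

    Coordinates are returned for the positive-eigenvalue dimensions,
    truncated to ``k_max`` (with a warning if ``k_max`` ≥ n, which cannot be
    honoured).
    """
    if isinstance(d, pd.DataFrame):
        ids = list(d.index)
        D = d.to_numpy(float)
    else:
        D = np.asarray(d, float)
        ids = [f"obj{i}" for i in range(D.shape[0])]
    n = D.shape[0]
    if D.shape != (n, n):
        raise ValueError("distance matrix must be square")
    if not np.isfinite(D).all():
        raise ValueError("non-finite distances")
    if not np.allclose(D, D.T, atol=1e-8):
        raise ValueError("distance matrix must be symmetric")

    if k_max is None:
        k_max = n - 1
    elif k_max >= n:
        warnings.warn(f"k_max={k_max} >= n={n}; truncated to {n - 1}", stacklevel=2)
        k_max = n - 1

    J = np.eye(n) - np.full((n, n), 1.0 / n)
    B = -0.5 * J @ (D * D) @ J
    B = (B + B.T) / 2.0
    eigvals, eigvecs = np.linalg.eigh(B)
    order = np.argsort(eigvals)[::-1]
    eigvals = eigvals[order]
    eigvecs = eigvecs[:, order]

    tol = max(1e-12, 1e-9 * abs(eigvals[0])) if eigvals.size else 0.0
    pos = eigvals > tol
    k_keep = min(int(pos.sum()), k_max)
    coords = eigvecs[:, :k_keep] * np.sqrt(eigvals[:k_keep])
    # deterministic orientation: largest-|loading| entry of each axis positive
    for j in range(k_keep):
        i = int(np.argmax(np.abs(coords[:, j])))
        if coords[i, j] < 0:
            coords[:, j] = -coords[:, j]

    p_curve = np.array([goodness_of_fit(eigvals, k) for k in range(1, n)])
    selected = select_dimensions(p_curve, cutoff=cutoff)
    frame = pd.DataFrame(
        coords, index=ids, columns=[f"dim{j + 1}" for j in range(k_keep)]
    )
    return MDSResult(
        eigenvalues=eigvals,
        coordinates=frame,
        p_k=p_curve,
        selected_k=selected,
        cutoff=cutoff,
        annotations=annotations,
    )


def goodness_of_fit(eigenvalues: np.ndarray, k: int) -> float:
    """Cumulative positive-eigenvalue mass of the first k dimensions.

    Negative eigenvalues are clamped to zero in both numerator and
    denominator.  On a full classical-scaling spectrum the centering-forced
    zero contributes nothing, so the denominator runs over the n−1
    informative terms.
    """
    lam = np.maximum(np.asarray(eigenvalues, float), 0.0)
    if not 1 <= k <= len(lam):
        raise ValueError(f"k must lie in [1, {len(lam)}]")
    total = lam.sum()
    if total <= 0:
        raise ValueError("all eigenvalues are non-positive")
    return float(lam[:k].sum() / total)


def select_dimensions(p_k: np.ndarray, cutoff: float = 0.8) -> int:
    """Smallest k with P_k ≥ cutoff; the full n−1 if unreachable (warns)."""
    p_k = np.asarray(p_k, float)
    if p_k.size == 0:
        raise ValueError("empty P_k curve")
    hits = np.flatnonzero(p_k >= cutoff)
    if hits.size == 0:
        warnings.warn(
            f"P_k never reaches cutoff {cutoff}; returning k = {len(p_k)}", stacklevel=2
        )
        return int(len(p_k))
    return int(hits[0] + 1)
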