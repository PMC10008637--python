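"""Principal coordinate analysis (metric MDS) of a distance matrix.

Classic Gower construction: B = -1/2 * J D^2 J with J the centring matrix,
eigendecomposition of B, coordinates = eigenvectors scaled by the square root
of their (positive) eigenvalues.  Negative eigenvalues — which arise when a
distance matrix is not Euclidean-embeddable, as chord-mean matrices can be —
are dropped and their total magnitude reported; no Lingoes/Cailliez
correction is applied.  Axis signs are fixed deterministically (first
non-zero loading positive).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .distance_tree import DistanceMatrix

_EIG_TOL = 1e-9


@dataclass
class PCoAResult:
    coordinates: pd.DataFrame       # accession x axis, columns PCo1..PCoK
    eigenvalues: np.ndarray         # positive eigenvalues, descending
    proportion_explained: np.ndarray
    negative_eigenvalue_mass: float  # |sum of dropped negative eigenvalues|


def pcoa(dm: DistanceMatrix, n_axes: int | None = None) -> PCoAResult:
    """PCoA of a symmetric zero-diagonal distance matrix."""
    D = np.asarray(dm.values, dtype=float)
    if np.isnan(D).any():
        raise ValueError("NaN in distance matrix")
    n = D.shape[0]
    if n_axes is not None and n_axes < 1:
        raise ValueError("n_axes must be >= 1")
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (D ** 2) @ J
    B = (B + B.T) / 2.0
    eigval, eigvec = np.linalg.eigh(B)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]
    scale = max(abs(eigval[0]), 1.0)
    pos = eigval > _EIG_TOL * scale
    neg_mass = float(abs(eigval[eigval < 0].sum()))
    lam = eigval[pos]
    V = eigvec[:, pos]
    # deterministic sign: first loading of non-negligible magnitude positive
    for k in range(V.shape[1]):
        nz = np.nonzero(np.abs(V[:, k]) > 1e-12)[0]
        if nz.size and V[nz[0], k] < 0:
            V[:, k] = -V[:, k]
    coords = V * np.sqrt(lam)
    if n_axes is not None:
        coords = coords[:, :n_axes]
    k = coords.shape[1]
    total_pos = lam.sum() if lam.size else 1.0
    return PCoAResult(
        coordinates=pd.DataFrame(
            coords, index=dm.labels, columns=[f"PCo{i + 1}" for i in range(k)]
        ),
        eigenvalues=lam,
        proportion_explained=lam / total_pos if lam.size else lam,
        negative_eigenvalue_mass=neg_mass,
    )
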