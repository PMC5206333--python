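"""Principal Coordinate Analysis (metric MDS) of a distance matrix.

Gower double-centering of -D^2/2 followed by an eigendecomposition;
coordinates are eigenvectors scaled by the square root of their (positive)
eigenvalues. Negative eigenvalues — which arise for non-Euclidean distances
such as Bruvo — are reported, not corrected.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .distances import DistanceMatrix

__all__ = ["PcoaResult", "pcoa"]


@dataclass
class PcoaResult:
    labels: list[str]
    coordinates: np.ndarray  # entities x positive axes
    eigenvalues: np.ndarray  # all eigenvalues, descending
    inertia_pct: np.ndarray  # per positive axis, % of positive-eigenvalue sum
    negative_eigenvalue_mass: float

    def to_frame(self, n_axes: int | None = None) -> pd.DataFrame:
        k = self.coordinates.shape[1] if n_axes is None else min(n_axes, self.coordinates.shape[1])
        return pd.DataFrame(
            self.coordinates[:, :k],
            index=self.labels,
            columns=[f"PCo{i+1}" for i in range(k)],
        )


def pcoa(d: DistanceMatrix, correction: str | None = None) -> PcoaResult:
    """Principal coordinates of a distance matrix.

    correction: None (default) reports negative eigenvalues as they are;
    "cailliez" adds the smallest constant to all off-diagonal distances that
    makes the configuration Euclidean.
    """
    D = np.asarray(d.values, float)
    if not np.allclose(D, D.T):
        raise ValueError("pcoa requires a symmetric matrix")
    if correction == "cailliez":
        D = _cailliez(D)
    elif correction is not None:
        raise ValueError(f"unknown correction {correction!r}")
    n = D.shape[0]
    A = -0.5 * D**2
    J = np.eye(n) - np.ones((n, n)) / n
    G = J @ A @ J
    G = (G + G.T) / 2
    w, v = np.linalg.eigh(G)
    order = np.argsort(w)[::-1]
    w, v = w[order], v[:, order]
    tol = max(abs(w[0]), 1.0) * 1e-10
    pos = w > tol
    coords = v[:, pos] * np.sqrt(w[pos])
    # reproducible axis signs: largest-magnitude loading positive
    for k in range(coords.shape[1]):
        j = np.argmax(np.abs(coords[:, k]))
        if coords[j, k] < 0:
            coords[:, k] *= -1
    pos_sum = w[pos].sum()
    inertia = 100.0 * w[pos] / pos_sum if pos_sum > 0 else np.array([])
    return PcoaResult(
        labels=list(d.labels),
        coordinates=coords,
        eigenvalues=w,
        inertia_pct=inertia,
        negative_eigenvalue_mass=float(-w[w < -tol].sum()),
    )


def _cailliez(D: np.ndarray) -> np.ndarray:
    """Cailliez constant: smallest c so that D + c (off-diagonal) is Euclidean."""
    n = D.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    F1 = J @ (-0.5 * D**2) @ J
    F2 = J @ (-0.5 * D) @ J
    B = np.block([[np.zeros((n, n)), 2 * F1], [-np.eye(n), -4 * F2]])
    c = float(np.max(np.real(np.linalg.eigvals(B))))
    if c <= 0:
        return D
    out = D + c
    np.fill_diagonal(out, 0.0)
    return out
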