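"""Matching-symmetry preprocessing: side reflection, centroid size, and
generalized Procrustes analysis (GPA).

Bilateral structures that come as two separate sides (e.g. left and right
hemimandibles) are analyzed under *matching symmetry*: one side is reflected
so that both sides become comparable shapes, and all configurations are then
superimposed jointly by GPA.  Rotations are restricted to proper rotations
(determinant +1) so that reflection asymmetry cannot be absorbed by the fit.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .tpsio import LandmarkDataset, normalize_side

__all__ = [
    "centroid_size",
    "reflect_side",
    "gpa_align",
    "procrustes_distance",
    "align_pair",
    "ProcrustesResult",
]


def centroid_size(coords: np.ndarray) -> float:
    """Square root of the summed squared distances of landmarks from their
    centroid — the standard geometric-morphometric size measure.  Invariant
    to translation and rotation; scales linearly with the configuration."""
    coords = np.asarray(coords, dtype=float)
    if not np.all(np.isfinite(coords)):
        raise ValueError("non-finite coordinates")
    centered = coords - coords.mean(axis=0)
    return float(np.sqrt((centered**2).sum()))


def reflect_side(dataset: LandmarkDataset, side_to_reflect: str = "right") -> LandmarkDataset:
    """Mirror the chosen side about the vertical axis (negate x).

    Landmark order is unchanged: landmarks are anatomical labels, so
    correspondence across sides is preserved.  The reflection axis is
    arbitrary because the subsequent GPA rotation absorbs orientation.
    """
    side = normalize_side(side_to_reflect)

    def _flip(c):
        if c.side == side:
            out = c.coords.copy()
            out[:, 0] = -out[:, 0]
            return out
        return c.coords

    return dataset.map_coords(_flip)


@dataclass
class ProcrustesResult:
    """Aligned configurations, consensus, and pre-scaling centroid sizes.

    ``aligned`` rows follow the canonical order of ``dataset.configurations``;
    ``keys`` carries the corresponding (specimen, side, image, digitizing)
    metadata.  Aligned configurations are centered at the origin with unit
    centroid size; ``centroid_sizes`` are in the original input units.
    """

    aligned: np.ndarray          # (n, k, 2)
    consensus: np.ndarray        # (k, 2), unit centroid size
    centroid_sizes: np.ndarray   # (n,)
    keys: pd.DataFrame
    iterations: int
    converged: bool
    k: int

    def to_frame(self) -> pd.DataFrame:
        """Wide table of aligned coordinates plus centroid size per row."""
        n, k, _ = self.aligned.shape
        cols = {}
        for j in range(k):
            cols[f"x{j + 1}"] = self.aligned[:, j, 0]
            cols[f"y{j + 1}"] = self.aligned[:, j, 1]
        out = pd.concat([self.keys.reset_index(drop=True), pd.DataFrame(cols)], axis=1)
        out["centroid_size"] = self.centroid_sizes
        return out

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "ProcrustesResult":
        key_cols = ["specimen_id", "population", "side", "image_rep", "digit_rep"]
        k = sum(1 for c in frame.columns if c.startswith("x") and c[1:].isdigit())
        aligned = np.empty((len(frame), k, 2))
        for j in range(k):
            aligned[:, j, 0] = frame[f"x{j + 1}"].to_numpy()
            aligned[:, j, 1] = frame[f"y{j + 1}"].to_numpy()
        consensus = aligned.mean(axis=0)
        consensus = consensus - consensus.mean(axis=0)
        consensus /= np.sqrt((consensus**2).sum())
        return cls(
            aligned=aligned,
            consensus=consensus,
            centroid_sizes=frame["centroid_size"].to_numpy(dtype=float),
            keys=frame[key_cols].copy(),
            iterations=0,
            converged=True,
            k=k,
        )


def _to_complex(arr: np.ndarray) -> np.ndarray:
    return arr[..., 0] + 1j * arr[..., 1]


def _to_real(z: np.ndarray) -> np.ndarray:
    return np.stack([z.real, z.imag], axis=-1)


def gpa_align(dataset: LandmarkDataset, tol: float = 1e-8, max_iter: int = 100) -> ProcrustesResult:
    """Iterative generalized Procrustes alignment of all configurations.

    Each configuration is centered, scaled to unit centroid size, and rotated
    (proper rotation only) onto the running consensus by the closed-form 2-D
    least-squares fit; the consensus is recomputed and the loop repeats until
    its root-mean-square change drops below ``tol`` or ``max_iter`` is hit.
    Centroid sizes are recorded before normalization, in input units.
    """
    X = dataset.coords_array()                       # (n, k, 2)
    keys = dataset.keys_frame()
    X = X - X.mean(axis=1, keepdims=True)
    sizes = np.sqrt((X**2).sum(axis=(1, 2)))
    degenerate = np.flatnonzero(sizes <= 0)
    if degenerate.size:
        bad = dataset.configurations[degenerate[0]].key()
        raise ValueError(f"degenerate (all-coincident) configuration: {bad}")
    Z = _to_complex(X) / sizes[:, None]              # (n, k) unit-size complex shapes

    consensus = Z[0].copy()
    iterations = 0
    converged = False
    for iterations in range(1, max_iter + 1):
        # optimal proper rotation of each row onto the consensus
        w = (np.conj(Z) * consensus).sum(axis=1)     # (n,)
        w = np.where(np.abs(w) > 0, w / np.abs(w), 1.0)
        Z = Z * w[:, None]
        new_consensus = Z.mean(axis=0)
        new_consensus = new_consensus - new_consensus.mean()
        norm = np.sqrt((np.abs(new_consensus) ** 2).sum())
        new_consensus = new_consensus / norm
        change = np.sqrt(np.mean(np.abs(new_consensus - consensus) ** 2))
        consensus = new_consensus
        if change < tol:
            converged = True
            break
    # final rotation pass onto the converged consensus
    w = (np.conj(Z) * consensus).sum(axis=1)
    w = np.where(np.abs(w) > 0, w / np.abs(w), 1.0)
    Z = Z * w[:, None]

    return ProcrustesResult(
        aligned=_to_real(Z),
        consensus=_to_real(consensus),
        centroid_sizes=sizes,
        keys=keys,
        iterations=iterations,
        converged=converged,
        k=dataset.k,
    )


def procrustes_distance(a: np.ndarray, b: np.ndarray) -> float:
    """Full Procrustes distance between two configurations (position, scale
    and proper rotation removed)."""
    za = _to_complex(np.asarray(a, float) - np.asarray(a, float).mean(axis=0))
    zb = _to_complex(np.asarray(b, float) - np.asarray(b, float).mean(axis=0))
    za = za / np.sqrt((np.abs(za) ** 2).sum())
    zb = zb / np.sqrt((np.abs(zb) ** 2).sum())
    w = (np.conj(za) * zb).sum()
    if np.abs(w) > 0:
        za = za * (w / np.abs(w))
    return float(np.sqrt((np.abs(za - zb) ** 2).sum()))


def align_pair(moving: np.ndarray, target: np.ndarray) -> np.ndarray:
    """Least-squares superimposition of ``moving`` onto ``target``:
    both are centered and unit-scaled, then ``moving`` is rotated (proper
    rotation) onto the target.  Returns the transformed ``moving``."""
    zm = _to_complex(np.asarray(moving, float) - np.asarray(moving, float).mean(axis=0))
    zt = _to_complex(np.asarray(target, float) - np.asarray(target, float).mean(axis=0))
    zm = zm / np.sqrt((np.abs(zm) ** 2).sum())
    zt = zt / np.sqrt((np.abs(zt) ** 2).sum())
    w = (np.conj(zm) * zt).sum()
    if np.abs(w) > 0:
        zm = zm * (w / np.abs(w))
    return _to_real(zm)
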