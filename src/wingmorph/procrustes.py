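"""Generalized least-squares Procrustes superimposition.

Classical GPA: every configuration is centered, scaled to unit centroid size
and rotated (no reflection) onto the running consensus; the consensus is the
arithmetic mean of the aligned coordinates and the loop repeats until it
stops moving (< 1e-8).  The final consensus is rotated onto its principal
axes so results are reproducible regardless of the input orientation.
Analyses downstream operate on these Procrustes coordinates directly; an
orthogonal tangent-space projection is available but off by default.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .landmarks import LandmarkConfiguration, stack_coords


class ZeroSizeError(ValueError):
    """Raised for degenerate (all points identical) configurations."""


class MissingSpeciesError(KeyError):
    """Raised when a species has no specimens in the aligned sample."""


@dataclass
class AlignedSample:
    """GPA output: aligned coordinates, sizes, consensus and labels."""

    coords: np.ndarray            # (n, k, 2)
    centroid_sizes: np.ndarray    # (n,)
    consensus: np.ndarray         # (k, 2)
    labels: pd.DataFrame | None = None
    n_iterations: int = 0
    sum_sq_history: list = field(default_factory=list)

    @property
    def n_specimens(self) -> int:
        return len(self.coords)

    def flat(self) -> np.ndarray:
        """(n, 2k) flattened shape variables (x1, y1, x2, y2, ...)."""
        return self.coords.reshape(self.n_specimens, -1)

    def to_frame(self) -> pd.DataFrame:
        """Aligned coordinates (x0, y0, x1, y1, ...) plus centroid size."""
        k = self.coords.shape[1]
        cols = [f"{ax}{i}" for i in range(k) for ax in ("x", "y")]
        df = pd.DataFrame(self.flat(), columns=cols)
        df.insert(0, "centroid_size", self.centroid_sizes)
        if self.labels is not None:
            df = pd.concat([self.labels.reset_index(drop=True), df], axis=1)
        return df

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def _center_scale(x: np.ndarray) -> tuple[np.ndarray, float]:
    c = x - x.mean(axis=0)
    size = np.sqrt((c ** 2).sum())
    if size <= 0:
        raise ZeroSizeError("configuration has zero centroid size")
    return c / size, float(size)


def _optimal_rotation(x: np.ndarray, target: np.ndarray) -> np.ndarray:
    """Rotation (det +1) minimizing ||x R - target||_F."""
    u, _, vt = np.linalg.svd(x.T @ target)
    d = np.sign(np.linalg.det(u @ vt))
    return u @ np.diag([1.0, d]) @ vt


def _principal_axis_rotation(shape: np.ndarray) -> np.ndarray:
    """Deterministic orientation: major axis along x, signs fixed by
    third-moment conventions."""
    _, _, vt = np.linalg.svd(shape - shape.mean(axis=0))
    R = vt.T
    if np.linalg.det(R) < 0:
        R[:, 1] = -R[:, 1]
    rotated = shape @ R
    if np.sum(rotated[:, 0] ** 3) < 0:
        R = R @ np.diag([-1.0, -1.0])   # rotate by pi; keeps det +1
    return R


def gpa_align(configurations, labels: pd.DataFrame | None = None,
              tol: float = 1e-8, max_iter: int = 200,
              tangent_project: bool = False) -> AlignedSample:
    """Align a sample of configurations by generalized Procrustes analysis.

    Accepts a list of :class:`LandmarkConfiguration` or an (n, k, 2) array.
    Reflections are never used (wings are pre-mirrored to a common pose).
    """
    if isinstance(configurations, np.ndarray):
        arr = configurations.astype(float)
        meta = None
    else:
        configurations = list(configurations)
        if len(configurations) == 0:
            raise ValueError("at least one configuration required")
        kcounts = {c.n_points for c in configurations}
        if len(kcounts) != 1:
            raise ValueError("all configurations must share one point scheme")
        arr = stack_coords(configurations)
        meta = pd.DataFrame([c.metadata for c in configurations])
    if arr.ndim != 3 or arr.shape[-1] != 2:
        raise ValueError("expected an (n, k, 2) coordinate array")
    if labels is None and meta is not None and not meta.empty:
        labels = meta

    n = len(arr)
    scaled = []
    sizes = np.empty(n)
    for i, x in enumerate(arr):
        s, sizes[i] = _center_scale(x)
        scaled.append(s)
    aligned = np.stack(scaled)

    consensus = aligned[0].copy()
    history = []
    it = 0
    for it in range(1, max_iter + 1):
        for i in range(n):
            aligned[i] = aligned[i] @ _optimal_rotation(aligned[i], consensus)
        new_consensus = aligned.mean(axis=0)
        new_consensus, _ = _center_scale(new_consensus)
        history.append(float(((aligned - new_consensus) ** 2).sum()))
        if np.abs(new_consensus - consensus).max() < tol and it > 1:
            consensus = new_consensus
            break
        consensus = new_consensus

    R = _principal_axis_rotation(consensus)
    consensus = consensus @ R
    aligned = aligned @ R
    consensus = aligned.mean(axis=0)

    if tangent_project:
        c = consensus.reshape(-1)
        c = c / np.linalg.norm(c)
        flat = aligned.reshape(n, -1)
        flat = flat - np.outer(flat @ c - 1.0, c)
        aligned = flat.reshape(aligned.shape)

    return AlignedSample(coords=aligned, centroid_sizes=sizes,
                         consensus=consensus, labels=labels,
                         n_iterations=it, sum_sq_history=history)


def species_means(sample: AlignedSample,
                  species: np.ndarray | None = None,
                  tip_order: list[str] | None = None) -> tuple[np.ndarray, list[str]]:
    """Per-species arithmetic mean of aligned coordinates.

    Returns an (N, k, 2) array ordered to ``tip_order`` (or sorted species
    names).  A requested species with zero specimens raises."""
    if species is None:
        if sample.labels is None or "species" not in sample.labels:
            raise ValueError("species labels required")
        species = sample.labels["species"].to_numpy()
    species = np.asarray(species)
    order = tip_order if tip_order is not None else sorted(set(species))
    means = []
    for sp in order:
        mask = species == sp
        if not mask.any():
            raise MissingSpeciesError(f"species {sp!r} has no specimens")
        means.append(sample.coords[mask].mean(axis=0))
    return np.stack(means), list(order)


class GPAAligner(BaseEstimator, TransformerMixin):
    """sklearn-style transformer wrapping :func:`gpa_align`.

    ``fit`` runs the full GPA on the training sample and stores the
    consensus; ``transform`` aligns configurations (training or new) onto
    that consensus and returns flattened shape variables.
    """

    def __init__(self, tol: float = 1e-8, max_iter: int = 200,
                 tangent_project: bool = False):
        self.tol = tol
        self.max_iter = max_iter
        self.tangent_project = tangent_project

    def fit(self, X, y=None):
        sample = gpa_align(X, tol=self.tol, max_iter=self.max_iter,
                           tangent_project=self.tangent_project)
        self.sample_ = sample
        self.consensus_ = sample.consensus
        self.n_points_ = sample.consensus.shape[0]
        return self

    def transform(self, X) -> np.ndarray:
        if isinstance(X, np.ndarray):
            arr = X.astype(float)
        else:
            arr = stack_coords(list(X))
        out = np.empty_like(arr)
        for i, x in enumerate(arr):
            s, _ = _center_scale(x)
            out[i] = s @ _optimal_rotation(s, self.consensus_)
        return out.reshape(len(arr), -1)
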