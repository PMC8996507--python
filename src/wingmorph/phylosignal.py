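"""Multivariate phylogenetic signal (K_mult) and phylomorphospace.

K_mult generalizes Blomberg's K to multivariate (shape) data.  With species
mean vectors Y (N x p) and the Brownian covariance matrix C of the tree:

    a     = (1' C^-1 1)^-1 (1' C^-1 Y)          (GLS phylogenetic mean)
    MSE0  = sum_i ||Y_i - a||^2                 (observed mean-square deviation)
    MSE   = sum_i ||Z_i||^2,  Z = C^{-1/2} (Y - 1a)
    K     = (MSE0 / MSE) / [(tr C - N / (1' C^-1 1)) / (N - 1)]

K equals 1 in expectation when the data evolved by Brownian motion on the
given tree, and identically 1 on a star phylogeny (C proportional to I).
Significance comes from a tip-permutation null: species means are randomly
reassigned to tips, C held fixed.  The primary verdict is two-tailed — an
observed K below the 2.5th or above the 97.5th percentile of the permuted
distribution indicates less, or more, phylogenetic structure than expected
under a random phylogeny; a one-tailed permutation p accompanies it.

C^{-1/2} uses a symmetric eigendecomposition (stable for near-singular C).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .trees import Phylogeny, PhyloCovariance, phylo_covariance


class DegenerateDataError(ValueError):
    """Raised when the species means carry no variance."""


@dataclass
class KmultResult:
    K_observed: float
    MSE0: float
    MSE: float
    phylo_mean: np.ndarray
    permuted_K: np.ndarray
    p_value: float
    percentile_low: float
    percentile_high: float
    significant_low: bool
    significant_high: bool
    B: int
    seed: int | None

    @property
    def significant(self) -> bool:
        """Two-tailed 95% percentile verdict."""
        return self.significant_low or self.significant_high


def _kmult_parts(Y: np.ndarray, C: np.ndarray):
    N = len(Y)
    ones = np.ones(N)
    try:
        Cinv = np.linalg.inv(C)
    except np.linalg.LinAlgError:
        warnings.warn("singular phylogenetic covariance; using pseudo-inverse")
        Cinv = np.linalg.pinv(C)
    denom = ones @ Cinv @ ones
    a = (Cinv @ ones) @ Y / denom                       # (p,) GLS mean
    R = Y - a
    w, V = np.linalg.eigh(C)
    w = np.clip(w, 1e-12, None)
    Cinv_half = V @ np.diag(1.0 / np.sqrt(w)) @ V.T
    Z = Cinv_half @ R
    mse0 = float((R ** 2).sum())
    mse = float((Z ** 2).sum())
    expectation = (np.trace(C) - N / denom) / (N - 1)
    return a, mse0, mse, expectation


def kmult(species_means: np.ndarray, C: np.ndarray | PhyloCovariance) -> float:
    """The multivariate K statistic for tip data ordered as C's tips."""
    if isinstance(C, PhyloCovariance):
        C = C.C
    Y = np.asarray(species_means, dtype=float)
    if Y.ndim == 1:
        Y = Y[:, None]
    if len(Y) < 3:
        raise ValueError("at least 3 species required")
    if len(Y) != len(C):
        raise ValueError("species_means rows must match C")
    if np.allclose(Y, Y[0]):
        raise DegenerateDataError("species means have zero total variance")
    _, mse0, mse, expectation = _kmult_parts(Y, C)
    return (mse0 / mse) / expectation


def kmult_test(species_means: np.ndarray, tree: Phylogeny | PhyloCovariance | np.ndarray,
               B: int = 1000, seed: int | None = None) -> KmultResult:
    """Permutation test of K_mult: B random reassignments of species means to
    tips (rows of Y shuffled, C fixed)."""
    if B < 1:
        raise ValueError("B must be >= 1")
    if isinstance(tree, Phylogeny):
        C = phylo_covariance(tree).C
    elif isinstance(tree, PhyloCovariance):
        C = tree.C
    else:
        C = np.asarray(tree, dtype=float)
    Y = np.asarray(species_means, dtype=float)
    if Y.ndim == 1:
        Y = Y[:, None]
    a, mse0, mse, expectation = _kmult_parts(Y, C)
    K_obs = (mse0 / mse) / expectation

    rng = np.random.default_rng(seed)
    perm = np.empty(B)
    for b in range(B):
        Yp = Y[rng.permutation(len(Y))]
        _, m0, m, _ = _kmult_parts(Yp, C)
        perm[b] = (m0 / m) / expectation
    lo, hi = np.percentile(perm, [2.5, 97.5])
    p = (1 + int((perm >= K_obs).sum())) / (B + 1)
    return KmultResult(K_observed=float(K_obs), MSE0=mse0, MSE=mse,
                       phylo_mean=a, permuted_K=perm, p_value=float(p),
                       percentile_low=float(lo), percentile_high=float(hi),
                       significant_low=bool(K_obs < lo),
                       significant_high=bool(K_obs > hi),
                       B=B, seed=seed)


def ancestral_states(species_means: np.ndarray, tree: Phylogeny) -> tuple[np.ndarray, list]:
    """Maximum-likelihood Brownian ancestral estimates at internal nodes.

    Solves, per trait, the normal equations of minimizing
    sum_edges (delta^2 / branch length) over internal-node values — the GLS
    estimate, equivalent to weighted squared-change parsimony on ultrametric
    trees.  Polytomies are handled by the same computation.

    Returns (node values, internal node list in preorder; the root first).
    """
    Y = np.asarray(species_means, dtype=float)
    if Y.ndim == 1:
        Y = Y[:, None]
    tips = tree.tip_names
    tip_index = {name: i for i, name in enumerate(tips)}
    if len(Y) != len(tips):
        raise ValueError("species_means rows must match tree tips")

    internal = [nd for nd in tree.tree.preorder_node_iter() if not nd.is_leaf()]
    idx = {nd: i for i, nd in enumerate(internal)}
    n = len(internal)
    A = np.zeros((n, n))
    Bv = np.zeros((n, Y.shape[1]))
    for nd in internal:
        i = idx[nd]
        neighbors = list(nd.child_nodes())
        if nd.parent_node is not None:
            neighbors.append(nd.parent_node)
        for nb in neighbors:
            edge = nb.edge if nb in nd.child_nodes() else nd.edge
            bl = edge.length or 0.0
            wgt = 1.0 / max(bl, 1e-12)
            A[i, i] += wgt
            if nb.is_leaf():
                Bv[i] += wgt * Y[tip_index[nb.taxon.label]]
            else:
                A[i, idx[nb]] -= wgt
    states = np.linalg.solve(A, Bv)
    return states, internal


@dataclass
class Phylomorphospace:
    tip_scores: np.ndarray       # (N, 2) PC1-PC2 scores of tip means
    node_scores: np.ndarray      # (n_internal, 2) projected ancestors
    edges: list                  # (parent, child) index pairs; tips have
                                 # indices 0..N-1, internal nodes N..N+m-1
    basis: np.ndarray            # (p, 2) principal axes
    center: np.ndarray
    eigenvalues: np.ndarray
    n_crossings: int


def _segments_cross(p1, p2, p3, p4) -> bool:
    """Proper crossing of open segments p1p2 and p3p4 (shared endpoints do
    not count)."""
    d = lambda a, b, c: (b[0] - a[0]) * (c[1] - a[1]) - (b[1] - a[1]) * (c[0] - a[0])
    d1, d2 = d(p3, p4, p1), d(p3, p4, p2)
    d3, d4 = d(p1, p2, p3), d(p1, p2, p4)
    return (d1 * d2 < 0) and (d3 * d4 < 0)


def phylomorphospace(species_means: np.ndarray, tree: Phylogeny) -> Phylomorphospace:
    """Tip and ancestral-node scores on the first two Procrustes principal
    components, with the branch edge list and a count of branch crossings in
    the PC1-PC2 plane (extensive crossing = weak phylogenetic structuring)."""
    Y = np.asarray(species_means, dtype=float)
    Y = Y.reshape(len(Y), -1)
    if Y.shape[1] < 2:
        raise ValueError("at least 2 shape variables required")
    center = Y.mean(axis=0)
    Xc = Y - center
    _, s, vt = np.linalg.svd(Xc, full_matrices=False)
    basis = vt[:2].T
    for j in range(2):
        k = np.argmax(np.abs(basis[:, j]))
        if basis[k, j] < 0:
            basis[:, j] = -basis[:, j]
    tip_scores = Xc @ basis
    eig = (s ** 2) / max(len(Y) - 1, 1)

    anc, internal = ancestral_states(Y, tree)
    node_scores = (anc - center) @ basis

    tips = tree.tip_names
    tip_index = {name: i for i, name in enumerate(tips)}
    node_index = {nd: len(tips) + i for i, nd in enumerate(internal)}
    edges = []
    for nd in internal:
        for ch in nd.child_nodes():
            child = tip_index[ch.taxon.label] if ch.is_leaf() else node_index[ch]
            edges.append((node_index[nd], child))

    pts = np.vstack([tip_scores, node_scores])
    crossings = 0
    for a in range(len(edges)):
        for b in range(a + 1, len(edges)):
            e1, e2 = edges[a], edges[b]
            if set(e1) & set(e2):
                continue
            if _segments_cross(pts[e1[0]], pts[e1[1]], pts[e2[0]], pts[e2[1]]):
                crossings += 1
    return Phylomorphospace(tip_scores=tip_scores, node_scores=node_scores,
                            edges=edges, basis=basis, center=center,
                            eigenvalues=eig, n_crossings=crossings)
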