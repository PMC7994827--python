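"""SVD/PCA clustering of aligned per-residue flexibility profiles.

Percentile-ranked DFI profiles of m proteins are stacked column-wise over
their n commonly aligned positions, reduced with a truncated singular value
decomposition X = U Σ Vᵀ to protein coordinates X* = V* Σ* (the biplot
coordinates on the leading components), and compared by Euclidean distance
and hierarchical clustering.  Centering rows (subtracting each position's
mean over proteins) turns the reduction into standard PCA; the uncentered
variant applies the decomposition to the raw profile matrix.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.cluster.hierarchy import linkage, to_tree
from scipy.spatial.distance import pdist, squareform

from .enm_prs import FlexibilityProfile
from .hinge_design import AlignmentMap

DEFAULT_COMPONENTS = 2
DEFAULT_LINKAGE = "average"


@dataclass
class ProfileMatrix:
    """n aligned positions × m proteins of percentile-ranked DFI."""

    matrix: np.ndarray  # (n, m)
    labels: list[str]
    positions: np.ndarray  # reference residue indices of the rows

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2:
            raise ValueError("profile matrix must be 2-D")
        if self.matrix.shape[1] != len(self.labels):
            raise ValueError("label count must match column count")

    @property
    def n_positions(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_proteins(self) -> int:
        return self.matrix.shape[1]


@dataclass
class ReducedEmbedding:
    """Protein coordinates on the leading r singular components."""

    coords: np.ndarray  # (m, r)
    singular_values: np.ndarray  # the r retained values
    labels: list[str]
    centered: bool


def build_profile_matrix(profiles: list[FlexibilityProfile],
                         maps: list[AlignmentMap] | None = None,
                         labels: list[str] | None = None) -> ProfileMatrix:
    """Stack %DFI profiles over the positions aligned across all proteins.

    ``maps[k]`` aligns the first (reference) protein to protein k+1; with
    no maps all profiles must have equal length and align by index.  Only
    reference positions mapped in every alignment are retained (the common
    core), in reference order.
    """
    if len(profiles) < 2:
        raise ValueError("need at least two profiles to compare")
    labels = labels or [p.label or f"protein_{i}" for i, p in enumerate(profiles)]
    n_ref = profiles[0].n_residues
    if maps is None:
        if any(p.n_residues != n_ref for p in profiles):
            raise ValueError("profiles differ in length; alignments required")
        core = list(range(n_ref))
        lookup = [{i: i for i in core} for _ in profiles[1:]]
    else:
        if len(maps) != len(profiles) - 1:
            raise ValueError("need one alignment per non-reference profile")
        lookup = [m.b_of_a() for m in maps]
        core = [i for i in range(n_ref) if all(i in lk for lk in lookup)]
        if not core:
            raise ValueError("no positions aligned across all proteins")
    cols = [profiles[0].pct_dfi[core]]
    for p, lk in zip(profiles[1:], lookup):
        cols.append(p.pct_dfi[[lk[i] for i in core]])
    return ProfileMatrix(matrix=np.column_stack(cols), labels=list(labels),
                         positions=np.asarray(core))


def svd_reduce(pm: ProfileMatrix, r: int = DEFAULT_COMPONENTS,
               center: bool = True) -> ReducedEmbedding:
    """Reduce the profile matrix to protein coordinates on r components.

    X (optionally row-centered) is decomposed as U Σ Vᵀ and each protein
    gets coordinates V* Σ* over the r largest singular values.  ``center``
    subtracts every position's mean across proteins first (ordinary PCA);
    without it the decomposition acts on the raw matrix.  The sign of each
    component is fixed so its largest-magnitude position loading is
    positive, making the embedding reproducible bit-for-bit.
    """
    if r < 1:
        raise ValueError("r must be ≥ 1")
    if r > min(pm.matrix.shape):
        raise ValueError(f"r={r} exceeds min(n, m)={min(pm.matrix.shape)}")
    x = pm.matrix - pm.matrix.mean(axis=1, keepdims=True) if center else pm.matrix
    u, s, vt = np.linalg.svd(x, full_matrices=False)
    tol = max(x.shape) * np.finfo(float).eps
    if s[0] <= tol * max(np.linalg.norm(pm.matrix), 1.0):
        # centering annihilated the data (e.g. identical profiles):
        # every protein sits at the origin of every component
        return ReducedEmbedding(coords=np.zeros((pm.n_proteins, r)),
                                singular_values=np.zeros(r),
                                labels=pm.labels, centered=center)
    rank = int(np.sum(s > s[0] * tol))
    if r > rank:
        raise ValueError(f"r={r} exceeds matrix rank {rank}")
    coords = vt[:r].T * s[:r]
    # deterministic sign: largest-|loading| entry of each left vector positive
    for k in range(r):
        j = int(np.argmax(np.abs(u[:, k])))
        if u[j, k] < 0:
            coords[:, k] = -coords[:, k]
    return ReducedEmbedding(coords=coords, singular_values=s[:r].copy(),
                            labels=pm.labels, centered=center)


def pairwise_distances(emb: ReducedEmbedding) -> np.ndarray:
    """m×m Euclidean distance matrix between protein coordinates."""
    return squareform(pdist(emb.coords))


def dendrogram_linkage(dist: np.ndarray, method: str = DEFAULT_LINKAGE) -> np.ndarray:
    """Agglomerative merge tree (scipy linkage matrix) from a distance matrix."""
    dist = np.asarray(dist, dtype=float)
    if dist.shape[0] < 2:
        raise ValueError("need at least two items to cluster")
    return linkage(squareform(dist, checks=False), method=method)


def linkage_to_newick(z: np.ndarray, labels: list[str]) -> str:
    """Serialize a scipy linkage matrix as a Newick tree with branch lengths."""
    tree = to_tree(z)

    def rec(node, parent_height: float) -> str:
        length = parent_height - (0.0 if node.is_leaf() else node.dist)
        if node.is_leaf():
            return f"{labels[node.id]}:{parent_height:.6g}"
        left = rec(node.get_left(), node.dist)
        right = rec(node.get_right(), node.dist)
        return f"({left},{right}):{length:.6g}"

    if tree.is_leaf():
        return f"{labels[tree.id]};"
    left = rec(tree.get_left(), tree.dist)
    right = rec(tree.get_right(), tree.dist)
    return f"({left},{right});"
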