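"""Elastic-network Hessian, covariance, perturbation-response scanning, DFI and DCI.

The chain is coarse-grained to Cα nodes joined by harmonic springs within a
distance cutoff (anisotropic network model).  Linear response theory gives
the displacement caused by a force applied at one residue as ΔR = G F, with
G the positional covariance — either the pseudo-inverse of the network
Hessian or an estimate from a conformational ensemble.  Scanning a unit
force over every site and averaging the squared response over force
directions yields the N×N response matrix, from which the dynamic
flexibility index (DFI, the share of total response concentrated at a
residue) and the dynamic coupling index (DCI, preferential response to a
functional subset) follow.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.sparse.csgraph import connected_components
from scipy.spatial.distance import pdist, squareform

from .structure_model import StructureModel

DEFAULT_CUTOFF = 13.0  # Å
DEFAULT_GAMMA = 1.0
ZERO_MODE_TOL = 1e-10  # eigenvalues below tol·λ_max are rigid-body modes


class NetworkConnectivityError(ValueError):
    """The spring network is disconnected at the chosen cutoff."""


@dataclass
class Hessian:
    """3N×3N second-derivative matrix of the harmonic network."""

    matrix: np.ndarray
    cutoff: float
    gamma: float

    @property
    def n_residues(self) -> int:
        return self.matrix.shape[0] // 3


@dataclass
class CovarianceMatrix:
    """3N×3N positional covariance G (Å²) with its provenance."""

    matrix: np.ndarray
    provenance: str  # "enm_pseudoinverse" | "ensemble_estimate"

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        n3 = self.matrix.shape[0]
        if self.matrix.shape != (n3, n3) or n3 % 3:
            raise ValueError("covariance must be square with 3N rows")

    @property
    def n_residues(self) -> int:
        return self.matrix.shape[0] // 3


@dataclass
class ResponseMatrix:
    """N×N matrix of |ΔR^j|_i: response magnitude at residue i to a unit
    force scanned over residue j, averaged over force directions."""

    matrix: np.ndarray
    force_model: str  # "closed_form" | "monte_carlo(M,seed)"

    @property
    def n_residues(self) -> int:
        return self.matrix.shape[0]


@dataclass
class FlexibilityProfile:
    """Per-residue DFI (sums to 1) and its percentile rank %DFI."""

    dfi: np.ndarray
    pct_dfi: np.ndarray
    label: str = ""

    @property
    def n_residues(self) -> int:
        return self.dfi.size


@dataclass
class CouplingProfile:
    """Per-residue DCI for a stated functional set, with percentile ranks."""

    dci: np.ndarray
    pct_dci: np.ndarray
    functional: np.ndarray
    label: str = ""


def build_hessian(structure: StructureModel, cutoff: float = DEFAULT_CUTOFF,
                  gamma: float = DEFAULT_GAMMA,
                  spring_scale: dict[int, float] | None = None) -> Hessian:
    """Anisotropic-network Hessian of a Cα structure.

    Residue pairs with Cα–Cα distance ≤ ``cutoff`` are joined by a spring of
    constant ``gamma``; the 3×3 off-diagonal block for a contact (i, j) is
    −γ_ij · d dᵀ / |d|² with d the displacement vector, and diagonal blocks
    make every block row sum to zero (translation invariance).

    ``spring_scale`` maps residue indices to a multiplicative factor applied
    to every contact touching that residue (a factor on both endpoints is
    applied once) — the hook used to emulate rigidifying or softening
    substitutions.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    xyz = structure.ca_xyz
    n = structure.n_residues
    dist = squareform(pdist(xyz))
    contact = (dist <= cutoff) & ~np.eye(n, dtype=bool)

    n_comp, _ = connected_components(contact, directed=False)
    if n_comp > 1:
        raise NetworkConnectivityError(
            f"network splits into {n_comp} components at cutoff {cutoff} Å; "
            "increase the cutoff"
        )

    h = np.zeros((3 * n, 3 * n))
    ii, jj = np.where(np.triu(contact, k=1))
    for i, j in zip(ii, jj):
        d = xyz[j] - xyz[i]
        g = gamma
        if spring_scale and (i in spring_scale or j in spring_scale):
            g = g * spring_scale.get(i, spring_scale.get(j))
        block = -g * np.outer(d, d) / (d @ d)
        h[3 * i:3 * i + 3, 3 * j:3 * j + 3] = block
        h[3 * j:3 * j + 3, 3 * i:3 * i + 3] = block
        h[3 * i:3 * i + 3, 3 * i:3 * i + 3] -= block
        h[3 * j:3 * j + 3, 3 * j:3 * j + 3] -= block
    return Hessian(matrix=h, cutoff=cutoff, gamma=gamma)


def covariance_from_hessian(h: Hessian, zero_mode_tol: float = ZERO_MODE_TOL) -> CovarianceMatrix:
    """Moore–Penrose pseudo-inverse of the Hessian with rigid-body modes removed.

    Eigenvalues below ``zero_mode_tol``·λ_max are treated as the six
    translational/rotational zero modes and projected out; more than six
    such modes indicates a disconnected or degenerate network.
    """
    evals, evecs = np.linalg.eigh(h.matrix)
    lam_max = evals[-1]
    zero = evals < zero_mode_tol * lam_max
    n_zero = int(zero.sum())
    if n_zero > 6:
        raise NetworkConnectivityError(
            f"{n_zero} near-zero modes (expected 6): network disconnected or collinear"
        )
    keep = ~zero
    g = (evecs[:, keep] / evals[keep]) @ evecs[:, keep].T
    g = 0.5 * (g + g.T)
    return CovarianceMatrix(matrix=g, provenance="enm_pseudoinverse")


def _blocks(g: np.ndarray) -> np.ndarray:
    """View the 3N×3N covariance as an (N, 3, N, 3) block array."""
    n = g.shape[0] // 3
    return g.reshape(n, 3, n, 3)


def response_matrix(g: CovarianceMatrix, force_model: str = "closed_form",
                    n_forces: int = 10_000, seed: int | None = None) -> ResponseMatrix:
    """Perturbation-response scanning of a covariance matrix.

    A unit force f is applied at residue j; linear response gives the
    displacement of residue i as B_ij f with B_ij the 3×3 covariance block.
    Entry (i, j) is sqrt(⟨|ΔR|²⟩), the root-mean-square response magnitude
    averaged over force directions uniform on the sphere.

    ``closed_form`` uses the exact sphere average ⟨|B f|²⟩ = ‖B‖_F²/3.
    ``monte_carlo`` draws ``n_forces`` random unit forces per perturbed
    site (seeded, reproducible) and averages the squared responses; it is
    the stochastic reference for the closed form.
    """
    gm = g.matrix
    n = g.n_residues
    if force_model == "closed_form":
        b = _blocks(gm)
        sq = np.einsum("iajb,iajb->ij", b, b) / 3.0
        return ResponseMatrix(matrix=np.sqrt(sq), force_model="closed_form")
    if force_model == "monte_carlo":
        if n_forces < 1:
            raise ValueError("n_forces must be ≥ 1")
        rng = np.random.default_rng(seed)
        out = np.empty((n, n))
        for j in range(n):
            f = rng.normal(size=(3, n_forces))
            f /= np.linalg.norm(f, axis=0, keepdims=True)
            dr = gm[:, 3 * j:3 * j + 3] @ f  # (3N, M)
            sq = dr.reshape(n, 3, n_forces) ** 2
            out[:, j] = np.sqrt(sq.sum(axis=1).mean(axis=1))
        return ResponseMatrix(matrix=out, force_model=f"monte_carlo({n_forces},{seed})")
    raise ValueError(f"unknown force model {force_model!r}")


def dfi(a: ResponseMatrix, label: str = "") -> FlexibilityProfile:
    """Dynamic flexibility index: DFI_i = Σ_j A_ij / Σ_ij A_ij.

    The profile sums to one; a residue's DFI is the fraction of the total
    perturbation response concentrated at it when every site is perturbed
    in turn.  %DFI is its percentile rank within the protein.
    """
    total = a.matrix.sum()
    if total <= 0:
        raise ValueError("response matrix is all zero; DFI undefined")
    scores = a.matrix.sum(axis=1) / total
    return FlexibilityProfile(dfi=scores, pct_dfi=percentile_rank(scores), label=label)


def percentile_rank(values: np.ndarray) -> np.ndarray:
    """Fractional rank in (0, 1]: rank_i = #{j : value_j ≤ value_i} / N.

    Ties share the maximal rank, so a residue with rank 0.1 is among the
    10% lowest values.  The maximal-rank tie rule keeps hinge calls
    (rank < threshold) conservative.
    """
    values = np.asarray(values, dtype=float)
    order = np.sort(values)
    return np.searchsorted(order, values, side="right") / values.size


def dci(a: ResponseMatrix, functional: np.ndarray, label: str = "") -> CouplingProfile:
    """Dynamic coupling index of each residue to a functional residue set.

    DCI_i = mean_{j∈functional} A_ij / mean_{j=1..N} A_ij — the response of
    residue i to perturbations of the functional sites relative to its
    response to perturbations anywhere.  DCI ≡ 1 when the functional set is
    all residues; values above 1 mark preferential coupling.
    """
    functional = np.asarray(functional, dtype=int)
    if functional.size == 0:
        raise ValueError("functional set must be non-empty")
    n = a.n_residues
    if functional.min() < 0 or functional.max() >= n:
        raise ValueError("functional indices out of range")
    den = a.matrix.mean(axis=1)
    if functional.size == n and np.array_equal(np.sort(functional), np.arange(n)):
        num = den  # full set: ratio of identical means, exactly one
    else:
        num = a.matrix[:, functional].mean(axis=1)
    scores = num / den
    return CouplingProfile(dci=scores, pct_dci=percentile_rank(scores),
                           functional=functional, label=label)


def pairwise_dci(a: ResponseMatrix) -> np.ndarray:
    """Pairwise coupling DCI_i^j = A_ij / (Σ_j A_ij / N); every row has mean 1."""
    return a.matrix / a.matrix.mean(axis=1, keepdims=True)


def percentile_pairwise_dci(pw: np.ndarray, rank_within: str = "perturbed") -> np.ndarray:
    """Percentile-rank a pairwise DCI matrix for threshold-based selection.

    ``rank_within="perturbed"`` (default) ranks, for each perturbed site j,
    the couplings DCI_·^j across responding residues — a residue above 0.8
    is among the 20% strongest responders to that site.  ``"global"`` ranks
    all entries of the matrix jointly.
    """
    pw = np.asarray(pw, dtype=float)
    if rank_within == "perturbed":
        out = np.empty_like(pw)
        for j in range(pw.shape[1]):
            out[:, j] = percentile_rank(pw[:, j])
        return out
    if rank_within == "global":
        return percentile_rank(pw.ravel()).reshape(pw.shape)
    raise ValueError(f"unknown ranking scope {rank_within!r}")


def dfi_from_structure(structure: StructureModel, cutoff: float = DEFAULT_CUTOFF,
                       gamma: float = DEFAULT_GAMMA, label: str = "") -> FlexibilityProfile:
    """Convenience: structure → ANM Hessian → covariance → PRS → DFI."""
    g = covariance_from_hessian(build_hessian(structure, cutoff=cutoff, gamma=gamma))
    return dfi(response_matrix(g), label=label or structure.label)
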