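"""Synthetic structures, ground-truth covariances and Gaussian ensembles.

Every stage of the pipeline can be exercised without external data: toy Cα
topologies (jittered chain, ideal α-helix, two helices with a linker), the
elastic-network covariance of such a fixture as a known ground truth, and
coordinate ensembles drawn from the corresponding Gaussian — optionally
composed with random rigid-body motions to exercise superposition.

"Mutants" are emulated by scaling the spring constants of contacts touching
chosen residues: stiffening rigidifies a position (lowers its DFI),
softening does the opposite.  This is the minimal perturbation with an
exactly known ground-truth covariance, which is what recovery and
hinge-shift tests need; it makes no claim to side-chain chemistry.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.transform import Rotation

from .enm_prs import (
    DEFAULT_CUTOFF,
    DEFAULT_GAMMA,
    CovarianceMatrix,
    build_hessian,
    covariance_from_hessian,
)
from .structure_model import EnsembleTrajectory, StructureModel

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

# ideal α-helix geometry: 1.5 Å rise and 100° rotation per residue at 2.3 Å radius
HELIX_RISE = 1.5
HELIX_TWIST_DEG = 100.0
HELIX_RADIUS = 2.3
CHAIN_SPACING = 3.8  # consecutive Cα distance along an extended trace


@dataclass
class FixtureSpec:
    """Recipe for one synthetic fixture."""

    topology: str = "helix"  # chain | helix | two-domain
    n_residues: int = 10
    spacing: float = CHAIN_SPACING
    perturbation: dict | None = None  # {"positions": [...], "factor": float}
    seed: int = 0

    def __post_init__(self) -> None:
        if self.topology not in ("chain", "helix", "two-domain"):
            raise ValueError(f"unknown topology {self.topology!r}")
        if self.n_residues < 3:
            raise ValueError("need at least 3 residues")
        if self.spacing <= 0:
            raise ValueError("spacing must be positive")
        if self.perturbation is not None and self.perturbation.get("factor", 1.0) <= 0:
            raise ValueError("perturbation factor must be positive")


def _helix_coords(n: int) -> np.ndarray:
    theta = np.deg2rad(HELIX_TWIST_DEG) * np.arange(n)
    return np.column_stack(
        [HELIX_RADIUS * np.cos(theta), HELIX_RADIUS * np.sin(theta),
         HELIX_RISE * np.arange(n)]
    )


def make_structure(spec: FixtureSpec) -> StructureModel:
    """Deterministic toy Cα trace for a fixture spec.

    ``chain``: Cα beads along x at ``spacing`` with seeded transverse jitter
    (so the trace is never collinear and superposition stays well-posed) —
    meant for tiny fixtures, since the bending mode of a long straight
    elastic chain softens toward the rigid-body null space; ``helix``:
    ideal α-helix; ``two-domain``: an antiparallel helix hairpin, the
    fixture of choice for larger systems.  The sequence is a seeded random
    draw over the 20 amino acids so alignment-based stages see realistic
    conservation.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_residues
    if spec.topology == "chain":
        xyz = np.column_stack([spec.spacing * np.arange(n, dtype=float),
                               np.zeros(n), np.zeros(n)])
        # ±~1 Å transverse wiggle: breaks collinearity and keeps the bending
        # stiffness of long chains well away from the rigid-body null space
        xyz[:, 1:] += rng.normal(scale=1.0, size=(n, 2))
    elif spec.topology == "helix":
        xyz = _helix_coords(n)
    else:  # two-domain
        # antiparallel helix hairpin: two packed helices joined by a loop,
        # so inter-domain contacts span varied directions (no floppy torsion)
        n_link = max(2, int(round(0.15 * n)))
        n1 = (n - n_link + 1) // 2
        n2 = n - n_link - n1
        h1 = _helix_coords(n1)
        h2_local = _helix_coords(n2)
        axis_sep = 8.0  # Å between helix axes, typical helix packing
        h2 = h2_local * np.array([1.0, 1.0, -1.0]) + np.array(
            [axis_sep, 1.0, h1[-1, 2] + 2.0]
        )
        t = np.linspace(0.0, 1.0, n_link + 2)[1:-1, None]
        loop = (1 - t) * h1[-1] + t * h2[0]
        loop[:, 1] += 3.0 * np.sin(np.pi * t[:, 0])  # arc out of the helix plane
        loop[:, 2] += 2.0
        xyz = np.vstack([h1, loop, h2])
    seq = "".join(rng.choice(list(AMINO_ACIDS), size=n))
    return StructureModel(
        author_resid=[str(i + 1) for i in range(n)],
        chain_id="A", aa=seq, ca_xyz=xyz,
        label=f"{spec.topology}{n}-seed{spec.seed}",
    )


def make_ground_truth_covariance(spec: FixtureSpec, cutoff: float = DEFAULT_CUTOFF,
                                 gamma: float = DEFAULT_GAMMA) -> CovarianceMatrix:
    """Elastic-network covariance of the fixture, the known G for recovery tests.

    The spec's ``perturbation`` scales the spring constant of every contact
    touching the listed positions by ``factor`` — the synthetic stand-in
    for a rigidifying (factor > 1) or softening (factor < 1) substitution.
    """
    structure = make_structure(spec)
    scale = None
    if spec.perturbation:
        factor = float(spec.perturbation.get("factor", 1.0))
        scale = {int(p): factor for p in spec.perturbation.get("positions", [])}
    h = build_hessian(structure, cutoff=cutoff, gamma=gamma, spring_scale=scale)
    return covariance_from_hessian(h)


def sample_ensemble(g: CovarianceMatrix, mean: StructureModel, n_frames: int,
                    frame_spacing: float = 0.1, seed: int = 0,
                    rigid_motions: bool = False) -> EnsembleTrajectory:
    """Draw coordinate frames from N(mean, G).

    Displacements are generated through the symmetric square root of G over
    its nonzero modes, so the population covariance of the frames is
    exactly G.  With ``rigid_motions`` each frame is additionally rotated
    and translated at random, emulating the arbitrary global pose of
    simulation snapshots that superposition must remove.
    """
    if n_frames < 2:
        raise ValueError("need at least 2 frames")
    evals, evecs = np.linalg.eigh(g.matrix)
    tol = 1e-10 * max(evals[-1], 1.0)
    if evals[0] < -tol:
        raise ValueError("covariance is not positive semi-definite")
    keep = evals > tol
    root = evecs[:, keep] * np.sqrt(evals[keep])
    rng = np.random.default_rng(seed)
    z = rng.normal(size=(n_frames, int(keep.sum())))
    disp = z @ root.T  # (n_frames, 3N)
    frames = mean.ca_xyz[None, :, :] + disp.reshape(n_frames, -1, 3)
    if rigid_motions:
        rots = Rotation.random(n_frames, rng)
        shifts = rng.uniform(-20.0, 20.0, size=(n_frames, 3))
        for m in range(n_frames):
            frames[m] = frames[m] @ rots[m].as_matrix().T + shifts[m]
    return EnsembleTrajectory(frames=frames, frame_spacing=frame_spacing,
                              atom_selection="ca")


@dataclass
class HingeShiftPair:
    """An (original, perturbed) fixture pair emulating a hinge shift."""

    structure_a: StructureModel
    structure_b: StructureModel
    cov_a: CovarianceMatrix
    cov_b: CovarianceMatrix
    stiffened: list[int] = field(default_factory=list)
    softened: list[int] = field(default_factory=list)


def make_hinge_shift_pair(spec: FixtureSpec, stiffen: list[int], soften: list[int],
                          stiffen_factor: float = 10.0, soften_factor: float = 0.1,
                          mutate_only: list[int] | None = None,
                          cutoff: float = DEFAULT_CUTOFF,
                          gamma: float = DEFAULT_GAMMA) -> HingeShiftPair:
    """Build protein A (the fixture) and protein B (springs rescaled, sequence
    mutated at the perturbed positions) for hinge-shift re-enactment.

    Stiffened contacts rigidify their residues so they gain hinge character
    in B; softened ones lose it.  B's sequence differs from A's exactly at
    the perturbed positions, so those sites are sequentially non-conserved.
    ``mutate_only`` positions get a substitution without any spring change —
    dynamics-neutral sequence divergence, e.g. non-conserved common hinges.
    """
    structure_a = make_structure(spec)
    h_a = build_hessian(structure_a, cutoff=cutoff, gamma=gamma)
    cov_a = covariance_from_hessian(h_a)

    scale = {int(p): float(stiffen_factor) for p in stiffen}
    scale.update({int(p): float(soften_factor) for p in soften})
    h_b = build_hessian(structure_a, cutoff=cutoff, gamma=gamma, spring_scale=scale)
    cov_b = covariance_from_hessian(h_b)

    seq = list(structure_a.aa)
    for p in list(stiffen) + list(soften) + list(mutate_only or []):
        idx = AMINO_ACIDS.index(seq[p])
        seq[p] = AMINO_ACIDS[(idx + 1) % len(AMINO_ACIDS)]
    structure_b = StructureModel(
        author_resid=list(structure_a.author_resid), chain_id=structure_a.chain_id,
        aa="".join(seq), ca_xyz=structure_a.ca_xyz.copy(),
        label=structure_a.label + "-shift",
    )
    return HingeShiftPair(structure_a=structure_a, structure_b=structure_b,
                          cov_a=cov_a, cov_b=cov_b,
                          stiffened=list(stiffen), softened=list(soften))
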