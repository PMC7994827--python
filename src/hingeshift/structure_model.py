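"""Coarse-grained protein structures, ensembles and rigid-body superposition.

Proteins are represented at the residue level by their Cα atoms (optionally
with the N/Cα/C/O backbone); this is the geometric substrate for the
elastic-network and covariance machinery in the rest of the package.
Structures are read from PDB files; multi-model PDB files double as the
canonical coordinate-ensemble format.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from Bio.Data.IUPACData import protein_letters_3to1
from Bio.PDB import PDBParser

logger = logging.getLogger(__name__)

#: order of backbone heavy atoms carried per residue when available
BACKBONE_ATOMS = ("N", "CA", "C", "O")

_THREE_TO_ONE = {k.upper(): v for k, v in protein_letters_3to1.items()}


class StructureError(ValueError):
    """Raised for unusable structural input (missing chain, no Cα, ...)."""


@dataclass
class StructureModel:
    """Per-residue Cα (and optional backbone) coordinates of one chain.

    ``residue_index`` is implicit: arrays are ordered 0..N-1 over parsed
    residues. ``author_resid`` keeps the residue numbering of the source
    file (with insertion codes appended) so reports can use the numbering
    practitioners know, while all internal indexing is 0-based sequential.
    """

    author_resid: list[str]
    chain_id: str
    aa: str  # one-letter sequence, X for unknown residues
    ca_xyz: np.ndarray  # (N, 3) Å
    backbone_xyz: np.ndarray | None = None  # (N, 4, 3) N/CA/C/O, NaN if absent
    label: str = ""

    def __post_init__(self) -> None:
        self.ca_xyz = np.asarray(self.ca_xyz, dtype=float)
        n = self.ca_xyz.shape[0]
        if n < 3:
            raise StructureError(f"need at least 3 residues, got {n}")
        if self.ca_xyz.shape != (n, 3) or not np.all(np.isfinite(self.ca_xyz)):
            raise StructureError("Cα coordinates must be a finite (N, 3) array")
        if len(self.author_resid) != n or len(self.aa) != n:
            raise StructureError("author_resid/aa length mismatch with coordinates")

    @property
    def n_residues(self) -> int:
        return self.ca_xyz.shape[0]

    @property
    def sequence(self) -> str:
        return self.aa


@dataclass
class EnsembleTrajectory:
    """Ordered coordinate frames congruent with a :class:`StructureModel`.

    ``atom_selection`` is ``"ca"`` (one atom per residue) or ``"backbone"``
    (four atoms per residue in :data:`BACKBONE_ATOMS` order).  ``ca_indices``
    maps residues to rows of each frame.
    """

    frames: np.ndarray  # (n_frames, n_atoms, 3)
    frame_spacing: float  # ns per frame
    atom_selection: str = "ca"
    ca_indices: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 3 or self.frames.shape[2] != 3:
            raise ValueError("frames must have shape (n_frames, n_atoms, 3)")
        if self.frame_spacing <= 0:
            raise ValueError("frame_spacing must be positive (ns)")
        if self.atom_selection not in ("ca", "backbone"):
            raise ValueError("atom_selection must be 'ca' or 'backbone'")
        if self.ca_indices is None:
            if self.atom_selection == "ca":
                self.ca_indices = np.arange(self.frames.shape[1])
            else:
                self.ca_indices = np.arange(self.frames.shape[1])[1::4]
        self.ca_indices = np.asarray(self.ca_indices, dtype=int)

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def n_residues(self) -> int:
        return self.ca_indices.size

    @property
    def duration(self) -> float:
        """Trajectory length in ns."""
        return self.n_frames * self.frame_spacing


def _residue_one_letter(resname: str) -> str:
    return _THREE_TO_ONE.get(resname.strip().upper(), "X")


def _select_altloc(residue, name: str):
    """Return the atom `name`, resolving altlocs by occupancy then file order."""
    if name not in residue:
        return None
    atom = residue[name]
    if atom.is_disordered():
        children = sorted(
            atom.child_dict.values(),
            key=lambda a: (-(a.get_occupancy() or 0.0), a.get_serial_number()),
        )
        return children[0]
    return atom


def _parse_chain(path, chain: str | None, model_index: int):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # tolerate nonstandard fixture PDBs
        structure = PDBParser(QUIET=True).get_structure("s", str(path))
    models = list(structure)
    if not models:
        raise StructureError(f"no models found in {path}")
    if model_index >= len(models):
        raise StructureError(
            f"model {model_index} requested but file has {len(models)} model(s)"
        )
    model = models[model_index]
    chain_ids = [c.id for c in model]
    if chain is None:
        chain = chain_ids[0]
    if chain not in chain_ids:
        raise StructureError(f"chain {chain!r} not in {path} (has {chain_ids})")
    return structure, model[chain]


def _chain_records(chain_obj):
    """Yield (resid_label, one_letter, ca_atom, residue) for ATOM residues with a Cα."""
    for residue in chain_obj:
        hetflag, resseq, icode = residue.id
        if hetflag.strip():  # HETATM / water: the model is Cα coarse-grained
            continue
        ca = _select_altloc(residue, "CA")
        label = f"{resseq}{icode.strip()}"
        if ca is None:
            logger.warning("residue %s %s lacks a Cα atom; skipped", residue.resname, label)
            continue
        yield label, _residue_one_letter(residue.resname), ca, residue


def read_structure(path, chain: str | None = None, model: int = 0,
                   backbone: bool = False, label: str = "") -> StructureModel:
    """Read one chain of one PDB model into a :class:`StructureModel`.

    Residues without a Cα atom are skipped with a logged warning; altlocs
    resolve to the highest-occupancy (then first-listed) conformer;
    insertion codes are kept as distinct residues; HETATM records are
    ignored.

    Parameters
    ----------
    path : PDB file path
    chain : chain identifier; default = first chain in the model
    model : 0-based model index
    backbone : also collect N/Cα/C/O coordinates where present
    """
    _, chain_obj = _parse_chain(path, chain, model)
    resids, letters, coords, bb = [], [], [], []
    for rlabel, one, ca, residue in _chain_records(chain_obj):
        resids.append(rlabel)
        letters.append(one)
        coords.append(ca.get_coord())
        if backbone:
            row = np.full((4, 3), np.nan)
            for k, name in enumerate(BACKBONE_ATOMS):
                atom = _select_altloc(residue, name)
                if atom is not None:
                    row[k] = atom.get_coord()
            bb.append(row)
    if not coords:
        raise StructureError(f"no Cα atoms found in chain of {path}")
    if len(coords) < 3:
        raise StructureError(f"only {len(coords)} Cα residues in {path}; need ≥3")
    return StructureModel(
        author_resid=resids,
        chain_id=chain_obj.id,
        aa="".join(letters),
        ca_xyz=np.array(coords, dtype=float),
        backbone_xyz=np.array(bb) if backbone else None,
        label=label or str(path),
    )


def read_ensemble(path, chain: str | None = None, frame_spacing: float = 1.0,
                  atom_selection: str = "ca") -> tuple[StructureModel, EnsembleTrajectory]:
    """Read a multi-model PDB as (first-model structure, coordinate ensemble).

    All models must present the same residues; frames carry Cα atoms only
    (``atom_selection="ca"``) or the N/Cα/C/O backbone where every residue
    has all four atoms (``"backbone"``).
    """
    structure, chain_obj = _parse_chain(path, chain, 0)
    ref = read_structure(path, chain=chain_obj.id, model=0,
                         backbone=(atom_selection == "backbone"), label=str(path))
    frames = []
    for model in structure:
        ch = model[chain_obj.id]
        coords = []
        for _, _, ca, residue in _chain_records(ch):
            if atom_selection == "ca":
                coords.append(ca.get_coord())
            else:
                for name in BACKBONE_ATOMS:
                    atom = _select_altloc(residue, name)
                    if atom is None:
                        raise StructureError(
                            f"backbone atom {name} missing in model {model.id}; "
                            "use atom_selection='ca'"
                        )
                    coords.append(atom.get_coord())
        frames.append(coords)
    frames = np.array(frames, dtype=float)
    if frames.ndim != 3:
        raise StructureError("models carry differing atom counts; not an ensemble")
    return ref, EnsembleTrajectory(frames=frames, frame_spacing=frame_spacing,
                                   atom_selection=atom_selection)


def kabsch_superpose(mobile: np.ndarray, reference: np.ndarray,
                     fit_atoms: np.ndarray | None = None) -> tuple[np.ndarray, float]:
    """Least-squares rigid superposition of ``mobile`` onto ``reference``.

    Returns the rotated+translated copy of all mobile atoms and the RMSD
    over ``fit_atoms`` (default: all atoms).  The optimal rotation is the
    Kabsch solution with reflections disallowed (determinant +1).

    Raises
    ------
    ValueError
        for mismatched shapes, fewer than 3 fit atoms, or a collinear
        (rank-deficient) fit set, for which the rotation is not determined.
    """
    mobile = np.asarray(mobile, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if mobile.shape != reference.shape:
        raise ValueError("mobile and reference must have identical shapes")
    if fit_atoms is None:
        fit_atoms = np.arange(mobile.shape[0])
    fit_atoms = np.asarray(fit_atoms, dtype=int)
    if fit_atoms.size < 3:
        raise ValueError("need at least 3 fit atoms")

    x = mobile[fit_atoms]
    y = reference[fit_atoms]
    xc, yc = x.mean(axis=0), y.mean(axis=0)
    x0, y0 = x - xc, y - yc
    # collinear point sets leave a rotation axis free
    if np.linalg.matrix_rank(x0, tol=1e-8 * max(1.0, np.abs(x0).max())) < 2:
        raise ValueError("fit set is collinear; superposition is degenerate")

    h = x0.T @ y0
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    rot = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    moved = (mobile - xc) @ rot.T + yc
    rmsd = float(np.sqrt(np.mean(np.sum((moved[fit_atoms] - reference[fit_atoms]) ** 2, axis=1))))
    return moved, rmsd


def write_bfactor_pdb(structure: StructureModel, values: np.ndarray, path) -> None:
    """Write the structure as a PDB with per-residue ``values`` in the B-factor column.

    Every atom of residue *i* (Cα, plus backbone atoms when present) carries
    ``values[i]``, e.g. a %DFI profile for color-coded rendering.
    """
    values = np.asarray(values, dtype=float)
    if values.shape != (structure.n_residues,):
        raise ValueError(
            f"values length {values.size} != residue count {structure.n_residues}"
        )
    if not np.all(np.isfinite(values)):
        raise ValueError("values must be finite")

    lines = []
    serial = 0

    def atom_line(name: str, resname: str, resid: str, xyz, bfac: float) -> str:
        nonlocal serial
        serial += 1
        icode = resid[-1] if resid and resid[-1].isalpha() else " "
        resseq = int(resid[:-1]) if icode != " " else int(resid)
        pad_name = f" {name:<3s}" if len(name) < 4 else name
        return (
            f"ATOM  {serial:5d} {pad_name}{'':1s}{resname:>3s} "
            f"{structure.chain_id:1s}{resseq:4d}{icode:1s}   "
            f"{xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}{1.0:6.2f}{bfac:6.2f}"
            f"          {name[0]:>2s}"
        )

    one_to_three = {v.upper(): k.upper() for k, v in protein_letters_3to1.items()}
    for i in range(structure.n_residues):
        resname = one_to_three.get(structure.aa[i], "UNK")
        resid = structure.author_resid[i]
        if structure.backbone_xyz is not None and np.all(np.isfinite(structure.backbone_xyz[i])):
            for k, name in enumerate(BACKBONE_ATOMS):
                lines.append(atom_line(name, resname, resid, structure.backbone_xyz[i, k], values[i]))
        else:
            lines.append(atom_line("CA", resname, resid, structure.ca_xyz[i], values[i]))
    lines.append("END")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def write_ensemble_pdb(structure: StructureModel, traj: EnsembleTrajectory, path) -> None:
    """Write a Cα ensemble as a multi-model PDB congruent with ``structure``."""
    if traj.atom_selection != "ca":
        raise ValueError("only Cα ensembles are written")
    one_to_three = {v.upper(): k.upper() for k, v in protein_letters_3to1.items()}
    with open(path, "w") as fh:
        for m in range(traj.n_frames):
            fh.write(f"MODEL     {m + 1:4d}\n")
            for i in range(structure.n_residues):
                resname = one_to_three.get(structure.aa[i], "UNK")
                resid = structure.author_resid[i]
                icode = resid[-1] if resid[-1].isalpha() else " "
                resseq = int(resid[:-1]) if icode != " " else int(resid)
                x, y, z = traj.frames[m, traj.ca_indices[i]]
                fh.write(
                    f"ATOM  {i + 1:5d}  CA  {resname:>3s} {structure.chain_id:1s}"
                    f"{resseq:4d}{icode:1s}   {x:8.3f}{y:8.3f}{z:8.3f}"
                    f"{1.0:6.2f}{0.0:6.2f}           C\n"
                )
            fh.write("ENDMDL\n")
        fh.write("END\n")
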