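"""Hinge classification across a protein pair and mutation-set selection.

Given flexibility profiles of an ancestor-like protein A and a
descendant-like protein B on a pairwise sequence alignment, residues with
%DFI below a threshold (default 0.2) are hinges.  Aligned positions fall
into four classes — common hinge, hinge only in A, hinge only in B, or
non-hinge — and three rule-based mutation sets redirect A's dynamics
toward B's:

* set X: non-conserved positions that are hinges in A only, kept when
  strongly coupled (percentile pairwise DCI ≥ threshold, default 0.8, in
  B's coupling matrix) to a hinge unique to B;
* set Y: non-conserved common hinges strongly coupled (in A's matrix) to a
  non-conserved non-common hinge — compensating substitutions;
* set Z ("DARC spots"): mid-flexibility residues of A (0.3 < %DFI < 0.5,
  open band), distal from the active site (min Cα–Cα distance > 8 Å),
  strongly coupled to a sequentially conserved non-common hinge.

Substituting set members with B's amino acids at the aligned positions is
the design move; selections carry the coupling partners and distances that
justified them.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio import Align
from Bio.Align import substitution_matrices

from .enm_prs import FlexibilityProfile, percentile_pairwise_dci
from .structure_model import StructureModel

logger = logging.getLogger(__name__)

HINGE_THRESHOLD = 0.2
DCI_THRESHOLD = 0.8
DARC_BAND = (0.3, 0.5)
MIN_ACTIVE_DISTANCE = 8.0  # Å

COMMON = "common_hinge"
NON_COMMON_A = "non_common_A"
NON_COMMON_B = "non_common_B"
NON_HINGE = "non_hinge"


@dataclass
class AlignmentMap:
    """Aligned residue-index pairs of two sequences with conservation flags."""

    pairs: list[tuple[int, int]]
    seq_a: str
    seq_b: str

    def __post_init__(self) -> None:
        last_a = last_b = -1
        seen_a: set[int] = set()
        seen_b: set[int] = set()
        for a, b in self.pairs:
            if a <= last_a or b <= last_b:
                raise ValueError("alignment pairs must be strictly increasing")
            if a in seen_a or b in seen_b:
                raise ValueError("alignment maps a position twice")
            seen_a.add(a)
            seen_b.add(b)
            last_a, last_b = a, b

    @property
    def conserved(self) -> np.ndarray:
        return np.array([self.seq_a[a] == self.seq_b[b] for a, b in self.pairs])

    def b_of_a(self) -> dict[int, int]:
        return {a: b for a, b in self.pairs}

    @property
    def n_pairs(self) -> int:
        return len(self.pairs)


@dataclass
class MutationRecord:
    position: int  # 0-based index in protein A
    author_resid: str | None
    from_aa: str
    to_aa: str | None
    evidence: dict = field(default_factory=dict)


@dataclass
class MutationSet:
    set_id: str
    members: list[MutationRecord]
    diagnostics: list[str] = field(default_factory=list)
    metadata: dict = field(default_factory=dict)

    @property
    def positions(self) -> list[int]:
        return [m.position for m in self.members]

    def to_dict(self) -> dict:
        return {
            "set_id": self.set_id,
            "members": [
                {
                    "position": m.position,
                    "author_resid": m.author_resid,
                    "from_aa": m.from_aa,
                    "to_aa": m.to_aa,
                    "evidence": m.evidence,
                }
                for m in self.members
            ],
            "diagnostics": self.diagnostics,
            "metadata": self.metadata,
        }


@dataclass
class DesignReport:
    sets: dict[str, MutationSet]
    table: pd.DataFrame
    metadata: dict = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(
            {
                "sets": {k: s.to_dict() for k, s in self.sets.items()},
                "n_aligned": int(len(self.table)),
                "class_counts": self.table["cls"].value_counts().to_dict(),
                "metadata": self.metadata,
            },
            indent=2,
        )

    @property
    def all_positions(self) -> list[int]:
        return sorted(p for s in self.sets.values() for p in s.positions)


def align_sequences(seq_a: str, seq_b: str) -> AlignmentMap:
    """Global Needleman–Wunsch alignment (BLOSUM62, gap open 10 / extend 0.5).

    Returns the aligned index pairs of the first optimal alignment; a
    precomputed mapping can be supplied directly via :class:`AlignmentMap`
    to bypass alignment entirely.
    """
    if not seq_a or not seq_b:
        raise ValueError("sequences must be non-empty")
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -10.0
    aligner.extend_gap_score = -0.5
    aln = aligner.align(seq_a, seq_b)[0]
    pairs: list[tuple[int, int]] = []
    for (a0, a1), (b0, b1) in zip(*aln.aligned):
        pairs.extend(zip(range(a0, a1), range(b0, b1)))
    return AlignmentMap(pairs=pairs, seq_a=seq_a, seq_b=seq_b)


def classify_hinges(prof_a: FlexibilityProfile, prof_b: FlexibilityProfile,
                    amap: AlignmentMap,
                    hinge_threshold: float = HINGE_THRESHOLD) -> pd.DataFrame:
    """Per-aligned-pair hinge table.

    A residue is a hinge when its %DFI is strictly below ``hinge_threshold``.
    Classes: ``common_hinge`` (both), ``non_common_A``/``non_common_B``
    (exactly one), ``non_hinge`` (neither); ``conserved`` flags identical
    amino acids.
    """
    rows = []
    conserved = amap.conserved
    for k, (ia, ib) in enumerate(amap.pairs):
        if ia >= prof_a.n_residues or ib >= prof_b.n_residues:
            raise ValueError(f"aligned pair ({ia},{ib}) outside profile range")
        ha = prof_a.pct_dfi[ia] < hinge_threshold
        hb = prof_b.pct_dfi[ib] < hinge_threshold
        cls = COMMON if (ha and hb) else NON_COMMON_A if ha else \
            NON_COMMON_B if hb else NON_HINGE
        rows.append(
            dict(pos_a=ia, pos_b=ib, aa_a=amap.seq_a[ia], aa_b=amap.seq_b[ib],
                 pct_dfi_a=prof_a.pct_dfi[ia], pct_dfi_b=prof_b.pct_dfi[ib],
                 hinge_a=bool(ha), hinge_b=bool(hb), cls=cls,
                 conserved=bool(conserved[k]))
        )
    return pd.DataFrame(rows)


def _pct(matrix: np.ndarray, already_ranked: bool) -> np.ndarray:
    return np.asarray(matrix, float) if already_ranked else percentile_pairwise_dci(matrix)


def _record(table_row, evidence: dict) -> MutationRecord:
    return MutationRecord(
        position=int(table_row.pos_a),
        author_resid=None,
        from_aa=table_row.aa_a,
        to_aa=table_row.aa_b,
        evidence=evidence,
    )


def select_set_X(table: pd.DataFrame, pairwise_dci_b: np.ndarray,
                 dci_threshold: float = DCI_THRESHOLD,
                 ranked: bool = False) -> MutationSet:
    """Non-conserved hinges unique to A, coupled to a hinge unique to B.

    Coupling is judged in protein B's percentile-ranked pairwise DCI: the
    candidate's aligned position in B must respond at percentile ≥
    ``dci_threshold`` to a perturbation at some non-common hinge of B.
    Pass ``ranked=True`` when ``pairwise_dci_b`` is already percentile
    ranked.
    """
    pct = _pct(pairwise_dci_b, ranked)
    cands = table[(table.cls == NON_COMMON_A) & (~table.conserved)]
    partners = table[table.cls == NON_COMMON_B]
    members, diags = [], []
    if cands.empty:
        diags.append("no non-conserved non-common hinges in protein A")
        logger.warning(diags[-1])
    for row in cands.itertuples():
        hits = [
            {"partner_pos_b": int(p.pos_b), "partner_pos_a": int(p.pos_a),
             "pct_dci": float(pct[row.pos_b, p.pos_b])}
            for p in partners.itertuples()
            if p.pos_b != row.pos_b and pct[row.pos_b, p.pos_b] >= dci_threshold
        ]
        if hits:
            members.append(_record(row, {"coupled_non_common_B": hits}))
    return MutationSet(set_id="X", members=members, diagnostics=diags,
                       metadata={"dci_threshold": dci_threshold,
                                 "coupling_matrix": "protein_B"})


def select_set_Y(table: pd.DataFrame, pairwise_dci_a: np.ndarray,
                 dci_threshold: float = DCI_THRESHOLD,
                 manual_include: list[int] | None = None,
                 ranked: bool = False) -> MutationSet:
    """Non-conserved common hinges coupled to a non-conserved non-common hinge.

    Coupling is judged in protein A's matrix (the protein being redesigned).
    ``manual_include`` lists A-positions to force into the set — honored
    only if they are non-conserved common hinges, otherwise rejected with a
    diagnostic; forced members are flagged in their evidence.
    """
    pct = _pct(pairwise_dci_a, ranked)
    cands = table[(table.cls == COMMON) & (~table.conserved)]
    partners = table[table.cls.isin([NON_COMMON_A, NON_COMMON_B]) & (~table.conserved)]
    members, diags = [], []
    if cands.empty:
        diags.append("no non-conserved common hinges")
        logger.warning(diags[-1])
    chosen: set[int] = set()
    for row in cands.itertuples():
        hits = [
            {"partner_pos_a": int(p.pos_a), "partner_cls": p.cls,
             "pct_dci": float(pct[row.pos_a, p.pos_a])}
            for p in partners.itertuples()
            if p.pos_a != row.pos_a and pct[row.pos_a, p.pos_a] >= dci_threshold
        ]
        if hits:
            members.append(_record(row, {"coupled_non_common": hits}))
            chosen.add(int(row.pos_a))
    for pos in manual_include or []:
        row = table[table.pos_a == pos]
        if row.empty or row.iloc[0].cls != COMMON or row.iloc[0].conserved:
            diags.append(f"manual include {pos} rejected: not a non-conserved common hinge")
            logger.warning(diags[-1])
            continue
        if pos in chosen:
            diags.append(f"manual include {pos} already selected by the coupling rule")
            continue
        members.append(_record(row.iloc[0], {"manual_include": True}))
        chosen.add(pos)
        diags.append(f"position {pos} force-included by request")
    members.sort(key=lambda m: m.position)
    return MutationSet(set_id="Y", members=members, diagnostics=diags,
                       metadata={"dci_threshold": dci_threshold,
                                 "coupling_matrix": "protein_A"})


def select_set_Z(profile: FlexibilityProfile, structure: StructureModel,
                 pairwise_dci_a: np.ndarray, table: pd.DataFrame,
                 active_site: list[int],
                 dfi_band: tuple[float, float] = DARC_BAND,
                 min_dist: float = MIN_ACTIVE_DISTANCE,
                 dci_threshold: float = DCI_THRESHOLD,
                 ranked: bool = False) -> MutationSet:
    """DARC spots: distal mid-flexibility residues of A coupled to conserved
    non-common hinges.

    Three filters, all strict: %DFI inside the open ``dfi_band``; minimum
    Cα–Cα distance to any active-site residue > ``min_dist`` Å; percentile
    pairwise coupling ≥ ``dci_threshold`` to at least one sequentially
    conserved non-common hinge.  Only aligned positions are eligible (the
    substitution target comes from protein B).
    """
    active = np.asarray(active_site, dtype=int)
    if active.size == 0:
        raise ValueError("active site must be non-empty")
    if active.min() < 0 or active.max() >= structure.n_residues:
        raise ValueError("active-site residue outside the structure")
    pct = _pct(pairwise_dci_a, ranked)
    lo, hi = dfi_band
    partners = table[table.cls.isin([NON_COMMON_A, NON_COMMON_B]) & table.conserved]
    aligned = {int(r.pos_a): r for r in table.itertuples()}
    members, diags = [], []
    dists_to_active = np.linalg.norm(
        structure.ca_xyz[:, None, :] - structure.ca_xyz[active][None, :, :], axis=2
    ).min(axis=1)
    for i in range(structure.n_residues):
        if not (lo < profile.pct_dfi[i] < hi):
            continue
        if i not in aligned:
            continue
        if dists_to_active[i] <= min_dist:
            diags.append(f"position {i} excluded: distance "
                         f"{dists_to_active[i]:.2f} Å ≤ {min_dist} Å from active site")
            continue
        hits = [
            {"partner_pos_a": int(p.pos_a), "partner_cls": p.cls,
             "pct_dci": float(pct[i, p.pos_a])}
            for p in partners.itertuples()
            if p.pos_a != i and pct[i, p.pos_a] >= dci_threshold
        ]
        if hits:
            row = aligned[i]
            members.append(
                MutationRecord(position=i, author_resid=structure.author_resid[i],
                               from_aa=row.aa_a, to_aa=row.aa_b,
                               evidence={"min_active_distance": float(dists_to_active[i]),
                                         "coupled_conserved_non_common": hits})
            )
    return MutationSet(set_id="Z", members=members, diagnostics=diags,
                       metadata={"dfi_band": list(dfi_band), "min_dist": min_dist,
                                 "dci_threshold": dci_threshold,
                                 "coupling_matrix": "protein_A"})


def design_report(set_x: MutationSet, set_y: MutationSet, set_z: MutationSet,
                  table: pd.DataFrame,
                  structure_a: StructureModel | None = None) -> DesignReport:
    """Aggregate the three mutation sets, enforcing positional disjointness."""
    sets = {"X": set_x, "Y": set_y, "Z": set_z}
    seen: dict[int, str] = {}
    for sid, s in sets.items():
        for m in s.members:
            if structure_a is not None and m.author_resid is None:
                m.author_resid = structure_a.author_resid[m.position]
            if m.position in seen:
                raise ValueError(
                    f"position {m.position} selected by both set {seen[m.position]} "
                    f"and set {sid}"
                )
            seen[m.position] = sid
    return DesignReport(sets=sets, table=table,
                        metadata={"n_substitutions": len(seen)})
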