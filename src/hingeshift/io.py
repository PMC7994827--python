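"""Plain-text serialization: covariance matrices, profiles, reports."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .enm_prs import CovarianceMatrix, CouplingProfile, FlexibilityProfile
from .structure_model import StructureModel


def write_covariance(g: CovarianceMatrix, path) -> None:
    """Dense whitespace-separated 3N×3N matrix plus a JSON sidecar
    (``<path>.json``) recording residue count, units and provenance."""
    path = Path(path)
    np.savetxt(path, g.matrix)
    sidecar = {"n_residues": g.n_residues, "units": "A^2", "provenance": g.provenance}
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar, indent=2))


def read_covariance(path) -> CovarianceMatrix:
    path = Path(path)
    matrix = np.loadtxt(path)
    provenance = "ensemble_estimate"
    sidecar = path.with_suffix(path.suffix + ".json")
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
        provenance = meta.get("provenance", provenance)
        n = meta.get("n_residues")
        if n is not None and matrix.shape[0] != 3 * n:
            raise ValueError(
                f"matrix is {matrix.shape[0]}×{matrix.shape[1]} but sidecar says N={n}"
            )
    return CovarianceMatrix(matrix=matrix, provenance=provenance)


def profile_frame(structure: StructureModel | None, profile: FlexibilityProfile,
                  coupling: CouplingProfile | None = None) -> pd.DataFrame:
    """Tabulate a flexibility (and optional coupling) profile per residue."""
    n = profile.n_residues
    df = pd.DataFrame({
        "residue_index": np.arange(n),
        "author_resid": structure.author_resid if structure else [str(i + 1) for i in range(n)],
        "aa": list(structure.aa) if structure else ["X"] * n,
        "dfi": profile.dfi,
        "pct_dfi": profile.pct_dfi,
    })
    if coupling is not None:
        df["dci"] = coupling.dci
        df["pct_dci"] = coupling.pct_dci
    return df


def write_profile(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_profile(path) -> FlexibilityProfile:
    df = pd.read_csv(path, sep="\t")
    return FlexibilityProfile(dfi=df["dfi"].to_numpy(),
                              pct_dfi=df["pct_dfi"].to_numpy(),
                              label=str(path))
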