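"""Covariance estimation from coordinate ensembles and convergence diagnostics.

A trajectory is cut into overlapping windows (window length W, start lag L,
initial burn-in discarded).  Within each window every frame is rigid-body
superposed onto the window's first frame — using backbone heavy atoms when
the ensemble carries them — and the 3N×3N Cα covariance is taken about the
window mean with the population (1/n) denominator.  Flexibility profiles
averaged per window size should be independent of the window size when all
frames sample one harmonic basin; that is the convergence criterion.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .enm_prs import CovarianceMatrix, FlexibilityProfile, dfi, percentile_rank, response_matrix
from .structure_model import EnsembleTrajectory, kabsch_superpose

DEFAULT_WINDOW_SIZES = (25.0, 50.0, 75.0, 100.0)  # ns
DEFAULT_LAG = 25.0  # ns between window starts
DEFAULT_BURN_IN = 100.0  # ns discarded before the first window
DEFAULT_PRODUCTION_WINDOW = 50.0  # ns window feeding DFI/DCI production runs
DEFAULT_CONVERGENCE_THRESHOLD = 0.9


@dataclass
class WindowSpec:
    """Windowing scheme for covariance estimation (times in ns)."""

    window_length: float
    lag: float = DEFAULT_LAG
    burn_in: float = DEFAULT_BURN_IN
    fit_selection: str = "backbone"  # fall back to Cα for Cα-only ensembles

    def __post_init__(self) -> None:
        if self.window_length <= 0 or self.lag <= 0 or self.burn_in < 0:
            raise ValueError("window_length and lag must be > 0, burn_in ≥ 0")

    def frames(self, value: float, frame_spacing: float) -> int:
        """Convert a time in ns to a whole number of frames (error if fractional)."""
        raw = value / frame_spacing
        n = round(raw)
        if abs(raw - n) > 1e-9:
            raise ValueError(
                f"{value} ns is not a whole number of frames at {frame_spacing} ns/frame"
            )
        return int(n)


@dataclass
class ConvergenceReport:
    """Pairwise agreement of mean DFI profiles across window sizes."""

    window_sizes: list[float]
    profiles: dict[float, np.ndarray]
    correlations: dict[tuple[float, float], float]
    threshold: float
    converged: bool
    diagnostics: list[str] = field(default_factory=list)

    def to_json(self) -> str:
        payload = {
            "window_sizes_ns": list(self.window_sizes),
            "mean_dfi_profiles": {str(k): v.tolist() for k, v in self.profiles.items()},
            "pairwise_correlations": {
                f"{a}|{b}": c for (a, b), c in self.correlations.items()
            },
            "threshold": self.threshold,
            "converged": self.converged,
            "diagnostics": self.diagnostics,
        }
        return json.dumps(payload, indent=2)


def window_count(n_frames: int, window: int, lag: int, burn_in: int) -> int:
    """Number of windows: floor((T − burn_in − W)/lag) + 1, or 0 if none fit."""
    if n_frames - burn_in < window:
        return 0
    return (n_frames - burn_in - window) // lag + 1


def windowed_covariances(traj: EnsembleTrajectory, spec: WindowSpec) -> list[CovarianceMatrix]:
    """Estimate one Cα covariance per window of the trajectory.

    Windows start at burn_in, burn_in + lag, … while a full window fits.
    Every frame of a window is Kabsch-superposed onto the window's first
    frame (backbone heavy atoms if carried, else Cα), then the covariance
    of the flattened Cα coordinates is taken about the window mean with
    denominator = frame count.
    """
    fs = traj.frame_spacing
    w = spec.frames(spec.window_length, fs)
    lag = spec.frames(spec.lag, fs)
    burn = spec.frames(spec.burn_in, fs)
    n_win = window_count(traj.n_frames, w, lag, burn)
    if n_win == 0:
        raise ValueError(
            f"trajectory of {traj.n_frames} frames too short for burn-in {burn} "
            f"+ window {w} frames"
        )
    if traj.atom_selection == "backbone" and spec.fit_selection == "ca":
        fit_atoms = traj.ca_indices
    else:
        # frames carry exactly the fit selection (backbone heavy atoms, or
        # Cα for Cα-only ensembles): fit on all atoms
        fit_atoms = None
    covs = []
    for k in range(n_win):
        start = burn + k * lag
        block = traj.frames[start:start + w]
        ref = block[0]
        fitted = np.empty((w, traj.ca_indices.size, 3))
        for f in range(w):
            moved, _ = kabsch_superpose(block[f], ref, fit_atoms)
            fitted[f] = moved[traj.ca_indices]
        flat = fitted.reshape(w, -1)
        centered = flat - flat.mean(axis=0)
        g = centered.T @ centered / w
        covs.append(CovarianceMatrix(matrix=g, provenance="ensemble_estimate"))
    return covs


def mean_dfi_by_window_size(traj: EnsembleTrajectory,
                            window_sizes=DEFAULT_WINDOW_SIZES,
                            lag: float = DEFAULT_LAG,
                            burn_in: float = DEFAULT_BURN_IN) -> dict[float, FlexibilityProfile]:
    """Average DFI profile per window size.

    For each size, DFI is computed from every window's covariance and the
    profiles are averaged elementwise, then renormalized to sum to one.
    """
    out: dict[float, FlexibilityProfile] = {}
    for size in window_sizes:
        spec = WindowSpec(window_length=size, lag=lag, burn_in=burn_in)
        covs = windowed_covariances(traj, spec)
        profiles = np.array([dfi(response_matrix(g)).dfi for g in covs])
        mean = profiles.mean(axis=0)
        mean = mean / mean.sum()
        out[size] = FlexibilityProfile(dfi=mean, pct_dfi=percentile_rank(mean),
                                       label=f"window={size}ns")
    return out


def check_convergence(profiles: dict[float, FlexibilityProfile],
                      threshold: float = DEFAULT_CONVERGENCE_THRESHOLD) -> ConvergenceReport:
    """Declare convergence iff every pair of mean profiles correlates ≥ threshold.

    A constant profile has an undefined Pearson correlation and is reported
    as not converged with a diagnostic rather than an error.
    """
    sizes = sorted(profiles)
    if len(sizes) < 2:
        raise ValueError("need at least two window sizes to compare")
    corrs: dict[tuple[float, float], float] = {}
    diagnostics: list[str] = []
    ok = True
    for a in range(len(sizes)):
        for b in range(a + 1, len(sizes)):
            pa, pb = profiles[sizes[a]].dfi, profiles[sizes[b]].dfi
            if np.std(pa) == 0 or np.std(pb) == 0:
                diagnostics.append(
                    f"constant profile at window {sizes[a] if np.std(pa) == 0 else sizes[b]} ns; "
                    "correlation undefined"
                )
                corrs[(sizes[a], sizes[b])] = float("nan")
                ok = False
                continue
            r = float(np.corrcoef(pa, pb)[0, 1])
            corrs[(sizes[a], sizes[b])] = r
            if r < threshold:
                ok = False
    return ConvergenceReport(window_sizes=list(sizes),
                             profiles={s: profiles[s].dfi for s in sizes},
                             correlations=corrs, threshold=threshold,
                             converged=ok, diagnostics=diagnostics)


def production_covariance(traj: EnsembleTrajectory,
                          window_length: float = DEFAULT_PRODUCTION_WINDOW,
                          lag: float = DEFAULT_LAG,
                          burn_in: float = DEFAULT_BURN_IN) -> CovarianceMatrix:
    """Mean covariance over production windows (default 50 ns), the input
    used for final DFI/DCI profiles."""
    covs = windowed_covariances(traj, WindowSpec(window_length, lag, burn_in))
    g = np.mean([c.matrix for c in covs], axis=0)
    return CovarianceMatrix(matrix=g, provenance="ensemble_estimate")
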