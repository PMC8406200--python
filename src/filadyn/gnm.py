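"""Gaussian network model (GNM) normal modes and per-mode residue correlations.

The GNM represents a protein (or protein assembly) as an elastic network on
Cα nodes: nodes within a distance cutoff are connected by identical springs,
and the collective motions are the eigenmodes of the Kirchhoff (graph
Laplacian) matrix Γ.  Mode k has frequency λ_k (the eigenvalue) and
amplitude 1/λ_k, so the lowest non-zero modes dominate the dynamics.

Within a single mode with eigenvector u, the inter-residue dynamic
correlation is

    c_ij = u_i u_j / sqrt(u_i u_i · u_j u_j)  =  sign(u_i) · sign(u_j),

i.e. residues moving in phase score +1 and residues moving out of phase
score −1.  The mean of c_ij over distinct residue pairs of a selection
(C_pocket for active-site residues, C_interface for junction residues) is a
per-mode deformation score: C = 1 means the set moves as a rigid block, and
low or negative C means the mode deforms the set.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

__all__ = [
    "ModeSpectrum",
    "ModeCorrelation",
    "build_kirchhoff",
    "mode_decomposition",
    "mode_correlation",
    "correlation_profile",
]

ZERO_MODE_TOL = 1e-10


class GNMError(Exception):
    pass


def build_kirchhoff(ca_coords: np.ndarray, cutoff: float = 7.5) -> np.ndarray:
    """Kirchhoff (connectivity) matrix: Γ_ij = −1 for contacting pairs
    (distance ≤ cutoff, i ≠ j), Γ_ii = node degree.  Row sums are zero.
    """
    coords = np.asarray(ca_coords, dtype=float).reshape(-1, 3)
    n = len(coords)
    if n < 2:
        raise GNMError("need at least 2 nodes")
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    adj = squareform(pdist(coords) <= cutoff).astype(float)
    gamma = -adj
    np.fill_diagonal(gamma, adj.sum(axis=1))
    return gamma


@dataclass
class ModeSpectrum:
    """Eigen-decomposition of a Kirchhoff matrix.

    ``eigenvalues`` are sorted ascending and include the zero (rigid-body)
    modes; ``n_zero`` of them are flagged as zero within ``zero_tol``.
    ``mode_index(k)`` maps the 1-based *internal* mode index (mode 1 = lowest
    non-zero frequency) to a column of ``eigenvectors``.
    """

    eigenvalues: np.ndarray           # (N,), ascending
    eigenvectors: np.ndarray          # (N, N), column k ↔ eigenvalue k
    cutoff: float
    zero_tol: float = ZERO_MODE_TOL
    n_zero: int = field(init=False)

    def __post_init__(self) -> None:
        self.eigenvalues = np.asarray(self.eigenvalues, dtype=float)
        self.eigenvectors = np.asarray(self.eigenvectors, dtype=float)
        self.n_zero = int(np.sum(self.eigenvalues < self.zero_tol))

    @property
    def n_modes(self) -> int:
        """Number of internal (non-zero) modes."""
        return len(self.eigenvalues) - self.n_zero

    @property
    def connected(self) -> bool:
        """One zero mode per connected component; a connected network has 1."""
        return self.n_zero == 1

    def mode_index(self, k: int) -> int:
        if not 1 <= k <= self.n_modes:
            raise GNMError(f"mode {k} out of range 1..{self.n_modes}")
        return self.n_zero + k - 1

    def frequency(self, k: int) -> float:
        return float(self.eigenvalues[self.mode_index(k)])

    def amplitude(self, k: int) -> float:
        """Mode amplitude 1/λ_k."""
        return 1.0 / self.frequency(k)

    def mode_vector(self, k: int) -> np.ndarray:
        return self.eigenvectors[:, self.mode_index(k)]


def mode_decomposition(kirchhoff: np.ndarray,
                       cutoff: float = float("nan")) -> ModeSpectrum:
    """Full symmetric eigendecomposition of the Kirchhoff matrix."""
    gamma = np.asarray(kirchhoff, dtype=float)
    if gamma.ndim != 2 or gamma.shape[0] != gamma.shape[1]:
        raise GNMError("Kirchhoff matrix must be square")
    if not np.allclose(gamma, gamma.T, atol=1e-10):
        raise GNMError("Kirchhoff matrix must be symmetric")
    w, v = np.linalg.eigh(gamma)
    w = np.where(np.abs(w) < ZERO_MODE_TOL, 0.0, w)
    return ModeSpectrum(w, v, cutoff)


@dataclass
class ModeCorrelation:
    """Inter-residue correlation matrix of one mode restricted to a residue set."""

    mode: int
    indices: np.ndarray              # node indices of the set (spectrum ordering)
    matrix: np.ndarray               # (m, m), entries in {−1, +1}, NaN where undefined
    mean: float                      # set-mean C over distinct pairs i < j


def mode_correlation(spectrum: ModeSpectrum, mode: int,
                     indices: Sequence[int],
                     component_tol_factor: float = 1e-9) -> ModeCorrelation:
    """Per-mode correlation c_ij over a residue set and its pair mean C.

    Components with |u_i| below ``component_tol_factor · max|u|`` carry no
    motion in this mode and are excluded from the pair average.
    """
    idx = np.asarray(sorted(indices), dtype=np.int64)
    if len(idx) < 2:
        raise GNMError("residue set must contain at least 2 residues")
    u = spectrum.mode_vector(mode)[idx]
    tol = component_tol_factor * np.abs(spectrum.mode_vector(mode)).max()
    active = np.abs(u) > tol
    if active.sum() < 2:
        raise GNMError("all set components are (numerically) zero in this mode")
    s = np.sign(u)
    c = np.outer(s, s)
    c[~active, :] = np.nan
    c[:, ~active] = np.nan
    np.fill_diagonal(c, np.where(active, 1.0, np.nan))
    iu = np.triu_indices(len(idx), k=1)
    vals = c[iu]
    mean = float(np.nanmean(vals))
    return ModeCorrelation(mode, idx, c, mean)


def correlation_profile(spectrum: ModeSpectrum,
                        indices: Sequence[int],
                        n_modes: int = 20,
                        label: str = "C") -> pd.DataFrame:
    """Per-mode table (mode, frequency λ, amplitude 1/λ, set-mean C) for the
    first *n_modes* internal modes — the C_pocket / C_interface profile.
    """
    if n_modes > spectrum.n_modes:
        raise GNMError(f"requested {n_modes} modes, only {spectrum.n_modes} available")
    rows = []
    for k in range(1, n_modes + 1):
        corr = mode_correlation(spectrum, k, indices)
        rows.append({"mode": k,
                     "frequency": spectrum.frequency(k),
                     "amplitude": spectrum.amplitude(k),
                     label: corr.mean})
    return pd.DataFrame(rows)


def mean_profile(profiles: Sequence[pd.DataFrame], label: str = "C") -> pd.DataFrame:
    """Average several per-set correlation profiles mode-by-mode (e.g. the
    four pockets of a tetramer, eight of an octamer)."""
    if not profiles:
        raise GNMError("no profiles to average")
    out = profiles[0][["mode", "frequency", "amplitude"]].copy()
    out[label] = np.mean([p[label].to_numpy() for p in profiles], axis=0)
    return out
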