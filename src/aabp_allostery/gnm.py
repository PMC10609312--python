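"""Gaussian network model (GNM) on Cα coordinates.

The GNM treats the protein as an isotropic elastic network: residues closer
than a cutoff (default 7.3 Å) are joined by identical springs and residue
fluctuations follow a multivariate Gaussian governed by the Kirchhoff
(connectivity) matrix Γ.  Mean-square fluctuations and cross-correlations
come from the pseudoinverse of Γ restricted to a mode subset:

    <ΔR_i · ΔR_j> = (3 k_B T / γ) [Γ⁺]_ij ,
    [Γ⁺]_ij = Σ_k v_ki v_kj / λ_k   over selected non-zero modes.

Slow (low-frequency) modes describe collective domain motion and hinges;
fast (high-frequency) mode minima mark kinetically hot residues.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import pdist, squareform
from scipy.sparse.csgraph import connected_components

ZERO_TOL = 1e-8  # relative threshold for zero eigenvalues


@dataclass
class GNMParams:
    """GNM spring network parameters.

    cutoff : contact cutoff in Å (default 7.3 Å — i.e. 0.73 nm)
    gamma : uniform spring constant (arbitrary units)
    kt : thermal factor k_B·T (arbitrary units); profiles scale with kt/γ
    """

    cutoff: float = 7.3
    gamma: float = 1.0
    kt: float = 1.0

    def __post_init__(self):
        if self.cutoff <= 0 or self.gamma <= 0:
            raise ValueError("cutoff and gamma must be positive")


@dataclass
class GNMResult:
    kirchhoff: np.ndarray
    eigenvalues: np.ndarray        # ascending
    eigenvectors: np.ndarray       # columns match eigenvalues
    n_zero: int
    params: GNMParams = field(default_factory=GNMParams)

    @property
    def n_residues(self) -> int:
        return self.kirchhoff.shape[0]

    @property
    def nonzero_modes(self) -> np.ndarray:
        return np.arange(self.n_zero, self.n_residues)


def build_kirchhoff(coords: np.ndarray, params: GNMParams | None = None) -> np.ndarray:
    """Kirchhoff matrix: Γ_ij = −1 for contacts (R_ij ≤ cutoff), diagonal
    = contact count; rows sum to zero."""
    params = params or GNMParams()
    coords = np.asarray(coords, dtype=float)
    if coords.ndim != 2 or coords.shape[1] != 3 or coords.shape[0] < 2:
        raise ValueError("coords must be (N>=2, 3)")
    if not np.all(np.isfinite(coords)):
        raise ValueError("non-finite coordinates")
    dmat = squareform(pdist(coords))
    contact = (dmat <= params.cutoff) & ~np.eye(len(coords), dtype=bool)
    gamma_mat = -contact.astype(float)
    np.fill_diagonal(gamma_mat, contact.sum(axis=1))
    if np.any(contact.sum(axis=1) == 0):
        warnings.warn("isolated node(s) in the contact network")
    return gamma_mat


def n_components(kirchhoff: np.ndarray) -> int:
    """Connected components of the contact graph underlying Γ."""
    adj = (kirchhoff < 0).astype(int)
    n, _ = connected_components(adj, directed=False)
    return n


def gnm_decompose(kirchhoff: np.ndarray, params: GNMParams | None = None) -> GNMResult:
    """Full eigendecomposition of Γ with zero modes identified.

    One zero eigenvalue per connected component of the contact graph.
    """
    kirchhoff = np.asarray(kirchhoff, dtype=float)
    if not np.allclose(kirchhoff, kirchhoff.T):
        raise ValueError("Kirchhoff matrix must be symmetric")
    evals, evecs = np.linalg.eigh(kirchhoff)
    scale = max(abs(evals[-1]), 1.0)
    n_zero = int(np.sum(np.abs(evals) < ZERO_TOL * scale))
    if n_zero > 1:
        warnings.warn(f"contact network has {n_zero} connected components")
    return GNMResult(kirchhoff=kirchhoff, eigenvalues=evals,
                     eigenvectors=evecs, n_zero=n_zero,
                     params=params or GNMParams())


def _mode_indices(r: GNMResult, mode: str, k: int | None) -> np.ndarray:
    nz = r.nonzero_modes
    if len(nz) == 0:
        raise ValueError("no non-zero modes")
    if mode == "all":
        return nz
    if k is None:
        raise ValueError("k required for slow/fast selections")
    if k > len(nz):
        raise ValueError(f"selection k={k} exceeds {len(nz)} available modes")
    if mode == "slow":
        return nz[:k]
    if mode == "fast":
        return nz[-k:]
    raise ValueError(f"unknown selection {mode!r}")


def _pseudoinverse(r: GNMResult, idx: np.ndarray) -> np.ndarray:
    v = r.eigenvectors[:, idx]
    return (v / r.eigenvalues[idx]) @ v.T


def mode_fluctuations(r: GNMResult, mode: str = "all", k: int | None = None) -> np.ndarray:
    """Per-residue mean-square fluctuations from a mode subset.

    ``mode`` is ``"slow"`` (k lowest non-zero modes), ``"fast"`` (k highest)
    or ``"all"`` (every non-zero mode, in which case the profile is the
    diagonal of (3 k_B T/γ) Γ⁺).
    """
    idx = _mode_indices(r, mode, k)
    scale = 3.0 * r.params.kt / r.params.gamma
    v = r.eigenvectors[:, idx]
    msf = scale * np.sum(v**2 / r.eigenvalues[idx], axis=1)
    return msf


def cross_correlation(r: GNMResult, mode: str = "slow", k: int | None = 2,
                      normalize: bool = True) -> np.ndarray:
    """N×N cross-correlation map from a mode subset.

    Unnormalized entries are (3 k_B T/γ)[Γ⁺]_ij over the selection; with
    ``normalize`` they become C_ij/√(C_ii C_jj) so the diagonal is 1.
    """
    idx = _mode_indices(r, mode, k)
    if len(idx) == 0:
        raise ValueError("empty mode selection")
    cov = 3.0 * r.params.kt / r.params.gamma * _pseudoinverse(r, idx)
    if not normalize:
        return cov
    d = np.sqrt(np.clip(np.diag(cov), 1e-300, None))
    return cov / np.outer(d, d)


def detect_extrema(profile: np.ndarray, kind: str = "hotspot",
                   quantile: float = 0.25) -> list[int]:
    """Residues at local minima of a fluctuation profile (0-based indices).

    ``hotspot``: local minima of the *fast*-mode profile below the given
    quantile (the GNM convention — fast-mode minima are the kinetically hot
    residues).  ``hinge``: local minima of the *slow*-mode profile below the
    quantile (near-zero slow fluctuation marks the rotation axis).
    Endpoints count as local minima when below their single neighbour.
    """
    profile = np.asarray(profile, dtype=float)
    if len(profile) < 3:
        raise ValueError("profile too short")
    if kind not in ("hotspot", "hinge"):
        raise ValueError(f"unknown kind {kind!r}")
    if np.ptp(profile) == 0:
        warnings.warn("flat profile; no extrema")
        return []
    thresh = np.quantile(profile, quantile)
    out = []
    for i in range(len(profile)):
        left = profile[i - 1] if i > 0 else np.inf
        right = profile[i + 1] if i < len(profile) - 1 else np.inf
        if profile[i] <= left and profile[i] <= right and profile[i] <= thresh:
            out.append(i)
    return out


def profile_correlation(profile_a: np.ndarray, profile_b: np.ndarray,
                        map_a: dict[int, int] | None = None,
                        map_b: dict[int, int] | None = None) -> float:
    """Pearson correlation of two per-residue profiles on shared consensus
    columns.

    ``map_a``/``map_b`` map 1-based residue index → consensus column (pass
    ``None`` for identity).  Only columns mapped in both proteins enter the
    correlation.
    """
    profile_a = np.asarray(profile_a, dtype=float)
    profile_b = np.asarray(profile_b, dtype=float)
    if map_a is None:
        map_a = {i + 1: i + 1 for i in range(len(profile_a))}
    if map_b is None:
        map_b = {i + 1: i + 1 for i in range(len(profile_b))}
    inv_b = {c: i for i, c in map_b.items()}
    pairs = [
        (profile_a[i - 1], profile_b[inv_b[c] - 1])
        for i, c in map_a.items() if c in inv_b
    ]
    if len(pairs) < 3:
        raise ValueError("fewer than 3 shared consensus columns")
    x, y = np.array(pairs).T
    return float(np.corrcoef(x, y)[0, 1])
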