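"""Anisotropic network model (ANM) on Cα coordinates.

Where the GNM gives only fluctuation amplitudes, the ANM's 3N×3N Hessian
yields motion *directions*: each off-diagonal 3×3 super-element of H is the
second-derivative block of the harmonic pair potential

    V_ij = (γ/2) (R_ij − R_ij⁰)²  →  h_ij = −(γ/R_ij²) d_ij d_ijᵀ

with d_ij = r_j − r_i at the input (equilibrium) geometry, non-zero only for
pairs within the cutoff (default 15 Å, the community standard for Cα ANM).
The six zero modes are rigid-body translations/rotations; the low non-zero
modes describe collective domain motion, e.g. the face-to-face lobe closure
of a binding protein.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import pdist, squareform

from aabp_allostery.trajectory import kabsch_superpose

ZERO_TOL = 1e-8


@dataclass
class ANMParams:
    cutoff: float = 15.0   # Å
    gamma: float = 1.0

    def __post_init__(self):
        if self.cutoff <= 0:
            raise ValueError("cutoff must be positive")


@dataclass
class ANMResult:
    hessian: np.ndarray           # (3N, 3N)
    eigenvalues: np.ndarray       # ascending
    eigenvectors: np.ndarray      # columns
    n_zero: int
    params: ANMParams = field(default_factory=ANMParams)

    @property
    def n_residues(self) -> int:
        return self.hessian.shape[0] // 3

    @property
    def internal_modes(self) -> np.ndarray:
        """Indices of non-rigid-body (internal) modes."""
        return np.arange(self.n_zero, 3 * self.n_residues)

    def mode_vectors(self, k: int) -> np.ndarray:
        """Eigenvector of mode ``k`` reshaped to per-residue 3-vectors."""
        return self.eigenvectors[:, k].reshape(-1, 3)


def build_hessian(coords: np.ndarray, params: ANMParams | None = None) -> np.ndarray:
    """Assemble the 3N×3N ANM Hessian from Cα coordinates."""
    params = params or ANMParams()
    coords = np.asarray(coords, dtype=float)
    n = coords.shape[0]
    if coords.ndim != 2 or coords.shape[1] != 3 or n < 3:
        raise ValueError("coords must be (N>=3, 3)")
    rank = np.linalg.matrix_rank(coords - coords.mean(axis=0), tol=1e-8)
    if rank < 2:
        warnings.warn("collinear geometry: extra zero modes expected")
    dmat = squareform(pdist(coords))
    hess = np.zeros((3 * n, 3 * n))
    for i in range(n):
        for j in range(i + 1, n):
            rij = dmat[i, j]
            if rij > params.cutoff or rij == 0.0:
                continue
            d = coords[j] - coords[i]
            block = -(params.gamma / rij**2) * np.outer(d, d)
            hess[3 * i:3 * i + 3, 3 * j:3 * j + 3] = block
            hess[3 * j:3 * j + 3, 3 * i:3 * i + 3] = block
            hess[3 * i:3 * i + 3, 3 * i:3 * i + 3] -= block
            hess[3 * j:3 * j + 3, 3 * j:3 * j + 3] -= block
    return hess


def anm_decompose(hessian: np.ndarray, params: ANMParams | None = None) -> ANMResult:
    """Eigendecomposition of H; the six rigid-body zero modes are flagged
    and excluded from derived quantities."""
    hessian = np.asarray(hessian, dtype=float)
    if not np.allclose(hessian, hessian.T):
        raise ValueError("Hessian must be symmetric")
    evals, evecs = np.linalg.eigh(hessian)
    scale = max(abs(evals[-1]), 1.0)
    n_zero = int(np.sum(np.abs(evals) < ZERO_TOL * scale))
    if n_zero > 6:
        warnings.warn(f"degenerate network: {n_zero} zero modes (expected 6)")
    elif n_zero < 6:
        warnings.warn(f"only {n_zero} zero modes found (expected 6)")
    return ANMResult(hessian=hessian, eigenvalues=evals, eigenvectors=evecs,
                     n_zero=n_zero, params=params or ANMParams())


def mode_displacements(r: ANMResult, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Unit-normalized per-residue displacement field of internal mode ``k``.

    Returns ``(vectors, amplitudes)`` with ``vectors`` of shape (N, 3) and
    ``amplitudes[i] = |v_i|``.  ``k`` indexes the full spectrum; rigid-body
    modes are rejected.
    """
    if k < r.n_zero:
        raise ValueError(f"mode {k} is a rigid-body mode")
    if k >= 3 * r.n_residues:
        raise ValueError(f"mode {k} out of range")
    v = r.mode_vectors(k)
    norm = np.linalg.norm(v)
    v = v / norm
    return v, np.linalg.norm(v, axis=1)


def overlap_with_transition(r: ANMResult, open_coords: np.ndarray,
                            closed_coords: np.ndarray,
                            shared: np.ndarray | None = None) -> np.ndarray:
    """Overlap of each internal mode with the open→closed difference vector.

    The closed structure is Kabsch-superposed onto the open one on the
    shared residues first, removing rigid-body contamination; then
    ``overlap_k = |v_k · Δr| / (|v_k| |Δr|)`` with Δr = closed − open.
    Returns an array indexed like ``r.internal_modes``.

    ``shared`` optionally gives the residue indices (into the ANM structure
    and both coordinate sets) used for the comparison; default all.
    """
    open_coords = np.asarray(open_coords, dtype=float)
    closed_coords = np.asarray(closed_coords, dtype=float)
    if shared is None:
        shared = np.arange(open_coords.shape[0])
    shared = np.asarray(shared, dtype=int)
    if len(shared) < 10:
        raise ValueError("fewer than 10 shared residues")
    if open_coords.shape != closed_coords.shape:
        raise ValueError("open/closed shapes differ")
    fitted, _ = kabsch_superpose(open_coords[shared], closed_coords[shared])
    delta = (fitted - open_coords[shared]).ravel()
    dn = np.linalg.norm(delta)
    if dn == 0:
        raise ValueError("identical open and closed coordinates")
    out = np.empty(len(r.internal_modes))
    for a, k in enumerate(r.internal_modes):
        v = r.mode_vectors(k)[shared].ravel()
        out[a] = abs(np.dot(v, delta)) / (np.linalg.norm(v) * dn)
    return out
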