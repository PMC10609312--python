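"""Coarse-grained trajectory container and statistics.

Holds frames × nodes × 3 Cα coordinates (Å) with optional per-frame
velocities, and provides the standard convergence statistics — Kabsch
least-squares superposition, per-frame RMSD and per-residue RMSF — plus the
6-dimensional (position, velocity) node features consumed by the
relational-inference model.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np


@dataclass
class Trajectory:
    """frames T × nodes N × 3 coordinates in Å; optional velocities (Å/frame)."""

    coords: np.ndarray
    velocities: np.ndarray | None = None
    timestep: float = 1.0
    label: str = ""

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise ValueError("coords must be (T, N, 3)")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("non-finite coordinates")
        if self.velocities is not None:
            self.velocities = np.asarray(self.velocities, dtype=float)
            if self.velocities.shape != self.coords.shape:
                raise ValueError("velocities incongruent with coordinates")

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def n_nodes(self) -> int:
        return self.coords.shape[1]

    # -- plain-text multi-frame XYZ I/O ------------------------------------

    def write_xyz(self, path) -> None:
        with open(path, "w") as fh:
            for t in range(self.n_frames):
                fh.write(f"{self.n_nodes}\nframe {t}\n")
                for x, y, z in self.coords[t]:
                    fh.write(f"CA {x:.6f} {y:.6f} {z:.6f}\n")

    @classmethod
    def read_xyz(cls, path, label: str = "") -> "Trajectory":
        frames = []
        lines = Path(path).read_text().splitlines()
        i = 0
        while i < len(lines):
            if not lines[i].strip():
                i += 1
                continue
            n = int(lines[i].strip())
            block = lines[i + 2:i + 2 + n]
            frames.append([[float(v) for v in ln.split()[1:4]] for ln in block])
            i += 2 + n
        return cls(coords=np.array(frames), label=label or str(path))


def kabsch_superpose(ref: np.ndarray, mobile: np.ndarray) -> tuple[np.ndarray, float]:
    """Least-squares rigid superposition of ``mobile`` onto ``ref``.

    Returns the transformed mobile coordinates and the post-fit RMSD.  Uses
    the standard SVD solution with the determinant sign correction, so the
    transform is a proper rotation.
    """
    ref = np.asarray(ref, dtype=float)
    mobile = np.asarray(mobile, dtype=float)
    if ref.shape != mobile.shape or ref.ndim != 2 or ref.shape[1] != 3:
        raise ValueError("ref and mobile must both be (N, 3)")
    if ref.shape[0] < 3:
        raise ValueError("need at least 3 points")
    ref_c = ref - ref.mean(axis=0)
    mob_c = mobile - mobile.mean(axis=0)
    if np.allclose(mob_c, 0) or np.allclose(ref_c, 0):
        raise ValueError("degenerate (all-coincident) coordinates")
    u, _, vt = np.linalg.svd(mob_c.T @ ref_c)
    d = np.sign(np.linalg.det(u @ vt))
    rot = (u @ np.diag([1.0, 1.0, d]) @ vt)
    fitted = mob_c @ rot + ref.mean(axis=0)
    rmsd = float(np.sqrt(np.mean(np.sum((fitted - ref) ** 2, axis=1))))
    return fitted, rmsd


def rmsd_series(traj: Trajectory, ref: np.ndarray | int = 0) -> np.ndarray:
    """Per-frame Kabsch RMSD to a reference frame (index or (N,3) array)."""
    if isinstance(ref, (int, np.integer)):
        ref = traj.coords[int(ref)]
    ref = np.asarray(ref, dtype=float)
    return np.array([kabsch_superpose(ref, frame)[1] for frame in traj.coords])


def rmsf_profile(traj: Trajectory) -> np.ndarray:
    """Per-residue root-mean-square fluctuation about the mean structure.

    Every frame is superposed onto the mean structure, the mean is rebuilt
    once from the superposed frames, and RMSF_i = sqrt(mean_t |r_i(t) −
    ⟨r_i⟩|²).
    """
    if traj.n_frames < 2:
        raise ValueError("need at least 2 frames for RMSF")
    mean = traj.coords.mean(axis=0)
    if np.allclose(traj.coords - traj.coords[0], 0):
        return np.zeros(traj.n_nodes)
    fitted = np.array([kabsch_superpose(mean, f)[0] for f in traj.coords])
    mean = fitted.mean(axis=0)   # one re-iteration of the reference
    fitted = np.array([kabsch_superpose(mean, f)[0] for f in fitted])
    mean = fitted.mean(axis=0)
    return np.sqrt(np.mean(np.sum((fitted - mean) ** 2, axis=2), axis=0))


@dataclass
class FeatureSet:
    """Standardized per-node feature series for relational inference.

    ``data`` has shape (T', N, 6): position xyz then velocity xyz per kept
    frame.  ``mean``/``std`` (each length-6) record the per-dimension
    standardization so raw features can be recovered exactly.
    """

    data: np.ndarray
    mean: np.ndarray
    std: np.ndarray

    def unstandardize(self) -> np.ndarray:
        return self.data * self.std + self.mean


def featurize_nri(traj: Trajectory, stride: int = 1) -> FeatureSet:
    """Build standardized 6-dim (position, velocity) node features.

    Velocities come from the trajectory when present, otherwise from central
    finite differences of the strided positions (one-sided at the ends).
    Each of the 6 dimensions is standardized to zero mean / unit variance
    over all frames and nodes, with the transform recorded.
    """
    if stride < 1:
        raise ValueError("stride must be >= 1")
    pos = traj.coords[::stride]
    if pos.shape[0] < 2:
        raise ValueError("too few frames after striding")
    if traj.velocities is not None:
        vel = traj.velocities[::stride] * stride
    else:
        vel = np.gradient(pos, axis=0)
    raw = np.concatenate([pos, vel], axis=2)
    mean = raw.mean(axis=(0, 1))
    std = raw.std(axis=(0, 1))
    std = np.where(std < 1e-12, 1.0, std)
    return FeatureSet(data=(raw - mean) / std, mean=mean, std=std)
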