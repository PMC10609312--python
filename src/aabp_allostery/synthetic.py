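"""Synthetic inputs for the whole pipeline.

Everything the analysis consumes can be generated here without structure
downloads or an MD engine:

- two-domain hinge structures that emulate the Thumb / Index-Finger / Linker
  architecture of an amino-acid-binding protein, with an adjustable hinge
  angle (large = open, small = closed);
- elastic-network-sampled Cα trajectories (Gaussian mode amplitudes with
  optional AR(1) time correlation, so finite-difference velocities carry
  signal);
- spring-particle systems with known connectivity, the standard ground
  truth for validating relational inference;
- per-residue energy tables with a planted key-residue set.

All generators are pure functions of (spec, seed).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.spatial.transform import Rotation

from aabp_allostery.anm import ANMParams, anm_decompose, build_hessian
from aabp_allostery.energetics import EnergyRecord, EnergyTable
from aabp_allostery.structure_io import CaStructure
from aabp_allostery.trajectory import Trajectory

CA_SPACING = 3.8  # Å, consecutive Cα distance

_AA3 = ["ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS",
        "ILE", "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP",
        "TYR", "VAL"]


@dataclass
class TwoDomainSpec:
    """Geometry of a synthetic two-lobe hinge protein.

    Defaults give a ~230-residue chain (two 110-residue lobes joined by a
    10-residue extended linker), matching the size of the binding proteins
    this package targets.  ``hinge_angle`` is the angle (degrees) at the
    linker midpoint between the two lobe centroids: ~150° is an open cleft,
    ~110° a closed one.
    """

    residues_per_lobe: int = 110
    linker_length: int = 10
    lobe_radius: float | None = None     # Å; None = sized from bead count
    hinge_angle: float = 150.0
    gap: float = 6.0                     # Å between facing lobe surfaces
    jitter: float = 0.2                  # Å, positional noise sd
    seed: int = 0

    def __post_init__(self):
        total = 2 * self.residues_per_lobe + self.linker_length
        if total < 30:
            raise ValueError("need at least 30 residues in total")
        if not 0.0 < self.hinge_angle < 180.0:
            raise ValueError("hinge angle must lie in (0, 180) degrees")


@dataclass
class SpringSystemSpec:
    """Interacting spring-particle benchmark (known connectivity).

    Particles of unit mass in 3D coupled by zero-rest-length springs
    (F_i = −k Σ_j A_ij (r_i − r_j)), integrated by velocity Verlet.
    """

    n_particles: int = 5
    edge_prob: float = 0.5
    spring_constant: float = 1.0
    dt: float = 0.05
    steps: int = 2000
    noise_sd: float = 0.0
    seed: int = 0
    #: seed for initial conditions and observation noise; None = ``seed``.
    #: Distinct init seeds with the same ``seed`` give independent rollouts
    #: of the same spring network.
    init_seed: int | None = None

    def __post_init__(self):
        if self.n_particles > 20:
            raise ValueError("spring benchmark limited to 20 particles")
        # stability for the stiffest normal mode: omega_max^2 <= 2 k N
        omega_max = np.sqrt(2.0 * self.spring_constant * self.n_particles)
        if self.dt * omega_max > 0.5:
            raise ValueError(
                f"dt={self.dt} unstable for stiffest spring "
                f"(need dt < {0.5 / omega_max:.3g})"
            )


def _spherical_spiral_lobe(n: int, radius: float | None, rng,
                           jitter: float) -> np.ndarray:
    """Self-avoiding globular lobe: beads at equal arc length on a
    spherical spiral, windings ~4.4 Å apart, plus jitter."""
    if radius is None:
        # arc length of the spiral ~ 4 pi R^2 / gap; solve for R so that
        # it accommodates n beads at CA_SPACING
        gap = 4.4
        radius = float(np.sqrt(n * CA_SPACING * gap / (4.0 * np.pi)))
    c = 2.0 * np.pi * radius / 4.4      # winding rate phi = c * theta
    pts = []
    theta = 0.05
    while len(pts) < n and theta < np.pi - 0.01:
        phi = c * theta
        pts.append(radius * np.array([
            np.sin(theta) * np.cos(phi),
            np.sin(theta) * np.sin(phi),
            np.cos(theta),
        ]))
        speed = radius * np.sqrt(1.0 + (c * np.sin(theta)) ** 2)
        theta += CA_SPACING / speed
    while len(pts) < n:                  # spill over onto a slightly larger shell
        prev = pts[-1]
        direction = prev / np.linalg.norm(prev)
        pts.append(prev + CA_SPACING * np.cross(direction, [0, 0, 1.0]))
    coords = np.array(pts[:n])
    coords += rng.normal(0.0, jitter, size=coords.shape)
    return _regularize_bonds(coords)


def _regularize_bonds(coords: np.ndarray, target: float = CA_SPACING,
                      tol: float = 0.3, iters: int = 100,
                      pin_ends: bool = False) -> np.ndarray:
    """Nudge consecutive beads until bond lengths sit within target ± tol.

    With ``pin_ends`` the first and last bead stay fixed and their bond
    corrections go entirely to the free partner.
    """
    coords = coords.copy()
    last = len(coords) - 1
    for _ in range(iters):
        d = np.linalg.norm(np.diff(coords, axis=0), axis=1)
        bad = np.abs(d - target) > tol
        if not bad.any():
            break
        for i in np.where(bad)[0]:
            vec = coords[i + 1] - coords[i]
            length = np.linalg.norm(vec)
            corr = (length - target) * vec / length
            w_lo = 0.0 if (pin_ends and i == 0) else 0.5
            w_hi = 0.0 if (pin_ends and i + 1 == last) else 0.5
            if w_lo + w_hi == 0.0:
                continue
            coords[i] += corr * w_lo / (w_lo + w_hi)
            coords[i + 1] -= corr * w_hi / (w_lo + w_hi)
    return coords


def hinge_angle_of(coords: np.ndarray, labels: list[str]) -> float:
    """Angle (degrees) at the linker midpoint between lobe centroids."""
    lab = np.asarray(labels)
    c_a = coords[lab == "lobeA"].mean(axis=0)
    c_b = coords[lab == "lobeB"].mean(axis=0)
    linker_idx = np.where(lab == "linker")[0]
    pivot = coords[linker_idx[len(linker_idx) // 2]]
    u, v = c_a - pivot, c_b - pivot
    cosang = np.dot(u, v) / (np.linalg.norm(u) * np.linalg.norm(v))
    return float(np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0))))


def _align_pole(coords: np.ndarray, pole: np.ndarray,
                target: np.ndarray) -> np.ndarray:
    """Rotate a centred lobe so ``pole`` points along ``target``."""
    pole = pole / np.linalg.norm(pole)
    target = target / np.linalg.norm(target)
    axis = np.cross(pole, target)
    norm = np.linalg.norm(axis)
    if norm < 1e-12:
        if np.dot(pole, target) > 0:
            return coords
        return Rotation.from_rotvec(
            np.pi * _any_perpendicular(target)).apply(coords)
    angle = np.arccos(np.clip(np.dot(pole, target), -1.0, 1.0))
    return Rotation.from_rotvec(axis / norm * angle).apply(coords)


def make_two_domain_structure(spec: TwoDomainSpec) -> tuple[CaStructure, list[str]]:
    """Two globular lobes facing each other across a small gap, joined by a
    folded linker, set to the requested hinge angle.

    The facing surfaces sit ``spec.gap`` Å apart so the inter-lobe
    interface is spring-connected in the elastic network (as in a real
    binding cleft); the linker zig-zags between the poles.  Returns the
    structure and per-residue labels (``lobeA`` / ``linker`` / ``lobeB``).
    """
    rng = np.random.default_rng(spec.seed)
    n, L = spec.residues_per_lobe, spec.linker_length

    lobe_a = _spherical_spiral_lobe(n, spec.lobe_radius, rng, spec.jitter)
    centred_a = lobe_a - lobe_a.mean(axis=0)
    # chain ends near the -z pole of the spiral; face it toward lobe B (+x)
    lobe_a = _align_pole(centred_a, centred_a[-1], np.array([1.0, 0.0, 0.0]))
    r_a = np.linalg.norm(lobe_a, axis=1).mean()

    lobe_b = _spherical_spiral_lobe(n, spec.lobe_radius, rng, spec.jitter)
    centred_b = lobe_b - lobe_b.mean(axis=0)
    # chain starts near the +z pole; face it back toward lobe A (-x)
    lobe_b = _align_pole(centred_b, centred_b[0], np.array([-1.0, 0.0, 0.0]))
    r_b = np.linalg.norm(lobe_b, axis=1).mean()
    lobe_b = lobe_b + np.array([r_a + spec.gap + r_b, 0.0, 0.0])

    # folded zig-zag linker between the facing poles; collinear beads would
    # leave the anisotropic network with zero-energy transverse modes
    exit_a, entry_b = lobe_a[-1], lobe_b[0]
    span = entry_b - exit_a
    step = np.linalg.norm(span) / (L + 1)
    amp = 0.5 * np.sqrt(max(CA_SPACING**2 - step**2, 1.0))
    perp1 = _any_perpendicular(span)
    perp2 = np.cross(span / np.linalg.norm(span), perp1)
    linker = np.array([
        exit_a + (k + 1) / (L + 1) * span
        + amp * (-1) ** k * perp1 + 0.3 * amp * np.cos(k) * perp2
        for k in range(L)
    ])
    linker += rng.normal(0.0, spec.jitter, size=linker.shape)
    linker = _regularize_bonds(np.vstack([exit_a[None], linker,
                                          entry_b[None]]),
                               pin_ends=True)[1:-1]

    coords = np.vstack([lobe_a, linker, lobe_b])
    labels = ["lobeA"] * n + ["linker"] * L + ["lobeB"] * n
    names = [str(_AA3[i]) for i in rng.integers(0, 20, size=len(coords))]
    s = CaStructure(
        residue_ids=np.arange(1, len(coords) + 1),
        residue_names=names,
        coords=coords,
        chain_id="A",
        label=f"synthetic-two-domain-{spec.hinge_angle:.0f}",
    )
    s = close_hinge(s, labels, spec.hinge_angle)
    return s, labels


def _any_perpendicular(v: np.ndarray) -> np.ndarray:
    trial = np.array([1.0, 0.0, 0.0])
    if abs(np.dot(trial, v)) > 0.9:
        trial = np.array([0.0, 1.0, 0.0])
    p = np.cross(v, trial)
    return p / np.linalg.norm(p)


def close_hinge(s: CaStructure, labels: list[str], new_angle: float) -> CaStructure:
    """Rigidly rotate lobe B about the linker midpoint to the target hinge
    angle; lobe-internal geometry is untouched."""
    if not 0.0 < new_angle < 180.0:
        raise ValueError("hinge angle must lie in (0, 180) degrees")
    lab = np.asarray(labels)
    coords = s.coords.copy()
    current = hinge_angle_of(coords, labels)
    delta = np.radians(current - new_angle)
    if abs(delta) < 1e-12:
        return CaStructure(residue_ids=s.residue_ids.copy(),
                           residue_names=list(s.residue_names),
                           coords=coords, chain_id=s.chain_id, label=s.label,
                           icodes=list(s.icodes))
    linker_idx = np.where(lab == "linker")[0]
    mid = len(linker_idx) // 2
    pivot = coords[linker_idx[mid]]
    c_a = coords[lab == "lobeA"].mean(axis=0)
    c_b = coords[lab == "lobeB"].mean(axis=0)
    u, v = c_a - pivot, c_b - pivot
    axis = np.cross(v, u)                 # rotating v toward u closes the angle
    if np.linalg.norm(axis) < 1e-9:
        axis = _any_perpendicular(u if np.linalg.norm(u) > 0 else v)
    axis = axis / np.linalg.norm(axis)
    rot = Rotation.from_rotvec(axis * delta)
    move = (lab == "lobeB")
    move[linker_idx[mid + 1:]] = True     # second linker half follows lobe B
    coords[move] = rot.apply(coords[move] - pivot) + pivot
    out = CaStructure(residue_ids=s.residue_ids.copy(),
                      residue_names=list(s.residue_names),
                      coords=coords, chain_id=s.chain_id,
                      label=s.label, icodes=list(s.icodes))
    achieved = hinge_angle_of(coords, labels)
    if abs(achieved - new_angle) > 1.0:
        warnings.warn(
            f"hinge angle {achieved:.1f}° differs from target {new_angle}°"
        )
    return out


def sample_enm_trajectory(s: CaStructure, n_frames: int = 200,
                          amplitude: float = 1.0, seed: int = 0,
                          params: ANMParams | None = None,
                          n_modes: int | None = 30,
                          ar_coeff: float = 0.9) -> Trajectory:
    """Sample a trajectory from the structure's anisotropic network model.

    Frame t is  x⁰ + Σ_k a_k(t) v_k  over the ``n_modes`` slowest internal
    modes, where each amplitude follows a stationary AR(1) process with
    variance ``amplitude / λ_k`` and lag-one correlation ``ar_coeff``
    (``ar_coeff = 0`` gives independent Gaussian frames).  A desk-scale
    stand-in for long explicit-solvent MD sampling of the same network.
    """
    if not 0.0 <= ar_coeff < 1.0:
        raise ValueError("ar_coeff must lie in [0, 1)")
    rng = np.random.default_rng(seed)
    res = anm_decompose(build_hessian(s.coords, params), params)
    if res.n_zero > 6:
        raise ValueError("disconnected network: cannot sample trajectory")
    internal = res.internal_modes
    if n_modes is not None:
        internal = internal[:n_modes]
    lam = res.eigenvalues[internal]
    vecs = res.eigenvectors[:, internal]            # (3N, K)
    sigma = np.sqrt(amplitude / lam)
    amps = np.empty((n_frames, len(lam)))
    if amplitude == 0:
        amps[:] = 0.0
    else:
        amps[0] = rng.normal(0.0, sigma)
        innov = np.sqrt(1.0 - ar_coeff**2) * sigma
        for t in range(1, n_frames):
            amps[t] = ar_coeff * amps[t - 1] + rng.normal(0.0, innov)
    disp = amps @ vecs.T                            # (T, 3N)
    coords = s.coords[None] + disp.reshape(n_frames, -1, 3)
    return Trajectory(coords=coords, timestep=1.0,
                      label=f"enm-sample-{s.label}")


def simulate_springs(spec: SpringSystemSpec) -> tuple[Trajectory, np.ndarray]:
    """Velocity-Verlet integration of a random spring network.

    Returns the (optionally observation-noisy) trajectory with velocities,
    and the exact symmetric adjacency matrix.  Aborts if total energy grows
    more than tenfold (unstable timestep).
    """
    graph_rng = np.random.default_rng(spec.seed)
    rng = np.random.default_rng(
        spec.seed if spec.init_seed is None else spec.init_seed
    )
    n, k, dt = spec.n_particles, spec.spring_constant, spec.dt
    adj = np.triu(graph_rng.random((n, n)) < spec.edge_prob, 1)
    adj = (adj | adj.T).astype(int)
    pos = rng.normal(0.0, 1.0, size=(n, 3))
    vel = rng.normal(0.0, 0.5, size=(n, 3))
    deg = adj.sum(axis=1)

    def forces(p):
        return -k * (deg[:, None] * p - adj @ p)

    def energy(p, v):
        kin = 0.5 * np.sum(v * v)
        diff = p[:, None, :] - p[None, :, :]
        pot = 0.25 * k * np.sum(adj[:, :, None] * diff**2)
        return kin + pot

    e0 = energy(pos, vel)
    coords = np.empty((spec.steps, n, 3))
    vels = np.empty((spec.steps, n, 3))
    f = forces(pos)
    for t in range(spec.steps):
        coords[t], vels[t] = pos, vel
        pos = pos + vel * dt + 0.5 * f * dt * dt
        f_new = forces(pos)
        vel = vel + 0.5 * (f + f_new) * dt
        f = f_new
    if e0 > 0 and energy(pos, vel) > 10.0 * e0:
        raise RuntimeError("unstable integration: energy grew >10x")
    if spec.noise_sd > 0:
        coords = coords + rng.normal(0.0, spec.noise_sd, size=coords.shape)
        vels = vels + rng.normal(0.0, spec.noise_sd, size=vels.shape)
    traj = Trajectory(coords=coords, velocities=vels * dt, timestep=dt,
                      label=f"springs-n{n}-seed{spec.seed}")
    return traj, adj


def make_energy_table(n_rows: int = 20, n_key: int = 5, seed: int = 0,
                      system: str = "synthetic") -> tuple[EnergyTable, list[int]]:
    """Random energy table with exactly ``n_key`` planted key residues
    (E_TOT < −1.00 kJ/mol, kept clear of the threshold).  Returns the table
    and the planted residue numbers."""
    if n_key > n_rows:
        raise ValueError("n_key cannot exceed n_rows")
    rng = np.random.default_rng(seed)
    residues = rng.choice(np.arange(1, 239), size=n_rows, replace=False)
    key_rows = set(rng.choice(n_rows, size=n_key, replace=False).tolist())
    records = []
    letters = "ARNDCQEGHILKMFPSTWYV"
    for row, res in enumerate(residues):
        comps = rng.normal(0.0, 0.8, size=4)
        target = (rng.uniform(-5.0, -1.2) if row in key_rows
                  else rng.uniform(-0.8, 1.5))
        comps[1] += target - comps.sum()
        comps = np.round(comps, 2)
        etot = round(float(comps.sum()), 2)
        records.append(EnergyRecord(
            residue=int(res), native=f"{letters[rng.integers(0, 20)]}{res}",
            e_vdw=float(comps[0]), e_ele=float(comps[1]),
            e_gb=float(comps[2]), e_gbsur=float(comps[3]), e_tot=etot,
        ))
    truth = sorted((records[r].residue for r in key_rows),
                   key=lambda resnum: next(
                       rec.e_tot for rec in records if rec.residue == resnum))
    return EnergyTable(system=system, records=records), truth
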