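"""Synthetic generators: hinge structures, ENM trajectories, springs,
energy tables, and the end-to-end open/closed signature."""

import numpy as np
import pytest
from scipy.spatial.distance import pdist, squareform

from aabp_allostery import (
    anm,
    build_hessian,
    build_kirchhoff,
    cross_correlation,
    gnm_decompose,
    key_residues,
    mode_fluctuations,
    overlap_with_transition,
    rmsf_profile,
    synthetic,
)
from aabp_allostery.anm import anm_decompose
from aabp_allostery.synthetic import (
    SpringSystemSpec,
    TwoDomainSpec,
    close_hinge,
    hinge_angle_of,
    make_energy_table,
    make_two_domain_structure,
    sample_enm_trajectory,
    simulate_springs,
)


class TestTwoDomainStructure:
    def test_same_seed_identical(self):
        spec = TwoDomainSpec(residues_per_lobe=35, linker_length=5, seed=9)
        s1, l1 = make_two_domain_structure(spec)
        s2, l2 = make_two_domain_structure(spec)
        np.testing.assert_array_equal(s1.coords, s2.coords)
        assert l1 == l2

    @pytest.mark.parametrize("seed", range(3))
    def test_backbone_spacing(self, seed):
        spec = TwoDomainSpec(residues_per_lobe=50, linker_length=8,
                             seed=seed)
        s, _ = make_two_domain_structure(spec)
        d = np.linalg.norm(np.diff(s.coords, axis=0), axis=1)
        assert d.min() > 3.8 - 0.5
        assert d.max() < 3.8 + 0.5

    def test_hinge_angle_honoured(self):
        for angle in (170.0, 140.0, 100.0):
            s, labels = make_two_domain_structure(
                TwoDomainSpec(residues_per_lobe=40, linker_length=6,
                              hinge_angle=angle, seed=2))
            assert hinge_angle_of(s.coords, labels) == pytest.approx(
                angle, abs=1.0)

    def test_gnm_interlobe_anticorrelation(self, small_two_domain):
        s_open, _, labels = small_two_domain
        lab = np.array(labels)
        res = gnm_decompose(build_kirchhoff(s_open.coords))
        cc = cross_correlation(res, "slow", 2)
        assert cc[np.ix_(lab == "lobeA", lab == "lobeB")].mean() < 0

    def test_invalid_specs_rejected(self):
        with pytest.raises(ValueError):
            TwoDomainSpec(residues_per_lobe=5, linker_length=2)
        with pytest.raises(ValueError):
            TwoDomainSpec(hinge_angle=200.0)


class TestCloseHinge:
    def test_same_angle_is_identity(self, small_two_domain):
        s_open, _, labels = small_two_domain
        angle = hinge_angle_of(s_open.coords, labels)
        same = close_hinge(s_open, labels, angle)
        np.testing.assert_allclose(same.coords, s_open.coords, atol=1e-9)

    def test_intra_lobe_distances_preserved(self, small_two_domain):
        s_open, s_closed, labels = small_two_domain
        lab = np.array(labels)
        for lobe in ("lobeA", "lobeB"):
            d_open = pdist(s_open.coords[lab == lobe])
            d_closed = pdist(s_closed.coords[lab == lobe])
            np.testing.assert_allclose(d_open, d_closed, atol=1e-6)

    def test_transition_concentrates_in_lowest_modes(self, small_two_domain):
        """The open→closed hinge motion projects mostly onto the three
        lowest internal modes of the anisotropic network."""
        s_open, s_closed, labels = small_two_domain
        res = anm_decompose(build_hessian(s_open.coords))
        ov = overlap_with_transition(res, s_open.coords, s_closed.coords)
        assert np.sum(ov[:3] ** 2) > 0.5

    def test_angle_out_of_range_rejected(self, small_two_domain):
        s_open, _, labels = small_two_domain
        with pytest.raises(ValueError):
            close_hinge(s_open, labels, 190.0)


class TestEnmTrajectory:
    @pytest.fixture(scope="class")
    def small_structure(self):
        s, _ = make_two_domain_structure(
            TwoDomainSpec(residues_per_lobe=14, linker_length=4, seed=5))
        return s

    def test_zero_amplitude_is_static(self, small_structure):
        traj = sample_enm_trajectory(small_structure, n_frames=10,
                                     amplitude=0.0, seed=0)
        np.testing.assert_allclose(rmsf_profile(traj), 0.0, atol=1e-12)

    def test_seeded_reproducibility(self, small_structure):
        t1 = sample_enm_trajectory(small_structure, n_frames=20, seed=3)
        t2 = sample_enm_trajectory(small_structure, n_frames=20, seed=3)
        np.testing.assert_array_equal(t1.coords, t2.coords)

    def test_per_mode_variance_matches_spectrum(self, small_structure):
        """Projected amplitude variance ≈ amplitude/λ_k (within 15%) for
        the softest sampled modes at T = 5000."""
        amplitude = 2.0
        res = anm_decompose(build_hessian(small_structure.coords))
        traj = sample_enm_trajectory(small_structure, n_frames=5000,
                                     amplitude=amplitude, seed=7,
                                     n_modes=10, ar_coeff=0.0)
        disp = (traj.coords - small_structure.coords[None]).reshape(
            traj.n_frames, -1)
        for k in res.internal_modes[:4]:
            v = res.eigenvectors[:, int(k)]
            proj = disp @ v
            expected = amplitude / res.eigenvalues[int(k)]
            assert proj.var() == pytest.approx(expected, rel=0.15)

    def test_rmsf_recovers_network_fluctuations(self, small_structure):
        """Trajectory RMSF² correlates (r > 0.8) with the network's
        per-residue square fluctuations."""
        res = anm_decompose(build_hessian(small_structure.coords))
        msf = np.zeros(small_structure.n_residues)
        for k in res.internal_modes[:10]:
            v = res.mode_vectors(int(k))
            msf += np.sum(v ** 2, axis=1) / res.eigenvalues[int(k)]
        traj = sample_enm_trajectory(small_structure, n_frames=3000,
                                     amplitude=1.0, seed=11, n_modes=10)
        rmsf = rmsf_profile(traj)
        r = np.corrcoef(rmsf ** 2, msf)[0, 1]
        assert r > 0.8


class TestSprings:
    def test_single_pair_oscillation_period(self):
        """Two coupled particles oscillate in separation with period
        2π/√(2k) (reduced mass ½, unit masses)."""
        # build a 2-particle system by forcing the edge
        spec = SpringSystemSpec(n_particles=2, edge_prob=1.0,
                                spring_constant=1.0, dt=0.01, steps=5000,
                                seed=1)
        traj, adj = simulate_springs(spec)
        assert adj[0, 1] == 1
        # x-component of the separation vector (|sep| would rectify the
        # oscillation and double the apparent frequency)
        sep = traj.coords[:, 0, 0] - traj.coords[:, 1, 0]
        sep = sep - sep.mean()
        # dominant discrete frequency vs closed form
        freqs = np.fft.rfftfreq(len(sep), d=spec.dt)
        peak = freqs[np.argmax(np.abs(np.fft.rfft(sep)))]
        expected = np.sqrt(2.0) / (2 * np.pi)
        assert peak == pytest.approx(expected, rel=0.05)

    def test_no_edges_is_free_flight(self):
        spec = SpringSystemSpec(n_particles=4, edge_prob=0.0, steps=200,
                                seed=2)
        traj, adj = simulate_springs(spec)
        assert adj.sum() == 0
        # straight lines: second differences vanish
        acc = np.diff(traj.coords, n=2, axis=0)
        np.testing.assert_allclose(acc, 0.0, atol=1e-12)

    def test_energy_conservation(self):
        spec = SpringSystemSpec(seed=3, steps=5000)
        traj, adj = simulate_springs(spec)
        k, dt = spec.spring_constant, spec.dt
        def energy(p, v):
            kin = 0.5 * np.sum(v * v)
            diff = p[:, None, :] - p[None, :, :]
            pot = 0.25 * k * np.sum(adj[:, :, None] * diff ** 2)
            return kin + pot
        e0 = energy(traj.coords[0], traj.velocities[0] / dt)
        e1 = energy(traj.coords[-1], traj.velocities[-1] / dt)
        assert abs(e1 - e0) / e0 < 0.01

    def test_unstable_dt_rejected(self):
        with pytest.raises(ValueError, match="unstable"):
            SpringSystemSpec(dt=1.0, spring_constant=10.0)

    def test_same_seed_identical(self):
        t1, a1 = simulate_springs(SpringSystemSpec(seed=4, steps=50))
        t2, a2 = simulate_springs(SpringSystemSpec(seed=4, steps=50))
        np.testing.assert_array_equal(t1.coords, t2.coords)
        np.testing.assert_array_equal(a1, a2)

    def test_init_seed_varies_rollout_not_graph(self):
        _, a1 = simulate_springs(SpringSystemSpec(seed=4, init_seed=1,
                                                  steps=10))
        t2, a2 = simulate_springs(SpringSystemSpec(seed=4, init_seed=2,
                                                   steps=10))
        np.testing.assert_array_equal(a1, a2)


class TestEnergyTableGenerator:
    def test_planted_keys_recovered_exactly(self):
        table, truth = make_energy_table(30, 8, seed=5)
        got = sorted(r.residue for r in key_residues(table))
        assert got == sorted(truth)

    def test_no_keys_filter_empty(self):
        table, truth = make_energy_table(10, 0, seed=6)
        assert truth == []
        assert key_residues(table) == []

    def test_seeded_determinism(self):
        t1, k1 = make_energy_table(12, 3, seed=7)
        t2, k2 = make_energy_table(12, 3, seed=7)
        assert k1 == k2
        for a, b in zip(t1.records, t2.records):
            assert (a.residue, a.e_tot) == (b.residue, b.e_tot)


class TestOpenClosedSignature:
    """End-to-end qualitative pattern of lobe closure."""

    def test_anticorrelation_stronger_when_open(self, small_two_domain):
        s_open, s_closed, labels = small_two_domain
        lab = np.array(labels)
        inter = {}
        for tag, s in (("open", s_open), ("closed", s_closed)):
            res = gnm_decompose(build_kirchhoff(s.coords))
            cc = cross_correlation(res, "slow", 2)
            inter[tag] = cc[np.ix_(lab == "lobeA", lab == "lobeB")].mean()
        assert inter["open"] < inter["closed"] < 0.5
        assert inter["open"] < 0

    def test_closed_state_fluctuates_less_on_average(self, small_two_domain):
        s_open, s_closed, labels = small_two_domain
        rmsf = {}
        for tag, s in (("open", s_open), ("closed", s_closed)):
            traj = sample_enm_trajectory(s, n_frames=400, amplitude=1.0,
                                         seed=13, n_modes=15)
            rmsf[tag] = rmsf_profile(traj)
        assert rmsf["closed"].mean() <= rmsf["open"].mean()
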