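"""Shared fixtures: small synthetic systems reused across the suite.

Expensive artifacts (trained relational-inference models, sampled
trajectories) are session-scoped so each is computed once.
"""

from __future__ import annotations

import numpy as np
import pytest

from aabp_allostery import featurize_nri, synthetic
from aabp_allostery.nri import (
    NRIConfig,
    correlation_baseline,
    edge_recovery_accuracy,
    train_nri,
)

#: Training settings for the spring-system edge-recovery studies.
SPRING_SEEDS = (0, 1, 2)
SPRING_ROLLOUTS = 3
SPRING_STEPS = 4000
SPRING_STRIDE = 4
NRI_TRAIN_CONFIG = dict(k=2, hidden=64, window=20, batch_size=32,
                        refeed=10, temperature=0.5, lr=2e-3, epochs=120)


@pytest.fixture(scope="session")
def small_two_domain():
    """An 86-residue open/closed hinge pair with labels."""
    spec = synthetic.TwoDomainSpec(residues_per_lobe=40, linker_length=6,
                                   hinge_angle=150.0, seed=1)
    s_open, labels = synthetic.make_two_domain_structure(spec)
    s_closed = synthetic.close_hinge(s_open, labels, 110.0)
    return s_open, s_closed, labels


@pytest.fixture(scope="session")
def default_two_domain():
    """The default-size (230-residue) open-state structure with labels."""
    spec = synthetic.TwoDomainSpec(seed=0)
    s, labels = synthetic.make_two_domain_structure(spec)
    return s, labels


def spring_features(seed: int, n_rollouts: int = SPRING_ROLLOUTS,
                    steps: int = SPRING_STEPS, stride: int = SPRING_STRIDE,
                    noise_sd: float = 0.0):
    """Feature series (list of rollouts) plus true adjacency for one
    spring network."""
    feats, adj = [], None
    for r in range(n_rollouts):
        spec = synthetic.SpringSystemSpec(
            seed=seed, init_seed=1000 * seed + r, steps=steps,
            noise_sd=noise_sd,
        )
        traj, adj = synthetic.simulate_springs(spec)
        feats.append(featurize_nri(traj, stride=stride).data)
    return feats, adj


@pytest.fixture(scope="session")
def spring_recovery_runs():
    """Trained NRI posteriors on the three benchmark spring systems.

    Returns a list of dicts with accuracy, baseline accuracy, posterior,
    training report and the true adjacency, one per seed.
    """
    runs = []
    for seed in SPRING_SEEDS:
        feats, adj = spring_features(seed)
        cfg = NRIConfig(seed=seed, **NRI_TRAIN_CONFIG)
        model, posterior, report = train_nri(feats, cfg)
        baseline = correlation_baseline(np.concatenate(feats, axis=0))
        mask = ~np.eye(adj.shape[0], dtype=bool)
        runs.append({
            "seed": seed,
            "accuracy": edge_recovery_accuracy(posterior, adj),
            "baseline_accuracy": float(
                np.mean(baseline[mask] == adj.astype(bool)[mask])
            ),
            "posterior": posterior,
            "report": report,
            "adjacency": adj,
        })
    return runs
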