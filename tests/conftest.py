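"""Shared fixtures and independent oracle helpers.

The oracle helpers deliberately use plain numpy broadcasting (no cell
lists, no numba) so that they stay independent of the code paths they
check.
"""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from sbstraffic.model import PolymerTopology, SimulationConfig, Trajectory

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


def min_image_diff(a: np.ndarray, b: np.ndarray, L: float) -> np.ndarray:
    """Brute-force minimum-image displacement b - a (broadcasting)."""
    d = np.asarray(b, float) - np.asarray(a, float)
    return d - L * np.floor(d / L + 0.5)


def pairwise_dist(pos_a: np.ndarray, pos_b: np.ndarray, L: float) -> np.ndarray:
    """All-pairs minimum-image distances (len(a) x len(b))."""
    d = min_image_diff(pos_a[:, None, :], pos_b[None, :, :], L)
    return np.sqrt((d**2).sum(axis=-1))


def brute_contact_matrix(mono: np.ndarray, L: float, t: float, min_sep: int = 2) -> np.ndarray:
    """Boolean contact count for one snapshot (strict < t), excluding
    pairs with |i - j| < min_sep."""
    N = mono.shape[0]
    d = pairwise_dist(mono, mono, L)
    H = (d < t).astype(np.int64)
    for off in range(-min_sep + 1, min_sep):
        idx = np.arange(max(0, -off), min(N, N - off))
        H[idx, idx + off] = 0
    return H


def brute_cross_counts(a: np.ndarray, b: np.ndarray, L: float, t: float) -> np.ndarray:
    """Per-row count of b-particles within t of each a-particle."""
    return (pairwise_dist(a, b, L) < t).sum(axis=1)


def synthetic_trajectory(
    seed: int,
    N: int = 20,
    n_anchors: int = 2,
    n_tracers: int = 5,
    box_edge: float = 12.0,
    n_snapshots: int = 3,
    include_binders: bool = True,
) -> Trajectory:
    """Random particle positions wrapped in a valid Trajectory container."""
    rng = np.random.default_rng(seed)
    anchors = tuple(int(i) for i in rng.choice(N, size=n_anchors, replace=False))
    topo = PolymerTopology(n_monomers=N, anchor_indices=anchors, phi=n_anchors / N)
    config = SimulationConfig(
        topology=topo,
        epsilon=1.0,
        n_tracers=n_tracers,
        box_edge=box_edge,
        n_equil=0,
        n_total=n_snapshots,
        sample_every=1,
        seed=seed,
        include_binders=include_binders,
    )
    n = config.n_particles
    positions = rng.uniform(0.0, box_edge, size=(n_snapshots, n, 3))
    return Trajectory(
        positions=positions,
        steps=np.arange(1, n_snapshots + 1),
        species=config.species_codes(),
        config=config,
        provenance={"synthetic": True},
    )


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


# ---------------------------------------------------------------------------
# session-scoped simulation campaigns shared by the physics property tests
# and the acceptance tests (each takes minutes; computed once per session)
# ---------------------------------------------------------------------------

#: grid runs keep the full equilibration but a shorter sampling window
#: (1000 snapshots), which is ample for the trend-level statistics
GRID_TEMPLATE = {
    "N": 300, "n_tracers": 10, "L": 50.0, "dt": 0.005,
    "n_equil": 200_000, "n_total": 300_000, "sample_every": 100,
}


@pytest.fixture(scope="session")
def epsilon_sweep():
    """Bound-time sweep at phi = 0.10: 5 affinities spanning the study
    range, 2 replicates, full-length desk runs."""
    from sbstraffic.sweeps import DESK_TEMPLATE, SweepPlan, run_sweep

    plan = SweepPlan((0.10,), (0.9, 1.3, 1.9, 2.3, 2.7),
                     n_replicates=2, base_seed=101)
    return run_sweep(plan, template=dict(DESK_TEMPLATE))


@pytest.fixture(scope="session")
def extreme_grid():
    """The four corners of the (phi, epsilon) plane, 2 replicates."""
    from sbstraffic.sweeps import SweepPlan, run_sweep

    plan = SweepPlan((0.02, 0.50), (0.9, 2.7), n_replicates=2, base_seed=202)
    return run_sweep(plan, template=dict(GRID_TEMPLATE))


def grid_cell(df, phi, eps, column):
    """Replicate-mean of one statistic in one grid cell."""
    sel = df[(df["phi"] == phi) & (df["epsilon"] == eps)]
    return float(sel[column].mean())


@pytest.fixture
def tiny_config():
    """A config small enough for second-scale full runs."""
    return SimulationConfig.from_params(
        N=30, phi=0.1, epsilon=1.5, n_tracers=4, seed=7,
        n_equil=500, n_total=1500, sample_every=50,
    )
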