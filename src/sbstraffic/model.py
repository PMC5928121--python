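"""Domain types for the strings-and-binders tracer model.

The system contains four species of spherical particles, all of radius
scale ``sigma`` (the simulation length unit, nominally 15 nm):

``p``
    ordinary polymer monomers, connected into a single bead--spring chain;
``a``
    anchor monomers -- chain monomers designated as binding sites.  Their
    fraction of the chain is the compaction parameter ``phi``;
``b``
    binders -- diffusible bridging particles with a strong affinity
    (10 kT) for anchors only.  Two binders are provided per anchor, so
    ``n_binders = 2 * phi * N``;
``t``
    tracers -- diffusible particles with a uniform non-specific affinity
    ``epsilon`` for every chain monomer (both p and a).  They model
    transcription factors in search mode.

Internal units: ``kT = 1``, ``sigma = 1``, drag ``gamma = 1``.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

__all__ = [
    "SPECIES",
    "P",
    "A",
    "B",
    "T",
    "InteractionTable",
    "PolymerTopology",
    "SimulationConfig",
    "SystemState",
    "Trajectory",
    "make_interaction_table",
    "build_topology",
    "parameter_grid",
    "load_config",
    "save_config",
]

#: Species labels in canonical order; integer codes index interaction tables.
SPECIES = ("p", "a", "b", "t")
P, A, B, T = range(4)
SPECIES_CODE = {label: code for code, label in enumerate(SPECIES)}

#: LJ well depth used for pairs that interact by hard-core repulsion only
#: (xi = 0).  The repulsive r^-12 branch needs a positive prefactor; 1 kT
#: is the conventional choice and sets the softness of the core.
HARDCORE_EPS = 1.0


@dataclass(frozen=True)
class InteractionTable:
    """Symmetric per-species-pair interaction parameters.

    ``eps[i][j]`` is the Lennard-Jones well parameter in kT and
    ``xi[i][j]`` the attraction switch (0 = hard-core only, 1 = attractive
    branch on) for species codes ``i, j``.  Bonded neighbors additionally
    feel a harmonic spring of stiffness ``k_bond`` and rest length ``r0``.
    """

    eps: np.ndarray
    xi: np.ndarray
    sigma: float = 1.0
    r_cut: float = 3.0
    k_bond: float = 330.0
    r0: float = 1.2
    #: physical length mapped onto one sigma; metadata only.
    sigma_nm: float = 15.0

    def __post_init__(self) -> None:
        eps = np.asarray(self.eps, dtype=float)
        xi = np.asarray(self.xi, dtype=float)
        if eps.shape != (4, 4) or xi.shape != (4, 4):
            raise ValueError("interaction tables must be 4x4 (one row per species)")
        if not np.allclose(eps, eps.T) or not np.allclose(xi, xi.T):
            raise ValueError("interaction tables must be symmetric")
        if self.r_cut <= self.r0:
            raise ValueError("LJ cutoff must exceed the bond rest length")
        object.__setattr__(self, "eps", eps)
        object.__setattr__(self, "xi", xi)


def make_interaction_table(
    epsilon_tracer: float,
    *,
    epsilon_ab: float = 10.0,
    sigma: float = 1.0,
    r_cut: float = 3.0,
    k_bond: float = 330.0,
    r0: float = 1.2,
) -> InteractionTable:
    """Build the interaction table for a given tracer affinity.

    ``epsilon_tracer`` is the uniform non-specific tracer-monomer affinity
    (applied to both t-p and t-a pairs).  Binders always attract anchors
    with ``epsilon_ab`` (10 kT); every other pair is hard-core repulsive.
    ``epsilon_tracer = 0`` switches the tracer attraction off entirely,
    leaving purely repulsive tracers (the volume-exclusion control).
    """
    if epsilon_tracer < 0:
        raise ValueError(f"tracer affinity must be non-negative, got {epsilon_tracer}")
    eps = np.full((4, 4), HARDCORE_EPS)
    xi = np.zeros((4, 4))
    eps[A, B] = eps[B, A] = epsilon_ab
    xi[A, B] = xi[B, A] = 1.0
    if epsilon_tracer > 0:
        for m in (P, A):
            eps[T, m] = eps[m, T] = epsilon_tracer
            xi[T, m] = xi[m, T] = 1.0
    return InteractionTable(eps=eps, xi=xi, sigma=sigma, r_cut=r_cut, k_bond=k_bond, r0=r0)


@dataclass(frozen=True)
class PolymerTopology:
    """A single unbranched chain of ``n_monomers`` beads with anchors."""

    n_monomers: int
    anchor_indices: tuple[int, ...]
    phi: float

    def __post_init__(self) -> None:
        if self.n_monomers < 2:
            raise ValueError("a chain needs at least two monomers")
        if not (0.0 < self.phi <= 1.0):
            raise ValueError(f"phi must be in (0, 1], got {self.phi}")
        anchors = tuple(sorted(int(i) for i in self.anchor_indices))
        if len(set(anchors)) != len(anchors):
            raise ValueError("anchor indices must be unique")
        if anchors and (anchors[0] < 0 or anchors[-1] >= self.n_monomers):
            raise ValueError("anchor index outside the chain")
        if len(anchors) != round(self.phi * self.n_monomers):
            raise ValueError("anchor count does not match round(phi * N)")
        object.__setattr__(self, "anchor_indices", anchors)

    @property
    def n_anchors(self) -> int:
        return len(self.anchor_indices)

    @property
    def bonds(self) -> list[tuple[int, int]]:
        return [(i, i + 1) for i in range(self.n_monomers - 1)]

    def monomer_species(self) -> np.ndarray:
        """Per-monomer species codes (P everywhere, A at anchors)."""
        codes = np.full(self.n_monomers, P, dtype=np.int8)
        codes[list(self.anchor_indices)] = A
        return codes


def build_topology(n_monomers: int, phi: float, seed: int | np.random.Generator) -> PolymerTopology:
    """Draw a topology with ``round(phi * N)`` anchors placed uniformly
    at random without replacement; reproducible from ``seed``."""
    if n_monomers < 2:
        raise ValueError("a chain needs at least two monomers")
    if not (0.0 < phi <= 1.0):
        raise ValueError(f"phi must be in (0, 1], got {phi}")
    n_anchors = round(phi * n_monomers)
    if n_anchors == 0:
        raise ValueError(f"round(phi * N) = 0 for N={n_monomers}, phi={phi}: no loops possible")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    anchors = rng.choice(n_monomers, size=n_anchors, replace=False)
    return PolymerTopology(n_monomers=n_monomers, anchor_indices=tuple(int(i) for i in anchors), phi=phi)


def parameter_grid() -> tuple[np.ndarray, np.ndarray]:
    """The full study grid: 25 anchor fractions (2%-50% in 2% steps) and
    10 tracer affinities (0.9-2.7 kT in 0.2 kT steps)."""
    phi_values = np.round(np.arange(1, 26) * 0.02, 2)
    epsilon_values = np.round(0.9 + 0.2 * np.arange(10), 1)
    return phi_values, epsilon_values


@dataclass
class SimulationConfig:
    """Full specification of one simulation run.

    Step counts follow the sampling protocol: ``n_equil`` steps are
    discarded, then one snapshot is taken every ``sample_every`` steps
    until ``n_total`` steps, yielding
    ``(n_total - n_equil) / sample_every`` snapshots.
    """

    topology: PolymerTopology
    epsilon: float
    n_tracers: int
    box_edge: float = 50.0
    gamma: float = 1.0
    kT: float = 1.0
    dt: float = 0.005
    n_equil: int = 100_000
    n_total: int = 300_000
    sample_every: int = 100
    seed: int = 0
    fixed_polymer: bool = False
    epsilon_zero_control: bool = False
    #: standard runs provide two binders per anchor; fixture-based
    #: controls (e.g. tracers on a frozen hand-built loop) may run
    #: without binders.
    include_binders: bool = True

    def __post_init__(self) -> None:
        if self.box_edge <= 0:
            raise ValueError("box edge must be positive")
        if self.dt <= 0:
            raise ValueError("timestep must be positive")
        if self.epsilon < 0:
            raise ValueError("tracer affinity must be non-negative")
        if self.n_tracers < 0:
            raise ValueError("tracer count must be non-negative")
        if self.n_total < self.n_equil:
            raise ValueError("total steps must not be smaller than equilibration steps")
        if self.sample_every <= 0 or (self.n_total - self.n_equil) % self.sample_every:
            raise ValueError("sample_every must divide the sampling window n_total - n_equil")

    @property
    def n_monomers(self) -> int:
        return self.topology.n_monomers

    @property
    def n_binders(self) -> int:
        # two binders per binding site
        return 2 * self.topology.n_anchors if self.include_binders else 0

    @property
    def n_particles(self) -> int:
        return self.n_monomers + self.n_binders + self.n_tracers

    @property
    def n_snapshots(self) -> int:
        return (self.n_total - self.n_equil) // self.sample_every

    @property
    def effective_epsilon(self) -> float:
        return 0.0 if self.epsilon_zero_control else self.epsilon

    def interaction_table(self) -> InteractionTable:
        return make_interaction_table(self.effective_epsilon)

    def species_codes(self) -> np.ndarray:
        """Species code per particle; layout is monomers, binders, tracers."""
        return np.concatenate(
            [
                self.topology.monomer_species(),
                np.full(self.n_binders, B, dtype=np.int8),
                np.full(self.n_tracers, T, dtype=np.int8),
            ]
        )

    @classmethod
    def from_params(
        cls,
        *,
        N: int,
        phi: float,
        epsilon: float,
        n_tracers: int,
        seed: int = 0,
        topology_seed: int | None = None,
        **kwargs,
    ) -> "SimulationConfig":
        """Build a config from flat scalar parameters, drawing the anchor
        placement from ``topology_seed`` (defaults to ``seed``)."""
        topo = build_topology(N, phi, seed if topology_seed is None else topology_seed)
        return cls(topology=topo, epsilon=epsilon, n_tracers=n_tracers, seed=seed, **kwargs)

    def to_flat_dict(self) -> dict:
        return {
            "N": self.n_monomers,
            "phi": self.topology.phi,
            "epsilon": self.epsilon,
            "n_tracers": self.n_tracers,
            "L": self.box_edge,
            "dt": self.dt,
            "n_equil": self.n_equil,
            "n_total": self.n_total,
            "sample_every": self.sample_every,
            "seed": self.seed,
            "fixed_polymer": self.fixed_polymer,
            "epsilon_zero_control": self.epsilon_zero_control,
            "include_binders": self.include_binders,
        }


_CONFIG_KEYS = {
    "N", "phi", "epsilon", "n_tracers", "L", "dt", "n_equil", "n_total",
    "sample_every", "seed", "fixed_polymer", "epsilon_zero_control",
    "include_binders",
}


def load_config(path: str | Path) -> SimulationConfig:
    """Read a flat key-value (YAML) run configuration."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise ValueError(f"{path}: expected a flat key-value mapping")
    unknown = set(raw) - _CONFIG_KEYS
    if unknown:
        raise ValueError(f"{path}: unknown config keys {sorted(unknown)}")
    for key in ("N", "phi", "epsilon", "n_tracers"):
        if key not in raw:
            raise ValueError(f"{path}: missing required key '{key}'")
    kwargs = {}
    for src, dst in (
        ("L", "box_edge"), ("dt", "dt"), ("n_equil", "n_equil"), ("n_total", "n_total"),
        ("sample_every", "sample_every"), ("fixed_polymer", "fixed_polymer"),
        ("epsilon_zero_control", "epsilon_zero_control"),
        ("include_binders", "include_binders"),
    ):
        if src in raw:
            kwargs[dst] = raw[src]
    return SimulationConfig.from_params(
        N=int(raw["N"]),
        phi=float(raw["phi"]),
        epsilon=float(raw["epsilon"]),
        n_tracers=int(raw["n_tracers"]),
        seed=int(raw.get("seed", 0)),
        **kwargs,
    )


def save_config(config: SimulationConfig, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config.to_flat_dict(), fh, sort_keys=False)


@dataclass
class SystemState:
    """Positions and species of every particle at one time point.

    Coordinates are kept wrapped into the periodic box ``[0, L)``;
    particle order is monomers (chain order), then binders, then tracers.
    """

    positions: np.ndarray
    species: np.ndarray
    box_edge: float
    step: int = 0

    def __post_init__(self) -> None:
        self.positions = np.ascontiguousarray(self.positions, dtype=np.float64)
        self.species = np.ascontiguousarray(self.species, dtype=np.int8)
        if self.positions.ndim != 2 or self.positions.shape[1] != 3:
            raise ValueError("positions must be an (n, 3) array")
        if self.species.shape != (self.positions.shape[0],):
            raise ValueError("species labels must match particle count")
        if np.any(self.species < 0) or np.any(self.species > 3):
            raise ValueError("species code outside {p, a, b, t}")

    @property
    def n_particles(self) -> int:
        return self.positions.shape[0]

    def wrap(self) -> None:
        L = self.box_edge
        self.positions -= L * np.floor(self.positions / L)

    def copy(self) -> "SystemState":
        return SystemState(self.positions.copy(), self.species.copy(), self.box_edge, self.step)


@dataclass
class Trajectory:
    """Ordered post-equilibration snapshots of one run.

    ``positions`` has shape (n_snapshots, n_particles, 3); ``steps`` gives
    the integrator step index of each snapshot.  The pre-equilibration
    initial state is carried separately and excluded from analysis.
    """

    positions: np.ndarray
    steps: np.ndarray
    species: np.ndarray
    config: SimulationConfig
    provenance: dict = field(default_factory=dict)
    initial_state: SystemState | None = None

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=np.float64)
        self.steps = np.asarray(self.steps, dtype=np.int64)
        self.species = np.asarray(self.species, dtype=np.int8)
        if self.positions.ndim != 3 or self.positions.shape[2] != 3:
            raise ValueError("trajectory positions must be (snapshots, particles, 3)")
        if self.steps.shape[0] != self.positions.shape[0]:
            raise ValueError("one step index per snapshot required")
        if self.species.shape[0] != self.positions.shape[1]:
            raise ValueError("species labels must match particle count")

    @property
    def n_snapshots(self) -> int:
        return self.positions.shape[0]

    @property
    def n_particles(self) -> int:
        return self.positions.shape[1]

    @property
    def box_edge(self) -> float:
        return self.config.box_edge

    @property
    def monomer_slice(self) -> slice:
        return slice(0, self.config.n_monomers)

    @property
    def binder_slice(self) -> slice:
        n = self.config.n_monomers
        return slice(n, n + self.config.n_binders)

    @property
    def tracer_slice(self) -> slice:
        return slice(self.config.n_monomers + self.config.n_binders, self.n_particles)

    def snapshot(self, index: int) -> SystemState:
        return SystemState(
            self.positions[index].copy(), self.species.copy(), self.box_edge, int(self.steps[index])
        )
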