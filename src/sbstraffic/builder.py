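"""Initial configurations and the equilibration protocol.

The chain is grown as a self-avoiding-ish random walk with step length
``r0``: candidate beads closer than ``min_separation`` (0.9 sigma) to any
placed particle are rejected, with backtracking when a bead cannot be
placed.  Binders and tracers are then inserted uniformly at random in the
periodic box, again avoiding overlaps.  A short capped-displacement
relaxation removes residual strain before dynamics start.

Equilibration advances the full system for ``n_equil`` steps and records
a stationarity diagnostic: the drift of the running mean of the polymer
radius of gyration over the last 20% of the equilibration window.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .forcefield import ForceField, UnstableConfigurationError
from .model import SimulationConfig, SystemState

__all__ = ["BuildRecipe", "build_initial_state", "add_tracers", "equilibrate"]

#: No pair may be closer than this at build time.
MIN_SEPARATION = 0.9
#: Largest single-particle move during the capped relaxation.
RELAX_CAP = 0.05


class PlacementError(RuntimeError):
    """Raised when random insertion fails after bounded retries."""


@dataclass
class BuildRecipe:
    config: SimulationConfig
    init_mode: str = "random-walk-chain"
    overlap_relax_steps: int = 50

    def __post_init__(self) -> None:
        if self.init_mode not in ("random-walk-chain", "stretched-chain"):
            raise ValueError(f"unknown init mode '{self.init_mode}'")


def _min_image_dist2(delta: np.ndarray, L: float) -> np.ndarray:
    d = delta - L * np.floor(delta / L + 0.5)
    return np.einsum("...k,...k->...", d, d)


def _grow_chain(n: int, r0: float, L: float, rng: np.random.Generator,
                min_sep: float, max_tries: int = 200) -> np.ndarray:
    pos = np.empty((n, 3))
    pos[0] = L / 2.0
    i = 1
    total_backtracks = 0
    while i < n:
        placed = False
        for _ in range(max_tries):
            u = rng.standard_normal(3)
            u /= np.linalg.norm(u)
            cand = pos[i - 1] + r0 * u
            d2 = _min_image_dist2(cand - pos[: i - 1], L) if i > 1 else np.array([np.inf])
            if d2.size == 0 or d2.min() >= min_sep * min_sep:
                pos[i] = cand
                i += 1
                placed = True
                break
        if not placed:
            total_backtracks += 1
            if total_backtracks > 50 * n:
                raise PlacementError(f"chain growth stalled at bead {i}")
            i = max(1, i - 1)
    return pos


def _insert_free(pos_existing: np.ndarray, count: int, L: float,
                 rng: np.random.Generator, min_sep: float) -> np.ndarray:
    out = np.empty((count, 3))
    placed = pos_existing
    for k in range(count):
        for attempt in range(2000):
            cand = rng.uniform(0.0, L, size=3)
            if placed.size == 0 or _min_image_dist2(cand - placed, L).min() >= min_sep * min_sep:
                out[k] = cand
                placed = np.vstack([placed, cand])
                break
        else:
            raise PlacementError(f"could not insert free particle {k} after 2000 tries")
    return out


def build_initial_state(
    recipe: BuildRecipe | SimulationConfig,
    rng: np.random.Generator | int | None = None,
    *,
    min_separation: float = MIN_SEPARATION,
) -> SystemState:
    """Construct the initial configuration for a run; deterministic per seed."""
    if isinstance(recipe, SimulationConfig):
        recipe = BuildRecipe(config=recipe)
    config = recipe.config
    if rng is None:
        rng = np.random.default_rng(config.seed)
    elif not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)

    L = config.box_edge
    table = config.interaction_table()
    n = config.n_particles
    # hard-core volume fraction must leave room for random insertion
    vfrac = n * (4.0 / 3.0) * np.pi * (table.sigma / 2.0) ** 3 / L**3
    if vfrac >= 0.3:
        raise ValueError(f"hard-core volume fraction {vfrac:.2f} too high for random placement")

    N = config.n_monomers
    if recipe.init_mode == "stretched-chain":
        chain = np.tile(np.array([L / 2.0, L / 2.0, L / 2.0]), (N, 1))
        chain[:, 0] = L / 2.0 + table.r0 * (np.arange(N) - N / 2.0)
    else:
        chain = _grow_chain(N, table.r0, L, rng, min_separation)
    free = _insert_free(chain, config.n_binders + config.n_tracers, L, rng, min_separation)

    state = SystemState(
        positions=np.vstack([chain, free]) if free.size else chain,
        species=config.species_codes(),
        box_edge=L,
        step=0,
    )
    state.wrap()
    _relax(state, config, recipe.overlap_relax_steps)
    return state


def add_tracers(state: SystemState, n_tracers: int, rng: np.random.Generator,
                min_separation: float = MIN_SEPARATION) -> SystemState:
    """Append randomly placed tracers to an existing configuration
    (used to seed fixed-polymer runs)."""
    from .model import T

    new = _insert_free(state.positions, n_tracers, state.box_edge, rng, min_separation)
    return SystemState(
        positions=np.vstack([state.positions, new]),
        species=np.concatenate([state.species, np.full(n_tracers, T, dtype=np.int8)]),
        box_edge=state.box_edge,
        step=state.step,
    )


def _relax(state: SystemState, config: SimulationConfig, n_steps: int) -> None:
    """Capped-displacement steepest descent; removes residual overlaps
    without altering the topology."""
    if n_steps <= 0:
        return
    ff = ForceField(config.interaction_table())
    h = 1.0e-4
    for _ in range(n_steps):
        f = ff.forces(state, config.n_monomers, check_floor=False)
        dx = f * h
        norms = np.linalg.norm(dx, axis=1)
        big = norms > RELAX_CAP
        if big.any():
            dx[big] *= (RELAX_CAP / norms[big])[:, None]
        state.positions += dx
    state.wrap()


def _chain_r_gyr(state: SystemState, n_monomers: int) -> float:
    """Radius of gyration of the chain from unwrapped coordinates."""
    if n_monomers < 2:
        return 0.0
    L = state.box_edge
    p = state.positions[:n_monomers]
    bonds = p[1:] - p[:-1]
    bonds -= L * np.floor(bonds / L + 0.5)
    unwrapped = np.vstack([p[0], p[0] + np.cumsum(bonds, axis=0)])
    centred = unwrapped - unwrapped.mean(axis=0)
    return float(np.sqrt((centred**2).sum(axis=1).mean()))


def _bound_tracer_count(state: SystemState, config: SimulationConfig) -> int:
    """Tracers within the 2-sigma contact threshold of any monomer."""
    if config.n_tracers == 0 or config.n_monomers == 0:
        return 0
    L = state.box_edge
    mono = state.positions[: config.n_monomers]
    tracers = state.positions[config.n_monomers + config.n_binders:]
    d = tracers[:, None, :] - mono[None, :, :]
    d -= L * np.floor(d / L + 0.5)
    return int(((d**2).sum(axis=2).min(axis=1) < 4.0).sum())


def equilibrate_with_driver(drv, config: SimulationConfig) -> dict:
    """Advance the driver through ``n_equil`` steps, recording the
    stationarity diagnostics (r_gyr series and, when tracers are
    present, the bound-tracer series)."""
    n_equil = config.n_equil
    if n_equil == 0:
        return {"n_equil": 0, "r_gyr_series": [], "bound_series": [],
                "running_mean_drift": 0.0}
    n_checks = min(50, max(1, n_equil // 100))
    chunk = n_equil // n_checks
    series = []
    bound_series = []
    done = 0
    for _ in range(n_checks):
        drv.advance(chunk)
        done += chunk
        series.append(_chain_r_gyr(drv.state, config.n_monomers))
        bound_series.append(_bound_tracer_count(drv.state, config))
    if done < n_equil:
        drv.advance(n_equil - done)
        series.append(_chain_r_gyr(drv.state, config.n_monomers))
        bound_series.append(_bound_tracer_count(drv.state, config))
    series_arr = np.array(series)
    drift = 0.0
    if len(series_arr) >= 5 and series_arr.mean() > 0:
        tail = max(1, len(series_arr) // 5)
        mean_all = series_arr[:-tail].mean() if len(series_arr) > tail else series_arr.mean()
        mean_tail = series_arr[-tail:].mean()
        drift = float(abs(mean_tail - mean_all) / mean_all) if mean_all > 0 else 0.0
    return {
        "n_equil": int(n_equil),
        "r_gyr_series": [float(x) for x in series_arr],
        "bound_series": [int(x) for x in bound_series],
        "running_mean_drift": float(drift),
        "stationary": bool(drift < 0.05),
    }


def equilibrate(
    state: SystemState,
    config: SimulationConfig,
    *,
    scheme: str = "baoab",
    mobile: np.ndarray | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[SystemState, dict]:
    """Run the equilibration protocol on ``state`` in place.

    Returns the state after ``n_equil`` steps together with the
    stationarity diagnostic (always emitted, also for trivial runs).
    """
    from .integrator import IntegratorSettings, _Advancer

    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence(config.seed).spawn(1)[0])
    ff = ForceField(config.interaction_table())
    settings = IntegratorSettings(
        dt=config.dt, gamma=config.gamma, kT=config.kT, seed=config.seed,
        mobile_mask=mobile, scheme=scheme,
    )
    drv = _Advancer(state, config.n_monomers, ff, settings, rng)
    diag = equilibrate_with_driver(drv, config)
    return state, diag
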