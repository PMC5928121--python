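"""Langevin time stepping at constant temperature.

Two schemes are provided:

``baoab`` (default)
    underdamped BAOAB splitting with unit particle mass and drag
    ``gamma = 1``.  This is the production scheme: per-step displacement
    is bounded by ``|v| dt``, so the steep r^-12 core of the strong
    (10 kT) binder-anchor attraction is integrated stably at
    ``dt = 0.005``.  With ``gamma = 0`` it reduces to velocity Verlet,
    which is used for energy-conservation checks of the deterministic
    forces.

``brownian``
    overdamped Euler-Maruyama,
    ``x += F dt / gamma + sqrt(2 kT dt / gamma) * xi``.  Exact for free
    diffusion and accurate for soft potentials; the force-proportional
    step makes it unstable against stiff LJ walls at production
    timesteps, so it is kept for diffusion/thermostat validation rather
    than full-system runs.

Both schemes sample the same configurational Boltzmann distribution;
all observables of interest are equilibrium configurational averages.

Frozen particles (``mobile_mask`` false) are never touched, which makes
fixed-polymer tracer runs cheap: forces are only evaluated on mobile
particles.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from numba import njit

from .forcefield import (
    HARD_FLOOR,
    ForceField,
    UnstableConfigurationError,
    nlist_grid_size,
)
from .model import SimulationConfig, SystemState, Trajectory

__all__ = ["IntegratorSettings", "step", "advance", "run", "production_forces"]

_NOISE_BLOCK = 200  # steps of pre-generated noise per kernel call
_SKIN = 0.45  # Verlet-list skin in sigma (see rebuild criterion below)
_NLIST_CAP = 192  # neighbor-list width; sized for a dense globule at the list radius


@njit(inline="always")
def _mi_half(d, L, halfL):
    # min-image for coordinates already wrapped into [0, L): |d| < L,
    # so one conditional shift suffices (cheaper than a floor call)
    if d > halfL:
        return d - L
    if d < -halfL:
        return d + L
    return d


@njit(inline="always")
def _wrap(x, L):
    while x >= L:
        x -= L
    while x < 0.0:
        x += L
    return x


@dataclass
class IntegratorSettings:
    """Parameters of the stochastic integrator."""

    dt: float
    gamma: float = 1.0
    kT: float = 1.0
    seed: int = 0
    mobile_mask: np.ndarray | None = None
    scheme: str = "baoab"

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ValueError("timestep must be positive")
        if self.gamma < 0:
            raise ValueError("drag coefficient must be non-negative")
        if self.scheme not in ("brownian", "baoab"):
            raise ValueError(f"unknown integration scheme '{self.scheme}'")
        if self.scheme == "brownian" and self.gamma == 0:
            raise ValueError("overdamped dynamics requires gamma > 0")


@njit(cache=True, fastmath=True)
def _soa_build(px, py, pz, L, r_list, mobile, species, eps, xi,
               nlist, ncount, pe, pxi, head, nxt, cx, cy, cz,
               rx, ry, rz):
    """Build per-particle Verlet lists on structure-of-arrays coordinates.

    Alongside the neighbor indices, the interaction parameters of each
    pair are cached (``pe`` = LJ well depth, ``pxi`` = attraction
    switch) so the force pass needs no indirect species lookups.  The
    reference coordinates ``rx/ry/rz`` are reset to the build positions.
    Returns the largest list length (above the list width = overflow).
    """
    n = px.shape[0]
    cap = nlist.shape[1]
    rlist2 = r_list * r_list
    invL = 1.0 / L
    halfL = 0.5 * L
    maxlen = 0
    ncell = int(L // r_list)
    if 3 <= ncell <= 64:
        invcell = ncell * invL
        for k in range(head.size):
            head[k] = -1
        for i in range(n):
            x = _wrap(px[i], L)
            y = _wrap(py[i], L)
            z = _wrap(pz[i], L)
            a = min(int(x * invcell), ncell - 1)
            b = min(int(y * invcell), ncell - 1)
            c = min(int(z * invcell), ncell - 1)
            cx[i] = a
            cy[i] = b
            cz[i] = c
            idx = (a * ncell + b) * ncell + c
            nxt[i] = head[idx]
            head[idx] = i
        for i in range(n):
            if not mobile[i]:
                ncount[i] = 0
                continue
            si = species[i]
            cnt = 0
            for ox in range(-1, 2):
                a = cx[i] + ox
                if a < 0:
                    a += ncell
                elif a >= ncell:
                    a -= ncell
                for oy in range(-1, 2):
                    b = cy[i] + oy
                    if b < 0:
                        b += ncell
                    elif b >= ncell:
                        b -= ncell
                    for oz in range(-1, 2):
                        c = cz[i] + oz
                        if c < 0:
                            c += ncell
                        elif c >= ncell:
                            c -= ncell
                        j = head[(a * ncell + b) * ncell + c]
                        while j >= 0:
                            if j != i:
                                dx = _mi_half(px[j] - px[i], L, halfL)
                                dy = _mi_half(py[j] - py[i], L, halfL)
                                dz = _mi_half(pz[j] - pz[i], L, halfL)
                                if dx * dx + dy * dy + dz * dz < rlist2:
                                    if cnt < cap:
                                        nlist[i, cnt] = j
                                        pe[i, cnt] = eps[si, species[j]]
                                        pxi[i, cnt] = xi[si, species[j]]
                                    cnt += 1
                            j = nxt[j]
            ncount[i] = cnt
            if cnt > maxlen:
                maxlen = cnt
    else:
        for i in range(n):
            if not mobile[i]:
                ncount[i] = 0
                continue
            si = species[i]
            cnt = 0
            for j in range(n):
                if j == i:
                    continue
                dx = _mi_half(px[j] - px[i], L, halfL)
                dy = _mi_half(py[j] - py[i], L, halfL)
                dz = _mi_half(pz[j] - pz[i], L, halfL)
                if dx * dx + dy * dy + dz * dz < rlist2:
                    if cnt < cap:
                        nlist[i, cnt] = j
                        pe[i, cnt] = eps[si, species[j]]
                        pxi[i, cnt] = xi[si, species[j]]
                    cnt += 1
            ncount[i] = cnt
            if cnt > maxlen:
                maxlen = cnt
    for i in range(n):
        rx[i] = px[i]
        ry[i] = py[i]
        rz[i] = pz[i]
    return maxlen


@njit(inline="always")
def _soa_needs_rebuild(px, py, pz, rx, ry, rz, mobile, L, halfL, skin):
    """Rebuild when the two largest displacements since the last build
    could sum to the skin width -- the exact pair-approach bound."""
    n = px.shape[0]
    m1 = 0.0
    m2 = 0.0
    for i in range(n):
        if mobile[i]:
            dx = _mi_half(px[i] - rx[i], L, halfL)
            dy = _mi_half(py[i] - ry[i], L, halfL)
            dz = _mi_half(pz[i] - rz[i], L, halfL)
            d2 = dx * dx + dy * dy + dz * dz
            if d2 > m1:
                m2 = m1
                m1 = d2
            elif d2 > m2:
                m2 = d2
    return math.sqrt(m1) + math.sqrt(m2) > skin


@njit(inline="always")
def _soa_force(px, py, pz, n_mono, rcut2, floor2, k_bond, r0, L, halfL, mobile,
               nlist, ncount, pe, pxi, fx, fy, fz):
    """Force pass over the cached Verlet lists (SoA layout); returns the
    number of pair distances seen below the hard floor.

    The pair loop is branch-free: beyond-cutoff and zero-eps pairs are
    zeroed through multiplicative masks, which keeps the pipeline full
    on unpredictable neighbor data.
    """
    n = px.shape[0]
    n_bad = 0
    for i in range(n):
        if not mobile[i]:
            continue
        xi0 = px[i]
        yi0 = py[i]
        zi0 = pz[i]
        ax = 0.0
        ay = 0.0
        az = 0.0
        for k in range(ncount[i]):
            j = nlist[i, k]
            dx = px[j] - xi0
            dx = dx - L * ((dx > halfL) - (dx < -halfL))
            dy = py[j] - yi0
            dy = dy - L * ((dy > halfL) - (dy < -halfL))
            dz = pz[j] - zi0
            dz = dz - L * ((dz > halfL) - (dz < -halfL))
            r2 = dx * dx + dy * dy + dz * dz
            # the hard floor guards the LJ core; inert (eps = 0) pairs
            # may legitimately approach, e.g. a harmonic tether
            n_bad += (r2 < floor2) & (pe[i, k] > 0.0)
            inv2 = 1.0 / r2
            sr6 = inv2 * inv2 * inv2
            coef = (r2 < rcut2) * 24.0 * pe[i, k] * (2.0 * sr6 * sr6 - pxi[i, k] * sr6) * inv2
            ax -= coef * dx
            ay -= coef * dy
            az -= coef * dz
        fx[i] = ax
        fy[i] = ay
        fz[i] = az
    for b0 in range(n_mono - 1):
        i = b0
        j = b0 + 1
        if not (mobile[i] or mobile[j]):
            continue
        dx = _mi_half(px[j] - px[i], L, halfL)
        dy = _mi_half(py[j] - py[i], L, halfL)
        dz = _mi_half(pz[j] - pz[i], L, halfL)
        r = math.sqrt(dx * dx + dy * dy + dz * dz)
        if r > 0.0:
            coef = k_bond * (r - r0) / r
            if mobile[i]:
                fx[i] += coef * dx
                fy[i] += coef * dy
                fz[i] += coef * dz
            if mobile[j]:
                fx[j] -= coef * dx
                fy[j] -= coef * dy
                fz[j] -= coef * dz
    return n_bad


@njit(cache=True, fastmath=True)
def _brownian_block(px, py, pz, species, n_mono, eps, xi, r_cut, skin, floor2, k_bond, r0,
                    L, mobile, noise, dt_over_gamma,
                    nlist, ncount, pe, pxi, head, nxt, cx, cy, cz, rx, ry, rz,
                    fx, fy, fz):
    n_steps = noise.shape[0]
    n = px.shape[0]
    rcut2 = r_cut * r_cut
    halfL = 0.5 * L
    for s in range(n_steps):
        if _soa_needs_rebuild(px, py, pz, rx, ry, rz, mobile, L, halfL, skin):
            if _soa_build(px, py, pz, L, r_cut + skin, mobile, species, eps, xi,
                          nlist, ncount, pe, pxi, head, nxt, cx, cy, cz,
                          rx, ry, rz) > nlist.shape[1]:
                return 1
        n_bad = _soa_force(px, py, pz, n_mono, rcut2, floor2, k_bond, r0, L, halfL, mobile,
                           nlist, ncount, pe, pxi, fx, fy, fz)
        if n_bad > 0:
            return 2
        for i in range(n):
            if mobile[i]:
                px[i] = _wrap(px[i] + fx[i] * dt_over_gamma + noise[s, i, 0], L)
                py[i] = _wrap(py[i] + fy[i] * dt_over_gamma + noise[s, i, 1], L)
                pz[i] = _wrap(pz[i] + fz[i] * dt_over_gamma + noise[s, i, 2], L)
    return 0


@njit(cache=True, fastmath=True)
def _baoab_block(px, py, pz, vx, vy, vz, fx, fy, fz, species, n_mono, eps, xi,
                 r_cut, skin, floor2, k_bond, r0, L, mobile, noise, dt, c1, c2,
                 nlist, ncount, pe, pxi, head, nxt, cx, cy, cz, rx, ry, rz):
    """One block of BAOAB steps; ``fx/fy/fz`` must hold forces for the
    entry positions and are left holding forces for the exit positions."""
    n_steps = noise.shape[0]
    n = px.shape[0]
    half = 0.5 * dt
    rcut2 = r_cut * r_cut
    halfL = 0.5 * L
    for s in range(n_steps):
        for i in range(n):
            if mobile[i]:
                v = vx[i] + half * fx[i]
                x = px[i] + half * v
                v = c1 * v + c2 * noise[s, i, 0]
                x = x + half * v
                px[i] = _wrap(x, L)
                vx[i] = v

                v = vy[i] + half * fy[i]
                x = py[i] + half * v
                v = c1 * v + c2 * noise[s, i, 1]
                x = x + half * v
                py[i] = _wrap(x, L)
                vy[i] = v

                v = vz[i] + half * fz[i]
                x = pz[i] + half * v
                v = c1 * v + c2 * noise[s, i, 2]
                x = x + half * v
                pz[i] = _wrap(x, L)
                vz[i] = v
        if _soa_needs_rebuild(px, py, pz, rx, ry, rz, mobile, L, halfL, skin):
            if _soa_build(px, py, pz, L, r_cut + skin, mobile, species, eps, xi,
                          nlist, ncount, pe, pxi, head, nxt, cx, cy, cz,
                          rx, ry, rz) > nlist.shape[1]:
                return 1
        n_bad = _soa_force(px, py, pz, n_mono, rcut2, floor2, k_bond, r0, L, halfL, mobile,
                           nlist, ncount, pe, pxi, fx, fy, fz)
        if n_bad > 0:
            return 2
        for i in range(n):
            if mobile[i]:
                vx[i] += half * fx[i]
                vy[i] += half * fy[i]
                vz[i] += half * fz[i]
    return 0


class _Advancer:
    """Stateful driver that advances a system in noise blocks.

    Coordinates are mirrored into structure-of-arrays buffers for the
    kernels and copied back into ``state.positions`` after every
    :meth:`advance` call.
    """

    def __init__(
        self,
        state: SystemState,
        n_monomers: int,
        ff: ForceField,
        settings: IntegratorSettings,
        rng: np.random.Generator,
    ):
        self.state = state
        self.n_monomers = n_monomers
        self.ff = ff
        self.settings = settings
        self.rng = rng
        n = state.n_particles
        if settings.mobile_mask is None:
            self.mobile = np.ones(n, dtype=np.bool_)
        else:
            self.mobile = np.ascontiguousarray(settings.mobile_mask, dtype=np.bool_)
            if self.mobile.shape != (n,):
                raise ValueError("mobile mask must have one entry per particle")
        self._species64 = state.species.astype(np.int64)
        self._px = np.ascontiguousarray(state.positions[:, 0])
        self._py = np.ascontiguousarray(state.positions[:, 1])
        self._pz = np.ascontiguousarray(state.positions[:, 2])
        self._nlist = np.empty((n, _NLIST_CAP), dtype=np.int32)
        self._ncount = np.zeros(n, dtype=np.int32)
        self._pe = np.empty((n, _NLIST_CAP), dtype=np.float32)
        self._pxi = np.empty((n, _NLIST_CAP), dtype=np.float32)
        self._head = np.empty(nlist_grid_size(state.box_edge, ff.table.r_cut + _SKIN), np.int32)
        self._nxt = np.empty(n, np.int32)
        self._cx = np.empty(n, np.int32)
        self._cy = np.empty(n, np.int32)
        self._cz = np.empty(n, np.int32)
        self._rx = np.empty(n)
        self._ry = np.empty(n)
        self._rz = np.empty(n)
        maxlen = _soa_build(
            self._px, self._py, self._pz, state.box_edge, ff.table.r_cut + _SKIN,
            self.mobile, self._species64, ff._eps, ff._xi,
            self._nlist, self._ncount, self._pe, self._pxi,
            self._head, self._nxt, self._cx, self._cy, self._cz,
            self._rx, self._ry, self._rz,
        )
        if maxlen > _NLIST_CAP:
            raise UnstableConfigurationError(
                f"neighbor list overflow ({maxlen} neighbors): density implies severe overlap"
            )
        self._fx = np.zeros(n)
        self._fy = np.zeros(n)
        self._fz = np.zeros(n)
        self._mobile_idx = np.flatnonzero(self.mobile)
        if settings.scheme == "baoab":
            self.vel = np.zeros((n, 3))
            self._vx = np.zeros(n)
            self._vy = np.zeros(n)
            self._vz = np.zeros(n)
            f0 = ff.forces(state, n_monomers, mobile=self.mobile, check_floor=False)
            self._fx[:] = f0[:, 0]
            self._fy[:] = f0[:, 1]
            self._fz[:] = f0[:, 2]

    def _draw_noise(self, block: int, amp: float) -> np.ndarray:
        """Gaussian noise for one block; drawn only for mobile particles
        (frozen rows stay zero and are never read)."""
        n = self.state.n_particles
        m = self._mobile_idx.size
        if m == n:
            out = self.rng.standard_normal((block, n, 3), dtype=np.float32)
            if amp != 1.0:
                out *= np.float32(amp)
            return out
        out = np.zeros((block, n, 3), dtype=np.float32)
        drawn = self.rng.standard_normal((block, m, 3), dtype=np.float32)
        if amp != 1.0:
            drawn *= np.float32(amp)
        out[:, self._mobile_idx, :] = drawn
        return out

    def _sync_state(self) -> None:
        self.state.positions[:, 0] = self._px
        self.state.positions[:, 1] = self._py
        self.state.positions[:, 2] = self._pz
        if self.settings.scheme == "baoab":
            self.vel[:, 0] = self._vx
            self.vel[:, 1] = self._vy
            self.vel[:, 2] = self._vz

    def advance(self, n_steps: int) -> None:
        s = self.settings
        t = self.ff.table
        st = self.state
        floor2 = HARD_FLOOR * HARD_FLOOR
        done = 0
        while done < n_steps:
            block = min(_NOISE_BLOCK, n_steps - done)
            if s.scheme == "brownian":
                amp = math.sqrt(2.0 * s.kT * s.dt / s.gamma)
                noise = self._draw_noise(block, amp)
                status = _brownian_block(
                    self._px, self._py, self._pz, self._species64, self.n_monomers,
                    self.ff._eps, self.ff._xi, t.r_cut, _SKIN, floor2, t.k_bond, t.r0,
                    st.box_edge, self.mobile, noise, s.dt / s.gamma,
                    self._nlist, self._ncount, self._pe, self._pxi,
                    self._head, self._nxt, self._cx, self._cy, self._cz,
                    self._rx, self._ry, self._rz, self._fx, self._fy, self._fz,
                )
            else:
                c1 = math.exp(-s.gamma * s.dt)
                c2 = math.sqrt(s.kT * (1.0 - c1 * c1))
                noise = self._draw_noise(block, 1.0) if c2 > 0 else np.zeros(
                    (block, st.n_particles, 3), dtype=np.float32
                )
                status = _baoab_block(
                    self._px, self._py, self._pz, self._vx, self._vy, self._vz,
                    self._fx, self._fy, self._fz, self._species64, self.n_monomers,
                    self.ff._eps, self.ff._xi, t.r_cut, _SKIN, floor2, t.k_bond, t.r0,
                    st.box_edge, self.mobile, noise, s.dt, c1, c2,
                    self._nlist, self._ncount, self._pe, self._pxi,
                    self._head, self._nxt, self._cx, self._cy, self._cz,
                    self._rx, self._ry, self._rz,
                )
            done += block
            st.step += block
            if status == 1:
                self._sync_state()
                raise UnstableConfigurationError(
                    f"neighbor list overflow at step {st.step}: density implies severe overlap"
                )
            if status == 2:
                self._sync_state()
                raise UnstableConfigurationError(
                    f"pair distance below hard floor {HARD_FLOOR} sigma near step {st.step}"
                )
        self._sync_state()
        if not np.isfinite(st.positions).all():
            raise UnstableConfigurationError(f"non-finite position at step {st.step}")


@njit(cache=True)
def _force_once(px, py, pz, n_mono, rcut2, floor2, k_bond, r0, L, halfL, mobile,
                nlist, ncount, pe, pxi, fx, fy, fz):
    return _soa_force(px, py, pz, n_mono, rcut2, floor2, k_bond, r0, L, halfL, mobile,
                      nlist, ncount, pe, pxi, fx, fy, fz)


def production_forces(state: SystemState, n_monomers: int, ff: ForceField,
                      mobile: np.ndarray | None = None) -> np.ndarray:
    """Forces as evaluated by the production (Verlet-list) kernels.

    Exists so tests can pin the optimized time-stepping force path
    against the all-pairs reference in :mod:`.forcefield`.
    """
    settings = IntegratorSettings(dt=1.0e-3, scheme="brownian", mobile_mask=mobile)
    drv = _Advancer(state.copy(), n_monomers, ff, settings, np.random.default_rng(0))
    t = ff.table
    n = state.n_particles
    fx = np.zeros(n)
    fy = np.zeros(n)
    fz = np.zeros(n)
    _force_once(drv._px, drv._py, drv._pz, n_monomers, t.r_cut * t.r_cut,
                HARD_FLOOR * HARD_FLOOR, t.k_bond, t.r0, state.box_edge,
                0.5 * state.box_edge, drv.mobile, drv._nlist, drv._ncount,
                drv._pe, drv._pxi, fx, fy, fz)
    return np.stack([fx, fy, fz], axis=1)


def step(state: SystemState, forces: np.ndarray, settings: IntegratorSettings,
         rng: np.random.Generator | None = None) -> SystemState:
    """Advance one overdamped step given precomputed forces.

    Convenience single-step rule (Euler-Maruyama); production runs use
    :func:`advance` / :func:`run`, which re-evaluate forces internally.
    """
    if settings.scheme != "brownian":
        raise ValueError("single-step API supports the overdamped scheme only")
    if rng is None:
        rng = np.random.default_rng(settings.seed)
    n = state.n_particles
    mobile = settings.mobile_mask
    if mobile is None:
        mobile = np.ones(n, dtype=bool)
    if not np.isfinite(forces).all() or not np.isfinite(state.positions).all():
        raise UnstableConfigurationError(f"non-finite input at step {state.step}")
    new = state.copy()
    amp = math.sqrt(2.0 * settings.kT * settings.dt / settings.gamma)
    kick = forces * (settings.dt / settings.gamma) + amp * rng.standard_normal((n, 3))
    new.positions[mobile] += kick[mobile]
    new.wrap()
    new.step += 1
    return new


def advance(
    state: SystemState,
    n_monomers: int,
    ff: ForceField,
    settings: IntegratorSettings,
    n_steps: int,
    rng: np.random.Generator | None = None,
) -> SystemState:
    """Advance ``state`` in place for ``n_steps`` and return it."""
    if rng is None:
        rng = np.random.default_rng(settings.seed)
    drv = _Advancer(state, n_monomers, ff, settings, rng)
    drv.advance(n_steps)
    return state


def run(
    config: SimulationConfig,
    *,
    scheme: str = "baoab",
    initial_state: SystemState | None = None,
    keep_initial: bool = True,
    mobile_mask: np.ndarray | None = None,
) -> Trajectory:
    """Execute a full run: build (or accept) an initial configuration,
    equilibrate for ``n_equil`` steps, then sample one snapshot every
    ``sample_every`` steps up to ``n_total`` steps.

    With ``config.fixed_polymer`` an equilibrated polymer+binder
    configuration must be supplied; monomers and binders are frozen and
    only the tracers move.  Runs are fully reproducible from
    ``config.seed``.
    """
    from . import builder  # local import to avoid a cycle

    ss = np.random.SeedSequence(config.seed)
    build_ss, tracer_ss, noise_ss = ss.spawn(3)

    if initial_state is None:
        if config.fixed_polymer:
            raise ValueError("fixed_polymer runs need a supplied equilibrated configuration")
        state = builder.build_initial_state(config, rng=np.random.default_rng(build_ss))
    else:
        state = initial_state.copy()
        n_frozen = config.n_monomers + config.n_binders
        if config.fixed_polymer and state.n_particles == n_frozen and config.n_tracers > 0:
            state = builder.add_tracers(state, config.n_tracers, rng=np.random.default_rng(tracer_ss))
        if state.n_particles != config.n_particles:
            raise ValueError(
                f"supplied state has {state.n_particles} particles, config expects {config.n_particles}"
            )
    state.step = 0

    if mobile_mask is not None:
        mobile = np.ascontiguousarray(mobile_mask, dtype=np.bool_)
    else:
        mobile = np.ones(state.n_particles, dtype=np.bool_)
        if config.fixed_polymer:
            mobile[: config.n_monomers + config.n_binders] = False

    ff = ForceField(config.interaction_table())
    settings = IntegratorSettings(
        dt=config.dt, gamma=config.gamma, kT=config.kT, seed=config.seed,
        mobile_mask=mobile, scheme=scheme,
    )
    rng = np.random.default_rng(noise_ss)
    drv = _Advancer(state, config.n_monomers, ff, settings, rng)

    init_snapshot = state.copy() if keep_initial else None

    diag = builder.equilibrate_with_driver(drv, config)

    n_snap = config.n_snapshots
    positions = np.empty((n_snap, state.n_particles, 3))
    steps = np.empty(n_snap, dtype=np.int64)
    for k in range(n_snap):
        drv.advance(config.sample_every)
        positions[k] = state.positions
        steps[k] = state.step

    provenance = {
        "seed": int(config.seed),
        "scheme": scheme,
        "code_version": _package_version(),
        "equilibration": diag,
    }
    return Trajectory(
        positions=positions,
        steps=steps,
        species=state.species.copy(),
        config=config,
        provenance=provenance,
        initial_state=init_snapshot,
    )


def _package_version() -> str:
    from . import __version__

    return __version__
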