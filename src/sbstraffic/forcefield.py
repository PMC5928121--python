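"""Energies and forces under cubic periodic boundary conditions.

Two contributions:

* harmonic bonds between successive chain monomers,
  ``E = 1/2 k (r - r0)^2`` with ``k = 330 kT/sigma^2`` and ``r0 = 1.2 sigma``;
* truncated Lennard-Jones pairs,
  ``E_ij(r) = 4 eps_ij [ (sigma/r)^12 - xi_ij (sigma/r)^6 ]`` cut at
  ``r_cut = 3 sigma``.

The potential is truncated without shifting; the resulting step at the
cutoff is ``4 eps (3^-12 - xi 3^-6)``, about ``-0.005 eps`` for attractive
pairs, and does not affect equilibrium sampling at the contact threshold
used downstream.  An optional energy shift is available for sensitivity
checks (energies only; forces are identical either way).

Non-bonded interactions are evaluated through a cell list (rebuilt every
evaluation, exact with respect to an all-pairs sum); bonded neighbors
feel the LJ pair in addition to their spring.  The time-stepping kernels
in :mod:`.integrator` use a Verlet neighbor list (cell-list build, skin
0.3 sigma, rebuilt whenever any particle has moved more than half the
skin), which is exact under the same criterion.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

from .model import InteractionTable, PolymerTopology, SystemState

__all__ = [
    "ForceField",
    "UnstableConfigurationError",
    "minimum_image_displacement",
    "bond_energy",
    "lj_pair_energy",
    "total_forces",
    "total_energy",
    "pair_list",
    "HARD_FLOOR",
]

#: Pair distances below this trigger an instability error: the r^-12 core
#: would generate forces far beyond what the integrator can resolve.
HARD_FLOOR = 0.3


class UnstableConfigurationError(RuntimeError):
    """Raised when a pair distance falls below the hard floor."""


def minimum_image_displacement(a, b, box_edge: float) -> np.ndarray:
    """Shortest periodic displacement ``b - a``; components in [-L/2, L/2)."""
    if box_edge <= 0:
        raise ValueError("box edge must be positive")
    d = np.asarray(b, dtype=float) - np.asarray(a, dtype=float)
    return d - box_edge * np.floor(d / box_edge + 0.5)


def bond_energy(r: float, k_bond: float = 330.0, r0: float = 1.2) -> float:
    """Harmonic bond energy at center-to-center distance ``r`` (sigma)."""
    if r < 0:
        raise ValueError("distance must be non-negative")
    return 0.5 * k_bond * (r - r0) ** 2


def lj_pair_energy(
    r: float,
    eps_ij: float,
    xi_ij: float,
    sigma: float = 1.0,
    r_cut: float = 3.0,
    shift: bool = False,
) -> float:
    """Truncated Lennard-Jones pair energy in kT."""
    if r <= 0:
        raise ValueError("LJ energy undefined at zero separation")
    if r >= r_cut:
        return 0.0
    sr6 = (sigma / r) ** 6
    e = 4.0 * eps_ij * (sr6 * sr6 - xi_ij * sr6)
    if shift:
        sc6 = (sigma / r_cut) ** 6
        e -= 4.0 * eps_ij * (sc6 * sc6 - xi_ij * sc6)
    return e


@njit(inline="always")
def _mimg(d, L):
    return d - L * math.floor(d / L + 0.5)


@njit(inline="always")
def _mimg_i(d, L, invL):
    # min-image via the precomputed reciprocal: avoids an FP division
    return d - L * math.floor(d * invL + 0.5)


@njit(cache=True)
def _forces_kernel(pos, species, n_mono, eps, xi, r_cut, k_bond, r0, L, mobile, f):
    """Accumulate forces on mobile particles; returns the minimum pair
    distance seen among pairs that involve at least one mobile particle."""
    n = pos.shape[0]
    for i in range(n):
        f[i, 0] = 0.0
        f[i, 1] = 0.0
        f[i, 2] = 0.0
    rcut2 = r_cut * r_cut
    rmin2 = 1.0e30

    ncell = int(L // r_cut)
    if 3 <= ncell <= 64:
        cell = L / ncell
        ncell2 = ncell * ncell
        head = np.full(ncell2 * ncell, -1, np.int64)
        nxt = np.empty(n, np.int64)
        cx = np.empty(n, np.int64)
        cy = np.empty(n, np.int64)
        cz = np.empty(n, np.int64)
        for i in range(n):
            x = pos[i, 0] - L * math.floor(pos[i, 0] / L)
            y = pos[i, 1] - L * math.floor(pos[i, 1] / L)
            z = pos[i, 2] - L * math.floor(pos[i, 2] / L)
            a = min(int(x / cell), ncell - 1)
            b = min(int(y / cell), ncell - 1)
            c = min(int(z / cell), ncell - 1)
            cx[i] = a
            cy[i] = b
            cz[i] = c
            idx = (a * ncell + b) * ncell + c
            nxt[i] = head[idx]
            head[idx] = i
        for i in range(n):
            if not mobile[i]:
                continue
            si = species[i]
            xi0 = pos[i, 0]
            xi1 = pos[i, 1]
            xi2 = pos[i, 2]
            for ox in range(-1, 2):
                a = (cx[i] + ox) % ncell
                for oy in range(-1, 2):
                    b = (cy[i] + oy) % ncell
                    for oz in range(-1, 2):
                        c = (cz[i] + oz) % ncell
                        j = head[(a * ncell + b) * ncell + c]
                        while j >= 0:
                            if j != i:
                                dx = _mimg(pos[j, 0] - xi0, L)
                                dy = _mimg(pos[j, 1] - xi1, L)
                                dz = _mimg(pos[j, 2] - xi2, L)
                                r2 = dx * dx + dy * dy + dz * dz
                                if r2 < rmin2:
                                    rmin2 = r2
                                if r2 < rcut2:
                                    e = eps[si, species[j]]
                                    if e > 0.0:
                                        inv2 = 1.0 / r2
                                        sr6 = inv2 * inv2 * inv2
                                        coef = 24.0 * e * (2.0 * sr6 * sr6 - xi[si, species[j]] * sr6) * inv2
                                        f[i, 0] -= coef * dx
                                        f[i, 1] -= coef * dy
                                        f[i, 2] -= coef * dz
                            j = nxt[j]
    else:
        for i in range(n):
            if not mobile[i]:
                continue
            si = species[i]
            for j in range(n):
                if j == i:
                    continue
                dx = _mimg(pos[j, 0] - pos[i, 0], L)
                dy = _mimg(pos[j, 1] - pos[i, 1], L)
                dz = _mimg(pos[j, 2] - pos[i, 2], L)
                r2 = dx * dx + dy * dy + dz * dz
                if r2 < rmin2:
                    rmin2 = r2
                if r2 < rcut2:
                    e = eps[si, species[j]]
                    if e > 0.0:
                        inv2 = 1.0 / r2
                        sr6 = inv2 * inv2 * inv2
                        coef = 24.0 * e * (2.0 * sr6 * sr6 - xi[si, species[j]] * sr6) * inv2
                        f[i, 0] -= coef * dx
                        f[i, 1] -= coef * dy
                        f[i, 2] -= coef * dz

    for b0 in range(n_mono - 1):
        i = b0
        j = b0 + 1
        if not (mobile[i] or mobile[j]):
            continue
        dx = _mimg(pos[j, 0] - pos[i, 0], L)
        dy = _mimg(pos[j, 1] - pos[i, 1], L)
        dz = _mimg(pos[j, 2] - pos[i, 2], L)
        r = math.sqrt(dx * dx + dy * dy + dz * dz)
        if r > 0.0:
            coef = k_bond * (r - r0) / r
            if mobile[i]:
                f[i, 0] += coef * dx
                f[i, 1] += coef * dy
                f[i, 2] += coef * dz
            if mobile[j]:
                f[j, 0] -= coef * dx
                f[j, 1] -= coef * dy
                f[j, 2] -= coef * dz
    return math.sqrt(rmin2)


def nlist_grid_size(L: float, r_list: float) -> int:
    """Number of cells in the grid used by the list builders (1 when the
    box is too small or too large for cells and brute force is used)."""
    ncell = int(L // r_list)
    return ncell * ncell * ncell if 3 <= ncell <= 64 else 1


@njit(cache=True)
def _energy_kernel(pos, species, n_mono, eps, xi, r_cut, k_bond, r0, L, shift):
    """Total potential energy by an all-pairs sum (used for tests and
    small systems; O(n^2))."""
    n = pos.shape[0]
    rcut2 = r_cut * r_cut
    e_tot = 0.0
    sc6 = (1.0 / r_cut) ** 6
    for i in range(n):
        for j in range(i + 1, n):
            dx = _mimg(pos[j, 0] - pos[i, 0], L)
            dy = _mimg(pos[j, 1] - pos[i, 1], L)
            dz = _mimg(pos[j, 2] - pos[i, 2], L)
            r2 = dx * dx + dy * dy + dz * dz
            if r2 < rcut2:
                e = eps[species[i], species[j]]
                if e > 0.0:
                    x = xi[species[i], species[j]]
                    inv2 = 1.0 / r2
                    sr6 = inv2 * inv2 * inv2
                    e_tot += 4.0 * e * (sr6 * sr6 - x * sr6)
                    if shift:
                        e_tot -= 4.0 * e * (sc6 * sc6 - x * sc6)
    for b0 in range(n_mono - 1):
        dx = _mimg(pos[b0 + 1, 0] - pos[b0, 0], L)
        dy = _mimg(pos[b0 + 1, 1] - pos[b0, 1], L)
        dz = _mimg(pos[b0 + 1, 2] - pos[b0, 2], L)
        r = math.sqrt(dx * dx + dy * dy + dz * dz)
        e_tot += 0.5 * k_bond * (r - r0) ** 2
    return e_tot


@njit(cache=True)
def _pairs_kernel(pos, r_cut, L):
    """All pairs (i < j) within the cutoff, via the same cell-list logic
    as the force kernel (falls back to brute force in small boxes)."""
    n = pos.shape[0]
    rcut2 = r_cut * r_cut
    out_i = []
    out_j = []
    ncell = int(L // r_cut)
    if 3 <= ncell <= 64:
        cell = L / ncell
        head = np.full(ncell * ncell * ncell, -1, np.int64)
        nxt = np.empty(n, np.int64)
        cx = np.empty(n, np.int64)
        cy = np.empty(n, np.int64)
        cz = np.empty(n, np.int64)
        for i in range(n):
            x = pos[i, 0] - L * math.floor(pos[i, 0] / L)
            y = pos[i, 1] - L * math.floor(pos[i, 1] / L)
            z = pos[i, 2] - L * math.floor(pos[i, 2] / L)
            a = min(int(x / cell), ncell - 1)
            b = min(int(y / cell), ncell - 1)
            c = min(int(z / cell), ncell - 1)
            cx[i] = a
            cy[i] = b
            cz[i] = c
            idx = (a * ncell + b) * ncell + c
            nxt[i] = head[idx]
            head[idx] = i
        for i in range(n):
            for ox in range(-1, 2):
                a = (cx[i] + ox) % ncell
                for oy in range(-1, 2):
                    b = (cy[i] + oy) % ncell
                    for oz in range(-1, 2):
                        c = (cz[i] + oz) % ncell
                        j = head[(a * ncell + b) * ncell + c]
                        while j >= 0:
                            if j > i:
                                dx = _mimg(pos[j, 0] - pos[i, 0], L)
                                dy = _mimg(pos[j, 1] - pos[i, 1], L)
                                dz = _mimg(pos[j, 2] - pos[i, 2], L)
                                if dx * dx + dy * dy + dz * dz < rcut2:
                                    out_i.append(i)
                                    out_j.append(j)
                            j = nxt[j]
    else:
        for i in range(n):
            for j in range(i + 1, n):
                dx = _mimg(pos[j, 0] - pos[i, 0], L)
                dy = _mimg(pos[j, 1] - pos[i, 1], L)
                dz = _mimg(pos[j, 2] - pos[i, 2], L)
                if dx * dx + dy * dy + dz * dz < rcut2:
                    out_i.append(i)
                    out_j.append(j)
    return out_i, out_j


def pair_list(positions: np.ndarray, box_edge: float, r_cut: float) -> set[tuple[int, int]]:
    """Interacting pairs (i < j) with periodic separation below ``r_cut``."""
    pos = np.ascontiguousarray(positions, dtype=np.float64)
    ii, jj = _pairs_kernel(pos, float(r_cut), float(box_edge))
    return {(int(i), int(j)) for i, j in zip(ii, jj)}


class ForceField:
    """Bundles an interaction table with evaluation routines."""

    def __init__(self, table: InteractionTable, energy_shift: bool = False):
        self.table = table
        self.energy_shift = energy_shift
        # int64 species matrices avoid per-call casts inside the kernels
        self._eps = np.ascontiguousarray(table.eps, dtype=np.float64)
        self._xi = np.ascontiguousarray(table.xi, dtype=np.float64)

    def forces(
        self,
        state: SystemState,
        n_monomers: int,
        mobile: np.ndarray | None = None,
        check_floor: bool = True,
    ) -> np.ndarray:
        n = state.n_particles
        if mobile is None:
            mobile = np.ones(n, dtype=np.bool_)
        f = np.empty((n, 3))
        rmin = _forces_kernel(
            state.positions,
            state.species.astype(np.int64),
            n_monomers,
            self._eps,
            self._xi,
            self.table.r_cut,
            self.table.k_bond,
            self.table.r0,
            state.box_edge,
            mobile,
            f,
        )
        if check_floor and rmin < HARD_FLOOR:
            raise UnstableConfigurationError(
                f"pair distance {rmin:.4f} sigma below hard floor {HARD_FLOOR} at step {state.step}"
            )
        return f

    def energy(self, state: SystemState, n_monomers: int) -> float:
        return float(
            _energy_kernel(
                state.positions,
                state.species.astype(np.int64),
                n_monomers,
                self._eps,
                self._xi,
                self.table.r_cut,
                self.table.k_bond,
                self.table.r0,
                state.box_edge,
                self.energy_shift,
            )
        )


def total_forces(
    state: SystemState,
    topology: PolymerTopology | None,
    ff: ForceField,
    mobile: np.ndarray | None = None,
) -> np.ndarray:
    """Forces (kT/sigma) on every particle; -grad of the total energy.

    ``topology`` identifies the bonded chain (the first ``N`` particles);
    pass ``None`` for systems without a polymer.
    """
    n_mono = 0 if topology is None else topology.n_monomers
    return ff.forces(state, n_mono, mobile=mobile)


def total_energy(state: SystemState, topology: PolymerTopology | None, ff: ForceField) -> float:
    n_mono = 0 if topology is None else topology.n_monomers
    return ff.energy(state, n_mono)
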