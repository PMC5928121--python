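"""Statistics computed on trajectories.

All contact-based quantities use the same rule: two particles are in
contact in a snapshot when their minimum-image center-to-center distance
is strictly below the threshold ``t`` (default ``2 sigma``, the particle
diameter, where the LJ interaction is practically zero).

* the intra-polymer contact matrix ``H`` sums a boolean contact matrix
  over snapshots; its row sum ``R_i`` is the total amount of contacts
  made by monomer ``i`` (the simulation analogue of a Hi-C row sum);
* the tracer traffic ``C_i`` counts, over all tracers and snapshots,
  the contacts between tracers and monomer ``i``;
* the binder occupancy is computed the same way from the binders.

The correspondence between traffic and polymer contacts is measured by
the Pearson correlation of the raw count profiles and by the divergence
``D_KL(C|R) = sum_i C_i log(R_i / C_i)`` evaluated on the profiles
normalized to unit sum.  In this orientation the value is <= 0, with 0
reached when the normalized profiles agree on the support of ``C``; its
magnitude is also reported, small magnitude meaning high correspondence.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from numba import njit
from scipy import stats

from .model import PolymerTopology, Trajectory

__all__ = [
    "ContactMatrix",
    "TrafficProfile",
    "CorrespondenceStats",
    "contact_matrix",
    "traffic_profile",
    "binder_occupancy",
    "kl_divergence",
    "correspondence",
    "coverage",
    "binder_exclusion",
    "gyration_and_density",
    "radius_of_gyration_series",
    "bound_fraction",
    "loop_traffic_ratio",
    "analyze_run",
]


@njit(cache=True)
def _mimg(d, L):
    return d - L * math.floor(d / L + 0.5)


@njit(cache=True)
def _contact_accumulate(pos, L, t, min_sep_index, H):
    """Sum boolean monomer-monomer contacts over snapshots.

    ``min_sep_index`` is the smallest |i - j| that counts (2 excludes
    bonded neighbors, 1 includes them; the diagonal is always excluded).
    """
    S, N = pos.shape[0], pos.shape[1]
    t2 = t * t
    for s in range(S):
        for i in range(N):
            for j in range(i + min_sep_index, N):
                dx = _mimg(pos[s, j, 0] - pos[s, i, 0], L)
                dy = _mimg(pos[s, j, 1] - pos[s, i, 1], L)
                dz = _mimg(pos[s, j, 2] - pos[s, i, 2], L)
                if dx * dx + dy * dy + dz * dz < t2:
                    H[i, j] += 1
                    H[j, i] += 1


@njit(cache=True)
def _cross_contacts(pos, a_lo, a_hi, b_lo, b_hi, L, t, C):
    """Per-particle contact counts of group A (indices a_lo..a_hi) with
    group B, summed over snapshots; C has length a_hi - a_lo."""
    S = pos.shape[0]
    t2 = t * t
    for s in range(S):
        for i in range(a_lo, a_hi):
            for j in range(b_lo, b_hi):
                dx = _mimg(pos[s, j, 0] - pos[s, i, 0], L)
                dy = _mimg(pos[s, j, 1] - pos[s, i, 1], L)
                dz = _mimg(pos[s, j, 2] - pos[s, i, 2], L)
                if dx * dx + dy * dy + dz * dz < t2:
                    C[i - a_lo] += 1


@njit(cache=True)
def _bound_observations(pos, n_mono, t_lo, t_hi, L, t):
    """Number of (tracer, snapshot) observations with at least one
    monomer within the contact threshold."""
    S = pos.shape[0]
    t2 = t * t
    count = 0
    for s in range(S):
        for i in range(t_lo, t_hi):
            for j in range(n_mono):
                dx = _mimg(pos[s, j, 0] - pos[s, i, 0], L)
                dy = _mimg(pos[s, j, 1] - pos[s, i, 1], L)
                dz = _mimg(pos[s, j, 2] - pos[s, i, 2], L)
                if dx * dx + dy * dy + dz * dz < t2:
                    count += 1
                    break
    return count


@dataclass
class ContactMatrix:
    """Summed boolean intra-polymer contacts at threshold ``t``."""

    H: np.ndarray
    threshold: float
    n_snapshots: int

    @property
    def row_sum(self) -> np.ndarray:
        """Polymer contacts R_i: total contacts made by each monomer."""
        return self.H.sum(axis=1)

    def to_dense_text(self, path: str | Path) -> None:
        np.savetxt(path, self.H, fmt="%d", delimiter="\t")

    def to_sparse_text(self, path: str | Path) -> None:
        ii, jj = np.nonzero(np.triu(self.H, k=1))
        with open(path, "w") as fh:
            fh.write("# i\tj\tcount\n")
            for i, j in zip(ii, jj):
                fh.write(f"{i}\t{j}\t{self.H[i, j]}\n")


@dataclass
class TrafficProfile:
    """Per-monomer contact counts with a diffusible species."""

    C: np.ndarray
    n_snapshots: int
    n_tracers: int

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("# monomer_index\tcount\n")
            for i, c in enumerate(self.C):
                fh.write(f"{i}\t{c}\n")


@dataclass
class CorrespondenceStats:
    """Agreement between tracer traffic and polymer contacts."""

    pearson_r: float | None
    d_kl: float
    normalization: str = "unit-sum, natural log, pseudo-count on empty R bins"

    @property
    def abs_d_kl(self) -> float:
        return abs(self.d_kl)


def contact_matrix(traj: Trajectory, t: float = 2.0, exclude_bonded: bool = True) -> ContactMatrix:
    """Intra-polymer contact matrix summed over snapshots.

    Bonded neighbors (|i - j| <= 1) are excluded by default: they sit at
    the spring rest length and would always register as contacts.
    """
    if t <= 0:
        raise ValueError("contact threshold must be positive")
    if traj.n_snapshots < 1:
        raise ValueError("trajectory has no snapshots")
    N = traj.config.n_monomers
    H = np.zeros((N, N), dtype=np.int64)
    pos = np.ascontiguousarray(traj.positions[:, traj.monomer_slice, :])
    _contact_accumulate(pos, traj.box_edge, float(t), 2 if exclude_bonded else 1, H)
    return ContactMatrix(H=H, threshold=float(t), n_snapshots=traj.n_snapshots)


def traffic_profile(traj: Trajectory, t: float = 2.0) -> TrafficProfile:
    """Tracer traffic: per-monomer tracer contacts summed over tracers
    and snapshots.  Both p and a monomers count; binders do not."""
    if t <= 0:
        raise ValueError("contact threshold must be positive")
    if traj.config.n_tracers == 0:
        raise ValueError("trajectory has no tracers")
    N = traj.config.n_monomers
    C = np.zeros(N, dtype=np.int64)
    tr = traj.tracer_slice
    _cross_contacts(traj.positions, 0, N, tr.start, tr.stop, traj.box_edge, float(t), C)
    return TrafficProfile(C=C, n_snapshots=traj.n_snapshots, n_tracers=traj.config.n_tracers)


def binder_occupancy(traj: Trajectory, t: float = 2.0) -> TrafficProfile:
    """Binder occupancy profile, computed the same way as the traffic."""
    if traj.config.n_binders == 0:
        raise ValueError("trajectory has no binders")
    N = traj.config.n_monomers
    C = np.zeros(N, dtype=np.int64)
    b = traj.binder_slice
    _cross_contacts(traj.positions, 0, N, b.start, b.stop, traj.box_edge, float(t), C)
    return TrafficProfile(C=C, n_snapshots=traj.n_snapshots, n_tracers=traj.config.n_binders)


def kl_divergence(C: np.ndarray, R: np.ndarray, pseudocount: float = 1.0) -> float:
    """Divergence ``sum_i C_i log(R_i / C_i)`` on unit-sum profiles.

    Profiles are interpreted as probability distributions (normalized to
    unit sum); terms with ``C_i = 0`` contribute nothing.  Monomers with
    ``R_i = 0`` but ``C_i > 0`` receive ``pseudocount`` in the raw R
    profile before normalization to keep the sum finite.  The result is
    <= 0, and 0 exactly when the normalized profiles coincide on the
    support of C.
    """
    C = np.asarray(C, dtype=float)
    R = np.asarray(R, dtype=float)
    if C.shape != R.shape or C.ndim != 1:
        raise ValueError("profiles must be one-dimensional and equally long")
    if np.any(C < 0) or np.any(R < 0):
        raise ValueError("profiles must be non-negative")
    if C.sum() == 0 or R.sum() == 0:
        raise ValueError("profiles must not be all-zero")
    needy = (R == 0) & (C > 0)
    if needy.any():
        R = R.copy()
        R[needy] = pseudocount
    c = C / C.sum()
    r = R / R.sum()
    mask = c > 0
    return float(np.sum(c[mask] * np.log(r[mask] / c[mask])))


def _pearson(x: np.ndarray, y: np.ndarray) -> float | None:
    """Pearson r, or None when either input has zero variance."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.std() == 0 or y.std() == 0:
        return None
    return float(stats.pearsonr(x, y).statistic)


def correspondence(cm: ContactMatrix, tp: TrafficProfile) -> CorrespondenceStats:
    """Pearson r on raw counts and the divergence on normalized profiles."""
    C = tp.C
    R = cm.row_sum
    if C.shape != R.shape:
        raise ValueError("traffic and contact profiles index different monomers")
    # an all-zero profile leaves the divergence undefined: report missing
    d_kl = kl_divergence(C, R) if C.sum() > 0 and R.sum() > 0 else float("nan")
    return CorrespondenceStats(pearson_r=_pearson(C, R), d_kl=d_kl)


def coverage(tp: TrafficProfile) -> float:
    """Percentage of monomers visited by any tracer at least once."""
    return 100.0 * float(np.count_nonzero(tp.C)) / tp.C.size


def binder_exclusion(traj: Trajectory, t: float = 2.0) -> float | None:
    """Pearson correlation between tracer traffic and binder occupancy.

    Negative values indicate that binders exclude tracers from looping
    sites (the volume-exclusion signature at high compaction)."""
    tp = traffic_profile(traj, t)
    bo = binder_occupancy(traj, t)
    return _pearson(tp.C, bo.C)


def _unwrap_chain_block(pos: np.ndarray, L: float) -> np.ndarray:
    """Periodic-image-consistent chain coordinates, per snapshot, by
    walking the chain bond by bond (bonds are always << L/2)."""
    bonds = pos[:, 1:, :] - pos[:, :-1, :]
    bonds -= L * np.floor(bonds / L + 0.5)
    out = np.empty_like(pos)
    out[:, 0, :] = pos[:, 0, :]
    np.cumsum(bonds, axis=1, out=bonds)
    out[:, 1:, :] = pos[:, 0:1, :] + bonds
    return out


def radius_of_gyration_series(traj: Trajectory) -> np.ndarray:
    """Per-snapshot radius of gyration of the chain (unwrapped)."""
    pos = traj.positions[:, traj.monomer_slice, :]
    unwrapped = _unwrap_chain_block(pos, traj.box_edge)
    centred = unwrapped - unwrapped.mean(axis=1, keepdims=True)
    return np.sqrt((centred**2).sum(axis=2).mean(axis=1))


def gyration_and_density(traj: Trajectory) -> tuple[float, float]:
    """Mean radius of gyration and the local density
    ``rho_local = N (sigma / r_gyr)^3`` derived from it."""
    r_gyr = float(radius_of_gyration_series(traj).mean())
    N = traj.config.n_monomers
    sigma = traj.config.interaction_table().sigma
    rho = N * (sigma / r_gyr) ** 3
    return r_gyr, float(rho)


def bound_fraction(traj: Trajectory, t: float = 2.0) -> float:
    """Percentage of (tracer, snapshot) observations with at least one
    monomer within the contact threshold: the bound-time fraction."""
    if traj.config.n_tracers == 0:
        raise ValueError("trajectory has no tracers")
    tr = traj.tracer_slice
    n_obs = traj.n_snapshots * traj.config.n_tracers
    bound = _bound_observations(
        traj.positions, traj.config.n_monomers, tr.start, tr.stop, traj.box_edge, float(t)
    )
    return 100.0 * bound / n_obs


def loop_traffic_ratio(tp: TrafficProfile, topology: PolymerTopology, halo: int = 5) -> float:
    """Traffic at the loop-anchor contact point relative to the chain
    interior.

    The anchor region is the anchor monomers themselves; the interior
    baseline averages monomers at least ``halo`` bonds away from every
    anchor and from the chain ends."""
    anchors = np.array(topology.anchor_indices)
    if anchors.size == 0:
        raise ValueError("topology has no anchors")
    N = topology.n_monomers
    idx = np.arange(N)
    interior = np.ones(N, dtype=bool)
    for a in anchors:
        interior &= np.abs(idx - a) >= halo
    interior &= (idx >= halo) & (idx < N - halo)
    if not interior.any():
        raise ValueError("no interior monomers left at this halo")
    denom = tp.C[interior].mean()
    if denom == 0:
        raise ValueError("no interior traffic observed")
    return float(tp.C[anchors].mean() / denom)


def analyze_run(traj: Trajectory, t: float = 2.0) -> dict:
    """The per-run statistics grid: correspondence, coverage, exclusion,
    bound time, and polymer geometry."""
    out: dict = {}
    cm = contact_matrix(traj, t)
    r_gyr, rho = gyration_and_density(traj)
    out["r_gyr"] = r_gyr
    out["rho_local"] = rho
    if traj.config.n_tracers > 0:
        tp = traffic_profile(traj, t)
        corr = correspondence(cm, tp)
        out["pearson_r"] = corr.pearson_r
        out["d_kl"] = corr.d_kl
        out["abs_d_kl"] = corr.abs_d_kl
        out["coverage"] = coverage(tp)
        out["bound_fraction"] = bound_fraction(traj, t)
        if traj.config.n_binders > 0:
            out["binder_exclusion_r"] = binder_exclusion(traj, t)
    return out
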