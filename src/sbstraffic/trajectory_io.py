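"""Trajectory persistence and hand-built fixture configurations.

Native archive layout: one JSON header line (UTF-8, newline-terminated)
that fully describes the run -- particle count, species labels, box,
flat simulation config, seed, code version, snapshot count -- followed
by fixed-size binary records, one per snapshot: the step index (int64,
little-endian) then the coordinates (n * 3 float64, little-endian, C
order).  Coordinates round-trip bit-exactly.  Because records are
appended sequentially, an interrupted write leaves a readable prefix;
the reader flags the truncation instead of failing.

An extended-XYZ exporter covers interoperability with standard
molecular viewers (species label + x y z per line; the comment line
carries the cubic lattice).
"""

from __future__ import annotations

import json
import struct
from pathlib import Path

import numpy as np

from .model import (
    SPECIES,
    SPECIES_CODE,
    PolymerTopology,
    SimulationConfig,
    SystemState,
    Trajectory,
)

__all__ = [
    "write_trajectory",
    "read_trajectory",
    "write_xyz",
    "read_xyz",
    "make_fixture",
    "ArchiveError",
]

_MAGIC = "sbstraffic-trajectory"
_FORMAT_VERSION = 1


class ArchiveError(ValueError):
    """Raised for malformed trajectory archives."""


def write_trajectory(traj: Trajectory, path: str | Path) -> None:
    """Write the native archive (see module docstring)."""
    header = {
        "magic": _MAGIC,
        "format_version": _FORMAT_VERSION,
        "n_particles": int(traj.n_particles),
        "n_snapshots": int(traj.n_snapshots),
        "species": "".join(SPECIES[c] for c in traj.species),
        "config": traj.config.to_flat_dict(),
        "anchor_indices": list(traj.config.topology.anchor_indices),
        "provenance": _jsonable(traj.provenance),
    }
    with open(path, "wb") as fh:
        fh.write(json.dumps(header).encode() + b"\n")
        for k in range(traj.n_snapshots):
            fh.write(struct.pack("<q", int(traj.steps[k])))
            fh.write(np.ascontiguousarray(traj.positions[k], dtype="<f8").tobytes())


def read_trajectory(path: str | Path) -> Trajectory:
    """Read a native archive; raises :class:`ArchiveError` on malformed
    input.  A truncated archive yields the readable snapshot prefix with
    ``provenance['truncated'] = True``."""
    with open(path, "rb") as fh:
        line = fh.readline()
        try:
            header = json.loads(line.decode())
        except (UnicodeDecodeError, json.JSONDecodeError) as exc:
            raise ArchiveError(f"{path}: missing or unreadable archive header") from exc
        if not isinstance(header, dict) or header.get("magic") != _MAGIC:
            raise ArchiveError(f"{path}: not a trajectory archive (bad magic)")
        for key in ("n_particles", "n_snapshots", "species", "config"):
            if key not in header:
                raise ArchiveError(f"{path}: header record missing '{key}'")
        n = int(header["n_particles"])
        labels = header["species"]
        if len(labels) != n:
            raise ArchiveError(f"{path}: header species length {len(labels)} != n_particles {n}")
        bad = set(labels) - set(SPECIES)
        if bad:
            raise ArchiveError(f"{path}: species label outside {{p,a,b,t}}: {sorted(bad)}")
        species = np.array([SPECIES_CODE[c] for c in labels], dtype=np.int8)

        rec_size = 8 + n * 3 * 8
        declared = int(header["n_snapshots"])
        blob = fh.read()
    n_complete = len(blob) // rec_size
    steps = np.empty(n_complete, dtype=np.int64)
    positions = np.empty((n_complete, n, 3))
    for k in range(n_complete):
        off = k * rec_size
        steps[k] = struct.unpack_from("<q", blob, off)[0]
        positions[k] = np.frombuffer(blob, dtype="<f8", count=n * 3, offset=off + 8).reshape(n, 3)

    config = _config_from_header(header)
    provenance = dict(header.get("provenance", {}))
    if n_complete < declared or len(blob) % rec_size:
        provenance["truncated"] = True
    return Trajectory(
        positions=positions,
        steps=steps,
        species=species,
        config=config,
        provenance=provenance,
    )


def _config_from_header(header: dict) -> SimulationConfig:
    flat = header["config"]
    topo = PolymerTopology(
        n_monomers=int(flat["N"]),
        anchor_indices=tuple(header.get("anchor_indices", [])),
        phi=float(flat["phi"]),
    )
    return SimulationConfig(
        topology=topo,
        epsilon=float(flat["epsilon"]),
        n_tracers=int(flat["n_tracers"]),
        box_edge=float(flat["L"]),
        dt=float(flat["dt"]),
        n_equil=int(flat["n_equil"]),
        n_total=int(flat["n_total"]),
        sample_every=int(flat["sample_every"]),
        seed=int(flat["seed"]),
        fixed_polymer=bool(flat["fixed_polymer"]),
        epsilon_zero_control=bool(flat["epsilon_zero_control"]),
        include_binders=bool(flat.get("include_binders", True)),
    )


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj


def write_xyz(state: SystemState, path: str | Path, comment: str = "") -> None:
    """Export one snapshot as extended XYZ (viewable in OVITO/VMD)."""
    L = state.box_edge
    lattice = f'Lattice="{L} 0 0 0 {L} 0 0 0 {L}"'
    props = "Properties=species:S:1:pos:R:3"
    with open(path, "w") as fh:
        fh.write(f"{state.n_particles}\n")
        fh.write(f"{lattice} {props} {comment}".strip() + "\n")
        for code, (x, y, z) in zip(state.species, state.positions):
            fh.write(f"{SPECIES[code]} {x:.12g} {y:.12g} {z:.12g}\n")


def read_xyz(path: str | Path) -> SystemState:
    """Read back an extended-XYZ snapshot written by :func:`write_xyz`."""
    with open(path) as fh:
        lines = fh.read().splitlines()
    if len(lines) < 2:
        raise ArchiveError(f"{path}: not an XYZ file")
    n = int(lines[0])
    comment = lines[1]
    if 'Lattice="' not in comment:
        raise ArchiveError(f"{path}: XYZ comment line carries no lattice")
    lat = comment.split('Lattice="', 1)[1].split('"', 1)[0].split()
    L = float(lat[0])
    species = np.empty(n, dtype=np.int8)
    positions = np.empty((n, 3))
    for k in range(n):
        parts = lines[2 + k].split()
        if parts[0] not in SPECIES_CODE:
            raise ArchiveError(f"{path}: line {3 + k}: species label '{parts[0]}' outside {{p,a,b,t}}")
        species[k] = SPECIES_CODE[parts[0]]
        positions[k] = [float(v) for v in parts[1:4]]
    return SystemState(positions=positions, species=species, box_edge=L, step=0)


# ---------------------------------------------------------------------------
# deterministic fixtures for exact analysis tests
# ---------------------------------------------------------------------------

FIXTURE_NAMES = ("two-monomer", "single-loop", "globule-shell")

_LOOP_N = 100
_LOOP_ANCHORS = (25, 75)
_ANCHOR_GAP = 1.5  # anchors held at this separation, inside the 2-sigma contact threshold


def make_fixture(name: str, box_edge: float = 50.0) -> Trajectory:
    """Hand-placed single-snapshot configurations with known geometry.

    ``two-monomer``
        a 2-bead chain at separation 1.5 sigma: exactly one pair within
        the 2 sigma contact threshold (visible with bonded pairs
        included).
    ``single-loop``
        a 100-bead open chain whose anchor monomers 25 and 75 are held
        1.5 sigma apart, forming one stable loop; the only non-neighbor
        pair within 2 sigma is the anchor pair.  Tails and loop are
        arranged so every other pair with |i - j| >= 2 stays beyond the
        threshold.
    ``globule-shell``
        a dense 5x5x5 serpentine block with spacing 1.2 sigma; the
        surface monomer set (beads on the block faces) is recorded in
        ``provenance['surface_indices']``.
    """
    if name == "two-monomer":
        positions = np.array([[25.0, 25.0, 25.0], [26.5, 25.0, 25.0]])
        return _fixture_trajectory(positions, anchors=(), phi=0.1, box_edge=box_edge)
    if name == "single-loop":
        return _single_loop_fixture(box_edge)
    if name == "globule-shell":
        return _globule_shell_fixture(box_edge)
    raise ValueError(f"unknown fixture '{name}'; choose from {FIXTURE_NAMES}")


def _fixture_trajectory(
    positions: np.ndarray,
    anchors: tuple[int, ...],
    phi: float | None,
    box_edge: float,
    provenance: dict | None = None,
) -> Trajectory:
    N = positions.shape[0]
    if phi is None:
        phi = len(anchors) / N
    topo = PolymerTopology(n_monomers=N, anchor_indices=anchors, phi=phi)
    config = SimulationConfig(
        topology=topo, epsilon=0.0, n_tracers=0, box_edge=box_edge,
        n_equil=0, n_total=1, sample_every=1, seed=0, include_binders=False,
    )
    prov = {"fixture": True}
    if provenance:
        prov.update(provenance)
    return Trajectory(
        positions=positions[None, :, :],
        steps=np.array([0]),
        species=config.species_codes(),
        config=config,
        provenance=prov,
    )


def _single_loop_curve() -> np.ndarray:
    """The loop section (monomers 25..75) as a closed balloon curve.

    Headings of the 50 bonds follow
    ``theta(u) = theta0 + span * u + a * sin(2 pi u)``; the symmetric
    family closes the y-displacement exactly, and the amplitude ``a`` is
    solved so the x-displacement equals the anchor gap.
    """
    from scipy.optimize import brentq

    n_bonds = _LOOP_N // 2  # 50 bonds between the two anchors
    b = 1.2
    theta0 = np.deg2rad(101.5)
    span = -2.0 * theta0  # symmetric: theta ends at -theta0
    u = (np.arange(n_bonds) + 0.5) / n_bonds

    def x_closure(a):
        theta = theta0 + span * u + a * np.sin(2 * np.pi * u)
        return b * np.cos(theta).sum() - _ANCHOR_GAP

    a = brentq(x_closure, 0.0, np.pi)
    theta = theta0 + span * u + a * np.sin(2 * np.pi * u)
    steps = b * np.stack([np.cos(theta), np.sin(theta), np.zeros(n_bonds)], axis=1)
    pts = np.vstack([[-_ANCHOR_GAP / 2, 0.0, 0.0], np.cumsum(steps, axis=0) + [-_ANCHOR_GAP / 2, 0.0, 0.0]])
    return pts  # 51 points, first at anchor 1, last at anchor 2


def _single_loop_fixture(box_edge: float) -> Trajectory:
    a1, a2 = _LOOP_ANCHORS
    N = _LOOP_N
    b = 1.2
    loop = _single_loop_curve()  # indices 25..75
    # straight tails leave the anchors away from each other and out of the
    # loop plane, with corner angles wide enough that no |i-j| = 2 pair
    # comes within the contact threshold
    u1 = np.array([-0.2, -0.84, -0.5])
    u1 /= np.linalg.norm(u1)
    u2 = np.array([0.2, -0.84, 0.5])
    u2 /= np.linalg.norm(u2)
    positions = np.empty((N, 3))
    positions[a1 : a2 + 1] = loop
    for k in range(1, a1 + 1):
        positions[a1 - k] = loop[0] + b * k * u1
    for k in range(1, N - a2):
        positions[a2 + k] = loop[-1] + b * k * u2
    positions += np.array([box_edge / 2, box_edge / 2, box_edge / 2])

    _validate_single_loop(positions)
    return _fixture_trajectory(positions, anchors=_LOOP_ANCHORS, phi=0.02, box_edge=box_edge)


def _validate_single_loop(positions: np.ndarray) -> None:
    """By-construction contract: anchors within the contact threshold,
    every other non-neighbor pair outside it, bonds near rest length."""
    d = np.linalg.norm(positions[:, None, :] - positions[None, :, :], axis=2)
    N = positions.shape[0]
    a1, a2 = _LOOP_ANCHORS
    bond = np.diagonal(d, offset=1)
    assert np.all(np.abs(bond - 1.2) < 0.05), "bond lengths off rest length"
    ii, jj = np.triu_indices(N, k=2)
    close = d[ii, jj] < 2.0
    pairs = set(zip(ii[close].tolist(), jj[close].tolist()))
    assert pairs == {(a1, a2)}, f"unexpected contacts in loop fixture: {pairs}"


def _globule_shell_fixture(box_edge: float) -> Trajectory:
    m = 5
    spacing = 1.2
    order = []
    row = 0
    for iz in range(m):
        ys = range(m) if iz % 2 == 0 else range(m - 1, -1, -1)
        for iy in ys:
            xs = range(m) if row % 2 == 0 else range(m - 1, -1, -1)
            order.extend((ix, iy, iz) for ix in xs)
            row += 1
    coords = np.array(order, dtype=float) * spacing
    coords += box_edge / 2 - coords.mean(axis=0)
    surface = [
        k for k, (ix, iy, iz) in enumerate(order)
        if 0 in (ix, iy, iz) or (m - 1) in (ix, iy, iz)
    ]
    return _fixture_trajectory(
        coords, anchors=(), phi=1.0e-3, box_edge=box_edge,
        provenance={"surface_indices": surface},
    )
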