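"""Text trajectory formats: extended XYZ, a LAMMPS-dump dialect, topology
sidecars and tab-separated energy tables."""

from __future__ import annotations

import warnings
from pathlib import Path
from typing import Iterable

import numpy as np

from .builder import ParticleSystem, Topology
from .engine import EnergyReport
from .forcefield import SPECIES, SPECIES_INDEX


class TrajectoryError(RuntimeError):
    """Raised with the offending frame index on malformed trajectory input."""

    def __init__(self, message: str, frame: int | None = None):
        super().__init__(message if frame is None else f"frame {frame}: {message}")
        self.frame = frame


# ---------------------------------------------------------------------------
# extended XYZ
# ---------------------------------------------------------------------------


def write_xyz(path: str | Path, frames: Iterable[ParticleSystem], mode: str = "w") -> None:
    """Write frames as extended XYZ (species, position, velocity columns)."""
    with open(path, mode) as fh:
        for fr in frames:
            L = fr.box
            fh.write(f"{fr.n_beads}\n")
            fh.write(
                f'Lattice="{L:g} 0 0 0 {L:g} 0 0 0 {L:g}" '
                f"Properties=species:S:1:pos:R:3:vel:R:3 Time={fr.time:.10g}\n"
            )
            for s, p, v in zip(fr.species, fr.positions, fr.velocities):
                fh.write(
                    f"{SPECIES[s]} {p[0]:.10g} {p[1]:.10g} {p[2]:.10g} "
                    f"{v[0]:.10g} {v[1]:.10g} {v[2]:.10g}\n"
                )


def read_xyz(path: str | Path, salvage: bool = False) -> list[ParticleSystem]:
    """Read an extended-XYZ trajectory written by :func:`write_xyz`.

    A truncated or malformed frame raises :class:`TrajectoryError` carrying
    the frame index; with ``salvage=True`` the complete frames read so far
    are returned instead (with a warning) when at least one exists.
    """
    frames: list[ParticleSystem] = []
    with open(path) as fh:
        lines = fh.read().splitlines()
    i = 0
    frame_no = 0
    try:
        while i < len(lines):
            if not lines[i].strip():
                i += 1
                continue
            try:
                n = int(lines[i].strip())
            except ValueError as exc:
                raise TrajectoryError(f"bad atom count line: {lines[i]!r}", frame_no) from exc
            if i + 1 >= len(lines):
                raise TrajectoryError("missing comment line", frame_no)
            comment = lines[i + 1]
            box = _parse_lattice(comment, frame_no)
            time = 0.0
            for token in comment.split():
                if token.startswith("Time="):
                    time = float(token[5:])
            body = lines[i + 2 : i + 2 + n]
            if len(body) < n:
                raise TrajectoryError(
                    f"truncated frame: expected {n} atom lines, found {len(body)}", frame_no
                )
            pos = np.empty((n, 3))
            vel = np.zeros((n, 3))
            spec = np.empty(n, dtype=np.int64)
            for k, line in enumerate(body):
                parts = line.split()
                if len(parts) < 4:
                    raise TrajectoryError(f"bad atom line: {line!r}", frame_no)
                spec[k] = SPECIES_INDEX[parts[0]]
                pos[k] = [float(x) for x in parts[1:4]]
                if len(parts) >= 7:
                    vel[k] = [float(x) for x in parts[4:7]]
            frames.append(ParticleSystem(pos, vel, spec, box, time))
            i += 2 + n
            frame_no += 1
    except TrajectoryError as exc:
        if salvage and frames:
            warnings.warn(f"{exc}; analyzing the {len(frames)} complete frame(s)", stacklevel=2)
            return frames
        raise
    return frames


def _parse_lattice(comment: str, frame_no: int) -> float:
    start = comment.find('Lattice="')
    if start < 0:
        raise TrajectoryError("missing Lattice in comment line", frame_no)
    end = comment.find('"', start + 9)
    values = [float(x) for x in comment[start + 9 : end].split()]
    if len(values) != 9:
        raise TrajectoryError("Lattice must have 9 components", frame_no)
    return values[0]


# ---------------------------------------------------------------------------
# LAMMPS-dump dialect
# ---------------------------------------------------------------------------


def write_lammps_dump(
    path: str | Path, frames: Iterable[ParticleSystem], dt: float = 0.01, mode: str = "w"
) -> None:
    """Write frames in the plain-text LAMMPS dump dialect."""
    with open(path, mode) as fh:
        for fr in frames:
            step = int(round(fr.time / dt)) if dt > 0 else 0
            fh.write("ITEM: TIMESTEP\n")
            fh.write(f"{step}\n")
            fh.write("ITEM: NUMBER OF ATOMS\n")
            fh.write(f"{fr.n_beads}\n")
            fh.write("ITEM: BOX BOUNDS pp pp pp\n")
            for _ in range(3):
                fh.write(f"0 {fr.box:.10g}\n")
            fh.write("ITEM: ATOMS id type x y z vx vy vz\n")
            for k, (s, p, v) in enumerate(zip(fr.species, fr.positions, fr.velocities)):
                fh.write(
                    f"{k + 1} {s + 1} {p[0]:.10g} {p[1]:.10g} {p[2]:.10g} "
                    f"{v[0]:.10g} {v[1]:.10g} {v[2]:.10g}\n"
                )


def read_lammps_dump(path: str | Path, dt: float = 0.01) -> list[ParticleSystem]:
    frames: list[ParticleSystem] = []
    with open(path) as fh:
        lines = fh.read().splitlines()
    i = 0
    frame_no = 0
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        if not lines[i].startswith("ITEM: TIMESTEP"):
            raise TrajectoryError(f"expected ITEM: TIMESTEP, got {lines[i]!r}", frame_no)
        try:
            step = int(lines[i + 1])
            n = int(lines[i + 3])
            box = float(lines[i + 5].split()[1])
        except (IndexError, ValueError) as exc:
            raise TrajectoryError("malformed frame header", frame_no) from exc
        header = lines[i + 8]
        if not header.startswith("ITEM: ATOMS"):
            raise TrajectoryError(f"expected ITEM: ATOMS, got {header!r}", frame_no)
        cols = header.split()[2:]
        body = lines[i + 9 : i + 9 + n]
        if len(body) < n:
            raise TrajectoryError(
                f"truncated frame: expected {n} atom lines, found {len(body)}", frame_no
            )
        pos = np.empty((n, 3))
        vel = np.zeros((n, 3))
        spec = np.empty(n, dtype=np.int64)
        col = {c: k for k, c in enumerate(cols)}
        for line in body:
            parts = line.split()
            idx = int(parts[col["id"]]) - 1
            spec[idx] = int(parts[col["type"]]) - 1
            pos[idx] = [float(parts[col[c]]) for c in ("x", "y", "z")]
            if "vx" in col:
                vel[idx] = [float(parts[col[c]]) for c in ("vx", "vy", "vz")]
        frames.append(ParticleSystem(pos, vel, spec, box, step * dt))
        i += 9 + n
        frame_no += 1
    return frames


# ---------------------------------------------------------------------------
# topology sidecar and energy table
# ---------------------------------------------------------------------------


def write_topology(path: str | Path, topo: Topology) -> None:
    """Plain-text sidecar: chain runs, `bond i j` and `angle i j k` lines."""
    with open(path, "w") as fh:
        for c in range(topo.n_chains):
            fh.write(
                f"chain {topo.chain_start[c]} {topo.chain_len[c]} "
                f"{topo.chain_type[c]} {topo.chain_head_len[c]}\n"
            )
        for i, j in topo.bonds:
            fh.write(f"bond {i} {j}\n")
        for i, j, k in topo.angles:
            fh.write(f"angle {i} {j} {k}\n")


def read_topology(path: str | Path) -> Topology:
    chains, bonds, angles = [], [], []
    with open(path) as fh:
        for line in fh:
            parts = line.split()
            if not parts:
                continue
            if parts[0] == "chain":
                chains.append(tuple(int(x) for x in parts[1:5]))
            elif parts[0] == "bond":
                bonds.append((int(parts[1]), int(parts[2])))
            elif parts[0] == "angle":
                angles.append((int(parts[1]), int(parts[2]), int(parts[3])))
    ch = np.asarray(chains, dtype=np.int64).reshape(-1, 4)
    return Topology(
        bonds=np.asarray(bonds, dtype=np.int64).reshape(-1, 2),
        angles=np.asarray(angles, dtype=np.int64).reshape(-1, 3),
        chain_start=ch[:, 0],
        chain_len=ch[:, 1],
        chain_type=ch[:, 2],
        chain_head_len=ch[:, 3],
    )


ENERGY_COLUMNS = ("step", "time_tau", "KE", "PE_pair", "PE_bond", "PE_angle", "total", "kBT")


def write_energy_table(path: str | Path, reports: Iterable[EnergyReport]) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(ENERGY_COLUMNS) + "\n")
        for r in reports:
            fh.write(
                f"{r.step}\t{r.time:.6g}\t{r.kinetic:.10g}\t{r.potential_pair:.10g}\t"
                f"{r.potential_bond:.10g}\t{r.potential_angle:.10g}\t{r.total:.10g}\t"
                f"{r.temperature:.10g}\n"
            )


def read_energy_table(path: str | Path) -> np.ndarray:
    return np.loadtxt(path, skiprows=1)
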