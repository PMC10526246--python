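"""Seeded construction of initial configurations and chain topologies.

A system is a cubic periodic box of edge ``L`` (in rc) filled to bead density
``rho`` (default 3 beads/rc^3).  ``n_lipids`` amphiphilic chains are split
between the two lipid types; every remaining bead is water.  Because the DPD
conservative force is soft and bounded, chains and water are placed at random
without overlap rejection -- transient overlaps relax within a few steps and
introduce no equilibration bias.

Chains are laid down as near-linear random walks with step length ``rs`` (the
equilibrium bond length), so the topology starts essentially relaxed.
Velocities are drawn from the Maxwell-Boltzmann distribution at ``kBT`` and
the net momentum is removed exactly.

:func:`make_fixture` builds deterministic idealized aggregates (bilayer,
perforated bilayer, micelle, vesicle shell, stacked discs, cylindrical
micelle) used to exercise the density/classification pipeline without running
any dynamics.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .forcefield import (
    SPECIES_INDEX,
    ForceFieldParams,
    LipidSpec,
    lipid_type_I,
    lipid_type_II,
)

WATER = SPECIES_INDEX["W"]


@dataclass(frozen=True)
class SystemSpec:
    """Declarative description of one system realization."""

    box_length: float = 30.0
    density: float = 3.0
    n_lipids: int = 0
    lipid_I: LipidSpec = field(default_factory=lambda: lipid_type_I(2))
    lipid_II: LipidSpec = field(default_factory=lambda: lipid_type_II(4))
    split: float = 0.5
    seed: int = 0

    @property
    def n_beads(self) -> int:
        return int(round(self.density * self.box_length**3))

    @property
    def n_type_I(self) -> int:
        return int(round(self.n_lipids * self.split))

    @property
    def n_type_II(self) -> int:
        return self.n_lipids - self.n_type_I

    @property
    def n_lipid_beads(self) -> int:
        return self.n_type_I * self.lipid_I.length + self.n_type_II * self.lipid_II.length

    def replace(self, **changes) -> "SystemSpec":
        return replace(self, **changes)


def concentration(spec: SystemSpec) -> float:
    """Lipid chain concentration phi = n / V in chains per rc^3."""
    if spec.box_length <= 0:
        raise ValueError("box length must be positive")
    return spec.n_lipids / spec.box_length**3


@dataclass
class Topology:
    """Bond pairs and angle triples derived from the chain definitions.

    ``chain_start``/``chain_len``/``chain_type``/``chain_head_len`` describe
    each chain as a contiguous bead-index run; water beads belong to no chain.
    """

    bonds: np.ndarray  # (nb, 2) int64
    angles: np.ndarray  # (na, 3) int64
    chain_start: np.ndarray  # (nc,) int64
    chain_len: np.ndarray  # (nc,) int64
    chain_type: np.ndarray  # (nc,) int64: 0 = type I, 1 = type II
    chain_head_len: np.ndarray  # (nc,) int64

    @property
    def n_chains(self) -> int:
        return len(self.chain_start)

    def chain_indices(self, c: int) -> np.ndarray:
        s = int(self.chain_start[c])
        return np.arange(s, s + int(self.chain_len[c]))

    @classmethod
    def empty(cls) -> "Topology":
        z = np.zeros(0, dtype=np.int64)
        return cls(z.reshape(0, 2), z.reshape(0, 3), z, z, z, z)


@dataclass
class ParticleSystem:
    """Positions/velocities/species of all beads in a cubic periodic box.

    Positions are wrapped into the half-open box [0, L)^3; the minimum-image
    convention applies to all distances.
    """

    positions: np.ndarray  # (N, 3) float64, wrapped
    velocities: np.ndarray  # (N, 3) float64
    species: np.ndarray  # (N,) int64 codes into SPECIES
    box: float
    time: float = 0.0

    @property
    def n_beads(self) -> int:
        return len(self.positions)

    def copy(self) -> "ParticleSystem":
        return ParticleSystem(
            self.positions.copy(),
            self.velocities.copy(),
            self.species.copy(),
            self.box,
            self.time,
        )

    def wrap(self) -> None:
        np.mod(self.positions, self.box, out=self.positions)


def minimum_image(d: np.ndarray, box: float) -> np.ndarray:
    """Nearest-image displacement(s) for a cubic box."""
    return d - box * np.round(d / box)


def _build_topology(chain_specs: list[tuple[LipidSpec, int]], include_junction_angle: bool) -> tuple[Topology, np.ndarray]:
    """chain_specs: list of (LipidSpec, type_code) in bead-layout order."""
    bonds: list[tuple[int, int]] = []
    angles: list[tuple[int, int, int]] = []
    starts: list[int] = []
    lens: list[int] = []
    types: list[int] = []
    head_lens: list[int] = []
    codes: list[np.ndarray] = []
    offset = 0
    for lip, tcode in chain_specs:
        n = lip.length
        starts.append(offset)
        lens.append(n)
        types.append(tcode)
        head_lens.append(lip.n_head)
        codes.append(lip.species_codes())
        for k in range(n - 1):
            bonds.append((offset + k, offset + k + 1))
        for k in range(n - 2):
            i = offset + k
            # triple (i, i+1, i+2); it straddles the head-tail junction when
            # it contains beads from both blocks
            straddles = k + 2 >= lip.n_head and k < lip.n_head
            if straddles and not include_junction_angle:
                continue
            angles.append((i, i + 1, i + 2))
        offset += n
    topo = Topology(
        bonds=np.asarray(bonds, dtype=np.int64).reshape(-1, 2),
        angles=np.asarray(angles, dtype=np.int64).reshape(-1, 3),
        chain_start=np.asarray(starts, dtype=np.int64),
        chain_len=np.asarray(lens, dtype=np.int64),
        chain_type=np.asarray(types, dtype=np.int64),
        chain_head_len=np.asarray(head_lens, dtype=np.int64),
    )
    all_codes = (
        np.concatenate(codes) if codes else np.zeros(0, dtype=np.int64)
    )
    return topo, all_codes


def _maxwell_velocities(n: int, kBT: float, rng: np.random.Generator) -> np.ndarray:
    v = rng.normal(0.0, math.sqrt(kBT), size=(n, 3))
    v -= v.mean(axis=0)  # remove net momentum exactly
    return v


def build_system(
    spec: SystemSpec,
    ff: ForceFieldParams,
    include_junction_angle: bool = True,
) -> tuple[ParticleSystem, Topology]:
    """Generate a seeded random initial configuration and its topology.

    Chains of type I come first, then type II, then water; the bead layout is
    therefore deterministic given the spec alone, and positions/velocities are
    deterministic given the seed.
    """
    L = spec.box_length
    if L <= 2 * ff.rc:
        raise ValueError(f"box length {L:g} must exceed 2*rc = {2 * ff.rc:g}")
    N = spec.n_beads
    if spec.n_lipid_beads > N:
        raise ValueError(
            f"lipid beads ({spec.n_lipid_beads}) exceed total bead budget ({N})"
        )
    if not 0.0 <= spec.split <= 1.0:
        raise ValueError("split must lie in [0, 1]")

    rng = np.random.default_rng(spec.seed)
    chain_specs = [(spec.lipid_I, 0)] * spec.n_type_I + [(spec.lipid_II, 1)] * spec.n_type_II
    topo, lipid_codes = _build_topology(chain_specs, include_junction_angle)

    positions = np.empty((N, 3))
    # near-linear random walks with step rs
    for c in range(topo.n_chains):
        n = int(topo.chain_len[c])
        start = int(topo.chain_start[c])
        p = rng.uniform(0.0, L, size=3)
        d = rng.normal(size=3)
        d /= np.linalg.norm(d)
        positions[start] = p
        for k in range(1, n):
            d = d + 0.25 * rng.normal(size=3)
            d /= np.linalg.norm(d)
            p = p + ff.rs * d
            positions[start + k] = p
    n_lip = spec.n_lipid_beads
    positions[n_lip:] = rng.uniform(0.0, L, size=(N - n_lip, 3))
    positions %= L

    species = np.empty(N, dtype=np.int64)
    species[:n_lip] = lipid_codes
    species[n_lip:] = WATER

    velocities = _maxwell_velocities(N, ff.kBT, rng)
    system = ParticleSystem(positions, velocities, species, L, 0.0)
    return system, topo


def select_lowest_energy_seed(
    spec: SystemSpec,
    ff: ForceFieldParams,
    seeds: list[int],
    energy_fn,
) -> int:
    """Multi-seed helper: build one candidate per seed, return the seed whose
    initial state minimizes ``energy_fn(system, topology)``."""
    best_seed, best_e = None, math.inf
    for s in seeds:
        sys_s, topo_s = build_system(spec.replace(seed=s), ff)
        e = energy_fn(sys_s, topo_s)
        if e < best_e:
            best_seed, best_e = s, e
    return best_seed


# ---------------------------------------------------------------------------
# Deterministic analysis fixtures
# ---------------------------------------------------------------------------

FIXTURE_KINDS = (
    "flat_bilayer",
    "perforated_bilayer",
    "spherical_micelle",
    "vesicle_shell",
    "stacked_discs",
    "cylindrical_micelle",
)


def _fill_water(
    lipid_pos: np.ndarray, lipid_codes: np.ndarray, spec: SystemSpec
) -> ParticleSystem:
    L = spec.box_length
    N = int(round(spec.density * L**3))
    n_lip = len(lipid_pos)
    if n_lip > N:
        raise ValueError("fixture lipid beads exceed the bead budget")
    rng = np.random.default_rng(spec.seed)
    positions = np.empty((N, 3))
    positions[:n_lip] = lipid_pos % L
    positions[n_lip:] = rng.uniform(0.0, L, size=(N - n_lip, 3))
    species = np.empty(N, dtype=np.int64)
    species[:n_lip] = lipid_codes
    species[n_lip:] = WATER
    velocities = np.zeros((N, 3))
    return ParticleSystem(positions, velocities, species, L, 0.0)


def _straight_chain(origin: np.ndarray, direction: np.ndarray, n: int, spacing: float) -> np.ndarray:
    """Beads 0..n-1 marching from origin along direction (head bead first)."""
    steps = np.arange(n)[:, None] * spacing
    return origin[None, :] + steps * direction[None, :]


def _fibonacci_sphere(n: int) -> np.ndarray:
    """n roughly uniform unit vectors (deterministic)."""
    k = np.arange(n) + 0.5
    phi = np.arccos(1.0 - 2.0 * k / n)
    theta = math.pi * (1.0 + math.sqrt(5.0)) * k
    return np.stack(
        [np.sin(phi) * np.cos(theta), np.sin(phi) * np.sin(theta), np.cos(phi)], axis=1
    )


def make_fixture(
    kind: str,
    spec: SystemSpec,
    spacing: float = 0.5,
    hole_radius: float = 3.0,
    include_junction_angle: bool = True,
) -> tuple[ParticleSystem, Topology]:
    """Build a deterministic idealized aggregate plus uniform water.

    ``spec.n_lipids``, the two lipid specs and the box define the aggregate;
    ``spacing`` is the intra-chain bead spacing (kept <= rs so bonds start
    compressed but intact).  Geometries:

    - ``flat_bilayer``: two leaflets spanning x-y at mid-box; type-I chains
      fill the upper (+z, "right") leaflet, type-II the lower one, heads out.
    - ``perforated_bilayer``: same with chains removed inside a cylindrical
      hole of ``hole_radius``.
    - ``spherical_micelle``: radial chains, tails inward.
    - ``vesicle_shell``: two concentric leaflets enclosing a water core.
    - ``stacked_discs``: bilayer discs stacked along y inside a cylinder,
      adjacent discs touching head-to-head (the hierarchical-disc morphology).
    - ``cylindrical_micelle``: chains radiating from a line along y.
    """
    if kind not in FIXTURE_KINDS:
        raise ValueError(f"unknown fixture kind {kind!r}; expected one of {FIXTURE_KINDS}")
    L = spec.box_length
    n_I, n_II = spec.n_type_I, spec.n_type_II
    lip_I, lip_II = spec.lipid_I, spec.lipid_II
    center = np.full(3, L / 2.0)

    chains: list[np.ndarray] = []
    chain_specs: list[tuple[LipidSpec, int]] = []

    def add_chain(lip: LipidSpec, tcode: int, head_origin: np.ndarray, inward: np.ndarray) -> None:
        chains.append(_straight_chain(head_origin, inward, lip.length, spacing))
        chain_specs.append((lip, tcode))

    if kind in ("flat_bilayer", "perforated_bilayer"):
        # grid placement in the x-y plane, one leaflet per lipid type; when
        # n < n_side^2 the unused slots are spread evenly so the leaflet
        # stays laterally connected (clustered holes would break spanning)
        z_mid = L / 2.0
        for lip, tcode, sign, n in ((lip_I, 0, +1.0, n_I), (lip_II, 1, -1.0, n_II)):
            if n == 0:
                continue
            n_side = math.ceil(math.sqrt(n))
            pitch = L / n_side
            slots = [(ix, iy) for ix in range(n_side) for iy in range(n_side)]
            if kind == "perforated_bilayer":
                slots = [
                    (ix, iy)
                    for ix, iy in slots
                    if ((ix + 0.5) * pitch - L / 2) ** 2 + ((iy + 0.5) * pitch - L / 2) ** 2
                    >= hole_radius**2
                ]
            use = min(n, len(slots))
            keep = np.unique(np.linspace(0, len(slots) - 1, use).round().astype(int))
            for k in keep:
                ix, iy = slots[k]
                x = (ix + 0.5) * pitch
                y = (iy + 0.5) * pitch
                z_head = z_mid + sign * (0.3 + (lip.length - 1) * spacing)
                head = np.array([x, y, z_head])
                add_chain(lip, tcode, head, np.array([0.0, 0.0, -sign]))
    elif kind == "spherical_micelle":
        n = n_I + n_II
        dirs = _fibonacci_sphere(n)
        r_out_I = 0.3 + (lip_I.length - 1) * spacing
        r_out_II = 0.3 + (lip_II.length - 1) * spacing
        for c in range(n):
            lip, tcode = (lip_I, 0) if c < n_I else (lip_II, 1)
            r_out = r_out_I if c < n_I else r_out_II
            head = center + r_out * dirs[c]
            add_chain(lip, tcode, head, -dirs[c])
    elif kind == "vesicle_shell":
        # outer leaflet heads out, inner leaflet heads in; water core remains
        thick_I = (lip_I.length - 1) * spacing
        thick_II = (lip_II.length - 1) * spacing
        r_core = max(2.0, 0.15 * L)
        r_inner_head = r_core
        # outer tail tips sit 0.5 rc outside the inner leaflet's outward tail
        # tips so the two leaflets form one connected shell
        r_outer_head = r_core + thick_II + 0.5 + thick_I
        if r_outer_head > L / 2 - 1.0:
            raise ValueError("box too small for the vesicle shell; enlarge the box or shorten chains")
        n_out = n_I
        n_in = n_II
        dirs_out = _fibonacci_sphere(max(n_out, 1))
        dirs_in = _fibonacci_sphere(max(n_in, 1))
        for c in range(n_out):
            head = center + r_outer_head * dirs_out[c]
            add_chain(lip_I, 0, head, -dirs_out[c])
        for c in range(n_in):
            head = center + r_inner_head * dirs_in[c]
            add_chain(lip_II, 1, head, dirs_in[c])
    elif kind == "stacked_discs":
        # discs normal to y, stacked with head layers of adjacent discs
        # within contact range; confined to a cylinder in the x-z plane
        n_discs = 3
        period = L / n_discs
        # half-thickness chosen so adjacent discs' head layers sit 0.8 rc
        # apart (head-to-head contact) and tails from both faces meet mid-disc
        half_thick = (period - 0.8) / 2.0
        radius = min(0.3 * L, L / 2 - 2.0)
        n_per_leaflet = max(1, (n_I + n_II) // (2 * n_discs))
        golden = math.pi * (1.0 + math.sqrt(5.0))
        placed = 0
        total = n_I + n_II
        for d in range(n_discs):
            y_mid = (d + 0.5) * period
            for sign in (+1.0, -1.0):
                for k in range(n_per_leaflet):
                    if placed >= total:
                        break
                    lip, tcode = (lip_I, 0) if placed < n_I else (lip_II, 1)
                    pitch = (half_thick - 0.2) / (lip.length - 1)
                    rr = radius * math.sqrt((k + 0.5) / n_per_leaflet)
                    th = golden * k
                    x = L / 2 + rr * math.cos(th)
                    z = L / 2 + rr * math.sin(th)
                    y_head = y_mid + sign * half_thick
                    head = np.array([x, y_head, z])
                    chains.append(
                        _straight_chain(head, np.array([0.0, -sign, 0.0]), lip.length, pitch)
                    )
                    chain_specs.append((lip, tcode))
                    placed += 1
    elif kind == "cylindrical_micelle":
        # chains radiate from the axis x=z=L/2 along y
        n = n_I + n_II
        golden = math.pi * (1.0 + math.sqrt(5.0))
        for c in range(n):
            lip, tcode = (lip_I, 0) if c < n_I else (lip_II, 1)
            y = (c + 0.5) * L / n
            th = golden * c
            u = np.array([math.cos(th), 0.0, math.sin(th)])
            r_out = 0.3 + (lip.length - 1) * spacing
            head = np.array([L / 2, y, L / 2]) + r_out * u
            add_chain(lip, tcode, head, -u)

    topo, lipid_codes = _build_topology(chain_specs, include_junction_angle)
    lipid_pos = np.vstack(chains) if chains else np.zeros((0, 3))
    system = _fill_water(lipid_pos, lipid_codes, spec)
    return system, topo
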