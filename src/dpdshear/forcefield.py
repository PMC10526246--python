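"""Model parameters for the coarse-grained two-lipid/water DPD system.

Everything here lives in reduced DPD units: the interaction cut-off ``rc`` is
the unit of length, ``kBT`` the unit of energy, the (common) bead mass ``m``
the unit of mass, and ``tau = rc * sqrt(m / kBT)`` the unit of time.  The
mapping to physical units (0.5 nm per rc, 1.88 ns per tau for this
lipid/water parameterization) is carried separately by :class:`UnitMap` and
never enters the dynamics.

Five bead species exist: head and tail beads of lipid type I (``H1``, ``T1``),
head and tail beads of type II (``H2``, ``T2``), and water (``W``).  Their
mutual soft repulsions ``a_ij`` encode hydrophilicity (head-water 40) and
hydrophobicity (tail-water 100); like beads repel with 25.  The repulsions map
linearly onto Flory-Huggins chi parameters, see :func:`flory_huggins_chi`.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field

import numpy as np

#: Canonical species ordering used for all integer species codes.
SPECIES: tuple[str, ...] = ("H1", "T1", "W", "H2", "T2")
SPECIES_INDEX: dict[str, int] = {s: i for i, s in enumerate(SPECIES)}

#: Linear coefficient of the repulsion -> Flory-Huggins mapping.
FLORY_COEFFICIENT = 0.286

_DEFAULT_OFFDIAG = {
    frozenset({"H1", "T1"}): 100.0,
    frozenset({"H1", "W"}): 40.0,
    frozenset({"H1", "H2"}): 25.0,
    frozenset({"H1", "T2"}): 100.0,
    frozenset({"T1", "W"}): 100.0,
    frozenset({"T1", "H2"}): 100.0,
    frozenset({"T1", "T2"}): 100.0,
    frozenset({"W", "H2"}): 40.0,
    frozenset({"W", "T2"}): 100.0,
    frozenset({"H2", "T2"}): 100.0,
}


def _default_matrix() -> np.ndarray:
    a = np.full((5, 5), 25.0)
    for pair, value in _DEFAULT_OFFDIAG.items():
        i, j = (SPECIES_INDEX[s] for s in pair)
        a[i, j] = a[j, i] = value
    a.setflags(write=False)
    return a


@dataclass(frozen=True)
class InteractionMatrix:
    """Symmetric 5x5 matrix of soft repulsion strengths ``a_ij``."""

    a: np.ndarray = field(default_factory=_default_matrix)

    def __post_init__(self) -> None:
        a = np.asarray(self.a, dtype=float)
        if a.shape != (5, 5):
            raise ValueError(f"interaction matrix must be 5x5, got {a.shape}")
        a = a.copy()
        a.setflags(write=False)
        object.__setattr__(self, "a", a)

    def __getitem__(self, pair: tuple[str, str]) -> float:
        i, j = pair
        return float(self.a[SPECIES_INDEX[i], SPECIES_INDEX[j]])

    def is_symmetric(self, tol: float = 0.0) -> bool:
        return bool(np.all(np.abs(self.a - self.a.T) <= tol))


@dataclass(frozen=True)
class BeadSpecies:
    """One of the five bead species; all beads share the unit mass."""

    label: str
    mass: float = 1.0

    def __post_init__(self) -> None:
        if self.label not in SPECIES:
            raise ValueError(f"unknown species {self.label!r}; expected one of {SPECIES}")


@dataclass(frozen=True)
class ForceFieldParams:
    """Complete reduced-unit parameter set for the DPD force field.

    The pair thermostat requires the fluctuation-dissipation relation
    ``sigma**2 == 2 * gamma * kBT``; :func:`validate` flags any set that
    breaks it.
    """

    aij: InteractionMatrix = field(default_factory=InteractionMatrix)
    gamma: float = 4.5
    sigma: float = 3.0
    kBT: float = 1.0
    rc: float = 1.0
    ks: float = 120.0
    rs: float = 0.7
    ktheta: float = 6.0
    theta0: float = math.pi
    dt: float = 0.01

    def replace(self, **changes) -> "ForceFieldParams":
        return dataclasses.replace(self, **changes)


def default_forcefield() -> ForceFieldParams:
    """The published parameter set: gamma=4.5, sigma=3.0, ks=120, rs=0.7 rc,
    ktheta=6, theta0=pi, dt=0.01 tau, and the standard repulsion matrix."""
    return ForceFieldParams()


def flory_huggins_chi(a_ij: float, a_ii: float) -> float:
    """Map a DPD repulsion to the Flory-Huggins chi: ``0.286 * (a_ij - a_ii)``.

    For the defaults this gives 4.29 for the head-water pair (40 vs 25) and
    21.45 for the tail-water pair (100 vs 25).
    """
    if a_ij < 0 or a_ii < 0:
        raise ValueError("repulsion strengths must be non-negative")
    return FLORY_COEFFICIENT * (a_ij - a_ii)


@dataclass(frozen=True)
class UnitMap:
    """Physical interpretation of the reduced units for this lipid model.

    ``tau_ns`` comes from matching in-plane lipid diffusion constants;
    ``rc_nm`` from the bead volume at density rho = 3 beads/rc^3 (the model
    quotes 0.5 nm even though (rho * VP)^(1/3) = 0.448 nm; the display value
    is stored as published).
    """

    tau_ns: float = 1.88
    rc_nm: float = 0.5
    bead_volume_nm3: float = 0.03
    density: float = 3.0


def map_to_physical(units: UnitMap, t_reduced: float) -> float:
    """Convert a duration in tau to nanoseconds."""
    if units.tau_ns <= 0:
        raise ValueError("tau_ns must be positive")
    return t_reduced * units.tau_ns


@dataclass(frozen=True)
class LipidSpec:
    """A linear amphiphile: ``n_head`` head beads followed by ``n_tail`` tail
    beads, all connected by harmonic bonds."""

    head_species: str
    tail_species: str
    n_head: int = 3
    n_tail: int = 2

    def __post_init__(self) -> None:
        for s in (self.head_species, self.tail_species):
            if s not in SPECIES:
                raise ValueError(f"unknown species {s!r}")
        if self.n_head < 1 or self.n_tail < 1:
            raise ValueError("head and tail blocks need at least one bead each")

    @property
    def length(self) -> int:
        return self.n_head + self.n_tail

    def species_codes(self) -> np.ndarray:
        codes = np.empty(self.length, dtype=np.int64)
        codes[: self.n_head] = SPECIES_INDEX[self.head_species]
        codes[self.n_head :] = SPECIES_INDEX[self.tail_species]
        return codes


def lipid_type_I(n_tail: int, n_head: int = 3) -> LipidSpec:
    return LipidSpec("H1", "T1", n_head, n_tail)


def lipid_type_II(n_tail: int, n_head: int = 3) -> LipidSpec:
    return LipidSpec("H2", "T2", n_head, n_tail)


def validate(params: ForceFieldParams, tol: float = 1e-9) -> list[str]:
    """Return the list of violated invariants (empty when the set is valid)."""
    violations: list[str] = []
    if abs(params.sigma**2 - 2.0 * params.gamma * params.kBT) > tol:
        violations.append(
            "fluctuation-dissipation: sigma^2 != 2*gamma*kBT "
            f"({params.sigma**2:g} vs {2 * params.gamma * params.kBT:g})"
        )
    if not params.aij.is_symmetric():
        violations.append("symmetry: interaction matrix is not symmetric")
    diag = np.diag(params.aij.a)
    if not np.all(diag == diag[0]):
        violations.append("diagonal: like-pair repulsions are not all equal")
    if not (0 < params.rs <= params.rc):
        violations.append(f"bond length: rs={params.rs:g} outside (0, rc={params.rc:g}]")
    if params.dt <= 0:
        violations.append("time step: dt must be positive")
    if params.rc <= 0:
        violations.append("cutoff: rc must be positive")
    if params.ks < 0 or params.ktheta < 0:
        violations.append("stiffness: ks and ktheta must be non-negative")
    return violations
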