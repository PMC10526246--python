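"""DPD integrator: soft pair forces, bonded forces, and the pair thermostat.

Newton's equations are advanced with the Groot-Warren modified velocity-Verlet
scheme (lambda = 1/2): positions update with the current force, the
dissipative force at the new positions is evaluated with a half-step velocity
prediction, and the velocity completes with the mean of old and new forces.
One force evaluation per step.

Forces are pairwise antisymmetric (including the shared-noise random term),
so total momentum is conserved to floating-point accumulation error; the
dissipative/random pair satisfies fluctuation-dissipation, thermostatting the
system to kBT = 1 with the small, well-known O(dt) temperature offset of DPD.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from . import _kernels
from .builder import ParticleSystem, Topology, minimum_image
from .forcefield import ForceFieldParams


def weight(rij: float | np.ndarray, rc: float) -> float | np.ndarray:
    """DPD weight function: 1 - r/rc inside the cutoff, 0 outside."""
    w = 1.0 - np.asarray(rij, dtype=float) / rc
    w = np.where(np.asarray(rij) < rc, w, 0.0)
    if np.ndim(rij) == 0:
        return float(w)
    return w


def compute_temperature(system: ParticleSystem) -> float:
    """Instantaneous kinetic temperature 2*KE/(3N) in reduced units.

    No constraint correction is applied for the zeroed total momentum; for
    the bead counts used here the 3/(3N) correction is far below the
    thermostat's own dt-dependent offset.
    """
    v = system.velocities
    return float(np.sum(v * v) / (3 * system.n_beads))


@dataclass(frozen=True)
class EnergyReport:
    """Per-step observables in reduced units."""

    step: int
    time: float
    kinetic: float
    potential_pair: float
    potential_bond: float
    potential_angle: float
    temperature: float

    @property
    def potential(self) -> float:
        return self.potential_pair + self.potential_bond + self.potential_angle

    @property
    def total(self) -> float:
        return self.kinetic + self.potential


class NonFiniteStateError(RuntimeError):
    pass


def _check_finite(system: ParticleSystem, step: int) -> None:
    if not (np.all(np.isfinite(system.positions)) and np.all(np.isfinite(system.velocities))):
        raise NonFiniteStateError(
            f"non-finite positions/velocities at step {step}; "
            "the time step may be too large for the current forces"
        )


_EMPTY_BONDS = np.zeros((0, 2), dtype=np.int64)
_EMPTY_ANGLES = np.zeros((0, 3), dtype=np.int64)


def _call_kernel(system, ff, bonds, angles, seed, step, gaussian, velocities=None):
    vel = system.velocities if velocities is None else velocities
    f, e_pair, e_bond, e_angle, err = _kernels.compute_forces(
        system.positions,
        vel,
        system.species,
        float(system.box),
        np.asarray(ff.aij.a, dtype=float),
        float(ff.gamma),
        float(ff.sigma),
        float(ff.rc),
        float(ff.ks),
        float(ff.rs),
        float(ff.ktheta),
        float(ff.theta0),
        1.0 / math.sqrt(ff.dt),
        np.ascontiguousarray(bonds, dtype=np.int64).reshape(-1, 2),
        np.ascontiguousarray(angles, dtype=np.int64).reshape(-1, 3),
        int(seed),
        int(step),
        bool(gaussian),
    )
    if err == 1:
        raise ZeroDivisionError("bond with zero length: force direction undefined")
    if err == 2:
        raise ZeroDivisionError("angle with a zero-length arm: geometry degenerate")
    return f, e_pair, e_bond, e_angle


def pair_forces(
    system: ParticleSystem,
    ff: ForceFieldParams,
    seed: int = 0,
    step: int = 0,
    gaussian: bool = False,
) -> tuple[np.ndarray, float]:
    """Non-bonded DPD forces (conservative + dissipative + random) and the
    accumulated conservative pair energy."""
    _check_finite(system, step)
    f, e_pair, _, _ = _call_kernel(system, ff, _EMPTY_BONDS, _EMPTY_ANGLES, seed, step, gaussian)
    return f, e_pair


def _bonded_only_ff(ff: ForceFieldParams) -> ForceFieldParams:
    from .forcefield import InteractionMatrix

    return ff.replace(aij=InteractionMatrix(np.zeros((5, 5))), sigma=0.0, gamma=0.0)


def bond_forces(system: ParticleSystem, topo: Topology, ff: ForceFieldParams) -> tuple[np.ndarray, float]:
    """Harmonic bond forces ks*(1 - r/rs) along rhat and their energy."""
    f, _, e_bond, _ = _call_kernel(
        system, _bonded_only_ff(ff), topo.bonds, _EMPTY_ANGLES, 0, 0, False
    )
    return f, e_bond


def angle_forces(system: ParticleSystem, topo: Topology, ff: ForceFieldParams) -> tuple[np.ndarray, float]:
    """Bending forces, the negative gradient of ktheta*(theta - theta0)^2."""
    f, _, _, e_angle = _call_kernel(
        system, _bonded_only_ff(ff), _EMPTY_BONDS, topo.angles, 0, 0, False
    )
    return f, e_angle


def forces_reference(
    system: ParticleSystem,
    topo: Topology,
    ff: ForceFieldParams,
    seed: int = 0,
    step: int = 0,
    gaussian: bool = False,
) -> tuple[np.ndarray, float, float, float]:
    """O(N^2) all-pairs force evaluation in plain numpy.

    Independent of the cell-list path (no shared pair enumeration); uses the
    same counter-based noise so results must agree to rounding error.
    """
    pos, vel, spec = system.positions, system.velocities, system.species
    N, L, rc = system.n_beads, system.box, ff.rc
    f = np.zeros((N, 3))
    e_pair = 0.0
    inv_sqrt_dt = 1.0 / math.sqrt(ff.dt)
    a = ff.aij.a
    for i in range(N):
        for j in range(i + 1, N):
            d = minimum_image(pos[i] - pos[j], L)
            r = math.sqrt(float(d @ d))
            if r >= rc or r == 0.0:
                continue
            w = 1.0 - r / rc
            e = d / r
            vdotr = float((vel[i] - vel[j]) @ e)
            zeta = _kernels.pair_noise(seed, step, i, j, gaussian)
            fmag = (
                a[spec[i], spec[j]] * w
                - ff.gamma * w * w * vdotr
                + ff.sigma * w * zeta * inv_sqrt_dt
            )
            f[i] += fmag * e
            f[j] -= fmag * e
            e_pair += 0.5 * a[spec[i], spec[j]] * rc * w * w
    e_bond = 0.0
    for i, j in topo.bonds:
        d = minimum_image(pos[i] - pos[j], L)
        r = math.sqrt(float(d @ d))
        fmag = ff.ks * (1.0 - r / ff.rs)
        f[i] += fmag * d / r
        f[j] -= fmag * d / r
        e_bond += 0.5 * ff.ks / ff.rs * (r - ff.rs) ** 2
    e_angle = 0.0
    for i, j, k in topo.angles:
        d1 = minimum_image(pos[i] - pos[j], L)
        d2 = minimum_image(pos[k] - pos[j], L)
        r1, r2 = np.linalg.norm(d1), np.linalg.norm(d2)
        c = float(np.clip(d1 @ d2 / (r1 * r2), -1.0, 1.0))
        s = max(math.sqrt(1.0 - c * c), 1e-12)
        dtheta = math.acos(c) - ff.theta0
        e_angle += ff.ktheta * dtheta**2
        acoef = -2.0 * ff.ktheta * dtheta / s
        f1 = (acoef * c / r1**2) * d1 + (-acoef / (r1 * r2)) * d2
        f3 = (acoef * c / r2**2) * d2 + (-acoef / (r1 * r2)) * d1
        f[i] += f1
        f[k] += f3
        f[j] -= f1 + f3
    return f, e_pair, e_bond, e_angle


@dataclass
class RunResult:
    """Energy series and periodic snapshots from :meth:`Simulation.run`."""

    reports: list[EnergyReport] = field(default_factory=list)
    frames: list[ParticleSystem] = field(default_factory=list)
    ledger: "object | None" = None  # SwapLedger when shear was active

    def energy_array(self) -> np.ndarray:
        """(n, 8) array: step, time, KE, PE_pair, PE_bond, PE_angle, total, kBT."""
        return np.array(
            [
                (r.step, r.time, r.kinetic, r.potential_pair, r.potential_bond,
                 r.potential_angle, r.total, r.temperature)
                for r in self.reports
            ]
        )


class Simulation:
    """Owns the mutable state of one trajectory.

    Parameters are immutable once the simulation starts; the ``seed`` fixes
    the entire noise stream, so two simulations built from the same inputs
    produce bitwise-identical trajectories on the same platform.
    """

    def __init__(
        self,
        system: ParticleSystem,
        topology: Topology | None,
        ff: ForceFieldParams,
        seed: int = 0,
        gaussian_noise: bool = False,
    ):
        self.system = system
        self.topology = topology if topology is not None else Topology.empty()
        self.ff = ff
        self.seed = int(seed) & 0x7FFFFFFFFFFFFFFF
        self.gaussian_noise = gaussian_noise
        self.step_count = 0
        self._forces: np.ndarray | None = None
        self._energies: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def _evaluate(self, velocities: np.ndarray) -> None:
        f, e_pair, e_bond, e_angle = _call_kernel(
            self.system,
            self.ff,
            self.topology.bonds,
            self.topology.angles,
            self.seed,
            self.step_count,
            self.gaussian_noise,
            velocities=velocities,
        )
        self._forces = f
        self._energies = (e_pair, e_bond, e_angle)

    def report(self) -> EnergyReport:
        e_pair, e_bond, e_angle = self._energies
        ke = 0.5 * float(np.sum(self.system.velocities**2))
        return EnergyReport(
            step=self.step_count,
            time=self.system.time,
            kinetic=ke,
            potential_pair=e_pair,
            potential_bond=e_bond,
            potential_angle=e_angle,
            temperature=2.0 * ke / (3.0 * self.system.n_beads),
        )

    def integrate_step(self) -> EnergyReport:
        """One modified velocity-Verlet step of length dt."""
        sys_ = self.system
        dt = self.ff.dt
        _check_finite(sys_, self.step_count)
        if self._forces is None:
            self._evaluate(sys_.velocities)
        f_old = self._forces
        sys_.positions += dt * sys_.velocities + 0.5 * dt * dt * f_old
        sys_.wrap()
        v_pred = sys_.velocities + 0.5 * dt * f_old  # lambda = 1/2 prediction
        self.step_count += 1
        self._evaluate(v_pred)
        sys_.velocities += 0.5 * dt * (f_old + self._forces)
        sys_.time += dt
        return self.report()

    def run(
        self,
        n_steps: int,
        shear=None,
        sample_every: int = 100,
        frame_every: int | None = None,
        ledger=None,
    ) -> RunResult:
        """Advance ``n_steps``, optionally applying momentum-swap shear.

        ``shear`` is a :class:`~dpdshear.shear.ShearProtocol`; swaps happen
        every ``shear.swap_every`` steps.  Energy reports are recorded every
        ``sample_every`` steps and snapshots every ``frame_every`` (defaults
        to ``sample_every``).
        """
        from .shear import SwapLedger, swap_momenta

        if n_steps < 0:
            raise ValueError("n_steps must be >= 0")
        if frame_every is None:
            frame_every = sample_every
        result = RunResult()
        if shear is not None:
            result.ledger = ledger if ledger is not None else SwapLedger()
        for k in range(n_steps):
            if shear is not None and self.step_count % shear.swap_every == 0:
                swap_momenta(self.system, shear, result.ledger)
            rep = self.integrate_step()
            if result.ledger is not None:
                result.ledger.elapsed += self.ff.dt
            if self.step_count % sample_every == 0:
                result.reports.append(rep)
            if self.step_count % frame_every == 0:
                result.frames.append(self.system.copy())
        return result
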