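"""Desk-scale stochastic dynamics and titration-curve recovery.

A minimal constant-volume Langevin (BAOAB) integrator over the package's
nonbonded potential, plus simple harmonic restraints, used to validate the
pH-scaled force field on toy systems: the end-to-end check is that sampling
a one-site toy system across a pH grid recovers the input pKa as the
midpoint of the simulated binding curve.

Units: Å, kcal/mol, amu, fs, K. Internally time is converted to the AKMA
unit (≈48.888 fs) so that accelerations come out in Å per AKMA-time² from
forces in kcal/mol/Å and masses in amu.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Protocol, Sequence

import numpy as np
from scipy.optimize import least_squares

from .energy import nonbonded_energy_and_forces, _pair_list
from .errors import (
    InvalidParameterError,
    UnderdeterminedFitError,
    UnstableIntegrationError,
)
from .forcefield import ScaledSystem
from .structure import Structure, TrajectoryEnsemble
from .titration import TitratableSite, TitrationParameters, assign_site_lambdas

__all__ = [
    "BOLTZMANN_KCAL",
    "Potential",
    "NonbondedPotential",
    "HarmonicAnchor",
    "SphericalWall",
    "AxisRestraint",
    "CompositePotential",
    "langevin_sample",
    "ToyTitrationSystem",
    "ToyTitrationResult",
    "simulate_titration_curve",
]

#: Boltzmann constant, kcal/(mol·K).
BOLTZMANN_KCAL = 0.0019872041

#: One AKMA time unit in femtoseconds.
AKMA_TIME_FS = 48.88821291

#: Atomic masses (amu) by element symbol; unknown elements fall back to 12.
ATOMIC_MASSES = {"H": 1.008, "C": 12.011, "N": 14.007, "O": 15.999, "S": 32.06,
                 "P": 30.974, "X": 12.0}

_FORCE_OVERFLOW = 1e6  # kcal/mol/Å; beyond this the integration has blown up


class Potential(Protocol):
    def energy_and_forces(self, coords: np.ndarray) -> tuple[float, np.ndarray]:
        """Potential energy (kcal/mol) and forces (kcal/mol/Å)."""
        ...


class NonbondedPotential:
    """The package's switched nonbonded potential as a sampler target.

    For small systems the non-excluded pair list is precomputed once
    (``static_pairs=True``); pairs drifting beyond the cutoff still
    contribute zero through the switching envelope.
    """

    def __init__(
        self,
        system: ScaledSystem,
        cutoff: float = 12.0,
        switch_on: float = 10.0,
        static_pairs: bool = False,
        initial_coords: np.ndarray | None = None,
    ) -> None:
        self.system = system
        self.cutoff = cutoff
        self.switch_on = switch_on
        self._pairs = None
        if static_pairs:
            coords = (
                np.asarray(initial_coords, float)
                if initial_coords is not None
                else system.structure.coords
            )
            # generous margin so the cached list stays valid while atoms move
            self._pairs = _pair_list(coords, system, cutoff + 1e6)

    def energy_and_forces(self, coords: np.ndarray) -> tuple[float, np.ndarray]:
        breakdown, forces = nonbonded_energy_and_forces(
            coords, self.system, self.cutoff, self.switch_on, pairs=self._pairs
        )
        return breakdown.total, forces


@dataclass
class HarmonicAnchor:
    """U = ½ k Σ |x_i − x0_i|² over the anchored atoms."""

    indices: np.ndarray
    anchors: np.ndarray  # (len(indices), 3)
    k: float  # kcal/mol/Å²

    def energy_and_forces(self, coords):
        d = coords[self.indices] - self.anchors
        forces = np.zeros_like(coords)
        forces[self.indices] = -self.k * d
        return 0.5 * self.k * float(np.sum(d * d)), forces


@dataclass
class SphericalWall:
    """Flat-bottom harmonic wall: U = ½ k (|x−c| − R)² outside radius R."""

    center: np.ndarray
    radius: float
    k: float
    indices: np.ndarray | None = None  # default: all atoms

    def energy_and_forces(self, coords):
        idx = np.arange(len(coords)) if self.indices is None else self.indices
        d = coords[idx] - self.center
        r = np.linalg.norm(d, axis=1)
        over = r > self.radius
        forces = np.zeros_like(coords)
        e = 0.0
        if np.any(over):
            exc = r[over] - self.radius
            e = 0.5 * self.k * float(np.sum(exc * exc))
            unit = d[over] / r[over, None]
            forces[idx[over]] = -self.k * exc[:, None] * unit
        return e, forces


@dataclass
class AxisRestraint:
    """Harmonic confinement of selected atoms to the x-axis (restrains y, z)."""

    indices: np.ndarray
    k: float

    def energy_and_forces(self, coords):
        forces = np.zeros_like(coords)
        yz = coords[self.indices][:, 1:]
        forces[self.indices, 1:] = -self.k * yz
        return 0.5 * self.k * float(np.sum(yz * yz)), forces


@dataclass
class CompositePotential:
    terms: list

    def energy_and_forces(self, coords):
        total = 0.0
        forces = np.zeros_like(coords)
        for term in self.terms:
            e, f = term.energy_and_forces(coords)
            total += e
            forces += f
        return total, forces


def masses_for(structure: Structure) -> np.ndarray:
    return np.array(
        [ATOMIC_MASSES.get(str(e).upper(), 12.0) for e in structure.element]
    )


def langevin_sample(
    system: ScaledSystem | Potential,
    coords0: np.ndarray,
    n_steps: int,
    dt: float = 2.0,
    temperature: float = 310.0,
    friction: float = 5.0,
    seed: int = 0,
    stride: int = 10,
    masses: np.ndarray | None = None,
    fixed_atoms: np.ndarray | None = None,
    topology: Structure | None = None,
    ph_label: float = float("nan"),
) -> TrajectoryEnsemble:
    """Sample configurations with BAOAB Langevin dynamics.

    Parameters: ``dt`` in fs (default 2), ``temperature`` in K (default
    310), ``friction`` in ps⁻¹. ``fixed_atoms`` freezes a boolean mask of
    atoms (their coordinates never move). Identical seeds give bit-identical
    trajectories. Frames are recorded every ``stride`` steps.
    """
    if isinstance(system, ScaledSystem):
        potential: Potential = NonbondedPotential(
            system, static_pairs=system.n_atoms <= 256, initial_coords=coords0
        )
        topology = topology or system.structure
        if masses is None:
            masses = masses_for(system.structure)
    else:
        potential = system
    coords = np.array(coords0, dtype=float)
    n = len(coords)
    if masses is None:
        masses = np.full(n, 12.0)
    masses = np.asarray(masses, float)
    if topology is None:
        topology = Structure(
            ["A"] * n, np.arange(1, n + 1), ["BEA"] * n,
            [f"X{i+1}" for i in range(n)], ["X"] * n, coords,
        )
    mobile = (
        np.ones(n, dtype=bool) if fixed_atoms is None else ~np.asarray(fixed_atoms)
    )

    rng = np.random.default_rng(seed)
    h = dt / AKMA_TIME_FS  # AKMA time step
    gamma = friction * 1e-3 * AKMA_TIME_FS  # ps⁻¹ → AKMA⁻¹
    kt = BOLTZMANN_KCAL * temperature
    c1 = np.exp(-gamma * h)
    c2 = np.sqrt(max(kt, 0.0) * (1.0 - c1 * c1))
    inv_m = 1.0 / masses[:, None]

    vel = np.zeros((n, 3))
    if temperature > 0:
        vel = rng.normal(size=(n, 3)) * np.sqrt(kt / masses)[:, None]
    vel[~mobile] = 0.0

    _, forces = potential.energy_and_forces(coords)
    frames = [coords.copy()]
    for step in range(1, n_steps + 1):
        if not np.all(np.isfinite(forces)) or np.max(np.abs(forces)) > _FORCE_OVERFLOW:
            raise UnstableIntegrationError(step)
        vel[mobile] += 0.5 * h * (forces * inv_m)[mobile]
        coords[mobile] += 0.5 * h * vel[mobile]
        noise = rng.normal(size=(n, 3))  # drawn for all atoms: seed-stable layout
        vel[mobile] = c1 * vel[mobile] + c2 * (noise / np.sqrt(masses)[:, None])[mobile]
        coords[mobile] += 0.5 * h * vel[mobile]
        _, forces = potential.energy_and_forces(coords)
        vel[mobile] += 0.5 * h * (forces * inv_m)[mobile]
        if step % stride == 0:
            frames.append(coords.copy())

    return TrajectoryEnsemble(
        topology=topology,
        frames=np.array(frames),
        ph_label=ph_label,
        frame_stride_ps=stride * dt * 1e-3,
    )


# --- toy titration ----------------------------------------------------------


@dataclass
class ToyTitrationSystem:
    """A one-site toy construct for end-to-end pKa recovery.

    A mobile probe bead diffuses between two oppositely weighted attractor
    sites whose charges interpolate with λ: site A carries the protonated-
    state attraction (∝ λ), site B the deprotonated one (∝ 1−λ). "Bound"
    means the probe sits within ``bound_cutoff`` of the site-A anchor atom,
    so the mean bound fraction traces λ and the binding curve's midpoint
    estimates the input pKa.
    """

    structure: Structure
    templates: dict
    sites: list[TitratableSite]
    pka: float
    probe_index: int
    anchor_index: int  # site-A reference atom for the distance criterion
    bound_cutoff: float  # Å
    restraints: list = field(default_factory=list)
    cutoff: float = 12.0
    switch_on: float = 10.0


@dataclass
class ToyTitrationResult:
    ph_grid: list[float]
    bound_fraction: list[float]
    fitted_midpoint: float
    seed: int


def _fit_sigmoid_midpoint(ph: np.ndarray, frac: np.ndarray) -> float:
    def resid(m):
        return 1.0 / (1.0 + 10.0 ** (ph - m[0])) - frac

    sol = least_squares(resid, x0=[float(np.median(ph))])
    return float(sol.x[0])


def simulate_titration_curve(
    toy: ToyTitrationSystem,
    ph_grid: Sequence[float],
    n_steps: int = 240_000,
    seed: int = 0,
    dt: float = 2.0,
    temperature: float = 310.0,
    friction: float = 5.0,
    stride: int = 40,
    burn_in: float = 0.2,
    params: TitrationParameters | None = None,
) -> ToyTitrationResult:
    """Run the full ECpH chain on the toy system over a pH grid.

    For each pH: assign λ from the Hill equation, build the effective
    system, neutralize, sample with Langevin dynamics (only the probe
    moves), and record the fraction of post-burn-in frames with the probe
    bound. The sigmoid 1/(1+10^(pH−m)) is then least-squares fitted to the
    bound fractions; ``fitted_midpoint`` is the recovered pKa.
    """
    from .forcefield import build_effective_system
    from .neutralize import neutralize

    ph_grid = [float(p) for p in ph_grid]
    if len(ph_grid) < 4:
        raise UnderdeterminedFitError(
            f"need at least 4 pH grid points to fit a midpoint, got {len(ph_grid)}"
        )
    if n_steps < 1:
        raise InvalidParameterError("n_steps must be positive")

    overrides = {toy.sites[0].key: toy.pka}
    fixed = np.ones(toy.structure.n_atoms, dtype=bool)
    fixed[toy.probe_index] = False

    fractions: list[float] = []
    for k, ph in enumerate(ph_grid):
        sites = assign_site_lambdas(toy.sites, ph, params, overrides)
        system = build_effective_system(toy.structure, ph, toy.templates, sites)
        system, _ = neutralize(system, target_net_charge=system.net_charge)
        nb = NonbondedPotential(
            system, toy.cutoff, toy.switch_on, static_pairs=True,
            initial_coords=toy.structure.coords,
        )
        potential = CompositePotential([nb, *toy.restraints])
        traj = langevin_sample(
            potential,
            toy.structure.coords,
            n_steps,
            dt=dt,
            temperature=temperature,
            friction=friction,
            seed=(seed * 1009 + k) % (2**31),
            stride=stride,
            masses=masses_for(toy.structure),
            fixed_atoms=fixed,
            topology=toy.structure,
            ph_label=ph,
        )
        start = int(burn_in * traj.n_frames)
        d = np.linalg.norm(
            traj.frames[start:, toy.probe_index] - traj.frames[start:, toy.anchor_index],
            axis=1,
        )
        fractions.append(float(np.mean(d <= toy.bound_cutoff)))

    midpoint = _fit_sigmoid_midpoint(np.array(ph_grid), np.array(fractions))
    return ToyTitrationResult(ph_grid, fractions, midpoint, seed)
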