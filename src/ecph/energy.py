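"""Reference nonbonded energy evaluator.

Pairwise Coulomb + 12-6 Lennard-Jones over all non-excluded pairs, with the
CHARMM energy-switching function tapering each pair energy smoothly to zero
between the switch-on distance (default 10 Å) and the cutoff (default 12 Å):

    S(r) = 1                                                  r ≤ r_on
    S(r) = (r_c²−r²)² (r_c²+2r²−3r_on²) / (r_c²−r_on²)³       r_on < r < r_c
    S(r) = 0                                                  r ≥ r_c

S is C¹: both S and dS/dr are continuous at r_on and r_c. Lennard-Jones
parameters combine by Lorentz–Berthelot (σ_ij arithmetic mean, ε_ij
geometric mean), which is also what makes parameter-level λ-scaling of
titratable protons (charge λ·q, ε as λ²·ε) reproduce pair energies scaled
by λ.

Two evaluation paths are provided: :func:`nonbonded_energy` (neighbor list
via a k-d tree, vectorized — the production path) and
:func:`brute_force_nonbonded_energy` (explicit double loop over the scalar
pair formulas — the independent reference used for cross-validation).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .errors import InvalidParameterError, SingularGeometryError
from .forcefield import (
    COULOMB_CONSTANT,
    ScaledSystem,
    scaled_electrostatic_energy,
    scaled_lj_energy,
)

__all__ = [
    "EnergyBreakdown",
    "switching_function",
    "nonbonded_energy",
    "brute_force_nonbonded_energy",
    "nonbonded_energy_and_forces",
]

#: Pair distances below this (Å) on a non-excluded pair are treated as a
#: singular geometry.
OVERLAP_TOLERANCE = 1e-6


@dataclass
class EnergyBreakdown:
    electrostatic: float  # kcal/mol
    lennard_jones: float  # kcal/mol
    total: float  # kcal/mol
    n_pairs_evaluated: int


def switching_function(r: np.ndarray | float, switch_on: float, cutoff: float):
    """CHARMM energy switching factor S(r) and its derivative dS/dr."""
    r = np.asarray(r, dtype=float)
    c2, o2 = cutoff * cutoff, switch_on * switch_on
    denom = (c2 - o2) ** 3
    a = c2 - r * r
    b = c2 + 2.0 * r * r - 3.0 * o2
    s = np.where(r <= switch_on, 1.0, np.where(r >= cutoff, 0.0, a * a * b / denom))
    ds = np.where(
        (r > switch_on) & (r < cutoff), 4.0 * r * a * (a - b) / denom, 0.0
    )
    return s, ds


def _check_cutoffs(cutoff: float, switch_on: float) -> None:
    if not (cutoff > switch_on > 0):
        raise InvalidParameterError(
            f"require cutoff > switch_on > 0, got cutoff={cutoff}, switch_on={switch_on}"
        )


def _pair_list(coords: np.ndarray, system: ScaledSystem, cutoff: float):
    """Non-excluded atom pairs within the cutoff, as index arrays."""
    tree = cKDTree(coords)
    pairs = tree.query_pairs(cutoff, output_type="ndarray")
    if pairs.size == 0:
        return np.empty((0, 2), dtype=int)
    if system.exclusions:
        excl = np.array(sorted(system.exclusions), dtype=int)
        # encode (i, j) with i < j as a single integer for set-difference
        n = system.n_atoms
        lo = np.minimum(pairs[:, 0], pairs[:, 1])
        hi = np.maximum(pairs[:, 0], pairs[:, 1])
        keep = ~np.isin(lo * n + hi, excl[:, 0] * n + excl[:, 1])
        pairs = np.column_stack([lo[keep], hi[keep]])
    return pairs


def _pair_terms(coords, system, pairs, switch_on, cutoff):
    """Switched per-pair electrostatic and LJ energies plus geometry terms."""
    i, j = pairs[:, 0], pairs[:, 1]
    dvec = coords[i] - coords[j]
    r = np.linalg.norm(dvec, axis=1)
    if np.any(r < OVERLAP_TOLERANCE):
        k = int(np.argmin(r))
        raise SingularGeometryError(
            f"atoms {i[k]} and {j[k]} overlap (r = {r[k]:.2e} Å)"
        )
    qq = system.charges[i] * system.charges[j]
    u_elec = COULOMB_CONSTANT * qq / r
    sig = 0.5 * (system.lj_sigma[i] + system.lj_sigma[j])
    eps = np.sqrt(system.lj_epsilon[i] * system.lj_epsilon[j])
    with np.errstate(divide="ignore", invalid="ignore"):
        sr6 = np.where(eps > 0, (sig / r) ** 6, 0.0)
    u_lj = 4.0 * eps * (sr6 * sr6 - sr6)
    s, ds = switching_function(r, switch_on, cutoff)
    return i, j, dvec, r, u_elec, u_lj, s, ds, eps, sr6


def nonbonded_energy(
    coords: np.ndarray,
    system: ScaledSystem,
    cutoff: float = 12.0,
    switch_on: float = 10.0,
) -> EnergyBreakdown:
    """Total nonbonded energy of one configuration (kcal/mol)."""
    _check_cutoffs(cutoff, switch_on)
    coords = np.asarray(coords, dtype=float).reshape(system.n_atoms, 3)
    pairs = _pair_list(coords, system, cutoff)
    if len(pairs) == 0:
        return EnergyBreakdown(0.0, 0.0, 0.0, 0)
    _, _, _, _, u_elec, u_lj, s, _, _, _ = _pair_terms(
        coords, system, pairs, switch_on, cutoff
    )
    e_elec = float(np.sum(s * u_elec))
    e_lj = float(np.sum(s * u_lj))
    return EnergyBreakdown(e_elec, e_lj, e_elec + e_lj, int(len(pairs)))


def brute_force_nonbonded_energy(
    coords: np.ndarray,
    system: ScaledSystem,
    cutoff: float = 12.0,
    switch_on: float = 10.0,
) -> EnergyBreakdown:
    """O(N²) double-loop reference evaluation over the scalar pair formulas.

    Independent of the neighbor-listed path; used to cross-validate it.
    """
    _check_cutoffs(cutoff, switch_on)
    coords = np.asarray(coords, dtype=float).reshape(system.n_atoms, 3)
    e_elec = e_lj = 0.0
    n_pairs = 0
    for i in range(system.n_atoms):
        for j in range(i + 1, system.n_atoms):
            if (i, j) in system.exclusions:
                continue
            r = float(np.linalg.norm(coords[i] - coords[j]))
            if r >= cutoff:
                continue
            if r < OVERLAP_TOLERANCE:
                raise SingularGeometryError(
                    f"atoms {i} and {j} overlap (r = {r:.2e} Å)"
                )
            n_pairs += 1
            s = float(switching_function(r, switch_on, cutoff)[0])
            e_elec += s * scaled_electrostatic_energy(
                1.0, system.charges[i], system.charges[j], r
            )
            sig = 0.5 * (system.lj_sigma[i] + system.lj_sigma[j])
            eps = float(np.sqrt(system.lj_epsilon[i] * system.lj_epsilon[j]))
            e_lj += s * scaled_lj_energy(1.0, sig, eps, r)
    return EnergyBreakdown(e_elec, e_lj, e_elec + e_lj, n_pairs)


def nonbonded_energy_and_forces(
    coords: np.ndarray,
    system: ScaledSystem,
    cutoff: float = 12.0,
    switch_on: float = 10.0,
    pairs: np.ndarray | None = None,
) -> tuple[EnergyBreakdown, np.ndarray]:
    """Energy plus analytic forces (kcal/mol/Å) for dynamics.

    ``pairs`` may be a precomputed non-excluded pair list (e.g. for small
    systems sampled repeatedly); otherwise the neighbor list is rebuilt.
    d(S·U)/dr = S'·U + S·U' for each pair, directed along the pair vector.
    """
    _check_cutoffs(cutoff, switch_on)
    coords = np.asarray(coords, dtype=float).reshape(system.n_atoms, 3)
    if pairs is None:
        pairs = _pair_list(coords, system, cutoff)
    forces = np.zeros_like(coords)
    if len(pairs) == 0:
        return EnergyBreakdown(0.0, 0.0, 0.0, 0), forces
    i, j, dvec, r, u_elec, u_lj, s, ds, eps, sr6 = _pair_terms(
        coords, system, pairs, switch_on, cutoff
    )
    in_range = r < cutoff
    du_elec = -u_elec / r
    du_lj = 4.0 * eps * (-12.0 * sr6 * sr6 + 6.0 * sr6) / r
    dudr = np.where(in_range, ds * (u_elec + u_lj) + s * (du_elec + du_lj), 0.0)
    fpair = (-dudr / r)[:, None] * dvec  # force on atom i
    np.add.at(forces, i, fpair)
    np.add.at(forces, j, -fpair)
    e_elec = float(np.sum(np.where(in_range, s * u_elec, 0.0)))
    e_lj = float(np.sum(np.where(in_range, s * u_lj, 0.0)))
    return (
        EnergyBreakdown(e_elec, e_lj, e_elec + e_lj, int(np.sum(in_range))),
        forces,
    )
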