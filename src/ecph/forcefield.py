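"""pH-scaled effective nonbonded parameters.

The core of the ECpH scheme: with the system topology fixed (no protons ever
added or removed), the presence of each titratable proton is encoded by
scaling its nonbonded interactions by the site's protonation probability λ,

    U_elec(λ, r_ij) = λ · k_C · q_i q_j / r_ij
    U_LJ(λ, r_ij)   = λ · 4 ε_ij [ (σ_ij/r_ij)^12 − (σ_ij/r_ij)^6 ],

and the partial charges of the remaining atoms of the titratable residue are
interpolated linearly between their protonated and deprotonated template
values by the same λ:

    q(λ) = q_prot − (1 − λ) · Δq_prot→deprot .

At λ = 1 the residue is exactly its protonated template; at λ = 0 the proton
becomes a zero-charge, zero-ε ghost particle (keeping its bonded terms and
mass, so particle count and kinetic energy are pH-independent) and every
other atom carries its deprotonated charge.

Scaling is applied at the *parameter* level so that any standard pairwise
evaluator produces the λ-scaled energies: the proton's charge is stored as
λ·q_prot, and its Lennard-Jones ε as λ²·ε_prot, which under Lorentz–Berthelot
combination (ε_ij = √(ε_i ε_j)) scales each proton–environment pair energy
by exactly λ. Only nonbonded terms are touched; bonded terms and masses are
λ-independent.

Units: charges in elementary charge e, distances in Å, energies in kcal/mol.
The Coulomb constant is the CHARMM convention 332.0636 kcal·Å/(mol·e²).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .errors import (
    InvalidGeometryError,
    InvalidParameterError,
    MissingProtonError,
    UnparameterizedResidueError,
)
from .structure import Structure
from .titration import TitratableSite

__all__ = [
    "COULOMB_CONSTANT",
    "AtomParameters",
    "ResidueTemplate",
    "ResidueTemplatePair",
    "ScaledSystem",
    "scaled_electrostatic_energy",
    "scaled_lj_energy",
    "interpolated_charge",
    "infer_bonds",
    "connectivity_exclusions",
    "build_effective_system",
]

#: Coulomb constant k_C in kcal·Å/(mol·e²), CHARMM convention.
COULOMB_CONSTANT = 332.0636

#: Residue names recognised as water when locating solvent molecules.
WATER_RESNAMES = frozenset({"HOH", "WAT", "TIP3", "SOL", "TIP3P"})


@dataclass
class AtomParameters:
    """Nonbonded parameters of one atom: partial charge (e), LJ σ (Å) and
    ε (kcal/mol), and whether the atom is a titratable proton."""

    atom_name: str
    partial_charge: float
    lj_sigma: float
    lj_epsilon: float
    is_titratable_proton: bool = False

    def __post_init__(self) -> None:
        if self.lj_epsilon < 0:
            raise InvalidParameterError(f"{self.atom_name}: LJ epsilon must be >= 0")
        if self.lj_epsilon > 0 and self.lj_sigma <= 0:
            raise InvalidParameterError(
                f"{self.atom_name}: LJ sigma must be > 0 when epsilon > 0"
            )


@dataclass
class ResidueTemplate:
    """Single-state parameter template for a non-titratable residue type."""

    residue_type: str
    atoms: list[AtomParameters]

    @property
    def atom_map(self) -> dict[str, AtomParameters]:
        return {a.atom_name: a for a in self.atoms}

    @property
    def net_charge(self) -> float:
        return float(sum(a.partial_charge for a in self.atoms))


@dataclass
class ResidueTemplatePair:
    """Protonated and deprotonated parameter sets for one titratable residue
    type.

    The two states share the same atom names except the titratable proton,
    which appears only in the protonated list; on construction a zero-charge
    zero-ε entry for it is appended to the deprotonated state so both lists
    describe the same particle set. ``delta_q`` holds q_prot − q_deprot per
    shared atom.
    """

    residue_type: str
    protonated_atoms: list[AtomParameters]
    deprotonated_atoms: list[AtomParameters]
    titratable_proton_name: str
    delta_q: dict[str, float] = field(init=False)

    def __post_init__(self) -> None:
        prot = {a.atom_name: a for a in self.protonated_atoms}
        deprot = {a.atom_name: a for a in self.deprotonated_atoms}
        if self.titratable_proton_name not in prot:
            raise InvalidParameterError(
                f"{self.residue_type}: titratable proton "
                f"{self.titratable_proton_name!r} not in protonated atom list"
            )
        if self.titratable_proton_name not in deprot:
            ghost = AtomParameters(
                self.titratable_proton_name, 0.0, 0.0, 0.0, is_titratable_proton=True
            )
            self.deprotonated_atoms = list(self.deprotonated_atoms) + [ghost]
            deprot[self.titratable_proton_name] = ghost
        if set(prot) != set(deprot):
            raise InvalidParameterError(
                f"{self.residue_type}: protonated/deprotonated atom name sets differ "
                f"beyond the titratable proton: {set(prot) ^ set(deprot)}"
            )
        prot[self.titratable_proton_name].is_titratable_proton = True
        deprot[self.titratable_proton_name].is_titratable_proton = True
        self.delta_q = {
            name: prot[name].partial_charge - deprot[name].partial_charge
            for name in prot
            if name != self.titratable_proton_name
        }

    @property
    def protonated_map(self) -> dict[str, AtomParameters]:
        return {a.atom_name: a for a in self.protonated_atoms}

    @property
    def deprotonated_map(self) -> dict[str, AtomParameters]:
        return {a.atom_name: a for a in self.deprotonated_atoms}

    def net_charge(self, state: str) -> float:
        atoms = self.protonated_atoms if state == "protonated" else self.deprotonated_atoms
        return float(sum(a.partial_charge for a in atoms))


def scaled_electrostatic_energy(
    lambda_: float, q_i: float, q_j: float, r_ij: float
) -> float:
    """λ-scaled Coulomb pair energy, kcal/mol."""
    if r_ij <= 0:
        raise InvalidGeometryError(f"pair distance must be positive, got {r_ij}")
    if not 0.0 <= lambda_ <= 1.0:
        raise InvalidParameterError(f"lambda must lie in [0, 1], got {lambda_}")
    return lambda_ * COULOMB_CONSTANT * q_i * q_j / r_ij


def scaled_lj_energy(
    lambda_: float, sigma_ij: float, epsilon_ij: float, r_ij: float
) -> float:
    """λ-scaled 12-6 Lennard-Jones pair energy, kcal/mol.

    Zero when ε_ij = 0 or λ = 0; minimum −λ·ε_ij at r = 2^(1/6)·σ_ij.
    """
    if r_ij <= 0:
        raise InvalidGeometryError(f"pair distance must be positive, got {r_ij}")
    if epsilon_ij < 0:
        raise InvalidParameterError(f"epsilon must be >= 0, got {epsilon_ij}")
    if not 0.0 <= lambda_ <= 1.0:
        raise InvalidParameterError(f"lambda must lie in [0, 1], got {lambda_}")
    if epsilon_ij == 0.0 or lambda_ == 0.0:
        return 0.0
    sr6 = (sigma_ij / r_ij) ** 6
    return lambda_ * 4.0 * epsilon_ij * (sr6 * sr6 - sr6)


def interpolated_charge(lambda_: float, q_prot: float, delta_q: float) -> float:
    """Linear charge interpolation q(λ) = q_prot − (1 − λ)·Δq, in e."""
    if not 0.0 <= lambda_ <= 1.0:
        raise InvalidParameterError(f"lambda must lie in [0, 1], got {lambda_}")
    return q_prot - (1.0 - lambda_) * delta_q


# --- connectivity -----------------------------------------------------------

# Distance criteria (Å) for inferring covalent bonds from geometry.
_BOND_MAX_HEAVY = 1.9  # covers C-S at 1.81 Å
_BOND_MAX_H = 1.3


def infer_bonds(structure: Structure) -> list[tuple[int, int]]:
    """Covalent bonds inferred from interatomic distances.

    Atoms closer than 1.3 Å (when one is hydrogen) or 1.9 Å (two heavy
    atoms) are bonded; H–H pairs never are. Adequate for the idealised
    fixture geometries this package consumes; real structures with clashes
    should provide explicit connectivity instead.
    """
    coords = structure.coords
    is_h = np.char.upper(structure.element) == "H"
    n = structure.n_atoms
    if n < 2:
        return []
    from scipy.spatial import cKDTree

    tree = cKDTree(coords)
    bonds = []
    for i, j in tree.query_pairs(_BOND_MAX_HEAVY):
        i, j = (i, j) if i < j else (j, i)
        r = float(np.linalg.norm(coords[i] - coords[j]))
        if is_h[i] and is_h[j]:
            continue
        if (is_h[i] or is_h[j]) and r > _BOND_MAX_H:
            continue
        bonds.append((i, j))
    return sorted(bonds)


def connectivity_exclusions(
    n_atoms: int, bonds: Sequence[tuple[int, int]]
) -> tuple[set[tuple[int, int]], set[tuple[int, int]]]:
    """Standard nonbonded exclusion sets from the bond graph.

    Returns ``(excluded, pairs14)``: 1–2 and 1–3 pairs are fully excluded;
    1–4 pairs are listed separately (evaluated at full strength by default,
    the scale being a property of the evaluator, not the topology).
    """
    adj: list[set[int]] = [set() for _ in range(n_atoms)]
    for i, j in bonds:
        adj[i].add(j)
        adj[j].add(i)
    excluded: set[tuple[int, int]] = set()
    pairs14: set[tuple[int, int]] = set()
    for i, j in bonds:
        excluded.add((min(i, j), max(i, j)))
    for b in range(n_atoms):
        for a in adj[b]:
            for c in adj[b]:
                if a < c:
                    excluded.add((a, c))  # 1-3
    for a in range(n_atoms):
        for b in adj[a]:
            for c in adj[b]:
                if c == a:
                    continue
                for d in adj[c]:
                    if d in (a, b):
                        continue
                    pair = (min(a, d), max(a, d))
                    if pair not in excluded and a != d:
                        pairs14.add(pair)
    pairs14 -= excluded
    return excluded, pairs14


@dataclass
class ScaledSystem:
    """A structure with effective per-atom nonbonded parameters at one pH.

    ``charges`` already carry the λ-scaling/interpolation; ``lj_epsilon`` of
    a titratable proton is stored as λ²·ε so that geometric-mean combination
    yields pair energies scaled by λ. ``exclusions`` holds 1–2/1–3 pairs,
    ``pairs14`` the 1–4 pairs (full strength by default).
    """

    structure: Structure
    charges: np.ndarray
    lj_sigma: np.ndarray
    lj_epsilon: np.ndarray
    is_titratable_proton: np.ndarray
    sites: list[TitratableSite]
    ph: float
    exclusions: set[tuple[int, int]] = field(default_factory=set)
    pairs14: set[tuple[int, int]] = field(default_factory=set)

    def __post_init__(self) -> None:
        n = self.structure.n_atoms
        self.charges = np.asarray(self.charges, dtype=float).reshape(n)
        self.lj_sigma = np.asarray(self.lj_sigma, dtype=float).reshape(n)
        self.lj_epsilon = np.asarray(self.lj_epsilon, dtype=float).reshape(n)
        self.is_titratable_proton = np.asarray(self.is_titratable_proton, dtype=bool).reshape(n)

    @property
    def n_atoms(self) -> int:
        return self.structure.n_atoms

    @property
    def net_charge(self) -> float:
        """Sum of effective partial charges, e."""
        return float(np.sum(self.charges))

    @property
    def water_oxygen_indices(self) -> np.ndarray:
        s = self.structure
        return np.flatnonzero(
            np.isin(s.res_name, list(WATER_RESNAMES)) & (np.char.upper(s.element) == "O")
        )

    @property
    def water_atom_indices(self) -> np.ndarray:
        return np.flatnonzero(np.isin(self.structure.res_name, list(WATER_RESNAMES)))

    def copy(self) -> "ScaledSystem":
        return ScaledSystem(
            self.structure.copy(),
            self.charges.copy(),
            self.lj_sigma.copy(),
            self.lj_epsilon.copy(),
            self.is_titratable_proton.copy(),
            list(self.sites),
            self.ph,
            set(self.exclusions),
            set(self.pairs14),
        )


def _lookup_template(
    templates: Mapping[str, ResidueTemplate | ResidueTemplatePair],
    resname: str,
    site: TitratableSite | None,
) -> ResidueTemplate | ResidueTemplatePair:
    if site is not None and site.residue_type == "HIS":
        key = f"HIS:{site.tautomer}"
        if key in templates:
            return templates[key]
    if resname in templates:
        return templates[resname]
    raise UnparameterizedResidueError(
        f"no residue template for {resname!r}; available: {sorted(templates)}"
    )


def build_effective_system(
    structure: Structure,
    ph: float,
    templates: Mapping[str, ResidueTemplate | ResidueTemplatePair],
    sites: Sequence[TitratableSite],
    bonds: Sequence[tuple[int, int]] | None = None,
) -> ScaledSystem:
    """Assemble the effective pH-scaled parameter set for a structure.

    Every site's λ must already be assigned (see
    :func:`ecph.titration.assign_site_lambdas`). Residues without a site use
    their template unchanged (a :class:`ResidueTemplatePair` defaults to its
    protonated state). Particle count is identical at every pH.
    """
    site_map = {s.key: s for s in sites}
    n = structure.n_atoms
    charges = np.zeros(n)
    sigma = np.zeros(n)
    epsilon = np.zeros(n)
    proton_mask = np.zeros(n, dtype=bool)

    for chain, resid, resname in structure.residues():
        mask = structure.residue_mask(chain, resid)
        idx = np.flatnonzero(mask)
        names = structure.atom_name[idx]
        site = site_map.get((chain, resid))
        tpl = _lookup_template(templates, resname, site)

        if site is not None:
            if not isinstance(tpl, ResidueTemplatePair):
                raise UnparameterizedResidueError(
                    f"{resname} {chain}{resid} is titratable but its template "
                    "has no protonated/deprotonated state pair"
                )
            lam = site.lambda_
            prot = tpl.protonated_map
            deprot = tpl.deprotonated_map
            if tpl.titratable_proton_name not in set(names):
                raise MissingProtonError(
                    f"titratable proton {tpl.titratable_proton_name!r} missing from "
                    f"{resname} {chain}{resid}; add hydrogens to the structure first"
                )
            for k, name in zip(idx, names):
                if name not in prot:
                    raise UnparameterizedResidueError(
                        f"atom {name!r} of {resname} {chain}{resid} not in template"
                    )
                p = prot[name]
                if name == tpl.titratable_proton_name:
                    charges[k] = lam * p.partial_charge
                    sigma[k] = p.lj_sigma
                    epsilon[k] = lam * lam * p.lj_epsilon
                    proton_mask[k] = True
                else:
                    # endpoints reproduce the template states bit-for-bit
                    if lam == 0.0:
                        charges[k] = deprot[name].partial_charge
                    elif lam == 1.0:
                        charges[k] = p.partial_charge
                    else:
                        charges[k] = interpolated_charge(
                            lam, p.partial_charge, tpl.delta_q[name]
                        )
                    sigma[k] = p.lj_sigma
                    epsilon[k] = p.lj_epsilon
        else:
            amap = (
                tpl.protonated_map if isinstance(tpl, ResidueTemplatePair) else tpl.atom_map
            )
            for k, name in zip(idx, names):
                if name not in amap:
                    raise UnparameterizedResidueError(
                        f"atom {name!r} of {resname} {chain}{resid} not in template"
                    )
                p = amap[name]
                charges[k] = p.partial_charge
                sigma[k] = p.lj_sigma
                epsilon[k] = p.lj_epsilon

    if bonds is None:
        bonds = infer_bonds(structure)
    excluded, pairs14 = connectivity_exclusions(n, bonds)

    return ScaledSystem(
        structure=structure,
        charges=charges,
        lj_sigma=sigma,
        lj_epsilon=epsilon,
        is_titratable_proton=proton_mask,
        sites=list(sites),
        ph=ph,
        exclusions=excluded,
        pairs14=pairs14,
    )
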