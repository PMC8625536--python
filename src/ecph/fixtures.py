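"""Synthetic test-input generators.

Everything the validation surface consumes is generated here: residue
parameter templates with protonated/deprotonated states, small titratable
peptide structures, lattice water boxes, two-state trajectories with a
planted pH-dependent shift, synthetic ensemble pKa prediction samples, and
the one-site toy titration system.

Fixtures are geometric, not physical: bond lengths and charges are
chemically sensible (correct residue net charges, no heavy-atom clashes
below 1.5 Å, titratable protons present) but the geometries are idealised
and the charge sets are this package's own synthetic templates, not a real
published force field. All randomness flows through one seeded generator
per fixture, so identical parameters and seed regenerate identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np

from .errors import InvalidParameterError
from .forcefield import AtomParameters, ResidueTemplate, ResidueTemplatePair
from .pka import PkaSampleSet
from .sampling import AxisRestraint, SphericalWall, ToyTitrationSystem
from .structure import Structure, TrajectoryEnsemble
from .titration import TitratableSite

__all__ = [
    "FixtureSpec",
    "make_residue_templates",
    "make_titratable_peptide",
    "make_water_box",
    "make_solvated_peptide",
    "make_two_state_trajectory",
    "make_pka_samples",
    "make_toy_titration_system",
]

# Generic LJ parameters (σ Å, ε kcal/mol) by element class.
_LJ = {
    "C": (3.6, 0.07),
    "O": (2.9, 0.12),
    "N": (3.3, 0.20),
    "S": (3.6, 0.45),
    "HP": (0.4, 0.046),  # polar hydrogen
    "HA": (2.4, 0.03),  # aliphatic hydrogen
}


def _atom(name: str, q: float, elem_class: str, titratable: bool = False) -> AtomParameters:
    sigma, eps = _LJ[elem_class]
    return AtomParameters(name, q, sigma, eps, is_titratable_proton=titratable)


def _balance(atoms: list[AtomParameters], target: float, balance_atom: str) -> list[AtomParameters]:
    """Adjust one atom's charge so the residue sum equals the target exactly."""
    others = sum(a.partial_charge for a in atoms if a.atom_name != balance_atom)
    for a in atoms:
        if a.atom_name == balance_atom:
            a.partial_charge = target - others
    return atoms


_BACKBONE_CHARGES = [
    ("N", -0.47, "N"), ("HN", 0.31, "HP"), ("CA", 0.07, "C"), ("HA", 0.09, "HA"),
    ("C", 0.51, "C"), ("O", -0.51, "O"),
]


def _residue_atoms(side: list[tuple], target: float, balance: str = "CB") -> list[AtomParameters]:
    atoms = [_atom(*spec) for spec in _BACKBONE_CHARGES + side]
    return _balance(atoms, target, balance)


def make_residue_templates() -> dict[str, ResidueTemplate | ResidueTemplatePair]:
    """The synthetic template library: state pairs for GLU, ASP, HIS (both
    tautomers), CYS and LYS, plus single-state ALA and TIP3P-like water.

    Net charges are exact by construction: protonated GLU/ASP/CYS are 0 and
    deprotonated −1; protonated HIS/LYS are +1 and neutral forms 0.
    """
    glu = ResidueTemplatePair(
        "GLU",
        _residue_atoms(
            [("CB", 0.0, "C"), ("CG", -0.21, "C"), ("CD", 0.75, "C"),
             ("OE1", -0.55, "O"), ("OE2", -0.61, "O"), ("HE2", 0.44, "HP", True)],
            0.0,
        ),
        _residue_atoms(
            [("CB", 0.0, "C"), ("CG", -0.28, "C"), ("CD", 0.62, "C"),
             ("OE1", -0.76, "O"), ("OE2", -0.76, "O")],
            -1.0,
        ),
        "HE2",
    )
    asp = ResidueTemplatePair(
        "ASP",
        _residue_atoms(
            [("CB", 0.0, "C"), ("CG", 0.75, "C"),
             ("OD1", -0.55, "O"), ("OD2", -0.61, "O"), ("HD2", 0.44, "HP", True)],
            0.0,
        ),
        _residue_atoms(
            [("CB", 0.0, "C"), ("CG", 0.62, "C"),
             ("OD1", -0.76, "O"), ("OD2", -0.76, "O")],
            -1.0,
        ),
        "HD2",
    )
    cys = ResidueTemplatePair(
        "CYS",
        _residue_atoms([("CB", 0.0, "C"), ("SG", -0.23, "S"), ("HG1", 0.16, "HP", True)], 0.0),
        _residue_atoms([("CB", 0.0, "C"), ("SG", -0.80, "S")], -1.0),
        "HG1",
    )
    lys = ResidueTemplatePair(
        "LYS",
        _residue_atoms(
            [("CB", 0.0, "C"), ("CG", -0.18, "C"), ("CD", -0.18, "C"), ("CE", 0.21, "C"),
             ("NZ", -0.30, "N"), ("HZ1", 0.33, "HP"), ("HZ2", 0.33, "HP"),
             ("HZ3", 0.33, "HP", True)],
            1.0,
        ),
        _residue_atoms(
            [("CB", 0.0, "C"), ("CG", -0.18, "C"), ("CD", -0.18, "C"), ("CE", 0.21, "C"),
             ("NZ", -0.96, "N"), ("HZ1", 0.34, "HP"), ("HZ2", 0.34, "HP")],
            0.0,
        ),
        "HZ3",
    )
    hsp = [  # doubly protonated imidazolium, +1
        ("CB", 0.0, "C"), ("CG", 0.19, "C"), ("ND1", -0.51, "N"), ("HD1", 0.44, "HP"),
        ("CD2", 0.19, "C"), ("HD2", 0.13, "HA"), ("CE1", 0.32, "C"), ("HE1", 0.18, "HA"),
        ("NE2", -0.51, "N"), ("HE2", 0.44, "HP"),
    ]
    hse = [  # neutral ε tautomer: proton on NE2, HD1 absent
        ("CB", 0.0, "C"), ("CG", 0.22, "C"), ("ND1", -0.70, "N"),
        ("CD2", -0.05, "C"), ("HD2", 0.09, "HA"), ("CE1", 0.25, "C"), ("HE1", 0.13, "HA"),
        ("NE2", -0.36, "N"), ("HE2", 0.32, "HP"),
    ]
    hsd = [  # neutral δ tautomer: proton on ND1, HE2 absent
        ("CB", 0.0, "C"), ("CG", 0.22, "C"), ("ND1", -0.36, "N"), ("HD1", 0.32, "HP"),
        ("CD2", -0.05, "C"), ("HD2", 0.09, "HA"), ("CE1", 0.25, "C"), ("HE1", 0.13, "HA"),
        ("NE2", -0.70, "N"),
    ]

    def _his_pair(neutral: list[tuple], proton: str) -> ResidueTemplatePair:
        prot_atoms = _residue_atoms([s for s in hsp], 1.0)
        for a in prot_atoms:
            a.is_titratable_proton = a.atom_name == proton
        return ResidueTemplatePair("HIS", prot_atoms, _residue_atoms(neutral, 0.0), proton)

    templates: dict[str, ResidueTemplate | ResidueTemplatePair] = {
        "GLU": glu,
        "ASP": asp,
        "CYS": cys,
        "LYS": lys,
        "HIS:epsilon": _his_pair(hse, "HD1"),
        "HIS:delta": _his_pair(hsd, "HE2"),
    }
    templates["HIS"] = templates["HIS:epsilon"]
    templates["ALA"] = ResidueTemplate(
        "ALA",
        _balance(
            [_atom(*s) for s in _BACKBONE_CHARGES
             + [("CB", -0.27, "C"), ("HB1", 0.09, "HA"), ("HB2", 0.09, "HA"),
                ("HB3", 0.09, "HA")]],
            0.0, "CB",
        ),
    )
    templates["HOH"] = ResidueTemplate(
        "HOH",
        [AtomParameters("O", -0.834, 3.1507, 0.1521),
         AtomParameters("H1", 0.417, 0.4, 0.046),
         AtomParameters("H2", 0.417, 0.4, 0.046)],
    )
    return templates


# --- geometry ---------------------------------------------------------------

# Backbone + carbonyl positions shared by all single-residue fixtures (Å).
_BACKBONE_XYZ = {
    "N": (0.00, 0.00, 0.00),
    "HN": (-0.45, -0.85, 0.00),
    "CA": (1.46, 0.00, 0.00),
    "HA": (1.80, -0.65, 0.75),
    "C": (2.20, 1.25, 0.00),
    "O": (2.00, 2.46, 0.00),
    "CB": (1.96, -0.80, -1.20),
}


def _his_ring_xyz() -> dict[str, tuple[float, float, float]]:
    """Imidazole ring as a regular pentagon grown off CB, protons radial."""
    cb = np.array(_BACKBONE_XYZ["CB"])
    d = np.array([0.0, -0.853, -0.522])  # side-chain growth direction
    e = np.array([0.0, 0.522, -0.853])  # in-plane normal to d
    cg = cb + 1.50 * d
    center = cg + 1.17 * d
    u = -d
    names = ["CG", "ND1", "CE1", "NE2", "CD2"]
    coords: dict[str, tuple[float, float, float]] = {}
    for k, name in enumerate(names):
        th = np.radians(72.0 * k)
        pos = center + 1.17 * (np.cos(th) * u + np.sin(th) * e)
        coords[name] = tuple(pos)
        if name != "CG":  # CG carries the CB link, not a hydrogen
            h = pos + 1.0 * (pos - center) / 1.17
            coords["H" + name[1:]] = tuple(h)
    return coords


def _sidechain_xyz(residue_type: str) -> dict[str, tuple[float, float, float]]:
    if residue_type == "GLU":
        return {
            "CG": (1.96, -2.10, -1.95),
            "CD": (1.96, -3.35, -2.70),
            "OE1": (1.96, -4.45, -2.15),
            "OE2": (1.96, -3.35, -3.95),
            "HE2": (1.96, -4.15, -4.45),
        }
    if residue_type == "ASP":
        return {
            "CG": (1.96, -2.05, -1.95),
            "OD1": (1.96, -3.15, -1.40),
            "OD2": (1.96, -2.05, -3.20),
            "HD2": (1.96, -2.85, -3.70),
        }
    if residue_type == "CYS":
        return {"SG": (1.96, -1.80, -2.80), "HG1": (1.96, -2.95, -3.15)}
    if residue_type == "LYS":
        return {
            "CG": (1.96, -2.10, -1.95),
            "CD": (1.96, -3.35, -2.70),
            "CE": (1.96, -4.60, -3.45),
            "NZ": (1.96, -5.85, -4.25),
            "HZ1": (1.19, -6.40, -4.10),
            "HZ2": (2.73, -6.40, -4.10),
            "HZ3": (1.96, -5.60, -5.23),
        }
    if residue_type == "HIS":
        return _his_ring_xyz()
    raise InvalidParameterError(f"unsupported residue type {residue_type!r}")


_ALA_LOCAL = {  # relative to the ALA nitrogen
    "N": (0.00, 0.00, 0.00),
    "HN": (0.00, -0.98, 0.00),
    "CA": (1.46, 0.00, 0.00),
    "HA": (1.70, -0.80, 0.78),
    "CB": (1.81, 1.05, 1.05),
    "HB1": (2.71, 1.55, 1.05),
    "HB2": (1.51, 1.65, 1.90),
    "HB3": (1.91, 1.40, 0.05),
    "C": (2.86, -0.45, 0.00),
    "O": (3.16, -1.64, 0.00),
}


def _element_of(atom_name: str) -> str:
    return atom_name[0] if atom_name[0] not in "0123456789" else atom_name[1]


def make_titratable_peptide(
    residue_type: str = "GLU", capped: bool = True, seed: int = 0
) -> tuple[Structure, dict]:
    """A single titratable residue (plus, when ``capped``, a bonded alanine
    cap following its carbonyl), with the matching template library.

    Deterministic for a given seed; the seed drives a 0.01 Å jitter so
    distinct seeds give distinct but equivalent geometries.
    """
    if residue_type not in ("GLU", "ASP", "HIS", "CYS", "LYS"):
        raise InvalidParameterError(f"unsupported residue type {residue_type!r}")
    rng = np.random.default_rng(seed)
    names: list[str] = []
    coords: list[tuple[float, float, float]] = []
    resids: list[int] = []
    resnames: list[str] = []
    for name, xyz in {**_BACKBONE_XYZ, **_sidechain_xyz(residue_type)}.items():
        names.append(name)
        coords.append(xyz)
        resids.append(1)
        resnames.append(residue_type)
    if capped:
        # ALA nitrogen placed 1.33 Å from the C of residue 1 (peptide bond)
        offset = np.array(_BACKBONE_XYZ["C"]) + np.array([1.31, -0.25, 0.0])
        for name, xyz in _ALA_LOCAL.items():
            names.append(name)
            coords.append(tuple(offset + np.array(xyz)))
            resids.append(2)
            resnames.append("ALA")
    xyz = np.array(coords) + rng.normal(scale=0.01, size=(len(coords), 3))
    structure = Structure(
        chain_id=["A"] * len(names),
        res_id=resids,
        res_name=resnames,
        atom_name=names,
        element=[_element_of(n) for n in names],
        coords=xyz,
    )
    return structure, make_residue_templates()


def make_water_box(
    n_waters: int = 216, spacing: float = 3.1, seed: int = 0,
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0),
    chain: str = "W",
) -> Structure:
    """A cubic lattice of rigid TIP3P-like waters (O–H 0.9572 Å, 104.52°)."""
    side = round(n_waters ** (1 / 3))
    if side**3 != n_waters:
        raise InvalidParameterError(f"n_waters must be a perfect cube, got {n_waters}")
    rng = np.random.default_rng(seed)
    half = np.radians(104.52 / 2)
    h1 = 0.9572 * np.array([np.cos(half), np.sin(half), 0.0])
    h2 = 0.9572 * np.array([np.cos(half), -np.sin(half), 0.0])
    names, coords, resids = [], [], []
    res = 0
    for i in range(side):
        for j in range(side):
            for k in range(side):
                res += 1
                o = np.array(origin) + spacing * np.array([i, j, k])
                o = o + rng.normal(scale=0.01, size=3)
                for name, pos in (("O", o), ("H1", o + h1), ("H2", o + h2)):
                    names.append(name)
                    coords.append(pos)
                    resids.append(res)
    return Structure(
        chain_id=[chain] * len(names),
        res_id=resids,
        res_name=["HOH"] * len(names),
        atom_name=names,
        element=[n[0] for n in names],
        coords=np.array(coords),
    )


def _concat(a: Structure, b: Structure) -> Structure:
    return Structure(
        np.concatenate([a.chain_id, b.chain_id]),
        np.concatenate([a.res_id, b.res_id]),
        np.concatenate([a.res_name, b.res_name]),
        np.concatenate([a.atom_name, b.atom_name]),
        np.concatenate([a.element, b.element]),
        np.vstack([a.coords, b.coords]),
    )


def make_solvated_peptide(
    residue_type: str = "GLU", n_waters: int = 216, seed: int = 0
) -> tuple[Structure, dict]:
    """Capped titratable peptide plus a non-overlapping lattice water box."""
    peptide, templates = make_titratable_peptide(residue_type, capped=True, seed=seed)
    box = make_water_box(n_waters, seed=seed + 1, origin=(9.0, -9.0, -9.0))
    return _concat(peptide, box), templates


def make_two_state_trajectory(
    n_frames: int,
    shift: float,
    weights: tuple[float, float] = (0.5, 0.5),
    seed: int = 0,
    base_distance: float = 95.0,
    noise_sigma: float = 0.2,
    ph_label: float = float("nan"),
) -> TrajectoryEnsemble:
    """Frames drawn from two rigid states separated by ``shift`` Å along +x.

    Two single-residue chains A and B; in the minority/second state chain B
    is displaced by the planted shift, so any chain-A-to-chain-B distance
    carries a bimodal signal of separation ``shift``. Isotropic Gaussian
    noise of ``noise_sigma`` is added to every atom of every frame.
    """
    if n_frames < 1:
        raise InvalidParameterError("n_frames must be >= 1")
    if shift <= 0:
        raise InvalidParameterError(f"planted shift must be positive, got {shift}")
    if abs(sum(weights) - 1.0) > 1e-9 or any(w < 0 for w in weights):
        raise InvalidParameterError(f"state weights must be >= 0 and sum to 1, got {weights}")

    unit = {
        "N": (0.0, 1.40, 0.0), "CA": (0.0, 0.0, 0.0),
        "C": (1.40, -0.50, 0.0), "CB": (-1.10, -1.05, 0.0),
    }
    names, chains, coords = [], [], []
    for chain, origin in (("A", np.zeros(3)), ("B", np.array([base_distance, 0.0, 0.0]))):
        for name, xyz in unit.items():
            names.append(name)
            chains.append(chain)
            coords.append(origin + np.array(xyz))
    base = np.array(coords)
    top = Structure(
        chain_id=chains,
        res_id=[1] * len(names),
        res_name=["ALA"] * len(names),
        atom_name=names,
        element=[n[0] for n in names],
        coords=base,
    )
    rng = np.random.default_rng(seed)
    states = rng.choice(2, size=n_frames, p=list(weights))
    b_atoms = top.chain_id == "B"
    frames = np.repeat(base[None], n_frames, axis=0)
    frames[:, b_atoms, 0] += shift * states[:, None]
    frames += rng.normal(scale=noise_sigma, size=frames.shape)
    return TrajectoryEnsemble(top, frames, ph_label=ph_label)


def make_pka_samples(
    true_median: float, true_std: float, n: int, seed: int = 0,
    chain: str = "A", residue_number: int = 1, residue_type: str = "GLU",
) -> PkaSampleSet:
    """Gaussian per-frame pKa predictions emulating ensemble predictor output."""
    if n < 1:
        raise InvalidParameterError("need at least one sample")
    if true_std < 0:
        raise InvalidParameterError("true_std must be >= 0")
    rng = np.random.default_rng(seed)
    samples = true_median + true_std * rng.standard_normal(n)
    return PkaSampleSet(chain, residue_number, residue_type, samples)


def make_toy_titration_system(
    pka: float = 5.0, seed: int = 0, separation: float = 8.0, n_waters: int = 4
) -> ToyTitrationSystem:
    """The one-site toy construct used for end-to-end pKa recovery.

    A mobile probe bead (+0.09 e) shuttles along the x-axis between two
    attractor sites 8 Å apart belonging to one titratable pseudo-residue:
    site A's charge scales with λ (protonated-state attraction, including a
    small λ-scaled charge on the titratable proton itself) and site B's
    with 1 − λ. By construction the two binding wells are equally deep at
    λ = ½, so the bound fraction crosses ½ at pH = pKa and the fitted
    binding-curve midpoint estimates the input pKa. A handful of distant,
    frozen waters are included so the charge-neutralization step of the
    chain operates on a solvated system.
    """
    half = separation / 2.0
    names = ["OA", "HT", "OB", "P"]
    resids = [1, 1, 1, 2]
    resnames = ["TIA", "TIA", "TIA", "PRB"]
    elements = ["O", "H", "O", "C"]
    coords = np.array([
        [-half, 0.0, 0.0],
        [-half, 1.0, 0.0],
        [half, 0.0, 0.0],
        [0.4, 0.0, 0.0],
    ])
    core = Structure(["A"] * 4, resids, resnames, names, elements, coords)
    rng = np.random.default_rng(seed)
    jitter = rng.normal(scale=0.01)
    waters = make_water_box(n_waters=1, seed=seed + 1, origin=(0.0, 25.0 + jitter, 0.0))
    boxes = [waters]
    for w in range(1, n_waters):
        boxes.append(
            make_water_box(n_waters=1, seed=seed + 1 + w, origin=(4.0 * w, 25.0, 0.0))
        )
    structure = core
    for k, b in enumerate(boxes):
        b.res_id[:] = k + 1
        structure = _concat(structure, b)

    tia = ResidueTemplatePair(
        "TIA",
        [AtomParameters("OA", -0.11, 2.0, 0.05),
         AtomParameters("HT", 0.02, 0.4, 0.0, is_titratable_proton=True),
         AtomParameters("OB", 0.0, 2.0, 0.05)],
        [AtomParameters("OA", 0.0, 2.0, 0.05),
         AtomParameters("OB", -0.09, 2.0, 0.05)],
        "HT",
    )
    templates = make_residue_templates()
    templates["TIA"] = tia
    templates["PRB"] = ResidueTemplate("PRB", [AtomParameters("P", 0.09, 2.0, 0.05)])

    probe_index = 3
    site = TitratableSite("A", 1, "GLU", pka=pka)
    restraints = [
        AxisRestraint(np.array([probe_index]), k=5.0),
        SphericalWall(np.zeros(3), radius=6.0, k=10.0, indices=np.array([probe_index])),
    ]
    return ToyTitrationSystem(
        structure=structure,
        templates=templates,
        sites=[site],
        pka=pka,
        probe_index=probe_index,
        anchor_index=0,
        bound_cutoff=half,
        restraints=restraints,
    )


@dataclass
class FixtureSpec:
    """Declarative fixture request: kind, seed and free-form parameters.

    Identical specs (including the seed) regenerate identical outputs.
    """

    kind: str
    seed: int = 0
    parameters: dict[str, Any] = field(default_factory=dict)

    _MAKERS = {
        "peptide": make_titratable_peptide,
        "water_box": make_water_box,
        "solvated_peptide": make_solvated_peptide,
        "two_state_trajectory": make_two_state_trajectory,
        "pka_samples": make_pka_samples,
        "toy_titration_system": make_toy_titration_system,
    }

    def build(self):
        if self.kind not in self._MAKERS:
            raise InvalidParameterError(
                f"unknown fixture kind {self.kind!r}; choices: {sorted(self._MAKERS)}"
            )
        return self._MAKERS[self.kind](seed=self.seed, **self.parameters)
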