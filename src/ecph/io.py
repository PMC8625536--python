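"""Readers and writers.

* PDB structures and multi-model PDB trajectories (via biotite), honoring
  chains, author residue numbers and insertion codes; only the first altloc
  of each atom is kept (a warning is logged when alternates are dropped).
* The residue-template dialect: a plain-text format with one record per
  residue type, a ``protonated`` and (for titratable residues) a
  ``deprotonated`` block, one ``atom NAME CHARGE SIGMA EPSILON`` line per
  atom. Charges in e, σ in Å, ε in kcal/mol.
* Comma-separated pKa tables: per-frame prediction samples
  (chain,resid,resname,frame,pka) and the override table
  (chain,resid,resname,pka).
* The effective-parameter export: a structured-text per-atom table with the
  unit system in the header, plus the neutralization report.
* :class:`RunConfig`: the resolved configuration written next to every
  CLI run, JSON round-trippable.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import biotite.structure as bst
import biotite.structure.io.pdb as pdb

from .errors import ParseError
from .forcefield import AtomParameters, ResidueTemplate, ResidueTemplatePair, ScaledSystem
from .neutralize import NeutralizationReport
from .pka import PkaSampleSet
from .structure import Structure, TrajectoryEnsemble

__all__ = [
    "read_pdb",
    "write_pdb",
    "read_trajectory_pdb",
    "write_trajectory_pdb",
    "read_templates",
    "write_templates",
    "read_pka_overrides",
    "write_pka_overrides",
    "read_pka_samples",
    "write_scaled_system",
    "write_neutralization_report",
    "RunConfig",
]

logger = logging.getLogger("ecph")

UNIT_HEADER = "# units: distance=Angstrom energy=kcal/mol charge=e angle=degree"


def _atom_array_to_structure(arr: bst.AtomArray) -> Structure:
    return Structure(
        chain_id=arr.chain_id,
        res_id=arr.res_id,
        res_name=arr.res_name,
        atom_name=arr.atom_name,
        element=arr.element,
        coords=arr.coord,
    )


def _structure_to_atom_array(structure: Structure) -> bst.AtomArray:
    n = structure.n_atoms
    arr = bst.AtomArray(n)
    arr.chain_id = structure.chain_id
    arr.res_id = structure.res_id
    arr.res_name = structure.res_name
    arr.atom_name = structure.atom_name
    arr.element = structure.element
    arr.coord = structure.coords.astype(np.float32)
    arr.hetero = np.isin(structure.res_name, ["HOH", "WAT", "TIP3"])
    return arr


def read_pdb(path: str | Path) -> Structure:
    """Read the first model of a PDB file, keeping the first altloc."""
    try:
        pdb_file = pdb.PDBFile.read(str(path))
        arr = pdb_file.get_structure(model=1, altloc="first")
    except Exception as exc:  # biotite raises assorted types on bad records
        raise ParseError(f"cannot parse PDB file {path}: {exc}") from exc
    for line in pdb_file.lines:
        if line.startswith(("ATOM", "HETATM")) and len(line) > 16 and line[16] not in " A":
            logger.warning(
                "%s contains alternate locations; keeping the first altloc only", path
            )
            break
    return _atom_array_to_structure(arr)


def write_pdb(structure: Structure, path: str | Path) -> None:
    pdb_file = pdb.PDBFile()
    pdb_file.set_structure(_structure_to_atom_array(structure))
    pdb_file.write(str(path))


def read_trajectory_pdb(
    path: str | Path, ph_label: float = float("nan"), frame_stride_ps: float = 1.0
) -> TrajectoryEnsemble:
    """Read a multi-model PDB as a trajectory (frame count = MODEL count)."""
    try:
        pdb_file = pdb.PDBFile.read(str(path))
        stack = pdb_file.get_structure(model=None, altloc="first")
    except Exception as exc:
        raise ParseError(f"cannot parse PDB trajectory {path}: {exc}") from exc
    top = _atom_array_to_structure(stack[0])
    return TrajectoryEnsemble(
        top, np.asarray(stack.coord, dtype=float), ph_label, frame_stride_ps
    )


def write_trajectory_pdb(traj: TrajectoryEnsemble, path: str | Path) -> None:
    n = traj.n_atoms
    stack = bst.AtomArrayStack(traj.n_frames, n)
    template = _structure_to_atom_array(traj.topology)
    for name in ("chain_id", "res_id", "res_name", "atom_name", "element", "hetero"):
        stack.set_annotation(name, getattr(template, name))
    stack.coord = traj.frames.astype(np.float32)
    pdb_file = pdb.PDBFile()
    pdb_file.set_structure(stack)
    pdb_file.write(str(path))


# --- residue templates ------------------------------------------------------


def write_templates(
    templates: dict[str, ResidueTemplate | ResidueTemplatePair], path: str | Path
) -> None:
    lines = [UNIT_HEADER, "# residue templates: atom NAME CHARGE SIGMA EPSILON"]
    for key in sorted(templates):
        tpl = templates[key]
        if key == "HIS" and tpl is templates.get("HIS:epsilon"):
            continue  # plain HIS is an alias of HIS:epsilon; reconstructed on load
        lines.append(f"residue {key}")
        if isinstance(tpl, ResidueTemplatePair):
            lines.append(f"  proton {tpl.titratable_proton_name}")
            for state, atoms in (
                ("protonated", tpl.protonated_atoms),
                ("deprotonated", tpl.deprotonated_atoms),
            ):
                lines.append(f"  state {state}")
                for a in atoms:
                    if state == "deprotonated" and a.atom_name == tpl.titratable_proton_name:
                        continue  # ghost entry is reconstructed on load
                    lines.append(
                        f"    atom {a.atom_name} {a.partial_charge:.6f} "
                        f"{a.lj_sigma:.4f} {a.lj_epsilon:.4f}"
                    )
        else:
            lines.append("  state protonated")
            for a in tpl.atoms:
                lines.append(
                    f"    atom {a.atom_name} {a.partial_charge:.6f} "
                    f"{a.lj_sigma:.4f} {a.lj_epsilon:.4f}"
                )
        lines.append("end")
    Path(path).write_text("\n".join(lines) + "\n")


def read_templates(path: str | Path) -> dict[str, ResidueTemplate | ResidueTemplatePair]:
    templates: dict[str, ResidueTemplate | ResidueTemplatePair] = {}
    name = proton = state = None
    blocks: dict[str, list[AtomParameters]] = {}

    def finish(lineno: int) -> None:
        nonlocal name, proton, blocks
        if name is None:
            return
        if "deprotonated" in blocks:
            if proton is None:
                raise ParseError(
                    f"{path}:{lineno}: residue {name} has two states but no 'proton' line"
                )
            templates[name] = ResidueTemplatePair(
                name.split(":")[0], blocks["protonated"], blocks["deprotonated"], proton
            )
        else:
            templates[name] = ResidueTemplate(name, blocks["protonated"])
        name = proton = None
        blocks = {}

    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        tokens = line.split()
        try:
            if tokens[0] == "residue":
                finish(lineno)
                name = tokens[1]
            elif tokens[0] == "proton":
                proton = tokens[1]
            elif tokens[0] == "state":
                state = tokens[1]
                blocks[state] = []
            elif tokens[0] == "atom":
                blocks[state].append(
                    AtomParameters(tokens[1], float(tokens[2]), float(tokens[3]),
                                   float(tokens[4]))
                )
            elif tokens[0] == "end":
                finish(lineno)
            else:
                raise ValueError(f"unknown keyword {tokens[0]!r}")
        except (IndexError, ValueError, KeyError, TypeError) as exc:
            raise ParseError(f"{path}:{lineno}: {exc}") from exc
    finish(-1)
    if "HIS:epsilon" in templates and "HIS" not in templates:
        templates["HIS"] = templates["HIS:epsilon"]
    return templates


# --- tabular pKa files ------------------------------------------------------


def write_pka_overrides(
    overrides: dict[tuple[str, int], tuple[str, float]], path: str | Path
) -> None:
    """Write the override table consumed by λ assignment.

    ``overrides`` maps (chain, resid) to (resname, pka).
    """
    rows = [
        {"chain": c, "resid": r, "resname": rn, "pka": pka}
        for (c, r), (rn, pka) in sorted(overrides.items())
    ]
    pd.DataFrame(rows, columns=["chain", "resid", "resname", "pka"]).to_csv(
        path, index=False
    )


def read_pka_overrides(path: str | Path) -> dict[tuple[str, int], float]:
    try:
        df = pd.read_csv(path, dtype={"chain": str})
    except Exception as exc:
        raise ParseError(f"cannot parse pKa override table {path}: {exc}") from exc
    missing = {"chain", "resid", "pka"} - set(df.columns)
    if missing:
        raise ParseError(f"{path}: missing column(s) {sorted(missing)}")
    return {
        (str(row.chain), int(row.resid)): float(row.pka) for row in df.itertuples()
    }


def read_pka_samples(path: str | Path) -> list[PkaSampleSet]:
    """Read per-frame predictions (chain,resid,resname,frame,pka) grouped by
    residue, in order of first appearance."""
    try:
        df = pd.read_csv(path, dtype={"chain": str})
    except Exception as exc:
        raise ParseError(f"cannot parse pKa sample table {path}: {exc}") from exc
    missing = {"chain", "resid", "resname", "pka"} - set(df.columns)
    if missing:
        raise ParseError(f"{path}: missing column(s) {sorted(missing)}")
    out = []
    for (chain, resid, resname), group in df.groupby(
        ["chain", "resid", "resname"], sort=False
    ):
        out.append(
            PkaSampleSet(str(chain), int(resid), str(resname), group["pka"].to_numpy())
        )
    return out


# --- exports ----------------------------------------------------------------


def write_scaled_system(system: ScaledSystem, path: str | Path) -> None:
    """Effective per-atom nonbonded parameters as structured text."""
    s = system.structure
    lines = [
        UNIT_HEADER,
        f"# effective nonbonded parameters at pH {system.ph:g}",
        f"# net_charge_e {system.net_charge:.10f}",
        "# columns: index chain resid resname atom charge sigma epsilon titratable_proton",
    ]
    for i in range(system.n_atoms):
        lines.append(
            f"{i} {s.chain_id[i]} {s.res_id[i]} {s.res_name[i]} {s.atom_name[i]} "
            f"{system.charges[i]:.10f} {system.lj_sigma[i]:.6f} "
            f"{system.lj_epsilon[i]:.10f} {int(system.is_titratable_proton[i])}"
        )
    for site in system.sites:
        lines.append(
            f"# site {site.chain_id} {site.residue_number} {site.residue_type} "
            f"pka={site.pka:.4f} lambda={site.lambda_:.10g} titratable={site.titratable}"
        )
    Path(path).write_text("\n".join(lines) + "\n")


def write_neutralization_report(report: NeutralizationReport, path: str | Path) -> None:
    Path(path).write_text(json.dumps(asdict(report), indent=2) + "\n")


# --- run configuration ------------------------------------------------------


@dataclass
class RunConfig:
    """Resolved configuration of one run; written next to its outputs."""

    structure_path: str = ""
    template_path: str = ""
    pka_override_path: str | None = None
    output_dir: str = "."
    ph: float | None = None
    ph_grid: list[float] = field(default_factory=list)
    seed: int = 0
    neutralization_mode: str = "oxygen"
    target_net_charge: float | None = None
    cutoff: float = 12.0
    switch_on: float = 10.0
    hill_coefficient: float = 1.0

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "RunConfig":
        return cls(**json.loads(Path(path).read_text()))
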