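"""Lightweight structure and trajectory containers.

A :class:`Structure` is a flat, array-backed atom table (chain, author residue
number, residue name, atom name, element, coordinates) — the minimal metadata
the pH-scaling and analysis operators need. A :class:`TrajectoryEnsemble`
shares one atom table across an ordered list of coordinate frames and carries
the pH label of the ensemble it samples.

Coordinates are in Å throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import SelectionError

__all__ = ["Structure", "TrajectoryEnsemble"]


@dataclass
class Structure:
    chain_id: np.ndarray  # (N,) str
    res_id: np.ndarray  # (N,) int, author numbering
    res_name: np.ndarray  # (N,) str
    atom_name: np.ndarray  # (N,) str
    element: np.ndarray  # (N,) str
    coords: np.ndarray  # (N, 3) float, Å

    def __post_init__(self) -> None:
        n = len(self.atom_name)
        self.chain_id = np.asarray(self.chain_id, dtype="U4")
        self.res_id = np.asarray(self.res_id, dtype=int)
        self.res_name = np.asarray(self.res_name, dtype="U5")
        self.atom_name = np.asarray(self.atom_name, dtype="U6")
        self.element = np.asarray(self.element, dtype="U2")
        self.coords = np.asarray(self.coords, dtype=float).reshape(n, 3)

    @property
    def n_atoms(self) -> int:
        return len(self.atom_name)

    def residues(self) -> list[tuple[str, int, str]]:
        """Unique (chain, resid, resname) triples in order of first appearance."""
        seen: dict[tuple[str, int, str], None] = {}
        for c, r, n in zip(self.chain_id, self.res_id, self.res_name):
            seen.setdefault((str(c), int(r), str(n)))
        return list(seen)

    def residue_mask(self, chain: str, resid: int) -> np.ndarray:
        return (self.chain_id == chain) & (self.res_id == resid)

    def atom_index(self, chain: str, resid: int, atom: str) -> int:
        """Index of a uniquely identified atom; raises on zero or many matches."""
        hits = np.flatnonzero(self.residue_mask(chain, resid) & (self.atom_name == atom))
        if hits.size == 0:
            raise SelectionError(f"no atom {atom!r} in chain {chain!r} residue {resid}")
        if hits.size > 1:
            raise SelectionError(
                f"selection chain {chain!r} residue {resid} atom {atom!r} is ambiguous "
                f"({hits.size} matches)"
            )
        return int(hits[0])

    def copy(self) -> "Structure":
        return Structure(
            self.chain_id.copy(),
            self.res_id.copy(),
            self.res_name.copy(),
            self.atom_name.copy(),
            self.element.copy(),
            self.coords.copy(),
        )


@dataclass
class TrajectoryEnsemble:
    """Ordered coordinate frames over one shared atom table.

    ``ph_label`` tags which constant-pH ensemble the frames sample;
    ``frame_stride_ps`` is the wall-clock spacing of saved frames.
    """

    topology: Structure
    frames: np.ndarray  # (n_frames, N, 3) Å
    ph_label: float = float("nan")
    frame_stride_ps: float = field(default=1.0)

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim == 2:
            self.frames = self.frames[None]
        if self.frames.ndim != 3 or self.frames.shape[1] != self.topology.n_atoms:
            raise SelectionError(
                "frames must be (n_frames, n_atoms, 3) matching the atom table; "
                f"got {self.frames.shape} for {self.topology.n_atoms} atoms"
            )

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.topology.n_atoms

    def __len__(self) -> int:
        return self.n_frames
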