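"""Comparative-ensemble statistics for detecting pH-dependent conformational
change.

These are the operators used to contrast constant-pH trajectory ensembles
tagged with different pH labels: inter-subunit Cα distances, backbone RMSD
distributions after optimal superposition, side-chain χ1/χ2 dihedral
histograms, hydrogen-bond donor–acceptor distance densities, minimum
side-chain distances between residue pairs, and the retained fraction of
native contacts at a 5 Å heavy-atom cutoff.

All distances are in Å, angles in degrees. Every operator is invariant
under a global rotation + translation applied to all frames, and every
distribution summary is invariant under frame reordering.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.transform import Rotation
from scipy.stats import gaussian_kde

from .errors import (
    NoContactsError,
    NoDihedralError,
    NoSidechainError,
    SelectionError,
    UnderdeterminedFitError,
)
from .structure import TrajectoryEnsemble

__all__ = [
    "DistributionSummary",
    "summarize_distribution",
    "intersubunit_ca_distance",
    "backbone_rmsd_distribution",
    "dihedral_angles",
    "chi_dihedral_histogram",
    "Chi2DHistogram",
    "hbond_distance_density",
    "min_sidechain_distance",
    "native_contacts_fraction",
]

BACKBONE_ATOMS = ("N", "CA", "C", "O")

#: Standard side-chain χ1/χ2 atom quadruples per residue type.
CHI_ATOMS: dict[str, list[tuple[str, str, str, str]]] = {
    "ARG": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD")],
    "ASN": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "OD1")],
    "ASP": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "OD1")],
    "CYS": [("N", "CA", "CB", "SG")],
    "GLN": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD")],
    "GLU": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD")],
    "HIS": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "ND1")],
    "ILE": [("N", "CA", "CB", "CG1"), ("CA", "CB", "CG1", "CD1")],
    "LEU": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD1")],
    "LYS": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD")],
    "MET": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "SD")],
    "PHE": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD1")],
    "PRO": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD")],
    "SER": [("N", "CA", "CB", "OG")],
    "THR": [("N", "CA", "CB", "OG1")],
    "TRP": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD1")],
    "TYR": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD1")],
    "VAL": [("N", "CA", "CB", "CG1")],
}


@dataclass
class DistributionSummary:
    """Per-frame scalar values with a Gaussian-kernel density estimate."""

    values: np.ndarray
    kde_x: np.ndarray
    kde_density: np.ndarray
    mean: float
    median: float


def summarize_distribution(
    values: np.ndarray, bandwidth: float | str | None = None, grid_points: int = 512
) -> DistributionSummary:
    """Kernel density summary of per-frame values (Scott's rule by default).

    Degenerate (constant) samples get a narrow Gaussian bump centered on the
    constant so the density still integrates to one.
    """
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise SelectionError("cannot summarize an empty value set")
    spread = float(np.std(values))
    if spread < 1e-9 * max(1.0, abs(float(np.mean(values)))) or values.size < 2:
        # degenerate (constant) sample: narrow Gaussian bump at the value
        bw = 1e-3
        center = float(np.mean(values))
        x = np.linspace(center - 6 * bw, center + 6 * bw, grid_points)
        dens = np.exp(-0.5 * ((x - center) / bw) ** 2) / (bw * np.sqrt(2 * np.pi))
    else:
        kde = gaussian_kde(values, bw_method=bandwidth or "scott")
        half_width = 4.0 * spread * kde.factor + 0.5 * np.ptp(values)
        x = np.linspace(
            values.min() - half_width, values.max() + half_width, grid_points
        )
        dens = kde(x)
    return DistributionSummary(
        values=values,
        kde_x=x,
        kde_density=dens,
        mean=float(np.mean(values)),
        median=float(np.median(values)),
    )


def _pairwise_distance(traj: TrajectoryEnsemble, i: int, j: int) -> np.ndarray:
    return np.linalg.norm(traj.frames[:, i] - traj.frames[:, j], axis=1)


def intersubunit_ca_distance(
    traj: TrajectoryEnsemble,
    residue: tuple[int, str],
    chain_a: str,
    chain_b: str,
) -> DistributionSummary:
    """Per-frame distance between the Cα atoms of the same residue in two
    chains (subunits), e.g. M373–M373 across the dimer interface."""
    if chain_a == chain_b:
        raise SelectionError(
            f"inter-subunit distance needs two distinct chains, got {chain_a!r} twice"
        )
    resnum, resname = residue
    top = traj.topology
    ia = top.atom_index(chain_a, resnum, "CA")
    ib = top.atom_index(chain_b, resnum, "CA")
    for idx, chain in ((ia, chain_a), (ib, chain_b)):
        if str(top.res_name[idx]) != resname:
            raise SelectionError(
                f"residue {resnum} in chain {chain} is {top.res_name[idx]}, "
                f"expected {resname}"
            )
    return summarize_distribution(_pairwise_distance(traj, ia, ib))


def superpose(mobile: np.ndarray, reference: np.ndarray) -> np.ndarray:
    """Least-squares (Kabsch) superposition of one coordinate set onto a
    reference; returns the transformed mobile coordinates."""
    if len(mobile) < 3:
        raise UnderdeterminedFitError(
            f"superposition needs at least 3 atoms, got {len(mobile)}"
        )
    mob_c = mobile - mobile.mean(axis=0)
    ref_c = reference - reference.mean(axis=0)
    rot, _ = Rotation.align_vectors(ref_c, mob_c)
    return rot.apply(mob_c) + reference.mean(axis=0)


def backbone_rmsd_distribution(
    traj: TrajectoryEnsemble,
    reference: np.ndarray,
    chains: list[str] | None = None,
    residue_range: tuple[int, int] | None = None,
    atom_names: tuple[str, ...] = BACKBONE_ATOMS,
) -> DistributionSummary:
    """Per-frame backbone RMSD to a reference after optimal superposition.

    The selection (chains × residue range × backbone atom names) is used
    both for the fit and for the RMSD, matching per-helix RMSD
    distributions relative to a starting conformation.
    """
    top = traj.topology
    mask = np.isin(top.atom_name, list(atom_names))
    if chains is not None:
        mask &= np.isin(top.chain_id, chains)
    if residue_range is not None:
        lo, hi = residue_range
        mask &= (top.res_id >= lo) & (top.res_id <= hi)
    idx = np.flatnonzero(mask)
    if idx.size == 0:
        raise SelectionError("backbone selection matched no atoms")
    if idx.size < 3:
        raise UnderdeterminedFitError(
            f"superposition needs at least 3 atoms, got {idx.size}"
        )
    reference = np.asarray(reference, dtype=float)
    if reference.shape != (top.n_atoms, 3):
        raise SelectionError(
            f"reference must match the atom table: expected {(top.n_atoms, 3)}, "
            f"got {reference.shape}"
        )
    ref_sel = reference[idx]
    rmsds = np.empty(traj.n_frames)
    for f in range(traj.n_frames):
        moved = superpose(traj.frames[f, idx], ref_sel)
        rmsds[f] = np.sqrt(np.mean(np.sum((moved - ref_sel) ** 2, axis=1)))
    return summarize_distribution(rmsds)


def dihedral_angles(
    p0: np.ndarray, p1: np.ndarray, p2: np.ndarray, p3: np.ndarray
) -> np.ndarray:
    """Signed dihedral angle (degrees, in (−180, 180]) for stacked frames."""
    b0 = p1 - p0
    b1 = p2 - p1
    b2 = p3 - p2
    n1 = np.cross(b0, b1)
    n2 = np.cross(b1, b2)
    m1 = np.cross(n1, b1 / np.linalg.norm(b1, axis=-1, keepdims=True))
    x = np.sum(n1 * n2, axis=-1)
    y = np.sum(m1 * n2, axis=-1)
    ang = np.degrees(np.arctan2(y, x))
    return np.where(ang <= -180.0, ang + 360.0, ang)


@dataclass
class Chi2DHistogram:
    """Normalized 2D probability histogram over (χ1, χ2), degrees."""

    chi1: np.ndarray  # per-frame χ1
    chi2: np.ndarray  # per-frame χ2
    edges: np.ndarray  # shared bin edges for both axes
    probability: np.ndarray  # (nbins, nbins), sums to 1


def chi_dihedral_histogram(
    traj: TrajectoryEnsemble,
    chain: str,
    resnum: int,
    bin_width: float = 10.0,
) -> Chi2DHistogram:
    """2D histogram of side-chain χ1/χ2 for one residue across frames."""
    top = traj.topology
    mask = top.residue_mask(chain, resnum)
    if not mask.any():
        raise SelectionError(f"no residue {resnum} in chain {chain!r}")
    resname = str(top.res_name[np.flatnonzero(mask)[0]])
    quads = CHI_ATOMS.get(resname, [])
    if len(quads) < 2:
        raise NoDihedralError(
            f"{resname} {chain}{resnum} has no defined chi2 dihedral"
        )
    chis = []
    for quad in quads[:2]:
        idx = [top.atom_index(chain, resnum, name) for name in quad]
        chis.append(
            dihedral_angles(*(traj.frames[:, i] for i in idx))
        )
    edges = np.arange(-180.0, 180.0 + bin_width / 2, bin_width)
    hist, _, _ = np.histogram2d(chis[0], chis[1], bins=[edges, edges])
    total = hist.sum()
    return Chi2DHistogram(chis[0], chis[1], edges, hist / total)


def hbond_distance_density(
    traj: TrajectoryEnsemble,
    donor_sel: tuple[str, int, str],
    acceptor_sel: tuple[str, int, str],
    bandwidth: float | str | None = None,
) -> DistributionSummary:
    """Kernel density of a donor–acceptor distance over frames.

    Each selection is (chain, residue number, atom name) and must resolve
    to exactly one atom.
    """
    if traj.n_frames == 0:
        raise SelectionError("trajectory has no frames")
    top = traj.topology
    i = top.atom_index(*donor_sel)
    j = top.atom_index(*acceptor_sel)
    return summarize_distribution(_pairwise_distance(traj, i, j), bandwidth=bandwidth)


def _sidechain_heavy(traj: TrajectoryEnsemble, chain: str, resnum: int) -> np.ndarray:
    top = traj.topology
    mask = top.residue_mask(chain, resnum)
    if not mask.any():
        raise SelectionError(f"no residue {resnum} in chain {chain!r}")
    mask &= ~np.isin(top.atom_name, list(BACKBONE_ATOMS) + ["OXT"])
    mask &= np.char.upper(top.element) != "H"
    idx = np.flatnonzero(mask)
    if idx.size == 0:
        resname = top.res_name[top.residue_mask(chain, resnum)][0]
        raise NoSidechainError(
            f"{resname} {chain}{resnum} has no side-chain heavy atoms"
        )
    return idx


def min_sidechain_distance(
    traj: TrajectoryEnsemble,
    res_a: tuple[str, int],
    res_b: tuple[str, int],
) -> DistributionSummary:
    """Per-frame minimum distance over all side-chain heavy-atom pairs of
    two residues (e.g. the R230–E414 salt-bridge indicator)."""
    if res_a == res_b:
        raise SelectionError("minimum side-chain distance needs two distinct residues")
    ia = _sidechain_heavy(traj, *res_a)
    ib = _sidechain_heavy(traj, *res_b)
    diff = traj.frames[:, ia, None, :] - traj.frames[:, None, ib, :]
    dmin = np.min(np.linalg.norm(diff, axis=-1), axis=(1, 2))
    return summarize_distribution(dmin)


def native_contacts_fraction(
    traj: TrajectoryEnsemble,
    reference: np.ndarray,
    cutoff: float = 5.0,
    min_seq_separation: int = 3,
) -> np.ndarray:
    """Per-frame retained fraction of native heavy-atom contacts.

    The contact set is defined on the reference structure: heavy-atom pairs
    from residues at least ``min_seq_separation`` apart in sequence (or on
    different chains) whose reference distance is within ``cutoff``.
    Counting is hard (step function at the cutoff).
    """
    top = traj.topology
    reference = np.asarray(reference, dtype=float)
    heavy = np.flatnonzero(np.char.upper(top.element) != "H")
    pairs = []
    for a_pos, i in enumerate(heavy):
        for j in heavy[a_pos + 1 :]:
            different_chain = top.chain_id[i] != top.chain_id[j]
            far_in_seq = abs(int(top.res_id[i]) - int(top.res_id[j])) >= min_seq_separation
            if not (different_chain or far_in_seq):
                continue
            if np.linalg.norm(reference[i] - reference[j]) <= cutoff:
                pairs.append((i, j))
    if not pairs:
        raise NoContactsError(
            "reference structure has no native contacts under the current "
            f"cutoff ({cutoff} Å) and sequence-separation rule"
        )
    pi, pj = np.array(pairs).T
    d = np.linalg.norm(traj.frames[:, pi] - traj.frames[:, pj], axis=-1)
    return np.mean(d <= cutoff, axis=1)
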