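"""Net-charge conservation by redistribution onto the solvent.

Interpolating titratable-residue charges with pH changes the solute's net
charge by a pH-dependent, generally non-integer amount. To keep the total
system charge fixed across the whole pH range — mimicking a wet-lab
titration, where the bath absorbs the protons — the excess charge is spread
over the water molecules.

Two spreading modes are provided:

* ``"oxygen"`` (default): a uniform shift on every water oxygen. Minimal
  perturbation per molecule; hydrogen charges stay standard.
* ``"all_atoms"``: the correction divided uniformly over every water atom
  (O and H alike).

Both leave solute charges and all geometry untouched.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import CannotNeutralizeError, InvalidParameterError
from .forcefield import ScaledSystem

__all__ = ["NeutralizationReport", "neutralize"]


@dataclass
class NeutralizationReport:
    """Bookkeeping for one neutralization: how much excess charge existed,
    how it was spread, and the net charge actually achieved."""

    excess_charge: float  # e, before correction
    n_water: int
    per_water_correction: float  # e, shift applied per carrier atom
    target_net_charge: float  # e
    achieved_net_charge: float  # e
    mode: str = "oxygen"


def neutralize(
    system: ScaledSystem,
    target_net_charge: float | None = None,
    mode: str = "oxygen",
) -> tuple[ScaledSystem, NeutralizationReport]:
    """Shift water charges so the system's net charge equals the target.

    ``target_net_charge`` defaults to 0 e (a counterion-balanced build);
    pass the net charge of the fully protonated system to preserve it
    instead. Returns a corrected copy of the system plus a report; the input
    system is not modified. Raises :class:`CannotNeutralizeError` when a
    nonzero excess has no water to carry it.
    """
    if mode not in ("oxygen", "all_atoms"):
        raise InvalidParameterError(f"unknown neutralization mode {mode!r}")
    target = 0.0 if target_net_charge is None else float(target_net_charge)

    out = system.copy()
    excess = out.net_charge - target
    carriers = (
        out.water_oxygen_indices if mode == "oxygen" else out.water_atom_indices
    )
    n_water = int(out.water_oxygen_indices.size)

    per_water = 0.0
    if carriers.size == 0:
        if abs(excess) > 1e-12:
            raise CannotNeutralizeError(
                f"excess charge {excess:+.6f} e but no water molecules to absorb it"
            )
    else:
        per_water = -excess / n_water
        out.charges[carriers] += -excess / carriers.size

    report = NeutralizationReport(
        excess_charge=float(excess),
        n_water=n_water,
        per_water_correction=float(per_water),
        target_net_charge=target,
        achieved_net_charge=out.net_charge,
        mode=mode,
    )
    return out, report
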