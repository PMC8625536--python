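"""Protonation probabilities for titratable sites.

The ECpH scheme represents the protonation state of each titratable residue
(Asp, Glu, His, Cys, Lys) not as a binary occupancy but as an ensemble
protonation probability λ ∈ [0, 1], computed from the equilibrium constant of
the protonation/deprotonation reaction via the Hill equation

    λ(pH) = 1 / (1 + 10^(n·(pH − pKa)))

with Hill coefficient n = 1 for independent single-proton sites (the
Henderson–Hasselbalch protonated fraction). λ is evaluated once per ambient
pH when the effective force field is built and held constant during sampling.

Histidine carries two parameters: the λ that models deprotonation of the
doubly protonated (+1) imidazole, and a binary tautomer flag selecting which
neutral form (ε or δ) is the deprotonated endpoint. The second His constant
(9.1) associated with the tautomer channel is stored on
:class:`TitrationParameters` but does not enter the default λ computation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping

from .errors import InvalidParameterError, UnknownSiteError

__all__ = [
    "EPSILON_TAUTOMER",
    "DELTA_TAUTOMER",
    "TITRATABLE_RESIDUES",
    "TitratableSite",
    "TitrationParameters",
    "protonation_probability",
    "assign_site_lambdas",
]

EPSILON_TAUTOMER = "epsilon"
DELTA_TAUTOMER = "delta"

#: Residue types carrying a titratable proton.
TITRATABLE_RESIDUES = frozenset({"ASP", "GLU", "HIS", "CYS", "LYS"})

#: Default model pKa per residue type (pH units).
MODEL_PKAS: dict[str, float] = {
    "GLU": 4.4,
    "ASP": 4.0,
    "LYS": 10.4,
    "HIS": 6.5,
    "CYS": 9.5,
}

#: Secondary histidine constant tied to the tautomer channel; unused by the
#: default single-transition λ model.
HIS_TAUTOMER_PKA = 9.1


@dataclass
class TitratableSite:
    """One protonatable site in a structure.

    ``titratable=False`` freezes the site in the protonated state (λ = 1);
    this is how disulfide-bonded cysteines are handled.
    """

    chain_id: str
    residue_number: int
    residue_type: str
    pka: float = math.nan
    lambda_: float = 1.0
    tautomer: str | None = None
    titratable: bool = True

    def __post_init__(self) -> None:
        if self.residue_type not in TITRATABLE_RESIDUES:
            raise InvalidParameterError(
                f"unsupported residue type {self.residue_type!r}; "
                f"titratable types are {sorted(TITRATABLE_RESIDUES)}"
            )
        if self.residue_type == "HIS":
            if self.tautomer is None:
                self.tautomer = EPSILON_TAUTOMER
            if self.tautomer not in (EPSILON_TAUTOMER, DELTA_TAUTOMER):
                raise InvalidParameterError(f"unknown tautomer {self.tautomer!r}")
        elif self.tautomer is not None:
            raise InvalidParameterError("tautomer flag is defined only for HIS")
        if not 0.0 <= self.lambda_ <= 1.0:
            raise InvalidParameterError(f"lambda must lie in [0, 1], got {self.lambda_}")

    @property
    def key(self) -> tuple[str, int]:
        return (self.chain_id, self.residue_number)


@dataclass
class TitrationParameters:
    """Hill coefficient and the per-residue-type model pKa table."""

    hill_coefficient: float = 1.0
    model_pkas: Mapping[str, float] = field(default_factory=lambda: dict(MODEL_PKAS))

    def __post_init__(self) -> None:
        if not (math.isfinite(self.hill_coefficient) and self.hill_coefficient > 0):
            raise InvalidParameterError(
                f"Hill coefficient must be finite and positive, got {self.hill_coefficient}"
            )


def protonation_probability(ph: float, pka: float, hill_coefficient: float = 1.0) -> float:
    """Protonated fraction λ of a single site at the given ambient pH.

    λ = 1 / (1 + 10^(n·(pH − pKa))). Strictly decreasing in pH, equal to 1/2
    at pH = pKa, and approaching 1 (0) far below (above) the pKa.
    """
    if not (math.isfinite(hill_coefficient) and hill_coefficient > 0):
        raise InvalidParameterError(
            f"Hill coefficient must be finite and positive, got {hill_coefficient}"
        )
    if not (math.isfinite(ph) and math.isfinite(pka)):
        raise InvalidParameterError("pH and pKa must be finite")
    x = hill_coefficient * (ph - pka)
    # 10**x overflows float64 near x ~ 308; the limit value is exact there.
    if x > 300.0:
        return 0.0
    return 1.0 / (1.0 + 10.0**x)


def assign_site_lambdas(
    sites: list[TitratableSite],
    ph: float,
    params: TitrationParameters | None = None,
    overrides: Mapping[tuple[str, int], float] | None = None,
    *,
    known_sites: set[tuple[str, int]] | None = None,
) -> list[TitratableSite]:
    """Resolve each site's pKa (override > model value) and recompute λ.

    Non-titratable sites are frozen at λ = 1. ``overrides`` maps
    (chain, residue_number) to an individual pKa, e.g. from an ensemble pKa
    prediction; an override naming a residue that is not among the sites (nor
    in ``known_sites``, when the caller passes the full structure inventory)
    raises :class:`UnknownSiteError`.
    """
    params = params or TitrationParameters()
    overrides = dict(overrides or {})

    present = {s.key for s in sites}
    checkable = present if known_sites is None else present | set(known_sites)
    missing = sorted(set(overrides) - checkable)
    if missing:
        raise UnknownSiteError(
            f"pKa override(s) for residues absent from the structure: {missing}"
        )

    out: list[TitratableSite] = []
    for site in sites:
        if not site.titratable:
            out.append(replace(site, lambda_=1.0))
            continue
        pka = overrides.get(site.key, params.model_pkas[site.residue_type])
        lam = protonation_probability(ph, pka, params.hill_coefficient)
        out.append(replace(site, pka=pka, lambda_=lam))
    return out
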