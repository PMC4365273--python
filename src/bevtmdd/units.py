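"""Unit handling for molar/mass concentration interconversion.

All internal model computation uses nanomolar (nM) concentrations and days;
mass units (mg/L for total antibody, ng/L for free ligand) appear only at
I/O boundaries.  Conversion requires the molar masses of the two binding
partners, collected in :class:`MolarConstants`.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = [
    "MolarConstants",
    "DEFAULT_MOLAR_CONSTANTS",
    "mass_to_molar",
    "molar_to_mass",
]

#: grams per mole, by mass-concentration unit, needed to land on nmol/L.
#: ng/L divided by g/mol is already nmol/L, hence factor 1.
_UNIT_TO_NG_PER_L = {"ng/L": 1.0, "ug/L": 1e3, "mg/L": 1e6, "g/L": 1e9}


@dataclass(frozen=True)
class MolarConstants:
    """Molar masses (g/mol) of the drug and its soluble target.

    Defaults: a full-length IgG1 monoclonal antibody (149 kDa) binding the
    VEGF165 homodimer.  The 40 kDa target mass reproduces the reported
    baseline pair 212 ng/L = 0.0053 nM exactly.
    """

    mw_drug: float = 149_000.0
    mw_target: float = 40_000.0

    def __post_init__(self) -> None:
        if self.mw_drug <= 0 or self.mw_target <= 0:
            raise ValueError("molar masses must be strictly positive")


DEFAULT_MOLAR_CONSTANTS = MolarConstants()


def mass_to_molar(value: float, mw: float, unit: str = "ng/L") -> float:
    """Convert a mass concentration to nM.

    Parameters
    ----------
    value : mass concentration (>= 0) in ``unit``.
    mw : molar mass in g/mol (> 0).
    unit : one of ``ng/L``, ``ug/L``, ``mg/L``, ``g/L``.
    """
    if mw <= 0:
        raise ValueError(f"molar mass must be > 0, got {mw}")
    try:
        factor = _UNIT_TO_NG_PER_L[unit]
    except KeyError:
        raise ValueError(f"unknown mass-concentration unit {unit!r}") from None
    return value * factor / mw


def molar_to_mass(value: float, mw: float, unit: str = "ng/L") -> float:
    """Convert a nM concentration to a mass concentration in ``unit``.

    Exact inverse of :func:`mass_to_molar`.
    """
    if mw <= 0:
        raise ValueError(f"molar mass must be > 0, got {mw}")
    try:
        factor = _UNIT_TO_NG_PER_L[unit]
    except KeyError:
        raise ValueError(f"unknown mass-concentration unit {unit!r}") from None
    return value * mw / factor


def dose_mg_to_nmol(amount_mg: float, mw: float) -> float:
    """Convert a dose amount in mg to nmol (mg / (g/mol) * 1e6)."""
    if mw <= 0:
        raise ValueError(f"molar mass must be > 0, got {mw}")
    return amount_mg / mw * 1e6
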