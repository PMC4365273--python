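"""Reference parameter sets of the bevacizumab-VEGF165 analysis.

These are the published population estimates for a 70 kg reference
patient and define the study conditions the synthetic-data generator
emulates: the PK-only model (total antibody analysed alone, proportional
error) and the simultaneous QSS TMDD model (both analytes, additive
error on the log scale, complex clearance tied to CL).
"""

from __future__ import annotations

from .dataset import Analyte
from .population import (
    ErrorModel,
    PopulationModelSpec,
    ResidualErrorSpec,
    StructuralModel,
    allometric_relations,
)
from .structural import PKParameters, TMDDParameters
from .units import DEFAULT_MOLAR_CONSTANTS, mass_to_molar

__all__ = [
    "REFERENCE_WEIGHT_KG",
    "PK_TYPICAL",
    "TMDD_TYPICAL",
    "BM0_NG_PER_L",
    "pk_reference_spec",
    "tmdd_reference_spec",
]

REFERENCE_WEIGHT_KG = 70.0

#: free-target baseline in reported units (ng/L); 0.0053 nM at 40 kDa
BM0_NG_PER_L = 212.0
_BM0_NM = mass_to_molar(BM0_NG_PER_L, DEFAULT_MOLAR_CONSTANTS.mw_target, "ng/L")

#: two-compartment PK model, total antibody analysed alone
PK_TYPICAL = PKParameters(CL=0.17, V1=3.14, Q=0.36, V2=2.63)

#: simultaneous TMDD model; CL_RC = CL
TMDD_TYPICAL = TMDDParameters(
    CL=0.18, V1=3.23, Q=1.38, V2=3.1,
    CL_RC=0.18, BM0=_BM0_NM, kout=0.401, Kss=267.0,
)

#: inter-individual variability (CV fraction = omega) and residual SDs
PK_IIV = {"CL": 0.23, "V1": 0.15}
PK_SIGMA_PROP = 0.24
TMDD_IIV = {"CL": 0.20, "V1": 0.22, "BM0": 0.33}
TMDD_SIGMA_LOG = {Analyte.TOTAL_DRUG: 0.28, Analyte.FREE_TARGET: 0.32}


def pk_reference_spec(allometric: bool = True) -> PopulationModelSpec:
    """Step-1 population model at the published estimates: 2-compartment
    PK, IIV on CL and V1, proportional error, allometric weight scaling
    (exponent 0.75 on clearances, 1 on volumes, reference 70 kg)."""
    return PopulationModelSpec(
        structural=StructuralModel.LINEAR_PK,
        theta={"CL": PK_TYPICAL.CL, "V1": PK_TYPICAL.V1,
               "Q": PK_TYPICAL.Q, "V2": PK_TYPICAL.V2},
        omega2={p: w**2 for p, w in PK_IIV.items()},
        error={Analyte.TOTAL_DRUG: ResidualErrorSpec(
            ErrorModel.PROPORTIONAL, PK_SIGMA_PROP
        )},
        relations=tuple(
            allometric_relations(["CL", "V1", "Q", "V2"], REFERENCE_WEIGHT_KG)
        ) if allometric else (),
    )


def tmdd_reference_spec(allometric: bool = True) -> PopulationModelSpec:
    """Step-2 population model at the published estimates: QSS TMDD with
    CL_RC tied to CL, IIV on CL, V1 and BM0, additive-log error per
    analyte, allometric weight on all clearance and volume parameters."""
    return PopulationModelSpec(
        structural=StructuralModel.QSS_TMDD,
        theta={"CL": TMDD_TYPICAL.CL, "V1": TMDD_TYPICAL.V1,
               "Q": TMDD_TYPICAL.Q, "V2": TMDD_TYPICAL.V2,
               "BM0": TMDD_TYPICAL.BM0, "kout": TMDD_TYPICAL.kout,
               "Kss": TMDD_TYPICAL.Kss},
        omega2={p: w**2 for p, w in TMDD_IIV.items()},
        error={a: ResidualErrorSpec(ErrorModel.ADDITIVE_LOG, s)
               for a, s in TMDD_SIGMA_LOG.items()},
        relations=tuple(
            allometric_relations(["CL", "V1", "Q", "V2"], REFERENCE_WEIGHT_KG)
        ) if allometric else (),
    )
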