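"""Built-in reconstitution conditions for the NaAtm1 ATPase assay.

Three named conditions — detergent micelles (DDM/C12E8), MSP1D1 nanodiscs,
and proteoliposomes — are preloaded with the published global-fit kinetic
parameters, their reported standard errors, the basal turnover numbers from
the per-GSSG-level Michaelis–Menten fits, and the assay design (replicate
counts, sampling times, protein loading).  Rate constants are per transporter
homodimer (MW 135 kDa).
"""

from __future__ import annotations

from .errors import UnknownConditionError
from .models import ActivatorParams

CONDITIONS = ("detergent", "nanodiscs", "proteoliposomes")

#: Published five-parameter global-fit estimates per condition.
REFERENCE_PARAMS: dict[str, ActivatorParams] = {
    "detergent": ActivatorParams(k=17.58, K_T=0.82, K_S=13.34, alpha=1.03, beta=8.30),
    "nanodiscs": ActivatorParams(k=31.86, K_T=1.41, K_S=9.65, alpha=10.05, beta=76.60),
    "proteoliposomes": ActivatorParams(k=9.49, K_T=1.64, K_S=12.79, alpha=2.64, beta=28.69),
}

#: Reported asymptotic standard errors for the estimates above, same order
#: as ActivatorParams.names().
REFERENCE_SE: dict[str, dict[str, float]] = {
    "detergent": {"k": 0.75, "K_T": 0.07, "K_S": 2.20, "alpha": 0.20, "beta": 0.46},
    "nanodiscs": {"k": 1.04, "K_T": 0.08, "K_S": 0.74, "alpha": 1.73, "beta": 8.68},
    "proteoliposomes": {"k": 1.26, "K_T": 0.34, "K_S": 4.09, "alpha": 1.26, "beta": 6.30},
}

#: Basal (no activator) turnover numbers from per-GSSG Michaelis-Menten
#: fits, min^-1, uncorrected for orientation.
BASAL_KCAT: dict[str, float] = {
    "detergent": 18.0,
    "nanodiscs": 30.9,
    "proteoliposomes": 9.5,
}

#: Replicates per concentration cell in the assay design.
N_REPLICATES: dict[str, int] = {
    "detergent": 6,
    "nanodiscs": 3,
    "proteoliposomes": 6,
}

#: MgATP (mM) and GSSG (mM) concentration series of the assay design.
ATP_CONCENTRATIONS_MM = (0.0, 0.1, 0.2, 0.5, 1.0, 2.0, 5.0, 10.0)
GSSG_CONCENTRATIONS_MM = (0.0, 1.0, 2.5, 5.0, 10.0, 20.0)

#: Sampling times, min: one aliquot every 5 min, four aliquots.
TIME_POINTS_MIN = (0.0, 5.0, 10.0, 15.0)

TRANSPORTER_MW_KDA = 135.0
SCAFFOLD_MW_KDA = 25.0
SCAFFOLDS_PER_TRANSPORTER = 2
ASSAY_PROTEIN_MASS_MG_PER_ML = 0.05


def require_condition(name: str) -> str:
    """Validate a condition name, returning it; raise UnknownConditionError otherwise."""
    if name not in CONDITIONS:
        raise UnknownConditionError(
            f"unknown condition {name!r}; expected one of {CONDITIONS}"
        )
    return name
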