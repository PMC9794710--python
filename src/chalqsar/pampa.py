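"""PAMPA effective permeability and CNS-permeation classification.

The effective permeability of a sandwich-plate PAMPA well is

    Pe = -ln(1 - C_A / C_eq) / (A * (1/V_D + 1/V_A) * t)      [cm/s]

with the theoretical equilibrium concentration

    C_eq = (C_D * V_D + C_A * V_A) / (V_D + V_A)

where C_D/C_A are the end-point donor/acceptor concentrations (any
consistent units), V_D/V_A the compartment volumes (mL), A the effective
filter area (cm²) and t the incubation time (s).

Classification thresholds: Pe > 4.0e-6 cm/s -> CNS+, Pe < 2.0e-6 -> CNS−,
the closed interval [2.0e-6, 4.0e-6] -> uncertain.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass

from .errors import DomainError, SaturationError

__all__ = [
    "CnsClass",
    "PampaWell",
    "PampaResult",
    "CNS_PLUS_THRESHOLD",
    "CNS_MINUS_THRESHOLD",
    "equilibrium_concentration",
    "classify_pe",
    "effective_permeability",
]

CNS_PLUS_THRESHOLD = 4.0e-6  # cm/s
CNS_MINUS_THRESHOLD = 2.0e-6  # cm/s


class CnsClass(str, enum.Enum):
    CNS_PLUS = "CNS+"
    CNS_MINUS = "CNS-"
    CNS_UNCERTAIN = "CNS+/-"


@dataclass(frozen=True)
class PampaWell:
    c_donor: float
    c_acceptor: float
    v_donor: float  # mL
    v_acceptor: float  # mL
    area: float = 0.3  # cm²
    time: float = 64800.0  # s (18 h default incubation)

    def __post_init__(self):
        if min(self.v_donor, self.v_acceptor, self.area, self.time) <= 0:
            raise DomainError("volumes, area and time must be positive")
        if self.c_acceptor < 0 or self.c_donor < 0:
            raise DomainError("concentrations must be non-negative")


@dataclass(frozen=True)
class PampaResult:
    pe: float  # cm/s
    cns_class: CnsClass


def equilibrium_concentration(w: PampaWell) -> float:
    """Volume-weighted mean concentration of the two compartments."""
    total = w.v_donor + w.v_acceptor
    if total <= 0:
        raise DomainError("total volume must be positive")
    return (w.c_donor * w.v_donor + w.c_acceptor * w.v_acceptor) / total


def classify_pe(pe: float) -> CnsClass:
    if pe > CNS_PLUS_THRESHOLD:
        return CnsClass.CNS_PLUS
    if pe < CNS_MINUS_THRESHOLD:
        return CnsClass.CNS_MINUS
    return CnsClass.CNS_UNCERTAIN


def effective_permeability(w: PampaWell) -> PampaResult:
    """Effective permeability (cm/s) and CNS class for one well.

    Raises :class:`SaturationError` when the acceptor concentration has
    reached the equilibrium value (the log expression diverges; the
    incubation was too long to resolve Pe).
    """
    c_eq = equilibrium_concentration(w)
    if w.c_acceptor >= c_eq and not (w.c_acceptor == 0 and c_eq == 0):
        raise SaturationError(
            f"acceptor concentration {w.c_acceptor} at/above equilibrium {c_eq}"
        )
    if w.c_acceptor == 0:
        pe = 0.0
    else:
        pe = -math.log(1.0 - w.c_acceptor / c_eq) / (
            w.area * (1.0 / w.v_donor + 1.0 / w.v_acceptor) * w.time
        )
    return PampaResult(pe=pe, cns_class=classify_pe(pe))
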