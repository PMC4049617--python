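"""Core value types: metabolite state, fixed environment, enzyme levels.

Concentrations are in mM, rates in mM/h, time in h throughout the package.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields, replace
from typing import Iterator

import numpy as np

from .errors import DomainError

#: Order of the twelve balanced glycolytic intermediates.  This fixes the
#: meaning of every state vector, Jacobian row and trajectory column in the
#: package: intracellular glucose, then the hexose phosphates (including
#: fructose-2,6-bisphosphate, which is balanced because the PFKFB reaction
#: couples it dynamically to the rest of the pathway), the trioses, and the
#: lower-glycolysis intermediates down to cytosolic pyruvate.
SPECIES: tuple[str, ...] = (
    "GLC",     # intracellular glucose
    "G6P",     # glucose-6-phosphate
    "F6P",     # fructose-6-phosphate
    "F16BP",   # fructose-1,6-bisphosphate
    "F26BP",   # fructose-2,6-bisphosphate
    "DHAP",    # dihydroxyacetone phosphate
    "GAP",     # glyceraldehyde-3-phosphate
    "BPG13",   # 1,3-bisphosphoglycerate
    "PG3",     # 3-phosphoglycerate
    "PG2",     # 2-phosphoglycerate
    "PEP",     # phosphoenolpyruvate
    "PYR",     # cytosolic pyruvate
)

N_SPECIES = len(SPECIES)

#: Enzyme / transport-step roster (keys of EnzymeLevels and of flux dicts).
ENZYMES: tuple[str, ...] = (
    "GLUT", "HK", "PGI", "PFK", "PFKFB", "ALDO", "TPI",
    "GAPDH", "PGK", "PGAM", "ENO", "PK", "LDH", "MCT_MITO", "ALA_SINK",
)


@dataclass(frozen=True)
class MetaboliteState:
    """Concentrations (mM) of the 12 balanced glycolytic intermediates."""

    GLC: float
    G6P: float
    F6P: float
    F16BP: float
    F26BP: float
    DHAP: float
    GAP: float
    BPG13: float
    PG3: float
    PG2: float
    PEP: float
    PYR: float

    def __post_init__(self) -> None:
        for name in SPECIES:
            value = getattr(self, name)
            if not np.isfinite(value):
                raise DomainError(f"concentration of {name} is not finite: {value!r}")
            if value < 0:
                raise DomainError(f"concentration of {name} is negative: {value!r}")

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, name) for name in SPECIES], dtype=float)

    @classmethod
    def from_array(cls, values) -> "MetaboliteState":
        values = np.asarray(values, dtype=float)
        if values.shape != (N_SPECIES,):
            raise DomainError(f"state vector must have shape ({N_SPECIES},), got {values.shape}")
        return cls(**dict(zip(SPECIES, map(float, values))))

    def replace(self, **changes: float) -> "MetaboliteState":
        return replace(self, **changes)

    def __iter__(self) -> Iterator[float]:
        return iter(self.as_array())


@dataclass(frozen=True)
class Environment:
    """Concentrations held fixed during a solve or transient run (mM).

    Energy nucleotides, redox cofactors, ions, mitochondrial pyruvate,
    extracellular lactate and alanine, plus the extracellular glucose input.
    Holding these constant insulates the glycolytic balance equations from
    fluctuations elsewhere in metabolism.  ``PEP_NODE`` is only consulted by
    the reduced F6P-node subsystem, where phosphoenolpyruvate is not a
    balanced species but still feeds back on the PFKFB kinase domain.
    """

    ATP: float = 3.0
    ADP: float = 0.5
    AMP: float = 0.1
    NAD: float = 0.6
    NADH: float = 0.06
    MG: float = 0.8
    K: float = 140.0
    CA: float = 1e-4
    PYR_M: float = 0.1     # mitochondrial pyruvate
    LAC: float = 1.8       # extracellular lactate
    ALA: float = 0.5       # alanine pool seen by the transaminase-like sink
    GLC_EXT: float = 5.0   # extracellular glucose
    PEP_NODE: float = 0.008  # fixed PEP used by the isolated F6P-node subsystem

    def __post_init__(self) -> None:
        for f in fields(self):
            value = getattr(self, f.name)
            if not np.isfinite(value) or value < 0:
                raise DomainError(f"environment field {f.name} must be finite and >= 0, got {value!r}")

    def replace(self, **changes: float) -> "Environment":
        return replace(self, **changes)


@dataclass(frozen=True)
class EnzymeLevels:
    """Relative activity multipliers on each reference V_max (dimensionless).

    1.0 everywhere reproduces the reference proliferative-cell enzyme
    complement the default kinetic catalog was calibrated for.
    """

    GLUT: float = 1.0
    HK: float = 1.0
    PGI: float = 1.0
    PFK: float = 1.0
    PFKFB: float = 1.0
    ALDO: float = 1.0
    TPI: float = 1.0
    GAPDH: float = 1.0
    PGK: float = 1.0
    PGAM: float = 1.0
    ENO: float = 1.0
    PK: float = 1.0
    LDH: float = 1.0
    MCT_MITO: float = 1.0
    ALA_SINK: float = 1.0

    def __post_init__(self) -> None:
        for f in fields(self):
            value = getattr(self, f.name)
            if not np.isfinite(value) or value <= 0:
                raise DomainError(f"enzyme level {f.name} must be finite and > 0, got {value!r}")

    def get(self, enzyme: str) -> float:
        return getattr(self, enzyme)

    def replace(self, **changes: float) -> "EnzymeLevels":
        return replace(self, **changes)

    def as_dict(self) -> dict[str, float]:
        return {f.name: getattr(self, f.name) for f in fields(self)}
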