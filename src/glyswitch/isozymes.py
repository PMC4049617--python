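"""Isozyme-specific allosteric constants for PFK, PK and PFKFB.

The isoform-discriminating constants (F16BP activation constants, PK PEP
Km / ATP Ki values, PFKFB kinase-to-phosphatase activity ratios) are the
experimentally reported values for mammalian isozymes.  The remaining shape
constants of the rate laws (allosteric tension ``L0``, Hill orders, effector
constants for F26BP and AMP, half-saturations) are shared across isoforms of
an enzyme and were calibrated once so that the two-enzyme F6P node exhibits
its switch-down/switch-up concentrations at 0.09 and 0.30 mM F6P; the
provenance of every number is recorded in the bundled default config.

Absence of a regulation is structural: an isoform that is not activated by
F16BP carries ``ka_f16bp = None`` and the corresponding factor is omitted
from the rate law, not driven to a limit through a sentinel constant.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

from .errors import ConfigurationError


def _require_positive(name: str, value: float | None, allow_none: bool = False) -> None:
    if value is None:
        if allow_none:
            return
        raise ConfigurationError(f"required kinetic constant {name} is missing")
    if not value > 0:
        raise ConfigurationError(f"kinetic constant {name} must be > 0, got {value!r}")


@dataclass(frozen=True)
class PFKIsozyme:
    """Allosteric constants of one phosphofructokinase isoform.

    The rate law is V * s(F6P) / (1 + L) where the allosteric tension
    L = l0 * (ATP/ki_atp)^2 / [(1 + F16BP/ka_f16bp)^h_f16bp
    * (1 + F26BP/ka_f26bp)^h_f26bp * (1 + AMP/ka_amp)^h_amp]; the F16BP
    factor is present only for isoforms that carry feedback activation.
    """

    name: str
    ka_f16bp: float | None      # mM; None => no F16BP feedback activation (PFKP)
    ka_f26bp: float             # mM
    ka_amp: float               # mM
    ki_atp: float               # mM
    km_f6p: float               # mM (half-saturation of the Hill substrate term)
    l0: float                   # basal allosteric tension (dimensionless)
    h_f6p: float = 4.0
    h_f16bp: float = 4.0
    h_f26bp: float = 4.0
    h_amp: float = 2.0
    h_atp: float = 2.0

    def __post_init__(self) -> None:
        _require_positive(f"{self.name}.ka_f16bp", self.ka_f16bp, allow_none=True)
        for attr in ("ka_f26bp", "ka_amp", "ki_atp", "km_f6p", "l0"):
            _require_positive(f"{self.name}.{attr}", getattr(self, attr))

    @property
    def activated_by_f16bp(self) -> bool:
        return self.ka_f16bp is not None

    def replace(self, **changes) -> "PFKIsozyme":
        return replace(self, **changes)


@dataclass(frozen=True)
class PKIsozyme:
    """Allosteric constants of one pyruvate kinase isoform.

    F16BP feed-forward activation lowers the apparent PEP half-saturation;
    ATP raises it.  PKM1 carries no F16BP activation term.
    """

    name: str
    km_pep: float               # mM
    ki_atp: float               # mM
    ka_f16bp: float | None      # mM; None => no F16BP activation (PKM1)
    h_pep: float = 4.0
    ki_pyr: float = 6.0         # mM, product inhibition by cytosolic pyruvate
    km_adp: float = 0.3         # mM

    def __post_init__(self) -> None:
        _require_positive(f"{self.name}.ka_f16bp", self.ka_f16bp, allow_none=True)
        for attr in ("km_pep", "ki_atp", "ki_pyr", "km_adp"):
            _require_positive(f"{self.name}.{attr}", getattr(self, attr))

    @property
    def activated_by_f16bp(self) -> bool:
        return self.ka_f16bp is not None

    def replace(self, **changes) -> "PKIsozyme":
        return replace(self, **changes)


@dataclass(frozen=True)
class PFKFBIsozyme:
    """Kinetics of the bifunctional 6-phosphofructo-2-kinase / fructose-2,6-
    bisphosphatase.

    ``kp_ratio`` (K/P) multiplies the kinase maximal rate relative to the
    phosphatase rate constant, while the expression level scales both domains
    equally; the steady-state F26BP concentration therefore depends on K/P
    but not on the level.  PEP inhibits the kinase domain only.
    """

    name: str
    kp_ratio: float             # dimensionless K/P activity ratio
    km_f6p: float               # mM, kinase
    km_atp: float               # mM, kinase
    ki_pep: float               # mM, kinase inhibition
    h_pep: float = 4.0
    f26bp_scale: float = 0.005  # mM; steady-state F26BP = f26bp_scale * K/P * u
    vref_phos: float = 4.5      # 1/h; phosphatase first-order rate constant at level 1
    kp_range: tuple[float, float] | None = None  # reported K/P range, if any

    def __post_init__(self) -> None:
        for attr in ("kp_ratio", "km_f6p", "km_atp", "ki_pep", "f26bp_scale", "vref_phos"):
            _require_positive(f"{self.name}.{attr}", getattr(self, attr))

    def replace(self, **changes) -> "PFKFBIsozyme":
        return replace(self, **changes)
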