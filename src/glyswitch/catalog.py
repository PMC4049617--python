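"""Isozyme catalog, model configurations and their (de)serialization.

``table1_catalog`` encodes the reported kinetic properties and allosteric
regulations of the mammalian PFK, PK and PFKFB isozymes; ``build_config``
assembles a complete :class:`ModelConfig` from an isozyme selection, and
``loop_status`` reports which of the two positive regulatory loops the
selection activates:

* Loop 1 - feedback activation of PFK by F16BP (plus F26BP activation of
  PFK); operational with PFKM or PFKL, absent with PFKP.
* Loop 2 - feed-forward activation of PK by F16BP, PEP feedback inhibition
  of the PFKFB kinase, and F26BP activation of PFK; operational with PKM2,
  PKL or PKR, absent with PKM1.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import yaml

from .errors import ConfigurationError
from .isozymes import PFKFBIsozyme, PFKIsozyme, PKIsozyme
from .ratelaws import ChainParams
from .state import Environment, EnzymeLevels

# Shape constants shared by all PFK isoforms; l0 and km_f6p are the
# calibrated anchors of the F6P-node switch concentrations.
_PFK_SHARED = dict(
    ka_f26bp=0.012,
    ka_amp=0.1,
    ki_atp=1.0,
    km_f6p=0.201336,
    l0=1000.0,
)

# Kinase-domain constants shared by all PFKFB isoforms.
_PFKFB_SHARED = dict(
    km_f6p=0.03,
    km_atp=0.5,
    ki_pep=0.007,
    f26bp_scale=0.008,
    vref_phos=4.5,
)


def table1_catalog() -> dict[str, PFKIsozyme | PKIsozyme | PFKFBIsozyme]:
    """Catalog of mammalian glycolytic isozymes and their allosteric constants.

    F16BP activation constants, PK PEP/ATP constants and PFKFB tissue K/P
    ratios are the reported experimental values; isoforms lacking an
    activation carry no entry for it (structural absence).  The liver PFKFB1
    K/P is reported as a 1.5-2.5 range and stored at its midpoint with the
    range kept as metadata.
    """
    cat: dict[str, PFKIsozyme | PKIsozyme | PFKFBIsozyme] = {}
    # --- phosphofructokinase ---
    cat["PFKM"] = PFKIsozyme(name="PFKM", ka_f16bp=0.35, **_PFK_SHARED)
    cat["PFKL"] = PFKIsozyme(name="PFKL", ka_f16bp=0.65, **_PFK_SHARED)
    cat["PFKP"] = PFKIsozyme(name="PFKP", ka_f16bp=None, **_PFK_SHARED)
    # --- pyruvate kinase ---
    cat["PKL"] = PKIsozyme(name="PKL", km_pep=0.6, ki_atp=0.05, ka_f16bp=0.01)
    cat["PKR"] = PKIsozyme(name="PKR", km_pep=1.2, ki_atp=0.12, ka_f16bp=0.04)
    cat["PKM1"] = PKIsozyme(name="PKM1", km_pep=0.08, ki_atp=2.5, ka_f16bp=None)
    cat["PKM2"] = PKIsozyme(name="PKM2", km_pep=0.4, ki_atp=3.5, ka_f16bp=0.04)
    # --- PFKFB tissue presets ---
    cat["PFKFB1_liver"] = PFKFBIsozyme(name="PFKFB1_liver", kp_ratio=2.0,
                                       kp_range=(1.5, 2.5), **_PFKFB_SHARED)
    cat["PFKFB1_muscle"] = PFKFBIsozyme(name="PFKFB1_muscle", kp_ratio=0.4,
                                        **_PFKFB_SHARED)
    cat["PFKFB2_heart"] = PFKFBIsozyme(name="PFKFB2_heart", kp_ratio=1.8,
                                       **_PFKFB_SHARED)
    cat["PFKFB3_brain"] = PFKFBIsozyme(name="PFKFB3_brain", kp_ratio=3.1,
                                       **_PFKFB_SHARED)
    cat["PFKFB3_inducible"] = PFKFBIsozyme(name="PFKFB3_inducible", kp_ratio=710.0,
                                           **_PFKFB_SHARED)
    cat["PFKFB4_testis"] = PFKFBIsozyme(name="PFKFB4_testis", kp_ratio=4.1,
                                        **_PFKFB_SHARED)
    return cat


@dataclass(frozen=True)
class LoopStatus:
    """Which of the two positive regulatory loops a configuration activates."""

    loop1_active: bool
    loop2_active: bool


@dataclass(frozen=True)
class ModelConfig:
    """Complete parameterization of the glycolysis model."""

    pfk_fractions: dict[str, float]
    pk: str
    pfkfb: PFKFBIsozyme
    levels: EnzymeLevels = field(default_factory=EnzymeLevels)
    env: Environment = field(default_factory=Environment)
    chain: ChainParams = field(default_factory=ChainParams)
    pfk_catalog: dict[str, PFKIsozyme] = field(default_factory=dict)
    pk_catalog: dict[str, PKIsozyme] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.pfk_catalog or not self.pk_catalog:
            cat = table1_catalog()
            object.__setattr__(self, "pfk_catalog", dict(self.pfk_catalog) or {
                k: v for k, v in cat.items() if isinstance(v, PFKIsozyme)})
            object.__setattr__(self, "pk_catalog", dict(self.pk_catalog) or {
                k: v for k, v in cat.items() if isinstance(v, PKIsozyme)})
        total = sum(self.pfk_fractions.values())
        if abs(total - 1.0) > 1e-9:
            raise ConfigurationError(f"PFK fractions must sum to 1, got {total!r}")
        for name, w in self.pfk_fractions.items():
            if name not in self.pfk_catalog:
                raise ConfigurationError(
                    f"unknown PFK isoform {name!r}; valid: {sorted(self.pfk_catalog)}")
            if w < 0:
                raise ConfigurationError(f"PFK fraction for {name} must be >= 0")
        if self.pk not in self.pk_catalog:
            raise ConfigurationError(
                f"unknown PK isoform {self.pk!r}; valid: {sorted(self.pk_catalog)}")
        if not self.pfkfb.kp_ratio > 0:
            raise ConfigurationError("PFKFB K/P ratio must be > 0")
        if not 0 < self.levels.PFKFB <= 10:
            raise ConfigurationError("PFKFB level must be in (0, 10]")

    # -- convenience accessors -------------------------------------------
    @property
    def pk_iso(self) -> PKIsozyme:
        return self.pk_catalog[self.pk]

    @property
    def kp_ratio(self) -> float:
        return self.pfkfb.kp_ratio

    def loop_status(self) -> LoopStatus:
        loop1 = any(w > 0 and self.pfk_catalog[name].activated_by_f16bp
                    for name, w in self.pfk_fractions.items())
        loop2 = self.pk_iso.activated_by_f16bp
        return LoopStatus(loop1_active=loop1, loop2_active=loop2)

    def replace(self, **changes) -> "ModelConfig":
        return replace(self, **changes)

    def with_levels(self, **level_changes: float) -> "ModelConfig":
        return self.replace(levels=self.levels.replace(**level_changes))

    def with_env(self, **env_changes: float) -> "ModelConfig":
        return self.replace(env=self.env.replace(**env_changes))

    def with_kp_ratio(self, kp_ratio: float) -> "ModelConfig":
        return self.replace(pfkfb=self.pfkfb.replace(kp_ratio=kp_ratio))

    # -- serialization ----------------------------------------------------
    def to_dict(self) -> dict:
        def iso_dict(iso):
            d = asdict(iso)
            if d.get("kp_range") is not None:
                d["kp_range"] = list(d["kp_range"])
            return d

        return {
            "isozymes": {
                "pfk_fractions": dict(self.pfk_fractions),
                "pk": self.pk,
                "pfkfb": iso_dict(self.pfkfb),
            },
            "enzyme_levels": self.levels.as_dict(),
            "environment": asdict(self.env),
            "allosteric_constants": {
                "pfk": {k: iso_dict(v) for k, v in sorted(self.pfk_catalog.items())},
                "pk": {k: iso_dict(v) for k, v in sorted(self.pk_catalog.items())},
            },
            "chain": asdict(self.chain),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ModelConfig":
        iso = d["isozymes"]
        pfkfb_d = dict(iso["pfkfb"])
        if pfkfb_d.get("kp_range") is not None:
            pfkfb_d["kp_range"] = tuple(pfkfb_d["kp_range"])
        pfk_cat = {k: PFKIsozyme(**v)
                   for k, v in d.get("allosteric_constants", {}).get("pfk", {}).items()}
        pk_cat = {k: PKIsozyme(**v)
                  for k, v in d.get("allosteric_constants", {}).get("pk", {}).items()}
        return cls(
            pfk_fractions=dict(iso["pfk_fractions"]),
            pk=iso["pk"],
            pfkfb=PFKFBIsozyme(**pfkfb_d),
            levels=EnzymeLevels(**d.get("enzyme_levels", {})),
            env=Environment(**d.get("environment", {})),
            chain=ChainParams(**d.get("chain", {})),
            pfk_catalog=pfk_cat,
            pk_catalog=pk_cat,
        )

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ModelConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    def digest(self) -> str:
        """Stable SHA-256 digest of the full parameterization."""
        payload = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()


def build_config(pfk: str | dict[str, float], pk: str, kp_ratio: float = 10.0,
                 **overrides) -> ModelConfig:
    """Assemble a ModelConfig from an isozyme selection.

    ``pfk`` is a single isoform name or a fraction map; ``kp_ratio`` sets the
    PFKFB kinase/phosphatase activity ratio.  ``overrides`` may supply
    ``levels``, ``env``, ``chain``, ``pfkfb`` or catalog replacements.
    """
    if isinstance(pfk, str):
        pfk_fractions = {pfk: 1.0}
    else:
        pfk_fractions = dict(pfk)
    if not kp_ratio > 0:
        raise ConfigurationError(f"K/P ratio must be > 0, got {kp_ratio!r}")
    pfkfb = overrides.pop("pfkfb", None)
    if pfkfb is None:
        pfkfb = PFKFBIsozyme(name="PFKFB_custom", kp_ratio=float(kp_ratio),
                             **_PFKFB_SHARED)
    else:
        pfkfb = pfkfb.replace(kp_ratio=float(kp_ratio))
    allowed = {"levels", "env", "chain", "pfk_catalog", "pk_catalog"}
    unknown = set(overrides) - allowed
    if unknown:
        raise ConfigurationError(f"unknown build_config overrides: {sorted(unknown)}")
    return ModelConfig(pfk_fractions=pfk_fractions, pk=pk, pfkfb=pfkfb, **overrides)


def loop_status(config: ModelConfig) -> LoopStatus:
    """Module-level alias for :meth:`ModelConfig.loop_status`."""
    return config.loop_status()


def catalog_to_csv() -> str:
    """Render the isozyme catalog as CSV text (one row per isoform)."""
    import io

    import pandas as pd

    rows = []
    for name, iso in table1_catalog().items():
        d = asdict(iso)
        d["enzyme"] = type(iso).__name__.replace("Isozyme", "")
        d["isoform"] = d.pop("name")
        rows.append(d)
    frame = pd.DataFrame(rows)
    lead = ["enzyme", "isoform"]
    frame = frame[lead + [c for c in frame.columns if c not in lead]]
    buf = io.StringIO()
    frame.to_csv(buf, index=False)
    return buf.getvalue()


def default_config() -> ModelConfig:
    """The bundled HeLa-like reference configuration (both loops active)."""
    path = Path(__file__).parent / "data" / "default_config.yaml"
    return ModelConfig.from_yaml(path)
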