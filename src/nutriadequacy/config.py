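"""Analysis-wide constants and configuration.

Everything a user might legitimately want to swap out — molar masses,
Atwater factors, intake CVs, unit conversions — lives here rather than
being hard-coded at the point of use.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import yaml

#: Atwater energy conversion factors, kcal per gram.
ATWATER_KCAL_PER_G: dict[str, float] = {
    "protein": 4.0,
    "fat": 9.0,
    "carbohydrate": 4.0,
    "fiber": 2.0,
}

#: Molar masses in g/mol used for phytate:mineral molar ratios.
#: Phytic acid = myo-inositol hexakisphosphate, C6H18O24P6.
MOLAR_MASS_G_PER_MOL: dict[str, float] = {
    "phytate": 660.04,
    "iron": 55.845,
    "zinc": 65.38,
    "calcium": 40.078,
}

#: Within-subject intake coefficients of variation by nutrient.
#: energy/protein/zinc/calcium 0.25, vitamin A 0.45, vitamin C and iron
#: 0.40 follow published within-subject variation estimates; fat 0.25,
#: folate 0.30 and carbohydrate/fiber 0.25 are assumed defaults.
DEFAULT_INTAKE_CVS: dict[str, float] = {
    "energy": 0.25,
    "protein": 0.25,
    "fat": 0.25,
    "carbohydrate": 0.25,
    "fiber": 0.25,
    "calcium": 0.25,
    "iron": 0.40,
    "zinc": 0.25,
    "vitamin_a": 0.45,
    "vitamin_c": 0.40,
    "folate": 0.30,
}

#: Intake distributions are modelled as normal for CV at or below this
#: threshold and lognormal above it.
MODEL_RULE_THRESHOLD: float = 0.3

#: Default requirement CV for the RNI -> EAR conversion
#: (RNI = EAR x (1 + 2 CV), so EAR = RNI / 1.2 at CV 0.10).
DEFAULT_REQUIREMENT_CV: float = 0.10

#: Human gestation length in days; pregnant population fraction = CBR x 280/365.
PREGNANCY_DAYS: float = 280.0
#: Breastfeeding assumed to continue two years; lactating fraction = CBR x 2.
LACTATION_YEARS: float = 2.0

DAYS_PER_YEAR: float = 365.0

#: Unit-mass conversions for items recorded in native units.
EGG_MASS_G: float = 50.0
MILK_DENSITY_G_PER_ML: float = 1.03

#: The three agroecological zones, ordered by elevation.
AEZS: tuple[str, ...] = ("midland", "highland", "upper_highland")

#: Major crops handled by the composition module.
CROPS: tuple[str, ...] = ("teff", "wheat", "bean", "barley", "sorghum")

#: Crop growing pattern by zone: which zones each crop is cultivated in.
CROP_AEZ_PATTERN: dict[str, tuple[str, ...]] = {
    "teff": ("midland", "highland"),
    "wheat": ("midland", "highland"),
    "sorghum": ("midland",),
    "bean": ("highland",),
    "barley": ("upper_highland",),
}

#: WHO seven food groups used for supply profiling.
FOOD_GROUPS: tuple[str, ...] = (
    "grains_roots_tubers",
    "legumes_nuts",
    "dairy",
    "flesh_foods",
    "eggs",
    "vitA_fruits_vegetables",
    "other_fruits_vegetables",
)


@dataclass
class AnalysisConfig:
    """Tunable analysis parameters, loadable from YAML.

    Parameters
    ----------
    intake_cvs
        Per-nutrient coefficient of variation of the intake distribution.
    model_rule_threshold
        CV at or below which the normal model is used (lognormal above).
    sd_anchor
        Whether the intake SD is ``cv * ear`` ("ear", default) or
        ``cv * mean`` ("mean").
    requirement_cv
        Default CV of the requirement distribution for RNI -> EAR.
    molar_masses
        g/mol values for the molar-ratio calculations.
    egg_mass_g, milk_density_g_per_ml
        Native-unit conversions for production records.
    loss_fraction
        Optional post-harvest loss multiplier applied to production
        (0 = no losses, mirroring a production-not-consumption analysis).
    """

    intake_cvs: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_INTAKE_CVS))
    model_rule_threshold: float = MODEL_RULE_THRESHOLD
    sd_anchor: str = "ear"
    requirement_cv: float = DEFAULT_REQUIREMENT_CV
    molar_masses: dict[str, float] = field(
        default_factory=lambda: dict(MOLAR_MASS_G_PER_MOL))
    egg_mass_g: float = EGG_MASS_G
    milk_density_g_per_ml: float = MILK_DENSITY_G_PER_ML
    loss_fraction: float = 0.0

    def __post_init__(self) -> None:
        if self.sd_anchor not in ("ear", "mean"):
            raise ValueError(f"sd_anchor must be 'ear' or 'mean', got {self.sd_anchor!r}")
        if not 0.0 <= self.loss_fraction < 1.0:
            raise ValueError("loss_fraction must be in [0, 1)")
        for nutrient, cv in self.intake_cvs.items():
            if not 0.0 < cv < 1.0:
                raise ValueError(f"intake CV for {nutrient} must be in (0, 1), got {cv}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AnalysisConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        merged = cls()
        for key, value in raw.items():
            if isinstance(value, dict):
                getattr(merged, key).update(value)
            else:
                setattr(merged, key, value)
        merged.__post_init__()
        return merged
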