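"""Synthetic study-system generator.

Emulates the data structure of a South Wollo-style agroecological
survey so the full pipeline runs without any real (unpublished) survey
data: crop composition samples drawn around the locally analysed
means/SDs, zone-level production ledgers built from land area, crop-mix
shares, yields and household livestock holdings, a population pyramid
with a crude birth rate, and a sex/age requirement table.

Every draw is driven by one global seed; each generator consumes its
own deterministic substream, so adding a generator does not perturb the
draws of the others. Setting ``sd_scale = 0`` collapses every
distribution to its mean, which makes the pipeline's expected output
available in closed form (see :func:`expected_supply` and
:func:`end_to_end_fixture`).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml
from scipy.stats import truncnorm

from . import reference
from .adequacy import AdequacySpec, deficit_table
from .composition import (
    CropSample,
    MineralAntinutrientProfile,
    ProximateComposition,
    write_samples_csv,
)
from .config import AEZS, CROP_AEZ_PATTERN, DAYS_PER_YEAR
from .requirements import DemographicGroup, PopulationStructure
from .supply import (
    FoodItem,
    ProductionRecord,
    default_food_items,
    write_items_csv,
    write_production_csv,
)

# substream indices: adding new streams at the end keeps old draws stable
_STREAMS = {"crop_samples": 0, "yields": 1, "livestock": 2}

_MINERAL_FIELDS = ("iron", "zinc", "calcium", "vitamin_c", "phytate", "tannin")
_PROXIMATE_FIELDS = ("protein", "fat", "fiber", "ash")

#: Default per-zone childbearing age bands.
CHILDBEARING_BANDS = ("15-19", "20-29", "30-39", "40-49")

#: Ethiopian-style rural population pyramid: share of total population
#: per (age band, sex); heavily young, near-even sex ratio.
DEFAULT_POPULATION_SHARES: dict[tuple[str, str], float] = {
    (band, sex): share / 2.0
    for band, share in {
        "0-4": 0.145, "5-9": 0.14, "10-14": 0.13, "15-19": 0.11,
        "20-29": 0.155, "30-39": 0.12, "40-49": 0.08, "50-59": 0.06,
        "60+": 0.06,
    }.items()
    for sex in ("female", "male")
}

#: Plausible adult reference intakes (RNI scale) per nutrient and sex,
#: with low Fe/Zn bioavailability and low-animal-protein Ca tiers.
_ADULT_RNIS: dict[str, dict[str, float]] = {
    "energy": {"female": 2200.0, "male": 2600.0},
    "protein": {"female": 46.0, "male": 56.0},
    "iron": {"female": 29.4, "male": 13.7},
    "zinc": {"female": 9.8, "male": 14.0},
    "calcium": {"female": 1000.0, "male": 1000.0},
    "vitamin_a": {"female": 500.0, "male": 600.0},
    "vitamin_c": {"female": 45.0, "male": 45.0},
    "folate": {"female": 400.0, "male": 400.0},
}
_AGE_MULTIPLIERS = {"0-4": 0.45, "5-9": 0.60, "10-14": 0.80, "15-19": 1.0,
                    "20-29": 1.0, "30-39": 1.0, "40-49": 1.0, "50-59": 1.0,
                    "60+": 1.0}
_STAGE_MULTIPLIERS = {"pregnant": 1.20, "lactating": 1.25}


@dataclass
class GeneratorConfig:
    """Parameters of the synthetic study system.

    Composition means/SDs default to the locally analysed per-crop
    summaries (with zone-specific teff/wheat shifts when
    ``aez_crop_effects`` is on, e.g. the ~25% higher midland teff
    phytate). Production defaults are chosen to be realistic for an
    Ethiopian smallholder system: household counts and land/livestock
    holdings at survey magnitudes, cereal-dominated crop mixes with the
    documented teff land shares, and typical smallholder yields.
    ``sd_scale`` multiplies every SD (0 = deterministic means).
    """

    seed: int = 0
    sd_scale: float = 1.0
    aez_crop_effects: bool = True

    crop_params: dict[str, dict[str, tuple[float, float]]] = field(
        default_factory=lambda: {c: dict(p) for c, p in reference.CROP_COMPOSITION.items()})
    crop_sample_sizes: dict[str, int] = field(
        default_factory=lambda: dict(reference.CROP_SAMPLE_SIZES))

    n_households: dict[str, int] = field(
        default_factory=lambda: {aez: 2000 for aez in AEZS})
    persons_per_household: float = 4.6
    area_ha_per_hh: dict[str, float] = field(
        default_factory=lambda: {"midland": 0.52, "highland": 0.76,
                                 "upper_highland": 0.80})
    crop_shares: dict[str, dict[str, float]] = field(default_factory=lambda: {
        "midland": {"teff": 0.38, "wheat": 0.32, "sorghum": 0.19, "bean": 0.11},
        "highland": {"teff": 0.18, "wheat": 0.42, "bean": 0.40},
        "upper_highland": {"barley": 1.0},
    })
    yields_kg_ha: dict[str, tuple[float, float]] = field(default_factory=lambda: {
        "teff": (1500.0, 225.0), "wheat": (2200.0, 330.0),
        "sorghum": (2300.0, 345.0), "bean": (1600.0, 240.0),
        "barley": (1800.0, 270.0),
    })
    season_split: dict[str, dict[str, float]] = field(default_factory=lambda: {
        "midland": {"meher": 0.90, "belg": 0.10},
        "highland": {"meher": 0.85, "belg": 0.15},
        "upper_highland": {"meher": 0.25, "belg": 0.75},
    })

    livestock: dict[str, dict[str, float]] = field(
        default_factory=lambda: {aez: dict(p) for aez, p in reference.LIVESTOCK.items()})
    lactation_days_per_year: float = 180.0

    population_shares: dict[tuple[str, str], float] = field(
        default_factory=lambda: dict(DEFAULT_POPULATION_SHARES))
    crude_birth_rate: float = 0.032
    childbearing_bands: tuple[str, ...] = CHILDBEARING_BANDS
    year: int = 2020

    def __post_init__(self) -> None:
        if self.sd_scale < 0:
            raise ValueError("sd_scale must be >= 0")
        for aez, shares in self.crop_shares.items():
            total = sum(shares.values())
            if abs(total - 1.0) > 1e-9:
                raise ValueError(f"crop shares for {aez} sum to {total}, not 1")
        for crop, params in self.crop_params.items():
            for fld, (_, sd) in params.items():
                if sd < 0:
                    raise ValueError(f"{crop}.{fld} SD must be >= 0")

    def population(self, aez: str) -> float:
        return self.n_households[aez] * self.persons_per_household

    def rng(self, stream: str) -> np.random.Generator:
        seq = np.random.SeedSequence(entropy=self.seed,
                                     spawn_key=(_STREAMS[stream],))
        return np.random.default_rng(seq)


def _draw(rng: np.random.Generator, mean: float, sd: float, size: int | None = None):
    """Normal draw truncated at zero; degenerate at the mean when sd = 0."""
    if sd == 0:
        return mean if size is None else np.full(size, mean)
    a = (0.0 - mean) / sd
    return truncnorm.rvs(a, np.inf, loc=mean, scale=sd, size=size, random_state=rng)


def generate_crop_samples(cfg: GeneratorConfig) -> list[CropSample]:
    """Draw per-sample crop compositions.

    Samples are assigned to zones following the growing pattern (teff
    and wheat split evenly between midland and highland; sorghum
    midland; bean highland; barley upper highland). With
    ``aez_crop_effects`` on, teff/wheat fields with zone-specific
    summaries use the zone means/SDs — notably the higher midland teff
    phytate.
    """
    rng = cfg.rng("crop_samples")
    samples: list[CropSample] = []
    for crop in sorted(cfg.crop_params):
        zones = CROP_AEZ_PATTERN[crop]
        n = cfg.crop_sample_sizes[crop]
        for i in range(n):
            aez = zones[i % len(zones)]
            values: dict[str, float] = {}
            for fld in (*_PROXIMATE_FIELDS, *_MINERAL_FIELDS):
                mean, sd = cfg.crop_params[crop][fld]
                if (cfg.aez_crop_effects
                        and crop in reference.CROP_AEZ_COMPOSITION
                        and fld in reference.CROP_AEZ_COMPOSITION[crop][aez]):
                    mean, sd = reference.CROP_AEZ_COMPOSITION[crop][aez][fld]
                values[fld] = float(_draw(rng, mean, sd * cfg.sd_scale))
            samples.append(CropSample(
                sample_id=f"{crop}-{i + 1:03d}",
                crop=crop, aez=aez,
                proximate=ProximateComposition(
                    moisture=0.0, crude_protein=values["protein"],
                    crude_fat=values["fat"], crude_fiber=values["fiber"],
                    total_ash=values["ash"], basis="dry_weight"),
                minerals=MineralAntinutrientProfile(
                    iron=values["iron"], zinc=values["zinc"],
                    calcium=values["calcium"], vitamin_c=values["vitamin_c"],
                    phytate=values["phytate"], tannin=values["tannin"]),
            ))
    return samples


def _livestock_quantities(cfg: GeneratorConfig, aez: str,
                          rng: np.random.Generator | None) -> dict[str, float]:
    """Annual milk liters, egg count and honey kg for one zone.

    Survey dispersions for per-household means are standard errors; the
    generator samples the zone mean from normal(mean, SE), truncated at
    zero (``rng=None`` returns the expectation).
    """
    p = cfg.livestock[aez]
    n_hh = cfg.n_households[aez]

    def value(mean_key: str) -> float:
        mean = p[mean_key]
        se = p.get(f"{mean_key}_se", 0.0) * cfg.sd_scale
        if rng is None or se == 0:
            return mean
        return float(_draw(rng, mean, se))

    milk_l = (n_hh * value("milk_cows_per_hh") * value("milk_l_per_cow_day")
              * cfg.lactation_days_per_year)
    eggs = n_hh * p["frac_hh_with_layers"] * value("eggs_per_hh_day") * DAYS_PER_YEAR
    honey_kg = n_hh * p["frac_hh_honey"] * value("honey_kg_per_hh_year")
    return {"milk": milk_l, "eggs": eggs, "honey": honey_kg}


def generate_production_ledger(cfg: GeneratorConfig) -> list[ProductionRecord]:
    """Zone-level annual production records in native units.

    Crop quantities are cultivated area x crop-mix share x a yield
    draw, split across the meher/belg seasons following each zone's
    adoption pattern; livestock products come from household counts,
    ownership fractions and productivity draws.
    """
    yield_rng = cfg.rng("yields")
    live_rng = cfg.rng("livestock") if cfg.sd_scale > 0 else None
    records: list[ProductionRecord] = []
    for aez in AEZS:
        if aez not in cfg.crop_shares:
            continue
        area_total = cfg.n_households[aez] * cfg.area_ha_per_hh[aez]
        for crop in sorted(cfg.crop_shares[aez]):
            share = cfg.crop_shares[aez][crop]
            mean, sd = cfg.yields_kg_ha[crop]
            yield_draw = float(_draw(yield_rng, mean, sd * cfg.sd_scale))
            total_kg = area_total * share * yield_draw
            for season, frac in sorted(cfg.season_split[aez].items()):
                if frac > 0:
                    records.append(ProductionRecord(
                        aez=aez, item=crop, season=season,
                        quantity=total_kg * frac, year=cfg.year))
        for item, qty in sorted(_livestock_quantities(cfg, aez, live_rng).items()):
            if qty > 0:
                records.append(ProductionRecord(aez=aez, item=item,
                                                season="annual", quantity=qty,
                                                year=cfg.year))
    return records


def generate_population(cfg: GeneratorConfig) -> PopulationStructure:
    """Population pyramid shared by all zones (deterministic)."""
    shares = {DemographicGroup(band, sex): share
              for (band, sex), share in cfg.population_shares.items()}
    total = sum(cfg.population(aez) for aez in cfg.n_households)
    return PopulationStructure(shares=shares,
                               crude_birth_rate=cfg.crude_birth_rate,
                               total_population=total,
                               childbearing_bands=cfg.childbearing_bands)


def generate_requirement_table(cfg: GeneratorConfig) -> pd.DataFrame:
    """Synthetic sex/age/life-stage RNI table (deterministic).

    Adult reference intakes are scaled down for children and up for
    pregnancy/lactation; values are plausible magnitudes, not a
    reproduction of any published requirement table.
    """
    rows = []
    bands = sorted({band for band, _ in cfg.population_shares})
    for nutrient, by_sex in _ADULT_RNIS.items():
        for band in bands:
            mult = _AGE_MULTIPLIERS.get(band, 1.0)
            for sex, adult in by_sex.items():
                rows.append({"nutrient": nutrient, "age_band": band, "sex": sex,
                             "life_stage": "none", "rni": adult * mult,
                             "unit": "per_day", "requirement_cv": 0.10})
                if sex == "female" and band in cfg.childbearing_bands:
                    for stage, smult in _STAGE_MULTIPLIERS.items():
                        rows.append({"nutrient": nutrient, "age_band": band,
                                     "sex": sex, "life_stage": stage,
                                     "rni": adult * mult * smult,
                                     "unit": "per_day", "requirement_cv": 0.10})
    return pd.DataFrame(rows)


def expected_supply(cfg: GeneratorConfig,
                    items: Mapping[str, FoodItem] | None = None) -> pd.DataFrame:
    """Closed-form expected per-capita daily nutrient supply per zone.

    Computed directly from the generator's mean yields and livestock
    parameters by plain arithmetic (no sampling, no use of the supply
    aggregation code), so it can serve as an analytic cross-check of
    the pipeline.
    """
    items = items or default_food_items()
    rows = {}
    for aez in cfg.crop_shares:
        pop = cfg.population(aez)
        grams: dict[str, float] = {}
        area_total = cfg.n_households[aez] * cfg.area_ha_per_hh[aez]
        for crop, share in cfg.crop_shares[aez].items():
            grams[crop] = area_total * share * cfg.yields_kg_ha[crop][0] * 1000.0
        live = _livestock_quantities(cfg, aez, rng=None)
        grams["milk"] = live["milk"] * 1000.0 * float(items["milk"].density_g_per_ml)
        grams["eggs"] = live["eggs"] * float(items["eggs"].unit_mass_g)
        grams["honey"] = live["honey"] * 1000.0
        nutrients: dict[str, float] = {}
        for item_key, g in grams.items():
            edible = g * items[item_key].edible_portion
            for nutrient, content in items[item_key].composition.items():
                nutrients[nutrient] = (nutrients.get(nutrient, 0.0)
                                       + edible * content / 100.0 / pop / DAYS_PER_YEAR)
        rows[aez] = nutrients
    frame = pd.DataFrame(rows).T
    frame.index.name = "aez"
    return frame


@dataclass
class FixtureBundle:
    """File paths plus the analytically expected outputs of a fixture."""

    samples_csv: Path
    production_csv: Path
    items_csv: Path
    population_csv: Path
    ears_csv: Path
    config_yaml: Path
    expected_supply: pd.DataFrame
    expected_deficits: pd.DataFrame
    population: dict[str, float]


def end_to_end_fixture(cfg: GeneratorConfig, out_dir: str | Path,
                       ears: Mapping[str, float] | None = None,
                       spec: AdequacySpec | None = None) -> FixtureBundle:
    """Write a complete input bundle plus its expected deficit table.

    Emits every CSV the pipeline consumes and, alongside them, the
    deficit table implied by the generator's *true* means (closed-form
    expected supply pushed through the cut-point formula), enabling
    pipeline-vs-analytic comparison.
    """
    out = Path(out_dir)
    try:
        out.mkdir(parents=True, exist_ok=True)
    except OSError as exc:
        raise OSError(f"cannot create fixture directory {out}: {exc}") from exc

    items = default_food_items()
    ears = dict(ears) if ears is not None else dict(reference.PER_CAPITA_EARS)
    spec = spec or AdequacySpec()

    paths = {name: out / fname for name, fname in [
        ("samples_csv", "samples.csv"), ("production_csv", "production.csv"),
        ("items_csv", "items.csv"), ("population_csv", "population.csv"),
        ("ears_csv", "ears.csv"), ("config_yaml", "config.yaml"),
    ]}
    write_samples_csv(generate_crop_samples(cfg), paths["samples_csv"])
    write_production_csv(generate_production_ledger(cfg), paths["production_csv"])
    write_items_csv(items, paths["items_csv"])
    pop = generate_population(cfg)
    pd.DataFrame([{"age_band": g.age_band, "sex": g.sex, "share": s}
                  for g, s in pop.shares.items()]).to_csv(
        paths["population_csv"], index=False)
    pd.Series(ears, name="ear").rename_axis("nutrient").to_csv(paths["ears_csv"])
    with open(paths["config_yaml"], "w", encoding="utf-8") as fh:
        yaml.safe_dump({
            "crude_birth_rate": cfg.crude_birth_rate,
            "childbearing_bands": list(cfg.childbearing_bands),
            "population_by_aez": {aez: cfg.population(aez) for aez in cfg.n_households},
            "cvs": {n: spec.cvs[n] for n in sorted(spec.cvs)},
            "model_rule_threshold": spec.model_rule_threshold,
            "sd_anchor": spec.sd_anchor,
        }, fh)

    exp_supply = expected_supply(cfg, items)
    exp_deficits = deficit_table(exp_supply, ears, spec)
    return FixtureBundle(
        **paths, expected_supply=exp_supply, expected_deficits=exp_deficits,
        population={aez: cfg.population(aez) for aez in cfg.n_households},
    )
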