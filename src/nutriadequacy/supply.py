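"""Per-capita food and nutrient supply from agricultural production.

Annual crop and livestock production per agroecological zone (AEZ) is
converted into edible grams, translated into energy and nutrients with
a food-composition table, divided by the zone population and by 365 to
give per-person per-day supply, and profiled into the WHO seven food
groups. This is a production-side (food balance sheet style) accounting:
markets, post-harvest losses and intra-household allocation are outside
its scope, although an optional uniform loss fraction can be applied.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .config import (
    AnalysisConfig,
    DAYS_PER_YEAR,
    FOOD_GROUPS,
)

NUTRIENT_COLUMNS = [
    "energy", "protein", "fat", "carbohydrate", "fiber",
    "calcium", "iron", "zinc", "vitamin_c", "vitamin_a", "folate",
]

#: CSV column names for the per-100 g composition of a food item.
_ITEM_NUTRIENT_CSV = {
    "energy_kcal": "energy", "protein_g": "protein", "fat_g": "fat",
    "carb_g": "carbohydrate", "fiber_g": "fiber", "ca_mg": "calcium",
    "fe_mg": "iron", "zn_mg": "zinc", "vitc_mg": "vitamin_c",
    "vita_ug_rae": "vitamin_a", "folate_ug": "folate",
}


class SupplyError(ValueError):
    """Raised for invalid production or food-item inputs."""


@dataclass(frozen=True)
class ProductionRecord:
    """One production entry: a quantity of an item in one zone and season.

    ``quantity`` is in the item's native unit: kg for crops and honey,
    liters for milk, count for eggs.
    """

    aez: str
    item: str
    season: str  # "meher" | "belg" | "annual"
    quantity: float
    year: int = 0

    def __post_init__(self) -> None:
        if self.quantity < 0:
            raise SupplyError(f"quantity must be >= 0, got {self.quantity}")
        if self.season not in ("meher", "belg", "annual"):
            raise SupplyError(f"season must be meher/belg/annual, got {self.season!r}")


@dataclass(frozen=True)
class FoodItem:
    """A food item: its food group, unit conversions and composition.

    ``composition`` holds per-100 g edible contents keyed by nutrient
    (energy kcal; protein/fat/carbohydrate/fiber g; Ca/Fe/Zn/vitamin C
    mg; vitamin A ug RAE; folate ug). ``unit`` declares the native unit
    of production records ("kg", "liter" or "count").
    """

    key: str
    food_group: str
    composition: Mapping[str, float]
    unit: str = "kg"
    edible_portion: float = 1.0
    unit_mass_g: float | None = None
    density_g_per_ml: float | None = None

    def __post_init__(self) -> None:
        if self.food_group not in FOOD_GROUPS:
            raise SupplyError(f"{self.key}: unknown food group {self.food_group!r}")
        if not 0.0 < self.edible_portion <= 1.0:
            raise SupplyError(f"{self.key}: edible_portion must be in (0, 1]")
        if self.unit not in ("kg", "liter", "count"):
            raise SupplyError(f"{self.key}: unit must be kg/liter/count")
        if self.unit == "count" and not self.unit_mass_g:
            raise SupplyError(f"{self.key}: count-based items need unit_mass_g")
        if self.unit == "liter" and not self.density_g_per_ml:
            raise SupplyError(f"{self.key}: liter-based items need density_g_per_ml")
        if any(v < 0 for v in self.composition.values()):
            raise SupplyError(f"{self.key}: negative composition value")

    def edible_grams(self, quantity: float) -> float:
        """Convert a native-unit quantity to grams of edible mass."""
        if self.unit == "kg":
            grams = quantity * 1000.0
        elif self.unit == "liter":
            grams = quantity * 1000.0 * float(self.density_g_per_ml)
        else:  # count
            grams = quantity * float(self.unit_mass_g)
        return grams * self.edible_portion


@dataclass
class SupplySummary:
    """Per-capita daily nutrient supply and food-group profile per zone.

    ``nutrients``: DataFrame indexed by aez, one column per nutrient
    (amount/person/day). ``food_groups``: DataFrame indexed by aez with
    columns ``(group, "g_per_day")`` and ``(group, "percent")``.
    """

    nutrients: pd.DataFrame
    food_groups: pd.DataFrame


@dataclass(frozen=True)
class CropCutSample:
    """Fresh/threshed grain masses from small fixed-area subplots of one plot."""

    plot_id: str
    subplot_masses_g: tuple[float, ...]
    subplot_area_m2: float = 1.0
    plot_area_m2: float | None = None

    def __post_init__(self) -> None:
        if len(self.subplot_masses_g) == 0:
            raise SupplyError(f"plot {self.plot_id}: no subplot masses")
        if self.subplot_area_m2 <= 0:
            raise SupplyError(f"plot {self.plot_id}: subplot area must be > 0")
        if any(m < 0 for m in self.subplot_masses_g):
            raise SupplyError(f"plot {self.plot_id}: negative subplot mass")


def yield_from_crop_cuts(s: CropCutSample) -> float:
    """Crop-cut yield estimate in kg/ha.

    Mean subplot mass per m2 (g/m2), scaled by 10 to kg/ha
    (1 ha = 10^4 m2, 1 kg = 10^3 g).
    """
    g_per_m2 = float(np.mean(s.subplot_masses_g)) / s.subplot_area_m2
    return g_per_m2 * 10.0


def annualize(records: Iterable[ProductionRecord],
              items: Mapping[str, FoodItem],
              loss_fraction: float = 0.0) -> pd.DataFrame:
    """Aggregate seasonal records to annual edible grams per (aez, item).

    Meher, belg and annual entries for the same item are summed, native
    units are converted via the item's unit conversions and edible
    portion, and an optional uniform post-harvest loss fraction is
    removed. Returns a DataFrame with columns aez, item, edible_g.
    """
    if not 0.0 <= loss_fraction < 1.0:
        raise SupplyError("loss_fraction must be in [0, 1)")
    records = list(records)
    unknown = sorted({r.item for r in records} - set(items))
    if unknown:
        raise SupplyError(f"production records reference unknown items: {unknown}")
    seen: set[tuple] = set()
    totals: dict[tuple[str, str], float] = {}
    for r in records:
        dedup_key = (r.aez, r.item, r.season, r.year)
        if dedup_key in seen:
            raise SupplyError(f"duplicate production record {dedup_key}")
        seen.add(dedup_key)
        key = (r.aez, r.item)
        totals[key] = totals.get(key, 0.0) + items[r.item].edible_grams(r.quantity)
    rows = [{"aez": aez, "item": item, "edible_g": grams * (1.0 - loss_fraction)}
            for (aez, item), grams in sorted(totals.items())]
    return pd.DataFrame(rows, columns=["aez", "item", "edible_g"])


def per_capita_daily_supply(annual: pd.DataFrame,
                            items: Mapping[str, FoodItem],
                            population: Mapping[str, float]) -> SupplySummary:
    """Per-person per-day nutrient supply and food-group profile.

    ``annual`` is the (aez, item, edible_g) frame from :func:`annualize`;
    ``population`` maps aez -> persons. Each nutrient's supply is
    sum over items of edible grams x content per gram, divided by the
    population and by 365.
    """
    for aez, pop in population.items():
        if pop <= 0:
            raise SupplyError(f"population for {aez} must be > 0, got {pop}")
    missing_pop = sorted(set(annual["aez"]) - set(population))
    if missing_pop:
        raise SupplyError(f"no population given for zones: {missing_pop}")

    aezs = sorted(population)
    nutrients = pd.DataFrame(0.0, index=pd.Index(aezs, name="aez"),
                             columns=NUTRIENT_COLUMNS)
    grams = pd.DataFrame(0.0, index=pd.Index(aezs, name="aez"),
                         columns=list(FOOD_GROUPS))
    for rec in annual.itertuples(index=False):
        item = items[rec.item]
        denom = population[rec.aez] * DAYS_PER_YEAR
        g_per_day = rec.edible_g / denom
        grams.loc[rec.aez, item.food_group] += g_per_day
        for nutrient in NUTRIENT_COLUMNS:
            content = item.composition.get(nutrient, 0.0)
            nutrients.loc[rec.aez, nutrient] += g_per_day * content / 100.0

    totals = grams.sum(axis=1)
    percent = grams.div(totals.where(totals > 0), axis=0) * 100.0
    food_groups = pd.concat({"g_per_day": grams, "percent": percent}, axis=1)
    food_groups = food_groups.swaplevel(axis=1).sort_index(axis=1)
    return SupplySummary(nutrients=nutrients, food_groups=food_groups)


def food_group_profile(annual: pd.DataFrame,
                       items: Mapping[str, FoodItem],
                       population: Mapping[str, float]) -> pd.DataFrame:
    """Per-capita g/day and percent share by WHO food group per zone."""
    return per_capita_daily_supply(annual, items, population).food_groups


def energy_share_bound(summary: SupplySummary | pd.DataFrame) -> float:
    """Minimum over zones of the percent of energy from available carbohydrate.

    Uses the 4 kcal/g Atwater factor: 100 x 4 x carbohydrate_g / energy_kcal.
    """
    nutrients = summary.nutrients if isinstance(summary, SupplySummary) else summary
    if (nutrients["energy"] <= 0).any():
        bad = list(nutrients.index[nutrients["energy"] <= 0])
        raise SupplyError(f"zero energy supply in zones: {bad}")
    shares = 100.0 * 4.0 * nutrients["carbohydrate"] / nutrients["energy"]
    return float(shares.min())


#: Borrowed (non-local) vitamin A (ug RAE/100 g) and folate (ug/100 g)
#: defaults for the major crops, in the spirit of national/USDA food
#: composition tables; local laboratory analysis covers the other fields.
_BORROWED_CROP_VITAMINS: dict[str, tuple[float, float]] = {
    # crop: (vitamin_a, folate)
    "teff": (0.0, 38.0),
    "wheat": (0.0, 38.0),
    "bean": (3.0, 423.0),
    "barley": (0.0, 19.0),
    "sorghum": (0.0, 20.0),
}

#: Borrowed whole-food composition defaults for livestock products
#: (per 100 g edible), from generic food-composition-table magnitudes.
_BORROWED_LIVESTOCK_ITEMS: dict[str, dict] = {
    "milk": {
        "food_group": "dairy", "unit": "liter",
        "composition": {"energy": 61.0, "protein": 3.2, "fat": 3.3,
                        "carbohydrate": 4.8, "fiber": 0.0, "calcium": 113.0,
                        "iron": 0.03, "zinc": 0.37, "vitamin_c": 0.0,
                        "vitamin_a": 46.0, "folate": 5.0},
    },
    "eggs": {
        "food_group": "eggs", "unit": "count",
        "composition": {"energy": 143.0, "protein": 12.6, "fat": 9.5,
                        "carbohydrate": 0.7, "fiber": 0.0, "calcium": 56.0,
                        "iron": 1.75, "zinc": 1.29, "vitamin_c": 0.0,
                        "vitamin_a": 160.0, "folate": 47.0},
    },
    "honey": {
        "food_group": "other_fruits_vegetables", "unit": "kg",
        "composition": {"energy": 304.0, "protein": 0.3, "fat": 0.0,
                        "carbohydrate": 82.4, "fiber": 0.2, "calcium": 6.0,
                        "iron": 0.42, "zinc": 0.22, "vitamin_c": 0.5,
                        "vitamin_a": 0.0, "folate": 2.0},
    },
}


def default_food_items(config: AnalysisConfig | None = None) -> dict[str, FoodItem]:
    """Packaged default food-item table.

    The five major crops use the locally analysed dry-weight composition
    summaries; vitamin A, folate and the livestock products (milk, eggs,
    honey) carry borrowed, non-local defaults from generic composition
    tables and should be replaced with local values where available.
    Whole-grain edible portion defaults to 1.0 (whole production is
    converted, as in a food balance sheet).
    """
    from . import reference

    cfg = config or AnalysisConfig()
    crop_groups = {"teff": "grains_roots_tubers", "wheat": "grains_roots_tubers",
                   "barley": "grains_roots_tubers", "sorghum": "grains_roots_tubers",
                   "bean": "legumes_nuts"}
    items: dict[str, FoodItem] = {}
    for crop, params in reference.CROP_COMPOSITION.items():
        vit_a, folate = _BORROWED_CROP_VITAMINS[crop]
        composition = {
            "energy": reference.CROP_ENERGY[crop][0],
            "protein": params["protein"][0],
            "fat": params["fat"][0],
            "carbohydrate": reference.CROP_AVAILABLE_CARB[crop][0],
            "fiber": params["fiber"][0],
            "calcium": params["calcium"][0],
            "iron": params["iron"][0],
            "zinc": params["zinc"][0],
            "vitamin_c": params["vitamin_c"][0],
            "vitamin_a": vit_a,
            "folate": folate,
        }
        items[crop] = FoodItem(key=crop, food_group=crop_groups[crop],
                               composition=composition, unit="kg")
    for key, spec in _BORROWED_LIVESTOCK_ITEMS.items():
        items[key] = FoodItem(
            key=key, food_group=spec["food_group"], composition=spec["composition"],
            unit=spec["unit"],
            unit_mass_g=cfg.egg_mass_g if spec["unit"] == "count" else None,
            density_g_per_ml=cfg.milk_density_g_per_ml if spec["unit"] == "liter" else None,
        )
    return items


# ---------------------------------------------------------------------------
# CSV interface

def read_items_csv(path: str | Path) -> dict[str, FoodItem]:
    """Load the food-item table CSV into a key -> FoodItem mapping."""
    df = pd.read_csv(path)
    required = {"key", "food_group", "edible_portion"} | set(_ITEM_NUTRIENT_CSV)
    missing = required - set(df.columns)
    if missing:
        raise SupplyError(f"items CSV missing columns: {sorted(missing)}")
    items: dict[str, FoodItem] = {}
    for rec in df.itertuples(index=False):
        composition = {nut: float(getattr(rec, col))
                       for col, nut in _ITEM_NUTRIENT_CSV.items()}
        unit = str(getattr(rec, "unit", "kg") or "kg")
        unit_mass = getattr(rec, "unit_mass_g", None)
        density = getattr(rec, "density", None)
        items[str(rec.key)] = FoodItem(
            key=str(rec.key), food_group=str(rec.food_group),
            composition=composition, unit=unit,
            edible_portion=float(rec.edible_portion),
            unit_mass_g=None if pd.isna(unit_mass) else float(unit_mass),
            density_g_per_ml=None if pd.isna(density) else float(density),
        )
    return items


def write_items_csv(items: Mapping[str, FoodItem], path: str | Path) -> None:
    rows = []
    for item in items.values():
        row = {
            "key": item.key, "food_group": item.food_group, "unit": item.unit,
            "edible_portion": item.edible_portion,
            "unit_mass_g": item.unit_mass_g, "density": item.density_g_per_ml,
        }
        for col, nut in _ITEM_NUTRIENT_CSV.items():
            row[col] = item.composition.get(nut, 0.0)
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


def read_production_csv(path: str | Path) -> list[ProductionRecord]:
    """Load production records from a CSV with columns aez,item,season,quantity[,year]."""
    df = pd.read_csv(path)
    missing = {"aez", "item", "season", "quantity"} - set(df.columns)
    if missing:
        raise SupplyError(f"production CSV missing columns: {sorted(missing)}")
    return [
        ProductionRecord(aez=str(r.aez), item=str(r.item), season=str(r.season),
                         quantity=float(r.quantity),
                         year=int(getattr(r, "year", 0) or 0))
        for r in df.itertuples(index=False)
    ]


def write_production_csv(records: Sequence[ProductionRecord], path: str | Path) -> None:
    pd.DataFrame([{
        "aez": r.aez, "item": r.item, "season": r.season,
        "quantity": r.quantity, "unit": "native", "year": r.year,
    } for r in records]).to_csv(path, index=False)
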