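"""Bundled reference inputs for the South Wollo (Ethiopia) study system.

The village-level registers and the supplementary demographic tables
behind the original survey are not public, so this module ships the
aggregate quantities needed to exercise the full pipeline:

* per-crop nutrient composition summaries (mean, SD, n) from locally
  analysed grain samples, on a dry-weight basis;
* agroecological-zone-specific composition of teff and wheat;
* per-capita daily supply of energy and nutrients by zone, and the
  matching per-capita population-weighted EARs;
* livestock ownership and productivity magnitudes by zone.

These values are inputs (and synthetic-generator defaults), not outputs:
nothing here is recomputed by the package, and the adequacy pipeline will
happily run on user-supplied tables of the same shape instead.
"""

from __future__ import annotations

import pandas as pd

#: Per-crop composition, dry-weight basis. Proximate fields in g/100 g,
#: minerals/vitamin C/antinutrients in mg/100 g. ``n`` = samples analysed.
CROP_COMPOSITION: dict[str, dict[str, tuple[float, float]]] = {
    # field: (mean, sd)
    "teff": {
        "protein": (8.81, 1.01), "fat": (3.03, 0.77), "fiber": (5.66, 3.53),
        "ash": (2.59, 0.43),
        "iron": (11.21, 6.05), "zinc": (3.44, 1.19), "calcium": (30.69, 13.47),
        "vitamin_c": (0.529, 0.181),
        "phytate": (363.69, 87.86), "tannin": (89.62, 14.39),
    },
    "wheat": {
        "protein": (10.10, 1.66), "fat": (2.42, 0.48), "fiber": (5.44, 1.50),
        "ash": (1.83, 0.15),
        "iron": (3.79, 2.26), "zinc": (2.38, 1.00), "calcium": (8.79, 6.70),
        "vitamin_c": (0.864, 0.144),
        "phytate": (255.64, 36.08), "tannin": (98.11, 19.91),
    },
    "bean": {
        "protein": (23.59, 1.87), "fat": (1.68, 0.51), "fiber": (12.18, 3.17),
        "ash": (2.47, 0.89),
        "iron": (4.20, 0.63), "zinc": (2.74, 0.25), "calcium": (29.81, 8.72),
        "vitamin_c": (1.346, 0.549),
        "phytate": (223.63, 15.75), "tannin": (128.07, 13.44),
    },
    "barley": {
        "protein": (8.06, 0.67), "fat": (1.84, 0.65), "fiber": (8.91, 2.82),
        "ash": (2.60, 0.47),
        "iron": (8.36, 2.94), "zinc": (3.05, 1.11), "calcium": (13.26, 1.09),
        "vitamin_c": (0.476, 0.141),
        "phytate": (223.34, 35.73), "tannin": (102.05, 6.69),
    },
    "sorghum": {
        "protein": (7.45, 1.26), "fat": (3.22, 0.86), "fiber": (5.90, 2.13),
        "ash": (2.16, 0.37),
        "iron": (3.31, 0.64), "zinc": (1.78, 0.44), "calcium": (23.33, 11.08),
        "vitamin_c": (0.475, 0.371),
        "phytate": (251.26, 31.53), "tannin": (148.54, 27.76),
    },
}

#: Samples analysed per crop.
CROP_SAMPLE_SIZES: dict[str, int] = {
    "teff": 30, "wheat": 30, "sorghum": 24, "bean": 18, "barley": 18,
}

#: Reported per-crop gross energy summaries (kcal/100 g, mean, sd),
#: computed per sample before averaging.
CROP_ENERGY: dict[str, tuple[float, float]] = {
    "teff": (361.12, 12.18),
    "wheat": (359.37, 6.33),
    "bean": (344.34, 8.66),
    "barley": (345.73, 5.29),
    "sorghum": (362.97, 4.52),
}

#: Reported per-crop available carbohydrate summaries (g/100 g, mean, sd),
#: per-sample values averaged.
CROP_AVAILABLE_CARB: dict[str, tuple[float, float]] = {
    "teff": (71.48, 4.42),
    "wheat": (71.40, 2.68),
    "bean": (52.21, 4.32),
    "barley": (69.63, 2.44),
    "sorghum": (73.23, 2.41),
}

#: Zone-specific composition of the two crops grown in both the midland
#: and highland (mean, sd per zone).
CROP_AEZ_COMPOSITION: dict[str, dict[str, dict[str, tuple[float, float]]]] = {
    "wheat": {
        "midland": {
            "ash": (1.75, 0.013), "fiber": (5.04, 1.05), "protein": (11.36, 2.37),
            "fat": (2.25, 0.45), "iron": (3.39, 1.95), "zinc": (2.33, 1.20),
            "calcium": (10.98, 7.21), "tannin": (93.35, 16.74),
            "phytate": (258.43, 27.13),
        },
        "highland": {
            "ash": (1.87, 0.18), "fiber": (5.72, 1.72), "protein": (9.47, 0.68),
            "fat": (2.51, 0.47), "iron": (4.06, 2.47), "zinc": (2.42, 0.89),
            "calcium": (5.49, 4.35), "tannin": (100.97, 21.62),
            "phytate": (253.78, 41.82),
        },
    },
    "teff": {
        "midland": {
            "ash": (2.48, 0.37), "fiber": (4.50, 2.47), "protein": (8.43, 0.91),
            "fat": (3.29, 0.56), "iron": (11.93, 6.56), "zinc": (3.60, 1.05),
            "calcium": (35.44, 15.76), "tannin": (86.37, 12.63),
            "phytate": (398.97, 60.93),
        },
        "highland": {
            "ash": (2.74, 0.46), "fiber": (7.11, 4.19), "protein": (9.49, 0.90),
            "fat": (2.46, 1.18), "iron": (10.31, 5.47), "zinc": (3.24, 1.36),
            "calcium": (24.76, 6.61), "tannin": (93.69, 15.93),
            "phytate": (319.59, 98.50),
        },
    },
}

#: Per-capita daily production-side supply by zone. Units: energy kcal;
#: protein/fat/carbohydrate/fiber g; calcium/iron/zinc/vitamin C mg;
#: vitamin A ug RAE; folate ug — all per person per day.
PER_CAPITA_SUPPLY: dict[str, dict[str, float]] = {
    "midland": {
        "energy": 2234.3, "protein": 62.7, "fat": 20.1, "carbohydrate": 431.8,
        "fiber": 37.5, "calcium": 169.0, "iron": 35.9, "zinc": 15.4,
        "vitamin_a": 36.5, "folate": 363.0, "vitamin_c": 5.1,
    },
    "highland": {
        "energy": 3453.0, "protein": 98.6, "fat": 27.5, "carbohydrate": 667.8,
        "fiber": 68.8, "calcium": 196.6, "iron": 57.3, "zinc": 26.1,
        "vitamin_a": 86.6, "folate": 541.2, "vitamin_c": 9.4,
    },
    "upper_highland": {
        "energy": 4431.6, "protein": 107.8, "fat": 30.4, "carbohydrate": 873.7,
        "fiber": 112.0, "calcium": 250.7, "iron": 105.5, "zinc": 38.7,
        "vitamin_a": 146.2, "folate": 296.7, "vitamin_c": 8.9,
    },
}

#: Population-weighted per-capita EARs for the study population, in the
#: same units as :data:`PER_CAPITA_SUPPLY`. Derived from WHO/FAO and IOM
#: reference intakes with low mineral bioavailability assumed for Fe/Zn
#: and low animal protein for Ca; shipped as aggregate constants because
#: the underlying demographic requirement table is not public.
PER_CAPITA_EARS: dict[str, float] = {
    "energy": 2869.7, "protein": 51.9, "fat": 85.5, "carbohydrate": 148.1,
    "fiber": 31.5, "calcium": 700.1, "iron": 12.1, "zinc": 11.3,
    "vitamin_a": 625.6, "folate": 329.9, "vitamin_c": 38.6,
}

#: Household-survey livestock magnitudes per zone: means are per
#: household (or proportions of households); ``n_households`` surveyed.
#: Dispersion for the per-household means is a standard error.
LIVESTOCK: dict[str, dict[str, float]] = {
    "midland": {
        "n_households": 175,
        "milk_cows_per_hh": 0.35, "milk_cows_per_hh_se": 0.04,
        "milk_l_per_cow_day": 1.62, "milk_l_per_cow_day_se": 0.07,
        "frac_hh_with_layers": 0.440,
        "eggs_per_hh_day": 2.49, "eggs_per_hh_day_se": 0.11,
        "frac_hh_honey": 0.1029,
        "honey_kg_per_hh_year": 4.22, "honey_kg_per_hh_year_se": 0.36,
    },
    "highland": {
        "n_households": 166,
        "milk_cows_per_hh": 0.64, "milk_cows_per_hh_se": 0.05,
        "milk_l_per_cow_day": 1.46, "milk_l_per_cow_day_se": 0.07,
        "frac_hh_with_layers": 0.6145,
        "eggs_per_hh_day": 3.43, "eggs_per_hh_day_se": 0.36,
        "frac_hh_honey": 0.0964,
        "honey_kg_per_hh_year": 4.25, "honey_kg_per_hh_year_se": 0.38,
    },
    "upper_highland": {
        "n_households": 137,
        "milk_cows_per_hh": 0.47, "milk_cows_per_hh_se": 0.05,
        "milk_l_per_cow_day": 2.52, "milk_l_per_cow_day_se": 0.17,
        "frac_hh_with_layers": 0.292,
        "eggs_per_hh_day": 2.45, "eggs_per_hh_day_se": 0.27,
        "frac_hh_honey": 0.0146,
        "honey_kg_per_hh_year": 2.50, "honey_kg_per_hh_year_se": 0.18,
    },
}


def supply_frame() -> pd.DataFrame:
    """Reference per-capita supply as a tidy DataFrame (aez, nutrient, amount)."""
    rows = [
        {"aez": aez, "nutrient": nutrient, "amount": amount}
        for aez, nutrients in PER_CAPITA_SUPPLY.items()
        for nutrient, amount in nutrients.items()
    ]
    return pd.DataFrame(rows)


def ear_series() -> pd.Series:
    """Reference per-capita EARs as a Series indexed by nutrient."""
    return pd.Series(PER_CAPITA_EARS, name="ear")
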