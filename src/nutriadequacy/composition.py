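"""Food-composition arithmetic for crop samples.

Carbohydrate is computed by difference from the proximate analysis,
gross energy by Atwater factors (4/9/4/2 kcal per g of protein / fat /
available carbohydrate / fiber), and mineral bioavailability is screened
via phytate:mineral molar ratios. Derived quantities (energy, ratios)
are computed per sample and then averaged, so summary tables report the
mean of per-sample values, not the value at the mean composition.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd

from .config import (
    ATWATER_KCAL_PER_G,
    CROP_AEZ_PATTERN,
    MOLAR_MASS_G_PER_MOL,
)

RatioKind = Literal["phy_fe", "phy_zn", "phy_ca"]

#: Mineral targeted by each ratio kind.
RATIO_MINERAL: dict[str, str] = {
    "phy_fe": "iron",
    "phy_zn": "zinc",
    "phy_ca": "calcium",
}


class CompositionError(ValueError):
    """Raised for physically impossible composition inputs."""


@dataclass(frozen=True)
class ProximateComposition:
    """Proximate macronutrient profile, g per 100 g of sample.

    ``basis`` records whether values are per 100 g as analysed (moisture
    included) or per 100 g dry matter (moisture must then be 0).
    """

    moisture: float
    crude_protein: float
    crude_fat: float
    crude_fiber: float
    total_ash: float
    basis: Literal["as_analyzed", "dry_weight"] = "dry_weight"

    def __post_init__(self) -> None:
        for name in ("moisture", "crude_protein", "crude_fat", "crude_fiber", "total_ash"):
            if getattr(self, name) < 0:
                raise CompositionError(f"{name} must be >= 0, got {getattr(self, name)}")
        if self.basis == "dry_weight" and self.moisture != 0:
            raise CompositionError("dry_weight basis requires moisture == 0")
        # 0.5 g slack: published composition rows carry rounding noise,
        # and mild overshoot is handled by clamping carbohydrate at 0
        total = (self.moisture + self.crude_protein + self.crude_fat
                 + self.crude_fiber + self.total_ash)
        if total > 100.5:
            raise CompositionError(
                "moisture + protein + fat + fiber + ash "
                f"= {total:.4g} exceeds 100 g/100 g")

    def to_dry_weight(self) -> "ProximateComposition":
        """Re-express an as-analysed profile per 100 g dry matter."""
        if self.basis == "dry_weight":
            return self
        dry = 1.0 - self.moisture / 100.0
        if dry <= 0:
            raise CompositionError("moisture = 100 leaves no dry matter")
        return ProximateComposition(
            moisture=0.0,
            crude_protein=self.crude_protein / dry,
            crude_fat=self.crude_fat / dry,
            crude_fiber=self.crude_fiber / dry,
            total_ash=self.total_ash / dry,
            basis="dry_weight",
        )


@dataclass(frozen=True)
class MineralAntinutrientProfile:
    """Minerals, vitamin C and antinutrients, mg per 100 g."""

    iron: float
    zinc: float
    calcium: float
    vitamin_c: float
    phytate: float
    tannin: float

    def __post_init__(self) -> None:
        for name in ("iron", "zinc", "calcium", "vitamin_c", "phytate", "tannin"):
            if getattr(self, name) < 0:
                raise CompositionError(f"{name} must be >= 0, got {getattr(self, name)}")


@dataclass(frozen=True)
class MolarRatioResult:
    """A phytate:mineral molar ratio and its bioavailability category."""

    ratio_kind: RatioKind
    value: float
    category: Literal["high", "moderate", "poor", "desired", "above_critical", "unclassified"]


@dataclass(frozen=True)
class CropSample:
    sample_id: str
    crop: str
    aez: str
    proximate: ProximateComposition
    minerals: MineralAntinutrientProfile

    def validate_crop_aez(self) -> None:
        """Check the crop is one grown in the sample's agroecological zone."""
        allowed = CROP_AEZ_PATTERN.get(self.crop)
        if allowed is not None and self.aez not in allowed:
            raise CompositionError(
                f"sample {self.sample_id}: {self.crop} is not grown in the "
                f"{self.aez} zone (grown in: {', '.join(allowed)})")


def total_carbohydrate(p: ProximateComposition) -> float:
    """Total carbohydrate by difference, g/100 g.

    100 minus the sum of moisture, crude protein, crude fat and ash.
    Inconsistent inputs that would go negative are clamped to 0 with a
    warning (survey composition tables carry rounding noise).
    """
    value = 100.0 - (p.moisture + p.crude_protein + p.crude_fat + p.total_ash)
    if value < 0:
        warnings.warn(
            f"total carbohydrate by difference is negative ({value:.4g}); clamping to 0",
            stacklevel=2)
        return 0.0
    return value


def available_carbohydrate(p: ProximateComposition) -> float:
    """Available carbohydrate by difference: total carbohydrate minus crude fiber."""
    value = 100.0 - (p.moisture + p.crude_protein + p.crude_fat
                     + p.total_ash + p.crude_fiber)
    if value < 0:
        warnings.warn(
            f"available carbohydrate by difference is negative ({value:.4g}); clamping to 0",
            stacklevel=2)
        return 0.0
    return value


def gross_energy(p: ProximateComposition, avail_carb: float | None = None) -> float:
    """Gross energy in kcal/100 g from Atwater factors.

    9*fat + 4*protein + 4*available carbohydrate + 2*fiber. When
    ``avail_carb`` is omitted it is computed by difference from ``p``.
    """
    if avail_carb is None:
        avail_carb = available_carbohydrate(p)
    if avail_carb < 0:
        raise CompositionError(f"avail_carb must be >= 0, got {avail_carb}")
    return (ATWATER_KCAL_PER_G["fat"] * p.crude_fat
            + ATWATER_KCAL_PER_G["protein"] * p.crude_protein
            + ATWATER_KCAL_PER_G["carbohydrate"] * avail_carb
            + ATWATER_KCAL_PER_G["fiber"] * p.crude_fiber)


def energy_shares(p: ProximateComposition,
                  avail_carb: float | None = None,
                  energy: float | None = None) -> dict[str, float]:
    """Percent of gross energy contributed by each energy-yielding component.

    share_x = 100 * atwater_x * mass_x / energy. When ``energy`` comes
    from :func:`gross_energy` on the same inputs the shares sum to 100.
    """
    if avail_carb is None:
        avail_carb = available_carbohydrate(p)
    if energy is None:
        energy = gross_energy(p, avail_carb)
    if energy <= 0:
        raise CompositionError("energy shares undefined for energy <= 0")
    masses = {
        "protein": p.crude_protein,
        "fat": p.crude_fat,
        "carbohydrate": avail_carb,
        "fiber": p.crude_fiber,
    }
    return {comp: 100.0 * ATWATER_KCAL_PER_G[comp] * mass / energy
            for comp, mass in masses.items()}


def classify_ratio(kind: RatioKind, value: float) -> str:
    """Bioavailability category for a phytate:mineral molar ratio.

    Phy:Fe below the critical value 1 indicates desirable iron
    bioavailability. Phy:Zn below 5 indicates high, 5-15 (inclusive)
    moderate, and above 15 poor zinc bioavailability. No accepted
    threshold exists for Phy:Ca, which stays unclassified.
    """
    if kind == "phy_fe":
        return "desired" if value < 1.0 else "above_critical"
    if kind == "phy_zn":
        if value < 5.0:
            return "high"
        if value <= 15.0:
            return "moderate"
        return "poor"
    return "unclassified"


def phytate_mineral_molar_ratio(
        m: MineralAntinutrientProfile,
        kind: RatioKind,
        molar_masses: dict[str, float] | None = None) -> MolarRatioResult:
    """Molar ratio (phytate / MW_phytate) / (mineral / MW_mineral)."""
    if kind not in RATIO_MINERAL:
        raise ValueError(f"unknown ratio kind {kind!r}")
    mm = molar_masses if molar_masses is not None else MOLAR_MASS_G_PER_MOL
    mineral_name = RATIO_MINERAL[kind]
    mineral = getattr(m, mineral_name)
    if mineral <= 0:
        raise ZeroDivisionError(
            f"cannot form {kind} ratio: {mineral_name} concentration is 0")
    value = (m.phytate / mm["phytate"]) / (mineral / mm[mineral_name])
    return MolarRatioResult(ratio_kind=kind, value=value,
                            category=classify_ratio(kind, value))


# ---------------------------------------------------------------------------
# Per-crop summaries

_PROXIMATE_FIELDS = ("moisture", "crude_protein", "crude_fat", "crude_fiber", "total_ash")
_MINERAL_FIELDS = ("iron", "zinc", "calcium", "vitamin_c", "phytate", "tannin")


def sample_frame(samples: Iterable[CropSample]) -> pd.DataFrame:
    """Flatten samples to one row each, adding per-sample derived columns.

    Derived columns: total/available carbohydrate, gross energy and the
    three molar ratios (NaN when the mineral is absent).
    """
    rows = []
    for s in samples:
        p = s.proximate.to_dry_weight()
        row: dict[str, object] = {"sample_id": s.sample_id, "crop": s.crop, "aez": s.aez}
        for f in _PROXIMATE_FIELDS:
            row[f] = getattr(p, f)
        for f in _MINERAL_FIELDS:
            row[f] = getattr(s.minerals, f)
        row["total_carbohydrate"] = total_carbohydrate(p)
        row["available_carbohydrate"] = available_carbohydrate(p)
        row["gross_energy"] = gross_energy(p)
        for kind in RATIO_MINERAL:
            mineral = getattr(s.minerals, RATIO_MINERAL[kind])
            row[kind] = (phytate_mineral_molar_ratio(s.minerals, kind).value
                         if mineral > 0 else math.nan)
        rows.append(row)
    if not rows:
        raise ValueError("no samples supplied")
    return pd.DataFrame(rows)


def summarize_by_crop(samples: Sequence[CropSample]) -> pd.DataFrame:
    """Per-crop mean and SD of every measured and derived quantity.

    Energy and molar ratios are computed per sample *before* averaging.
    SD uses the n-1 denominator and is reported missing (NaN) for
    single-sample crops.
    """
    df = sample_frame(samples)
    value_cols = [c for c in df.columns if c not in ("sample_id", "crop", "aez")]
    grouped = df.groupby("crop")[value_cols]
    summary = grouped.agg(["mean", "std", "count"])
    summary.columns = [f"{col}_{stat}" for col, stat in summary.columns]
    return summary


def ratio_report(samples: Sequence[CropSample]) -> dict:
    """Per-crop mean molar ratios with bioavailability categories (JSON-ready)."""
    df = sample_frame(samples)
    out: dict[str, dict] = {}
    for crop, sub in df.groupby("crop"):
        entry = {}
        for kind in RATIO_MINERAL:
            mean = float(sub[kind].mean())
            entry[kind] = {"mean_ratio": mean,
                           "category": classify_ratio(kind, mean)}  # type: ignore[arg-type]
        out[str(crop)] = entry
    return out


# ---------------------------------------------------------------------------
# CSV interface

_CSV_COLUMNS = ["sample_id", "crop", "aez", "moisture", "protein", "fat",
                "fiber", "ash", "fe", "zn", "ca", "vitc", "phytate", "tannin",
                "basis"]


def read_samples_csv(path: str | Path, validate_crop_aez: bool = False) -> list[CropSample]:
    """Read crop samples from the one-row-per-sample CSV layout."""
    df = pd.read_csv(path)
    missing = set(_CSV_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"samples CSV {path} is missing columns: {sorted(missing)}")
    samples = []
    for rec in df.itertuples(index=False):
        sample = CropSample(
            sample_id=str(rec.sample_id),
            crop=str(rec.crop),
            aez=str(rec.aez),
            proximate=ProximateComposition(
                moisture=float(rec.moisture), crude_protein=float(rec.protein),
                crude_fat=float(rec.fat), crude_fiber=float(rec.fiber),
                total_ash=float(rec.ash), basis=str(rec.basis)),  # type: ignore[arg-type]
            minerals=MineralAntinutrientProfile(
                iron=float(rec.fe), zinc=float(rec.zn), calcium=float(rec.ca),
                vitamin_c=float(rec.vitc), phytate=float(rec.phytate),
                tannin=float(rec.tannin)),
        )
        if validate_crop_aez:
            sample.validate_crop_aez()
        samples.append(sample)
    return samples


def write_samples_csv(samples: Sequence[CropSample], path: str | Path) -> None:
    rows = []
    for s in samples:
        p = s.proximate
        m = s.minerals
        rows.append({
            "sample_id": s.sample_id, "crop": s.crop, "aez": s.aez,
            "moisture": p.moisture, "protein": p.crude_protein, "fat": p.crude_fat,
            "fiber": p.crude_fiber, "ash": p.total_ash,
            "fe": m.iron, "zn": m.zinc, "ca": m.calcium, "vitc": m.vitamin_c,
            "phytate": m.phytate, "tannin": m.tannin, "basis": p.basis,
        })
    pd.DataFrame(rows, columns=_CSV_COLUMNS).to_csv(path, index=False)
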