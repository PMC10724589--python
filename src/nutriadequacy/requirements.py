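"""Population-weighted estimated average requirements (EARs).

RNIs (intake sufficient for ~97.5% of a sex/life-stage group) are
converted to EARs as EAR = RNI / (1 + 2 CV), where CV is the coefficient
of variation of the requirement distribution (default 0.10, giving the
familiar RNI/1.2). Group EARs are then aggregated to a single per-capita
requirement by weighting with the population age-sex structure, after
carving pregnant and lactating fractions out of the childbearing female
bands using the crude birth rate: the pregnant fraction of the total
population is CBR x 280/365 (280-day gestation) and the lactating
fraction is CBR x 2 (two years of breastfeeding).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .config import DAYS_PER_YEAR, DEFAULT_REQUIREMENT_CV, LACTATION_YEARS, PREGNANCY_DAYS

LIFE_STAGES = ("none", "pregnant", "lactating")


class RequirementError(ValueError):
    """Raised for invalid requirement or population inputs."""


@dataclass(frozen=True)
class DemographicGroup:
    age_band: str
    sex: str  # "female" | "male"
    life_stage: str = "none"

    def __post_init__(self) -> None:
        if self.sex not in ("female", "male"):
            raise RequirementError(f"sex must be female/male, got {self.sex!r}")
        if self.life_stage not in LIFE_STAGES:
            raise RequirementError(f"life_stage must be one of {LIFE_STAGES}")
        if self.life_stage != "none" and self.sex != "female":
            raise RequirementError("pregnant/lactating groups must be female")


@dataclass
class PopulationStructure:
    """Age-sex population shares plus the crude birth rate.

    ``shares`` maps base groups (life_stage == "none") to their
    proportion of the total population; pregnancy/lactation splits are
    applied downstream, not stored here.
    """

    shares: dict[DemographicGroup, float]
    crude_birth_rate: float
    total_population: float = 1.0
    childbearing_bands: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        total = sum(self.shares.values())
        if abs(total - 1.0) > 1e-9:
            raise RequirementError(f"population shares sum to {total!r}, not 1")
        if any(v < 0 for v in self.shares.values()):
            raise RequirementError("population shares must be >= 0")
        if not 0.0 <= self.crude_birth_rate <= 0.1:
            raise RequirementError(
                f"crude_birth_rate {self.crude_birth_rate} outside plausible [0, 0.1]")
        if any(g.life_stage != "none" for g in self.shares):
            raise RequirementError("shares must be keyed by base (life_stage='none') groups")


def rni_to_ear(rni: float, requirement_cv: float = DEFAULT_REQUIREMENT_CV) -> float:
    """Convert an RNI to an EAR: EAR = RNI / (1 + 2 CV)."""
    if rni <= 0:
        raise RequirementError(f"RNI must be > 0, got {rni}")
    if not 0.0 <= requirement_cv < 0.5:
        raise RequirementError(f"requirement_cv must be in [0, 0.5), got {requirement_cv}")
    return rni / (1.0 + 2.0 * requirement_cv)


def pregnancy_fraction(cbr: float) -> float:
    """Fraction of the total population pregnant at any time: CBR x 280/365."""
    if cbr < 0:
        raise RequirementError("crude birth rate must be >= 0")
    return cbr * PREGNANCY_DAYS / DAYS_PER_YEAR


def lactation_fraction(cbr: float) -> float:
    """Fraction of the total population lactating at any time: CBR x 2."""
    if cbr < 0:
        raise RequirementError("crude birth rate must be >= 0")
    return cbr * LACTATION_YEARS


class RequirementTable:
    """Per-(nutrient, group) requirement values.

    Stores RNIs and converts to EARs lazily; rows where only an EAR is
    known can be loaded by setting ``requirement_cv`` to 0 and supplying
    the EAR in the ``rni`` column.
    """

    def __init__(self, frame: pd.DataFrame):
        required = {"nutrient", "age_band", "sex", "life_stage", "rni"}
        missing = required - set(frame.columns)
        if missing:
            raise RequirementError(f"requirement table missing columns: {sorted(missing)}")
        frame = frame.copy()
        if "requirement_cv" not in frame.columns:
            frame["requirement_cv"] = DEFAULT_REQUIREMENT_CV
        frame["requirement_cv"] = frame["requirement_cv"].fillna(DEFAULT_REQUIREMENT_CV)
        if (frame["rni"] <= 0).any():
            bad = frame.loc[frame["rni"] <= 0, "nutrient"].unique()
            raise RequirementError(f"non-positive requirement values for {list(bad)}")
        self._frame = frame
        self._index: dict[tuple[str, str, str, str], tuple[float, float]] = {}
        for rec in frame.itertuples(index=False):
            key = (str(rec.nutrient), str(rec.age_band), str(rec.sex), str(rec.life_stage))
            self._index[key] = (float(rec.rni), float(rec.requirement_cv))

    @classmethod
    def from_csv(cls, path: str | Path) -> "RequirementTable":
        return cls(pd.read_csv(path))

    @property
    def frame(self) -> pd.DataFrame:
        return self._frame.copy()

    @property
    def nutrients(self) -> list[str]:
        return sorted(self._frame["nutrient"].unique())

    def ear(self, nutrient: str, group: DemographicGroup) -> float:
        key = (nutrient, group.age_band, group.sex, group.life_stage)
        if key not in self._index:
            # fall back to the base row when no stage-specific entry exists
            base = (nutrient, group.age_band, group.sex, "none")
            if group.life_stage != "none" and base in self._index:
                key = base
            else:
                raise RequirementError(
                    f"no requirement for nutrient {nutrient!r}, group "
                    f"{group.age_band}/{group.sex}/{group.life_stage}")
        rni, cv = self._index[key]
        return rni_to_ear(rni, cv)


def adjusted_shares(pop: PopulationStructure) -> dict[DemographicGroup, float]:
    """Population shares after the pregnancy/lactation split.

    The total pregnant (CBR x 280/365) and lactating (CBR x 2) fractions
    are distributed over the childbearing female age bands in proportion
    to each band's share of childbearing-age women; within each band the
    remainder keeps life_stage "none". Shares still sum to 1.
    """
    preg_total = pregnancy_fraction(pop.crude_birth_rate)
    lact_total = lactation_fraction(pop.crude_birth_rate)
    childbearing = {
        g: s for g, s in pop.shares.items()
        if g.sex == "female" and g.age_band in pop.childbearing_bands
    }
    cb_total = sum(childbearing.values())
    if (preg_total > 0 or lact_total > 0) and cb_total == 0:
        raise RequirementError(
            "positive birth rate but no childbearing female population share")

    out: dict[DemographicGroup, float] = {}
    for group, share in pop.shares.items():
        if group in childbearing and cb_total > 0:
            w = share / cb_total
            preg = preg_total * w
            lact = lact_total * w
            if preg + lact > share + 1e-12:
                raise RequirementError(
                    f"pregnant+lactating fraction {preg + lact:.4g} exceeds the "
                    f"{group.age_band} female share {share:.4g}")
            out[DemographicGroup(group.age_band, "female", "pregnant")] = preg
            out[DemographicGroup(group.age_band, "female", "lactating")] = lact
            out[group] = share - preg - lact
        else:
            out[group] = share
    return out


def population_weighted_ear(req: RequirementTable, pop: PopulationStructure,
                            nutrient: str) -> float:
    """Per-capita EAR: sum over adjusted groups of share x group EAR."""
    shares = adjusted_shares(pop)
    return sum(share * req.ear(nutrient, group) for group, share in shares.items())


def weighted_ear_table(req: RequirementTable, pop: PopulationStructure,
                       nutrients: Iterable[str] | None = None) -> pd.Series:
    """Per-capita EARs for several nutrients as a Series."""
    names = list(nutrients) if nutrients is not None else req.nutrients
    return pd.Series({n: population_weighted_ear(req, pop, n) for n in names},
                     name="ear")


def read_population_csv(path: str | Path, crude_birth_rate: float,
                        childbearing_bands: Sequence[str] = (),
                        total_population: float = 1.0) -> PopulationStructure:
    """Load a population pyramid CSV with columns age_band, sex, share."""
    df = pd.read_csv(path)
    missing = {"age_band", "sex", "share"} - set(df.columns)
    if missing:
        raise RequirementError(f"population CSV missing columns: {sorted(missing)}")
    shares = {
        DemographicGroup(str(r.age_band), str(r.sex)): float(r.share)
        for r in df.itertuples(index=False)
    }
    return PopulationStructure(shares=shares, crude_birth_rate=crude_birth_rate,
                               total_population=total_population,
                               childbearing_bands=tuple(childbearing_bands))
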