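"""Prevalence of nutrient-supply deficits via the EAR cut-point method.

The per-capita supply mean for each nutrient and zone anchors an
assumed intake distribution whose spread is set by a per-nutrient
coefficient of variation (CV). The distribution is normal for CV at or
below 0.3 and lognormal above; the prevalence of deficit is the mass of
that distribution falling below the population-weighted EAR.

For the normal model the SD is anchored to the EAR by default
(sigma = CV x EAR); anchoring to the mean (sigma = CV x mean) is
available via configuration. The lognormal model is moment-matched to
(mean, CV): sigma_log^2 = ln(1 + CV^2), mu_log = ln(mean) - sigma_log^2/2.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.stats import norm

from .config import AnalysisConfig, DEFAULT_INTAKE_CVS, MODEL_RULE_THRESHOLD
from .supply import SupplySummary


class AdequacyError(ValueError):
    """Raised for invalid adequacy inputs."""


@dataclass
class AdequacySpec:
    """Per-nutrient CVs plus the model rule and SD anchoring choice."""

    cvs: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_INTAKE_CVS))
    model_rule_threshold: float = MODEL_RULE_THRESHOLD
    sd_anchor: str = "ear"

    def __post_init__(self) -> None:
        if not 0.0 < self.model_rule_threshold < 1.0:
            raise AdequacyError("model_rule_threshold must be in (0, 1)")
        if self.sd_anchor not in ("ear", "mean"):
            raise AdequacyError("sd_anchor must be 'ear' or 'mean'")
        for nutrient, cv in self.cvs.items():
            if not 0.0 < cv < 1.0:
                raise AdequacyError(f"CV for {nutrient} must be in (0, 1), got {cv}")

    @classmethod
    def from_config(cls, config: AnalysisConfig) -> "AdequacySpec":
        return cls(cvs=dict(config.intake_cvs),
                   model_rule_threshold=config.model_rule_threshold,
                   sd_anchor=config.sd_anchor)


@dataclass(frozen=True)
class DeficitEstimate:
    nutrient: str
    aez: str
    mean_supply: float
    ear: float
    model: str  # "normal" | "lognormal"
    prevalence_pct: float

    @property
    def adequacy_pct(self) -> float:
        return 100.0 - self.prevalence_pct


def choose_model(cv: float, threshold: float = MODEL_RULE_THRESHOLD) -> str:
    """Normal for CV <= threshold, lognormal above."""
    if cv <= 0:
        raise AdequacyError(f"cv must be > 0, got {cv}")
    return "normal" if cv <= threshold else "lognormal"


def prevalence_below_ear(mean_supply: float, ear: float, cv: float,
                         spec: AdequacySpec | None = None) -> float:
    """Percent of the intake distribution below the EAR.

    Normal model: 100 x Phi((EAR - mean) / sigma) with sigma = cv x EAR
    (default anchoring) or cv x mean. Lognormal model: moment-matched,
    100 x Phi((ln EAR - mu_log) / sigma_log).
    """
    if mean_supply <= 0:
        raise AdequacyError(f"mean_supply must be > 0, got {mean_supply}")
    if ear <= 0:
        raise AdequacyError(f"ear must be > 0, got {ear}")
    spec = spec or AdequacySpec()
    model = choose_model(cv, spec.model_rule_threshold)
    if model == "normal":
        sigma = cv * (ear if spec.sd_anchor == "ear" else mean_supply)
        z = (ear - mean_supply) / sigma
    else:
        sigma_log = np.sqrt(np.log1p(cv * cv))
        mu_log = np.log(mean_supply) - 0.5 * sigma_log * sigma_log
        z = (np.log(ear) - mu_log) / sigma_log
    return float(100.0 * norm.cdf(z))


def adequacy_met(estimate: DeficitEstimate) -> float:
    """Percent of the requirement met in distribution: 100 - prevalence."""
    return 100.0 - estimate.prevalence_pct


def round_half_up(value: float, decimals: int = 1) -> float:
    """Decimal half-up rounding used for report exports."""
    quantum = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(value)).quantize(quantum, rounding=ROUND_HALF_UP))


def deficit_table(supply: SupplySummary | pd.DataFrame,
                  ears: Mapping[str, float] | pd.Series,
                  spec: AdequacySpec | None = None) -> pd.DataFrame:
    """One deficit estimate per (zone, nutrient).

    ``supply`` is a SupplySummary or its nutrient frame (index aez,
    columns nutrients); ``ears`` maps nutrient -> per-capita EAR.
    Returns a tidy DataFrame with columns nutrient, aez, mean_supply,
    ear, cv, model, prevalence_pct, adequacy_pct; prevalences are
    full-precision (round for export with :func:`export_deficit_table`).
    """
    spec = spec or AdequacySpec()
    nutrients_frame = supply.nutrients if isinstance(supply, SupplySummary) else supply
    rows = []
    for nutrient in nutrients_frame.columns:
        if nutrient not in spec.cvs:
            raise AdequacyError(f"no intake CV configured for nutrient {nutrient!r}")
        if nutrient not in ears:
            raise AdequacyError(f"no EAR supplied for nutrient {nutrient!r}")
        cv = spec.cvs[nutrient]
        ear = float(ears[nutrient])
        model = choose_model(cv, spec.model_rule_threshold)
        for aez in nutrients_frame.index:
            mean_supply = float(nutrients_frame.loc[aez, nutrient])
            prevalence = prevalence_below_ear(mean_supply, ear, cv, spec)
            rows.append({
                "nutrient": nutrient, "aez": aez, "mean_supply": mean_supply,
                "ear": ear, "cv": cv, "model": model,
                "prevalence_pct": prevalence,
                "adequacy_pct": 100.0 - prevalence,
            })
    return pd.DataFrame(rows)


def export_deficit_table(table: pd.DataFrame, out_dir: str | Path) -> None:
    """Write the wide deficit CSV (one row per nutrient, one column per
    zone, half-up rounded to one decimal) and a JSON model report."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    wide = table.pivot(index="nutrient", columns="aez", values="prevalence_pct")
    wide = wide.map(lambda v: round_half_up(v, 1))
    wide["ear"] = table.drop_duplicates("nutrient").set_index("nutrient")["ear"]
    wide.to_csv(out / "deficits.csv")
    models = (table.drop_duplicates("nutrient")
              .set_index("nutrient")[["cv", "model"]]
              .to_dict(orient="index"))
    pd.Series(models).to_json(out / "models.json", indent=2)
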