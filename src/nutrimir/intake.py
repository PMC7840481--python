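"""FFQ-based estimation of daily natural-compound intake.

A food-frequency questionnaire (FFQ) records, per subject and food
item, how often the item is eaten (consumptions/day) and the portion
eaten each time (grams).  Combined with a food-composition table
(nutrient amounts per 100 g edible portion, plus energy in kcal per
100 g) this yields each subject's estimated daily intake of every
nutrient, which is then expressed relative to total energy intake so
that subjects with different overall consumption are comparable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .constants import NATURAL_COMPOUNDS

logger = logging.getLogger(__name__)

FFQ_COLUMNS = ("subject_id", "item_id", "frequency_per_day", "portion_g")


@dataclass
class IntakeTable:
    """Per-subject daily nutrient intakes.

    Attributes
    ----------
    raw : pandas.DataFrame
        subject x nutrient, units/day.
    energy_kcal_day : pandas.Series
        Daily energy intake per subject.
    normalized : pandas.DataFrame or None
        Energy-adjusted intakes (by default nutrient density per
        1,000 kcal); absent until :func:`kcal_normalize` is applied.
    excluded_subjects : list of str
        Subjects dropped from ``normalized`` for zero energy intake.
    """

    raw: pd.DataFrame
    energy_kcal_day: pd.Series
    normalized: pd.DataFrame | None = None
    excluded_subjects: list[str] = field(default_factory=list)

    @property
    def nc_ids(self) -> list[str]:
        return list(self.raw.columns)

    @property
    def subject_ids(self) -> list[str]:
        return list(self.raw.index)

    def analysis_values(self) -> pd.DataFrame:
        """The intake table downstream stages correlate against."""
        if self.normalized is None:
            raise ValueError("intake table not yet kcal-normalized")
        return self.normalized


def validate_nc_vocabulary(nc_ids) -> list[str]:
    """Return the NC ids not in the canonical 23-compound vocabulary."""
    return [nc for nc in nc_ids if nc not in NATURAL_COMPOUNDS]


def _check_ffq(ffq: pd.DataFrame) -> None:
    missing = [c for c in FFQ_COLUMNS if c not in ffq.columns]
    if missing:
        raise ValueError(f"FFQ table missing columns: {missing}")
    if (ffq["frequency_per_day"] < 0).any():
        bad = ffq.loc[ffq["frequency_per_day"] < 0, "item_id"].tolist()[:5]
        raise ValueError(f"negative frequency for items {bad}")
    if (ffq["portion_g"] <= 0).any():
        bad = ffq.loc[ffq["portion_g"] <= 0, "item_id"].tolist()[:5]
        raise ValueError(f"non-positive portion for items {bad}")
    if ffq.duplicated(["subject_id", "item_id"]).any():
        raise ValueError("duplicate (subject_id, item_id) rows in FFQ table")


def compute_intake(
    ffq: pd.DataFrame, composition: pd.DataFrame, missing_as_zero: bool = True
) -> IntakeTable:
    """Estimate raw daily nutrient intakes from FFQ responses.

    For nutrient *k* and subject *s*::

        raw_k(s) = sum over items  frequency * portion_g * amount_k / 100

    and daily energy is computed the same way from ``energy_kcal``.

    Parameters
    ----------
    ffq : long table with columns subject_id, item_id, frequency_per_day,
        portion_g.
    composition : indexed by item_id, with an ``energy_kcal`` column and
        one column per nutrient (amount per 100 g).
    missing_as_zero : treat NaN amounts in the composition table as 0
        (with a logged count); if False, raise instead.
    """
    _check_ffq(ffq)
    if composition.index.has_duplicates:
        raise ValueError("composition table has duplicate item_id rows")
    if "energy_kcal" not in composition.columns:
        raise ValueError("composition table missing energy_kcal column")
    unknown = sorted(set(ffq["item_id"]) - set(composition.index))
    if unknown:
        raise ValueError(f"FFQ references items absent from composition table: {unknown[:10]}")
    comp = composition.copy()
    n_missing = int(comp.isna().sum().sum())
    if n_missing:
        if not missing_as_zero:
            raise ValueError(f"composition table has {n_missing} missing values")
        logger.warning("treating %d missing composition values as 0", n_missing)
        comp = comp.fillna(0.0)
    if (comp < 0).any().any():
        raise ValueError("composition amounts must be >= 0")

    nutrients = [c for c in comp.columns if c != "energy_kcal"]
    grams = ffq["frequency_per_day"].to_numpy() * ffq["portion_g"].to_numpy()
    per_item = comp.loc[ffq["item_id"], ["energy_kcal", *nutrients]].to_numpy() / 100.0
    contrib = pd.DataFrame(
        per_item * grams[:, None],
        columns=["energy_kcal", *nutrients],
        index=ffq.index,
    )
    contrib["subject_id"] = ffq["subject_id"].to_numpy()
    totals = contrib.groupby("subject_id", sort=True).sum()
    return IntakeTable(
        raw=totals[nutrients],
        energy_kcal_day=totals["energy_kcal"].rename("energy_kcal_day"),
    )


def kcal_normalize(intake: IntakeTable, method: str = "density") -> IntakeTable:
    """Energy-adjust raw intakes.

    ``density`` (default): nutrient units per 1,000 kcal,
    ``raw / energy * 1000``.  ``residual``: the Willett residual method
    — per nutrient, the residual of a least-squares fit of raw intake
    on energy, recentred at the mean raw intake.

    Subjects with zero daily energy cannot be normalized; they are
    excluded from the normalized table with a logged warning and listed
    in ``excluded_subjects``.
    """
    if method not in {"density", "residual"}:
        raise ValueError(f"unknown normalization method {method!r}")
    energy = intake.energy_kcal_day
    keep = energy > 0
    excluded = list(energy.index[~keep])
    if excluded:
        logger.warning("excluding %d zero-energy subjects from normalization: %s",
                       len(excluded), excluded[:5])
    raw = intake.raw.loc[keep]
    e = energy.loc[keep]
    if method == "density":
        normalized = raw.div(e, axis=0) * 1000.0
    else:
        x = e.to_numpy()
        xc = x - x.mean()
        denom = float(xc @ xc)
        normalized = raw.copy()
        for col in raw.columns:
            y = raw[col].to_numpy()
            slope = float(xc @ (y - y.mean())) / denom if denom > 0 else 0.0
            normalized[col] = y - slope * xc
    return IntakeTable(
        raw=intake.raw.copy(),
        energy_kcal_day=energy.copy(),
        normalized=normalized,
        excluded_subjects=excluded,
    )
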