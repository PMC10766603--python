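"""Sampling-effort standardization: swept area, imputation, catch rates.

Swept area (km²) is the seafloor surface covered by the net: trawled
distance × gear opening.  When the distance is not recorded it is derived
from haul duration and vessel speed (1 knot = 1.852 km/h exactly).  Hauls
that still lack a swept area get one from a survey-specific ordinary
least-squares model on whatever predictors the survey records (haul
duration, depth, sweep length, country, vessel).  Weights missing from the
source can be reconstructed from abundance-at-length with the allometric
length-weight relationship w = a·l^b (w in grams, l in cm).  Standardized
rates are catch per hour (CPUE) and catch per km² (CPUA).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.formula.api as smf

from .dataset import SurveyDataset
from .errors import DomainError, FittingError, IntegrityError
from .taxonomy import Backbone

KNOTS_TO_KM_PER_H = 1.852

CANDIDATE_PREDICTORS = ("haul_dur", "depth", "sweep_length", "country", "vessel")
_CATEGORICAL = {"country", "vessel"}


def swept_area_from_distance(distance_km, gear_opening_m):
    """Swept area (km²) from trawled distance (km) and gear opening (m)."""
    distance_km = np.asarray(distance_km, dtype=float)
    gear_opening_m = np.asarray(gear_opening_m, dtype=float)
    if np.any(distance_km <= 0) or np.any(gear_opening_m <= 0):
        raise DomainError("distance and gear opening must be positive")
    area = distance_km * (gear_opening_m / 1000.0)
    return float(area) if area.ndim == 0 else area


def swept_area_from_speed(haul_dur_min, speed_knots, gear_opening_m):
    """Swept area (km²) from duration (min), speed (knots) and opening (m).

    The trawled distance is speed × duration with 1 kn = 1.852 km/h, then
    the distance-based formula applies (shared code path, so the two
    expressions agree exactly).
    """
    haul_dur_min = np.asarray(haul_dur_min, dtype=float)
    speed_knots = np.asarray(speed_knots, dtype=float)
    if np.any(haul_dur_min <= 0) or np.any(speed_knots <= 0):
        raise DomainError("duration and speed must be positive")
    distance_km = speed_knots * KNOTS_TO_KM_PER_H * haul_dur_min / 60.0
    return swept_area_from_distance(distance_km, gear_opening_m)


def derive_swept_area(
    ds: SurveyDataset, fallback_opening_m: float | None = None
) -> SurveyDataset:
    """Fill ``area_swept`` from recorded effort fields where possible.

    Priority per haul: keep a recorded area; else distance × opening; else
    duration × speed × opening.  ``fallback_opening_m`` (a standardized gear
    opening communicated per survey) substitutes for a missing haul-level
    opening.  Hauls still lacking the needed fields are left absent for the
    model-based imputation stage.
    """
    out = ds.copy()
    hauls = out.hauls
    opening = hauls["gear_opening"].astype(float)
    if fallback_opening_m is not None:
        opening = opening.fillna(float(fallback_opening_m))

    missing = hauls["area_swept"].isna()
    from_dist = (
        missing & hauls["distance"].gt(0).fillna(False) & opening.gt(0).fillna(False)
    )
    hauls.loc[from_dist, "area_swept"] = hauls.loc[from_dist, "distance"] * (
        opening[from_dist] / 1000.0
    )

    missing = hauls["area_swept"].isna()
    from_speed = (
        missing
        & hauls["haul_dur"].gt(0).fillna(False)
        & hauls["speed"].gt(0).fillna(False)
        & opening.gt(0).fillna(False)
    )
    dist = (
        hauls.loc[from_speed, "speed"]
        * KNOTS_TO_KM_PER_H
        * hauls.loc[from_speed, "haul_dur"]
        / 60.0
    )
    hauls.loc[from_speed, "area_swept"] = dist * (opening[from_speed] / 1000.0)
    out.log(
        f"swept area derived for {int(from_dist.sum())} haul(s) from distance, "
        f"{int(from_speed.sum())} from speed; "
        f"{int(hauls['area_swept'].isna().sum())} still missing"
    )
    return out


@dataclass
class SweptAreaModel:
    """Fitted OLS model predicting swept area from haul covariates."""

    predictors: tuple[str, ...]
    result: object  # statsmodels RegressionResults
    n_fit: int
    r2: float
    _levels: dict[str, set] = None  # seen categorical levels

    @property
    def params(self) -> pd.Series:
        return self.result.params

    def predict(self, hauls: pd.DataFrame) -> pd.Series:
        """Predict swept area; NaN where a predictor is missing or a
        categorical level was not seen during fitting."""
        usable = hauls[list(self.predictors)].notna().all(axis=1)
        for col, levels in (self._levels or {}).items():
            usable &= hauls[col].isin(levels)
        pred = pd.Series(np.nan, index=hauls.index, dtype=float)
        if usable.any():
            pred.loc[usable] = self.result.predict(hauls.loc[usable])
        return pred


def fit_swept_area_model(
    hauls: pd.DataFrame,
    candidate_predictors: Sequence[str] = CANDIDATE_PREDICTORS,
    min_rows: int = 10,
    availability: float = 0.8,
) -> SweptAreaModel:
    """Fit OLS of swept area on the largest well-recorded predictor subset.

    Training rows are hauls with a known positive swept area.  A candidate
    predictor enters the model when it is non-missing in at least
    ``availability`` (default 80%) of those rows; categoricals enter as
    indicator contrasts.  The fit uses complete cases on the chosen subset
    and requires at least ``min_rows`` rows and more rows than parameters.

    Raises
    ------
    FittingError
        when too few rows are available; callers should fall back to a fixed
        per-survey gear opening.
    """
    train = hauls[hauls["area_swept"].notna() & (hauls["area_swept"] > 0)]
    chosen = [
        p
        for p in candidate_predictors
        if p in train.columns and train[p].notna().mean() >= availability
    ]
    if not chosen:
        raise FittingError(
            "no candidate predictor is available in enough hauls; "
            "fall back to a fixed per-survey gear opening"
        )
    complete = train.dropna(subset=chosen)
    terms = [f"C({p})" if p in _CATEGORICAL else p for p in chosen]
    formula = "area_swept ~ " + " + ".join(terms)
    n_params = 1 + sum(
        (complete[p].nunique() - 1) if p in _CATEGORICAL else 1 for p in chosen
    )
    if len(complete) < min_rows or len(complete) <= n_params:
        raise FittingError(
            f"only {len(complete)} complete-case rows for {n_params} parameters; "
            "fall back to a fixed per-survey gear opening"
        )
    result = smf.ols(formula, data=complete).fit()
    levels = {p: set(complete[p].dropna()) for p in chosen if p in _CATEGORICAL}
    return SweptAreaModel(
        predictors=tuple(chosen),
        result=result,
        n_fit=len(complete),
        r2=float(result.rsquared),
        _levels=levels,
    )


def impute_swept_area(ds: SurveyDataset, model: SweptAreaModel) -> SurveyDataset:
    """Fill missing swept areas with model predictions.

    Known areas are never touched.  Non-positive predictions are replaced by
    the smallest observed positive area with a warning; hauls missing every
    model predictor stay absent and are logged.
    """
    out = ds.copy()
    hauls = out.hauls
    missing = hauls["area_swept"].isna()
    if not missing.any():
        out.log("swept-area imputation: nothing to impute")
        return out
    pred = model.predict(hauls[missing])
    floor = hauls.loc[~missing & (hauls["area_swept"] > 0), "area_swept"].min()
    nonpos = pred.notna() & (pred <= 0)
    if nonpos.any():
        pred[nonpos] = floor
        out.log(
            f"warning: {int(nonpos.sum())} non-positive swept-area prediction(s) "
            f"floored to smallest observed area {floor:.6g} km²"
        )
    hauls.loc[missing, "area_swept"] = pred
    still = hauls["area_swept"].isna()
    imputed_ids = hauls.loc[missing & ~still, "haul_id"].tolist()
    out.log(
        f"imputed swept area for {len(imputed_ids)} haul(s) with model on "
        f"{model.predictors} (n_fit={model.n_fit}, r2={model.r2:.4f})"
    )
    if still.any():
        out.log(
            f"warning: {int(still.sum())} haul(s) lack every model predictor; "
            "swept area left absent"
        )
    return out


def weight_from_lengths(
    bins: Sequence[tuple[float, float]], lw_a: float, lw_b: float
) -> float:
    """Total weight (kg) of a length composition under w_g = a·l_cm^b.

    ``bins`` is a list of (length_cm midpoint, count) pairs; the empty list
    weighs 0 kg.  Coefficients are calibrated for grams and centimetres, as
    conventionally tabulated.
    """
    if not (lw_a > 0 and lw_b > 0):
        raise DomainError("length-weight coefficients must be positive")
    total_g = 0.0
    for length_cm, count in bins:
        if length_cm <= 0:
            raise DomainError(f"non-positive length {length_cm}")
        if count < 0:
            raise DomainError(f"negative count {count}")
        total_g += count * lw_a * length_cm**lw_b
    return total_g / 1000.0


def reconstruct_weights(
    ds: SurveyDataset, lengths: pd.DataFrame, backbone: Backbone
) -> SurveyDataset:
    """Fill missing catch weights from a long-format length table.

    ``lengths`` columns: haul_id, taxon (accepted name), length_cm, count.
    Only records whose wgt is absent are filled; taxa without backbone a/b
    coefficients are skipped with a warning.
    """
    out = ds.copy()
    catches = out.catches
    filled = 0
    skipped: set[str] = set()
    grouped = lengths.groupby(["haul_id", "taxon"])
    for (haul_id, taxon), grp in grouped:
        coeffs = backbone.length_weight(taxon)
        if coeffs is None:
            skipped.add(str(taxon))
            continue
        mask = (
            (catches["haul_id"] == haul_id)
            & (catches["accepted_name"] == taxon)
            & catches["wgt"].isna()
        )
        if mask.any():
            wgt = weight_from_lengths(
                list(zip(grp["length_cm"], grp["count"])), *coeffs
            )
            catches.loc[mask, "wgt"] = wgt
            filled += int(mask.sum())
    out.log(f"reconstructed weight for {filled} catch record(s) from lengths")
    if skipped:
        out.log(
            "warning: no length-weight coefficients for "
            f"{sorted(skipped)}; weights left absent"
        )
    return out


def compute_rates(ds: SurveyDataset) -> SurveyDataset:
    """Derive standardized catch rates on aggregated catches.

    num_cpue/wgt_cpue are per hour (num ÷ duration in hours); num_cpua/
    wgt_cpua per km² (num ÷ swept area).  A rate is absent whenever its
    numerator or denominator is absent.  Zero denominators cannot survive
    the quality filters; they raise an integrity error if encountered.
    """
    out = ds.copy()
    catches = out.catches
    hauls = out.hauls.set_index("haul_id")
    dur_h = catches["haul_id"].map(hauls["haul_dur"]).astype(float) / 60.0
    area = catches["haul_id"].map(hauls["area_swept"]).astype(float)
    if (dur_h == 0).any() or (area == 0).any():
        raise IntegrityError("zero effort denominator; quality filters not applied?")
    catches["num_cpue"] = catches["num"] / dur_h
    catches["wgt_cpue"] = catches["wgt"] / dur_h
    catches["num_cpua"] = catches["num"] / area
    catches["wgt_cpua"] = catches["wgt"] / area
    out.log("computed CPUE (per hour) and CPUA (per km²) rates")
    return out
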