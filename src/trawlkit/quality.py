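"""Haul validity rules and dataset-level quality filtering.

A haul is usable for standardized catch rates only if it carries a precise
geolocation, a full calendar date, the gear used, and at least one effort
proxy (haul duration or swept area).  On top of the per-haul predicate, the
dataset-level filter drops hauls the source marked invalid, hauls not taken
with otter trawls, hauls whose catch rows carry no abundance or weight at
all, and individual catch records with negative values (which indicate data
corruption, never real catches).
"""

from __future__ import annotations

from collections.abc import Mapping

import pandas as pd

from .dataset import FilterReport, SurveyDataset

#: Rule labels emitted by :func:`validate_haul` / :func:`apply_quality_filters`.
RULE_GEOLOCATION = "geolocation"
RULE_DATE = "date"
RULE_GEAR = "gear"
RULE_EFFORT = "effort"
RULE_INVALID = "invalid_flag"
RULE_GEAR_CATEGORY = "gear"
RULE_NO_CATCH = "no_catch_values"
RULE_NEGATIVE = "negative_value"


def _present(value) -> bool:
    return value is not None and not pd.isna(value)


def validate_haul(haul: Mapping) -> list[str]:
    """Return rule-violation labels for one haul (empty list = valid).

    Checks, in order: geolocation (latitude and longitude present and within
    [-90, 90] / [-180, 180]), full date (year, month, day), gear code
    present, and effort (haul_dur or area_swept present and positive) —
    either effort proxy suffices.  Catch presence is a dataset-level check.
    """
    violations: list[str] = []
    lat, lon = haul.get("latitude"), haul.get("longitude")
    if not (
        _present(lat) and _present(lon) and -90 <= lat <= 90 and -180 <= lon <= 180
    ):
        violations.append(RULE_GEOLOCATION)
    if not all(_present(haul.get(k)) for k in ("year", "month", "day")):
        violations.append(RULE_DATE)
    if not _present(haul.get("gear")):
        violations.append(RULE_GEAR)
    dur, area = haul.get("haul_dur"), haul.get("area_swept")
    if not ((_present(dur) and dur > 0) or (_present(area) and area > 0)):
        violations.append(RULE_EFFORT)
    return violations


def _vector_violations(hauls: pd.DataFrame) -> pd.DataFrame:
    """Vectorized equivalent of :func:`validate_haul` over a haul frame."""
    lat = hauls["latitude"]
    lon = hauls["longitude"]
    geo_ok = lat.notna() & lon.notna() & lat.between(-90, 90) & lon.between(-180, 180)
    date_ok = hauls[["year", "month", "day"]].notna().all(axis=1)
    gear_ok = hauls["gear"].notna()
    dur = hauls["haul_dur"]
    area = hauls["area_swept"]
    effort_ok = (dur.notna() & (dur > 0)) | (area.notna() & (area > 0))
    return pd.DataFrame(
        {
            RULE_GEOLOCATION: ~geo_ok,
            RULE_DATE: ~date_ok,
            RULE_GEAR: ~gear_ok,
            RULE_EFFORT: ~effort_ok.astype(bool),
        },
        index=hauls.index,
    )


def apply_quality_filters(ds: SurveyDataset) -> tuple[SurveyDataset, FilterReport]:
    """Drop invalid hauls and corrupt catch records.

    Removal rules, each recorded in the report:

    - ``invalid_flag``: the source survey marked the haul invalid;
    - ``gear``: gear category is not otter trawl, or gear missing;
    - ``geolocation`` / ``date`` / ``effort``: :func:`validate_haul` rules;
    - ``negative_value``: catch record with negative num or wgt (record-level,
      an integrity violation — removed, not zeroed);
    - ``no_catch_values``: haul whose remaining catch records are all absent
      in both num and wgt.

    The operation is idempotent and removals are conservative: catches of a
    removed haul are removed with it.  An empty result is a warning, not an
    error.
    """
    hauls = ds.hauls
    catches = ds.catches
    removals: list[tuple[str, str]] = []

    # Record-level rule first: negative values are corruption.
    neg = (catches["num"] < 0) | (catches["wgt"] < 0)
    for _, row in catches[neg.fillna(False)].iterrows():
        removals.append((f"{row['haul_id']}:{row['verbatim_name']}", RULE_NEGATIVE))
    catches = catches[~neg.fillna(False)]

    viol = _vector_violations(hauls)
    invalid = hauls["quality_flag"].fillna("valid").str.lower().eq("invalid")
    not_otter = hauls["gear_category"].fillna("other").str.lower().ne("otter")

    has_value = catches[["num", "wgt"]].notna().any(axis=1)
    hauls_with_values = set(catches.loc[has_value, "haul_id"])
    no_catch = ~hauls["haul_id"].isin(hauls_with_values)

    drop = invalid | not_otter | viol.any(axis=1) | no_catch
    for idx in hauls.index[drop]:
        hid = hauls.at[idx, "haul_id"]
        if invalid[idx]:
            removals.append((hid, RULE_INVALID))
        elif not_otter[idx]:
            removals.append((hid, RULE_GEAR_CATEGORY))
        elif viol.loc[idx].any():
            for rule, flagged in viol.loc[idx].items():
                if flagged:
                    removals.append((hid, rule))
        else:
            removals.append((hid, RULE_NO_CATCH))

    kept_hauls = hauls[~drop].reset_index(drop=True)
    kept_ids = set(kept_hauls["haul_id"])
    kept_catches = catches[catches["haul_id"].isin(kept_ids)].reset_index(drop=True)

    out = SurveyDataset(kept_hauls, kept_catches, list(ds.provenance))
    report = FilterReport(n_in=len(hauls), n_out=len(kept_hauls), removals=removals)
    out.log(
        "quality filters: kept "
        f"{report.n_out}/{report.n_in} hauls; removals by rule: "
        f"{report.counts_by_rule()}"
    )
    if report.n_out == 0 and report.n_in > 0:
        out.log("warning: no hauls remain after quality filtering")
    return out, report
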