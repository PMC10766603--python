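"""Temporal taxonomic-consistency flags.

Surveys sometimes change the rank or name under which a taxon is recorded
(e.g. new field guides allow species-level identification where only the
genus was recorded before).  After harmonization such protocol changes show
up as a taxon present for one contiguous span of years and absent otherwise.
The flag rule marks a taxon as suspicious when, over the years its survey
unit actually sampled, it was present in less than 95% of years AND its
yearly presence sequence switched between present and absent fewer than
four times — few switches with low coverage is the signature of a naming
change, while frequent switching indicates a genuinely patchy species.
Both statistics are reported alongside the boolean so users can re-derive
alternative rules.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .dataset import SurveyDataset
from .errors import DomainError

PRESENCE_FRACTION_THRESHOLD = 0.95
TRANSITION_THRESHOLD = 4


@dataclass
class PresenceSeries:
    """Yearly presence of one taxon within one survey unit.

    ``years`` are the years the unit sampled at all (strictly increasing);
    ``present[i]`` is true when any haul of year ``years[i]`` recorded a
    strictly positive abundance or weight for the taxon.  Years the unit did
    not operate are excluded, so gaps in survey operation create no
    artificial transitions.
    """

    survey_unit: str
    taxon: str
    years: list[int]
    present: np.ndarray

    def __post_init__(self):
        self.present = np.asarray(self.present, dtype=bool)
        if list(self.years) != sorted(set(self.years)):
            raise DomainError("years must be strictly increasing")
        if len(self.years) != len(self.present):
            raise DomainError("years/present length mismatch")


def build_presence_series(
    ds: SurveyDataset, survey_unit: str | None = None
) -> list[PresenceSeries]:
    """One presence series per (survey unit, accepted taxon).

    Requires a harmonized, aggregated dataset.  Presence follows strictly
    positive num or wgt; null catches count as absence.  The year axis is
    the set of years in which the unit sampled at least one haul.
    """
    hauls = ds.hauls
    if survey_unit is not None:
        hauls = hauls[hauls["survey_unit"] == survey_unit]
    catches = ds.catches.merge(
        hauls[["haul_id", "survey_unit", "year"]], on="haul_id", how="inner"
    )
    series: list[PresenceSeries] = []
    for unit, unit_hauls in hauls.groupby("survey_unit", sort=True):
        years = sorted(unit_hauls["year"].dropna().astype(int).unique())
        year_pos = {y: i for i, y in enumerate(years)}
        unit_catches = catches[catches["survey_unit"] == unit]
        positive = unit_catches[
            (unit_catches["num"] > 0) | (unit_catches["wgt"] > 0)
        ]
        for taxon, grp in positive.groupby("accepted_name", sort=True):
            present = np.zeros(len(years), dtype=bool)
            for y in grp["year"].astype(int).unique():
                present[year_pos[y]] = True
            series.append(PresenceSeries(str(unit), str(taxon), years, present))
    return series


def count_transitions(present) -> int:
    """Number of adjacent present/absent switches in a presence sequence."""
    arr = np.asarray(present, dtype=bool)
    if arr.size == 0:
        raise DomainError("empty presence sequence")
    return int(np.sum(arr[1:] != arr[:-1]))


def evaluate_flag(present) -> tuple[float, int, bool]:
    """(presence_fraction, n_transitions, flagged) for one presence sequence.

    Flagged iff fraction < 0.95 AND transitions < 4, both strict.
    """
    arr = np.asarray(present, dtype=bool)
    if arr.size == 0:
        raise DomainError("empty presence sequence")
    fraction = float(arr.mean())
    transitions = count_transitions(arr)
    flagged = (
        fraction < PRESENCE_FRACTION_THRESHOLD
        and transitions < TRANSITION_THRESHOLD
    )
    return fraction, transitions, flagged


def flag_taxa(series: list[PresenceSeries]) -> pd.DataFrame:
    """Apply the flag rule to every presence series.

    Returns a table (survey_unit, accepted_name, presence_fraction,
    n_transitions, flag_taxon).  Survey units with fewer than two sampled
    years cannot support the rule; their series are skipped with a warning
    row left out of the table.
    """
    rows = []
    skipped_units: set[str] = set()
    for s in series:
        if len(s.years) < 2:
            skipped_units.add(s.survey_unit)
            continue
        fraction, transitions, flagged = evaluate_flag(s.present)
        rows.append(
            {
                "survey_unit": s.survey_unit,
                "accepted_name": s.taxon,
                "presence_fraction": fraction,
                "n_transitions": transitions,
                "flag_taxon": flagged,
            }
        )
    if skipped_units:
        import logging

        logging.getLogger(__name__).warning(
            "taxon flagging skipped for unit(s) with < 2 sampled years: %s",
            sorted(skipped_units),
        )
    return pd.DataFrame(
        rows,
        columns=[
            "survey_unit",
            "accepted_name",
            "presence_fraction",
            "n_transitions",
            "flag_taxon",
        ],
    )
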