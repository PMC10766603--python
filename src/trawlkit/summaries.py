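"""Per-survey summaries for technical validation.

Mirrors the quality-control overviews users should inspect before an
analysis: hauls per year, per-year distributions of sampling and biological
variables, trends of the most abundant taxa, and the share of hauls/taxa
flagged by each standardization method.  Everything is emitted as delimited
tables plus a plain-text report, so summaries are diffable and testable.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from . import schema
from .dataset import SurveyDataset

SUMMARY_VARIABLES = [
    "area_swept",
    "haul_dur",
    "depth",
    "num_cpue",
    "wgt_cpue",
    "num_cpua",
    "wgt_cpua",
]
QUANTILES = (0.05, 0.25, 0.5, 0.75, 0.95)


@dataclass
class SurveySummary:
    survey_unit: str
    hauls_per_year: pd.Series
    variable_distributions: pd.DataFrame  # (year, variable) x quantiles
    top_taxa_trends: pd.DataFrame  # year x taxon, yearly mean rate
    flag_percentages: dict[str, float]

    def to_text(self) -> str:
        lines = [
            f"survey unit: {self.survey_unit}",
            f"total hauls: {int(self.hauls_per_year.sum())} over "
            f"{len(self.hauls_per_year)} year(s)",
            "",
            "hauls per year:",
            self.hauls_per_year.to_string(),
            "",
            "flag percentages (% of hauls / taxa suggested for removal):",
        ]
        for name, pct in self.flag_percentages.items():
            lines.append(f"  {name}: {pct:.1f}%")
        lines += ["", "top taxa yearly mean rates:", self.top_taxa_trends.to_string()]
        return "\n".join(lines)

    def write(self, directory: str | Path) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        tag = self.survey_unit.replace("/", "_")
        self.hauls_per_year.rename("n_hauls").to_csv(
            directory / f"{tag}_hauls_per_year.csv"
        )
        self.variable_distributions.to_csv(
            directory / f"{tag}_variable_distributions.csv"
        )
        self.top_taxa_trends.to_csv(directory / f"{tag}_top_taxa_trends.csv")
        (directory / f"{tag}_summary.txt").write_text(self.to_text() + "\n")


def _rank_taxa(catches: pd.DataFrame, n: int = 6) -> list[str]:
    """Most abundant taxa by total num, falling back to wgt."""
    by_num = catches.groupby("accepted_name")["num"].sum(min_count=1)
    if by_num.notna().any():
        ranked = by_num.fillna(0.0)
    else:
        ranked = catches.groupby("accepted_name")["wgt"].sum(min_count=1).fillna(0.0)
    return list(ranked.sort_values(ascending=False).head(n).index)


def summarize(
    ds: SurveyDataset,
    footprint_flags: pd.DataFrame | None = None,
    taxon_flags: pd.DataFrame | None = None,
    survey_unit: str | None = None,
    n_top_taxa: int = 6,
) -> SurveySummary:
    """Summarize one survey unit of a fully processed dataset."""
    hauls = ds.hauls
    if survey_unit is None:
        survey_unit = str(hauls["survey_unit"].iloc[0])
    hauls = hauls[hauls["survey_unit"] == survey_unit]
    catches = ds.catches[ds.catches["haul_id"].isin(set(hauls["haul_id"]))]
    year_of = hauls.set_index("haul_id")["year"].astype(int)

    hauls_per_year = (
        hauls["year"].astype(int).value_counts().sort_index().rename("n_hauls")
    )

    long = catches.assign(year=catches["haul_id"].map(year_of))
    merged = long.merge(
        hauls[["haul_id", "area_swept", "haul_dur", "depth"]], on="haul_id"
    )
    dist_rows = []
    for var in SUMMARY_VARIABLES:
        source = hauls.assign(year=hauls["year"].astype(int)) if var in (
            "area_swept",
            "haul_dur",
            "depth",
        ) else merged
        for year, grp in source.groupby("year"):
            q = grp[var].quantile(QUANTILES)
            row = {"year": int(year), "variable": var}
            row.update({f"q{int(p * 100):02d}": q.loc[p] for p in QUANTILES})
            dist_rows.append(row)
    distributions = pd.DataFrame(dist_rows).set_index(["year", "variable"])

    top = _rank_taxa(catches, n_top_taxa)
    rate = "num_cpue" if long["num_cpue"].notna().any() else "wgt_cpue"
    trends = (
        long[long["accepted_name"].isin(top)]
        .pivot_table(index="year", columns="accepted_name", values=rate, aggfunc="mean")
        .reindex(columns=top)
    )
    trends.columns.name = f"mean_{rate}"

    flag_pcts: dict[str, float] = {}
    if footprint_flags is not None:
        sub = footprint_flags.loc[footprint_flags.index.isin(set(hauls["haul_id"]))]
        for col in schema.FLAG_COLUMNS:
            flag_pcts[col] = round(100.0 * sub[col].mean(), 1)
    if taxon_flags is not None:
        tsub = taxon_flags[taxon_flags["survey_unit"] == survey_unit]
        if len(tsub):
            flag_pcts["flag_taxon"] = round(100.0 * tsub["flag_taxon"].mean(), 1)

    return SurveySummary(
        survey_unit=survey_unit,
        hauls_per_year=hauls_per_year,
        variable_distributions=distributions,
        top_taxa_trends=trends,
        flag_percentages=flag_pcts,
    )
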