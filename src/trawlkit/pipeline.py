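"""High-level standardization pipeline.

Chains the stage functions in their canonical order: quality filters →
taxonomic harmonization → fish-class filter → per-taxon-per-haul
aggregation → re-applied quality filters (hauls emptied by harmonization) →
swept-area derivation and model imputation → standardized rates.  Each
stage also works standalone; this module exists so the CLI, the examples
and tests all run the exact same sequence.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .dataset import FilterReport, SurveyDataset
from .effort import (
    compute_rates,
    derive_swept_area,
    fit_swept_area_model,
    impute_swept_area,
)
from .errors import FittingError
from .quality import apply_quality_filters
from .taxonomy import (
    AliasTable,
    Backbone,
    aggregate_per_taxon_haul,
    filter_fish_classes,
    harmonize_dataset,
)


@dataclass
class PipelineReport:
    quality: FilterReport
    unmatched_names: pd.DataFrame
    class_filter: FilterReport
    post_harmonization_quality: FilterReport
    notes: list[str] = field(default_factory=list)


def standardize(
    ds: SurveyDataset,
    backbone: Backbone,
    aliases: AliasTable | None = None,
    fallback_opening_m: float | None = None,
    impute: bool = True,
) -> tuple[SurveyDataset, PipelineReport]:
    """Run the full standardization on a raw dataset.

    ``fallback_opening_m`` supplies a fixed per-survey gear opening when the
    haul-level opening is missing.  With ``impute`` true, hauls still
    lacking a swept area after direct derivation get model predictions; a
    fit failure downgrades to a note rather than an error, since rates per
    hour remain computable.
    """
    notes: list[str] = []
    ds, quality_report = apply_quality_filters(ds)
    ds, unmatched = harmonize_dataset(ds, backbone, aliases)
    ds, class_report = filter_fish_classes(ds)
    ds = aggregate_per_taxon_haul(ds)
    # hauls whose catches all vanished during harmonization drop out here
    ds, post_report = apply_quality_filters(ds)
    ds = derive_swept_area(ds, fallback_opening_m=fallback_opening_m)
    if impute and ds.hauls["area_swept"].isna().any():
        try:
            model = fit_swept_area_model(ds.hauls)
            ds = impute_swept_area(ds, model)
        except FittingError as exc:
            notes.append(f"swept-area imputation skipped: {exc}")
            ds.log(f"warning: {notes[-1]}")
    ds = compute_rates(ds)
    return ds, PipelineReport(
        quality=quality_report,
        unmatched_names=unmatched,
        class_filter=class_report,
        post_harmonization_quality=post_report,
        notes=notes,
    )
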