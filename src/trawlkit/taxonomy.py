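"""Taxonomic harmonization against a local backbone table.

Verbatim names and identifiers reported by each survey are resolved to their
currently accepted scientific name using a user-supplied snapshot of a marine
taxonomic register (an AphiaID-style backbone).  Resolution is deterministic
and fully offline: (1) survey-specific override aliases, (2) exact identifier
match, (3) exact name match (case-insensitive, whitespace-normalized), with
synonyms following their ``accepted_taxon_id`` pointer in a single step.
There is no fuzzy matching — unmatched names are reported for curation and
removed from the dataset, never silently kept.
"""

from __future__ import annotations

import hashlib
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import NamedTuple

import numpy as np
import pandas as pd

from . import schema
from .dataset import FilterReport, SurveyDataset
from .errors import ConfigurationError, IntegrityError

BACKBONE_COLUMNS = [
    "name",
    "taxon_id",
    "status",
    "accepted_taxon_id",
    "accepted_name",
    "rank",
    "class_name",
    "spec_code",
    "lw_a",
    "lw_b",
]

_WS = re.compile(r"\s+")


def normalize_name(name: str) -> str:
    """Case-fold and collapse internal whitespace for exact matching."""
    return _WS.sub(" ", str(name).strip()).casefold()


class Match(NamedTuple):
    accepted_name: str
    taxon_id: int
    rank: str
    class_name: str
    spec_code: int | None


class Backbone:
    """Indexed view over a taxonomic backbone table.

    The table must satisfy: accepted entries point to themselves
    (``accepted_taxon_id == taxon_id``) and every synonym's
    ``accepted_taxon_id`` resolves to an accepted entry, so synonym
    resolution reaches a fixed point in one step.
    """

    def __init__(self, table: pd.DataFrame):
        missing = [c for c in BACKBONE_COLUMNS[:7] if c not in table.columns]
        if missing:
            raise ConfigurationError(f"backbone missing columns: {missing}")
        table = table.copy()
        for col in ("lw_a", "lw_b", "spec_code"):
            if col not in table.columns:
                table[col] = np.nan
        table["taxon_id"] = table["taxon_id"].astype(int)
        table["accepted_taxon_id"] = table["accepted_taxon_id"].astype(int)
        self.table = table
        self._by_id = {int(r.taxon_id): r for r in table.itertuples()}
        self._by_name = {normalize_name(r.name): r for r in table.itertuples()}
        self._validate()

    def _validate(self) -> None:
        for row in self.table.itertuples():
            if row.status == "accepted" and row.accepted_taxon_id != row.taxon_id:
                raise ConfigurationError(
                    f"accepted entry {row.name!r} does not point to itself"
                )
            target = self._by_id.get(int(row.accepted_taxon_id))
            if target is None or target.status != "accepted":
                raise ConfigurationError(
                    f"entry {row.name!r}: accepted_taxon_id "
                    f"{row.accepted_taxon_id} does not resolve to an accepted entry"
                )

    @property
    def content_hash(self) -> str:
        payload = self.table.sort_values("taxon_id").to_csv(index=False)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]

    def _to_match(self, row) -> Match:
        accepted = self._by_id[int(row.accepted_taxon_id)]
        spec = None if pd.isna(accepted.spec_code) else int(accepted.spec_code)
        return Match(
            accepted_name=accepted.name,
            taxon_id=int(accepted.taxon_id),
            rank=accepted.rank,
            class_name=accepted.class_name,
            spec_code=spec,
        )

    def lookup_id(self, taxon_id: int) -> Match | None:
        row = self._by_id.get(int(taxon_id))
        return None if row is None else self._to_match(row)

    def lookup_name(self, name: str) -> Match | None:
        row = self._by_name.get(normalize_name(name))
        return None if row is None else self._to_match(row)

    def length_weight(self, accepted_name: str) -> tuple[float, float] | None:
        """(a, b) coefficients for weight [g] = a * length[cm] ** b."""
        row = self._by_name.get(normalize_name(accepted_name))
        if row is None or pd.isna(row.lw_a) or pd.isna(row.lw_b):
            return None
        return float(row.lw_a), float(row.lw_b)


def read_backbone(path: str | Path, sep: str = ",") -> Backbone:
    return Backbone(pd.read_csv(path, sep=sep))


@dataclass
class AliasTable:
    """Survey-specific name overrides, e.g. lumping hard-to-distinguish
    congeners to their genus.  Keys are ``(survey_unit or "*", verbatim
    name)``; values are backbone names (any rank)."""

    entries: dict[tuple[str, str], str] = field(default_factory=dict)

    @classmethod
    def from_frame(cls, table: pd.DataFrame) -> "AliasTable":
        entries = {
            (str(r.survey_unit), normalize_name(r.verbatim_name)): str(r.target_name)
            for r in table.itertuples()
        }
        return cls(entries)

    @classmethod
    def read(cls, path: str | Path, sep: str = ",") -> "AliasTable":
        return cls.from_frame(pd.read_csv(path, sep=sep))

    def validate_against(self, backbone: Backbone) -> None:
        for key, target in self.entries.items():
            if backbone.lookup_name(target) is None:
                raise ConfigurationError(
                    f"alias {key} points to {target!r}, absent from backbone"
                )

    def get(self, survey_unit: str, verbatim: str) -> str | None:
        key = normalize_name(verbatim)
        return self.entries.get((str(survey_unit), key)) or self.entries.get(
            ("*", key)
        )


def harmonize_name(
    verbatim: str,
    verbatim_id: int | None,
    backbone: Backbone,
    aliases: AliasTable | None = None,
    survey_unit: str = "*",
    conflicts: list[str] | None = None,
) -> Match | None:
    """Resolve one verbatim name/identifier to its accepted taxon.

    Resolution order: alias for (survey_unit, name) or ("*", name); exact
    identifier match; exact normalized-name match.  When the identifier and
    the name resolve to *different* accepted taxa the identifier wins and the
    conflict is appended to ``conflicts``.  Returns None when unmatched.
    """
    if aliases is not None:
        target = aliases.get(survey_unit, verbatim)
        if target is not None:
            match = backbone.lookup_name(target)
            if match is None:
                raise ConfigurationError(
                    f"alias target {target!r} not in backbone"
                )
            return match

    id_match = None
    if verbatim_id is not None and not pd.isna(verbatim_id):
        id_match = backbone.lookup_id(int(verbatim_id))
    name_match = backbone.lookup_name(verbatim) if verbatim else None

    if id_match is not None and name_match is not None:
        if id_match.taxon_id != name_match.taxon_id and conflicts is not None:
            conflicts.append(
                f"{survey_unit}: {verbatim!r} (id {verbatim_id}) resolves to "
                f"{id_match.accepted_name!r} by id but "
                f"{name_match.accepted_name!r} by name; kept id"
            )
        return id_match
    return id_match or name_match


def harmonize_dataset(
    ds: SurveyDataset,
    backbone: Backbone,
    aliases: AliasTable | None = None,
) -> tuple[SurveyDataset, pd.DataFrame]:
    """Fill accepted taxonomy on every catch record; drop unmatched names.

    Returns the harmonized dataset and an unmatched-name report
    (survey_unit, verbatim_name, n_records) for curation into the alias
    table.  Harmonization is per unique (survey_unit, verbatim_name,
    verbatim_aphia_id) key, hence order-independent over input rows.
    """
    if aliases is not None:
        aliases.validate_against(backbone)
    out = ds.copy()
    catches = out.catches
    unit_of = ds.hauls.set_index("haul_id")["survey_unit"]
    units = catches["haul_id"].map(unit_of)

    conflicts: list[str] = []
    keys = pd.DataFrame(
        {
            "survey_unit": units.astype(str),
            "verbatim_name": catches["verbatim_name"].astype(str),
            "verbatim_aphia_id": catches["verbatim_aphia_id"],
        }
    )
    resolved: dict[tuple, Match | None] = {}
    for key in set(map(tuple, keys.itertuples(index=False))):
        unit, name, vid = key
        resolved[key] = harmonize_name(
            name, None if pd.isna(vid) else int(vid), backbone, aliases, unit, conflicts
        )

    matches = [resolved[t] for t in map(tuple, keys.itertuples(index=False))]
    matched_mask = np.array([m is not None for m in matches])

    catches = catches.copy()
    catches["accepted_name"] = [m.accepted_name if m else pd.NA for m in matches]
    catches["aphia_id"] = pd.array(
        [m.taxon_id if m else pd.NA for m in matches], dtype="Int64"
    )
    catches["rank"] = [m.rank if m else pd.NA for m in matches]
    catches["class_name"] = [m.class_name if m else pd.NA for m in matches]
    catches["spec_code"] = pd.array(
        [m.spec_code if m else pd.NA for m in matches], dtype="Int64"
    )

    unmatched = (
        keys[~matched_mask]
        .groupby(["survey_unit", "verbatim_name"], as_index=False)
        .size()
        .rename(columns={"size": "n_records"})
    )
    out.catches = catches[matched_mask].reset_index(drop=True)
    out.log(
        f"harmonized against backbone {backbone.content_hash}: "
        f"{int(matched_mask.sum())}/{len(matched_mask)} records matched, "
        f"{len(unmatched)} unmatched name(s) removed"
    )
    for c in conflicts:
        out.log(f"warning: id/name conflict — {c}")
    return out, unmatched


def filter_fish_classes(
    ds: SurveyDataset, allowlist: tuple[str, ...] = schema.FISH_CLASSES
) -> tuple[SurveyDataset, FilterReport]:
    """Keep only catches whose taxonomic class is in the fish allowlist.

    Records with an absent class (unmatched taxonomy) are removed too and
    counted under their own rule label.
    """
    catches = ds.catches
    has_class = catches["class_name"].notna()
    keep = has_class & catches["class_name"].isin(allowlist)
    removals = []
    for _, row in catches[~keep].iterrows():
        rule = "non_fish_class" if pd.notna(row["class_name"]) else "no_class"
        removals.append((f"{row['haul_id']}:{row['verbatim_name']}", rule))
    out = ds.copy()
    out.catches = catches[keep].reset_index(drop=True)
    report = FilterReport(n_in=len(catches), n_out=len(out.catches), removals=removals)
    out.log(
        f"fish-class filter: kept {report.n_out}/{report.n_in} catch records "
        f"({report.counts_by_rule()})"
    )
    return out, report


def aggregate_per_taxon_haul(ds: SurveyDataset) -> SurveyDataset:
    """Merge catch records sharing (haul_id, accepted taxon).

    num and wgt are summed treating absent as missing (the sum is absent only
    when every contributing value is absent); verbatim names are concatenated
    with ';' as provenance.  Requires harmonization to have populated
    ``accepted_name``.
    """
    catches = ds.catches
    if catches["accepted_name"].isna().any():
        raise IntegrityError("aggregate_per_taxon_haul requires harmonized catches")

    keys = ["haul_id", "accepted_name"]
    grouped = catches.groupby(keys, sort=False)
    sums = grouped[["num", "wgt"]].sum(min_count=1)
    firsts = grouped[
        ["verbatim_name", "verbatim_aphia_id", "aphia_id", "rank", "class_name", "spec_code"]
    ].first()
    agg = firsts.join(sums)
    # concatenate verbatim names only where a group really merged records
    sizes = grouped.size()
    merged_keys = sizes[sizes > 1].index
    if len(merged_keys):
        dup_rows = catches.set_index(keys).loc[merged_keys]
        joined = (
            dup_rows.groupby(keys, sort=False)["verbatim_name"]
            .agg(lambda s: ";".join(dict.fromkeys(s.astype(str))))
        )
        agg.loc[joined.index, "verbatim_name"] = joined
    agg = agg.reset_index()
    for col in ("num_cpue", "wgt_cpue", "num_cpua", "wgt_cpua"):
        agg[col] = np.nan
    out = ds.copy()
    out.catches = agg[schema.CATCH_COLUMNS].reset_index(drop=True)
    out.log(
        f"aggregated per taxon per haul: {len(catches)} -> {len(agg)} records"
    )
    return out
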