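"""Canonical column dialect for haul-level bottom-trawl survey tables.

A survey table is a delimited text file with one row per taxon per haul.
Haul-level attributes (position, date, gear, effort) repeat on every row of
the same haul; catch-level attributes (taxonomy, abundance, weight, rates)
vary per row.  The canonical column names are snake_case; other dialects are
mapped onto this one with a rename map at read time.

Absent values are encoded as the empty string on disk and as NA in memory.
Units: latitude/longitude in decimal degrees (WGS84), depth in metres,
haul_dur in minutes, distance in km, speed in knots, gear_opening and
sweep_length in metres, area_swept in km², num in individuals, wgt in kg,
CPUE per hour, CPUA per km².
"""

from __future__ import annotations

# Haul-level columns (one logical record per haul_id).
HAUL_STRING_COLUMNS = [
    "haul_id",
    "survey",
    "survey_unit",
    "season",
    "station",
    "stratum",
    "stat_rec",
    "country",
    "vessel",
    "gear",
    "gear_category",
    "quality_flag",
]
HAUL_INT_COLUMNS = ["year", "month", "day", "quarter"]
HAUL_FLOAT_COLUMNS = [
    "latitude",
    "longitude",
    "depth",
    "haul_dur",
    "distance",
    "speed",
    "gear_opening",
    "sweep_length",
    "area_swept",
]
HAUL_COLUMNS = (
    HAUL_STRING_COLUMNS[:3]
    + HAUL_INT_COLUMNS
    + HAUL_STRING_COLUMNS[3:]
    + HAUL_FLOAT_COLUMNS
)

# Catch-level columns (one row per taxon per haul).
CATCH_STRING_COLUMNS = ["verbatim_name", "accepted_name", "rank", "class_name"]
CATCH_INT_COLUMNS = ["verbatim_aphia_id", "aphia_id", "spec_code"]
CATCH_FLOAT_COLUMNS = [
    "num",
    "wgt",
    "num_cpue",
    "wgt_cpue",
    "num_cpua",
    "wgt_cpua",
]
CATCH_COLUMNS = (
    ["haul_id"]
    + CATCH_STRING_COLUMNS[:1]
    + CATCH_INT_COLUMNS[:1]
    + CATCH_STRING_COLUMNS[1:]
    + CATCH_INT_COLUMNS[1:]
    + CATCH_FLOAT_COLUMNS
)

#: Columns that must be resolvable (possibly through the dialect map) for a
#: file to be readable at all.  Everything else is optional and filled with NA.
MANDATORY_COLUMNS = [
    "haul_id",
    "survey",
    "survey_unit",
    "latitude",
    "longitude",
    "year",
    "verbatim_name",
]

#: Gear categories; only otter-trawl hauls survive the quality filters.
GEAR_CATEGORIES = ("otter", "beam", "other")

#: Taxonomic classes retained by the fish-class filter: cartilaginous fishes
#: (sharks, rays, chimaeras) and the bony-fish lineages.
FISH_CLASSES = (
    "Elasmobranchii",
    "Holocephali",
    "Chondrostei",
    "Holostei",
    "Teleostei",
)

#: The five footprint flag columns, true = haul suggested for removal.
FLAG_COLUMNS = [
    "flag_hex_r7_t0",
    "flag_hex_r8_t0",
    "flag_hex_r7_t2",
    "flag_hex_r8_t2",
    "flag_biotime",
]
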