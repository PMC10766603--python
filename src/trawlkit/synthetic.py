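"""Synthetic bottom-trawl surveys with known ground truth.

The generator emulates the heterogeneity that makes real survey integration
hard — footprint drift (a stable core of cells sampled every year plus
transient peripheral cells visited sporadically), identification-protocol
changes (a species recorded under a different name from a given year
onward), and missing effort fields — while keeping the truth on record so
every pipeline stage has a recovery test.

Spatial layout: haul clusters are discs centred on hexagon centroids of the
resolution-7 equal-area grid (every other cell of a spiral, so clusters are
well separated); hauls scatter uniformly within each disc.  Catches follow a
Bernoulli-occupancy × lognormal-abundance model per species: each haul
catches species *s* with probability ``occupancy``; when caught, the true
catch-per-unit-area is lognormal, and the abundance is CPUA × the haul's
true swept area.

Randomness uses one seed with deterministically derived sub-streams per
stage (layout schedule, haul placement/effort, one stream per species), so
adding a species never perturbs haul placement.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, ValidationError, model_validator

from . import schema
from .dataset import SurveyDataset, _coerce_numeric, _coerce_string
from .errors import ConfigurationError, IntegrityError
from .grids import HexGrid
from .taxonomy import Backbone

_KM_PER_DEG_LAT = 111.19


class SpeciesConfig(BaseModel):
    name: str
    occupancy: float = Field(ge=0.0, le=1.0)
    mean_log_cpua: float  # mean of log CPUA (individuals per km²)
    sdlog: float = Field(ge=0.0)
    mean_weight_kg: float = Field(gt=0.0, default=0.2)


class RelabelEvent(BaseModel):
    """From ``year`` onward the species is recorded under ``replacement``."""

    species: str
    year: int
    replacement: str


def _default_species() -> list[SpeciesConfig]:
    rows = [
        ("Gadus morhua", 0.9, math.log(150.0), 0.8, 1.5),
        ("Melanogrammus aeglefinus", 0.8, math.log(120.0), 0.9, 0.6),
        ("Merlangius merlangus", 0.7, math.log(200.0), 1.0, 0.25),
        ("Pleuronectes platessa", 0.6, math.log(80.0), 1.0, 0.3),
        ("Glyptocephalus cynoglossus", 0.5, math.log(40.0), 1.0, 0.2),
        ("Clupea harengus", 0.6, math.log(500.0), 1.2, 0.1),
        ("Scomber scombrus", 0.4, math.log(60.0), 1.0, 0.3),
        ("Argentina sphyraena", 1.0, math.log(90.0), 0.8, 0.05),
    ]
    return [
        SpeciesConfig(
            name=n, occupancy=p, mean_log_cpua=m, sdlog=s, mean_weight_kg=w
        )
        for n, p, m, s, w in rows
    ]


class SimConfig(BaseModel):
    """Study conditions for one generated survey.

    Defaults describe a 20-year survey with a 9-cell stable core sampled
    every year, 6 transient cells each sampled with 30% yearly probability,
    and 4 hauls per sampled cell-year; complete effort fields unless
    ``missing_area_fraction`` > 0.
    """

    seed: int = Field(ge=0)
    n_years: int = Field(default=20, ge=2)
    start_year: int = 2000
    core_cells: int = Field(default=9, ge=1)
    transient_cells: int = Field(default=6, ge=0)
    transient_prob: float = Field(default=0.3, ge=0.0, le=1.0)
    hauls_per_cell_year: int = Field(default=4, ge=1)
    center_lat: float = 54.0
    center_lon: float = 6.0
    layout_resolution: int = 7
    jitter_km: float = Field(default=20.0, gt=0.0)
    species_pool: list[SpeciesConfig] = Field(default_factory=_default_species)
    #: None = one mid-series genus-lumping event for the always-present
    #: species; [] = no identification-protocol change.
    relabel_events: list[RelabelEvent] | None = None
    dur_mean: float = Field(default=30.0, gt=0.0)  # minutes
    dur_sd: float = Field(default=5.0, ge=0.0)
    speed_kn: float = Field(default=4.0, gt=0.0)
    opening_m: float = Field(default=20.0, gt=0.0)
    missing_area_fraction: float = Field(default=0.0, ge=0.0, le=1.0)
    survey: str = "SYN"
    survey_unit: str = "SYN-1"

    @model_validator(mode="after")
    def _check(self):
        if self.relabel_events is None:
            self.relabel_events = [
                RelabelEvent(
                    species="Argentina sphyraena",
                    year=self.start_year + self.n_years // 2,
                    replacement="Argentina",
                )
            ]
        names = {s.name for s in self.species_pool}
        for ev in self.relabel_events:
            if ev.species not in names:
                raise ValueError(f"relabel event for unknown species {ev.species!r}")
            if not (self.start_year <= ev.year < self.start_year + self.n_years):
                raise ValueError(
                    f"relabel year {ev.year} outside the survey period"
                )
        return self


def validate_config(raw: dict) -> SimConfig:
    """Build a :class:`SimConfig`, turning pydantic errors into
    :class:`ConfigurationError` naming the offending fields."""
    try:
        return SimConfig.model_validate(raw)
    except (ValidationError, ValueError) as exc:
        raise ConfigurationError(f"invalid simulation config: {exc}") from exc


@dataclass
class GroundTruth:
    """What the generator knows and the pipeline should recover."""

    cell_of_haul: pd.Series  # haul_id -> layout cell label
    transient_cells: set[str]
    relabel_pairs: list[tuple[str, str, int]]  # (original, replacement, year)
    area_true: pd.Series  # haul_id -> true swept area (km²)

    def is_transient_haul(self, haul_ids) -> pd.Series:
        cells = self.cell_of_haul.reindex(haul_ids)
        if cells.isna().any():
            raise IntegrityError("unknown haul_id in truth lookup")
        return cells.isin(self.transient_cells)


def _spiral_axial(n: int) -> list[tuple[int, int]]:
    """First n axial coordinates of a hexagon spiral around (0, 0)."""
    coords = [(0, 0)]
    directions = [(1, 0), (1, -1), (0, -1), (-1, 0), (-1, 1), (0, 1)]
    ring = 1
    while len(coords) < n:
        q, r = -ring, ring  # start corner of this ring
        for dq, dr in directions:
            for _ in range(ring):
                coords.append((q, r))
                q, r = q + dq, r + dr
        ring += 1
    return coords[:n]


def _rng(seed: int, *key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence((seed, *key)))


def generate_survey(cfg: SimConfig) -> tuple[SurveyDataset, GroundTruth]:
    """Generate one survey dataset plus its ground truth.

    Deterministic given ``cfg.seed``: the same config yields byte-identical
    tables.
    """
    if not isinstance(cfg, SimConfig):
        cfg = validate_config(cfg)
    grid = HexGrid(cfg.center_lat, cfg.center_lon, cfg.layout_resolution)
    n_cells = cfg.core_cells + cfg.transient_cells
    # every other spiral cell (axial × 2) keeps neighbouring clusters
    # at least two hexagon widths apart
    axial = [(2 * q, 2 * r) for q, r in _spiral_axial(n_cells)]
    centers = [grid.centroid(f"{q}|{r}") for q, r in axial]
    labels = [f"cell{i:02d}" for i in range(n_cells)]
    transient = set(labels[cfg.core_cells :])

    years = list(range(cfg.start_year, cfg.start_year + cfg.n_years))
    rng_sched = _rng(cfg.seed, 1)
    sched = {}
    for i, lab in enumerate(labels):
        if lab in transient:
            sampled = rng_sched.random(cfg.n_years) < cfg.transient_prob
        else:
            sampled = np.ones(cfg.n_years, dtype=bool)
        sched[lab] = sampled

    rng_haul = _rng(cfg.seed, 2)
    relabel = {ev.species: ev for ev in cfg.relabel_events}

    haul_rows = []
    counter = 0
    for yi, year in enumerate(years):
        for ci, lab in enumerate(labels):
            if not sched[lab][yi]:
                continue
            lat0, lon0 = centers[ci]
            for _ in range(cfg.hauls_per_cell_year):
                counter += 1
                # uniform in a disc of radius jitter_km
                rad = cfg.jitter_km * math.sqrt(rng_haul.random())
                ang = rng_haul.random() * 2.0 * math.pi
                dlat = rad * math.sin(ang) / _KM_PER_DEG_LAT
                dlon = rad * math.cos(ang) / (
                    _KM_PER_DEG_LAT * math.cos(math.radians(lat0))
                )
                dur = max(10.0, rng_haul.normal(cfg.dur_mean, cfg.dur_sd))
                dist = cfg.speed_kn * 1.852 * dur / 60.0
                area = dist * cfg.opening_m / 1000.0
                depth = 50.0 + 5.0 * ci + rng_haul.normal(0.0, 2.0)
                missing_area = rng_haul.random() < cfg.missing_area_fraction
                haul_rows.append(
                    {
                        "haul_id": f"{cfg.survey}-{year}-{counter:05d}",
                        "year": year,
                        "month": 6,
                        "day": int(rng_haul.integers(1, 29)),
                        "quarter": 2,
                        "season": "summer",
                        "latitude": lat0 + dlat,
                        "longitude": lon0 + dlon,
                        "depth": depth,
                        "haul_dur": dur,
                        "distance": dist,
                        "speed": cfg.speed_kn,
                        "gear_opening": cfg.opening_m,
                        "area_swept": np.nan if missing_area else area,
                        "area_true": area,
                        "country": "A" if ci % 2 == 0 else "B",
                        "vessel": f"V{year % 2 + 1}",
                        "cell_label": lab,
                    }
                )

    hauls = pd.DataFrame(haul_rows)
    hauls["survey"] = cfg.survey
    hauls["survey_unit"] = cfg.survey_unit
    hauls["station"] = pd.NA
    hauls["stratum"] = pd.NA
    hauls["stat_rec"] = pd.NA
    hauls["gear"] = "OTB"
    hauls["gear_category"] = "otter"
    hauls["quality_flag"] = "valid"
    hauls["sweep_length"] = 60.0

    catch_parts = []
    n_hauls = len(hauls)
    area_true = hauls["area_true"].to_numpy()
    for si, sp in enumerate(cfg.species_pool):
        rng_sp = _rng(cfg.seed, 3, si)
        caught = rng_sp.random(n_hauls) < sp.occupancy
        cpua = np.exp(rng_sp.normal(sp.mean_log_cpua, sp.sdlog, n_hauls))
        num = cpua * area_true
        sub = pd.DataFrame(
            {
                "haul_id": hauls.loc[caught, "haul_id"].to_numpy(),
                "year": hauls.loc[caught, "year"].to_numpy(),
                "num": num[caught],
            }
        )
        sub["wgt"] = sub["num"] * sp.mean_weight_kg
        ev = relabel.get(sp.name)
        if ev is None:
            sub["verbatim_name"] = sp.name
        else:
            sub["verbatim_name"] = np.where(
                sub["year"] >= ev.year, ev.replacement, sp.name
            )
        catch_parts.append(sub.drop(columns="year"))

    catches = pd.concat(catch_parts, ignore_index=True)
    catches = catches.sort_values(["haul_id", "verbatim_name"], kind="stable")
    catches["verbatim_aphia_id"] = pd.NA
    for col in ("accepted_name", "rank", "class_name"):
        catches[col] = pd.NA
    for col in ("aphia_id", "spec_code"):
        catches[col] = pd.NA
    for col in ("num_cpue", "wgt_cpue", "num_cpua", "wgt_cpua"):
        catches[col] = np.nan

    truth = GroundTruth(
        cell_of_haul=hauls.set_index("haul_id")["cell_label"],
        transient_cells=transient,
        relabel_pairs=[
            (ev.species, ev.replacement, ev.year) for ev in cfg.relabel_events
        ],
        area_true=hauls.set_index("haul_id")["area_true"],
    )

    hauls = hauls.drop(columns=["area_true", "cell_label"])
    _coerce_numeric(hauls, schema.HAUL_INT_COLUMNS, "int")
    _coerce_numeric(hauls, schema.HAUL_FLOAT_COLUMNS, "float")
    _coerce_string(hauls, schema.HAUL_STRING_COLUMNS)
    _coerce_numeric(catches, schema.CATCH_INT_COLUMNS, "int")
    _coerce_numeric(catches, schema.CATCH_FLOAT_COLUMNS, "float")
    _coerce_string(catches, schema.CATCH_STRING_COLUMNS)

    ds = SurveyDataset(
        hauls[schema.HAUL_COLUMNS].reset_index(drop=True),
        catches[schema.CATCH_COLUMNS].reset_index(drop=True),
    )
    ds.log(
        f"generated synthetic survey (seed={cfg.seed}): {ds.n_hauls} hauls, "
        f"{ds.n_catches} catches, {cfg.core_cells} core + "
        f"{cfg.transient_cells} transient cells over {cfg.n_years} years"
    )
    ds.validate()
    return ds, truth


def default_backbone() -> Backbone:
    """A small taxonomic backbone covering the default species pool.

    Synthetic stand-in for a register snapshot: accepted species of the
    pool, their genera, one synonym pair for resolution tests, and one
    non-fish taxon for the class filter.
    """
    rows = [
        # name, taxon_id, status, accepted_taxon_id, accepted_name, rank, class, spec_code, a, b
        ("Gadus morhua", 126436, "accepted", 126436, "Gadus morhua", "species", "Teleostei", 69, 0.0070, 3.08),
        ("Melanogrammus aeglefinus", 126437, "accepted", 126437, "Melanogrammus aeglefinus", "species", "Teleostei", 70, 0.0060, 3.10),
        ("Merlangius merlangus", 126438, "accepted", 126438, "Merlangius merlangus", "species", "Teleostei", 71, 0.0055, 3.05),
        ("Pleuronectes platessa", 127143, "accepted", 127143, "Pleuronectes platessa", "species", "Teleostei", 72, 0.0090, 3.02),
        ("Glyptocephalus cynoglossus", 127136, "accepted", 127136, "Glyptocephalus cynoglossus", "species", "Teleostei", 73, 0.0045, 3.12),
        ("Pleuronectes cynoglossus", 154377, "synonym", 127136, "Glyptocephalus cynoglossus", "species", "Teleostei", None, None, None),
        ("Clupea harengus", 126417, "accepted", 126417, "Clupea harengus", "species", "Teleostei", 24, 0.0050, 3.10),
        ("Scomber scombrus", 127023, "accepted", 127023, "Scomber scombrus", "species", "Teleostei", 118, 0.0060, 3.08),
        ("Argentina sphyraena", 125885, "accepted", 125885, "Argentina sphyraena", "species", "Teleostei", 1330, 0.0040, 3.15),
        ("Argentina silus", 126715, "accepted", 126715, "Argentina silus", "species", "Teleostei", 1331, 0.0042, 3.12),
        ("Argentina", 125799, "accepted", 125799, "Argentina", "genus", "Teleostei", None, None, None),
        ("Gadus", 125732, "accepted", 125732, "Gadus", "genus", "Teleostei", None, None, None),
        ("Squalus acanthias", 105923, "accepted", 105923, "Squalus acanthias", "species", "Elasmobranchii", 139, 0.0032, 3.05),
        ("Crangon crangon", 107552, "accepted", 107552, "Crangon crangon", "species", "Malacostraca", None, None, None),
    ]
    table = pd.DataFrame(
        rows,
        columns=[
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
        ],
    )
    return Backbone(table)


def truth_metrics(
    footprint_flags: pd.DataFrame | None,
    truth: GroundTruth,
    flag_column: str = "flag_hex_r7_t0",
    taxon_flags: pd.DataFrame | None = None,
) -> dict:
    """Confusion-matrix recovery report against the generator's truth.

    Footprint: sensitivity = flagged transient hauls / transient hauls,
    specificity = unflagged core hauls / core hauls, plus the raw counts.
    Taxon flags: fraction of relabel name pairs whose two names are both
    flagged.  Raises :class:`IntegrityError` on identifier mismatches.
    """
    out: dict = {}
    if footprint_flags is not None:
        flagged = footprint_flags[flag_column]
        transient = truth.is_transient_haul(footprint_flags.index)
        tp = int((flagged & transient).sum())
        fn = int((~flagged & transient).sum())
        fp = int((flagged & ~transient).sum())
        tn = int((~flagged & ~transient).sum())
        out.update(
            tp=tp,
            fn=fn,
            fp=fp,
            tn=tn,
            sensitivity=tp / (tp + fn) if tp + fn else float("nan"),
            specificity=tn / (tn + fp) if tn + fp else float("nan"),
        )
    if taxon_flags is not None:
        flagged_names = set(
            taxon_flags.loc[taxon_flags["flag_taxon"], "accepted_name"]
        )
        detected = sum(
            1
            for orig, repl, _ in truth.relabel_pairs
            if orig in flagged_names and repl in flagged_names
        )
        out["taxon_pairs"] = len(truth.relabel_pairs)
        out["taxon_pairs_detected"] = detected
        out["taxon_detection_rate"] = (
            detected / len(truth.relabel_pairs) if truth.relabel_pairs else float("nan")
        )
    return out
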