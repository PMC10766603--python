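"""Spatio-temporal footprint flags.

Survey footprints drift: cells visited opportunistically in a few years
contaminate time-series analyses.  Two flag families identify hauls outside
a consistently sampled core:

* **Hex cell-year completeness** — hauls are binned on the equal-area
  hexagonal grid (resolutions 7 and 8); cells and years are ordered by
  marginal coverage and the largest top-left rectangle of the ordered
  incidence matrix whose missing cell-year fraction is within a threshold
  (0% or 2%) is retained.  Hauls outside the retained cells × years are
  flagged.  Four flags: {resolution 7, 8} × {0%, 2%}.

* **BioTIME rule** — hauls on the survey-specific 5×5 grid are flagged when
  their cell-year holds fewer than 4 hauls, and whole cells are flagged when
  fewer than 10 years meet that 4-haul minimum.

Every filtered haul ends up with exactly five boolean flags
(true = suggested for removal).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import schema
from .dataset import SurveyDataset
from .errors import DomainError, IntegrityError
from .grids import assign_biotime_cells, assign_hex_cells


@dataclass
class IncidenceMatrix:
    """Boolean cells × years sampling structure for one survey unit."""

    survey_unit: str
    cells: list[str]
    years: list[int]
    sampled: np.ndarray  # bool, shape (len(cells), len(years))
    haul_index: dict[tuple[str, int], list[str]]

    def __post_init__(self):
        self.sampled = np.asarray(self.sampled, dtype=bool)
        if self.sampled.shape != (len(self.cells), len(self.years)):
            raise IntegrityError("incidence shape mismatch")

    def to_frame(self, core: "CoreSelection | None" = None) -> pd.DataFrame:
        """Diagnostic cells × years table (1 = sampled), writable as CSV.

        With a ``core`` selection, retained cell-years are marked with an
        asterisk so the retained rectangle is visible in the ordered table.
        """
        frame = pd.DataFrame(
            self.sampled.astype(int), index=self.cells, columns=self.years
        )
        frame.index.name = "cell"
        if core is not None:
            marked = frame.astype(str)
            for c in core.retained_cells:
                for y in core.retained_years:
                    marked.loc[c, y] += "*"
            frame = marked
        return frame


def build_incidence(
    hauls: pd.DataFrame, cell_ids: pd.Series, survey_unit: str = ""
) -> IncidenceMatrix:
    """Cross-tabulate hauls into a boolean cells × years matrix.

    Only observed cells appear as rows and only sampled years as columns;
    the result is invariant to the input row order (cells and years are
    sorted).
    """
    if len(hauls) == 0:
        raise DomainError("no hauls")
    years = hauls["year"].astype(int)
    cells = cell_ids.astype(str)
    tab = pd.crosstab(cells, years)
    tab = tab.sort_index(axis=0).sort_index(axis=1)
    haul_index: dict[tuple[str, int], list[str]] = {}
    for cell, year, hid in zip(cells, years, hauls["haul_id"]):
        haul_index.setdefault((cell, int(year)), []).append(hid)
    return IncidenceMatrix(
        survey_unit=survey_unit,
        cells=list(tab.index),
        years=[int(y) for y in tab.columns],
        sampled=tab.to_numpy() > 0,
        haul_index=haul_index,
    )


@dataclass
class CoreSelection:
    """Retained cells × years rectangle and its bookkeeping."""

    retained_cells: list[str]
    retained_years: list[int]
    missing_fraction: float
    objective: int  # retained cell-year count


def select_core(incidence: IncidenceMatrix, missing_threshold: float) -> CoreSelection:
    """Largest ordered cells × years rectangle within a missing budget.

    Cells are sorted by number of sampled years (descending) and years by
    number of sampled cells (descending), ties broken lexicographically for
    determinism.  Over all top-i cells × top-j years rectangles, the one
    maximizing i×j subject to missing/(i×j) ≤ threshold is returned; ties
    prefer more years, then more cells.  Whenever any rectangle meets the
    budget, the result does too — in particular at threshold 0 the retained
    rectangle then contains no missing cell-year.  In the degenerate case
    where no ordered rectangle meets the budget (possible only through
    coverage ties, e.g. a permutation-like incidence), the rectangle with
    the smallest missing fraction is returned, same tie-breaks; callers can
    detect this via ``missing_fraction`` exceeding the threshold.

    The unrestricted maximum-complete-submatrix problem is NP-hard; the
    ordered-rectangle family mirrors the marginal-coverage ordering under
    which well-sampled cells and years collect in one corner, and is exactly
    solvable in O(n·m).
    """
    M = incidence.sampled
    if M.size == 0:
        raise DomainError("empty incidence matrix")
    ncells, nyears = M.shape
    cell_order = sorted(
        range(ncells), key=lambda i: (-int(M[i].sum()), incidence.cells[i])
    )
    year_order = sorted(
        range(nyears), key=lambda j: (-int(M[:, j].sum()), incidence.years[j])
    )
    P = M[np.ix_(cell_order, year_order)].astype(np.int64)
    cum = P.cumsum(axis=0).cumsum(axis=1)

    best: tuple[int, int, int] | None = None  # (objective, j, i)
    fallback: tuple[float, int, int, int] | None = None  # (-fraction, obj, j, i)
    for i in range(1, ncells + 1):
        for j in range(1, nyears + 1):
            total = i * j
            missing = total - int(cum[i - 1, j - 1])
            if missing <= missing_threshold * total + 1e-9:
                cand = (total, j, i)
                if best is None or cand > best:
                    best = cand
            fcand = (-missing / total, total, j, i)
            if fallback is None or fcand > fallback:
                fallback = fcand
    if best is not None:
        objective, j, i = best
    else:
        _, objective, j, i = fallback
    missing = i * j - int(cum[i - 1, j - 1])
    return CoreSelection(
        retained_cells=[incidence.cells[k] for k in cell_order[:i]],
        retained_years=[incidence.years[k] for k in year_order[:j]],
        missing_fraction=missing / (i * j),
        objective=objective,
    )


def _hex_flags_for_unit(
    hauls: pd.DataFrame,
    survey_unit: str,
    resolutions=(7, 8),
    thresholds=(0.0, 0.02),
) -> pd.DataFrame:
    flags = pd.DataFrame(index=hauls.index)
    years = hauls["year"].astype(int)
    for res in resolutions:
        cell_ids, _grid = assign_hex_cells(hauls, res)
        inc = build_incidence(hauls, cell_ids, survey_unit)
        for thr in thresholds:
            core = select_core(inc, thr)
            keep_cells = set(core.retained_cells)
            keep_years = set(core.retained_years)
            col = f"flag_hex_r{res}_t{0 if thr == 0 else 2}"
            flags[col] = ~(
                cell_ids.isin(keep_cells) & years.isin(keep_years)
            )
    return flags


def flag_hauls_hex(
    ds: SurveyDataset, resolutions=(7, 8), thresholds=(0.0, 0.02)
) -> pd.DataFrame:
    """Four hex cell-year completeness flags per haul (indexed by haul_id).

    Grids, incidence matrices and core selections are computed per survey
    unit; a haul is flagged when its cell or its year falls outside that
    unit's retained rectangle.
    """
    parts = []
    for unit, grp in ds.hauls.groupby("survey_unit", sort=False):
        f = _hex_flags_for_unit(grp, str(unit), resolutions, thresholds)
        f.index = grp["haul_id"].to_numpy()
        parts.append(f)
    out = pd.concat(parts)
    out.index.name = "haul_id"
    return out


def flag_hauls_biotime(
    ds: SurveyDataset, min_hauls: int = 4, min_years: int = 10
) -> pd.DataFrame:
    """BioTIME-style footprint flag per haul (indexed by haul_id).

    Stage 1 flags hauls whose (cell, year) holds fewer than ``min_hauls``
    hauls; stage 2 flags every haul of a cell with fewer than ``min_years``
    years that meet the ``min_hauls`` rule.  The 5×5 grid is survey-unit
    specific.
    """
    parts = []
    for unit, grp in ds.hauls.groupby("survey_unit", sort=False):
        cells = assign_biotime_cells(grp)
        years = grp["year"].astype(int)
        key = pd.DataFrame({"cell": cells, "year": years})
        per_cell_year = key.groupby(["cell", "year"]).size()
        dense_cell_years = per_cell_year[per_cell_year >= min_hauls]
        years_per_cell = dense_cell_years.groupby("cell").size()
        good_cells = set(years_per_cell[years_per_cell >= min_years].index)

        n_in_cell_year = per_cell_year.loc[
            pd.MultiIndex.from_frame(key)
        ].to_numpy()
        stage1 = n_in_cell_year < min_hauls
        stage2 = ~cells.isin(good_cells).to_numpy()
        f = pd.DataFrame(
            {"flag_biotime": stage1 | stage2}, index=grp["haul_id"].to_numpy()
        )
        parts.append(f)
    out = pd.concat(parts)
    out.index.name = "haul_id"
    return out


def combine_flags(ds: SurveyDataset) -> pd.DataFrame:
    """All five footprint flags per haul (columns of :data:`schema.FLAG_COLUMNS`)."""
    hex_flags = flag_hauls_hex(ds)
    bio = flag_hauls_biotime(ds)
    flags = hex_flags.join(bio, how="outer")
    if flags.isna().any().any() or len(flags) != ds.n_hauls:
        raise IntegrityError("footprint methods disagree on the haul set")
    return flags[schema.FLAG_COLUMNS].astype(bool)


def flag_summary(ds: SurveyDataset, flags: pd.DataFrame) -> pd.DataFrame:
    """Per survey unit, % of hauls flagged by each method (1 decimal)."""
    unit_of = ds.hauls.set_index("haul_id")["survey_unit"]
    units = flags.index.map(unit_of)
    rows = []
    for unit, grp in flags.groupby(units):
        row = {"survey_unit": unit, "n_hauls": len(grp)}
        for col in schema.FLAG_COLUMNS:
            row[f"pct_{col}"] = round(100.0 * grp[col].mean(), 1)
        rows.append(row)
    return pd.DataFrame(rows)
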