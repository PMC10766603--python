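"""Incidence construction, core-rectangle selection and the five haul flags."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import trawlkit as tk
from conftest import make_dataset, make_hauls
from trawlkit.footprint import IncidenceMatrix, build_incidence, select_core


def brute_force_core(matrix, cells, years, threshold):
    """Independent oracle: explicit search over all sorted-marginal rectangles.

    Re-sorts axes by marginal coverage, then walks every (i, j) rectangle
    counting missing entries one by one.
    """
    M = np.asarray(matrix, dtype=bool)
    ncells, nyears = M.shape
    cell_order = sorted(range(ncells), key=lambda i: (-M[i].sum(), cells[i]))
    year_order = sorted(range(nyears), key=lambda j: (-M[:, j].sum(), years[j]))
    best = None
    fallback = None
    for i in range(1, ncells + 1):
        for j in range(1, nyears + 1):
            missing = 0
            for ci in cell_order[:i]:
                for yj in year_order[:j]:
                    if not M[ci, yj]:
                        missing += 1
            if missing <= threshold * i * j + 1e-9:
                cand = (i * j, j, i)
                if best is None or cand > best:
                    best = cand
            fcand = (-missing / (i * j), i * j, j, i)
            if fallback is None or fcand > fallback:
                fallback = fcand
    if best is not None:
        obj, j, i = best
    else:  # no rectangle meets the budget: smallest missing fraction wins
        _, obj, j, i = fallback
    return obj, [cells[k] for k in cell_order[:i]], [years[k] for k in year_order[:j]]


def make_incidence(matrix, cells=None, years=None):
    matrix = np.asarray(matrix, dtype=bool)
    ncells, nyears = matrix.shape
    cells = cells or [chr(ord("A") + i) for i in range(ncells)]
    years = years or list(range(2001, 2001 + nyears))
    haul_index = {
        (cells[i], years[j]): [f"{cells[i]}{years[j]}"]
        for i in range(ncells)
        for j in range(nyears)
        if matrix[i, j]
    }
    return IncidenceMatrix("U", list(cells), list(years), matrix, haul_index)


WORKED = [[1, 1, 1], [1, 1, 0], [1, 0, 0]]


class TestBuildIncidence:
    def test_single_haul_single_cell_year(self):
        frame = pd.DataFrame(
            [{**make_hauls(), "verbatim_name": "X", "num": 1.0, "wgt": 1.0}]
        )
        ds = make_dataset(frame)
        cells, _ = tk.assign_hex_cells(ds.hauls, 7)
        inc = build_incidence(ds.hauls, cells)
        assert inc.sampled.shape == (1, 1) and inc.sampled.all()

    def _pattern_hauls(self):
        # cells A/B/C at distant longitudes; sampling pattern = WORKED matrix
        lons = {"A": 0.0, "B": 6.0, "C": 12.0}
        pattern = {"A": [2001, 2002, 2003], "B": [2001, 2002], "C": [2001]}
        rows = []
        i = 0
        for cell, yrs in pattern.items():
            for y in yrs:
                i += 1
                rows.append(
                    {**make_hauls(haul_id=f"H{i}", year=y, longitude=lons[cell]),
                     "verbatim_name": "X", "num": 1.0, "wgt": 1.0}
                )
        return make_dataset(pd.DataFrame(rows))

    def test_worked_three_by_three_pattern(self):
        ds = self._pattern_hauls()
        cells, _ = tk.assign_hex_cells(ds.hauls, 7)
        inc = build_incidence(ds.hauls, cells)
        # reorder rows by coverage to compare against the worked matrix
        order = np.argsort(-inc.sampled.sum(axis=1), kind="stable")
        np.testing.assert_array_equal(
            inc.sampled[order].astype(int), np.array(WORKED)
        )

    def test_invariant_to_haul_order(self):
        ds = self._pattern_hauls()
        shuffled = ds.copy()
        shuffled.hauls = shuffled.hauls.sample(frac=1, random_state=3).reset_index(
            drop=True
        )
        c1, _ = tk.assign_hex_cells(ds.hauls, 7)
        c2, _ = tk.assign_hex_cells(shuffled.hauls, 7)
        a = build_incidence(ds.hauls, c1)
        b = build_incidence(shuffled.hauls, c2)
        assert a.cells == b.cells and a.years == b.years
        np.testing.assert_array_equal(a.sampled, b.sampled)


class TestSelectCore:
    def test_worked_example_objective_four(self):
        inc = make_incidence(WORKED)
        core = select_core(inc, 0.0)
        assert core.objective == 4
        assert core.retained_cells == ["A", "B"]
        assert core.retained_years == [2001, 2002]
        assert core.missing_fraction == 0.0

    def test_diagnostic_frame_marks_retained_rectangle(self):
        inc = make_incidence(WORKED)
        core = select_core(inc, 0.0)
        frame = inc.to_frame(core)
        assert frame.loc["A", 2001] == "1*"
        assert frame.loc["C", 2001] == "1"
        assert frame.loc["B", 2003] == "0"

    def test_complete_matrix_fully_retained(self):
        inc = make_incidence(np.ones((4, 5)))
        core = select_core(inc, 0.0)
        assert core.objective == 20 and core.missing_fraction == 0.0

    def test_empty_matrix_is_domain_error(self):
        with pytest.raises(tk.DomainError):
            select_core(make_incidence(np.ones((0, 0)).reshape(0, 0)), 0.0)

    @given(st.integers(0, 10_000))
    @settings(max_examples=60)
    def test_matches_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        m = rng.random((rng.integers(1, 9), rng.integers(1, 9))) < 0.6
        if not m.any():
            m[0, 0] = True
        inc = make_incidence(m)
        for thr in (0.0, 0.02):
            core = select_core(inc, thr)
            obj, cells, years = brute_force_core(m, inc.cells, inc.years, thr)
            assert core.objective == obj
            assert core.retained_cells == cells
            assert core.retained_years == years

    @given(st.integers(0, 10_000))
    @settings(max_examples=60)
    def test_zero_threshold_rectangle_is_complete(self, seed):
        rng = np.random.default_rng(seed)
        m = rng.random((6, 6)) < 0.5
        if not m.any():
            m[2, 3] = True
        inc = make_incidence(m)
        core = select_core(inc, 0.0)
        ci = [inc.cells.index(c) for c in core.retained_cells]
        yi = [inc.years.index(y) for y in core.retained_years]
        if core.missing_fraction == 0.0:
            assert m[np.ix_(ci, yi)].all()  # hard assert: no missing cell-years
        else:
            # only legal when no ordered rectangle is complete at all
            _, cells0, years0 = brute_force_core(m, inc.cells, inc.years, 0.0)
            ci0 = [inc.cells.index(c) for c in cells0]
            yi0 = [inc.years.index(y) for y in years0]
            assert not m[np.ix_(ci0, yi0)].all()

    @given(st.integers(0, 10_000))
    @settings(max_examples=60)
    def test_objective_monotone_in_threshold(self, seed):
        rng = np.random.default_rng(seed)
        m = rng.random((6, 6)) < 0.5
        if not m.any():
            m[0, 0] = True
        inc = make_incidence(m)
        assert select_core(inc, 0.02).objective >= select_core(inc, 0.0).objective


def _pattern_dataset():
    lons = {"A": 0.0, "B": 6.0, "C": 12.0}
    pattern = {"A": [2001, 2002, 2003], "B": [2001, 2002], "C": [2001]}
    rows = []
    i = 0
    for cell, yrs in pattern.items():
        for y in yrs:
            i += 1
            rows.append(
                {**make_hauls(haul_id=f"{cell}-{y}", year=y, longitude=lons[cell]),
                 "verbatim_name": "X", "num": 1.0, "wgt": 1.0}
            )
    return make_dataset(pd.DataFrame(rows))


class TestHexFlags:
    def test_worked_pattern_flags_outer_cell_and_year(self):
        ds = _pattern_dataset()
        flags = tk.flag_hauls_hex(ds, resolutions=(7,), thresholds=(0.0,))
        flagged = set(flags.index[flags["flag_hex_r7_t0"]])
        # retained core is {A,B} x {2001,2002}: cell C and year 2003 flagged
        assert flagged == {"C-2001", "A-2003"}

    def test_complete_survey_has_no_flags(self, small_survey):
        rows = []
        i = 0
        for cell_lon in (0.0, 6.0, 12.0):
            for y in (2001, 2002, 2003):
                i += 1
                rows.append(
                    {**make_hauls(haul_id=f"H{i}", year=y, longitude=cell_lon),
                     "verbatim_name": "X", "num": 1.0, "wgt": 1.0}
                )
        ds = make_dataset(pd.DataFrame(rows))
        flags = tk.flag_hauls_hex(ds)
        assert not flags.to_numpy().any()

    @given(st.integers(0, 5_000))
    @settings(max_examples=30)
    def test_zero_threshold_flags_at_least_as_many_hauls(self, seed):
        """One haul per sampled cell-year on random 6x6 patterns: the 0%
        core never keeps more hauls than the 2% core."""
        rng = np.random.default_rng(seed)
        m = rng.random((6, 6)) < 0.5
        if not m.any():
            m[0, 0] = True
        inc = make_incidence(m)
        flagged = {}
        for thr in (0.0, 0.02):
            core = select_core(inc, thr)
            keep = set(core.retained_cells), set(core.retained_years)
            flagged[thr] = sum(
                1
                for (c, y) in inc.haul_index
                if c not in keep[0] or y not in keep[1]
            )
        assert flagged[0.0] >= flagged[0.02]


class TestBioTimeFlags:
    def _dataset(self, cell_years, hauls_per=4):
        """cell_years: {lon_offset: {year: n_hauls}} clusters far apart."""
        rows = []
        i = 0
        for lon, years in cell_years.items():
            for year, n in years.items():
                for _ in range(n):
                    i += 1
                    rows.append(
                        {**make_hauls(haul_id=f"H{i}", year=year,
                                      longitude=lon, latitude=54.0),
                         "verbatim_name": "X", "num": 1.0, "wgt": 1.0}
                    )
        return make_dataset(pd.DataFrame(rows))

    def test_sparse_cell_year_flags_its_hauls(self):
        # cell at lon 0: 12 years of 4 hauls (healthy); year 2013 only 3
        years = {2001 + k: 4 for k in range(12)}
        years[2013] = 3
        ds = self._dataset({0.0: years, 10.0: {2001 + k: 4 for k in range(12)}})
        flags = tk.flag_hauls_biotime(ds)
        hauls = ds.hauls.set_index("haul_id")
        f2013 = flags.loc[hauls[hauls["year"] == 2013].index, "flag_biotime"]
        assert f2013.all() and len(f2013) == 3
        healthy = flags.loc[hauls[hauls["year"] != 2013].index, "flag_biotime"]
        assert not healthy.any()

    def test_nine_year_cell_entirely_flagged(self):
        ds = self._dataset(
            {0.0: {2001 + k: 4 for k in range(9)},
             10.0: {2001 + k: 4 for k in range(12)}}
        )
        flags = tk.flag_hauls_biotime(ds)
        hauls = ds.hauls.set_index("haul_id")
        west = flags.loc[hauls[hauls["longitude"] == 0.0].index, "flag_biotime"]
        assert west.all()  # < 10 qualifying years

    def test_twelve_year_cell_unflagged_in_qualifying_years(self):
        ds = self._dataset(
            {0.0: {2001 + k: 4 for k in range(12)},
             10.0: {2001 + k: 4 for k in range(12)}}
        )
        flags = tk.flag_hauls_biotime(ds)
        assert not flags["flag_biotime"].any()


class TestCombineAndSummarize:
    def test_five_flags_per_haul_and_conservation(self, small_survey):
        ds, _ = small_survey
        flags = tk.combine_flags(ds)
        assert list(flags.columns) == [
            "flag_hex_r7_t0",
            "flag_hex_r8_t0",
            "flag_hex_r7_t2",
            "flag_hex_r8_t2",
            "flag_biotime",
        ]
        assert len(flags) == ds.n_hauls
        for col in flags.columns:
            assert flags[col].sum() + (~flags[col]).sum() == ds.n_hauls

    def test_summary_percentages_to_one_decimal(self, small_survey):
        ds, _ = small_survey
        flags = tk.combine_flags(ds)
        summary = tk.flag_summary(ds, flags)
        row = summary.iloc[0]
        for col in flags.columns:
            expected = round(100.0 * flags[col].mean(), 1)
            assert row[f"pct_{col}"] == expected
            assert 0.0 <= row[f"pct_{col}"] <= 100.0
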