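"""In-memory survey container and delimited-text I/O.

A :class:`SurveyDataset` holds two pandas DataFrames — ``hauls`` (one row per
sampling event) and ``catches`` (one row per taxon per haul) — plus a
line-oriented provenance log.  On disk the two are stored joined, one row per
taxon per haul, in the canonical column dialect (see :mod:`trawlkit.schema`).
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import schema
from .errors import IntegrityError, SchemaError

logger = logging.getLogger(__name__)


@dataclass
class FilterReport:
    """Accounting of a filtering step.

    ``n_in``/``n_out`` count the filtered units (hauls for haul-level rules,
    catch records for record-level rules); ``removals`` lists one
    ``(key, rule_label)`` pair per removed unit, so
    ``n_in - n_out == len({key for key, _ in removals})``.
    """

    n_in: int
    n_out: int
    removals: list[tuple[str, str]] = field(default_factory=list)

    def counts_by_rule(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for _, rule in self.removals:
            out[rule] = out.get(rule, 0) + 1
        return out


@dataclass
class SurveyDataset:
    """Hauls, catches and a processing log for one or more survey units."""

    hauls: pd.DataFrame
    catches: pd.DataFrame
    provenance: list[str] = field(default_factory=list)

    def log(self, message: str) -> None:
        self.provenance.append(message)
        logger.info(message)

    def copy(self) -> "SurveyDataset":
        return SurveyDataset(
            self.hauls.copy(), self.catches.copy(), list(self.provenance)
        )

    @property
    def n_hauls(self) -> int:
        return len(self.hauls)

    @property
    def n_catches(self) -> int:
        return len(self.catches)

    def validate(self) -> None:
        """Check structural invariants; raise :class:`IntegrityError`."""
        if self.hauls["haul_id"].duplicated().any():
            dup = self.hauls.loc[self.hauls["haul_id"].duplicated(), "haul_id"]
            raise IntegrityError(f"duplicate haul_id values: {sorted(set(dup))[:5]}")
        known = set(self.hauls["haul_id"])
        orphan = ~self.catches["haul_id"].isin(known)
        if orphan.any():
            bad = sorted(set(self.catches.loc[orphan, "haul_id"]))[:5]
            raise IntegrityError(f"catch records reference unknown hauls: {bad}")


def _empty_frame(columns: list[str]) -> pd.DataFrame:
    return pd.DataFrame({c: pd.Series(dtype=object) for c in columns})


def _parse_float(value) -> float:
    # float() is correctly rounded; pandas' fast to_numeric parser is not,
    # which would break bit-for-bit round-trips
    try:
        return float(value)
    except (TypeError, ValueError):
        return np.nan


def _coerce_numeric(df: pd.DataFrame, columns: list[str], kind: str) -> list[str]:
    """Coerce columns in place; return warnings for unparseable cells."""
    warnings: list[str] = []
    for col in columns:
        if col not in df.columns:
            df[col] = np.nan
        raw = df[col]
        if pd.api.types.is_numeric_dtype(raw):
            coerced = raw.astype(float)
        else:
            coerced = raw.map(_parse_float).astype(float)
        bad = coerced.isna() & raw.notna() & (raw.astype(str).str.strip() != "")
        if bad.any():
            examples = sorted(set(raw[bad].astype(str)))[:3]
            warnings.append(
                f"column {col!r}: {int(bad.sum())} unparseable cell(s) set to "
                f"absent (e.g. {examples})"
            )
        if kind == "int":
            df[col] = coerced.round().astype("Int64")
        else:
            df[col] = coerced.astype(float)
    return warnings


def _coerce_string(df: pd.DataFrame, columns: list[str]) -> None:
    for col in columns:
        if col not in df.columns:
            df[col] = pd.NA
        s = df[col].astype("string")
        s = s.str.strip()
        df[col] = s.where(s.notna() & (s != ""), pd.NA)


def read_survey_table(
    path: str | Path,
    dialect: dict[str, str] | None = None,
    sep: str | None = None,
) -> SurveyDataset:
    """Read a one-row-per-taxon-per-haul delimited table.

    Parameters
    ----------
    path:
        UTF-8 delimited text file with a header row.  Comma separated by
        default; tab accepted (inferred from a ``.tsv`` suffix or forced with
        ``sep``).
    dialect:
        Optional ``{source_column: canonical_column}`` rename map for files in
        other column dialects.

    Raises
    ------
    SchemaError
        if a mandatory canonical column cannot be resolved.
    IntegrityError
        if one ``haul_id`` carries conflicting haul attributes.
    """
    path = Path(path)
    if sep is None:
        sep = "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","
    raw = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    raw = raw.replace("", np.nan).infer_objects(copy=False)
    if dialect:
        raw = raw.rename(columns=dialect)

    for col in schema.MANDATORY_COLUMNS:
        if col not in raw.columns:
            raise SchemaError(f"mandatory column {col!r} missing from {path.name}")

    ds = _dataset_from_long(raw)
    digest = hashlib.sha256(path.read_bytes()).hexdigest()[:16]
    ds.log(f"read {path.name}: {ds.n_hauls} hauls, {ds.n_catches} catches (sha256:{digest})")
    return ds


def _dataset_from_long(raw: pd.DataFrame) -> SurveyDataset:
    """Split a long-format table into haul and catch frames."""
    df = raw.copy()
    warnings: list[str] = []
    warnings += _coerce_numeric(df, schema.HAUL_INT_COLUMNS + schema.CATCH_INT_COLUMNS, "int")
    warnings += _coerce_numeric(df, schema.HAUL_FLOAT_COLUMNS + schema.CATCH_FLOAT_COLUMNS, "float")
    _coerce_string(df, schema.HAUL_STRING_COLUMNS + schema.CATCH_STRING_COLUMNS)

    hauls = df[schema.HAUL_COLUMNS].drop_duplicates(subset="haul_id", keep="first")
    # Detect conflicting haul attributes under one haul_id.
    grouped = df[schema.HAUL_COLUMNS].groupby("haul_id", sort=False)
    nun = grouped.nunique(dropna=True)
    conflicts = nun.gt(1).any(axis=1)
    if conflicts.any():
        bad = list(conflicts[conflicts].index[:5])
        raise IntegrityError(
            f"haul_id(s) with conflicting haul attributes: {bad}"
        )
    hauls = hauls.reset_index(drop=True)
    catches = df[schema.CATCH_COLUMNS].reset_index(drop=True)

    ds = SurveyDataset(hauls, catches)
    for w in warnings:
        ds.log(f"warning: {w}")
    ds.validate()
    return ds


def dataset_from_frame(raw: pd.DataFrame) -> SurveyDataset:
    """Build a dataset from an in-memory long-format frame (canonical names)."""
    for col in schema.MANDATORY_COLUMNS:
        if col not in raw.columns:
            raise SchemaError(f"mandatory column {col!r} missing")
    return _dataset_from_long(raw)


def to_long_frame(ds: SurveyDataset) -> pd.DataFrame:
    """Join hauls and catches back into one row per taxon per haul."""
    long = ds.catches.merge(ds.hauls, on="haul_id", how="left", validate="m:1")
    cols = schema.HAUL_COLUMNS + [c for c in schema.CATCH_COLUMNS if c != "haul_id"]
    return long[cols]


def write_survey_table(ds: SurveyDataset, path: str | Path, sep: str = ",") -> None:
    """Write the canonical long-format table; absent values become ''.

    Floats are serialized with the shortest representation that round-trips
    to the same double, so write → read reproduces numerics bit-for-bit.
    """
    path = Path(path)
    long = to_long_frame(ds).copy()
    for col in schema.HAUL_FLOAT_COLUMNS + schema.CATCH_FLOAT_COLUMNS:
        long[col] = long[col].map(lambda v: "" if pd.isna(v) else repr(float(v)))
    long.to_csv(path, sep=sep, index=False, na_rep="")
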