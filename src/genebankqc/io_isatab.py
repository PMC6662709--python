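"""Readers and writers for the tab-delimited study/assay layout.

The historical phenotypes ship as ISA-Tab-style pairs of files: a *study*
file (``s_*.txt``) with one row per accession carrying passport metadata
(accession number and ID, organism, sowing date, harvest year, origin) and
an *assay* file (``a_*.txt``) with one row per accession x regeneration
year carrying the trait scores (FT in days, PH in cm, TGW in g).  Weather
ships the same way with monthly rows for the five parameters.

Only the study/assay tables are parsed; full ISA-Tab investigation-file
semantics are out of scope.  Column headers are mapped through configurable
alias lists because deposits differ in capitalisation and wording.

Missing values: the empty string and ``"NA"`` are both treated as missing
and dropped (never zero-filled).
"""

from __future__ import annotations

import datetime as _dt
import logging
import warnings
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .exceptions import ValidationError

logger = logging.getLogger(__name__)

TRAITS = ("FT", "PH", "TGW")
WEATHER_PARAMETERS = ("T.avg", "T.min", "T.max", "Rain", "Moisture")
MISSING_SENTINELS = {"", "NA"}

#: decimals used when rendering numeric columns to text
_DECIMALS = {
    "value": 2,
    "YE": 2,
    "blue": 2,
    "se": 2,
    "h2": 2,
    "z": 2,
    "sigma2_e_star": 4,
    "cv": 4,
    "sigma2_g": 4,
    "sigma2_y": 4,
    "sigma2_e": 4,
    "studentized_residual": 4,
    "p_value": 6,
    "holm_p": 6,
    "diff_pct": 2,
}

DEFAULT_STUDY_ALIASES: Mapping[str, Sequence[str]] = {
    "accession_number": ("Accession number", "accession_number"),
    "accession_id": ("Accession ID", "accession_id"),
    "organism": ("Organism", "organism"),
    "sowing_date": ("Sowing date", "sowing_date"),
    "harvest_year": ("Harvest year", "harvest_year"),
    "origin_country": ("Origin country", "Origin", "origin_country"),
    "origin_group": ("Comment[Group]", "Group", "origin_group"),
}

DEFAULT_ASSAY_ALIASES: Mapping[str, Sequence[str]] = {
    "accession_id": ("Accession ID", "accession_id"),
    "year": ("Year", "Harvest year", "year"),
    "FT": ("FT", "Flowering time", "FT [days]"),
    "PH": ("PH", "Plant height", "PH [cm]"),
    "TGW": ("TGW", "Thousand grain weight", "TGW [g]"),
}

DEFAULT_WEATHER_ALIASES: Mapping[str, Sequence[str]] = {
    "year": ("Year", "year"),
    "month": ("Month", "month"),
    "T.avg": ("T.avg", "T.avg [deg C]", "Tavg"),
    "T.min": ("T.min", "T.min [deg C]", "Tmin"),
    "T.max": ("T.max", "T.max [deg C]", "Tmax"),
    "Rain": ("Rain", "Rain [mm]"),
    "Moisture": ("Moisture", "Moisture [%]"),
}

_MONTH_NAMES = {
    name.lower(): i + 1
    for i, name in enumerate(
        ["January", "February", "March", "April", "May", "June", "July",
         "August", "September", "October", "November", "December"]
    )
}
_MONTH_NAMES.update({k[:3]: v for k, v in list(_MONTH_NAMES.items())})


def _read_tsv(path) -> pd.DataFrame:
    try:
        df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    except OSError as exc:  # unreadable file
        raise OSError(f"cannot read tab-delimited file {path!r}: {exc}") from exc
    return df


def _map_columns(df: pd.DataFrame, aliases: Mapping[str, Sequence[str]],
                 required: Iterable[str], path) -> pd.DataFrame:
    rename = {}
    for canonical, names in aliases.items():
        for name in names:
            if name in df.columns:
                rename[name] = canonical
                break
    out = df.rename(columns=rename)
    missing = [c for c in required if c not in out.columns]
    if missing:
        raise ValidationError(
            f"{path}: required column(s) {missing} not found; "
            f"present: {list(df.columns)}"
        )
    return out


def _is_missing(series: pd.Series) -> pd.Series:
    return series.isna() | series.str.strip().isin(MISSING_SENTINELS)


def _parse_sowing_date(text: str, row: int, path) -> _dt.date | None:
    """Parse day.month.year; two-digit years are rejected, blanks are None."""
    if text is None or text.strip() in MISSING_SENTINELS:
        return None
    parts = text.strip().split(".")
    if len(parts) != 3 or len(parts[2]) != 4:
        raise ValidationError(
            f"{path} row {row}: sowing date {text!r} is not day.month.year "
            "with a four-digit year"
        )
    try:
        return _dt.date(int(parts[2]), int(parts[1]), int(parts[0]))
    except ValueError as exc:
        raise ValidationError(f"{path} row {row}: bad sowing date {text!r}") from exc


def read_study_file(path, aliases: Mapping[str, Sequence[str]] | None = None
                    ) -> pd.DataFrame:
    """Read a study file into one row per accession.

    Returns a DataFrame with columns ``accession_number, accession_id,
    organism, sowing_date, harvest_year, origin_country, origin_group``.
    """
    aliases = aliases or DEFAULT_STUDY_ALIASES
    raw = _read_tsv(path)
    df = _map_columns(raw, aliases, ["accession_id"], path)
    if df["accession_id"].str.strip().eq("").any():
        raise ValidationError(f"{path}: empty accession_id")
    if df["accession_id"].duplicated().any():
        dups = df.loc[df["accession_id"].duplicated(), "accession_id"].unique()
        raise ValidationError(f"{path}: duplicated accession_id values {list(dups)[:5]}")
    out = pd.DataFrame({"accession_id": df["accession_id"].str.strip()})
    for col in ("accession_number", "organism", "origin_country", "origin_group"):
        out[col] = df[col].str.strip() if col in df.columns else ""
    if "origin_country" in df.columns:
        out["origin_country"] = out["origin_country"].replace("", "Unknown")
    if "harvest_year" in df.columns:
        years = pd.to_numeric(df["harvest_year"], errors="coerce")
        bad = years.notna() & ~years.between(1900, 2100)
        if bad.any():
            raise ValidationError(
                f"{path}: harvest_year outside [1900, 2100] in rows "
                f"{list(df.index[bad] + 2)}"
            )
        out["harvest_year"] = years.astype("Int64")
    else:
        out["harvest_year"] = pd.Series([pd.NA] * len(df), dtype="Int64")
    if "sowing_date" in df.columns:
        out["sowing_date"] = [
            _parse_sowing_date(v, i + 2, path) for i, v in enumerate(df["sowing_date"])
        ]
    else:
        out["sowing_date"] = None
    # sowing must fall no later than the harvest year
    for i, (sow, hy) in enumerate(zip(out["sowing_date"], out["harvest_year"])):
        if sow is not None and pd.notna(hy) and sow.year > int(hy):
            raise ValidationError(
                f"{path} row {i + 2}: sowing date {sow} after harvest year {hy}"
            )
    return out


def read_phenotype_data(study_path, assay_path, trait: str,
                        study_aliases=None, assay_aliases=None
                        ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Read one trait's records from a study/assay file pair.

    Returns ``(records, study)`` where *records* has columns
    ``accession_id, year, trait, value, replicate_index`` (one row per
    non-missing trait cell, replicate_index counting duplicates within an
    accession x year) and *study* is the accession metadata table.

    Missing cells (empty or ``NA``) are dropped, not zero-filled.
    """
    if trait not in TRAITS:
        raise ValidationError(f"unknown trait {trait!r}; expected one of {TRAITS}")
    study = read_study_file(study_path, study_aliases)
    raw = _read_tsv(assay_path)
    assay = _map_columns(raw, assay_aliases or DEFAULT_ASSAY_ALIASES,
                         ["accession_id", "year", trait], assay_path)
    assay = assay.assign(accession_id=assay["accession_id"].str.strip())

    unknown = sorted(set(assay["accession_id"]) - set(study["accession_id"]))
    if unknown:
        raise ValidationError(
            f"{assay_path}: accession(s) absent from study file: {unknown[:10]}"
            + (" ..." if len(unknown) > 10 else "")
        )

    years = pd.to_numeric(assay["year"], errors="coerce")
    if years.isna().any():
        rows = list(assay.index[years.isna()] + 2)
        raise ValidationError(f"{assay_path}: non-numeric year in rows {rows[:10]}")

    cells = assay[trait]
    keep = ~_is_missing(cells)
    values = pd.to_numeric(cells[keep], errors="coerce")
    if values.isna().any():
        rows = list(values.index[values.isna()] + 2)
        raise ValidationError(
            f"{assay_path}: non-numeric {trait} cell in rows {rows[:10]}"
        )
    records = pd.DataFrame(
        {
            "accession_id": assay.loc[keep, "accession_id"].to_numpy(),
            "year": years[keep].astype(int).to_numpy(),
            "trait": trait,
            "value": values.to_numpy(float),
        }
    )
    _validate_trait_values(records, assay_path)
    records = records.sort_values(["year", "accession_id"], kind="stable")
    records["replicate_index"] = (
        records.groupby(["accession_id", "year"]).cumcount() + 1
    )
    records = records.reset_index(drop=True)
    logger.info("read %d non-missing %s records from %s",
                len(records), trait, assay_path)
    return records, study


def _validate_trait_values(records: pd.DataFrame, path) -> None:
    v = records["value"].to_numpy(float)
    if not np.isfinite(v).all():
        raise ValidationError(f"{path}: non-finite trait values")
    trait = records["trait"].iloc[0] if len(records) else None
    if trait == "FT" and ((v <= 0) | (v > 366)).any():
        raise ValidationError(f"{path}: FT values outside (0, 366]")
    if trait in ("PH", "TGW") and (v <= 0).any():
        raise ValidationError(f"{path}: non-positive {trait} values")


def _parse_month(value: str, row: int, path) -> int:
    text = str(value).strip()
    if text.lower() in _MONTH_NAMES:
        return _MONTH_NAMES[text.lower()]
    try:
        month = int(text)
    except ValueError as exc:
        raise ValidationError(f"{path} row {row}: unparseable month {value!r}") from exc
    if not 1 <= month <= 12:
        raise ValidationError(f"{path} row {row}: month {month} outside 1-12")
    return month


def read_weather_data(study_path, assay_path, aliases=None) -> pd.DataFrame:
    """Read monthly weather records into long form.

    Returns a DataFrame with columns ``year, month, parameter, value`` and
    one row per non-missing (year, month, parameter) cell.  Months may be
    coded 1-12 or by (English) name.  Gaps simply yield no rows.
    """
    _read_tsv(study_path)  # presence/readability check; metadata unused
    raw = _read_tsv(assay_path)
    aliases = aliases or DEFAULT_WEATHER_ALIASES
    present_params = [p for p in WEATHER_PARAMETERS
                      if any(n in raw.columns for n in aliases[p])]
    df = _map_columns(raw, aliases, ["year", "month"], assay_path)
    years = pd.to_numeric(df["year"], errors="coerce")
    if years.isna().any():
        raise ValidationError(f"{assay_path}: non-numeric year")
    months = [_parse_month(m, i + 2, assay_path) for i, m in enumerate(df["month"])]

    long_rows = []
    for param in present_params:
        cells = df[param]
        keep = ~_is_missing(cells)
        vals = pd.to_numeric(cells[keep], errors="coerce")
        if vals.isna().any():
            rows = list(vals.index[vals.isna()] + 2)
            raise ValidationError(
                f"{assay_path}: non-numeric {param} cell in rows {rows[:10]}"
            )
        part = pd.DataFrame(
            {
                "year": years[keep].astype(int).to_numpy(),
                "month": np.asarray(months)[keep.to_numpy()],
                "parameter": param,
                "value": vals.to_numpy(float),
            }
        )
        long_rows.append(part)
    weather = (pd.concat(long_rows, ignore_index=True)
               if long_rows else
               pd.DataFrame(columns=["year", "month", "parameter", "value"]))

    dup = weather.duplicated(["year", "month", "parameter"], keep=False)
    if dup.any():
        conflicting = (
            weather[dup].groupby(["year", "month", "parameter"])["value"].nunique()
        )
        if (conflicting > 1).any():
            keys = list(conflicting[conflicting > 1].index)
            raise ValidationError(
                f"{assay_path}: conflicting duplicate weather cells {keys[:5]}"
            )
        weather = weather.drop_duplicates(["year", "month", "parameter"])

    _validate_weather_values(weather, assay_path)
    weather = weather.sort_values(["year", "month", "parameter"],
                                  kind="stable").reset_index(drop=True)
    logger.info("read %d weather records from %s", len(weather), assay_path)
    return weather


def _validate_weather_values(weather: pd.DataFrame, path) -> None:
    moist = weather.loc[weather["parameter"] == "Moisture", "value"]
    if ((moist < 0) | (moist > 100)).any():
        raise ValidationError(f"{path}: Moisture outside [0, 100]")
    rain = weather.loc[weather["parameter"] == "Rain", "value"]
    if (rain < 0).any():
        raise ValidationError(f"{path}: negative Rain")
    wide = weather.pivot_table(index=["year", "month"], columns="parameter",
                               values="value")
    if {"T.min", "T.avg", "T.max"} <= set(wide.columns):
        t = wide[["T.min", "T.avg", "T.max"]].dropna()
        bad = (t["T.min"] > t["T.avg"]) | (t["T.avg"] > t["T.max"])
        if bad.any():
            # Warning only: independently simulated parameters can cross.
            warnings.warn(
                f"{path}: T.min <= T.avg <= T.max violated for "
                f"{list(t.index[bad])[:5]}", stacklevel=2,
            )


# ---------------------------------------------------------------------------
# writers

def _format_frame(df: pd.DataFrame) -> pd.DataFrame:
    out = df.copy()
    for col in out.columns:
        if pd.api.types.is_float_dtype(out[col]):
            nd = _DECIMALS.get(col, 4)
            out[col] = out[col].map(
                lambda x, nd=nd: "" if pd.isna(x) else f"{x:.{nd}f}"
            )
    return out


def _sorted_for_output(df: pd.DataFrame) -> pd.DataFrame:
    keys = [k for k in ("year", "accession_id", "month", "parameter")
            if k in df.columns]
    return df.sort_values(keys, kind="stable") if keys else df


def write_table(table, path) -> None:
    """Write a pipeline output table as tab-delimited text.

    Accepts a CV table, an outlier-report fragment, a record collection, a
    BLUE table or any other DataFrame produced by the pipeline.  Numeric
    cells are rendered with fixed decimals (4 for variances/CV, 2 for trait
    scale quantities); rows are ordered year-ascending then accession_id so
    output is byte-stable.
    """
    from .outlier_qc import OutlierReport  # local import to avoid a cycle

    if isinstance(table, OutlierReport):
        table = table.removed_records
    if not isinstance(table, pd.DataFrame):
        raise TypeError(f"cannot write object of type {type(table).__name__}")
    df = _format_frame(_sorted_for_output(table))
    df.to_csv(path, sep="\t", index=False, lineterminator="\n")


def read_output_table(path) -> pd.DataFrame:
    """Re-read a table produced by :func:`write_table` with numeric parsing."""
    df = pd.read_csv(path, sep="\t")
    return df


def write_isatab(records: pd.DataFrame, study: pd.DataFrame, out_dir,
                 stem: str = "synthetic") -> tuple[str, str]:
    """Write a records/study pair back into the study/assay layout.

    One assay row per record (wide by trait), one study row per accession.
    Returns the (study_path, assay_path) written.  Used for round-trips and
    for exporting simulated datasets in the deposit's shape.
    """
    import os

    os.makedirs(out_dir, exist_ok=True)
    study_path = os.path.join(out_dir, f"s_{stem}.txt")
    assay_path = os.path.join(out_dir, f"a_{stem}.txt")

    s = study.copy()
    s["sowing_date"] = [
        "" if d is None or pd.isna(d) else f"{d.day:02d}.{d.month:02d}.{d.year}"
        for d in s.get("sowing_date", [None] * len(s))
    ]
    cols = {
        "accession_number": "Accession number",
        "accession_id": "Accession ID",
        "organism": "Organism",
        "sowing_date": "Sowing date",
        "harvest_year": "Harvest year",
        "origin_country": "Origin country",
        "origin_group": "Comment[Group]",
    }
    s = s[[c for c in cols if c in s.columns]].rename(columns=cols)
    s.to_csv(study_path, sep="\t", index=False, lineterminator="\n")

    wide = records.pivot_table(
        index=["accession_id", "year", "replicate_index"],
        columns="trait", values="value",
    ).reset_index()
    wide = wide.sort_values(["year", "accession_id", "replicate_index"],
                            kind="stable")
    out = pd.DataFrame({"Accession ID": wide["accession_id"],
                        "Year": wide["year"]})
    for trait in TRAITS:
        if trait in wide.columns:
            out[trait] = wide[trait].map(
                lambda x: "" if pd.isna(x) else f"{x:.6g}"
            )
    out.to_csv(assay_path, sep="\t", index=False, lineterminator="\n")
    return study_path, assay_path
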