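"""CSV readers/writers and configuration files.

All tabular interchange is plain UTF-8 comma-separated text with "." as the
decimal mark. Readers validate schemas and label vocabularies and point at
offending rows; writers emit the canonical column sets so that write/read
round-trips are lossless on valid data.
"""

from __future__ import annotations

import logging
from pathlib import Path

import pandas as pd
import yaml

from .simulate import COVARIATES

__all__ = [
    "OBSERVER_COLUMNS", "TAG_SERIES_COLUMNS", "TAG_METADATA_COLUMNS",
    "read_observer_csv", "write_observer_csv",
    "read_tag_series_csv", "write_tag_series_csv",
    "read_tag_metadata_csv", "write_tag_metadata_csv",
    "load_yaml_config",
]

log = logging.getLogger("bycatchsurv")

OBSERVER_COLUMNS = ["region", "year", "fate", "sex", "fl_cm", "hook_depth_m",
                    "leader_m", "soak_h", "mainline_km", "sst_c"]
TAG_SERIES_COLUMNS = ["tag_id", "elapsed_min", "depth_m", "temp_c"]
TAG_METADATA_COLUMNS = ["tag_id", "deployment_date", "dal", "fate", "fl_cm",
                        "landing_condition", "release_condition", "leader_m",
                        "sst_c", "soak_h", "hook_depth_m"]


def read_observer_csv(path) -> pd.DataFrame:
    """Read observer records, validating schema and label vocabularies.

    Fate must be 0/1; sex one of F/M or empty (missing). Malformed rows are
    reported by (1-based, header-exclusive) row number.
    """
    df = pd.read_csv(path, dtype={"sex": "string"})
    missing = [c for c in OBSERVER_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    bad = df.index[~df["fate"].isin([0, 1])] + 1
    if len(bad):
        raise ValueError(f"{path}: invalid fate values at rows "
                         f"{list(bad[:20])}")
    sex_ok = df["sex"].isin(["F", "M"]) | df["sex"].isna()
    bad = df.index[~sex_ok] + 1
    if len(bad):
        raise ValueError(f"{path}: invalid sex labels at rows "
                         f"{list(bad[:20])}")
    for c in COVARIATES:
        if not pd.api.types.is_numeric_dtype(df[c]):
            nonnum = pd.to_numeric(df[c], errors="coerce")
            bad = df.index[nonnum.isna() & df[c].notna()] + 1
            if len(bad):
                raise ValueError(f"{path}: non-numeric {c} at rows "
                                 f"{list(bad[:20])}")
            df[c] = nonnum
    log.info("read %d observer records from %s", len(df), path)
    return df[OBSERVER_COLUMNS]


def write_observer_csv(records: pd.DataFrame, path) -> None:
    records[OBSERVER_COLUMNS].to_csv(path, index=False)
    log.info("wrote %d observer records to %s", len(records), path)


def write_tag_series_csv(series: dict[str, pd.DataFrame] | pd.DataFrame,
                         path) -> None:
    """Write one or many tag series (long format keyed by tag_id)."""
    if isinstance(series, pd.DataFrame):
        series = {str(series.get("tag_id", pd.Series(["tag"])).iloc[0]):
                  series}
    frames = []
    for tag_id, df in series.items():
        out = df[["elapsed_min", "depth_m", "temp_c"]].copy()
        out.insert(0, "tag_id", tag_id)
        frames.append(out)
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_tag_series_csv(path) -> dict[str, pd.DataFrame]:
    df = pd.read_csv(path, dtype={"tag_id": "string"})
    missing = [c for c in TAG_SERIES_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    return {str(tag): g.drop(columns="tag_id").reset_index(drop=True)
            for tag, g in df.groupby("tag_id", sort=False)}


def write_tag_metadata_csv(metadata: pd.DataFrame, path) -> None:
    metadata[TAG_METADATA_COLUMNS].to_csv(path, index=False)


def read_tag_metadata_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"fate": "string",
                                  "landing_condition": "string",
                                  "release_condition": "string"})
    missing = [c for c in TAG_METADATA_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    bad = df.index[~df["fate"].str.upper().isin(["A", "D"])] + 1
    if len(bad):
        raise ValueError(f"{path}: invalid fate labels at rows "
                         f"{list(bad[:20])}")
    return df


def load_yaml_config(path, known_keys: set[str] | None = None) -> dict:
    """Load a YAML/JSON-style key-value configuration file.

    Unknown top-level keys are rejected when ``known_keys`` is given, to
    catch typos rather than silently ignoring settings.
    """
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise ValueError(f"{path}: top level must be a mapping")
    if known_keys is not None:
        unknown = set(data) - known_keys
        if unknown:
            raise ValueError(f"{path}: unknown config keys {sorted(unknown)}")
    return data
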