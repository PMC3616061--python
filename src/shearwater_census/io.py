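"""Reading and writing survey tables, result tables, configs and manifests.

All on-disk records are comma-separated UTF-8 text with a header row; the
run configuration is a YAML file and the run manifest is JSON.  Readers
validate every row against the record invariants and report the file, row
number and field of the first violation.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import fields as dc_fields
from pathlib import Path
from typing import Dict, List, Sequence, Type

import pandas as pd
import yaml

from .mcmc import PosteriorSummary
from .records import (CarcassTransect, ChickStation, Colony, HistoricalSummary,
                      MarkedCarcassStudy, OccupancyRecord, RunConfig,
                      TransectSection, ValidationError)

__all__ = [
    "TABLE_SCHEMAS", "read_survey_tables", "read_bundle", "write_records",
    "write_results", "read_results", "load_config", "save_config",
    "write_manifest", "file_digest",
]

_BOOL_STRINGS = {"true": True, "1": True, "yes": True,
                 "false": False, "0": False, "no": False}

# table kind -> (record type, canonical file name)
TABLE_SCHEMAS: Dict[str, tuple] = {
    "colonies": (Colony, "colonies.csv"),
    "sections": (TransectSection, "sections.csv"),
    "stations": (ChickStation, "stations.csv"),
    "occupancy": (OccupancyRecord, "occupancy.csv"),
    "historical": (HistoricalSummary, "historical.csv"),
    "carcass_transects": (CarcassTransect, "carcass_transects.csv"),
    "marked_carcasses": (MarkedCarcassStudy, "marked_carcasses.csv"),
}


def _coerce(value, target_type, field_name: str):
    if target_type is bool:
        if isinstance(value, (bool,)):
            return value
        s = str(value).strip().lower()
        if s in _BOOL_STRINGS:
            return _BOOL_STRINGS[s]
        raise ValidationError(f"field {field_name}: unparseable boolean {value!r}")
    if target_type is int:
        f = float(value)
        if f != int(f):
            raise ValidationError(f"field {field_name}: expected integer, got {value!r}")
        return int(f)
    if target_type is float:
        return float(value)
    return str(value)


_FIELD_TYPES = {"colony_id": str, "name": str, "area_m2": float,
                "fully_counted": bool, "transect_id": str, "section_index": int,
                "burrow_count": int, "station_id": str, "burrows_checked": int,
                "chicks_found": int, "season": str, "burrows_occupied": int,
                "metric": str, "mean": float, "se": float, "road_id": str,
                "carcass_count": int, "c1": int, "c2": int, "t1": int, "t2": int}


def read_survey_tables(path, schema: str) -> list:
    """Read one delimited survey table into validated records.

    ``schema`` is a table kind from :data:`TABLE_SCHEMAS`.  Raises
    :class:`ValidationError` naming the file, row and field on the first
    invalid value; an empty file with only a header yields an empty list.
    """
    if schema not in TABLE_SCHEMAS:
        raise ValueError(f"unknown table schema {schema!r}")
    record_type, _ = TABLE_SCHEMAS[schema]
    path = Path(path)
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    wanted = [f.name for f in dc_fields(record_type)
              if f.name != "distance_band_counts"]
    missing = [c for c in wanted if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: missing column(s) {missing}")
    records = []
    for i, row in enumerate(df.itertuples(index=False), start=2):  # header is line 1
        kwargs = {}
        rowd = dict(zip(df.columns, row))
        for name in wanted:
            try:
                kwargs[name] = _coerce(rowd[name], _FIELD_TYPES[name], name)
            except (ValueError, ValidationError) as exc:
                raise ValidationError(f"{path}, row {i}, field {name}: {exc}") from exc
        try:
            records.append(record_type(**kwargs))
        except ValidationError as exc:
            raise ValidationError(f"{path}, row {i}: {exc}") from exc
    return records


def read_bundle(directory) -> dict:
    """Read every survey table present in ``directory`` under canonical names."""
    directory = Path(directory)
    bundle = {}
    for schema, (_, fname) in TABLE_SCHEMAS.items():
        fpath = directory / fname
        if fpath.exists():
            bundle[schema] = read_survey_tables(fpath, schema)
    return bundle


def write_records(records: Sequence, path) -> None:
    """Write records of one type as a delimited table (round-trips with read)."""
    if not records:
        raise ValueError("refusing to write an empty record collection")
    names = [f.name for f in dc_fields(type(records[0]))
             if f.name != "distance_band_counts"]
    rows = [{n: getattr(r, n) for n in names} for r in records]
    pd.DataFrame(rows, columns=names).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# result tables

_RESULT_COLUMNS = ["name", "mean", "psd", "ci_2.5%", "ci_97.5%", "rhat", "ess"]


def write_results(summaries: Dict[str, List[PosteriorSummary]], out_dir) -> dict:
    """Write one delimited result table per family (burrows, chicks, ...).

    Each row carries mean, posterior SD and the 2.5/97.5% credible bounds.
    Returns {family: written path}.
    """
    if not summaries:
        raise ValueError("no summaries to write")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = {}
    for family, items in summaries.items():
        if not items:
            raise ValueError(f"result family {family!r} is empty")
        rows = []
        for s in items:
            if s.ci95 is None or len(s.ci95) != 2:
                raise ValueError(f"summary {s.name!r} is missing its credible interval")
            rows.append(s.to_row())
        path = out_dir / f"{family}.csv"
        pd.DataFrame(rows, columns=_RESULT_COLUMNS).to_csv(
            path, index=False, float_format="%.6g")
        written[family] = path
    return written


def read_results(path) -> pd.DataFrame:
    return pd.read_csv(path)


# ---------------------------------------------------------------------------
# config + manifest

def load_config(path) -> RunConfig:
    with open(path, "r", encoding="utf-8") as fh:
        raw = yaml.safe_load(fh) or {}
    for key in ("shape_prior_bounds", "density_prior", "occupancy_prior"):
        if key in raw:
            raw[key] = tuple(raw[key])
    return RunConfig(**raw)


def save_config(config: RunConfig, path) -> None:
    d = config.to_dict()
    for key, value in d.items():
        if isinstance(value, tuple):
            d[key] = list(value)
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(d, fh, sort_keys=False)


def file_digest(path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()[:16]


def write_manifest(path, *, seed: int, config: RunConfig,
                   diagnostics: dict, inputs: dict,
                   warnings: Sequence[str] = (), version: str = "") -> None:
    """JSON run manifest: seed, config echo, per-node Rhat/ESS, input digests."""
    manifest = {
        "seed": seed,
        "version": version,
        "config": {k: (list(v) if isinstance(v, tuple) else v)
                   for k, v in config.to_dict().items()},
        "diagnostics": diagnostics,
        "input_digests": {str(k): file_digest(v) for k, v in inputs.items()},
        "warnings": list(warnings),
    }
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, default=str)
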