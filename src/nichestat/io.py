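"""Readers, writers and validators for cell, transcript and polygon tables.

All coordinates are micrometres. Cell and transcript tables are plain
:class:`pandas.DataFrame` objects validated against a minimal schema;
polygon sets carry :class:`shapely.geometry.Polygon` objects in a
``polygon`` column. Pixel-coordinate exports (e.g. CosMx flat files) are
converted to µm at read time via ``um_per_px``.
"""

from __future__ import annotations

import json
import math
from typing import Mapping

import numpy as np
import pandas as pd
import shapely
from shapely.geometry import Polygon, mapping, shape
from shapely.geometry.polygon import orient

from .errors import FormatError, ValidationError

CELL_COLUMNS = ("cell_id", "sample_id", "x", "y", "type_l2")
TRANSCRIPT_COLUMNS = ("x", "y", "gene")

#: Column renames for known instrument dialects. Unknown dialects fall back
#: to canonical column names.
DIALECTS: dict[str, Mapping[str, str]] = {
    "canonical": {},
    "cosmx": {
        "cell_ID": "cell_id",
        "CenterX_global_px": "x",
        "CenterY_global_px": "y",
        "x_global_px": "x",
        "y_global_px": "y",
        "target": "gene",
        "Run_Tissue_name": "sample_id",
    },
}

UNASSIGNED = "unassigned"


def _read_table(path, delimiter: str | None) -> pd.DataFrame:
    if delimiter is None:
        with open(path, "r", encoding="utf-8") as fh:
            header = fh.readline()
        delimiter = "\t" if header.count("\t") > header.count(",") else ","
    return pd.read_csv(path, sep=delimiter, dtype={"cell_id": str, "sample_id": str})


def _apply_dialect(df: pd.DataFrame, dialect: str) -> pd.DataFrame:
    renames = DIALECTS.get(dialect, {})
    return df.rename(columns={k: v for k, v in renames.items() if k in df.columns})


def validate_cells(cells: pd.DataFrame) -> pd.DataFrame:
    """Validate a cell table in place and return it.

    Raises :class:`FormatError` for missing mandatory columns and
    :class:`ValidationError` for duplicate ids, non-finite coordinates or
    empty type labels.
    """
    for col in CELL_COLUMNS:
        if col not in cells.columns:
            raise FormatError(f"cell table is missing mandatory column {col!r}")
    dup = cells.duplicated(subset=["sample_id", "cell_id"])
    if dup.any():
        bad = cells.loc[dup, "cell_id"].iloc[0]
        raise ValidationError(f"duplicate cell_id within sample: {bad!r}")
    xy = cells[["x", "y"]].to_numpy(dtype=float)
    if not np.isfinite(xy).all():
        raise ValidationError("cell coordinates must be finite")
    t2 = cells["type_l2"]
    if t2.isna().any() or (t2.astype(str).str.len() == 0).any():
        raise ValidationError("every cell needs a non-empty type_l2 label")
    return cells


def validate_transcripts(
    tx: pd.DataFrame, cells: pd.DataFrame | None = None
) -> pd.DataFrame:
    """Validate a transcript table; optionally check cell_id references."""
    for col in TRANSCRIPT_COLUMNS:
        if col not in tx.columns:
            raise FormatError(f"transcript table is missing mandatory column {col!r}")
    xy = tx[["x", "y"]].to_numpy(dtype=float)
    if not np.isfinite(xy).all():
        row = int(np.flatnonzero(~np.isfinite(xy).all(axis=1))[0])
        raise FormatError(f"non-finite coordinate in transcript row {row}")
    if tx["gene"].isna().any() or (tx["gene"].astype(str).str.len() == 0).any():
        raise ValidationError("every molecule needs a non-empty gene label")
    if cells is not None and "cell_id" in tx.columns:
        assigned = tx.loc[tx["cell_id"] != UNASSIGNED, "cell_id"]
        known = set(cells["cell_id"])
        missing = set(assigned) - known
        if missing:
            raise ValidationError(
                f"transcript cell_id not present in cell table: {sorted(missing)[:5]}"
            )
    return tx


def read_cells(path, dialect: str = "canonical", delimiter: str | None = None,
               um_per_px: float = 1.0) -> pd.DataFrame:
    """Read a delimited cell table into a validated DataFrame.

    Parameters
    ----------
    path
        Delimited UTF-8 text file with a header; delimiter auto-detected
        among comma/tab unless given.
    dialect
        ``"canonical"`` or ``"cosmx"`` (instrument flat-file column names).
    um_per_px
        Multiplied onto x/y; use the instrument pixel size when coordinates
        are exported in pixels.
    """
    df = _apply_dialect(_read_table(path, delimiter), dialect)
    if um_per_px != 1.0:
        for c in ("x", "y"):
            if c in df.columns:
                df[c] = df[c] * um_per_px
    try:
        df[["x", "y"]] = df[["x", "y"]].astype(float)
    except (ValueError, KeyError) as exc:
        raise FormatError(f"could not parse coordinates: {exc}") from exc
    df["cell_id"] = df["cell_id"].astype(str) if "cell_id" in df else df.get("cell_id")
    return validate_cells(df)


def read_transcripts(path, dialect: str = "canonical", delimiter: str | None = None,
                     um_per_px: float = 1.0) -> pd.DataFrame:
    """Read a delimited transcript table; blank cell_id becomes "unassigned"."""
    df = _apply_dialect(_read_table(path, delimiter), dialect)
    for col in TRANSCRIPT_COLUMNS:
        if col not in df.columns:
            raise FormatError(f"transcript table is missing mandatory column {col!r}")
    coords = df[["x", "y"]].apply(pd.to_numeric, errors="coerce")
    bad = coords.isna().any(axis=1) & df[["x", "y"]].notna().any(axis=1)
    if bad.any():
        raise FormatError(f"non-numeric coordinate in row {int(np.flatnonzero(bad)[0])}")
    df[["x", "y"]] = coords * um_per_px if um_per_px != 1.0 else coords
    if "cell_id" not in df.columns:
        df["cell_id"] = UNASSIGNED
    else:
        df["cell_id"] = df["cell_id"].fillna(UNASSIGNED).astype(str)
        df.loc[df["cell_id"].str.len() == 0, "cell_id"] = UNASSIGNED
    return validate_transcripts(df)


def write_cells(cells: pd.DataFrame, path, delimiter: str = ",") -> None:
    cells.to_csv(path, sep=delimiter, index=False)


def write_transcripts(tx: pd.DataFrame, path, delimiter: str = ",") -> None:
    out = tx.copy()
    out.to_csv(path, sep=delimiter, index=False)


def _validate_polygon(obj_id: str, poly) -> Polygon:
    if poly.geom_type != "Polygon":
        raise ValidationError(
            f"object {obj_id!r}: multi-part or non-polygon geometry ({poly.geom_type})"
        )
    if not poly.is_valid or not poly.is_simple:
        raise ValidationError(f"object {obj_id!r}: self-intersecting or invalid ring")
    if poly.area <= 0:
        raise ValidationError(f"object {obj_id!r}: zero-area polygon")
    # CCW exterior for signed-area consistency downstream
    return orient(poly, sign=1.0)


def read_polygons(path, format: str | None = None) -> pd.DataFrame:
    """Read polygons from WKT-per-row CSV or a GeoJSON FeatureCollection.

    Returns a DataFrame with columns object_id, sample_id, object_class and
    a ``polygon`` column of shapely polygons (exterior normalised CCW).
    """
    path = str(path)
    if format is None:
        format = "geojson" if path.endswith((".json", ".geojson")) else "wkt"
    records = []
    if format == "geojson":
        with open(path, "r", encoding="utf-8") as fh:
            fc = json.load(fh)
        if fc.get("type") != "FeatureCollection":
            raise FormatError("GeoJSON input must be a FeatureCollection")
        for feat in fc.get("features", []):
            props = feat.get("properties") or {}
            geom = shape(feat["geometry"])
            records.append(
                (
                    str(props.get("object_id", len(records))),
                    props.get("sample_id", "sample_0"),
                    props.get("object_class", ""),
                    geom,
                )
            )
    elif format == "wkt":
        df = pd.read_csv(path)
        if "wkt" not in df.columns:
            raise FormatError("WKT polygon table is missing mandatory column 'wkt'")
        for i, row in df.iterrows():
            try:
                geom = shapely.from_wkt(row["wkt"])
            except shapely.errors.GEOSException as exc:
                raise FormatError(f"bad WKT in row {i}: {exc}") from exc
            records.append(
                (
                    str(row.get("object_id", i)),
                    row.get("sample_id", "sample_0"),
                    row.get("object_class", ""),
                    geom,
                )
            )
    else:
        raise FormatError(f"unknown polygon format {format!r}")
    out = pd.DataFrame(records, columns=["object_id", "sample_id", "object_class", "polygon"])
    if out["object_id"].duplicated().any():
        raise ValidationError("duplicate object_id in polygon set")
    out["polygon"] = [
        _validate_polygon(oid, p) for oid, p in zip(out["object_id"], out["polygon"])
    ]
    return out


def write_polygons(polys: pd.DataFrame, path, format: str | None = None) -> None:
    path = str(path)
    if format is None:
        format = "geojson" if path.endswith((".json", ".geojson")) else "wkt"
    if format == "geojson":
        features = [
            {
                "type": "Feature",
                "geometry": mapping(row.polygon),
                "properties": {
                    "object_id": row.object_id,
                    "sample_id": row.sample_id,
                    "object_class": row.object_class,
                },
            }
            for row in polys.itertuples()
        ]
        with open(path, "w", encoding="utf-8") as fh:
            json.dump({"type": "FeatureCollection", "features": features}, fh)
    else:
        out = polys.drop(columns=["polygon"]).copy()
        out["wkt"] = [shapely.to_wkt(p, rounding_precision=-1) for p in polys["polygon"]]
        out.to_csv(path, index=False)


def regular_polygon(cx: float, cy: float, radius: float, n_vertices: int = 12) -> Polygon:
    """Regular n-gon centred at (cx, cy); used for synthetic cell boundaries."""
    theta = 2 * math.pi * np.arange(n_vertices) / n_vertices
    return Polygon(np.column_stack([cx + radius * np.cos(theta),
                                    cy + radius * np.sin(theta)]))
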