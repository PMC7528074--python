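"""Specimen pigmentation records and lineage-level trait summaries.

Two traits quantify dorsal pigmentation per specimen:

* **DM** — number of dorsal marks (angles of the zigzag pattern along the
  right side of the body, head and tail excluded);
* **WPI** — weighted pigmentation index,
  ``(1·rect_des + 0.5·rect_half) / (10·n_sample)``, the pigmented fraction of
  a standardized dorsal sampling rectangle of 10 scales by ``n_sample`` rows.

Lineage means are taken over the ten largest zigzag-patterned specimens
(or all of them when fewer than ten are available); specimens without an
evident zigzag pattern (melanistic, striped, uniform) are excluded first.
"""

from __future__ import annotations

import warnings
from typing import Mapping

import numpy as np
import pandas as pd

__all__ = [
    "PATTERN_CLASSES",
    "SPECIMEN_COLUMNS",
    "TraitError",
    "compute_wpi",
    "read_specimens",
    "validate_specimens",
    "filter_zigzag",
    "assign_point",
    "assign_to_lineage",
    "aggregate_lineage",
    "lineage_trait_table",
    "write_trait_table",
]

PATTERN_CLASSES = frozenset({"zigzag", "melanistic", "striped", "uniform"})

SPECIMEN_COLUMNS = [
    "specimen_id",
    "lineage_id",
    "lon",
    "lat",
    "body_size_mm",
    "pattern",
    "dm",
    "rect_des",
    "rect_half",
    "n_sample",
]


class TraitError(ValueError):
    """Raised on invalid specimen data or trait-computation contracts."""


def compute_wpi(rect_des, rect_half, n_sample):
    """Weighted pigmentation index in [0, 1].

    Fully pigmented scales count 1, half-pigmented scales 0.5, divided by
    the total number of scales in the sampling rectangle (10·n_sample).
    Vectorized over array-like inputs.
    """
    rect_des = np.asarray(rect_des)
    rect_half = np.asarray(rect_half)
    n_sample = np.asarray(n_sample)
    if np.any(n_sample <= 0):
        raise TraitError("n_sample must be a positive number of scale rows")
    if np.any(rect_des < 0) or np.any(rect_half < 0):
        raise TraitError("scale counts must be non-negative")
    total = 10 * n_sample
    if np.any(rect_des + rect_half > total):
        raise TraitError(
            "rect_des + rect_half exceeds the rectangle size 10*n_sample"
        )
    wpi = (1.0 * rect_des + 0.5 * rect_half) / total
    return float(wpi) if wpi.ndim == 0 else wpi


def validate_specimens(df: pd.DataFrame) -> pd.DataFrame:
    """Validate a specimen table and add the derived ``wpi`` column.

    Fails fast on unknown pattern classes, non-positive body sizes, negative
    counts, or counts exceeding the sampling rectangle.
    """
    missing = [c for c in SPECIMEN_COLUMNS if c not in df.columns]
    if missing:
        raise TraitError(f"specimen table missing columns: {missing}")
    df = df.copy()
    bad_patterns = set(df["pattern"].unique()) - PATTERN_CLASSES
    if bad_patterns:
        raise TraitError(
            f"unknown pattern class(es) {sorted(bad_patterns)}; "
            f"expected one of {sorted(PATTERN_CLASSES)}"
        )
    if df["specimen_id"].duplicated().any():
        dupes = df.loc[df["specimen_id"].duplicated(), "specimen_id"].tolist()
        raise TraitError(f"duplicate specimen ids: {dupes[:5]}")
    if (df["body_size_mm"] <= 0).any():
        raise TraitError("body_size_mm must be positive")
    if (df["dm"] < 0).any():
        raise TraitError("dm must be non-negative")
    df["wpi"] = compute_wpi(
        df["rect_des"].to_numpy(),
        df["rect_half"].to_numpy(),
        df["n_sample"].to_numpy(),
    )
    return df


def read_specimens(path) -> pd.DataFrame:
    """Read and validate the specimen CSV (see SPECIMEN_COLUMNS)."""
    df = pd.read_csv(path, dtype={"specimen_id": str, "lineage_id": str})
    df["lineage_id"] = df["lineage_id"].fillna("")
    return validate_specimens(df)


def filter_zigzag(df: pd.DataFrame) -> tuple[pd.DataFrame, pd.Series]:
    """Keep only zigzag-patterned specimens.

    Returns the retained table and a per-lineage count of removed specimens.
    """
    keep = df["pattern"] == "zigzag"
    removed = df.loc[~keep]
    removed_counts = removed.groupby("lineage_id").size()
    if keep.sum() == 0:
        warnings.warn("no zigzag-patterned specimens remain", stacklevel=2)
    return df.loc[keep].copy(), removed_counts


def assign_point(lon: float, lat: float, masks: Mapping[str, "object"], grid) -> str:
    """Assign a collection locality to the lineage whose range contains it.

    ``masks`` maps lineage_id to a RangeMask on ``grid``.  Returns the
    lineage id, or ``""`` (unassigned) if no mask contains the point's cell.
    A point inside two or more overlapping ranges is an ambiguity error —
    reported, never silently resolved.
    """
    cell = grid.cell_of(lon, lat)
    hits = [lid for lid, mask in masks.items() if cell in mask.cells]
    if len(hits) > 1:
        raise TraitError(
            f"point ({lon:.4f}, {lat:.4f}) falls in {len(hits)} overlapping "
            f"ranges: {sorted(hits)}"
        )
    return hits[0] if hits else ""


def assign_to_lineage(df: pd.DataFrame, masks, grid) -> pd.DataFrame:
    """Fill empty ``lineage_id`` fields from coordinates and range masks.

    Specimens with a pre-filled lineage_id keep it (museum provenance takes
    precedence); the rest are assigned through :func:`assign_point`.
    """
    df = df.copy()
    needs = df["lineage_id"].isna() | (df["lineage_id"] == "")
    for idx in df.index[needs]:
        lon, lat = df.at[idx, "lon"], df.at[idx, "lat"]
        if pd.isna(lon) or pd.isna(lat):
            raise TraitError(
                f"specimen {df.at[idx, 'specimen_id']!r} has neither a "
                "lineage_id nor coordinates"
            )
        df.at[idx, "lineage_id"] = assign_point(float(lon), float(lat), masks, grid)
    n_unassigned = int((df["lineage_id"] == "").sum())
    if n_unassigned:
        warnings.warn(
            f"{n_unassigned} specimen(s) fall outside every range and remain "
            "unassigned",
            stacklevel=2,
        )
    return df


def aggregate_lineage(df: pd.DataFrame, max_n: int = 10) -> pd.DataFrame:
    """Per-lineage trait means over the ``max_n`` largest specimens.

    Specimens are ranked by body size (descending), ties broken by
    specimen_id (ascending) so the selection is order-independent.  Returns
    one row per lineage: mean_dm, mean_wpi, n_used.
    """
    if len(df) == 0:
        raise TraitError("no specimens to aggregate")
    if "wpi" not in df.columns:
        df = validate_specimens(df)
    ranked = df.sort_values(
        ["lineage_id", "body_size_mm", "specimen_id"],
        ascending=[True, False, True],
        kind="mergesort",
    )
    top = ranked.groupby("lineage_id", sort=True).head(max_n)
    out = (
        top.groupby("lineage_id")
        .agg(mean_dm=("dm", "mean"), mean_wpi=("wpi", "mean"), n_used=("dm", "size"))
        .reset_index()
    )
    return out


def lineage_trait_table(
    df: pd.DataFrame,
    masks=None,
    grid=None,
    max_n: int = 10,
) -> pd.DataFrame:
    """Full specimen-to-lineage flow: filter zigzag, assign, aggregate.

    Adds ``n_excluded_pattern`` (specimens removed by the zigzag filter) to
    the aggregated table.  Specimens that remain unassigned after coordinate
    overlap are dropped with a warning.
    """
    df = validate_specimens(df) if "wpi" not in df.columns else df
    zig, removed = filter_zigzag(df)
    if masks is not None:
        zig = assign_to_lineage(zig, masks, grid)
    zig = zig[zig["lineage_id"] != ""]
    out = aggregate_lineage(zig, max_n=max_n)
    out["n_excluded_pattern"] = (
        out["lineage_id"].map(removed).fillna(0).astype(int)
    )
    return out


def write_trait_table(table: pd.DataFrame, path) -> None:
    """Write the lineage trait table; WPI rounded to 3 decimals at report time."""
    out = table.copy()
    out["mean_wpi"] = out["mean_wpi"].round(3)
    out["mean_dm"] = out["mean_dm"].round(3)
    out.to_csv(path, index=False)
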