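"""Text-format I/O: stratified count tables, tract GeoJSON, truth sidecars."""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd
from shapely.geometry import mapping as shapely_mapping

COUNT_COLUMNS = ["tract_id", "age_group", "sex", "race", "cases", "person_years"]


def write_counts(counts: pd.DataFrame, path) -> None:
    """Write a stratified count table (tab-delimited, fixed column order)."""
    missing = [c for c in COUNT_COLUMNS if c not in counts.columns]
    if missing:
        raise ValueError(f"count table missing column(s): {missing}")
    counts[COUNT_COLUMNS].to_csv(path, sep="\t", index=False)


def read_counts(path) -> pd.DataFrame:
    counts = pd.read_csv(path, sep="\t", dtype={"tract_id": str, "age_group": str})
    missing = [c for c in COUNT_COLUMNS if c not in counts.columns]
    if missing:
        raise ValueError(f"count table missing column(s): {missing}")
    return counts


def write_tracts_geojson(tracts: pd.DataFrame, path, geometry_col: str = "geometry") -> None:
    """Write tract attributes + polygons as a GeoJSON FeatureCollection."""
    features = []
    for _, row in tracts.iterrows():
        props = {
            k: (row[k].item() if hasattr(row[k], "item") else row[k])
            for k in tracts.columns
            if k not in (geometry_col,)
        }
        features.append(
            {
                "type": "Feature",
                "id": row["tract_id"],
                "properties": props,
                "geometry": shapely_mapping(row[geometry_col]),
            }
        )
    with open(path, "w") as fh:
        json.dump({"type": "FeatureCollection", "features": features}, fh)


def write_json(obj, path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def read_json(path):
    return json.loads(Path(path).read_text())
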