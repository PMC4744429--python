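"""Plain-text serialisation: GeoJSON tract maps, weights JSON, manifests."""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import pandas as pd
from shapely.geometry import mapping, shape

from .spatial import SpatialWeights, rook_adjacency

__all__ = [
    "write_tracts_geojson",
    "read_tracts_geojson",
    "write_weights_json",
    "file_digest",
]


def write_tracts_geojson(tracts: pd.DataFrame, path, properties: list[str] | None = None) -> None:
    """Write a tract table with shapely geometries as a GeoJSON FeatureCollection."""
    if properties is None:
        properties = [c for c in tracts.columns if c != "geometry"]
    features = []
    for row in tracts.itertuples(index=False):
        d = row._asdict()
        props = {}
        for k in properties:
            v = d[k]
            props[k] = v.item() if hasattr(v, "item") else v
        features.append({"type": "Feature", "geometry": mapping(d["geometry"]),
                         "properties": props})
    Path(path).write_text(json.dumps(
        {"type": "FeatureCollection", "features": features}, sort_keys=True))


def read_tracts_geojson(path) -> pd.DataFrame:
    gj = json.loads(Path(path).read_text())
    rows = []
    for f in gj["features"]:
        row = dict(f["properties"])
        row["geometry"] = shape(f["geometry"])
        rows.append(row)
    return pd.DataFrame(rows)


def write_weights_json(weights: SpatialWeights, path) -> None:
    Path(path).write_text(json.dumps(
        {"style": weights.style, "neighbours": weights.neighbour_lists()},
        sort_keys=True))


def file_digest(path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()
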