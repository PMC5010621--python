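"""Readers and writers for the pipeline's plain-text artifact formats.

Tabular data are CSV; geometry is GeoJSON; sparse matrices are MatrixMarket
(MTX); sidecars and manifests are JSON.  Every JSON artifact carries a
``format_version`` field and loaders reject unknown versions loudly.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.io import mmread, mmwrite

FORMAT_VERSION = "1"

#: float formatting with 17 significant digits round-trips IEEE doubles exactly
FLOAT_FMT = "%.17g"


def write_csv(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False, float_format=FLOAT_FMT)


def read_csv(path) -> pd.DataFrame:
    path = Path(path)
    try:
        return pd.read_csv(path, float_precision="round_trip")
    except Exception as exc:
        raise ValueError(f"corrupted or unreadable CSV {path.name}: {exc}") from exc


def write_json(obj: dict, path) -> None:
    obj = dict(obj)
    obj.setdefault("format_version", FORMAT_VERSION)
    Path(path).write_text(json.dumps(obj, indent=2, default=_json_default, sort_keys=True))


def read_json(path) -> dict:
    obj = json.loads(Path(path).read_text())
    ver = obj.get("format_version")
    if ver != FORMAT_VERSION:
        raise ValueError(f"{Path(path).name}: unknown format_version {ver!r}")
    return obj


def _json_default(o):
    if isinstance(o, np.ndarray):
        return o.tolist()
    if isinstance(o, (np.floating, np.integer)):
        return o.item()
    if dataclasses.is_dataclass(o):
        return dataclasses.asdict(o)
    raise TypeError(f"not JSON serialisable: {type(o)}")


def write_universe(universe, outdir) -> None:
    """Serialise a study universe: samples/areas/strata CSVs, adjacency
    edge list, ground-truth + config JSON sidecar, centroid GeoJSON."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    write_csv(universe.samples, out / "samples.csv")
    write_csv(universe.areas, out / "areas.csv")
    write_csv(universe.strata, out / "strata.csv")
    adj = pd.DataFrame(universe.adjacency, columns=["i", "j"])
    write_csv(adj, out / "adjacency.csv")
    truth = dataclasses.asdict(universe.truth)
    cfg = dataclasses.asdict(universe.config)
    cfg.pop("truth", None)
    write_json(
        {"domain_bbox": list(universe.domain_bbox), "truth": truth, "config": cfg},
        out / "truth.json",
    )
    write_centroid_geojson(universe.areas, out / "centroids.geojson")


def read_universe_tables(outdir) -> dict:
    out = Path(outdir)
    return {
        "samples": read_csv(out / "samples.csv"),
        "areas": read_csv(out / "areas.csv"),
        "strata": read_csv(out / "strata.csv"),
        "adjacency": [tuple(r) for r in read_csv(out / "adjacency.csv").to_numpy()],
        "sidecar": read_json(out / "truth.json"),
    }


def write_centroid_geojson(areas: pd.DataFrame, path) -> None:
    features = [
        {
            "type": "Feature",
            "geometry": {"type": "Point", "coordinates": [float(r.x_km), float(r.y_km)]},
            "properties": {"area_id": r.area_id},
        }
        for r in areas.itertuples()
    ]
    Path(path).write_text(
        json.dumps({"type": "FeatureCollection", "features": features})
    )


def write_mesh(mesh, outdir, stem: str = "mesh") -> None:
    out = Path(outdir)
    write_csv(
        pd.DataFrame(
            {
                "x_km": mesh.vertices[:, 0],
                "y_km": mesh.vertices[:, 1],
                "interior": mesh.interior_mask.astype(int),
            }
        ),
        out / f"{stem}_vertices.csv",
    )
    write_csv(pd.DataFrame(mesh.triangles, columns=["v0", "v1", "v2"]), out / f"{stem}_triangles.csv")


def read_mesh(outdir, stem: str = "mesh"):
    from .mesh import Mesh

    out = Path(outdir)
    v = read_csv(out / f"{stem}_vertices.csv")
    t = read_csv(out / f"{stem}_triangles.csv")
    return Mesh(
        vertices=v[["x_km", "y_km"]].to_numpy(),
        triangles=t.to_numpy(int),
        interior_mask=v["interior"].to_numpy(bool),
        max_edge_interior=np.nan,
    )


def write_sparse(matrix, path) -> None:
    mmwrite(str(path), sp.coo_matrix(matrix))


def read_sparse(path):
    return sp.csr_matrix(mmread(str(path)))
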