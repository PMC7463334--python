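"""Reef conservation indices from predicted genetic separation.

Given the directional dFST matrix between reef cells, reef areas (km^2)
and per-cell adaptive-genotype probabilities PA:

- OCI(i), outbound connectivity: total area of other reefs reachable FROM
  reef i within the dFST threshold (sum of area_j over j with
  dfst(i -> j) < T).
- ICI(i), inbound connectivity: total area of other reefs that can reach
  reef i (dfst(j -> i) < T).
- API(i), adaptive potential: ICI with each contributing reef's area
  weighted by its PA — the area of adapted-genotype sources feeding i.

The focal cell's own area is excluded (the indices count neighbouring
reefs) and the comparison is strict (< T) by default; both are
configurable.  All three indices are nondecreasing in T, and API <= ICI
whenever PA lies in [0, 1].
"""

from __future__ import annotations

import numpy as np
import pandas as pd

DEFAULT_THRESHOLD = 0.02


def _reach(dfst: np.ndarray, T: float, strict: bool, include_focal: bool) -> np.ndarray:
    dfst = np.asarray(dfst, float)
    if dfst.ndim != 2 or dfst.shape[0] != dfst.shape[1]:
        raise ValueError("dfst must be a square matrix")
    within = dfst < T if strict else dfst <= T
    if not include_focal:
        within = within & ~np.eye(len(dfst), dtype=bool)
    return within


def oci(
    dfst: np.ndarray, areas: np.ndarray, T: float = DEFAULT_THRESHOLD,
    strict: bool = True, include_focal: bool = False,
) -> np.ndarray:
    """Outbound connectivity index, km^2 per reef cell."""
    areas = _check_areas(areas, dfst)
    within = _reach(dfst, T, strict, include_focal)  # rows: origin
    return within @ areas


def ici(
    dfst: np.ndarray, areas: np.ndarray, T: float = DEFAULT_THRESHOLD,
    strict: bool = True, include_focal: bool = False,
) -> np.ndarray:
    """Inbound connectivity index, km^2 per reef cell."""
    areas = _check_areas(areas, dfst)
    within = _reach(dfst, T, strict, include_focal)
    return within.T @ areas


def api(
    dfst: np.ndarray, areas: np.ndarray, pa: np.ndarray,
    T: float = DEFAULT_THRESHOLD, strict: bool = True, include_focal: bool = False,
) -> np.ndarray:
    """Adaptive potential index, km^2 per reef cell (PA-weighted ICI)."""
    areas = _check_areas(areas, dfst)
    pa = np.asarray(pa, float)
    if pa.shape != areas.shape:
        raise ValueError("pa must match areas")
    finite = pa[np.isfinite(pa)]
    if ((finite < 0) | (finite > 1)).any():
        raise ValueError("PA values must lie in [0, 1]")
    within = _reach(dfst, T, strict, include_focal)
    return within.T @ (areas * np.nan_to_num(pa, nan=0.0))


def _check_areas(areas: np.ndarray, dfst: np.ndarray) -> np.ndarray:
    areas = np.asarray(areas, float)
    if areas.shape != (np.asarray(dfst).shape[0],):
        raise ValueError("areas length must match dfst")
    if (areas <= 0).any():
        raise ValueError("areas must be positive")
    return areas


def index_table(
    cell_ids: np.ndarray, dfst: np.ndarray, areas: np.ndarray,
    pa: np.ndarray | None = None, T: float = DEFAULT_THRESHOLD,
    strict: bool = True, include_focal: bool = False,
) -> pd.DataFrame:
    """Per-reef-cell OCI/ICI (and API when PA is given), with the threshold
    recorded."""
    out = pd.DataFrame({
        "cell_id": np.asarray(cell_ids),
        "area_km2": np.asarray(areas, float),
        "oci_km2": oci(dfst, areas, T, strict, include_focal),
        "ici_km2": ici(dfst, areas, T, strict, include_focal),
    })
    if pa is not None:
        out["pa"] = np.asarray(pa, float)
        out["api_km2"] = api(dfst, areas, pa, T, strict, include_focal)
    out["dfst_threshold"] = T
    return out


def to_geojson(table: pd.DataFrame, lons: np.ndarray, lats: np.ndarray, path: str) -> None:
    """Write an index table as a GeoJSON FeatureCollection of points (one
    feature per reef cell, index values as properties)."""
    import json

    features = []
    for i, row in enumerate(table.to_dict("records")):
        features.append({
            "type": "Feature",
            "geometry": {"type": "Point",
                         "coordinates": [float(lons[i]), float(lats[i])]},
            "properties": {k: (None if isinstance(v, float) and np.isnan(v) else v)
                           for k, v in row.items()},
        })
    with open(path, "w") as fh:
        json.dump({"type": "FeatureCollection", "features": features}, fh)
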