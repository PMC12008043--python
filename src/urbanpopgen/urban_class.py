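"""Urbanization metrics and urban/rural habitat classification.

Sampling sites are classified twice: by great-circle distance to the city
center (urban iff <= 30 km; Toronto's center at 43.6563 N, -79.3809 W is
the default) and, when an urbanization score column is available, by score
(urban iff score > 0). The score itself is an input measured elsewhere,
never computed here.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

EARTH_RADIUS_KM = 6371.0088
CITY_CENTER = (43.6563, -79.3809)
URBAN_DISTANCE_KM = 30.0


def haversine_km(lat1, lon1, lat2, lon2) -> np.ndarray:
    """Great-circle distance in km on a spherical Earth (R = 6371.0088 km)."""
    lat1, lon1, lat2, lon2 = (np.asarray(x, dtype=float) for x in (lat1, lon1, lat2, lon2))
    for lat, lon in ((lat1, lon1), (lat2, lon2)):
        if np.any(np.abs(lat) > 90) or np.any(np.abs(lon) > 180):
            raise ValueError("coordinates out of range")
    p1, p2 = np.radians(lat1), np.radians(lat2)
    dphi = np.radians(lat2 - lat1)
    dlam = np.radians(lon2 - lon1)
    a = np.sin(dphi / 2.0) ** 2 + np.cos(p1) * np.cos(p2) * np.sin(dlam / 2.0) ** 2
    return 2.0 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(a, 0.0, 1.0)))


def distance_to_center(lat, lon, center: tuple[float, float] = CITY_CENTER):
    """Distance (km) from point(s) to the city center."""
    return haversine_km(lat, lon, center[0], center[1])


def classify_habitat(frame: pd.DataFrame, center: tuple[float, float] = CITY_CENTER,
                     distance_threshold_km: float = URBAN_DISTANCE_KM) -> pd.DataFrame:
    """Attach dist_km and habitat labels to a sample metadata frame.

    All samples at a site share the site centroid's labels. Sites whose
    samples disagree on coordinates by more than 1 km trigger a warning and
    use the centroid. ``habitat_by_score`` is only set when an
    ``urban_score`` column is present; the score boundary is exclusive
    (score 0 -> rural) while the distance boundary is inclusive
    (exactly 30 km -> urban).
    """
    out = frame.copy()
    cent = out.groupby("site_id")[["lat", "lon"]].mean()
    # flag sites with internally conflicting coordinates
    for site, sub in out.groupby("site_id"):
        if len(sub) > 1:
            d = haversine_km(sub["lat"].values, sub["lon"].values,
                             cent.loc[site, "lat"], cent.loc[site, "lon"])
            if np.any(d > 1.0):
                warnings.warn(f"site {site}: sample coordinates conflict by >1 km; "
                              "using the site centroid", stacklevel=2)
    dist = distance_to_center(cent["lat"].values, cent["lon"].values, center)
    site_dist = pd.Series(dist, index=cent.index)
    out["dist_km"] = out["site_id"].map(site_dist)
    out["habitat_by_distance"] = np.where(out["dist_km"] <= distance_threshold_km,
                                          "urban", "rural")
    if "urban_score" in out.columns:
        site_score = out.groupby("site_id")["urban_score"].mean()
        score = out["site_id"].map(site_score)
        out["habitat_by_score"] = np.where(score > 0.0, "urban", "rural")
    return out
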