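"""Spherical-Earth geodesy helpers.

All distances and areas use a sphere of radius 6371.0088 km (the IUGG mean
Earth radius); at the 5-km scales relevant to occurrence thinning and
centroid tracking the ellipsoidal correction is far below a cell width.
"""

from __future__ import annotations

import numpy as np

EARTH_RADIUS_KM = 6371.0088

#: kilometres per degree of latitude on the sphere (also per degree of
#: longitude at the equator)
KM_PER_DEGREE = EARTH_RADIUS_KM * np.pi / 180.0


def haversine_km(lon1, lat1, lon2, lat2):
    """Great-circle distance in km between points given in decimal degrees.

    Accepts scalars or broadcastable arrays.
    """
    lon1, lat1, lon2, lat2 = (np.radians(np.asarray(v, dtype=float))
                              for v in (lon1, lat1, lon2, lat2))
    dlon = lon2 - lon1
    dlat = lat2 - lat1
    a = np.sin(dlat / 2.0) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2.0) ** 2
    return 2.0 * EARTH_RADIUS_KM * np.arcsin(np.minimum(1.0, np.sqrt(a)))


def cell_area_km2(lat_bottom_deg, lat_top_deg, cell_width_deg):
    """Geodesic area (km^2) of a plate-carree cell spanning the given
    latitude band with the given longitudinal width.

    Closed-form spherical quad: R^2 * dlambda * (sin(phi_top) - sin(phi_bot)).
    """
    dlam = np.radians(np.asarray(cell_width_deg, dtype=float))
    s = np.sin(np.radians(np.asarray(lat_top_deg, dtype=float))) - \
        np.sin(np.radians(np.asarray(lat_bottom_deg, dtype=float)))
    return EARTH_RADIUS_KM ** 2 * dlam * s
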