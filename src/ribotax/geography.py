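"""Geographic distances, site-pair genetic summaries, and the
speciation-by-distance regression.

Great-circle distances use the haversine formula (Earth radius 6371 km).
Site pairs whose direct great-circle path crosses ecologically impossible
territory (e.g. over the poles between ocean basins) can be re-routed
through explicit waypoints. Mean patristic distance per site pair is
regressed on geographic distance; pairs falling below/above a confidence
band around the fit are classified genetically under-/overdispersed.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace

import numpy as np
from scipy import stats
from skbio import DistanceMatrix

from .records import Site

logger = logging.getLogger(__name__)

EARTH_RADIUS_KM = 6371.0

Coord = tuple[float, float]  # (latitude, longitude) decimal degrees


def _check(lat: float, lon: float) -> None:
    if not -90.0 <= lat <= 90.0:
        raise ValueError(f"latitude {lat} out of [-90, 90]")
    if not -180.0 < lon <= 180.0:
        raise ValueError(f"longitude {lon} out of (-180, 180]")


def _as_coord(x: Site | Coord) -> Coord:
    if isinstance(x, Site):
        return (x.latitude, x.longitude)
    return (float(x[0]), float(x[1]))


def haversine_km(
    a: Site | Coord, b: Site | Coord, waypoints: list[Site | Coord] | None = None
) -> float:
    """Great-circle distance in km; with waypoints, the sum of the legs."""
    points = [_as_coord(a)] + [_as_coord(w) for w in (waypoints or [])] + [_as_coord(b)]
    total = 0.0
    for (lat1, lon1), (lat2, lon2) in zip(points, points[1:]):
        _check(lat1, lon1)
        _check(lat2, lon2)
        phi1, phi2 = math.radians(lat1), math.radians(lat2)
        dphi = phi2 - phi1
        dlam = math.radians(lon2 - lon1)
        h = math.sin(dphi / 2) ** 2 + math.cos(phi1) * math.cos(phi2) * math.sin(dlam / 2) ** 2
        total += 2.0 * EARTH_RADIUS_KM * math.asin(min(1.0, math.sqrt(h)))
    return total


@dataclass(frozen=True)
class GeoPairRecord:
    site_a: str
    site_b: str
    geographic_km: float
    patristic_mean: float
    patristic_min: float
    patristic_max: float
    predicted: float | None = None
    dispersion: str | None = None  # underdispersed | consistent | overdispersed


@dataclass(frozen=True)
class RegressionResult:
    slope: float
    intercept: float
    r_squared: float
    p_value: float
    band_halfwidth: float


def build_pair_table(
    sites: dict[str, Site],
    site_tips: dict[str, set[str]],
    patristic: DistanceMatrix,
    routing_overrides: dict[frozenset[str], list[Coord]] | None = None,
    include: list[str] | None = None,
) -> list[GeoPairRecord]:
    """One record per unordered pair of sites with placed sequences.

    ``site_tips`` maps each site to the tree tips (basetypes) observed
    there; patristic summaries run over all cross-site tip pairs. Sites
    with no placed tips are excluded with a warning. ``routing_overrides``
    maps a pair (frozenset of two site ids) to a waypoint list replacing
    the direct great circle.
    """
    routing_overrides = routing_overrides or {}
    chosen = include if include is not None else sorted(sites)
    usable = []
    for sid in chosen:
        if sid not in sites:
            raise ValueError(f"unknown site in include list: {sid!r}")
        if not site_tips.get(sid):
            logger.warning("site %s has no placed sequences; excluded from pairs", sid)
            continue
        usable.append(sid)
    records = []
    for i, a in enumerate(usable):
        for b in usable[i + 1 :]:
            a_, b_ = sorted((a, b))
            waypoints = routing_overrides.get(frozenset((a_, b_)))
            km = haversine_km(sites[a_], sites[b_], waypoints)
            values = [
                float(patristic[ta, tb])
                for ta in sorted(site_tips[a_])
                for tb in sorted(site_tips[b_])
            ]
            records.append(
                GeoPairRecord(
                    site_a=a_, site_b=b_, geographic_km=km,
                    patristic_mean=float(np.mean(values)),
                    patristic_min=float(np.min(values)),
                    patristic_max=float(np.max(values)),
                )
            )
    return records


def fit_regression(pairs: list[GeoPairRecord], band: str = "half_range") -> RegressionResult:
    """OLS of mean patristic distance on geographic distance.

    The confidence band halfwidth is the mean within-pair patristic range
    divided by two (``band="half_range"``, default) or the full mean range
    (``band="full_range"``).
    """
    if len(pairs) < 3:
        raise ValueError("regression requires >= 3 pairs")
    if band not in ("half_range", "full_range"):
        raise ValueError(f"unknown band rule {band!r}")
    x = np.array([p.geographic_km for p in pairs])
    y = np.array([p.patristic_mean for p in pairs])
    if np.allclose(x, x[0]):
        raise ValueError("zero variance in geographic distance")
    fit = stats.linregress(x, y)
    ranges = np.array([p.patristic_max - p.patristic_min for p in pairs])
    halfwidth = float(ranges.mean() / 2.0)
    if band == "full_range":
        halfwidth = float(ranges.mean())
    return RegressionResult(
        slope=float(fit.slope), intercept=float(fit.intercept),
        r_squared=float(fit.rvalue**2), p_value=float(fit.pvalue),
        band_halfwidth=halfwidth,
    )


def classify_dispersion(
    pairs: list[GeoPairRecord], fit: RegressionResult
) -> list[GeoPairRecord]:
    """Label each pair against the regression band.

    underdispersed: mean patristic below prediction - halfwidth;
    overdispersed: above prediction + halfwidth; otherwise consistent.
    """
    out = []
    for p in pairs:
        predicted = fit.intercept + fit.slope * p.geographic_km
        if p.patristic_mean < predicted - fit.band_halfwidth:
            label = "underdispersed"
        elif p.patristic_mean > predicted + fit.band_halfwidth:
            label = "overdispersed"
        else:
            label = "consistent"
        out.append(replace(p, predicted=predicted, dispersion=label))
    return out
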