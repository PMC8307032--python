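"""Synthetic Germany-scale distribution geography.

Generates a reproducible three-tier network on a planar km grid: receipt
hubs (where vaccine shipments arrive), intermediary hubs, pharmacies and GP
practices.  Pharmacies and GP practices are drawn from a mixture of Gaussian
metropolitan clusters plus a uniform rural background, truncated to the
region; hubs are placed by k-means over the pharmacy distribution so that
hub coverage follows demand density.  Everything is deterministic given a
single master seed, from which independent sub-streams are derived per stage
(adding a stage never perturbs earlier stages).

Planar coordinates in km are used throughout — the distance model downstream
is straight-line times a road factor, so a projected plane loses nothing.
A GeoJSON export places the plane affinely onto a nominal lon/lat box for
visualization only.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree
from sklearn.cluster import KMeans

from .errors import ConfigError

__all__ = [
    "Region",
    "GeographyParams",
    "GeographyModel",
    "generate_geography",
    "assign_pharmacies_to_wholesalers",
    "attach_gps_to_pharmacies",
    "DEFAULT_WHOLESALER_SHARES",
    "DEFAULT_WHOLESALER_NAMES",
    "default_wholesaler_zones",
]

TIERS = ("receipt_hub", "intermediary_hub", "pharmacy", "gp")

# Nominal lon/lat frame for GeoJSON visualization (roughly Germany's extent).
_LL_BOX = (5.87, 47.27, 15.04, 55.06)  # lon_min, lat_min, lon_max, lat_max


@dataclass(frozen=True)
class Region:
    """Axis-aligned study region in km; defaults approximate Germany's extent."""

    width_km: float = 630.0
    height_km: float = 570.0

    @property
    def area_km2(self) -> float:
        return self.width_km * self.height_km

    def contains(self, pts: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(pts)
        return (
            (pts[:, 0] >= 0) & (pts[:, 0] <= self.width_km)
            & (pts[:, 1] >= 0) & (pts[:, 1] <= self.height_km)
        )


@dataclass(frozen=True)
class GeographyParams:
    """Counts and spatial-mixture settings of the synthetic network.

    Defaults emulate the German vaccine distribution network: 41 receipt
    hubs, 69 intermediary hubs, 15,000 pharmacies serving 35,000 GP
    practices.  ``metro_weight`` of the points live in ``n_metro_clusters``
    Gaussian metropolitan clusters of scale ``metro_sigma_km``; the rest are
    uniform background.
    """

    n_receipt_hubs: int = 41
    n_intermediary_hubs: int = 69
    n_pharmacies: int = 15_000
    n_gp_practices: int = 35_000
    region: Region = field(default_factory=Region)
    n_metro_clusters: int = 12
    metro_weight: float = 0.7
    metro_sigma_km: float = 25.0

    def __post_init__(self) -> None:
        counts = (self.n_receipt_hubs, self.n_intermediary_hubs,
                  self.n_pharmacies, self.n_gp_practices, self.n_metro_clusters)
        if min(counts) < 1:
            raise ConfigError(f"all counts must be >= 1, got {counts}")
        if self.region.area_km2 <= 0:
            raise ConfigError("region area must be > 0")
        if not 0.0 <= self.metro_weight <= 1.0:
            raise ConfigError(f"metro_weight must be in [0, 1], got {self.metro_weight}")
        if self.metro_sigma_km <= 0:
            raise ConfigError(f"metro_sigma_km must be > 0, got {self.metro_sigma_km}")


@dataclass
class GeographyModel:
    """Generated network: point arrays per tier plus optional assignments.

    ``wholesalers`` holds one integer label per pharmacy (index into
    ``wholesaler_names``); ``gp_pharmacy`` maps each GP practice to the index
    of its serving pharmacy.  Both are ``None`` until assigned.
    """

    region: Region
    receipt_hubs: np.ndarray      # (n_receipt, 2) km
    intermediary_hubs: np.ndarray  # (n_intermediary, 2) km
    pharmacies: np.ndarray        # (n_pharmacies, 2) km
    gp_practices: np.ndarray      # (n_gps, 2) km
    seed: int | None = None
    params: GeographyParams | None = None
    wholesalers: np.ndarray | None = None       # (n_pharmacies,) int
    wholesaler_names: list[str] | None = None
    gp_pharmacy: np.ndarray | None = None       # (n_gps,) int

    @property
    def all_hubs(self) -> np.ndarray:
        """Receipt hubs stacked above intermediary hubs; a flat depot array."""
        return np.vstack([self.receipt_hubs, self.intermediary_hubs])

    def scaled(self, c: float) -> "GeographyModel":
        """Copy of the model with all coordinates (and the region) scaled by ``c``."""
        return replace(
            self,
            region=Region(self.region.width_km * c, self.region.height_km * c),
            receipt_hubs=self.receipt_hubs * c,
            intermediary_hubs=self.intermediary_hubs * c,
            pharmacies=self.pharmacies * c,
            gp_practices=self.gp_practices * c,
        )

    # -- tabular / GeoJSON IO ---------------------------------------------
    def to_frame(self) -> pd.DataFrame:
        names = self.wholesaler_names or []
        labels = []
        for tier, pts in self._tier_points():
            if tier == "pharmacy" and self.wholesalers is not None:
                labels += [names[w] if w < len(names) else str(w) for w in self.wholesalers]
            else:
                labels += [""] * len(pts)
        xy = np.vstack([pts for _, pts in self._tier_points()])
        tiers = sum(([t] * len(p) for t, p in self._tier_points()), [])
        return pd.DataFrame({"tier": tiers, "x_km": xy[:, 0], "y_km": xy[:, 1], "label": labels})

    def _tier_points(self):
        return [
            ("receipt_hub", self.receipt_hubs),
            ("intermediary_hub", self.intermediary_hubs),
            ("pharmacy", self.pharmacies),
            ("gp", self.gp_practices),
        ]

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_frame(cls, df: pd.DataFrame, region: Region | None = None) -> "GeographyModel":
        region = region or Region()
        by = {t: df[df["tier"] == t] for t in TIERS}
        for t in ("receipt_hub", "intermediary_hub", "pharmacy", "gp"):
            if by[t].empty:
                raise ConfigError(f"geography table has no rows for tier {t!r}")
        ph = by["pharmacy"]
        labels = ph["label"].fillna("").astype(str).tolist()
        wholesalers = names = None
        if any(labels):
            names = sorted(set(labels))
            idx = {n: i for i, n in enumerate(names)}
            wholesalers = np.array([idx[l] for l in labels])
        return cls(
            region=region,
            receipt_hubs=by["receipt_hub"][["x_km", "y_km"]].to_numpy(float),
            intermediary_hubs=by["intermediary_hub"][["x_km", "y_km"]].to_numpy(float),
            pharmacies=ph[["x_km", "y_km"]].to_numpy(float),
            gp_practices=by["gp"][["x_km", "y_km"]].to_numpy(float),
            wholesalers=wholesalers,
            wholesaler_names=names,
        )

    @classmethod
    def from_csv(cls, path: str | Path, region: Region | None = None) -> "GeographyModel":
        df = pd.read_csv(path, keep_default_na=False, float_precision="round_trip")
        return cls.from_frame(df, region)

    def to_geojson(self, path: str | Path | None = None) -> dict:
        """FeatureCollection of Points; planar km coordinates are mapped
        affinely onto a nominal lon/lat box and also kept in the properties,
        so the export round-trips exactly."""
        lon0, lat0, lon1, lat1 = _LL_BOX
        w, h = self.region.width_km, self.region.height_km
        names = self.wholesaler_names or []
        features = []
        for tier, pts in self._tier_points():
            for i, (x, y) in enumerate(np.atleast_2d(pts)):
                props = {"tier": tier, "x_km": float(x), "y_km": float(y)}
                if tier == "pharmacy" and self.wholesalers is not None:
                    wl = int(self.wholesalers[i])
                    props["wholesaler"] = names[wl] if wl < len(names) else str(wl)
                features.append({
                    "type": "Feature",
                    "geometry": {
                        "type": "Point",
                        "coordinates": [lon0 + x / w * (lon1 - lon0),
                                        lat0 + y / h * (lat1 - lat0)],
                    },
                    "properties": props,
                })
        fc = {"type": "FeatureCollection", "features": features}
        if path is not None:
            Path(path).write_text(json.dumps(fc))
        return fc

    @classmethod
    def from_geojson(cls, source: dict | str | Path, region: Region | None = None
                     ) -> "GeographyModel":
        if not isinstance(source, dict):
            source = json.loads(Path(source).read_text())
        rows = []
        for feat in source["features"]:
            p = feat["properties"]
            rows.append({"tier": p["tier"], "x_km": p["x_km"], "y_km": p["y_km"],
                         "label": p.get("wholesaler", "")})
        return cls.from_frame(pd.DataFrame(rows), region)


# ---------------------------------------------------------------------------
# Generation
# ---------------------------------------------------------------------------

def _sub_seed(seed: int, index: int) -> np.random.Generator:
    """Independent per-stage stream: stage index appended to the master seed."""
    return np.random.default_rng(np.random.SeedSequence([int(seed), index]))


def _kmeans_seed(seed: int, index: int) -> int:
    return int(_sub_seed(seed, index).integers(0, 2**31 - 1))


def _sample_mixture(n: int, centers: np.ndarray, sigma: float, weight: float,
                    region: Region, rng: np.random.Generator) -> np.ndarray:
    """Draw ``n`` points from metro Gaussians (prob. ``weight``) plus uniform
    background, rejecting draws that fall outside the region."""
    out = np.empty((n, 2))
    filled = 0
    while filled < n:
        m = n - filled
        is_metro = rng.random(m) < weight
        cand = rng.uniform([0.0, 0.0], [region.width_km, region.height_km], (m, 2))
        k = int(is_metro.sum())
        if k:
            which = rng.integers(0, len(centers), k)
            cand[is_metro] = centers[which] + rng.normal(0.0, sigma, (k, 2))
        ok = region.contains(cand)
        good = cand[ok]
        out[filled:filled + len(good)] = good
        filled += len(good)
    return out


def _place_hubs(n_hubs: int, demand: np.ndarray, region: Region, km_seed: int,
                rng: np.random.Generator) -> np.ndarray:
    """Hub locations as k-means centroids of the demand points; falls back to
    uniform placement when there are fewer demand points than hubs."""
    if len(demand) < n_hubs:
        return rng.uniform([0.0, 0.0], [region.width_km, region.height_km], (n_hubs, 2))
    km = KMeans(n_clusters=n_hubs, n_init=4, random_state=km_seed)
    km.fit(demand)
    return km.cluster_centers_


def generate_geography(params: GeographyParams | None = None, seed: int = 0) -> GeographyModel:
    """Generate the synthetic network; deterministic for given params and seed."""
    params = params or GeographyParams()

    margin = min(params.metro_sigma_km, params.region.width_km / 4,
                 params.region.height_km / 4)
    metro_rng = _sub_seed(seed, 0)
    centers = metro_rng.uniform(
        [margin, margin],
        [params.region.width_km - margin, params.region.height_km - margin],
        (params.n_metro_clusters, 2),
    )

    pharmacies = _sample_mixture(params.n_pharmacies, centers, params.metro_sigma_km,
                                 params.metro_weight, params.region, _sub_seed(seed, 1))
    gps = _sample_mixture(params.n_gp_practices, centers, params.metro_sigma_km,
                          params.metro_weight, params.region, _sub_seed(seed, 2))

    receipt = _place_hubs(params.n_receipt_hubs, pharmacies, params.region,
                          _kmeans_seed(seed, 3), _sub_seed(seed, 3))
    intermediary = _place_hubs(params.n_intermediary_hubs, pharmacies, params.region,
                               _kmeans_seed(seed, 4), _sub_seed(seed, 4))

    return GeographyModel(
        region=params.region,
        receipt_hubs=receipt,
        intermediary_hubs=intermediary,
        pharmacies=pharmacies,
        gp_practices=gps,
        seed=seed,
        params=params,
    )


# ---------------------------------------------------------------------------
# Wholesaler assignment
# ---------------------------------------------------------------------------

#: Market shares of five nationwide and five regional wholesalers.
DEFAULT_WHOLESALER_SHARES = (0.17, 0.15, 0.13, 0.11, 0.09, 0.07, 0.07, 0.07, 0.07, 0.07)
DEFAULT_WHOLESALER_NAMES = ("N1", "N2", "N3", "N4", "N5", "R1", "R2", "R3", "R4", "R5")


def default_wholesaler_zones(region: Region) -> list[tuple[float, float, float, float] | None]:
    """Operating zones matching the default shares: five nationwide (None)
    plus west / east / north / south halves and a central box."""
    w, h = region.width_km, region.height_km
    return [
        None, None, None, None, None,
        (0, 0, w / 2, h),
        (w / 2, 0, w, h),
        (0, h / 2, w, h),
        (0, 0, w, h / 2),
        (w / 4, h / 4, 3 * w / 4, 3 * h / 4),
    ]


def _largest_remainder_counts(shares: np.ndarray, n: int) -> np.ndarray:
    raw = shares * n
    counts = np.floor(raw).astype(int)
    short = n - counts.sum()
    if short > 0:
        order = np.argsort(-(raw - counts), kind="stable")
        counts[order[:short]] += 1
    return counts


def assign_pharmacies_to_wholesalers(
    model: GeographyModel,
    shares=None,
    zones=None,
    names=None,
    seed: int = 0,
) -> GeographyModel:
    """Label every pharmacy with a wholesaler, honouring market shares.

    Target counts per wholesaler come from largest-remainder rounding of the
    shares, so empirical shares match targets to within one pharmacy.
    Regional wholesalers (those with a rectangular zone) are filled first
    from the pharmacies inside their zone; if a zone is too sparse the
    shortfall spills over to the nationwide pool.  The model is labelled in
    place and returned.
    """
    n = len(model.pharmacies)
    if shares is None:
        shares = DEFAULT_WHOLESALER_SHARES
        zones = default_wholesaler_zones(model.region) if zones is None else zones
        names = DEFAULT_WHOLESALER_NAMES if names is None else names
    shares = np.asarray(shares, dtype=float)
    if abs(shares.sum() - 1.0) > 1e-9:
        raise ConfigError(f"wholesaler shares must sum to 1, got {shares.sum()!r}")
    if zones is None:
        zones = [None] * len(shares)
    if names is None:
        names = [f"W{i + 1}" for i in range(len(shares))]
    if not (len(shares) == len(zones) == len(names)):
        raise ConfigError("shares, zones and names must have equal length")

    rng = _sub_seed(seed, 100)
    counts = _largest_remainder_counts(shares, n)
    labels = np.full(n, -1, dtype=int)
    xy = model.pharmacies

    spill = 0
    for j, zone in enumerate(zones):
        if zone is None:
            continue
        x0, y0, x1, y1 = zone
        cand = np.flatnonzero(
            (labels == -1)
            & (xy[:, 0] >= x0) & (xy[:, 0] <= x1)
            & (xy[:, 1] >= y0) & (xy[:, 1] <= y1)
        )
        take = min(counts[j], len(cand))
        chosen = rng.permutation(cand)[:take]
        labels[chosen] = j
        spill += counts[j] - take

    nationwide = [j for j, z in enumerate(zones) if z is None]
    pool_counts = {j: int(counts[j]) for j in nationwide}
    if spill:
        targets = nationwide or list(range(len(shares)))
        for k in range(spill):
            j = targets[k % len(targets)]
            pool_counts[j] = pool_counts.get(j, 0) + 1
    remaining = np.flatnonzero(labels == -1)
    pool = np.concatenate([np.full(c, j, dtype=int) for j, c in pool_counts.items()]) \
        if pool_counts else np.empty(0, dtype=int)
    if len(pool) != len(remaining):  # all-regional configs with spill
        pool = np.resize(pool, len(remaining)) if len(pool) else np.zeros(len(remaining), int)
    labels[remaining] = rng.permutation(pool)

    model.wholesalers = labels
    model.wholesaler_names = list(names)
    return model


def attach_gps_to_pharmacies(model: GeographyModel) -> np.ndarray:
    """Map every GP practice to its nearest pharmacy.

    The road metric is straight-line distance times a constant factor, so
    nearest-by-road equals nearest-by-Euclid; ties resolve to the lowest
    pharmacy index.  Stores and returns the (n_gps,) index mapping.
    """
    if len(model.pharmacies) == 0:
        raise ConfigError("cannot attach GP practices: pharmacy list is empty")
    _, idx = cKDTree(model.pharmacies).query(model.gp_practices)
    model.gp_pharmacy = np.asarray(idx, dtype=int)
    return model.gp_pharmacy
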