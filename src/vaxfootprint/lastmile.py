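"""Three-tier last-mile delivery simulation with TSP tour optimization.

Models one month of vaccine distribution over a labelled
:class:`~vaxfootprint.geography.GeographyModel`:

* **network tier** — star legs between each active intermediary hub and its
  nearest receipt hub (two-way, 90 km/h);
* **pharmacy-cluster tier** — pharmacies of each (wholesaler, hub) group are
  cut into delivery clusters of 15-30 neighbours by an angular sweep around
  the hub, each served by one closed TSP tour (60 km/h, 10 min per stop,
  20 min loading);
* **GP tier** — each pharmacy runs one tour over its attached GP practices
  (40 km/h, 10 min per stop, 30 min preparation).

All distances are straight-line times a road factor (default 1.3).  Tours
are optimized by nearest-neighbour construction plus 2-opt improvement; an
exact brute-force solver is available for small instances as an oracle.

Monthly emissions come in two accounting modes: *most likely*, where the
vaccine rides existing tours as additional load and only its freight units
(t·km) count, and *worst case*, where dedicated tours are charged per
vehicle-km.  The two differ by roughly two orders of magnitude.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import permutations
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree
from scipy.spatial.distance import cdist

from .errors import ConfigError, DomainError
from .geography import GeographyModel, attach_gps_to_pharmacies

__all__ = [
    "road_distance",
    "DeliveryCluster",
    "make_clusters",
    "Tour",
    "tsp_tour",
    "tour_duration",
    "SimulationParams",
    "LastMileResult",
    "simulate_month",
    "lastmile_emissions",
]

BRUTE_FORCE_LIMIT = 9


def road_distance(p, q, road_factor: float = 1.3) -> float:
    """Approximate road distance: Euclidean distance times a road factor >= 1."""
    if road_factor < 1:
        raise DomainError(f"road_factor must be >= 1, got {road_factor}")
    p = np.asarray(p, float)
    q = np.asarray(q, float)
    return float(np.hypot(*(p - q))) * road_factor


# ---------------------------------------------------------------------------
# Clustering
# ---------------------------------------------------------------------------

@dataclass
class DeliveryCluster:
    """A group of neighbouring pharmacies served on one tour from a hub."""

    wholesaler: int
    hub_index: int            # index into the model's stacked hub array
    hub: np.ndarray           # (2,) km
    members: np.ndarray       # pharmacy indices (into the model's pharmacy array)


def make_clusters(
    hub, points: np.ndarray, min_size: int = 15, max_size: int = 30
) -> list[np.ndarray]:
    """Partition a hub's pharmacies into delivery clusters by angular sweep.

    Points are sorted by angle around the hub (radius breaks ties) and cut
    into consecutive arcs of target size ``round(n / ceil(n / max_size))``,
    balancing cluster sizes under the maximum.  A trailing remainder smaller
    than ``min_size / 2`` is merged into its angular neighbour; a single
    undersized remainder may survive otherwise.  Returns index arrays that
    partition ``range(len(points))``.
    """
    if min_size > max_size:
        raise DomainError(f"min_size {min_size} > max_size {max_size}")
    points = np.atleast_2d(points)
    n = len(points)
    if n == 0:
        return []
    hub = np.asarray(hub, float)
    d = points - hub
    ang = np.arctan2(d[:, 1], d[:, 0])
    order = np.lexsort((np.hypot(d[:, 0], d[:, 1]), ang))
    target = round(n / math.ceil(n / max_size))
    arcs = [order[i:i + target] for i in range(0, n, target)]
    if len(arcs) > 1 and len(arcs[-1]) < min_size / 2:
        tail = arcs.pop()
        arcs[-1] = np.concatenate([arcs[-1], tail])
    return arcs


# ---------------------------------------------------------------------------
# TSP tours
# ---------------------------------------------------------------------------

@dataclass
class Tour:
    """A closed delivery tour: depot -> stops -> depot.

    ``stops`` holds the visited coordinates in order, with the depot as the
    first and last row.  ``order`` gives the visit order as indices into the
    original stop array.
    """

    stops: np.ndarray         # (k+2, 2) including depot at both ends
    order: np.ndarray         # (k,) indices into the input stops
    road_distance: float      # km
    drive_speed: float = 60.0  # km/h
    stop_minutes: float = 10.0
    fixed_minutes: float = 0.0

    @property
    def n_stops(self) -> int:
        return len(self.order)

    @property
    def duration(self) -> float:
        """Minutes: driving plus per-stop service plus fixed handling time."""
        return tour_duration(self, self.drive_speed, self.stop_minutes, self.fixed_minutes)


def tour_duration(tour: Tour, speed: float, per_stop_min: float, fixed_min: float) -> float:
    """Tour time in minutes: ``distance / speed * 60 + stops * per_stop + fixed``."""
    if speed <= 0:
        raise DomainError(f"speed must be > 0, got {speed}")
    return tour.road_distance / speed * 60.0 + tour.n_stops * per_stop_min + fixed_min


def _route_length(D: np.ndarray, route: Sequence[int]) -> float:
    return float(sum(D[route[i], route[i + 1]] for i in range(len(route) - 1)))


def _nearest_neighbour(D: np.ndarray) -> list[int]:
    n = D.shape[0]
    unvisited = np.ones(n, dtype=bool)
    unvisited[0] = False
    route = [0]
    for _ in range(n - 1):
        d = D[route[-1]].copy()
        d[~unvisited] = np.inf
        nxt = int(np.argmin(d))  # argmin breaks ties by lowest index
        route.append(nxt)
        unvisited[nxt] = False
    return route + [0]


def _two_opt(D: np.ndarray, route: list[int], tol: float = 1e-12) -> list[int]:
    """First-improvement 2-opt on a closed route until no strict gain remains."""
    route = list(route)
    n = len(route)
    improved = True
    while improved:
        improved = False
        for i in range(1, n - 2):
            a, b = route[i - 1], route[i]
            for j in range(i + 1, n - 1):
                c, e = route[j], route[j + 1]
                delta = (D[a, c] + D[b, e]) - (D[a, b] + D[c, e])
                if delta < -tol:
                    route[i:j + 1] = route[i:j + 1][::-1]
                    improved = True
                    a, b = route[i - 1], route[i]
    return route


def _brute_force(D: np.ndarray) -> list[int]:
    n = D.shape[0] - 1  # stops excluding depot
    best = None
    best_len = np.inf
    for perm in permutations(range(1, n + 1)):
        route = (0, *perm, 0)
        length = _route_length(D, route)
        if length < best_len - 1e-12:  # first (lexicographically lowest) wins ties
            best_len = length
            best = list(route)
    return best


def tsp_tour(
    depot,
    stops,
    method: Literal["nearest_neighbour", "two_opt", "brute_force"] = "two_opt",
    road_factor: float = 1.3,
    speed: float = 60.0,
    per_stop_min: float = 10.0,
    fixed_min: float = 0.0,
) -> Tour:
    """Closed tour from the depot through all stops and back.

    ``two_opt`` (default) refines the nearest-neighbour tour and is never
    worse than it; ``brute_force`` enumerates all orders and is refused above
    :data:`BRUTE_FORCE_LIMIT` stops.
    """
    if road_factor < 1:
        raise DomainError(f"road_factor must be >= 1, got {road_factor}")
    depot = np.asarray(depot, float).reshape(2)
    stops = np.asarray(stops, float).reshape(-1, 2)
    k = len(stops)
    if k == 0:
        return Tour(np.vstack([depot, depot]), np.empty(0, int), 0.0,
                    speed, per_stop_min, fixed_min)

    pts = np.vstack([depot, stops])
    D = cdist(pts, pts) * road_factor

    if method == "nearest_neighbour":
        route = _nearest_neighbour(D)
    elif method == "two_opt":
        route = _two_opt(D, _nearest_neighbour(D))
    elif method == "brute_force":
        if k > BRUTE_FORCE_LIMIT:
            raise DomainError(
                f"brute_force refused for {k} stops (limit {BRUTE_FORCE_LIMIT})"
            )
        route = _brute_force(D)
    else:
        raise DomainError(f"unknown TSP method {method!r}")

    order = np.array(route[1:-1]) - 1  # back to stop indices
    return Tour(pts[route], order, _route_length(D, route), speed, per_stop_min, fixed_min)


# ---------------------------------------------------------------------------
# Monthly simulation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SimulationParams:
    """Operating parameters of one month of distribution.

    Speeds in km/h per tier, handling times in minutes, and the monthly
    demand (vials, doses, shipped mass per vial in grams including the
    cryo-case share).  ``recluster_per_wave`` re-runs the sweep clustering
    with a rotated start angle for every delivery wave; by default clusters
    are fixed for the month.
    """

    deliveries_per_month: int = 4
    network_speed: float = 90.0
    cluster_speed: float = 60.0
    gp_speed: float = 40.0
    road_factor: float = 1.3
    hub_loading_min: float = 20.0
    intermediary_reload_min: float = 10.0
    pharmacy_stop_min: float = 10.0
    pharmacy_prep_min: float = 30.0
    gp_stop_min: float = 10.0
    min_cluster: int = 15
    max_cluster: int = 30
    hub_min_load: int | None = None  # default: ceil(min_cluster / 2)
    tsp_method: str = "two_opt"
    recluster_per_wave: bool = False
    vials_per_month: int = 1_050_000
    doses_per_month: int = 6_300_000
    per_vial_mass_g: float = 40.0  # vial incl. cryo-case share
    freight_from_legs: bool = False  # sum leg-mass x leg-km instead of mean-distance form

    def __post_init__(self) -> None:
        if self.deliveries_per_month < 0:
            raise ConfigError("deliveries_per_month must be >= 0")
        if min(self.network_speed, self.cluster_speed, self.gp_speed) <= 0:
            raise ConfigError("speeds must be > 0")
        if self.road_factor < 1:
            raise ConfigError("road_factor must be >= 1")


@dataclass
class LastMileResult:
    """Aggregated monthly metrics of the three delivery tiers."""

    network_km: float
    cluster_km: float
    gp_km: float
    network_tours: int = 0
    cluster_tours: int = 0
    gp_tours: int = 0
    network_min: float = 0.0
    cluster_min: float = 0.0
    gp_min: float = 0.0
    deliveries_per_month: int = 4
    vials_per_month: int = 1_050_000
    loading_mass_kg: float = 42_000.0
    representative_km: float = 0.0   # distance over which the payload mass travels
    n_clusters: int = 0
    mean_cluster_size: float = 0.0
    seed: int | None = None
    tours: pd.DataFrame | None = field(default=None, repr=False)

    @property
    def total_km(self) -> float:
        return self.network_km + self.cluster_km + self.gp_km

    @property
    def freight_tkm(self) -> float:
        """Freight units: payload tonnes times representative carried distance."""
        return self.loading_mass_kg / 1000.0 * self.representative_km

    def summary(self) -> dict:
        return {
            "deliveries_per_month": self.deliveries_per_month,
            "vials_per_month": self.vials_per_month,
            "loading_mass_kg": self.loading_mass_kg,
            "n_clusters": self.n_clusters,
            "mean_cluster_size": self.mean_cluster_size,
            "network_km": self.network_km,
            "cluster_km": self.cluster_km,
            "gp_km": self.gp_km,
            "total_km": self.total_km,
            "representative_km": self.representative_km,
            "freight_tkm": self.freight_tkm,
            "network_min": self.network_min,
            "cluster_min": self.cluster_min,
            "gp_min": self.gp_min,
            "tour_counts": {
                "network": self.network_tours,
                "cluster": self.cluster_tours,
                "gp": self.gp_tours,
            },
            "seed": self.seed,
        }


def _group_pharmacies(model: GeographyModel, min_load: int = 0
                      ) -> dict[tuple[int, int], np.ndarray]:
    """Group pharmacy indices by (wholesaler, serving hub).

    Each pharmacy initially goes to its nearest hub.  With ``min_load > 0``
    a consolidation rule is applied per wholesaler: a hub serving fewer than
    ``min_load`` of the wholesaler's pharmacies does not get a dedicated
    tour; its pharmacies are re-served from the next-nearest remaining hub.
    This mirrors how wholesalers concentrate low-volume territory on fewer
    depots and keeps delivery clusters near their target size.
    """
    hubs = model.all_hubs
    groups: dict[tuple[int, int], np.ndarray] = {}
    for w in np.unique(model.wholesalers):
        mine = np.flatnonzero(model.wholesalers == w)
        xy = model.pharmacies[mine]
        active = np.arange(len(hubs))
        _, hub_of = cKDTree(hubs).query(xy)
        while True:
            loads = np.bincount(hub_of, minlength=len(hubs))
            used = loads[active]
            weak = active[(used > 0) & (used < min_load)]
            if len(weak) == 0 or len(active) <= 1:
                break
            drop = weak[np.argmin(loads[weak])]  # weakest hub first
            active = active[active != drop]
            tree = cKDTree(hubs[active])
            moving = hub_of == drop
            _, near = tree.query(xy[moving])
            hub_of[moving] = active[near]
        for h in np.unique(hub_of):
            groups[(int(w), int(h))] = mine[hub_of == h]
    return dict(sorted(groups.items()))


def simulate_month(
    model: GeographyModel,
    params: SimulationParams | None = None,
    seed: int = 0,
) -> LastMileResult:
    """Run one month of three-tier distribution over a labelled model.

    Requires wholesaler labels (:func:`assign_pharmacies_to_wholesalers`);
    the GP mapping is computed on the fly if absent.  The pipeline is fully
    deterministic for a given model, parameter set and seed (the seed only
    matters when ``recluster_per_wave`` rotates the sweep between waves).
    """
    params = params or SimulationParams()
    if model.wholesalers is None:
        raise ConfigError("model has no wholesaler labels; "
                          "run assign_pharmacies_to_wholesalers first")
    if model.gp_pharmacy is None:
        attach_gps_to_pharmacies(model)

    hubs = model.all_hubs
    n_receipt = len(model.receipt_hubs)
    min_load = (params.hub_min_load if params.hub_min_load is not None
                else math.ceil(params.min_cluster / 2))
    groups = _group_pharmacies(model, min_load=min_load)

    # Two-way star leg from each hub to its nearest receipt hub (zero when
    # the depot is itself a receipt hub).
    d_to_receipt, _ = cKDTree(model.receipt_hubs).query(hubs)
    network_leg = 2.0 * d_to_receipt * params.road_factor

    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 7]))
    waves = params.deliveries_per_month
    one_wave = not params.recluster_per_wave

    tours_rows = []
    net_km = net_min = 0.0
    cl_km = cl_min = 0.0
    rep_sum = 0.0
    n_net = n_cl = 0
    cluster_sizes: list[int] = []

    for wave in range(min(waves, 1) if one_wave else waves):
        offset = 0.0 if one_wave else float(rng.uniform(0, 2 * np.pi))
        active_hub_by_w: dict[int, set[int]] = {}
        for (w, h), members in groups.items():
            pts = model.pharmacies[members]
            if offset:
                # rotate the sweep start by re-ordering angles with an offset
                hub_xy = hubs[h]
                ang = np.arctan2(pts[:, 1] - hub_xy[1], pts[:, 0] - hub_xy[0])
                rot = np.argsort((ang - offset) % (2 * np.pi), kind="stable")
                pts = pts[rot]
                members = members[rot]
            arcs = make_clusters(hubs[h], pts, params.min_cluster, params.max_cluster)
            active_hub_by_w.setdefault(w, set()).add(h)
            for arc in arcs:
                tour = tsp_tour(hubs[h], pts[arc], params.tsp_method,
                                params.road_factor, params.cluster_speed,
                                params.pharmacy_stop_min, params.hub_loading_min)
                cl_km += tour.road_distance
                cl_min += tour.duration
                n_cl += 1
                cluster_sizes.append(len(arc))
                rep_sum += network_leg[h] + tour.road_distance / 2.0
                tours_rows.append(("cluster", w, int(h), len(arc),
                                   tour.road_distance, tour.duration))
        for w, hset in sorted(active_hub_by_w.items()):
            for h in sorted(hset):
                if h < n_receipt:
                    continue  # depot is a receipt hub; no network leg
                leg = float(network_leg[h])
                minutes = leg / params.network_speed * 60.0 + params.intermediary_reload_min
                net_km += leg
                net_min += minutes
                n_net += 1
                tours_rows.append(("network", w, int(h), 1, leg, minutes))

    # GP tier: one tour per pharmacy per wave; independent of clustering.
    gp_km = gp_min = 0.0
    n_gp_tours = 0
    gp_groups: dict[int, list[int]] = {}
    for g, p in enumerate(model.gp_pharmacy):
        gp_groups.setdefault(int(p), []).append(g)
    for p, gs in sorted(gp_groups.items()):
        tour = tsp_tour(model.pharmacies[p], model.gp_practices[gs], params.tsp_method,
                        params.road_factor, params.gp_speed,
                        params.gp_stop_min, params.pharmacy_prep_min)
        gp_km += tour.road_distance
        gp_min += tour.duration
        n_gp_tours += 1
        tours_rows.append(("gp", -1, p, len(gs), tour.road_distance, tour.duration))

    # Scale the single computed wave to the full month.
    wave_mult = waves if one_wave else 1
    if waves == 0:
        wave_mult = 0
    net_km *= wave_mult; net_min *= wave_mult; n_net *= wave_mult
    cl_km *= wave_mult; cl_min *= wave_mult
    rep_sum *= wave_mult
    n_cl_total = n_cl * wave_mult
    gp_mult = waves  # GP tours repeat every wave regardless of clustering mode
    gp_km *= gp_mult; gp_min *= gp_mult; n_gp_tours *= gp_mult

    n_month_clusters = n_cl if one_wave else int(round(n_cl / max(waves, 1)))
    mean_size = float(np.mean(cluster_sizes)) if cluster_sizes else 0.0
    representative = rep_sum / n_cl_total if n_cl_total else 0.0
    representative *= waves  # carried distance accumulates over the month's waves

    tours = pd.DataFrame(tours_rows,
                         columns=["tier", "wholesaler", "hub_or_pharmacy",
                                  "n_stops", "km", "minutes"])
    loading = params.vials_per_month * params.per_vial_mass_g / 1000.0
    return LastMileResult(
        network_km=net_km, cluster_km=cl_km, gp_km=gp_km,
        network_tours=n_net, cluster_tours=n_cl_total, gp_tours=n_gp_tours,
        network_min=net_min, cluster_min=cl_min, gp_min=gp_min,
        deliveries_per_month=waves,
        vials_per_month=params.vials_per_month,
        loading_mass_kg=loading,
        representative_km=representative,
        n_clusters=n_month_clusters,
        mean_cluster_size=mean_size,
        seed=seed,
        tours=tours,
    )


def lastmile_emissions(
    result: LastMileResult,
    mode: Literal["most_likely", "worst_case"] = "most_likely",
    per_tkm: float = 0.1,
    per_vehicle_km: float = 0.3,
) -> tuple[float, float]:
    """Monthly emissions (kg CO2e) and per-vial value under one accounting mode.

    ``most_likely`` charges only the vaccine's freight units at ``per_tkm``
    (additional load on existing tours); ``worst_case`` charges every driven
    kilometre of dedicated tours at ``per_vehicle_km``.
    """
    if per_tkm <= 0 or per_vehicle_km <= 0:
        raise DomainError("emission factors must be > 0")
    if result.vials_per_month <= 0:
        raise DomainError("vials_per_month must be > 0 for a per-vial value")
    if mode == "most_likely":
        total = result.freight_tkm * per_tkm
    elif mode == "worst_case":
        total = result.total_km * per_vehicle_km
    else:
        raise DomainError(f"unknown mode {mode!r}")
    return total, total / result.vials_per_month
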