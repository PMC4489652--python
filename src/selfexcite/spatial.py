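"""Temporal/geospatial clustering tests.

If incidents incited similar incidents *nearby* (local imitation rather
than, say, nationwide media exposure), pairs of events close in time
would also tend to be close in space.  This module tests that with the
Mantel permutation test: the correlation between the pairwise
inter-event time matrix and the pairwise great-circle distance matrix,
with significance from jointly permuting the event labels of one matrix.
The one-sided alternative (positive association = clustering) is the
default.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .event_io import EventCatalog

__all__ = [
    "EARTH_RADIUS_KM",
    "PairwiseDistances",
    "haversine_km",
    "pairwise_distances",
    "mantel_test",
    "time_distance_correlation",
    "MantelResult",
]

EARTH_RADIUS_KM = 6371.0


def haversine_km(lat1, lon1, lat2, lon2):
    """Great-circle distance in km (spherical Earth, radius 6371 km)."""
    lat1, lon1, lat2, lon2 = (np.asarray(x, dtype=float) for x in (lat1, lon1, lat2, lon2))
    for lat in (lat1, lat2):
        if np.any(np.abs(lat) > 90.0):
            raise ValueError("latitude outside [-90, 90]")
    for lon in (lon1, lon2):
        if np.any(np.abs(lon) > 180.0):
            raise ValueError("longitude outside [-180, 180]")
    p1, p2 = np.radians(lat1), np.radians(lat2)
    dphi = p2 - p1
    dlam = np.radians(lon2) - np.radians(lon1)
    a = np.sin(dphi / 2.0) ** 2 + np.cos(p1) * np.cos(p2) * np.sin(dlam / 2.0) ** 2
    return 2.0 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(a, 0.0, 1.0)))


@dataclass(frozen=True)
class PairwiseDistances:
    """Symmetric pairwise |time difference| (days) and distance (km)."""

    temporal: np.ndarray
    spatial: np.ndarray
    n_events: int
    n_dropped_missing_coords: int = 0

    def __post_init__(self) -> None:
        t, s = np.asarray(self.temporal, float), np.asarray(self.spatial, float)
        if t.shape != s.shape or t.ndim != 2 or t.shape[0] != t.shape[1]:
            raise ValueError("matrices must be square with equal shapes")
        for m in (t, s):
            if not np.allclose(m, m.T) or not np.allclose(np.diag(m), 0.0):
                raise ValueError("matrices must be symmetric with zero diagonal")
        object.__setattr__(self, "temporal", t)
        object.__setattr__(self, "spatial", s)


def pairwise_distances(catalog: EventCatalog) -> PairwiseDistances:
    """Build the pairwise matrices from a catalog.

    Records with missing coordinates are dropped (kept for temporal-only
    analyses elsewhere); the number dropped is reported.
    """
    df = catalog.data
    has_coords = df["latitude"].notna() & df["longitude"].notna()
    dropped = int((~has_coords).sum())
    df = df[has_coords]
    days = (df["date"] - df["date"].min()).dt.days.to_numpy(dtype=float)
    lat = df["latitude"].to_numpy(dtype=float)
    lon = df["longitude"].to_numpy(dtype=float)
    temporal = np.abs(days[:, None] - days[None, :])
    spatial = haversine_km(lat[:, None], lon[:, None], lat[None, :], lon[None, :])
    np.fill_diagonal(spatial, 0.0)
    return PairwiseDistances(temporal, spatial, n_events=len(df), n_dropped_missing_coords=dropped)


@dataclass(frozen=True)
class MantelResult:
    statistic: float
    p_value: float
    n_events: int
    n_perm: int
    method: str
    alternative: str
    n_dropped_missing_coords: int = 0

    def as_dict(self) -> dict:
        return {
            "statistic": self.statistic,
            "p_value": self.p_value,
            "n_events": self.n_events,
            "n_perm": self.n_perm,
            "method": self.method,
            "alternative": self.alternative,
            "n_dropped_missing_coords": self.n_dropped_missing_coords,
        }


def _condensed(m: np.ndarray, iu: tuple[np.ndarray, np.ndarray]) -> np.ndarray:
    return m[iu]


def _rank_matrix(m: np.ndarray, iu) -> np.ndarray:
    """Replace off-diagonal entries by their ranks (Spearman trick:
    ranks are label-permutation equivariant, so rank once, then Pearson)."""
    out = np.zeros_like(m)
    r = stats.rankdata(m[iu])
    out[iu] = r
    out.T[iu] = r
    return out


def mantel_test(
    dists: PairwiseDistances,
    n_perm: int = 9999,
    seed: int | None = 0,
    method: str = "pearson",
    alternative: str = "greater",
) -> MantelResult:
    """Mantel permutation test between the two pairwise matrices.

    The statistic is the Pearson (or Spearman) correlation over the
    off-diagonal pairs; the null distribution jointly permutes the
    row/column labels of the spatial matrix, which respects the
    dependence among pairs sharing an event.
    ``p = (1 + #{r* as extreme as r}) / (n_perm + 1)``.
    """
    if dists.n_events < 4:
        raise ValueError("Mantel test needs at least 4 events")
    n = dists.n_events
    iu = np.triu_indices(n, k=1)
    A, B = dists.temporal, dists.spatial
    if method == "spearman":
        A, B = _rank_matrix(A, iu), _rank_matrix(B, iu)
    elif method != "pearson":
        raise ValueError(f"unknown method {method!r}")

    a = _condensed(A, iu)
    b = _condensed(B, iu)
    if np.ptp(a) == 0.0 or np.ptp(b) == 0.0:
        raise ValueError("a distance matrix is constant; correlation undefined")
    a_c = a - a.mean()
    a_norm = np.sqrt(a_c @ a_c)

    def corr_with(mat_b: np.ndarray) -> float:
        v = mat_b[iu]
        v_c = v - v.mean()
        return float(a_c @ v_c / (a_norm * np.sqrt(v_c @ v_c)))

    r_obs = corr_with(B)
    rng = np.random.default_rng(seed)
    exceed = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        r_star = corr_with(B[np.ix_(perm, perm)])
        if alternative == "greater":
            exceed += r_star >= r_obs - 1e-12
        elif alternative == "two-sided":
            exceed += abs(r_star) >= abs(r_obs) - 1e-12
        else:
            raise ValueError(f"unknown alternative {alternative!r}")
    p = (1.0 + exceed) / (n_perm + 1.0)
    return MantelResult(
        statistic=r_obs,
        p_value=p,
        n_events=n,
        n_perm=n_perm,
        method=method,
        alternative=alternative,
        n_dropped_missing_coords=dists.n_dropped_missing_coords,
    )


def time_distance_correlation(
    catalog: EventCatalog,
    n_perm: int = 9999,
    seed: int | None = 0,
    method: str = "pearson",
    alternative: str = "greater",
) -> MantelResult:
    """Correlation between inter-event times and distances, over all
    unordered pairs, with Mantel permutation inference (the pairs are not
    independent, so an ordinary correlation p-value would be invalid)."""
    dists = pairwise_distances(catalog)
    return mantel_test(dists, n_perm=n_perm, seed=seed, method=method, alternative=alternative)
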