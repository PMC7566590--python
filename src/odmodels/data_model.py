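"""Domain containers and I/O for origin-destination flow data.

The central objects are

* :class:`SiteTable` — one row per site with the three count values used
  by every model: population ``P_i``, commuters departing ``O_i`` and
  commuters arriving ``I_i``, plus optional lat/lon coordinates;
* :class:`DistanceMatrix` — symmetric pairwise great-circle separations
  in kilometres, either computed from coordinates with
  :func:`haversine_distances` or loaded from a precomputed table;
* :class:`FlowMatrix` — observed integer flow counts over ordered site
  pairs ``i != j`` (the diagonal is undefined and stored as zero).

All matrices share the canonical site order, which is the row order of
the sites file.  File dialects are plain UTF-8 CSV with ``\\n`` line
endings so that a write/read round trip is exact.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .exceptions import ValidationError

logger = logging.getLogger(__name__)

#: IUGG mean Earth radius, km.  Used for all great-circle distances.
EARTH_RADIUS_KM = 6371.0088

SITE_COLUMNS = ["site_id", "lat", "lon", "population", "out_flow", "in_flow"]
FLOW_COLUMNS = ["origin", "dest", "flow"]
DIST_COLUMNS = ["site_a", "site_b", "km"]


@dataclass
class SiteTable:
    """Per-site data values in canonical (input file) order.

    Parameters
    ----------
    site_id
        Unique string labels.
    population, out_flow, in_flow
        Nonnegative integer counts ``P_i``, ``O_i``, ``I_i``.
    lat, lon
        Decimal-degree coordinates; either both present for every site
        or both ``None`` (in which case a distance matrix must be
        supplied externally).
    """

    site_id: np.ndarray
    population: np.ndarray
    out_flow: np.ndarray
    in_flow: np.ndarray
    lat: np.ndarray | None = None
    lon: np.ndarray | None = None
    _index: dict[str, int] = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        self.site_id = np.asarray(self.site_id, dtype=object)
        n = self.site_id.size
        if n == 0:
            raise ValidationError("site table is empty")
        ids = [str(s) for s in self.site_id]
        if len(set(ids)) != n:
            seen: set[str] = set()
            dup = next(s for s in ids if s in seen or seen.add(s))
            raise ValidationError(f"duplicate site_id {dup!r}")
        for name in ("population", "out_flow", "in_flow"):
            arr = np.asarray(getattr(self, name))
            if arr.shape != (n,):
                raise ValidationError(f"{name} must have one value per site")
            if not np.issubdtype(arr.dtype, np.integer):
                as_int = np.asarray(arr, dtype=float)
                if not np.all(np.isfinite(as_int)) or np.any(as_int != np.round(as_int)):
                    raise ValidationError(f"{name} must be integer-valued")
                arr = as_int.astype(np.int64)
            else:
                arr = arr.astype(np.int64)
            if np.any(arr < 0):
                raise ValidationError(f"{name} contains negative values")
            setattr(self, name, arr)
        if (self.lat is None) != (self.lon is None):
            raise ValidationError("lat and lon must be supplied together")
        if self.lat is not None:
            self.lat = np.asarray(self.lat, dtype=float)
            self.lon = np.asarray(self.lon, dtype=float)
            if self.lat.shape != (n,) or self.lon.shape != (n,):
                raise ValidationError("coordinate arrays must match site count")
            if np.any(~np.isfinite(self.lat)) or np.any(~np.isfinite(self.lon)):
                raise ValidationError("some sites are missing coordinates")
        self._index = {str(s): i for i, s in enumerate(self.site_id)}

    @property
    def n_sites(self) -> int:
        return self.site_id.size

    @property
    def has_coords(self) -> bool:
        return self.lat is not None

    def loc(self, site_id: str) -> int:
        """Position of *site_id* in canonical order."""
        try:
            return self._index[site_id]
        except KeyError:
            raise ValidationError(f"unknown site id {site_id!r}") from None

    def with_marginals(self, out_flow: np.ndarray, in_flow: np.ndarray) -> "SiteTable":
        """Copy of this table with ``O_i``/``I_i`` replaced."""
        return SiteTable(
            site_id=self.site_id.copy(),
            population=self.population.copy(),
            out_flow=np.asarray(out_flow),
            in_flow=np.asarray(in_flow),
            lat=None if self.lat is None else self.lat.copy(),
            lon=None if self.lon is None else self.lon.copy(),
        )

    def to_frame(self) -> pd.DataFrame:
        data = {"site_id": [str(s) for s in self.site_id]}
        if self.has_coords:
            data["lat"] = self.lat
            data["lon"] = self.lon
        data.update(
            population=self.population, out_flow=self.out_flow, in_flow=self.in_flow
        )
        return pd.DataFrame(data)

    def to_csv(self, path: str | Path) -> None:
        _write_csv(self.to_frame(), path)


@dataclass
class DistanceMatrix:
    """Symmetric nonnegative pairwise separations ``d_ij`` in km."""

    values: np.ndarray

    def __post_init__(self) -> None:
        d = np.asarray(self.values, dtype=float)
        if d.ndim != 2 or d.shape[0] != d.shape[1]:
            raise ValidationError("distance matrix must be square")
        if not np.all(np.isfinite(d)):
            raise ValidationError("distance matrix contains non-finite values")
        if np.any(d < 0):
            raise ValidationError("distances must be nonnegative")
        if not np.allclose(d, d.T):
            raise ValidationError("distance matrix must be symmetric")
        if np.any(np.diag(d) != 0):
            raise ValidationError("distance matrix diagonal must be zero")
        self.values = d

    @property
    def n_sites(self) -> int:
        return self.values.shape[0]

    def require_positive_offdiagonal(self) -> None:
        """Raise if any inter-site distance is zero.

        Power-law deterrence is singular at ``d = 0``, so callers that
        use it must check this first.
        """
        off = self.values[~np.eye(self.n_sites, dtype=bool)]
        if np.any(off <= 0):
            raise ValidationError(
                "zero inter-site distance: power-law deterrence is undefined"
            )


@dataclass
class FlowMatrix:
    """Observed integer counts ``F_ij`` over ordered pairs ``i != j``.

    Stored dense with a zero diagonal; the diagonal carries no meaning
    (the models only predict flows between distinct sites).
    """

    values: np.ndarray

    def __post_init__(self) -> None:
        f = np.asarray(self.values)
        if f.ndim != 2 or f.shape[0] != f.shape[1]:
            raise ValidationError("flow matrix must be square")
        if not np.issubdtype(f.dtype, np.integer):
            ff = np.asarray(f, dtype=float)
            if not np.all(np.isfinite(ff)) or np.any(ff != np.round(ff)):
                raise ValidationError("flows must be integer-valued")
            f = ff.astype(np.int64)
        else:
            f = f.astype(np.int64)
        if np.any(f < 0):
            raise ValidationError("flows must be nonnegative")
        f = f.copy()
        np.fill_diagonal(f, 0)
        self.values = f

    @property
    def n_sites(self) -> int:
        return self.values.shape[0]

    @property
    def total(self) -> int:
        return int(self.values.sum())

    def to_edge_frame(self, sites: SiteTable) -> pd.DataFrame:
        """Edge list (origin, dest, flow) of the nonzero entries."""
        i, j = np.nonzero(self.values)
        return pd.DataFrame(
            {
                "origin": [str(s) for s in sites.site_id[i]],
                "dest": [str(s) for s in sites.site_id[j]],
                "flow": self.values[i, j],
            }
        )

    def to_csv(self, path: str | Path, sites: SiteTable) -> None:
        _write_csv(self.to_edge_frame(sites), path)


def _write_csv(frame: pd.DataFrame, path: str | Path) -> None:
    # fixed dialect: UTF-8, \n endings, no index -> bit-exact round trips
    frame.to_csv(path, index=False, lineterminator="\n", encoding="utf-8")


def _read_csv(path: str | Path, required: list[str], what: str) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise ValidationError(f"{what} file not found: {path}")
    frame = pd.read_csv(path)
    missing = [c for c in required if c not in frame.columns]
    if missing:
        raise ValidationError(f"{what} file {path} missing columns {missing}")
    return frame


def load_sites(path: str | Path) -> SiteTable:
    """Read a sites CSV (``site_id,lat,lon,population,out_flow,in_flow``).

    The lat/lon columns are optional but must be present together and
    populated for every site.  Row order becomes the canonical site
    order shared by every matrix.
    """
    frame = _read_csv(path, ["site_id", "population", "out_flow", "in_flow"], "sites")
    has_lat, has_lon = "lat" in frame.columns, "lon" in frame.columns
    if has_lat != has_lon:
        raise ValidationError("sites file must have both lat and lon or neither")
    lat = lon = None
    if has_lat:
        if frame["lat"].isna().any() or frame["lon"].isna().any():
            raise ValidationError("some sites are missing coordinates")
        lat, lon = frame["lat"].to_numpy(float), frame["lon"].to_numpy(float)
    for col in ("population", "out_flow", "in_flow"):
        if frame[col].isna().any():
            raise ValidationError(f"sites file has missing {col} values")
    return SiteTable(
        site_id=frame["site_id"].astype(str).to_numpy(object),
        population=frame["population"].to_numpy(),
        out_flow=frame["out_flow"].to_numpy(),
        in_flow=frame["in_flow"].to_numpy(),
        lat=lat,
        lon=lon,
    )


def load_flows(path: str | Path, sites: SiteTable) -> FlowMatrix:
    """Read an edge-list flows CSV (``origin,dest,flow``).

    Duplicate edges are summed; self-flows are dropped with a warning
    (the models are defined for ``i != j`` only); pairs not listed are
    zero.
    """
    frame = _read_csv(path, FLOW_COLUMNS, "flows")
    return flows_from_edges(
        frame["origin"].astype(str),
        frame["dest"].astype(str),
        frame["flow"],
        sites,
    )


def flows_from_edges(origin, dest, flow, sites: SiteTable) -> FlowMatrix:
    """Aggregate an edge list into a :class:`FlowMatrix`."""
    flow = np.asarray(flow)
    if flow.size == 0:  # an all-zero flow matrix round-trips as an empty edge list
        return FlowMatrix(np.zeros((sites.n_sites, sites.n_sites), dtype=np.int64))
    if flow.dtype == object or not np.issubdtype(flow.dtype, np.number):
        raise ValidationError("flow values must be numeric")
    ff = np.asarray(flow, dtype=float)
    if not np.all(np.isfinite(ff)) or np.any(ff != np.round(ff)):
        raise ValidationError("flow values must be integers")
    if np.any(ff < 0):
        raise ValidationError("flow values must be nonnegative")
    counts = ff.astype(np.int64)
    oi = np.array([sites.loc(s) for s in origin], dtype=np.intp)
    di = np.array([sites.loc(s) for s in dest], dtype=np.intp)
    self_mask = oi == di
    if np.any(self_mask):
        dropped = int(counts[self_mask].sum())
        msg = (
            f"dropped {int(self_mask.sum())} self-flow edge(s) "
            f"totalling {dropped} trips (models predict i != j only)"
        )
        logger.warning(msg)
        warnings.warn(msg, stacklevel=2)
        oi, di, counts = oi[~self_mask], di[~self_mask], counts[~self_mask]
    n = sites.n_sites
    values = np.zeros((n, n), dtype=np.int64)
    np.add.at(values, (oi, di), counts)
    return FlowMatrix(values)


def haversine_distances(sites: SiteTable) -> DistanceMatrix:
    """Great-circle distance matrix from site coordinates.

    Uses the haversine formula on a sphere of radius
    :data:`EARTH_RADIUS_KM` (6371.0088 km, the IUGG mean radius).
    """
    if not sites.has_coords:
        raise ValidationError("sites have no coordinates; supply a distance file")
    lat = np.radians(sites.lat)
    lon = np.radians(sites.lon)
    dlat = 0.5 * (lat[:, None] - lat[None, :])
    dlon = 0.5 * (lon[:, None] - lon[None, :])
    a = np.sin(dlat) ** 2 + np.cos(lat)[:, None] * np.cos(lat)[None, :] * np.sin(dlon) ** 2
    a = np.clip(a, 0.0, 1.0)
    d = 2.0 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(a))
    np.fill_diagonal(d, 0.0)
    d = 0.5 * (d + d.T)  # kill rounding asymmetry
    return DistanceMatrix(d)


def load_distances(path: str | Path, sites: SiteTable) -> DistanceMatrix:
    """Read a long-format distance CSV (``site_a,site_b,km``).

    Each unordered pair may appear once (it is mirrored) or twice with
    equal values; conflicting duplicates and missing pairs are errors.
    """
    frame = _read_csv(path, DIST_COLUMNS, "distances")
    n = sites.n_sites
    d = np.full((n, n), np.nan)
    np.fill_diagonal(d, 0.0)
    for a, b, km in zip(
        frame["site_a"].astype(str), frame["site_b"].astype(str), frame["km"]
    ):
        i, j = sites.loc(a), sites.loc(b)
        km = float(km)
        if not np.isfinite(km) or km < 0:
            raise ValidationError(f"invalid distance {km} for pair ({a}, {b})")
        for ii, jj in ((i, j), (j, i)):
            if not np.isnan(d[ii, jj]) and not np.isclose(d[ii, jj], km):
                raise ValidationError(
                    f"inconsistent distances for pair ({a}, {b}): "
                    f"{d[ii, jj]} vs {km}"
                )
        d[i, j] = d[j, i] = km
    if np.isnan(d).any():
        i, j = np.argwhere(np.isnan(d))[0]
        raise ValidationError(
            f"distance file incomplete: missing pair "
            f"({sites.site_id[i]}, {sites.site_id[j]})"
        )
    return DistanceMatrix(d)


def write_distances(path: str | Path, D: DistanceMatrix, sites: SiteTable) -> None:
    """Write the upper triangle of *D* in the long-format dialect."""
    i, j = np.triu_indices(D.n_sites, k=1)
    frame = pd.DataFrame(
        {
            "site_a": [str(s) for s in sites.site_id[i]],
            "site_b": [str(s) for s in sites.site_id[j]],
            "km": D.values[i, j],
        }
    )
    _write_csv(frame, path)


def derive_marginals(flows: FlowMatrix) -> tuple[np.ndarray, np.ndarray]:
    """Row/column sums of the flow matrix.

    Returns ``(O, I)`` with ``O_i = sum_{j!=i} F_ij`` (departures) and
    ``I_i = sum_{j!=i} F_ji`` (arrivals); both sum to the total flow.
    """
    out_flow = flows.values.sum(axis=1)
    in_flow = flows.values.sum(axis=0)
    return out_flow, in_flow
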