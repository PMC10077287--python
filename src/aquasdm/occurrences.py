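"""Presence-only occurrence records: ingest, clean, and spatially thin.

The cleaning stage validates coordinates, removes exact duplicates and
keeps only marine records (realm flag, else an ocean-mask lookup).
Thinning then subsamples so no two retained records lie within the
minimum distance, using the randomized maximal-degree-deletion
heuristic of the spThin package: many independent attempts, keep the
largest retained set.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .grids import GridSpec

log = logging.getLogger(__name__)

EARTH_RADIUS_KM = 6371.0

#: duplicate definition: coordinates equal after rounding to 6 dp (~0.1 m)
_DEDUP_DECIMALS = 6

MARINE_REALMS = {"marine"}
NONMARINE_REALMS = {"freshwater", "terrestrial"}


@dataclass
class OccurrenceSet:
    """Cleaned (and possibly thinned) presences for one species.

    ``records`` holds at least ``species``, ``lon``, ``lat`` columns;
    ``provenance`` counts records surviving each cleaning stage.
    """

    records: pd.DataFrame
    provenance: dict[str, int] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.records)

    @property
    def lons(self) -> np.ndarray:
        return self.records["lon"].to_numpy(dtype=float)

    @property
    def lats(self) -> np.ndarray:
        return self.records["lat"].to_numpy(dtype=float)


def read_occurrences_csv(path: str | Path) -> pd.DataFrame:
    """Read a `species,lon,lat[,realm]` CSV (header required, UTF-8)."""
    df = pd.read_csv(path, encoding="utf-8")
    missing = {"species", "lon", "lat"} - set(df.columns)
    if missing:
        raise ValueError(f"occurrence CSV lacks columns: {sorted(missing)}")
    return df


def write_occurrences_csv(occ: OccurrenceSet, path: str | Path) -> None:
    """Write records as CSV with the provenance counts as sidecar JSON."""
    path = Path(path)
    occ.records.to_csv(path, index=False, encoding="utf-8")
    sidecar = path.with_suffix(path.suffix + ".provenance.json")
    sidecar.write_text(json.dumps(occ.provenance, indent=2))


def great_circle_km(a: tuple[float, float], b: tuple[float, float]) -> float:
    """Haversine distance in km between (lon, lat) pairs, R = 6371 km."""
    lon1, lat1 = np.radians(a)
    lon2, lat2 = np.radians(b)
    s = (
        np.sin((lat2 - lat1) / 2.0) ** 2
        + np.cos(lat1) * np.cos(lat2) * np.sin((lon2 - lon1) / 2.0) ** 2
    )
    return float(2.0 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(s, 0.0, 1.0))))


def pairwise_distances_km(lons: np.ndarray, lats: np.ndarray) -> np.ndarray:
    """Symmetric haversine distance matrix (km)."""
    lam = np.radians(np.asarray(lons, dtype=float))
    phi = np.radians(np.asarray(lats, dtype=float))
    dphi = phi[:, None] - phi[None, :]
    dlam = lam[:, None] - lam[None, :]
    s = np.sin(dphi / 2.0) ** 2 + np.cos(phi)[:, None] * np.cos(phi)[None, :] * np.sin(dlam / 2.0) ** 2
    return 2.0 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(s, 0.0, 1.0)))


def clean_occurrences(
    records: pd.DataFrame,
    ocean_mask: np.ndarray | None = None,
    grid: GridSpec | None = None,
) -> OccurrenceSet:
    """Validate, deduplicate and marine-filter occurrence records.

    Stages, each recorded in provenance:

    raw -> valid (finite, in-range coordinates; non-empty species)
        -> deduplicated (exact lon/lat equality after rounding to 6 dp,
           first record kept)
        -> marine (realm flag wins where present; otherwise a
           nearest-cell lookup in ``ocean_mask``; records outside the
           mask extent are dropped and counted, not an error)

    Raises on empty input.
    """
    if len(records) == 0:
        raise ValueError("no records")
    df = records.copy()
    prov = {"raw": len(df)}

    lon = pd.to_numeric(df["lon"], errors="coerce")
    lat = pd.to_numeric(df["lat"], errors="coerce")
    valid = (
        np.isfinite(lon)
        & np.isfinite(lat)
        & (lon >= -180.0)
        & (lon < 180.0)
        & (lat >= -90.0)
        & (lat <= 90.0)
        & df["species"].astype(str).str.len().gt(0)
    )
    df = df.loc[valid].copy()
    df["lon"] = lon[valid]
    df["lat"] = lat[valid]
    prov["valid"] = len(df)
    prov["invalid"] = prov["raw"] - prov["valid"]

    key = list(zip(df["lon"].round(_DEDUP_DECIMALS), df["lat"].round(_DEDUP_DECIMALS)))
    df = df.loc[~pd.Index(key).duplicated(keep="first")].copy()
    prov["deduplicated"] = len(df)

    realm = df["realm"].astype(str).str.lower() if "realm" in df.columns else pd.Series("", index=df.index)
    keep = pd.Series(False, index=df.index)
    keep[realm.isin(MARINE_REALMS)] = True
    undecided = ~realm.isin(MARINE_REALMS) & ~realm.isin(NONMARINE_REALMS)
    n_outside = 0
    if undecided.any():
        if ocean_mask is None or grid is None:
            raise ValueError("ocean mask and grid required when realm flags are absent")
        sub = df.loc[undecided]
        row, col, inside = grid.index_of(sub["lon"].to_numpy(), sub["lat"].to_numpy())
        marine = np.zeros(len(sub), dtype=bool)
        marine[inside] = np.asarray(ocean_mask, dtype=bool)[row[inside], col[inside]]
        n_outside = int((~inside).sum())
        keep.loc[sub.index] = marine
    df = df.loc[keep].copy()
    prov["marine"] = len(df)
    prov["outside_mask"] = n_outside
    if n_outside:
        log.info("dropped %d records outside the ocean-mask extent", n_outside)

    return OccurrenceSet(records=df.reset_index(drop=True), provenance=prov)


def _thin_once(dist: np.ndarray, min_dist_km: float, rng: np.random.Generator) -> np.ndarray:
    """One spThin pass: delete a max-degree record until no close pairs.

    Returns the retained indices (sorted).  Ties in degree are broken
    uniformly at random.
    """
    n = dist.shape[0]
    adj = (dist < min_dist_km).astype(np.int64)
    np.fill_diagonal(adj, 0)
    alive = np.ones(n, dtype=bool)
    degree = adj.sum(axis=1)
    while True:
        dmax = degree[alive].max() if alive.any() else 0
        if dmax == 0:
            break
        cands = np.flatnonzero(alive & (degree == dmax))
        victim = int(rng.choice(cands))
        alive[victim] = False
        degree -= adj[victim]
        degree[victim] = 0
        adj[victim, :] = 0
        adj[:, victim] = 0
    return np.flatnonzero(alive)


def thin_occurrences(
    occ: OccurrenceSet,
    min_dist_km: float = 10.0,
    iterations: int = 100,
    seed: int = 0,
) -> OccurrenceSet:
    """Spatially thin so all pairwise distances are >= ``min_dist_km``.

    Runs ``iterations`` independent randomized maximal-degree-deletion
    passes and returns the largest retained set (first found on ties),
    mirroring spThin's "maximum number of records" objective with the
    published defaults of 10 km and 100 iterations.
    """
    if min_dist_km <= 0:
        raise ValueError("thinning distance must be positive")
    if iterations <= 0:
        raise ValueError("iterations must be positive")
    n = len(occ)
    if n <= 1:
        out = OccurrenceSet(occ.records.copy(), dict(occ.provenance))
        out.provenance["thinned"] = n
        return out

    dist = pairwise_distances_km(occ.lons, occ.lats)
    rng = np.random.default_rng(seed)
    best: np.ndarray | None = None
    if not (dist[np.triu_indices(n, k=1)] < min_dist_km).any():
        best = np.arange(n)  # empty proximity graph: nothing to do
    else:
        for _ in range(iterations):
            kept = _thin_once(dist, min_dist_km, rng)
            if best is None or kept.size > best.size:
                best = kept
    sub = dist[np.ix_(best, best)]
    off_diag = sub[np.triu_indices(best.size, k=1)]
    assert off_diag.size == 0 or off_diag.min() >= min_dist_km, "thinning violated the minimum distance"
    out = OccurrenceSet(occ.records.iloc[best].reset_index(drop=True), dict(occ.provenance))
    out.provenance["thinned"] = int(best.size)
    return out
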