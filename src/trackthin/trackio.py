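"""Reading, validation, projection and leg decomposition of GPS tracks.

A *track* is an ordered sequence of timestamped GPS fixes recorded while
following one animal.  Tracks arrive in geographic coordinates (WGS84
lon/lat) from GPX files or delimited tables; distance computations require
a local metric frame, obtained by an equirectangular projection about the
track centroid.  A track is dropped from analysis when any gap between
consecutive fixes exceeds a threshold (60 s by default), mirroring the
field protocol's exclusion of interrupted follows.
"""

from __future__ import annotations

import math
import warnings
import xml.etree.ElementTree as ET
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd

EARTH_RADIUS_M = 6_371_000.0

GEOGRAPHIC = "geographic"
LOCAL_METRIC = "local-metric"


class Fix(NamedTuple):
    """One GPS position record: epoch timestamp (UTC seconds) and position.

    In the geographic frame ``x`` is longitude and ``y`` latitude, in
    degrees WGS84; in the local metric frame both are metres.
    """

    timestamp: float
    x: float
    y: float


@dataclass(frozen=True)
class Track:
    """Ordered GPS fixes for one follow.

    Coordinates are stored as arrays; ``frame`` tags whether they are
    degrees (``"geographic"``) or metres in a local plane
    (``"local-metric"``).  Timestamps are real seconds (interpolation
    produces fractional seconds) and must be strictly increasing.
    """

    track_id: str
    subject_id: str
    t: np.ndarray  # seconds since epoch, float
    x: np.ndarray  # lon (deg) or easting (m)
    y: np.ndarray  # lat (deg) or northing (m)
    frame: str = GEOGRAPHIC

    def __post_init__(self) -> None:
        t = np.asarray(self.t, dtype=float)
        x = np.asarray(self.x, dtype=float)
        y = np.asarray(self.y, dtype=float)
        object.__setattr__(self, "t", t)
        object.__setattr__(self, "x", x)
        object.__setattr__(self, "y", y)
        if not (t.shape == x.shape == y.shape) or t.ndim != 1:
            raise ValueError("t, x, y must be 1-D arrays of equal length")
        if t.size < 1:
            raise ValueError(f"track {self.track_id!r}: needs at least one fix")
        if not np.all(np.isfinite(t)):
            raise ValueError(f"track {self.track_id!r}: non-finite timestamp")
        if np.any(np.diff(t) <= 0):
            i = int(np.argmax(np.diff(t) <= 0))
            raise ValueError(
                f"track {self.track_id!r}: timestamps not strictly increasing "
                f"at fix {i + 2}"
            )
        if self.frame == GEOGRAPHIC:
            if np.any(np.abs(y) > 90) or np.any(np.abs(x) > 180):
                raise ValueError(f"track {self.track_id!r}: lon/lat out of range")
        elif self.frame != LOCAL_METRIC:
            raise ValueError(f"unknown frame {self.frame!r}")

    @property
    def n_fixes(self) -> int:
        return int(self.t.size)

    @property
    def duration_s(self) -> float:
        return float(self.t[-1] - self.t[0])

    @property
    def fixes(self) -> list[Fix]:
        return [Fix(float(t), float(x), float(y)) for t, x, y in zip(self.t, self.x, self.y)]


class Leg(NamedTuple):
    """Segment between two consecutive fixes: duration (s), displacement (m)."""

    dt: float
    dist: float


@dataclass(frozen=True)
class GapFilterReport:
    """Partition of a track set by the maximum-gap exclusion rule."""

    retained: list[str]
    excluded: list[str]
    max_gap_s: float


# ---------------------------------------------------------------------------
# GPX


def _localname(tag: str) -> str:
    return tag.rsplit("}", 1)[-1]


def _parse_gpx_time(text: str) -> float:
    ts = pd.Timestamp(text)
    if ts.tzinfo is None:
        ts = ts.tz_localize("UTC")
    return float(ts.timestamp())


def read_gpx(path: str | Path) -> list[Track]:
    """Read a GPX 1.0/1.1 file into one :class:`Track` per ``<trk>``.

    Segments of a track are concatenated in time order.  Every track point
    must carry a ``<time>`` element; a point without one rejects the file
    with a diagnostic naming the first offending point.  Tracks with
    non-monotone timestamps are rejected.
    """
    path = Path(path)
    root = ET.parse(path).getroot()
    tracks: list[Track] = []
    trk_idx = 0
    for trk in root.iter():
        if _localname(trk.tag) != "trk":
            continue
        trk_idx += 1
        name = None
        pts: list[tuple[float, float, float]] = []
        pt_idx = 0
        for el in trk.iter():
            ln = _localname(el.tag)
            if ln == "name" and name is None:
                name = (el.text or "").strip() or None
            elif ln == "trkpt":
                pt_idx += 1
                time_el = next(
                    (c for c in el if _localname(c.tag) == "time"), None
                )
                if time_el is None or not (time_el.text or "").strip():
                    raise ValueError(
                        f"{path.name}: track {trk_idx}, point {pt_idx} has no "
                        f"<time> element"
                    )
                pts.append(
                    (
                        _parse_gpx_time(time_el.text.strip()),
                        float(el.attrib["lon"]),
                        float(el.attrib["lat"]),
                    )
                )
        if not pts:
            continue
        pts.sort(key=lambda p: p[0])
        t, lon, lat = (np.array(c) for c in zip(*pts))
        track_id = name or f"{path.stem}-{trk_idx}"
        tracks.append(Track(track_id, track_id, t, lon, lat, GEOGRAPHIC))
    return tracks


# ---------------------------------------------------------------------------
# Delimited tables

DEFAULT_COLUMNS = {
    "track_id": "track_id",
    "subject_id": "subject_id",
    "timestamp": "timestamp",
    "lon": "lon",
    "lat": "lat",
}


def _parse_timestamps(col: pd.Series) -> np.ndarray:
    if pd.api.types.is_numeric_dtype(col):
        return col.to_numpy(dtype=float)
    out = np.empty(len(col), dtype=float)
    for i, (row_label, v) in enumerate(col.items()):
        try:
            ts = pd.Timestamp(v)
            if ts.tzinfo is None:
                ts = ts.tz_localize("UTC")
            out[i] = ts.timestamp()
        except (ValueError, TypeError) as exc:
            raise ValueError(
                f"unparsable timestamp {v!r} at data row {row_label}"
            ) from exc
    return out


def read_track_table(
    path: str | Path, column_map: Mapping[str, str] | None = None
) -> list[Track]:
    """Read tracks from a delimited table (CSV by default).

    ``column_map`` maps the roles ``track_id``, ``timestamp``, ``lon``,
    ``lat`` (and optionally ``subject_id``) to column names in the file.
    Rows are grouped by track id and sorted by timestamp; duplicate
    timestamps within a track are an error.
    """
    cmap = dict(DEFAULT_COLUMNS)
    if column_map:
        unknown = set(column_map) - set(DEFAULT_COLUMNS)
        if unknown:
            raise ValueError(f"unknown column roles in column_map: {sorted(unknown)}")
        cmap.update(column_map)
    df = pd.read_csv(path, comment="#")
    required = ["track_id", "timestamp", "lon", "lat"]
    missing = [cmap[k] for k in required if cmap[k] not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    has_subject = cmap["subject_id"] in df.columns
    df = df.copy()
    df["_t"] = _parse_timestamps(df[cmap["timestamp"]])
    tracks = []
    for tid, grp in df.groupby(cmap["track_id"], sort=True):
        grp = grp.sort_values("_t", kind="mergesort")
        tvals = grp["_t"].to_numpy()
        if np.any(np.diff(tvals) == 0):
            raise ValueError(f"track {tid!r}: duplicated timestamp")
        subject = str(grp[cmap["subject_id"]].iloc[0]) if has_subject else str(tid)
        tracks.append(
            Track(
                str(tid),
                subject,
                tvals,
                grp[cmap["lon"]].to_numpy(dtype=float),
                grp[cmap["lat"]].to_numpy(dtype=float),
                GEOGRAPHIC,
            )
        )
    return tracks


def write_track_table(tracks: Sequence[Track], path: str | Path) -> None:
    """Write geographic tracks to the canonical CSV (ISO-8601 UTC times)."""
    rows = []
    for tr in tracks:
        if tr.frame != GEOGRAPHIC:
            raise ValueError(f"track {tr.track_id!r}: only geographic tracks are written")
        for t, lon, lat in zip(tr.t, tr.x, tr.y):
            rows.append(
                {
                    "track_id": tr.track_id,
                    "subject_id": tr.subject_id,
                    "timestamp": pd.Timestamp(t, unit="s", tz="UTC").isoformat(),
                    "lon": lon,
                    "lat": lat,
                }
            )
    pd.DataFrame(rows).to_csv(path, index=False, float_format="%.8f")


# ---------------------------------------------------------------------------
# Projection and legs


def project_local(track: Track) -> Track:
    """Project a geographic track to a local metric plane.

    Equirectangular about the track centroid (lon0, lat0):
    ``x = R (lon - lon0) cos(lat0) pi/180``, ``y = R (lat - lat0) pi/180``
    with R = 6 371 000 m.  Adequate for tracks spanning a few kilometres;
    a track spanning more than 1 degree of latitude triggers a warning.
    """
    if track.frame != GEOGRAPHIC:
        raise ValueError(f"track {track.track_id!r} is already in a metric frame")
    lat_span = float(track.y.max() - track.y.min())
    if lat_span > 1.0:
        warnings.warn(
            f"track {track.track_id!r} spans {lat_span:.2f} deg latitude; "
            "equirectangular projection error grows with extent",
            stacklevel=2,
        )
    lon0 = float(track.x.mean())
    lat0 = float(track.y.mean())
    k = EARTH_RADIUS_M * math.pi / 180.0
    x = k * (track.x - lon0) * math.cos(math.radians(lat0))
    y = k * (track.y - lat0)
    return replace(track, x=x, y=y, frame=LOCAL_METRIC)


def compute_legs(track: Track) -> list[Leg]:
    """Decompose a metric track into its n_fixes - 1 legs.

    Each leg carries the time delta between the bounding fixes and their
    Euclidean displacement.  Tracks with fewer than two fixes yield an
    empty list.
    """
    if track.frame != LOCAL_METRIC:
        raise ValueError("compute_legs requires a local-metric track; project first")
    if track.n_fixes < 2:
        return []
    dt = np.diff(track.t)
    dist = np.hypot(np.diff(track.x), np.diff(track.y))
    return [Leg(float(a), float(b)) for a, b in zip(dt, dist)]


def filter_by_max_gap(
    tracks: Iterable[Track], max_gap_s: float = 60.0
) -> GapFilterReport:
    """Partition tracks by the maximum-gap rule.

    A track is excluded iff any inter-fix interval strictly exceeds
    ``max_gap_s``; an interval of exactly ``max_gap_s`` is retained, since
    gaps at the threshold occur inside valid follows.
    """
    if max_gap_s <= 0:
        raise ValueError("max_gap_s must be positive")
    retained, excluded = [], []
    for tr in tracks:
        gaps = np.diff(tr.t)
        if gaps.size and float(gaps.max()) > max_gap_s:
            excluded.append(tr.track_id)
        else:
            retained.append(tr.track_id)
    if not retained and not excluded:
        raise ValueError("no tracks supplied")
    return GapFilterReport(retained=retained, excluded=excluded, max_gap_s=float(max_gap_s))
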