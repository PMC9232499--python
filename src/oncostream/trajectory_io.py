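"""Reading, writing and kinematic reduction of cell tracks.

Tracks are time-stamped 2-D positions of individual cells, as produced by a
spot-tracking tool such as TrackMate.  All internal computation is in
micrometres and minutes; speeds are reported in µm/h, the unit conventional
for glioma time-lapse work.  The raw observable for every downstream motion
statistic is the per-step *angle velocity*: the direction
``theta = atan2(dy, dx) mod 2pi`` of each displacement between consecutive
frames, together with its speed.
"""

from __future__ import annotations

import csv
import io
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lxml import etree

__all__ = [
    "Track",
    "TrackTable",
    "ZoneROI",
    "TrackParseError",
    "TrackValidationError",
    "ConfigurationError",
    "read_tracks",
    "write_tracks",
    "write_tracks_xml",
    "compute_kinematics",
    "assign_zones",
    "summarize_speeds",
    "UNZONED",
]

#: Zone label applied to kinematics rows falling outside every ROI.
UNZONED = "unzoned"

#: Default acquisition interval, minutes.
DEFAULT_FRAME_INTERVAL_MIN = 10.0

CSV_COLUMNS = ["track_id", "frame", "t_min", "x_um", "y_um"]
_FLOAT_FMT = "{:.6f}"


class TrackParseError(ValueError):
    """A track file does not conform to its declared dialect."""


class TrackValidationError(ValueError):
    """A track violates an invariant (e.g. non-increasing time stamps)."""


class ConfigurationError(ValueError):
    """Required configuration (e.g. frame interval) is missing."""


@dataclass
class Track:
    """One cell's trajectory: ordered samples of (t [min], x [µm], y [µm])."""

    track_id: str
    t: np.ndarray
    x: np.ndarray
    y: np.ndarray

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if not (self.t.shape == self.x.shape == self.y.shape):
            raise TrackValidationError(
                f"track {self.track_id!r}: t/x/y lengths differ"
            )
        if not (
            np.all(np.isfinite(self.t))
            and np.all(np.isfinite(self.x))
            and np.all(np.isfinite(self.y))
        ):
            raise TrackValidationError(
                f"track {self.track_id!r}: non-finite coordinates"
            )

    @property
    def n_samples(self) -> int:
        return self.t.size


@dataclass
class TrackTable:
    """A collection of tracks sharing one acquisition frame interval."""

    tracks: list[Track] = field(default_factory=list)
    frame_interval: float = DEFAULT_FRAME_INTERVAL_MIN  # minutes

    def __post_init__(self) -> None:
        if not self.frame_interval > 0:
            raise TrackValidationError("frame_interval must be > 0")

    def __len__(self) -> int:
        return len(self.tracks)


@dataclass(frozen=True)
class ZoneROI:
    """Axis-aligned rectangular analysis zone, half-open in both axes."""

    zone_id: str
    x_min: float
    x_max: float
    y_min: float
    y_max: float

    def __post_init__(self) -> None:
        if not (self.x_min < self.x_max and self.y_min < self.y_max):
            raise TrackValidationError(
                f"zone {self.zone_id!r}: degenerate extent"
            )

    def contains(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        # half-open [min, max): a point exactly on the upper edge is outside
        return (
            (x >= self.x_min)
            & (x < self.x_max)
            & (y >= self.y_min)
            & (y < self.y_max)
        )


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def read_tracks(
    path,
    format: str | None = None,
    frame_interval: float | None = None,
) -> TrackTable:
    """Read tracks from a CSV table or TrackMate-dialect XML file.

    Parameters
    ----------
    path
        Input file.  ``format`` is inferred from the suffix (``.xml`` →
        ``trackmate-xml``, otherwise ``tracks-csv``) when not given.
    format
        ``"trackmate-xml"`` or ``"tracks-csv"``.
    frame_interval
        Override for the acquisition interval in minutes.  Required when the
        file carries frame indices but no time stamps or interval metadata.

    Returns
    -------
    TrackTable
        Samples sorted by time within each track; coordinates in µm.
    """
    path = str(path)
    if format is None:
        format = "trackmate-xml" if path.lower().endswith(".xml") else "tracks-csv"
    if format == "trackmate-xml":
        return _read_trackmate_xml(path, frame_interval)
    if format == "tracks-csv":
        return _read_tracks_csv(path, frame_interval)
    raise ValueError(f"unknown track format {format!r}")


def _read_tracks_csv(path: str, frame_interval: float | None) -> TrackTable:
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None:
            raise TrackParseError(f"{path}: empty file, header required")
        missing = [c for c in CSV_COLUMNS if c not in reader.fieldnames]
        if missing:
            raise TrackParseError(f"{path}: missing column(s) {missing}")
        rows: dict[str, list[tuple[float, float, float]]] = {}
        for i, rec in enumerate(reader, start=2):
            try:
                tid = rec["track_id"]
                t = float(rec["t_min"])
                x = float(rec["x_um"])
                y = float(rec["y_um"])
            except (TypeError, ValueError) as exc:
                raise TrackParseError(f"{path}: bad record at line {i}: {rec}") from exc
            rows.setdefault(tid, []).append((t, x, y))
    tracks = []
    for tid, samples in rows.items():
        samples.sort(key=lambda s: s[0])
        arr = np.array(samples, dtype=float)
        tracks.append(Track(tid, arr[:, 0], arr[:, 1], arr[:, 2]))
    dt = frame_interval if frame_interval is not None else _infer_interval(tracks)
    return TrackTable(tracks, dt)


def _infer_interval(tracks: list[Track]) -> float:
    diffs = np.concatenate(
        [np.diff(tr.t) for tr in tracks if tr.n_samples >= 2] or [np.array([])]
    )
    diffs = diffs[diffs > 0]
    if diffs.size == 0:
        return DEFAULT_FRAME_INTERVAL_MIN
    return float(np.median(diffs))


def _read_trackmate_xml(path: str, frame_interval: float | None) -> TrackTable:
    """Parse the TrackMate dialect: ``Model/AllSpots`` + ``Model/AllTracks``.

    Spot positions are read from POSITION_X / POSITION_Y (µm) and times from
    POSITION_T (min) or, failing that, FRAME × the frame interval; the
    interval comes from ``Model/@timeinterval``, a ``Settings/ImageData``
    attribute, or the ``frame_interval`` override.
    """
    try:
        tree = etree.parse(path)
    except (etree.XMLSyntaxError, OSError) as exc:
        raise TrackParseError(f"{path}: not parseable XML: {exc}") from exc
    root = tree.getroot()
    model = root.find("Model") if root.tag != "Model" else root
    if model is None:
        raise TrackParseError(f"{path}: no <Model> element")

    dt = frame_interval
    if dt is None:
        for holder, attr in ((model, "timeinterval"),):
            val = holder.get(attr)
            if val is not None:
                dt = float(val)
    if dt is None:
        img = root.find("Settings/ImageData")
        if img is not None and img.get("timeinterval") is not None:
            dt = float(img.get("timeinterval"))

    spots: dict[str, tuple[float | None, float | None, float, float]] = {}
    for spot in model.iterfind("AllSpots/SpotsInFrame/Spot"):
        sid = spot.get("ID")
        if sid is None:
            raise TrackParseError(f"{path}: <Spot> without ID")
        try:
            x = float(spot.get("POSITION_X"))
            y = float(spot.get("POSITION_Y"))
        except (TypeError, ValueError) as exc:
            raise TrackParseError(f"{path}: spot {sid}: bad position") from exc
        t_raw = spot.get("POSITION_T")
        f_raw = spot.get("FRAME")
        t = float(t_raw) if t_raw is not None else None
        frame = float(f_raw) if f_raw is not None else None
        spots[sid] = (t, frame, x, y)

    tracks: list[Track] = []
    for tr in model.iterfind("AllTracks/Track"):
        tid = tr.get("TRACK_ID", tr.get("name", str(len(tracks))))
        ids: set[str] = set()
        for edge in tr.iterfind("Edge"):
            for key in ("SPOT_SOURCE_ID", "SPOT_TARGET_ID"):
                sid = edge.get(key)
                if sid is None:
                    raise TrackParseError(
                        f"{path}: track {tid}: edge missing {key}"
                    )
                if sid not in spots:
                    raise TrackParseError(
                        f"{path}: track {tid}: unknown spot id {sid}"
                    )
                ids.add(sid)
        if not ids:
            continue
        samples = []
        for sid in ids:
            t, frame, x, y = spots[sid]
            if t is None:
                if frame is None:
                    raise TrackParseError(
                        f"{path}: spot {sid}: neither POSITION_T nor FRAME"
                    )
                if dt is None:
                    raise ConfigurationError(
                        f"{path}: spots carry FRAME only and no frame interval "
                        "is available; pass frame_interval="
                    )
                t = frame * dt
            samples.append((t, x, y))
        samples.sort(key=lambda s: s[0])
        arr = np.array(samples, dtype=float)
        tracks.append(Track(str(tid), arr[:, 0], arr[:, 1], arr[:, 2]))

    if dt is None:
        dt = _infer_interval(tracks)
    return TrackTable(tracks, dt)


def write_tracks(table: TrackTable, path) -> None:
    """Write the CSV dialect (lossless round-trip with :func:`read_tracks`).

    Floats are written with a fixed ``%.6f`` format so that identical tables
    serialize to identical bytes.
    """
    buf = io.StringIO()
    w = csv.writer(buf, lineterminator="\n")
    w.writerow(CSV_COLUMNS)
    for tr in table.tracks:
        frames = np.round(tr.t / table.frame_interval).astype(int)
        for f, t, x, y in zip(frames, tr.t, tr.x, tr.y):
            w.writerow(
                [tr.track_id, int(f)]
                + [_FLOAT_FMT.format(v) for v in (t, x, y)]
            )
    with open(path, "w", newline="", encoding="utf-8") as fh:
        fh.write(buf.getvalue())


def write_tracks_xml(table: TrackTable, path) -> None:
    """Write tracks in the TrackMate dialect read by :func:`read_tracks`."""
    root = etree.Element("TrackMate")
    model = etree.SubElement(
        root,
        "Model",
        spatialunits="micron",
        timeunits="min",
        timeinterval=_FLOAT_FMT.format(table.frame_interval),
    )
    allspots = etree.SubElement(model, "AllSpots")
    alltracks = etree.SubElement(model, "AllTracks")
    frames: dict[int, etree._Element] = {}
    sid = 0
    for tr in table.tracks:
        track_el = etree.SubElement(alltracks, "Track", TRACK_ID=str(tr.track_id))
        spot_ids = []
        for t, x, y in zip(tr.t, tr.x, tr.y):
            frame = int(round(t / table.frame_interval))
            if frame not in frames:
                frames[frame] = etree.SubElement(
                    allspots, "SpotsInFrame", frame=str(frame)
                )
            etree.SubElement(
                frames[frame],
                "Spot",
                ID=str(sid),
                FRAME=str(frame),
                POSITION_T=_FLOAT_FMT.format(t),
                POSITION_X=_FLOAT_FMT.format(x),
                POSITION_Y=_FLOAT_FMT.format(y),
            )
            spot_ids.append(sid)
            sid += 1
        for a, b in zip(spot_ids[:-1], spot_ids[1:]):
            etree.SubElement(
                track_el, "Edge", SPOT_SOURCE_ID=str(a), SPOT_TARGET_ID=str(b)
            )
    etree.ElementTree(root).write(
        str(path), xml_declaration=True, encoding="utf-8", pretty_print=True
    )


# ---------------------------------------------------------------------------
# kinematics
# ---------------------------------------------------------------------------

def compute_kinematics(table: TrackTable) -> pd.DataFrame:
    """Reduce tracks to per-step headings and speeds.

    For every pair of consecutive samples the heading is
    ``theta = atan2(dy, dx) mod 2pi`` and the speed is
    ``|dr| / dt_pair * 60`` in µm/h, using the actual time difference of the
    pair (so gaps in a track are handled correctly).  Zero-displacement steps
    are retained with ``valid = False`` and speed 0; their heading is
    undefined and set to NaN.

    Returns
    -------
    pandas.DataFrame
        Columns ``track_id, t_mid, x_mid, y_mid, theta, speed, valid``; one
        row per consecutive sample pair.
    """
    recs = []
    for tr in table.tracks:
        if tr.n_samples < 2:
            continue
        dt = np.diff(tr.t)
        if np.any(dt <= 0):
            raise TrackValidationError(
                f"track {tr.track_id!r}: time stamps not strictly increasing"
            )
        dx = np.diff(tr.x)
        dy = np.diff(tr.y)
        disp = np.hypot(dx, dy)
        valid = disp > 0
        theta = np.where(valid, np.mod(np.arctan2(dy, dx), 2 * np.pi), np.nan)
        speed = disp / dt * 60.0
        recs.append(
            pd.DataFrame(
                {
                    "track_id": tr.track_id,
                    "t_mid": 0.5 * (tr.t[:-1] + tr.t[1:]),
                    "x_mid": 0.5 * (tr.x[:-1] + tr.x[1:]),
                    "y_mid": 0.5 * (tr.y[:-1] + tr.y[1:]),
                    "theta": theta,
                    "speed": speed,
                    "valid": valid,
                }
            )
        )
    if not recs:
        return pd.DataFrame(
            columns=["track_id", "t_mid", "x_mid", "y_mid", "theta", "speed", "valid"]
        )
    return pd.concat(recs, ignore_index=True)


def assign_zones(kin: pd.DataFrame, rois: list[ZoneROI]) -> pd.DataFrame:
    """Label kinematics rows with analysis zones.

    Membership is evaluated at the step midpoint with half-open intervals
    ``[min, max)`` on both axes, so a point exactly on an upper edge belongs
    to no zone and zone tilings never double-count.  Zones may overlap: a row
    inside k zones appears k times in the output, once per zone.  Rows inside
    no zone are labeled :data:`UNZONED`.
    """
    if kin.empty:
        out = kin.copy()
        out["zone"] = pd.Series(dtype=object)
        return out
    x = kin["x_mid"].to_numpy()
    y = kin["y_mid"].to_numpy()
    pieces = []
    covered = np.zeros(len(kin), dtype=bool)
    for roi in rois:
        mask = roi.contains(x, y)
        covered |= mask
        if mask.any():
            sub = kin.loc[mask].copy()
            sub["zone"] = roi.zone_id
            pieces.append(sub)
    if not covered.all():
        sub = kin.loc[~covered].copy()
        sub["zone"] = UNZONED
        pieces.append(sub)
    return pd.concat(pieces, ignore_index=True)


def summarize_speeds(
    kin: pd.DataFrame,
    group_by: str = "zone",
    bin_edges: np.ndarray | None = None,
    include_stationary: bool = False,
) -> dict[str, dict]:
    """Per-group speed summaries: mean, SD, n and a histogram.

    By default only valid (moving) steps enter the statistics; with
    ``include_stationary`` zero-displacement steps contribute their zero
    speed.  Empty groups are reported with ``n = 0`` and ``mean = None``
    rather than raising.
    """
    if bin_edges is None:
        bin_edges = np.arange(0.0, 21.0, 1.0)
    bin_edges = np.asarray(bin_edges, dtype=float)
    out: dict[str, dict] = {}
    if kin.empty:
        return out
    groups = kin.groupby(group_by, sort=True) if group_by in kin.columns else [("all", kin)]
    for name, grp in groups:
        speeds = grp["speed"].to_numpy() if include_stationary else grp.loc[
            grp["valid"], "speed"
        ].to_numpy()
        n = int(speeds.size)
        counts, _ = np.histogram(speeds, bins=bin_edges)
        out[str(name)] = {
            "n": n,
            "mean": float(np.mean(speeds)) if n else None,
            "sd": float(np.std(speeds, ddof=1)) if n > 1 else None,
            "histogram": {
                "bin_edges": bin_edges.tolist(),
                "counts": counts.tolist(),
            },
        }
    return out
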