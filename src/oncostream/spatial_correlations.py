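"""Pairwise spatial and directional order statistics.

Given zone-labeled kinematics, cells are regrouped into per-frame snapshots
and three local-order statistics are computed:

* pair directional correlation ``C(r) = <cos(theta_i - theta_j)>`` over cell
  pairs binned by separation (optionally resolved by the neighbor's bearing
  sector in the focal cell's heading frame);
* the relative-position map: the 2-D histogram of neighbor displacements
  rotated so the focal heading points along +x ("front");
* nearest-neighbor distance statistics.

Because stream cells move in antiparallel lanes, the polar kernel
``cos(dtheta)`` averages toward zero in a perfect stream; a nematic variant
``cos 2(dtheta)`` insensitive to polarity is available via ``nematic=True``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree
from scipy.spatial.distance import pdist

__all__ = [
    "FrameSnapshot",
    "PairDirectionalCorrelation",
    "RelativePositionMap",
    "NearestNeighborStats",
    "SECTORS",
    "build_snapshots",
    "pair_directional_correlation",
    "relative_position_map",
    "nearest_neighbor_distances",
]

#: Sector names, in bearing order starting at "front" (focal heading +x).
SECTORS = ("front", "right", "back", "left")

#: Default separation bins: 0-50 µm in 10 µm steps.
DEFAULT_R_BIN_EDGES = np.arange(0.0, 60.0, 10.0)


@dataclass
class FrameSnapshot:
    """All cells of one zone at one time point."""

    zone_id: str
    t: float
    track_ids: np.ndarray
    xy: np.ndarray  # (n, 2) µm
    theta: np.ndarray  # radians; NaN where invalid
    valid: np.ndarray  # bool

    @property
    def n_cells(self) -> int:
        return len(self.track_ids)


@dataclass
class PairDirectionalCorrelation:
    r_bin_edges: np.ndarray
    C: np.ndarray  # (n_bins,) or (4, n_bins) in sector mode; NaN where empty
    n_pairs: np.ndarray  # same shape, int
    by_sector: bool = False
    nematic: bool = False

    def to_dataframe(self) -> pd.DataFrame:
        """Long-form table: bin_lo_um, bin_hi_um, sector, C, n_pairs."""
        lo, hi = self.r_bin_edges[:-1], self.r_bin_edges[1:]
        rows = []
        if self.by_sector:
            for s, name in enumerate(SECTORS):
                for b in range(len(lo)):
                    rows.append((lo[b], hi[b], name, self.C[s, b], self.n_pairs[s, b]))
        else:
            for b in range(len(lo)):
                rows.append((lo[b], hi[b], "all", self.C[b], self.n_pairs[b]))
        return pd.DataFrame(
            rows, columns=["bin_lo_um", "bin_hi_um", "sector", "C", "n_pairs"]
        )


@dataclass
class RelativePositionMap:
    bin_edges: np.ndarray  # shared for x and y, µm
    density: np.ndarray  # (n, n), sums to 1 when any pair exists
    n_pairs: int


@dataclass
class NearestNeighborStats:
    distances: np.ndarray  # pooled, µm
    median: float | None = None
    iqr: float | None = None
    histogram: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------

def build_snapshots(kin: pd.DataFrame) -> list[FrameSnapshot]:
    """Regroup zone-labeled kinematics rows into per-(zone, time) snapshots.

    Invalid (zero-displacement) rows keep their position in the snapshot but
    are excluded from directional statistics by consumers.
    """
    if kin.empty:
        return []
    if "zone" not in kin.columns:
        kin = kin.assign(zone="all")
    snaps = []
    for (zone, t), grp in kin.groupby(["zone", "t_mid"], sort=True):
        snaps.append(
            FrameSnapshot(
                zone_id=str(zone),
                t=float(t),
                track_ids=grp["track_id"].to_numpy(),
                xy=grp[["x_mid", "y_mid"]].to_numpy(dtype=float),
                theta=grp["theta"].to_numpy(dtype=float),
                valid=grp["valid"].to_numpy(dtype=bool),
            )
        )
    return snaps


def _sector_index(bearing: np.ndarray) -> np.ndarray:
    """Map bearings (radians, focal frame) to sector indices.

    Sectors are quarter-turns with half-open intervals (lo, hi] in degrees:
    front (-45, 45], right (45, 135], back (135, 225], left (225, 315].
    """
    deg = np.degrees(bearing) % 360.0
    # subtract a hair so that an exact upper boundary lands in its sector
    return ((deg + 45.0 - 1e-9) % 360.0 // 90.0).astype(int)


def pair_directional_correlation(
    snapshots: list[FrameSnapshot],
    r_bin_edges: np.ndarray | None = None,
    by_sector: bool = False,
    frame_weighted: bool = False,
    nematic: bool = False,
) -> PairDirectionalCorrelation:
    """Mean heading-alignment of cell pairs versus separation distance.

    For every pair of valid cells in every snapshot whose separation falls
    in a bin, ``cos(theta_i - theta_j)`` (or ``cos 2(theta_i - theta_j)``
    with ``nematic``) is accumulated; ``C`` is the per-bin mean pooled over
    snapshots (pair-weighted; per-snapshot averaging via ``frame_weighted``).
    In sector mode each unordered pair contributes twice, once per choice of
    focal cell, classified by the neighbor's bearing in the focal heading
    frame.  Empty input or empty bins yield NaN, never an exception.
    """
    edges = (
        DEFAULT_R_BIN_EDGES if r_bin_edges is None else np.asarray(r_bin_edges, float)
    )
    n_bins = len(edges) - 1
    shape = (len(SECTORS), n_bins) if by_sector else (n_bins,)
    sums = np.zeros(shape)
    counts = np.zeros(shape, dtype=np.int64)
    frame_C: list[np.ndarray] = []

    for snap in snapshots:
        m = snap.valid & np.isfinite(snap.theta)
        if m.sum() < 2:
            continue
        xy = snap.xy[m]
        th = snap.theta[m]
        k = len(th)
        iu, ju = np.triu_indices(k, 1)
        d = xy[ju] - xy[iu]
        r = np.hypot(d[:, 0], d[:, 1])
        binidx = np.searchsorted(edges, r, side="right") - 1
        inbin = (binidx >= 0) & (binidx < n_bins) & (r < edges[-1])
        if not inbin.any():
            continue
        dth = th[iu] - th[ju]
        align = np.cos(2.0 * dth) if nematic else np.cos(dth)
        f_sums = np.zeros(shape)
        f_counts = np.zeros(shape, dtype=np.int64)
        if by_sector:
            # ordered pairs: (i focal, j neighbor) and (j focal, i neighbor)
            for foc, nb, disp in ((iu, ju, d), (ju, iu, -d)):
                bearing = np.arctan2(disp[:, 1], disp[:, 0]) - th[foc]
                sec = _sector_index(bearing)
                np.add.at(f_sums, (sec[inbin], binidx[inbin]), align[inbin])
                np.add.at(f_counts, (sec[inbin], binidx[inbin]), 1)
        else:
            np.add.at(f_sums, binidx[inbin], align[inbin])
            np.add.at(f_counts, binidx[inbin], 1)
        sums += f_sums
        counts += f_counts
        if frame_weighted:
            with np.errstate(invalid="ignore"):
                frame_C.append(np.where(f_counts > 0, f_sums / f_counts, np.nan))

    if frame_weighted and frame_C:
        stack = np.stack(frame_C)
        with np.errstate(invalid="ignore"):
            C = np.nanmean(stack, axis=0)
    else:
        with np.errstate(invalid="ignore"):
            C = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    return PairDirectionalCorrelation(
        r_bin_edges=edges, C=C, n_pairs=counts, by_sector=by_sector, nematic=nematic
    )


def relative_position_map(
    snapshots: list[FrameSnapshot],
    r_max: float = 50.0,
    bin_width: float = 5.0,
) -> RelativePositionMap:
    """Histogram of neighbor positions in the focal cell's heading frame.

    Each ordered pair's displacement (neighbor minus focal) is rotated by
    ``-theta_focal`` so the focal heading maps to +x; displacements within
    the ``[-r_max, r_max]^2`` square are binned and normalized to a
    probability map.  A front-back/left-right anisotropy of this map is the
    signature of organized (stream/flock) neighborhoods.
    """
    edges = np.arange(-r_max, r_max + bin_width / 2, bin_width)
    n = len(edges) - 1
    H = np.zeros((n, n))
    total = 0
    for snap in snapshots:
        focal = np.flatnonzero(snap.valid & np.isfinite(snap.theta))
        if focal.size == 0 or snap.n_cells < 2:
            continue
        # focal cells need a heading; neighbors only need a position
        for f in focal:
            nb = np.arange(snap.n_cells) != f
            disp = snap.xy[nb] - snap.xy[f]
            c, s = np.cos(-snap.theta[f]), np.sin(-snap.theta[f])
            rx = c * disp[:, 0] - s * disp[:, 1]
            ry = s * disp[:, 0] + c * disp[:, 1]
            h, _, _ = np.histogram2d(rx, ry, bins=[edges, edges])
            H += h
            total += int(h.sum())
    if total > 0:
        H = H / total
    return RelativePositionMap(bin_edges=edges, density=H, n_pairs=total)


def nearest_neighbor_distances(
    snapshots: list[FrameSnapshot],
    toroidal: bool = False,
    box: tuple[float, float] | None = None,
    bin_edges: np.ndarray | None = None,
) -> NearestNeighborStats:
    """Per-cell-per-frame distance to the closest other cell, pooled.

    All cells with a position participate (motion validity is irrelevant to
    spacing).  ``toroidal`` wraps distances on the ``box`` rectangle — an
    edge correction used when validating against the Poisson-process
    closed form ``E[NN] = 1/(2 sqrt(lambda))``; real imaging fields are
    analyzed unwrapped, as the source analyses were.
    """
    dists = []
    for snap in snapshots:
        if snap.n_cells < 2:
            continue
        xy = snap.xy
        if toroidal:
            if box is None:
                raise ValueError("toroidal=True requires box=(Lx, Ly)")
            tree = cKDTree(np.mod(xy, box), boxsize=box)
        else:
            tree = cKDTree(xy)
        dd, _ = tree.query(np.mod(xy, box) if toroidal else xy, k=2)
        dists.append(dd[:, 1])
    if not dists:
        return NearestNeighborStats(distances=np.array([]))
    pooled = np.concatenate(dists)
    if bin_edges is None:
        bin_edges = np.arange(0.0, max(float(pooled.max()), 1.0) + 5.0, 5.0)
    counts, _ = np.histogram(pooled, bins=bin_edges)
    q1, med, q3 = np.percentile(pooled, [25, 50, 75])
    return NearestNeighborStats(
        distances=pooled,
        median=float(med),
        iqr=float(q3 - q1),
        histogram={"bin_edges": np.asarray(bin_edges).tolist(), "counts": counts.tolist()},
    )
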