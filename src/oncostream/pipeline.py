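"""Orchestration: config-driven end-to-end analysis and report rendering.

A single TOML config drives the full chain

    tracks -> kinematics -> zones -> pattern classification
           -> speed summaries -> pairwise correlations (-> report JSON)

plus optional shape (labeled mask) and border (two-phase image) analyses.
The report is a plain JSON-serializable dict; re-running on identical inputs
produces byte-identical JSON (the report carries content hashes but no
timestamps).

Config schema (all sections optional except ``io.tracks`` for zone analysis)::

    [io]
    tracks = "tracks.csv"          # CSV or TrackMate-dialect XML
    frame_interval_min = 10.0

    [analysis]
    min_n = 30                     # smallest heading sample to classify
    kappa_max = 500.0
    use_aicc = false
    include_stationary = false     # keep zero-displacement steps in speeds
    per_track_mean = false         # one heading per track instead of per step

    [[zones]]                      # any number; omit to analyze one zone
    zone_id = "A"
    x_min = 0.0
    x_max = 200.0
    y_min = 0.0
    y_max = 400.0

    [correlations]
    r_bin_edges = [0.0, 10.0, 20.0, 30.0, 40.0, 50.0]
    by_sector = false
    nematic = false
    frame_weighted = false

    [shapes]
    mask = "mask.tif"
    pixel_size_um = 1.0
    min_area_px = 10
    ar_threshold = 2.0
    exclude_border_objects = false

    [border]
    image = "border.png"
    pixel_size_um = 1.0
    threshold = "otsu"             # or a number
    epsilon_um = 2.0
    n_steps = 200
"""

from __future__ import annotations

import hashlib
import json
import logging
import tomllib
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from . import border_geometry as bg
from . import motion_classifier as mc
from . import shape_alignment as sa
from . import spatial_correlations as sc
from . import trajectory_io as tio

__all__ = ["load_config", "run_zone_analysis", "render_report", "report_to_json"]

log = logging.getLogger("oncostream")


def load_config(path) -> dict:
    with open(path, "rb") as fh:
        return tomllib.load(fh)


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _jsonable(obj):
    """Recursively convert numpy scalars/arrays for json.dumps."""
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return [_jsonable(v) for v in obj.tolist()]
    if isinstance(obj, (np.floating, np.integer, np.bool_)):
        obj = obj.item()
    if isinstance(obj, float) and not np.isfinite(obj):
        return None
    return obj


def report_to_json(report: dict) -> str:
    """Deterministic serialization: sorted keys, fixed layout, no timestamps."""
    return json.dumps(_jsonable(report), sort_keys=True, indent=2) + "\n"


# ---------------------------------------------------------------------------

def _track_headings(kin: pd.DataFrame) -> np.ndarray:
    """Per-track circular mean heading (the ``per_track_mean`` variant)."""
    out = []
    for _, grp in kin[kin["valid"]].groupby("track_id"):
        th = grp["theta"].to_numpy()
        if th.size:
            out.append(np.mod(np.arctan2(np.sin(th).sum(), np.cos(th).sum()), 2 * np.pi))
    return np.asarray(out)


def run_zone_analysis(config_path, out_dir=None) -> dict:
    """Execute the configured analyses and return the report dict.

    When ``out_dir`` is given, ``report.json`` and CSV side tables are
    written there.  Zones with fewer headings than ``analysis.min_n`` are
    reported with a null label and a warning; other zones are unaffected.
    """
    cfg = load_config(config_path)
    base = Path(config_path).parent
    report: dict = {
        "version": __version__,
        "provenance": {
            "config_sha256": _sha256(config_path),
            "input_sha256": {},
        },
    }
    an = cfg.get("analysis", {})
    min_n = int(an.get("min_n", 30))
    kappa_max = float(an.get("kappa_max", mc.KAPPA_MAX))
    use_aicc = bool(an.get("use_aicc", False))
    include_stationary = bool(an.get("include_stationary", False))
    per_track_mean = bool(an.get("per_track_mean", False))

    io_cfg = cfg.get("io", {})
    if "tracks" in io_cfg:
        tracks_path = base / io_cfg["tracks"]
        report["provenance"]["input_sha256"]["tracks"] = _sha256(tracks_path)
        table = tio.read_tracks(
            tracks_path, frame_interval=io_cfg.get("frame_interval_min")
        )
        kin = tio.compute_kinematics(table)
        rois = [
            tio.ZoneROI(
                str(z["zone_id"]),
                float(z["x_min"]),
                float(z["x_max"]),
                float(z["y_min"]),
                float(z["y_max"]),
            )
            for z in cfg.get("zones", [])
        ]
        zoned = tio.assign_zones(kin, rois) if rois else kin.assign(zone="all")
        speed_summary = tio.summarize_speeds(
            zoned, include_stationary=include_stationary
        )
        corr_cfg = cfg.get("correlations", {})
        edges = np.asarray(
            corr_cfg.get("r_bin_edges", sc.DEFAULT_R_BIN_EDGES), dtype=float
        )
        zones_out = {}
        for zone, grp in zoned.groupby("zone"):
            valid_th = grp.loc[grp["valid"], "theta"].to_numpy()
            if per_track_mean:
                valid_th = _track_headings(grp)
            zrep: dict = {"n_steps": int(len(grp))}
            if valid_th.size >= 1:
                sample = mc.HeadingSample(valid_th, zone_id=str(zone))
                fit = mc.classify_pattern(
                    sample, min_n=min_n, kappa_max=kappa_max, use_aicc=use_aicc
                )
                if fit.insufficient_sample:
                    log.warning(
                        "zone %s: only %d headings (< min_n=%d); label null",
                        zone,
                        fit.n,
                        min_n,
                    )
                else:
                    for fam, f in fit.fits.items():
                        if f.kappa_clipped:
                            log.warning(
                                "zone %s: %s fit hit kappa_max=%g",
                                zone,
                                fam,
                                kappa_max,
                            )
                zrep["pattern"] = fit.to_dict()
                counts, hist_edges = mc.angle_histogram(sample)
                zrep["angle_histogram"] = {
                    "bin_edges": hist_edges.tolist(),
                    "counts": counts.tolist(),
                }
                kde = mc.circular_kde(sample)
                zrep["kde"] = {
                    "grid": kde.grid.tolist(),
                    "density": kde.density.tolist(),
                    "bandwidth_kappa": kde.bandwidth_kappa,
                }
            else:
                zrep["pattern"] = None
                log.warning("zone %s: no valid headings", zone)
            zrep["speeds"] = speed_summary.get(str(zone))
            snaps = sc.build_snapshots(grp.assign(zone=zone))
            corr = sc.pair_directional_correlation(
                snaps,
                r_bin_edges=edges,
                by_sector=bool(corr_cfg.get("by_sector", False)),
                frame_weighted=bool(corr_cfg.get("frame_weighted", False)),
                nematic=bool(corr_cfg.get("nematic", False)),
            )
            zrep["pair_correlation"] = corr.to_dataframe().to_dict(orient="list")
            nn = sc.nearest_neighbor_distances(snaps)
            zrep["nearest_neighbor"] = {
                "n": int(nn.distances.size),
                "median_um": nn.median,
                "iqr_um": nn.iqr,
                "histogram": nn.histogram,
            }
            zones_out[str(zone)] = zrep
        for roi in rois:  # configured zones that caught no steps still appear
            if roi.zone_id not in zones_out:
                log.warning("zone %s: no steps fell inside the ROI", roi.zone_id)
                zones_out[roi.zone_id] = {
                    "n_steps": 0,
                    "pattern": None,
                    "speeds": None,
                    "pair_correlation": None,
                    "nearest_neighbor": None,
                }
        report["zones"] = zones_out

    if "shapes" in cfg:
        sh = cfg["shapes"]
        mask_path = base / sh["mask"]
        report["provenance"]["input_sha256"]["mask"] = _sha256(mask_path)
        mask = _read_image(mask_path).astype(np.int64)
        desc = sa.measure_shapes(
            mask,
            pixel_size=float(sh.get("pixel_size_um", 1.0)),
            min_area_px=int(sh.get("min_area_px", 10)),
            exclude_border_objects=bool(sh.get("exclude_border_objects", False)),
        )
        if len(desc):
            desc, summary = sa.classify_cell_shape(
                desc, ar_threshold=float(sh.get("ar_threshold", sa.DEFAULT_AR_THRESHOLD))
            )
            align = sa.nematic_order(desc["feret_deg"].dropna().to_numpy())
            report["shapes"] = {
                "summary": summary,
                "nematic_order": align.nematic_order,
                "mean_axis_deg": align.mean_axis_deg,
                "descriptors": desc.to_dict(orient="list"),
            }
        else:
            report["shapes"] = {"summary": None}
            log.warning("shape analysis: no objects above min_area_px")

    if "border" in cfg:
        bo = cfg["border"]
        img_path = base / bo["image"]
        report["provenance"]["input_sha256"]["border_image"] = _sha256(img_path)
        img = _read_image(img_path).astype(float)
        thr = bo.get("threshold", "otsu")
        field = bg.binarize_tumor_image(
            img,
            threshold=thr if thr == "otsu" else float(thr),
            pixel_size=float(bo.get("pixel_size_um", 1.0)),
            epsilon=bo.get("epsilon_um"),
        )
        smoothed = bg.allen_cahn_smooth(field, n_steps=int(bo.get("n_steps", 200)))
        curve = bg.extract_border_curve(smoothed)
        entry = {
            "closed": curve.closed,
            "length_um": curve.length,
            "endpoint_distance_um": curve.endpoint_distance,
            "n_points": int(len(curve.points)),
        }
        if curve.closed:
            entry["sinuosity"] = None
            log.warning("border: only closed interfaces found; sinuosity undefined")
        else:
            entry["sinuosity"] = bg.sinuosity(curve)
        report["border"] = entry
        report["_border_curve"] = curve  # kept for rendering; stripped on save

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        saved = {k: v for k, v in report.items() if not k.startswith("_")}
        (out / "report.json").write_text(report_to_json(saved))
        if "_border_curve" in report:
            curve = report["_border_curve"]
            pd.DataFrame(curve.points, columns=["x_um", "y_um"]).to_csv(
                out / "border_polyline.csv", index=False, float_format="%.6f"
            )
    return report


def _read_image(path) -> np.ndarray:
    path = str(path)
    if path.lower().endswith((".tif", ".tiff")):
        import tifffile

        return tifffile.imread(path)
    from skimage.io import imread

    img = imread(path)
    if img.ndim == 3:  # drop alpha / collapse identical channels
        img = img[..., 0]
    return img


# ---------------------------------------------------------------------------
# figures
# ---------------------------------------------------------------------------

def render_report(report: dict, out_dir) -> list[str]:
    """Write rose plots, model-comparison panels and summary figures.

    For each zone: a polar rose of the heading histogram and a panel showing
    the circular KDE of the data with the three fitted candidate densities
    and their Akaike weights.  Also speed histograms, the pair-correlation
    curve, and the border polyline when present.  Returns the written paths;
    an empty report produces no files (with a warning).
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[str] = []
    zones = report.get("zones", {})
    if not zones and "shapes" not in report and "border" not in report:
        log.warning("empty report: nothing to render")
        return written

    for zone, z in zones.items():
        fig, (ax_rose, ax_fit) = plt.subplots(
            1, 2, figsize=(9, 4), subplot_kw=None
        )
        ax_rose.remove()
        ax_rose = fig.add_subplot(1, 2, 1, projection="polar")
        hist = z.get("angle_histogram")
        if hist:
            edges = np.asarray(hist["bin_edges"])
            counts = np.asarray(hist["counts"])
            widths = np.diff(edges)
            ax_rose.bar(
                edges[:-1], counts, width=widths, align="edge",
                color="0.4", edgecolor="k", linewidth=0.3,
            )
        ax_rose.set_title(f"zone {zone}: headings")
        kde = z.get("kde")
        pat = z.get("pattern")
        if kde:
            grid = np.asarray(kde["grid"])
            ax_fit.plot(grid, np.asarray(kde["density"]), "k-", lw=1.5, label="data (KDE)")
        if pat and not pat.get("insufficient_sample"):
            grid = np.linspace(0, 2 * np.pi, 361)
            aw = pat["akaike_weights"]
            mus, kappas = pat["mu"], pat["kappa"]
            ax_fit.axhline(
                1 / (2 * np.pi), color="tab:blue", ls="--",
                label=f"swarm (AW={aw['swarm']:.2f})",
            )
            ax_fit.plot(
                grid,
                np.exp(mc.vonmises_logpdf(grid, mus["flock"], kappas["flock"])),
                color="tab:red",
                label=f"flock (AW={aw['flock']:.2f})",
            )
            ax_fit.plot(
                grid,
                np.exp(mc.bimodal_logpdf(grid, mus["stream"], kappas["stream"])),
                color="tab:orange",
                label=f"stream (AW={aw['stream']:.2f})",
            )
            ax_fit.set_title(f"label: {pat['label']}")
        ax_fit.set_xlabel(r"$\theta$ (rad)")
        ax_fit.set_ylabel("density")
        ax_fit.legend(fontsize=7)
        path = out / f"zone_{zone}_pattern.png"
        fig.savefig(path, dpi=120)
        plt.close(fig)
        written.append(str(path))

        sp = z.get("speeds")
        if sp and sp.get("n"):
            fig, ax = plt.subplots(figsize=(4.5, 3.2))
            e = np.asarray(sp["histogram"]["bin_edges"])
            c = np.asarray(sp["histogram"]["counts"])
            ax.bar(e[:-1], c, width=np.diff(e), align="edge", color="0.6", edgecolor="k")
            ax.set_xlabel("speed (µm/h)")
            ax.set_ylabel("steps")
            ax.set_title(f"zone {zone}: mean {sp['mean']:.2f} µm/h (n={sp['n']})")
            path = out / f"zone_{zone}_speed.png"
            fig.savefig(path, dpi=120)
            plt.close(fig)
            written.append(str(path))

        pc = z.get("pair_correlation")
        if pc and len(pc.get("C", [])):
            fig, ax = plt.subplots(figsize=(4.5, 3.2))
            df = pd.DataFrame(pc)
            for sector, grp in df.groupby("sector"):
                mid = 0.5 * (grp["bin_lo_um"] + grp["bin_hi_um"])
                ax.plot(mid, grp["C"], "o-", label=str(sector))
            ax.axhline(0, color="k", lw=0.5)
            ax.set_xlabel("separation (µm)")
            ax.set_ylabel(r"$\langle\cos(\theta_i-\theta_j)\rangle$")
            ax.set_ylim(-1.05, 1.05)
            ax.legend(fontsize=7)
            path = out / f"zone_{zone}_correlation.png"
            fig.savefig(path, dpi=120)
            plt.close(fig)
            written.append(str(path))

    curve = report.get("_border_curve")
    if curve is not None:
        fig, ax = plt.subplots(figsize=(5, 3.5))
        ax.plot(curve.points[:, 0], curve.points[:, 1], "-", lw=1)
        s = report.get("border", {}).get("sinuosity")
        ax.set_title(f"border (S = {s:.3f})" if s else "border (closed)")
        ax.set_xlabel("x (µm)")
        ax.set_ylabel("y (µm)")
        ax.set_aspect("equal")
        path = out / "border_curve.png"
        fig.savefig(path, dpi=120)
        plt.close(fig)
        written.append(str(path))
    return written
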