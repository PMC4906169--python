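"""Stage dispatch: turn a RunConfig into output files plus provenance.

Each stage is a thin orchestration over the library modules; every output
is regenerable from (inputs, config, seed) alone.
"""

from __future__ import annotations

import datetime
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__, coloc_gold, frap, io, profiles, synth, tracking
from .config import ConfigError, RunConfig, config_to_dict

logger = logging.getLogger(__name__)


@dataclass
class ResultBundle:
    stage: str
    outputs: dict            # name -> DataFrame / dict / ndarray
    files: dict              # name -> written path (str)
    provenance: dict

    def summary_json(self) -> str:
        def default(o):
            if isinstance(o, (np.floating, np.integer)):
                return o.item()
            if isinstance(o, np.ndarray):
                return o.tolist()
            raise TypeError(type(o).__name__)
        serializable = {k: v for k, v in self.outputs.items() if isinstance(v, dict)}
        return json.dumps(
            {"stage": self.stage, "outputs": serializable,
             "files": self.files, "provenance": self.provenance},
            indent=2, default=default)


def _provenance(cfg: RunConfig) -> dict:
    return {
        "package": "golgiring",
        "version": __version__,
        "seed": cfg.seed,
        "timestamp": datetime.datetime.now(datetime.timezone.utc).isoformat(),
        "config": config_to_dict(cfg),
    }


def _outdir(cfg: RunConfig) -> Path:
    out = Path(cfg.output or ".")
    out.mkdir(parents=True, exist_ok=True)
    return out


def run_pipeline(cfg: RunConfig) -> ResultBundle:
    try:
        handler = _STAGES[cfg.stage]
    except KeyError:
        raise ConfigError(
            f"unknown stage {cfg.stage!r}; valid stages: {', '.join(sorted(_STAGES))}"
        ) from None
    try:
        outputs, files = handler(cfg)
    except Exception as exc:
        raise type(exc)(f"stage {cfg.stage!r}: {exc}") from exc
    bundle = ResultBundle(cfg.stage, outputs, files, _provenance(cfg))
    out = _outdir(cfg)
    (out / f"{cfg.stage}_summary.json").write_text(bundle.summary_json())
    return bundle


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------


def _resolve_spec(cfg: RunConfig):
    if cfg.preset is not None:
        return synth.preset(cfg.preset)
    for sec in ("golgi", "frap_spec", "tracks"):
        spec = getattr(cfg, sec)
        if spec is not None:
            return spec
    raise ConfigError("simulate needs a 'preset' or one of the golgi/frap_spec/tracks sections")


def _stage_simulate(cfg: RunConfig):
    spec = _resolve_spec(cfg)
    out = _outdir(cfg)
    files = {}
    if isinstance(spec, synth.GolgiPopulationSpec):
        image, truth = synth.generate_golgi_image(spec, cfg.imaging, seed=cfg.seed)
        profs, ptruth = synth.generate_profile_population(spec, cfg.imaging, seed=cfg.seed)
        io.write_image_stack(out / "golgi_field.tif", image)
        prof_tbl = pd.concat(
            [pd.DataFrame({"source_id": p.source_id, "position_nm": p.positions,
                           "intensity": p.intensities}) for p in profs],
            ignore_index=True)
        io.write_table(prof_tbl, out / "profiles.csv")
        io.write_table(ptruth.table, out / "truth.csv")
        files = {"image": str(out / "golgi_field.tif"),
                 "profiles": str(out / "profiles.csv"),
                 "truth": str(out / "truth.csv")}
        outputs = {"truth": ptruth.table,
                   "counts": {"n_objects": int(len(ptruth.table))}}
    elif isinstance(spec, synth.FrapSpec):
        movie, truth = synth.generate_frap_movie(spec, cfg.imaging, seed=cfg.seed)
        io.write_image_stack(out / "frap_movie.tif", movie)
        io.write_table(truth.table, out / "truth.csv")
        files = {"movie": str(out / "frap_movie.tif"), "truth": str(out / "truth.csv")}
        outputs = {"truth": truth.table,
                   "counts": {"n_events": int(len(truth.table))}}
    elif isinstance(spec, synth.TrackSpec):
        det, truth = synth.generate_track_set(spec, cfg.imaging, seed=cfg.seed)
        io.write_table(det, out / "detections.csv")
        io.write_table(truth.table, out / "truth.csv")
        files = {"detections": str(out / "detections.csv"),
                 "truth": str(out / "truth.csv")}
        outputs = {"truth": truth.table,
                   "counts": {"n_tracks": int(len(truth.table))}}
    else:  # pragma: no cover
        raise ConfigError(f"cannot simulate from spec type {type(spec).__name__}")
    return outputs, files


def _profiles_from_csv(path) -> list:
    tbl = io.read_table(path)
    profs = []
    if "source_id" in tbl.columns:
        groups = tbl.groupby("source_id", sort=False)
    else:
        groups = [("0", tbl)]
    for sid, g in groups:
        profs.append(profiles.Profile(
            positions=g["position_nm"].to_numpy(),
            intensities=g["intensity"].to_numpy(),
            source_id=str(sid)))
    return profs


def _stage_classify(cfg: RunConfig):
    if cfg.input is None:
        raise ConfigError("classify needs 'input' (a profiles CSV or a TIFF image)")
    path = Path(cfg.input)
    if path.suffix.lower() in (".tif", ".tiff"):
        image = io.read_image_stack(path)[0]
        objs = profiles.segment_objects(image)
        profs = []
        for i, obj in enumerate(objs):
            try:
                profs.append(profiles.extract_cross_section(
                    image, obj.centroid_xy, obj.orientation,
                    pixel_size_nm=cfg.imaging.pixel_size, source_id=str(i)))
            except ValueError as exc:
                logger.warning("skipping object %d: %s", i, exc)
    else:
        profs = _profiles_from_csv(path)
    summary, table = profiles.analyze_population(profs, cfg.analysis)
    out = _outdir(cfg)
    io.write_table(table, out / "objects.csv")
    summary_dict = {
        "n_total": summary.n_total, "n_ring": summary.n_ring,
        "n_solid": summary.n_solid, "n_rejected": summary.n_rejected,
        "fraction_solid": summary.fraction_solid,
        "fraction_ring": summary.fraction_ring,
        "mean_diameter_nm": summary.mean_diameter,
        "median_diameter_nm": summary.median_diameter,
        "sd_diameter_nm": summary.sd_diameter,
    }
    return ({"summary": summary_dict, "objects": table},
            {"objects": str(out / "objects.csv")})


def _stage_frap(cfg: RunConfig):
    if cfg.input is None:
        raise ConfigError("frap needs 'input' (a TIFF movie)")
    movie = io.read_image_stack(cfg.input)
    events, est = frap.score_movie(movie, cfg.frame_interval_s, cfg.imaging, cfg.frap_params)
    ev_tbl = pd.DataFrame(
        [(e.x_um, e.y_um, e.first_frame, e.time_s, e.persistence) for e in events],
        columns=["x_um", "y_um", "frame", "time_s", "persistence"])
    out = _outdir(cfg)
    io.write_table(ev_tbl, out / "events.csv")
    rate_tbl = pd.DataFrame([{
        "n_events": est.n_events, "area_um2": est.area_um2,
        "duration_h": est.duration_h, "rate_per_um2_per_h": est.rate}])
    io.write_table(rate_tbl, out / "delivery_rate.csv")
    return ({"events": ev_tbl,
             "rate": {"n_events": est.n_events, "area_um2": est.area_um2,
                      "duration_h": est.duration_h, "rate_per_um2_per_h": est.rate}},
            {"events": str(out / "events.csv"),
             "rate": str(out / "delivery_rate.csv")})


def _stage_track(cfg: RunConfig):
    if cfg.input is None:
        raise ConfigError("track needs 'input' (a TIFF movie or detections CSV)")
    path = Path(cfg.input)
    if path.suffix.lower() in (".tif", ".tiff"):
        movie = io.read_image_stack(path)
        sigma_px = cfg.imaging.psf_sigma / cfg.imaging.pixel_size
        det = tracking.detect_movie_foci(movie, sigma_px,
                                         pixel_size_nm=cfg.imaging.pixel_size)
    else:
        det = io.read_table(path)
    lk = cfg.linking
    tracks = tracking.link_trajectories(det, lk.d_max_nm, lk.max_gap, lk.min_track_len)
    speeds = tracking.speeds_table(tracks, cfg.frame_interval_s,
                                   method=lk.speed_method, min_track_len=lk.min_track_len)
    track_tbl = pd.concat(
        [pd.DataFrame({"track_id": tr.track_id, "frame": tr.frames,
                       "x_nm": tr.x_nm, "y_nm": tr.y_nm}) for tr in tracks],
        ignore_index=True) if tracks else pd.DataFrame(
        columns=["track_id", "frame", "x_nm", "y_nm"])
    out = _outdir(cfg)
    io.write_table(track_tbl, out / "tracks.csv")
    io.write_table(speeds, out / "speeds.csv")
    mean_speed = float(speeds["speed_nm_min"].mean()) if len(speeds) else float("nan")
    return ({"speeds": speeds,
             "speed_summary": {"n_tracks": int(len(speeds)),
                               "mean_speed_nm_min": mean_speed}},
            {"tracks": str(out / "tracks.csv"), "speeds": str(out / "speeds.csv")})


def _stage_coloc(cfg: RunConfig):
    if cfg.input is None or cfg.input_b is None:
        raise ConfigError("coloc needs 'input' and 'input_b' (two TIFF channels)")
    a = io.read_image_stack(cfg.input)[0]
    b = io.read_image_stack(cfg.input_b)[0]
    res = coloc_gold.manders(a, b)
    return ({"coloc": {"m1": res.m1, "m2": res.m2,
                       "threshold_a": res.threshold_a, "threshold_b": res.threshold_b,
                       "method": res.method}}, {})


def _stage_gold(cfg: RunConfig):
    if cfg.input is None:
        raise ConfigError("gold needs 'input' (a particle CSV)")
    tbl = io.read_table(cfg.input)
    if {"x_nm", "y_nm"}.issubset(tbl.columns) and cfg.input_b is not None:
        outline = io.read_table(cfg.input_b)[["x_nm", "y_nm"]].to_numpy()
        dist = coloc_gold.gold_relative_distance(
            tbl[["x_nm", "y_nm"]].to_numpy(), outline=outline)
    elif "position_nm" in tbl.columns:
        length = float(tbl["position_nm"].max())
        dist = coloc_gold.gold_relative_distance(
            tbl["position_nm"].to_numpy(), golgi_length=length)
    else:
        raise ConfigError("gold input needs (x_nm, y_nm) + outline, or position_nm")
    summ = coloc_gold.summarize_distribution(dist.relative_distances)
    out = _outdir(cfg)
    io.write_table(pd.DataFrame({"relative_distance": dist.relative_distances}),
                   out / "gold_distances.csv")
    return ({"gold": {"n": summ.n, "median": summ.median,
                      "q25": summ.q25, "q75": summ.q75}},
            {"distances": str(out / "gold_distances.csv")})


def _stage_compare(cfg: RunConfig):
    if cfg.input is None or cfg.input_b is None:
        raise ConfigError("compare needs 'input' and 'input_b' (single-column CSVs)")
    a = io.read_table(cfg.input).iloc[:, -1].to_numpy(dtype=float)
    b = io.read_table(cfg.input_b).iloc[:, -1].to_numpy(dtype=float)
    res = profiles.compare_groups(a, b)
    return ({"comparison": {"t": res.statistic, "df": res.df,
                            "p_two_tailed": res.p_two_tailed,
                            "variance_test_p": res.variance_test_p,
                            "method": res.method}}, {})


_STAGES = {
    "simulate": _stage_simulate,
    "classify": _stage_classify,
    "frap": _stage_frap,
    "track": _stage_track,
    "coloc": _stage_coloc,
    "gold": _stage_gold,
    "compare": _stage_compare,
}
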