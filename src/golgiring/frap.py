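"""Scoring of plasma-membrane CSC insertion events in post-bleach movies.

After photobleaching the plasma-membrane focal plane, newly delivered
cellulose synthase complexes appear as fluorescent foci.  An appearance is
scored as a genuine insertion event by two criteria: (i) the immediate
neighbourhood of the appearance position must be devoid of foci in the
preceding frames, and (ii) the new focus must persist and track over the
following frames, as a real complex does.  Only events in the central
subregion of the bleached field are counted, so that complexes migrating in
from outside cannot masquerade as deliveries.  The delivery rate is the
event count divided by subregion area and scoring duration (events per um^2
per hour).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .synth import ImagingParams
from .tracking import detect_movie_foci, link_trajectories


@dataclass(frozen=True)
class FrapParams:
    """Scoring thresholds for insertion-event detection.

    r_excl_nm / k_before operationalize "the neighbourhood must be devoid of
    foci before delivery"; k_after is the minimum number of frames a focus
    must remain trackable after appearing; d_max_nm bounds frame-to-frame
    displacement during linking; margin_frac crops the field per side to the
    central scoring subregion; detect_nsigma sets the robust detection
    threshold.
    """

    r_excl_nm: float = 500.0
    k_before: int = 2
    k_after: int = 4
    d_max_nm: float = 400.0
    max_gap: int = 1
    margin_frac: float = 0.2
    detect_nsigma: float = 6.0

    def __post_init__(self) -> None:
        if self.r_excl_nm <= 0:
            raise ValueError("r_excl_nm must be > 0")
        if self.k_before < 1 or self.k_after < 1:
            raise ValueError("k_before and k_after must be >= 1")
        if not 0.0 <= self.margin_frac < 0.5:
            raise ValueError("margin_frac must be in [0, 0.5)")


@dataclass(frozen=True)
class InsertionEvent:
    x_um: float
    y_um: float
    first_frame: int
    time_s: float
    persistence: int  # frames tracked after appearance


@dataclass(frozen=True)
class DeliveryEstimate:
    n_events: int
    area_um2: float
    duration_h: float
    rate: float  # events per um^2 per hour


def delivery_rate(events, area_um2: float, duration_s: float) -> DeliveryEstimate:
    """rate = n_events / (area x duration-in-hours)."""
    if area_um2 <= 0:
        raise ValueError("area_um2 must be > 0")
    if duration_s <= 0:
        raise ValueError("duration_s must be > 0")
    n = events if isinstance(events, (int, np.integer)) else len(events)
    duration_h = duration_s / 3600.0
    return DeliveryEstimate(int(n), float(area_um2), duration_h,
                            rate=n / (area_um2 * duration_h))


def detect_insertion_events(
    movie: np.ndarray,
    imaging: ImagingParams | None = None,
    params: FrapParams | None = None,
    detections=None,
) -> list[InsertionEvent]:
    """Score insertion events in a (T, H, W) post-bleach movie.

    Foci are detected per frame and linked into tracks; a track whose first
    detection is at frame t0 scores an event iff

    * t0 >= k_before (enough history to test the devoid criterion),
    * no other detection lies within r_excl_nm of the appearance position in
      the k_before preceding frames,
    * the track persists >= k_after frames beyond t0, and
    * the appearance position lies inside the central subregion.
    """
    imaging = imaging or ImagingParams()
    params = params or FrapParams()
    movie = np.asarray(movie, dtype=float)
    if movie.ndim != 3:
        raise ValueError("movie must be a (T, H, W) stack")
    n_frames = movie.shape[0]
    if n_frames < params.k_before + params.k_after + 1:
        raise ValueError(
            f"movie has {n_frames} frames; scoring needs >= "
            f"{params.k_before + params.k_after + 1}"
        )

    if detections is None:
        sigma_px = imaging.psf_sigma / imaging.pixel_size
        detections = detect_movie_foci(movie, sigma_px, nsigma=params.detect_nsigma,
                                       pixel_size_nm=imaging.pixel_size)
    det = detections
    tracks = link_trajectories(det, d_max_nm=params.d_max_nm,
                               max_gap=params.max_gap, min_track_len=1)

    by_frame = {int(f): g[["x_nm", "y_nm"]].to_numpy()
                for f, g in det.groupby("frame", sort=True)}
    h_nm = movie.shape[1] * imaging.pixel_size
    w_nm = movie.shape[2] * imaging.pixel_size
    x_lo, x_hi = params.margin_frac * w_nm, (1.0 - params.margin_frac) * w_nm
    y_lo, y_hi = params.margin_frac * h_nm, (1.0 - params.margin_frac) * h_nm

    events = []
    for tr in tracks:
        t0 = tr.start_frame
        if t0 < params.k_before:
            continue
        persistence = tr.end_frame - t0
        if persistence < params.k_after:
            continue
        x0, y0 = tr.x_nm[0], tr.y_nm[0]
        if not (x_lo <= x0 <= x_hi and y_lo <= y0 <= y_hi):
            continue
        devoid = True
        for f in range(t0 - params.k_before, t0):
            prev = by_frame.get(f)
            if prev is not None and prev.size and (
                np.hypot(prev[:, 0] - x0, prev[:, 1] - y0).min() <= params.r_excl_nm
            ):
                devoid = False
                break
        if devoid:
            events.append(InsertionEvent(
                x_um=x0 / 1000.0, y_um=y0 / 1000.0,
                first_frame=t0, time_s=float("nan"), persistence=int(persistence),
            ))
    return events


def central_area_um2(movie_shape, imaging: ImagingParams, margin_frac: float) -> float:
    """Area of the central scoring subregion in um^2."""
    _, h, w = movie_shape
    px_um = imaging.pixel_size / 1000.0
    return (w * px_um * (1 - 2 * margin_frac)) * (h * px_um * (1 - 2 * margin_frac))


def _unblocked_fraction_per_frame(
    movie_shape, detections, imaging: ImagingParams, params: FrapParams
) -> np.ndarray:
    """Fraction of the central subregion where criterion (i) could fire.

    An appearance within r_excl of any detection in the k_before preceding
    frames can never be scored; that area is dead exposure.  The blocked
    mask is rasterized at pixel resolution from the actual detections, so
    the correction mirrors the scoring rule exactly.
    """
    n_frames, h, w = movie_shape
    r_px = params.r_excl_nm / imaging.pixel_size
    r_int = int(np.ceil(r_px))
    yy, xx = np.mgrid[-r_int:r_int + 1, -r_int:r_int + 1]
    disk = (xx**2 + yy**2) <= r_px**2
    by_frame = {int(f): g[["x_nm", "y_nm"]].to_numpy()
                for f, g in detections.groupby("frame", sort=True)}
    x0 = int(round(params.margin_frac * w))
    x1 = int(round((1 - params.margin_frac) * w))
    y0 = int(round(params.margin_frac * h))
    y1 = int(round((1 - params.margin_frac) * h))
    central_px = max(1, (x1 - x0) * (y1 - y0))

    frac = np.ones(n_frames)
    for f in range(params.k_before, n_frames):
        blocked = np.zeros((h, w), dtype=bool)
        for g in range(f - params.k_before, f):
            for x_nm, y_nm in by_frame.get(g, ()):
                cx = int(round(x_nm / imaging.pixel_size))
                cy = int(round(y_nm / imaging.pixel_size))
                ylo, yhi = max(0, cy - r_int), min(h, cy + r_int + 1)
                xlo, xhi = max(0, cx - r_int), min(w, cx + r_int + 1)
                if ylo >= yhi or xlo >= xhi:
                    continue
                blocked[ylo:yhi, xlo:xhi] |= disk[
                    ylo - (cy - r_int):yhi - (cy - r_int),
                    xlo - (cx - r_int):xhi - (cx - r_int)]
        frac[f] = 1.0 - blocked[y0:y1, x0:x1].sum() / central_px
    return frac


def score_movie(
    movie: np.ndarray,
    frame_interval_s: float,
    imaging: ImagingParams | None = None,
    params: FrapParams | None = None,
    occlusion_correction: bool = True,
):
    """Detect events and convert to a delivery rate for one movie.

    The rate denominator is the central-subregion area times the *effective*
    scoring duration.  Appearances are only scoreable in frames
    [k_before, T-1-k_after]; within that window, each frame contributes its
    unblocked fraction of the subregion (the part not within r_excl of a
    focus in the preceding frames, where the devoid criterion can never
    fire).  Setting ``occlusion_correction=False`` uses the raw window with
    no dead-area discount.  Returns (events, DeliveryEstimate) with event
    times filled from the frame interval.
    """
    imaging = imaging or ImagingParams()
    params = params or FrapParams()
    movie = np.asarray(movie, dtype=float)
    sigma_px = imaging.psf_sigma / imaging.pixel_size
    det = detect_movie_foci(movie, sigma_px, nsigma=params.detect_nsigma,
                            pixel_size_nm=imaging.pixel_size)
    events = detect_insertion_events(movie, imaging, params, detections=det)
    events = [
        InsertionEvent(e.x_um, e.y_um, e.first_frame,
                       time_s=e.first_frame * frame_interval_s,
                       persistence=e.persistence)
        for e in events
    ]
    area = central_area_um2(movie.shape, imaging, params.margin_frac)
    last_scoreable = movie.shape[0] - 1 - params.k_after
    if occlusion_correction:
        frac = _unblocked_fraction_per_frame(movie.shape, det, imaging, params)
        duration_s = frac[params.k_before:last_scoreable + 1].sum() * frame_interval_s
    else:
        duration_s = (last_scoreable - params.k_before + 1) * frame_interval_s
    return events, delivery_rate(events, area, duration_s)
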