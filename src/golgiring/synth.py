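"""Seeded synthetic-data generators with per-entity ground truth.

No raw imaging data accompany the measurements this package re-implements,
so every estimator is validated by parameter recovery on simulations that
emulate the original imaging conditions: PSF-blurred ring-shaped and solid
(sub-resolution) Golgi bodies, Poisson-timed plasma-membrane insertion
events with post-insertion motility, constant-velocity foci with
localization noise, and gold-particle positions along a Golgi long axis.
Named presets carry the reported population parameters for the wild-type
and mutant conditions.

Every generator takes an explicit seed (spec field, overridable per call)
and is bit-reproducible; noise can be switched off by setting
``photon_scale=0`` and ``read_noise_sd=0``.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, replace

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .profiles import FWHM_FACTOR, Profile

# ---------------------------------------------------------------------------
# specs
# ---------------------------------------------------------------------------


def _require(cond: bool, name: str, msg: str) -> None:
    if not cond:
        raise ValueError(f"invalid field {name!r}: {msg}")


@dataclass(frozen=True)
class ImagingParams:
    """Optical and camera parameters shared by all image generators.

    pixel_size and psf_fwhm are nm; the default PSF FWHM of 266 nm is the
    stated resolution limit of the spinning-disc system being emulated, and
    the 133 nm pixel is Nyquist sampling of it.  photon_scale sets the
    strength of Poisson shot noise (counts per intensity unit; 0 disables);
    read_noise_sd is additive Gaussian camera noise.  field_size is
    (width, height) in micrometres.
    """

    pixel_size: float = 133.0
    psf_fwhm: float = 266.0
    background: float = 10.0
    photon_scale: float = 1.0
    read_noise_sd: float = 2.0
    field_size: tuple[float, float] = (20.0, 20.0)

    def __post_init__(self) -> None:
        _require(self.pixel_size > 0, "pixel_size", "must be > 0")
        _require(self.psf_fwhm >= self.pixel_size, "psf_fwhm", "must be >= pixel_size")
        _require(self.photon_scale >= 0, "photon_scale", "must be >= 0")
        _require(self.read_noise_sd >= 0, "read_noise_sd", "must be >= 0")
        _require(self.background >= 0, "background", "must be >= 0")
        _require(
            len(self.field_size) == 2 and min(self.field_size) > 0,
            "field_size", "must be a positive (width, height) in um",
        )

    @property
    def psf_sigma(self) -> float:
        """PSF standard deviation in nm."""
        return self.psf_fwhm / FWHM_FACTOR

    def noiseless(self) -> "ImagingParams":
        return replace(self, photon_scale=0.0, read_noise_sd=0.0)


@dataclass(frozen=True)
class GolgiPopulationSpec:
    """A mixed population of ring-shaped and solid Golgi bodies."""

    n_objects: int
    solid_fraction: float
    ring_diameter_mean: float = 800.0
    ring_diameter_sd: float = 150.0
    ring_amplitude: float = 100.0
    solid_amplitude: float = 100.0
    seed: int = 0

    def __post_init__(self) -> None:
        _require(self.n_objects >= 0, "n_objects", "must be >= 0")
        _require(0.0 <= self.solid_fraction <= 1.0, "solid_fraction", "must be in [0, 1]")
        _require(self.ring_diameter_mean > 0, "ring_diameter_mean", "must be > 0")
        _require(self.ring_diameter_sd >= 0, "ring_diameter_sd", "must be >= 0")
        _require(self.ring_amplitude > 0, "ring_amplitude", "must be > 0")
        _require(self.solid_amplitude > 0, "solid_amplitude", "must be > 0")


@dataclass(frozen=True)
class FrapSpec:
    """Post-bleach movie of plasma-membrane insertion events.

    true_rate and decoy_density are events per um^2 per hour.  Inserted foci
    persist and translate at track_speed (nm/min) for track_lifetime seconds
    before leaving the shallow focal volume; decoy flashes last exactly one
    frame so the persistence criterion is the discriminating test.
    """

    true_rate: float
    frame_interval: float = 5.0
    duration: float = 600.0
    track_speed: float = 300.0
    decoy_density: float = 1.0
    track_lifetime: float = 40.0
    amplitude: float = 100.0
    seed: int = 0

    def __post_init__(self) -> None:
        _require(self.true_rate >= 0, "true_rate", "must be >= 0")
        _require(self.frame_interval > 0, "frame_interval", "must be > 0")
        _require(self.duration > self.frame_interval, "duration", "must exceed frame_interval")
        _require(self.track_speed >= 0, "track_speed", "must be >= 0")
        _require(self.decoy_density >= 0, "decoy_density", "must be >= 0")
        _require(self.track_lifetime >= self.frame_interval, "track_lifetime",
                 "must cover at least one frame")
        _require(self.amplitude > 0, "amplitude", "must be > 0")

    @property
    def n_frames(self) -> int:
        return int(round(self.duration / self.frame_interval)) + 1


@dataclass(frozen=True)
class TrackSpec:
    """Constant-velocity foci with isotropic localization noise.

    Speeds are drawn from a normal truncated at 0 whose parameters are
    moment-matched so the *realized* population has mean speed_mean and
    standard deviation speed_sd (nm/min).
    """

    n_tracks: int
    speed_mean: float
    speed_sd: float
    n_frames: int = 30
    frame_interval: float = 5.0
    loc_noise_sd: float = 50.0
    seed: int = 0

    def __post_init__(self) -> None:
        _require(self.n_tracks >= 1, "n_tracks", "must be >= 1")
        _require(self.speed_mean > 0, "speed_mean", "must be > 0")
        _require(self.speed_sd >= 0, "speed_sd", "must be >= 0")
        _require(self.n_frames >= 2, "n_frames", "must be >= 2")
        _require(self.frame_interval > 0, "frame_interval", "must be > 0")
        _require(self.loc_noise_sd >= 0, "loc_noise_sd", "must be >= 0")


@dataclass(frozen=True)
class SimTruth:
    """Ground truth emitted by a generator: one row per generated entity."""

    table: pd.DataFrame
    spec: dict
    seed: int

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# helpers
# ---------------------------------------------------------------------------


def _rng(spec_seed: int, seed: int | None) -> np.random.Generator:
    return np.random.default_rng(spec_seed if seed is None else seed)


def _rng_pair(spec_seed: int, seed: int | None):
    """Independent (structure, noise) streams from one seed.

    Keeping noise on its own stream guarantees that switching noise on or
    off cannot perturb the generated ground truth.
    """
    ss = np.random.SeedSequence(spec_seed if seed is None else seed)
    s_truth, s_noise = ss.spawn(2)
    return np.random.default_rng(s_truth), np.random.default_rng(s_noise)


def _apply_noise(clean: np.ndarray, imaging: ImagingParams, rng: np.random.Generator) -> np.ndarray:
    out = np.asarray(clean, dtype=float)
    if imaging.photon_scale > 0:
        out = rng.poisson(np.clip(out, 0.0, None) * imaging.photon_scale) / imaging.photon_scale
    else:
        out = out.copy()
    if imaging.read_noise_sd > 0:
        out = out + rng.normal(0.0, imaging.read_noise_sd, out.shape)
    return out


def _render_spot(image: np.ndarray, x_px: float, y_px: float, sigma_px: float, flux: float) -> None:
    """Add a normalized 2D Gaussian of total integral ``flux`` in place."""
    h, w = image.shape
    r = int(np.ceil(4.0 * sigma_px)) + 1
    x0, x1 = max(0, int(np.floor(x_px)) - r), min(w, int(np.ceil(x_px)) + r + 1)
    y0, y1 = max(0, int(np.floor(y_px)) - r), min(h, int(np.ceil(y_px)) + r + 1)
    if x0 >= x1 or y0 >= y1:
        return
    xs = np.arange(x0, x1) - x_px
    ys = np.arange(y0, y1) - y_px
    g = np.exp(-0.5 * (ys[:, None] ** 2 + xs[None, :] ** 2) / sigma_px**2)
    image[y0:y1, x0:x1] += flux / (2.0 * np.pi * sigma_px**2) * g


def _grid_shape(imaging: ImagingParams) -> tuple[int, int]:
    w_um, h_um = imaging.field_size
    nx = int(round(w_um * 1000.0 / imaging.pixel_size))
    ny = int(round(h_um * 1000.0 / imaging.pixel_size))
    return ny, nx


def field_area_um2(imaging: ImagingParams) -> float:
    """Area of the rendered pixel grid in um^2 (grid snaps to whole pixels)."""
    ny, nx = _grid_shape(imaging)
    px_um = imaging.pixel_size / 1000.0
    return nx * px_um * ny * px_um


# ---------------------------------------------------------------------------
# profile population
# ---------------------------------------------------------------------------


def generate_profile_population(
    spec: GolgiPopulationSpec,
    imaging: ImagingParams | None = None,
    seed: int | None = None,
    window_nm: float = 2660.0,
):
    """Cross-section profiles through a ring/solid Golgi population.

    Ring profiles are two Gaussians of PSF width centred at -/+D/2 (the
    transect crosses the rim twice); solid profiles are a single PSF-width
    Gaussian.  Ring diameters are drawn from N(mean, sd) truncated below at
    2x the PSF FWHM so that rings are resolvable by construction.  Sampling
    step is pixel_size/2 over a ``window_nm`` window centred on the object.

    Returns (list of Profile, SimTruth) where the truth table has columns
    object_id, class, true_diameter_nm (0 for solids).
    """
    imaging = imaging or ImagingParams()
    _require(2000.0 <= window_nm <= 3000.0, "window_nm", "must be in [2000, 3000] nm")
    rng, rng_noise = _rng_pair(spec.seed, seed)
    step = imaging.pixel_size / 2.0
    n = int(np.floor(window_nm / step)) + 1
    x = (np.arange(n) - (n - 1) / 2.0) * step
    sigma = imaging.psf_sigma
    d_min = 2.0 * imaging.psf_fwhm
    _require(spec.ring_diameter_mean > imaging.psf_fwhm, "ring_diameter_mean",
             "rings must exceed the PSF FWHM to be resolvable")

    profiles, rows = [], []
    for i in range(spec.n_objects):
        is_solid = rng.random() < spec.solid_fraction
        if is_solid:
            clean = imaging.background + spec.solid_amplitude * np.exp(-0.5 * (x / sigma) ** 2)
            d_true = 0.0
            label = "solid"
        else:
            d_true = rng.normal(spec.ring_diameter_mean, spec.ring_diameter_sd)
            while d_true < d_min:  # truncate: sub-resolution rings are not rings
                d_true = rng.normal(spec.ring_diameter_mean, spec.ring_diameter_sd)
            clean = imaging.background + spec.ring_amplitude * (
                np.exp(-0.5 * ((x - d_true / 2.0) / sigma) ** 2)
                + np.exp(-0.5 * ((x + d_true / 2.0) / sigma) ** 2)
            )
            label = "ring"
        noisy = _apply_noise(clean, imaging, rng_noise)
        profiles.append(Profile(positions=x, intensities=noisy, source_id=str(i)))
        rows.append({"object_id": i, "class": label, "true_diameter_nm": d_true})

    truth = SimTruth(pd.DataFrame(rows, columns=["object_id", "class", "true_diameter_nm"]),
                     asdict(spec), spec.seed if seed is None else seed)
    return profiles, truth


# ---------------------------------------------------------------------------
# 2D Golgi field image
# ---------------------------------------------------------------------------


def generate_golgi_image(
    spec: GolgiPopulationSpec,
    imaging: ImagingParams | None = None,
    seed: int | None = None,
    max_tries: int = 10_000,
):
    """Render a field of ring and solid Golgi bodies.

    Rings are a circle of sub-pixel point sources convolved with the
    Gaussian PSF; solids are a single point source.  Total flux per object is
    amplitude x 2*pi*sigma_px^2 regardless of diameter (flux conservation).
    Objects are rejection-placed with centre spacing >= 2x the largest
    diameter; a field too small to host n_objects raises.
    """
    imaging = imaging or ImagingParams()
    rng, rng_noise = _rng_pair(spec.seed, seed)
    ny, nx = _grid_shape(imaging)
    image = np.full((ny, nx), float(imaging.background))
    sigma_px = imaging.psf_sigma / imaging.pixel_size
    d_min = 2.0 * imaging.psf_fwhm
    d_max_nm = max(spec.ring_diameter_mean + 4.0 * spec.ring_diameter_sd, d_min)
    min_sep_px = 2.0 * d_max_nm / imaging.pixel_size
    margin_px = d_max_nm / imaging.pixel_size / 2.0 + 4.0 * sigma_px + 1.0

    centres: list[tuple[float, float]] = []
    rows = []
    for i in range(spec.n_objects):
        for _ in range(max_tries):
            cx = rng.uniform(margin_px, nx - 1 - margin_px)
            cy = rng.uniform(margin_px, ny - 1 - margin_px)
            if all((cx - px) ** 2 + (cy - py) ** 2 >= min_sep_px**2 for px, py in centres):
                break
        else:
            raise ValueError(
                f"field of {nx}x{ny} px cannot place {spec.n_objects} objects "
                f"with centre spacing >= {min_sep_px:.0f} px"
            )
        centres.append((cx, cy))
        is_solid = rng.random() < spec.solid_fraction
        if is_solid:
            flux = spec.solid_amplitude * 2.0 * np.pi * sigma_px**2
            _render_spot(image, cx, cy, sigma_px, flux)
            d_true, label = 0.0, "solid"
        else:
            d_true = rng.normal(spec.ring_diameter_mean, spec.ring_diameter_sd)
            while d_true < d_min:
                d_true = rng.normal(spec.ring_diameter_mean, spec.ring_diameter_sd)
            r_px = d_true / 2.0 / imaging.pixel_size
            n_pts = max(32, int(np.ceil(2.0 * np.pi * r_px / (sigma_px / 4.0))))
            flux = spec.ring_amplitude * 2.0 * np.pi * sigma_px**2
            angles = np.arange(n_pts) * 2.0 * np.pi / n_pts
            for ang in angles:
                _render_spot(image, cx + r_px * np.cos(ang), cy + r_px * np.sin(ang),
                             sigma_px, flux / n_pts)
            label = "ring"
        rows.append({
            "object_id": i, "class": label, "true_diameter_nm": d_true,
            "x_px": cx, "y_px": cy, "orientation": 0.0,
        })

    image = _apply_noise(image, imaging, rng_noise)
    truth = SimTruth(
        pd.DataFrame(rows, columns=["object_id", "class", "true_diameter_nm",
                                    "x_px", "y_px", "orientation"]),
        asdict(spec), spec.seed if seed is None else seed)
    return image, truth


# ---------------------------------------------------------------------------
# FRAP movie
# ---------------------------------------------------------------------------


def generate_frap_movie(
    spec: FrapSpec,
    imaging: ImagingParams | None = None,
    seed: int | None = None,
):
    """Post-bleach time-lapse with Poisson-timed insertion events.

    Insertion times follow a homogeneous Poisson process of intensity
    true_rate x field area; each event appears as a PSF-sized focus that
    persists for ``track_lifetime`` seconds while translating at
    ``track_speed``.  Decoy flashes (density ``decoy_density``) appear for
    exactly one frame.  The truth table lists true events only
    (event_id, time_s, first_frame, x_um, y_um, direction_rad).
    """
    imaging = imaging or ImagingParams()
    rng, rng_noise = _rng_pair(spec.seed, seed)
    ny, nx = _grid_shape(imaging)
    px_um = imaging.pixel_size / 1000.0
    w_um, h_um = nx * px_um, ny * px_um
    area = w_um * h_um
    duration_h = spec.duration / 3600.0
    n_frames = spec.n_frames
    dt = spec.frame_interval
    sigma_px = imaging.psf_sigma / imaging.pixel_size
    flux = spec.amplitude * 2.0 * np.pi * sigma_px**2
    lifetime_frames = max(1, int(round(spec.track_lifetime / dt)))
    speed_um_s = spec.track_speed / 1000.0 / 60.0

    def _draw_events(rate):
        n = rng.poisson(rate * area * duration_h)
        t = np.sort(rng.uniform(0.0, spec.duration, n))
        x = rng.uniform(0.0, w_um, n)
        y = rng.uniform(0.0, h_um, n)
        return t, x, y

    t_ev, x_ev, y_ev = _draw_events(spec.true_rate)
    dir_ev = rng.uniform(0.0, 2.0 * np.pi, t_ev.size)
    t_dc, x_dc, y_dc = _draw_events(spec.decoy_density)

    # an event at time t first appears in the next acquired frame
    first_frame = np.minimum(np.ceil(t_ev / dt).astype(int), n_frames - 1)
    decoy_frame = np.minimum(np.ceil(t_dc / dt).astype(int), n_frames - 1)

    movie = np.empty((n_frames, ny, nx), dtype=float)
    for f in range(n_frames):
        frame = np.full((ny, nx), float(imaging.background))
        visible = (first_frame <= f) & (f < first_frame + lifetime_frames)
        for j in np.nonzero(visible)[0]:
            el = f * dt - t_ev[j]
            x = x_ev[j] + speed_um_s * el * np.cos(dir_ev[j])
            y = y_ev[j] + speed_um_s * el * np.sin(dir_ev[j])
            _render_spot(frame, x / px_um, y / px_um, sigma_px, flux)
        for j in np.nonzero(decoy_frame == f)[0]:
            _render_spot(frame, x_dc[j] / px_um, y_dc[j] / px_um, sigma_px, 0.8 * flux)
        movie[f] = _apply_noise(frame, imaging, rng_noise)

    truth = SimTruth(
        pd.DataFrame({
            "event_id": np.arange(t_ev.size), "time_s": t_ev,
            "first_frame": first_frame, "x_um": x_ev, "y_um": y_ev,
            "direction_rad": dir_ev,
        }),
        asdict(spec), spec.seed if seed is None else seed)
    return movie, truth


# ---------------------------------------------------------------------------
# track set
# ---------------------------------------------------------------------------


def _truncnorm_base_params(mean: float, sd: float) -> tuple[float, float]:
    """Underlying N(mu, sigma) such that truncation at 0 yields (mean, sd).

    For distributions well away from 0 the correction is small; the solve
    keeps the realized first two moments exactly on target.
    """
    if sd == 0:
        return mean, 0.0

    def moments(p):
        mu, sigma = p
        a = -mu / sigma
        d = stats.truncnorm(a, np.inf, loc=mu, scale=sigma)
        return [d.mean() - mean, d.std() - sd]

    sol = optimize.fsolve(moments, x0=[mean, sd], full_output=False)
    mu, sigma = float(sol[0]), float(sol[1])
    return mu, abs(sigma)


def generate_track_set(
    spec: TrackSpec,
    imaging: ImagingParams | None = None,
    seed: int | None = None,
    origin_spacing_um: float = 5.0,
):
    """Straight constant-velocity tracks with localization noise.

    Track origins sit on a sparse grid (``origin_spacing_um``) so that
    nearest-neighbour linking is unambiguous at the generated density; each
    track picks a uniform random direction and a truncated-normal speed.

    Returns (detections DataFrame [frame, x_nm, y_nm, intensity, truth_track],
    SimTruth [track_id, true_speed_nm_min, direction_rad]).
    """
    rng, rng_noise = _rng_pair(spec.seed, seed)
    mu, sigma = _truncnorm_base_params(spec.speed_mean, spec.speed_sd)
    speeds = np.empty(spec.n_tracks)
    for i in range(spec.n_tracks):
        s = rng.normal(mu, sigma) if sigma > 0 else mu
        while s <= 0:
            s = rng.normal(mu, sigma)
        speeds[i] = s
    dirs = rng.uniform(0.0, 2.0 * np.pi, spec.n_tracks)

    side = int(np.ceil(np.sqrt(spec.n_tracks)))
    spacing = origin_spacing_um * 1000.0  # nm
    t = np.arange(spec.n_frames) * spec.frame_interval  # s
    rows = []
    for k in range(spec.n_tracks):
        ox = (k % side) * spacing
        oy = (k // side) * spacing
        v = speeds[k] / 60.0  # nm/s
        x = ox + v * t * np.cos(dirs[k])
        y = oy + v * t * np.sin(dirs[k])
        if spec.loc_noise_sd > 0:
            x = x + rng_noise.normal(0.0, spec.loc_noise_sd, spec.n_frames)
            y = y + rng_noise.normal(0.0, spec.loc_noise_sd, spec.n_frames)
        for f in range(spec.n_frames):
            rows.append((f, x[f], y[f], 1.0, k))

    det = pd.DataFrame(rows, columns=["frame", "x_nm", "y_nm", "intensity", "truth_track"])
    det = det.sort_values(["frame", "truth_track"], kind="stable").reset_index(drop=True)
    truth = SimTruth(
        pd.DataFrame({"track_id": np.arange(spec.n_tracks),
                      "true_speed_nm_min": speeds, "direction_rad": dirs}),
        asdict(spec), spec.seed if seed is None else seed)
    return det, truth


# ---------------------------------------------------------------------------
# gold particles
# ---------------------------------------------------------------------------

GOLD_MODES = ("uniform", "peripheral", "central")


def generate_gold_particles(
    n: int,
    golgi_length: float,
    mode: str = "uniform",
    concentration: float = 2.0,
    seed: int = 0,
) -> pd.DataFrame:
    """1D axial gold-particle positions along a Golgi of length L.

    uniform: flat on [0, L].  central / peripheral: symmetric Beta densities
    about L/2 — central uses Beta(1 + c, 1 + c), peripheral the reciprocal
    shape Beta(1/(1 + c), 1/(1 + c)); c = ``concentration`` (c = 0 recovers
    uniform in both).  Returns a table with columns particle_id, position_nm,
    relative_distance (the |s - L/2| / L periphery statistic, in [0, 0.5]).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if golgi_length <= 0:
        raise ValueError("golgi_length must be > 0")
    if mode not in GOLD_MODES:
        raise ValueError(f"unknown mode {mode!r}; valid modes: {', '.join(GOLD_MODES)}")
    if concentration <= 0:
        raise ValueError("concentration must be > 0")
    rng = np.random.default_rng(seed)
    if mode == "uniform":
        u = rng.uniform(0.0, 1.0, n)
    elif mode == "central":
        u = rng.beta(1.0 + concentration, 1.0 + concentration, n)
    else:
        a = 1.0 / (1.0 + concentration)
        u = rng.beta(a, a, n)
    pos = u * golgi_length
    return pd.DataFrame({
        "particle_id": np.arange(n),
        "position_nm": pos,
        "relative_distance": np.abs(u - 0.5),
    })


# ---------------------------------------------------------------------------
# two-channel co-localization pair
# ---------------------------------------------------------------------------


def generate_coloc_pair(
    n_objects: int,
    overlap_fraction: float,
    imaging: ImagingParams | None = None,
    seed: int = 0,
    amplitude: float = 100.0,
):
    """Two-channel image pair with a controlled co-localized fraction.

    Each channel contains ``n_objects`` Gaussian spots of equal flux;
    ``round(overlap_fraction * n_objects)`` of them sit at identical
    positions in both channels, the rest are channel-exclusive.  With noise
    off and any threshold below the spot signal, Manders M1 = M2 =
    overlap_fraction by construction.  Truth lists per-object channel
    membership ('both', 'a', 'b') and position.
    """
    imaging = imaging or ImagingParams()
    if not 0.0 <= overlap_fraction <= 1.0:
        raise ValueError("overlap_fraction must be in [0, 1]")
    if n_objects < 0:
        raise ValueError("n_objects must be >= 0")
    rng, rng_noise = _rng_pair(seed, None)
    ny, nx = _grid_shape(imaging)
    sigma_px = imaging.psf_sigma / imaging.pixel_size
    margin = 5.0 * sigma_px + 1.0
    min_sep = 10.0 * sigma_px

    n_both = int(round(overlap_fraction * n_objects))
    n_excl = n_objects - n_both
    n_spots = n_both + 2 * n_excl
    centres: list[tuple[float, float]] = []
    for _ in range(n_spots):
        for _ in range(10_000):
            cx = rng.uniform(margin, nx - 1 - margin)
            cy = rng.uniform(margin, ny - 1 - margin)
            if all((cx - px) ** 2 + (cy - py) ** 2 >= min_sep**2 for px, py in centres):
                break
        else:
            raise ValueError(f"field too small to place {n_spots} non-overlapping spots")
        centres.append((cx, cy))

    a = np.full((ny, nx), float(imaging.background))
    b = np.full((ny, nx), float(imaging.background))
    flux = amplitude * 2.0 * np.pi * sigma_px**2
    rows = []
    for i, (cx, cy) in enumerate(centres):
        if i < n_both:
            membership = "both"
        elif i < n_both + n_excl:
            membership = "a"
        else:
            membership = "b"
        if membership in ("both", "a"):
            _render_spot(a, cx, cy, sigma_px, flux)
        if membership in ("both", "b"):
            _render_spot(b, cx, cy, sigma_px, flux)
        rows.append({"object_id": i, "channel": membership, "x_px": cx, "y_px": cy})

    a = _apply_noise(a, imaging, rng_noise)
    b = _apply_noise(b, imaging, rng_noise)
    truth = SimTruth(pd.DataFrame(rows, columns=["object_id", "channel", "x_px", "y_px"]),
                     {"n_objects": n_objects, "overlap_fraction": overlap_fraction}, seed)
    return a, b, truth


# ---------------------------------------------------------------------------
# presets
# ---------------------------------------------------------------------------

#: Named presets carrying the reported population parameters: ring/solid
#: fractions (8% of 870 wild-type Golgi, 54% of 820 mutant Golgi), FRAP
#: delivery rates (4.8 vs 2.2 foci um^-2 h^-1) and foci speeds
#: (255±128 vs 191±92 nm/min).
_PRESETS = {
    "wt_golgi": lambda: GolgiPopulationSpec(n_objects=870, solid_fraction=0.08),
    "stl_golgi": lambda: GolgiPopulationSpec(n_objects=820, solid_fraction=0.54),
    "wt_frap": lambda: FrapSpec(true_rate=4.8, track_speed=255.0),
    "stl_frap": lambda: FrapSpec(true_rate=2.2, track_speed=191.0),
    "wt_speed": lambda: TrackSpec(n_tracks=500, speed_mean=255.0, speed_sd=128.0),
    "stl_speed": lambda: TrackSpec(n_tracks=500, speed_mean=191.0, speed_sd=92.0),
}


def preset(name: str):
    """Return the fully populated spec for a named experimental condition."""
    try:
        factory = _PRESETS[name]
    except KeyError:
        raise ValueError(
            f"unknown preset {name!r}; valid presets: {', '.join(sorted(_PRESETS))}"
        ) from None
    return factory()
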