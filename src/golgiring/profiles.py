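"""Ring-vs-solid Golgi morphometry from 1D fluorescence cross-sections.

A transect through a Golgi body whose cargo sits in the cisternal rim shows
two intensity peaks (a "ring"); a body whose cargo is confined below the
resolution limit shows a single peak (a "solid").  Profiles are classified by
peak counting, then fitted with a two-Gaussian-plus-baseline model:

    I(x) = b + A1 exp(-(x - mu1)^2 / 2 sigma1^2)
             + A2 exp(-(x - mu2)^2 / 2 sigma2^2)

In *free* mode the peak separation ``mu2 - mu1`` is a fit parameter (rings).
In *fixed* mode the separation is pinned to the microscope resolution limit
(266 nm by default), appropriate for unresolved solid bodies.  The object
diameter is defined as the peak separation plus the width of each Gaussian.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import scipy.ndimage as ndi
from scipy import optimize, signal, stats

logger = logging.getLogger(__name__)

#: FWHM of a Gaussian = FWHM_FACTOR * sigma
FWHM_FACTOR = 2.0 * np.sqrt(2.0 * np.log(2.0))

#: Default microscope resolution limit in nm (fixed-mode peak separation).
DEFAULT_RESOLUTION_LIMIT_NM = 266.0


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Profile:
    """A uniformly sampled 1D intensity cross-section.

    positions are physical nm along the transect (ascending, constant step,
    conventionally centred on 0 at the object centroid); intensities are
    arbitrary units.
    """

    positions: np.ndarray
    intensities: np.ndarray
    source_id: str = ""

    def __post_init__(self) -> None:
        pos = np.asarray(self.positions, dtype=float)
        inten = np.asarray(self.intensities, dtype=float)
        object.__setattr__(self, "positions", pos)
        object.__setattr__(self, "intensities", inten)
        if pos.ndim != 1 or inten.shape != pos.shape:
            raise ValueError("positions and intensities must be equal-length 1D arrays")
        if pos.size < 16:
            raise ValueError(f"profile needs >= 16 samples, got {pos.size}")
        steps = np.diff(pos)
        if np.any(steps <= 0):
            raise ValueError("positions must be strictly ascending")
        if np.ptp(steps) > 1e-9 * abs(steps[0]):
            raise ValueError("positions must be uniformly spaced")

    @property
    def step(self) -> float:
        return float(self.positions[1] - self.positions[0])

    @property
    def n(self) -> int:
        return int(self.positions.size)


@dataclass(frozen=True)
class PeakSet:
    """Detected local maxima: (position nm, height a.u., prominence a.u.)."""

    positions: np.ndarray
    heights: np.ndarray
    prominences: np.ndarray

    @property
    def n_peaks(self) -> int:
        return int(np.asarray(self.positions).size)


#: classification labels
RING = "ring"
SOLID = "solid"
REJECTED = "rejected"


@dataclass(frozen=True)
class DoubleGaussianFit:
    baseline: float
    a1: float
    a2: float
    mu1: float
    mu2: float
    sigma1: float
    sigma2: float
    mode: str  # "free" | "fixed"
    resolution_limit: float
    residual_ss: float
    converged: bool

    @property
    def separation(self) -> float:
        return self.mu2 - self.mu1


@dataclass(frozen=True)
class DiameterResult:
    separation: float
    w1: float
    w2: float
    diameter: float
    width_definition: str  # "fwhm" | "two_sigma"


@dataclass(frozen=True)
class PopulationSummary:
    n_total: int
    n_ring: int
    n_solid: int
    n_rejected: int
    fraction_solid: float
    fraction_ring: float
    diameters: np.ndarray
    mean_diameter: float
    median_diameter: float
    sd_diameter: float


@dataclass(frozen=True)
class GroupComparison:
    statistic: float
    df: float
    p_two_tailed: float
    variance_test_p: float
    method: str  # "student_pooled" | "welch"


@dataclass(frozen=True)
class AnalysisConfig:
    """Thresholds for the peak-find / classify / fit pipeline."""

    min_prominence_frac: float = 0.2
    min_separation_nm: float = 200.0
    smooth_sigma_samples: float = 1.0
    resolution_limit_nm: float = DEFAULT_RESOLUTION_LIMIT_NM
    width_definition: str = "fwhm"


# ---------------------------------------------------------------------------
# peak finding and classification
# ---------------------------------------------------------------------------


def estimate_baseline(profile: Profile, outer_frac: float = 0.1) -> float:
    """Mean intensity of the outer ``outer_frac`` of samples (both tails)."""
    k = max(1, int(round(0.5 * outer_frac * profile.n)))
    tails = np.concatenate([profile.intensities[:k], profile.intensities[-k:]])
    return float(tails.mean())


def find_profile_peaks(
    profile: Profile,
    min_prominence_frac: float = 0.2,
    min_separation_nm: float = 200.0,
    smooth_sigma_samples: float = 1.0,
) -> PeakSet:
    """Local maxima with a relative prominence and minimum-spacing gate.

    The profile is lightly Gaussian-smoothed (``smooth_sigma_samples``, in
    sample units) before peak finding so that single-sample shot-noise spikes
    do not register as peaks; the smoothing kernel is narrow relative to the
    PSF so genuine peaks are preserved.  Prominence must exceed
    ``min_prominence_frac`` x (max - baseline), where the baseline is the mean
    of the outer 10% of samples.
    """
    y = profile.intensities
    if smooth_sigma_samples > 0:
        y = ndi.gaussian_filter1d(y, smooth_sigma_samples, mode="nearest")
    baseline = estimate_baseline(profile)
    amplitude = float(y.max() - baseline)
    if amplitude <= 0:
        return PeakSet(np.empty(0), np.empty(0), np.empty(0))
    distance = max(1, int(np.ceil(min_separation_nm / profile.step)))
    idx, props = signal.find_peaks(
        y, prominence=min_prominence_frac * amplitude, distance=distance
    )
    return PeakSet(
        positions=profile.positions[idx],
        heights=y[idx],
        prominences=props["prominences"],
    )


def classify_profile(peaks: PeakSet) -> str:
    """1 peak -> solid, 2 peaks -> ring, otherwise rejected."""
    if peaks.n_peaks == 1:
        return SOLID
    if peaks.n_peaks == 2:
        return RING
    return REJECTED


# ---------------------------------------------------------------------------
# double-Gaussian fitting
# ---------------------------------------------------------------------------


def _model_free(p: np.ndarray, x: np.ndarray) -> np.ndarray:
    b, a1, a2, mu1, mu2, s1, s2 = p
    return (
        b
        + a1 * np.exp(-0.5 * ((x - mu1) / s1) ** 2)
        + a2 * np.exp(-0.5 * ((x - mu2) / s2) ** 2)
    )


def _model_fixed(p: np.ndarray, x: np.ndarray, r: float) -> np.ndarray:
    b, a1, a2, c, s1, s2 = p
    return (
        b
        + a1 * np.exp(-0.5 * ((x - (c - r / 2.0)) / s1) ** 2)
        + a2 * np.exp(-0.5 * ((x - (c + r / 2.0)) / s2) ** 2)
    )


def _initial_guess(profile: Profile, r: float) -> tuple[float, float, float, float, float]:
    """(baseline, a1, a2, mu1, mu2) seeds from detected peaks."""
    b0 = estimate_baseline(profile)
    peaks = find_profile_peaks(profile, min_prominence_frac=0.1)
    x, y = profile.positions, profile.intensities
    if peaks.n_peaks >= 2:
        order = np.argsort(peaks.prominences)[::-1][:2]
        mus = np.sort(peaks.positions[order])
        heights = np.interp(mus, x, y)
        return b0, max(heights[0] - b0, 0.0), max(heights[1] - b0, 0.0), mus[0], mus[1]
    if peaks.n_peaks == 1:
        c = float(peaks.positions[0])
        h = max(float(peaks.heights[0]) - b0, 0.0)
        return b0, h, h, c - r / 2.0, c + r / 2.0
    # no peaks: seed around the intensity-weighted centroid
    w = np.clip(y - b0, 0.0, None)
    c = float((x * w).sum() / w.sum()) if w.sum() > 0 else float(x.mean())
    h = max(float(y.max()) - b0, 0.0)
    return b0, h, h, c - r / 2.0, c + r / 2.0


def fit_double_gaussian(
    profile: Profile,
    mode: str = "free",
    resolution_limit: float = DEFAULT_RESOLUTION_LIMIT_NM,
    psf_fwhm: float = DEFAULT_RESOLUTION_LIMIT_NM,
) -> DoubleGaussianFit:
    """Bounded nonlinear least-squares fit of the two-Gaussian model.

    mode="free": 7 parameters (b, A1, A2, mu1, mu2, sigma1, sigma2).
    mode="fixed": peak separation pinned to ``resolution_limit``; the fit is
    reparameterized by the midpoint c with mu_{1,2} = c -/+ R/2 (6 params).

    A non-converged solver never raises: the result carries converged=False.
    """
    if mode not in ("free", "fixed"):
        raise ValueError(f"mode must be 'free' or 'fixed', got {mode!r}")
    r = float(resolution_limit)
    if mode == "fixed" and r <= 0:
        raise ValueError("resolution_limit must be > 0 in fixed mode")

    x, y = profile.positions, profile.intensities
    span = float(x[-1] - x[0])
    sigma0 = psf_fwhm / FWHM_FACTOR
    sigma_lo, sigma_hi = profile.step / 2.0, span / 2.0
    sigma0 = float(np.clip(sigma0, sigma_lo, sigma_hi))
    b0, a1_0, a2_0, mu1_0, mu2_0 = _initial_guess(profile, r)
    a_hi = max(2.0 * float(np.ptp(y)), 1.0)
    b_lo = min(float(y.min()), 0.0) - 1.0
    b_hi = float(y.max()) + 1.0

    if mode == "free":
        p0 = np.array(
            [b0, a1_0, a2_0,
             np.clip(mu1_0, x[0], x[-1]), np.clip(mu2_0, x[0], x[-1]),
             sigma0, sigma0]
        )
        lo = np.array([b_lo, 0.0, 0.0, x[0], x[0], sigma_lo, sigma_lo])
        hi = np.array([b_hi, a_hi, a_hi, x[-1], x[-1], sigma_hi, sigma_hi])
        res = optimize.least_squares(
            lambda p: _model_free(p, x) - y, p0, bounds=(lo, hi),
            ftol=1e-12, xtol=1e-12, gtol=1e-12, max_nfev=2000,
        )
        b, a1, a2, mu1, mu2, s1, s2 = res.x
        if mu1 > mu2:  # enforce mu1 < mu2 by relabelling
            a1, a2, mu1, mu2, s1, s2 = a2, a1, mu2, mu1, s2, s1
    else:
        c0 = 0.5 * (mu1_0 + mu2_0)
        p0 = np.array([b0, a1_0, a2_0, np.clip(c0, x[0], x[-1]), sigma0, sigma0])
        lo = np.array([b_lo, 0.0, 0.0, x[0], sigma_lo, sigma_lo])
        hi = np.array([b_hi, a_hi, a_hi, x[-1], sigma_hi, sigma_hi])
        res = optimize.least_squares(
            lambda p: _model_fixed(p, x, r) - y, p0, bounds=(lo, hi),
            ftol=1e-12, xtol=1e-12, gtol=1e-12, max_nfev=2000,
        )
        b, a1, a2, c, s1, s2 = res.x
        mu1, mu2 = c - r / 2.0, c + r / 2.0

    return DoubleGaussianFit(
        baseline=float(b), a1=float(a1), a2=float(a2),
        mu1=float(mu1), mu2=float(mu2), sigma1=float(s1), sigma2=float(s2),
        mode=mode, resolution_limit=r,
        residual_ss=float(2.0 * res.cost), converged=bool(res.success),
    )


def object_diameter(fit: DoubleGaussianFit, width_definition: str = "fwhm") -> DiameterResult:
    """Diameter = peak separation + the width of each Gaussian.

    ``fwhm`` uses 2*sqrt(2 ln 2)*sigma per peak (default); ``two_sigma``
    uses 2*sigma.
    """
    if not fit.converged:
        raise ValueError("cannot compute a diameter from a non-converged fit")
    if width_definition == "fwhm":
        w1, w2 = FWHM_FACTOR * fit.sigma1, FWHM_FACTOR * fit.sigma2
    elif width_definition == "two_sigma":
        w1, w2 = 2.0 * fit.sigma1, 2.0 * fit.sigma2
    else:
        raise ValueError(f"width_definition must be 'fwhm' or 'two_sigma', got {width_definition!r}")
    sep = fit.separation
    return DiameterResult(
        separation=sep, w1=w1, w2=w2, diameter=sep + w1 + w2,
        width_definition=width_definition,
    )


# ---------------------------------------------------------------------------
# population analysis
# ---------------------------------------------------------------------------


def analyze_population(profiles, config: AnalysisConfig | None = None):
    """Classify, fit and size every profile; aggregate population statistics.

    Returns (PopulationSummary, per-object pandas.DataFrame).  Rings are
    fitted with a free separation, solids with the separation fixed to the
    resolution limit; rejected profiles (0 or >= 3 peaks) are excluded from
    the class fractions.
    """
    import pandas as pd

    cfg = config or AnalysisConfig()
    rows = []
    for i, prof in enumerate(profiles):
        peaks = find_profile_peaks(
            prof, cfg.min_prominence_frac, cfg.min_separation_nm, cfg.smooth_sigma_samples
        )
        label = classify_profile(peaks)
        rec = {
            "source_id": prof.source_id or str(i),
            "class": label,
            "n_peaks": peaks.n_peaks,
            "separation_nm": np.nan, "w1_nm": np.nan, "w2_nm": np.nan,
            "diameter_nm": np.nan, "converged": False,
        }
        if label in (RING, SOLID):
            fit = fit_double_gaussian(
                prof,
                mode="free" if label == RING else "fixed",
                resolution_limit=cfg.resolution_limit_nm,
            )
            rec["converged"] = fit.converged
            if fit.converged:
                d = object_diameter(fit, cfg.width_definition)
                rec.update(
                    separation_nm=d.separation, w1_nm=d.w1, w2_nm=d.w2,
                    diameter_nm=d.diameter,
                )
        rows.append(rec)

    table = pd.DataFrame(rows)
    n_total = len(table)
    n_ring = int((table["class"] == RING).sum())
    n_solid = int((table["class"] == SOLID).sum())
    n_rejected = n_total - n_ring - n_solid
    n_classified = n_ring + n_solid
    if n_classified == 0:
        logger.warning("all %d profiles rejected by the peak classifier", n_total)
        frac_solid = frac_ring = float("nan")
    else:
        frac_solid = n_solid / n_classified
        frac_ring = n_ring / n_classified
    diams = table["diameter_nm"].dropna().to_numpy()
    summary = PopulationSummary(
        n_total=n_total, n_ring=n_ring, n_solid=n_solid, n_rejected=n_rejected,
        fraction_solid=frac_solid, fraction_ring=frac_ring, diameters=diams,
        mean_diameter=float(diams.mean()) if diams.size else float("nan"),
        median_diameter=float(np.median(diams)) if diams.size else float("nan"),
        sd_diameter=float(diams.std(ddof=1)) if diams.size > 1 else float("nan"),
    )
    return summary, table


# ---------------------------------------------------------------------------
# group comparison (F-test gated t-test)
# ---------------------------------------------------------------------------


def compare_groups(sample_a, sample_b, alpha_var: float = 0.05) -> GroupComparison:
    """Two-tailed t-test with an F-test deciding pooled vs Welch variance.

    A two-sided F-test on the variance ratio chooses the t-test flavour:
    p >= alpha_var -> pooled Student's t, p < alpha_var -> Welch's t.
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each sample needs n >= 2")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if va == 0 or vb == 0:
        raise ValueError("each sample needs nonzero variance")
    fstat = va / vb
    fdist = stats.f(a.size - 1, b.size - 1)
    p_var = float(min(1.0, 2.0 * min(fdist.cdf(fstat), fdist.sf(fstat))))
    equal_var = p_var >= alpha_var
    res = stats.ttest_ind(a, b, equal_var=equal_var)
    return GroupComparison(
        statistic=float(res.statistic),
        df=float(res.df),
        p_two_tailed=float(res.pvalue),
        variance_test_p=p_var,
        method="student_pooled" if equal_var else "welch",
    )


# ---------------------------------------------------------------------------
# segmentation and transect extraction
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SegmentedObject:
    label: int
    mask: np.ndarray           # boolean, full-image shape
    centroid_xy: tuple[float, float]  # (x=col, y=row), intensity-weighted, px
    orientation: float         # radians of the major axis, from +x, in (-pi/2, pi/2]
    area_px: int


def segment_objects(
    image: np.ndarray,
    min_area_px: int = 4,
    max_area_px: int = 10_000,
    smoothing_sigma_px: float = 1.0,
    threshold: float | None = None,
):
    """Smooth, threshold (Otsu unless given), label and filter by area.

    Centroids are intensity-weighted; orientation is the major axis of the
    intensity-weighted second central moments, as the angle from the +x
    (column) axis.  Returns a possibly empty list of SegmentedObject.
    """
    from skimage.filters import threshold_otsu
    from skimage.measure import label as sk_label

    img = np.asarray(image, dtype=float)
    if img.ndim != 2:
        raise ValueError("segment_objects expects a 2D image")
    sm = ndi.gaussian_filter(img, smoothing_sigma_px) if smoothing_sigma_px > 0 else img
    if threshold is None:
        if np.ptp(sm) == 0:
            return []
        threshold = float(threshold_otsu(sm))
    mask = sm > threshold
    labels = sk_label(mask)
    out = []
    for lab in range(1, labels.max() + 1):
        obj_mask = labels == lab
        area = int(obj_mask.sum())
        if not (min_area_px <= area <= max_area_px):
            continue
        w = np.where(obj_mask, img, 0.0)
        total = w.sum()
        rows, cols = np.nonzero(obj_mask)
        wv = w[rows, cols]
        cy = float((rows * wv).sum() / total)
        cx = float((cols * wv).sum() / total)
        # intensity-weighted second central moments in (x, y)
        dx, dy = cols - cx, rows - cy
        mxx = float((wv * dx * dx).sum() / total)
        myy = float((wv * dy * dy).sum() / total)
        mxy = float((wv * dx * dy).sum() / total)
        theta = 0.5 * np.arctan2(2.0 * mxy, mxx - myy)
        out.append(SegmentedObject(lab, obj_mask, (cx, cy), float(theta), area))
    return out


def extract_cross_section(
    image: np.ndarray,
    centroid_xy: tuple[float, float],
    orientation: float,
    length_nm: float = 2000.0,
    pixel_size_nm: float = 133.0,
    source_id: str = "",
) -> Profile:
    """Bilinear line-scan through a centroid at a given orientation.

    Sampling step is pixel_size/2; positions are nm, centred on 0 at the
    centroid.  Raises if the transect leaves the image.
    """
    step = pixel_size_nm / 2.0
    n = int(np.floor(length_nm / step)) + 1
    s = (np.arange(n) - (n - 1) / 2.0) * step
    cx, cy = centroid_xy
    xs = cx + np.cos(orientation) * s / pixel_size_nm
    ys = cy + np.sin(orientation) * s / pixel_size_nm
    h, w = image.shape
    if xs.min() < 0 or xs.max() > w - 1 or ys.min() < 0 or ys.max() > h - 1:
        raise ValueError(
            f"transect for object {source_id or '<unnamed>'} leaves the image "
            f"(x in [{xs.min():.1f}, {xs.max():.1f}], y in [{ys.min():.1f}, {ys.max():.1f}])"
        )
    vals = ndi.map_coordinates(np.asarray(image, dtype=float), [ys, xs], order=1)
    return Profile(positions=s, intensities=vals, source_id=source_id)
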