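"""Manders co-localization coefficients and the immuno-gold periphery statistic.

Manders M1 is the fraction of channel A's intensity (summed over A's
above-threshold pixels) that lies in pixels where channel B is above its
threshold; M2 swaps the roles.  Thresholds default to per-channel Otsu —
reproducible, unlike manually chosen thresholds — with manual override.

The immuno-gold statistic quantifies where cargo sits within a Golgi
cisternal stack seen in a TEM section: each gold particle is projected onto
the Golgi long axis and its distance from the axis midpoint is divided by
the total axis length, giving a value in [0, 0.5] (0 = dead centre,
0.5 = extreme periphery).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np


@dataclass(frozen=True)
class ColocResult:
    m1: float | None
    m2: float | None
    threshold_a: float
    threshold_b: float
    method: str  # "otsu" | "manual"


@dataclass(frozen=True)
class GoldDistribution:
    relative_distances: np.ndarray  # each in [0, 0.5]
    n: int
    median: float
    axis_start: tuple[float, float]
    axis_end: tuple[float, float]


@dataclass(frozen=True)
class DistributionSummary:
    n: int
    median: float
    q25: float
    q75: float
    whisker_low: float
    whisker_high: float
    degenerate: bool
    kde: object | None  # scipy gaussian_kde, None if degenerate


def manders(
    channel_a: np.ndarray,
    channel_b: np.ndarray,
    threshold_a: float | None = None,
    threshold_b: float | None = None,
) -> ColocResult:
    """Thresholded Manders coefficients M1 and M2.

    M1 = sum of A over pixels with B > T_B, divided by the sum of A over
    pixels with A > T_A; M2 symmetric.  Missing thresholds are filled by
    per-channel Otsu.  A channel with zero above-threshold signal yields an
    undefined coefficient reported as None with a warning (never 0).
    """
    from skimage.filters import threshold_otsu

    a = np.asarray(channel_a, dtype=float)
    b = np.asarray(channel_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"channel shapes differ: {a.shape} vs {b.shape}")
    method = "manual" if (threshold_a is not None and threshold_b is not None) else "otsu"
    if threshold_a is None:
        threshold_a = float(threshold_otsu(a))
    if threshold_b is None:
        threshold_b = float(threshold_otsu(b))

    sum_a = a[a > threshold_a].sum()
    sum_b = b[b > threshold_b].sum()
    if sum_a > 0:
        m1 = float(a[b > threshold_b].sum() / sum_a)
    else:
        warnings.warn("channel A has no above-threshold signal; M1 undefined")
        m1 = None
    if sum_b > 0:
        m2 = float(b[a > threshold_a].sum() / sum_b)
    else:
        warnings.warn("channel B has no above-threshold signal; M2 undefined")
        m2 = None
    return ColocResult(m1, m2, float(threshold_a), float(threshold_b), method)


def _principal_axis_endpoints(outline: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Endpoints of the outline's principal (long) axis."""
    pts = np.asarray(outline, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 2:
        raise ValueError("outline must be an (n >= 2, 2) array of points")
    centre = pts.mean(axis=0)
    _, _, vt = np.linalg.svd(pts - centre, full_matrices=False)
    axis = vt[0]
    proj = (pts - centre) @ axis
    return centre + proj.min() * axis, centre + proj.max() * axis


def gold_relative_distance(
    particles: np.ndarray,
    axis_endpoints: tuple | None = None,
    outline: np.ndarray | None = None,
    golgi_length: float | None = None,
    tol: float = 0.05,
) -> GoldDistribution:
    """Per-particle relative distance from the Golgi centre along its axis.

    ``particles`` is an (n, 2) array of 2D points, or a 1D array of axial
    positions if ``golgi_length`` is given.  The axis is either explicit
    ``axis_endpoints`` ((x0, y0), (x1, y1)) or the principal axis of an
    ``outline`` point set.  Each particle is projected onto the axis;
    d_rel = |s - L/2| / L, clipped to [0, 0.5].  Particles projecting
    outside [-tol, 1 + tol] x L raise (wrong outline or axis).
    """
    particles = np.asarray(particles, dtype=float)
    if particles.ndim == 1:
        if golgi_length is None:
            raise ValueError("1D axial positions need golgi_length")
        p0 = np.array([0.0, 0.0])
        p1 = np.array([float(golgi_length), 0.0])
        pts = np.column_stack([particles, np.zeros_like(particles)])
    else:
        pts = particles
        if axis_endpoints is not None:
            p0, p1 = (np.asarray(p, dtype=float) for p in axis_endpoints)
        elif outline is not None:
            p0, p1 = _principal_axis_endpoints(outline)
        else:
            raise ValueError("provide axis_endpoints or outline for 2D particles")
    if pts.shape[0] < 1:
        raise ValueError("need at least one particle")
    length = float(np.linalg.norm(p1 - p0))
    if length <= 0:
        raise ValueError("axis length must be > 0")
    u = (p1 - p0) / length
    s = (pts - p0) @ u / length  # fractional position along the axis
    if s.min() < -tol or s.max() > 1.0 + tol:
        raise ValueError(
            f"particles project outside the axis (fractions in "
            f"[{s.min():.3f}, {s.max():.3f}]); check the outline/endpoints"
        )
    rel = np.clip(np.abs(np.clip(s, 0.0, 1.0) - 0.5), 0.0, 0.5)
    return GoldDistribution(
        relative_distances=rel, n=int(rel.size), median=float(np.median(rel)),
        axis_start=(float(p0[0]), float(p0[1])), axis_end=(float(p1[0]), float(p1[1])),
    )


def summarize_distribution(values) -> DistributionSummary:
    """Median, quartiles, 1.5xIQR whiskers and a kernel density estimate.

    Percentiles use linear interpolation (the type-7 convention).  A
    zero-variance sample is flagged degenerate and gets no density estimate.
    """
    from scipy.stats import gaussian_kde

    v = np.asarray(values, dtype=float)
    if v.size < 1:
        raise ValueError("need at least one value")
    q25, med, q75 = np.percentile(v, [25, 50, 75])
    iqr = q75 - q25
    degenerate = bool(np.ptp(v) == 0)
    kde = None
    if not degenerate and v.size >= 2:
        kde = gaussian_kde(v)
    return DistributionSummary(
        n=int(v.size), median=float(med), q25=float(q25), q75=float(q75),
        whisker_low=float(q25 - 1.5 * iqr), whisker_high=float(q75 + 1.5 * iqr),
        degenerate=degenerate, kde=kde,
    )
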