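"""Profile-mode peak statistics.

Centroiding collapses the cloud of raw (m/z, intensity) points that traces
each spectral peak into a single number and throws away the spread, which is
precisely the information needed to attach an uncertainty to the peak.  This
module keeps the cloud: points are noise-filtered, clustered into peaks by a
relative (ppm) gap rule, and each cluster is summarised by an
intensity-weighted centroid, a t-based confidence interval of the mean m/z
(in ppm of the centroid), a Shapiro-Wilk normality p-value, the point count
and the peak's share of the total spectrum intensity.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, NamedTuple, Sequence

import numpy as np
from scipy import stats

__all__ = [
    "ProfilePoint",
    "PeakCluster",
    "Peak",
    "filter_noise",
    "cluster_points",
    "estimate_peak",
    "pick_peaks",
]


class ProfilePoint(NamedTuple):
    """One raw signal point of a profile-mode spectrum."""

    mz: float
    intensity: float


@dataclass(frozen=True)
class PeakCluster:
    """A maximal run of profile points belonging to one spectral peak."""

    points: tuple[ProfilePoint, ...]

    def __post_init__(self) -> None:
        if not self.points:
            raise ValueError("a peak cluster cannot be empty")

    @property
    def mz(self) -> np.ndarray:
        return np.array([p.mz for p in self.points])

    @property
    def intensity(self) -> np.ndarray:
        return np.array([p.intensity for p in self.points])

    @property
    def total_intensity(self) -> float:
        return float(self.intensity.sum())

    def __len__(self) -> int:
        return len(self.points)


@dataclass(frozen=True)
class Peak:
    """A spectral peak with its centroid and uncertainty summary.

    ``ci_ppm`` is the half-width of the two-sided confidence interval of the
    mean m/z, expressed in ppm of the centroid; it is ``None`` for a
    single-point cluster, where no dispersion estimate exists.  ``shapiro_p``
    is ``None`` when the normality test is undefined (fewer than three
    points, or zero spread).
    """

    centroid_mz: float
    ci_ppm: float | None
    n_points: int
    total_intensity: float
    relative_intensity_pct: float
    shapiro_p: float | None = None

    @property
    def normality_warning(self) -> bool:
        """Shapiro-Wilk rejected normality at the 5% level."""
        return self.shapiro_p is not None and self.shapiro_p < 0.05


def _as_points(points: Iterable) -> list[ProfilePoint]:
    return [p if isinstance(p, ProfilePoint) else ProfilePoint(float(p[0]), float(p[1]))
            for p in points]


def filter_noise(points: Sequence, noise_threshold: float) -> list[ProfilePoint]:
    """Drop points below the intensity threshold, preserving order."""
    if noise_threshold < 0:
        raise ValueError("noise threshold must be non-negative")
    return [p for p in _as_points(points) if p.intensity >= noise_threshold]


def cluster_points(points: Sequence, gap_ppm: float) -> list[PeakCluster]:
    """Partition m/z-sorted points into maximal runs whose consecutive gaps
    do not exceed ``gap_ppm`` relative to the local m/z."""
    pts = _as_points(points)
    if not pts:
        return []
    mzs = [p.mz for p in pts]
    if any(b < a for a, b in zip(mzs, mzs[1:])):
        raise ValueError("points must be sorted by ascending m/z")
    clusters: list[PeakCluster] = []
    start = 0
    for i in range(1, len(pts)):
        gap = pts[i].mz - pts[i - 1].mz
        if gap > gap_ppm * pts[i - 1].mz * 1e-6:
            clusters.append(PeakCluster(tuple(pts[start:i])))
            start = i
    clusters.append(PeakCluster(tuple(pts[start:])))
    return clusters


def estimate_peak(
    cluster: PeakCluster,
    confidence_level: float = 0.95,
    spectrum_total_intensity: float | None = None,
    weighted: bool = True,
) -> Peak:
    """Summarise a cluster into a :class:`Peak`.

    The centroid is the intensity-weighted mean m/z by default (``weighted=False``
    gives the plain mean, useful for sensitivity checks).  The confidence
    interval is the classical t-interval of the mean,
    ``t(level, n-1) * s / sqrt(n)``, converted to ppm of the centroid, with
    ``s`` the unweighted sample standard deviation of the m/z values.
    """
    if not 0 < confidence_level < 1:
        raise ValueError("confidence level must be in (0, 1)")
    mz = cluster.mz
    inten = cluster.intensity
    n = len(mz)
    total = cluster.total_intensity
    if weighted and total > 0:
        centroid = float(np.average(mz, weights=inten))
    else:
        centroid = float(mz.mean())

    ci_ppm: float | None
    if n == 1:
        ci_ppm = None
    else:
        s = float(mz.std(ddof=1))
        half = stats.t.ppf(0.5 + confidence_level / 2, n - 1) * s / np.sqrt(n)
        ci_ppm = float(half / centroid * 1e6)

    shapiro_p: float | None = None
    if n >= 3 and float(mz.std()) > 0:
        shapiro_p = float(stats.shapiro(mz).pvalue)

    if spectrum_total_intensity is None or spectrum_total_intensity <= 0:
        rel = 100.0
    else:
        rel = 100.0 * total / spectrum_total_intensity
    return Peak(
        centroid_mz=centroid,
        ci_ppm=ci_ppm,
        n_points=n,
        total_intensity=total,
        relative_intensity_pct=rel,
        shapiro_p=shapiro_p,
    )


def pick_peaks(
    points: Sequence,
    noise_threshold: float = 0.0,
    gap_ppm: float = 10.0,
    confidence_level: float = 0.95,
    min_cluster_points: int = 3,
    intensity_floor_pct: float = 1.0,
    weighted: bool = True,
) -> list[Peak]:
    """Full profile -> peak pipeline: noise filter, ppm-gap clustering, and
    per-cluster estimation.

    Clusters smaller than ``min_cluster_points`` are kept only when they are
    intensity-dominant (at least ``intensity_floor_pct`` percent of the total
    retained intensity); the Shapiro-Wilk test needs three points, and tiny
    stray clusters are usually split-offs or residual noise.
    """
    kept = filter_noise(points, noise_threshold)
    kept.sort(key=lambda p: p.mz)
    clusters = cluster_points(kept, gap_ppm)
    total = sum(c.total_intensity for c in clusters)
    peaks = []
    for c in clusters:
        if len(c) < min_cluster_points:
            if total <= 0 or 100.0 * c.total_intensity / total < intensity_floor_pct:
                continue
        peaks.append(
            estimate_peak(c, confidence_level, spectrum_total_intensity=total,
                          weighted=weighted)
        )
    return peaks
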