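"""Orientation histograms and circular statistics of fiber direction.

Fiber orientation in a 2-D image is an axial quantity (θ and θ+180° are the
same direction), summarized here by a normalized 180-bin histogram f(θ) over
[0°, 180°) with 1° bins.  Three histograms are produced per image: one from
the Fourier spectrum of each channel (SHG, TPEF) and one from the angles of
individually traced collagen fibers.

From each histogram the mean vector V̄ = (X̄, Ȳ) is accumulated directly on
the [0, π) support,

    X̄ = Σ f(θ) cos θ,   Ȳ = Σ f(θ) sin θ,

without the doubled-angle transform of classical axial statistics.  The mean
vector length MVL = √(X̄² + Ȳ²) then measures directional concentration, but
note a perfectly uniform histogram yields MVL = 2/π ≈ 0.6366 rather than 0;
a doubled-angle variant is available as a separate diagnostic.  The range R
is the smallest circular arc (in radians, respecting the period π) whose bins
carry strictly more than half of the histogram's weight.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

N_BINS = 180
BIN_RAD = np.pi / N_BINS  # 1 degree


class DegenerateHistogramError(ValueError):
    pass


@dataclass
class OrientationHistogram:
    """Normalized axial histogram over [0°, 180°), 1° bins at integer degrees."""

    f: np.ndarray
    source: str = ""

    def __post_init__(self) -> None:
        self.f = np.asarray(self.f, dtype=np.float64)
        if self.f.shape != (N_BINS,):
            raise ValueError(f"expected {N_BINS} bins, got {self.f.shape}")
        if np.any(self.f < 0):
            raise ValueError("histogram frequencies must be nonnegative")

    @property
    def theta_rad(self) -> np.ndarray:
        return np.arange(N_BINS) * BIN_RAD

    def normalized(self) -> "OrientationHistogram":
        total = self.f.sum()
        if total <= 0:
            raise DegenerateHistogramError("histogram has zero total weight")
        return OrientationHistogram(self.f / total, source=self.source)


@dataclass
class CircularSummary:
    """Mean vector and dispersion of one orientation histogram.

    Attributes
    ----------
    x_bar, y_bar : components of the mean vector V̄.
    mvl : mean vector length √(X̄²+Ȳ²), in [0, 1].
    range_rad : smallest arc (radians) holding > 1/2 of the weight, in (0, π].
    mean_angle_rad : mean direction Θ̄ mapped to [0, π).
    """

    x_bar: float
    y_bar: float
    mvl: float
    range_rad: float
    mean_angle_rad: float


def circular_summary(hist: OrientationHistogram) -> CircularSummary:
    """Summarize a normalized orientation histogram.

    The histogram must be normalized (Σf = 1 within 1e-9).  The range is
    found by exhaustive scan over all circularly-contiguous bin runs; ties
    between runs of equal weight condition are broken toward the shorter arc,
    then the smaller start angle.
    """
    f = hist.f
    if abs(f.sum() - 1.0) > 1e-9:
        raise ValueError("histogram must be normalized to Σf = 1")
    theta = hist.theta_rad
    x_bar = float(np.sum(f * np.cos(theta)))
    y_bar = float(np.sum(f * np.sin(theta)))
    mvl = float(np.hypot(x_bar, y_bar))
    mean_angle = float(np.arctan2(y_bar, x_bar) % np.pi)
    return CircularSummary(x_bar, y_bar, mvl, _range_scan(f), mean_angle)


def _range_scan(f: np.ndarray) -> float:
    """Shortest circular run of bins with summed weight strictly > 1/2.

    Scans run lengths in increasing order so the first hit is the shortest
    arc; within a length, start bins are scanned in increasing angle order.
    Run length L covers L bins = L degrees of arc.
    """
    n = f.size
    # circular windowed sums via doubled prefix sums
    ext = np.concatenate([f, f])
    csum = np.concatenate([[0.0], np.cumsum(ext)])
    for length in range(1, n + 1):
        window = csum[length : length + n] - csum[:n]
        hits = np.nonzero(window > 0.5 + 1e-15)[0]
        if hits.size:
            return length * BIN_RAD
    return n * BIN_RAD


def doubled_angle_mvl(hist: OrientationHistogram) -> float:
    """Classical axial concentration: MVL on doubled angles (uniform → 0).

    Diagnostic only; the headline MVL is the direct-accumulation form above.
    """
    f = hist.f / hist.f.sum()
    theta2 = 2.0 * hist.theta_rad
    return float(np.hypot(np.sum(f * np.cos(theta2)), np.sum(f * np.sin(theta2))))


def angle_mismatch(summary_a: CircularSummary, summary_b: CircularSummary) -> float:
    """Axial circular distance between two mean angles, period π, in [0, π/2]."""
    d = abs(summary_a.mean_angle_rad - summary_b.mean_angle_rad) % np.pi
    return float(min(d, np.pi - d))


def fiber_angle_histogram(angles_deg) -> OrientationHistogram:
    """Bin per-fiber orientation angles (degrees in [0, 180)) into 1° bins."""
    angles = np.asarray(angles_deg, dtype=np.float64)
    if angles.size == 0:
        raise DegenerateHistogramError("no fibers to histogram")
    bins = np.floor(angles % 180.0).astype(int)
    f = np.bincount(bins, minlength=N_BINS).astype(np.float64)
    return OrientationHistogram(f / f.sum(), source="fiber_angles")


def directionality_histogram(frame: np.ndarray, source: str = "") -> OrientationHistogram:
    """Fourier-spectrum orientation distribution of image structures.

    The windowed power spectrum of the frame is binned by polar angle.
    Spectral energy at spatial frequency direction φ comes from structures
    oriented at φ + 90°, so bins are mapped back to the structure angle with
    0° along the image x-axis and counterclockwise positive.  The DC region
    is excluded; the histogram is normalized to Σf = 1.
    """
    img = np.asarray(frame, dtype=np.float64)
    if img.ndim != 2:
        raise ValueError("frame must be 2-D")
    if img.std() == 0:
        raise DegenerateHistogramError("constant frame has no directionality")
    h, w = img.shape
    win = np.outer(np.hanning(h), np.hanning(w))
    spec = np.abs(np.fft.fftshift(np.fft.fft2((img - img.mean()) * win))) ** 2

    yy, xx = np.mgrid[0:h, 0:w]
    cy, cx = h // 2, w // 2
    # image row axis points down; use -dy so angles are CCW in conventional axes
    dy, dx = -(yy - cy).astype(float), (xx - cx).astype(float)
    r = np.hypot(dx, dy)
    # structure angle = spectral angle + 90°, axial (mod 180)
    ang = (np.degrees(np.arctan2(dy, dx)) + 90.0) % 180.0
    rmax = min(cy, cx)
    sel = (r >= 2.0) & (r <= rmax)
    bins = np.floor(ang[sel]).astype(int) % N_BINS
    f = np.bincount(bins, weights=spec[sel], minlength=N_BINS)
    total = f.sum()
    if total <= 0:
        raise DegenerateHistogramError("no spectral energy off DC")
    return OrientationHistogram(f / total, source=source)
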