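"""Synthetic two-channel fibrous-tissue image generator.

Generates labeled (SHG, TPEF) image pairs that emulate the three myocardial
phenotypes seen after infarction:

* ``muscle`` — TPEF-dominant long parallel myocyte fibers with a few short,
  thin collagen strands between them;
* ``border`` — interlaced, longer and thicker collagen among disordered
  myocardium;
* ``fibrosis`` — SHG-dominant mesh of thick, long, wavy collagen with sparse
  amorphous residual fluorescence.

Each fiber is an additive ridge with an approximately Gaussian cross-section
rendered along a (possibly wavy) centerline.  Orientations are axial: they
are drawn with the doubled-angle construction (a von Mises draw on the full
circle at concentration kappa around the doubled mean, halved back to
[0°, 180°)), which keeps kappa interpretable as a concentration for axial
data.  Noise is Poisson shot noise on the rendered signal plus additive
Gaussian read noise; images are stored in 16-bit containers with a ~10-bit
signal range.

Ground truth (the exact fiber records rendered per channel) is returned with
every image so downstream estimators can be validated by parameter recovery.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .fibers import FiberRecord
from .image_io import TwoChannelStack

DEFAULT_SIZE_PX = 512
DEFAULT_PIXEL_SIZE_UM = 508.0 / 512.0
U16_MAX = 65535


@dataclass
class TissuePhenotype:
    """Parameter bundle for one tissue class.

    Lengths and widths are micrometres; orientation means are degrees in
    [0, 180); kappa values are von-Mises-style concentrations on doubled
    angles (0 = isotropic); waviness in [0, 1] (0 = straight fibers);
    intensity scales and background are photon-count-like levels that must
    fit the 16-bit container.
    """

    label: str
    collagen_fiber_count: int
    collagen_length_mean_um: float
    collagen_length_sd_um: float
    collagen_width_mean_um: float
    collagen_width_sd_um: float
    collagen_orientation_mean_deg: float
    collagen_orientation_kappa: float
    collagen_waviness: float
    collagen_intensity_scale: float
    myocardium_fiber_count: int
    myocardium_orientation_kappa: float
    myocardium_intensity_scale: float
    myocardium_orientation_mean_deg: float = 90.0
    myocardium_length_mean_um: float = 300.0
    myocardium_length_sd_um: float = 60.0
    myocardium_width_mean_um: float = 14.0
    myocardium_width_sd_um: float = 3.0
    myocardium_waviness: float = 0.1
    tpef_diffuse_level: float = 0.0  # amorphous low-level autofluorescence
    background_level: float = 8.0
    noise_gaussian_sd: float = 3.0

    def __post_init__(self) -> None:
        if self.collagen_fiber_count < 0 or self.myocardium_fiber_count < 0:
            raise ValueError("fiber counts must be >= 0")
        if self.collagen_orientation_kappa < 0 or self.myocardium_orientation_kappa < 0:
            raise ValueError("kappa must be >= 0")
        if not 0.0 <= self.collagen_waviness <= 1.0:
            raise ValueError("waviness must lie in [0, 1]")
        if not 0.0 <= self.collagen_orientation_mean_deg < 180.0:
            raise ValueError("orientation mean must lie in [0, 180)")
        for name in ("collagen_length_mean_um", "collagen_width_mean_um"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        peak = max(self.collagen_intensity_scale, self.myocardium_intensity_scale)
        if self.background_level < 0 or self.background_level + peak > U16_MAX:
            raise ValueError("intensity scales must fit the 16-bit container")


@dataclass
class GroundTruth:
    """Rendered fiber records per channel plus the generating parameters."""

    collagen_fibers: list[FiberRecord]
    myocardium_fibers: list[FiberRecord]
    phenotype: TissuePhenotype
    seed: int


def render_fiber(centerline: np.ndarray, width_px: float, peak_intensity: float,
                 canvas: np.ndarray, profile: str = "gaussian") -> np.ndarray:
    """Add one fiber ridge to ``canvas`` and return it.

    With the default ``profile="gaussian"`` the ridge cross-section is
    approximately Gaussian with full width at half maximum ≈ ``width_px``
    and maximum ``peak_intensity`` on the centerline.  ``profile="plateau"``
    saturates the same ridge into a flat-topped cross-section, emulating the
    filled, near-uniform fluorescence of myocyte bundles (a Gaussian ridge
    emulates a thin bright collagen strand instead).  The centerline must
    lie inside the canvas bounds.
    """
    centerline = np.asarray(centerline, dtype=float)
    if centerline.size == 0:
        raise ValueError("empty centerline: a fiber needs at least one point")
    centerline = np.atleast_2d(centerline)
    if width_px < 1:
        raise ValueError("width_px must be >= 1")
    h, w = canvas.shape
    if (centerline[:, 0].min() < 0 or centerline[:, 0].max() > h - 1
            or centerline[:, 1].min() < 0 or centerline[:, 1].max() > w - 1):
        raise ValueError("centerline exceeds canvas bounds")
    if peak_intensity == 0:
        return canvas

    from scipy.ndimage import gaussian_filter

    sigma = width_px / 2.3548  # FWHM -> Gaussian sigma
    pad = int(np.ceil(4 * sigma)) + 2
    r0 = max(int(np.floor(centerline[:, 0].min())) - pad, 0)
    r1 = min(int(np.ceil(centerline[:, 0].max())) + pad + 1, h)
    c0 = max(int(np.floor(centerline[:, 1].min())) - pad, 0)
    c1 = min(int(np.ceil(centerline[:, 1].max())) + pad + 1, w)

    patch = np.zeros((r1 - r0, c1 - c0))
    pts = _densify(centerline, step=0.4)
    rows = np.clip(np.rint(pts[:, 0]).astype(int) - r0, 0, patch.shape[0] - 1)
    cols = np.clip(np.rint(pts[:, 1]).astype(int) - c0, 0, patch.shape[1] - 1)
    patch[rows, cols] = 1.0
    patch = gaussian_filter(patch, sigma)
    m = patch.max()
    if m > 0:
        if profile == "plateau":
            patch = np.tanh(3.0 * patch / m) / np.tanh(3.0)
            m = patch.max()
        elif profile != "gaussian":
            raise ValueError(f"unknown profile {profile!r}")
        patch *= peak_intensity / m
    canvas[r0:r1, c0:c1] += patch
    return canvas


def _densify(poly: np.ndarray, step: float = 0.4) -> np.ndarray:
    """Resample a polyline at roughly uniform arc-length spacing."""
    if len(poly) == 1:
        return poly
    seg = np.hypot(*np.diff(poly, axis=0).T)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    if s[-1] == 0:
        return poly[:1]
    t = np.arange(0.0, s[-1] + step, step)
    return np.column_stack([np.interp(t, s, poly[:, 0]), np.interp(t, s, poly[:, 1])])


def _sample_axial_angle(mean_deg: float, kappa: float, rng: np.random.Generator) -> float:
    """Doubled-angle axial draw: von Mises on 2θ, halved back to [0, 180)."""
    mu2 = np.radians(2.0 * mean_deg)
    phi = rng.vonmises(mu2, kappa) if kappa > 0 else rng.uniform(-np.pi, np.pi)
    return float(np.degrees(phi / 2.0) % 180.0)


def _trunc_positive_normal(mean: float, sd: float, rng: np.random.Generator,
                           floor: float = 1e-3) -> float:
    for _ in range(100):
        x = rng.normal(mean, sd)
        if x > floor:
            return float(x)
    return max(mean, floor)


def sample_fiber(
    phenotype: TissuePhenotype,
    channel: str,
    rng: np.random.Generator,
    size_px: int = DEFAULT_SIZE_PX,
    pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM,
) -> FiberRecord:
    """Draw one fiber's geometry for the given channel ("SHG" or "TPEF").

    Length and width come from the phenotype's truncated-normal
    distributions; orientation from the doubled-angle axial model; a waviness
    > 0 bends the centerline into a smooth sinusoid whose straightness
    (endpoint distance / arc length) decreases as waviness grows.
    """
    if channel == "SHG":
        length = _trunc_positive_normal(phenotype.collagen_length_mean_um,
                                        phenotype.collagen_length_sd_um, rng)
        width = _trunc_positive_normal(phenotype.collagen_width_mean_um,
                                       phenotype.collagen_width_sd_um, rng)
        angle = _sample_axial_angle(phenotype.collagen_orientation_mean_deg,
                                    phenotype.collagen_orientation_kappa, rng)
        waviness = phenotype.collagen_waviness
    elif channel == "TPEF":
        length = _trunc_positive_normal(phenotype.myocardium_length_mean_um,
                                        phenotype.myocardium_length_sd_um, rng)
        width = _trunc_positive_normal(phenotype.myocardium_width_mean_um,
                                       phenotype.myocardium_width_sd_um, rng)
        angle = _sample_axial_angle(phenotype.myocardium_orientation_mean_deg,
                                    phenotype.myocardium_orientation_kappa, rng)
        waviness = phenotype.myocardium_waviness
    else:
        raise ValueError(f"unknown channel {channel!r}")

    length_px = length / pixel_size_um
    centerline = _wavy_centerline(length_px, angle, waviness, size_px, rng)
    arc = float(np.sum(np.hypot(*np.diff(centerline, axis=0).T))) if len(centerline) > 1 else 0.0
    chord = float(np.hypot(*(centerline[-1] - centerline[0]))) if len(centerline) > 1 else 0.0
    straightness = min(chord / arc, 1.0) if arc > 0 else 1.0
    return FiberRecord(
        centerline=centerline,
        length_um=arc * pixel_size_um,
        width_um=width,
        straightness=straightness,
        angle_deg=angle,
    )


def _wavy_centerline(length_px: float, angle_deg: float, waviness: float,
                     size_px: int, rng: np.random.Generator) -> np.ndarray:
    """Sinusoidally perturbed centerline of the requested arc length."""
    n = max(int(np.ceil(length_px)), 2)
    t = np.linspace(0.0, 1.0, n)
    if waviness > 0:
        n_periods = rng.integers(1, 3)
        phase = rng.uniform(0, 2 * np.pi)
        amp = 0.25 * waviness * length_px / n_periods
        lateral = amp * np.sin(2 * np.pi * n_periods * t + phase)
    else:
        lateral = np.zeros_like(t)
    x_loc = t * length_px
    # rescale along-axis coordinate so the arc length matches length_px
    arc = np.sum(np.hypot(np.diff(x_loc), np.diff(lateral)))
    if arc > 0:
        x_loc *= length_px / arc
        lateral *= length_px / arc

    ang = np.radians(angle_deg)
    # CCW-positive angle in image coordinates (row axis points down)
    rows = -np.sin(ang) * x_loc + np.cos(ang) * lateral
    cols = np.cos(ang) * x_loc + np.sin(ang) * lateral
    poly = np.column_stack([rows, cols])
    poly -= poly.mean(axis=0)

    margin = 2.0
    span = poly.max(axis=0) - poly.min(axis=0)
    free = np.maximum(size_px - 1 - 2 * margin - span, 0.0)
    lo = margin - poly.min(axis=0)
    center = lo + rng.uniform(0, 1, size=2) * free
    poly = poly + center
    return np.clip(poly, margin, size_px - 1 - margin)


def generate_image(
    phenotype: TissuePhenotype,
    size_px: int = DEFAULT_SIZE_PX,
    pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM,
    seed: int = 0,
) -> tuple[tuple[np.ndarray, np.ndarray], GroundTruth]:
    """Render one (SHG, TPEF) frame pair plus its ground truth.

    Deterministic given ``seed``.  The SHG channel holds the rendered
    collagen fibers, the TPEF channel the myocardium fibers; both get the
    phenotype's background level, Poisson shot noise on the signal and
    additive Gaussian read noise, clipped into the 16-bit container.
    """
    if size_px < 64:
        raise ValueError("size_px must be >= 64")
    rng = np.random.default_rng(seed)
    channels = {}
    truth: dict[str, list[FiberRecord]] = {}
    for channel, count, scale, profile in (
        ("SHG", phenotype.collagen_fiber_count,
         phenotype.collagen_intensity_scale, "gaussian"),
        ("TPEF", phenotype.myocardium_fiber_count,
         phenotype.myocardium_intensity_scale, "plateau"),
    ):
        canvas = np.zeros((size_px, size_px))
        fibers = []
        for _ in range(count):
            fib = sample_fiber(phenotype, channel, rng, size_px, pixel_size_um)
            peak = scale * rng.uniform(0.7, 1.3)
            render_fiber(fib.centerline, max(fib.width_um / pixel_size_um, 1.0),
                         peak, canvas, profile=profile)
            fibers.append(fib)
        if count > 0 and scale > 0:
            # signal saturates at tissue level: overlapping structures do
            # not double their emission (fluorophore density saturates;
            # crossing collagen fibers do not phase-match coherently) and
            # the detector range is finite
            canvas = scale * np.tanh(canvas / scale)
        if channel == "TPEF":
            if phenotype.tpef_diffuse_level > 0:
                # amorphous residual fluorescence: a smooth nonnegative haze
                # that raises the mean intensity without segmentable structure
                from scipy.ndimage import gaussian_filter
                haze = gaussian_filter(rng.normal(0.0, 1.0, canvas.shape),
                                       size_px / 16)
                haze = haze - haze.min()
                mean = haze.mean()
                if mean > 0:
                    canvas = canvas + phenotype.tpef_diffuse_level * haze / mean
        truth[channel] = fibers
        shot = rng.poisson(np.clip(canvas, 0, None)).astype(np.float64)
        out = shot + phenotype.background_level \
            + rng.normal(0.0, phenotype.noise_gaussian_sd, canvas.shape)
        channels[channel] = np.clip(np.floor(out + 0.5), 0, U16_MAX).astype(np.uint16)
    gt = GroundTruth(truth["SHG"], truth["TPEF"], phenotype, seed)
    return (channels["SHG"], channels["TPEF"]), gt


def default_presets() -> dict[str, TissuePhenotype]:
    """Study-condition phenotypes for the three tissue classes.

    The presets encode the qualitative class contrast of infarcted
    myocardium: muscle is TPEF-dominant (collagen intensity ratio near 0.1)
    with sparse thin aligned collagen; border carries more numerous, longer
    and thicker interlaced collagen among disordered myocardium; fibrosis is
    an SHG-dominant mesh of thick wavy collagen with sparse amorphous TPEF
    (ratio near 0.3 for both pathological classes).
    """
    return {
        "muscle": TissuePhenotype(
            label="muscle",
            collagen_fiber_count=10,
            collagen_length_mean_um=22.0, collagen_length_sd_um=8.0,
            collagen_width_mean_um=3.5, collagen_width_sd_um=0.6,
            collagen_orientation_mean_deg=90.0, collagen_orientation_kappa=6.0,
            collagen_waviness=0.05,
            collagen_intensity_scale=400.0,
            myocardium_fiber_count=30, myocardium_orientation_kappa=8.0,
            myocardium_intensity_scale=260.0,
            background_level=20.0,
        ),
        "border": TissuePhenotype(
            label="border",
            collagen_fiber_count=50,
            collagen_length_mean_um=31.0, collagen_length_sd_um=9.0,
            collagen_width_mean_um=4.5, collagen_width_sd_um=0.8,
            collagen_orientation_mean_deg=90.0, collagen_orientation_kappa=1.0,
            collagen_waviness=0.35,
            collagen_intensity_scale=550.0,
            myocardium_fiber_count=22, myocardium_orientation_kappa=0.8,
            myocardium_intensity_scale=240.0,
            myocardium_waviness=0.3,
            background_level=20.0,
        ),
        "fibrosis": TissuePhenotype(
            label="fibrosis",
            collagen_fiber_count=60,
            collagen_length_mean_um=40.0, collagen_length_sd_um=12.0,
            collagen_width_mean_um=4.8, collagen_width_sd_um=0.7,
            collagen_orientation_mean_deg=45.0, collagen_orientation_kappa=1.2,
            collagen_waviness=0.5,
            collagen_intensity_scale=500.0,
            myocardium_fiber_count=6, myocardium_orientation_kappa=0.2,
            myocardium_intensity_scale=260.0,
            myocardium_length_mean_um=120.0, myocardium_length_sd_um=40.0,
            myocardium_width_mean_um=25.0, myocardium_width_sd_um=6.0,
            myocardium_waviness=0.5,
            tpef_diffuse_level=85.0,
            background_level=20.0,
        ),
    }


def generate_dataset(
    presets: dict[str, TissuePhenotype] | None = None,
    n_per_class_per_roi: int = 10,
    n_rois: int = 2,
    seed: int = 0,
    size_px: int = DEFAULT_SIZE_PX,
    pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM,
    roi_jitter_sd: float = 0.08,
) -> tuple[dict[str, TwoChannelStack], pd.DataFrame, dict[str, GroundTruth]]:
    """Generate a labeled multi-ROI dataset mirroring the study layout.

    Each class contributes ``n_rois`` regions of interest (depth stacks of
    ``n_per_class_per_roi`` frames each).  ROI-level multiplicative jitter of
    the phenotype parameters (log-normal, sd ``roi_jitter_sd``) plus a random
    per-ROI global orientation offset create within-class batch structure;
    with ``roi_jitter_sd = 0`` all ROIs of a class share identical
    parameters.  ROIs are partitioned into two pseudo-subjects (first half
    "S1", second half "S2") so train/test splits can segregate subjects.

    Returns
    -------
    stacks
        Mapping roi id -> TwoChannelStack of that ROI's frames.
    manifest
        One row per frame: frame, class, roi, subject, seed and the
        (jittered) phenotype parameters.
    truths
        Mapping frame id -> GroundTruth.
    """
    if n_per_class_per_roi < 1:
        raise ValueError("n_per_class_per_roi must be >= 1")
    presets = default_presets() if presets is None else presets
    root = np.random.SeedSequence(seed)
    stacks: dict[str, TwoChannelStack] = {}
    truths: dict[str, GroundTruth] = {}
    rows = []
    jitter_fields = [
        "collagen_length_mean_um", "collagen_length_sd_um",
        "collagen_width_mean_um", "collagen_width_sd_um",
        "collagen_intensity_scale", "myocardium_intensity_scale",
        "myocardium_length_mean_um", "myocardium_width_mean_um",
    ]
    for ci, (cls, base) in enumerate(sorted(presets.items())):
        for roi in range(n_rois):
            roi_id = f"{cls}_roi{roi}"
            subject = "S1" if roi < (n_rois + 1) // 2 else "S2"
            roi_ss = np.random.SeedSequence(
                entropy=root.entropy, spawn_key=(ci, roi))
            roi_rng = np.random.default_rng(roi_ss)
            pheno = base
            if roi_jitter_sd > 0:
                updates = {f: getattr(base, f) * roi_rng.lognormal(0.0, roi_jitter_sd)
                           for f in jitter_fields}
                updates["collagen_fiber_count"] = max(int(round(
                    base.collagen_fiber_count * roi_rng.lognormal(0.0, roi_jitter_sd))), 0)
                updates["myocardium_fiber_count"] = max(int(round(
                    base.myocardium_fiber_count * roi_rng.lognormal(0.0, roi_jitter_sd))), 0)
                offset = roi_rng.uniform(0.0, 180.0)
                updates["collagen_orientation_mean_deg"] = \
                    (base.collagen_orientation_mean_deg + offset) % 180.0
                updates["myocardium_orientation_mean_deg"] = \
                    (base.myocardium_orientation_mean_deg + offset) % 180.0
                pheno = replace(base, **updates)
            frames = []
            for z in range(n_per_class_per_roi):
                frame_id = f"{roi_id}_z{z:03d}"
                frame_seed = int(np.random.SeedSequence(
                    entropy=root.entropy, spawn_key=(ci, roi, z)
                ).generate_state(1)[0] % (2**31))
                frame, gt = generate_image(pheno, size_px, pixel_size_um, frame_seed)
                frames.append(frame)
                truths[frame_id] = gt
                row = {"frame": frame_id, "class": cls, "roi": roi_id,
                       "subject": subject, "seed": frame_seed}
                row.update({f: getattr(pheno, f) for f in
                            [fld.name for fld in dataclasses.fields(pheno)
                             if fld.name != "label"]})
                rows.append(row)
            stacks[roi_id] = TwoChannelStack(
                frames, bit_depth=16, pixel_size_um=pixel_size_um,
                provenance=f"synthetic:{roi_id}:seed={seed}")
    return stacks, pd.DataFrame(rows), truths
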