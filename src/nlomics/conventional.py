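"""The 16 conventional imaging features: collagen amount, morphology, orientation.

Per frame the feature vector holds, in order: the collagen intensity ratio
C_I = mean(SHG)/(mean(SHG)+mean(TPEF)); the segmentation ratio
C_S = N_SHG/(N_SHG+N_TPEF) over segmented pixels; the traced fiber count and
mean/sd of fiber length, width and straightness; MVL and range of the
fiber-angle histogram; MVL and range of the SHG and TPEF Fourier
directionality histograms; and the axial mean-angle mismatch between the two
channels.  Degenerate inputs (no fibers, constant frames) propagate as NaN
rather than fabricated zeros.
"""

from __future__ import annotations

import numpy as np

from .fibers import FiberRecord, fiber_morphology_summary
from .orientation import (
    DegenerateHistogramError,
    angle_mismatch,
    circular_summary,
    directionality_histogram,
    fiber_angle_histogram,
)

FEATURE_NAMES = (
    "collagen_intensity",
    "collagen_segmentation",
    "fiber_count",
    "fiber_length_mean",
    "fiber_length_sd",
    "fiber_width_mean",
    "fiber_width_sd",
    "fiber_straightness_mean",
    "fiber_straightness_sd",
    "ctfire_mvl",
    "ctfire_range",
    "shg_mvl",
    "shg_range",
    "tpef_mvl",
    "tpef_range",
    "shg_tpef_mismatch",
)


class UndefinedRatioError(ValueError):
    pass


def collagen_intensity_ratio(shg_frame: np.ndarray, tpef_frame: np.ndarray) -> float:
    """C_I: mean SHG intensity over the summed channel means (full frame)."""
    m_shg = float(np.asarray(shg_frame, dtype=np.float64).mean())
    m_tpef = float(np.asarray(tpef_frame, dtype=np.float64).mean())
    if m_shg + m_tpef == 0:
        raise UndefinedRatioError("both channels are all-zero")
    return m_shg / (m_shg + m_tpef)


def collagen_segmentation_ratio(shg_mask: np.ndarray, tpef_mask: np.ndarray) -> float:
    """C_S: segmented SHG pixel count over total segmented pixel count."""
    shg_mask = np.asarray(shg_mask).astype(bool)
    tpef_mask = np.asarray(tpef_mask).astype(bool)
    if shg_mask.shape != tpef_mask.shape:
        raise ValueError("masks must share a shape")
    n_shg, n_tpef = int(shg_mask.sum()), int(tpef_mask.sum())
    if n_shg + n_tpef == 0:
        raise UndefinedRatioError("both segmentations are empty")
    return n_shg / (n_shg + n_tpef)


def conventional_feature_vector(
    shg_frame: np.ndarray,
    tpef_frame: np.ndarray,
    shg_mask: np.ndarray,
    tpef_mask: np.ndarray,
    fibers: list[FiberRecord],
) -> dict[str, float]:
    """Assemble all 16 features for one frame (NaN where undefined)."""
    out: dict[str, float] = {}
    try:
        out["collagen_intensity"] = collagen_intensity_ratio(shg_frame, tpef_frame)
    except UndefinedRatioError:
        out["collagen_intensity"] = float("nan")
    try:
        out["collagen_segmentation"] = collagen_segmentation_ratio(shg_mask, tpef_mask)
    except UndefinedRatioError:
        out["collagen_segmentation"] = float("nan")

    morph = fiber_morphology_summary(fibers)
    out["fiber_count"] = morph["fiber_count"]
    for short, key in (("length", "length"), ("width", "width"),
                       ("straightness", "straightness")):
        out[f"fiber_{short}_mean"] = morph[f"{key}_mean"]
        out[f"fiber_{short}_sd"] = morph[f"{key}_sd"]

    try:
        fib_summary = circular_summary(fiber_angle_histogram(
            [f.angle_deg for f in fibers]))
        out["ctfire_mvl"] = fib_summary.mvl
        out["ctfire_range"] = fib_summary.range_rad
    except DegenerateHistogramError:
        out["ctfire_mvl"] = out["ctfire_range"] = float("nan")

    summaries = {}
    for name, frame in (("shg", shg_frame), ("tpef", tpef_frame)):
        try:
            summaries[name] = circular_summary(
                directionality_histogram(frame, source=name.upper()))
            out[f"{name}_mvl"] = summaries[name].mvl
            out[f"{name}_range"] = summaries[name].range_rad
        except DegenerateHistogramError:
            summaries[name] = None
            out[f"{name}_mvl"] = out[f"{name}_range"] = float("nan")

    if summaries["shg"] is not None and summaries["tpef"] is not None:
        out["shg_tpef_mismatch"] = angle_mismatch(summaries["shg"], summaries["tpef"])
    else:
        out["shg_tpef_mismatch"] = float("nan")

    assert tuple(out) == FEATURE_NAMES
    return out
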