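"""Two-channel image stacks: container, TIFF round trip, requantization.

The acquisition saves each region of interest (ROI) as a multi-page TIFF in
which every depth plane contributes two co-registered channels: second
harmonic generation (SHG, fibrillar collagen) followed by two-photon excited
fluorescence (TPEF, cardiomyocytes).  This module owns that container and the
stack-level linear rescaling used to requantize a whole stack to 8 or 16 bits.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import tifffile

CHANNEL_ORDER = ("SHG", "TPEF")


class StackFormatError(ValueError):
    """Raised when a file does not hold an interleaved two-channel stack."""


@dataclass
class TwoChannelStack:
    """Ordered frames of co-registered (SHG, TPEF) rasters.

    Parameters
    ----------
    frames
        List of ``(shg, tpef)`` pairs of equal-shape 2-D integer arrays.
    bit_depth
        Declared container depth (8 or 16); pixel values must fit in it.
    pixel_size_um
        Lateral pixel pitch in micrometres per pixel.
    provenance
        Free-text origin (source path, generator parameters, ...).
    """

    frames: list[tuple[np.ndarray, np.ndarray]]
    bit_depth: int = 16
    pixel_size_um: float = 508.0 / 512.0
    provenance: str = ""

    def __post_init__(self) -> None:
        if not self.frames:
            raise StackFormatError("stack must contain at least one frame")
        shape = self.frames[0][0].shape
        for shg, tpef in self.frames:
            if shg.shape != shape or tpef.shape != shape:
                raise StackFormatError("all frames/channels must share one shape")
        if self.bit_depth not in (8, 16):
            raise StackFormatError(f"unsupported bit depth {self.bit_depth}")

    def __len__(self) -> int:
        return len(self.frames)

    @property
    def shape(self) -> tuple[int, int]:
        return self.frames[0][0].shape

    def channel(self, name: str) -> np.ndarray:
        """Return one channel as a (n_frames, H, W) array."""
        idx = CHANNEL_ORDER.index(name)
        return np.stack([frame[idx] for frame in self.frames])


def write_stack(path, stack: TwoChannelStack) -> None:
    """Write an interleaved multi-page TIFF: SHG page then TPEF page per frame."""
    dtype = np.uint8 if stack.bit_depth == 8 else np.uint16
    pages = []
    for shg, tpef in stack.frames:
        pages.append(np.asarray(shg, dtype=dtype))
        pages.append(np.asarray(tpef, dtype=dtype))
    tifffile.imwrite(
        path,
        np.stack(pages),
        metadata={
            "channel_order": ",".join(CHANNEL_ORDER),
            "pixel_size_um": stack.pixel_size_um,
            "layout": "interleaved",
        },
    )


def read_stack(path, pixel_size_um: float | None = None) -> TwoChannelStack:
    """Read an interleaved two-channel multi-page TIFF written by write_stack.

    Channel order is taken from TIFF metadata when present, otherwise the
    SHG-then-TPEF default applies.  A file whose pages do not pair up into
    two channels per frame is rejected.
    """
    with tifffile.TiffFile(str(path)) as tif:
        data = tif.asarray()
        meta = tif.shaped_metadata[0] if tif.shaped_metadata else {}
    if data.ndim == 2:
        raise StackFormatError("single-page file cannot hold two channels")
    if data.ndim == 4:
        # (frames, channels, H, W) layout
        if data.shape[1] != 2:
            raise StackFormatError(
                f"expected 2 channels per frame, found {data.shape[1]}"
            )
        pages = data.reshape(-1, *data.shape[2:])
    else:
        pages = data
    if pages.shape[0] % 2 != 0:
        raise StackFormatError(
            f"odd page count {pages.shape[0]} for interleaved 2-channel layout"
        )
    if not np.issubdtype(pages.dtype, np.integer):
        raise StackFormatError(f"non-integer pixel data ({pages.dtype})")

    order = tuple(str(meta.get("channel_order", ",".join(CHANNEL_ORDER))).split(","))
    if sorted(order) != sorted(CHANNEL_ORDER):
        raise StackFormatError(f"unsupported channel set {order}")
    shg_first = order[0] == "SHG"

    frames = []
    for i in range(0, pages.shape[0], 2):
        a, b = pages[i], pages[i + 1]
        frames.append((a, b) if shg_first else (b, a))
    bit_depth = 8 if pages.dtype.itemsize == 1 else 16
    px = pixel_size_um if pixel_size_um is not None else float(
        meta.get("pixel_size_um", 508.0 / 512.0)
    )
    return TwoChannelStack(frames, bit_depth=bit_depth, pixel_size_um=px,
                           provenance=str(path))


def rescale_to_bits(images: np.ndarray, target_bits: int) -> np.ndarray:
    """Linearly requantize an array to ``target_bits`` using its global min/max.

    ``out = round((in - min) / (max - min) * (2**bits - 1))`` with min/max
    taken over the whole input (the entire stack of one modality), so that a
    single linear map applies to every frame.  Rounding is half away from
    zero; a constant input maps to all zeros.
    """
    if target_bits not in (8, 16):
        raise ValueError(f"target_bits must be 8 or 16, got {target_bits}")
    images = np.asarray(images, dtype=np.float64)
    lo, hi = images.min(), images.max()
    top = float(2**target_bits - 1)
    if hi == lo:
        out = np.zeros_like(images)
    else:
        out = (images - lo) / (hi - lo) * top
    # np.round is banker's rounding; use floor(x + 0.5) for half-away-from-zero
    out = np.floor(out + 0.5)
    dtype = np.uint8 if target_bits == 8 else np.uint16
    return out.astype(dtype)


def rescale_stack(stack: TwoChannelStack, target_bits: int) -> TwoChannelStack:
    """Requantize both channels of a stack, each with its own stack-wide range."""
    shg = rescale_to_bits(stack.channel("SHG"), target_bits)
    tpef = rescale_to_bits(stack.channel("TPEF"), target_bits)
    frames = [(shg[i], tpef[i]) for i in range(len(stack))]
    return TwoChannelStack(frames, bit_depth=target_bits,
                           pixel_size_um=stack.pixel_size_um,
                           provenance=stack.provenance + f" [rescaled {target_bits}b]")
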