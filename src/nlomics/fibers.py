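"""Skeleton-based collagen fiber tracing.

Traces individual fibers from a binary collagen segmentation and reports the
per-fiber quantities used downstream: centerline, length (µm), width (µm),
straightness (endpoint distance / arc length) and axial orientation angle.

The tracer skeletonizes the foreground, splits the skeleton at junction
pixels, orders each branch into a polyline, and re-merges branches that
continue through a junction with a turn angle below a threshold, so that a
long fiber crossed by another is recovered as one object.  Width is derived
from the mean Euclidean distance-transform value along the centerline (the
local half-thickness of the segmented footprint).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.morphology import skeletonize


@dataclass
class FiberRecord:
    """One traced fiber."""

    centerline: np.ndarray  # (n, 2) array of (row, col) pixel coordinates
    length_um: float
    width_um: float
    straightness: float  # endpoint distance / arc length, in (0, 1]
    angle_deg: float  # orientation of the endpoint chord, in [0, 180)

    @property
    def n_points(self) -> int:
        return len(self.centerline)


_NBR = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]


def _order_branch(points: set[tuple[int, int]]) -> list[tuple[int, int]]:
    """Order an 8-connected branch (path or cycle) into a pixel sequence."""
    if len(points) == 1:
        return list(points)
    nbrs = {p: [q for d in _NBR if (q := (p[0] + d[0], p[1] + d[1])) in points]
            for p in points}
    ends = [p for p, ns in nbrs.items() if len(ns) <= 1]
    start = min(ends) if ends else min(points)
    path = [start]
    seen = {start}
    cur = start
    while True:
        nxt = [q for q in nbrs[cur] if q not in seen]
        if not nxt:
            break
        # prefer 4-connected continuation to avoid diagonal shortcuts
        nxt.sort(key=lambda q: (abs(q[0] - cur[0]) + abs(q[1] - cur[1]), q))
        cur = nxt[0]
        path.append(cur)
        seen.add(cur)
    return path


def _arc_length(poly: np.ndarray) -> float:
    if len(poly) < 2:
        return 0.0
    return float(np.sum(np.hypot(*np.diff(poly.astype(float), axis=0).T)))


def _end_direction(poly: np.ndarray, at_start: bool, k: int = 5) -> np.ndarray:
    """Unit vector pointing outward from the polyline at one end."""
    pts = poly[: min(k, len(poly))] if at_start else poly[-min(k, len(poly)):]
    vec = (pts[0] - pts[-1]) if at_start else (pts[-1] - pts[0])
    vec = vec.astype(float)
    norm = np.hypot(*vec)
    return vec / norm if norm > 0 else vec


class _Chains:
    """Polyline chains supporting endpoint-to-endpoint stitching."""

    def __init__(self, polys: list[np.ndarray]):
        self.chains: dict[int, np.ndarray] = dict(enumerate(polys))
        self.owner = {i: i for i in range(len(polys))}  # original idx -> chain id

    def root(self, i: int) -> int:
        while self.owner[i] != i:
            self.owner[i] = self.owner[self.owner[i]]
            i = self.owner[i]
        return i

    def merge(self, i: int, i_at_start: bool, j: int, j_at_start: bool) -> bool:
        ri, rj = self.root(i), self.root(j)
        if ri == rj:
            return False
        a, b = self.chains[ri], self.chains[rj]
        # orient a to end at the merging endpoint, b to start at its endpoint
        if i_at_start:
            a = a[::-1]
        if not j_at_start:
            b = b[::-1]
        self.chains[ri] = np.vstack([a, b])
        del self.chains[rj]
        self.owner[rj] = ri
        return True


def trace_fibers(
    binary_frame: np.ndarray,
    pixel_size_um: float = 1.0,
    min_length_px: float = 15.0,
    merge_angle_deg: float = 30.0,
) -> list[FiberRecord]:
    """Trace fibers from a binary collagen frame.

    Parameters
    ----------
    binary_frame
        Foreground segmentation (nonzero = collagen).
    pixel_size_um
        Pixel pitch for converting lengths and widths to micrometres.
    min_length_px
        Fibers with centerline arc length below this are pruned.
    merge_angle_deg
        Two branches meeting at a junction are merged into one fiber when
        the turn angle between them is below this threshold.
    """
    mask = np.asarray(binary_frame) > 0
    if not mask.any():
        return []
    skel = skeletonize(mask)
    dist = ndimage.distance_transform_edt(mask)

    nbr_count = ndimage.convolve(skel.astype(int), np.ones((3, 3), int),
                                 mode="constant") - skel.astype(int)
    junctions = skel & (nbr_count >= 3)
    branches = skel & ~junctions

    lbl, n_lbl = ndimage.label(branches, structure=np.ones((3, 3), int))
    polys: list[np.ndarray] = []
    for i in range(1, n_lbl + 1):
        pts = set(map(tuple, np.argwhere(lbl == i)))
        polys.append(np.array(_order_branch(pts)))
    if not polys:
        # skeleton is all junction pixels (tiny blob): treat as one fiber
        polys = [np.argwhere(skel)]

    chains = _Chains(polys)
    # stitch branches continuing through junction clusters
    jlbl, n_j = ndimage.label(junctions, structure=np.ones((3, 3), int))
    for j in range(1, n_j + 1):
        jpix = set(map(tuple, np.argwhere(jlbl == j)))
        incident = []  # (branch idx, at_start, outward direction)
        for bi, poly in enumerate(polys):
            for at_start in (True, False):
                end = tuple(poly[0] if at_start else poly[-1])
                near = any((end[0] + d[0], end[1] + d[1]) in jpix for d in _NBR)
                if near:
                    incident.append((bi, at_start, _end_direction(poly, at_start)))
        # pair endpoints by smallest turn angle (outward dirs near-opposite)
        pairs = []
        for a in range(len(incident)):
            for b in range(a + 1, len(incident)):
                bi, sa, da = incident[a]
                bj, sb, db = incident[b]
                if bi == bj:
                    continue
                cos_turn = -float(np.dot(da, db))  # continuation: da ≈ -db
                turn = np.degrees(np.arccos(np.clip(cos_turn, -1, 1)))
                if turn < merge_angle_deg:
                    pairs.append((turn, a, b))
        used: set[int] = set()
        for _, a, b in sorted(pairs):
            if a in used or b in used:
                continue
            bi, sa, _ = incident[a]
            bj, sb, _ = incident[b]
            if chains.merge(bi, not sa, bj, sb):
                used.update((a, b))

    records = []
    for poly in chains.chains.values():
        arc = _arc_length(poly)
        if arc < min_length_px or len(poly) < 2:
            continue
        chord = poly[-1].astype(float) - poly[0].astype(float)
        chord_len = float(np.hypot(*chord))
        straightness = min(chord_len / arc, 1.0) if arc > 0 else 1.0
        # image rows grow downward: negate the row delta for CCW angles
        angle = np.degrees(np.arctan2(-chord[0], chord[1])) % 180.0
        # edt measures to the nearest background pixel center: one pixel more
        # than the half-thickness of the footprint, hence the -1
        width = max(2.0 * float(dist[tuple(poly.T)].mean()) - 1.0, 1.0)
        records.append(FiberRecord(
            centerline=poly,
            length_um=arc * pixel_size_um,
            width_um=width * pixel_size_um,
            straightness=straightness,
            angle_deg=float(angle),
        ))
    return records


def fiber_morphology_summary(fibers: list[FiberRecord]) -> dict[str, float]:
    """Count plus mean/sd (population) of length, width and straightness.

    An empty fiber list yields count 0 and NaN for the six moments.
    """
    out = {"fiber_count": float(len(fibers))}
    for name, values in (
        ("length", [f.length_um for f in fibers]),
        ("width", [f.width_um for f in fibers]),
        ("straightness", [f.straightness for f in fibers]),
    ):
        arr = np.asarray(values, dtype=float)
        out[f"{name}_mean"] = float(arr.mean()) if arr.size else float("nan")
        out[f"{name}_sd"] = float(arr.std()) if arr.size else float("nan")
    return out
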