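"""2-D IBSI-style radiomics panel on masked, binned, renormalized 8-bit images.

Feature families: intensity statistics (``stat.*``), local intensity
(``loc.peak.global``), intensity histogram (``ih.*``), intensity-volume
histogram (``ivh.*``), 2-D morphology of the foreground mask (``morph.*``),
gray-level co-occurrence (``cm.*``), run length (``rlm.*``), size zone
(``szm.*``), neighbourhood gray-tone difference (``ntg.*``) and neighbouring
gray-level dependence (``ngl.*``).  Feature keys follow the
``<MODALITY>::<Family>::<ibsi-name>`` convention, e.g.
``"TPEF::Histogram::ih.max"``.

Conventions (documented because IBSI is written for 3-D volumes):

* a single image is a single "slice"; directional families (GLCM, GLRLM)
  compute features per direction over the 4 axial/diagonal 2-D directions
  and average them ("2D, averaged" aggregation);
* discretization is fixed bin size 1 on the 0..255 levels produced by
  preprocessing; texture matrices index gray level as ``level + 1`` so the
  IBSI 1-based level weightings (e.g. low gray level emphasis) apply;
* the 3-D morphology family maps to 2-D: area stands in for volume and
  perimeter for surface (``morph.av`` = mask area in px²,
  ``morph.com`` = centroid shift between geometric and intensity-weighted
  centroids);
* features undefined on degenerate inputs (e.g. ``cm.corr`` on a
  single-level region) are carried as NaN and listed in the returned flag
  set, never silently zeroed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

N_LEVELS = 256

GLCM_OFFSETS = ((0, 1), (1, 1), (1, 0), (1, -1))


@dataclass
class DiscretizedImage:
    """Integer raster with gray levels in 0..n_levels-1 plus foreground mask."""

    pixels: np.ndarray
    mask: np.ndarray
    modality: str = ""
    n_levels: int = N_LEVELS

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        self.mask = np.asarray(self.mask).astype(bool)
        if self.pixels.shape != self.mask.shape:
            raise ValueError("pixels and mask must share a shape")
        if not self.mask.any():
            raise ValueError("mask must be non-empty")
        if self.pixels.min() < 0 or self.pixels.max() >= self.n_levels:
            raise ValueError("pixel levels outside declared range")

    @property
    def masked_values(self) -> np.ndarray:
        return self.pixels[self.mask].astype(np.float64)


# ---------------------------------------------------------------------------
# Texture matrices
# ---------------------------------------------------------------------------

def build_glcm(img: DiscretizedImage, distance: int = 1) -> dict[tuple, np.ndarray]:
    """Symmetrized co-occurrence counts per direction over masked pixel pairs."""
    out = {}
    lv = img.pixels.astype(np.int64)
    for dr, dc in GLCM_OFFSETS:
        m = np.zeros((img.n_levels, img.n_levels), dtype=np.float64)
        a, b = _offset_views(lv, img.mask, dr * distance, dc * distance)
        if a.size:
            np.add.at(m, (a, b), 1.0)
        out[(dr, dc)] = m + m.T  # symmetrize
    return out


def _offset_views(levels: np.ndarray, mask: np.ndarray, dr: int, dc: int):
    """Paired center/neighbour levels for one offset, both inside the mask."""
    h, w = levels.shape
    r0, r1 = max(0, -dr), min(h, h - dr)
    c0, c1 = max(0, -dc), min(w, w - dc)
    center = levels[r0:r1, c0:c1]
    nbr = levels[r0 + dr:r1 + dr, c0 + dc:c1 + dc]
    ok = mask[r0:r1, c0:c1] & mask[r0 + dr:r1 + dr, c0 + dc:c1 + dc]
    return center[ok], nbr[ok]


def build_glrlm(img: DiscretizedImage) -> dict[tuple, np.ndarray]:
    """Run-length counts (level × run length) per direction, masked only.

    A run is a maximal colinear string of same-level masked pixels; mask
    gaps break runs.  Column j (0-based) holds runs of length j+1.
    """
    h, w = img.pixels.shape
    max_run = max(h, w)
    lv = np.where(img.mask, img.pixels.astype(np.int64), -1)
    out = {}
    for d in GLCM_OFFSETS:
        m = np.zeros((img.n_levels, max_run), dtype=np.float64)
        for line in _lines(lv, d):
            for level, run in _runs(line):
                m[level, run - 1] += 1.0
        out[d] = m
    return out


def _lines(lv: np.ndarray, direction: tuple) -> list[np.ndarray]:
    h, w = lv.shape
    if direction == (0, 1):
        return [lv[r] for r in range(h)]
    if direction == (1, 0):
        return [lv[:, c] for c in range(w)]
    if direction == (1, 1):
        return [np.diagonal(lv, k) for k in range(-h + 1, w)]
    if direction == (1, -1):
        fl = lv[:, ::-1]
        return [np.diagonal(fl, k) for k in range(-h + 1, w)]
    raise ValueError(f"unsupported direction {direction}")


def _runs(line: np.ndarray):
    """Yield (level, run_length) for maximal same-level runs, skipping -1."""
    line = np.asarray(line)
    if line.size == 0:
        return
    change = np.nonzero(np.diff(line) != 0)[0]
    starts = np.concatenate([[0], change + 1])
    ends = np.concatenate([change + 1, [line.size]])
    for s, e in zip(starts, ends):
        if line[s] >= 0:
            yield int(line[s]), int(e - s)


def build_glszm(img: DiscretizedImage) -> np.ndarray:
    """Zone counts (level × zone size): 8-connected same-level components."""
    h, w = img.pixels.shape
    m = np.zeros((img.n_levels, h * w), dtype=np.float64)
    struct = np.ones((3, 3), int)
    lv = img.pixels
    for level in np.unique(lv[img.mask]):
        lbl, n = ndimage.label((lv == level) & img.mask, structure=struct)
        if n:
            sizes = np.bincount(lbl.ravel())[1:]
            for s in sizes:
                m[level, s - 1] += 1.0
    return m


def build_ngtdm(img: DiscretizedImage) -> tuple[np.ndarray, np.ndarray]:
    """Neighbourhood gray-tone difference: per-level (s_i, n_i).

    s_i sums |i - A| over masked pixels of level i, where A is the mean of
    the pixel's masked 8-neighbours; pixels without masked neighbours are
    excluded from n_i.
    """
    k = np.ones((3, 3))
    k[1, 1] = 0
    vals = np.where(img.mask, img.pixels.astype(np.float64), 0.0)
    nbr_sum = ndimage.correlate(vals, k, mode="constant")
    nbr_cnt = ndimage.correlate(img.mask.astype(np.float64), k, mode="constant")
    valid = img.mask & (nbr_cnt > 0)
    levels = img.pixels[valid]
    diffs = np.abs(levels - nbr_sum[valid] / nbr_cnt[valid])
    s = np.bincount(levels, weights=diffs, minlength=img.n_levels).astype(np.float64)
    n = np.bincount(levels, minlength=img.n_levels).astype(np.float64)
    return s, n


def build_ngldm(img: DiscretizedImage, alpha: int = 0) -> np.ndarray:
    """Dependence counts (level × dependence): masked 8-neighbours within
    coarseness alpha of the center level; column j holds dependence j
    (j = neighbour count, 0..8)."""
    lv = img.pixels.astype(np.int64)
    dep = np.zeros(lv.shape, dtype=np.int64)
    for dr, dc in ((0, 1), (1, 1), (1, 0), (1, -1),
                   (0, -1), (-1, -1), (-1, 0), (-1, 1)):
        h, w = lv.shape
        r0, r1 = max(0, -dr), min(h, h - dr)
        c0, c1 = max(0, -dc), min(w, w - dc)
        close = (np.abs(lv[r0:r1, c0:c1] - lv[r0 + dr:r1 + dr, c0 + dc:c1 + dc])
                 <= alpha)
        both = img.mask[r0:r1, c0:c1] & img.mask[r0 + dr:r1 + dr, c0 + dc:c1 + dc]
        dep[r0:r1, c0:c1] += (close & both)
    m = np.zeros((img.n_levels, 9), dtype=np.float64)
    np.add.at(m, (lv[img.mask], dep[img.mask]), 1.0)
    return m


# ---------------------------------------------------------------------------
# Family feature computations
# ---------------------------------------------------------------------------

def _entropy2(p: np.ndarray) -> float:
    p = p[p > 0]
    return float(-np.sum(p * np.log2(p)))


def glcm_features(glcm: np.ndarray) -> dict[str, float]:
    """Features of one symmetrized, un-normalized co-occurrence matrix."""
    total = glcm.sum()
    out = {}
    if total == 0:
        return {k: float("nan") for k in _GLCM_KEYS}
    p = glcm / total
    ng = p.shape[0]
    i = np.arange(1, ng + 1, dtype=np.float64)
    ii, jj = np.meshgrid(i, i, indexing="ij")
    pi = p.sum(axis=1)  # marginal (symmetric)
    mu = float(np.sum(i * pi))
    var = float(np.sum((i - mu) ** 2 * pi))

    out["cm.joint.max"] = float(p.max())
    out["cm.joint.avg"] = float(np.sum(ii * p))
    out["cm.joint.var"] = float(np.sum((ii - out["cm.joint.avg"]) ** 2 * p))
    out["cm.joint.entr"] = _entropy2(p.ravel())

    k_diff = np.abs(ii - jj)
    out["cm.diff.avg"] = float(np.sum(k_diff * p))
    out["cm.diff.var"] = float(np.sum((k_diff - out["cm.diff.avg"]) ** 2 * p))
    pd_k = np.bincount(k_diff.astype(int).ravel(), weights=p.ravel(),
                       minlength=ng)
    out["cm.diff.entr"] = _entropy2(pd_k)
    k_sum = ii + jj
    out["cm.sum.avg"] = float(np.sum(k_sum * p))
    out["cm.sum.var"] = float(np.sum((k_sum - out["cm.sum.avg"]) ** 2 * p))
    ps_k = np.bincount(k_sum.astype(int).ravel(), weights=p.ravel())
    out["cm.sum.entr"] = _entropy2(ps_k)

    out["cm.energy"] = float(np.sum(p ** 2))
    out["cm.contrast"] = float(np.sum((ii - jj) ** 2 * p))
    out["cm.dissimilarity"] = float(np.sum(k_diff * p))
    out["cm.inv.diff"] = float(np.sum(p / (1 + k_diff)))
    out["cm.inv.diff.norm"] = float(np.sum(p / (1 + k_diff / ng)))
    out["cm.inv.diff.mom"] = float(np.sum(p / (1 + (ii - jj) ** 2)))
    out["cm.inv.diff.mom.norm"] = float(np.sum(p / (1 + (ii - jj) ** 2 / ng**2)))
    out["cm.auto.corr"] = float(np.sum(ii * jj * p))
    out["cm.corr"] = (float((out["cm.auto.corr"] - mu**2) / var)
                      if var > 0 else float("nan"))
    out["cm.clust.tend"] = float(np.sum((ii + jj - 2 * mu) ** 2 * p))
    out["cm.clust.shade"] = float(np.sum((ii + jj - 2 * mu) ** 3 * p))
    out["cm.clust.prom"] = float(np.sum((ii + jj - 2 * mu) ** 4 * p))
    return out


_GLCM_KEYS = list(glcm_features(np.ones((4, 4))).keys())


def _size_weighted_features(m: np.ndarray, prefix: str, size_name: str,
                            n_masked: int) -> dict[str, float]:
    """Shared GLRLM/GLSZM/NGLDM feature formulas (level × size matrices).

    ``m[i, j]`` counts objects of 1-based gray level i+1 and size/length/
    dependence j+1.
    """
    out = {}
    ns = m.sum()
    if ns == 0:
        names = ["sre", "lre", "lgre", "hgre", "srlge", "srhge", "lrlge",
                 "lrhge", "glnu", "glnu.norm", f"{size_name}nu",
                 f"{size_name}nu.norm", "perc", "gl.var", f"{size_name}.var",
                 f"{size_name}.entr"]
        return {f"{prefix}{n}": float("nan") for n in names}
    # trim trailing all-zero columns (indices of the rest are unchanged)
    last = int(np.nonzero(m.any(axis=0))[0][-1]) + 1
    m = m[:, :last]
    i = np.arange(1, m.shape[0] + 1, dtype=np.float64)
    j = np.arange(1, m.shape[1] + 1, dtype=np.float64)
    p = m / ns
    ri = m.sum(axis=1)
    rj = m.sum(axis=0)
    out[f"{prefix}sre"] = float(np.sum(rj / j**2) / ns)
    out[f"{prefix}lre"] = float(np.sum(rj * j**2) / ns)
    out[f"{prefix}lgre"] = float(np.sum(ri / i**2) / ns)
    out[f"{prefix}hgre"] = float(np.sum(ri * i**2) / ns)
    out[f"{prefix}srlge"] = float((1 / i**2) @ m @ (1 / j**2) / ns)
    out[f"{prefix}srhge"] = float(i**2 @ m @ (1 / j**2) / ns)
    out[f"{prefix}lrlge"] = float((1 / i**2) @ m @ j**2 / ns)
    out[f"{prefix}lrhge"] = float(i**2 @ m @ j**2 / ns)
    out[f"{prefix}glnu"] = float(np.sum(ri**2) / ns)
    out[f"{prefix}glnu.norm"] = float(np.sum(ri**2) / ns**2)
    out[f"{prefix}{size_name}nu"] = float(np.sum(rj**2) / ns)
    out[f"{prefix}{size_name}nu.norm"] = float(np.sum(rj**2) / ns**2)
    out[f"{prefix}perc"] = float(ns / n_masked)
    mu_i = float(np.sum(i * ri)) / ns
    out[f"{prefix}gl.var"] = float(np.sum((i - mu_i) ** 2 * ri) / ns)
    mu_j = float(np.sum(j * rj)) / ns
    out[f"{prefix}{size_name}.var"] = float(np.sum((j - mu_j) ** 2 * rj) / ns)
    out[f"{prefix}{size_name}.entr"] = _entropy2(p.ravel())
    return out


def _rename(d: dict[str, float], mapping: dict[str, str]) -> dict[str, float]:
    return {mapping.get(k, k): v for k, v in d.items()}


def glrlm_features(m: np.ndarray, n_masked: int) -> dict[str, float]:
    out = _size_weighted_features(m, "rlm.", "rl", n_masked)
    return _rename(out, {"rlm.rlnu": "rlm.rlnu", "rlm.perc": "rlm.r.perc"})


def glszm_features(m: np.ndarray, n_masked: int) -> dict[str, float]:
    out = _size_weighted_features(m, "szm.", "zs", n_masked)
    mapping = {"szm.sre": "szm.sze", "szm.lre": "szm.lze",
               "szm.lgre": "szm.lgze", "szm.hgre": "szm.hgze",
               "szm.srlge": "szm.szlge", "szm.srhge": "szm.szhge",
               "szm.lrlge": "szm.lzlge", "szm.lrhge": "szm.lzhge",
               "szm.perc": "szm.z.perc"}
    return _rename(out, mapping)


def ngldm_features(m: np.ndarray, n_masked: int) -> dict[str, float]:
    # dependence j stored 0..8 -> 1-based column index j+1 handled by caller
    out = _size_weighted_features(m, "ngl.", "dc", n_masked)
    mapping = {"ngl.sre": "ngl.lde", "ngl.lre": "ngl.hde",
               "ngl.lgre": "ngl.lgce", "ngl.hgre": "ngl.hgce",
               "ngl.srlge": "ngl.ldlge", "ngl.srhge": "ngl.ldhge",
               "ngl.lrlge": "ngl.hdlge", "ngl.lrhge": "ngl.hdhge",
               "ngl.perc": "ngl.dc.perc"}
    out = _rename(out, mapping)
    p = m / m.sum() if m.sum() else m
    out["ngl.dc.energy"] = float(np.sum(p ** 2))
    return out


def ngtdm_features(s: np.ndarray, n: np.ndarray) -> dict[str, float]:
    out = {}
    nv = n.sum()
    if nv == 0:
        return {f"ntg.{k}": float("nan") for k in
                ("coarseness", "contrast", "busyness", "complexity", "strength")}
    p = n / nv
    i = np.arange(1, s.size + 1, dtype=np.float64)  # 1-based levels
    present = p > 0
    ngp = int(present.sum())
    denom = float(np.sum(p * s))
    out["ntg.coarseness"] = 1.0 / denom if denom > 0 else 1e6
    if ngp > 1:
        pi_, pj_ = np.meshgrid(p[present], p[present], indexing="ij")
        ii, jj = np.meshgrid(i[present], i[present], indexing="ij")
        out["ntg.contrast"] = float(
            np.sum(pi_ * pj_ * (ii - jj) ** 2) / (ngp * (ngp - 1))
            * s.sum() / nv)
        bus_den = float(np.sum(np.abs(ii * pi_ - jj * pj_)))
        out["ntg.busyness"] = denom / bus_den if bus_den > 0 else 0.0
        si_, sj_ = np.meshgrid(s[present], s[present], indexing="ij")
        out["ntg.complexity"] = float(
            np.sum(np.abs(ii - jj) * (pi_ * si_ + pj_ * sj_) / (pi_ + pj_)) / nv)
        stren_num = float(np.sum((pi_ + pj_) * (ii - jj) ** 2))
        out["ntg.strength"] = stren_num / s.sum() if s.sum() > 0 else 0.0
    else:
        out["ntg.contrast"] = 0.0
        out["ntg.busyness"] = 0.0
        out["ntg.complexity"] = 0.0
        out["ntg.strength"] = 0.0
    return out


# ---------------------------------------------------------------------------
# Intensity / histogram / IVH / morphology
# ---------------------------------------------------------------------------

def _moment_stats(x: np.ndarray, prefix: str) -> dict[str, float]:
    out = {}
    mu = float(x.mean())
    var = float(x.var())
    sd = np.sqrt(var)
    p10, p25, p50, p75, p90 = np.percentile(x, [10, 25, 50, 75, 90])
    out[f"{prefix}.mean"] = mu
    out[f"{prefix}.var"] = var
    out[f"{prefix}.skew"] = (float(np.mean((x - mu) ** 3) / sd**3)
                             if sd > 0 else float("nan"))
    out[f"{prefix}.kurt"] = (float(np.mean((x - mu) ** 4) / var**2 - 3.0)
                             if sd > 0 else float("nan"))
    out[f"{prefix}.median"] = float(p50)
    out[f"{prefix}.min"] = float(x.min())
    out[f"{prefix}.p10"] = float(p10)
    out[f"{prefix}.p90"] = float(p90)
    out[f"{prefix}.max"] = float(x.max())
    out[f"{prefix}.iqr"] = float(p75 - p25)
    out[f"{prefix}.range"] = float(x.max() - x.min())
    out[f"{prefix}.mad"] = float(np.mean(np.abs(x - mu)))
    mid = x[(x >= p10) & (x <= p90)]
    out[f"{prefix}.rmad"] = (float(np.mean(np.abs(mid - mid.mean())))
                             if mid.size else float("nan"))
    out[f"{prefix}.medad"] = float(np.mean(np.abs(x - p50)))
    out[f"{prefix}.cov"] = sd / mu if mu != 0 else float("nan")
    out[f"{prefix}.qcod"] = (float((p75 - p25) / (p75 + p25))
                             if (p75 + p25) != 0 else float("nan"))
    return out


def intensity_features(img: DiscretizedImage,
                       peak_radius_px: float = 3.0) -> dict[str, float]:
    x = img.masked_values
    out = _moment_stats(x, "stat")
    out["stat.energy"] = float(np.sum(x ** 2))
    out["stat.rms"] = float(np.sqrt(np.mean(x ** 2)))
    out["loc.peak.global"] = _global_intensity_peak(img, peak_radius_px)
    return out


def _global_intensity_peak(img: DiscretizedImage, radius: float) -> float:
    """Highest neighbourhood mean (disk of given radius, all pixels) among
    the masked pixels attaining the global maximum intensity."""
    r = int(np.ceil(radius))
    offs = [(dr, dc) for dr in range(-r, r + 1) for dc in range(-r, r + 1)
            if dr * dr + dc * dc <= radius * radius]
    vals = img.pixels.astype(np.float64)
    h, w = vals.shape
    peak_level = img.pixels[img.mask].max()
    best = -np.inf
    for pr, pc in np.argwhere(img.mask & (img.pixels == peak_level)):
        acc, cnt = 0.0, 0
        for dr, dc in offs:
            rr, cc = pr + dr, pc + dc
            if 0 <= rr < h and 0 <= cc < w:
                acc += vals[rr, cc]
                cnt += 1
        best = max(best, acc / cnt)
    return float(best)


def histogram_features(img: DiscretizedImage) -> dict[str, float]:
    """Discrete histogram features on 1-based levels 1..n_levels."""
    counts = np.bincount(img.pixels[img.mask].ravel(),
                         minlength=img.n_levels).astype(np.float64)
    i = np.arange(1, img.n_levels + 1, dtype=np.float64)
    x = np.repeat(i, counts.astype(int))
    out = _moment_stats(x, "ih")
    p = counts / counts.sum()
    out["ih.entropy"] = _entropy2(p)
    out["ih.uniformity"] = float(np.sum(p ** 2))
    # mode: most frequent level; ties resolve toward the level nearest the mean
    top = np.nonzero(counts == counts.max())[0]
    mean_lv = out["ih.mean"]
    out["ih.mode"] = float(i[top[np.argmin(np.abs(i[top] - mean_lv))]])
    # histogram gradient (central differences, one-sided at the edges)
    grad = np.empty_like(counts)
    grad[1:-1] = (counts[2:] - counts[:-2]) / 2.0
    grad[0] = counts[1] - counts[0]
    grad[-1] = counts[-1] - counts[-2]
    out["ih.max.grad"] = float(grad.max())
    out["ih.max.grad.gl"] = float(i[int(np.argmax(grad))])
    out["ih.min.grad"] = float(grad.min())
    out["ih.min.grad.gl"] = float(i[int(np.argmin(grad))])
    return out


def ivh_features(img: DiscretizedImage) -> dict[str, float]:
    """Intensity-volume histogram fractions on the observed level range.

    V(γ) is the fraction of masked pixels with intensity at or above
    ``min + γ (max - min)``; I(x) is the smallest intensity whose
    at-or-above fraction does not exceed x.
    """
    x = img.masked_values
    lo, hi = x.min(), x.max()
    out = {}

    def v_at(gamma: float) -> float:
        thr = lo + gamma * (hi - lo)
        return float(np.mean(x >= thr))

    out["ivh.V10"] = v_at(0.10)
    out["ivh.V90"] = v_at(0.90)

    def i_at(frac: float) -> float:
        levels = np.arange(lo, hi + 1)
        fr = np.array([np.mean(x >= g) for g in levels])
        ok = np.nonzero(fr <= frac)[0]
        return float(levels[ok[0]]) if ok.size else float(hi)

    out["ivh.I10"] = i_at(0.10)
    out["ivh.I90"] = i_at(0.90)
    out["ivh.diff.V10.V90"] = out["ivh.V10"] - out["ivh.V90"]
    out["ivh.diff.I10.I90"] = out["ivh.I10"] - out["ivh.I90"]
    return out


def morphology_features(img: DiscretizedImage) -> dict[str, float]:
    out = {}
    mask = img.mask
    area = float(mask.sum())
    out["morph.av"] = area
    # perimeter: exposed unit edges of the pixel footprint
    padded = np.pad(mask, 1)
    perim = 0.0
    for dr, dc in ((0, 1), (0, -1), (1, 0), (-1, 0)):
        perim += float(np.sum(padded & ~np.roll(padded, (dr, dc), axis=(0, 1))))
    out["morph.perimeter"] = perim
    out["morph.compactness"] = 4 * np.pi * area / perim**2 if perim else float("nan")
    coords = np.argwhere(mask).astype(np.float64)
    geo = coords.mean(axis=0)
    weights = img.pixels[mask].astype(np.float64)
    if weights.sum() > 0:
        com = (coords * weights[:, None]).sum(axis=0) / weights.sum()
        out["morph.com"] = float(np.hypot(*(geo - com)))
    else:
        out["morph.com"] = 0.0
    return out


# ---------------------------------------------------------------------------
# Dataset-level preprocessing for the panel
# ---------------------------------------------------------------------------

def radiomics_preprocess(
    frame_pairs,
    bin_factor: int = 4,
) -> tuple[list[tuple[DiscretizedImage, DiscretizedImage] | None], list[str]]:
    """Prepare (SHG, TPEF) frame pairs for feature extraction.

    Per frame: 4×4 block-average binning of both channels, a Li OR foreground
    mask on the binned frames, and per-modality division by the mean
    background.  The renormalized frames are then requantized to 0..255 with
    one linear map per modality over the whole dataset, so the dataset-wide
    maximum maps to 255.

    Frames on which the mask or renormalization degenerates (constant
    channel, empty background) are skipped: their slot holds None and a log
    entry records the reason.
    """
    from .preprocess import (DegenerateHistogramError as _DegHist,
                             background_renormalize, bin_image,
                             build_foreground_mask)

    binned = []
    log: list[str] = []
    for idx, (shg, tpef) in enumerate(frame_pairs):
        try:
            shg_b = bin_image(shg, bin_factor)
            tpef_b = bin_image(tpef, bin_factor)
            mask = build_foreground_mask(np.floor(shg_b + 0.5).astype(np.int64),
                                         np.floor(tpef_b + 0.5).astype(np.int64))
            shg_r = background_renormalize(shg_b, mask)
            tpef_r = background_renormalize(tpef_b, mask)
        except (_DegHist, ValueError) as exc:
            log.append(f"frame {idx} skipped: {exc}")
            binned.append(None)
            continue
        binned.append((shg_r, tpef_r, mask))

    valid = [b for b in binned if b is not None]
    if not valid:
        return [None] * len(binned), log
    out: list[tuple[DiscretizedImage, DiscretizedImage] | None] = []
    ranges = {}
    for ch, idx in (("SHG", 0), ("TPEF", 1)):
        allv = np.concatenate([b[idx].ravel() for b in valid])
        ranges[ch] = (allv.min(), allv.max())
    for b in binned:
        if b is None:
            out.append(None)
            continue
        imgs = []
        for ch, idx in (("SHG", 0), ("TPEF", 1)):
            lo, hi = ranges[ch]
            scaled = (np.floor((b[idx] - lo) / (hi - lo) * (N_LEVELS - 1) + 0.5)
                      if hi > lo else np.zeros_like(b[idx]))
            imgs.append(DiscretizedImage(scaled.astype(np.int64), b[2].mask,
                                         modality=ch))
        out.append((imgs[0], imgs[1]))
    return out, log


# ---------------------------------------------------------------------------
# Panel
# ---------------------------------------------------------------------------

_FAMILY = {
    "stat": "Intensity", "loc": "Intensity", "ih": "Histogram",
    "ivh": "IVHistogram", "morph": "Morphological", "cm": "GLCM",
    "rlm": "GLRLM", "szm": "GLSZM", "ntg": "NGTDM", "ngl": "NGLDM",
}


def compute_feature_panel(
    img: DiscretizedImage,
    glcm_distance: int = 1,
    peak_radius_px: float = 3.0,
) -> tuple[dict[str, float], set[str]]:
    """Compute the full radiomics panel for one discretized image.

    Returns ``(features, flagged)`` where ``features`` maps
    ``"<MODALITY>::<Family>::<name>"`` to a float (NaN when undefined) and
    ``flagged`` lists the undefined feature keys.
    """
    n_masked = int(img.mask.sum())
    feats: dict[str, float] = {}
    feats.update(intensity_features(img, peak_radius_px))
    feats.update(histogram_features(img))
    feats.update(ivh_features(img))
    feats.update(morphology_features(img))

    glcms = build_glcm(img, glcm_distance)
    per_dir = [glcm_features(m) for m in glcms.values()]
    for key in per_dir[0]:
        vals = [d[key] for d in per_dir]
        feats[key] = float(np.nanmean(vals)) if not all(
            np.isnan(v) for v in vals) else float("nan")

    rlms = build_glrlm(img)
    per_dir = [glrlm_features(m, n_masked) for m in rlms.values()]
    for key in per_dir[0]:
        vals = [d[key] for d in per_dir]
        feats[key] = float(np.nanmean(vals)) if not all(
            np.isnan(v) for v in vals) else float("nan")

    feats.update(glszm_features(build_glszm(img), n_masked))
    # NGLDM: shift dependence columns to 1-based (dependence k -> column k+1)
    ngldm = build_ngldm(img)
    feats.update(ngldm_features(ngldm, n_masked))
    feats.update(ngtdm_features(*build_ngtdm(img)))

    keyed = {}
    flagged = set()
    for name, value in feats.items():
        family = _FAMILY[name.split(".")[0]]
        key = f"{img.modality}::{family}::{name}"
        keyed[key] = value
        if isinstance(value, float) and np.isnan(value):
            flagged.add(key)
    return keyed, flagged
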