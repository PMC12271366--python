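"""Independent brute-force reference implementations used as test oracles.

Everything here is written as plainly as possible — explicit double loops,
exhaustive scans, direct formula transcriptions — and deliberately shares no
code with the package implementation it checks.
"""

from __future__ import annotations

import math

import numpy as np

# ---------------------------------------------------------------------------
# Circular statistics
# ---------------------------------------------------------------------------

def range_prefix_sum(f: np.ndarray) -> float:
    """Smallest circular arc with weight strictly > 1/2, via explicit
    start/length double loop (prefix sums only for the window total)."""
    n = f.size
    best = n
    for start in range(n):
        acc = 0.0
        for length in range(1, n + 1):
            acc += f[(start + length - 1) % n]
            if acc > 0.5 + 1e-15:
                best = min(best, length)
                break
    return best * math.pi / n


# ---------------------------------------------------------------------------
# Histogram thresholds
# ---------------------------------------------------------------------------

def renyi_entropy_sum(hist: np.ndarray, t: int, alpha: float) -> float:
    """Sum of Rényi entropies of the <=t and >t normalized distributions."""
    p = hist / hist.sum()
    lo, hi = p[: t + 1], p[t + 1:]
    w_lo, w_hi = lo.sum(), hi.sum()
    if w_lo <= 0 or w_hi <= 0:
        return -math.inf
    total = 0.0
    for part, w in ((lo, w_lo), (hi, w_hi)):
        q = part / w
        q = q[q > 0]
        if abs(alpha - 1.0) < 1e-12:
            total += -float(np.sum(q * np.log(q)))
        else:
            total += float(np.log(np.sum(q**alpha)) / (1.0 - alpha))
    return total


def max_entropy_exhaustive(hist: np.ndarray, alpha: float = 1.0) -> int:
    scores = [renyi_entropy_sum(hist, t, alpha) for t in range(hist.size)]
    return int(np.argmax(scores))


def li_exhaustive(hist: np.ndarray) -> int:
    """Threshold minimizing the Li cross-entropy objective, exhaustive scan.

    Levels are shifted so the lowest occupied level maps to 1 (the same
    convention the implementation documents).
    """
    occ = np.nonzero(hist)[0]
    g = np.arange(hist.size, dtype=float) - (occ[0] - 1.0)
    best_t, best_eta = None, math.inf
    for t in range(occ[0], occ[-1]):
        eta = 0.0
        ok = True
        for sel in (np.arange(hist.size) <= t, np.arange(hist.size) > t):
            w = hist[sel].sum()
            if w == 0:
                ok = False
                break
            m = float(np.average(g[sel], weights=hist[sel]))
            eta -= w * m * math.log(m)
        if ok and eta < best_eta:
            best_eta, best_t = eta, t
    return best_t


# ---------------------------------------------------------------------------
# Frangi building blocks
# ---------------------------------------------------------------------------

def hessian_eigen_response(image: np.ndarray, sigma: float, beta: float = 0.5):
    """Per-pixel |λ1|<=|λ2| eigenvalues of the gamma-normalized Gaussian
    Hessian, via the closed-form 2x2 eigendecomposition.

    The second-derivative kernel's response to a constant (its kernel sum
    times the local mean) is subtracted so a flat image has zero Hessian.
    """
    from scipy.ndimage import gaussian_filter

    ks2 = float(gaussian_filter(np.ones_like(image), sigma, order=(2, 0),
                                mode="reflect")[0, 0])
    smooth = gaussian_filter(image, sigma, mode="reflect")
    hrr = (gaussian_filter(image, sigma, order=(2, 0), mode="reflect")
           - ks2 * smooth) * sigma**2
    hcc = (gaussian_filter(image, sigma, order=(0, 2), mode="reflect")
           - ks2 * smooth) * sigma**2
    hrc = gaussian_filter(image, sigma, order=(1, 1), mode="reflect") * sigma**2
    tr = hrr + hcc
    disc = np.sqrt(((hrr - hcc) / 2) ** 2 + hrc**2)
    e1 = tr / 2 + disc
    e2 = tr / 2 - disc
    lam1 = np.where(np.abs(e1) <= np.abs(e2), e1, e2)
    lam2 = np.where(np.abs(e1) <= np.abs(e2), e2, e1)
    return lam1, lam2


# ---------------------------------------------------------------------------
# Radiomics: naive texture matrices
# ---------------------------------------------------------------------------

OFFSETS4 = ((0, 1), (1, 1), (1, 0), (1, -1))
OFFSETS8 = ((0, 1), (1, 1), (1, 0), (1, -1), (0, -1), (-1, -1), (-1, 0), (-1, 1))


def glcm_naive(pixels, mask, offset, n_levels):
    h, w = pixels.shape
    dr, dc = offset
    m = np.zeros((n_levels, n_levels))
    for r in range(h):
        for c in range(w):
            r2, c2 = r + dr, c + dc
            if 0 <= r2 < h and 0 <= c2 < w and mask[r, c] and mask[r2, c2]:
                m[pixels[r, c], pixels[r2, c2]] += 1
    return m + m.T


def glrlm_naive(pixels, mask, offset, n_levels):
    """Runs by walking every line in the offset direction pixel by pixel."""
    h, w = pixels.shape
    dr, dc = offset
    max_run = max(h, w)
    m = np.zeros((n_levels, max_run))
    # line starts: pixels with no predecessor in the direction
    for r in range(h):
        for c in range(w):
            pr, pc = r - dr, c - dc
            if 0 <= pr < h and 0 <= pc < w:
                continue  # has a predecessor: not a line start
            rr, cc = r, c
            run_level, run_len = None, 0
            while 0 <= rr < h and 0 <= cc < w:
                if mask[rr, cc]:
                    lv = pixels[rr, cc]
                    if lv == run_level:
                        run_len += 1
                    else:
                        if run_level is not None:
                            m[run_level, run_len - 1] += 1
                        run_level, run_len = lv, 1
                else:
                    if run_level is not None:
                        m[run_level, run_len - 1] += 1
                    run_level, run_len = None, 0
                rr += dr
                cc += dc
            if run_level is not None:
                m[run_level, run_len - 1] += 1
    return m


def glszm_naive(pixels, mask, n_levels):
    """Zones by flood fill over 8-connected same-level masked pixels."""
    h, w = pixels.shape
    seen = np.zeros((h, w), bool)
    m = np.zeros((n_levels, h * w))
    for r in range(h):
        for c in range(w):
            if not mask[r, c] or seen[r, c]:
                continue
            level = pixels[r, c]
            stack, size = [(r, c)], 0
            seen[r, c] = True
            while stack:
                rr, cc = stack.pop()
                size += 1
                for dr, dc in OFFSETS8:
                    r2, c2 = rr + dr, cc + dc
                    if (0 <= r2 < h and 0 <= c2 < w and mask[r2, c2]
                            and not seen[r2, c2] and pixels[r2, c2] == level):
                        seen[r2, c2] = True
                        stack.append((r2, c2))
            m[level, size - 1] += 1
    return m


def ngtdm_naive(pixels, mask, n_levels):
    h, w = pixels.shape
    s = np.zeros(n_levels)
    n = np.zeros(n_levels)
    for r in range(h):
        for c in range(w):
            if not mask[r, c]:
                continue
            nbrs = []
            for dr, dc in OFFSETS8:
                r2, c2 = r + dr, c + dc
                if 0 <= r2 < h and 0 <= c2 < w and mask[r2, c2]:
                    nbrs.append(pixels[r2, c2])
            if not nbrs:
                continue
            lv = pixels[r, c]
            s[lv] += abs(lv - sum(nbrs) / len(nbrs))
            n[lv] += 1
    return s, n


def ngldm_naive(pixels, mask, n_levels, alpha=0):
    h, w = pixels.shape
    m = np.zeros((n_levels, 9))
    for r in range(h):
        for c in range(w):
            if not mask[r, c]:
                continue
            dep = 0
            for dr, dc in OFFSETS8:
                r2, c2 = r + dr, c + dc
                if (0 <= r2 < h and 0 <= c2 < w and mask[r2, c2]
                        and abs(int(pixels[r2, c2]) - int(pixels[r, c])) <= alpha):
                    dep += 1
            m[pixels[r, c], dep] += 1
    return m


# ---------------------------------------------------------------------------
# Radiomics: naive feature formulas
# ---------------------------------------------------------------------------

def glcm_features_naive(glcm):
    total = glcm.sum()
    if total == 0:
        return {}
    p = glcm / total
    ng = p.shape[0]
    out = {}
    mu = sum((i + 1) * p[i, j] for i in range(ng) for j in range(ng))
    var = sum((i + 1 - mu) ** 2 * p[i, j] for i in range(ng) for j in range(ng))
    out["cm.joint.max"] = p.max()
    ja = sum((i + 1) * p[i, j] for i in range(ng) for j in range(ng))
    out["cm.joint.avg"] = ja
    out["cm.joint.var"] = sum((i + 1 - ja) ** 2 * p[i, j]
                              for i in range(ng) for j in range(ng))
    out["cm.joint.entr"] = -sum(p[i, j] * math.log2(p[i, j])
                                for i in range(ng) for j in range(ng) if p[i, j] > 0)
    da = sum(abs(i - j) * p[i, j] for i in range(ng) for j in range(ng))
    out["cm.diff.avg"] = da
    out["cm.diff.var"] = sum((abs(i - j) - da) ** 2 * p[i, j]
                             for i in range(ng) for j in range(ng))
    pd = [sum(p[i, j] for i in range(ng) for j in range(ng) if abs(i - j) == k)
          for k in range(ng)]
    out["cm.diff.entr"] = -sum(q * math.log2(q) for q in pd if q > 0)
    sa = sum((i + j + 2) * p[i, j] for i in range(ng) for j in range(ng))
    out["cm.sum.avg"] = sa
    out["cm.sum.var"] = sum((i + j + 2 - sa) ** 2 * p[i, j]
                            for i in range(ng) for j in range(ng))
    ps = [sum(p[i, j] for i in range(ng) for j in range(ng) if i + j + 2 == k)
          for k in range(2, 2 * ng + 1)]
    out["cm.sum.entr"] = -sum(q * math.log2(q) for q in ps if q > 0)
    out["cm.energy"] = sum(p[i, j] ** 2 for i in range(ng) for j in range(ng))
    out["cm.contrast"] = sum((i - j) ** 2 * p[i, j]
                             for i in range(ng) for j in range(ng))
    out["cm.dissimilarity"] = da
    out["cm.inv.diff"] = sum(p[i, j] / (1 + abs(i - j))
                             for i in range(ng) for j in range(ng))
    out["cm.inv.diff.norm"] = sum(p[i, j] / (1 + abs(i - j) / ng)
                                  for i in range(ng) for j in range(ng))
    out["cm.inv.diff.mom"] = sum(p[i, j] / (1 + (i - j) ** 2)
                                 for i in range(ng) for j in range(ng))
    out["cm.inv.diff.mom.norm"] = sum(p[i, j] / (1 + (i - j) ** 2 / ng**2)
                                      for i in range(ng) for j in range(ng))
    ac = sum((i + 1) * (j + 1) * p[i, j] for i in range(ng) for j in range(ng))
    out["cm.auto.corr"] = ac
    out["cm.corr"] = (ac - mu**2) / var if var > 0 else float("nan")
    out["cm.clust.tend"] = sum((i + j + 2 - 2 * mu) ** 2 * p[i, j]
                               for i in range(ng) for j in range(ng))
    out["cm.clust.shade"] = sum((i + j + 2 - 2 * mu) ** 3 * p[i, j]
                                for i in range(ng) for j in range(ng))
    out["cm.clust.prom"] = sum((i + j + 2 - 2 * mu) ** 4 * p[i, j]
                               for i in range(ng) for j in range(ng))
    return out


def size_matrix_features_naive(m, n_masked):
    """Shared GLRLM/GLSZM/NGLDM weighted sums, naive double loops.

    Returns generic keys (sre, lre, ...) with 1-based i (rows) and j (cols).
    """
    ns = m.sum()
    if ns == 0:
        return {}
    nl, nj = m.shape
    out = {}
    out["sre"] = sum(m[i, j] / (j + 1) ** 2 for i in range(nl) for j in range(nj)) / ns
    out["lre"] = sum(m[i, j] * (j + 1) ** 2 for i in range(nl) for j in range(nj)) / ns
    out["lgre"] = sum(m[i, j] / (i + 1) ** 2 for i in range(nl) for j in range(nj)) / ns
    out["hgre"] = sum(m[i, j] * (i + 1) ** 2 for i in range(nl) for j in range(nj)) / ns
    out["srlge"] = sum(m[i, j] / ((i + 1) ** 2 * (j + 1) ** 2)
                       for i in range(nl) for j in range(nj)) / ns
    out["srhge"] = sum(m[i, j] * (i + 1) ** 2 / (j + 1) ** 2
                       for i in range(nl) for j in range(nj)) / ns
    out["lrlge"] = sum(m[i, j] * (j + 1) ** 2 / (i + 1) ** 2
                       for i in range(nl) for j in range(nj)) / ns
    out["lrhge"] = sum(m[i, j] * (i + 1) ** 2 * (j + 1) ** 2
                       for i in range(nl) for j in range(nj)) / ns
    out["glnu"] = sum(m[i, :].sum() ** 2 for i in range(nl)) / ns
    out["glnu.norm"] = out["glnu"] / ns
    out["snu"] = sum(m[:, j].sum() ** 2 for j in range(nj)) / ns
    out["snu.norm"] = out["snu"] / ns
    out["perc"] = ns / n_masked
    mu_i = sum((i + 1) * m[i, j] for i in range(nl) for j in range(nj)) / ns
    out["gl.var"] = sum((i + 1 - mu_i) ** 2 * m[i, j]
                        for i in range(nl) for j in range(nj)) / ns
    mu_j = sum((j + 1) * m[i, j] for i in range(nl) for j in range(nj)) / ns
    out["s.var"] = sum((j + 1 - mu_j) ** 2 * m[i, j]
                       for i in range(nl) for j in range(nj)) / ns
    out["s.entr"] = -sum(m[i, j] / ns * math.log2(m[i, j] / ns)
                         for i in range(nl) for j in range(nj) if m[i, j] > 0)
    out["s.energy"] = sum((m[i, j] / ns) ** 2
                          for i in range(nl) for j in range(nj))
    return out


def ngtdm_features_naive(s, n):
    nv = n.sum()
    if nv == 0:
        return {}
    p = n / nv
    nl = len(s)
    present = [i for i in range(nl) if p[i] > 0]
    ngp = len(present)
    out = {}
    denom = sum(p[i] * s[i] for i in range(nl))
    out["coarseness"] = 1.0 / denom if denom > 0 else 1e6
    if ngp > 1:
        out["contrast"] = (sum(p[i] * p[j] * (i - j) ** 2
                               for i in present for j in present)
                           / (ngp * (ngp - 1)) * s.sum() / nv)
        bd = sum(abs((i + 1) * p[i] - (j + 1) * p[j])
                 for i in present for j in present)
        out["busyness"] = denom / bd if bd > 0 else 0.0
        out["complexity"] = sum(abs(i - j) * (p[i] * s[i] + p[j] * s[j])
                                / (p[i] + p[j])
                                for i in present for j in present) / nv
        sn = sum((p[i] + p[j]) * (i - j) ** 2 for i in present for j in present)
        out["strength"] = sn / s.sum() if s.sum() > 0 else 0.0
    else:
        out["contrast"] = out["busyness"] = 0.0
        out["complexity"] = out["strength"] = 0.0
    return out


def intensity_stats_naive(x):
    x = np.asarray(x, float)
    n = x.size
    mu = x.sum() / n
    var = sum((v - mu) ** 2 for v in x) / n
    sd = math.sqrt(var)
    p10, p25, p50, p75, p90 = np.percentile(x, [10, 25, 50, 75, 90])
    out = {
        "mean": mu, "var": var,
        "skew": sum((v - mu) ** 3 for v in x) / n / sd**3 if sd > 0 else float("nan"),
        "kurt": sum((v - mu) ** 4 for v in x) / n / var**2 - 3 if sd > 0 else float("nan"),
        "median": p50, "min": x.min(), "p10": p10, "p90": p90, "max": x.max(),
        "iqr": p75 - p25, "range": x.max() - x.min(),
        "mad": sum(abs(v - mu) for v in x) / n,
        "medad": sum(abs(v - p50) for v in x) / n,
        "cov": sd / mu if mu != 0 else float("nan"),
        "qcod": (p75 - p25) / (p75 + p25) if (p75 + p25) != 0 else float("nan"),
        "energy": float(sum(v * v for v in x)),
        "rms": math.sqrt(sum(v * v for v in x) / n),
    }
    mid = [v for v in x if p10 <= v <= p90]
    mm = sum(mid) / len(mid)
    out["rmad"] = sum(abs(v - mm) for v in mid) / len(mid)
    return out


def ivh_v_naive(x, gamma):
    x = np.asarray(x, float)
    thr = x.min() + gamma * (x.max() - x.min())
    return sum(v >= thr for v in x) / x.size


def moments_naive(values):
    """Two-pass mean and population sd."""
    values = list(values)
    n = len(values)
    mean = sum(values) / n
    sd = math.sqrt(sum((v - mean) ** 2 for v in values) / n)
    return mean, sd


def pearson_naive(x, y):
    n = len(x)
    mx, my = sum(x) / n, sum(y) / n
    num = sum((a - mx) * (b - my) for a, b in zip(x, y))
    dx = math.sqrt(sum((a - mx) ** 2 for a in x))
    dy = math.sqrt(sum((b - my) ** 2 for b in y))
    return num / (dx * dy)


def random_toy(rng, size=8, n_levels=6):
    """Random small discretized raster with a random non-trivial mask."""
    pixels = rng.integers(0, n_levels, size=(size, size))
    mask = rng.random((size, size)) < 0.8
    if not mask.any():
        mask[0, 0] = True
    return pixels, mask
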