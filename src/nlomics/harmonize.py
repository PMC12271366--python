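"""Feature harmonization screen and group statistics.

Features extracted from two different animals can carry batch effects: the
distribution of a feature over the training subject may barely overlap its
distribution over the test subject, making the feature useless (or harmful)
for a model that must generalize.  The screen quantifies this with the KDE
overlap — the integral of the pointwise minimum of Gaussian kernel density
estimates of the train and test samples — and discards features whose
overlap falls below a threshold (default 0.75).

Group significance uses the Kruskal–Wallis rank test (k classes) and the
two-sided Wilcoxon rank-sum test (healthy vs pathological), both
distribution-free; p-values below 0.05 are flagged significant with no
multiple-testing correction by default (a Benjamini–Hochberg option exists).
Radiomic-vs-conventional association uses the Pearson correlation matrix.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats
from scipy.fft import dct
from scipy.optimize import brentq

OVERLAP_GRID_POINTS = 1024


# ---------------------------------------------------------------------------
# Kernel density estimation
# ---------------------------------------------------------------------------

def silverman_bandwidth(x: np.ndarray) -> float:
    x = np.asarray(x, dtype=float)
    sd = x.std(ddof=1)
    iqr = np.subtract(*np.percentile(x, [75, 25]))
    a = min(sd, iqr / 1.349) if iqr > 0 else sd
    return 0.9 * a * x.size ** (-0.2)

def botev_bandwidth(x: np.ndarray, n_grid: int = 2**12) -> float:
    """Diffusion-style (improved Sheather–Jones) bandwidth selection.

    Solves the ISJ fixed point on a DCT representation of the binned data;
    falls back to the Silverman rule when the fixed point has no root in the
    bracket (small or pathological samples).
    """
    x = np.asarray(x, dtype=float)
    n = x.size
    lo, hi = x.min(), x.max()
    span = hi - lo
    lo, hi = lo - span / 10, hi + span / 10
    counts, _ = np.histogram(x, bins=n_grid, range=(lo, hi))
    p = counts / n
    a = dct(p)
    k2 = np.arange(1, n_grid, dtype=float) ** 2
    a2 = (a[1:] / 2.0) ** 2

    def xi_gamma(t: float, l: int = 7) -> float:
        f = 2.0 * np.pi ** (2 * l) * np.sum(k2 ** l * a2 *
                                            np.exp(-k2 * np.pi**2 * t))
        for s in range(l - 1, 1, -1):
            k0 = np.prod(np.arange(1, 2 * s, 2)) / np.sqrt(2 * np.pi)
            const = (1 + 0.5 ** (s + 0.5)) / 3.0
            t_s = (2 * const * k0 / (n * f)) ** (2.0 / (3 + 2 * s))
            f = 2.0 * np.pi ** (2 * s) * np.sum(k2 ** s * a2 *
                                                np.exp(-k2 * np.pi**2 * t_s))
        return (2 * n * np.sqrt(np.pi) * f) ** (-0.4)

    try:
        with np.errstate(divide="ignore", invalid="ignore"):
            t_star = brentq(lambda t: t - xi_gamma(t), 1e-12, 0.1)
            bw = np.sqrt(t_star) * (hi - lo)
        if not np.isfinite(bw) or bw <= 0:
            raise ValueError
        return float(bw)
    except (ValueError, ZeroDivisionError):
        return float(silverman_bandwidth(x))


def kde_estimate(samples, grid, bandwidth: float | None = None) -> np.ndarray:
    """Gaussian kernel density of the samples evaluated on the grid."""
    samples = np.asarray(samples, dtype=float)
    grid = np.asarray(grid, dtype=float)
    samples = samples[np.isfinite(samples)]
    if samples.size < 5:
        raise ValueError("need >= 5 finite samples for a density estimate")
    if samples.std() == 0:
        raise ValueError("zero-variance sample has no density estimate")
    h = bandwidth if bandwidth is not None else botev_bandwidth(samples)
    z = (grid[:, None] - samples[None, :]) / h
    return np.exp(-0.5 * z**2).sum(axis=1) / (samples.size * h * np.sqrt(2 * np.pi))


def kde_overlap(train_samples, test_samples) -> float:
    """∫ min(f_train, f_test) over a shared grid; symmetric, in [0, 1].

    The grid spans both samples' ranges padded by five bandwidths (1024
    points), wide enough that identical samples integrate to 1 within 1e-6.
    """
    a = np.asarray(train_samples, dtype=float)
    b = np.asarray(test_samples, dtype=float)
    a, b = a[np.isfinite(a)], b[np.isfinite(b)]
    h_a, h_b = botev_bandwidth(a) if a.std() else 0, botev_bandwidth(b) if b.std() else 0
    if a.std() == 0 or b.std() == 0:
        raise ValueError("zero-variance sample in overlap computation")
    pad = 5.0 * max(h_a, h_b)
    lo = min(a.min(), b.min()) - pad
    hi = max(a.max(), b.max()) + pad
    grid = np.linspace(lo, hi, OVERLAP_GRID_POINTS)
    fa = kde_estimate(a, grid, h_a)
    fb = kde_estimate(b, grid, h_b)
    return float(np.trapezoid(np.minimum(fa, fb), grid))


@dataclass
class ScreenResult:
    """Per-feature KDE overlap and keep decision."""

    overlaps: pd.Series  # feature -> overlap (NaN if not computable)
    kept: pd.Series  # feature -> bool
    threshold: float
    dropped_reasons: dict[str, str]

    @property
    def kept_features(self) -> list[str]:
        return list(self.kept.index[self.kept])


def screen_features(
    table: pd.DataFrame,
    threshold: float = 0.75,
    feature_columns: list[str] | None = None,
    max_missing_frac: float = 0.2,
) -> ScreenResult:
    """Screen features on train-vs-test KDE overlap.

    ``table`` must carry a ``split`` column with values ``train``/``test``.
    Features with more than ``max_missing_frac`` missing values, or on which
    the density estimate degenerates, are dropped with a logged reason.
    """
    if feature_columns is None:
        meta = {"class", "roi", "subject", "split", "frame", "seed"}
        feature_columns = [c for c in table.columns
                           if c not in meta and pd.api.types.is_numeric_dtype(table[c])]
    splits = set(table["split"])
    if not {"train", "test"} <= splits:
        raise ValueError("table must contain both train and test splits")
    overlaps, kept, reasons = {}, {}, {}
    tr = table[table["split"] == "train"]
    te = table[table["split"] == "test"]
    for col in feature_columns:
        if table[col].isna().mean() > max_missing_frac:
            overlaps[col], kept[col] = float("nan"), False
            reasons[col] = "too many missing values"
            continue
        try:
            overlaps[col] = kde_overlap(tr[col].dropna(), te[col].dropna())
        except ValueError as exc:
            overlaps[col], kept[col] = float("nan"), False
            reasons[col] = str(exc)
            continue
        kept[col] = overlaps[col] >= threshold
    return ScreenResult(pd.Series(overlaps), pd.Series(kept), threshold, reasons)


# ---------------------------------------------------------------------------
# Rank tests
# ---------------------------------------------------------------------------

def kruskal_wallis(*groups) -> tuple[float, float]:
    """Tie-corrected Kruskal–Wallis H and chi-square p over k >= 2 groups."""
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2 or any(g.size == 0 for g in groups):
        raise ValueError("need >= 2 non-empty groups")
    pooled = np.concatenate(groups)
    if np.all(pooled == pooled[0]):
        return 0.0, 1.0
    h, p = stats.kruskal(*groups)
    return float(h), float(p)


def ranksum(group_a, group_b) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum test.

    Exact enumeration of all C(n_a+n_b, n_a) labelings (tie-safe, via
    midranks) when n_a + n_b <= 12, otherwise the normal approximation with
    tie correction.  Returns (W, p) where W is the rank sum of group_a.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([a, b])
    ranks = stats.rankdata(pooled)
    w = float(ranks[: a.size].sum())
    n = a.size + b.size
    if n <= 12:
        e = a.size * (n + 1) / 2.0
        obs = abs(w - e)
        count = total = 0
        for idx in combinations(range(n), a.size):
            total += 1
            if abs(ranks[list(idx)].sum() - e) >= obs - 1e-12:
                count += 1
        return w, count / total
    _, p = stats.mannwhitneyu(a, b, alternative="two-sided",
                              method="asymptotic", use_continuity=True)
    return w, float(p)


def benjamini_hochberg(p_values) -> np.ndarray:
    """BH-adjusted q-values (optional; the default protocol applies none)."""
    p = np.asarray(p_values, dtype=float)
    order = np.argsort(p)
    m = p.size
    q = np.empty(m)
    prev = 1.0
    for rank_idx in range(m - 1, -1, -1):
        i = order[rank_idx]
        prev = min(prev, p[i] * m / (rank_idx + 1))
        q[i] = prev
    return q


def pearson_matrix(conv: pd.DataFrame, rad: pd.DataFrame) -> pd.DataFrame:
    """Pearson r between every (radiomic, conventional) feature pair.

    Rows are radiomic features, columns conventional features; each entry is
    computed over the pairwise-complete rows.  Zero-variance columns yield
    NaN entries.
    """
    if len(conv) != len(rad):
        raise ValueError("feature tables must have paired rows")
    out = pd.DataFrame(index=rad.columns, columns=conv.columns, dtype=float)
    for r in rad.columns:
        for c in conv.columns:
            x = rad[r].to_numpy(dtype=float)
            y = conv[c].to_numpy(dtype=float)
            ok = np.isfinite(x) & np.isfinite(y)
            if ok.sum() < 3 or x[ok].std() == 0 or y[ok].std() == 0:
                out.loc[r, c] = float("nan")
                continue
            out.loc[r, c] = float(np.corrcoef(x[ok], y[ok])[0, 1])
    return out
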