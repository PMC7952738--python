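"""Cross-sectional population analysis in atlas space.

Group mean/std maps, pixelwise two-sided Mann-Whitney U comparisons with
Benjamini-Hochberg FDR control at 5%, and topographic profiles (feature
mean as a function of eccentricity from the fovea).  One eye contributes
one map per analysis: converters their scan one month before conversion,
non-progressors their last available scan.  Tests operate on eye-level
values — never on pooled pixels — to avoid pseudo-replication.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .refframe import eccentricity_map
from .types import AtlasGrid, EnfaceMap

__all__ = [
    "GroupStatResult",
    "TopographicProfile",
    "select_analysis_scan",
    "group_maps",
    "pixelwise_mwu",
    "fdr_correct",
    "topographic_profile",
]


@dataclass
class GroupStatResult:
    mean: dict = field(default_factory=dict)  # group -> 2D array
    std: dict = field(default_factory=dict)
    n: dict = field(default_factory=dict)
    difference: np.ndarray | None = None  # A - B
    p: np.ndarray | None = None
    q: np.ndarray | None = None
    significant: np.ndarray | None = None
    pair: tuple[str, str] | None = None


@dataclass
class TopographicProfile:
    bin_centers_mm: np.ndarray
    mean: dict  # group -> per-bin mean over eyes
    ci_lo: dict
    ci_hi: dict
    n: dict
    p: np.ndarray | None = None
    q: np.ndarray | None = None
    significant: np.ndarray | None = None
    pair: tuple[str, str] | None = None

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for g in self.mean:
            for k, c in enumerate(self.bin_centers_mm):
                rows.append(
                    {
                        "bin_center_mm": c,
                        "group": g,
                        "mean": self.mean[g][k],
                        "ci_lo": self.ci_lo[g][k],
                        "ci_hi": self.ci_hi[g][k],
                        "n": self.n[g][k],
                        "p": np.nan if self.p is None else self.p[k],
                        "q": np.nan if self.q is None else self.q[k],
                    }
                )
        return pd.DataFrame(rows)


def select_analysis_scan(
    visit_months, group: str, conversion_month: float | None = None
):
    """Choose the analysis time point for one eye.

    Converters use the visit closest to one month before conversion
    (restricted to strictly pre-conversion visits; ties go to the earlier
    visit), non-progressors their last available visit.  Returns the
    chosen month, or None when a converter has no pre-conversion visit.
    """
    months = sorted(float(m) for m in visit_months)
    if not months:
        raise ValueError("empty visit list")
    if group == "NONP" or conversion_month is None:
        return months[-1]
    candidates = [m for m in months if m < conversion_month]
    if not candidates:
        return None
    target = conversion_month - 1.0
    return min(candidates, key=lambda m: (abs(m - target), m))


def _stack(maps: list[EnfaceMap]) -> tuple[np.ndarray, np.ndarray]:
    vals = np.stack([m.values for m in maps])
    mask = np.stack([m.valid_mask for m in maps])
    return np.where(mask, vals, np.nan), mask


def group_maps(
    maps: list[EnfaceMap], min_n: int = 2
) -> GroupStatResult:
    """Pixelwise mean/std/n maps per group (one map per eye).

    Pixels where fewer than ``min_n`` eyes are valid are excluded; a
    group with fewer than 2 eyes is rejected.
    """
    groups = sorted({m.group for m in maps})
    result = GroupStatResult()
    for g in groups:
        gm = [m for m in maps if m.group == g]
        if len(gm) < 2:
            raise ValueError(f"group {g!r} has fewer than 2 eyes")
        vals, mask = _stack(gm)
        n = mask.sum(axis=0)
        enough = n >= max(min_n, 2)
        import warnings as _warnings

        with np.errstate(invalid="ignore"), _warnings.catch_warnings():
            _warnings.simplefilter("ignore", RuntimeWarning)
            mean = np.nanmean(vals, axis=0)
            std = np.nanstd(vals, axis=0, ddof=1)
        mean[~enough] = np.nan
        std[~enough] = np.nan
        result.mean[g], result.std[g], result.n[g] = mean, std, n
    return result


def pixelwise_mwu(
    maps_a: list[EnfaceMap],
    maps_b: list[EnfaceMap],
    min_n: int = 3,
) -> tuple[np.ndarray, np.ndarray]:
    """Difference-of-means map and two-sided Mann-Whitney p map.

    The test is exact when the combined sample is small (≤ 12) and free
    of ties, otherwise the tie-corrected normal approximation with
    continuity correction is used.  Pixels with fewer than ``min_n``
    valid eyes per group are untested (NaN); all-tied pixels get p = 1.
    """
    import warnings as _warnings

    va, ma = _stack(maps_a)
    vb, mb = _stack(maps_b)
    na = ma.sum(axis=0)
    nb = mb.sum(axis=0)
    testable = (na >= min_n) & (nb >= min_n)
    with np.errstate(invalid="ignore"), _warnings.catch_warnings():
        _warnings.simplefilter("ignore", RuntimeWarning)
        diff = np.nanmean(va, axis=0) - np.nanmean(vb, axis=0)
    diff[~testable] = np.nan
    p = np.full(diff.shape, np.nan)
    complete = testable & (na == len(maps_a)) & (nb == len(maps_b))
    small = len(maps_a) + len(maps_b) <= 12
    if complete.any() and not small:
        res = stats.mannwhitneyu(
            va[:, complete], vb[:, complete], axis=0, method="asymptotic"
        )
        p[complete] = res.pvalue
    # small samples, or pixels with missing eyes: per-pixel fallback
    rest = testable & (~complete | small)
    for idx in zip(*np.nonzero(rest)):
        a = va[(slice(None), *idx)]
        b = vb[(slice(None), *idx)]
        a, b = a[np.isfinite(a)], b[np.isfinite(b)]
        if np.ptp(np.concatenate([a, b])) == 0:
            p[idx] = 1.0
            continue
        ties = len(np.unique(np.concatenate([a, b]))) < len(a) + len(b)
        method = "exact" if (len(a) + len(b) <= 12 and not ties) else "asymptotic"
        p[idx] = stats.mannwhitneyu(a, b, method=method).pvalue
    # all-tied pixels under the vectorized path
    with np.errstate(invalid="ignore"), _warnings.catch_warnings():
        _warnings.simplefilter("ignore", RuntimeWarning)
        allsame = testable & (np.nanmax(va, axis=0) == np.nanmin(va, axis=0)) & (
            np.nanmax(vb, axis=0) == np.nanmin(vb, axis=0)
        ) & (np.nanmax(va, axis=0) == np.nanmax(vb, axis=0))
    p[allsame] = 1.0
    return diff, p


def fdr_correct(p: np.ndarray, alpha: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up over the family of valid (finite) tests.

    Returns (significance mask, adjusted q values); invalid entries stay
    False / NaN.
    """
    p = np.asarray(p, dtype=float)
    valid = np.isfinite(p)
    mask = np.zeros(p.shape, dtype=bool)
    q = np.full(p.shape, np.nan)
    if valid.any():
        rej, qv, *_ = multipletests(p[valid], alpha=alpha, method="fdr_bh")
        mask[valid] = rej
        q[valid] = qv
    return mask, q


def topographic_profile(
    maps: list[EnfaceMap],
    bin_width_mm: float = 0.1,
    max_ecc_mm: float | None = None,
    test_pair: tuple[str, str] | None = None,
    alpha: float = 0.05,
    min_n: int = 3,
) -> TopographicProfile:
    """Feature mean as a function of eccentricity, with group tests.

    Per eye and annulus the mean over valid pixels is taken; per bin the
    group mean and normal-theory 0.95 CI of the mean over eyes, and a
    two-sided Mann-Whitney test between ``test_pair`` with BH-FDR across
    bins.  Maps must live on the atlas grid.
    """
    grid = AtlasGrid()
    ecc = eccentricity_map(grid).values
    if max_ecc_mm is None:
        max_ecc_mm = grid.extent_mm / 2.0
    edges = np.arange(0.0, max_ecc_mm + bin_width_mm / 2, bin_width_mm)
    if edges[-1] < max_ecc_mm:
        edges = np.append(edges, max_ecc_mm)
    centers = 0.5 * (edges[:-1] + edges[1:])
    bin_idx = np.digitize(ecc.ravel(), edges) - 1
    n_bins = len(centers)

    in_range = (bin_idx >= 0) & (bin_idx < n_bins)
    groups = sorted({m.group for m in maps})
    eye_means: dict[str, np.ndarray] = {}
    for g in groups:
        gm = [m for m in maps if m.group == g]
        per_eye = np.full((len(gm), n_bins), np.nan)
        for i, m in enumerate(gm):
            v = np.where(m.valid_mask, m.values, np.nan).ravel()
            ok = in_range & np.isfinite(v)
            sums = np.bincount(bin_idx[ok], weights=v[ok], minlength=n_bins)
            counts = np.bincount(bin_idx[ok], minlength=n_bins)
            nz = counts > 0
            per_eye[i, nz] = sums[nz] / counts[nz]
        eye_means[g] = per_eye

    mean, lo, hi, n = {}, {}, {}, {}
    for g in groups:
        pe = eye_means[g]
        cnt = np.isfinite(pe).sum(axis=0)
        with np.errstate(invalid="ignore"):
            mu = np.nanmean(pe, axis=0)
            sem = np.nanstd(pe, axis=0, ddof=1) / np.sqrt(np.maximum(cnt, 1))
        mean[g], n[g] = mu, cnt
        lo[g] = mu - 1.96 * sem
        hi[g] = mu + 1.96 * sem

    p = q = sig = None
    pair = test_pair
    if pair is None and len(groups) >= 2:
        pair = (groups[0], groups[1])
    if pair is not None:
        p = np.full(n_bins, np.nan)
        for k in range(n_bins):
            a = eye_means[pair[0]][:, k]
            b = eye_means[pair[1]][:, k]
            a, b = a[np.isfinite(a)], b[np.isfinite(b)]
            if len(a) < min_n or len(b) < min_n:
                continue
            if np.ptp(np.concatenate([a, b])) == 0:
                p[k] = 1.0
                continue
            ties = len(np.unique(np.concatenate([a, b]))) < len(a) + len(b)
            method = "exact" if (len(a) + len(b) <= 12 and not ties) else "asymptotic"
            p[k] = stats.mannwhitneyu(a, b, method=method).pvalue
        sig, q = fdr_correct(p, alpha=alpha)
    return TopographicProfile(
        bin_centers_mm=centers,
        mean=mean,
        ci_lo=lo,
        ci_hi=hi,
        n=n,
        p=p,
        q=q,
        significant=sig,
        pair=pair,
    )
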