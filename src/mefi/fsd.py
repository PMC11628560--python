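"""Per-site fragmentation profiles: the FSD score track and its processing.

The fragment size distribution (FSD) score at each mitochondrial site is the
coverage-depth ratio of long to short fragments, where "long" and "short"
are split at the sample's own median fragment size.  Sites protected by
bound protein are depleted of internal cleavage, so covering fragments tend
to be long and the FSD score rises; the per-site track therefore reads out
protein occupancy along the circle.  The raw ratio is corrected for GC
content with LOESS (span 0.75, degree 1) against a per-site GC covariate and
scaled to a z-score against the overall mean, giving the fragmentation
profile used by the peak and window features.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats
from statsmodels.nonparametric.smoothers_lowess import lowess

from .fragments import FragmentSet

logger = logging.getLogger(__name__)


@dataclass
class SiteProfile:
    """Per-site arrays over 1..L plus the sample's median fragment size."""

    depth: np.ndarray
    long_depth: np.ndarray
    short_depth: np.ndarray
    fsd_raw: np.ndarray
    fsd_gc_corrected: np.ndarray
    fsd_z: np.ndarray
    median_fragment_size: float


def split_long_short(fs: FragmentSet) -> tuple[float, np.ndarray]:
    """Median fragment size and a per-fragment long/short label.

    A fragment is short iff its length <= the sample median (ties go to
    short, so "all lengths equal" degenerates to all-short).
    """
    if len(fs) < 2:
        raise ValueError("need at least 2 fragments to split by median size")
    lengths = fs.lengths
    median = float(np.median(lengths))
    is_long = lengths > median
    return median, is_long


def site_depths(fs: FragmentSet, is_long: np.ndarray, L: int | None = None):
    """Per-site long and short coverage depths (wrap-aware).

    A fragment covers every site of its circular span; implemented with
    difference arrays so cost is O(n_fragments + L).
    """
    L = L or fs.L
    out = []
    for mask in (is_long, ~is_long):
        diff = np.zeros(L + 1, dtype=np.int64)
        s = fs.start[mask]
        e = fs.end[mask]
        wrap = s > e
        # non-wrapping span [s, e]
        np.add.at(diff, s[~wrap] - 1, 1)
        np.add.at(diff, e[~wrap], -1)
        # wrapping span [s, L] + [1, e]; the [s, L] piece runs to the last
        # site so its closing decrement falls at index L, outside the cumsum
        np.add.at(diff, s[wrap] - 1, 1)
        diff[0] += int(wrap.sum())
        np.add.at(diff, e[wrap], -1)
        out.append(np.cumsum(diff[:L]))
    long_depth, short_depth = out
    return long_depth, short_depth


def fsd_raw(
    long_depth: np.ndarray, short_depth: np.ndarray, pseudocount: float = 1.0
) -> np.ndarray:
    """FSD[i] = (long_depth[i] + pc) / (short_depth[i] + pc).

    The pseudocount keeps zero-coverage sites defined (ratio 1 = neutral) and
    is negligible at capture-scale depth.
    """
    return (long_depth + pseudocount) / (short_depth + pseudocount)


def gc_correct_loess(
    fsd: np.ndarray,
    gc_track: np.ndarray,
    span: float = 0.75,
    degree: int = 1,
) -> np.ndarray:
    """Residual-plus-mean LOESS GC correction of the raw FSD track.

    Fits a degree-1 LOESS of FSD on the per-site GC fraction (span 0.75) and
    returns ``fsd - fit(gc) + mean(fsd)``, removing the smooth GC dependence
    while preserving the track's scale.  A constant GC track makes the fit
    undefined; the correction is then the identity (logged).
    """
    if degree != 1:
        raise ValueError("only degree-1 (locally linear) LOESS is supported")
    fsd = np.asarray(fsd, dtype=float)
    gc = np.asarray(gc_track, dtype=float)
    if fsd.shape != gc.shape:
        raise ValueError("fsd and gc tracks differ in length")
    if np.ptp(gc) == 0:
        logger.warning("constant GC track; LOESS correction skipped (identity)")
        return fsd.copy()
    # the GC covariate takes few distinct values (window counts / window
    # size), so delta-interpolation makes the fit effectively O(unique x)
    delta = 0.001 * np.ptp(gc)
    fit = lowess(
        fsd, gc, frac=span, it=2, delta=delta, return_sorted=False
    )
    return fsd - fit + fsd.mean()


def zscore(values: np.ndarray) -> np.ndarray:
    """(x - mean) / sd with the population (n-denominator) sd.

    Zero-variance input returns all zeros (logged) rather than NaN.
    """
    values = np.asarray(values, dtype=float)
    sd = values.std()
    if sd == 0:
        logger.warning("zero-variance input to zscore; returning zeros")
        return np.zeros_like(values)
    return (values - values.mean()) / sd


#: z-scored per-site sequencing depth (used for ATAC-style occupancy tracks);
#: shares the z-score kernel.
standardized_depth = zscore


def profile_correlation(profile_z: np.ndarray, reference_profile_z: np.ndarray) -> float:
    """Spearman rank correlation between a sample profile and the reference
    (median healthy-control) profile, with average-rank ties."""
    a = np.asarray(profile_z, float)
    b = np.asarray(reference_profile_z, float)
    if a.shape != b.shape:
        raise ValueError("profiles differ in length")
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise ValueError("constant profile has no rank correlation")
    rho, _ = stats.spearmanr(a, b)
    return float(rho)


def reference_profile(panel: list[SiteProfile]) -> np.ndarray:
    """Reference fragmentation profile from a healthy-control panel.

    Site-wise median of the panel members' GC-corrected FSD tracks, then
    z-scaled.  The median makes the reference robust to individual outlier
    profiles.
    """
    if not panel:
        raise ValueError("empty reference panel")
    stack = np.vstack([p.fsd_gc_corrected for p in panel])
    return zscore(np.median(stack, axis=0))


def compute_profile(
    fs: FragmentSet, gc_track: np.ndarray, pseudocount: float = 1.0,
    span: float = 0.75,
) -> SiteProfile:
    """Full pipeline: median split → depths → raw FSD → GC correction → z."""
    median, is_long = split_long_short(fs)
    long_depth, short_depth = site_depths(fs, is_long)
    raw = fsd_raw(long_depth, short_depth, pseudocount)
    corrected = gc_correct_loess(raw, gc_track, span=span)
    return SiteProfile(
        depth=long_depth + short_depth,
        long_depth=long_depth,
        short_depth=short_depth,
        fsd_raw=raw,
        fsd_gc_corrected=corrected,
        fsd_z=zscore(corrected),
        median_fragment_size=median,
    )
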