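"""Peak calling and window features on z-scored fragmentation profiles.

A peak is a maximal circular run of consecutive sites strictly above (or
strictly below) the baseline of 0, at least 5 bp wide; zero-valued sites
break runs.  "New" peaks of a sample, relative to the healthy-control
reference profile, are peaks whose apex lies more than 20 bp (circular
apex-to-apex distance) from every reference apex.  For window features the
genome is tiled into 255 windows of 65 bp (the last window is 59 bp), and
per window the positive and negative areas of the z track and the Euclidean
distance to the reference profile are computed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "Peak",
    "call_peaks",
    "circular_distance",
    "new_peaks",
    "windows",
    "window_areas",
    "window_distances",
]


@dataclass(frozen=True)
class Peak:
    sign: str  # '+' or '-'
    start_site: int
    end_site: int  # start > end encodes an origin-wrapping run
    width: int
    apex_site: int  # site of max |z| within the run; ties -> smallest site
    area: float  # signed sum of z over the run


def call_peaks(
    profile_z: np.ndarray, min_width: int = 5, baseline: float = 0.0
) -> list[Peak]:
    """Maximal circular runs of sites strictly above/below the baseline.

    Runs shorter than ``min_width`` are discarded.  Sites exactly at the
    baseline are uninformative and break runs.  Apex ties are broken to the
    smallest genomic site index.
    """
    z = np.asarray(profile_z, dtype=float)
    L = z.size
    sign = np.zeros(L, dtype=np.int8)
    sign[z > baseline] = 1
    sign[z < baseline] = -1

    if L == 0:
        return []
    if np.all(sign == sign[0]):
        if sign[0] == 0:
            return []
        runs = [(0, L)]  # whole circle is one run
        offset = 0
    else:
        # rotate so the array starts at a run boundary, then scan linearly
        boundaries = np.flatnonzero(sign != np.roll(sign, 1))
        offset = int(boundaries[0])
        rot = np.roll(sign, -offset)
        change = np.flatnonzero(np.diff(rot) != 0) + 1
        starts = np.concatenate([[0], change])
        ends = np.concatenate([change, [L]])
        runs = list(zip(starts, ends))

    peaks: list[Peak] = []
    for a, b in runs:
        s = sign[(a + offset) % L]
        if s == 0:
            continue
        width = b - a
        if width < min_width:
            continue
        idx = (np.arange(a, b) + offset) % L  # 0-based genomic indices
        vals = z[idx]
        apex_local = np.flatnonzero(np.abs(vals) == np.abs(vals).max())
        apex_site = int(idx[apex_local].min()) + 1
        peaks.append(
            Peak(
                sign="+" if s > 0 else "-",
                start_site=int(idx[0]) + 1,
                end_site=int(idx[-1]) + 1,
                width=int(width),
                apex_site=apex_site,
                area=float(vals.sum()),
            )
        )
    peaks.sort(key=lambda p: p.start_site)
    return peaks


def circular_distance(a: int, b: int, L: int) -> int:
    d = abs(a - b) % L
    return min(d, L - d)


def new_peaks(
    sample_peaks: list[Peak],
    reference_peaks: list[Peak],
    L: int,
    min_distance: int = 20,
) -> tuple[list[Peak], int]:
    """Sample peaks whose apex is > ``min_distance`` bp (circular) from every
    reference-peak apex; the count is the model feature."""
    if not reference_peaks:
        return list(sample_peaks), len(sample_peaks)
    ref_apexes = [p.apex_site for p in reference_peaks]
    novel = [
        p
        for p in sample_peaks
        if all(circular_distance(p.apex_site, ra, L) > min_distance for ra in ref_apexes)
    ]
    return novel, len(novel)


def windows(L: int = 16569, n: int = 255) -> list[tuple[int, int]]:
    """Tile 1..L into n windows of ceil(L/n) bp; the last window is shorter.

    For the mitochondrial genome: 254 windows of 65 bp and one of 59 bp.
    """
    if n < 1:
        raise ValueError("need at least one window")
    w = -(-L // n)
    out = []
    for k in range(1, n + 1):
        start = (k - 1) * w + 1
        end = min(k * w, L)
        if start > L:
            raise ValueError(f"{n} windows of {w} bp overrun the genome")
        out.append((start, end))
    return out


def window_areas(
    profile_z: np.ndarray,
    window_list: list[tuple[int, int]],
    baseline: float = 0.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Positive and negative areas of the z track per window, at baseline 0.

    pos = sum of max(z - baseline, 0), neg = sum of max(baseline - z, 0);
    integrated over the full track (not only called peaks), so
    sum(pos) - sum(neg) = sum(z) = 0 for a z-scaled profile.
    """
    z = np.asarray(profile_z, dtype=float) - baseline
    pos = np.empty(len(window_list))
    neg = np.empty(len(window_list))
    for i, (s, e) in enumerate(window_list):
        seg = z[s - 1 : e]
        pos[i] = seg.clip(min=0).sum()
        neg[i] = (-seg).clip(min=0).sum()
    return pos, neg


def window_distances(
    profile_z: np.ndarray,
    reference_profile_z: np.ndarray,
    window_list: list[tuple[int, int]],
) -> np.ndarray:
    """Per-window Euclidean distance between sample and reference profiles."""
    a = np.asarray(profile_z, dtype=float)
    b = np.asarray(reference_profile_z, dtype=float)
    if a.shape != b.shape:
        raise ValueError("profiles differ in length")
    d = np.empty(len(window_list))
    for i, (s, e) in enumerate(window_list):
        diff = a[s - 1 : e] - b[s - 1 : e]
        d[i] = np.sqrt((diff**2).sum())
    return d
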