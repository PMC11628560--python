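"""5' end base proportions, genome-normalized preferences, and motif diversity.

cfDNA fragmentation is non-random: the nucleases that cleave circulating DNA
leave characteristic bases and 4-mer motifs at fragment 5' ends.  Three
summaries are computed per sample (optionally restricted to fragments whose
5' end falls inside a functional region):

* end-base proportion — fraction of 5' ends carrying each base;
* end-base preference — proportion normalized by the genome's base
  composition, so 1.0 means "no preference";
* motif diversity score (MDS) — the normalized Shannon entropy of the
  256-motif 5' end 4-mer spectrum,

      MDS = sum_i -P_i * log(P_i) / log(256),

  which ranges from 0 (a single motif) to 1 (uniform cleavage).

Both strand ends of every fragment contribute: the light-strand 5' end at
the leftmost site, and the heavy-strand 5' end at the rightmost site with
base/motif complemented into 5'→3' orientation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .fragments import N_MOTIFS, FragmentSet, _five_prime_end_arrays, motif_string
from .reference import MtReference, RegionAnnotation, class_track

__all__ = [
    "MotifSpectrum",
    "EndFeatures",
    "end_base_proportion",
    "end_base_preference",
    "motif_spectrum",
    "motif_diversity_score",
    "compute_end_features",
]


@dataclass(frozen=True)
class MotifSpectrum:
    """Proportions of the 256 4-mer 5' end motifs, in lexicographic order."""

    proportions: np.ndarray
    total_ends: int

    def __post_init__(self) -> None:
        p = np.asarray(self.proportions, dtype=float)
        if p.shape != (N_MOTIFS,):
            raise ValueError(f"spectrum must have {N_MOTIFS} entries")
        if (p < 0).any():
            raise ValueError("negative motif proportion")
        if self.total_ends > 0 and abs(p.sum() - 1.0) > 1e-9:
            raise ValueError("motif proportions must sum to 1")
        object.__setattr__(self, "proportions", p)

    def as_dict(self) -> dict[str, float]:
        return {motif_string(i): float(self.proportions[i]) for i in range(N_MOTIFS)}


@dataclass(frozen=True)
class EndFeatures:
    end_base_proportion: dict[str, float]
    end_base_preference: dict[str, float]
    mds: float


def _region_end_mask(
    fs: FragmentSet,
    ref: MtReference,
    region: RegionAnnotation | list[RegionAnnotation] | None,
):
    sites, bases, codes = _five_prime_end_arrays(fs, ref)
    if region is None:
        mask = np.ones(sites.size, dtype=bool)
    else:
        anns = [region] if isinstance(region, RegionAnnotation) else list(region)
        track = np.zeros(ref.length, dtype=bool)
        for a in anns:
            track[a.sites(ref.length) - 1] = True
        mask = track[sites - 1]
    return bases, codes, mask


def end_base_proportion(
    fs: FragmentSet,
    ref: MtReference,
    region: RegionAnnotation | list[RegionAnnotation] | None = None,
) -> dict[str, float]:
    """Fraction of 5' fragment ends with each base, over counted ends.

    A fragment end is counted iff its 5' site lies in ``region`` (all ends
    when region is None).  Ends on an N reference base are excluded.
    """
    bases, _, mask = _region_end_mask(fs, ref, region)
    counted = bases[mask]
    counted = counted[counted != "N"]
    if counted.size == 0:
        raise ValueError("no counted 5' ends in region")
    return {b: float(np.mean(counted == b)) for b in "ACGT"}


def duplex_composition(ref: MtReference) -> dict[str, float]:
    """Strand-symmetrized base composition: g_b = (f_b + f_complement(b)) / 2.

    Because every fragment contributes a light-strand and a heavy-strand 5'
    end, the no-preference expectation for an end base is the composition of
    the duplex, not of the reference strand alone.  Under uniform cleavage
    the observed end-base proportions converge to exactly this composition.
    """
    from .reference import base_composition

    f = base_composition(ref)
    comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
    return {b: (f[b] + f[comp[b]]) / 2 for b in "ACGT"}


def end_base_preference(
    proportions: dict[str, float], genome_composition: dict[str, float]
) -> dict[str, float]:
    """Preference_b = observed proportion_b / genome base fraction_b.

    1.0 marks the no-preference point; >1 means the base is over-represented
    at 5' ends relative to the genome's composition.  When both strand ends
    are tallied, pass the :func:`duplex_composition` so the null is exact.
    """
    pref = {}
    for b in "ACGT":
        g = genome_composition[b]
        if g <= 0:
            raise ValueError(f"zero genome fraction for base {b}")
        pref[b] = proportions[b] / g
    return pref


def motif_spectrum(
    fs: FragmentSet,
    ref: MtReference,
    region: RegionAnnotation | list[RegionAnnotation] | None = None,
) -> MotifSpectrum:
    """Normalized spectrum over all 256 4-mers (absent motifs get 0)."""
    _, codes, mask = _region_end_mask(fs, ref, region)
    eligible = codes[mask & (codes >= 0)]
    if eligible.size == 0:
        raise ValueError("no motif-eligible 5' ends in region")
    counts = np.bincount(eligible, minlength=N_MOTIFS).astype(float)
    return MotifSpectrum(counts / counts.sum(), total_ends=int(eligible.size))


def motif_diversity_score(spec: MotifSpectrum | np.ndarray) -> float:
    """Normalized Shannon entropy of the motif spectrum, in [0, 1].

    Zero-probability motifs contribute 0; the log base cancels in the
    normalization by log(256).
    """
    p = spec.proportions if isinstance(spec, MotifSpectrum) else np.asarray(spec, float)
    nz = p[p > 0]
    return float(-(nz * np.log(nz)).sum() / np.log(N_MOTIFS))


def compute_end_features(
    fs: FragmentSet,
    ref: MtReference,
    genome_composition: dict[str, float],
    region: RegionAnnotation | list[RegionAnnotation] | None = None,
) -> EndFeatures:
    prop = end_base_proportion(fs, ref, region)
    pref = end_base_preference(prop, genome_composition)
    mds = motif_diversity_score(motif_spectrum(fs, ref, region))
    return EndFeatures(prop, pref, mds)
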