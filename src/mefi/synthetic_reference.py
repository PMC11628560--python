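"""Synthetic stand-in for the rCRS mitochondrial reference sequence.

This module builds a deterministic, clearly synthetic 16,569-bp circular
sequence for tests, examples and simulations.  It is NOT the NC_012920.1
sequence: bases are placed at random within each annotated functional region,
with per-region base composition matched to the published composition of the
real rCRS — G+C fractions of 46.79% (D-loop), 44.68% (mRNA), 44.88% (rRNA)
and 36.63% (tRNA) — and with the genome-wide heavy/light strand skew of human
mtDNA (C ≈ 31%, G ≈ 13%, A ≈ 31%, T ≈ 25%).  The single N placeholder the
rCRS keeps at site 3107 is mirrored so coordinate bookkeeping matches.

Any analysis that depends only on regional base composition (GC tracks,
end-base preference normalization, region GC summaries) behaves as it would
on the real reference; analyses that depend on the literal base order (e.g.
real motif spectra) see a randomized sequence.  Supply a genuine rCRS FASTA
via :func:`mefi.reference.load_reference` for work on real data.
"""

from __future__ import annotations

import numpy as np

from .reference import (
    RCRS_LENGTH,
    MtReference,
    RegionAnnotation,
    class_sites,
    default_annotations,
)

# Published per-region G+C fractions of the rCRS.
REGION_GC = {"D-loop": 0.4679, "mRNA": 0.4468, "rRNA": 0.4488, "tRNA": 0.3663}
INTERGENIC_GC = 0.4436  # approximate genome-wide rCRS G+C

# Genome-wide strand-skew splits of the rCRS: C/(C+G) and A/(A+T).
_C_OF_GC = 0.705
_A_OF_AT = 0.556

_N_SITE = 3107  # placeholder N, mirroring rCRS historical numbering


def synthetic_reference(
    seed: int = 12061999,
    annotations: list[RegionAnnotation] | None = None,
) -> MtReference:
    """Deterministic synthetic rCRS-like genome (see module docstring).

    The same seed always yields the same sequence; per-region base counts are
    fixed by rounding (not sampled), so regional GC matches the published
    values to well under 0.1 percentage points regardless of seed.
    """
    if annotations is None:
        annotations = default_annotations()
    L = RCRS_LENGTH
    rng = np.random.default_rng(seed)
    seq = np.full(L, "", dtype="U1")

    assigned = np.zeros(L, dtype=bool)
    groups: list[tuple[np.ndarray, float]] = []
    for cls, gc in REGION_GC.items():
        sites = class_sites(annotations, cls, L)
        sites = sites[sites != _N_SITE]
        groups.append((sites, gc))
        assigned[sites - 1] = True
    assigned[_N_SITE - 1] = True
    intergenic = np.flatnonzero(~assigned) + 1
    groups.append((intergenic, INTERGENIC_GC))

    for sites, gc in groups:
        n = sites.size
        if n == 0:
            continue
        n_gc = int(round(n * gc))
        n_c = int(round(n_gc * _C_OF_GC))
        n_g = n_gc - n_c
        n_at = n - n_gc
        n_a = int(round(n_at * _A_OF_AT))
        n_t = n_at - n_a
        bases = np.array(
            ["C"] * n_c + ["G"] * n_g + ["A"] * n_a + ["T"] * n_t, dtype="U1"
        )
        rng.shuffle(bases)
        seq[sites - 1] = bases

    seq[_N_SITE - 1] = "N"
    return MtReference("".join(seq), name="synthetic-rCRS-standin")


def write_synthetic_reference_fasta(path, seed: int = 12061999) -> None:
    """Write the synthetic stand-in genome to a FASTA file."""
    ref = synthetic_reference(seed=seed)
    with open(path, "w") as fh:
        fh.write(f">{ref.name} synthetic stand-in, not NC_012920.1\n")
        for i in range(0, ref.length, 70):
            fh.write(ref.sequence[i : i + 70] + "\n")
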