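"""Per-sample collections of sequenced cfDNA fragments on the circular genome.

A fragment is the outer span of a properly paired read pair, stored in
1-based closed circular coordinates; ``start > end`` denotes a fragment that
wraps through the origin (representable in BED/simulator mode only — a
linearized-reference BAM cannot encode wraps unambiguously).  Every fragment
exposes two 5' ends: the light-strand end at its leftmost site (reference
base, motif read left to right) and the heavy-strand end at its rightmost
site (complement base, motif reverse-complemented into 5'→3' orientation).
End bases and motifs are taken from the reference sequence at the terminal
coordinates, so BED-mode data without read bases is fully supported.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np

from .reference import MtReference, RegionAnnotation, class_track, complement

logger = logging.getLogger(__name__)

GROUP_LABELS = ("MT", "BT", "INF", "HC")
CANCER_TYPES = ("NSCLC", "HCC", "CRC", "SOC", "BC", "ccRCC", "none")

_BASE_CODE = {"A": 0, "C": 1, "G": 2, "T": 3}
MOTIF_K = 4
N_MOTIFS = 4**MOTIF_K


def motif_index(motif: str) -> int:
    """Lexicographic index of a 4-mer over {A,C,G,T} (AAAA=0 .. TTTT=255)."""
    code = 0
    for b in motif:
        code = code * 4 + _BASE_CODE[b]
    return code


def motif_string(index: int) -> str:
    out = []
    for _ in range(MOTIF_K):
        out.append("ACGT"[index % 4])
        index //= 4
    return "".join(reversed(out))


@dataclass(frozen=True)
class Fragment:
    """One cfDNA fragment with derived 5' end attributes."""

    start: int
    end: int
    length: int
    light_end_site: int
    heavy_end_site: int
    light_end_base: str
    heavy_end_base: str
    light_motif: str | None
    heavy_motif: str | None
    carries_alt: tuple[int, str] | None = None


@dataclass
class FragmentSet:
    """A per-sample fragment collection backed by numpy arrays.

    ``start``/``end`` are 1-based closed circular coordinates (start > end
    wraps).  ``strand`` records the read-1 strand from the source BED/BAM and
    is carried for round-trip fidelity.  ``alt_site``/``alt_base`` tag
    fragments that carry a spiked or observed alternate allele (-1 / '' when
    absent).
    """

    sample_id: str
    L: int
    start: np.ndarray
    end: np.ndarray
    strand: np.ndarray | None = None
    alt_site: np.ndarray | None = None
    alt_base: np.ndarray | None = None
    group_label: str = "HC"
    cancer_type: str = "none"
    batch_id: str = "batch0"

    def __post_init__(self) -> None:
        self.start = np.asarray(self.start, dtype=np.int64)
        self.end = np.asarray(self.end, dtype=np.int64)
        if self.start.shape != self.end.shape:
            raise ValueError("start/end length mismatch")
        if self.start.size and (
            self.start.min() < 1
            or self.end.min() < 1
            or self.start.max() > self.L
            or self.end.max() > self.L
        ):
            raise ValueError("fragment coordinates out of [1, L]")
        if self.strand is None:
            self.strand = np.full(self.start.size, "+", dtype="U1")
        else:
            self.strand = np.asarray(self.strand, dtype="U1")
        if self.alt_site is None:
            self.alt_site = np.full(self.start.size, -1, dtype=np.int64)
        else:
            self.alt_site = np.asarray(self.alt_site, dtype=np.int64)
        if self.alt_base is None:
            self.alt_base = np.full(self.start.size, "", dtype="U1")
        else:
            self.alt_base = np.asarray(self.alt_base, dtype="U1")

    def __len__(self) -> int:
        return int(self.start.size)

    @property
    def lengths(self) -> np.ndarray:
        """Fragment lengths in bp, wrap-aware."""
        return np.where(
            self.start <= self.end,
            self.end - self.start + 1,
            self.L - self.start + 1 + self.end,
        )

    def fragment(self, i: int, ref: MtReference) -> Fragment:
        """Materialize fragment ``i`` with its 5' end bases and motifs."""
        s, e = int(self.start[i]), int(self.end[i])
        length = int(self.lengths[i])
        lb, hb, lm, hm = five_prime_ends_at(s, e, length, ref)
        alt = None
        if self.alt_site[i] >= 0:
            alt = (int(self.alt_site[i]), str(self.alt_base[i]))
        return Fragment(s, e, length, s, e, lb, hb, lm, hm, carries_alt=alt)

    def subset(self, idx: np.ndarray) -> "FragmentSet":
        return FragmentSet(
            sample_id=self.sample_id,
            L=self.L,
            start=self.start[idx],
            end=self.end[idx],
            strand=self.strand[idx],
            alt_site=self.alt_site[idx],
            alt_base=self.alt_base[idx],
            group_label=self.group_label,
            cancer_type=self.cancer_type,
            batch_id=self.batch_id,
        )


def five_prime_ends_at(
    start: int, end: int, length: int, ref: MtReference
) -> tuple[str, str, str | None, str | None]:
    """Light/heavy 5' end bases and 4-mer motifs of one fragment.

    Light-strand 5' end: reference base at the leftmost site, motif the
    reference 4-mer starting there (left to right, circular).  Heavy-strand
    5' end: complement of the reference base at the rightmost site, motif the
    reverse-complement of the reference 4-mer ending there.  Fragments
    shorter than 4 bp have end bases but no motifs.
    """
    light_base = ref.base(start)
    heavy_base = complement(ref.base(end))
    light_motif: str | None = None
    heavy_motif: str | None = None
    if length >= MOTIF_K:
        lm = ref.subseq(start, MOTIF_K)
        hm_raw = ref.subseq(end - MOTIF_K + 1, MOTIF_K)
        hm = complement(hm_raw)[::-1]
        light_motif = lm if "N" not in lm else None
        heavy_motif = hm if "N" not in hm else None
    if "N" in light_base:
        light_base = "N"
    return light_base, heavy_base, light_motif, heavy_motif


def five_prime_ends(frag_or_fs, ref: MtReference):
    """5' end bases/motifs for a Fragment (tuple) or a FragmentSet (arrays).

    For a FragmentSet, returns ``(sites, bases, motif_codes)`` stacking the
    light ends then the heavy ends of every fragment (both strand ends
    contribute to end-feature tallies).  ``motif_codes`` is -1 where a motif
    is undefined (fragment < 4 bp or N in window).
    """
    if isinstance(frag_or_fs, Fragment):
        f = frag_or_fs
        return five_prime_ends_at(f.start, f.end, f.length, ref)
    return _five_prime_end_arrays(frag_or_fs, ref)


def _five_prime_end_arrays(
    fs: FragmentSet, ref: MtReference
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    L = ref.length
    if fs.L != L:
        raise ValueError("fragment set and reference genome length differ")
    seq = ref.base_array()
    code = np.full(L, -1000, dtype=np.int64)  # N poisons any motif it touches
    for b, v in _BASE_CODE.items():
        code[seq == b] = v

    starts = fs.start - 1  # 0-based
    ends = fs.end - 1
    lengths = fs.lengths

    light_bases = seq[starts]
    comp_map = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}
    heavy_bases = np.vectorize(comp_map.get, otypes=["U1"])(seq[ends])

    # motif codes
    light_codes = np.zeros(len(fs), dtype=np.int64)
    heavy_codes = np.zeros(len(fs), dtype=np.int64)
    for k in range(MOTIF_K):
        light_codes = light_codes * 4 + code[(starts + k) % L]
        heavy_codes = heavy_codes * 4 + (3 - code[(ends - k) % L])
    too_short = lengths < MOTIF_K
    light_codes[(light_codes < 0) | too_short] = -1
    heavy_codes[(heavy_codes < 0) | (heavy_codes > N_MOTIFS - 1) | too_short] = -1

    sites = np.concatenate([fs.start, fs.end])
    bases = np.concatenate([light_bases, heavy_bases])
    codes = np.concatenate([light_codes, heavy_codes])
    return sites, bases, codes


def assign_region(
    end_site: int | np.ndarray,
    annotations: list[RegionAnnotation],
    L: int,
) -> np.ndarray | str | None:
    """Region class of 5' end site(s); fragments are counted for a region iff
    the 5' end falls inside it."""
    track = class_track(annotations, L)
    if np.isscalar(end_site):
        cls = track[int(end_site) - 1]
        return cls if cls else None
    return track[np.asarray(end_site) - 1]


def downsample(
    fs: FragmentSet,
    fraction: float | None = None,
    target_mean_depth: float | None = None,
    seed: int = 0,
) -> FragmentSet:
    """Uniform random subset of fragments, without replacement.

    Exactly one of ``fraction`` and ``target_mean_depth`` must be given; the
    latter is converted to a fraction via the current mean per-site depth
    (sum of fragment lengths / L).  Deterministic under a fixed seed.
    """
    if (fraction is None) == (target_mean_depth is None):
        raise ValueError("give exactly one of fraction / target_mean_depth")
    if target_mean_depth is not None:
        current = fs.lengths.sum() / fs.L
        if current <= 0:
            raise ValueError("empty fragment set")
        fraction = min(1.0, target_mean_depth / current)
    if not 0 < fraction <= 1:
        raise ValueError("fraction must be in (0, 1]")
    n = len(fs)
    k = int(round(fraction * n))
    rng = np.random.default_rng(seed)
    idx = np.sort(rng.choice(n, size=k, replace=False))
    return fs.subset(idx)


# ---------------------------------------------------------------------------
# BED-like TSV I/O
#
# Columns: chrom, start (0-based half-open), end, strand-of-read1, sample_id
# [, alt_site, alt_base].  Origin-wrapping fragments are written with an
# unwrapped end coordinate (end > L); rows with end <= start are malformed
# and skipped with a warning.
# ---------------------------------------------------------------------------

def write_fragments_bed(fs: FragmentSet, path, chrom: str = "chrM") -> None:
    wraps = fs.start > fs.end
    bed_start = fs.start - 1
    bed_end = np.where(wraps, fs.end + fs.L, fs.end)
    has_alt = bool((fs.alt_site >= 0).any())
    with open(path, "w") as fh:
        for i in range(len(fs)):
            row = [chrom, str(bed_start[i]), str(bed_end[i]), str(fs.strand[i]), fs.sample_id]
            if has_alt:
                row += [str(fs.alt_site[i]), str(fs.alt_base[i])]
            fh.write("\t".join(row) + "\n")


def read_fragments_bed(path, ref: MtReference, **meta) -> FragmentSet:
    """Read the BED dialect written by :func:`write_fragments_bed`.

    Malformed rows (non-integer coordinates, end <= start, out-of-range) are
    skipped; the count is reported through a warning.
    """
    L = ref.length
    starts, ends, strands, alts, altb = [], [], [], [], []
    sample_id = meta.pop("sample_id", None)
    n_bad = 0
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.rstrip("\n").split("\t")
            try:
                s0, e = int(parts[1]), int(parts[2])
            except (ValueError, IndexError):
                n_bad += 1
                continue
            if e <= s0 or s0 < 0 or s0 >= L or e > 2 * L:
                n_bad += 1
                continue
            start = s0 + 1
            end = e if e <= L else e - L
            starts.append(start)
            ends.append(end)
            strands.append(parts[3] if len(parts) > 3 else "+")
            if sample_id is None and len(parts) > 4:
                sample_id = parts[4]
            if len(parts) > 6:
                alts.append(int(parts[5]))
                altb.append(parts[6])
            else:
                alts.append(-1)
                altb.append("")
    if n_bad:
        warnings.warn(f"skipped {n_bad} malformed row(s) in {path}")
    return FragmentSet(
        sample_id=sample_id or "sample",
        L=L,
        start=np.array(starts, dtype=np.int64),
        end=np.array(ends, dtype=np.int64),
        strand=np.array(strands, dtype="U1"),
        alt_site=np.array(alts, dtype=np.int64),
        alt_base=np.array(altb, dtype="U1"),
        **meta,
    )


def read_fragments_bam(
    bam_path, ref: MtReference, min_mapq: int = 20, **meta
) -> FragmentSet:
    """Extract fragments from a coordinate-sorted paired-end BAM/SAM.

    Keeps one fragment per properly paired, non-duplicate, non-secondary,
    non-supplementary template whose two mates both have MAPQ >= ``min_mapq``
    (the standard mapping-quality cut for mtDNA capture data).  The fragment
    is the outer span of the pair on the linearized reference.
    """
    import pysam

    mode = "rb" if str(bam_path).endswith(".bam") else "r"
    starts, ends, strands = [], [], []
    with pysam.AlignmentFile(str(bam_path), mode, check_sq=False) as bam:
        refs = list(zip(bam.references or (), bam.lengths or ()))
        if refs:
            match = [l for n, l in refs if l == ref.length]
            if not match:
                raise ValueError(
                    f"no BAM contig of length {ref.length} matches the reference"
                )
        mapq: dict[str, list[int]] = {}
        seen_mapped = False
        reads = {}
        for rec in bam.fetch(until_eof=True):
            if (
                rec.is_unmapped
                or rec.is_secondary
                or rec.is_supplementary
                or rec.is_duplicate
                or rec.is_qcfail
                or not rec.is_proper_pair
            ):
                continue
            seen_mapped = True
            mapq.setdefault(rec.query_name, []).append(rec.mapping_quality)
            if rec.is_read1:
                reads[rec.query_name] = rec
        if not seen_mapped:
            raise ValueError("BAM contains no usable mapped reads")
        for qname, rec in reads.items():
            quals = mapq.get(qname, [])
            if len(quals) < 2 or min(quals) < min_mapq:
                continue
            tlen = rec.template_length
            if tlen == 0:
                continue
            if tlen > 0:
                start = rec.reference_start + 1
                end = rec.reference_start + tlen
            else:
                end = rec.reference_end
                start = end + tlen + 1
            if start < 1 or end > ref.length:
                continue  # linearized BAMs cannot encode wraps; skip
            starts.append(start)
            ends.append(end)
            strands.append("-" if rec.is_reverse else "+")
    return FragmentSet(
        sample_id=meta.pop("sample_id", "sample"),
        L=ref.length,
        start=np.array(starts, dtype=np.int64),
        end=np.array(ends, dtype=np.int64),
        strand=np.array(strands, dtype="U1"),
        **meta,
    )
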