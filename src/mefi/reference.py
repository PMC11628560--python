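"""Circular mitochondrial reference genome and functional-region annotations.

The human mitochondrial genome (rCRS, NC_012920.1) is a 16,569-bp circle
conventionally indexed 1..16,569, with site 16,569 adjacent to site 1.  All
coordinates in this package are 1-based closed and circular; an interval whose
start exceeds its end wraps through the origin (e.g. the D-loop control region
spans 16024..576).  The four functional region classes used throughout —
D-loop, mRNA (the 13 protein-coding genes), rRNA (12S/16S) and tRNA (the 22
tRNA genes) — partition almost the whole circle, leaving a few dozen
intergenic sites in no class.  The D-loop is further split into the 7S DNA
segment (16106..191, the stably incorporated third strand) and its non-7S
remainder.

A default annotation table with standard MITOMAP rCRS gene coordinates is
shipped as package data and loaded by :func:`default_annotations`.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

RCRS_LENGTH = 16569
REGION_CLASSES = ("D-loop", "mRNA", "rRNA", "tRNA")

_VALID_BASES = frozenset("ACGTN")
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


@dataclass(frozen=True)
class MtReference:
    """A circular mitochondrial reference sequence.

    Parameters
    ----------
    sequence
        Upper-case sequence over {A, C, G, T, N}.  The rCRS carries a single
        N placeholder at site 3107, kept to preserve historical numbering.
    name
        Sequence identifier, default ``"rCRS"``.
    """

    sequence: str
    name: str = "rCRS"

    def __post_init__(self) -> None:
        bad = set(self.sequence) - _VALID_BASES
        if bad:
            raise ValueError(f"invalid characters in reference sequence: {sorted(bad)}")
        if len(self.sequence) == 0:
            raise ValueError("empty reference sequence")

    @property
    def length(self) -> int:
        return len(self.sequence)

    def base(self, site: int) -> str:
        """Reference base at a 1-based circular site."""
        return self.sequence[(site - 1) % self.length]

    def subseq(self, start: int, length: int) -> str:
        """Circular substring of ``length`` bases starting at 1-based ``start``."""
        idx = (np.arange(start - 1, start - 1 + length)) % self.length
        arr = np.frombuffer(self.sequence.encode(), dtype="S1")
        return b"".join(arr[idx]).decode()

    def base_array(self) -> np.ndarray:
        """Sequence as a length-L array of single characters (dtype ``U1``)."""
        return np.frombuffer(self.sequence.encode(), dtype="S1").astype("U1")


def complement(base_or_seq: str) -> str:
    return base_or_seq.translate(_COMPLEMENT)


def reverse_complement(seq: str) -> str:
    return complement(seq)[::-1]


@dataclass(frozen=True)
class RegionAnnotation:
    """A named annotation: one region class and one or more circular intervals.

    ``intervals`` are 1-based closed; ``start > end`` encodes an
    origin-wrapping interval.  ``sub_region`` distinguishes the 7S / non-7S
    subdivision of the D-loop and is empty for ordinary gene annotations.
    """

    name: str
    region_class: str
    intervals: tuple[tuple[int, int], ...]
    sub_region: str = ""

    def sites(self, L: int) -> np.ndarray:
        """Sorted unique 1-based sites covered by this annotation."""
        out: list[np.ndarray] = []
        for s, e in self.intervals:
            if not (1 <= s <= L and 1 <= e <= L):
                raise ValueError(f"{self.name}: interval ({s},{e}) out of [1,{L}]")
            if s <= e:
                out.append(np.arange(s, e + 1))
            else:  # wraps through the origin
                out.append(np.arange(s, L + 1))
                out.append(np.arange(1, e + 1))
        return np.unique(np.concatenate(out))

    def n_sites(self, L: int) -> int:
        return self.sites(L).size

    def contains(self, site: int, L: int) -> bool:
        for s, e in self.intervals:
            if s <= e:
                if s <= site <= e:
                    return True
            elif site >= s or site <= e:
                return True
        return False


def load_reference(
    fasta_path: str | Path,
    annotation_path: str | Path | None = None,
) -> tuple[MtReference, list[RegionAnnotation]]:
    """Load a mitochondrial reference FASTA and an annotation table.

    The FASTA must contain exactly one record; sequences longer than 100 kb
    are rejected as non-mitochondrial.  The annotation table is a TSV with
    columns ``name, class, start, end, sub_region`` (one interval per row;
    ``start > end`` wraps).  ``annotation_path=None`` returns an empty
    annotation list.
    """
    fasta_path = Path(fasta_path)
    if not fasta_path.exists():
        raise FileNotFoundError(fasta_path)
    name = None
    chunks: list[str] = []
    n_records = 0
    with open(fasta_path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(";"):
                continue
            if line.startswith(">"):
                n_records += 1
                if n_records == 1:
                    name = line[1:].split()[0] or "rCRS"
            elif n_records:
                chunks.append(line.upper())
    if n_records != 1:
        raise ValueError(f"expected exactly one FASTA record, found {n_records}")
    seq = "".join(chunks)
    if len(seq) > 100_000:
        raise ValueError(
            f"sequence of {len(seq)} bp is not mitochondrial-scale (>100 kb)"
        )
    ref = MtReference(seq, name=name or "rCRS")
    annotations: list[RegionAnnotation] = []
    if annotation_path is not None:
        annotations = load_annotations(annotation_path, L=ref.length)
    return ref, annotations


def load_annotations(path: str | Path, L: int = RCRS_LENGTH) -> list[RegionAnnotation]:
    """Parse a ``name/class/start/end/sub_region`` TSV into annotations."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    annotations: list[RegionAnnotation] = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        col = {c: i for i, c in enumerate(header)}
        for c in ("name", "class", "start", "end"):
            if c not in col:
                raise ValueError(f"annotation table missing column {c!r}")
        for line in fh:
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            start, end = int(parts[col["start"]]), int(parts[col["end"]])
            if not (1 <= start <= L and 1 <= end <= L):
                raise ValueError(f"interval ({start},{end}) out of [1,{L}]")
            sub = ""
            if "sub_region" in col and len(parts) > col["sub_region"]:
                sub = parts[col["sub_region"]].strip()
            annotations.append(
                RegionAnnotation(
                    name=parts[col["name"]],
                    region_class=parts[col["class"]],
                    intervals=((start, end),),
                    sub_region=sub,
                )
            )
    return annotations


def default_annotations(L: int = RCRS_LENGTH) -> list[RegionAnnotation]:
    """Standard rCRS gene annotations vendored with the package."""
    with importlib.resources.as_file(
        importlib.resources.files("mefi.data").joinpath("rcrs_annotations.tsv")
    ) as p:
        return load_annotations(p, L=L)


def class_sites(
    annotations: list[RegionAnnotation],
    region_class: str,
    L: int = RCRS_LENGTH,
    sub_region: str | None = None,
) -> np.ndarray:
    """Union of sites of all annotations of one class (optionally sub-region).

    Annotations carrying a sub_region tag are skipped unless ``sub_region`` is
    requested, so the D-loop is not double counted through its 7S split.
    """
    parts = []
    for a in annotations:
        if a.region_class != region_class:
            continue
        if sub_region is None and a.sub_region:
            continue
        if sub_region is not None and a.sub_region != sub_region:
            continue
        parts.append(a.sites(L))
    if not parts:
        return np.empty(0, dtype=int)
    return np.unique(np.concatenate(parts))


def class_track(
    annotations: list[RegionAnnotation], L: int = RCRS_LENGTH
) -> np.ndarray:
    """Per-site region class, as a length-L array of strings ('' = intergenic).

    Index i corresponds to site i+1.  Classes never overlap in the standard
    annotation; if a site were annotated with two classes the first class in
    ``REGION_CLASSES`` order wins.
    """
    track = np.full(L, "", dtype="U6")
    for cls in reversed(REGION_CLASSES):
        s = class_sites(annotations, cls, L)
        track[s - 1] = cls
    return track


def region_of_site(
    annotations: list[RegionAnnotation], site: int, L: int = RCRS_LENGTH
) -> str | None:
    """Region class of a 1-based site, or None if intergenic."""
    if not (1 <= site <= L):
        raise ValueError(f"site {site} out of [1,{L}]")
    for cls in REGION_CLASSES:
        for a in annotations:
            if a.region_class == cls and not a.sub_region and a.contains(site, L):
                return cls
    return None


def base_composition(
    ref: MtReference,
    region: RegionAnnotation | list[RegionAnnotation] | np.ndarray | None = None,
) -> dict[str, float]:
    """Fraction of A/C/G/T over a region (or the whole genome).

    N sites are excluded from both numerator and denominator.  ``region`` may
    be a single annotation, a list of annotations (union of their sites), or a
    precomputed site array.
    """
    arr = ref.base_array()
    if region is None:
        bases = arr
    else:
        if isinstance(region, RegionAnnotation):
            sites = region.sites(ref.length)
        elif isinstance(region, np.ndarray):
            sites = region
        else:
            sites = np.unique(
                np.concatenate([a.sites(ref.length) for a in region])
            )
        if sites.size == 0:
            raise ValueError("region covers zero sites")
        bases = arr[sites - 1]
    counted = bases[bases != "N"]
    if counted.size == 0:
        raise ValueError("region has no A/C/G/T sites")
    return {b: float(np.mean(counted == b)) for b in "ACGT"}


def gc_fraction(ref: MtReference, region=None) -> float:
    comp = base_composition(ref, region)
    return comp["G"] + comp["C"]


def gc_fraction_track(ref: MtReference, window_halfwidth: int = 50) -> np.ndarray:
    """Per-site GC fraction of the circular window [i-hw, i+hw].

    Used as the covariate for LOESS GC correction of fragmentation profiles.
    N bases are excluded from numerator and denominator within each window.
    A half-width of at least L/2 makes every window the whole circle, so the
    track becomes the global GC fraction everywhere.
    """
    if window_halfwidth < 0:
        raise ValueError("window_halfwidth must be >= 0")
    arr = ref.base_array()
    L = ref.length
    hw = min(window_halfwidth, L // 2)  # window wider than the circle saturates
    is_gc = np.isin(arr, ["G", "C"]).astype(float)
    is_acgt = (arr != "N").astype(float)
    w = 2 * hw + 1
    if w >= L:
        val = is_gc.sum() / is_acgt.sum()
        return np.full(L, val)
    # circular window sums via padded cumulative sums
    def circ_window_sum(x: np.ndarray) -> np.ndarray:
        padded = np.concatenate([x[-hw:], x, x[:hw]])
        c = np.concatenate([[0.0], np.cumsum(padded)])
        return c[w:] - c[:-w]

    gc = circ_window_sum(is_gc)
    denom = circ_window_sum(is_acgt)
    return gc / denom
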