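"""mtDNA heteroplasmy calling, origin classification, and copy number.

Substitution variants are called from per-site, strand-split allele counts
(minor allele frequency, MAF = minor-allele reads / depth) and pass through
five filters before acceptance:

1. strand support — at least three reads on each strand for the mutant
   allele;
2. MAF floor — minimum MAF of 1%;
3. repeat regions — rCRS repeat tracts 66-71, 303-311, 514-523,
   12418-12425 and 16184-16193 are excluded (alignment artifacts);
4. oxidation — C>A / G>T substitutions below 10% MAF are removed as
   artifacts of guanine oxidation during library preparation;
5. binomial — the mutant rate must exceed the sequencing-error expectation
   and the mutant base quality must be convincingly high, each by a
   one-sided binomial test at P <= 0.001.

Failed calls are retained with their filter reasons rather than dropped.
Tumor-derived mutations are those present in tumor tissue but in neither
paired leukocytes nor para-tumor tissue; germline variants are present in
tumor and both controls.  Relative mtDNA copy number is
2 x (mean mtDNA depth) / (mean nuclear reference-gene depth).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .fragments import FragmentSet
from .reference import MtReference

logger = logging.getLogger(__name__)

#: rCRS repeat tracts excluded from heteroplasmy calling (1-based, inclusive).
REPEAT_REGIONS = ((66, 71), (303, 311), (514, 523), (12418, 12425), (16184, 16193))

_OXIDATION_PAIRS = {("C", "A"), ("G", "T")}
BASES = ("A", "C", "G", "T")


@dataclass
class AlleleCounts:
    """Strand-split base counts and mean Phred quality at one site."""

    site: int
    ref_base: str
    fwd: dict[str, int]
    rev: dict[str, int]
    mean_quality: dict[str, float]

    @property
    def depth(self) -> int:
        return sum(self.fwd.values()) + sum(self.rev.values())

    def count(self, base: str) -> int:
        return self.fwd[base] + self.rev[base]

    def minor_allele(self) -> tuple[str, int]:
        """Highest-count non-reference base and its count."""
        alts = [(self.count(b), b) for b in BASES if b != self.ref_base]
        c, b = max(alts)
        return b, c


@dataclass
class VariantCall:
    site: int
    ref_base: str
    alt_base: str
    maf: float
    fwd_alt: int
    rev_alt: int
    filters_failed: frozenset[str]
    p_rate: float
    p_quality: float
    origin: str = "unclassified"

    @property
    def passed(self) -> bool:
        return not self.filters_failed


def in_repeat_region(site: int) -> bool:
    return any(s <= site <= e for s, e in REPEAT_REGIONS)


def binomial_filters(
    alt_count: int,
    depth: int,
    alt_qualities: np.ndarray,
    ref_qualities: np.ndarray,
    alpha: float = 0.001,
    hq_threshold: int = 30,
    hq_null: float = 0.5,
) -> tuple[bool, float, float]:
    """Binomial tests on mutant rate and mutant base quality.

    Rate test: upper-tail binomial P(X >= alt_count | n=depth, p=p_err),
    where p_err is the mean per-base error implied by the site's Phred
    qualities.  Quality test: upper-tail binomial on the number of alt bases
    with Q >= ``hq_threshold`` against the null fraction ``hq_null``
    (evidence that mutant base calls are predominantly high quality).  The
    site passes iff both P <= alpha.
    """
    if depth <= 0:
        raise ValueError("zero depth")
    if alt_count > depth:
        raise ValueError("alt_count exceeds depth")
    alt_q = np.asarray(alt_qualities, dtype=float)
    ref_q = np.asarray(ref_qualities, dtype=float)
    all_q = np.concatenate([alt_q, ref_q]) if alt_q.size or ref_q.size else np.array([30.0])
    p_err = float(np.mean(10 ** (-all_q / 10)))
    p_rate = float(stats.binom.sf(alt_count - 1, depth, p_err)) if alt_count > 0 else 1.0
    n_hq = int((alt_q >= hq_threshold).sum())
    p_quality = (
        float(stats.binom.sf(n_hq - 1, alt_q.size, hq_null)) if alt_q.size else 1.0
    )
    return (p_rate <= alpha and p_quality <= alpha), p_rate, p_quality


@dataclass
class CallerParams:
    min_strand_reads: int = 3
    min_maf: float = 0.01
    oxidation_maf: float = 0.10
    alpha: float = 0.001
    hq_threshold: int = 30
    hq_null: float = 0.5


def call_variants(
    counts: list[AlleleCounts], params: CallerParams | None = None
) -> list[VariantCall]:
    """Apply the five-filter caller to per-site allele counts.

    Every covered site with a non-zero minor allele yields a call; sites
    failing any filter are retained with ``filters_failed`` recording the
    reasons.  Filters are each evaluated on the raw counts, so the final
    verdict is order-independent.
    """
    params = params or CallerParams()
    calls: list[VariantCall] = []
    for ac in counts:
        alt, alt_count = ac.minor_allele()
        if alt_count == 0:
            continue
        depth = ac.depth
        maf = alt_count / depth
        failed = set()
        if ac.fwd[alt] < params.min_strand_reads or ac.rev[alt] < params.min_strand_reads:
            failed.add("strand_support")
        if maf < params.min_maf:
            failed.add("maf_floor")
        if in_repeat_region(ac.site):
            failed.add("repeat_region")
        if (ac.ref_base, alt) in _OXIDATION_PAIRS and maf < params.oxidation_maf:
            failed.add("oxidation")
        alt_q = np.full(alt_count, ac.mean_quality.get(alt, 30.0))
        ref_q = np.full(ac.count(ac.ref_base), ac.mean_quality.get(ac.ref_base, 30.0))
        ok, p_rate, p_quality = binomial_filters(
            alt_count,
            depth,
            alt_q,
            ref_q,
            alpha=params.alpha,
            hq_threshold=params.hq_threshold,
            hq_null=params.hq_null,
        )
        if not ok:
            failed.add("binomial")
        calls.append(
            VariantCall(
                site=ac.site,
                ref_base=ac.ref_base,
                alt_base=alt,
                maf=maf,
                fwd_alt=ac.fwd[alt],
                rev_alt=ac.rev[alt],
                filters_failed=frozenset(failed),
                p_rate=p_rate,
                p_quality=p_quality,
                origin="rejected" if failed else "unclassified",
            )
        )
    return calls


def classify_origin(
    tumor_calls: list[VariantCall],
    leukocyte_calls: list[VariantCall] | None,
    paratumor_calls: list[VariantCall] | None,
) -> dict[tuple[int, str], str]:
    """Tumor-derived vs germline classification of passing tumor variants.

    tumor_derived: in tumor, in neither control; germline: in tumor and in
    both controls; anything else: somatic_unclassified.  If either paired
    control set is missing the classification is skipped (logged).
    """
    if leukocyte_calls is None or paratumor_calls is None:
        logger.warning("paired control calls missing; origin classification skipped")
        return {}
    keys = lambda calls: {(c.site, c.alt_base) for c in calls if c.passed}
    leuko, para = keys(leukocyte_calls), keys(paratumor_calls)
    out = {}
    for c in tumor_calls:
        if not c.passed:
            continue
        k = (c.site, c.alt_base)
        if k not in leuko and k not in para:
            out[k] = "tumor_derived"
        elif k in leuko and k in para:
            out[k] = "germline"
        else:
            out[k] = "somatic_unclassified"
    return out


def copy_number(mean_mt_depth: float, mean_nuclear_ref_depth: float) -> float:
    """Relative mtDNA copy number: 2 x mt depth / nuclear reference depth."""
    if mean_nuclear_ref_depth <= 0:
        raise ValueError("nuclear reference depth must be positive")
    return 2.0 * mean_mt_depth / mean_nuclear_ref_depth


def fragment_subsets_by_allele(
    fs: FragmentSet, site: int, alt: str
) -> tuple[FragmentSet, FragmentSet]:
    """Partition fragments covering ``site`` into alt-carrying and wild-type.

    Requires fragments to carry allele tags (``alt_site``/``alt_base``), as
    produced by the simulator's spike-in machinery or allele-aware BAM
    extraction.  Enables size and end-feature comparison between mutant and
    wild-type molecules.
    """
    covers = _covers_site(fs, site)
    if not covers.any():
        raise ValueError(f"no fragments cover site {site}")
    is_alt = covers & (fs.alt_site == site) & (fs.alt_base == alt)
    return fs.subset(np.flatnonzero(is_alt)), fs.subset(np.flatnonzero(covers & ~is_alt))


def _covers_site(fs: FragmentSet, site: int) -> np.ndarray:
    nonwrap = fs.start <= fs.end
    c = np.empty(len(fs), dtype=bool)
    c[nonwrap] = (fs.start[nonwrap] <= site) & (site <= fs.end[nonwrap])
    w = ~nonwrap
    c[w] = (fs.start[w] <= site) | (site <= fs.end[w])
    return c


# ---------------------------------------------------------------------------
# Pileup TSV and minimal VCF output
# ---------------------------------------------------------------------------

_PILEUP_COLS = (
    ["site", "ref"]
    + [f"{b}_fwd" for b in BASES]
    + [f"{b}_rev" for b in BASES]
    + [f"q{b}" for b in BASES]
)


def write_pileup_tsv(counts: list[AlleleCounts], path) -> None:
    rows = []
    for ac in counts:
        rows.append(
            [ac.site, ac.ref_base]
            + [ac.fwd[b] for b in BASES]
            + [ac.rev[b] for b in BASES]
            + [round(ac.mean_quality.get(b, 0.0), 4) for b in BASES]
        )
    pd.DataFrame(rows, columns=_PILEUP_COLS).to_csv(path, sep="\t", index=False)


def read_pileup_tsv(path) -> list[AlleleCounts]:
    df = pd.read_csv(path, sep="\t")
    missing = set(_PILEUP_COLS) - set(df.columns)
    if missing:
        raise ValueError(f"pileup table missing columns: {sorted(missing)}")
    out = []
    for row in df.itertuples(index=False):
        d = row._asdict()
        out.append(
            AlleleCounts(
                site=int(d["site"]),
                ref_base=str(d["ref"]),
                fwd={b: int(d[f"{b}_fwd"]) for b in BASES},
                rev={b: int(d[f"{b}_rev"]) for b in BASES},
                mean_quality={b: float(d[f"q{b}"]) for b in BASES},
            )
        )
    return out


def allele_counts_from_pileup(path) -> list[AlleleCounts]:
    """Alias for loading a pileup table produced here or by the simulator."""
    return read_pileup_tsv(path)


def write_vcf(calls: list[VariantCall], path, ref_name: str = "chrM", L: int = 16569) -> None:
    """Minimal substitution-only VCF with MAF and strand-count INFO fields."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##contig=<ID={ref_name},length={L}>\n")
        fh.write('##INFO=<ID=MAF,Number=1,Type=Float,Description="Minor allele frequency">\n')
        fh.write('##INFO=<ID=SF,Number=2,Type=Integer,Description="Alt fwd,rev strand counts">\n')
        fh.write('##INFO=<ID=ORIGIN,Number=1,Type=String,Description="Variant origin class">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for c in sorted(calls, key=lambda v: v.site):
            filt = "PASS" if c.passed else ";".join(sorted(c.filters_failed))
            info = f"MAF={c.maf:.4f};SF={c.fwd_alt},{c.rev_alt};ORIGIN={c.origin}"
            fh.write(
                f"{ref_name}\t{c.site}\t.\t{c.ref_base}\t{c.alt_base}\t.\t{filt}\t{info}\n"
            )
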