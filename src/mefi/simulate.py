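"""Synthetic ccf-mtDNA fragment cohorts with known ground truth.

The generator emulates the statistical structure the fragmentomic analyses
assume, so every pipeline stage is testable without sequencing data:

* cleavage model — a two-cut process on the circle.  A light-strand 5' cut
  site is drawn with probability proportional to (end-base bias) /
  (protection); a fragment length is drawn from the region-specific length
  law of the cut site; the implied second cut is accepted with probability
  proportional to its own cleavage weight.  Protein-protected loci thus
  deplete cuts on both sides, producing the long-fragment excess (elevated
  FSD score) the per-site profile detects;
* region-specific lengths — fragments starting in the D-loop are shortest
  and tRNA-region fragments longest, mirroring the ordering seen in capture
  data, around a healthy-control median of 128 bp (sd 35);
* group effects — malignant-tumor samples get a size shift (default
  -10 bp), extra protected loci (new peaks), and a flattened end-bias
  (higher motif diversity); benign-tumor and inflammatory groups sit between
  healthy and malignant;
* spike-ins — minor alleles placed on a configured fraction of covering
  fragments, with length offset (mutant molecules shorter), strand balance
  and base quality, feeding the variant caller.

All randomness flows from a single master seed; per-sample seeds are spawned
deterministically, so a cohort is bit-reproducible.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field, replace

import numpy as np

from .fragments import FragmentSet
from .fsd import site_depths
from .reference import MtReference, class_track, default_annotations
from .synthetic_reference import synthetic_reference
from .variants import BASES, AlleleCounts, write_pileup_tsv


@dataclass(frozen=True)
class Spike:
    """A minor-allele spike-in: (site, alt) on a fraction of covering
    fragments, with a fragment-length offset, forward-strand balance and
    Phred base quality for the alternate calls."""

    site: int
    alt: str
    fraction: float
    length_offset: float = 0.0
    strand_balance: float = 0.5
    base_quality: float = 33.0


@dataclass(frozen=True)
class GroupEffects:
    """Per-group shifts applied on top of the healthy baseline."""

    size_shift: float = 0.0
    extra_peak_loci: tuple[int, ...] = ()
    end_bias_exponent: float = 1.0  # <1 flattens the end bias (raises MDS)
    base_bias_scale: dict | None = None  # per-base multiplicative tweak


DEFAULT_GROUP_EFFECTS: dict[str, GroupEffects] = {
    "HC": GroupEffects(),
    "INF": GroupEffects(size_shift=-2.0, end_bias_exponent=0.98),
    "BT": GroupEffects(size_shift=-3.0, end_bias_exponent=0.97),
    "MT": GroupEffects(
        size_shift=-10.0, extra_peak_loci=(13839, 7292), end_bias_exponent=0.85
    ),
}

#: Distinct per-cancer-type signatures layered onto the MT effects, so the
#: tissue-of-origin task has a recoverable signal.
CANCER_TYPE_EFFECTS: dict[str, GroupEffects] = {
    "NSCLC": GroupEffects(size_shift=0.0, extra_peak_loci=(1368, 12040)),
    "HCC": GroupEffects(size_shift=-4.0, extra_peak_loci=(2292, 9327)),
    "CRC": GroupEffects(size_shift=+4.0, extra_peak_loci=(2968, 12911)),
    "SOC": GroupEffects(size_shift=-8.0, extra_peak_loci=(5927,)),
    "BC": GroupEffects(size_shift=+8.0, extra_peak_loci=(11461,)),
    "ccRCC": GroupEffects(size_shift=-12.0, extra_peak_loci=(11019, 8085)),
}

#: Healthy-baseline fragment length laws (mean, sd) per region class of the
#: 5' cut site; "" is intergenic.  The 128-bp healthy median anchors the
#: scale, with the D-loop shortest and tRNA regions longest.
DEFAULT_LENGTH_LAWS: dict[str, tuple[float, float]] = {
    "D-loop": (120.0, 35.0),
    "rRNA": (127.0, 35.0),
    "mRNA": (128.0, 35.0),
    "tRNA": (134.0, 35.0),
    "": (128.0, 35.0),
}

#: Healthy-baseline 5' end-base cleavage bias (G/A-end preference of
#: ccf-mtDNA relative to composition).
DEFAULT_END_BIAS: dict[str, float] = {"A": 1.25, "C": 0.85, "G": 1.45, "T": 0.75}


@dataclass
class SimConfig:
    """Study conditions for the synthetic cohort generator."""

    seed: int = 0
    n_fragments: int = 150000
    protection_loci: tuple[tuple[int, int, float], ...] | None = None
    length_laws: dict = field(default_factory=lambda: dict(DEFAULT_LENGTH_LAWS))
    end_bias: dict = field(default_factory=lambda: dict(DEFAULT_END_BIAS))
    group_effects: dict = field(
        default_factory=lambda: dict(DEFAULT_GROUP_EFFECTS)
    )
    cancer_type_effects: dict = field(
        default_factory=lambda: dict(CANCER_TYPE_EFFECTS)
    )
    spikes: tuple[Spike, ...] = ()
    min_length: int = 40
    max_length: int = 320

    def to_json(self, path) -> None:
        d = asdict(self)
        d["group_effects"] = {k: asdict(v) for k, v in self.group_effects.items()}
        d["cancer_type_effects"] = {
            k: asdict(v) for k, v in self.cancer_type_effects.items()
        }
        d["spikes"] = [asdict(s) for s in self.spikes]
        with open(path, "w") as fh:
            json.dump(d, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "SimConfig":
        with open(path) as fh:
            d = json.load(fh)
        d["group_effects"] = {
            k: GroupEffects(
                size_shift=v["size_shift"],
                extra_peak_loci=tuple(v["extra_peak_loci"]),
                end_bias_exponent=v["end_bias_exponent"],
                base_bias_scale=v.get("base_bias_scale"),
            )
            for k, v in d["group_effects"].items()
        }
        d["cancer_type_effects"] = {
            k: GroupEffects(
                size_shift=v["size_shift"],
                extra_peak_loci=tuple(v["extra_peak_loci"]),
                end_bias_exponent=v["end_bias_exponent"],
                base_bias_scale=v.get("base_bias_scale"),
            )
            for k, v in d["cancer_type_effects"].items()
        }
        d["spikes"] = tuple(Spike(**s) for s in d["spikes"])
        d["length_laws"] = {k: tuple(v) for k, v in d["length_laws"].items()}
        if d.get("protection_loci") is not None:
            d["protection_loci"] = tuple(tuple(x) for x in d["protection_loci"])
        return cls(**d)


def default_protection_loci(
    L: int = 16569, n_loci: int = 60, factor: float = 8.0, seed: int = 71
) -> tuple[tuple[int, int, float], ...]:
    """Fixed protein-footprint surrogate: n protected loci of 25-60 bp.

    Seeded independently of sample seeds so the whole cohort (and the
    healthy reference panel) shares the same baseline protection landscape.
    The footprint scale emulates the dense protein coating of mtDNA, which
    makes the fragmentation profile signal- rather than noise-dominated at
    capture-level depth.
    """
    rng = np.random.default_rng(seed)
    starts = np.sort(rng.choice(L - 400, size=n_loci, replace=False)) + 100
    widths = rng.integers(25, 61, size=n_loci)
    return tuple(
        (int(s), int(min(s + w - 1, L)), float(factor)) for s, w in zip(starts, widths)
    )


def protection_track(
    loci: tuple[tuple[int, int, float], ...], L: int = 16569
) -> np.ndarray:
    """Per-site protection weight >= 1 from a list of (start, end, factor)."""
    track = np.ones(L)
    for s, e, f in loci:
        track[s - 1 : e] = np.maximum(track[s - 1 : e], f)
    return track


def _effective_effects(
    cfg: SimConfig, group_label: str, cancer_type: str
) -> GroupEffects:
    g = cfg.group_effects.get(group_label, GroupEffects())
    if group_label == "MT" and cancer_type in cfg.cancer_type_effects:
        t = cfg.cancer_type_effects[cancer_type]
        return GroupEffects(
            size_shift=g.size_shift + t.size_shift,
            extra_peak_loci=g.extra_peak_loci + t.extra_peak_loci,
            end_bias_exponent=g.end_bias_exponent * t.end_bias_exponent,
            base_bias_scale=g.base_bias_scale,
        )
    return g


def scale_effects(effects: GroupEffects, factor: float) -> GroupEffects:
    """Shrink (factor < 1) or grow a group's programmed effect sizes."""
    return GroupEffects(
        size_shift=effects.size_shift * factor,
        extra_peak_loci=effects.extra_peak_loci if factor > 0 else (),
        end_bias_exponent=1.0 + (effects.end_bias_exponent - 1.0) * factor,
        base_bias_scale=effects.base_bias_scale,
    )


def simulate_sample(
    cfg: SimConfig,
    group_label: str = "HC",
    cancer_type: str = "none",
    sample_id: str = "sim",
    ref: MtReference | None = None,
    seed: int | None = None,
    batch_id: str = "batch0",
) -> FragmentSet:
    """Draw one sample's fragment set under the configured study conditions."""
    if ref is None:
        ref = synthetic_reference()
    L = ref.length
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    eff = _effective_effects(cfg, group_label, cancer_type)

    loci = cfg.protection_loci
    if loci is None:
        loci = default_protection_loci(L)
    loci = loci + tuple((p - 60, p + 60, 15.0) for p in eff.extra_peak_loci)
    protection = protection_track(loci, L)

    bias = dict(cfg.end_bias)
    if eff.base_bias_scale:
        for b, s in eff.base_bias_scale.items():
            bias[b] = bias[b] * s
    seq = ref.base_array()
    base_w = np.zeros(L)  # N placeholder sites are never cut
    for b in "ACGT":
        base_w[seq == b] = bias.get(b, 1.0)
    base_w = base_w ** eff.end_bias_exponent

    weight = base_w / protection
    if weight.sum() <= 0:
        raise ValueError("zero total cleavage weight")
    p_cut = weight / weight.sum()
    accept_w = weight / weight.max()

    track = class_track(default_annotations(L) if L == 16569 else [], L)
    means = np.array([cfg.length_laws.get(c, cfg.length_laws[""])[0] for c in track])
    sds = np.array([cfg.length_laws.get(c, cfg.length_laws[""])[1] for c in track])

    n = cfg.n_fragments
    starts_out = np.empty(0, dtype=np.int64)
    ends_out = np.empty(0, dtype=np.int64)
    while starts_out.size < n:
        m = max(1024, int((n - starts_out.size) * 1.8))
        s0 = rng.choice(L, size=m, p=p_cut)  # 0-based cut index
        lens = rng.normal(means[s0] + eff.size_shift, sds[s0])
        lens = np.clip(np.round(lens), cfg.min_length, cfg.max_length).astype(np.int64)
        e0 = (s0 + lens - 1) % L
        second_cut = (e0 + 1) % L  # cut after the last included base
        keep = rng.random(m) < accept_w[second_cut]
        starts_out = np.concatenate([starts_out, s0[keep] + 1])
        ends_out = np.concatenate([ends_out, e0[keep] + 1])
    starts_out = starts_out[:n]
    ends_out = ends_out[:n]
    strands = np.where(rng.random(n) < 0.5, "+", "-").astype("U1")

    fs = FragmentSet(
        sample_id=sample_id,
        L=L,
        start=starts_out,
        end=ends_out,
        strand=strands,
        group_label=group_label,
        cancer_type=cancer_type,
        batch_id=batch_id,
    )
    for spike in cfg.spikes:
        _apply_spike(fs, spike, rng)
    return fs


def _apply_spike(fs: FragmentSet, spike: Spike, rng: np.random.Generator) -> None:
    from .variants import _covers_site

    covers = _covers_site(fs, spike.site)
    idx = np.flatnonzero(covers & (fs.alt_site < 0))
    if idx.size == 0:
        return
    chosen = idx[rng.random(idx.size) < spike.fraction]
    if chosen.size == 0:
        return
    # mutant molecules may run systematically shorter: re-draw their span
    # around the variant site with the configured length offset
    if spike.length_offset:
        new_len = np.maximum(
            30, (fs.lengths[chosen] + spike.length_offset).astype(np.int64)
        )
        u = (rng.random(chosen.size) * new_len).astype(np.int64)
        new_start0 = (spike.site - 1 - u) % fs.L
        new_end0 = (new_start0 + new_len - 1) % fs.L
        fs.start[chosen] = new_start0 + 1
        fs.end[chosen] = new_end0 + 1
    fs.alt_site[chosen] = spike.site
    fs.alt_base[chosen] = spike.alt
    fs.strand[chosen] = np.where(
        rng.random(chosen.size) < spike.strand_balance, "+", "-"
    )


def simulate_cohort(
    cfg: SimConfig,
    n_per_group: dict[str, int],
    ref: MtReference | None = None,
    cancer_types: tuple[str, ...] = ("NSCLC", "HCC", "CRC"),
    n_batches: int = 2,
):
    """Simulate a labelled cohort; returns (fragment sets, ground-truth table).

    MT samples cycle through ``cancer_types``; batches are assigned round
    robin across the whole cohort.  Per-sample seeds are spawned from the
    master seed, so the same master seed reproduces the cohort exactly.
    """
    import pandas as pd

    if ref is None:
        ref = synthetic_reference()
    bad = [g for g, n in n_per_group.items() if n <= 0]
    if bad:
        raise ValueError(f"non-positive sample count for group(s) {bad}")
    ss = np.random.SeedSequence(cfg.seed)
    samples: list[FragmentSet] = []
    truth_rows = []
    i = 0
    for group, n in sorted(n_per_group.items()):
        for j in range(n):
            ctype = cancer_types[j % len(cancer_types)] if group == "MT" else "none"
            child_seed = int(ss.spawn(1)[0].generate_state(1)[0] % (2**31))
            sid = f"{group}_{j:04d}"
            eff = _effective_effects(cfg, group, ctype)
            fs = simulate_sample(
                cfg,
                group_label=group,
                cancer_type=ctype,
                sample_id=sid,
                ref=ref,
                seed=child_seed,
                batch_id=f"batch{i % n_batches}",
            )
            samples.append(fs)
            truth_rows.append(
                {
                    "sample_id": sid,
                    "group": group,
                    "cancer_type": ctype,
                    "batch_id": fs.batch_id,
                    "seed": child_seed,
                    "size_shift": eff.size_shift,
                    "n_extra_peak_loci": len(eff.extra_peak_loci),
                    "end_bias_exponent": eff.end_bias_exponent,
                }
            )
            i += 1
    return samples, pd.DataFrame(truth_rows)


def write_pileup(
    fs: FragmentSet,
    ref: MtReference,
    error_rate: float = 1e-3,
    seed: int = 0,
    path=None,
    spikes: tuple[Spike, ...] = (),
) -> list[AlleleCounts]:
    """Per-site strand-split allele counts from a fragment set.

    Every fragment contributes one base observation at each covered site:
    the reference base, flipped to a random other base with probability
    ``error_rate``, or the spiked alternate on tagged fragments at the spike
    site.  Phred qualities encode the error rate (capped at Q40); spiked
    bases carry their configured quality.
    """
    if not 0 <= error_rate <= 0.1:
        raise ValueError("error_rate must be in [0, 0.1]")
    rng = np.random.default_rng(seed)
    L = ref.length
    seq = ref.base_array()
    fwd_set = fs.subset(np.flatnonzero(fs.strand == "+"))
    rev_set = fs.subset(np.flatnonzero(fs.strand == "-"))
    depth_fwd, _ = site_depths(fwd_set, np.ones(len(fwd_set), dtype=bool), L)
    depth_rev, _ = site_depths(rev_set, np.ones(len(rev_set), dtype=bool), L)
    spike_q = {(s.site, s.alt): s.base_quality for s in spikes}

    base_q = min(40.0, -10 * np.log10(error_rate)) if error_rate > 0 else 40.0
    bidx = {b: i for i, b in enumerate(BASES)}

    # spiked alt observations per site/strand
    alt_fwd = {}
    alt_rev = {}
    spiked = np.flatnonzero(fs.alt_site >= 0)
    for i in spiked:
        site, alt = int(fs.alt_site[i]), str(fs.alt_base[i])
        key = (site, alt)
        if str(fs.strand[i]) == "+":
            alt_fwd[key] = alt_fwd.get(key, 0) + 1
        else:
            alt_rev[key] = alt_rev.get(key, 0) + 1

    counts: list[AlleleCounts] = []
    covered = np.flatnonzero((depth_fwd + depth_rev) > 0)
    err_fwd = rng.binomial(depth_fwd[covered], error_rate)
    err_rev = rng.binomial(depth_rev[covered], error_rate)
    for k, i0 in enumerate(covered):
        site = int(i0) + 1
        refb = str(seq[i0])
        if refb == "N":
            continue
        fwd = {b: 0 for b in BASES}
        rev = {b: 0 for b in BASES}
        fwd[refb] = int(depth_fwd[i0])
        rev[refb] = int(depth_rev[i0])
        qual = {b: base_q for b in BASES}
        for key, ncar in alt_fwd.items():
            if key[0] == site:
                fwd[key[1]] += ncar
                fwd[refb] -= ncar  # spiked molecules replace ref observations
                qual[key[1]] = spike_q.get(key, 33.0)
        for key, ncar in alt_rev.items():
            if key[0] == site:
                rev[key[1]] += ncar
                rev[refb] -= ncar
                qual[key[1]] = spike_q.get(key, 33.0)
        others = [b for b in BASES if b != refb]
        for e, d in ((int(err_fwd[k]), fwd), (int(err_rev[k]), rev)):
            e = min(e, d[refb])
            if e > 0:
                split = rng.multinomial(e, [1 / 3] * 3)
                d[refb] -= e
                for b, c in zip(others, split):
                    d[b] += int(c)
        counts.append(AlleleCounts(site, refb, fwd, rev, qual))
    if path is not None:
        write_pileup_tsv(counts, path)
    return counts
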