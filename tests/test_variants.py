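"""Heteroplasmy filters, binomial tests, origin classes, copy number."""

import numpy as np
import pytest
from scipy import stats

from mefi.fragments import FragmentSet
from mefi.variants import (
    AlleleCounts,
    CallerParams,
    VariantCall,
    binomial_filters,
    call_variants,
    classify_origin,
    copy_number,
    fragment_subsets_by_allele,
    read_pileup_tsv,
    write_pileup_tsv,
    write_vcf,
)


def ac(site=1000, ref="C", alt="T", fwd_alt=10, rev_alt=10, depth=200, q=33.0):
    """Build AlleleCounts with the remainder of the depth on the ref base."""
    fwd = {b: 0 for b in "ACGT"}
    rev = {b: 0 for b in "ACGT"}
    fwd[alt] += fwd_alt
    rev[alt] += rev_alt
    n_ref = depth - fwd_alt - rev_alt
    fwd[ref] += n_ref // 2
    rev[ref] += n_ref - n_ref // 2
    return AlleleCounts(site, ref, fwd, rev, {b: q for b in "ACGT"})


class TestFilters:
    def test_insufficient_strand_support(self):
        # 2 forward / 5 reverse at 7% MAF -> strand filter fails
        calls = call_variants([ac(fwd_alt=2, rev_alt=5, depth=100)])
        assert "strand_support" in calls[0].filters_failed
        assert calls[0].origin == "rejected"

    def test_maf_floor(self):
        calls = call_variants([ac(fwd_alt=4, rev_alt=4, depth=1000)])
        assert "maf_floor" in calls[0].filters_failed

    def test_repeat_region_site_305(self):
        calls = call_variants([ac(site=305, fwd_alt=5, rev_alt=5, depth=200)])
        assert "repeat_region" in calls[0].filters_failed

    @pytest.mark.parametrize(
        "site,expect",
        [(66, True), (71, True), (65, False), (72, False),
         (303, True), (311, True), (514, True), (523, True),
         (12418, True), (12425, True), (16184, True), (16193, True)],
    )
    def test_repeat_region_boundaries_inclusive(self, site, expect):
        from mefi.variants import in_repeat_region

        assert in_repeat_region(site) is expect

    def test_oxidation_low_maf_fails_high_maf_passes(self):
        # C>A at 8% -> oxidation artifact; C>A at 15% -> oxidation filter passed
        low = call_variants([ac(ref="C", alt="A", fwd_alt=8, rev_alt=8, depth=200)])
        assert "oxidation" in low[0].filters_failed
        high = call_variants([ac(ref="C", alt="A", fwd_alt=15, rev_alt=15, depth=200)])
        assert "oxidation" not in high[0].filters_failed
        # G>T is the complementary artifact
        gt = call_variants([ac(ref="G", alt="T", fwd_alt=8, rev_alt=8, depth=200)])
        assert "oxidation" in gt[0].filters_failed
        # T>G is not an oxidation signature
        tg = call_variants([ac(ref="T", alt="G", fwd_alt=8, rev_alt=8, depth=200)])
        assert "oxidation" not in tg[0].filters_failed

    def test_clean_variant_passes_all_filters(self):
        calls = call_variants([ac(fwd_alt=15, rev_alt=15, depth=200)])
        assert calls[0].passed
        assert calls[0].maf == pytest.approx(0.15)

    def test_filters_evaluated_on_raw_counts_order_independent(self):
        # a call failing several filters reports all of them
        calls = call_variants([ac(site=305, ref="C", alt="A", fwd_alt=2, rev_alt=1,
                                  depth=200)])
        assert {"strand_support", "repeat_region", "oxidation"} <= calls[0].filters_failed

    def test_empty_input_empty_output(self):
        assert call_variants([]) == []


class TestBinomialFilters:
    def test_strong_signal_passes_rate_test(self):
        # 10 alt / 1000 at Q30 (p_err = 0.001): far above error expectation
        ok, p_rate, p_q = binomial_filters(
            10, 1000, np.full(10, 30.0), np.full(990, 30.0)
        )
        # exact tail: P(X >= 10 | n=1000, p=1e-3) ~ 1.1e-7, far below alpha
        assert p_rate < 1e-6
        assert ok

    def test_single_read_fails_rate_test(self):
        ok, p_rate, _ = binomial_filters(1, 1000, np.full(1, 30.0), np.full(999, 30.0))
        # P(X >= 1) = 1 - 0.999^1000 ~ 0.632
        assert p_rate == pytest.approx(1 - 0.999**1000, abs=1e-9)
        assert not ok

    def test_no_alt_reads_trivially_fails(self):
        ok, p_rate, p_q = binomial_filters(0, 1000, np.empty(0), np.full(1000, 30.0))
        assert p_rate == 1.0 and not ok

    def test_low_quality_alt_bases_fail_quality_test(self):
        ok, _, p_q = binomial_filters(20, 1000, np.full(20, 10.0), np.full(980, 30.0))
        assert p_q > 0.001 and not ok

    def test_rate_test_monotone_in_alt_count(self):
        pvals = [
            binomial_filters(k, 1000, np.full(max(k, 1), 30.0), np.full(1000 - k, 30.0))[1]
            for k in range(0, 30, 3)
        ]
        assert all(a >= b for a, b in zip(pvals, pvals[1:]))

    def test_zero_depth_rejected(self):
        with pytest.raises(ValueError):
            binomial_filters(0, 0, np.empty(0), np.empty(0))


class TestOriginClassification:
    def _calls(self, keys):
        return [
            VariantCall(site, "C", alt, 0.1, 5, 5, frozenset(), 1e-9, 1e-9)
            for site, alt in keys
        ]

    def test_origin_definitions(self):
        tumor = self._calls([(100, "T"), (200, "G"), (300, "A")])
        leuko = self._calls([(200, "G"), (300, "A")])
        para = self._calls([(200, "G")])
        origins = classify_origin(tumor, leuko, para)
        assert origins[(100, "T")] == "tumor_derived"  # tumor only
        assert origins[(200, "G")] == "germline"  # tumor + both controls
        assert origins[(300, "A")] == "somatic_unclassified"  # one control only

    def test_missing_control_set_skips_classification(self):
        out = classify_origin(self._calls([(100, "T")]), None, self._calls([]))
        assert out == {}

    def test_rejected_calls_not_classified(self):
        rej = [VariantCall(100, "C", "T", 0.1, 1, 1,
                           frozenset({"strand_support"}), 1.0, 1.0)]
        assert classify_origin(rej, self._calls([]), self._calls([])) == {}


class TestCopyNumber:
    def test_arithmetic(self):
        assert copy_number(5000, 10) == 1000.0

    def test_diploid_identity(self):
        assert copy_number(30, 30) == 2.0

    def test_zero_nuclear_depth_rejected(self):
        with pytest.raises(ValueError):
            copy_number(100, 0)

    def test_programmed_copy_number_recovered_in_simulation(self, ref):
        """CN = 2 * mt/nuclear recovers the programmed ratio from simulated
        depths."""
        from mefi.fsd import site_depths
        from mefi.simulate import SimConfig, simulate_sample

        cfg = SimConfig(seed=8, n_fragments=30000)
        fs = simulate_sample(cfg, "HC", ref=ref, seed=8)
        long_d, short_d = site_depths(fs, np.zeros(len(fs), dtype=bool))
        mt_depth = (long_d + short_d).mean()
        programmed_cn = 500.0
        nuclear_depth = 2 * mt_depth / programmed_cn
        assert copy_number(mt_depth, nuclear_depth) == pytest.approx(programmed_cn)


class TestAlleleSubsets:
    def test_partition_sums_to_covering_depth(self):
        fs = FragmentSet(
            "s", 1000,
            np.array([100, 150, 400, 190]),
            np.array([250, 300, 600, 310]),
            alt_site=np.array([200, -1, -1, 200]),
            alt_base=np.array(["T", "", "", "T"]),
        )
        alt_fs, wt_fs = fragment_subsets_by_allele(fs, 200, "T")
        assert len(alt_fs) == 2 and len(wt_fs) == 1  # fragment 400..600 not covering
        assert len(alt_fs) + len(wt_fs) == 3

    def test_no_tagged_fragments(self):
        fs = FragmentSet("s", 1000, np.array([100]), np.array([300]))
        alt_fs, wt_fs = fragment_subsets_by_allele(fs, 200, "T")
        assert len(alt_fs) == 0 and len(wt_fs) == 1

    def test_uncovered_site_rejected(self):
        fs = FragmentSet("s", 1000, np.array([100]), np.array([300]))
        with pytest.raises(ValueError):
            fragment_subsets_by_allele(fs, 900, "T")


class TestIO:
    def test_pileup_round_trip(self, tmp_path):
        counts = [ac(site=5, fwd_alt=3, rev_alt=4, depth=50),
                  ac(site=9, ref="G", alt="T", fwd_alt=0, rev_alt=0, depth=30)]
        p = tmp_path / "p.tsv"
        write_pileup_tsv(counts, p)
        back = read_pileup_tsv(p)
        assert [b.site for b in back] == [5, 9]
        assert back[0].fwd == counts[0].fwd and back[0].rev == counts[0].rev
        assert back[0].mean_quality == counts[0].mean_quality

    def test_vcf_writer_minimal_format(self, tmp_path):
        calls = call_variants([ac(fwd_alt=15, rev_alt=15, depth=200),
                               ac(site=305, fwd_alt=5, rev_alt=5, depth=200)])
        p = tmp_path / "out.vcf"
        write_vcf(calls, p)
        text = p.read_text()
        assert "##contig=<ID=chrM,length=16569>" in text
        lines = [l for l in text.splitlines() if not l.startswith("#")]
        assert len(lines) == 2
        # records are site-sorted: 305 (repeat-filtered) before 1000 (PASS)
        assert "repeat_region" in lines[0] and "PASS" in lines[1]


class TestErrorOnlyFalsePositives:
    def test_error_pileup_pass_rate_within_alpha_budget(self):
        """Across 16,569 sites of pure sequencing error (p=1e-3, depth 1000),
        the full caller's per-site pass rate stays within the alpha = 0.001
        conjunction expectation."""
        rng = np.random.default_rng(123)
        L, depth, p_err = 16569, 1000, 1e-3
        errors = rng.binomial(depth, p_err, size=L)
        counts = []
        for i in range(L):
            e = int(errors[i])
            if e == 0:
                continue
            e_fwd = int(rng.binomial(e, 0.5))
            split = rng.multinomial(e, [1 / 3] * 3)
            fwd = {"A": 0, "C": 0, "G": 0, "T": 0}
            rev = {"A": 0, "C": 0, "G": 0, "T": 0}
            for b, c in zip("ACG", split):  # ref base T at every site
                half = int(rng.binomial(c, 0.5))
                fwd[b] = half
                rev[b] = int(c) - half
            fwd["T"] = depth // 2 - sum(fwd[b] for b in "ACG")
            rev["T"] = depth - depth // 2 - sum(rev[b] for b in "ACG")
            counts.append(AlleleCounts(i + 1, "T", fwd, rev,
                                       {b: 30.0 for b in "ACGT"}))
        calls = call_variants(counts)
        n_pass = sum(c.passed for c in calls)
        assert n_pass <= int(np.ceil(0.001 * L))
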