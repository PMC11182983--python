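"""QC filtering, binned counting, interval screening and the mtDNA ratio."""

import numpy as np
import pytest

from mitoquant.genome import GenomicBin
from mitoquant.quant import (
    BinCountMatrix,
    NormalizationInterval,
    QcConfig,
    compute_mtdna_ratio,
    count_bin_reads,
    filter_reads,
    screen_normalization_interval,
)
from mitoquant.reads import AlignedRead, ReadSet
from mitoquant.simulate import SimReadConfig, simulate_biopsy_reads


def _read(chrom="1", pos=0, mapq=60, unmapped=False, dup=False, sec=False,
          nm=0, aligned_len=100):
    return AlignedRead(chrom=None if unmapped else chrom, pos=pos, mapq=mapq,
                       is_unmapped=unmapped, is_duplicate=dup,
                       is_secondary_or_supplementary=sec, nm=nm,
                       aligned_len=aligned_len)


class TestFilterReads:
    def test_clean_reads_all_retained(self):
        rs = ReadSet.from_records([_read(pos=i) for i in range(10)], ["1"])
        retained, stats = filter_reads(rs, QcConfig())
        assert len(retained) == 10
        assert stats.removed() == 0

    def test_first_failing_filter_wins_attribution(self):
        # flagged duplicate AND mapq 0: the duplicate filter comes first
        rs = ReadSet.from_records([_read(mapq=0, dup=True)], ["1"])
        _, stats = filter_reads(rs, QcConfig(min_mapq=20))
        assert stats.duplicate == 1
        assert stats.low_mapq == 0

    def test_unmapped_precedes_duplicate(self):
        rs = ReadSet.from_records([AlignedRead(None, -1, 0, True, True, False, 0, 0)], [])
        _, stats = filter_reads(rs, QcConfig())
        assert stats.unmapped == 1
        assert stats.duplicate == 0

    def test_poor_alignment_cut_on_mismatch_fraction(self):
        rs = ReadSet.from_records(
            [_read(nm=10, aligned_len=100), _read(nm=11, aligned_len=100)], ["1"]
        )
        retained, stats = filter_reads(rs, QcConfig(max_mismatch_frac=0.10))
        assert len(retained) == 1
        assert stats.poor_alignment == 1

    def test_filters_configurable_off(self):
        rs = ReadSet.from_records([_read(dup=True), _read(sec=True)], ["1"])
        retained, _ = filter_reads(rs, QcConfig(drop_duplicates=False,
                                                drop_secondary=False))
        assert len(retained) == 2

    def test_conservation_input_equals_retained_plus_removed(self, small_genome,
                                                             small_bins):
        sim = simulate_biopsy_reads(SimReadConfig(seed=3, nuclear_coverage=40.0),
                                    small_bins, genome=small_genome)
        retained, stats = filter_reads(sim.reads, QcConfig())
        assert stats.input == stats.retained + stats.removed()
        assert stats.retained == len(retained)


class TestCountBinReads:
    def test_zero_reads_gives_all_zero_matrix(self, small_bins):
        rs = ReadSet.empty(["5"])
        m = count_bin_reads(rs, small_bins)
        assert m.counts.sum() == 0 and m.mt_counts.sum() == 0

    def test_read_assigned_to_containing_bin(self):
        bins = [GenomicBin("1", 0, 1_000_000), GenomicBin("1", 1_000_000, 2_000_000)]
        rs = ReadSet.from_records([_read(pos=0), _read(pos=999_999), _read(pos=1_000_000)],
                                  ["1"])
        m = count_bin_reads(rs, bins)
        assert list(m.counts[0]) == [2, 1]

    def test_mt_reads_accumulate_separately(self, small_bins):
        rs = ReadSet.from_records([_read(chrom="MT", pos=5), _read(chrom="5", pos=5)],
                                  ["MT", "5"])
        m = count_bin_reads(rs, small_bins)
        assert m.mt_counts[0] == 1
        assert m.counts.sum() == 1

    def test_undeclared_contig_raises_by_default_discard_optional(self, small_bins):
        rs = ReadSet.from_records([_read(chrom="17", pos=0)], ["17"])
        with pytest.raises(ValueError, match="undeclared"):
            count_bin_reads(rs, small_bins)
        m = count_bin_reads(rs, small_bins, on_undeclared="discard")
        assert m.counts.sum() == 0

    def test_counts_match_poisson_expectations(self, small_genome, small_bins):
        """Observed per-bin counts stay within 99.9% Poisson bounds of the
        generator's expectations."""
        from scipy import stats as st

        cfg = SimReadConfig(frac_duplicates=0, frac_unmapped=0, frac_low_mapq=0,
                            frac_poor_alignment=0, nuclear_coverage=200.0, seed=11)
        sim = simulate_biopsy_reads(cfg, small_bins, genome=small_genome)
        retained, _ = filter_reads(sim.reads, QcConfig())
        m = count_bin_reads(retained, small_bins)
        lam = sim.expected_bin_counts
        lo = st.poisson.ppf(0.0005, lam)
        hi = st.poisson.ppf(0.9995, lam)
        within = (m.counts[0] >= lo) & (m.counts[0] <= hi)
        assert within.all()

    def test_conservation_through_filter_and_count(self, small_genome, small_bins):
        sim = simulate_biopsy_reads(SimReadConfig(seed=9, nuclear_coverage=30.0),
                                    small_bins, genome=small_genome)
        retained, stats = filter_reads(sim.reads, QcConfig())
        m = count_bin_reads(retained, small_bins, qc_stats=stats)
        assert m.counts.sum() + m.mt_counts.sum() == stats.retained


def _matrix(counts_by_chrom: dict[str, np.ndarray], mt=None, bin_size=100_000):
    """Build a BinCountMatrix from per-chromosome (samples x bins) blocks."""
    bins, blocks = [], []
    for chrom, block in counts_by_chrom.items():
        block = np.atleast_2d(block)
        for j in range(block.shape[1]):
            bins.append(GenomicBin(chrom, j * bin_size, (j + 1) * bin_size))
        blocks.append(block)
    counts = np.hstack(blocks)
    n = counts.shape[0]
    return BinCountMatrix(
        sample_ids=[f"s{i}" for i in range(n)], bins=bins, counts=counts,
        mt_counts=np.zeros(n, dtype=int) if mt is None else np.asarray(mt),
    )


class TestScreening:
    def test_identical_samples_give_zero_cv_first_window_tiebreak(self):
        base = np.tile(np.full(12, 100), (3, 1))
        m = _matrix({"5": base, "6": base})
        freq = {"5": 0.05, "6": 0.01}
        interval = screen_normalization_interval(m, aneuploidy_freq=freq, window_bins=4)
        assert interval.chrom == "6"
        assert interval.start == 0
        assert interval.stability_score == 0.0

    def test_noisy_chromosomes_lose_to_quiet_one(self, rng):
        n, bins_per = 10, 15
        quiet = np.tile(np.full(bins_per, 200.0), (n, 1))
        jitter = rng.uniform(0.6, 1.4, size=(n, 1))
        noisy5 = np.full((n, bins_per), 200.0) * jitter
        noisy9 = np.full((n, bins_per), 200.0) * rng.uniform(0.6, 1.4, size=(n, 1))
        m = _matrix({"5": noisy5, "6": quiet, "9": noisy9})
        freq = {"5": 0.02, "6": 0.02, "9": 0.05}
        interval = screen_normalization_interval(m, aneuploidy_freq=freq, window_bins=5)
        # 5 and 6 tie on aneuploidy frequency; only 6 is dispersion-free
        assert interval.chrom == "6"

    def test_least_aneuploid_restriction_overrides_raw_cv(self, rng):
        n, bins_per = 8, 12
        quiet = np.tile(np.full(bins_per, 300.0), (n, 1))
        noisy = np.full((n, bins_per), 300.0) * rng.uniform(0.8, 1.2, size=(n, 1))
        m = _matrix({"5": quiet, "6": noisy})
        freq = {"5": 0.05, "6": 0.01}  # 6 least aneuploid despite higher CV
        interval = screen_normalization_interval(m, aneuploidy_freq=freq, window_bins=4)
        assert interval.chrom == "6"

    def test_matches_brute_force_argmin(self, rng):
        n, bins_per = 6, 14
        counts = {c: rng.poisson(150, size=(n, bins_per)).astype(float)
                  for c in ("5", "6", "9")}
        freq = {"5": 0.01, "6": 0.01, "9": 0.01}
        window = 4
        m = _matrix(counts)
        interval, report = screen_normalization_interval(
            m, aneuploidy_freq=freq, window_bins=window, return_report=True
        )
        # independent brute force over all windows
        totals = m.counts.sum(axis=1).astype(float)
        best = None
        for chrom in ("5", "6", "9"):
            idx = [i for i, b in enumerate(m.bins) if b.chrom == chrom]
            for w in range(len(idx) - window + 1):
                frac = m.counts[:, idx[w:w + window]].sum(axis=1) / totals
                cv = frac.std(ddof=1) / frac.mean()
                key = (chrom, m.bins[idx[w]].start)
                if best is None or cv < best[0] - 1e-15:
                    best = (cv, key)
        assert (interval.chrom, interval.start) == best[1]
        assert interval.stability_score == pytest.approx(best[0])
        assert len(report) == 3 * (bins_per - window + 1)

    def test_single_sample_reference_rejected(self):
        m = _matrix({"6": np.full((1, 12), 50)})
        with pytest.raises(ValueError, match="at least 2"):
            screen_normalization_interval(m, aneuploidy_freq={"6": 0.01})

    def test_sex_chromosomes_excluded_from_candidates_and_totals(self):
        auto = np.tile(np.full(12, 100), (3, 1))
        x = np.array([np.full(12, 100), np.full(12, 50), np.full(12, 100)])
        m = _matrix({"6": auto, "X": x})
        interval = screen_normalization_interval(
            m, aneuploidy_freq={"6": 0.01}, window_bins=4
        )
        assert interval.chrom == "6"
        assert interval.stability_score == 0.0  # X jitter must not leak in


class TestMtDnaRatio:
    def test_basic_arithmetic(self):
        m = _matrix({"6": np.full((1, 10), 15)}, mt=[300])
        interval = NormalizationInterval("6", 0, 1_000_000)
        r = compute_mtdna_ratio(m, interval)[0]
        assert r.value == pytest.approx(2.0)
        assert (r.reads_mt, r.reads_interval) == (300, 150)

    def test_zero_mt_gives_zero_not_undefined(self):
        m = _matrix({"6": np.full((1, 10), 50)}, mt=[0])
        r = compute_mtdna_ratio(m, NormalizationInterval("6", 0, 1_000_000))[0]
        assert r.value == 0.0 and not r.undefined

    def test_zero_denominator_flagged_undefined(self):
        m = _matrix({"6": np.zeros((1, 10), dtype=int)}, mt=[100])
        r = compute_mtdna_ratio(m, NormalizationInterval("6", 0, 1_000_000))[0]
        assert r.undefined and np.isnan(r.value)

    def test_scale_equivariance_under_count_doubling(self):
        counts = np.arange(1, 11)[None, :]
        m1 = _matrix({"6": counts}, mt=[123])
        m2 = _matrix({"6": counts * 2}, mt=[246])
        interval = NormalizationInterval("6", 0, 1_000_000)
        r1 = compute_mtdna_ratio(m1, interval)[0]
        r2 = compute_mtdna_ratio(m2, interval)[0]
        assert r1.value == pytest.approx(r2.value)

    def test_scale_multiplier_applied(self):
        m = _matrix({"6": np.full((1, 10), 10)}, mt=[100])
        r = compute_mtdna_ratio(m, NormalizationInterval("6", 0, 1_000_000), scale=7.0)[0]
        assert r.value == pytest.approx(7.0)

    def test_min_reads_threshold_flags_not_drops(self):
        m = _matrix({"6": np.full((1, 10), 10)}, mt=[3])
        r = compute_mtdna_ratio(m, NormalizationInterval("6", 0, 1_000_000),
                                min_mt_reads=10)[0]
        assert r.below_min_reads and not r.undefined

    def test_partial_interval_uses_only_contained_bins(self):
        m = _matrix({"6": np.arange(1, 11)[None, :]}, mt=[60])
        r = compute_mtdna_ratio(m, NormalizationInterval("6", 0, 300_000))[0]
        assert r.reads_interval == 1 + 2 + 3

    def test_recovery_monotone_and_within_sampling_error(self, small_genome, small_bins):
        """Estimated ratios over truths {0.5, 1, 2, 4} are monotone and each
        within 3 binomial SEs at moderate depth."""
        interval = NormalizationInterval("6", 0, 1_000_000)
        estimates = []
        for truth in (0.5, 1.0, 2.0, 4.0):
            copies = truth * 10 * 2 * 100_000 / 16_569
            cfg = SimReadConfig(mt_copies_per_cell=copies, nuclear_coverage=400.0,
                                frac_duplicates=0, frac_unmapped=0, frac_low_mapq=0,
                                frac_poor_alignment=0, seed=int(truth * 10))
            sim = simulate_biopsy_reads(cfg, small_bins, genome=small_genome)
            retained, _ = filter_reads(sim.reads, QcConfig())
            m = count_bin_reads(retained, small_bins, sample_id="s")
            r = compute_mtdna_ratio(m, interval)[0]
            se = r.value * np.sqrt(1 / max(r.reads_mt, 1) + 1 / r.reads_interval)
            assert abs(r.value - truth) < 3 * se
            estimates.append(r.value)
        assert estimates == sorted(estimates)
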