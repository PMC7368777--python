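import numpy as np
import pandas as pd
import pytest

from chromloop.chipdiff import (
    DifferentialBindingModel,
    ReadSample,
    call_peaks,
    compute_ripm,
    count_reads_in_intervals,
    filter_artifact_peaks,
    filter_standard,
    frip_downsample,
    manorm_lenient,
    merge_samples,
    negbin_ratio_test,
    reads_in_peaks,
    ripm_peak_signal,
    sex_independent_set,
    stringency_bands,
)


def sample_from_starts(starts, read_len=100, chrom="chr1", **kw):
    starts = np.asarray(starts, dtype=np.int64)
    reads = {chrom: np.column_stack([starts, starts + read_len])}
    return ReadSample(kw.get("factor", "CTCF"), kw.get("sex", "M"),
                      kw.get("replicate_id", "r1"), reads)


def uniform_sample(rng, n, L, read_len=100, **kw):
    starts = rng.integers(0, L - read_len, size=n)
    return sample_from_starts(starts, read_len=read_len, **kw)


def test_read_sample_from_bed_matches_in_memory(tmp_path, rng):
    starts = np.sort(rng.integers(0, 50_000, size=200))
    df = pd.DataFrame({"chrom": "chr1", "start": starts, "end": starts + 100})
    path = tmp_path / "reads.bed"
    df.to_csv(path, sep="\t", header=False, index=False)
    s = ReadSample.from_bed(path, "CTCF", "M", "r1")
    assert s.total_mapped == 200
    assert np.array_equal(s.reads["chr1"], df[["start", "end"]].to_numpy())


class TestRipm:
    def test_frip_and_divisor_arithmetic(self):
        # 2000 reads, 400 inside the single peak -> FRiP 0.2
        starts = np.concatenate([
            np.linspace(10_000, 10_300, 400).astype(int),          # in peak
            np.linspace(100_000, 900_000, 1600).astype(int),       # outside
        ])
        s = sample_from_starts(starts)
        peaks = pd.DataFrame({"chrom": ["chr1"], "start": [10_000], "end": [10_500]})
        qc = compute_ripm(s, peaks)
        assert qc.frip == pytest.approx(0.2)
        assert qc.ripm_divisor == pytest.approx(400 / 1e6)

    def test_signal_invariant_to_depth_doubling(self):
        starts = np.concatenate([np.arange(1_000, 1_400, 2), np.arange(50_000, 90_000, 100)])
        s1 = sample_from_starts(starts)
        s2 = sample_from_starts(np.concatenate([starts, starts]))  # doubled depth
        peaks = pd.DataFrame({"chrom": ["chr1"] * 2, "start": [900, 60_000],
                              "end": [1_500, 61_000]})
        sig1 = ripm_peak_signal(s1, peaks, union_peaks=peaks)
        sig2 = ripm_peak_signal(s2, peaks, union_peaks=peaks)
        assert np.allclose(sig1, sig2)

    def test_pure_background_sample_has_low_frip(self, rng):
        s = uniform_sample(rng, 20_000, 2_000_000)
        # a modest peak list covering ~2% of the genome
        peaks = pd.DataFrame({"chrom": ["chr1"] * 20,
                              "start": np.arange(20) * 100_000,
                              "end": np.arange(20) * 100_000 + 2_000})
        qc = compute_ripm(s, peaks)
        assert qc.frip <= 0.05

    def test_zero_reads_in_peaks_is_degenerate(self, rng):
        s = uniform_sample(rng, 100, 10_000)
        peaks = pd.DataFrame({"chrom": ["chr9"], "start": [0], "end": [100]})
        with pytest.raises(ValueError):
            compute_ripm(s, peaks)


class TestPeakCalling:
    def test_uniform_background_yields_no_peaks(self, rng):
        s = uniform_sample(rng, 50_000, 10_000_000)
        peaks = call_peaks(s, chrom_lengths={"chr1": 10_000_000})
        assert len(peaks) <= 1  # <= 1 false peak per 10 Mb at p < 1e-5

    def test_single_enriched_region_called_once(self, rng):
        bg = rng.integers(0, 999_900, size=5_000)
        peak_reads = rng.normal(500_000, 80, size=2_500).astype(int)
        s = sample_from_starts(np.concatenate([bg, peak_reads]))
        peaks = call_peaks(s, chrom_lengths={"chr1": 1_000_000})
        assert len(peaks) == 1
        assert peaks.iloc[0].start <= 500_000 <= peaks.iloc[0].end

    def test_zero_coverage_input(self):
        s = ReadSample("CTCF", "M", "r", {"chr1": np.empty((0, 2), dtype=np.int64)})
        assert len(call_peaks(s, chrom_lengths={"chr1": 1_000})) == 0


class TestArtifactFilter:
    def _peaks(self):
        return pd.DataFrame({"chrom": ["chr1"], "start": [1_000], "end": [1_400]})

    def test_pure_duplicate_stack_removed(self):
        s = sample_from_starts([1_100] * 7)
        out = filter_artifact_peaks(self._peaks(), [s])
        assert len(out) == 0

    def test_stack_with_offset_read_retained(self):
        s = sample_from_starts([1_100] * 7 + [1_150])
        out = filter_artifact_peaks(self._peaks(), [s])
        assert len(out) == 1

    def test_small_stack_retained(self):
        s = sample_from_starts([1_100] * 4)
        out = filter_artifact_peaks(self._peaks(), [s])
        assert len(out) == 1

    def test_blacklist_removal(self):
        from chromloop.intervals import GenomicInterval, IntervalCollection

        s = sample_from_starts([1_000, 1_050, 1_100, 1_200])
        bl = IntervalCollection([GenomicInterval("chr1", 1_200, 1_300)])
        out = filter_artifact_peaks(self._peaks(), [s], blacklist=bl)
        assert len(out) == 0


class TestNegbinTest:
    def test_identical_groups_are_null(self):
        counts = np.tile([[20, 25, 22]], (5, 1)).astype(float)
        p, z, l2, disp = negbin_ratio_test(counts, counts)
        assert np.allclose(l2, 0)
        assert np.all(p > 0.8)

    def test_large_effect_is_significant(self, rng):
        ca = rng.poisson(200, size=(10, 3)).astype(float)
        cb = rng.poisson(50, size=(10, 3)).astype(float)
        p, z, l2, disp = negbin_ratio_test(ca, cb)
        assert np.all(p < 1e-4)
        assert np.all(l2 > 1)

    def test_exact_fallback_flagged_for_single_replicates(self, rng):
        m = [uniform_sample(rng, 2_000, 100_000, sex="M")]
        f = [uniform_sample(rng, 2_000, 100_000, sex="F")]
        res = DifferentialBindingModel(m, f, chrom_lengths={"chr1": 100_000}).fit()
        assert res.fallback


class TestStandardFilter:
    BASE = dict(chrom="chr1", start=1_000, end=1_400, log2_mf=np.log2(5),
                counts_m=90, counts_f=18, p=1e-5, fdr=1e-3,
                direction="male-biased")
    PEAKS = pd.DataFrame({"chrom": ["chr1"], "start": [900], "end": [1_500]})

    def _run(self, **overrides):
        row = {**self.BASE, **overrides}
        sites = pd.DataFrame([row])
        return filter_standard(sites, self.PEAKS).iloc[0].tier

    def test_all_conditions_met(self):
        assert self._run() == "standard"

    def test_too_few_reads_rejected(self):
        assert self._run(counts_m=6, counts_f=3) == "rejected"  # 9 < 10 reads

    def test_small_fold_rejected(self):
        assert self._run(log2_mf=np.log2(1.8)) == "rejected"

    def test_no_peak_overlap_rejected(self):
        assert self._run(start=5_000, end=5_400) == "rejected"

    def test_high_fdr_rejected(self):
        assert self._run(fdr=0.08) == "rejected"


class TestFripDownsample:
    def _paired(self, rng, n_in_m, n_in_f, n_out=4_000):
        def build(n_in, sex):
            starts = np.concatenate([
                rng.integers(10_000, 11_900, size=n_in),
                rng.integers(100_000, 996_000, size=n_out),
            ])
            return sample_from_starts(starts, sex=sex)
        peaks = pd.DataFrame({"chrom": ["chr1"], "start": [9_900], "end": [12_100]})
        return build(n_in_m, "M"), build(n_in_f, "F"), peaks

    def test_downsample_factor_mirrors_in_peak_ratio(self, rng):
        m, f, peaks = self._paired(rng, 10_000, 7_460)
        mm, ff, factors = frip_downsample(m, f, peaks, seed=5)
        assert factors["M"] == pytest.approx(0.746, abs=0.01)
        assert factors["F"] == 1.0

    def test_equal_samples_untouched(self, rng):
        m, f, peaks = self._paired(rng, 5_000, 5_000)
        mm, ff, factors = frip_downsample(m, f, peaks, seed=5)
        assert factors == {"M": 1.0, "F": 1.0}
        assert mm is m and ff is f

    def test_post_condition_recount_within_tolerance(self, rng):
        for n_m, n_f in [(10_000, 7_460), (3_333, 9_999), (8_000, 7_999)]:
            m, f, peaks = self._paired(rng, n_m, n_f)
            mm, ff, _ = frip_downsample(m, f, peaks, seed=2)
            rm, _ = reads_in_peaks(mm, peaks)
            rf, _ = reads_in_peaks(ff, peaks)
            assert abs(rm - rf) <= 0.001 * max(rm, rf)


class TestMAnorm:
    def _peaks(self, n, spacing=3_000, width=600):
        starts = 5_000 + np.arange(n) * spacing
        return pd.DataFrame({"chrom": "chr1", "start": starts, "end": starts + width})

    def _sample_for_counts(self, rng, counts, peaks, sex):
        starts = []
        for c, r in zip(counts, peaks.itertuples()):
            starts.append(rng.integers(r.start, r.end - 100, size=int(c)))
        return sample_from_starts(np.concatenate(starts), sex=sex)

    def test_symmetric_samples_give_no_lenient_sites(self, rng):
        peaks = self._peaks(60)
        base = rng.poisson(120, size=60)
        m = self._sample_for_counts(rng, base, peaks, "M")
        f = self._sample_for_counts(rng, base, peaks, "F")
        lenient, ma = manorm_lenient(m, f, peaks)
        assert len(lenient) == 0
        assert abs(np.median(ma.m_rescaled)) < 0.1

    def test_depth_imbalance_recentered(self, rng):
        """A global 2x depth imbalance with no true differences is absorbed
        by the MA rescaling; false lenient calls stay rare."""
        peaks = self._peaks(200)
        mu = rng.uniform(60, 300, size=200)
        cm = rng.poisson(2 * mu)  # male library sequenced twice as deep
        cf = rng.poisson(mu)
        m = self._sample_for_counts(rng, cm, peaks, "M")
        f = self._sample_for_counts(rng, cf, peaks, "F")
        lenient, ma = manorm_lenient(m, f, peaks)
        common = (ma.counts_m >= 10) & (ma.counts_f >= 10)
        assert abs(np.median(ma.m_rescaled[common])) < 0.1
        assert len(lenient) <= 0.05 * len(peaks)

    def test_planted_threefold_recovered_as_lenient(self, rng):
        peaks = self._peaks(80)
        mu = np.full(80, 150.0)
        cm = rng.poisson(mu)
        cm[0] = int(mu[0] * 3)  # planted 3-fold male-biased peak
        cf = rng.poisson(mu)
        m = self._sample_for_counts(rng, cm, peaks, "M")
        f = self._sample_for_counts(rng, cf, peaks, "F")
        lenient, _ = manorm_lenient(m, f, peaks)
        assert len(lenient) >= 1
        assert (lenient.start == peaks.iloc[0].start).any()

    def test_too_few_common_peaks_raises(self, rng):
        peaks = self._peaks(5)
        counts = rng.poisson(50, size=5)
        m = self._sample_for_counts(rng, counts, peaks, "M")
        f = self._sample_for_counts(rng, counts, peaks, "F")
        with pytest.raises(ValueError):
            manorm_lenient(m, f, peaks)


class TestSexIndependentSet:
    def _peaks(self, ratios, totals=None):
        n = len(ratios)
        totals = np.ones(n) if totals is None else np.asarray(totals, float)
        sig_f = totals / (1 + np.asarray(ratios, float))
        sig_m = totals - sig_f
        return pd.DataFrame({"chrom": "chr1", "start": np.arange(n) * 1000,
                             "end": np.arange(n) * 1000 + 500,
                             "signal_m": sig_m, "signal_f": sig_f})

    def test_unit_ratio_ranks_first(self):
        df = self._peaks([2.0, 1.0, 0.3])
        out = sex_independent_set(df, n=1)
        assert out.iloc[0].start == 1000

    def test_ordering(self):
        df = self._peaks([1.0, 1.1, 0.5])
        out = sex_independent_set(df, n=2)
        assert set(out.start) == {0, 1000}

    def test_label_swap_invariance(self, rng):
        df = self._peaks(rng.uniform(0.2, 5.0, size=50), totals=rng.uniform(1, 10, 50))
        sel = sex_independent_set(df, n=10)
        swapped = df.rename(columns={"signal_m": "signal_f", "signal_f": "signal_m"})
        sel_sw = sex_independent_set(swapped, n=10)
        assert set(sel.start) == set(sel_sw.start)

    def test_n_larger_than_peaks_returns_all(self):
        df = self._peaks([1.0, 2.0])
        assert len(sex_independent_set(df, n=10)) == 2


class TestStringencyBands:
    @pytest.mark.parametrize(
        "fold,padj,reads,expected",
        [
            (3.0, 0.01, 40, "strict"),
            (2.0, 0.01, 40, "lenient"),
            (3.0, 0.2, 40, "none"),
            (1.2, 0.01, 40, "none"),
            (1.0 / 3.0, 0.01, 40, "strict"),  # female-biased fold, symmetric rule
            (3.0, 0.01, 10, "none"),
        ],
    )
    def test_band_rules(self, fold, padj, reads, expected):
        df = pd.DataFrame([{"chrom": "chr1", "start": 0, "end": 100,
                            "fold": fold, "padj": padj, "reads_up": reads}])
        assert stringency_bands(df).iloc[0].band == expected
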