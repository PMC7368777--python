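import re

import numpy as np
import pandas as pd
import pytest

from chromloop.fourc import (
    FourCProfile,
    FragmentMap,
    ReducedGenome,
    ViewpointSpec,
    call_interactions,
    compare_sexes,
    demultiplex_and_trim,
    find_cut_sites,
    iterative_map,
    normalize_and_merge,
    sliding_median,
    smooth_profile,
    viewpoint_mask,
    write_bedgraph,
)


def random_seq(rng, n):
    return "".join(rng.choice(list("ACGT"), size=n))


def make_viewpoint(fm, chrom="chr1", pos=None, primer="ACGT" * 5):
    pos = pos if pos is not None else fm.chrom_lengths[chrom] // 2
    return ViewpointSpec("vp", primer, fm.fragment_at(chrom, pos), chrom, pos)


class TestCutSites:
    @pytest.mark.parametrize("seq,expected", [
        ("AAGATCAA", [2]),
        ("GATCGATC", [0, 4]),
        ("GATGATC", [3]),
        ("AAAA", []),
    ])
    def test_examples(self, seq, expected):
        assert find_cut_sites(seq).tolist() == expected

    def test_matches_regex_scan_on_random_sequence(self, rng):
        seq = random_seq(rng, 100_000)
        expected = [m.start() for m in re.finditer("(?=GATC)", seq)]
        assert find_cut_sites(seq).tolist() == expected

    def test_uncut_chromosome_flagged(self):
        fm = FragmentMap({"chr1": "ACGT" * 100})
        assert fm.uncut_chroms == ["chr1"]
        assert len(fm.fragments) == 1


class TestReducedGenome:
    def test_flank_coordinates(self, rng):
        seq = random_seq(rng, 10_000)
        seq = seq[:150] + "GATC" + seq[154:]
        seq = re.sub("GATC", "GGTC", seq[:150]) + seq[150:154] + re.sub("GATC", "GGTC", seq[154:])
        fm = FragmentMap({"chr1": seq})
        assert fm.cut_sites["chr1"].tolist() == [150]
        red = ReducedGenome({"chr1": seq}, fm)
        spans = {(e.interval.start, e.interval.end, e.side) for e in red.entries}
        assert (45, 150, "upstream") in spans
        assert (154, 259, "downstream") in spans

    def test_boundary_truncation(self, rng):
        seq = "A" * 50 + "GATC" + random_seq(rng, 500).replace("GATC", "GGTC")
        fm = FragmentMap({"chr1": seq})
        assert 50 in fm.cut_sites["chr1"]
        red = ReducedGenome({"chr1": seq}, fm)
        up = [e for e in red.entries if e.side == "upstream" and e.interval.end == 50]
        assert up and up[0].interval.start == 0 and len(up[0].sequence) == 50

    def test_entry_count_is_twice_cut_sites(self, small_truth):
        red = small_truth.reduced_genome()
        n_cuts = sum(len(c) for c in small_truth.cut_sites.values())
        # all planted cut sites sit away from chromosome ends
        assert len(red.entries) == 2 * n_cuts

    def test_round_trip_every_flank_maps_to_itself(self, small_truth):
        """Each entry's own sequence maps uniquely back to its origin entry
        (duplicated-sequence twins are legitimately ambiguous)."""
        red = small_truth.reduced_genome()
        seqs = {}
        for i, e in enumerate(red.entries):
            seqs.setdefault(e.sequence[: len(e.sequence)], []).append(i)
        n_checked = 0
        for i, e in enumerate(red.entries):
            if len(e.sequence) < 20:
                continue
            idx, iteration = red.map_read(e.sequence)
            if len(seqs[e.sequence]) == 1:
                assert idx == i
                assert iteration == 0
                n_checked += 1
            else:
                assert idx == ReducedGenome.UNMAPPED
        assert n_checked >= 0.99 * len(red.entries)


class TestDemultiplex:
    PRIMER_A = "A" * 20
    PRIMER_B = "C" * 20

    def _vps(self, fm):
        return [
            ViewpointSpec("a", self.PRIMER_A, 0, "chr1", 10),
            ViewpointSpec("b", self.PRIMER_B, 0, "chr1", 10),
        ]

    def test_exact_match_and_trim(self, rng, small_truth):
        fm = small_truth.fragment_map()
        insert = random_seq(rng, 105)
        reads = [self.PRIMER_A + insert]
        out, unassigned = demultiplex_and_trim(reads, self._vps(fm))
        assert out["a"] == [insert]
        assert unassigned == 0

    def test_single_mismatch_unassigned(self, rng, small_truth):
        fm = small_truth.fragment_map()
        read = "G" + self.PRIMER_A[1:] + random_seq(rng, 105)
        out, unassigned = demultiplex_and_trim([read], self._vps(fm))
        assert unassigned == 1

    def test_150nt_reads_trimmed_to_105(self, rng, small_truth):
        fm = small_truth.fragment_map()
        read = self.PRIMER_A + random_seq(rng, 130)  # 150 nt library
        out, _ = demultiplex_and_trim([read], self._vps(fm))
        assert len(out["a"][0]) == 105

    def test_duplicate_primers_rejected(self, small_truth):
        fm = small_truth.fragment_map()
        vps = [ViewpointSpec("a", self.PRIMER_A, 0, "chr1", 10),
               ViewpointSpec("b", self.PRIMER_A, 0, "chr1", 10)]
        with pytest.raises(ValueError):
            demultiplex_and_trim([], vps)


class TestIterativeMapping:
    def test_junction_read_rescued_to_first_fragment(self, small_truth):
        red = small_truth.reduced_genome()
        a, b = red.entries[10], red.entries[400]
        read = a.sequence[:52] + b.sequence[:53]
        idx, iteration = red.map_read(read)
        assert red.entries[idx] is a
        assert 1 <= iteration <= 6  # trimmed from 105 by 10 nt steps to <= 45

    def test_short_read_step_is_two(self, small_truth):
        red = small_truth.reduced_genome()
        a = red.entries[20]
        tail = "".join("A" if c != "A" else "C" for c in a.sequence[26:30])
        read = a.sequence[:26] + tail  # 30 nt whose junction tail cannot match
        idx, iteration = red.map_read(read)
        assert red.entries[idx] is a
        assert iteration == 2  # 30 -> 28 -> 26

    def test_ambiguous_read_never_counted(self, rng):
        seq_core = random_seq(rng, 105)
        spacer1 = random_seq(rng, 300)
        spacer2 = random_seq(rng, 300)
        genome = {"chr1": (spacer1 + "GATC" + seq_core + spacer2
                           + "GATC" + seq_core + spacer1)}
        genome["chr1"] = genome["chr1"]  # two identical downstream flanks
        fm = FragmentMap({"chr1": re.sub("GATC", "GGTC", spacer1) + "GATC" + seq_core
                          + re.sub("GATC", "GGTC", spacer2) + "GATC" + seq_core
                          + re.sub("GATC", "GGTC", spacer1)})
        g = {"chr1": re.sub("GATC", "GGTC", spacer1) + "GATC" + seq_core
             + re.sub("GATC", "GGTC", spacer2) + "GATC" + seq_core
             + re.sub("GATC", "GGTC", spacer1)}
        red = ReducedGenome(g, fm)
        counts, stats, assigned = iterative_map([seq_core], red)
        assert assigned[0] == ReducedGenome.UNMAPPED
        assert counts.sum() == 0


class TestSmoothing:
    def test_constant_profile_unchanged(self):
        assert np.allclose(sliding_median(np.full(50, 3.5), 11), 3.5)

    def test_single_spike_removed(self):
        v = np.zeros(41)
        v[20] = 100.0
        sm = sliding_median(v, 11)
        assert np.allclose(sm[5:-5], 0.0)

    def test_even_window_rejected(self):
        with pytest.raises(ValueError):
            sliding_median(np.zeros(5), 4)

    def test_matches_brute_force_everywhere(self, rng):
        v = rng.exponential(5.0, size=301)
        sm = sliding_median(v, 11)
        for i in range(v.size):
            k = min(5, i, v.size - 1 - i)
            assert sm[i] == np.median(v[i - k : i + k + 1])

    def test_smooth_profile_respects_chromosome_boundaries(self, small_truth):
        fm = small_truth.fragment_map()
        prof = FourCProfile(fm, np.arange(fm.n_fragments(), dtype=float), 1_000)
        smooth_profile(prof, 11)
        assert prof.smoothed is not None and prof.smoothed.size == fm.n_fragments()


class TestNormalizeAndMerge:
    def _profile(self, fm, counts, total):
        return FourCProfile(fm, counts, total)

    def test_median_merge(self, small_truth):
        fm = small_truth.fragment_map()
        n = fm.n_fragments()
        vp = small_truth.viewpoint
        profs = [self._profile(fm, np.full(n, v, dtype=float), 1_000_000)
                 for v in (1.0, 2.0, 9.0)]
        merged = normalize_and_merge(profs, vp)
        mask = merged.viewpoint_masked
        assert np.allclose(merged.smoothed[~mask], 2.0)
        assert np.isnan(merged.smoothed[mask]).all()

    def test_single_replicate_identity(self, small_truth):
        fm = small_truth.fragment_map()
        n = fm.n_fragments()
        prof = self._profile(fm, np.arange(n, dtype=float), 500_000)
        merged = normalize_and_merge([prof], small_truth.viewpoint)
        mask = merged.viewpoint_masked
        assert np.allclose(merged.smoothed[~mask], prof.smoothed[~mask])

    def test_rpm_invariance_to_depth(self, small_truth):
        fm = small_truth.fragment_map()
        n = fm.n_fragments()
        counts = np.arange(n, dtype=float)
        a = self._profile(fm, counts, int(counts.sum()))
        b = self._profile(fm, counts * 2, int(counts.sum() * 2))
        assert np.allclose(a.rpm, b.rpm)

    def test_zero_read_replicate_dropped(self, small_truth):
        fm = small_truth.fragment_map()
        n = fm.n_fragments()
        good = self._profile(fm, np.ones(n), 1_000)
        empty = self._profile(fm, np.zeros(n), 0)
        merged = normalize_and_merge([good, empty], small_truth.viewpoint)
        mask = merged.viewpoint_masked
        assert np.allclose(merged.smoothed[~mask], good.smoothed[~mask])
        with pytest.raises(ValueError):
            normalize_and_merge([empty], small_truth.viewpoint)


class TestInteractionCalling:
    def _decay_profile(self, truth, boost_regions=(), noise=None, seed=0):
        """A profile lying exactly on a power-law decay curve, optionally
        boosted over given (start, end, fold) regions."""
        fm = truth.fragment_map()
        frag = fm.fragments
        vp = truth.viewpoint
        mids = ((frag.start + frag.end) // 2).to_numpy()
        vals = np.zeros(len(frag))
        cis = (frag.chrom == vp.chrom).to_numpy()
        d = np.abs(mids - vp.position) + 2_000
        vals[cis] = 1e7 * d[cis] ** -1.0
        for start, end, fold in boost_regions:
            sel = cis & (mids >= start) & (mids < end)
            vals[sel] *= fold
        if noise is not None:
            rng = np.random.default_rng(seed)
            vals = rng.poisson(vals).astype(float)
        prof = FourCProfile(fm, vals, int(vals.sum()))
        prof.rpm = vals  # treat as already normalized
        smooth_profile(prof)
        prof.viewpoint_masked = viewpoint_mask(fm, vp)
        prof.smoothed = np.where(prof.viewpoint_masked, np.nan, prof.smoothed)
        return prof

    def test_pure_decay_profile_gives_no_calls(self, small_truth):
        prof = self._decay_profile(small_truth)
        res = call_interactions(prof, small_truth.viewpoint)
        assert len(res.calls) == 0
        tested = res.fragment_stats.dropna(subset=["z"])
        assert np.nanmax(np.abs(tested.z)) < 3 or (tested.fdr > 0.05).all()

    def test_planted_block_called(self, small_truth):
        vp = small_truth.viewpoint
        region = (vp.position + 40_000, vp.position + 44_000, 5.0)
        prof = self._decay_profile(small_truth, [region], noise=True, seed=4)
        res = call_interactions(prof, vp)
        assert len(res.calls) >= 1
        hit = ((res.calls.start < region[1]) & (res.calls.end > region[0])).any()
        assert hit

    def test_summary_mentions_viewpoint(self, small_truth):
        prof = self._decay_profile(small_truth)
        res = call_interactions(prof, small_truth.viewpoint)
        assert small_truth.viewpoint.name in res.summary()


class TestCompareSexes:
    def _profiles(self, truth, scales, seed=0):
        fm = truth.fragment_map()
        n = fm.n_fragments()
        rng = np.random.default_rng(seed)
        base = rng.uniform(10, 100, size=n)
        out = []
        for s in scales:
            counts = rng.poisson(base * s)
            out.append(FourCProfile(fm, counts, int(counts.sum())))
        return out

    def test_identical_relabeled_replicates_never_called(self, small_truth):
        profs = self._profiles(small_truth, [1, 1, 1])
        regions = pd.DataFrame([{"chrom": "chr1", "start": 10_000, "end": 14_000}])
        res = compare_sexes(profs, list(profs), regions)
        assert (res.sex_differential_fdr >= 0.999).all()

    def test_depth_rescaling_does_not_create_calls(self, small_truth):
        profs = self._profiles(small_truth, [1, 1, 1])
        doubled = [FourCProfile(p.fragment_map, p.raw_count * 2, p.total_mapped * 2)
                   for p in profs]
        regions = pd.DataFrame([{"chrom": "chr1", "start": 10_000, "end": 14_000}])
        res = compare_sexes(profs, doubled, regions)
        assert (res.sex_differential_fdr > 0.1).all()

    def test_single_replicate_fallback_flagged(self, small_truth):
        profs = self._profiles(small_truth, [1, 1, 1])
        regions = pd.DataFrame([{"chrom": "chr1", "start": 10_000, "end": 14_000}])
        res = compare_sexes(profs[:1], profs[1:], regions)
        assert res.fallback.all()
        assert res.p.isna().all()


def test_bedgraph_output(tmp_path, small_truth):
    fm = small_truth.fragment_map()
    prof = FourCProfile(fm, np.ones(fm.n_fragments()), 1_000)
    smooth_profile(prof)
    path = tmp_path / "x.bedgraph"
    write_bedgraph(prof, path, which="smoothed")
    df = pd.read_csv(path, sep="\t", header=None)
    assert len(df) == fm.n_fragments()
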