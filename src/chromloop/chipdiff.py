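"""Differential ChIP-seq binding: peak calling, RIPM/FRiP normalization,
windowed negative-binomial sex comparison, and the standard/lenient filter
cascade.

The discovery route is: call peaks per factor (or import an external peak
BED), tile the genome in 200-bp sliding windows (step = half window), test
each window's male vs female replicate counts with a moment-matched
negative-binomial Wald test, merge adjacent significant windows into sites,
then apply the standard-stringency filters (union-peak overlap, >= 10 reads,
> 2-fold, FDR < 0.05). A lenient tier is added by an MA-normalization
comparison of FRiP-matched merged samples.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .intervals import GenomicInterval, IntervalCollection
from .stats import bh_fdr

LOG2 = np.log(2.0)


# ---------------------------------------------------------------------------
# read samples


@dataclass
class ReadSample:
    """Aligned reads for one replicate: per-chromosome (start, end) arrays,
    kept sorted by start."""

    factor: str
    sex: str
    replicate_id: str
    reads: dict[str, np.ndarray]  # chrom -> (n, 2) int array
    total_mapped: int = 0

    def __post_init__(self):
        total = 0
        for chrom, arr in self.reads.items():
            arr = np.asarray(arr, dtype=np.int64).reshape(-1, 2)
            order = np.argsort(arr[:, 0], kind="stable")
            self.reads[chrom] = arr[order]
            total += arr.shape[0]
        self.total_mapped = total

    @classmethod
    def from_bed(cls, path, factor: str, sex: str, replicate_id: str) -> "ReadSample":
        """Load aligned reads from a BED3+ file of read intervals."""
        from .intervals import read_bed

        df = read_bed(path)
        reads = {
            str(chrom): sub[["start", "end"]].to_numpy(dtype=np.int64)
            for chrom, sub in df.groupby("chrom")
        }
        return cls(factor, sex, replicate_id, reads)

    def midpoints(self, chrom: str) -> np.ndarray:
        arr = self.reads.get(chrom)
        if arr is None or arr.size == 0:
            return np.empty(0, dtype=np.int64)
        return (arr[:, 0] + arr[:, 1]) // 2

    def chrom_max(self) -> dict[str, int]:
        return {c: int(a[:, 1].max()) for c, a in self.reads.items() if a.size}


def merge_samples(samples: list[ReadSample], replicate_id: str = "merged") -> ReadSample:
    reads: dict[str, list[np.ndarray]] = {}
    for s in samples:
        for chrom, arr in s.reads.items():
            reads.setdefault(chrom, []).append(arr)
    merged = {c: np.vstack(arrs) for c, arrs in reads.items()}
    s0 = samples[0]
    return ReadSample(s0.factor, s0.sex, replicate_id, merged)


def merge_intervals(df: pd.DataFrame) -> pd.DataFrame:
    """Merge overlapping/abutting intervals per chromosome."""
    rows = []
    for chrom, sub in df.groupby("chrom", sort=True):
        sub = sub.sort_values("start")
        cur_s, cur_e = None, None
        for r in sub.itertuples():
            if cur_s is None:
                cur_s, cur_e = r.start, r.end
            elif r.start <= cur_e:
                cur_e = max(cur_e, r.end)
            else:
                rows.append((chrom, cur_s, cur_e))
                cur_s, cur_e = r.start, r.end
        if cur_s is not None:
            rows.append((chrom, cur_s, cur_e))
    return pd.DataFrame(rows, columns=["chrom", "start", "end"])


def count_reads_in_intervals(sample: ReadSample, intervals: pd.DataFrame) -> np.ndarray:
    """Reads overlapping (>= 1 bp) each interval."""
    out = np.zeros(len(intervals), dtype=np.int64)
    intervals = intervals.reset_index(drop=True)
    for chrom, sub in intervals.groupby("chrom"):
        arr = sample.reads.get(chrom)
        if arr is None or arr.size == 0:
            continue
        starts = arr[:, 0]
        ends_sorted = np.sort(arr[:, 1])
        s = sub.start.to_numpy()
        e = sub.end.to_numpy()
        n_start_before = np.searchsorted(starts, e, side="left")
        n_end_at_or_before = np.searchsorted(ends_sorted, s, side="right")
        out[sub.index.to_numpy()] = n_start_before - n_end_at_or_before
    return out


def reads_in_peaks(sample: ReadSample, union_peaks: pd.DataFrame) -> tuple[int, np.ndarray | None]:
    """Number of reads overlapping any (merged) union peak.

    Also returns, per chromosome concatenated in sample order, a boolean
    in-peak mask (used for stratified down-sampling)."""
    merged = merge_intervals(union_peaks)
    total_in = 0
    masks: dict[str, np.ndarray] = {}
    for chrom, arr in sample.reads.items():
        sub = merged[merged.chrom == chrom]
        if len(sub) == 0 or arr.size == 0:
            masks[chrom] = np.zeros(arr.shape[0], dtype=bool)
            continue
        pstarts = sub.start.to_numpy()
        pends = sub.end.to_numpy()
        j = np.searchsorted(pstarts, arr[:, 1], side="left") - 1
        ok = j >= 0
        in_peak = np.zeros(arr.shape[0], dtype=bool)
        in_peak[ok] = pends[j[ok]] > arr[ok, 0]
        masks[chrom] = in_peak
        total_in += int(in_peak.sum())
    return total_in, masks


# ---------------------------------------------------------------------------
# peak calling (simplified windowed Poisson caller; external peak BEDs can be
# used instead anywhere a peak DataFrame is accepted)


def call_peaks(samples, p_threshold: float = 1e-5, window: int = 200,
               step: int = 50, chrom_lengths: dict[str, int] | None = None) -> pd.DataFrame:
    """Windowed Poisson-enrichment peak caller over pooled samples.

    Windows of ``window`` bp (step ``step``) whose pooled read-midpoint count
    exceeds a uniform-background Poisson expectation at p < ``p_threshold``
    are merged into peaks; the summit is the maximum-count fine bin.
    """
    if isinstance(samples, ReadSample):
        samples = [samples]
    pooled = merge_samples(samples) if len(samples) > 1 else samples[0]
    if pooled.total_mapped == 0:
        return pd.DataFrame(columns=["chrom", "start", "end", "summit", "count", "p"])
    if chrom_lengths is None:
        chrom_lengths = pooled.chrom_max()
    genome_len = sum(chrom_lengths.values())
    lam = pooled.total_mapped * window / genome_len
    nbin_per_win = max(1, window // step)
    rows = []
    for chrom, L in chrom_lengths.items():
        mids = pooled.midpoints(chrom)
        if mids.size == 0:
            continue
        nbins = int(np.ceil(L / step))
        hist = np.bincount(np.clip(mids // step, 0, nbins - 1), minlength=nbins)
        win_counts = np.convolve(hist, np.ones(nbin_per_win, dtype=int), mode="valid")
        pvals = sps.poisson.sf(win_counts - 1, lam)
        sig = np.nonzero(pvals < p_threshold)[0]
        if sig.size == 0:
            continue
        # merge windows whose spans overlap
        groups = [[int(sig[0])]]
        for a, b in zip(sig[:-1], sig[1:]):
            if (b - a) * step < window:
                groups[-1].append(int(b))
            else:
                groups.append([int(b)])
        for g in groups:
            start = g[0] * step
            end = min(L, g[-1] * step + window)
            fine = hist[start // step : int(np.ceil(end / step))]
            summit = start + (int(np.argmax(fine)) * step) + step // 2
            cnt = int(hist[start // step : int(np.ceil(end / step))].sum())
            rows.append((chrom, start, end, summit, cnt,
                         float(pvals[g].min())))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "summit", "count", "p"])


def filter_artifact_peaks(peaks: pd.DataFrame, samples: list[ReadSample],
                          blacklist: IntervalCollection | None = None) -> pd.DataFrame:
    """Drop peaks whose signal is exclusively a PCR-duplicate stack: >= 5
    identical-coordinate reads with no other overlapping read. Also drops
    peaks intersecting the blacklist."""
    keep = np.ones(len(peaks), dtype=bool)
    by_chrom: dict[str, np.ndarray] = {}
    for s in samples:
        for chrom, arr in s.reads.items():
            by_chrom.setdefault(chrom, []).append(arr)
    by_chrom = {c: np.vstack(a)[np.argsort(np.vstack(a)[:, 0], kind="stable")]
                for c, a in by_chrom.items()}
    for i, r in enumerate(peaks.itertuples()):
        if blacklist is not None and blacklist.any_overlap(
            GenomicInterval(r.chrom, int(r.start), int(r.end))
        ):
            keep[i] = False
            continue
        arr = by_chrom.get(r.chrom)
        if arr is None or arr.size == 0:
            continue
        starts = arr[:, 0]
        lo = np.searchsorted(starts, r.start - 10_000, side="left")
        hi = np.searchsorted(starts, r.end, side="left")
        cand = arr[lo:hi]
        cand = cand[cand[:, 1] > r.start]
        if cand.shape[0] == 0:
            continue
        uniq = np.unique(cand, axis=0)
        if uniq.shape[0] == 1 and cand.shape[0] >= 5:
            # verify no other read overlaps the stack itself
            s0, e0 = int(uniq[0, 0]), int(uniq[0, 1])
            lo2 = np.searchsorted(starts, s0 - 10_000, side="left")
            hi2 = np.searchsorted(starts, e0, side="left")
            over = arr[lo2:hi2]
            over = over[over[:, 1] > s0]
            if np.unique(over, axis=0).shape[0] == 1:
                keep[i] = False
    return peaks[keep].reset_index(drop=True)


# ---------------------------------------------------------------------------
# RIPM / FRiP


@dataclass(frozen=True)
class SampleQC:
    frip: float
    reads_in_peaks: int
    total_mapped: int
    downsample_factor: float = 1.0

    @property
    def ripm_divisor(self) -> float:
        """Reads-in-peaks per million: normalization divisor for signal."""
        return self.reads_in_peaks / 1e6


def compute_ripm(sample: ReadSample, union_peaks: pd.DataFrame) -> SampleQC:
    rip, _ = reads_in_peaks(sample, union_peaks)
    if rip == 0:
        raise ValueError("degenerate sample: zero reads in peaks")
    return SampleQC(frip=rip / sample.total_mapped, reads_in_peaks=rip,
                    total_mapped=sample.total_mapped)


def ripm_peak_signal(sample: ReadSample, peaks: pd.DataFrame,
                     qc: SampleQC | None = None,
                     union_peaks: pd.DataFrame | None = None) -> np.ndarray:
    """Per-peak signal in reads-in-peaks-per-million units (in-peak read
    count divided by the sample's RIPM divisor)."""
    if qc is None:
        qc = compute_ripm(sample, peaks if union_peaks is None else union_peaks)
    counts = count_reads_in_intervals(sample, peaks)
    return counts / qc.ripm_divisor


def frip_downsample(merged_male: ReadSample, merged_female: ReadSample,
                    union_peaks: pd.DataFrame, seed: int = 0):
    """Down-sample the merged sample with more reads-in-peaks so both sexes
    carry the same number of reads in peaks (within rounding).

    Stratified exact subsampling: in-peak reads of the larger sample are
    subsampled to exactly the smaller sample's in-peak count, out-of-peak
    reads by the same factor. Returns (male, female, factors dict).
    """
    rng = np.random.default_rng(seed)
    rip_m, mask_m = reads_in_peaks(merged_male, union_peaks)
    rip_f, mask_f = reads_in_peaks(merged_female, union_peaks)
    factors = {"M": 1.0, "F": 1.0}
    if rip_m == rip_f:
        return merged_male, merged_female, factors
    if rip_m > rip_f:
        big, small_rip, masks, key = merged_male, rip_f, mask_m, "M"
    else:
        big, small_rip, masks, key = merged_female, rip_m, mask_f, "F"
    big_rip = max(rip_m, rip_f)
    factor = small_rip / big_rip
    factors[key] = factor
    new_reads: dict[str, np.ndarray] = {}
    # allocate the exact in-peak target proportionally across chromosomes
    chroms = list(big.reads.keys())
    rip_per_chrom = np.array([int(masks[c].sum()) for c in chroms])
    targets = np.floor(rip_per_chrom * factor).astype(int)
    deficit = small_rip - int(targets.sum())
    # distribute the rounding deficit to chromosomes with the largest remainder
    remainders = rip_per_chrom * factor - np.floor(rip_per_chrom * factor)
    for i in np.argsort(-remainders)[: max(0, deficit)]:
        targets[i] += 1
    for c, target_in in zip(chroms, targets):
        arr = big.reads[c]
        in_mask = masks[c]
        in_idx = np.nonzero(in_mask)[0]
        out_idx = np.nonzero(~in_mask)[0]
        keep_in = rng.choice(in_idx, size=min(int(target_in), in_idx.size),
                             replace=False) if in_idx.size else np.empty(0, int)
        n_out = int(round(out_idx.size * factor))
        keep_out = rng.choice(out_idx, size=min(n_out, out_idx.size),
                              replace=False) if out_idx.size else np.empty(0, int)
        keep = np.sort(np.concatenate([keep_in, keep_out]).astype(int))
        new_reads[c] = arr[keep]
    downsampled = ReadSample(big.factor, big.sex, big.replicate_id + "_ds", new_reads)
    if key == "M":
        return downsampled, merged_female, factors
    return merged_male, downsampled, factors


# ---------------------------------------------------------------------------
# windowed negative-binomial differential test


def pooled_nb_dispersion(counts_a: np.ndarray, counts_b: np.ndarray) -> float:
    """Moment-matched pooled NB dispersion (variance = mean + alpha * mean^2)
    across windows and groups.

    The denominator estimates sum(mu^2) unbiasedly as sum(mbar^2 - s^2/n);
    the naive sum(mbar^2) is inflated by the sampling variance of the group
    mean and biases the dispersion downward."""
    alpha, _ = _pooled_nb_dispersion_se(counts_a, counts_b)
    return alpha


def _pooled_nb_dispersion_se(counts_a: np.ndarray, counts_b: np.ndarray):
    """Pooled dispersion estimate with a window-level delta-method standard
    error (windows treated as independent)."""
    u = v = None
    for c in (counts_a, counts_b):
        n = c.shape[1]
        if n < 2:
            continue
        m = c.mean(axis=1)
        s2 = c.var(axis=1, ddof=1)
        uw = np.where(m > 0, s2 - m, 0.0)
        vw = np.where(m > 0, m ** 2 - s2 / n, 0.0)
        u = uw if u is None else u + uw
        v = vw if v is None else v + vw
    if u is None or float(v.sum()) <= 0:
        return 0.0, 0.0
    den = float(v.sum())
    alpha = max(0.0, float(u.sum()) / den)
    se = float(np.sqrt(np.sum((u - alpha * v) ** 2))) / den
    return alpha, se


def _betabinom_exact_p(sa: np.ndarray, total: np.ndarray, a: float, b: float,
                       chunk: int = 512) -> np.ndarray:
    """Exact two-sided conditional p-values.

    If the group sums are negative binomial with a shared success
    probability, the first group's sum given the window total follows a
    beta-binomial (negative hypergeometric) law BB(total, a, b) with shape
    parameters a = n_a/alpha and b = n_b/alpha. The two-sided p sums the
    probabilities of all outcomes no more likely than the observed one
    (minimum-likelihood method, as in Fisher's exact test).
    """
    from scipy.special import gammaln

    sa = np.asarray(sa, dtype=np.int64)
    total = np.asarray(total, dtype=np.int64)
    p_out = np.ones(sa.size, dtype=float)
    const = gammaln(a + b) - gammaln(a) - gammaln(b)
    for lo in range(0, sa.size, chunk):
        hi = min(lo + chunk, sa.size)
        T = total[lo:hi]
        s = sa[lo:hi]
        tmax = int(T.max()) if T.size else 0
        x = np.arange(tmax + 1)
        Tc = T[:, None]
        with np.errstate(invalid="ignore"):
            logpmf = (
                gammaln(Tc + 1) - gammaln(x + 1) - gammaln(np.maximum(Tc - x, 0) + 1)
                + gammaln(x + a) + gammaln(Tc - x + b) - gammaln(Tc + a + b)
                + const
            )
        logpmf = np.where(x > Tc, -np.inf, logpmf)
        obs = logpmf[np.arange(T.size), s]
        le = logpmf <= obs[:, None] + 1e-10
        pmf = np.exp(logpmf, where=np.isfinite(logpmf), out=np.zeros_like(logpmf))
        p_out[lo:hi] = np.minimum(1.0, (pmf * le).sum(axis=1))
    return p_out


def negbin_ratio_test(counts_a: np.ndarray, counts_b: np.ndarray,
                      dispersion: float | None = None, pseudo: float = 0.5,
                      min_dispersion: float = 1e-6):
    """Per-window negative-binomial comparison of two replicate groups.

    ``counts_a``/``counts_b`` are (n_windows, n_replicates). The dispersion
    (variance = mean + alpha * mean^2) is moment-matched pooled across
    windows; p-values come from the exact beta-binomial conditional test of
    the group-A sum given the window total (assumes comparable per-replicate
    depths, as in a balanced design); the reported z is a delta-method Wald
    statistic on the log ratio of group means, used for direction and
    diagnostics.

    Returns (p, z, log2_ratio, dispersion).
    """
    counts_a = np.atleast_2d(np.asarray(counts_a, dtype=float))
    counts_b = np.atleast_2d(np.asarray(counts_b, dtype=float))
    na, nb = counts_a.shape[1], counts_b.shape[1]
    if dispersion is None:
        # conservative plug-in: point estimate + 2 SE, so p-values stay
        # valid under dispersion-estimation uncertainty
        est, se = _pooled_nb_dispersion_se(counts_a, counts_b)
        dispersion = est
        test_dispersion = est + 2.0 * se
    else:
        test_dispersion = dispersion
    ma = counts_a.mean(axis=1)
    mb = counts_b.mean(axis=1)
    var_a = (1.0 / (ma + pseudo) + test_dispersion) / na
    var_b = (1.0 / (mb + pseudo) + test_dispersion) / nb
    diff = np.log(ma + pseudo) - np.log(mb + pseudo)
    z = diff / np.sqrt(var_a + var_b)
    alpha = max(test_dispersion, min_dispersion)
    sa = counts_a.sum(axis=1).round().astype(np.int64)
    sb = counts_b.sum(axis=1).round().astype(np.int64)
    p = _betabinom_exact_p(sa, sa + sb, na / alpha, nb / alpha)
    return p, z, diff / LOG2, dispersion


@dataclass
class DifferentialBindingResults:
    """Windowed differential-binding fit: per-window table, merged sites,
    pooled dispersion, and the standard-stringency filter."""

    windows: pd.DataFrame
    sites: pd.DataFrame
    dispersion: float
    model: "DifferentialBindingModel"
    fallback: bool = False

    def filter_standard(self, union_peaks: pd.DataFrame, min_reads: int = 10,
                        min_fold: float = 2.0, max_fdr: float = 0.05) -> pd.DataFrame:
        return filter_standard(self.sites, union_peaks, min_reads=min_reads,
                               min_fold=min_fold, max_fdr=max_fdr)

    def summary(self) -> str:
        n_sig = int((self.sites.fdr < 0.05).sum()) if len(self.sites) else 0
        return "\n".join(
            [
                "Windowed differential binding (male vs female)",
                f"  windows tested: {len(self.windows)}",
                f"  pooled NB dispersion: {self.dispersion:.4f}",
                f"  merged sites: {len(self.sites)} ({n_sig} at FDR < 0.05)",
                f"  exact-test fallback: {self.fallback}",
            ]
        )


class DifferentialBindingModel:
    """Sliding-window negative-binomial comparison of male vs female
    replicate read counts (200-bp windows, step = half window by default)."""

    def __init__(self, male_samples: list[ReadSample], female_samples: list[ReadSample],
                 window_size: int = 200, step: int | None = None,
                 chrom_lengths: dict[str, int] | None = None,
                 site_fdr: float = 0.05):
        self.male_samples = male_samples
        self.female_samples = female_samples
        self.window_size = window_size
        self.step = step or window_size // 2
        self.site_fdr = site_fdr
        if chrom_lengths is None:
            chrom_lengths = {}
            for s in male_samples + female_samples:
                for c, mx in s.chrom_max().items():
                    chrom_lengths[c] = max(chrom_lengths.get(c, 0), mx)
        self.chrom_lengths = chrom_lengths

    def _window_counts(self, sample: ReadSample, chrom: str, n_windows: int) -> np.ndarray:
        L = self.chrom_lengths[chrom]
        nbins = int(np.ceil(L / self.step))
        mids = sample.midpoints(chrom)
        hist = np.bincount(np.clip(mids // self.step, 0, nbins - 1), minlength=nbins)
        k = max(1, self.window_size // self.step)
        win = np.convolve(hist, np.ones(k, dtype=int), mode="full")[k - 1 : k - 1 + nbins]
        return win[:n_windows]

    def fit(self) -> DifferentialBindingResults:
        frames = []
        for chrom, L in sorted(self.chrom_lengths.items()):
            n_windows = int(np.ceil(L / self.step))
            cm = np.column_stack(
                [self._window_counts(s, chrom, n_windows) for s in self.male_samples]
            )
            cf = np.column_stack(
                [self._window_counts(s, chrom, n_windows) for s in self.female_samples]
            )
            starts = np.arange(n_windows) * self.step
            frames.append(
                pd.DataFrame(
                    {
                        "chrom": chrom,
                        "start": starts,
                        "end": np.minimum(starts + self.window_size, L),
                        **{f"m{i}": cm[:, i] for i in range(cm.shape[1])},
                        **{f"f{i}": cf[:, i] for i in range(cf.shape[1])},
                    }
                )
            )
        win = pd.concat(frames, ignore_index=True)
        mcols = [c for c in win.columns if c.startswith("m") and c != "m"]
        fcols = [c for c in win.columns if c.startswith("f") and c != "f"]
        cm = win[mcols].to_numpy(dtype=float)
        cf = win[fcols].to_numpy(dtype=float)
        total = cm.sum(axis=1) + cf.sum(axis=1)
        tested = total > 0
        win = win[tested].reset_index(drop=True)
        cm, cf = cm[tested], cf[tested]
        fallback = cm.shape[1] < 2 or cf.shape[1] < 2
        if fallback:
            depth_m = sum(s.total_mapped for s in self.male_samples)
            depth_f = sum(s.total_mapped for s in self.female_samples)
            p, z, log2fc = _exact_binomial_fallback(cm.sum(1), cf.sum(1),
                                                    depth_m, depth_f)
            dispersion = np.nan
        else:
            p, z, log2fc, dispersion = negbin_ratio_test(cm, cf)
        win["counts_m"] = cm.sum(axis=1).astype(int)
        win["counts_f"] = cf.sum(axis=1).astype(int)
        win["log2_mf"] = log2fc
        win["z"] = z
        win["p"] = p
        win["fdr"] = bh_fdr(p)
        sites = self._merge_sites(win)
        return DifferentialBindingResults(win, sites, float(dispersion)
                                          if dispersion == dispersion else np.nan,
                                          self, fallback=fallback)

    def _merge_sites(self, win: pd.DataFrame) -> pd.DataFrame:
        depth_m = sum(s.total_mapped for s in self.male_samples) or 1
        depth_f = sum(s.total_mapped for s in self.female_samples) or 1
        rows = []
        sig = win[(win.fdr < self.site_fdr)]
        for chrom, sub in sig.groupby("chrom"):
            sub = sub.sort_values("start")
            group: list[pd.Series] = []
            for _, r in sub.iterrows():
                if group and r.start < group[-1].end and np.sign(r.log2_mf) == np.sign(group[-1].log2_mf):
                    group.append(r)
                else:
                    if group:
                        rows.append(self._site_from_group(chrom, group, depth_m, depth_f))
                    group = [r]
            if group:
                rows.append(self._site_from_group(chrom, group, depth_m, depth_f))
        cols = ["chrom", "start", "end", "log2_mf", "counts_m", "counts_f",
                "p", "fdr", "direction"]
        return pd.DataFrame(rows, columns=cols)

    def _site_from_group(self, chrom, group, depth_m, depth_f):
        start = int(min(r.start for r in group))
        end = int(max(r.end for r in group))
        cm = self._recount(self.male_samples, chrom, start, end)
        cf = self._recount(self.female_samples, chrom, start, end)
        norm_ratio = ((cm + 0.5) / depth_m) / ((cf + 0.5) / depth_f)
        log2_mf = float(np.log2(norm_ratio))
        return {
            "chrom": chrom,
            "start": start,
            "end": end,
            "log2_mf": log2_mf,
            "counts_m": int(cm),
            "counts_f": int(cf),
            "p": float(min(r.p for r in group)),
            "fdr": float(min(r.fdr for r in group)),
            "direction": "male-biased" if log2_mf > 0 else "female-biased",
        }

    def _recount(self, samples, chrom, start, end) -> int:
        total = 0
        iv = pd.DataFrame({"chrom": [chrom], "start": [start], "end": [end]})
        for s in samples:
            total += int(count_reads_in_intervals(s, iv)[0])
        return total


def _exact_binomial_fallback(cm: np.ndarray, cf: np.ndarray, depth_m: int, depth_f: int):
    """1-vs-1 fallback: conditional binomial test of the male read share."""
    n = cm + cf
    pr = depth_m / (depth_m + depth_f)
    with np.errstate(divide="ignore", invalid="ignore"):
        lower = sps.binom.cdf(cm, n, pr)
        upper = sps.binom.sf(cm - 1, n, pr)
    p = np.minimum(1.0, 2 * np.minimum(lower, upper))
    log2fc = np.log2((cm + 0.5) / depth_m) - np.log2((cf + 0.5) / depth_f)
    z = sps.norm.isf(p / 2) * np.sign(log2fc)
    return p, z, log2fc


def diff_windows(male_reps: list[ReadSample], female_reps: list[ReadSample],
                 window_size: int = 200, **kwargs) -> DifferentialBindingResults:
    """Functional wrapper around :class:`DifferentialBindingModel`."""
    return DifferentialBindingModel(male_reps, female_reps,
                                    window_size=window_size, **kwargs).fit()


def filter_standard(sites: pd.DataFrame, union_peaks: pd.DataFrame,
                    min_reads: int = 10, min_fold: float = 2.0,
                    max_fdr: float = 0.05) -> pd.DataFrame:
    """Standard-stringency filter: >= 1 bp union-peak overlap, at least
    ``min_reads`` reads (summed over all replicates), strictly more than
    ``min_fold``-fold normalized sex difference, FDR < ``max_fdr``."""
    peaks_ic = IntervalCollection.from_dataframe(union_peaks) if len(union_peaks) else None
    out = sites.copy()
    tiers = []
    for r in out.itertuples():
        in_peak = peaks_ic is not None and peaks_ic.any_overlap(
            GenomicInterval(r.chrom, int(r.start), int(r.end))
        )
        enough_reads = (r.counts_m + r.counts_f) >= min_reads
        big_fold = 2 ** abs(r.log2_mf) > min_fold
        significant = r.fdr < max_fdr
        tiers.append("standard" if (in_peak and enough_reads and big_fold and significant)
                     else "rejected")
    out["tier"] = tiers
    return out


# ---------------------------------------------------------------------------
# MA normalization (lenient tier)


def manorm_lenient(matched_male: ReadSample, matched_female: ReadSample,
                   peaks: pd.DataFrame, standard_sites: pd.DataFrame | None = None,
                   min_fold: float = 2.0, max_padj: float = 0.01,
                   min_reads: int = 15, trim: float = 0.05,
                   min_common: int = 10, pseudo: float = 0.5):
    """MA comparison of FRiP-matched merged samples over a common peak list.

    M = log2 ratio and A = mean log2 intensity per peak; a least-squares line
    of M on A fitted over common peaks (both-sex occupancy, after trimming
    the ``trim`` fraction of extreme M values) is subtracted from M; p-values
    come from a normal approximation on the rescaled M. Lenient sites must
    show >= ``min_fold`` rescaled sex bias, BH-adjusted p < ``max_padj``, and
    more than ``min_reads`` reads in the upregulated sample; peaks already on
    the standard list are excluded.

    Returns (lenient_sites, ma_stats).
    """
    cm = count_reads_in_intervals(matched_male, peaks).astype(float)
    cf = count_reads_in_intervals(matched_female, peaks).astype(float)
    M = np.log2(cm + pseudo) - np.log2(cf + pseudo)
    A = 0.5 * (np.log2(cm + pseudo) + np.log2(cf + pseudo))
    common = (cm >= min_common) & (cf >= min_common)
    if common.sum() < 10:
        raise ValueError("fewer than 10 common peaks: MA rescaling is degenerate")
    Mc, Ac = M[common], A[common]
    lo, hi = np.quantile(Mc, [trim / 2, 1 - trim / 2])
    keep = (Mc >= lo) & (Mc <= hi)
    slope, intercept = np.polyfit(Ac[keep], Mc[keep], 1)
    m_rescaled = M - (intercept + slope * A)
    var_m = (1.0 / (cm + pseudo) + 1.0 / (cf + pseudo)) / (LOG2 ** 2)
    z = m_rescaled / np.sqrt(var_m)
    p = 2 * sps.norm.sf(np.abs(z))
    padj = bh_fdr(p)
    ma = peaks[["chrom", "start", "end"]].copy()
    ma["counts_m"] = cm.astype(int)
    ma["counts_f"] = cf.astype(int)
    ma["a_value"] = A
    ma["m_value"] = M
    ma["m_rescaled"] = m_rescaled
    ma["p"] = p
    ma["padj"] = padj
    reads_up = np.where(m_rescaled > 0, cm, cf)
    passing = (
        (np.abs(m_rescaled) >= np.log2(min_fold))
        & (padj < max_padj)
        & (reads_up > min_reads)
    )
    if standard_sites is not None and len(standard_sites):
        std_ic = IntervalCollection.from_dataframe(standard_sites)
        overlaps_std = np.array(
            [std_ic.any_overlap(GenomicInterval(r.chrom, int(r.start), int(r.end)))
             for r in ma.itertuples()]
        )
        passing &= ~overlaps_std
    lenient = ma[passing].copy()
    lenient["tier"] = "lenient"
    lenient["direction"] = np.where(lenient.m_rescaled > 0, "male-biased", "female-biased")
    return lenient.reset_index(drop=True), ma


def sex_independent_set(peaks: pd.DataFrame, n: int = 1000,
                        signal_m: str = "signal_m", signal_f: str = "signal_f",
                        eps: float = 1e-9) -> pd.DataFrame:
    """The ``n`` peaks whose male/female RIPM signal ratio is closest to 1
    (ties broken by stronger total signal)."""
    ratio = (peaks[signal_m] + eps) / (peaks[signal_f] + eps)
    key = np.abs(np.log(ratio))
    total = peaks[signal_m] + peaks[signal_f]
    order = np.lexsort((-total.to_numpy(), key.to_numpy()))
    return peaks.iloc[order[: min(n, len(peaks))]].reset_index(drop=True)


def stringency_bands(diff_peaks: pd.DataFrame, kind: str = "H3K27ac",
                     fold_col: str = "fold", padj_col: str = "padj",
                     reads_col: str = "reads_up", max_padj: float = 0.05,
                     min_reads: int = 15) -> pd.DataFrame:
    """Label significant sex-biased peaks strict / lenient / none by the fold
    band used for DHS and H3K27ac marks (M/F or F/M > 2.5 strict; > 1.5 but
    < 2.5 lenient), gated on adjusted p and upregulated read count."""
    out = diff_peaks.copy()
    f = out[fold_col].to_numpy(dtype=float)
    f = np.maximum(f, 1.0 / np.where(f > 0, f, np.inf))  # symmetric M/F or F/M
    gate = (out[padj_col].to_numpy() < max_padj) & (out[reads_col].to_numpy() > min_reads)
    band = np.full(len(out), "none", dtype=object)
    band[gate & (f > 1.5)] = "lenient"
    band[gate & (f > 2.5)] = "strict"
    out["band"] = band
    out["kind"] = kind
    return out
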