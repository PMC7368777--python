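"""4C-seq processing: reduced genome, iterative mapping, smoothing,
normalization, and interaction calling.

The pipeline mirrors standard viewpoint-based chromosome-conformation
analysis: the genome is digested in silico at every DpnII site (GATC), a
"reduced genome" of fixed-length flanks around each cut site serves as the
mapping target, reads failing to map full-length (multi-junction ligation
products) are 3'-trimmed iteratively and re-mapped, per-fragment signal is
median-smoothed and RPM-normalized, replicates are merged by median, and
interactions are called as fragments rising significantly above a fitted
distance-decay expectation (z > 3 at BH FDR < 0.05 by default).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .intervals import GenomicInterval
from .stats import bh_fdr

CUT_SEQ = "GATC"
DEFAULT_FLANK = 105
DEFAULT_MIN_LEN = 20
DEFAULT_SMOOTH_WINDOW = 11


# ---------------------------------------------------------------------------
# fragment map and reduced genome


def find_cut_sites(sequence: str, cut: str = CUT_SEQ) -> np.ndarray:
    """Start offsets of every (possibly overlapping) occurrence of ``cut``."""
    positions = []
    i = sequence.find(cut)
    while i != -1:
        positions.append(i)
        i = sequence.find(cut, i + 1)
    return np.array(positions, dtype=int)


class FragmentMap:
    """Restriction fragments per chromosome.

    Fragment boundaries are the *start* coordinates of consecutive cut-site
    matches, plus the chromosome termini; fragments tile each chromosome
    without overlap. Chromosomes without a cut site become one whole-length
    fragment and are flagged in ``uncut_chroms``.
    """

    def __init__(self, genome: dict[str, str], cut: str = CUT_SEQ):
        self.cut = cut
        self.cut_sites: dict[str, np.ndarray] = {}
        self.chrom_lengths: dict[str, int] = {}
        self.uncut_chroms: list[str] = []
        frags = []
        for chrom, seq in genome.items():
            sites = find_cut_sites(seq, cut)
            self.cut_sites[chrom] = sites
            self.chrom_lengths[chrom] = len(seq)
            if sites.size == 0:
                self.uncut_chroms.append(chrom)
                bounds = np.array([0, len(seq)])
            else:
                bounds = np.concatenate([[0], sites, [len(seq)]])
                bounds = np.unique(bounds)
            for lo, hi in zip(bounds[:-1], bounds[1:]):
                frags.append((chrom, int(lo), int(hi)))
        self.fragments = pd.DataFrame(frags, columns=["chrom", "start", "end"])
        self.fragments["fragment_id"] = np.arange(len(self.fragments))

    def n_fragments(self) -> int:
        return len(self.fragments)

    def fragment_at(self, chrom: str, pos: int) -> int:
        """Fragment id containing position ``pos`` on ``chrom``."""
        sub = self.fragments[self.fragments.chrom == chrom]
        starts = sub.start.to_numpy()
        i = int(np.searchsorted(starts, pos, side="right")) - 1
        row = sub.iloc[i]
        if not (row.start <= pos < row.end):
            raise ValueError(f"position {chrom}:{pos} outside chromosome")
        return int(row.fragment_id)


@dataclass(frozen=True)
class ReducedGenomeEntry:
    sequence: str
    origin_cut_index: int  # global index over (chrom, cut) pairs
    side: str  # "upstream" | "downstream"
    interval: GenomicInterval
    fragment_id: int


class ReducedGenome:
    """Fixed-length flanks around every cut site; the 4C mapping target.

    For a cut match ``[c, c+4)`` the upstream entry spans ``[c - flank, c)``
    and the downstream entry ``[c + 4, c + 4 + flank)``, truncated at
    chromosome boundaries. The upstream flank belongs to the fragment ending
    at ``c``, the downstream flank to the fragment starting at ``c``.
    """

    def __init__(self, genome: dict[str, str], fragment_map: FragmentMap,
                 flank: int = DEFAULT_FLANK):
        self.flank = flank
        self.fragment_map = fragment_map
        entries: list[ReducedGenomeEntry] = []
        cut_counter = 0
        frag = fragment_map.fragments
        for chrom, seq in genome.items():
            sub = frag[frag.chrom == chrom]
            starts = sub.start.to_numpy()
            frag_ids = sub.fragment_id.to_numpy()
            L = len(seq)
            for c in fragment_map.cut_sites[chrom]:
                c = int(c)
                up_lo = max(0, c - flank)
                if c > up_lo:
                    # fragment ending at c: the one whose interval contains c-1
                    fid = int(frag_ids[np.searchsorted(starts, c - 1, side="right") - 1])
                    entries.append(
                        ReducedGenomeEntry(seq[up_lo:c], cut_counter, "upstream",
                                           GenomicInterval(chrom, up_lo, c), fid)
                    )
                dn_lo = c + len(fragment_map.cut)
                dn_hi = min(L, dn_lo + flank)
                if dn_hi > dn_lo:
                    fid = int(frag_ids[np.searchsorted(starts, c, side="right") - 1])
                    entries.append(
                        ReducedGenomeEntry(seq[dn_lo:dn_hi], cut_counter, "downstream",
                                           GenomicInterval(chrom, dn_lo, dn_hi), fid)
                    )
                cut_counter += 1
        self.entries = entries
        self._prefix_cache: dict[int, dict[str, int]] = {}

    def __len__(self) -> int:
        return len(self.entries)

    AMBIGUOUS = -2
    UNMAPPED = -1

    def _prefix_index(self, length: int) -> dict[str, int]:
        """Map length-``length`` prefixes to a unique entry index, or
        AMBIGUOUS when two entries share the prefix."""
        cached = self._prefix_cache.get(length)
        if cached is not None:
            return cached
        index: dict[str, int] = {}
        for i, e in enumerate(self.entries):
            if len(e.sequence) < length:
                continue
            key = e.sequence[:length]
            if key in index and index[key] != i:
                index[key] = self.AMBIGUOUS
            else:
                index[key] = i
        self._prefix_cache[length] = index
        return index

    def map_read(self, read: str, min_len: int = DEFAULT_MIN_LEN,
                 step: int | None = None) -> tuple[int, int]:
        """Map one trimmed read.

        Returns ``(entry_index, iteration)``; entry_index is UNMAPPED when
        the read never maps uniquely. A read maps at a given length when it
        equals the prefix of exactly one reduced-genome entry. Non-unique or
        unmapped reads are 3'-trimmed by ``step`` (10 nt for reads > 50 nt,
        2 nt otherwise) and retried until shorter than ``min_len``.
        """
        if step is None:
            step = 10 if len(read) > 50 else 2
        length = len(read)
        iteration = 0
        while length >= min_len:
            hit = self._prefix_index(length).get(read[:length], self.UNMAPPED)
            if hit >= 0:
                return hit, iteration
            length -= step
            iteration += 1
        return self.UNMAPPED, iteration


def build_fragment_map(genome: dict[str, str], cut: str = CUT_SEQ) -> FragmentMap:
    return FragmentMap(genome, cut)


def build_reduced_genome(genome: dict[str, str], fragment_map: FragmentMap,
                         flank: int = DEFAULT_FLANK) -> ReducedGenome:
    return ReducedGenome(genome, fragment_map, flank)


# ---------------------------------------------------------------------------
# demultiplexing / trimming


@dataclass(frozen=True)
class ViewpointSpec:
    name: str
    reading_primer: str  # 20 nt, must begin every informative read
    viewpoint_fragment: int
    chrom: str
    position: int  # viewpoint anchor position
    nonreading_primer: str = ""
    barcode: str = ""
    exclusion_fragments: int = 2  # fragments masked on each side of the viewpoint

    def __post_init__(self):
        if len(self.reading_primer) != 20:
            raise ValueError("reading primer must be 20 nt")


def demultiplex_and_trim(reads: list[str], viewpoints: list[ViewpointSpec]) -> tuple[dict[str, list[str]], int]:
    """Assign reads to viewpoints by exact 20-nt reading-primer match and trim.

    150-nt reads are first 3'-trimmed by 25 nt so all long libraries yield
    105-nt inserts after primer removal; 50-nt reads yield 30-nt inserts.
    Returns (per-viewpoint trimmed reads, number of unassigned reads).
    """
    primers = [v.reading_primer for v in viewpoints]
    if len(set(primers)) != len(primers):
        raise ValueError("viewpoint reading primers must be distinct")
    primer_to_name = {v.reading_primer: v.name for v in viewpoints}
    out: dict[str, list[str]] = {v.name: [] for v in viewpoints}
    unassigned = 0
    for read in reads:
        if len(read) == 150:
            read = read[:125]
        name = primer_to_name.get(read[:20])
        if name is None:
            unassigned += 1
        else:
            out[name].append(read[20:])
    return out, unassigned


# ---------------------------------------------------------------------------
# iterative mapping


def iterative_map(trimmed_reads: list[str], reduced: ReducedGenome,
                  min_len: int = DEFAULT_MIN_LEN, step: int | None = None):
    """Map trimmed reads against the reduced genome with iterative 3' trimming.

    Returns ``(per_fragment_counts, stats, entry_assignments)`` where
    ``per_fragment_counts`` is indexed by fragment_id over the whole fragment
    map, ``stats`` is a DataFrame of reads mapped per trimming iteration
    (iteration 0 = full length), and ``entry_assignments`` gives the mapped
    reduced-genome entry per read (UNMAPPED for unmapped).
    """
    n_frag = reduced.fragment_map.n_fragments()
    counts = np.zeros(n_frag, dtype=int)
    iters: dict[int, int] = {}
    assignments = np.full(len(trimmed_reads), ReducedGenome.UNMAPPED, dtype=int)
    # fast path: resolve full-length unique matches with one dict lookup per
    # read, then run the trimming loop only on the remainder
    by_len: dict[int, list[int]] = {}
    for r, read in enumerate(trimmed_reads):
        by_len.setdefault(len(read), []).append(r)
    for length, idxs in by_len.items():
        get = reduced._prefix_index(length).get
        pending = []
        n_full = 0
        for r in idxs:
            hit = get(trimmed_reads[r], ReducedGenome.UNMAPPED)
            if hit >= 0:
                assignments[r] = hit
                counts[reduced.entries[hit].fragment_id] += 1
                n_full += 1
            else:
                pending.append(r)
        if n_full:
            iters[0] = iters.get(0, 0) + n_full
        for r in pending:
            entry_idx, iteration = reduced.map_read(trimmed_reads[r],
                                                    min_len=min_len, step=step)
            if entry_idx >= 0:
                assignments[r] = entry_idx
                counts[reduced.entries[entry_idx].fragment_id] += 1
                iters[iteration] = iters.get(iteration, 0) + 1
    stats = pd.DataFrame(
        sorted(iters.items()), columns=["iteration", "reads_mapped"]
    )
    return counts, stats, assignments


def profile_from_reads(trimmed_reads: list[str], reduced: ReducedGenome,
                       min_len: int = DEFAULT_MIN_LEN) -> tuple["FourCProfile", pd.DataFrame]:
    """Map trimmed reads and build a per-fragment profile.

    ``total_mapped`` (the RPM denominator) is the number of uniquely mapped
    reads for this viewpoint/replicate.
    """
    counts, stats, assignments = iterative_map(trimmed_reads, reduced, min_len=min_len)
    total = int((assignments >= 0).sum())
    return FourCProfile(reduced.fragment_map, counts, total), stats


# ---------------------------------------------------------------------------
# profiles


@dataclass
class FourCProfile:
    """Per-fragment signal for one viewpoint/replicate (or a merged set)."""

    fragment_map: FragmentMap
    raw_count: np.ndarray
    total_mapped: int
    rpm: np.ndarray = field(init=False)
    smoothed: np.ndarray | None = None
    viewpoint_masked: np.ndarray | None = None

    def __post_init__(self):
        self.raw_count = np.asarray(self.raw_count, dtype=float)
        if self.total_mapped > 0:
            self.rpm = self.raw_count * 1e6 / self.total_mapped
        else:
            self.rpm = np.zeros_like(self.raw_count)


def sliding_median(values: np.ndarray, window: int) -> np.ndarray:
    """Median over a centered window; the window shrinks symmetrically at the
    ends so position i uses half-width min(w//2, i, n-1-i)."""
    if window % 2 == 0 or window < 1:
        raise ValueError("window must be odd and >= 1")
    n = values.size
    half = window // 2
    out = np.empty(n)
    for i in range(n):
        k = min(half, i, n - 1 - i)
        out[i] = np.median(values[i - k : i + k + 1])
    return out


def smooth_profile(profile: FourCProfile, window: int = DEFAULT_SMOOTH_WINDOW) -> FourCProfile:
    """Median-smooth the RPM signal chromosome by chromosome (fragment order
    = genomic order)."""
    frag = profile.fragment_map.fragments
    smoothed = np.empty_like(profile.rpm)
    for chrom in frag.chrom.unique():
        ids = frag.index[frag.chrom == chrom].to_numpy()
        smoothed[ids] = sliding_median(profile.rpm[ids], window)
    profile.smoothed = smoothed
    return profile


def normalize_and_merge(replicates: list[FourCProfile], viewpoint: ViewpointSpec,
                        window: int = DEFAULT_SMOOTH_WINDOW) -> FourCProfile:
    """RPM-normalize, smooth, and median-merge replicate profiles; mask the
    viewpoint fragment plus ``exclusion_fragments`` neighbors on each side.

    Replicates with zero mapped reads are dropped (a warning would fire in
    logging-enabled contexts); at least one usable replicate is required.
    """
    usable = [p for p in replicates if p.total_mapped > 0]
    if not usable:
        raise ValueError("no replicate with mapped reads")
    for p in usable:
        if p.smoothed is None:
            smooth_profile(p, window)
    stack = np.vstack([p.smoothed for p in usable])
    merged_vals = np.median(stack, axis=0)
    fm = usable[0].fragment_map
    merged = FourCProfile(fm, np.median(np.vstack([p.raw_count for p in usable]), axis=0),
                          total_mapped=0)
    merged.rpm = np.median(np.vstack([p.rpm for p in usable]), axis=0)
    merged.smoothed = merged_vals
    merged.viewpoint_masked = viewpoint_mask(fm, viewpoint)
    merged.smoothed = np.where(merged.viewpoint_masked, np.nan, merged.smoothed)
    return merged


def viewpoint_mask(fragment_map: FragmentMap, viewpoint: ViewpointSpec) -> np.ndarray:
    """Boolean mask: viewpoint fragment +/- exclusion_fragments on its chromosome."""
    frag = fragment_map.fragments
    mask = np.zeros(len(frag), dtype=bool)
    vp_fid = viewpoint.viewpoint_fragment
    chrom = frag.loc[vp_fid, "chrom"]
    chrom_ids = frag.index[frag.chrom == chrom].to_numpy()
    pos = int(np.where(chrom_ids == vp_fid)[0][0])
    k = viewpoint.exclusion_fragments
    lo, hi = max(0, pos - k), min(len(chrom_ids), pos + k + 1)
    mask[chrom_ids[lo:hi]] = True
    return mask


# ---------------------------------------------------------------------------
# interaction calling


@dataclass
class FourCResults:
    """Interaction calls and per-fragment diagnostics for one viewpoint."""

    calls: pd.DataFrame  # chrom, start, end, z_score, fdr, n_fragments
    fragment_stats: pd.DataFrame  # fragment_id, distance, observed, expected, z, p, fdr
    model: "FourCInteractionModel"

    def summary(self) -> str:
        lines = [
            f"4C interaction calls for viewpoint '{self.model.viewpoint.name}'",
            f"  fragments tested: {len(self.fragment_stats)}",
            f"  regions called (z > {self.model.z_threshold}, "
            f"FDR < {self.model.fdr_threshold}): {len(self.calls)}",
        ]
        for r in self.calls.itertuples():
            lines.append(
                f"    {r.chrom}:{r.start}-{r.end}  z={r.z_score:.2f}  fdr={r.fdr:.3g}"
            )
        return "\n".join(lines)

    def plot_profile(self, ax=None):
        """Smoothed viewpoint profile with called regions highlighted."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(8, 3))
        fs = self.fragment_stats
        ax.plot(fs["midpoint"], fs["observed"], lw=0.8, label="smoothed RPM")
        ax.plot(fs["midpoint"], fs["expected"], lw=0.8, label="decay fit")
        for r in self.calls.itertuples():
            ax.axvspan(r.start, r.end, color="red", alpha=0.3)
        ax.set_xlabel("position (bp)")
        ax.set_ylabel("signal")
        ax.set_yscale("log")
        ax.legend(frameon=False)
        return ax


class FourCInteractionModel:
    """Distance-decay interaction caller for one viewpoint.

    A monotone decay expectation is fitted per side of the viewpoint as a
    linear regression of log(smoothed + eps) on log(distance); per-fragment
    z-scores are residuals divided by a MAD-robust residual scale, one-sided
    p-values come from the normal reference, BH FDR is computed over tested
    fragments, and significant fragments (z > z_threshold, FDR <
    fdr_threshold) separated by at most ``merge_gap`` fragments are merged
    into regions. Region significance is additionally evaluated over the
    region extended by ``region_pad`` bp (Stouffer combination).
    """

    def __init__(self, merged_profile: FourCProfile, viewpoint: ViewpointSpec,
                 z_threshold: float = 3.0, fdr_threshold: float = 0.05,
                 eps: float = 0.5, merge_gap: int = 1, region_pad: int = 2500,
                 min_fragments_per_side: int = 30):
        self.profile = merged_profile
        self.viewpoint = viewpoint
        self.z_threshold = z_threshold
        self.fdr_threshold = fdr_threshold
        self.eps = eps
        self.merge_gap = merge_gap
        self.region_pad = region_pad
        self.min_fragments_per_side = min_fragments_per_side

    def fit(self) -> FourCResults:
        fm = self.profile.fragment_map
        frag = fm.fragments
        vp_chrom = self.viewpoint.chrom
        vp_pos = self.viewpoint.position
        mask = self.profile.viewpoint_masked
        if mask is None:
            mask = viewpoint_mask(fm, self.viewpoint)
        cis = (frag.chrom == vp_chrom).to_numpy() & ~mask
        ids = frag.index[cis].to_numpy()
        mids = ((frag.start + frag.end) // 2).to_numpy()[ids]
        dist = mids - vp_pos
        obs = self.profile.smoothed[ids]
        ok = ~np.isnan(obs)
        ids, mids, dist, obs = ids[ok], mids[ok], dist[ok], obs[ok]

        logy = np.log(obs + self.eps)
        expected = np.full(ids.size, np.nan)
        resid = np.full(ids.size, np.nan)
        for side in (dist < 0, dist > 0):
            if side.sum() < self.min_fragments_per_side:
                continue
            x = np.log(np.abs(dist[side]).astype(float))
            y = logy[side]
            slope, intercept = np.polyfit(x, y, 1)
            fitted = intercept + slope * x
            expected[side] = fitted
            resid[side] = y - fitted
        tested = ~np.isnan(resid)
        if tested.sum() == 0:
            empty = pd.DataFrame(columns=["chrom", "start", "end", "z_score", "fdr",
                                          "n_fragments"])
            stats_df = pd.DataFrame(columns=["fragment_id", "midpoint", "distance",
                                             "observed", "expected", "z", "p", "fdr"])
            return FourCResults(empty, stats_df, self)
        r = resid[tested]
        scale = 1.4826 * np.median(np.abs(r - np.median(r)))
        if scale <= 0:
            scale = max(np.std(r), 1e-12)
        z = np.full(ids.size, np.nan)
        z[tested] = resid[tested] / scale
        p = np.full(ids.size, np.nan)
        p[tested] = sps.norm.sf(z[tested])
        fdr = np.full(ids.size, np.nan)
        fdr[tested] = bh_fdr(p[tested])

        stats_df = pd.DataFrame(
            {
                "fragment_id": ids,
                "midpoint": mids,
                "distance": dist,
                "observed": obs,
                "expected": np.exp(expected) - self.eps,
                "z": z,
                "p": p,
                "fdr": fdr,
            }
        )
        sig = tested & (z > self.z_threshold) & (fdr < self.fdr_threshold)
        calls = self._merge_regions(stats_df, sig, frag)
        return FourCResults(calls, stats_df, self)

    def _merge_regions(self, stats_df: pd.DataFrame, sig: np.ndarray,
                       frag: pd.DataFrame) -> pd.DataFrame:
        rows = []
        sig_pos = np.nonzero(sig)[0]
        if sig_pos.size:
            groups = [[int(sig_pos[0])]]
            for a, b in zip(sig_pos[:-1], sig_pos[1:]):
                if b - a <= self.merge_gap + 1:
                    groups[-1].append(int(b))
                else:
                    groups.append([int(b)])
            for g in groups:
                fids = stats_df.fragment_id.to_numpy()[g]
                start = int(frag.loc[fids, "start"].min())
                end = int(frag.loc[fids, "end"].max())
                zmax = float(np.nanmax(stats_df.z.to_numpy()[g]))
                fdr_min = float(np.nanmin(stats_df.fdr.to_numpy()[g]))
                # region +/- pad significance: Stouffer over fragments in window
                mids = stats_df.midpoint.to_numpy()
                in_window = (mids >= start - self.region_pad) & (mids < end + self.region_pad)
                zw = stats_df.z.to_numpy()[in_window & ~np.isnan(stats_df.z.to_numpy())]
                region_z = float(zw.sum() / np.sqrt(zw.size)) if zw.size else np.nan
                rows.append(
                    {
                        "chrom": self.viewpoint.chrom,
                        "start": start,
                        "end": end,
                        "z_score": zmax,
                        "fdr": fdr_min,
                        "n_fragments": len(g),
                        "region_z": region_z,
                    }
                )
        return pd.DataFrame(rows, columns=["chrom", "start", "end", "z_score", "fdr",
                                           "n_fragments", "region_z"])


def call_interactions(merged_profile: FourCProfile, viewpoint: ViewpointSpec,
                      fdr_threshold: float = 0.05, z_threshold: float = 3.0,
                      **kwargs) -> FourCResults:
    """Functional wrapper around :class:`FourCInteractionModel`."""
    model = FourCInteractionModel(merged_profile, viewpoint,
                                  z_threshold=z_threshold,
                                  fdr_threshold=fdr_threshold, **kwargs)
    return model.fit()


# ---------------------------------------------------------------------------
# sex comparison


def region_replicate_rpm(profiles: list[FourCProfile], region) -> np.ndarray:
    """Per-replicate RPM summed over fragments overlapping ``region``
    (a GenomicInterval or a row with chrom/start/end)."""
    chrom = getattr(region, "chrom")
    start = int(getattr(region, "start"))
    end = int(getattr(region, "end"))
    fm = profiles[0].fragment_map
    frag = fm.fragments
    sel = ((frag.chrom == chrom) & (frag.start < end) & (frag.end > start)).to_numpy()
    return np.array([p.rpm[sel].sum() for p in profiles])


def compare_sexes(profiles_m: list[FourCProfile], profiles_f: list[FourCProfile],
                  regions: pd.DataFrame, eps: float = 0.5) -> pd.DataFrame:
    """Replicate-level differential interaction test per region.

    Per-replicate region RPM sums are compared between sexes with a Welch t
    test on log2(RPM + eps); identical groups give p = 1. BH FDR is computed
    across the tested regions. With fewer than 2 replicates in a group, an
    exact (fold-only) fallback is flagged: p is set to NaN and
    ``fallback=True``.
    """
    rows = []
    fallback = len(profiles_m) < 2 or len(profiles_f) < 2
    for region in regions.itertuples():
        vm = np.log2(region_replicate_rpm(profiles_m, region) + eps)
        vf = np.log2(region_replicate_rpm(profiles_f, region) + eps)
        log2fc = float(vm.mean() - vf.mean())
        if fallback:
            p = np.nan
        else:
            sm, sf = vm.var(ddof=1), vf.var(ddof=1)
            se = np.sqrt(sm / vm.size + sf / vf.size)
            if se == 0:
                p = 1.0 if log2fc == 0 else 0.0
            else:
                df_w = (sm / vm.size + sf / vf.size) ** 2 / (
                    (sm / vm.size) ** 2 / (vm.size - 1)
                    + (sf / vf.size) ** 2 / (vf.size - 1) + 1e-300
                )
                t = log2fc / se
                p = float(2 * sps.t.sf(abs(t), max(df_w, 1.0)))
        rows.append({"chrom": region.chrom, "start": region.start, "end": region.end,
                     "log2_mf": log2fc, "p": p, "fallback": fallback})
    out = pd.DataFrame(rows)
    if len(out) and not fallback:
        out["sex_differential_fdr"] = bh_fdr(out["p"].to_numpy())
    else:
        out["sex_differential_fdr"] = np.nan
    return out


# ---------------------------------------------------------------------------
# bedGraph output


def write_bedgraph(profile: FourCProfile, path, which: str = "smoothed") -> None:
    frag = profile.fragment_map.fragments
    values = getattr(profile, which)
    df = frag[["chrom", "start", "end"]].copy()
    df["value"] = values
    df = df.dropna()
    df.to_csv(path, sep="\t", header=False, index=False)
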