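"""Synthetic data with known planted truth for every pipeline stage.

The generator builds a toy genome (restriction sites with geometric spacing,
TAD partition, oriented CTCF consensus embeddings, planted CTCF/cohesin
peaks with sex effects, convergent anchor pairs forming intra-TAD loops),
then simulates per-replicate ChIP read samples (negative-binomial peak
counts over a uniform background), 4C-seq reads (distance-decay capture with
planted focal interactions and multi-junction ligation reads), and
expression matrices with planted depletion effects. All generators are
bit-reproducible under a fixed seed.

Default parameters emulate the study design this package targets: 4+4
CTCF and 3+3 cohesin replicates, ~4-fold planted sex effects, DpnII (GATC)
digestion with ~256-bp fragments, 105-nt 4C inserts, 3 biological 4C
replicates per sex, and a 4+4 wild-type vs cohesin-depleted expression
design with strong (10-fold) suppression of distally regulated genes and
weak (1.4-fold) suppression of proximally regulated ones.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .chipdiff import ReadSample
from .expression import ExpressionMatrix
from .fourc import FragmentMap, ReducedGenome, ViewpointSpec
from .intervals import GenomicInterval, IntervalCollection
from .motifs import CTCF_CONSENSUS, MotifHit, PositionWeightMatrix, reverse_complement

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass(frozen=True)
class SimConfig:
    """Study-condition parameters for all synthetic generators."""

    n_chroms: int = 2
    chrom_length: int = 400_000
    gatc_spacing_mean: float = 256.0
    n_tads: int = 4  # per chromosome
    n_motifs: int = 40  # per chromosome, anchor motifs included
    motif_info_content: float = 1.3  # bits per motif position
    chip_depth: int = 60_000  # background reads per replicate
    nb_dispersion: float = 0.1
    sex_effect_fold: float = 4.0
    decay_exponent: float = 1.0
    n_4c_reads: int = 200_000
    junction_fraction: float = 0.2
    seed: int = 0
    # secondary knobs (defaults chosen once as realistic desk-scale values)
    peak_mean_reads: float = 80.0
    read_length: int = 100
    frag_jitter_sd: float = 60.0
    frac_sex_biased: float = 0.3
    peak_width: int = 400
    flank: int = 105
    decay_offset: float = 2_000.0
    trans_read_fraction: float = 0.02
    interaction_fold: float = 5.0
    n_4c_interactions: int = 3
    interaction_span: int = 2_500
    expression_sigma: float = 0.2
    depletion_fold_distal: float = 0.1
    depletion_fold_proximal: float = 1.0 / 1.4
    n_genes_proximal: int = 29
    n_genes_distal: int = 32
    n_genes_neither: int = 30
    n_genes_ineligible: int = 29

    def __post_init__(self):
        if min(self.n_chroms, self.chrom_length, self.n_tads) < 1:
            raise ValueError("counts must be >= 1")
        if self.nb_dispersion < 0 or self.decay_exponent <= 0:
            raise ValueError("dispersion must be >= 0 and decay_exponent > 0")
        if not (0 <= self.junction_fraction <= 1):
            raise ValueError("junction_fraction must be in [0, 1]")
        if self.chrom_length < self.n_tads * 30_000:
            raise ValueError("chrom_length too small for the requested TAD count")


def match_prob_for_information(bits_per_position: float) -> float:
    """Consensus-base probability giving the requested per-position
    information content (uniform background)."""

    def info(p):
        q = (1 - p) / 3
        return p * np.log2(4 * p) + (1 - p) * np.log2(4 * q) - bits_per_position

    return float(brentq(info, 0.2501 + 1e-9, 1 - 1e-9))


@dataclass
class SyntheticTruth:
    """Everything the generators planted, for closed-loop testing."""

    config: SimConfig
    genome: dict[str, str]
    cut_sites: dict[str, np.ndarray]
    tads: pd.DataFrame
    motifs: list[MotifHit]
    pwm: PositionWeightMatrix
    planted_peaks: pd.DataFrame
    planted_loops: pd.DataFrame
    planted_interactions: pd.DataFrame
    planted_expression: pd.DataFrame
    male_dhs: IntervalCollection
    male_k27ac: IntervalCollection
    viewpoint: ViewpointSpec
    seed: int
    _fragment_map: FragmentMap | None = field(default=None, repr=False)
    _reduced: ReducedGenome | None = field(default=None, repr=False)

    @property
    def tad_collection(self) -> IntervalCollection:
        return IntervalCollection.from_dataframe(self.tads)

    def fragment_map(self) -> FragmentMap:
        if self._fragment_map is None:
            self._fragment_map = FragmentMap(self.genome)
        return self._fragment_map

    def reduced_genome(self) -> ReducedGenome:
        if self._reduced is None:
            self._reduced = ReducedGenome(self.genome, self.fragment_map(),
                                          flank=self.config.flank)
        return self._reduced

    def peaks_for_factor(self, factor: str) -> pd.DataFrame:
        wanted = {"CTCF": ("CTCF", "both"), "cohesin": ("cohesin", "both")}[factor]
        return self.planted_peaks[self.planted_peaks.factors.isin(wanted)].reset_index(drop=True)


# ---------------------------------------------------------------------------
# genome construction


def _plan_cut_sites(rng: np.random.Generator, config: SimConfig) -> np.ndarray:
    spacing = 4 + rng.geometric(1.0 / max(config.gatc_spacing_mean - 4, 1.0),
                                size=int(3 * config.chrom_length / config.gatc_spacing_mean) + 16)
    pos = np.cumsum(spacing) + 100
    return pos[pos < config.chrom_length - 200]


def _plan_tads(config: SimConfig) -> list[tuple[int, int]]:
    usable = config.chrom_length - 20_000
    gap = 5_000
    tad_len = (usable - (config.n_tads - 1) * gap) // config.n_tads
    tads = []
    pos = 10_000
    for _ in range(config.n_tads):
        tads.append((pos, pos + tad_len))
        pos += tad_len + gap
    return tads


def _scrub_stray_gatc(seq: np.ndarray, planted: set[int],
                      motif_spans: list[tuple[int, int]],
                      rng: np.random.Generator) -> None:
    """Mutate accidental GATC occurrences in place, leaving planted cut
    sites and motif embeddings untouched."""
    gatc = np.frombuffer(b"GATC", dtype=np.uint8)
    spans = np.array(motif_spans) if motif_spans else np.empty((0, 2), dtype=int)
    for _ in range(10):
        hits = np.nonzero(
            (seq[:-3] == gatc[0]) & (seq[1:-2] == gatc[1])
            & (seq[2:-1] == gatc[2]) & (seq[3:] == gatc[3])
        )[0]
        stray = [h for h in hits if h not in planted]
        if not stray:
            return
        for h in stray:
            for off in (2, 1, 3, 0):  # prefer mutating the T
                pos = h + off
                inside_motif = bool(
                    spans.size and np.any((spans[:, 0] <= pos) & (pos < spans[:, 1]))
                )
                if not inside_motif:
                    current = seq[pos]
                    choices = _BASES[_BASES != current]
                    seq[pos] = rng.choice(choices)
                    break
    raise RuntimeError("failed to scrub stray GATC occurrences")  # pragma: no cover


def make_genome(config: SimConfig | None = None, seed: int | None = None) -> SyntheticTruth:
    """Build the toy genome and all planted truth tables."""
    config = config or SimConfig()
    seed = config.seed if seed is None else seed
    rng = np.random.default_rng(seed)
    match_prob = match_prob_for_information(config.motif_info_content)
    pwm = PositionWeightMatrix.from_consensus(CTCF_CONSENSUS, match_prob)
    width = pwm.width

    genome: dict[str, str] = {}
    cut_sites: dict[str, np.ndarray] = {}
    tad_rows, motif_list, peak_rows, loop_rows = [], [], [], []

    for ci in range(config.n_chroms):
        chrom = f"chr{ci + 1}"
        cuts = _plan_cut_sites(rng, config)
        tads = _plan_tads(config)
        motif_plan: list[tuple[int, str, str, bool]] = []  # (pos, strand, role, anchor)

        # convergent anchor pairs per TAD (outer loop; nested pair in even TADs)
        for t, (ts, te) in enumerate(tads):
            tlen = te - ts
            anchor_specs = [(ts + int(0.05 * tlen), "+"), (te - int(0.05 * tlen) - width, "-")]
            if t % 2 == 0:
                anchor_specs += [(ts + int(0.30 * tlen), "+"), (ts + int(0.60 * tlen), "-")]
            for pos, strand in anchor_specs:
                motif_plan.append((pos, strand, "anchor", True))
        motif_plan = motif_plan[: config.n_motifs]  # n_motifs bounds all embeddings

        # extra motifs: sex-biased CAC sites and Lone-CTCF sites inside TADs
        n_extra = max(0, config.n_motifs - len(motif_plan))
        taken = [p for p, *_ in motif_plan]
        for k in range(n_extra):
            for _ in range(200):
                t = int(rng.integers(len(tads)))
                ts, te = tads[t]
                pos = int(rng.integers(ts + 2_000, te - 2_000))
                if all(abs(pos - q) > 600 for q in taken):
                    break
            else:  # pragma: no cover - config pathological
                continue
            taken.append(pos)
            strand = "+" if rng.random() < 0.5 else "-"
            role = "cac_extra" if k % 2 == 0 else "lone"
            motif_plan.append((pos, strand, role, False))

        # keep motifs clear of cut sites: drop any cut site inside a motif span
        motif_spans = [(p, p + width) for p, *_ in motif_plan]
        keep_cut = np.ones(cuts.size, dtype=bool)
        for lo, hi in motif_spans:
            keep_cut &= ~((cuts + 4 > lo) & (cuts < hi))
        cuts = cuts[keep_cut]

        # sequence assembly
        seq = rng.choice(_BASES, size=config.chrom_length)
        gatc = np.frombuffer(b"GATC", dtype=np.uint8)
        for c in cuts:
            seq[c : c + 4] = gatc
        for pos, strand, _, _ in motif_plan:
            text = CTCF_CONSENSUS if strand == "+" else reverse_complement(CTCF_CONSENSUS)
            seq[pos : pos + width] = np.frombuffer(text.encode(), dtype=np.uint8)
        _scrub_stray_gatc(seq, set(int(c) for c in cuts), motif_spans, rng)
        genome[chrom] = seq.tobytes().decode("ascii")
        cut_sites[chrom] = cuts

        for t, (ts, te) in enumerate(tads):
            tad_rows.append({"chrom": chrom, "start": ts, "end": te})

        # motif hits (planted truth)
        chrom_motifs = []
        for pos, strand, role, is_anchor in sorted(motif_plan):
            sub = genome[chrom][pos : pos + width]
            hit = MotifHit(GenomicInterval(chrom, pos, pos + width, strand),
                           score=float(np.sum(np.max(pwm.log_odds, axis=1))),
                           contains_cpg="CG" in sub)
            motif_list.append(hit)
            chrom_motifs.append((pos, strand, role, is_anchor, hit))

        # planted peaks at motifs
        half = config.peak_width // 2
        anchors_by_tad: dict[int, list[dict]] = {}
        extra_counter = 0
        for pos, strand, role, is_anchor, hit in chrom_motifs:
            center = pos + width // 2
            strength = float(np.exp(rng.normal(0.5 if is_anchor else 0.0, 0.3)))
            if role in ("anchor", "cac_extra"):
                factors, site_class = "both", "CAC"
            else:
                factors, site_class = "CTCF", "Lone"
            if is_anchor:
                sex_bias = "none"
            elif rng.random() < config.frac_sex_biased:
                sex_bias = "M" if extra_counter % 2 == 0 else "F"
                extra_counter += 1
            else:
                sex_bias = "none"
            row = {
                "chrom": chrom, "start": center - half, "end": center + half,
                "summit": center, "factors": factors, "site_class": site_class,
                "strength": strength, "sex_bias": sex_bias,
                "fold": config.sex_effect_fold if sex_bias != "none" else 1.0,
                "is_anchor": is_anchor, "motif_start": pos, "motif_strand": strand,
            }
            peak_rows.append(row)
            if is_anchor:
                for t, (ts, te) in enumerate(tads):
                    if ts <= center < te:
                        anchors_by_tad.setdefault(t, []).append(row | {"tad_local": t})
                        break

        # CNC peaks: cohesin-only, motif-free
        n_cnc = max(4, config.n_motifs // 3)
        cnc_count = 0
        for _ in range(400):
            if cnc_count >= n_cnc:
                break
            t = int(rng.integers(len(tads)))
            ts, te = tads[t]
            center = int(rng.integers(ts + 2_000, te - 2_000))
            if all(abs(center - (q + width // 2)) > 800 for q in taken):
                sex_bias = "none"
                if rng.random() < config.frac_sex_biased:
                    sex_bias = "M" if cnc_count % 2 == 0 else "F"
                peak_rows.append(
                    {
                        "chrom": chrom, "start": center - half, "end": center + half,
                        "summit": center, "factors": "cohesin", "site_class": "CNC",
                        "strength": float(np.exp(rng.normal(-0.3, 0.3))),
                        "sex_bias": sex_bias,
                        "fold": config.sex_effect_fold if sex_bias != "none" else 1.0,
                        "is_anchor": False, "motif_start": -1, "motif_strand": ".",
                    }
                )
                taken.append(center - width // 2)
                cnc_count += 1

        # planted loops: convergent anchor pairs within each TAD
        for t, anchors in anchors_by_tad.items():
            plus = sorted((a for a in anchors if a["motif_strand"] == "+"),
                          key=lambda a: a["start"])
            minus = sorted((a for a in anchors if a["motif_strand"] == "-"),
                           key=lambda a: a["start"])
            if plus and minus:
                # outer loop: first + anchor with last - anchor
                pairs = [(plus[0], minus[-1])]
                if len(plus) > 1 and len(minus) > 1:
                    pairs.append((plus[1], minus[0]))  # nested pair
                for a5, a3 in pairs:
                    if a5["start"] < a3["start"]:
                        loop_rows.append(
                            {
                                "chrom": chrom,
                                "start": a5["start"], "end": a3["end"],
                                "anchor5_start": a5["start"], "anchor5_end": a5["end"],
                                "anchor3_start": a3["start"], "anchor3_end": a3["end"],
                                "tad_id": len(tad_rows) - len(tads) + t,
                                "nested": a5 is not plus[0],
                            }
                        )

    tads_df = pd.DataFrame(tad_rows)
    peaks_df = pd.DataFrame(peak_rows).sort_values(["chrom", "start"]).reset_index(drop=True)
    loops_df = pd.DataFrame(loop_rows)

    # 4C viewpoint and planted interactions on chr1
    fm = FragmentMap(genome)
    vp_pos = config.chrom_length // 2
    primer = "".join(chr(b) for b in rng.choice(_BASES, size=20))
    viewpoint = ViewpointSpec(
        name="vp1", reading_primer=primer,
        viewpoint_fragment=fm.fragment_at("chr1", vp_pos),
        chrom="chr1", position=vp_pos,
    )
    inter_rows = []
    offsets = np.linspace(-0.3, 0.35, config.n_4c_interactions + 1)
    for i, frac in enumerate(offsets):
        center = vp_pos + int(frac * config.chrom_length)
        if abs(center - vp_pos) < 10_000:
            center = vp_pos + 40_000
        sex = "F" if i == len(offsets) - 1 else "both"  # last one is female-only
        inter_rows.append(
            {
                "viewpoint": viewpoint.name, "chrom": "chr1",
                "start": center - config.interaction_span // 2,
                "end": center + config.interaction_span // 2,
                "fold": config.interaction_fold, "sex": sex,
            }
        )
    interactions_df = pd.DataFrame(inter_rows)

    expr_df, dhs_ic, k27_ic = _plan_expression(rng, config)

    truth = SyntheticTruth(
        config=config, genome=genome, cut_sites=cut_sites, tads=tads_df,
        motifs=motif_list, pwm=pwm, planted_peaks=peaks_df,
        planted_loops=loops_df, planted_interactions=interactions_df,
        planted_expression=expr_df, male_dhs=dhs_ic, male_k27ac=k27_ic,
        viewpoint=viewpoint, seed=seed,
    )
    truth._fragment_map = fm
    return truth


def _plan_expression(rng: np.random.Generator, config: SimConfig):
    """Genes on an annotation-only virtual chromosome, 100 kb apart, with
    male-biased DHS / H3K27ac features planted at controlled distances."""
    rows, dhs, k27 = [], [], []
    spacing = 100_000
    groups = (
        ["proximal"] * config.n_genes_proximal
        + ["distal"] * config.n_genes_distal
        + ["neither"] * config.n_genes_neither
        + ["ineligible"] * config.n_genes_ineligible
    )
    for i, group in enumerate(groups):
        tss = 50_000 + i * spacing
        chrom = "chrE"
        if group == "proximal":
            d1 = int(rng.integers(1_000, 15_000))
            d2 = int(rng.integers(1_000, 15_000))
            fold = config.depletion_fold_proximal
        elif group == "distal":
            d1 = int(rng.integers(25_000, 45_000))
            d2 = int(rng.integers(25_000, 45_000))
            fold = config.depletion_fold_distal
        elif group == "neither":
            d1 = int(rng.integers(1_000, 15_000))
            d2 = int(rng.integers(25_000, 45_000))
            fold = 0.9
        else:
            d1 = int(rng.integers(1_000, 15_000))
            d2 = int(rng.integers(1_000, 15_000))
            fold = 1.0
        dhs.append(GenomicInterval(chrom, tss + d1, tss + d1 + 500))
        k27.append(GenomicInterval(chrom, max(0, tss - d2 - 500), tss - d2 if tss - d2 > 0 else 1))
        if group == "ineligible":
            fpkm = float(np.exp(rng.normal(-1.0, 0.3)))
            mf = float(np.exp(rng.normal(0.0, 0.2)))
        else:
            fpkm = float(np.exp(rng.normal(2.0, 0.8))) + 1.5
            mf = float(np.exp(rng.normal(2.0, 0.5))) + 3.0
        rows.append(
            {
                "gene": f"gene{i:03d}", "chrom": chrom, "tss": tss,
                "length": int(rng.integers(1_000, 5_000)),
                "wt_mean": fpkm, "fpkm": fpkm, "mf_ratio": mf,
                "depletion_fold": fold, "group_truth": group,
            }
        )
    return pd.DataFrame(rows), IntervalCollection(dhs), IntervalCollection(k27)


# ---------------------------------------------------------------------------
# ChIP replicate simulation


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    mean = np.asarray(mean, dtype=float)
    if dispersion < 1e-9:
        return rng.poisson(mean)
    n = 1.0 / dispersion
    p = n / (n + mean)
    return rng.negative_binomial(n, p)


def simulate_chip_replicates(truth: SyntheticTruth, factor: str,
                             n_male: int, n_female: int,
                             config: SimConfig | None = None,
                             seed: int | None = None) -> list[ReadSample]:
    """Per-replicate ChIP read samples for one factor.

    Per-peak counts are NegBin(depth x strength x sex multiplier,
    dispersion) with read positions jittered around the summit; a uniform
    background contributes ``chip_depth`` expected reads per replicate. The
    sex multiplier equals the planted fold in the favored sex of sex-biased
    peaks and 1 elsewhere.
    """
    config = config or truth.config
    seed = truth.seed + 1000 if seed is None else seed
    rng = np.random.default_rng(seed)
    peaks = truth.peaks_for_factor(factor)
    chrom_lengths = {c: len(s) for c, s in truth.genome.items()}
    genome_len = sum(chrom_lengths.values())
    samples = []
    for sex, count in (("M", n_male), ("F", n_female)):
        for rep in range(count):
            mult = np.where(peaks.sex_bias == sex, peaks.fold, 1.0)
            mu = peaks.strength.to_numpy() * config.peak_mean_reads * mult
            counts = _nb_draw(rng, mu, config.nb_dispersion)
            reads: dict[str, list[np.ndarray]] = {c: [] for c in chrom_lengths}
            for (chrom, summit), n_reads in zip(
                zip(peaks.chrom, peaks.summit), counts
            ):
                if n_reads == 0:
                    continue
                centers = rng.normal(summit, config.frag_jitter_sd, size=n_reads)
                starts = np.clip(centers - config.read_length // 2, 0,
                                 chrom_lengths[chrom] - config.read_length).astype(np.int64)
                reads[chrom].append(
                    np.column_stack([starts, starts + config.read_length])
                )
            for chrom, L in chrom_lengths.items():
                n_bg = rng.poisson(config.chip_depth * L / genome_len)
                starts = rng.integers(0, max(1, L - config.read_length), size=n_bg)
                reads[chrom].append(np.column_stack([starts, starts + config.read_length]))
            sample = ReadSample(
                factor=factor, sex=sex, replicate_id=f"{factor}_{sex}{rep + 1}",
                reads={c: np.vstack(a) if a else np.empty((0, 2), dtype=np.int64)
                       for c, a in reads.items()},
            )
            samples.append(sample)
    return samples


# ---------------------------------------------------------------------------
# 4C read simulation


@dataclass
class FourCReadSet:
    """Simulated reads for one viewpoint/replicate plus per-read truth."""

    viewpoint: ViewpointSpec
    sex: str
    replicate_id: str
    reads: list[str]
    truth: pd.DataFrame  # entry1, entry2 (-1 for junction-free), split

    def to_fastq(self, path) -> None:
        with open(path, "w") as fh:
            for i, read in enumerate(self.reads):
                fh.write(f"@{self.replicate_id}:{i}\n{read}\n+\n{'I' * len(read)}\n")


def _entry_weights(truth: SyntheticTruth, viewpoint: ViewpointSpec,
                   config: SimConfig, sex: str) -> np.ndarray:
    reduced = truth.reduced_genome()
    fm = truth.fragment_map()
    n = len(reduced)
    mids = np.array([(e.interval.start + e.interval.end) // 2 for e in reduced.entries])
    chroms = np.array([e.interval.chrom for e in reduced.entries])
    lengths = np.array([len(e.sequence) for e in reduced.entries])
    usable = lengths == config.flank  # skip boundary-truncated entries
    # skip entries whose full-length sequence is not a unique mapping target
    # (e.g., twin flanks when consecutive cut sites are flank+4 apart)
    prefix = reduced._prefix_index(config.flank)
    unique = np.array(
        [
            len(e.sequence) == config.flank
            and prefix.get(e.sequence[: config.flank]) == i
            for i, e in enumerate(reduced.entries)
        ]
    )
    usable &= unique
    # fragments in the viewpoint exclusion zone are not sampled (models the
    # removal of self-ligation products)
    from .fourc import viewpoint_mask

    vp_mask = viewpoint_mask(fm, viewpoint)
    frag_ids = np.array([e.fragment_id for e in reduced.entries])
    usable &= ~vp_mask[frag_ids]

    w = np.zeros(n)
    cis = (chroms == viewpoint.chrom) & usable
    dist = np.abs(mids - viewpoint.position)
    w[cis] = (dist[cis] + config.decay_offset) ** (-config.decay_exponent)
    for r in truth.planted_interactions.itertuples():
        if r.viewpoint != viewpoint.name:
            continue
        if r.sex != "both" and r.sex != sex:
            continue
        sel = cis & (chroms == r.chrom) & (mids >= r.start) & (mids < r.end)
        w[sel] *= r.fold
    cis_total = w.sum()
    trans = (~(chroms == viewpoint.chrom)) & usable
    if trans.any() and config.trans_read_fraction > 0:
        w[trans] = (
            cis_total * config.trans_read_fraction / (1 - config.trans_read_fraction)
        ) / trans.sum()
    return w / w.sum()


def simulate_4c_reads(truth: SyntheticTruth, viewpoint: ViewpointSpec | None = None,
                      config: SimConfig | None = None, sex: str = "M",
                      replicate_id: str = "rep1",
                      seed: int | None = None) -> FourCReadSet:
    """Simulate one 4C-seq replicate for a viewpoint.

    Each read is the 20-nt reading primer followed by a 105-nt captured
    flank from the reduced genome; capture probability follows a power-law
    distance decay on the viewpoint chromosome, multiplied by the planted
    enrichment fold inside interaction regions (sex-matched). A
    ``junction_fraction`` of reads concatenates two captured flanks so the
    full-length read cannot map and must be rescued by iterative trimming.
    """
    config = config or truth.config
    viewpoint = viewpoint or truth.viewpoint
    seed = truth.seed + 2000 if seed is None else seed
    rng = np.random.default_rng(seed)
    reduced = truth.reduced_genome()
    weights = _entry_weights(truth, viewpoint, config, sex)
    n = config.n_4c_reads
    entry1 = rng.choice(len(reduced), size=n, p=weights)
    is_junction = rng.random(n) < config.junction_fraction
    entry2 = np.where(is_junction, rng.choice(len(reduced), size=n, p=weights), -1)
    splits = np.where(is_junction, rng.integers(15, 91, size=n), config.flank)
    seqs = [e.sequence for e in reduced.entries]
    primer = viewpoint.reading_primer
    reads = []
    flank = config.flank
    for e1, e2, k in zip(entry1, entry2, splits):
        if e2 < 0:
            reads.append(primer + seqs[e1])
        else:
            reads.append(primer + seqs[e1][:k] + seqs[e2][: flank - k])
    truth_df = pd.DataFrame({"entry1": entry1, "entry2": entry2, "split": splits})
    return FourCReadSet(viewpoint, sex, replicate_id, reads, truth_df)


def simulate_4c_replicates(truth: SyntheticTruth, n_per_sex: int = 3,
                           config: SimConfig | None = None,
                           seed: int | None = None) -> list[FourCReadSet]:
    """Replicate design: ``n_per_sex`` biological replicates per sex."""
    config = config or truth.config
    base = (truth.seed + 2000 if seed is None else seed)
    out = []
    for si, sex in enumerate(("M", "F")):
        for rep in range(n_per_sex):
            out.append(
                simulate_4c_reads(truth, config=config, sex=sex,
                                  replicate_id=f"{sex}{rep + 1}",
                                  seed=base + 97 * si + rep)
            )
    return out


# ---------------------------------------------------------------------------
# expression simulation


def simulate_expression(truth: SyntheticTruth, n_wt: int = 4, n_depleted: int = 4,
                        config: SimConfig | None = None,
                        seed: int | None = None) -> ExpressionMatrix:
    """FPKM matrix: lognormal noise around each gene's WT mean; depleted
    replicates scaled by the planted depletion fold."""
    config = config or truth.config
    seed = truth.seed + 3000 if seed is None else seed
    rng = np.random.default_rng(seed)
    genes = truth.planted_expression
    cols, conds, data = [], [], []
    for cond, count in (("WT", n_wt), ("depleted", n_depleted)):
        for rep in range(count):
            noise = np.exp(rng.normal(0.0, config.expression_sigma, size=len(genes)))
            scale = genes.depletion_fold.to_numpy() if cond == "depleted" else 1.0
            data.append(genes.wt_mean.to_numpy() * scale * noise)
            cols.append(f"{cond}{rep + 1}")
            conds.append(cond)
    values = pd.DataFrame(np.column_stack(data), index=genes.gene, columns=cols)
    condition = pd.Series(conds, index=cols)
    lengths = pd.Series(genes.length.to_numpy(), index=genes.gene)
    return ExpressionMatrix(values, condition, lengths)
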