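"""Classification of sex-differential sites into CAC / CNC / Lone-CTCF
classes by replicate-overlap counting, and proximity annotation relative to
sex-biased genes, enhancers, TADs, and intra-TAD loops.

Replicate-overlap rules (an overlap is >= 1 bp with any peak of a replicate,
counted against the replicate peak sets of the sex showing higher binding):

* sex-differential cohesin sites vs 4 CTCF replicates: 3-4 hits -> CAC,
  0-1 -> CNC, exactly 2 -> excluded;
* sex-differential CTCF sites vs 3 cohesin replicates: 2-3 hits -> CAC,
  0-1 -> Lone CTCF (no excluded class).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .intervals import GenomicInterval, IntervalCollection, nearest_distance
from .stats import TestResult, ks_test

PROXIMAL_DISTANCE = 20_000


def _site_interval(site) -> GenomicInterval:
    return GenomicInterval(str(site.chrom), int(site.start), int(site.end))


def count_replicate_hits(site, replicate_peaks: list[IntervalCollection]) -> int:
    """Number of replicates with at least one >= 1 bp overlapping peak."""
    iv = _site_interval(site)
    return sum(1 for rep in replicate_peaks if rep.any_overlap(iv))


def classify_cohesin_site(site, ctcf_replicate_peaks: list[IntervalCollection],
                          n_expected: int = 4) -> tuple[str, int]:
    """Class of one sex-differential cohesin site given the 4 CTCF replicate
    peak sets of the sex with higher cohesin binding.

    Returns (site_class, replicate_hits) with site_class in
    {"CAC", "CNC", "excluded"}.
    """
    if len(ctcf_replicate_peaks) != n_expected:
        raise ValueError(
            f"expected {n_expected} CTCF replicate peak sets, got "
            f"{len(ctcf_replicate_peaks)}; pass n_expected explicitly to rescale"
        )
    hits = count_replicate_hits(site, ctcf_replicate_peaks)
    if hits >= n_expected - 1:
        return "CAC", hits
    if hits <= 1:
        return "CNC", hits
    return "excluded", hits


def classify_ctcf_site(site, cohesin_replicate_peaks: list[IntervalCollection],
                       n_expected: int = 3) -> tuple[str, int]:
    """Class of one sex-differential CTCF site given the 3 cohesin replicate
    peak sets of the matching sex: 2-3 hits -> CAC, 0-1 -> Lone CTCF."""
    if len(cohesin_replicate_peaks) != n_expected:
        raise ValueError(
            f"expected {n_expected} cohesin replicate peak sets, got "
            f"{len(cohesin_replicate_peaks)}; pass n_expected explicitly to rescale"
        )
    hits = count_replicate_hits(site, cohesin_replicate_peaks)
    if hits >= 2:
        return "CAC", hits
    return "LoneCTCF", hits


def classify_sites(sites: pd.DataFrame, factor: str,
                   replicate_peaks_by_sex: dict[str, list[IntervalCollection]]) -> pd.DataFrame:
    """Classify every site of a sex-differential set for one factor.

    ``replicate_peaks_by_sex`` maps 'M'/'F' to the other factor's replicate
    peak collections; the set used per site is that of the sex with higher
    binding (site ``direction``).
    """
    classes, hit_counts = [], []
    for site in sites.itertuples():
        sex = "M" if site.direction == "male-biased" else "F"
        reps = replicate_peaks_by_sex[sex]
        if factor == "cohesin":
            cls, hits = classify_cohesin_site(site, reps, n_expected=len(reps))
        elif factor == "CTCF":
            cls, hits = classify_ctcf_site(site, reps, n_expected=len(reps))
        else:
            raise ValueError(f"unknown factor {factor!r}")
        classes.append(cls)
        hit_counts.append(hits)
    out = sites.copy()
    out["site_class"] = classes
    out["other_factor_replicate_hits"] = hit_counts
    return out


def cross_factor_overlap(diff_ctcf_sites: pd.DataFrame,
                         diff_cohesin_sites: pd.DataFrame,
                         autosomes: set[str] | None = None) -> dict:
    """Sites showing sex-differential binding of both factors (>= 1 bp
    overlap between the two standard-tier site sets).

    Because one CTCF site may overlap several cohesin sites (and vice
    versa), counts are reported per factor, with autosomal subsets when a
    set of autosome names is given.
    """
    coh_ic = IntervalCollection.from_dataframe(diff_cohesin_sites) if len(diff_cohesin_sites) else None
    ctcf_flags = np.zeros(len(diff_ctcf_sites), dtype=bool)
    coh_flags = np.zeros(len(diff_cohesin_sites), dtype=bool)
    pairs = []
    for i, site in enumerate(diff_ctcf_sites.itertuples()):
        if coh_ic is None:
            break
        hits = coh_ic.overlapping(_site_interval(site))
        if hits:
            ctcf_flags[i] = True
            for j in hits:
                coh_flags[j] = True
                pairs.append((i, j))
    result = {
        "n_ctcf_joint": int(ctcf_flags.sum()),
        "n_cohesin_joint": int(coh_flags.sum()),
        "pairs": pairs,
        "ctcf_joint_mask": ctcf_flags,
        "cohesin_joint_mask": coh_flags,
    }
    if autosomes is not None:
        auto_ctcf = diff_ctcf_sites.chrom.isin(autosomes).to_numpy()
        auto_coh = diff_cohesin_sites.chrom.isin(autosomes).to_numpy()
        result["n_ctcf_joint_autosomal"] = int((ctcf_flags & auto_ctcf).sum())
        result["n_cohesin_joint_autosomal"] = int((coh_flags & auto_coh).sum())
    return result


def proximity_category(site, sex_biased_tss: IntervalCollection,
                       loops: pd.DataFrame, tads: pd.DataFrame,
                       proximal_distance: int = PROXIMAL_DISTANCE) -> str:
    """Mutually exclusive proximity label of a site relative to sex-biased
    genes: Proximal (< 20 kb from a sex-biased TSS) > IntraTAD (same
    intra-TAD loop as a sex-biased gene) > TAD (same TAD) > Outside.

    Distances are measured site edge to TSS point; loops and TADs are
    interval tables with chrom/start/end columns.
    """
    iv = _site_interval(site)
    hit = nearest_distance(iv, sex_biased_tss)
    if hit.reachable and hit.distance < proximal_distance:
        return "Proximal"
    for container, label in ((loops, "IntraTAD"), (tads, "TAD")):
        for r in container.itertuples():
            if r.chrom != iv.chrom:
                continue
            dom = GenomicInterval(r.chrom, int(r.start), int(r.end))
            if _contained(iv, dom) and _any_tss_in(sex_biased_tss, dom):
                return label
    return "Outside"


def _contained(iv: GenomicInterval, dom: GenomicInterval) -> bool:
    from .intervals import overlap_bp

    return overlap_bp(iv, dom) > 0


def _any_tss_in(tss: IntervalCollection, dom: GenomicInterval) -> bool:
    return tss.any_overlap(dom)


def annotate_proximity(sites: pd.DataFrame, sex_biased_tss: IntervalCollection,
                       loops: pd.DataFrame, tads: pd.DataFrame) -> pd.DataFrame:
    out = sites.copy()
    out["proximity"] = [
        proximity_category(s, sex_biased_tss, loops, tads) for s in sites.itertuples()
    ]
    return out


def annotate_enhancer_context(sites: pd.DataFrame, enhancer_dhs: IntervalCollection,
                              sex_biased_regions: IntervalCollection,
                              tss: IntervalCollection | None = None) -> pd.DataFrame:
    """Per-site nearest-enhancer (and optionally nearest-TSS) distances plus
    an overlap flag against the merged sex-biased DHS/H3K27ac list."""
    out = sites.copy()
    enh_d, flags, tss_d = [], [], []
    for site in sites.itertuples():
        iv = _site_interval(site)
        enh_d.append(nearest_distance(iv, enhancer_dhs).distance)
        flags.append(sex_biased_regions.any_overlap(iv))
        if tss is not None:
            tss_d.append(nearest_distance(iv, tss).distance)
    out["nearest_enhancer_bp"] = enh_d
    out["overlaps_sex_biased_enhancer"] = flags
    if tss is not None:
        out["nearest_tss_bp"] = tss_d
    return out


def distance_cdf_comparison(distances_a, distances_b) -> tuple[TestResult, pd.DataFrame]:
    """Two-sample KS comparison of nearest-feature distance distributions,
    with the cumulative curves used for plotting."""
    a = np.sort(np.asarray(distances_a, dtype=float))
    b = np.sort(np.asarray(distances_b, dtype=float))
    a = a[np.isfinite(a)]
    b = b[np.isfinite(b)]
    res = ks_test(a, b)
    grid = np.unique(np.concatenate([a, b]))
    cdf = pd.DataFrame(
        {
            "distance": grid,
            "cdf_a": np.searchsorted(a, grid, side="right") / a.size,
            "cdf_b": np.searchsorted(b, grid, side="right") / b.size,
        }
    )
    return res, cdf
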