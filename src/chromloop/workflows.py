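"""End-to-end study workflows tying the simulators to the pipelines.

These helpers run the full closed loop used for validation: simulate 4C
replicates for both sexes, push them through demultiplexing, iterative
mapping, smoothing/merging and interaction calling, then score the calls
against the planted truth.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .chipdiff import merge_intervals
from .fourc import (
    FourCResults,
    call_interactions,
    compare_sexes,
    demultiplex_and_trim,
    normalize_and_merge,
    profile_from_reads,
)
from .simulate import SyntheticTruth, simulate_4c_replicates


def run_4c_study(truth: SyntheticTruth, seed: int, n_per_sex: int = 3,
                 z_threshold: float = 3.0, fdr_threshold: float = 0.05) -> dict:
    """Simulate and process one complete two-sex 4C experiment.

    Returns per-sex replicate profiles, merged profiles, interaction-call
    results, and per-replicate mapping statistics.
    """
    read_sets = simulate_4c_replicates(truth, n_per_sex=n_per_sex, seed=seed)
    reduced = truth.reduced_genome()
    vp = truth.viewpoint
    profiles: dict[str, list] = {"M": [], "F": []}
    mapping_stats = []
    for rs in read_sets:
        assigned, unassigned = demultiplex_and_trim(rs.reads, [vp])
        prof, stats = profile_from_reads(assigned[vp.name], reduced)
        profiles[rs.sex].append(prof)
        stats = stats.assign(replicate=rs.replicate_id, unassigned=unassigned)
        mapping_stats.append(stats)
    merged = {sex: normalize_and_merge(profs, vp) for sex, profs in profiles.items()}
    results: dict[str, FourCResults] = {
        sex: call_interactions(m, vp, fdr_threshold=fdr_threshold,
                               z_threshold=z_threshold)
        for sex, m in merged.items()
    }
    return {
        "profiles": profiles,
        "merged": merged,
        "results": results,
        "mapping_stats": pd.concat(mapping_stats, ignore_index=True),
    }


def _planted_regions_for_sex(truth: SyntheticTruth, sex: str) -> pd.DataFrame:
    ints = truth.planted_interactions
    return ints[(ints.sex == "both") | (ints.sex == sex)]


def fourc_recovery_metrics(truth: SyntheticTruth, study: dict,
                           sexdiff_fdr: float = 0.1,
                           smooth_pad_fragments: int = 5) -> dict:
    """Score one processed 4C study against the planted truth.

    * sensitivity counts planted shared interactions recovered by the
      interaction caller in each sex where they are planted;
    * the fragment-level false-call rate counts significant fragments
      outside any planted region (expanded by ``smooth_pad_fragments`` on
      each side, since median smoothing legitimately bleeds enrichment into
      neighboring fragments);
    * the sex comparison is evaluated on the union of called regions, and a
      label-permutation null (both groups = the same replicate set) must
      produce no calls.
    """
    fm = truth.fragment_map()
    frag = fm.fragments
    recovered = 0
    total = 0
    false_frags = 0
    tested_frags = 0
    for sex, res in study["results"].items():
        planted = _planted_regions_for_sex(truth, sex)
        shared = planted[planted.sex == "both"]
        for r in shared.itertuples():
            total += 1
            hit = (
                (res.calls.chrom == r.chrom)
                & (res.calls.start < r.end)
                & (res.calls.end > r.start)
            ).any()
            recovered += int(hit)
        stats = res.fragment_stats.dropna(subset=["z"])
        sig = stats[(stats.z > 3) & (stats.fdr < 0.05)]
        tested_frags += len(stats)
        pad_bp = smooth_pad_fragments * int(
            np.median(np.diff(frag[frag.chrom == truth.viewpoint.chrom].start))
        )
        for s in sig.itertuples():
            inside = (
                (planted.start - pad_bp <= s.midpoint)
                & (s.midpoint < planted.end + pad_bp)
            ).any()
            false_frags += int(not inside)

    # sex-differential detection on the union of called regions
    calls = pd.concat([res.calls for res in study["results"].values()])
    detected_female_only = False
    if len(calls):
        regions = merge_intervals(calls[["chrom", "start", "end"]])
        diff = compare_sexes(study["profiles"]["M"], study["profiles"]["F"], regions)
        fo = truth.planted_interactions[truth.planted_interactions.sex == "F"]
        for r in fo.itertuples():
            m = (
                (diff.chrom == r.chrom)
                & (diff.start < r.end)
                & (diff.end > r.start)
                & (diff.sex_differential_fdr < sexdiff_fdr)
                & (diff.log2_mf < 0)
            )
            if m.any():
                detected_female_only = True
        null = compare_sexes(study["profiles"]["M"], list(study["profiles"]["M"]),
                             regions)
        null_calls = int((null.sex_differential_fdr < sexdiff_fdr).sum())
    else:  # pragma: no cover - degenerate
        null_calls = 0
    return {
        "recovered": recovered,
        "planted": total,
        "false_fragments": false_frags,
        "tested_fragments": tested_frags,
        "female_only_detected": detected_female_only,
        "null_calls": null_calls,
    }
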