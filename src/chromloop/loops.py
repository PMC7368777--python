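"""Intra-TAD loop prediction from convergently oriented CTCF motifs at CAC
sites.

A loop candidate is an ordered pair of anchors inside one TAD with the
upstream anchor's best CTCF motif on the + strand and the downstream
anchor's on the - strand (convergent orientation). Candidates are scored by
the geometric mean of the two anchor strengths damped by an exponential span
penalty, then accepted greedily in score order; nesting is allowed to any
depth but partially crossing loops within a TAD are rejected. Anchors may be
reused across loops (nested structures share anchors).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .intervals import GenomicInterval, IntervalCollection, reciprocal_overlap
from .motifs import PositionWeightMatrix, best_hit

MOTIF_THRESHOLD = 10.0
DEFAULT_SPAN_SCALE = 200_000.0
DEFAULT_INITIAL_COUNT = 20_000


def build_anchors(cac_peaks: pd.DataFrame, genome: dict[str, str],
                  pwm: PositionWeightMatrix,
                  threshold: float = MOTIF_THRESHOLD) -> pd.DataFrame:
    """Anchor candidates: one best-scoring motif (> threshold) per CAC peak.

    ``cac_peaks`` needs chrom/start/end and a ``strength`` column (combined
    normalized CTCF+cohesin signal). Peaks without a passing motif are
    dropped. Ties on score go to the leftmost motif.
    """
    rows = []
    for r in cac_peaks.itertuples():
        seq = genome[r.chrom][int(r.start):int(r.end)]
        hit = best_hit(seq, pwm, threshold, chrom=r.chrom, offset=int(r.start))
        if hit is None:
            continue
        rows.append(
            {
                "chrom": r.chrom,
                "start": int(r.start),
                "end": int(r.end),
                "motif_start": hit.interval.start,
                "motif_end": hit.interval.end,
                "orientation": hit.strand,
                "motif_score": hit.score,
                "strength": float(r.strength),
            }
        )
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "motif_start",
                                       "motif_end", "orientation", "motif_score",
                                       "strength"])


def loop_score(strength5: float, strength3: float, span: int,
               span_scale: float = DEFAULT_SPAN_SCALE) -> float:
    return float(np.sqrt(strength5 * strength3) * np.exp(-span / span_scale))


def _candidates(anchors: pd.DataFrame, tads: pd.DataFrame,
                span_scale: float) -> pd.DataFrame:
    rows = []
    for t, tad in enumerate(tads.itertuples()):
        sub = anchors[
            (anchors.chrom == tad.chrom)
            & (anchors.start >= tad.start)
            & (anchors.end <= tad.end)
        ].sort_values("start")
        plus = sub[sub.orientation == "+"]
        minus = sub[sub.orientation == "-"]
        for a5 in plus.itertuples():
            for a3 in minus.itertuples():
                if a3.start <= a5.start:
                    continue
                span = int(a3.end - a5.start)
                rows.append(
                    {
                        "chrom": tad.chrom,
                        "start": int(a5.start),
                        "end": int(a3.end),
                        "anchor5_start": int(a5.start),
                        "anchor5_end": int(a5.end),
                        "anchor3_start": int(a3.start),
                        "anchor3_end": int(a3.end),
                        "span": span,
                        "score": loop_score(a5.strength, a3.strength, span, span_scale),
                        "tad_id": t,
                    }
                )
    cols = ["chrom", "start", "end", "anchor5_start", "anchor5_end",
            "anchor3_start", "anchor3_end", "span", "score", "tad_id"]
    return pd.DataFrame(rows, columns=cols)


def _compatible(a, b) -> bool:
    """Loops in the same TAD must be disjoint or nested, never partially
    crossing."""
    if a["tad_id"] != b["tad_id"]:
        return True
    lo = max(a["start"], b["start"])
    hi = min(a["end"], b["end"])
    if hi <= lo:
        return True  # disjoint
    a_in_b = b["start"] <= a["start"] and a["end"] <= b["end"]
    b_in_a = a["start"] <= b["start"] and b["end"] <= a["end"]
    return a_in_b or b_in_a


def predict_loops(anchors: pd.DataFrame, tads: pd.DataFrame,
                  initial_count: int = DEFAULT_INITIAL_COUNT,
                  span_scale: float = DEFAULT_SPAN_SCALE) -> pd.DataFrame:
    """Greedy selection of convergent-anchor intra-TAD loops.

    All convergent anchor pairs within a TAD are scored; the top
    ``initial_count`` candidates are considered in descending score order
    (ties: smaller span, then leftmost) and accepted unless they partially
    cross an already accepted loop in the same TAD. Output is sorted by
    score.
    """
    cols = ["chrom", "start", "end", "anchor5_start", "anchor5_end",
            "anchor3_start", "anchor3_end", "span", "score", "tad_id"]
    if len(anchors) == 0:
        return pd.DataFrame(columns=cols)
    cand = _candidates(anchors, tads, span_scale)
    cand = cand.sort_values(["score", "span", "chrom", "start"],
                            ascending=[False, True, True, True],
                            kind="stable").head(initial_count)
    accepted: list[dict] = []
    for _, c in cand.iterrows():
        c = c.to_dict()
        if all(_compatible(c, a) for a in accepted):
            accepted.append(c)
    out = pd.DataFrame(accepted, columns=cand.columns)
    return out.reset_index(drop=True)


def validate_loops(loops: pd.DataFrame, anchors: pd.DataFrame, tads: pd.DataFrame) -> None:
    """Assert the structural invariants of a predicted loop set: convergence
    (by construction anchor5 < anchor3 with +/- orientations), same-TAD
    containment, and nesting-only geometry."""
    for r in loops.itertuples():
        tad = tads.iloc[int(r.tad_id)]
        assert tad.chrom == r.chrom
        assert tad.start <= r.start and r.end <= tad.end, "loop escapes its TAD"
        assert r.anchor5_start < r.anchor3_start, "anchors out of order"
        assert r.span <= tad.end - tad.start, "span exceeds TAD length"
    recs = loops.to_dict("records")
    for i in range(len(recs)):
        for j in range(i + 1, len(recs)):
            assert _compatible(recs[i], recs[j]), "partially crossing loops emitted"


def compare_loop_sets(loops_a: pd.DataFrame, loops_b: pd.DataFrame,
                      fraction: float = 0.8) -> dict:
    """Shared/unique partition of two loop sets by reciprocal span overlap.

    A loop in A is shared iff some loop in B overlaps it reciprocally by at
    least ``fraction``; sharing percentages are reported both directions.
    """
    a_iv = [GenomicInterval(r.chrom, int(r.start), int(r.end)) for r in loops_a.itertuples()]
    b_iv = [GenomicInterval(r.chrom, int(r.start), int(r.end)) for r in loops_b.itertuples()]
    b_ic = IntervalCollection(b_iv) if b_iv else None
    a_ic = IntervalCollection(a_iv) if a_iv else None

    def shared_flags(src, other_ic, other_iv_sorted):
        flags = np.zeros(len(src), dtype=bool)
        for i, iv in enumerate(src):
            if other_ic is None:
                continue
            for j in other_ic.overlapping(iv):
                if reciprocal_overlap(iv, other_ic.intervals[j], fraction):
                    flags[i] = True
                    break
        return flags

    a_shared = shared_flags(a_iv, b_ic, None)
    b_shared = shared_flags(b_iv, a_ic, None)
    return {
        "a_shared": a_shared,
        "b_shared": b_shared,
        "pct_a_shared": 100.0 * a_shared.mean() if len(a_iv) else np.nan,
        "pct_b_shared": 100.0 * b_shared.mean() if len(b_iv) else np.nan,
    }


def anchors_vs_diff_sites(loop_anchors: pd.DataFrame, diff_sites: pd.DataFrame,
                          single_sex_loops: pd.DataFrame | None = None) -> pd.DataFrame:
    """Flag each sex-differential site overlapping (>= 1 bp) a loop anchor;
    optionally flag whether the overlapped anchor belongs to a loop predicted
    in one sex only."""
    anchor_iv = []
    for r in loop_anchors.itertuples():
        anchor_iv.append(GenomicInterval(r.chrom, int(r.start), int(r.end)))
    anchor_ic = IntervalCollection(anchor_iv) if anchor_iv else None
    out = diff_sites.copy()
    flags, single_sex = [], []
    ss_ic = None
    if single_sex_loops is not None and len(single_sex_loops):
        ss_ic = IntervalCollection.from_dataframe(single_sex_loops)
    for r in diff_sites.itertuples():
        iv = GenomicInterval(r.chrom, int(r.start), int(r.end))
        flags.append(anchor_ic is not None and anchor_ic.any_overlap(iv))
        single_sex.append(ss_ic is not None and ss_ic.any_overlap(iv))
    out["overlaps_anchor"] = flags
    if single_sex_loops is not None:
        out["anchor_single_sex_loop"] = single_sex
    return out


def loop_anchor_table(loops: pd.DataFrame) -> pd.DataFrame:
    """Deduplicated anchor intervals of a loop set (anchors shared by nested
    loops appear once)."""
    rows = []
    for r in loops.itertuples():
        rows.append((r.chrom, int(r.anchor5_start), int(r.anchor5_end)))
        rows.append((r.chrom, int(r.anchor3_start), int(r.anchor3_end)))
    df = pd.DataFrame(rows, columns=["chrom", "start", "end"]).drop_duplicates()
    return df.sort_values(["chrom", "start"]).reset_index(drop=True)


def write_bedpe(loops: pd.DataFrame, path) -> None:
    cols = ["chrom", "anchor5_start", "anchor5_end", "chrom", "anchor3_start",
            "anchor3_end", "score", "tad_id"]
    df = loops.copy()
    df["chrom2"] = df["chrom"]
    df[["chrom", "anchor5_start", "anchor5_end", "chrom2", "anchor3_start",
        "anchor3_end", "score", "tad_id"]].to_csv(path, sep="\t", header=False, index=False)
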