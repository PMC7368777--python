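"""Cohesin-depletion expression response: RPKM normalization, expression
relative to the wild-type mean, proximal/distal regulatory grouping of
male-biased genes, and the depletion-effect contrast.

The central question: are male-biased genes whose sex-biased enhancers are
all distal (> 20 kb from the TSS) more sensitive to cohesin depletion than
genes with proximal sex-biased enhancers? The contrast is summarized as the
two group medians of mean depleted/wild-type expression ratios with a
two-tailed Mann-Whitney test.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .intervals import GenomicInterval, IntervalCollection, nearest_distance
from .stats import TestResult, mann_whitney

WT_PSEUDOCOUNT = 1e-6
PROXIMAL_DISTANCE = 20_000


@dataclass
class ExpressionMatrix:
    """FPKM values (genes x replicates) with per-replicate condition labels
    ('WT' or 'depleted') and gene lengths in bp."""

    values: pd.DataFrame
    condition: pd.Series
    gene_lengths: pd.Series | None = None

    def __post_init__(self):
        if (self.values.to_numpy() < 0).any():
            raise ValueError("FPKM values must be non-negative")
        if not self.condition.isin(["WT", "depleted"]).all():
            raise ValueError("conditions must be 'WT' or 'depleted'")
        if (self.condition == "WT").sum() < 1:
            raise ValueError("need at least one WT replicate")

    @property
    def wt_columns(self) -> list[str]:
        return list(self.condition.index[self.condition == "WT"])

    @property
    def depleted_columns(self) -> list[str]:
        return list(self.condition.index[self.condition == "depleted"])


def rpkm_normalize(raw_counts: pd.DataFrame, gene_lengths: pd.Series,
                   totals: pd.Series | None = None,
                   condition: pd.Series | None = None) -> ExpressionMatrix:
    """RPKM = count * 1e9 / (gene length * total mapped reads)."""
    if totals is None:
        totals = raw_counts.sum(axis=0)
    if (gene_lengths <= 0).any():
        raise ValueError("gene lengths must be positive")
    if (totals <= 0).any():
        raise ValueError("library totals must be positive")
    lengths = gene_lengths.reindex(raw_counts.index)
    fpkm = raw_counts.mul(1e9).div(lengths, axis=0).div(totals, axis=1)
    if condition is None:
        condition = pd.Series("WT", index=raw_counts.columns)
    return ExpressionMatrix(fpkm, condition, lengths)


def relative_to_wt(matrix: ExpressionMatrix, pseudocount: float = WT_PSEUDOCOUNT) -> pd.DataFrame:
    """Per-gene, per-replicate expression ratio to the wild-type group mean
    (plus a small pseudocount so all-zero genes stay finite). The WT group
    mean of ratios is 1 by construction whenever the WT mean is positive."""
    wt_mean = matrix.values[matrix.wt_columns].mean(axis=1)
    return matrix.values.div(wt_mean + pseudocount, axis=0)


def group_summary(ratios: pd.DataFrame, matrix: ExpressionMatrix) -> pd.DataFrame:
    """Mean +/- SD of relative expression per condition group (the bar-graph
    convention: WT bars sit at 1)."""
    rows = {}
    for cond, cols in (("WT", matrix.wt_columns), ("depleted", matrix.depleted_columns)):
        rows[f"{cond}_mean"] = ratios[cols].mean(axis=1)
        rows[f"{cond}_sd"] = ratios[cols].std(axis=1, ddof=1)
    return pd.DataFrame(rows)


def _point_distance(chrom: str, pos: int, features: IntervalCollection) -> float:
    """Base-to-base distance from a TSS point to the nearest feature edge:
    0 inside a feature, |tss - nearest covered base| otherwise."""
    hit = nearest_distance(GenomicInterval(chrom, pos, pos + 1), features)
    if not hit.reachable:
        return float("inf")
    return hit.distance if hit.distance == 0 else hit.distance + 1


def group_genes(genes: pd.DataFrame, male_dhs: IntervalCollection,
                male_k27ac: IntervalCollection,
                min_fpkm: float = 1.0, min_mf_ratio: float = 3.0,
                proximal_distance: int = PROXIMAL_DISTANCE,
                relaxed: bool = False) -> pd.DataFrame:
    """Regulatory-context grouping of expressed, strongly male-biased genes.

    Eligibility: FPKM > ``min_fpkm`` and male/female expression ratio >
    ``min_mf_ratio``. Distances are measured TSS point to feature edge (0
    when the TSS falls inside a feature). A gene is ``proximal`` when its
    TSS is strictly within ``proximal_distance`` of the nearest male-biased
    DHS *and* the nearest male-biased H3K27ac region; ``distal`` when
    strictly beyond that distance from both; anything else (including a TSS
    at exactly the boundary) is ``neither``. In ``relaxed`` mode proximal
    requires closeness to *either* feature and distal remains "far from
    both".

    ``genes`` needs columns: gene, chrom, tss, fpkm, mf_ratio.
    """
    out = genes.copy()
    d_dhs, d_k27 = [], []
    for r in genes.itertuples():
        d_dhs.append(_point_distance(str(r.chrom), int(r.tss), male_dhs))
        d_k27.append(_point_distance(str(r.chrom), int(r.tss), male_k27ac))
    out["dist_dhs"] = d_dhs
    out["dist_k27ac"] = d_k27
    eligible = (out.fpkm > min_fpkm) & (out.mf_ratio > min_mf_ratio)
    out["eligible"] = eligible
    d1 = out.dist_dhs.to_numpy(dtype=float)
    d2 = out.dist_k27ac.to_numpy(dtype=float)
    if relaxed:
        proximal = (d1 < proximal_distance) | (d2 < proximal_distance)
    else:
        proximal = (d1 < proximal_distance) & (d2 < proximal_distance)
    distal = (d1 > proximal_distance) & (d2 > proximal_distance)
    group = np.full(len(out), "neither", dtype=object)
    group[proximal] = "proximal"
    group[distal & ~proximal] = "distal"
    group[~eligible.to_numpy()] = "ineligible"
    out["group"] = group
    return out


@dataclass
class DepletionResponseResults:
    """Group medians of mean depleted relative expression with the
    Mann-Whitney contrast."""

    per_gene: pd.DataFrame
    median_proximal: float
    median_distal: float
    test: TestResult

    @property
    def median_ratio(self) -> float:
        return self.median_distal / self.median_proximal

    def summary(self) -> str:
        return "\n".join(
            [
                "Cohesin-depletion response of male-biased genes",
                f"  proximal genes: n={int((self.per_gene.group == 'proximal').sum())}, "
                f"median relative expression = {self.median_proximal:.3f}",
                f"  distal genes:   n={int((self.per_gene.group == 'distal').sum())}, "
                f"median relative expression = {self.median_distal:.3f}",
                f"  fold contrast (distal/proximal medians): {self.median_ratio:.3f}",
                f"  Mann-Whitney U = {self.test.statistic:.1f}, p = {self.test.p_value:.2e}",
            ]
        )

    def boxplot(self, ax=None):
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(3, 4))
        data = [
            self.per_gene.loc[self.per_gene.group == g, "depleted_relative"]
            for g in ("proximal", "distal")
        ]
        ax.boxplot(data, tick_labels=["proximal", "distal"], whis=1.5)
        ax.set_ylabel("relative expression (depleted / WT)")
        ax.set_yscale("log")
        return ax


class DepletionResponseModel:
    """Contrast of depletion sensitivity between proximally and distally
    regulated male-biased genes.

    Built from an :class:`ExpressionMatrix` and the regulatory-context table
    from :func:`group_genes`; ``fit`` computes each gene's mean
    depleted-replicate relative expression and compares the proximal and
    distal groups.
    """

    def __init__(self, matrix: ExpressionMatrix, contexts: pd.DataFrame,
                 pseudocount: float = WT_PSEUDOCOUNT):
        self.matrix = matrix
        self.contexts = contexts
        self.pseudocount = pseudocount

    def fit(self) -> DepletionResponseResults:
        ratios = relative_to_wt(self.matrix, self.pseudocount)
        depleted_mean = ratios[self.matrix.depleted_columns].mean(axis=1)
        per_gene = self.contexts.copy()
        per_gene["depleted_relative"] = depleted_mean.reindex(
            per_gene["gene"] if "gene" in per_gene else per_gene.index
        ).to_numpy()
        prox = per_gene.loc[per_gene.group == "proximal", "depleted_relative"].dropna()
        dist = per_gene.loc[per_gene.group == "distal", "depleted_relative"].dropna()
        if len(prox) == 0 or len(dist) == 0:
            raise ValueError("both proximal and distal groups must be non-empty")
        test = mann_whitney(prox, dist)
        return DepletionResponseResults(
            per_gene,
            float(np.median(prox)),
            float(np.median(dist)),
            test,
        )


def compare_depletion_effect(matrix: ExpressionMatrix,
                             contexts: pd.DataFrame) -> DepletionResponseResults:
    """Functional wrapper around :class:`DepletionResponseModel`."""
    return DepletionResponseModel(matrix, contexts).fit()
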