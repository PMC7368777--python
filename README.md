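# chromloop

Tools for studying how 3D genome organization — CTCF/cohesin binding,
intra-TAD loops, and viewpoint-based chromatin interactions — shapes
sex-biased gene expression, in the style of the mouse-liver sex-dimorphism
literature. The package implements the full computational chain for this
kind of study and pairs every stage with a synthetic-data generator that
plants known truth, so each pipeline can be validated in a closed loop
without any sequencing downloads.

## What it does

* **Differential ChIP-seq binding** (`chromloop.chipdiff`): a windowed
  negative-binomial comparison of male vs female replicate read counts
  (200-bp sliding windows, step = half window). Per window with group sums
  `S_M`, `S_F` and pooled dispersion `α` (variance = `μ + αμ²`), the
  p-value is the exact conditional test `S_M | S_M + S_F ~
  BetaBinomial(S_M + S_F, n_M/α, n_F/α)`. Merged significant windows are
  filtered to *standard-stringency* sex-differential sites (union-peak
  overlap, ≥ 10 reads, > 2-fold, FDR < 0.05); a *lenient* tier comes from
  an MA-normalization comparison (`M = log2 m/f`, `A = ½·log2 mf`, common-
  peak linear rescaling) of FRiP-matched merged samples (≥ 2-fold,
  p-adj < 0.01, > 15 reads). Includes a windowed Poisson peak caller (an
  external peak BED can be supplied instead), PCR-artifact peak removal,
  RIPM (reads-in-peaks-per-million) normalization, FRiP-matched
  down-sampling and sex-independent peak selection.
* **Site classification** (`chromloop.classify`): CAC / CNC / Lone-CTCF
  assignment of sex-differential sites by counting overlaps against the
  other factor's replicate peak sets (cohesin sites vs 4 CTCF replicates:
  3–4 hits → CAC, 0–1 → CNC, 2 → excluded; CTCF sites vs 3 cohesin
  replicates: 2–3 → CAC, 0–1 → Lone CTCF), plus mutually exclusive
  proximity labels (Proximal < 20 kb > IntraTAD > TAD > Outside) and
  enhancer-distance annotation with KS comparisons.
* **Intra-TAD loop prediction** (`chromloop.loops`): loops are convergent
  pairs of CAC anchors (best CTCF motif score > 10, `+` upstream / `−`
  downstream) within one TAD, scored `√(s₅·s₃)·exp(−span/λ)` and accepted
  greedily; nesting is allowed, partial crossings are rejected. Loop sets
  are compared by ≥ 80% reciprocal overlap.
* **4C-seq pipeline** (`chromloop.fourc`): in-silico DpnII digestion
  (GATC), a reduced genome of 105-bp flanks around every cut site,
  exact-primer demultiplexing and trimming (150/125-nt reads → 105-nt
  inserts), iterative 3′-trimmed unique mapping (10-nt steps, 2-nt for
  short reads, down to 20 nt), 11-fragment median smoothing, RPM
  normalization, median replicate merging with viewpoint masking, and
  interaction calling against a fitted log–log distance-decay expectation
  (z > 3 and BH FDR < 0.05), plus a replicate-level sex comparison
  (FDR < 0.1).
* **Cohesin-depletion response** (`chromloop.expression`): RPKM
  normalization, per-gene expression relative to the wild-type mean
  (pseudocount 1e−6), grouping of strongly male-biased genes (FPKM > 1,
  M/F > 3) into enhancer-proximal (< 20 kb from the nearest male-biased
  DHS *and* H3K27ac region) vs distal (> 20 kb from both), and the
  Mann-Whitney contrast of group medians.
* **Synthetic truth** (`chromloop.simulate`): toy genomes with geometric
  GATC spacing, TADs, oriented CTCF consensus embeddings, planted
  CAC/CNC/Lone peaks with sex effects, negative-binomial ChIP replicates,
  decay-model 4C reads with multi-junction ligation products and planted
  focal interactions, and expression matrices with planted depletion folds.

## Worked example

```python
from chromloop import (SimConfig, make_genome, simulate_expression,
                       group_genes, DepletionResponseModel)
from chromloop.workflows import run_4c_study

truth = make_genome(SimConfig(seed=0))

# cohesin-depletion contrast: distal vs proximal male-biased genes
contexts = group_genes(truth.planted_expression, truth.male_dhs, truth.male_k27ac)
mat = simulate_expression(truth, n_wt=4, n_depleted=4, seed=1)
print(DepletionResponseModel(mat, contexts).fit().summary())

# full 4C study: simulate 3 replicates/sex, map, smooth, merge, call
study = run_4c_study(truth, seed=1)
print(study["results"]["F"].summary())
```

```
Cohesin-depletion response of male-biased genes
  proximal genes: n=29, median relative expression = 0.716
  distal genes:   n=32, median relative expression = 0.098
  fold contrast (distal/proximal medians): 0.137
  Mann-Whitney U = 928.0, p = 2.17e-11

4C interaction calls for viewpoint 'vp1'
  fragments tested: 1523
  regions called (z > 3.0, FDR < 0.05): 4
    chr1:78544-81516  z=24.51  fdr=3.72e-131
    chr1:165344-168106  z=25.61  fdr=9.39e-142
    chr1:251870-254553  z=25.37  fdr=9.17e-140
    chr1:338702-341222  z=24.26  fdr=1.29e-128
```

The depletion medians recover the planted 10-fold (distal) and 1.4-fold
(proximal) suppressions: genes whose sex-biased enhancers are all distal
lose most of their expression when cohesin is depleted, while proximally
regulated genes barely change. The female 4C profile calls all four planted
interaction blocks (three shared, one female-only); the male profile calls
only the three shared ones, and `chromloop.fourc.compare_sexes` flags the
female-only region at FDR < 0.1.

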