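# midmei

Analysis toolkit for the transcriptional network that shuts down yeast
middle-meiosis genes: the activator **Ndt80** turns middle sporulation
genes on, and the repressor **Sum1** turns them off again in late
meiosis — either *directly*, by binding a target's promoter, or
*indirectly*, by repressing *NDT80* itself.  Together the two factors
form a coherent type-2 feed-forward loop, and the central question the
package addresses is: **for each target gene, how much of its late
repression flows through each arm of the loop?**

The package is aimed at computational biologists working with
two-colour microarray (or microarray-like) data from staged cultures.
It implements the complete analysis chain as composable library
modules, plus a synthetic-data generator with full ground truth so
every stage can be exercised and validated without any external
download.

## What it computes

**Normalization** (`midmei.arrays`) — robust lowess regression of
M = log2(sample/reference) on A = ½·log2(sample·reference) per array,
dye-swap handling, quality filtering and duplicate-spot / replicate
averaging.

**Deconvolution** (`midmei.deconvolution`) — a sporulating culture is
asynchronous, so expression at hour *t* mixes cells at different
meiotic stages: x_g(t) = Σ_s C(t,s)·e_g(s) + ε.  The composition C is
estimated from DAPI nuclear staging counts (mono-/bi-/tetranucleate
cells) through a progression model (Normal start-time offsets, fixed
stage durations), and the synchronous profiles e_g are recovered by
ridge least squares, one shared factorization of (CᵀC + λI) for all
genes.

**ChIP target calling** (`midmei.binding`) — per-promoter Z scores of
averaged binding ratios; the detection threshold is chosen by a
mirrored-null FDR: assuming the unbound Z distribution is symmetric
about zero, FDR(c) = #{Z ≤ −c} / #{Z ≥ c}, and the smallest cutoff
with FDR ≤ α (default 0.05) is used.  Called activator and repressor
target sets are classified into activator-only / common /
repressor-only groups, with hypergeometric overlap statistics.

**Motif scanning** (`midmei.motifs`) — log-odds PSSMs
W(nuc,j) = log2((f(nuc,j)+ε)/p(nuc)) from frequency matrices, scanning
of both promoter strands, per-promoter maxima, and a threshold
calibrated so that a configured fraction (default 5%) of the promoter
universe is called; per-group fold enrichments of site presence.

**Clustering** (`midmei.clustering`) — selection of temporally variable
genes (log2 range strictly above a cutoff) and k-means under
correlation distance d(x,y) = 1 − r(x,y), with hypergeometric /
Benjamini–Hochberg annotation enrichment.

**Feed-forward-loop dissection** (`midmei.ffl`) — per-gene linear
repression folds R = 2^(x(middle) − x(late)) in three genetic
backgrounds (wild type; *sum1Δ*, which removes both repression arms;
and an estradiol-inducible-*NDT80* "ER" strain, which severs only the
indirect arm), and the **indirect-contribution weight**

    W = clamp(1 − ln R_ER / ln R_wt, 0, 1)

W = 0 means the ER mutant represses like the wild type (direct
repression suffices); W = 1 means repression vanishes when *NDT80*
escapes Sum1 (the indirect arm carries everything).  Equivalently
R_ER = R_wt^(1−W).

**Synthetic studies** (`midmei.synthetic_data`) — expression in the
three backgrounds, DAPI counts, replicated ChIP ratios with a symmetric
null, and promoters with planted MSE/MSE*-like sites, all generated
from one seed with the ground truth (gene classes, stage profiles,
planted weights, site positions) recorded for validation.

## Worked example

Run the full pipeline on the default synthetic study (2,000 genes,
240 bound promoters, twelve wild-type timepoints over 18 h):

```python
from midmei.pipeline import run_study, classification_accuracy

result = run_study(seed=1)
print({k: len(getattr(result.groups, k))
       for k in ("activator_only", "common", "repressor_only")})
print(result.group_summary[["n", "mean_R_wt", "mean_R_er",
                            "mean_R_sumdel", "mean_W", "p_wt_vs_er"]].round(3))
print("classification accuracy:", classification_accuracy(result))
```

prints

```
{'activator_only': 80, 'common': 40, 'repressor_only': 120}
                  n  mean_R_wt  mean_R_er  mean_R_sumdel  mean_W  p_wt_vs_er
group
activator_only   80     23.319      0.990          1.010   0.976       0.000
common           40     26.521     25.822          1.007   0.038       0.464
repressor_only  120      1.019      0.986          1.013     NaN       0.367
classification accuracy: 1.0
```

Reading the table: activator-only targets are strongly repressed late
in the wild type (mean fold 23.3) but lose essentially all repression
in the ER strain (fold ≈ 1, paired p ≈ 10⁻⁶⁸, mean W ≈ 0.98 — their
repression is indirect, via Sum1's control of *NDT80*); common targets
repress equally in both strains (W ≈ 0 — direct Sum1 binding suffices);
and both groups are fully de-repressed (fold ≈ 1) when *SUM1* is
deleted.  That is exactly the planted feed-forward-loop structure, and
all 240 bound promoters were placed in their true ChIP group.

The same pipeline is available from the shell:

```sh
midmei run --out results_dir --seed 1
midmei simulate --out study_dir --seed 1       # data only
midmei scan --fasta study_dir/promoters.fasta \
            --pfm study_dir/pfm_activator.txt --fraction 0.05 --out scores.tsv
```

## Layout

```
src/midmei/
  synthetic_data.py   generator + ground truth + study I/O
  arrays.py           spot tables, lowess MA normalization, averaging
  deconvolution.py    DAPI staging -> composition; ridge inversion
  binding.py          Z scores, mirrored-null FDR, target groups
  motifs.py           PSSMs, promoter scanning, threshold calibration
  clustering.py       variable-gene selection, correlation k-means
  ffl.py              repression folds, indirect weight W, contrasts
  pipeline.py         end-to-end orchestration + run manifest
  cli.py              `midmei` command group
docs/methods.md       model assumptions, parameter choices, limitations
```
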