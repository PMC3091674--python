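# Methods

This note records the models behind each stage, the defaults and why
they were chosen, what the synthetic generator does and does not
emulate, and the numerical conventions.

## The biological model

Middle-meiosis genes in budding yeast are induced by the activator
Ndt80 and re-repressed in late meiosis by the repressor Sum1.  Sum1 can
repress a target directly (binding an MSE*-type site in its promoter)
and indirectly, by repressing *NDT80* itself — a coherent type-2
feed-forward loop.  Three genetic backgrounds separate the arms:

- **wild type** — both arms intact; targets pulse in middle meiosis and
  fall back late;
- ***sum1Δ*** — both arms removed; targets stay high late
  (repression fold R ≈ 1);
- **ER** (estradiol-inducible *NDT80*) — *NDT80* escapes Sum1, severing
  only the indirect arm; a target retains exactly the direct fraction
  of its repression.

## Repression fold and the indirect weight W

Per gene, R = 2^(x(middle) − x(late)) on log2 expression, R > 1
meaning late repression.  The weight of the indirect arm is

    W = clamp(1 − ln R_ER / ln R_wt, 0, 1),     R_ER = R_wt^(1−W).

Properties: W is a ratio of logarithms and therefore independent of the
log base; it is continuous and non-increasing in R_ER; W = 0 iff the ER
strain represses like the wild type; W = 1 iff the ER strain does not
repress at all.  W is only defined where the wild type actually
represses (R_wt > 1); such genes carry a reason flag instead of a
value.  **Caveat:** the equation defining this weight in the source
study is not recoverable from its text (it survives only as a figure
image); the form above is a reconstruction that satisfies every
property stated verbally, and it is the generative definition used by
the synthetic data, so recovery tests close the loop against the same
definition they plant.

The default cutoff selecting "repressed" targets for the W analysis is
R_wt ≥ 1.3; the group contrast between backgrounds uses a two-sided
paired t-test on per-gene log2 fold differences (Wilcoxon signed-rank
available as an alternative), with an all-zero difference vector
flagged as degenerate rather than tested.

## Deconvolution of asynchronous cultures

Observed expression mixes meiotic stages: x_g = C·e_g + ε.  The
composition model assumes each cell starts the meiotic program at
T0 ~ Normal(start_mean, start_sd) and then traverses stages of fixed
duration; stage s ≥ 1 is entered at T0 + (s−1)·d, the last stage is
absorbing, and stage 0 holds cells that have not started.  Row
occupancies are differences of the start-time CDF, so rows sum to 1
exactly and the degenerate sd = 0 case yields one-hot rows.

DAPI staging gives three categories per timepoint (mononucleate =
pre-MI stages, binucleate = post-MI, tetranucleate = post-MII; the
stage→category boundaries are declared in the model, default stages
0–3 / 4–5 / 6–7 of 8).  `composition_from_counts` either uses the raw
category fractions (3 stages, "direct" mode) or fits (start_mean,
start_sd) to the category fractions by least squares and expands to the
configured number of sub-stages ("model" mode, the pipeline default).

The inversion solves min_e ‖x_g − C e‖² + λ‖e‖² per gene with one
factorization of CᵀC + λI shared across genes; per-gene missing
timepoints drop rows of the system (solved per missing-pattern).
λ defaults to 1e-3 — small enough to be negligible where C is well
conditioned, large enough to stabilize under-determined fits.  No
non-negativity constraint is imposed: values are log ratios.  λ = 0
with a rank-deficient system is an error instructing the caller to
regularize, not a silent pseudo-inverse.  An optional first-difference
smoothness penalty was considered and left out: on the reference
conditions the ridge alone recovers profiles well (median per-gene
r ≈ 0.93), and a smoothness prior would bias the sharp pulse edges the
downstream fold analysis depends on.

## Mirrored-null FDR for ChIP target calling

Averaged per-promoter binding ratios are standardized to Z scores
(sample sd, n−1).  Assuming the unbound population is symmetric about
zero, the negative tail counts estimate false positives in the positive
tail: FDR(c) = #{Z ≤ −c} / max(1, #{Z ≥ c}), capped at 1, with every
observed positive |Z| a candidate cutoff; the smallest qualifying
cutoff is returned and promoters with Z at or above it are called.
Two estimator behaviours worth knowing:

- because the scan reaches the extreme tail, a pure-null study still
  calls the top-ranked score in roughly half of runs (FDR(max) = 0/1
  whenever the largest |Z| happens to be positive); called sets under
  the null are therefore *tiny* (almost always ≤ 2 of 6000) rather
  than strictly empty.  The conservative "+1 numerator" variant would
  remove this at the cost of changing the calling contract; the plain
  ratio is kept.
- standardization uses the mean and sd of the full mixture, so a large
  planted-signal fraction shifts the mirror point slightly and makes
  the estimator conservative; under the reference conditions (5%
  bound, shift 3, duplicate arrays averaged) realized FDR is ≈ 1% at
  the α = 0.05 level with ≈ 97% sensitivity.

## Motif scanning

Weights are W(nuc,j) = log2((f+ε)/p) with pseudocount ε = 0.01 and the
background as printed for yeast intergenic regions, p_G = p_C = 0.34,
p_A = p_T = 0.16.  Yeast intergenic DNA is AT-rich, so this looks like
an A/T↔G/C transposition in the source; the printed values are kept as
the default rather than silently corrected, and the background is a
parameter.  Because fixed score thresholds depend on the log base (the
base behind the published fixed cutoffs is not recoverable), the
primary calling mechanism is base-independent: the threshold is
calibrated so a configured fraction (default 5%) of the promoter
universe exceeds it, with strict exceedance.  Both strands are scanned
by default; windows containing N score −∞ and can never be maximal;
coordinates are 0-based, half-open, forward-strand.

A consequence of fraction calibration: fold enrichments are relative to
a fixed universe rate, so when planted/bound promoter classes are
common, the background class's fold sits slightly below 1 (the
enriched classes absorb part of the calibrated 5%).

## Clustering

Genes whose log2 range (max − min over timepoints, strict inequality)
exceeds the cutoff are clustered by Lloyd k-means under correlation
distance 1 − r.  Profiles are centred and scaled to unit norm per
gene, which makes the correlation-optimal centroid the renormalized
mean of member vectors (spherical k-means), so the objective is
provably non-increasing per iteration.  Empty clusters are reseeded at
the point farthest from its current centroid; the best of 20 seeded
restarts (by total distance) is kept, making results deterministic
given the seed.  Correlation distance makes assignments invariant to
per-gene shifts and positive rescalings.  Annotation enrichment is a
hypergeometric upper tail per (cluster, category) against a
user-declared universe with Benjamini–Hochberg adjustment across all
tested pairs (raw p values are also emitted).

## Normalization

Lowess span 0.3 with 3 robustifying iterations (the source names the
method only; these are the customary defaults), global over each
array's A range — no print-tip stratification.  Interpolation delta
defaults to 1% of the A range (the standard speed/accuracy tradeoff;
set 0 to fit every point).  Dye-swapped arrays are sign-flipped before
fitting, so toggling the flag negates an array's normalized values
exactly.  Like any MA normalization it removes the array-wide mean
ratio along with the dye trend, which is correct when most genes are
unchanged and slightly compresses strain-wide expression shifts
otherwise.  Flagged spots are excluded from fitting and from feature
averages; a feature is missing on an array only when all of its spots
are flagged, and missingness propagates as data, not errors.

## The synthetic generator

The generator's defaults define the reference study: 2,000 genes in
six classes (80 activator-only, 40 common, 120 repressor-only, 80
late-rising, 50 middle-repressed, 1,630 background), stage archetypes
that are piecewise-linear pulse / dip / ramp shapes chosen for
identifiability (the source shows only cluster heat maps), per-gene
peak amplitude 5 ± 20% log2 units, and Normal(0, 0.2) noise at both
the stage and observation level.  Cultures start the program at
Normal(9 h, 1 h) and spend 1.25 h per stage — the synchrony parameters
are not published anywhere, so these are design choices: the spread
was set from a conditioning analysis of the mixing matrix to represent
the tight synchrony reported for middle meiosis while keeping the
12-timepoint wild-type course (2.5–18 h) informative about all eight
stages.  Wild-type middle/late reference hours are 14/18; the deletion
strain samples 10/17/21 h; the ER strain is sampled on the same
absolute 8/14/18 h schedule as the wild-type reference hours so both
backgrounds are measured at identical culture stages (the source's ER
sampling is phrased relative to estradiol addition; the map is
configurable).

Planted indirect weights follow the loop's own mechanism: activator-
only targets default to W_true = 1 (no direct repressor site — all
repression is indirect) and common targets to W_true = 0 (direct
repression intact); both are configurable intervals, and the recovery
analyses use continuous W_true ∈ [0, 1].  The *sum1Δ* transformation
clamps post-peak stage values at the pulse level (running maximum) and
damps target amplitudes by 0.6 — sustained-high rather than continued
accumulation, keeping values bounded — while the ER transformation
maps post-peak values v to W·v_middle + (1−W)·v, which makes
R_ER = R_wt^(1−W) an exact identity of the noiseless construction.

ChIP ratios are two replicates per factor of a symmetric null
(Normal(0, 0.8) per replicate by default; Laplace and logistic
alternatives are available since the FDR procedure only assumes
symmetry) with bound promoters shifted by 4 log2 units (strong
sequence-specific binding; the FDR calibration study uses shift 3).
Promoters are 500 nt of AT-rich background (p_A = p_T = 0.34) with
sites sampled from synthetic MSE/MSE*-like frequency matrices — the
study's own matrices came from a de novo discovery tool and are not
printed, so these are synthetic constructions with uneven per-column
information, sharing a CACAAA core so the two motifs cross-react
partially, as the real sites do.  Spot tables encode each expression
matrix as two duplicate-spotted arrays per timepoint (one dye-swapped)
with a smooth intensity-dependent dye bias and spot noise scaled so
the four-spot average matches the matrix-level noise.

What the generator does **not** emulate: image-level artifacts and
background subtraction, print-tip spatial effects, saturation,
cross-hybridization, correlated biological replicates, stage-duration
heterogeneity between cells, and any sequence evolution.  Passing
tests therefore demonstrate correctness of the analysis under the
stated statistical model, not robustness to every artifact of real
arrays.

## Numerical conventions and edge cases

- log base 2 throughout for expression and binding ratios.
- Composition rows sum to 1 within 1e-12 by construction; DAPI counts
  are multinomial with 200 cells per timepoint.
- All randomness flows from one seed through named per-purpose
  generators (expression / observation / chip / sequence / composition
  / spots), so any data type can be regenerated independently and
  full studies are byte-reproducible.
- Calibrated motif thresholds use strict exceedance, so with N
  promoters the called fraction is about fraction − 1/N; fraction = 1
  returns a value below the minimum score.
- Mirrored-FDR called sets use Z ≥ threshold (inclusive), matching the
  scan's candidate semantics; ties at the threshold are called.
- Zero-variance profiles are rejected by the clusterer by name;
  constant inputs are errors for Z scoring; empty universes are errors
  for calibration and enrichment.

## Reference problem sizes

The validation suite runs the scanner-oracle comparison on 50×60 nt
sequences, FDR calibration on 100 replicate 6,000-promoter studies,
deconvolution recovery on 500 genes × 12 timepoints × 8 stages, weight
recovery on 800 genes, and the end-to-end contrast on 20 replicate
2,000-gene studies — sizes chosen so the whole suite completes in a
few minutes on one CPU while keeping Monte-Carlo error well inside the
asserted margins.
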