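# Methods

## Dose–response model families and likelihood

Both families treat the response as positive and continuous with
multiplicative noise: `log y ~ Normal(log f(x; θ), σ²)` with a common
log-scale σ across dose groups. Maximizing this likelihood is least squares
on log responses with σ profiled out analytically, and it makes the geometric
mean the natural location estimate (the level-1 MLE of `a` is exactly the
geometric mean of all responses). Log-normal errors are the standard choice
for viability percentages and cytokine concentrations, whose scatter grows
with the mean and which cannot go negative.

The two printed family definitions in common circulation contain algebraic
slips (a level-4 exponential that collapses to level 2, and a Hill
denominator `bd + x^d` that is dimensionally inconsistent); this package
implements the canonical nested forms (README table) in which level 3 is
level 5 with c = 0, level 4 is level 5 with d = 1, and every member reduces
to `y = a` at dose 0. The sign of `b` is free in the exponential family so
that both decreasing (viability) and increasing (IL-1β) curves are reachable
at every level, and the level-2 member embeds exactly into levels 4/5 via
(c = 0, b → −b); the Hill `b` is a dose-scale parameter constrained positive.

Parameter constraints: a > 0 (optimized as log a), d ∈ [1, 4], c ∈ [0, 20].
The lower bound d ≥ 1 excludes infinite-slope fits at dose 0 on sparse
designs; c ≤ 20 caps the asymptote factor at a 20-fold induction, ample for
the cytokine fold changes this pipeline targets.

### Optimization

Each member is fitted by bounded trust-region least squares
(`scipy.optimize.least_squares`, method `trf`) from deterministic multistarts
derived from data quantiles (background from the control geometric mean,
slope from the top-dose/control log ratio, Hill scale from the median
positive dose, d ∈ {1, 2}), plus warm starts that embed every already-fitted
nested submodel into the bigger one. The embedding guarantees the
log-likelihood is non-decreasing along the nesting chains regardless of
optimizer tolerance, because the bigger fit starts at the submodel's optimum
and trust-region steps never increase the cost.

### Selection, goodness of fit

Selection walks 1 → 2 → {3, 4} → 5, accepting an extension only when the
likelihood-ratio test (2Δloglik vs χ² with df = parameter-count difference)
is significant at α = 0.05 (configurable); when levels 3 and 4 both improve
on 2, the one with the higher likelihood proceeds. Levels above the stopping
point are never fitted.

The goodness-of-fit test compares the selected curve to the saturated "full
model" of per-dose-group log means; the model is retained when p > 0.05.
Because the LR statistic with σ profiled out is a monotone function of
`F = ((RSS_fit − RSS_full)/df1)/(RSS_full/df2)`, the p-value uses the exact
F(df1, df2) null: at three replicates per dose group the χ² approximation
rejects a correct model ~15% of the time at nominal 5%, which we verified by
simulation; the F form restores the nominal rate. The asymptotic χ² is kept
only for designs with one replicate per dose (no residual degrees of
freedom).

### Benchmark dose and profile-likelihood interval

The BMD solves `f(BMD) = a·(1 ± BMR)` in the direction the fitted curve
moves; closed forms exist for every member and are used directly (with a
guard rejecting BMDs beyond 10× the highest tested dose). BMR defaults to
0.10 in the analysis drivers; 0.50 is equally supported as a run-time
parameter — both conventions appear in toxicology practice and neither is
hard-coded.

For the 90% interval the model is reparameterized so the BMD is explicit:
`b` is eliminated through the closed-form inverse (which never involves `a`,
since the benchmark response is relative), and the profile log-likelihood at
a fixed BMD maximizes over the remaining parameters — `log a` analytically
(the curve is multiplicative in `a`), c and d by Nelder-Mead warm-started
from the MLE and the neighbouring profile point. BMDL/BMDU are found by
stepping geometrically away from the MLE BMD until the profile drops
½·χ²₁(0.90) = 1.3528 below its maximum, then Brent root refinement; a bound
not crossed within 10⁶× of the BMD is reported as 0 or ∞ rather than
invented. The test suite checks the bounds against an independent brute-force
oracle (200-point grid of constrained refits with `b` solved by bisection).

Model averaging follows the min/max rule: the reported BMD is the geometric
mean over accepted models and the interval spans the smallest BMDL to the
largest BMDU. Each model's own BMD is profiled (not the average) — this
matches the min-BMDL/max-BMDU combination rule.

### What the recovery simulations do and do not show

The acceptance-level recovery experiment (100 studies generated from E3 with
a = 100, b = −0.002, d = 1.5, log-scale SD 0.05, seven dose groups × three
replicates) yields a median relative error of ~7% for the procedure's
averaged BMD. Coverage of the 90% profile interval is measured on the MLE
fit of the generating model, where it is 85%: the asymptotic χ²₁ calibration
is a few points below nominal at n = 21. Intervals taken after
likelihood-ratio model selection cover ~80–82% — the additional loss is
selection bias, a generic property of select-then-estimate pipelines, not of
the profile machinery (which matches the brute-force oracle within 2%). We
deliberately keep the conventional 1.3528 drop rather than a small-sample
correction, as that is the field's standard procedure.

## Plate assays

WST-1 viability is `(A(cells,X) − A(medium,X)) / (A(cells,C) − A(medium,C))
× 100` on background-corrected A440 − A620 signals, replicate wells averaged
before the ratio; the quantity is invariant under a common detector gain.

The ELISA calibration is the asymmetric five-parameter logistic
`OD = lower + (upper − lower)/(1 + (conc/c50)^slope)^asymmetry` with
`slope < 0` so OD rises with concentration and the blank (concentration 0)
anchors the lower asymptote; fitting is unweighted Levenberg–Marquardt from
two slope starts. Inversion is analytic and only defined strictly between the
asymptotes — out-of-range ODs raise a flag instead of being clipped. Measured
supernatant concentrations are multiplied by the pre-dilution factor (20-fold
in the emulated IL-1β protocol).

Endotoxin classification multiplies the product limit (0.5 EU/mg) by the
tested concentration (100 µg/mL → 0.05 EU/mL) and reports A (below), B
(above) or C (particle interference — an input flag, because the published
interference criterion is not stated; an optional helper flags spike
recoveries outside the standard 50–200% LAL window).

Geometry: surface-to-volume is 2(r + h)/(r·h) for a flat-capped cylinder and
3/r for a sphere; dose conversion multiplies particle-number nM by the
per-particle mass factor (1.324 µg/mL per nM for the 60 × 14 nm rod).

## Microarray stage

Reliability filtering keeps features that pass all five scanner-style flags;
the flags are consumed, not computed (they come from feature-extraction
software, and the synthetic generator fabricates them). Quantile
normalization follows the definitional algorithm — each column's sorted
values are replaced by the mean sorted vector, ranks preserved — written
directly (a few lines; no installed Python package exposes this exact
operation). Collapse to gene symbols takes the per-symbol median, robust to
a single bad probe. The per-gene test is the equal-variance two-sample
*t*-test (conventional at n = 3 per group; Welch is a flag away), with the
zero-variance-zero-difference degenerate case reported as p = 1.

The DEG set is the union over comparisons at p < 0.001, with per-comparison
counts and pairwise overlaps retained so union arithmetic is auditable. The
FDR estimate is expected false positives over observed calls:
`(n_comparisons × n_genes × α) / total calls` — the only reading consistent
with published union/FDR bookkeeping of this design (7 × 10,246 × 0.001/656
≈ 11%); it is an inference about that bookkeeping, not an authorial formula.
PCA is the centered SVD with samples as observations; the heatmap clusters
per-gene log2FC vectors with Euclidean distance and average linkage
(configurable — no specific choice is canonical here).

At the generator's stated spike conditions (log2FC 2, within-group SD 0.25,
n = 3) the exact power of the t-test at α = 0.001 is 0.72 (noncentral t,
ncp = 2/(0.25·√(2/3)) = 9.80, df = 4); the spike-recovery test asserts the
empirical rate against this analytic value rather than a round aspiration.

## GSEA

Ranking is by signed t, ties broken lexicographically for determinism. The
enrichment score is the weighted Kolmogorov–Smirnov running sum (hit steps
∝ |metric|^p with p = 1, miss steps 1/(N − Nh)); ES is the extremum of the
running sum, with exact ties between equal-magnitude positive and negative
extrema resolved to the positive one (documented tie rule, needed only in
adversarial fixtures). Infinite metrics (zero-variance genes) are assigned
the largest finite hit weight. Significance uses gene-label permutation —
with three replicates per group, phenotype permutation admits only 10
distinct relabelings and cannot reach p < 0.1 — with
`p = (1 + #{|null ES| ≥ |ES|})/(1 + n_perm)`, NES as ES over the mean |null
ES| of matching sign, and Benjamini–Hochberg q across sets. Gene sets come
from user-supplied GMT files; no pathway collection is bundled as ground
truth, because no specific collection vintage can be verified.

## Synthetic data

The generators emulate the study conditions: 2-fold dose series (control +
3.125–100 µg/mL) with three replicates and multiplicative log-normal noise
(SD 0.05 for viability, 0.25 for cytokines — typical plate-assay CVs);
default curve truths follow the qualitative pattern of the emulated study
(rod: viability falls by E3 and IL-1β rises ~6-fold by E5; stars/spheres:
flat viability, mildly declining IL-1β). The ELISA plate carries an 8-point
2-fold standard series plus blank and four wells per sample. The expression
generator defaults to 10,246 genes × 8 conditions × 3 replicates with 1–3
probes per gene (probe offsets SD 0.15), baseline log2 means ~N(8, 2),
within-group SD 0.25, spiked DEGs concentrated in the rod-exposed
conditions, and two coherently down-shifted sets (cholesterol-synthesis-like
and oxidative-phosphorylation-like, −1 log2 unit in rod-exposed wildtype)
mirroring the pathway-level readout the enrichment stage should recover.

What the generator does **not** emulate: spatial scanner artefacts, dye
bias, probe-specific affinity, correlated gene-gene structure beyond the
spiked sets, batch effects, or dose-dependent heteroscedasticity. Passing
tests therefore demonstrate the statistical machinery is correct and
calibrated under its own assumptions — not that those assumptions hold for
any particular laboratory dataset.

Analyses and tests run the generator at reduced sizes (e.g. 500–2,000 genes,
100–1,000 permutations, 100–200 simulation seeds), chosen as the smallest
problems at which the checked properties are statistically decisive; every
generator default remains at study scale.

## Pipeline

`run_pipeline` executes synth → assay → bmd → microarray → gsea from one
validated YAML/dict config; stages communicate only through declared files,
and the manifest records inputs, parameters, seeds and SHA-256 checksums of
every tabular output (figures are listed but not checksummed). Identical
config and seed reproduce identical checksums. All randomness flows from
`numpy.random.default_rng` seeded per stage from the single config seed.
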