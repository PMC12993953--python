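# Methods

`histoclock` implements a complete workflow for building and stress-testing
histone-modification epigenetic clocks: age predictors trained on the
per-peak ChIP-seq signal of marks such as H3K27ac. This note records the
models, the numerical conventions, and the design choices made where the
procedure was genuinely open, in the order the pipeline runs.

## Feature space: consensus peaks

Peak calls arrive as BED/narrowPeak/broadPeak files, one per replicate per
age group. All coordinates are 0-based half-open; chromosome names are
opaque strings (no `chr1`/`1` aliasing), so any genome build works.

Replicate consistency is enforced at base-pair resolution: within an age
group, a position is retained if it is covered by at least `min_replicates`
replicate peak sets (default 2; a group with a single replicate falls back
to 1). Retained regions are merged into a per-group subconsensus, and the
subconsensus sets of all groups are merged (gap 0, abutting intervals
joined, matching `bedtools merge`) into the final consensus. This rule was
chosen over reciprocal-overlap or peak-count criteria because it is
order-invariant, monotone in `min_replicates`, and directly checkable
against a per-bp coverage-counting oracle — all three properties are tested.

## Signal quantification

Raw counts `c[g, j]` over consensus peaks become read densities

    d[g, j] = c[g, j] / (L_g / 1000) / (R_j / 1e6)

with `L_g` the peak length and `R_j` the sample's reads-in-peaks total, so
densities are reads per kb per million reads-in-peaks. The transform is
invariant to per-sample sequencing depth and conserves
`sum_g d[g, j] * L_g/1000 = 1e6` exactly.

Background handling on the log2 scale: with a matched input-control density
matrix the background is subtracted per cell (log2 IP/input ratio); without
one, each sample's column median of `log2(d + 1)` is subtracted, making
every column median exactly 0. The pseudocount defaults to 1.0. Both modes
exist because matched inputs are the better control but a download-free
path must work; the median mode is the package default.

Feature standardization uses the unbiased (n−1) standard deviation and is
always estimated on training samples only; constant features map to 0 and
are flagged. This is what makes the cross-validation below leak-free.

## Batch correction

Batch effects are removed with a parametric empirical-Bayes location/scale
model: per feature, a linear model with batch indicators plus biological
covariates (age, sex) is fit; data are standardized by the feature grand
mean and pooled variance; per-batch additive (γ̂) and multiplicative (δ̂)
effects are shrunk toward a normal / inverse-gamma prior fit by method of
moments, iterating the coupled posterior updates to convergence (max
absolute change < 1e-4, cap 100 iterations); the shrunken effects are
removed and covariate effects restored. Age and sex are preserved by
construction. The γ prior variance uses the n−1 denominator, the convention
of the sva reference implementation, against which the whole routine agrees
to ~1e-6 in tests. Batches with fewer than two samples are pooled into a
pseudo-batch with a warning; a single batch returns the input unchanged;
a design in which a covariate is aliased with batch raises an error.

Diagnostics report the mean per-feature one-way ANOVA F across batches and
the fraction of PC1–2 score variance explained by batch, before and after.
ComBat equalizes per-batch variances toward the pooled level, so it is only
approximately idempotent; tests assert the second pass moves the matrix by
under a tenth of the first.

## Age-association screening

Per peak, Spearman's ρ against age is computed on mid-ranks with two-sided
p from the t approximation on n−2 df (standard at n in the dozens or more;
an exhaustive-permutation mode exists for n ≤ 8 and is used in validation).
Benjamini–Hochberg adjustment is the literal step-up
`adj_(i) = min_{k≥i} p_(k)·m/k`. Candidates satisfy |ρ| ≥ 0.5 and p ≤ 0.05,
both inclusive — an effect-size-plus-nominal-p filter, appropriate when FDR
control over a large peak universe leaves nothing and the aim is nominating
candidates. Annotation enrichment uses the two-sided Fisher exact test with
the classical "probability mass ≤ observed" rule (not the doubling rule;
the two differ and the choice is deliberate). The PC1–age summary orients
the PC1 loading vector so its largest-magnitude component is positive,
making the sign of the reported correlation deterministic; only its
magnitude is interpretable.

## The clock

The predictor is an elastic net minimizing

    (1/2n) Σ (y − ŷ)² + λ (α‖w‖₁ + (1−α)/2 ‖w‖₂²)

on standardized features, intercept unpenalized. α = 0 is solved in closed
form as ridge, (XᵀX + nλI)⁻¹Xᵀy on centered data; α > 0 uses coordinate
descent (tolerance 1e-7, cap 1e5 iterations — deterministic, so reruns are
bit-identical). Stored models keep only nonzero coefficients together with
the training standardization parameters, serialized as JSON with
`chrom:start-end` feature ids.

Hyperparameters are chosen by leave-one-group-out cross-validation over age
strata: ages are split into equal-width bins (default 11; empty bins merge
into their nearest neighbor; a quantile mode is provided), each fold holds
out one whole stratum, re-standardizes on the remainder, fits the full λ
path (log-spaced from the smallest all-zero λ downward) for each α with
warm starts, and predicts the held-out stratum. The (α, λ) minimizing
pooled CV RMSE wins, ties broken toward larger λ (the sparser model), and
the final model is refit on all samples. The default grid is
α ∈ {0, 0.1, …, 1.0} with 100 λ points; the test and acceptance protocols
use a reduced grid (α ∈ {0.1, 0.5, 1.0}, 20 points) so the full suite runs
on a laptop-scale budget — problem sizes are stated with every protocol
below. Under this scheme a pure-noise feature set yields *negative* pooled
CV correlation, not zero: each fold predicts its training mean, which moves
opposite to the held-out stratum's ages. Tests therefore check "no positive
skill" for the null rather than r ≈ 0.

Accuracy is reported as RMSE, MAE, and Pearson's r. The age gap is
predicted minus chronological age. For paired (pre, post) treatment
designs, the scaled age gap of a pair is `(ŷ_post − ŷ_pre)/ŷ_pre` — the
relative change in predicted biological age — tested against zero with a
two-sided one-sample t test. The definition of "scaled" is a package
decision (an absolute-difference mode is provided); it is flagged because
other conventions exist.

## Evaluation protocols

**Noise robustness.** Gaussian noise with SD σ ∈ {0, 0.3, 0.6, 0.9, 1.2,
1.5} is added to the standardized feature values of the evaluation samples,
the trained model held fixed; σ is therefore in units of training-feature
SDs, the only scale on which that grid is meaningful. σ = 0 reproduces the
baseline bit-exactly (asserted per repetition; means over different rep
counts differ in the last float bit through summation order). Curves are
compared per σ with two-sided Mann–Whitney U: exact enumeration when both
sides have ≤ 20 reps without ties, normal approximation with tie
correction otherwise.

**Benchmarking.** A clock's RMSE is placed within a reference RMSE
distribution by midrank quantile, `(#{ref < x} + 0.5·#{ref = x})/|ref|`;
lower is better and ties are handled symmetrically.

**Saturation.** Per repetition, a fixed test set (default 20%) is held out
and the remaining samples are split into disjoint halves; for each
training size n, one clock is trained on n samples from each half (each
with its own LOGO-CV search) and the Pearson correlation of their test-set
predictions is recorded. The "estimated" variant first duplicates every
sample exactly (no jitter), approximating the stability attainable at twice
the effective sample size; its curve tends to lie at or above the observed
one at matched n, a tendency over seeds rather than a per-seed guarantee.

## Chromatin structure

Enhancer peaks within 12,500 bp (the common stitching window) on one
chromosome are joined into domains carrying constituent counts and summed
signal. Super-enhancers are called from the rank-signal curve: with rank
and signal both scaled to [0, 1], the cutoff is the point where the slope
of the convex curve passes 1, located as the point furthest below the
diagonal (ties resolve to the top rank); domains strictly above it are
super. On a perfectly linear curve every point ties and exactly the
top-ranked domain is called super — a documented convention for a
degenerate input. Fragmentation statistics tabulate per-age-group
super/typical counts and mean lengths and their Spearman trend against
group median age.

Trajectories are LOESS fits (local linear, tricube weights, span 0.5, grid
step 1 y) of mean z-scored signal over a chosen peak set. Inflections are
sign changes of the second finite difference whose magnitude exceeds 10% of
the curve's maximum |second difference|, with an absolute curvature guard
(1e-8 of the fitted range) so numerically linear fits yield none; the
reported age interpolates the zero crossing. With dense, reasonably even
age sampling this finds a logistic bend to within the grid step; with
sparse or very uneven designs the LOESS fit itself can wiggle and produce
spurious crossings — a known limitation of any curvature-based detector.

## The synthetic-data generator

The generator emulates age-structured peak signal with known ground truth.
Latent log2 densities follow

    x[g, j] = b_g + effect_g(age_j) + sex + γ[g, batch_j] + ε[g, j]·s_batch

with baseline `b_g ~ N(3, 1)`, ages uniform on [5, 75] y by default (a
histogram-matching mode accepts a target age list), sex a balanced binary
covariate with optional additive effect, and ε i.i.d. Gaussian with SD 0.5.
Planted linear peaks change by `effect_size` log2 units across the age
range (default 1.75, which puts the true Pearson correlation near 0.71 and
Spearman near 0.7 under uniform ages — derived from ρ = k/√(1+k²) with
k = effect/(σ√12) before any recovery test was run); nonlinear peaks follow
a logistic step (width 3 y) at a breakpoint of 40 or 60 y. Batch shifts are
per-feature with random sign and magnitude ~|N(shift, shift/4)|: sign
symmetry keeps the per-sample median near zero, so median centering
preserves the full nominal shift (a feature-uniform shift would vanish
there, silently weakening any correction benchmark). Batch noise scaling
multiplies ε.

Counts are Poisson with mean `depth · 2^x · L/1000` (default depth 20,
mean counts ~10²; negative binomial was deliberately not used so the
exact-mode oracle stays closed-form); `exact_mode` skips counting and
returns the latent densities, the infinite-depth limit. Replicated peak
calls per age group threshold the group-mean latent signal plus call noise
(SD 0.5) at 0.5 log2 units, with ±50 bp boundary jitter; with 3 replicates
and bp-level 2-of-3 consensus this recovers ≥ 95% of planted peak bp.

The enhancer-cluster regime places clusters of 8 constituents spaced
6,000 bp apart (so a dropped interior constituent opens a 13,000 bp hole
that splits a domain stitched at 12,500 bp) with high baseline signal;
interior constituents lose signal at `fragmentation_rate` log2/y (scaled
per constituent by U(0.5, 1.5) so splits stagger across ages). This is the
mechanism — progressive interior signal loss fragmenting stitched domains
into more, shorter ones — that the observed count-up/length-down signature
implies.

What the generator does **not** emulate: genomic sequence context,
correlated peak blocks (LD-like structure), overdispersed counts in default
mode, irregular real age distributions (unless given), missing data, or
GC/mappability artifacts. Passing recovery tests therefore demonstrates the
correctness and calibration of the algorithms under the stated statistical
model, not performance on any real cohort.

## Problem sizes used in the shipped protocols

Screening recovery: 2,000 peaks × 60 samples, 200 planted monotone peaks.
Clock recovery: 2,000 peaks × 100 samples, 5% informative, 11 CV strata.
Batch protocol: 200 features × 60 samples (+2 shift, ×2 scale on one of two
batches); slope-recovery comparison over 20 replicates of 150 × 60.
Saturation: 300 peaks × 100 samples, training sizes {8, 16, 32}, 8 reps.
Fragmentation: 20 clusters among 400 peaks, 100 samples, 5 age groups.
These sizes are the package's standard desk-scale study conditions; every
protocol is a pure function of one seed and reruns bit-identically.
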