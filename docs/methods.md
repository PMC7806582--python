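# Methods

This note documents the models implemented in `isobiome`, the parameter
choices that matter, what the synthetic-data generator does and does not
emulate, and the numerical decisions a maintainer would want to know.

## Diet metrics from stable isotopes

The mixing model is the classical two-source formulation. The proportional
use of littoral carbon α is the position of the consumer's δ¹³C on the line
between a pelagic baseline (α = 0) and a littoral baseline (α = 1), after
an optional trophic-discrimination correction of Δ¹³C per trophic level
(default 0.4‰ applied zero times, i.e. no correction unless configured).
Trophic position is the baseline trophic level λ (default 2, primary
consumers) plus the consumer's δ¹⁵N enrichment over the α-weighted baseline
divided by the per-level enrichment factor Δ¹⁵N (default 3.4‰).

All constants live in `MixingModelConfig`; baseline prey values have no
universal default and must be supplied (the generator ships a
self-consistent set: δ¹³C −22/−17‰ pelagic/littoral, δ¹⁵N 7.65/8.5‰).
α is never clipped: clipping would distort downstream regression
covariates. Values outside [−0.25, 1.25] are flagged in the log. The model
is affine-invariant under a common re-zeroing of all δ¹³C inputs, strictly
monotone in each consumer isotope, and exactly invertible; the inverse is
what the generator uses to emit raw isotopes from known metrics.

## QC cascade

Stages run in a fixed order because the per-stage removal counts depend on
it: (1) contaminant ASVs — prevalence ≥ 0.5 across negative-control
samples (presence/absence only) *and* present in at least one fecal
sample — then the control samples themselves; (2) samples with fewer than
1000 reads (strict); (3) table-wide singletons (total count exactly 1) and,
reported separately, all-zero columns; (4) ASVs with no domain-level
assignment or with Mitochondria/Chloroplast anywhere in the lineage
(case-insensitive). The prevalence threshold is inclusive (≥); singletons
are defined table-wide, the common amplicon convention. The cascade only
drops rows/columns, never modifies counts, and is idempotent.

## The per-ASV quasibinomial screen

ASV counts are converted to relative abundances; features with mean
relative abundance strictly above 0.01% (`min_mean_rel_abund = 1e-4`) are
screened. For each candidate model the response is regressed on diet
covariates with a binomial-family logit-link GLM whose variance is inflated
by a free dispersion φ estimated from Pearson residuals (quasibinomial).
Fitting is iteratively reweighted least squares written in-package;
per-coefficient inference uses t statistics with n − p df and √φ-scaled
standard errors. Prior weights are unit by default — the response is a
normalized proportion, not a count — with per-sample read totals available
via `weights="depth"`.

Design matrices z-standardize each diet metric across the fitted samples,
and quadratic terms are squares of the standardized metric. Raw-scale
quadratics would be nearly collinear with their linear parts for a
covariate like δ³⁴S (≈ 18 ± 1‰), and raw-scale coefficients would be
incomparable across metrics whose spreads differ by two orders of
magnitude; standardization changes neither the model-level test nor any
coefficient sign. The candidate set is fixed to four models — α, TP, δ³⁴S,
and α + (δ³⁴S)² — plus any user-defined specs; there is no automated
model dredging.

**Model-level significance.** The statistic is the quasi-F of the full
model against intercept-only, F = [(D₀ − D)/q]/φ̂ with D the binomial
deviance. Its parametric F reference is accurate for well-populated
features but becomes anti-conservative for sparse, heavily overdispersed
ones: when the per-feature Dirichlet concentration is far below one, the
response degenerates to a few large spikes among near-zeros, the effective
degrees of freedom collapse, and the analytic test rejects a true null at
9–15% instead of 5% (we verified the same inflation in an independent GLM
implementation). The screen therefore calibrates the same quasi-F
statistic by permutation of the covariate labels (default 999 permutations,
seeded; observed and permuted statistics computed through one code path),
which is exactly valid under the null by exchangeability of samples. A
level-α permutation test rejects when p ≤ α — with the discrete
+1-corrected permutation p this is what gives the test exact size, and with
a continuous analytic p the distinction vanishes. The analytic p is always
recorded alongside (`p_model_analytic`, `p_mode="analytic"`).

**Exceedance test and FDR.** Per model, the number of significant features
among m converged fits is compared to the 5% null expectation with a one-df
goodness-of-fit χ² on (observed, m − observed) vs (0.05m, 0.95m), no
continuity correction. Benjamini–Hochberg step-up q-values are computed
within each model across features (not pooled across models). Non-converged
fits are excluded from both the numerator and denominator of the exceedance
test and from FDR.

When sample metadata is supplied, the screen restricts itself to
first-sampling-point, sexed, non-control samples with complete diet
metrics, one sample per bird — repeat samples within a bird are not
independent.

## Community ecology

Shannon diversity uses base 2 (bits) by default. Faith's PD sums branch
lengths over the union of root-to-leaf paths of the observed features, so
the branches connecting a subtree to the root are counted. Unweighted
UniFrac is unique-over-observed branch length; weighted UniFrac is
Σ l_b |p_ib − p_jb| over branches, divided by Σ l_b (p_ib + p_jb) in the
default normalized form. Note the normalized weighted distance is 1 only
for samples in disjoint *subtrees*; two sister leaves under a shared branch
have distance below 1 even with fully disjoint mass.

PCoA is classical scaling: double-centering of squared distances and an
eigendecomposition. Negative eigenvalues (non-Euclidean input) are retained
and reported; coordinates use positive axes only, with proportions
explained relative to the positive-eigenvalue sum. Biplot feature loadings
are relative-abundance-weighted means of sample coordinates, ranked by
magnitude.

PERMANOVA follows Anderson's partition of squared distances with
pseudo-F = (SS_between/(a−1))/(SS_within/(N−a)), R² = SS_between/SS_total,
raw-label permutation, one-sided upper-tail p with the +1 correction.
PERMDISP measures each sample's distance to its group *centroid* in the
full PCoA space with the imaginary-axis correction (squared distances on
negative axes subtracted, truncated at zero), then a one-way ANOVA F with a
permutation p. The centroid variant is used for closed-form testability;
median-based references will differ. Rank tests use midranks with
tie-corrected variances; the Mann–Whitney normal approximation applies a
0.5 continuity correction, the Wilcoxon signed-rank does not (and drops
zero differences). Permutation p-values are bit-reproducible given
(seed, n_perm).

## Synthetic-data generator

The generator draws the cohort first: sex (9:31:8
female:male:undetermined out of 48 by default), reproductive stage
(balanced incubating/chick-rearing), and per-bird diet metrics from
sex-specific normals — TP 3.79 ± 0.11 (female) / 3.48 ± 0.09 (male),
α 0.42 ± 0.05 / 0.41 ± 0.04, δ³⁴S 18.86 ± 1.24 / 18.06 ± 0.56 — with
additive stage offsets (TP ± 0.12, α ∓ 0.005, δ³⁴S ± 0.3, the
half-differences of the stage-level means). Sex and stage effects are
treated as additive because only marginal distributions are available;
cross-cell interactions are an unmodelled assumption. Raw δ¹³C/δ¹⁵N come
from inverting the mixing model, so the isotope stage is exercised
end-to-end and recovered metrics equal the truth to 1e-10.

Counts are Dirichlet-multinomial: per bird, expected proportions are the
softmax of per-ASV baseline logits (normal, SD 2, assigned in decreasing
order so the feature index doubles as an abundance rank) plus planted
effects; realized proportions are Dirichlet with total concentration
θ = 20 — strong inter-individual variation, the regime in which a single
dominant genus can swing from a few percent to nearly all of a gut
community — and counts are multinomial at a lognormal depth (CV 0.25).
The dominant ASV's baseline is set dominance:1 odds (default 1.5) against
the rest combined, giving it a mean share above one half. Planted effects
act on the logit of expected proportions through the same standardized
terms the screen fits, so recovered coefficient signs are directly
comparable to the truth. Trees are random sequential joins with
exponential branch lengths; negative controls are appended as new
low-depth samples carrying designated contaminant ASVs that are also
sprinkled into a few fecal samples, so the prevalence filter fires on
exactly the designated set.

Desk-scale test and acceptance runs use depth 5000 (the study-scale mean
76,942 remains the config default), 60 birds and 300 ASVs; these sizes
were chosen so the full suite exercises every stage at meaningful power on
a laptop. What the generator does *not* emulate: phylogenetic signal in
abundances (baselines are independent of the tree), per-ASV variation in
overdispersion, taxonomy (tests synthesize minimal lineages), read-level
error, or chimeras.

## Known limitations

- The screen assumes one sample per bird; longitudinal designs are only
  supported through the repeatability tests (Wilcoxon signed-rank,
  PERMANOVA between time points), not mixed models.
- Permutation model-level p-values have resolution 1/(n_perm+1); FDR
  discoveries saturate when many features hit the floor.
- Alpha-diversity magnitudes depend on rarefaction conventions; tables are
  used unrarefied here, so absolute Faith's PD/Shannon values are not
  comparable to rarefied pipelines.
- A global Dirichlet concentration makes rare synthetic features noisier
  than rare features in real gut data, where overdispersion varies by
  taxon; power estimates at the rare end are conservative.
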