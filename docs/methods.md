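# Methods

This note documents the models, defaults, and numerical choices behind
`dualtraj`, and what the synthetic cohort does and does not emulate.

## Study object and eligibility

A cohort is three aligned tables: subjects (sex, race, education, APOE ε4
carriage, baseline age, optional dementia onset time), visits (per-subject
time in years, calendar year, gait speed over a 6 m walk in m/s, CVLT
immediate-recall memory score on its 0–80 instrument range), and a
quantified metabolite panel in µM with a per-metabolite class label and
limit of detection (LOD). "Baseline" is each subject's first visit with
concurrent metabolomics, memory, and gait. Eligibility mirrors the
cohort-study design the package targets: age ≥ 50 and gait ≥ 0.6 m/s at
baseline, complete baseline covariates (no covariate imputation), visits
before baseline dropped. Visits with partial data after baseline
contribute to slope estimation but not to metabolite models.

## Phenotyping

Annual rates of change are per-subject OLS slopes (minimum 2 visits,
configurable upward); visits at or after dementia onset are excluded by
default, since the phenotype targets pre-diagnosis decline. Tertile
cut-points are the 33⅓rd empirical percentile (linear interpolation
between order statistics — a fixed, documented convention) of the signed
slope distributions, computed on the analytic sample after the dementia
exclusion; externally published cut-points can be supplied as an override
(stored as signed slopes, e.g. a published "decline of 0.67 points/year"
is the cut −0.67). Decline is inclusive of the boundary (slope ≤ cut):
the lowest tertile contains its edge. The four labels partition all
classified subjects by construction.

## Censored imputation

Concentrations below the LOD are left-censored, not missing at random.
The imputer models the log-density of log-concentration as a cubic
B-spline with equally spaced knots (14 segments spanning the observed
range extended 4 SDs below the LOD) and maximizes

    Σ_obs g(z_i) + n_cens · log ∫_{lo}^{L} e^g − n_obs · log ∫ e^g − λ‖Δ³c‖²

so the censored count informs the mass — and, jointly with the smoothness
penalty, the shape — of the density below the LOD. The penalty is on
third differences of the coefficients: its null space is quadratic
coefficient sequences, so heavy smoothing shrinks toward a Gaussian
log-density (a lognormal on the concentration scale) rather than the
exponential tail a second-difference penalty would produce in the
data-free censored region. Default λ = 1000 relative to the unnormalized
log-likelihood; with ~10³ observed values the data dominate wherever they
exist while the backbone governs the extrapolated region. Each censored
value is replaced by an inverse-CDF draw from the fitted density truncated
to (0, LOD); draws are seed-deterministic and above-LOD values are never
altered. With fewer than 30 observed values the density is not estimable
and the deterministic fallback LOD/√2 is used with a warning. Imputation
is pooled per metabolite across visits. Filtering precedes imputation: a
metabolite is dropped iff its censored fraction strictly exceeds 20%.

## Mixed-effects screening

Per response (log2 metabolite, log2 ratio, or module score):

- fixed effects: group (reference: no decline), anchored time, group×time,
  baseline age, sex, race (categorical, largest level as reference),
  education, APOE ε4, baseline gait, baseline memory, calendar year;
- random effect: subject intercept only — with ~2.7 visits per subject a
  random slope is not identifiable;
- estimation: REML via statsmodels MixedLM, trying L-BFGS, then BFGS,
  then Powell until one converges; non-converged fits are reported with
  NA p-values and excluded from the FDR family size.

Time anchoring sets each subject's most recent metabolomics visit to 0
with earlier visits at negative years, so the intercept is the expected
level at the latest assessment and group×time is the group's extra annual
rate of change. Continuous covariates are mean-centered; group and
group×time estimates are invariant to this, and the optimizer is far
better conditioned (design condition number drops ~20×).

The omnibus statistic is a joint Wald chi-square (6 df) on the three group
main effects and three group×time interactions, capturing cross-sectional
and longitudinal differences together. Pairwise contrasts are Wald z
tests on single interaction coefficients. The Benjamini–Hochberg step-up
rule is applied within each test family across the kept panel and supports
an externally supplied family size (for adjusting a printed subset of a
larger family); ratio biomarkers are judged at raw p < 0.05 without FDR,
reflecting their status as a small a-priori panel. Simulation places the
omnibus type-I error near nominal (≈0.06 at 150 subjects, within two
binomial SEs of 0.05 at 200 replicates) and 95% Wald coverage of a planted
0.05 log2/yr contrast at ≈0.95.

## Class enrichment

Competitive enrichment per class: a one-sided Wilcoxon rank-sum test of
the class's omnibus p-values against all others (alternative: in-class
p-values smaller), exact null for classes of ≤ 10 members when p-values
are tie-free, tie-corrected normal approximation otherwise. Singleton
classes cannot be tested competitively and are flagged "not estimable"; a
class covering the whole panel has no out-group and degenerates to p = 1.
The rank-sum choice is a documented convention — it is the standard
competitive test on p-value rankings — and is flagged as such in outputs;
other enrichment statistics exist and give different absolute p-values.

## Network modules

Signed WGCNA-style pipeline: Spearman correlation (pairwise-complete),
adjacency a_ij = ((1+ρ_ij)/2)^β with β = 6 (signed-network convention),
topological overlap TOM_ij = (Σ_u a_iu a_uj + a_ij)/(min(k_i,k_j)+1−a_ij),
average-linkage hierarchical clustering of 1 − TOM, and a deterministic
static cut in place of dynamic tree cut. The default cut height is 0.75
on the 1 − TOM scale: tight blocks (within-block ρ ≈ 0.8) finish merging
well below it while unstructured metabolites merge near 1, so the fixed
threshold separates the two regimes; a merge-height-quantile rule is
available via `cut_height=None`. Clusters under 5 members are left
unassigned (module 0); modules are renumbered by decreasing size with a
lexicographic tie-break, making labels invariant to input order. Hubs
maximize within-module adjacency sums (ties by name). Module scores are
the first principal component of the standardized (correlation-scale)
submatrix, sign-oriented to correlate positively with the module's mean
profile, with PC1 variance explained reported; scores re-enter the same
mixed model. At the planted-block reference signal (blocks of 20/15/10,
within-block correlation ≈ 0.8) recovery is exact (ARI 1.0 over 20
seeds) with no spurious modules on unstructured panels.

## Synthetic cohort

The generator is the package's study-conditions definition, not a tuning
knob. Defaults: 200 subjects at desk scale (855 at full scale, matching
the cohort size the pipeline targets); group proportions
0.47/0.20/0.20/0.13; visit counts on {2,…,6} with probabilities
(0.55, 0.28, 0.10, 0.05, 0.02), mean 2.71, gaps uniform on [1, 2.5] years
capped at 12; memory baseline ≈ N(52, 9²) points with group-mean slopes
(−0.1, −1.3, −0.1, −1.3) pts/yr (SD 0.35) and residual SD 3; gait
baseline ≈ N(1.17, 0.18²) m/s with group-mean slopes (−0.005, −0.005,
−0.045, −0.045) m/s/yr (SD 0.012) and residual SD 0.08. The slope means
straddle published tertile cut-points (−0.67 pts/yr, −0.022 m/s/yr) so
that tertile classification is meaningful, and the declining-group mass
(⅓ per domain) matches the tertile construction. Group is the generative
primitive — slopes are drawn around group means — deliberately inverting
the observational direction so classification accuracy against truth is
measurable.

Metabolites are generated on the log2 scale (mean level ≈ N(3, 1.5²) log2
µM; the 20 ratio constituents use fixed physiologically plausible means,
e.g. Trp ≈ 60 µM, Kyn ≈ 2 µM) as mean + group×time slope + subject
intercept (SD 0.5) + module factor (3 modules of 12/10/8 with loading
0.7) + noise (SD 0.5), then exponentiated, guaranteeing positivity. Five
filler metabolites carry a planted dual-decline slope of 0.05 log2/yr, and
the kynurenine/homoarginine pair carries ±0.05 so the IDO-activity and
hArg-synthesis ratios have planted longitudinal signal. LODs sit at the
5% quantile of each metabolite's marginal (three fillers at 30% to
exercise the >20% exclusion); censored cells are stored as 0 and flagged.
A 5% subset of subjects receives a dementia onset time to exercise the
visit-exclusion rule.

What passing tests on this cohort do **not** show: the generator makes no
attempt to match a real cohort's memory–gait slope covariance, real
metabolite distributions (skewness, heavy tails, batch effects), missing
covariates, or informative dropout. Detection-power statements transfer
only qualitatively. At desk scale the planted 0.05 log2/yr effects are
deliberately small against the configured noise — single-metabolite
discoveries at q < 0.05 are rare, pairwise β̂ for the ratios are
noise-dominated, and the loading-0.7 generator modules (within-module
ρ ≈ 0.55) sit below the default detector's operating point, so a
desk-scale run typically reports 0 modules; this mirrors the reality that
modest longitudinal effects need large cohorts, and it is why the
stage-level guarantees are established on dedicated calibrated
simulations rather than on the desk run.

## Numerical and degenerate-input conventions

- OLS slope undefined (all visits at one time) → subject omitted, logged.
- Zero ratio denominators yield NaN (flagged missing), never infinity.
- BH: NaN p-values pass through and do not count toward the default
  family size; an explicit family size must be ≥ the number of supplied
  p-values; ties share a q.
- Omnibus test with exactly zero coefficients returns p = 1; singular
  fixed-effect designs raise an error naming the aliased columns
  (QR with pivoting).
- Spearman on a constant metabolite, zero-variance module members, and
  constant module scores raise named errors rather than propagating NaN.
- All randomness (generator, imputation draws, pipeline stages) flows
  from explicit seeds; the pipeline derives per-stage child seeds from the
  global seed via `SeedSequence`, so identical configurations reproduce
  every output file byte-for-byte.

## Problem sizes

Default test and acceptance runs use desk scale (200 subjects, 60
metabolites), 200 null replicates at 150 subjects for test calibration,
100 replicates at 300 subjects for coverage, 50 seeds at n = 2000 for
imputation recovery, and 20 seeds for planted-module recovery; these
sizes give stable Monte-Carlo estimates while keeping a full run to a few
minutes on one CPU.
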