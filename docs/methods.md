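# Methods

`caremod` re-implements, as a tested pipeline over synthetic data, the
statistical analysis of an intracellular Ca²⁺-remodeling study in
colorectal cancer: normal (NCM460) and cancer (HT29) colonic cells,
with and without the polyamine-synthesis inhibitor DFMO, profiled by
single-cell calcium imaging and by two transcriptomic platforms.

## Calcium traces and features

A recording follows a three-phase protocol: resting baseline in 1 mM
Ca²⁺, store depletion by the SERCA inhibitor CPA in Ca²⁺-free medium,
and Ca²⁺ re-addition triggering store-operated Ca²⁺ entry (SOCE).
Traces are F340/F380 fura-2 ratios sampled every 5 s.

Per cell we extract five features: the **resting level** (median ratio
over the first 30 s), and for each of the two responses (store release,
SOCE) the **peak increment (Δmax)** and **trapezoidal AUC** of the
baseline-subtracted signal. Windows are half-open `[start, end)` in
seconds. The baseline reference for each response window is the median
of the 15 s immediately preceding the window — a local, drift-robust
convention; both spans are configurable because the original
convention is not fixed by the protocol itself. Negative excursions
are not clipped (clipping would bias small responses), no smoothing is
applied, and non-uniform sampling is handled by the trapezoid rule.

## The trace simulator

`simulate_calcium` generates, per cell,

    ratio(t) = r₀ + u_day + u_coverslip + u_cell + template(t) + ε(t)

with a flat baseline, a difference-of-exponentials release pulse
(rise τ₁ = 10 s, decay τ₂ = 60 s) confined to the Ca²⁺-free window,
and a saturating SOCE plateau (τ = 20 s) after re-addition. Each
template is normalised so its maximum over the *sampled* grid equals
the configured amplitude, making noiseless peak recovery exact. The
default design is 4 days × 2 coverslips per condition and day × 32
cells (256 cells per condition, matching the 220–300 per-condition
range of the motivating experiments), with additive intercept SDs
σ_day = σ_coverslip = 0.02, σ_cell = 0.05 and sampling noise 0.02
ratio units. Default condition means encode the studied phenotype:
cancer cells rest higher (0.50 vs 0.40), hold less releasable Ca²⁺
(0.35 vs 0.60) and show larger SOCE (0.90 vs 0.50); DFMO moves the
cancer line toward normal (0.42 / 0.55 / 0.60) while barely touching
normal cells. The magnitudes of the day/coverslip components are free
parameters of the design (no published values exist); the chosen SDs
put roughly as much variance at the day+coverslip level as a handful
of cells contribute, which is what makes the mixed model matter.

Two deliberate properties of this generative model: (i) because
random effects are additive intercepts, baseline subtraction removes
them from Δmax/AUC features — only the resting level carries the full
hierarchy; (ii) the maximum of a noisy series is upward-biased, so
Δmax features inherit a small positive bias from sampling noise (AUC
does not, being linear). For Monte-Carlo studies of the *statistics*
layer the package therefore ships `simulate_features`, which draws
per-cell feature values directly from the hierarchical linear model
(condition mean + day + coverslip intercepts + cell noise, σ_cell =
0.06) on the same 4×2×32 design, ~1000 cells per experiment. Passing
tests on these data demonstrate calibration of the inference
machinery, not robustness to peak-picking bias in real traces.

## Condition models

Features are analysed with a linear mixed model fitted by REML
(statsmodels `MixedLM`): fixed 2×2 factorial (line, treatment, their
interaction), random day intercept, and optionally a random coverslip
intercept nested within day — nesting reflects the physical design
(each coverslip exists on one day under one condition). An optional
Box–Cox transform is selected by profile likelihood on a grid
λ ∈ [−2, 2] step 0.01 (λ = 0 means log; an automatic shift handles
non-positive responses). Estimated marginal means are linear
combinations of the fixed effects; they are reported on the
transformed and the original scale, the latter as the inverse Box–Cox
of the mean without bias correction (the back-transformed mean is a
median-type summary; it is monotone in the transformed mean for any λ).

**Random-structure selection** compares REML fits sharing the full
fixed structure by `−2·loglik + 2·(#fixed + #variance parameters)`.
This is a pragmatic surrogate for the conditional AIC: because every
candidate keeps the identical fixed structure, the comparison reduces
to penalised REML likelihoods, which is all the top-down strategy
needs. Exact conditional AIC (effective degrees of freedom of the
random-effect hat matrix) is intentionally out of scope.

**Degrees of freedom.** Exact small-sample df for mixed models
(Satterthwaite/Kenward–Roger) are not available in the underlying
library. Two conventions are used, both documented per quantity:

* between-condition contrasts use the *containment* df,
  `n_coverslips − n_conditions` (28 at the default design); day
  effects cancel in these contrasts because days are crossed with
  conditions, so the coverslip is the replication unit. A Monte-Carlo
  check at the default design gives a family-wise error of ~0.05 for
  the Tukey procedure under an equal-means null.
* condition-mean CIs use a Satterthwaite-style combination df over the
  day, coverslip and residual variance contributions to the mean's
  variance (the day component has only `n_days − 1` df and often
  dominates). Coverage at the default 4-day design is ~93% for a
  nominal 95% — the residual shortfall reflects REML variance noise
  with 4 days and is reported honestly rather than patched.

**Diagnostics** run on conditional residuals (observed minus fitted
including predicted random effects): Shapiro–Wilk (subsampled above
the implementation's n cap) and Jarque–Bera for normality, Bartlett
across conditions and Breusch–Pagan on the fixed design for
homoscedasticity, Shapiro–Wilk on predicted random intercepts, and
outlier flags at |studentized residual| > 3 or Cook's distance > 4/n
(leverage from the fixed design — approximate for the mixed fit). A
fit with numerically constant residuals is refused as degenerate.

**Parametric bootstrap**: B simulate–refit replicates draw new day and
coverslip intercepts from the estimated variance components plus
residual noise around the fixed-effect surface; percentile CIs are
reported. Agreement of bootstrap and Wald summaries is part of the
test suite, mirroring the model-checking role the procedure plays in
practice.

**Two-group small-sample comparison** (`boxcox_group_compare`, used
for densitometry-style data, e.g. an unbalanced 6:3 design): Box–Cox
selection, OLS on a group indicator, Shapiro–Wilk and Bartlett
reported. Gross outliers (|studentized| > 3) are removed once and the
model refitted; Cook's distances are reported but do not trigger
removal, because at n ≈ 9 the 4/n screening cutoff discards ordinary
points and inflates the type-I error (measured: 13% → ~6%). Groups
with zero residual variance but distinct means are reported as exact
separations rather than fed to a t-test.

## Letter display

All six pairwise condition contrasts are tested with the single-step
Tukey–Kramer adjustment (studentized-range distribution, contrast df
as above). The similarity graph places an edge between conditions
whose adjusted p ≥ α (default 0.05); all maximal cliques are
enumerated with Bron–Kerbosch with pivoting (an exhaustive-search
oracle and networkx serve as cross-checks in tests); cliques are
ordered by the ascending mean of their members' marginal means and
lettered a, b, c…; each condition collects the letters of every clique
containing it. Two conditions share a letter iff they are adjacent in
the similarity graph (every edge lies in some maximal clique). Letter
ordering by clique mean is a convention; permuting condition order
changes letter names, never the partition.

## Expression pipeline

The pipeline ingests summarised log2 gene×sample matrices (platform-
level background correction and probe summarisation are out of scope).
Steps: quantile normalisation (columns mapped onto the mean of sorted
columns, ties sharing the mean reference of their tied ranks —
idempotent by construction); a non-specific filter keeping genes whose
IQR strictly exceeds the median IQR, with the Ca²⁺-panel override
retaining all 89 panel genes regardless of variability; per-gene OLS of

    log2 expr ~ line + treatment + line:treatment + day

with day as a fixed block (with one replicate per condition per day a
fixed block is the standard identifiable choice even though the design
treats day as a random draw; a consensus intra-block correlation
alternative is out of scope). Four contrasts are exported: the line
effect (HT29 − NCM460, in control), the treatment effect within each
line (DFMO − control), and the interaction. Sign conventions are
stated in every output.

**Moderation.** Residual variances are shrunk by empirical Bayes:
log s²_g are moment-matched to a scaled-F model via digamma/trigamma
equations, giving prior df d₀ and prior variance s₀²; the posterior
variance is (d₀s₀² + d·s²_g)/(d₀ + d) and the moderated t uses d₀ + d
df (standard normal when d₀ = ∞, which is the correct limit when the
observed variances are no more dispersed than chi-square sampling
explains; the trigamma inversion failing on a negative target falls
back to d₀ = ∞ with a warning). The implementation is validated
against Bioconductor limma on fixtures (agreement to <0.005 in t for
finite d₀). Benjamini–Hochberg adjustment is applied per contrast;
FDR < 0.05 is the significance flag.

## Cross-platform concordance and reversal

The second platform is emulated at the matrix level as
`gain·truth + offset + independent noise` (defaults 1.1 / 0.3 / 0.35):
the concordance rule consumes only (q, logFC) pairs, so read-count
level simulation would add nothing the rule can see. A gene is called
DE between cell lines when at least one platform reaches q < 0.05, or
both reach q < 0.10, *and* both logFCs share a (nonzero) sign;
discordant signs veto the call, zero logFC is sign-indeterminate, and
genes measured on one platform only are "insufficient" rather than
"not DE". Significance is interpreted on the FDR scale (q-values), the
scale on which the pipeline defines significance; a raw-p option
exists.

A gene is **reversed** when its cancer-vs-normal DE is significant
(either by the combined two-platform call or by a single platform,
selectable), its treatment contrast within the cancer line has
q < 0.05, and the two effects have opposite signs. The default
expression truth plants 17 treatment-affected panel genes of which 11
are reversals (gene identities follow the studied system: CRACR2A,
ORMDL3, SEPTIN6/7/8/11, TRPC5, TRPV6, SPCA2, PMCA4, VDAC3 reversed;
STIM1/2, SEPTIN9, MCU, TRPC1, TRPP2 affected but not reversed), plus
background cancer-effect genes (25% of non-panel genes) and
cancer-line-only treatment genes (15%) echoing the strong selectivity
of the treatment for cancer cells. Effect size defaults to ±1.5 log2
units against σ_noise = 0.3 and σ_day = 0.2.

Recovery metrics: sensitivity = recovered true reversals / planted
reversals; the false-reversal rate is the false-positive rate over
truly-non-reversed panel genes. The false-*discovery* proportion among
reversal calls is intrinsically of FDR order and concentrated on
cancer-DE genes, because the line and treatment-in-cancer contrasts
share the cancer-control samples and are negatively correlated — a
property of the design, not of the implementation.

## QC

Samples are observations, genes variables; PCA on centred, unscaled
log2 data (genes are not standardised — variance carries signal at a
common scale). The retained set is the minimal leading components
explaining ≥ 70% of variance (PC70%). Outliers are flagged within each
line×treatment class by squared robust Mahalanobis distance (minimum
covariance determinant; classical covariance fallback with a warning
when the class is too small) against the χ² quantile at coverage
0.975 — the conventional MCD cutoff; it is asymptotic, and small
classes over-flag (measured: ~12% at n=25, ~3% at n=250 for nominal
2.5%). Ward clustering runs on Euclidean distances over the retained
components. RLE summaries report each sample's median and IQR of
gene-median-centred values, flagging |median| > 0.1 by default. NUSE
is not computed: it needs probe-level model residuals that do not
survive summarisation.

## qPCR

Relative quantification follows the Livak ΔΔCt convention: technical
replicates are aggregated by mean (median by flag), ΔCt = Ct_gene −
Ct_housekeeping per sample, relative abundance 2^(−ΔCt), ΔΔCt = mean
ΔCt(test) − mean ΔCt(calibrator), and the reported log2 fold change is
−ΔΔCt (0 = no change, positive = higher in the test group). The
negative-exponent convention is used throughout. Group differences are
two-sample t-tests on ΔCt with a Bonferroni multiplier equal to the
number of genes assayed (capped at 1). Amplification-efficiency
correction (Pfaffl) is out of scope. The Ct simulator draws
Ct = baseline − log2(relative abundance) + N(0, σ) with a
constant-abundance housekeeping gene (default σ_Ct = 0.2, triplicates,
3 biological samples per group).

## Problem sizes and numerical choices

Monte-Carlo suites use the default design throughout: ~1000 cells per
calcium experiment (100 replicates for CI coverage, 100 for letter
recovery, 400 for the null FWER check), 2000 genes × 16 samples for
expression (200 null replicates for moderated-t calibration, 6
replicates for reversal recovery), 500 random graphs (n ≤ 12) against
the exhaustive clique oracle, 1000 random p-vectors against an
independent BH step-up. `scripts/acceptance.py` recomputes the same
quantities at moderately smaller replicate counts chosen as a
reasonable Monte-Carlo budget. All randomness flows from explicit
integer seeds; the REML optimiser runs Powell first with a default-
method retry, and boundary (zero-variance) fits are accepted and
reported as zero components.

## Known limitations

* Mean CIs are mildly anticonservative (~93% at 95% nominal) with only
  4 days; more days restore nominal coverage.
* Δmax features carry an upward noise bias inherent to peak-picking;
  AUC features do not.
* The synthetic platform pair shares Gaussian noise assumptions; no
  count-model (negative binomial) behaviour, library-size effects, or
  annotation issues are emulated, so passing recovery tests bound
  performance only under these idealised conditions.
* The letter display reproduces clique-based grouping without
  letter-minimisation heuristics.
* Quantile normalisation under near-zero noise introduces systematic
  shifts larger than the residual scale (a property of the transform);
  construction-exactness tests therefore bypass it.
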