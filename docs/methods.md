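# Methods

This note records the modelling choices, defaults and numerical conventions
behind `mrmediate`, and what the synthetic-data validation does and does not
establish.

## Model and assumptions

All methods operate on summary-level two-sample MR data: per-instrument
exposure effects β̂ₓⱼ (SE σₓⱼ) and outcome effects β̂ᵧⱼ (SE σᵧⱼ) from
non-overlapping GWAS, harmonized to a shared effect allele. The working model
is β̂ᵧⱼ = θ β̂ₓⱼ + αⱼ + εⱼ, where θ is the causal effect of interest and αⱼ a
possible direct (pleiotropic) effect of instrument j on the outcome. IVW
assumes αⱼ ≡ 0; MR-Egger allows a common nonzero mean of αⱼ provided
instrument strength is independent of the direct effects (InSIDE); the
weighted median tolerates up to half the weight on invalid instruments; the
weighted mode requires only that the largest homogeneous cluster of ratio
estimates is valid; MR-PRESSO removes individual outliers under a
mostly-valid model. Binary outcomes are handled on the log-odds scale
throughout; odds ratios and 95% CIs are exp-transformed at presentation.

## Harmonization rules

The packages these studies conventionally delegate to do not document a single
canonical rule set, so ours is explicit:

- outcome alleles equal to the exposure's (directly or as strand
  complements) → kept as-is; swapped (directly or complement-swapped) →
  outcome β sign-flipped and EAF complemented;
- palindromic variants (A/T, C/G) cannot be resolved by allele labels. Default
  policy `drop_ambiguous`: orientation is taken from allele frequencies, and
  the variant is dropped when either EAF is missing or falls in [0.42, 0.58]
  (too close to 0.5 to call strand). `drop_all` drops every palindromic SNP.
- irreconcilable allele pairs are dropped; all drops are counted by reason.

Missing EAF or sample size never blocks reading a table (microbiome consortium
releases often omit them); operations that need them fail loudly instead of
imputing.

## Instrument selection

p-value screen (strict `<`), then greedy p-value-ranked LD clumping (ties
broken lexicographically by variant id; pairwise r² < 0.001 within a
10,000 kb same-chromosome window), then the per-SNP F = (β̂/σ̂)² filter with
strict F > 10. The F filter is applied to metabolite exposures by default and
is switchable for taxa (the convention in these studies states it only for
metabolites). The LD matrix is user-supplied; `ld=None` means "treat all
pairs as independent", while a *partial* matrix missing a candidate that
shares a window with another raises an ambiguity error rather than guessing.

## Estimator conventions

- **IVW**: closed-form weighted through-origin regression, weights 1/σᵧⱼ².
  Normal-based p-values. Multiplicative random-effects SE inflation
  √(Q/(k−1)) floored at 1 — heterogeneity can widen but never narrow the CI.
  The primary analysis uses fixed effects unless Cochran's Q has p < 0.05
  (strict), in which case multiplicative random effects are reported as
  primary.
- **MR-Egger**: weighted least squares with intercept via `statsmodels` WLS
  after orienting all β̂ₓⱼ ≥ 0. t(k−2) inference with the residual dispersion
  floored at 1 (same never-deflate convention).
- **Weighted median**: weighted empirical quantile function interpolated at
  0.5; weights (σᵧⱼ/|β̂ₓⱼ|)^−2 renormalized. SE from a parametric bootstrap
  (β̂ₓ, β̂ᵧ resampled from their sampling distributions; weights recomputed per
  replicate), default 1000 replicates, seed mandatory.
- **Weighted mode**: weighted Gaussian KDE over the ratios with bandwidth
  φ·0.9·min(sd, IQR/1.349)·k^(−1/5) (φ = 1 by default), argmax on a fixed
  2048-point grid spanning the ratio range ± 3 bandwidths; degenerate
  zero-bandwidth inputs return the common ratio. SE by the same bootstrap.
- **MR-PRESSO**: the observed statistic is the weighted residual sum of
  squares about leave-one-out IVW predictions (weights 1/σᵧⱼ², so per-SNP
  contributions are pivotal); the null distribution is simulated
  parametrically under the fitted model (default 1000 draws). Per-SNP
  contribution p-values are Bonferroni-adjusted (×k) and flagged below 0.05;
  the corrected estimate is IVW on the unflagged set. The distortion null
  removes random same-size subsets. Simulation p-values use add-one smoothing
  (count+1)/(n_sim+1) so they are never exactly 0 — the resolution is bounded
  by n_sim. The weighting of the RSS and the distortion null are our explicit
  choices; the originating method leaves room for variants.

## Mediation

Product-of-coefficients decomposition with the primary estimate (IVW, or Wald
at k = 1) for each leg; β₂ is estimated with the mediator's own instruments.
`direct` is computed as β_all − β₁β₂, so mediated + direct ≡ β_all to machine
precision by construction. The delta-method SE √(β₂²se₁² + β₁²se₂²) assumes
the two steps are independent (non-overlapping GWAS). No CI is reported for
the proportion by default: it is a ratio statistic with heavy tails; the
mediated-effect CI is reported instead. Screening gates default to p < 0.05
on each of the three legs; sign-inconsistent triples (sign(β₁β₂) ≠
sign(β_all)) are emitted but flagged.

## Multiplicity

Per-taxonomy-level Bonferroni: threshold 0.05/n with n defaulting to the raw
count of taxa tested at that level (an effective-number override is
accepted in the manifest, since "effective number of independent taxa" admits
several definitions). Three tiers, all strict: significant (p < 0.05/n),
suggestive (0.05/n ≤ p < 0.05), null. The reverse direction of the
bidirectional screen instruments the disease at the genome-wide 5×10⁻⁸
threshold (configurable).

## Synthetic data: what it emulates, and what it does not

Per instrument with allele frequency p and GWAS size n, the summary-level SE
is 1/√(2·n·p(1−p)); observed effects are drawn normally around their
generative means. Defaults state the emulated study shapes: exposure GWAS
n = 18,340 (16S microbiome consortium scale), metabolite GWAS n = 7,824,
case-control outcome n = 105,248 with effects directly on the log-odds scale
(no individual-level liability simulation — sufficient for summary-level
methods). Instrument effects default to |N(0, 0.08)| + 0.02; 10% of variants
receive palindromic allele pairs to exercise harmonization; same-chromosome
instruments are spaced 20,000 kb apart so they are independent under the
10,000 kb clumping window. The mediation generator emits the mediator's own,
independently drawn instrument set alongside the exposure's, mirroring the
two-step design in which step 2 uses mediator-specific instruments; at
default instrument strength the exposure's SNPs stay below the metabolite
selection threshold, as intended. LD fixtures are block-diagonal with exact
within-block r².

The `strong_instruments` preset (γ ~ |N(0, 0.15)| + 0.10, exposure n =
200,000) defines "strong instruments" for recovery experiments: mean F in the
hundreds, so two-sample regression dilution (of order mean 1/F) is an order
of magnitude below Monte-Carlo error at a few hundred replicates. It is a
preset, not the default, and was fixed analytically before the validation
suite was run.

Not modelled: individual-level genotypes, realistic 16S abundance
distributions, winner's curse in instrument discovery, sample overlap between
GWAS, and LD beyond block-diagonal r². A green validation suite therefore
establishes the estimators' statistical contracts (calibration, recovery,
robustness, oracle equivalence) under correctly specified summary-level
sampling — not robustness to those unmodelled features of real data.

## Numerical notes

- All randomness flows through `numpy.random.default_rng` seeds carried in
  configs; reports are byte-identical under a fixed seed.
- p-values are floored at the smallest positive float to honour the (0, 1]
  contract; CIs use the exact 0.975 normal quantile.
- Clumping tie-breaks (equal p) are lexicographic on variant id, making
  output independent of input order.
- Degenerate inputs are rejected early: σ ≤ 0 at set construction, β̂ₓ = 0 for
  ratio-based methods, k below each method's minimum (Wald 1, IVW/Q 2,
  Egger/median/mode 3, PRESSO 4).

## Known limitations

- No proxy-SNP lookup for instruments missing in the outcome GWAS; such
  instruments are dropped.
- MR-PRESSO's distortion test is reported but not used for gating.
- No Steiger filtering, multivariable MR or MR-RAPS; the bidirectional screen
  can select outcome instruments that are downstream of a true forward effect
  (reverse-causation contamination is a known caveat of the design).
- Mediation assumes a single mediator per triple; joint multi-mediator
  decompositions are out of scope.
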