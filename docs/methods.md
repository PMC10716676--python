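# Methods

## Scope and model

`cismr` estimates the causal effect of pharmacologically perturbing a drug
target from two-sample GWAS summary statistics, using cis variants in the
target gene as instruments. The exposure is a biomarker that weights the
variants' effect on the target (here: diastolic blood pressure for PDE5
inhibition); the biomarker need not be the mechanism through which the
target affects the outcome, only a consistent scale for it.

The estimator is generalised weighted least squares on the summary
estimates: θ̂ = (γ̂ᵀΩ⁻¹γ̂)⁻¹ γ̂ᵀΩ⁻¹Γ̂ with Ω = diag(σ_Γ)·ρ·diag(σ_Γ). This is
the standard summary-data formulation of meta-analysing per-variant Wald
ratios under an LD correlation matrix; the two framings agree to first
order, and GLS is adopted because it is exact under the working model and
numerically transparent. With identity LD and no overdispersion it reduces
to the textbook fixed-effect IVW of Wald ratios (tested against a
brute-force oracle at 1e-10).

Assumptions inherited from the MR design: instruments associate with the
exposure, affect the outcome only through it (addressed post hoc by
colocalisation and two-step adjustment, not guaranteed), and share no
confounder with the outcome. The per-variant Wald SE is first-order
(exposure-side uncertainty ignored), the convention of summary-data MR.

## Key parameters

- `prune_r2 = 0.35`, `window_kb = 10000`: LD-pruning thresholds for
  instrument selection; mildly correlated instruments are retained for
  power, since the estimator models their correlation.
- `eqtl_p = 5e-8` (strict `<`): genome-wide significance for the cis-eQTL
  filter; region boundaries are 1-based, closed, GRCh37.
- `mm_hg_per_dose = 5.5`, direction `lowering`: dose-equivalent scaling.
  Internally θ̂ is per 1 unit *higher* exposure; the lowering scale
  multiplies by −5.5 so inhibition effects read positively. Scaling
  preserves z-scores and p-values and refuses to run twice.
- Random effects: multiplicative, φ estimated from the GLS residual and
  floored at 1 for SE reporting (a multiplicative random-effects SE cannot
  undercut the fixed-effect SE); raw φ is kept in the result for
  diagnostics, and is undefined (None) for J = 1.
- Coloc priors: p1 = p2 = 1e-4, p12 = 1e-5; prior effect SD 0.15
  (quantitative) or 0.2 (binary) — the method's canonical defaults, all
  configurable. Decision threshold 0.8 for the H3/H4 labels.
- Palindromic variants (A/T, C/G) with exposure EAF within ±0.08 of 0.5
  are excluded at harmonisation as strand-ambiguous; outside that window
  strand is inferred by allele complement. Standard two-sample practice.
- Ω conditioning: eigenvalues below 1e-8 × the largest are dropped via a
  spectral pseudo-inverse with a warning; this makes duplicated or
  perfectly collinear instruments degrade gracefully to the correct
  lower-dimensional estimate. φ then uses the retained rank minus one.

## Two F statistics

Per-variant instrument strength is reported in two forms: the squared
z-score (β/σ)² and the regression form R²(n−2)/(1−R²) with
R² = 2f(1−f)β²/SD². Published instrument tables typically print the
R²-based form (it reproduces all five printed F integers of the reference
instrument set from the printed R² values); the two differ when printed
inputs are rounded. The diagnostics table reports both, plus the arithmetic
and geometric means of the R²-based F — for the reference set these are
36.4 and 26.4, a reminder that "average F" is ambiguous in the literature.

Recomputing R² from printed β/EAF reproduces the printed R² exactly (3
significant figures) for the lead variant; other rows drift by up to ~13%
because the published table evidently used unrounded inputs. The package
treats the printed inputs as authoritative and reports what they imply.

## Tie-breaking and determinism

Greedy LD pruning ranks by p-value; ties are broken by distance to the
midpoint of the candidate positions' span, then by rsid, making the output
a function of the ranking alone (invariant to input order). The
weakest-instrument exclusion removes the minimum-F variant, ties broken by
larger exposure p-value, then rsid. Pipeline runs are byte-identical under
a fixed config; all simulation randomness flows through an explicit seed
with the replicate index folded into the seed sequence.

## The simulator: what it emulates, and what it does not

Summary-level simulation only: per-variant estimates are drawn from their
asymptotic joint normal, with SEs sd/√(2nf(1−f)), cross-variant correlation
ρ from an AR(1), block, or identity model, and optional exposure–outcome
error correlation for sample overlap (implemented as a 2×2 ⊗ ρ Kronecker
covariance). Defaults mirror a large blood-pressure GWAS: 5 variants,
γ ≈ 0.1–0.16 mm Hg, EAF 0.03–0.79, exposure n = 757 601 and SD = 10.7
(implied SEs 0.017–0.049, within 10% of the published instrument set's
0.017–0.050), outcome n = 211 840 with unit trait SD. Pleiotropy enters as
a mean shift b_GC·b_CO on the outcome side.

Not emulated: individual genotypes, liability-scale binary traits (binary
outcomes are handled on the linear-probability scale, matching
mixed-model GWAS effect scales), winner's-curse selection of instruments,
population stratification, or LD estimation error (the analysis consumes
the same ρ that generated the data). Passing calibration tests therefore
demonstrates internal consistency of estimator and generative model, not
robustness to misspecified real-world LD or selection.

Coloc-region simulation draws z-scores MVN(z_signal·r[:,causal], ρ) and
reports β = z·se with a uniform se of 0.03, commensurate with the 0.15
prior effect SD; the "distinct" scenario places the second trait's causal
variant at the position least correlated with the first's.

## Known numerical behaviour and limitations

- Weak-instrument attenuation: because γ̂ enters the GLS weights and
  regressor, θ̂ has a finite-sample bias toward the null of order
  σ_γ²/γ² (≈ 2–3% of θ at the default scales, where per-variant (β/σ)²
  runs 8–90). Over 1000 replicates this sits near the edge of Monte-Carlo
  resolution (2–4 MC SEs depending on seed); 95% CI coverage remains
  0.95–0.96. No correction (e.g. Steiger/winner's-curse or modified
  weights) is applied, matching standard practice for this estimator.
- The two-step SE uses the exact product-variance formula, including the
  σ_GC²σ_CO² term, valid for independent errors across the two steps;
  cross-step covariance inputs are out of scope. Mediator corrections are
  additive, so the order of independent mediators does not change the
  point estimate.
- The five-hypothesis colocalisation assumes one causal variant per trait;
  no conditioning/masking or SuSiE-style extensions.
- CIs and p-values are normal-theory, matching summary-data MR convention.
- The FDR family is the set of outcomes analysed in one pipeline
  invocation; a single-outcome run has FDR p equal to raw p.

## Problem sizes used in tests

The calibration checks use 1000 replicates of the 5-variant study-scale
configuration (seconds of runtime), 100-variant regions for colocalisation,
10⁶ Monte-Carlo draws for the product-variance oracle, and exhaustive
orderings of length ≤ 6 for the FDR oracle — sizes at which every oracle
comparison is sharp while the full suite stays fast.
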