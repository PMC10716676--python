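# cismr

Drug-target **cis-Mendelian randomisation** from GWAS summary statistics:
correlated-instrument Wald-ratio/IVW estimation with multiplicative random
effects, cis-eQTL instrument selection with LD pruning, pharmacological
dose-equivalent scaling, Benjamini–Hochberg FDR, Bayesian colocalisation,
and two-step cis-MR pleiotropy adjustment — plus a summary-level simulator
so every stage can be exercised and calibrated without access to individual-
level data.

## Who this is for

Genetic epidemiologists estimating the causal effect of perturbing a drug
target (e.g. PDE5 inhibition proxied by blood-pressure-lowering variants in
the *PDE5A* region) on downstream outcomes, using only published per-variant
summary statistics from two non-overlapping (or partially overlapping) GWAS.

## The model

For instruments *j = 1..J* with variant–exposure estimates γ̂ⱼ (SE σ_γⱼ) and
variant–outcome estimates Γ̂ⱼ (SE σ_Γⱼ), the per-variant Wald ratio is
θ̂ⱼ = Γ̂ⱼ/γ̂ⱼ with first-order SE σ_Γⱼ/|γ̂ⱼ|. Correlated instruments are
combined by generalised weighted least squares with Ω = D ρ D, where
D = diag(σ_Γ) and ρ is the signed LD correlation matrix:

    θ̂ = (γ̂ᵀ Ω⁻¹ γ̂)⁻¹ γ̂ᵀ Ω⁻¹ Γ̂,   var(θ̂) = (γ̂ᵀ Ω⁻¹ γ̂)⁻¹

With identity ρ this is exactly the fixed-effect IVW mean of the Wald
ratios. Residual heterogeneity φ = (Γ̂ − θ̂γ̂)ᵀΩ⁻¹(Γ̂ − θ̂γ̂)/(J−1) inflates
the SE multiplicatively by max(1, √φ). Estimates are re-expressed per
pharmacological dose-equivalent (default: ×(−5.5), the approximate diastolic
blood pressure lowering of 100 mg sildenafil, signed so inhibition effects
read positively). Colocalisation uses Wakefield approximate Bayes factors
and enumerates the five single-causal-variant hypotheses H0–H4; two-step
cis-MR subtracts the mediated component b_GC·b_CO from each variant–outcome
association with an exact product-variance SE.

## Worked example

`examples/02_simulate_and_estimate.py` simulates a five-instrument
two-sample dataset at realistic GWAS scales (exposure n = 757 601,
SD = 10.7 mm Hg; outcome n = 211 840) with true effect −0.0509 per mm Hg,
and recovers it:

```
true effect:      -0.0509 per mm Hg higher exposure
IVW estimate:     -0.0621 (se 0.0172), phi = 1.15, J = 5
dose-equivalent:  0.342 (95% CI 0.156 to 0.527), p = 0.000312
```

The dose-equivalent line is the outcome change per 5.5 mm Hg lowering of
diastolic blood pressure through the target; a single replicate is noisy,
and the CI brackets the scaled truth −5.5·θ = 0.280. The other example
scripts cover instrument-strength diagnostics (`01`), colocalisation
scenarios (`03`), pleiotropy adjustment (`04`), and the end-to-end pipeline
with a declarative config (`05`). A thin CLI mirrors the library:
`cismr simulate|select-instruments|harmonise|mr|coloc|twostep|run|report`.

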