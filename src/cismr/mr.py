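"""Wald-ratio and correlated-instrument IVW estimation.

The causal effect of the exposure on the outcome is estimated from summary
statistics by generalised weighted least squares of the variant-outcome
estimates Gamma on the variant-exposure estimates gamma, with weight matrix
the inverse of Omega = D ρ D, where D is the diagonal of outcome standard
errors and ρ the LD correlation matrix. With identity LD this reduces to the
classical fixed-effect inverse-variance-weighted mean of per-variant Wald
ratios. A multiplicative random-effects model inflates the standard error by
the square root of the residual overdispersion when that exceeds one; it
never deflates it.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .summary_data import HarmonisedInstrumentSet

__all__ = [
    "MrResult",
    "wald_ratio",
    "ivw_correlated",
    "scale_estimate",
    "bh_fdr",
    "exclude_weakest",
]


@dataclass(frozen=True)
class MrResult:
    """Causal estimate with uncertainty and method metadata.

    ``estimate`` is in outcome units per 1-unit *higher* exposure until
    :func:`scale_estimate` re-expresses it per dose-equivalent.
    ``overdispersion`` is the raw (unfloored) residual dispersion phi, or
    None for a single instrument where it is undefined.
    """

    estimate: float
    se: float
    ci_low: float
    ci_high: float
    pval: float
    n_variants: int
    overdispersion: float | None = None
    scale_factor: float | None = None
    method_label: str = "ivw_correlated_mre"

    def __post_init__(self) -> None:
        if self.n_variants >= 1 and self.se <= 0:
            raise ValueError("se must be positive")
        if not self.ci_low <= self.estimate <= self.ci_high:
            raise ValueError("confidence interval does not bracket the estimate")

    @property
    def zscore(self) -> float:
        return self.estimate / self.se


def wald_ratio(
    Gamma: float, Gamma_se: float, gamma: float, gamma_se: float
) -> tuple[float, float]:
    """Per-variant causal estimate Gamma/gamma with first-order SE Gamma_se/|gamma|.

    The exposure-side uncertainty ``gamma_se`` does not enter the first-order
    SE; it is accepted for interface symmetry and diagnostics.
    """
    if Gamma_se <= 0 or gamma_se <= 0:
        raise ValueError("standard errors must be positive")
    if gamma == 0:
        raise ZeroDivisionError("unidentified ratio: variant-exposure effect is zero")
    return Gamma / gamma, Gamma_se / abs(gamma)


def ivw_correlated(
    h: HarmonisedInstrumentSet,
    random_effects: bool = True,
    condition_floor: float = 1e-8,
) -> MrResult:
    """Correlated-instrument IVW estimate by GLS with LD-aware weights.

    Omega = D ρ D with D = diag(Gamma_se). The point estimate is
    (γᵀΩ⁻¹γ)⁻¹ γᵀΩ⁻¹Γ with base variance (γᵀΩ⁻¹γ)⁻¹. For J ≥ 2 instruments
    the residual overdispersion phi = (Γ−θγ)ᵀΩ⁻¹(Γ−θγ)/(J−1) is estimated;
    with ``random_effects`` the reported SE is the base SE times
    max(1, sqrt(phi)). Eigenvalues of Omega below ``condition_floor`` times
    the largest are dropped via a spectral pseudo-inverse (with a warning),
    which handles duplicated or perfectly collinear instruments.
    """
    J = len(h)
    if J == 0:
        raise ValueError("no instruments")

    D = np.diag(h.Gamma_se)
    omega = D @ h.ld.r @ D
    evals, evecs = np.linalg.eigh(omega)
    floor = condition_floor * evals.max()
    keep = evals > floor
    if evals.max() <= 0:
        raise np.linalg.LinAlgError(
            f"Omega numerically singular; smallest eigenvalue {evals.min():.3e}"
        )
    if not keep.all():
        warnings.warn(
            f"Omega ill-conditioned: {np.sum(~keep)} eigenvalue(s) below "
            f"{floor:.3e} dropped (smallest {evals.min():.3e}); using spectral pseudo-inverse",
            RuntimeWarning,
            stacklevel=2,
        )
    omega_inv = (evecs[:, keep] / evals[keep]) @ evecs[:, keep].T

    gwg = float(h.gamma @ omega_inv @ h.gamma)
    if gwg <= 0:
        raise np.linalg.LinAlgError("gamma lies in the null space of the weight matrix")
    theta = float(h.gamma @ omega_inv @ h.Gamma) / gwg
    base_se = gwg**-0.5

    rank = int(keep.sum())
    phi: float | None = None
    if J >= 2 and rank >= 2:
        resid = h.Gamma - theta * h.gamma
        phi = float(resid @ omega_inv @ resid) / (rank - 1)

    se = base_se
    label = "ivw_correlated_fe"
    if random_effects:
        label = "ivw_correlated_mre"
        if phi is not None:
            se = base_se * max(1.0, np.sqrt(phi))

    z = theta / se
    pval = 2.0 * stats.norm.sf(abs(z))
    half = stats.norm.ppf(0.975) * se
    return MrResult(
        estimate=theta,
        se=se,
        ci_low=theta - half,
        ci_high=theta + half,
        pval=pval,
        n_variants=J,
        overdispersion=phi,
        method_label=label,
    )


def scale_estimate(
    res: MrResult,
    mm_hg_per_dose: float = 5.5,
    direction: str = "lowering",
) -> MrResult:
    """Re-express an MR estimate per pharmacological dose-equivalent.

    Multiplies estimate, SE and CI by ``mm_hg_per_dose`` (e.g. the 5.5 mm Hg
    diastolic blood pressure reduction of a standard 100 mg sildenafil dose)
    and negates the sign for ``direction='lowering'``, so that effects of
    target *inhibition* read with a positive sign. The z-score and p-value
    are unchanged. Scaling twice is an error.
    """
    if res.scale_factor is not None:
        raise ValueError("estimate already scaled; refusing to scale twice")
    if direction not in ("lowering", "raising"):
        raise ValueError(f"unknown direction {direction!r}")
    factor = -mm_hg_per_dose if direction == "lowering" else mm_hg_per_dose
    lo, hi = sorted((res.ci_low * factor, res.ci_high * factor))
    return replace(
        res,
        estimate=res.estimate * factor,
        se=res.se * abs(factor),
        ci_low=lo,
        ci_high=hi,
        scale_factor=factor,
    )


def bh_fdr(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order."""
    p = np.asarray(pvals, dtype=float)
    if p.ndim != 1 or p.size == 0:
        raise ValueError("pvals must be a non-empty 1-d vector")
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def exclude_weakest(
    h: HarmonisedInstrumentSet, strength: np.ndarray
) -> HarmonisedInstrumentSet:
    """Drop the single instrument with the smallest F statistic.

    A weak-instrument sensitivity analysis: remove the minimum-``strength``
    variant (ties broken by larger exposure p-value, then rsid) and subset
    the LD matrix to the survivors.
    """
    strength = np.asarray(strength, dtype=float)
    if len(h) < 2:
        raise ValueError("need at least 2 instruments to exclude one")
    if strength.shape != (len(h),):
        raise ValueError("strength vector length mismatch")
    pvals = h.exposure_pvals if h.exposure_pvals is not None else np.zeros(len(h))
    # sort ascending F, then descending exposure p, then rsid
    order = sorted(
        range(len(h)), key=lambda i: (strength[i], -pvals[i], h.rsids[i])
    )
    weakest = h.rsids[order[0]]
    return h.subset([r for r in h.rsids if r != weakest])
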