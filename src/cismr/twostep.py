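"""Two-step cis-MR adjustment for pleiotropic mediator pathways.

A variant may reach the outcome through a measured mediator rather than (or
in addition to) the exposure of interest. For each mediator pathway the
variant-outcome association is corrected by subtracting the transmitted
component: the variant-mediator effect b_GC times the mediator-outcome
effect b_CO. The corrected SE uses the exact variance of a product of
independent normals, so it can be validated against Monte-Carlo draws.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .mr import MrResult, ivw_correlated, wald_ratio
from .summary_data import HarmonisedInstrumentSet

__all__ = [
    "MediatorPath",
    "TwoStepResult",
    "estimate_mediator_effect",
    "adjust_variant_outcome",
    "adjusted_mr",
]


@dataclass
class MediatorPath:
    """One pleiotropic pathway: instrument-mediator and mediator-outcome effects.

    ``b_gc``/``se_gc`` are per-instrument-variant associations with the
    mediator; ``b_co``/``se_co`` is the (scalar) causal effect of the
    mediator on the outcome, typically itself an IVW estimate from the
    mediator's own instruments.
    """

    mediator: str
    b_gc: np.ndarray
    se_gc: np.ndarray
    b_co: float
    se_co: float

    def __post_init__(self) -> None:
        self.b_gc = np.asarray(self.b_gc, dtype=float)
        self.se_gc = np.asarray(self.se_gc, dtype=float)
        if self.b_gc.shape != self.se_gc.shape or self.b_gc.ndim != 1:
            raise ValueError("b_gc and se_gc must be 1-d vectors of equal length")
        if np.any(self.se_gc < 0) or self.se_co < 0:
            raise ValueError("standard errors must be nonnegative")


def estimate_mediator_effect(
    instruments_for_mediator: HarmonisedInstrumentSet,
) -> tuple[float, float]:
    """IVW estimate of the mediator-on-outcome effect from its own instruments.

    With a single instrument this is the Wald ratio.
    """
    h = instruments_for_mediator
    if len(h) == 1:
        return wald_ratio(h.Gamma[0], h.Gamma_se[0], h.gamma[0], h.gamma_se[0])
    res = ivw_correlated(h)
    return res.estimate, res.se


def adjust_variant_outcome(
    Gamma: float,
    Gamma_se: float,
    path: MediatorPath,
    variant_index: int,
) -> tuple[float, float]:
    """Remove one mediator pathway from a single variant-outcome association.

    Gamma_adj = Gamma - b_gc * b_co, with SE from the exact variance of a
    product of independent normal errors:

        se_adj^2 = Gamma_se^2 + b_gc^2 se_co^2 + b_co^2 se_gc^2
                   + se_gc^2 se_co^2
    """
    if not 0 <= variant_index < len(path.b_gc):
        raise IndexError(
            f"variant_index {variant_index} out of range for mediator {path.mediator!r}"
        )
    if Gamma_se < 0:
        raise ValueError("Gamma_se must be nonnegative")
    b_gc = path.b_gc[variant_index]
    se_gc = path.se_gc[variant_index]
    adj = Gamma - b_gc * path.b_co
    var = (
        Gamma_se**2
        + b_gc**2 * path.se_co**2
        + path.b_co**2 * se_gc**2
        + se_gc**2 * path.se_co**2
    )
    return adj, float(np.sqrt(var))


@dataclass(frozen=True)
class TwoStepResult:
    """Unadjusted and mediator-adjusted MR results side by side."""

    unadjusted: MrResult
    adjusted: MrResult
    mediators: tuple[str, ...]


def adjusted_mr(
    h: HarmonisedInstrumentSet,
    paths: list[MediatorPath],
    random_effects: bool = True,
) -> TwoStepResult:
    """Re-estimate the MR effect after removing mediator pathways.

    Each pathway's transmitted component is subtracted from every
    variant-outcome association (corrections are additive, so the order of
    independent mediators does not affect the point estimate), then the
    correlated IVW is re-run on the adjusted set. An empty pathway list
    returns the unadjusted result twice.
    """
    unadj = ivw_correlated(h, random_effects=random_effects)

    Gamma = h.Gamma.copy()
    Gamma_se = h.Gamma_se.copy()
    for path in paths:
        if len(path.b_gc) != len(h):
            raise ValueError(
                f"mediator {path.mediator!r} has {len(path.b_gc)} variant effects "
                f"for {len(h)} instruments"
            )
        for j in range(len(h)):
            Gamma[j], Gamma_se[j] = adjust_variant_outcome(
                Gamma[j], Gamma_se[j], path, j
            )

    h_adj = HarmonisedInstrumentSet(
        rsids=list(h.rsids),
        gamma=h.gamma,
        gamma_se=h.gamma_se,
        Gamma=Gamma,
        Gamma_se=Gamma_se,
        ld=h.ld,
        exposure_pvals=h.exposure_pvals,
        exclusions=list(h.exclusions),
    )
    adj = ivw_correlated(h_adj, random_effects=random_effects)
    return TwoStepResult(
        unadjusted=unadj,
        adjusted=adj,
        mediators=tuple(p.mediator for p in paths),
    )
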