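"""Bayesian colocalisation of two traits via approximate Bayes factors.

Under a single-causal-variant-per-trait assumption, each configuration of
causal variants across a region is weighted by per-variant approximate Bayes
factors (Wakefield's asymptotic form) and per-hypothesis priors, and the
evidence is summed over configurations to give posterior probabilities of
five hypotheses:

H0  no causal variant for either trait
H1  causal variant for trait 1 only
H2  causal variant for trait 2 only
H3  distinct causal variants for the two traits
H4  one shared causal variant

A high posterior for H4 supports a shared causal variant; a high posterior
for H3 indicates confounding by LD (two distinct signals); if neither
exceeds the decision threshold the analysis is likely underpowered.

All accumulation is in log space.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import logsumexp

__all__ = ["ColocResult", "log_abf", "coloc_abf", "coloc_label"]

#: Canonical per-variant priors: probability a variant is causal for trait 1
#: only, trait 2 only, or both.
DEFAULT_P1 = 1e-4
DEFAULT_P2 = 1e-4
DEFAULT_P12 = 1e-5

#: Prior SD of a true effect: 0.15 for a quantitative trait (per-SD units),
#: 0.2 for a binary trait (log-odds units).
PRIOR_SD_QUANTITATIVE = 0.15
PRIOR_SD_BINARY = 0.2


@dataclass(frozen=True)
class ColocResult:
    """Posterior probabilities of the five colocalisation hypotheses."""

    pp: tuple[float, float, float, float, float]
    n_variants: int
    priors: tuple[float, float, float]

    def __post_init__(self) -> None:
        if len(self.pp) != 5:
            raise ValueError("pp must have five entries (H0..H4)")
        if any(not 0 <= p <= 1 for p in self.pp):
            raise ValueError("posterior probabilities must lie in [0, 1]")
        if abs(sum(self.pp) - 1.0) > 1e-9:
            raise ValueError("posterior probabilities must sum to 1")

    @property
    def pp0(self) -> float:
        return self.pp[0]

    @property
    def pp1(self) -> float:
        return self.pp[1]

    @property
    def pp2(self) -> float:
        return self.pp[2]

    @property
    def pp3(self) -> float:
        return self.pp[3]

    @property
    def pp4(self) -> float:
        return self.pp[4]


def log_abf(beta: float, se: float, prior_sd: float) -> float:
    """Log approximate Bayes factor for a single association estimate.

    With V = se^2, W = prior_sd^2, z = beta/se and shrinkage r = W/(V+W):
    log ABF = 0.5 log(1 - r) + r z^2 / 2. Positive values favour a real
    effect; as the prior width W shrinks to zero the factor tends to 1.
    """
    if se <= 0:
        raise ValueError(f"se must be positive, got {se}")
    if prior_sd <= 0:
        raise ValueError(f"prior_sd must be positive, got {prior_sd}")
    V = se**2
    W = prior_sd**2
    r = W / (V + W)
    z = beta / se
    return 0.5 * np.log1p(-r) + 0.5 * r * z * z


def coloc_abf(
    trait1: np.ndarray,
    trait2: np.ndarray,
    p1: float = DEFAULT_P1,
    p2: float = DEFAULT_P2,
    p12: float = DEFAULT_P12,
    prior_sd1: float = PRIOR_SD_QUANTITATIVE,
    prior_sd2: float = PRIOR_SD_QUANTITATIVE,
) -> ColocResult:
    """Colocalise two traits over a shared variant list.

    ``trait1`` and ``trait2`` are (k, 2) arrays of (beta, se) for the same k
    variants in the same order. Hypothesis evidences are assembled by
    log-sum-exp over single-variant configurations: H1 and H2 sum each
    trait's per-variant ABFs, H4 sums same-variant products, and H3 sums
    cross-variant products (the full product of sums minus the same-variant
    terms).
    """
    b1 = np.atleast_2d(np.asarray(trait1, dtype=float))
    b2 = np.atleast_2d(np.asarray(trait2, dtype=float))
    if b1.shape != b2.shape or b1.shape[1] != 2:
        raise ValueError("trait arrays must both be (k, 2) of (beta, se)")
    k = b1.shape[0]
    if k < 2:
        raise ValueError("colocalisation needs at least 2 variants")
    if min(p1, p2, p12) <= 0 or p1 + p2 + p12 >= 1:
        raise ValueError("priors must be positive with p1 + p2 + p12 < 1")

    labf1 = np.array([log_abf(b, s, prior_sd1) for b, s in b1])
    labf2 = np.array([log_abf(b, s, prior_sd2) for b, s in b2])

    lsum1 = logsumexp(labf1)
    lsum2 = logsumexp(labf2)
    lsum12 = logsumexp(labf1 + labf2)  # same-variant products

    lh = np.empty(5)
    lh[0] = 0.0
    lh[1] = np.log(p1) + lsum1
    lh[2] = np.log(p2) + lsum2
    # sum over i != j of ABF1_i * ABF2_j  =  (sum_i)(sum_j) - sum_same
    cross = lsum1 + lsum2
    if cross <= lsum12:  # numerically empty cross term (k tiny / degenerate)
        lh[3] = -np.inf
    else:
        lh[3] = np.log(p1) + np.log(p2) + cross + np.log1p(-np.exp(lsum12 - cross))
    lh[4] = np.log(p12) + lsum12

    pp = np.exp(lh - logsumexp(lh))
    pp /= pp.sum()
    return ColocResult(pp=tuple(float(x) for x in pp), n_variants=k, priors=(p1, p2, p12))


def coloc_label(result: ColocResult, threshold: float = 0.8) -> str:
    """Qualitative reading of a colocalisation result.

    'shared causal variant' when the H4 posterior exceeds the threshold,
    'distinct causal variants (confounding by LD)' when H3 does, and
    'likely underpowered' otherwise.
    """
    if result.pp4 > threshold:
        return "shared causal variant"
    if result.pp3 > threshold:
        return "distinct causal variants (confounding by LD)"
    return "likely underpowered"
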