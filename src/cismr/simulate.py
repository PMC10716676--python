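"""Synthetic two-sample GWAS summary statistics with realistic structure.

Summary-level simulation: rather than simulating genotypes, per-variant
estimates are drawn directly from their asymptotic sampling distribution.
For a quantitative trait with standard deviation ``sd`` measured in ``n``
individuals, the standard error of a per-allele estimate at allele
frequency f is sd / sqrt(2 n f (1 - f)); estimation errors across variants
are correlated according to the LD matrix, and errors between the exposure
and outcome samples can be correlated to emulate participant overlap.

Defaults emulate a large blood-pressure exposure GWAS (n = 757 601,
SD = 10.7 mm Hg) with five cis instruments of per-allele effect ~0.1-0.16
mm Hg, and a male-only outcome GWAS (n = 211 840) — so simulated standard
errors land in the range seen in published instrument tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .summary_data import LDMatrix, SummaryDataset, VariantAssociation

__all__ = [
    "AR1",
    "Block",
    "Identity",
    "SimulationConfig",
    "simulate_ld",
    "simulate_summary_stats",
    "simulate_coloc_region",
    "table1_fixture",
    "table1_eqtl_fixture",
]


@dataclass(frozen=True)
class AR1:
    """First-order autoregressive LD decay: r_ij = rho^|i-j|."""

    rho: float

    def __post_init__(self) -> None:
        if not abs(self.rho) < 1:
            raise ValueError(f"|rho| must be < 1, got {self.rho}")


@dataclass(frozen=True)
class Block:
    """Block-diagonal LD: ``within_r`` inside each block, 0 between."""

    sizes: tuple[int, ...]
    within_r: float

    def __post_init__(self) -> None:
        if not abs(self.within_r) < 1:
            raise ValueError(f"|within_r| must be < 1, got {self.within_r}")


@dataclass(frozen=True)
class Identity:
    """Uncorrelated variants."""


LdModel = AR1 | Block | Identity

# Table-1-style instrument scales: per-allele mm Hg effects and frequencies
# of five cis variants in a PDE5-like gene region.
_DEFAULT_GAMMA = (0.131, 0.095, 0.144, 0.161, 0.102)
_DEFAULT_EAF = (0.338, 0.785, 0.033, 0.478, 0.141)


@dataclass
class SimulationConfig:
    """Full generative specification for a two-sample MR simulation.

    ``theta_true`` is the causal effect of the exposure on the outcome in
    outcome units per exposure unit. ``pleiotropy`` (b_gc vector, b_co
    scalar) adds a mediated component b_gc * b_co to every variant-outcome
    mean. ``overlap_rho`` correlates exposure- and outcome-side estimation
    errors, as arises when the two GWAS share participants.
    """

    n_variants: int = 5
    ld_model: LdModel = field(default_factory=Identity)
    gamma_true: np.ndarray = field(default_factory=lambda: np.array(_DEFAULT_GAMMA))
    theta_true: float = 0.0
    pleiotropy: tuple[np.ndarray, float] | None = None
    n_exposure: int = 757_601
    n_outcome: int = 211_840
    eaf: np.ndarray = field(default_factory=lambda: np.array(_DEFAULT_EAF))
    exposure_sd: float = 10.7
    outcome_sd: float = 1.0
    overlap_rho: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        self.gamma_true = np.asarray(self.gamma_true, dtype=float)
        self.eaf = np.asarray(self.eaf, dtype=float)
        k = self.n_variants
        if self.gamma_true.shape != (k,):
            raise ValueError(f"gamma_true must have length {k}")
        if self.eaf.shape != (k,):
            raise ValueError(f"eaf must have length {k}")
        if np.any((self.eaf <= 0) | (self.eaf >= 1)):
            raise ValueError("eaf values must lie strictly in (0, 1)")
        if not -1 <= self.overlap_rho <= 1:
            raise ValueError("overlap_rho must lie in [-1, 1]")
        if self.pleiotropy is not None:
            b_gc, b_co = self.pleiotropy
            b_gc = np.asarray(b_gc, dtype=float)
            if b_gc.shape != (k,):
                raise ValueError(f"pleiotropy b_gc must have length {k}")
            self.pleiotropy = (b_gc, float(b_co))


def simulate_ld(n_variants: int, model: LdModel) -> LDMatrix:
    """Construct a positive-semidefinite LD matrix from a structural model."""
    if isinstance(model, AR1):
        idx = np.arange(n_variants)
        r = model.rho ** np.abs(idx[:, None] - idx[None, :])
    elif isinstance(model, Block):
        if sum(model.sizes) != n_variants:
            raise ValueError(
                f"block sizes {model.sizes} do not sum to {n_variants}"
            )
        r = np.eye(n_variants)
        start = 0
        for size in model.sizes:
            sl = slice(start, start + size)
            block = np.full((size, size), model.within_r)
            np.fill_diagonal(block, 1.0)
            r[sl, sl] = block
            start += size
    elif isinstance(model, Identity):
        r = np.eye(n_variants)
    else:
        raise TypeError(f"unknown LD model {model!r}")
    rsids = [f"rs{i + 1:06d}" for i in range(n_variants)]
    return LDMatrix(rsids=rsids, ref_alleles=["A"] * n_variants, r=r)


def _gwas_se(sd: float, n: int, eaf: np.ndarray) -> np.ndarray:
    return sd / np.sqrt(2.0 * n * eaf * (1.0 - eaf))


def _two_sided_p(z: np.ndarray) -> np.ndarray:
    p = 2.0 * stats.norm.sf(np.abs(z))
    return np.clip(p, np.finfo(float).tiny, 1.0)


def _dataset(
    trait: str,
    rsids: list[str],
    eaf: np.ndarray,
    beta: np.ndarray,
    se: np.ndarray,
    n: int,
    trait_sd: float | None,
    positions: np.ndarray,
) -> SummaryDataset:
    pvals = _two_sided_p(beta / se)
    records = [
        VariantAssociation(
            rsid=rsids[j],
            chrom="4",
            pos=int(positions[j]),
            effect_allele="A",
            other_allele="G",
            eaf=float(eaf[j]),
            beta=float(beta[j]),
            se=float(se[j]),
            pval=float(pvals[j]),
            n=n,
        )
        for j in range(len(rsids))
    ]
    return SummaryDataset(trait=trait, trait_sd=trait_sd, records=records)


def simulate_summary_stats(
    config: SimulationConfig, replicate: int = 0
) -> tuple[SummaryDataset, SummaryDataset, LDMatrix]:
    """Draw one replicate of exposure and outcome summary statistics.

    Estimates are drawn jointly from a 2k-dimensional normal:
    gamma_hat ~ N(gamma_true, D_g rho D_g), Gamma_hat ~ N(theta gamma_true
    + b_gc b_co, D_G rho D_G), with cross-covariance overlap_rho * D_g rho
    D_G. Deterministic for a given (seed, replicate) pair.
    """
    k = config.n_variants
    rng = np.random.default_rng(np.random.SeedSequence((config.seed, replicate)))
    ld = simulate_ld(k, config.ld_model)

    se_g = _gwas_se(config.exposure_sd, config.n_exposure, config.eaf)
    se_G = _gwas_se(config.outcome_sd, config.n_outcome, config.eaf)

    mean_G = config.theta_true * config.gamma_true
    if config.pleiotropy is not None:
        b_gc, b_co = config.pleiotropy
        mean_G = mean_G + b_gc * b_co

    D = np.diag(np.concatenate([se_g, se_G]))
    overlap = np.array([[1.0, config.overlap_rho], [config.overlap_rho, 1.0]])
    cov = D @ np.kron(overlap, ld.r) @ D
    mean = np.concatenate([config.gamma_true, mean_G])
    draw = rng.multivariate_normal(mean, cov, method="svd")
    gamma_hat, Gamma_hat = draw[:k], draw[k:]

    positions = 120_415_550 + 25_000 * np.arange(1, k + 1)
    exposure = _dataset(
        "exposure", ld.rsids, config.eaf, gamma_hat, se_g,
        config.n_exposure, config.exposure_sd, positions,
    )
    outcome = _dataset(
        "outcome", ld.rsids, config.eaf, Gamma_hat, se_G,
        config.n_outcome, config.outcome_sd, positions,
    )
    return exposure, outcome, ld


def simulate_coloc_region(
    n_variants: int,
    scenario: str,
    z_signal: float,
    ld: LDMatrix,
    seed: int = 0,
    se_scale: float = 0.03,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate aligned regional association statistics for two traits.

    Per-variant z-scores are drawn as MVN(z_signal * r[:, causal], rho), so
    a planted signal leaks into neighbours through LD exactly as in a real
    region; estimates are reported as beta = z * se with a uniform
    GWAS-scale standard error ``se_scale`` (0.03, typical of a well-powered
    quantitative-trait GWAS, and commensurate with the canonical 0.15 prior
    effect SD). Scenarios: ``shared`` (one causal variant for both traits),
    ``distinct`` (the least-correlated pair, one per trait),
    ``trait1_only``, and ``null``.
    """
    if n_variants < 2:
        raise ValueError("need at least 2 variants")
    if len(ld) != n_variants:
        raise ValueError("LD matrix size does not match n_variants")
    rng = np.random.default_rng(np.random.SeedSequence((seed, 7)))

    c1 = n_variants // 2
    c2 = int(np.argmin(np.abs(ld.r[c1])))
    means = {
        "shared": (ld.r[:, c1], ld.r[:, c1]),
        "distinct": (ld.r[:, c1], ld.r[:, c2]),
        "trait1_only": (ld.r[:, c1], np.zeros(n_variants)),
        "null": (np.zeros(n_variants), np.zeros(n_variants)),
    }
    if scenario not in means:
        raise ValueError(f"unknown scenario {scenario!r}; choose from {sorted(means)}")
    m1, m2 = (z_signal * m for m in means[scenario])

    z1 = rng.multivariate_normal(m1, ld.r, method="svd")
    z2 = rng.multivariate_normal(m2, ld.r, method="svd")
    frame = lambda z: pd.DataFrame(
        {"rsid": ld.rsids, "beta": z * se_scale, "se": np.full_like(z, se_scale)}
    )
    return frame(z1), frame(z2)


# Published instrument table for the PDE5 region (GRCh37 chr4), used as a
# deterministic fixture: per-allele diastolic blood pressure effects from a
# 757 601-participant GWAS, with blood eQTL p-values (n = 31 684).
_TABLE1_ROWS = [
    # rsid, pos, effect, other, eaf, beta, se, pval, eqtl_pval
    ("rs10050092", 120_532_085, "T", "C", 0.338, 0.131, 0.018, 8.62e-13, 1.49e-18),
    ("rs12646525", 120_502_461, "C", "T", 0.785, 0.095, 0.021, 6.74e-06, 1.46e-09),
    ("rs17355550", 120_416_096, "T", "C", 0.033, 0.144, 0.050, 4.07e-03, 3.51e-08),
    ("rs66887589", 120_509_279, "C", "T", 0.478, 0.161, 0.017, 1.83e-20, 1.87e-40),
    ("rs80223330", 120_423_094, "A", "G", 0.141, 0.102, 0.027, 1.21e-04, 2.10e-34),
]

TABLE1_N = 757_601
TABLE1_EQTL_N = 31_684
TABLE1_DBP_SD = 10.7


def table1_fixture(ld_model: LdModel | None = None) -> tuple[SummaryDataset, LDMatrix]:
    """The five published cis instruments with their exposure associations.

    The source table prints no LD among the five variants (only that all
    pairwise r^2 < 0.35 after pruning), so the LD matrix is configurable and
    defaults to identity.
    """
    records = [
        VariantAssociation(
            rsid=rsid, chrom="4", pos=pos, effect_allele=ea, other_allele=oa,
            eaf=eaf, beta=beta, se=se, pval=pval, n=TABLE1_N,
        )
        for rsid, pos, ea, oa, eaf, beta, se, pval, _ in _TABLE1_ROWS
    ]
    dataset = SummaryDataset(
        trait="diastolic blood pressure", trait_sd=TABLE1_DBP_SD, records=records
    )
    if ld_model is None or isinstance(ld_model, Identity):
        r = np.eye(len(records))
    else:
        r = simulate_ld(len(records), ld_model).r
    ld = LDMatrix(
        rsids=[rec.rsid for rec in records],
        ref_alleles=[rec.effect_allele for rec in records],
        r=r,
    )
    return dataset, ld


def table1_eqtl_fixture() -> SummaryDataset:
    """Synthetic eQTL companion table for the five published instruments.

    The source prints only eQTL p-values; effect sizes here are synthetic,
    back-filled as |z| quantiles of the printed p-values with unit standard
    errors, which is sufficient for position/p-value-based cis filtering.
    """
    records = []
    for rsid, pos, ea, oa, eaf, _, _, _, eqtl_p in _TABLE1_ROWS:
        z = stats.norm.isf(eqtl_p / 2.0)
        records.append(
            VariantAssociation(
                rsid=rsid, chrom="4", pos=pos, effect_allele=ea, other_allele=oa,
                eaf=eaf, beta=float(z), se=1.0, pval=eqtl_p, n=TABLE1_EQTL_N,
            )
        )
    return SummaryDataset(trait="PDE5 expression", records=records)
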