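"""Cis-instrument selection and strength diagnostics.

Instruments for a drug-target analysis are variants inside the target gene's
region that associate with its expression at genome-wide significance, then
greedily pruned by LD so that no retained pair is strongly correlated.
Strength is summarised per variant by the proportion of exposure variance
explained and the corresponding F statistic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .summary_data import LDMatrix, SummaryDataset

__all__ = [
    "GeneRegion",
    "InstrumentDiagnostics",
    "filter_cis_eqtl",
    "prune_by_ld",
    "f_wald",
    "f_from_r2",
    "variance_explained",
    "diagnostics_table",
]


@dataclass(frozen=True)
class GeneRegion:
    """1-based closed genomic interval (GRCh37)."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"region start {self.start} > end {self.end}")

    def contains(self, chrom: str, pos: int) -> bool:
        return str(chrom) == self.chrom and self.start <= pos <= self.end

    @classmethod
    def parse(cls, text: str) -> "GeneRegion":
        """Parse 'chrom:start-end' (spaces and commas in numbers tolerated)."""
        chrom, _, span = text.partition(":")
        start, _, end = span.partition("-")
        clean = lambda s: int(s.replace(",", "").replace(" ", ""))
        return cls(chrom=chrom.strip(), start=clean(start), end=clean(end))


@dataclass(frozen=True)
class InstrumentDiagnostics:
    rsid: str
    f_wald: float
    f_r2: float
    r2_explained: float

    def __post_init__(self) -> None:
        if min(self.f_wald, self.f_r2, self.r2_explained) < 0:
            raise ValueError("diagnostics must be nonnegative")


def filter_cis_eqtl(
    eqtls: SummaryDataset,
    region: GeneRegion,
    p_threshold: float = 5e-8,
) -> SummaryDataset:
    """Keep eQTL records inside ``region`` with p strictly below ``p_threshold``.

    Boundaries are inclusive; the significance comparison is strict, so a
    variant at exactly the threshold is excluded. An empty result is legal.
    """
    kept = [
        rec
        for rec in eqtls
        if region.contains(rec.chrom, rec.pos) and rec.pval < p_threshold
    ]
    return SummaryDataset(
        trait=eqtls.trait,
        trait_type=eqtls.trait_type,
        trait_sd=eqtls.trait_sd,
        records=kept,
    )


def prune_by_ld(
    candidates: SummaryDataset,
    ranking_pvals: dict[str, float],
    ld: LDMatrix,
    r2_threshold: float = 0.35,
    window_kb: int = 10_000,
) -> list[str]:
    """Greedy p-value-ranked LD pruning (clumping).

    Repeatedly select the candidate with the smallest ranking p-value, then
    discard every unselected candidate within ``window_kb`` kilobases whose
    squared correlation with it is at least ``r2_threshold``. Ties on p are
    broken by distance to the midpoint of the candidate positions, then by
    rsid, so the output depends only on the ranking, not the input order.
    """
    recs = {rec.rsid: rec for rec in candidates}
    for rsid in recs:
        if rsid not in ranking_pvals:
            raise ValueError(f"no ranking p-value for {rsid}")
        ld.index_of(rsid)  # raises KeyError if absent
    if not recs:
        return []

    positions = [rec.pos for rec in recs.values()]
    midpoint = (min(positions) + max(positions)) / 2.0
    order = sorted(
        recs,
        key=lambda r: (ranking_pvals[r], abs(recs[r].pos - midpoint), r),
    )

    selected: list[str] = []
    remaining = list(order)
    while remaining:
        lead = remaining.pop(0)
        selected.append(lead)
        i = ld.index_of(lead)
        survivors = []
        for rsid in remaining:
            j = ld.index_of(rsid)
            within = abs(recs[rsid].pos - recs[lead].pos) <= window_kb * 1000
            if within and ld.r[i, j] ** 2 >= r2_threshold:
                continue
            survivors.append(rsid)
        remaining = survivors
    return selected


def f_wald(beta: float, se: float) -> float:
    """Squared z-score instrument-strength statistic, (beta/se)^2."""
    if se <= 0:
        raise ValueError(f"se must be positive, got {se}")
    return (beta / se) ** 2


def f_from_r2(r2: float, n: int) -> float:
    """F statistic from variance explained: r2 * (n - 2) / (1 - r2).

    This is the single-regressor F for a regression on one variant and is
    the form under which published per-variant R^2 and F columns agree.
    """
    if not 0 <= r2 < 1:
        raise ValueError(f"r2 must be in [0, 1), got {r2}")
    if n <= 2:
        raise ValueError(f"n must exceed 2, got {n}")
    return r2 * (n - 2) / (1 - r2)


def variance_explained(beta: float, eaf: float, trait_sd: float) -> float:
    """Proportion of trait variance explained: 2 f (1-f) beta^2 / sd^2.

    Assumes Hardy-Weinberg allele-dosage variance 2 f (1-f) and a per-allele
    additive effect ``beta`` on a trait with standard deviation ``trait_sd``.
    """
    if not 0 < eaf < 1:
        raise ValueError(f"eaf must be in (0, 1), got {eaf}")
    if trait_sd <= 0:
        raise ValueError(f"trait_sd must be positive, got {trait_sd}")
    return 2.0 * eaf * (1.0 - eaf) * beta**2 / trait_sd**2


def diagnostics_table(dataset: SummaryDataset, trait_sd: float | None = None) -> pd.DataFrame:
    """Per-variant strength diagnostics in a publication-style table.

    Columns mirror the usual instrument table: identifiers, alleles, EAF,
    beta, SE, p, variance explained (R2) and both F forms. The summary row
    statistics reported alongside are the arithmetic and geometric means of
    the R2-based F.
    """
    sd = trait_sd if trait_sd is not None else dataset.trait_sd
    if sd is None:
        raise ValueError("trait_sd required for variance explained")
    rows = []
    for rec in dataset:
        r2 = variance_explained(rec.beta, rec.eaf, sd)
        rows.append(
            {
                "rsid": rec.rsid,
                "chrom": rec.chrom,
                "pos": rec.pos,
                "effect_allele": rec.effect_allele,
                "other_allele": rec.other_allele,
                "eaf": rec.eaf,
                "beta": rec.beta,
                "se": rec.se,
                "pval": rec.pval,
                "r2_explained": r2,
                "f_r2": f_from_r2(r2, rec.n),
                "f_wald": f_wald(rec.beta, rec.se),
            }
        )
    df = pd.DataFrame(rows)
    df.attrs["f_r2_mean_arith"] = float(df["f_r2"].mean()) if len(df) else float("nan")
    df.attrs["f_r2_mean_geom"] = (
        float(np.exp(np.log(df["f_r2"]).mean())) if len(df) and (df["f_r2"] > 0).all() else float("nan")
    )
    return df
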