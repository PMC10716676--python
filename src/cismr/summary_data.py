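"""GWAS summary-statistic containers, file I/O, and allele harmonisation.

Two-sample Mendelian randomisation works entirely from published per-variant
association estimates: an effect size ``beta`` per copy of a declared effect
allele, its standard error, the effect allele frequency, a p-value and a
sample size. Before exposure and outcome estimates can be combined they must
be expressed with respect to the same effect allele at every variant, and the
signed LD correlation matrix must be anchored to those same alleles — that
alignment is what this module provides.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "VariantAssociation",
    "SummaryDataset",
    "LDMatrix",
    "HarmonisedInstrumentSet",
    "Exclusion",
    "read_summary",
    "write_summary",
    "read_ld",
    "write_ld",
    "harmonise",
    "align_ld",
]

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

#: Logical column names every summary-statistics table must resolve.
REQUIRED_COLUMNS = (
    "rsid",
    "chrom",
    "pos",
    "effect_allele",
    "other_allele",
    "eaf",
    "beta",
    "se",
    "pval",
    "n",
)


@dataclass(frozen=True)
class VariantAssociation:
    """A single variant's association with a single trait.

    ``beta`` is in trait units per copy of ``effect_allele``; ``eaf`` is the
    effect allele frequency in the association sample.
    """

    rsid: str
    chrom: str
    pos: int
    effect_allele: str
    other_allele: str
    eaf: float
    beta: float
    se: float
    pval: float
    n: int

    def __post_init__(self) -> None:
        for field_name in ("eaf", "beta", "se", "pval"):
            value = getattr(self, field_name)
            if not np.isfinite(value):
                raise ValueError(f"{self.rsid}: non-finite {field_name}: {value}")
        if self.se <= 0:
            raise ValueError(f"{self.rsid}: se must be positive, got {self.se}")
        if not 0.0 <= self.eaf <= 1.0:
            raise ValueError(f"{self.rsid}: eaf outside [0, 1]: {self.eaf}")
        if self.effect_allele == self.other_allele:
            raise ValueError(f"{self.rsid}: effect and other allele identical")
        if not 0.0 < self.pval <= 1.0:
            raise ValueError(f"{self.rsid}: pval outside (0, 1]: {self.pval}")
        if self.n <= 0:
            raise ValueError(f"{self.rsid}: sample size must be positive")

    @property
    def zscore(self) -> float:
        return self.beta / self.se

    def is_palindromic(self) -> bool:
        """A/T or C/G variants cannot be strand-resolved from alleles alone."""
        return _COMPLEMENT.get(self.effect_allele) == self.other_allele


@dataclass
class SummaryDataset:
    """Ordered collection of per-variant associations for one trait."""

    trait: str
    records: list[VariantAssociation]
    trait_type: str = "quantitative"
    trait_sd: float | None = None

    def __post_init__(self) -> None:
        if self.trait_type not in ("quantitative", "binary"):
            raise ValueError(f"unknown trait_type {self.trait_type!r}")
        seen: set[str] = set()
        for rec in self.records:
            if rec.rsid in seen:
                raise ValueError(f"duplicate rsid {rec.rsid} in dataset {self.trait!r}")
            seen.add(rec.rsid)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    @property
    def rsids(self) -> list[str]:
        return [r.rsid for r in self.records]

    def get(self, rsid: str) -> VariantAssociation:
        for rec in self.records:
            if rec.rsid == rsid:
                return rec
        raise KeyError(rsid)

    def subset(self, rsids: Sequence[str]) -> "SummaryDataset":
        """Restrict to ``rsids``, preserving the requested order."""
        return SummaryDataset(
            trait=self.trait,
            trait_type=self.trait_type,
            trait_sd=self.trait_sd,
            records=[self.get(r) for r in rsids],
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([vars(r) for r in self.records], columns=REQUIRED_COLUMNS)

    @classmethod
    def from_frame(
        cls,
        df: pd.DataFrame,
        trait: str,
        trait_type: str = "quantitative",
        trait_sd: float | None = None,
    ) -> "SummaryDataset":
        records = [
            VariantAssociation(
                rsid=str(row.rsid),
                chrom=str(row.chrom),
                pos=int(row.pos),
                effect_allele=str(row.effect_allele),
                other_allele=str(row.other_allele),
                eaf=float(row.eaf),
                beta=float(row.beta),
                se=float(row.se),
                pval=float(row.pval),
                n=int(row.n),
            )
            for row in df.itertuples(index=False)
        ]
        return cls(trait=trait, trait_type=trait_type, trait_sd=trait_sd, records=records)


@dataclass
class LDMatrix:
    """Signed LD correlation matrix with per-variant reference alleles.

    ``r[i, j]`` is the correlation between allele dosages counted with respect
    to ``ref_alleles[i]`` and ``ref_alleles[j]``; flipping a variant's
    reference allele negates its row and column.
    """

    rsids: list[str]
    ref_alleles: list[str]
    r: np.ndarray

    def __post_init__(self) -> None:
        self.r = np.asarray(self.r, dtype=float)
        k = len(self.rsids)
        if self.r.shape != (k, k):
            raise ValueError(f"LD matrix shape {self.r.shape} does not match {k} rsids")
        if len(self.ref_alleles) != k:
            raise ValueError("ref_alleles length does not match rsids")
        if not np.allclose(self.r, self.r.T, atol=1e-8):
            raise ValueError("LD matrix is not symmetric")
        if not np.allclose(np.diag(self.r), 1.0, atol=1e-8):
            raise ValueError("LD matrix diagonal is not 1")
        if np.any(np.abs(self.r) > 1 + 1e-8):
            raise ValueError("LD correlations must satisfy |r| <= 1")

    def __len__(self) -> int:
        return len(self.rsids)

    def index_of(self, rsid: str) -> int:
        try:
            return self.rsids.index(rsid)
        except ValueError:
            raise KeyError(f"rsid {rsid!r} absent from LD matrix") from None

    def subset(self, rsids: Sequence[str]) -> "LDMatrix":
        idx = [self.index_of(r) for r in rsids]
        return LDMatrix(
            rsids=list(rsids),
            ref_alleles=[self.ref_alleles[i] for i in idx],
            r=self.r[np.ix_(idx, idx)].copy(),
        )


@dataclass(frozen=True)
class Exclusion:
    """Record of a variant dropped during harmonisation or selection."""

    rsid: str
    stage: str
    reason: str


@dataclass
class HarmonisedInstrumentSet:
    """Exposure and outcome estimates on a shared, allele-aligned variant list.

    gamma / gamma_se are the variant-exposure estimates, Gamma / Gamma_se the
    variant-outcome estimates, and ``ld`` carries the correlations signed to
    the harmonised effect alleles.
    """

    rsids: list[str]
    gamma: np.ndarray
    gamma_se: np.ndarray
    Gamma: np.ndarray
    Gamma_se: np.ndarray
    ld: LDMatrix
    exposure_pvals: np.ndarray | None = None
    exclusions: list[Exclusion] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.gamma = np.asarray(self.gamma, dtype=float)
        self.gamma_se = np.asarray(self.gamma_se, dtype=float)
        self.Gamma = np.asarray(self.Gamma, dtype=float)
        self.Gamma_se = np.asarray(self.Gamma_se, dtype=float)
        k = len(self.rsids)
        for name in ("gamma", "gamma_se", "Gamma", "Gamma_se"):
            vec = getattr(self, name)
            if vec.shape != (k,):
                raise ValueError(f"{name} has shape {vec.shape}, expected ({k},)")
        if len(self.ld) != k or self.ld.rsids != list(self.rsids):
            raise ValueError("LD matrix variant list does not match instrument set")
        if np.any(self.gamma_se <= 0) or np.any(self.Gamma_se <= 0):
            raise ValueError("all standard errors must be positive")
        if self.exposure_pvals is not None:
            self.exposure_pvals = np.asarray(self.exposure_pvals, dtype=float)
            if self.exposure_pvals.shape != (k,):
                raise ValueError("exposure_pvals length mismatch")

    def __len__(self) -> int:
        return len(self.rsids)

    def subset(self, rsids: Sequence[str]) -> "HarmonisedInstrumentSet":
        idx = [self.rsids.index(r) for r in rsids]
        return HarmonisedInstrumentSet(
            rsids=list(rsids),
            gamma=self.gamma[idx],
            gamma_se=self.gamma_se[idx],
            Gamma=self.Gamma[idx],
            Gamma_se=self.Gamma_se[idx],
            ld=self.ld.subset(rsids),
            exposure_pvals=None if self.exposure_pvals is None else self.exposure_pvals[idx],
            exclusions=list(self.exclusions),
        )


class ColumnMappingError(KeyError):
    """A required logical column could not be resolved in the input file."""


@dataclass(frozen=True)
class ParseError:
    line: int
    rsid: str
    message: str


def read_summary(
    path: str | Path,
    column_map: Mapping[str, str] | None = None,
    trait: str = "trait",
    trait_type: str = "quantitative",
    trait_sd: float | None = None,
    sep: str = "\t",
) -> tuple[SummaryDataset, list[ParseError]]:
    """Read a delimited summary-statistics file into a :class:`SummaryDataset`.

    ``column_map`` maps logical names (``rsid``, ``beta``, ...) to the file's
    header names; identity mapping by default. Rows that fail to parse or
    violate the per-variant invariants are collected as :class:`ParseError`
    entries rather than silently dropped.
    """
    column_map = dict(column_map or {})
    df = pd.read_csv(path, sep=sep, dtype=str)
    resolved = {}
    for logical in REQUIRED_COLUMNS:
        source = column_map.get(logical, logical)
        if source not in df.columns:
            raise ColumnMappingError(
                f"column {source!r} (logical {logical!r}) missing from {path}"
            )
        resolved[logical] = source

    records: list[VariantAssociation] = []
    errors: list[ParseError] = []
    for i in range(len(df)):
        raw = {k: df.iloc[i][v] for k, v in resolved.items()}
        rsid = str(raw["rsid"])
        try:
            rec = VariantAssociation(
                rsid=rsid,
                chrom=str(raw["chrom"]),
                pos=int(float(raw["pos"])),
                effect_allele=str(raw["effect_allele"]).upper(),
                other_allele=str(raw["other_allele"]).upper(),
                eaf=float(raw["eaf"]),
                beta=float(raw["beta"]),
                se=float(raw["se"]),
                pval=float(raw["pval"]),
                n=int(float(raw["n"])),
            )
        except (TypeError, ValueError) as exc:
            errors.append(ParseError(line=i + 2, rsid=rsid, message=str(exc)))
            continue
        records.append(rec)
    if errors:
        logger.warning("%s: rejected %d of %d rows", path, len(errors), len(df))
    dataset = SummaryDataset(
        trait=trait, trait_type=trait_type, trait_sd=trait_sd, records=records
    )
    return dataset, errors


def write_summary(dataset: SummaryDataset, path: str | Path, sep: str = "\t") -> None:
    dataset.to_frame().to_csv(path, sep=sep, index=False)


def read_ld(matrix_path: str | Path, alleles_path: str | Path, sep: str = "\t") -> LDMatrix:
    """Read a square LD TSV (rsid header row/column) plus its allele sidecar.

    The sidecar is a two-column table ``rsid, ref_allele`` naming the allele
    each row's correlation signs are anchored to.
    """
    mat = pd.read_csv(matrix_path, sep=sep, index_col=0)
    rsids = [str(r) for r in mat.index]
    if list(mat.columns) != rsids:
        raise ValueError("LD matrix header row and column disagree")
    alleles = pd.read_csv(alleles_path, sep=sep, dtype=str)
    allele_map = dict(zip(alleles.iloc[:, 0], alleles.iloc[:, 1]))
    missing = [r for r in rsids if r not in allele_map]
    if missing:
        raise ValueError(f"reference alleles missing for {missing}")
    return LDMatrix(
        rsids=rsids,
        ref_alleles=[allele_map[r].upper() for r in rsids],
        r=mat.to_numpy(dtype=float),
    )


def write_ld(ld: LDMatrix, matrix_path: str | Path, alleles_path: str | Path, sep: str = "\t") -> None:
    pd.DataFrame(ld.r, index=ld.rsids, columns=ld.rsids).to_csv(matrix_path, sep=sep)
    pd.DataFrame({"rsid": ld.rsids, "ref_allele": ld.ref_alleles}).to_csv(
        alleles_path, sep=sep, index=False
    )


def align_ld(ld: LDMatrix, target_alleles: Mapping[str, str]) -> LDMatrix:
    """Re-sign an LD matrix so each variant's row is anchored to a target allele.

    Flipping variant *i* (target allele differs from the stored reference
    allele) multiplies row and column *i* by −1; the diagonal is untouched.
    """
    signs = np.ones(len(ld))
    new_refs = list(ld.ref_alleles)
    for rsid, allele in target_alleles.items():
        i = ld.index_of(rsid)
        if allele.upper() != ld.ref_alleles[i]:
            signs[i] = -1.0
            new_refs[i] = allele.upper()
    r = ld.r * np.outer(signs, signs)
    return LDMatrix(rsids=list(ld.rsids), ref_alleles=new_refs, r=r)


def _allele_relation(exp: VariantAssociation, out: VariantAssociation) -> str:
    """Classify outcome alleles relative to exposure: same, swapped, or incompatible.

    Strand complements are tried before giving up, so e.g. exposure T/C
    matches outcome A/G as 'same' on the flipped strand.
    """
    e = (exp.effect_allele, exp.other_allele)
    o = (out.effect_allele, out.other_allele)
    if o == e:
        return "same"
    if o == (e[1], e[0]):
        return "swapped"
    oc = (_COMPLEMENT.get(o[0]), _COMPLEMENT.get(o[1]))
    if oc == e:
        return "same"
    if oc == (e[1], e[0]):
        return "swapped"
    return "incompatible"


def harmonise(
    exposure: SummaryDataset,
    outcome: SummaryDataset,
    ld: LDMatrix,
    palindrome_eaf_window: float = 0.08,
) -> HarmonisedInstrumentSet:
    """Align outcome estimates and the LD matrix to the exposure effect alleles.

    Variants are restricted to the rsid intersection of all three inputs.
    Where the outcome's effect allele is the exposure's other allele the
    outcome beta is negated and its frequency complemented. Palindromic (A/T,
    C/G) variants with exposure EAF within ``palindrome_eaf_window`` of 0.5
    are excluded as strand-ambiguous; incompatible allele pairs are excluded
    with a reason. Applying the function to its own output is the identity.
    """
    shared = [r for r in exposure.rsids if r in set(outcome.rsids) & set(ld.rsids)]
    if not shared:
        raise ValueError("no rsid common to exposure, outcome, and LD matrix")

    exclusions: list[Exclusion] = []
    kept: list[str] = []
    gamma, gamma_se, Gamma, Gamma_se, pvals = [], [], [], [], []
    target_alleles: dict[str, str] = {}

    for rsid in shared:
        exp = exposure.get(rsid)
        out = outcome.get(rsid)
        if exp.is_palindromic() and abs(exp.eaf - 0.5) <= palindrome_eaf_window:
            exclusions.append(Exclusion(rsid, "harmonise", "ambiguous palindrome"))
            continue
        relation = _allele_relation(exp, out)
        if relation == "incompatible":
            exclusions.append(Exclusion(rsid, "harmonise", "incompatible alleles"))
            continue
        out_beta = out.beta if relation == "same" else -out.beta
        kept.append(rsid)
        gamma.append(exp.beta)
        gamma_se.append(exp.se)
        Gamma.append(out_beta)
        Gamma_se.append(out.se)
        pvals.append(exp.pval)
        target_alleles[rsid] = exp.effect_allele

    if not kept:
        raise ValueError("harmonisation excluded every shared variant")

    ld_aligned = align_ld(ld.subset(kept), target_alleles)
    return HarmonisedInstrumentSet(
        rsids=kept,
        gamma=np.array(gamma),
        gamma_se=np.array(gamma_se),
        Gamma=np.array(Gamma),
        Gamma_se=np.array(Gamma_se),
        ld=ld_aligned,
        exposure_pvals=np.array(pvals),
        exclusions=exclusions,
    )
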