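"""End-to-end cis-MR pipeline: select → harmonise → MR → coloc → two-step.

One declarative configuration drives the whole analysis so a run is fully
reproducible: instrument selection (gene-region eQTL filter then LD
pruning ranked by exposure p-value), allele harmonisation, correlated-
instrument IVW with dose scaling, a weakest-instrument sensitivity
analysis, optional mediator adjustment, BH-FDR across the configured
outcome family, and colocalisation for outcomes whose FDR-adjusted p-value
falls below the significance threshold. Every excluded variant is logged
with a reason.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import coloc as coloc_mod
from .instruments import GeneRegion, diagnostics_table, filter_cis_eqtl, prune_by_ld
from .mr import MrResult, bh_fdr, exclude_weakest, ivw_correlated, scale_estimate
from .summary_data import (
    Exclusion,
    HarmonisedInstrumentSet,
    LDMatrix,
    SummaryDataset,
    harmonise,
    read_ld,
    read_summary,
)
from .twostep import MediatorPath, adjusted_mr

logger = logging.getLogger(__name__)

__all__ = ["AnalysisConfig", "OutcomeSpec", "PipelineResult", "run_pipeline", "render_report"]


@dataclass
class OutcomeSpec:
    name: str
    path: str
    trait_type: str = "quantitative"
    column_map: dict = field(default_factory=dict)


@dataclass
class AnalysisConfig:
    """Declarative description of one full analysis run."""

    exposure_path: str
    outcome_specs: list[OutcomeSpec]
    ld_path: str
    ld_alleles_path: str
    eqtl_path: str
    region: str
    exposure_column_map: dict = field(default_factory=dict)
    eqtl_column_map: dict = field(default_factory=dict)
    exposure_sd: float | None = None
    eqtl_p: float = 5e-8
    prune_r2: float = 0.35
    window_kb: int = 10_000
    scale_mmhg: float = 5.5
    scale_direction: str = "lowering"
    coloc_p1: float = coloc_mod.DEFAULT_P1
    coloc_p2: float = coloc_mod.DEFAULT_P2
    coloc_p12: float = coloc_mod.DEFAULT_P12
    coloc_fdr_threshold: float = 0.05
    mediator_path: str | None = None
    out_dir: str = "cismr_out"
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.eqtl_p, self.prune_r2, self.window_kb, self.scale_mmhg) <= 0:
            raise ValueError("thresholds must be positive")
        names = [o.name for o in self.outcome_specs]
        if len(set(names)) != len(names):
            raise ValueError("outcome names must be unique")

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "AnalysisConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        raw.update({k: v for k, v in overrides.items() if v is not None})
        outcomes = [
            spec if isinstance(spec, OutcomeSpec) else OutcomeSpec(**spec)
            for spec in raw.pop("outcome_specs", [])
        ]
        return cls(outcome_specs=outcomes, **raw)

    def to_yaml(self, path: str | Path) -> None:
        raw = dataclasses.asdict(self)
        with open(path, "w") as fh:
            yaml.safe_dump(raw, fh, sort_keys=False)


@dataclass
class OutcomeResult:
    name: str
    main: MrResult
    weakest_excluded: MrResult | None
    adjusted: MrResult | None
    coloc: coloc_mod.ColocResult | None
    coloc_label: str | None
    fdr_pval: float | None = None


@dataclass
class PipelineResult:
    instrument_rsids: list[str]
    diagnostics: pd.DataFrame
    outcomes: list[OutcomeResult]
    exclusions: list[Exclusion]


def load_mediator_paths(
    path: str | Path, rsids: list[str], p_threshold: float = 1e-5
) -> list[MediatorPath]:
    """Read a mediator-association table into per-mediator pathways.

    Expected TSV columns: mediator, rsid, b_gc, se_gc, pval, b_co, se_co —
    one row per (mediator, variant); b_co/se_co repeat within a mediator.
    Rows with pval >= p_threshold are dropped (the mediator-discovery
    threshold); instrument variants missing from a mediator's rows get a
    zero pathway effect.
    """
    df = pd.read_csv(path, sep="\t")
    if "pval" in df.columns:
        df = df[df["pval"] < p_threshold]
    paths = []
    for mediator, grp in df.groupby("mediator", sort=True):
        lookup = {str(r.rsid): (float(r.b_gc), float(r.se_gc)) for r in grp.itertuples()}
        b_gc = np.array([lookup.get(r, (0.0, 0.0))[0] for r in rsids])
        se_gc = np.array([lookup.get(r, (0.0, 0.0))[1] for r in rsids])
        paths.append(
            MediatorPath(
                mediator=str(mediator),
                b_gc=b_gc,
                se_gc=se_gc,
                b_co=float(grp["b_co"].iloc[0]),
                se_co=float(grp["se_co"].iloc[0]),
            )
        )
    return paths


def _coloc_from_instruments(
    h: HarmonisedInstrumentSet, config: AnalysisConfig, outcome_type: str
) -> tuple[coloc_mod.ColocResult, str]:
    trait1 = np.column_stack([h.gamma, h.gamma_se])
    trait2 = np.column_stack([h.Gamma, h.Gamma_se])
    res = coloc_mod.coloc_abf(
        trait1,
        trait2,
        p1=config.coloc_p1,
        p2=config.coloc_p2,
        p12=config.coloc_p12,
        prior_sd1=coloc_mod.PRIOR_SD_QUANTITATIVE,
        prior_sd2=(
            coloc_mod.PRIOR_SD_BINARY
            if outcome_type == "binary"
            else coloc_mod.PRIOR_SD_QUANTITATIVE
        ),
    )
    return res, coloc_mod.coloc_label(res)


def run_pipeline(config: AnalysisConfig) -> PipelineResult:
    """Execute the full analysis described by ``config``.

    Deterministic for a fixed config: the only stochastic components live in
    the simulation module, and the pipeline itself consumes files.
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    log_path = out_dir / "run.log"
    handler = logging.FileHandler(log_path, mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    root = logging.getLogger("cismr")
    root.addHandler(handler)
    root.setLevel(logging.INFO)

    exclusions: list[Exclusion] = []
    try:
        region = GeneRegion.parse(config.region)
        exposure, exp_errors = read_summary(
            config.exposure_path,
            column_map=config.exposure_column_map,
            trait="exposure",
            trait_sd=config.exposure_sd,
        )
        eqtls, _ = read_summary(
            config.eqtl_path, column_map=config.eqtl_column_map, trait="eqtl"
        )
        ld = read_ld(config.ld_path, config.ld_alleles_path)
        for err in exp_errors:
            exclusions.append(Exclusion(err.rsid, "read_exposure", err.message))

        # --- instrument selection ---------------------------------------
        cis = filter_cis_eqtl(eqtls, region, p_threshold=config.eqtl_p)
        cis_set = set(cis.rsids)
        for rec in eqtls:
            if rec.rsid not in cis_set:
                exclusions.append(
                    Exclusion(rec.rsid, "filter_cis_eqtl", "outside region or above eQTL p")
                )
        candidates = exposure.subset([r for r in exposure.rsids if r in cis_set])
        ranking = {rec.rsid: rec.pval for rec in candidates}
        selected = prune_by_ld(
            candidates, ranking, ld,
            r2_threshold=config.prune_r2, window_kb=config.window_kb,
        )
        for rsid in candidates.rsids:
            if rsid not in selected:
                exclusions.append(Exclusion(rsid, "prune_by_ld", "pruned at r2 threshold"))
        logger.info("selected %d instruments: %s", len(selected), selected)
        instruments = exposure.subset(selected)
        diagnostics = diagnostics_table(instruments, trait_sd=config.exposure_sd)

        # --- per-outcome analyses ---------------------------------------
        results: list[OutcomeResult] = []
        for spec in config.outcome_specs:
            outcome, _ = read_summary(
                spec.path, column_map=spec.column_map,
                trait=spec.name, trait_type=spec.trait_type,
            )
            try:
                h = harmonise(instruments, outcome, ld)
            except ValueError as exc:
                raise RuntimeError(f"harmonise failed for outcome {spec.name!r}: {exc}") from exc
            exclusions.extend(h.exclusions)

            main = scale_estimate(
                ivw_correlated(h),
                mm_hg_per_dose=config.scale_mmhg,
                direction=config.scale_direction,
            )

            weakest = None
            if len(h) >= 2:
                strength = (h.gamma / h.gamma_se) ** 2
                h_strong = exclude_weakest(h, strength)
                weakest = scale_estimate(
                    ivw_correlated(h_strong),
                    mm_hg_per_dose=config.scale_mmhg,
                    direction=config.scale_direction,
                )

            adjusted = None
            if config.mediator_path:
                paths = load_mediator_paths(config.mediator_path, h.rsids)
                two = adjusted_mr(h, paths)
                adjusted = scale_estimate(
                    two.adjusted,
                    mm_hg_per_dose=config.scale_mmhg,
                    direction=config.scale_direction,
                )

            results.append(
                OutcomeResult(
                    name=spec.name, main=main, weakest_excluded=weakest,
                    adjusted=adjusted, coloc=None, coloc_label=None,
                )
            )

        # --- FDR across the configured outcome family -------------------
        fdr = bh_fdr([r.main.pval for r in results])
        for r, q in zip(results, fdr):
            r.fdr_pval = float(q)

        # --- colocalisation for FDR-flagged outcomes --------------------
        for r, spec in zip(results, config.outcome_specs):
            if r.fdr_pval is not None and r.fdr_pval < config.coloc_fdr_threshold:
                outcome, _ = read_summary(
                    spec.path, column_map=spec.column_map,
                    trait=spec.name, trait_type=spec.trait_type,
                )
                h = harmonise(instruments, outcome, ld)
                r.coloc, r.coloc_label = _coloc_from_instruments(h, config, spec.trait_type)
                logger.info("coloc %s: %s", spec.name, r.coloc_label)

        bundle = PipelineResult(
            instrument_rsids=selected,
            diagnostics=diagnostics,
            outcomes=results,
            exclusions=exclusions,
        )
        _write_outputs(bundle, config, out_dir)
        return bundle
    finally:
        root.removeHandler(handler)
        handler.close()


def _mr_row(name: str, label: str, res: MrResult, fdr: float | None) -> dict:
    return {
        "outcome": name,
        "analysis": label,
        "n_variants": res.n_variants,
        "estimate": res.estimate,
        "se": res.se,
        "ci_low": res.ci_low,
        "ci_high": res.ci_high,
        "pval": res.pval,
        "fdr_pval": fdr if fdr is not None else float("nan"),
        "phi": res.overdispersion if res.overdispersion is not None else float("nan"),
        "scale_factor": res.scale_factor if res.scale_factor is not None else 1.0,
        "method_label": res.method_label,
    }


def _write_outputs(bundle: PipelineResult, config: AnalysisConfig, out_dir: Path) -> None:
    rows = []
    for r in bundle.outcomes:
        rows.append(_mr_row(r.name, "main", r.main, r.fdr_pval))
        if r.weakest_excluded is not None:
            rows.append(_mr_row(r.name, "weakest_excluded", r.weakest_excluded, None))
        if r.adjusted is not None:
            rows.append(_mr_row(r.name, "mediator_adjusted", r.adjusted, None))
    pd.DataFrame(rows).to_csv(out_dir / "results.tsv", sep="\t", index=False)

    coloc_rows = [
        {
            "outcome": r.name,
            **{f"pp{i}": r.coloc.pp[i] for i in range(5)},
            "label": r.coloc_label,
        }
        for r in bundle.outcomes
        if r.coloc is not None
    ]
    pd.DataFrame(
        coloc_rows, columns=["outcome", "pp0", "pp1", "pp2", "pp3", "pp4", "label"]
    ).to_csv(out_dir / "coloc.tsv", sep="\t", index=False)

    pd.DataFrame(
        [vars(e) for e in bundle.exclusions], columns=["rsid", "stage", "reason"]
    ).to_csv(out_dir / "exclusions.tsv", sep="\t", index=False)

    bundle.diagnostics.to_csv(out_dir / "instruments.tsv", sep="\t", index=False)
    config.to_yaml(out_dir / "effective_config.yaml")


def render_report(bundle: PipelineResult) -> str:
    """Plain-text forest-style summary of a pipeline run."""
    lines = [
        f"Instruments ({len(bundle.instrument_rsids)}): "
        + ", ".join(bundle.instrument_rsids),
        "",
        f"{'outcome':<28}{'analysis':<20}{'estimate':>10}{'95% CI':>22}{'FDR p':>12}  coloc",
    ]
    for r in bundle.outcomes:
        entries = [("main", r.main, r.fdr_pval)]
        if r.weakest_excluded is not None:
            entries.append(("weakest_excluded", r.weakest_excluded, None))
        if r.adjusted is not None:
            entries.append(("mediator_adjusted", r.adjusted, None))
        for label, res, fdr in entries:
            ci = f"({res.ci_low:.3g}, {res.ci_high:.3g})"
            fdr_s = f"{fdr:.3g}" if fdr is not None else "-"
            coloc_s = r.coloc_label if (label == "main" and r.coloc_label) else ""
            lines.append(
                f"{r.name:<28}{label:<20}{res.estimate:>10.3g}{ci:>22}{fdr_s:>12}  {coloc_s}"
            )
    lines.append("")
    lines.append(f"Variants excluded along the way: {len(bundle.exclusions)}")
    return "\n".join(lines)
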