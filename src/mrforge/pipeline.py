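"""Config-driven end-to-end MR run: harmonize -> QC cascade -> estimate -> diagnose.

`analyze` is the in-memory engine; `run_pipeline` wraps it with file I/O and
writes a reproducible report bundle.  Stage outputs are pure functions of
(inputs, config): rerunning with the same config and seed yields a
byte-identical bundle.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .errors import InsufficientInstrumentsError, PipelineError
from .summary_io import (
    HarmonizedInstrument,
    VariantAssociation,
    harmonize,
    instruments_to_frame,
    read_gwas_summary,
)
from . import selection
from .selection import (
    DEFAULT_CLUMP_R2,
    DEFAULT_CLUMP_WINDOW_KB,
    DEFAULT_CONFOUNDER_TRAITS,
    DEFAULT_F_MIN,
    DEFAULT_GWAS_P,
    DEFAULT_N_EXPOSURE,
    DEFAULT_N_OUTCOME,
    LDMatrix,
    TraitAnnotation,
)
from .estimators import MREstimate, all_methods, ivw, wald_ratio
from .presso import PressoResult, format_presso_report, mr_presso
from .diagnostics import (
    cochran_q,
    funnel_data,
    leave_one_out,
    leave_one_out_frame,
    scatter_data,
)


@dataclass
class RunConfig:
    """Everything an end-to-end run needs; loadable from YAML/JSON."""

    exposure_path: str
    outcome_path: str
    ld_path: Optional[str] = None
    annotations_path: Optional[str] = None
    output_dir: str = "mrforge_out"
    exposure_columns: dict = field(default_factory=dict)
    outcome_columns: dict = field(default_factory=dict)
    intermediate_eaf_band: tuple[float, float] = (0.42, 0.58)
    clump_window_kb: Optional[int] = DEFAULT_CLUMP_WINDOW_KB
    clump_r2: float = DEFAULT_CLUMP_R2
    gwas_p: float = DEFAULT_GWAS_P
    f_min: float = DEFAULT_F_MIN
    confounder_traits: list = field(default_factory=lambda: sorted(DEFAULT_CONFOUNDER_TRAITS))
    steiger: bool = True
    n_exp: Optional[float] = None
    n_out: Optional[float] = None
    n_boot: int = 1000
    phi: float = 1.0
    n_sim: int = 1000
    seed: Optional[int] = None
    reverse: bool = False

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        cfg = cls(**raw)
        if isinstance(cfg.intermediate_eaf_band, list):
            cfg.intermediate_eaf_band = tuple(cfg.intermediate_eaf_band)
        return cfg


@dataclass
class AnalysisResult:
    """Full output bundle of one MR analysis."""

    instruments: list[HarmonizedInstrument]
    exclusions: pd.DataFrame
    wald_estimates: list[MREstimate]
    estimates: list[MREstimate]
    heterogeneity: list
    presso: Optional[PressoResult]
    loo: list
    funnel: pd.DataFrame
    scatter_points: pd.DataFrame
    scatter_lines: pd.DataFrame
    metadata: dict

    def results_table(self) -> pd.DataFrame:
        """Method / N SNPs / OR / 95% CI / p, one row per estimator."""
        rows = []
        for est in self.estimates:
            rows.append({
                "Method": est.method,
                "N SNPs": est.n_snps,
                "OR": round(est.or_, 3),
                "95% CI": f"{est.ci_low:.3f}-{est.ci_high:.3f}",
                "p Value": round(est.pvalue, 4),
            })
        if self.presso is not None:
            raw = self.presso.estimate_raw
            rows.append({
                "Method": f"mr_presso (raw, {len(self.presso.outliers)} outlier)",
                "N SNPs": raw.n_snps,
                "OR": round(raw.or_, 3),
                "95% CI": f"{raw.ci_low:.3f}-{raw.ci_high:.3f}",
                "p Value": round(raw.pvalue, 4),
            })
        return pd.DataFrame(rows, columns=["Method", "N SNPs", "OR", "95% CI", "p Value"])


def _append_exclusions(parts: list[pd.DataFrame], df: pd.DataFrame, stage: str):
    if len(df):
        df = df.copy()
        df["stage"] = stage
        parts.append(df)


def analyze(
    exposure: Sequence[VariantAssociation],
    outcome: Sequence[VariantAssociation],
    *,
    ld: Optional[LDMatrix] = None,
    annotations: Optional[Sequence[TraitAnnotation]] = None,
    intermediate_eaf_band: tuple[float, float] = (0.42, 0.58),
    clump_window_kb: Optional[int] = DEFAULT_CLUMP_WINDOW_KB,
    clump_r2: float = DEFAULT_CLUMP_R2,
    confounder_traits=DEFAULT_CONFOUNDER_TRAITS,
    gwas_p: float = DEFAULT_GWAS_P,
    f_min: float = DEFAULT_F_MIN,
    steiger: bool = True,
    n_exp: Optional[float] = None,
    n_out: Optional[float] = None,
    n_boot: int = 1000,
    phi: float = 1.0,
    n_sim: int = 1000,
    seed: Optional[int] = None,
) -> AnalysisResult:
    """Run the full analysis on in-memory summary statistics.

    Stages that do not apply are skipped: clumping requires an LD matrix,
    the confounder filter an annotation table, Steiger filtering allele
    frequencies on both sides.  A seed is mandatory — the median/mode
    bootstrap and MR-PRESSO are stochastic.  Raises
    :class:`PipelineError` naming the stage that emptied the instrument set.
    """
    if seed is None:
        raise PipelineError("a seed is required: bootstrap and resampling stages are stochastic",
                            stage="config")
    excl_parts: list[pd.DataFrame] = []

    if ld is not None:
        exposure = selection.clump(exposure, ld, window_kb=clump_window_kb, r2_threshold=clump_r2)
        if not exposure:
            raise PipelineError("no variants survived LD clumping", stage="clump")

    harm = harmonize(exposure, outcome, intermediate_eaf_band=intermediate_eaf_band)
    _append_exclusions(excl_parts, harm.exclusions, "harmonize")
    instruments = harm.instruments
    if not instruments:
        raise PipelineError("no instruments survived harmonization", stage="harmonize")

    if annotations is not None:
        res = selection.confounder_filter(instruments, annotations, confounder_traits, gwas_p)
        _append_exclusions(excl_parts, res.exclusions, "confounder_filter")
        instruments = res.retained
        if not instruments:
            raise PipelineError("no instruments survived the confounder filter",
                                stage="confounder_filter")

    if steiger:
        evaluable = all(i.eaf_exp is not None and i.eaf_out is not None for i in instruments)
        if evaluable:
            res = selection.steiger_filter(
                instruments,
                n_exp=n_exp if n_exp is not None else DEFAULT_N_EXPOSURE,
                n_out=n_out if n_out is not None else DEFAULT_N_OUTCOME,
            )
            _append_exclusions(excl_parts, res.exclusions, "steiger_filter")
            instruments = res.retained
            if not instruments:
                raise PipelineError("no instruments survived Steiger filtering",
                                    stage="steiger_filter")

    res = selection.weak_instrument_filter(instruments, f_min=f_min)
    _append_exclusions(excl_parts, res.exclusions, "weak_instrument_filter")
    instruments = res.retained
    if not instruments:
        raise PipelineError("no instruments survived the F-statistic filter",
                            stage="weak_instrument_filter")

    L = len(instruments)
    wald_estimates = [wald_ratio(i) for i in instruments if i.beta_exp != 0]

    estimates: list[MREstimate] = []
    heterogeneity = []
    presso_res = None
    loo_rows: list = []
    if L >= 3:
        estimates = all_methods(instruments, n_boot=n_boot, phi=phi, seed=seed)
        ivw_fit = estimates[0]
        egger_fit = estimates[1]
        heterogeneity = [cochran_q(instruments, ivw_fit), cochran_q(instruments, egger_fit)]
        loo_rows = leave_one_out(instruments, "ivw")
    elif L == 2:
        estimates = [ivw(instruments)]
        heterogeneity = [cochran_q(instruments, estimates[0])]
    if L >= 4:
        presso_res = mr_presso(instruments, n_sim=n_sim, seed=seed)

    funnel = funnel_data(instruments)
    scatter_pts, scatter_ln = scatter_data(instruments, estimates)

    exclusions = (
        pd.concat(excl_parts, ignore_index=True)
        if excl_parts
        else pd.DataFrame(columns=["variant_id", "reason", "stage"])
    )
    metadata = {
        "package": "mrforge",
        "version": __version__,
        "seed": seed,
        "n_instruments": L,
        "thresholds": {
            "intermediate_eaf_band": list(intermediate_eaf_band),
            "clump_window_kb": clump_window_kb,
            "clump_r2": clump_r2,
            "gwas_p": gwas_p,
            "f_min": f_min,
        },
        "options": {"n_boot": n_boot, "phi": phi, "n_sim": n_sim},
        "rng": "numpy PCG64",
    }
    return AnalysisResult(
        instruments=instruments,
        exclusions=exclusions,
        wald_estimates=wald_estimates,
        estimates=estimates,
        heterogeneity=heterogeneity,
        presso=presso_res,
        loo=loo_rows,
        funnel=funnel,
        scatter_points=scatter_pts,
        scatter_lines=scatter_ln,
        metadata=metadata,
    )


def write_bundle(result: AnalysisResult, out_dir) -> dict[str, Path]:
    """Write the full report bundle as delimited text + YAML metadata."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    paths["instruments"] = out / "instruments.tsv"
    instruments_to_frame(result.instruments).to_csv(paths["instruments"], sep="\t", index=False)

    paths["exclusions"] = out / "exclusions.tsv"
    result.exclusions.to_csv(paths["exclusions"], sep="\t", index=False)

    paths["results"] = out / "results.tsv"
    result.results_table().to_csv(paths["results"], sep="\t", index=False)

    paths["wald"] = out / "single_snp.tsv"
    pd.DataFrame(
        [{"variant_id": e.extras.get("variant_id"), "beta": e.beta, "se": e.se,
          "or": e.or_, "ci_low": e.ci_low, "ci_high": e.ci_high, "pvalue": e.pvalue}
         for e in result.wald_estimates]
    ).to_csv(paths["wald"], sep="\t", index=False)

    paths["heterogeneity"] = out / "heterogeneity.tsv"
    pd.DataFrame(
        [{"method": h.method, "Q": h.q, "df": h.df, "pvalue": h.pvalue}
         for h in result.heterogeneity]
    ).to_csv(paths["heterogeneity"], sep="\t", index=False)

    if result.presso is not None:
        paths["presso"] = out / "presso.txt"
        paths["presso"].write_text(format_presso_report(result.presso))

    paths["leave_one_out"] = out / "leave_one_out.tsv"
    leave_one_out_frame(result.loo).to_csv(paths["leave_one_out"], sep="\t", index=False)

    paths["funnel"] = out / "funnel.tsv"
    funnel = result.funnel.copy()
    funnel.to_csv(paths["funnel"], sep="\t", index=False)
    paths["funnel_lines"] = out / "funnel_lines.tsv"
    pd.DataFrame(
        [{"method": k, "ratio": v} for k, v in sorted(result.funnel.attrs.get("lines", {}).items())]
    ).to_csv(paths["funnel_lines"], sep="\t", index=False)

    paths["scatter_points"] = out / "scatter_points.tsv"
    result.scatter_points.to_csv(paths["scatter_points"], sep="\t", index=False)
    paths["scatter_lines"] = out / "scatter_lines.tsv"
    result.scatter_lines.to_csv(paths["scatter_lines"], sep="\t", index=False)

    paths["metadata"] = out / "run_metadata.yaml"
    with open(paths["metadata"], "w") as fh:
        yaml.safe_dump(result.metadata, fh, sort_keys=True)
    return paths


def run_pipeline(config: RunConfig) -> AnalysisResult:
    """File-based end-to-end run; writes the report bundle to config.output_dir."""
    exposure = read_gwas_summary(config.exposure_path, config.exposure_columns)
    outcome = read_gwas_summary(config.outcome_path, config.outcome_columns)
    if config.reverse:
        # Reverse-direction (outcome -> exposure) analysis: swap the roles.
        exposure, outcome = outcome, exposure
    ld = LDMatrix.read(config.ld_path) if config.ld_path else None
    annotations = (
        selection.read_annotations(config.annotations_path)
        if config.annotations_path
        else None
    )
    try:
        result = analyze(
            exposure,
            outcome,
            ld=ld,
            annotations=annotations,
            intermediate_eaf_band=tuple(config.intermediate_eaf_band),
            clump_window_kb=config.clump_window_kb,
            clump_r2=config.clump_r2,
            confounder_traits=set(config.confounder_traits),
            gwas_p=config.gwas_p,
            f_min=config.f_min,
            steiger=config.steiger,
            n_exp=config.n_exp,
            n_out=config.n_out,
            n_boot=config.n_boot,
            phi=config.phi,
            n_sim=config.n_sim,
            seed=config.seed,
        )
    except InsufficientInstrumentsError as exc:
        if config.reverse:
            raise PipelineError(
                "reverse-direction analysis halted: too few instruments for MR "
                f"({exc})", stage="reverse",
            ) from exc
        raise
    result.metadata["reverse"] = config.reverse
    write_bundle(result, config.output_dir)
    return result
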