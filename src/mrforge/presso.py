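"""MR-PRESSO: resampling tests for horizontal pleiotropy and outlying instruments.

The global test asks whether the instruments' outcome effects scatter around
the causal line more than their sampling errors allow.  The observed residual
sum of squares (RSS) is built leave-one-out: each SNP's residual is taken
against the IVW fit of the *other* SNPs, so an outlier cannot drag the line
toward itself.  The null distribution of RSS comes from parametric
simulation — per-SNP betas redrawn from their normal sampling distributions
centred on the leave-one-out predicted values — and the empirical p-value
uses the (k+1)/(n+1) convention so it is never exactly zero.

The outlier test compares each SNP's observed weighted squared residual to
its own simulated distribution (Bonferroni-adjusted across instruments);
the distortion test asks whether removing the outliers materially shifts
the causal estimate.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .errors import InsufficientInstrumentsError, InvalidInputError
from .estimators import MREstimate, ivw
from .summary_io import HarmonizedInstrument


@dataclass(frozen=True)
class PressoResult:
    """Outputs of the global, outlier and (when applicable) distortion tests."""

    rss_obs: float
    global_p: float
    per_snp_p: dict[str, float]
    outliers: frozenset[str]
    estimate_raw: MREstimate
    estimate_outlier_corrected: Optional[MREstimate]
    distortion_coefficient: Optional[float]
    distortion_p: Optional[float]
    n_sim: int
    seed: int
    metadata: dict = field(default_factory=dict)


def _loo_betas(w, bx, by):
    """IVW slope excluding each SNP in turn, via sum subtraction.

    Accepts (..., L) arrays; returns an array of the same shape where entry j
    is the slope fitted without SNP j.
    """
    sxy = np.sum(w * bx * by, axis=-1, keepdims=True)
    sxx = np.sum(w * bx * bx, axis=-1, keepdims=True)
    return (sxy - w * bx * by) / (sxx - w * bx * bx)


def mr_presso(
    instruments: Sequence[HarmonizedInstrument],
    n_sim: int = 1000,
    seed: Optional[int] = None,
    outlier_alpha: float = 0.05,
    multiplicity: str = "bonferroni",
) -> PressoResult:
    """Run the MR-PRESSO global, outlier and distortion tests.

    Requires at least 4 instruments (each leave-one-out fit needs >= 3).
    ``n_sim`` controls both the global null and the per-SNP residual
    distributions; 1000 or more is recommended.  Identical seed and inputs
    give bit-identical results.
    """
    L = len(instruments)
    if L < 4:
        raise InsufficientInstrumentsError("MR-PRESSO needs at least 4 instruments")
    if seed is None:
        raise InvalidInputError("mr_presso requires an explicit seed")
    if n_sim < 1:
        raise InvalidInputError("n_sim must be >= 1")
    if multiplicity not in ("bonferroni", "none"):
        raise InvalidInputError(f"unknown multiplicity correction {multiplicity!r}")

    ids = [i.variant_id for i in instruments]
    bx = np.array([i.beta_exp for i in instruments])
    sx = np.array([i.se_exp for i in instruments])
    by = np.array([i.beta_out for i in instruments])
    sy = np.array([i.se_out for i in instruments])
    w = 1.0 / sy**2

    # Observed leave-one-out residuals and their weighted squares.
    beta_loo = _loo_betas(w, bx, by)
    resid_obs = by - beta_loo * bx
    sq_obs = w * resid_obs**2
    rss_obs = float(np.sum(sq_obs))

    # Parametric null: betas redrawn around the leave-one-out predictions.
    rng = np.random.default_rng(seed)
    bx_sim = rng.normal(bx, sx, size=(n_sim, L))
    by_sim = rng.normal(beta_loo * bx_sim, sy, size=(n_sim, L))
    beta_loo_sim = _loo_betas(w, bx_sim, by_sim)
    sq_sim = w * (by_sim - beta_loo_sim * bx_sim) ** 2
    rss_sim = np.sum(sq_sim, axis=1)

    global_p = float((np.sum(rss_sim >= rss_obs) + 1) / (n_sim + 1))

    per_snp_raw = (np.sum(sq_sim >= sq_obs, axis=0) + 1) / (n_sim + 1)
    adjust = L if multiplicity == "bonferroni" else 1
    per_snp_adj = np.minimum(per_snp_raw * adjust, 1.0)
    per_snp_p = {vid: float(p) for vid, p in zip(ids, per_snp_adj)}
    outliers = frozenset(vid for vid, p in per_snp_p.items() if p < outlier_alpha)

    estimate_raw = ivw(instruments)
    estimate_corrected = None
    distortion_coef = None
    distortion_p = None
    if outliers:
        inliers = [i for i in instruments if i.variant_id not in outliers]
        if len(inliers) < 2:
            raise InvalidInputError(
                "MR-PRESSO flagged all (or all but one) instruments as outliers; "
                "the outlier-corrected estimate is undefined"
            )
        estimate_corrected = ivw(inliers)
        b_corr = estimate_corrected.beta
        if b_corr != 0:
            distortion_coef = float(100.0 * (estimate_raw.beta - b_corr) / abs(b_corr))
            # Null: re-introduce random inlier copies in place of the outliers.
            in_idx = np.array([k for k, i in enumerate(instruments) if i.variant_id not in outliers])
            n_out = L - len(in_idx)
            null = np.empty(n_sim)
            wb = w[in_idx] * bx[in_idx]
            sxy_in = float(np.sum(wb * by[in_idx]))
            sxx_in = float(np.sum(w[in_idx] * bx[in_idx] ** 2))
            for k in range(n_sim):
                pick = rng.choice(in_idx, size=n_out, replace=True)
                sxy = sxy_in + np.sum(w[pick] * bx[pick] * by[pick])
                sxx = sxx_in + np.sum(w[pick] * bx[pick] ** 2)
                b_full = sxy / sxx
                null[k] = 100.0 * (b_full - b_corr) / abs(b_corr)
            distortion_p = float((np.sum(np.abs(null) >= abs(distortion_coef)) + 1) / (n_sim + 1))

    return PressoResult(
        rss_obs=rss_obs,
        global_p=global_p,
        per_snp_p=per_snp_p,
        outliers=outliers,
        estimate_raw=estimate_raw,
        estimate_outlier_corrected=estimate_corrected,
        distortion_coefficient=distortion_coef,
        distortion_p=distortion_p,
        n_sim=n_sim,
        seed=seed,
        metadata={
            "rss_variant": "leave-one-out",
            "multiplicity": multiplicity,
            "outlier_alpha": outlier_alpha,
            "rng": "numpy PCG64",
        },
    )


def format_presso_report(result: PressoResult) -> str:
    """Human-readable structured text report (stable across reruns)."""
    lines = [
        "MR-PRESSO report",
        f"  rss_variant: {result.metadata.get('rss_variant')}",
        f"  n_sim: {result.n_sim}",
        f"  seed: {result.seed}",
        f"  RSS_obs: {result.rss_obs:.10g}",
        f"  global_p: {result.global_p:.6g}",
        f"  outliers: {', '.join(sorted(result.outliers)) if result.outliers else '(none)'}",
        "  per-SNP outlier p (adjusted):",
    ]
    for vid in sorted(result.per_snp_p):
        lines.append(f"    {vid}\t{result.per_snp_p[vid]:.6g}")
    lines.append(
        f"  raw IVW: beta={result.estimate_raw.beta:.10g} se={result.estimate_raw.se:.10g}"
    )
    if result.estimate_outlier_corrected is not None:
        e = result.estimate_outlier_corrected
        lines.append(f"  outlier-corrected IVW: beta={e.beta:.10g} se={e.se:.10g}")
        lines.append(f"  distortion_coefficient_pct: {result.distortion_coefficient:.6g}")
        lines.append(f"  distortion_p: {result.distortion_p:.6g}")
    return "\n".join(lines) + "\n"
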