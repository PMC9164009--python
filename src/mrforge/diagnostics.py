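"""Heterogeneity and sensitivity diagnostics for an MR instrument set.

Cochran's Q measures excess scatter of the per-SNP outcome effects about the
fitted causal line (zero-intercept for IVW, free intercept for Egger —
Ruecker's Q'); both use the same 1/se_out^2 weights, so Q - Q' isolates the
intercept's contribution.  Leave-one-out refits flag single influential
instruments, and the funnel/scatter exports provide the plot data in
bit-stable delimited form (rendering is a thin optional layer).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import InsufficientInstrumentsError, InvalidInputError
from .estimators import MREstimate, egger, ivw, wald_ratio, weighted_median, mode_estimate
from .summary_io import HarmonizedInstrument


@dataclass(frozen=True)
class HeterogeneityResult:
    method: str  # "ivw" or "egger"
    q: float
    df: int
    pvalue: float


def cochran_q(
    instruments: Sequence[HarmonizedInstrument],
    fit: MREstimate,
) -> HeterogeneityResult:
    """Cochran's Q (IVW fit) or Ruecker's Q' (Egger fit) with its chi-square p.

    Q = sum over SNPs of (beta_out - fitted)^2 / se_out^2, where the fitted
    value comes from the supplied estimate's line; df = L-1 (IVW) or L-2
    (Egger).  For an IVW fit this is exactly the Q the multiplicative
    random-effects SE scaling uses.
    """
    L = len(instruments)
    bx = np.array([i.beta_exp for i in instruments])
    by = np.array([i.beta_out for i in instruments])
    sy = np.array([i.se_out for i in instruments])
    w = 1.0 / sy**2
    if fit.method == "ivw":
        df = L - 1
        fitted = fit.beta * bx
    elif fit.method == "egger":
        df = L - 2
        # Egger was fitted on betas oriented to positive exposure effects.
        sign = np.where(bx < 0, -1.0, 1.0)
        fitted = sign * (fit.extras["intercept"] + fit.beta * (sign * bx))
    else:
        raise InvalidInputError(f"cochran_q expects an ivw or egger fit, got {fit.method!r}")
    if df < 1:
        raise InsufficientInstrumentsError(f"{fit.method}: need df >= 1, got {df}")
    q = float(np.sum(w * (by - fitted) ** 2))
    p = float(stats.chi2.sf(q, df))
    return HeterogeneityResult(method=fit.method, q=q, df=df, pvalue=p)


_METHODS = {
    "ivw": lambda ins, **kw: ivw(ins),
    "egger": lambda ins, **kw: egger(ins),
    "weighted_median": lambda ins, **kw: weighted_median(ins, **kw),
    "simple_mode": lambda ins, **kw: mode_estimate(ins, weighted=False, **kw),
    "weighted_mode": lambda ins, **kw: mode_estimate(ins, weighted=True, **kw),
}


def leave_one_out(
    instruments: Sequence[HarmonizedInstrument],
    method: str = "ivw",
    **options,
) -> list[tuple[str, Optional[MREstimate]]]:
    """Refit the chosen estimator once per omitted SNP.

    Returns exactly L rows of (left_out_id, estimate); if omitting a SNP
    drops the set below the estimator's minimum, that row carries ``None``
    rather than being silently skipped.
    """
    if method not in _METHODS:
        raise InvalidInputError(f"unknown estimator {method!r}; choose from {sorted(_METHODS)}")
    fit = _METHODS[method]
    rows: list[tuple[str, Optional[MREstimate]]] = []
    for j, left_out in enumerate(instruments):
        subset = [ins for k, ins in enumerate(instruments) if k != j]
        try:
            est = fit(subset, **options)
        except InsufficientInstrumentsError:
            est = None
        rows.append((left_out.variant_id, est))
    return rows


def leave_one_out_frame(rows: list[tuple[str, Optional[MREstimate]]]) -> pd.DataFrame:
    out = []
    for vid, est in rows:
        if est is None:
            out.append({"left_out": vid, "beta": None, "se": None, "or": None,
                        "ci_low": None, "ci_high": None, "pvalue": None, "flag": "insufficient"})
        else:
            out.append({"left_out": vid, "beta": est.beta, "se": est.se, "or": est.or_,
                        "ci_low": est.ci_low, "ci_high": est.ci_high, "pvalue": est.pvalue,
                        "flag": ""})
    return pd.DataFrame(out, columns=["left_out", "beta", "se", "or", "ci_low", "ci_high", "pvalue", "flag"])


def funnel_data(instruments: Sequence[HarmonizedInstrument]) -> pd.DataFrame:
    """Per-SNP Wald ratio vs precision, for funnel-plot rendering.

    Precision is 1/se(ratio) = |beta_exp|/se_out (first-order).  The IVW and
    (when L >= 3) Egger pooled estimates are attached as ``attrs['lines']``:
    the abscissae of the funnel's vertical reference lines.  Asymmetry of
    the scatter about those lines indicates heterogeneity.
    """
    if len(instruments) < 1:
        raise InvalidInputError("funnel_data needs at least 1 instrument")
    rows = []
    for ins in instruments:
        est = wald_ratio(ins)
        rows.append({"variant_id": ins.variant_id, "ratio": est.beta,
                     "precision": 1.0 / est.se})
    df = pd.DataFrame(rows, columns=["variant_id", "ratio", "precision"])
    lines = {}
    if len(instruments) >= 2:
        lines["ivw"] = ivw(instruments).beta
    if len(instruments) >= 3:
        lines["egger"] = egger(instruments).beta
    df.attrs["lines"] = lines
    return df


def scatter_data(
    instruments: Sequence[HarmonizedInstrument],
    fits: Sequence[MREstimate],
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Data behind the exposure-vs-outcome effect scatter plot.

    Returns (points, lines): per-SNP effects with SE bars, oriented so every
    exposure beta is positive, and one (slope, intercept) row per fitted
    method — intercept 0 for everything except MR-Egger, whose intercept is
    its pleiotropy estimate.
    """
    pts = []
    for ins in instruments:
        sign = -1.0 if ins.beta_exp < 0 else 1.0
        pts.append({"variant_id": ins.variant_id,
                    "beta_exp": sign * ins.beta_exp, "se_exp": ins.se_exp,
                    "beta_out": sign * ins.beta_out, "se_out": ins.se_out})
    points = pd.DataFrame(pts, columns=["variant_id", "beta_exp", "se_exp", "beta_out", "se_out"])
    ln = []
    for fit in fits:
        ln.append({"method": fit.method, "slope": fit.beta,
                   "intercept": fit.extras.get("intercept", 0.0)})
    lines = pd.DataFrame(ln, columns=["method", "slope", "intercept"])
    return points, lines
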