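"""Causal-effect estimators for summary-level Mendelian randomization.

Each instrument contributes a Wald ratio beta_out / beta_exp — the change in
outcome log-odds per unit change in exposure attributable to that SNP.  The
estimators here combine those ratios under different validity assumptions:

* **IVW** — inverse-variance weighted meta-analysis, equivalently a
  zero-intercept weighted regression of outcome on exposure betas; unbiased
  only if every instrument is valid.  The multiplicative random-effects
  flavour inflates the fixed-effect standard error by sqrt(Q / (L-1))
  (floored at 1) to absorb excess heterogeneity.
* **MR-Egger** — the same regression with a free intercept; the intercept
  estimates average directional pleiotropy and the slope remains consistent
  under the InSIDE assumption.  Inference uses t with L-2 df.
* **Weighted median** — consistent when instruments carrying at least half
  of the weight are valid; SE by parametric bootstrap.
* **Simple / weighted mode** — the most common Wald ratio, via a normal
  kernel density over the ratios; consistent when the largest homogeneous
  subset of instruments is valid.

Estimates are returned on the log-odds scale with the odds ratio and a 95%
CI (z-based) attached.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from .errors import InsufficientInstrumentsError, InvalidInputError
from .summary_io import HarmonizedInstrument

#: Two-sided 95% normal quantile used for all confidence intervals.
Z_95 = 1.959964


@dataclass(frozen=True)
class MREstimate:
    """One method's causal estimate: log-odds of ALS per unit ln(CRP)."""

    method: str
    n_snps: int
    beta: float
    se: float
    pvalue: float
    or_: float
    ci_low: float
    ci_high: float
    extras: dict = field(default_factory=dict)


def _make_estimate(method, n_snps, beta, se, pvalue, **extras) -> MREstimate:
    if not se >= 0:
        raise InvalidInputError(f"{method}: negative standard error")
    return MREstimate(
        method=method,
        n_snps=n_snps,
        beta=float(beta),
        se=float(se),
        pvalue=float(min(max(pvalue, 0.0), 1.0)),
        or_=float(np.exp(beta)),
        ci_low=float(np.exp(beta - Z_95 * se)),
        ci_high=float(np.exp(beta + Z_95 * se)),
        extras=extras,
    )


def _arrays(instruments: Sequence[HarmonizedInstrument]):
    bx = np.array([i.beta_exp for i in instruments], dtype=float)
    sx = np.array([i.se_exp for i in instruments], dtype=float)
    by = np.array([i.beta_out for i in instruments], dtype=float)
    sy = np.array([i.se_out for i in instruments], dtype=float)
    return bx, sx, by, sy


def _oriented(bx, sx, by, sy):
    """Flip SNPs so every exposure beta is positive (joint sign flip)."""
    sign = np.where(bx < 0, -1.0, 1.0)
    return bx * sign, sx, by * sign, sy


def wald_ratio(instrument: HarmonizedInstrument, second_order: bool = False) -> MREstimate:
    """Single-instrument causal estimate beta_out / beta_exp.

    The default standard error is the first-order delta method
    se_out / |beta_exp|, which ignores uncertainty in the exposure beta;
    ``second_order=True`` adds the beta_out^2 * se_exp^2 / beta_exp^4 term.
    """
    bx, sx, by, sy = (
        instrument.beta_exp,
        instrument.se_exp,
        instrument.beta_out,
        instrument.se_out,
    )
    if bx == 0:
        raise InvalidInputError(f"{instrument.variant_id}: Wald ratio undefined for beta_exp = 0")
    beta = by / bx
    var = sy**2 / bx**2
    if second_order:
        var += by**2 * sx**2 / bx**4
    se = np.sqrt(var)
    p = 2 * stats.norm.sf(abs(beta / se))
    return _make_estimate(
        "wald_ratio", 1, beta, se, p,
        variant_id=instrument.variant_id, second_order=second_order,
    )


def _ivw_core(bx, by, sy):
    """Zero-intercept WLS of by on bx with weights 1/sy^2; returns (beta, fixed SE, Q)."""
    w = 1.0 / sy**2
    sxx = np.sum(w * bx * bx)
    beta = np.sum(w * bx * by) / sxx
    se_fixed = sxx**-0.5
    q = float(np.sum(w * (by - beta * bx) ** 2))
    return float(beta), float(se_fixed), q


def ivw(
    instruments: Sequence[HarmonizedInstrument],
    model: str = "multiplicative_random",
) -> MREstimate:
    """Inverse-variance weighted estimate over two or more instruments.

    ``model="fixed"`` reports the fixed-effect SE; ``"multiplicative_random"``
    (default, and the primary analysis method) scales it by
    sqrt(Q / (L - 1)), floored at 1, where Q is Cochran's Q of the Wald
    ratios about the pooled estimate.  P-values are standard normal.
    """
    L = len(instruments)
    if L < 2:
        raise InsufficientInstrumentsError(
            "IVW needs at least 2 instruments; use wald_ratio for a single SNP"
        )
    if model not in ("fixed", "multiplicative_random"):
        raise InvalidInputError(f"unknown IVW model {model!r}")
    bx, sx, by, sy = _arrays(instruments)
    beta, se_fixed, q = _ivw_core(bx, by, sy)
    scale = max(1.0, np.sqrt(q / (L - 1))) if model == "multiplicative_random" else 1.0
    se = se_fixed * scale
    p = 2 * stats.norm.sf(abs(beta / se))
    return _make_estimate(
        "ivw", L, beta, se, p,
        model=model, q=q, se_fixed=se_fixed, re_scale=float(scale),
    )


def _egger_core(bx, by, sy):
    """With-intercept WLS; returns coefficients, covariance and Q'.

    Residual variance is the multiplicative over-dispersion max(1, Q'/(L-2)).
    """
    L = len(bx)
    w = 1.0 / sy**2
    X = np.column_stack([np.ones(L), bx])
    xtw = X.T * w
    xtwx = xtw @ X
    coef = np.linalg.solve(xtwx, xtw @ by)
    resid = by - X @ coef
    q_prime = float(np.sum(w * resid**2))
    sigma2 = max(1.0, q_prime / (L - 2))
    cov = np.linalg.inv(xtwx) * sigma2
    return coef, cov, q_prime


def egger(instruments: Sequence[HarmonizedInstrument]) -> MREstimate:
    """MR-Egger regression: slope = causal effect, intercept = mean pleiotropy.

    Instruments are first oriented so all exposure betas are positive (the
    regression is not invariant to per-SNP sign flips).  Slope and intercept
    p-values come from the t distribution with L-2 degrees of freedom.
    """
    L = len(instruments)
    if L < 3:
        raise InsufficientInstrumentsError("MR-Egger needs at least 3 instruments")
    bx, sx, by, sy = _oriented(*_arrays(instruments))
    coef, cov, q_prime = _egger_core(bx, by, sy)
    intercept, slope = coef
    se_int, se_slope = np.sqrt(np.diag(cov))
    df = L - 2
    p_slope = 2 * stats.t.sf(abs(slope / se_slope), df)
    p_int = 2 * stats.t.sf(abs(intercept / se_int), df)
    return _make_estimate(
        "egger", L, slope, se_slope, p_slope,
        intercept=float(intercept),
        intercept_se=float(se_int),
        intercept_p=float(p_int),
        q_prime=q_prime,
        df=df,
    )


def _wald_ratio_arrays(bx, sx, by, sy, weighting: str = "first_order"):
    """Per-SNP ratios and their inverse-variance weights."""
    ratios = by / bx
    if weighting == "first_order":
        var = sy**2 / bx**2
    elif weighting == "second_order":
        var = sy**2 / bx**2 + by**2 * sx**2 / bx**4
    else:
        raise InvalidInputError(f"unknown ratio weighting {weighting!r}")
    return ratios, 1.0 / var


def _weighted_median(ratios: np.ndarray, weights: np.ndarray) -> float:
    """Interpolated weighted median: the ratio at cumulative weight 0.5."""
    order = np.argsort(ratios)
    b = ratios[order]
    w = weights[order]
    cum = (np.cumsum(w) - 0.5 * w) / np.sum(w)
    return float(np.interp(0.5, cum, b))


def weighted_median(
    instruments: Sequence[HarmonizedInstrument],
    n_boot: int = 1000,
    seed: Optional[int] = None,
) -> MREstimate:
    """Weighted-median causal estimate with parametric-bootstrap SE.

    Wald ratios are ordered and the ratio at normalized cumulative
    inverse-variance weight 0.5 is interpolated.  The SE is the standard
    deviation of the estimate over ``n_boot`` parametric resamples of the
    per-SNP betas from their normal sampling distributions (weights held at
    their observed values).  A seed is required for reproducibility.
    """
    L = len(instruments)
    if L < 3:
        raise InsufficientInstrumentsError("weighted median needs at least 3 instruments")
    if seed is None:
        raise InvalidInputError("weighted_median requires an explicit seed")
    if n_boot < 100:
        import warnings

        warnings.warn(f"n_boot={n_boot} is small; bootstrap SE will be noisy", stacklevel=2)
    bx, sx, by, sy = _arrays(instruments)
    ratios, weights = _wald_ratio_arrays(bx, sx, by, sy)
    beta = _weighted_median(ratios, weights)

    rng = np.random.default_rng(seed)
    bx_b = rng.normal(bx, sx, size=(n_boot, L))
    by_b = rng.normal(by, sy, size=(n_boot, L))
    boots = np.empty(n_boot)
    for k in range(n_boot):
        boots[k] = _weighted_median(by_b[k] / bx_b[k], weights)
    se = float(np.std(boots, ddof=1))
    p = 2 * stats.norm.sf(abs(beta / se)) if se > 0 else (1.0 if beta == 0 else 0.0)
    return _make_estimate(
        "weighted_median", L, beta, se, p, n_boot=n_boot, seed=seed,
    )


def _mode_bandwidth(ratios: np.ndarray, weights: np.ndarray, phi: float) -> float:
    """phi times a robust Silverman-style rule on the (weighted) ratios."""
    mean = np.average(ratios, weights=weights)
    sd = np.sqrt(np.average((ratios - mean) ** 2, weights=weights))
    mad = 1.4826 * np.median(np.abs(ratios - np.median(ratios)))
    s = min(sd, mad) if mad > 0 else sd
    return phi * 0.9 * s * len(ratios) ** (-1 / 5)


def _mode_point(ratios: np.ndarray, weights: np.ndarray, phi: float, n_grid: int = 512) -> float:
    h = _mode_bandwidth(ratios, weights, phi)
    if h <= 0 or not np.isfinite(h):  # all ratios identical
        return float(ratios[0])
    lo, hi = ratios.min() - 3 * h, ratios.max() + 3 * h
    grid = np.linspace(lo, hi, n_grid)
    dens = np.exp(-0.5 * ((grid[:, None] - ratios[None, :]) / h) ** 2) @ weights
    return float(grid[np.argmax(dens)])


def mode_estimate(
    instruments: Sequence[HarmonizedInstrument],
    weighted: bool = False,
    phi: float = 1.0,
    n_boot: int = 1000,
    seed: Optional[int] = None,
) -> MREstimate:
    """Mode-based causal estimate (simple or inverse-variance weighted).

    The estimate is the argmax of a normal-kernel density over the Wald
    ratios, with bandwidth ``phi`` times a robust (MAD-based) rule.  SE by
    the same parametric bootstrap as :func:`weighted_median`; the p-value
    uses t with L-1 df.
    """
    L = len(instruments)
    if L < 3:
        raise InsufficientInstrumentsError("mode estimator needs at least 3 instruments")
    if not phi > 0:
        raise InvalidInputError(f"phi must be > 0, got {phi}")
    if seed is None:
        raise InvalidInputError("mode_estimate requires an explicit seed")
    if n_boot < 100:
        import warnings

        warnings.warn(f"n_boot={n_boot} is small; bootstrap SE will be noisy", stacklevel=2)
    bx, sx, by, sy = _arrays(instruments)
    ratios, iv_weights = _wald_ratio_arrays(bx, sx, by, sy)
    weights = iv_weights if weighted else np.ones(L)
    beta = _mode_point(ratios, weights, phi)

    rng = np.random.default_rng(seed)
    bx_b = rng.normal(bx, sx, size=(n_boot, L))
    by_b = rng.normal(by, sy, size=(n_boot, L))
    boots = np.empty(n_boot)
    for k in range(n_boot):
        boots[k] = _mode_point(by_b[k] / bx_b[k], weights, phi)
    se = float(np.std(boots, ddof=1))
    p = 2 * stats.t.sf(abs(beta / se), df=L - 1) if se > 0 else (1.0 if beta == 0 else 0.0)
    method = "weighted_mode" if weighted else "simple_mode"
    return _make_estimate(method, L, beta, se, p, phi=phi, n_boot=n_boot, seed=seed)


def all_methods(
    instruments: Sequence[HarmonizedInstrument],
    n_boot: int = 1000,
    phi: float = 1.0,
    seed: Optional[int] = None,
) -> list[MREstimate]:
    """IVW, MR-Egger, weighted median, simple mode and weighted mode in one call."""
    return [
        ivw(instruments),
        egger(instruments),
        weighted_median(instruments, n_boot=n_boot, seed=seed),
        mode_estimate(instruments, weighted=False, phi=phi, n_boot=n_boot, seed=seed),
        mode_estimate(instruments, weighted=True, phi=phi, n_boot=n_boot, seed=seed),
    ]
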