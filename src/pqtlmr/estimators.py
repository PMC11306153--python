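"""Two-sample MR estimators and sensitivity analyses.

Given L harmonized instruments with exposure effects beta_x_j (SE se_x_j)
and outcome effects beta_y_j (SE se_y_j), the per-variant Wald ratio is
theta_j = beta_y_j / beta_x_j with first-order SE se_y_j / |beta_x_j|.

The estimators:

* **IVW** — inverse-variance-weighted mean of the ratios with first-order
  weights w_j = beta_x_j^2 / se_y_j^2, algebraically identical to the
  zero-intercept weighted least-squares regression of beta_y on beta_x with
  weights 1/se_y^2.  The fixed-effect SE is (sum w_j)^{-1/2}; the
  multiplicative random-effects (MRE) model inflates it by
  max(1, sqrt(Q/(L-1))) to absorb balanced heterogeneity.
* **Cochran's Q** — sum of w_j (theta_j - theta_fe)^2, chi-square(L-1)
  under homogeneity.
* **MR-Egger** — weighted regression of beta_y on beta_x with a free
  intercept, after orienting all exposure effects non-negative; the slope
  estimates the causal effect under InSIDE, the intercept tests directional
  pleiotropy.  SEs use a multiplicative overdispersion floor of 1 and
  t(L-2) reference.
* **Weighted median** — the ratio at the 0.5 quantile of the
  inverse-variance-weighted ratio distribution; consistent when valid
  instruments carry >= 50% of the weight.  SE by parametric bootstrap.
* **Weighted mode** — argmax of a weighted Gaussian kernel density over the
  ratios; SE by the same bootstrap.
* **MR-PRESSO** — simulation-based global test on the weighted residual sum
  of squares around leave-one-out IVW fits, with per-variant outlier
  flagging and an outlier-corrected IVW estimate.

All p-values are two-sided; stochastic procedures are seeded and
single-threaded, so identical seeds give identical bytes out.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Literal

import numpy as np
from scipy import stats as sps

from .harmonize import InstrumentPair, InstrumentSet, orient_positive_exposure

log = logging.getLogger(__name__)

Method = Literal[
    "wald",
    "ivw_fe",
    "ivw_mre",
    "egger",
    "weighted_median",
    "weighted_mode",
    "presso_corrected",
]


class NoInstrumentsError(ValueError):
    """An estimator was invoked on an empty instrument set."""


@dataclass(frozen=True)
class MRResult:
    """One estimator's causal estimate on the log-odds scale, with OR CI."""

    method: str
    n_snp: int
    beta: float
    se: float
    or_point: float
    or_lcl: float
    or_ucl: float
    pvalue: float


@dataclass(frozen=True)
class SensitivityResult:
    """Heterogeneity and pleiotropy diagnostics for one instrument set."""

    q: float | None = None
    q_df: int | None = None
    q_pvalue: float | None = None
    egger_intercept: float | None = None
    egger_intercept_se: float | None = None
    egger_intercept_p: float | None = None
    presso_global_p: float | None = None
    presso_outliers: tuple[str, ...] = ()


@dataclass(frozen=True)
class EstimatorConfig:
    """Tuning constants for the stochastic estimators.

    ``seed`` must be set explicitly before any bootstrap/PRESSO call;
    ``mode_bandwidth_multiplier`` scales the rule-of-thumb kernel bandwidth.
    """

    bootstrap_iterations: int = 1000
    presso_simulations: int = 1000
    mode_bandwidth_multiplier: float = 1.0
    seed: int | None = None
    ci_level: float = 0.95
    mre_variance_floor: bool = True

    def __post_init__(self) -> None:
        if self.bootstrap_iterations < 100 or self.presso_simulations < 100:
            raise ValueError("iteration counts must be >= 100")
        if not 0 < self.ci_level < 1:
            raise ValueError("ci_level must lie in (0,1)")

    def rng(self) -> np.random.Generator:
        if self.seed is None:
            raise ValueError("seed must be set explicitly for stochastic estimators")
        return np.random.default_rng(self.seed)


# ---------------------------------------------------------------------------
# helpers

_P_FLOOR = np.finfo(float).tiny


def _two_sided_normal_p(z: float) -> float:
    return float(max(2.0 * sps.norm.sf(abs(z)), _P_FLOOR))


def to_odds_ratio(beta: float, se: float, ci_level: float = 0.95) -> tuple[float, float, float]:
    """Exponentiate a log-odds effect and its Wald CI: (OR, lower, upper)."""
    z = sps.norm.ppf(0.5 + ci_level / 2.0)
    return float(np.exp(beta)), float(np.exp(beta - z * se)), float(np.exp(beta + z * se))


def _result(method: str, n_snp: int, beta: float, se: float, pvalue: float, ci_level: float = 0.95) -> MRResult:
    or_point, or_lcl, or_ucl = to_odds_ratio(beta, se, ci_level)
    return MRResult(method, n_snp, float(beta), float(se), or_point, or_lcl, or_ucl, float(pvalue))


def _ratio_arrays(instruments: InstrumentSet) -> tuple[np.ndarray, np.ndarray]:
    """Wald ratios and their first-order inverse-variance weights."""
    bx, by, sy = instruments.beta_x, instruments.beta_y, instruments.se_y
    if np.any(bx == 0):
        raise ValueError("beta_x must be nonzero for ratio estimates")
    return by / bx, bx**2 / sy**2


# ---------------------------------------------------------------------------
# estimators


def wald_ratio(pair: InstrumentPair, ci_level: float = 0.95) -> MRResult:
    """Single-instrument causal estimate beta_y/beta_x, first-order SE se_y/|beta_x|."""
    if pair.beta_x == 0:
        raise ValueError("beta_x must be nonzero for the Wald ratio")
    beta = pair.beta_y / pair.beta_x
    se = pair.se_y / abs(pair.beta_x)
    return _result("wald", 1, beta, se, _two_sided_normal_p(beta / se), ci_level)


def ivw(
    instruments: InstrumentSet,
    model: Literal["fe", "mre"] = "mre",
    cfg: EstimatorConfig | None = None,
) -> MRResult:
    """Inverse-variance-weighted estimate over the Wald ratios.

    With a single instrument the result reduces to the Wald ratio
    regardless of ``model``.
    """
    ci = cfg.ci_level if cfg else 0.95
    floor = cfg.mre_variance_floor if cfg else True
    L = len(instruments)
    if L == 0:
        raise NoInstrumentsError("IVW requires at least one instrument")
    theta, w = _ratio_arrays(instruments)
    est = float(np.sum(w * theta) / np.sum(w))
    se = float(np.sum(w) ** -0.5)
    if L == 1:
        return _result(f"ivw_{model}", 1, est, se, _two_sided_normal_p(est / se), ci)
    if model == "mre":
        q = float(np.sum(w * (theta - est) ** 2))
        scale = np.sqrt(q / (L - 1))
        if floor:
            scale = max(1.0, scale)
        se *= scale
    return _result(f"ivw_{model}", L, est, se, _two_sided_normal_p(est / se), ci)


def cochran_q(instruments: InstrumentSet) -> SensitivityResult:
    """Heterogeneity of the per-variant ratios around the fixed-effect IVW."""
    L = len(instruments)
    if L < 2:
        return SensitivityResult()
    theta, w = _ratio_arrays(instruments)
    est = np.sum(w * theta) / np.sum(w)
    q = float(np.sum(w * (theta - est) ** 2))
    df = L - 1
    return SensitivityResult(q=q, q_df=df, q_pvalue=float(sps.chi2.sf(q, df)))


def _wls(x: np.ndarray, y: np.ndarray, w: np.ndarray, intercept: bool) -> tuple[np.ndarray, np.ndarray, float]:
    """Weighted least squares via the normal equations.

    Returns (coefficients, SEs with multiplicative overdispersion floored at
    1, residual scale).  Coefficient order: [intercept,] slope.
    """
    X = np.column_stack([np.ones_like(x), x]) if intercept else x[:, None]
    Xw = X * w[:, None]
    xtx = X.T @ Xw
    coef = np.linalg.solve(xtx, Xw.T @ y)
    resid = y - X @ coef
    df = len(y) - X.shape[1]
    scale2 = float(resid @ (w * resid) / df) if df > 0 else np.nan
    cov = np.linalg.inv(xtx) * max(1.0, scale2)
    return coef, np.sqrt(np.diag(cov)), scale2


def mr_egger(
    instruments: InstrumentSet, cfg: EstimatorConfig | None = None
) -> tuple[MRResult, SensitivityResult]:
    """Egger regression: slope as causal estimate, intercept as pleiotropy test.

    Exposure effects are oriented non-negative internally (the intercept is
    orientation-dependent); p-values use t(L-2).
    """
    ci = cfg.ci_level if cfg else 0.95
    L = len(instruments)
    if L < 3:
        raise ValueError("MR-Egger requires at least 3 instruments")
    oriented = orient_positive_exposure(instruments)
    w = 1.0 / oriented.se_y**2
    coef, ses, _ = _wls(oriented.beta_x, oriented.beta_y, w, intercept=True)
    df = L - 2
    slope_p = float(max(2.0 * sps.t.sf(abs(coef[1] / ses[1]), df), _P_FLOOR))
    int_p = float(max(2.0 * sps.t.sf(abs(coef[0] / ses[0]), df), _P_FLOOR))
    result = _result("egger", L, float(coef[1]), float(ses[1]), slope_p, ci)
    sens = SensitivityResult(
        egger_intercept=float(coef[0]),
        egger_intercept_se=float(ses[0]),
        egger_intercept_p=int_p,
    )
    return result, sens


def _weighted_median_point(theta: np.ndarray, w: np.ndarray) -> float:
    """Interpolated weighted median of ratios theta with weights w."""
    order = np.argsort(theta, kind="stable")
    theta_s = theta[order]
    wn = w[order] / np.sum(w)
    s = np.cumsum(wn) - wn / 2.0
    if 0.5 <= s[0]:
        return float(theta_s[0])
    if 0.5 >= s[-1]:
        return float(theta_s[-1])
    return float(np.interp(0.5, s, theta_s))


def _parametric_bootstrap(
    instruments: InstrumentSet,
    cfg: EstimatorConfig,
    point_fn,
) -> float:
    """SD of ``point_fn`` over parametric resamples of both effect columns."""
    rng = cfg.rng()
    B = cfg.bootstrap_iterations
    bx = rng.normal(instruments.beta_x, instruments.se_x, size=(B, len(instruments)))
    by = rng.normal(instruments.beta_y, instruments.se_y, size=(B, len(instruments)))
    sy = instruments.se_y
    ests = np.empty(B)
    for b in range(B):
        ests[b] = point_fn(by[b] / bx[b], bx[b] ** 2 / sy**2)
    return float(np.std(ests, ddof=1))


def weighted_median(instruments: InstrumentSet, cfg: EstimatorConfig) -> MRResult:
    """Weighted-median causal estimate with parametric-bootstrap SE."""
    L = len(instruments)
    if L < 3:
        raise ValueError("weighted median requires at least 3 instruments")
    theta, w = _ratio_arrays(instruments)
    est = _weighted_median_point(theta, w)
    se = _parametric_bootstrap(instruments, cfg, _weighted_median_point)
    return _result("weighted_median", L, est, se, _two_sided_normal_p(est / se), cfg.ci_level)


def _weighted_mode_point(theta: np.ndarray, w: np.ndarray, phi: float) -> float:
    """Argmax of the weighted Gaussian KDE over the ratios."""
    sd = float(np.std(theta, ddof=1))
    iqr = float(np.subtract(*np.percentile(theta, [75, 25])))
    h = phi * 0.9 * min(sd, iqr / 1.34) * len(theta) ** (-1 / 5)
    if h <= 0 or not np.isfinite(h):
        # all ratios (or their spread measure) identical
        return float(theta[int(np.argmax(w))])
    grid = np.linspace(theta.min() - 3 * h, theta.max() + 3 * h, 512)
    wn = w / np.sum(w)
    dens = np.sum(wn[None, :] * np.exp(-0.5 * ((grid[:, None] - theta[None, :]) / h) ** 2), axis=1)
    return float(grid[int(np.argmax(dens))])


def weighted_mode(instruments: InstrumentSet, cfg: EstimatorConfig) -> MRResult:
    """Weighted-mode causal estimate (KDE argmax) with parametric-bootstrap SE."""
    L = len(instruments)
    if L < 3:
        raise ValueError("weighted mode requires at least 3 instruments")
    theta, w = _ratio_arrays(instruments)
    phi = cfg.mode_bandwidth_multiplier
    est = _weighted_mode_point(theta, w, phi)
    se = _parametric_bootstrap(
        instruments, cfg, lambda t, ww: _weighted_mode_point(t, ww, phi)
    )
    return _result("weighted_mode", L, est, se, _two_sided_normal_p(est / se), cfg.ci_level)


def _loo_ivw(bx: np.ndarray, by: np.ndarray, sy: np.ndarray) -> np.ndarray:
    """Leave-one-out IVW estimates, vectorised over the left-out index.

    Accepts 1-D arrays or 2-D (replicate, variant) arrays.
    """
    theta = by / bx
    w = bx**2 / sy**2
    sw = np.sum(w, axis=-1, keepdims=True)
    swt = np.sum(w * theta, axis=-1, keepdims=True)
    return (swt - w * theta) / (sw - w)


def mr_presso(
    instruments: InstrumentSet, cfg: EstimatorConfig
) -> tuple[SensitivityResult, MRResult | None]:
    """MR-PRESSO global pleiotropy test with outlier flagging and correction.

    The observed statistic is the outcome-variance-weighted residual sum of
    squares around leave-one-out IVW fits; its null distribution is built by
    parametric simulation under the no-pleiotropy model.  Per-variant
    outlier p-values are Bonferroni-adjusted by L and flagged below 0.05;
    when any variant is flagged the outlier-corrected IVW (on the remaining
    instruments) is returned as well.
    """
    L = len(instruments)
    if L < 4:
        raise ValueError("MR-PRESSO requires at least 4 instruments")
    rng = cfg.rng()
    bx, by = instruments.beta_x, instruments.beta_y
    sx, sy = instruments.se_x, instruments.se_y
    w_resid = 1.0 / sy**2

    theta_loo = _loo_ivw(bx, by, sy)
    resid_obs = w_resid * (by - theta_loo * bx) ** 2
    rss_obs = float(np.sum(resid_obs))

    B = cfg.presso_simulations
    bx_sim = rng.normal(bx, sx, size=(B, L))
    by_sim = rng.normal(theta_loo * bx, sy, size=(B, L))
    theta_loo_sim = _loo_ivw(bx_sim, by_sim, sy)
    resid_sim = w_resid * (by_sim - theta_loo_sim * bx_sim) ** 2
    rss_sim = np.sum(resid_sim, axis=1)

    floor = 1.0 / B
    global_p = float(max(np.mean(rss_sim >= rss_obs), floor))
    outlier_p = np.maximum(np.mean(resid_sim >= resid_obs[None, :], axis=0), floor)
    adjusted = np.minimum(outlier_p * L, 1.0)
    flagged = adjusted < 0.05
    outliers = tuple(instruments.variant_ids[flagged])

    corrected: MRResult | None = None
    if flagged.any() and (~flagged).sum() >= 1:
        kept = InstrumentSet(
            instruments.exposure_id,
            instruments.outcome_id,
            instruments.table.loc[~flagged].reset_index(drop=True),
            dict(instruments.actions),
        )
        corrected = replace(ivw(kept, "mre", cfg), method="presso_corrected")
    sens = SensitivityResult(presso_global_p=global_p, presso_outliers=outliers)
    return sens, corrected


def sensitivity_suite(
    instruments: InstrumentSet, cfg: EstimatorConfig, run_presso: bool = True
) -> tuple[SensitivityResult, MRResult | None]:
    """Combine Cochran's Q, the Egger intercept and (optionally) MR-PRESSO."""
    L = len(instruments)
    qres = cochran_q(instruments)
    egger_sens = SensitivityResult()
    if L >= 3:
        _, egger_sens = mr_egger(instruments, cfg)
    presso_sens, corrected = (SensitivityResult(), None)
    if run_presso and L >= 4:
        presso_sens, corrected = mr_presso(instruments, cfg)
    merged = SensitivityResult(
        q=qres.q,
        q_df=qres.q_df,
        q_pvalue=qres.q_pvalue,
        egger_intercept=egger_sens.egger_intercept,
        egger_intercept_se=egger_sens.egger_intercept_se,
        egger_intercept_p=egger_sens.egger_intercept_p,
        presso_global_p=presso_sens.presso_global_p,
        presso_outliers=presso_sens.presso_outliers,
    )
    return merged, corrected
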