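"""Causal estimators for harmonized two-sample summary statistics.

Implements the Wald ratio, inverse-variance-weighted (IVW) combination
(fixed and multiplicative-random-effects), Egger regression, the weighted
median, and kernel-mode estimators (simple and weighted).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
from scipy import stats

from .errors import ConfigurationError, InsufficientInstrumentsError, UndefinedRatioError
from .sumstats import HarmonizedInstrumentSet

__all__ = [
    "MREstimate",
    "EggerResult",
    "MethodConfig",
    "MethodSuite",
    "wald_ratio",
    "ivw",
    "mr_egger",
    "weighted_median",
    "mode_estimate",
    "run_all_methods",
]

_Z95 = stats.norm.ppf(0.975)


def _two_sided_normal_p(beta: float, se: float) -> float:
    if se == 0:
        return 1.0 if beta == 0 else 0.0
    return float(2.0 * stats.norm.sf(abs(beta) / se))


@dataclass(frozen=True)
class MREstimate:
    """One method's causal estimate on the log-odds (beta) scale."""

    method: str
    beta: float
    se: float
    pval: float
    nsnp: int
    ci_low: float
    ci_high: float
    or_: float
    or_low: float
    or_high: float

    @classmethod
    def from_beta_se(
        cls,
        method: str,
        beta: float,
        se: float,
        nsnp: int,
        pval: float | None = None,
    ) -> "MREstimate":
        lo, hi = beta - _Z95 * se, beta + _Z95 * se
        return cls(
            method=method,
            beta=float(beta),
            se=float(se),
            pval=_two_sided_normal_p(beta, se) if pval is None else float(pval),
            nsnp=int(nsnp),
            ci_low=float(lo),
            ci_high=float(hi),
            or_=float(math.exp(beta)),
            or_low=float(math.exp(lo)),
            or_high=float(math.exp(hi)),
        )


def _arrays(hset: HarmonizedInstrumentSet) -> tuple[np.ndarray, ...]:
    r = hset.rows
    return (
        r["beta_exp"].to_numpy(float),
        r["se_exp"].to_numpy(float),
        r["beta_out"].to_numpy(float),
        r["se_out"].to_numpy(float),
    )


def wald_ratio(row) -> MREstimate:
    """Single-SNP causal estimate beta_out/beta_exp with first-order delta se.

    ``row`` is any object exposing ``beta_exp``, ``se_exp``, ``beta_out``
    and ``se_out`` (e.g. a row of ``HarmonizedInstrumentSet.rows``).
    """
    beta_exp, beta_out = float(row.beta_exp), float(row.beta_out)
    se_out = float(row.se_out)
    if beta_exp == 0:
        raise UndefinedRatioError("beta_exp is zero; Wald ratio undefined")
    beta = beta_out / beta_exp
    se = se_out / abs(beta_exp)
    return MREstimate.from_beta_se("wald_ratio", beta, se, nsnp=1)


def _ivw_fit(x: np.ndarray, y: np.ndarray, w: np.ndarray) -> tuple[float, float, float]:
    """Weighted through-origin regression. Returns (beta, se_fixed, Q)."""
    s_xx = float(np.sum(w * x * x))
    beta = float(np.sum(w * x * y)) / s_xx
    se_fixed = math.sqrt(1.0 / s_xx)
    q = float(np.sum(w * (y - beta * x) ** 2))
    return beta, se_fixed, q


def ivw(
    hset: HarmonizedInstrumentSet, model: str = "multiplicative_random"
) -> MREstimate:
    """Inverse-variance-weighted estimate (weighted regression through origin).

    ``model="fixed"`` uses the analytic fixed-effect se;
    ``"multiplicative_random"`` inflates it by sqrt(max(1, Q/(k-1))) where Q
    is Cochran's Q of the fit, never deflating below the fixed-effect width.
    """
    if model not in ("fixed", "multiplicative_random"):
        raise ConfigurationError(f"unknown IVW model {model!r}")
    k = hset.nsnp
    if k < 2:
        raise InsufficientInstrumentsError(
            f"IVW needs >= 2 instruments, got {k}; use wald_ratio for 1 SNP"
        )
    x, _, y, se_out = _arrays(hset)
    w = 1.0 / se_out**2
    beta, se_fixed, q = _ivw_fit(x, y, w)
    se = se_fixed
    if model == "multiplicative_random":
        se = se_fixed * math.sqrt(max(1.0, q / (k - 1)))
    method = "ivw_fe" if model == "fixed" else "ivw_mre"
    return MREstimate.from_beta_se(method, beta, se, nsnp=k)


@dataclass(frozen=True)
class EggerResult:
    slope: MREstimate
    intercept: float
    intercept_se: float
    intercept_pval: float


def _egger_fit(
    x: np.ndarray, y: np.ndarray, w: np.ndarray
) -> tuple[float, float, float, float, float]:
    """Weighted regression with intercept, oriented to beta_exp >= 0.

    Returns (slope, slope_se, intercept, intercept_se, scale) where both
    standard errors carry the residual scale sqrt(max(1, RSS_w/(k-2))).
    """
    sign = np.where(x < 0, -1.0, 1.0)
    xs, ys = x * sign, y * sign
    sw = np.sqrt(w)
    design = np.column_stack([np.ones_like(xs), xs])
    coef, *_ = np.linalg.lstsq(design * sw[:, None], ys * sw, rcond=None)
    intercept, slope = float(coef[0]), float(coef[1])
    resid = ys - (intercept + slope * xs)
    rss_w = float(np.sum(w * resid**2))
    k = len(xs)
    scale = max(1.0, rss_w / (k - 2))
    cov = np.linalg.inv(design.T @ (design * w[:, None])) * scale
    return slope, math.sqrt(cov[1, 1]), intercept, math.sqrt(cov[0, 0]), scale


def mr_egger(hset: HarmonizedInstrumentSet, t_pvalues: bool = False) -> EggerResult:
    """Egger regression: weighted fit of beta_out on beta_exp with intercept.

    Instruments are first oriented so every beta_exp is nonnegative (the
    outcome beta flips sign with its exposure beta). The slope is the
    pleiotropy-adjusted causal estimate; a nonzero intercept indicates
    directional pleiotropy. With ``t_pvalues`` the p-values use a t
    reference with k-2 df instead of the normal.
    """
    k = hset.nsnp
    if k < 3:
        raise InsufficientInstrumentsError(f"Egger needs >= 3 instruments, got {k}")
    x, _, y, se_out = _arrays(hset)
    w = 1.0 / se_out**2
    slope, slope_se, intercept, intercept_se, _ = _egger_fit(x, y, w)

    if t_pvalues:
        def pfun(b: float, s: float) -> float:
            if s == 0:
                return 1.0 if b == 0 else 0.0
            return float(2.0 * stats.t.sf(abs(b) / s, df=k - 2))
    else:
        pfun = _two_sided_normal_p

    slope_est = MREstimate.from_beta_se(
        "egger", slope, slope_se, nsnp=k, pval=pfun(slope, slope_se)
    )
    return EggerResult(
        slope=slope_est,
        intercept=intercept,
        intercept_se=intercept_se,
        intercept_pval=pfun(intercept, intercept_se),
    )


def _ratios_and_weights(
    x: np.ndarray, y: np.ndarray, se_out: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Per-SNP Wald ratios and their normalized inverse-variance weights."""
    if np.any(x == 0):
        raise UndefinedRatioError("zero beta_exp; Wald ratios undefined")
    ratios = y / x
    inv_var = x**2 / se_out**2  # 1 / var(ratio), first-order
    return ratios, inv_var / inv_var.sum()


def _weighted_median_point(ratios: np.ndarray, weights: np.ndarray) -> float:
    """Ratio at which cumulative normalized weight crosses 0.5.

    When the running total hits 0.5 exactly at a ratio, the estimate is the
    linear interpolation (midpoint) between that ratio and the next, which
    reproduces the sample median for equal weights.
    """
    order = np.argsort(ratios, kind="stable")
    r = ratios[order]
    w = weights[order] / weights.sum()
    cum = np.cumsum(w)
    idx = int(np.searchsorted(cum, 0.5, side="left"))
    idx = min(idx, len(r) - 1)
    if abs(cum[idx] - 0.5) <= 1e-12 and idx + 1 < len(r):
        return float(0.5 * (r[idx] + r[idx + 1]))
    return float(r[idx])


def _bootstrap_se(
    point_fn,
    x: np.ndarray,
    se_exp: np.ndarray,
    y: np.ndarray,
    se_out: np.ndarray,
    n_boot: int,
    seed: int,
) -> float:
    """Parametric bootstrap: redraw betas from normal(given, se), re-estimate."""
    rng = np.random.default_rng(seed)
    estimates = np.empty(n_boot)
    for b in range(n_boot):
        xb = rng.normal(x, se_exp)
        yb = rng.normal(y, se_out)
        xb = np.where(xb == 0, np.finfo(float).tiny, xb)
        estimates[b] = point_fn(yb / xb)
    return float(np.std(estimates, ddof=1))


def weighted_median(
    hset: HarmonizedInstrumentSet, n_boot: int = 1000, seed: int = 0
) -> MREstimate:
    """Weighted median of per-SNP Wald ratios with bootstrap standard error."""
    k = hset.nsnp
    if k < 3:
        raise InsufficientInstrumentsError(
            f"weighted median needs >= 3 instruments, got {k}"
        )
    x, se_exp, y, se_out = _arrays(hset)
    ratios, weights = _ratios_and_weights(x, y, se_out)
    point = _weighted_median_point(ratios, weights)

    inv_var = x**2 / se_out**2

    def refit(boot_ratios: np.ndarray) -> float:
        return _weighted_median_point(boot_ratios, inv_var / inv_var.sum())

    se = _bootstrap_se(refit, x, se_exp, y, se_out, n_boot, seed)
    return MREstimate.from_beta_se("weighted_median", point, se, nsnp=k)


def _mode_point(
    ratios: np.ndarray,
    weights: np.ndarray,
    bandwidth_factor: float,
    grid_points: int,
) -> float:
    """Argmax of a gaussian kernel density over the ratios.

    Bandwidth is ``bandwidth_factor`` times the normal-consistent MAD of the
    ratios; zero spread returns the common ratio directly.
    """
    mad = float(np.median(np.abs(ratios - np.median(ratios))))
    h = bandwidth_factor * 1.4826 * mad
    if h == 0:
        return float(np.median(ratios))
    grid = np.linspace(ratios.min() - 3 * h, ratios.max() + 3 * h, grid_points)
    z = (grid[None, :] - ratios[:, None]) / h
    density = np.sum(weights[:, None] * np.exp(-0.5 * z**2), axis=0)
    return float(grid[int(np.argmax(density))])


def mode_estimate(
    hset: HarmonizedInstrumentSet,
    weighted: bool = False,
    bandwidth_factor: float = 1.0,
    n_boot: int = 1000,
    seed: int = 0,
    grid_points: int = 10_000,
) -> MREstimate:
    """Mode of the kernel-smoothed Wald-ratio density (simple or weighted)."""
    k = hset.nsnp
    if k < 3:
        raise InsufficientInstrumentsError(
            f"mode estimator needs >= 3 instruments, got {k}"
        )
    x, se_exp, y, se_out = _arrays(hset)
    ratios, norm_weights = _ratios_and_weights(x, y, se_out)
    weights = norm_weights if weighted else np.full(k, 1.0 / k)
    point = _mode_point(ratios, weights, bandwidth_factor, grid_points)

    def refit(boot_ratios: np.ndarray) -> float:
        return _mode_point(boot_ratios, weights, bandwidth_factor, grid_points)

    se = _bootstrap_se(refit, x, se_exp, y, se_out, n_boot, seed)
    method = "weighted_mode" if weighted else "simple_mode"
    return MREstimate.from_beta_se(method, point, se, nsnp=k)


@dataclass(frozen=True)
class MethodConfig:
    """Knobs shared by the stochastic estimators; the seed is mandatory."""

    ivw_model: str = "multiplicative_random"
    n_boot: int = 1000
    seed: int = 0
    bandwidth_factor: float = 1.0
    grid_points: int = 10_000
    egger_t_pvalues: bool = False


@dataclass
class MethodSuite:
    """Estimates from every applicable method plus skip diagnostics."""

    estimates: dict[str, MREstimate] = field(default_factory=dict)
    egger_intercept: tuple[float, float, float] | None = None  # (est, se, p)
    skipped: list[tuple[str, str]] = field(default_factory=list)
    primary: str = "ivw"

    @property
    def primary_estimate(self) -> MREstimate:
        return self.estimates[self.primary]


def run_all_methods(
    hset: HarmonizedInstrumentSet,
    cfg: MethodConfig | Mapping | None = None,
) -> MethodSuite:
    """Run every method whose instrument-count precondition is met.

    One SNP yields only the Wald ratio; two yield IVW; three or more add
    Egger, the weighted median and both modes. Skipped methods are recorded
    with reasons. IVW (under ``cfg.ivw_model``) is flagged as primary.
    """
    if cfg is None:
        cfg = MethodConfig()
    elif isinstance(cfg, Mapping):
        cfg = MethodConfig(**cfg)
    k = hset.nsnp
    if k == 0:
        raise InsufficientInstrumentsError("empty instrument set")

    suite = MethodSuite()
    if k == 1:
        suite.estimates["wald_ratio"] = wald_ratio(hset.rows.iloc[0])
        suite.primary = "wald_ratio"
        for m in ("ivw", "egger", "weighted_median", "simple_mode", "weighted_mode"):
            suite.skipped.append((m, "needs more instruments (nsnp=1)"))
        return suite

    suite.estimates["ivw"] = ivw(hset, cfg.ivw_model)
    if k < 3:
        for m in ("egger", "weighted_median", "simple_mode", "weighted_mode"):
            suite.skipped.append((m, f"needs >= 3 instruments (nsnp={k})"))
        return suite

    egger = mr_egger(hset, t_pvalues=cfg.egger_t_pvalues)
    suite.estimates["egger"] = egger.slope
    suite.egger_intercept = (egger.intercept, egger.intercept_se, egger.intercept_pval)
    suite.estimates["weighted_median"] = weighted_median(
        hset, n_boot=cfg.n_boot, seed=cfg.seed
    )
    suite.estimates["simple_mode"] = mode_estimate(
        hset,
        weighted=False,
        bandwidth_factor=cfg.bandwidth_factor,
        n_boot=cfg.n_boot,
        seed=cfg.seed,
        grid_points=cfg.grid_points,
    )
    suite.estimates["weighted_mode"] = mode_estimate(
        hset,
        weighted=True,
        bandwidth_factor=cfg.bandwidth_factor,
        n_boot=cfg.n_boot,
        seed=cfg.seed,
        grid_points=cfg.grid_points,
    )
    return suite
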