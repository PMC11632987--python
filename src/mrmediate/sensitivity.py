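"""Heterogeneity, pleiotropy and influence diagnostics.

Cochran's Q (IVW and Egger variants), the Egger intercept test, a
simulation-based residual outlier procedure (global, per-SNP and distortion
tests), and leave-one-out analysis.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigurationError, InsufficientInstrumentsError
from .mr_core import MREstimate, _egger_fit, _ivw_fit, ivw, mr_egger
from .sumstats import HarmonizedInstrumentSet

__all__ = [
    "QResult",
    "PressoResult",
    "SensitivityReport",
    "cochran_q",
    "egger_intercept_test",
    "mr_presso",
    "leave_one_out",
    "sensitivity_report",
]


@dataclass(frozen=True)
class QResult:
    Q: float
    df: int
    pval: float


def _xyw(hset: HarmonizedInstrumentSet) -> tuple[np.ndarray, ...]:
    r = hset.rows
    x = r["beta_exp"].to_numpy(float)
    y = r["beta_out"].to_numpy(float)
    se_exp = r["se_exp"].to_numpy(float)
    se_out = r["se_out"].to_numpy(float)
    return x, y, se_exp, se_out, 1.0 / se_out**2


def cochran_q(hset: HarmonizedInstrumentSet, method: str = "ivw") -> QResult:
    """Weighted residual sum of squares around the named method's fit.

    Q = sum_j w_j (beta_out_j - fitted_j)^2 with w_j = 1/se_out_j^2; the
    reference distribution is chi-square with k-1 (IVW) or k-2 (Egger) df.
    """
    k = hset.nsnp
    if method == "ivw":
        if k < 2:
            raise InsufficientInstrumentsError("Q (IVW) needs >= 2 instruments")
        x, y, _, _, w = _xyw(hset)
        _, _, q = _ivw_fit(x, y, w)
        df = k - 1
    elif method == "egger":
        if k < 3:
            raise InsufficientInstrumentsError("Q (Egger) needs >= 3 instruments")
        x, y, _, _, w = _xyw(hset)
        sign = np.where(x < 0, -1.0, 1.0)
        xs, ys = x * sign, y * sign
        slope, _, intercept, _, _ = _egger_fit(x, y, w)
        q = float(np.sum(w * (ys - intercept - slope * xs) ** 2))
        df = k - 2
    else:
        raise ConfigurationError(f"unknown Q method {method!r}")
    return QResult(Q=q, df=df, pval=float(stats.chi2.sf(q, df)))


def egger_intercept_test(
    hset: HarmonizedInstrumentSet, t_pvalues: bool = False
) -> tuple[float, float, float]:
    """Egger intercept with its scaled se and two-sided p (directional pleiotropy)."""
    res = mr_egger(hset, t_pvalues=t_pvalues)
    return res.intercept, res.intercept_se, res.intercept_pval


def _loo_betas(x: np.ndarray, y: np.ndarray, w: np.ndarray) -> np.ndarray:
    """IVW estimate excluding each SNP in turn, vectorized."""
    s_xy = np.sum(w * x * y)
    s_xx = np.sum(w * x * x)
    return (s_xy - w * x * y) / (s_xx - w * x * x)


@dataclass
class PressoResult:
    global_rss: float
    global_p: float
    outlier_ids: list[str]
    outlier_pvals: pd.DataFrame  # variant_id, pval, pval_bonferroni
    distortion_p: float | None
    corrected_estimate: MREstimate | None


def mr_presso(
    hset: HarmonizedInstrumentSet,
    n_sim: int = 5000,
    seed: int = 0,
    outlier_alpha: float = 0.05,
    n_distortion: int = 1000,
    ivw_model: str = "multiplicative_random",
) -> PressoResult:
    """Residual-sum-of-squares pleiotropy test with outlier correction.

    Global test: the observed RSS uses leave-one-out expected outcome
    effects, RSS = sum_j w_j (beta_out_j - bhat_(-j) * beta_exp_j)^2; its
    null distribution comes from ``n_sim`` parametric draws
    beta_exp* ~ N(beta_exp, se_exp), beta_out* ~ N(bhat_(-j) beta_exp, se_out),
    each evaluated with its own leave-one-out fits. The p-value is
    (1 + #{RSS_sim >= RSS_obs}) / (n_sim + 1).

    Outlier test: each SNP's observed weighted squared residual is compared
    to its simulated distribution; per-SNP p-values are Bonferroni-adjusted
    by nsnp and flagged below ``outlier_alpha``.

    Distortion test: when outliers exist, the shift in the IVW estimate
    after removing them is compared (two-sided) to shifts from removing
    ``n_distortion`` random subsets of the same size.
    """
    k = hset.nsnp
    if k < 4:
        raise InsufficientInstrumentsError(
            f"outlier test needs >= 4 instruments, got {k}"
        )
    if n_sim < 1000:
        raise ConfigurationError("n_sim must be >= 1000")
    rng = np.random.default_rng(seed)
    x, y, se_exp, se_out, w = _xyw(hset)
    ids = hset.rows["variant_id"].tolist()

    b_loo = _loo_betas(x, y, w)
    resid_obs = w * (y - b_loo * x) ** 2
    rss_obs = float(resid_obs.sum())

    # Parametric null, fully vectorized over simulations.
    xs = rng.normal(x, se_exp, size=(n_sim, k))
    ys = rng.normal(b_loo * x, se_out, size=(n_sim, k))
    s_xy = np.sum(w * xs * ys, axis=1, keepdims=True)
    s_xx = np.sum(w * xs * xs, axis=1, keepdims=True)
    b_loo_sim = (s_xy - w * xs * ys) / (s_xx - w * xs * xs)
    resid_sim = w * (ys - b_loo_sim * xs) ** 2
    rss_sim = resid_sim.sum(axis=1)

    global_p = float((1 + np.sum(rss_sim >= rss_obs)) / (n_sim + 1))

    pvals = (1 + np.sum(resid_sim >= resid_obs, axis=0)) / (n_sim + 1)
    pvals_bonf = np.minimum(1.0, pvals * k)
    outlier_mask = pvals_bonf < outlier_alpha
    outlier_ids = [ids[j] for j in np.flatnonzero(outlier_mask)]
    outlier_table = pd.DataFrame(
        {"variant_id": ids, "pval": pvals, "pval_bonferroni": pvals_bonf}
    )

    distortion_p: float | None = None
    corrected: MREstimate | None = None
    n_out = len(outlier_ids)
    if 0 < n_out <= k - 2:
        keep = ~outlier_mask
        corrected = ivw(hset.subset([ids[j] for j in np.flatnonzero(keep)]), ivw_model)
        b_full, _, _ = _ivw_fit(x, y, w)
        d_obs = corrected.beta - b_full

        # Null: remove random subsets of the same size.
        pick = np.argsort(rng.random((n_distortion, k)), axis=1)[:, :n_out]
        wxy, wxx = w * x * y, w * x * x
        s_xy_sub = wxy.sum() - wxy[pick].sum(axis=1)
        s_xx_sub = wxx.sum() - wxx[pick].sum(axis=1)
        d_null = s_xy_sub / s_xx_sub - b_full
        distortion_p = float(
            (1 + np.sum(np.abs(d_null) >= abs(d_obs))) / (n_distortion + 1)
        )

    return PressoResult(
        global_rss=rss_obs,
        global_p=global_p,
        outlier_ids=outlier_ids,
        outlier_pvals=outlier_table,
        distortion_p=distortion_p,
        corrected_estimate=corrected,
    )


def leave_one_out(
    hset: HarmonizedInstrumentSet,
    ivw_model: str = "multiplicative_random",
    sig_threshold: float = 0.05,
) -> pd.DataFrame:
    """IVW estimate with each SNP removed in turn.

    Flags mark SNPs whose removal changes the estimate's sign or moves the
    p-value across ``sig_threshold``.
    """
    k = hset.nsnp
    if k < 3:
        raise InsufficientInstrumentsError("leave-one-out needs >= 3 instruments")
    full = ivw(hset, ivw_model)
    ids = hset.rows["variant_id"].tolist()
    rows = []
    for vid in ids:
        est = ivw(hset.subset([v for v in ids if v != vid]), ivw_model)
        rows.append(
            {
                "variant_id": vid,
                "beta_without": est.beta,
                "se_without": est.se,
                "p_without": est.pval,
                "sign_change": math.copysign(1, est.beta)
                != math.copysign(1, full.beta),
                "crosses_threshold": (est.pval < sig_threshold)
                != (full.pval < sig_threshold),
            }
        )
    return pd.DataFrame(rows)


@dataclass
class SensitivityReport:
    q_ivw: QResult | None
    q_egger: QResult | None
    egger_intercept: tuple[float, float, float] | None
    presso: PressoResult | None
    loo: pd.DataFrame | None

    def to_frame(self) -> pd.DataFrame:
        """One-row summary matching the sensitivity TSV layout."""
        row = {
            "q_ivw": self.q_ivw.Q if self.q_ivw else math.nan,
            "q_ivw_p": self.q_ivw.pval if self.q_ivw else math.nan,
            "q_egger": self.q_egger.Q if self.q_egger else math.nan,
            "q_egger_p": self.q_egger.pval if self.q_egger else math.nan,
            "egger_intercept": self.egger_intercept[0]
            if self.egger_intercept
            else math.nan,
            "egger_intercept_p": self.egger_intercept[2]
            if self.egger_intercept
            else math.nan,
            "presso_global_p": self.presso.global_p if self.presso else math.nan,
            "n_outliers": len(self.presso.outlier_ids) if self.presso else 0,
            "distortion_p": self.presso.distortion_p
            if self.presso and self.presso.distortion_p is not None
            else math.nan,
        }
        return pd.DataFrame([row])


def sensitivity_report(
    hset: HarmonizedInstrumentSet,
    presso_n_sim: int = 5000,
    seed: int = 0,
    outlier_alpha: float = 0.05,
    ivw_model: str = "multiplicative_random",
    sig_threshold: float = 0.05,
    run_presso: bool = True,
) -> SensitivityReport:
    """Run every diagnostic whose instrument-count precondition is met."""
    k = hset.nsnp
    return SensitivityReport(
        q_ivw=cochran_q(hset, "ivw") if k >= 2 else None,
        q_egger=cochran_q(hset, "egger") if k >= 3 else None,
        egger_intercept=egger_intercept_test(hset) if k >= 3 else None,
        presso=mr_presso(
            hset,
            n_sim=presso_n_sim,
            seed=seed,
            outlier_alpha=outlier_alpha,
            ivw_model=ivw_model,
        )
        if (run_presso and k >= 4)
        else None,
        loo=leave_one_out(hset, ivw_model, sig_threshold) if k >= 3 else None,
    )
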