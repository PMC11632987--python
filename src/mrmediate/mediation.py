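"""Two-step mediation: product-of-coefficients effects, mediated proportion,
delta-method uncertainty, the full three-leg pipeline, and the reverse-MR
screen.

Effects compose on the beta (log-odds/linear) scale; odds ratios must be
log-transformed before entering :func:`mediated_effect`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import pandas as pd
from scipy import stats

from .errors import (
    MediationLegError,
    MRToolError,
    SelfComparisonError,
    UndefinedProportionError,
)
from .instruments import InstrumentSelectionConfig, LDPairTable, select_instruments
from .mr_core import MREstimate, ivw, wald_ratio
from .sensitivity import SensitivityReport, sensitivity_report
from .sumstats import SummaryStatsTable, harmonize

__all__ = [
    "MediationConfig",
    "MediationResult",
    "ReverseScreenResult",
    "mediated_effect",
    "mediated_proportion",
    "mediation_se",
    "mediation_pvalue",
    "two_step_mediation",
    "reverse_mr_screen",
]


def mediated_effect(beta_a: float, beta_b: float) -> float:
    """Product of coefficients: direct effect A times direct effect B."""
    return beta_a * beta_b


def mediated_proportion(me: float, beta_total: float) -> float:
    """Mediated effect as a percentage of the total effect.

    Opposite signs of ``me`` and ``beta_total`` give a negative proportion
    by convention.
    """
    if beta_total == 0:
        raise UndefinedProportionError("total effect is zero")
    return 100.0 * me / beta_total


def mediation_se(
    beta_a: float,
    se_a: float,
    beta_b: float,
    se_b: float,
    method: str = "delta_full",
) -> float:
    """Delta-method standard error of the mediated effect.

    ``delta_full`` is the Sobel form sqrt(beta_a^2 se_b^2 + beta_b^2 se_a^2);
    ``delta_b_only`` keeps only the first-step uncertainty,
    sqrt(beta_b^2 se_a^2).
    """
    if se_a <= 0 or se_b <= 0:
        raise ValueError("standard errors must be positive")
    if method == "delta_full":
        return math.sqrt(beta_a**2 * se_b**2 + beta_b**2 * se_a**2)
    if method == "delta_b_only":
        return math.sqrt(beta_b**2 * se_a**2)
    raise ValueError(f"unknown mediation se method {method!r}")


def mediation_pvalue(me: float, me_se: float) -> float:
    """Two-sided normal p-value for the mediated effect."""
    if me_se == 0:
        return 1.0 if me == 0 else 0.0
    return float(2.0 * stats.norm.sf(abs(me) / me_se))


@dataclass(frozen=True)
class MediationConfig:
    """Configuration shared by the three MR legs of a mediation analysis."""

    selection: InstrumentSelectionConfig = InstrumentSelectionConfig()
    palindrome_policy: str = "infer_by_eaf"
    eaf_threshold: float = 0.08
    ivw_model: str = "multiplicative_random"
    se_method: str = "delta_full"
    seed: int = 0
    presso_n_sim: int = 5000
    with_sensitivity: bool = False
    screen_p: float = 0.05


@dataclass
class MediationResult:
    """Composed product-of-coefficients mediation result.

    ``me = beta_a * beta_b`` and ``mp`` (in %) satisfies
    ``mp * beta_total == 100 * me`` exactly.
    """

    exposure_id: str
    mediator_id: str
    outcome_id: str
    beta_total: float
    se_total: float
    beta_a: float
    se_a: float
    beta_b: float
    se_b: float
    me: float
    me_se: float
    mp: float
    pval: float
    leg_estimates: dict[str, MREstimate] = field(default_factory=dict)
    leg_sensitivity: dict[str, SensitivityReport] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "exposure": self.exposure_id,
                    "mediator": self.mediator_id,
                    "outcome": self.outcome_id,
                    "beta_total": self.beta_total,
                    "beta_a": self.beta_a,
                    "beta_b": self.beta_b,
                    "me": self.me,
                    "me_se": self.me_se,
                    "mp": self.mp,
                    "pval": self.pval,
                }
            ]
        )


def _run_leg(
    exposure: SummaryStatsTable,
    outcome: SummaryStatsTable,
    ld: LDPairTable | None,
    cfg: MediationConfig,
    leg: str,
) -> tuple[MREstimate, SensitivityReport | None]:
    """Instrument selection (from the leg's exposure) -> harmonize -> IVW."""
    try:
        selected, _ = select_instruments(exposure, ld, cfg.selection)
        hset = harmonize(
            selected, outcome, cfg.palindrome_policy, cfg.eaf_threshold
        )
        if hset.nsnp == 0:
            raise MRToolError("all shared instruments dropped during harmonization")
        if hset.nsnp == 1:
            est = wald_ratio(hset.rows.iloc[0])
        else:
            est = ivw(hset, cfg.ivw_model)
    except MRToolError as exc:
        raise MediationLegError(leg, exc) from exc
    report = None
    if cfg.with_sensitivity and hset.nsnp >= 2:
        report = sensitivity_report(
            hset,
            presso_n_sim=cfg.presso_n_sim,
            seed=cfg.seed,
            ivw_model=cfg.ivw_model,
        )
    return est, report


def two_step_mediation(
    exposure: SummaryStatsTable,
    mediator: SummaryStatsTable,
    outcome: SummaryStatsTable,
    ld: LDPairTable | None = None,
    cfg: MediationConfig = MediationConfig(),
) -> MediationResult:
    """Three full MR legs composed into a mediation result.

    Legs: total (exposure -> outcome), A (exposure -> mediator) and B
    (mediator -> outcome); instruments are always selected from the leg's
    own exposure table. Each leg's estimate is the configured primary
    method (IVW by default, Wald ratio when a single instrument survives).

    Raises
    ------
    MediationLegError
        Naming the first leg whose instrument selection or estimation fails.
    """
    total, sens_total = _run_leg(exposure, outcome, ld, cfg, "total")
    est_a, sens_a = _run_leg(exposure, mediator, ld, cfg, "a")
    est_b, sens_b = _run_leg(mediator, outcome, ld, cfg, "b")

    me = mediated_effect(est_a.beta, est_b.beta)
    me_se = mediation_se(est_a.beta, est_a.se, est_b.beta, est_b.se, cfg.se_method)
    mp = mediated_proportion(me, total.beta)
    result = MediationResult(
        exposure_id=exposure.trait_id,
        mediator_id=mediator.trait_id,
        outcome_id=outcome.trait_id,
        beta_total=total.beta,
        se_total=total.se,
        beta_a=est_a.beta,
        se_a=est_a.se,
        beta_b=est_b.beta,
        se_b=est_b.se,
        me=me,
        me_se=me_se,
        mp=mp,
        pval=mediation_pvalue(me, me_se),
        leg_estimates={"total": total, "a": est_a, "b": est_b},
    )
    for name, report in (("total", sens_total), ("a", sens_a), ("b", sens_b)):
        if report is not None:
            result.leg_sensitivity[name] = report
    return result


@dataclass
class ReverseScreenResult:
    """Per-trait reverse-MR estimates plus per-trait failures."""

    results: pd.DataFrame
    failures: list[tuple[str, str]] = field(default_factory=list)


def reverse_mr_screen(
    outcome_as_exposure: SummaryStatsTable,
    traits: list[SummaryStatsTable],
    ld: LDPairTable | None = None,
    cfg: MediationConfig = MediationConfig(),
    sig_threshold: float = 0.05,
) -> ReverseScreenResult:
    """MR of the outcome trait on each candidate trait (roles swapped).

    Instruments are selected once from the outcome-as-exposure table. A
    trait identical to the outcome is rejected by a guard and recorded as a
    failure rather than analyzed. Each row carries a significance flag at
    ``sig_threshold`` (the null expectation of the screen is no signal).
    """
    failures: list[tuple[str, str]] = []
    try:
        selected, _ = select_instruments(outcome_as_exposure, ld, cfg.selection)
    except MRToolError as exc:
        raise MediationLegError("reverse", exc) from exc

    rows = []
    for trait in traits:
        if trait.trait_id == outcome_as_exposure.trait_id:
            failures.append(
                (trait.trait_id, str(SelfComparisonError("exposure_id == outcome_id")))
            )
            continue
        try:
            hset = harmonize(
                selected, trait, cfg.palindrome_policy, cfg.eaf_threshold
            )
            if hset.nsnp == 0:
                raise MRToolError("all shared instruments dropped")
            est = (
                wald_ratio(hset.rows.iloc[0])
                if hset.nsnp == 1
                else ivw(hset, cfg.ivw_model)
            )
        except MRToolError as exc:
            failures.append((trait.trait_id, str(exc)))
            continue
        rows.append(
            {
                "exposure": outcome_as_exposure.trait_id,
                "outcome": trait.trait_id,
                "method": est.method,
                "nsnp": est.nsnp,
                "b": est.beta,
                "se": est.se,
                "pval": est.pval,
                "significant": est.pval < sig_threshold,
            }
        )
    columns = [
        "exposure",
        "outcome",
        "method",
        "nsnp",
        "b",
        "se",
        "pval",
        "significant",
    ]
    return ReverseScreenResult(pd.DataFrame(rows, columns=columns), failures)
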