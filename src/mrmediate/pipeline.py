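"""Run orchestration: config file handling, full MR runs, two-step mediation
runs, batch screening, and the worked-example replay."""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .errors import ConfigurationError
from .instruments import InstrumentSelectionConfig, LDPairTable, select_instruments
from .mediation import (
    MediationConfig,
    MediationResult,
    ReverseScreenResult,
    mediated_effect,
    mediated_proportion,
    reverse_mr_screen,
    two_step_mediation,
)
from .mr_core import MethodConfig, MethodSuite, run_all_methods
from .sensitivity import SensitivityReport, sensitivity_report
from .sumstats import (
    SummaryStatsTable,
    harmonize,
    read_sumstats,
    write_drop_log,
    write_harmonized,
)
from .synthetic_data import make_paper_fixture

__all__ = [
    "RunConfig",
    "RunReport",
    "TwoStepReport",
    "run_mr",
    "run_two_step",
    "screen_exposures",
    "replay_fixture",
    "estimates_frame",
]


@dataclass
class RunConfig:
    """Validated run configuration (typically loaded from YAML)."""

    exposure: Path
    outcome: Path
    out_dir: Path
    mediator: Path | None = None
    ld: Path | None = None
    selection: InstrumentSelectionConfig = field(
        default_factory=InstrumentSelectionConfig
    )
    palindrome_policy: str = "infer_by_eaf"
    eaf_threshold: float = 0.08
    ivw_model: str = "multiplicative_random"
    n_boot: int = 1000
    bandwidth_factor: float = 1.0
    presso_n_sim: int = 5000
    presso_outlier_alpha: float = 0.05
    run_presso: bool = True
    seed: int = 0
    screen_p: float = 0.05
    mediation_p: float = 0.05
    se_method: str = "delta_full"
    reverse_screen: bool = False

    @classmethod
    def from_yaml(cls, path: str | Path, seed: int | None = None) -> "RunConfig":
        path = Path(path)
        with path.open() as fh:
            raw = yaml.safe_load(fh) or {}
        if not isinstance(raw, dict):
            raise ConfigurationError(f"{path}: config must be a mapping")
        if "selection" in raw and isinstance(raw["selection"], dict):
            raw["selection"] = InstrumentSelectionConfig(**raw["selection"])
        for key in ("exposure", "outcome", "mediator", "ld", "out_dir"):
            if raw.get(key) is not None:
                raw[key] = (path.parent / raw[key]).resolve()
        if seed is not None:
            raw["seed"] = seed
        try:
            cfg = cls(**raw)
        except TypeError as exc:
            raise ConfigurationError(f"{path}: {exc}") from exc
        cfg.validate()
        return cfg

    def validate(self) -> None:
        for name in ("exposure", "outcome", "mediator", "ld"):
            value = getattr(self, name)
            if value is not None and not Path(value).exists():
                raise ConfigurationError(f"{name} path does not exist: {value}")

    def to_manifest(self) -> dict:
        data = dataclasses.asdict(self)
        for key, value in data.items():
            if isinstance(value, Path):
                data[key] = str(value)
        data["selection"] = dataclasses.asdict(self.selection)
        data["version"] = __version__
        return data

    def method_config(self) -> MethodConfig:
        return MethodConfig(
            ivw_model=self.ivw_model,
            n_boot=self.n_boot,
            seed=self.seed,
            bandwidth_factor=self.bandwidth_factor,
        )

    def mediation_config(self, with_sensitivity: bool = False) -> MediationConfig:
        return MediationConfig(
            selection=self.selection,
            palindrome_policy=self.palindrome_policy,
            eaf_threshold=self.eaf_threshold,
            ivw_model=self.ivw_model,
            se_method=self.se_method,
            seed=self.seed,
            presso_n_sim=self.presso_n_sim,
            with_sensitivity=with_sensitivity,
            screen_p=self.screen_p,
        )


def estimates_frame(
    suite: MethodSuite, exposure_id: str, outcome_id: str
) -> pd.DataFrame:
    """Estimates table with the published column layout."""
    rows = [
        {
            "exposure": exposure_id,
            "outcome": outcome_id,
            "method": est.method,
            "nsnp": est.nsnp,
            "b": est.beta,
            "se": est.se,
            "or": est.or_,
            "or_lci95": est.or_low,
            "or_uci95": est.or_high,
            "pval": est.pval,
        }
        for est in suite.estimates.values()
    ]
    return pd.DataFrame(rows)


@dataclass
class RunReport:
    estimates: pd.DataFrame
    suite: MethodSuite
    sensitivity: SensitivityReport
    manifest: dict


def _load_tables(config: RunConfig) -> tuple[SummaryStatsTable, ...]:
    exposure = read_sumstats(config.exposure).table
    outcome = read_sumstats(config.outcome).table
    mediator = (
        read_sumstats(config.mediator).table if config.mediator is not None else None
    )
    return exposure, outcome, mediator


def _load_ld(config: RunConfig) -> LDPairTable | None:
    return LDPairTable.from_tsv(config.ld) if config.ld is not None else None


def run_mr(config: RunConfig, write: bool = True) -> RunReport:
    """One exposure-outcome MR run with all methods and diagnostics.

    Outputs (written under ``config.out_dir`` only after the analysis has
    fully succeeded, so failures leave no partial files): ``estimates.tsv``,
    ``sensitivity.tsv``, ``leave_one_out.tsv``, ``harmonized.tsv``,
    ``drop_log.tsv``, ``selection_log.tsv`` and ``manifest.json``.
    """
    exposure, outcome, _ = _load_tables(config)
    ld = _load_ld(config)

    selected, sel_log = select_instruments(exposure, ld, config.selection)
    hset = harmonize(
        selected, outcome, config.palindrome_policy, config.eaf_threshold
    )
    suite = run_all_methods(hset, config.method_config())
    report = sensitivity_report(
        hset,
        presso_n_sim=config.presso_n_sim,
        seed=config.seed,
        outlier_alpha=config.presso_outlier_alpha,
        ivw_model=config.ivw_model,
        sig_threshold=config.screen_p,
        run_presso=config.run_presso,
    )

    estimates = estimates_frame(suite, exposure.trait_id, outcome.trait_id)
    manifest = {
        "config": config.to_manifest(),
        "selection_log": sel_log.counts(),
        "skipped_methods": suite.skipped,
        "n_harmonized": hset.nsnp,
        "n_dropped": len(hset.dropped),
    }

    if write:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        estimates.to_csv(out / "estimates.tsv", sep="\t", index=False)
        report.to_frame().to_csv(out / "sensitivity.tsv", sep="\t", index=False)
        if report.loo is not None:
            report.loo.to_csv(out / "leave_one_out.tsv", sep="\t", index=False)
        write_harmonized(hset, out / "harmonized.tsv")
        write_drop_log(hset, out / "drop_log.tsv")
        sel_log.write(out / "selection_log.tsv")
        with (out / "manifest.json").open("w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)

    return RunReport(estimates, suite, report, manifest)


@dataclass
class TwoStepReport:
    mediation: MediationResult
    mediation_table: pd.DataFrame
    forest_table: pd.DataFrame
    reverse: ReverseScreenResult | None
    manifest: dict


def run_two_step(config: RunConfig, write: bool = True) -> TwoStepReport:
    """Three-leg mediation run, optionally followed by a reverse-MR screen."""
    if config.mediator is None:
        raise ConfigurationError("two-step run requires a mediator path")
    exposure, outcome, mediator = _load_tables(config)
    ld = _load_ld(config)

    med_cfg = config.mediation_config(with_sensitivity=True)
    result = two_step_mediation(exposure, mediator, outcome, ld, med_cfg)

    forest_rows = []
    for label, est in result.leg_estimates.items():
        forest_rows.append(
            {
                "label": label,
                "estimate": est.beta,
                "ci_low": est.ci_low,
                "ci_high": est.ci_high,
            }
        )
    z = 1.959963984540054
    forest_rows.append(
        {
            "label": "mediated",
            "estimate": result.me,
            "ci_low": result.me - z * result.me_se,
            "ci_high": result.me + z * result.me_se,
        }
    )
    forest = pd.DataFrame(forest_rows)

    reverse = None
    if config.reverse_screen:
        reverse = reverse_mr_screen(
            outcome, [exposure, mediator], ld, med_cfg, config.screen_p
        )

    manifest = {"config": config.to_manifest()}
    med_table = result.to_frame()
    if write:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        med_table.to_csv(out / "mediation.tsv", sep="\t", index=False)
        forest.to_csv(out / "forest.tsv", sep="\t", index=False)
        if reverse is not None:
            reverse.results.to_csv(out / "reverse_screen.tsv", sep="\t", index=False)
            pd.DataFrame(reverse.failures, columns=["trait_id", "reason"]).to_csv(
                out / "reverse_failures.tsv", sep="\t", index=False
            )
        with (out / "manifest.json").open("w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)

    return TwoStepReport(result, med_table, forest, reverse, manifest)


def screen_exposures(
    exposures: list[SummaryStatsTable],
    outcome: SummaryStatsTable,
    ld: LDPairTable | None,
    config: RunConfig,
) -> tuple[pd.DataFrame, list[tuple[str, str]]]:
    """IVW screen of many exposures against one outcome.

    A failing pair is recorded and does not abort the batch. Bonferroni and
    Benjamini-Hochberg columns are reported alongside the raw p-values; the
    selection flag still uses the raw ``screen_p`` rule.
    """
    from .mr_core import ivw, wald_ratio  # local import avoids cycle at module load

    rows, failures = [], []
    for exposure in exposures:
        try:
            selected, _ = select_instruments(exposure, ld, config.selection)
            hset = harmonize(
                selected, outcome, config.palindrome_policy, config.eaf_threshold
            )
            if hset.nsnp == 0:
                raise ConfigurationError("all shared instruments dropped")
            est = (
                wald_ratio(hset.rows.iloc[0])
                if hset.nsnp == 1
                else ivw(hset, config.ivw_model)
            )
        except Exception as exc:  # batch robustness: collect, don't abort
            failures.append((exposure.trait_id, str(exc)))
            continue
        rows.append(
            {
                "exposure": exposure.trait_id,
                "outcome": outcome.trait_id,
                "method": est.method,
                "nsnp": est.nsnp,
                "b": est.beta,
                "se": est.se,
                "or": est.or_,
                "or_lci95": est.or_low,
                "or_uci95": est.or_high,
                "pval": est.pval,
            }
        )
    frame = pd.DataFrame(rows)
    if len(frame):
        m = len(frame)
        frame["pval_bonferroni"] = np.minimum(1.0, frame["pval"] * m)
        order = np.argsort(frame["pval"].to_numpy())
        ranked = frame["pval"].to_numpy()[order] * m / (np.arange(m) + 1)
        ranked = np.minimum.accumulate(ranked[::-1])[::-1]
        bh = np.empty(m)
        bh[order] = np.minimum(1.0, ranked)
        frame["pval_bh"] = bh
        frame["significant"] = frame["pval"] < config.screen_p
    return frame, failures


def replay_fixture(se_method: str = "delta_full") -> pd.DataFrame:
    """Recompute the published mediation arithmetic from transcribed inputs.

    For each published pathway: beta_a is the natural log of the printed
    step-2 odds ratio, beta_b the printed metabolite -> outcome beta, and
    beta_total the printed total-effect beta. The computed mediated effect
    and proportion sit next to the printed values for comparison.
    """
    fixture = make_paper_fixture()
    rows = []
    for _, printed in fixture.table3.iterrows():
        immune, metabolite = printed["immune_trait"], printed["metabolite"]
        beta_a = math.log(fixture.step2_or(immune, metabolite))
        beta_b = fixture.metabolite_beta(metabolite)
        beta_total = fixture.total_beta(immune)
        me = mediated_effect(beta_a, beta_b)
        mp = mediated_proportion(me, beta_total)
        rows.append(
            {
                "exposure": immune,
                "mediator": metabolite,
                "beta_a": beta_a,
                "beta_b": beta_b,
                "beta_total": beta_total,
                "me": me,
                "me_printed": printed["me"],
                "mp_pct": mp,
                "mp_printed": printed["mp_pct"],
            }
        )
    return pd.DataFrame(rows)
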