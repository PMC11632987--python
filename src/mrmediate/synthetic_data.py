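"""Synthetic three-trait GWAS summary statistics with known causal structure.

Generates exposure, mediator and outcome summary-statistics tables from a
latent exposure -> mediator -> outcome system (total effect
``theta = c + a*b``), with optional pleiotropy, outlier contamination and
LD blocks, plus a truth ledger so every pipeline stage can be scored
against known effects. Also ships the transcribed worked-example tables
used by the acceptance suite (:func:`make_paper_fixture`).
"""

from __future__ import annotations

import io
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ConfigurationError
from .instruments import LDPairTable
from .sumstats import SummaryStatsTable, VariantAssociation

__all__ = [
    "PleiotropyConfig",
    "SimulationConfig",
    "TruthLedger",
    "SimulatedSystem",
    "simulate_mediation_system",
    "PaperFixture",
    "make_paper_fixture",
]

# Ordered (effect, other) pairs that are never strand-ambiguous.
_NON_PALINDROMIC = [
    ("A", "G"), ("A", "C"), ("T", "G"), ("T", "C"),
    ("G", "A"), ("C", "A"), ("G", "T"), ("C", "T"),
]


@dataclass(frozen=True)
class PleiotropyConfig:
    """Direct SNP -> outcome effects violating the exclusion restriction.

    ``balanced`` draws alpha ~ N(0, sd); ``directional`` draws
    alpha ~ N(mean, sd); ``fraction`` of exposure instruments are affected.
    """

    mode: str = "none"
    sd: float = 0.0
    mean: float = 0.0
    fraction: float = 0.0

    def __post_init__(self) -> None:
        if self.mode not in ("none", "balanced", "directional"):
            raise ConfigurationError(f"unknown pleiotropy mode {self.mode!r}")
        if self.sd < 0:
            raise ConfigurationError("pleiotropy sd must be >= 0")
        if not (0.0 <= self.fraction <= 1.0):
            raise ConfigurationError("pleiotropy fraction must lie in [0, 1]")


@dataclass(frozen=True)
class SimulationConfig:
    """All knobs of the generator; ``seed`` is mandatory.

    ``n_snps`` exposure instruments carry true effects gamma ~ N(0, gamma_sd)
    on the exposure. ``n_snps_mediator`` / ``n_snps_outcome`` extra variants
    carry trait-specific effects (delta ~ N(0, delta_sd),
    omega ~ N(0, omega_sd)) so that the mediator and outcome have
    instruments of their own — required for the mediator -> outcome leg and
    the reverse-MR screen to be identified. Standard errors follow
    se = 1/sqrt(2 maf (1-maf) n); ``n_outcome_eff`` substitutes an effective
    sample size for the (binary) outcome when given.
    """

    seed: int
    n_snps: int = 50
    n_snps_mediator: int = 0
    n_snps_outcome: int = 0
    n_exposure: int = 100_000
    n_mediator: int = 100_000
    n_outcome: int = 100_000
    n_outcome_eff: int | None = None
    maf_range: tuple[float, float] = (0.05, 0.5)
    gamma_sd: float = 0.05
    delta_sd: float = 0.05
    omega_sd: float = 0.05
    a: float = 0.3
    b: float = 0.4
    c: float = 0.2
    pleiotropy: PleiotropyConfig = PleiotropyConfig()
    n_outliers: int = 0
    outlier_scale: float = 5.0
    ld_blocks: list[tuple[int, float]] | None = None

    def __post_init__(self) -> None:
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ConfigurationError("maf_range must lie within (0, 0.5]")
        if min(self.n_snps, self.n_snps_mediator, self.n_snps_outcome) < 0:
            raise ConfigurationError("SNP counts must be >= 0")
        if self.n_snps < 1:
            raise ConfigurationError("need at least one exposure instrument")
        if self.gamma_sd < 0 or self.delta_sd < 0 or self.omega_sd < 0:
            raise ConfigurationError("effect sds must be >= 0")
        if self.n_outliers > self.n_snps:
            raise ConfigurationError("n_outliers exceeds n_snps")
        if self.ld_blocks:
            if sum(size for size, _ in self.ld_blocks) > self.n_snps:
                raise ConfigurationError("ld_blocks cover more SNPs than n_snps")
            for size, r2 in self.ld_blocks:
                if size < 2 or not (0.0 <= r2 <= 1.0):
                    raise ConfigurationError("invalid ld block")

    @property
    def theta_total(self) -> float:
        return self.c + self.a * self.b


@dataclass
class TruthLedger:
    """Per-SNP and trait-level ground truth for scoring estimates.

    ``mp`` is the true mediated proportion in percent,
    100 * a*b / theta_total; ``theta_total = c + a*b`` exactly.
    """

    per_snp: pd.DataFrame  # variant_id role gamma delta omega alpha outlier
    a: float
    b: float
    c: float
    theta_total: float
    mp: float

    def write(self, path: str | Path) -> None:
        self.per_snp.to_csv(path, sep="\t", index=False)


@dataclass
class SimulatedSystem:
    exposure: SummaryStatsTable
    mediator: SummaryStatsTable
    outcome: SummaryStatsTable
    ld: LDPairTable
    truth: TruthLedger


def _se(maf: np.ndarray, n: int) -> np.ndarray:
    return 1.0 / np.sqrt(2.0 * maf * (1.0 - maf) * n)


def _table(
    trait_id: str,
    ids: list[str],
    chrom: np.ndarray,
    pos: np.ndarray,
    alleles: list[tuple[str, str]],
    maf: np.ndarray,
    beta: np.ndarray,
    se: np.ndarray,
    pval: np.ndarray,
    n: int,
) -> SummaryStatsTable:
    records = [
        VariantAssociation(
            variant_id=ids[j],
            chrom=str(chrom[j]),
            pos=int(pos[j]),
            effect_allele=alleles[j][0],
            other_allele=alleles[j][1],
            eaf=float(maf[j]),
            beta=float(beta[j]),
            se=float(se[j]),
            pval=float(pval[j]),
            n=n,
        )
        for j in range(len(ids))
    ]
    return SummaryStatsTable(trait_id, trait_id, records)


def simulate_mediation_system(cfg: SimulationConfig) -> SimulatedSystem:
    """Draw one three-trait summary-statistics system.

    Exposure instruments j carry gamma_j on the exposure, a*gamma_j on the
    mediator and (c + a*b)*gamma_j + alpha_j on the outcome; mediator- and
    outcome-specific variants carry delta_j / omega_j (propagated forward:
    a mediator variant moves the outcome by b*delta_j). Observed betas add
    N(0, se) noise with se = 1/sqrt(2 maf (1-maf) n_trait); two calls with
    the same config are byte-identical.
    """
    rng = np.random.default_rng(cfg.seed)

    k_exp, k_med, k_out = cfg.n_snps, cfg.n_snps_mediator, cfg.n_snps_outcome
    k = k_exp + k_med + k_out
    roles = np.array(
        ["exposure"] * k_exp + ["mediator"] * k_med + ["outcome"] * k_out
    )
    ids = [f"rs{j + 1}" for j in range(k)]
    chrom = (np.arange(k) % 22) + 1
    pos = 1_000_000 + (np.arange(k) // 22) * 20_000_000
    alleles = [
        _NON_PALINDROMIC[i] for i in rng.integers(0, len(_NON_PALINDROMIC), size=k)
    ]
    maf = rng.uniform(cfg.maf_range[0], cfg.maf_range[1], size=k)

    gamma = np.where(roles == "exposure", rng.normal(0.0, cfg.gamma_sd, size=k), 0.0)
    delta = np.where(roles == "mediator", rng.normal(0.0, cfg.delta_sd, size=k), 0.0)
    omega = np.where(roles == "outcome", rng.normal(0.0, cfg.omega_sd, size=k), 0.0)

    n_out_model = cfg.n_outcome_eff or cfg.n_outcome
    se_exp = _se(maf, cfg.n_exposure)
    se_med = _se(maf, cfg.n_mediator)
    se_out = _se(maf, n_out_model)

    # Horizontal pleiotropy on a fraction of exposure instruments.
    alpha = np.zeros(k)
    exp_idx = np.flatnonzero(roles == "exposure")
    pl = cfg.pleiotropy
    if pl.mode != "none" and pl.fraction > 0:
        n_pl = int(round(pl.fraction * k_exp))
        chosen = rng.choice(exp_idx, size=n_pl, replace=False)
        mean = pl.mean if pl.mode == "directional" else 0.0
        draws = rng.normal(mean, pl.sd, size=n_pl)
        # Directional pleiotropy is defined relative to the
        # exposure-increasing allele (otherwise instrument orientation
        # averages it away); align it with the sign of gamma.
        orient = np.where(gamma[chosen] < 0, -1.0, 1.0)
        alpha[chosen] = draws * orient

    # Outliers: gross direct outcome effects of outlier_scale outcome se's.
    outlier = np.zeros(k, dtype=bool)
    if cfg.n_outliers:
        chosen = rng.choice(exp_idx, size=cfg.n_outliers, replace=False)
        outlier[chosen] = True
        alpha[chosen] += (
            cfg.outlier_scale * se_out[chosen] * rng.choice([-1.0, 1.0], size=cfg.n_outliers)
        )

    true_exp = gamma
    true_med = cfg.a * gamma + delta
    true_out = cfg.theta_total * gamma + cfg.b * delta + omega + alpha

    beta_exp = true_exp + rng.normal(0.0, se_exp)
    beta_med = true_med + rng.normal(0.0, se_med)
    beta_out = true_out + rng.normal(0.0, se_out)

    p_exp = _norm_sf(beta_exp, se_exp)
    p_med = _norm_sf(beta_med, se_med)
    p_out = _norm_sf(beta_out, se_out)

    ld = LDPairTable()
    if cfg.ld_blocks:
        start = 0
        for size, r2 in cfg.ld_blocks:
            block = list(range(start, start + size))
            # Co-locate the block so it falls inside any sane clump window.
            for offset, j in enumerate(block):
                chrom[j] = chrom[block[0]]
                pos[j] = pos[block[0]] + offset * 50_000
            for i in block:
                for j in block:
                    if i < j:
                        ld.add(ids[i], ids[j], r2)
            start += size

    exposure = _table(
        "exposure", ids, chrom, pos, alleles, maf, beta_exp, se_exp, p_exp,
        cfg.n_exposure,
    )
    mediator = _table(
        "mediator", ids, chrom, pos, alleles, maf, beta_med, se_med, p_med,
        cfg.n_mediator,
    )
    outcome = _table(
        "outcome", ids, chrom, pos, alleles, maf, beta_out, se_out, p_out,
        cfg.n_outcome,
    )

    per_snp = pd.DataFrame(
        {
            "variant_id": ids,
            "role": roles,
            "gamma": gamma,
            "delta": delta,
            "omega": omega,
            "alpha": alpha,
            "outlier": outlier,
        }
    )
    theta = cfg.theta_total
    truth = TruthLedger(
        per_snp=per_snp,
        a=cfg.a,
        b=cfg.b,
        c=cfg.c,
        theta_total=theta,
        mp=100.0 * cfg.a * cfg.b / theta if theta != 0 else float("nan"),
    )
    return SimulatedSystem(exposure, mediator, outcome, ld, truth)


def _norm_sf(beta: np.ndarray, se: np.ndarray) -> np.ndarray:
    from scipy import stats

    p = 2.0 * stats.norm.sf(np.abs(beta) / se)
    # p-values of exactly 0 are outside the domain; clamp to the smallest
    # positive normal float.
    return np.maximum(p, np.finfo(float).tiny)


# --------------------------------------------------------------------------
# Transcribed worked-example tables (values copied, never computed).
# --------------------------------------------------------------------------

_TABLE1_TSV = """\
exposure\tnsnp\tb\tse\tor\tor_lci95\tor_uci95\tpval
Plasmacytoid DC %DC\t21\t0.10\t0.03\t1.10\t1.03\t1.18\t0.0028
CD39+ secreting Treg %secreting Treg\t20\t-0.07\t0.03\t0.93\t0.88\t0.98\t0.0087
Naive CD8br %CD8br\t24\t-0.09\t0.03\t0.91\t0.85\t0.98\t0.0089
T cell %leukocyte\t15\t-0.10\t0.03\t0.91\t0.85\t0.97\t0.0043
Granulocyte %leukocyte\t21\t0.13\t0.05\t1.14\t1.04\t1.26\t0.0062
CD28+ CD45RA+ CD8dim %T cell\t33\t-0.04\t0.01\t0.96\t0.94\t0.99\t0.0061
CD28+ CD45RA+ CD8dim AC\t35\t-0.03\t0.01\t0.97\t0.95\t0.99\t0.0034
CD28- CD127- CD25++ CD8br %T cell\t14\t-0.17\t0.06\t0.84\t0.75\t0.95\t0.0042
CD19 on IgD+ CD38br\t13\t-0.18\t0.05\t0.83\t0.75\t0.92\t0.0006
CD19 on IgD- CD27-\t22\t-0.16\t0.04\t0.85\t0.78\t0.93\t0.0003
CD25 on CD45RA+ CD4 not Treg\t20\t0.12\t0.04\t1.12\t1.05\t1.21\t0.0013
CD25 on resting Treg\t14\t-0.12\t0.04\t0.89\t0.82\t0.96\t0.0022
CD25 on CD4+\t12\t-0.13\t0.04\t0.88\t0.81\t0.96\t0.0023
CCR2 on granulocyte\t16\t0.15\t0.04\t1.16\t1.08\t1.24\t2.96E-05
"""

_TABLE2_TSV = """\
exposure\tnsnp\tb\tse\tor\tor_lci95\tor_uci95\tpval
4-methyl-2-oxopentanoate levels\t12\t0.32\t0.11\t1.38\t1.11\t1.71\t3.45E-03
Gamma-glutamylmethionine levels\t24\t-0.20\t0.08\t0.81\t0.70\t0.95\t9.63E-03
1-arachidonylglycerol (20:4) levels\t17\t0.25\t0.07\t1.28\t1.13\t1.46\t1.44E-04
Malonylcarnitine levels\t19\t-0.25\t0.09\t0.78\t0.65\t0.93\t4.87E-03
1-arachidonoyl-gpc (20:4n6) levels\t23\t0.12\t0.04\t1.13\t1.04\t1.22\t3.34E-03
1-arachidonoyl-GPE (20:4n6) levels\t29\t0.13\t0.05\t1.14\t1.04\t1.25\t4.55E-03
5alpha-androstan-3beta,17alpha-diol disulfate levels\t23\t0.28\t0.08\t1.33\t1.14\t1.54\t2.21E-04
Indole-3-carboxylate levels\t14\t0.24\t0.08\t1.27\t1.09\t1.48\t2.62E-03
2-aminophenol sulfate levels\t25\t0.21\t0.08\t1.23\t1.05\t1.44\t8.79E-03
1H-indole-7-acetic acid levels\t24\t0.25\t0.07\t1.28\t1.12\t1.46\t3.91E-04
3-hydroxyhexanoate levels\t12\t0.26\t0.10\t1.30\t1.07\t1.57\t7.11E-03
Linoleoyl ethanolamide levels\t20\t-0.22\t0.08\t0.80\t0.68\t0.94\t6.76E-03
1-stearoyl-2-linoleoyl-gpc (18:0/18:2) levels\t18\t-0.25\t0.09\t0.78\t0.65\t0.94\t8.04E-03
Dibutyl sulfosuccinate levels\t28\t-0.29\t0.10\t0.75\t0.62\t0.91\t3.49E-03
1-palmitoyl-2-linoleoyl-gpc (16:0/18:2) levels\t27\t-0.21\t0.06\t0.81\t0.73\t0.91\t3.67E-04
1-palmitoyl-2-linoleoyl-GPI (16:0/18:2) levels\t20\t-0.22\t0.07\t0.80\t0.69\t0.93\t2.61E-03
Eicosapentaenoate (EPA; 20:5n3) levels\t22\t0.23\t0.08\t1.26\t1.08\t1.47\t4.04E-03
Methionine levels\t17\t-0.24\t0.09\t0.78\t0.65\t0.94\t7.45E-03
Retinol (Vitamin A) to linoleoyl-arachidonoyl-glycerol (18:2 to 20:4) [1] ratio\t9\t-0.26\t0.10\t0.77\t0.64\t0.94\t8.47E-03
Retinol (Vitamin A) to linoleoyl-arachidonoyl-glycerol (18:2 to 20:4) [2] ratio\t12\t-0.24\t0.07\t0.79\t0.69\t0.90\t4.00E-04
Cholesterol to linoleoyl-arachidonoyl-glycerol (18:2 to 20:4) [1] ratio\t16\t-0.22\t0.07\t0.81\t0.70\t0.93\t3.63E-03
"""

_TABLE3_TSV = """\
immune_trait\tmetabolite\tme\tmp_pct\tpval
CD39+ secreting Treg %secreting Treg\t1-arachidonylglycerol (20:4) levels\t-0.00693\t9.71\t0.037
CD39+ secreting Treg %secreting Treg\t1-stearoyl-2-linoleoyl-gpc (18:0/18:2) levels\t0.00642\t-9.00\t0.043
T cell %leukocyte\tLinoleoyl ethanolamide levels\t-0.0114\t11.60\t0.016
CD28+ CD45RA+ CD8dim %T cell\tIndole-3-carboxylate levels\t0.00354\t-9.59\t0.047
CD28+ CD45RA+ CD8dim AC\tIndole-3-carboxylate levels\t0.00336\t-10.00\t0.004
CD28- CD127- CD25++ CD8br %T cell\t3-hydroxyhexanoate levels\t0.0125\t-7.34\t0.042
CD28- CD127- CD25++ CD8br %T cell\tMethionine levels\t0.0143\t-8.39\t0.027
CD25 on CD4+\tMethionine levels\t-0.00851\t6.77\t0.030
CCR2 on granulocyte\t5alpha-androstan-3beta,17alpha-diol disulfate levels\t0.0116\t7.82\t0.037
"""

# Step-2 odds ratios (immune trait -> metabolite) as printed in the results
# narrative; 11 causal pairs, 9 of which became mediation pathways.
_STEP2_TSV = """\
immune_trait\tmetabolite\tor\tor_lci95\tor_uci95\tpval
CD39+ secreting Treg %secreting Treg\t1-arachidonylglycerol (20:4) levels\t0.973\t0.948\t0.998\t0.036
CD39+ secreting Treg %secreting Treg\t1-stearoyl-2-linoleoyl-gpc (18:0/18:2) levels\t0.974\t0.950\t0.999\t0.042
T cell %leukocyte\tLinoleoyl ethanolamide levels\t1.053\t1.011\t1.096\t0.014
CD28+ CD45RA+ CD8dim %T cell\tIndole-3-carboxylate levels\t1.015\t1.000\t1.030\t0.046
CD28+ CD45RA+ CD8dim AC\tIndole-3-carboxylate levels\t1.014\t1.005\t1.024\t0.003
CD28- CD127- CD25++ CD8br %T cell\t3-hydroxyhexanoate levels\t1.049\t1.002\t1.097\t0.039
CD28- CD127- CD25++ CD8br %T cell\tMethionine levels\t0.943\t0.897\t0.992\t0.023
CD19 on IgD+ CD38br\tCholesterol to linoleoyl-arachidonoyl-glycerol (18:2 to 20:4) [1] ratio\t0.947\t0.899\t0.998\t0.043
CD25 on CD45RA+ CD4 not Treg\tLinoleoyl ethanolamide levels\t1.034\t1.000\t1.069\t0.047
CD25 on CD4+\tMethionine levels\t1.035\t1.004\t1.068\t0.028
CCR2 on granulocyte\t5alpha-androstan-3beta,17alpha-diol disulfate levels\t1.042\t1.003\t1.082\t0.036
"""


@dataclass(frozen=True)
class PaperFixture:
    """Transcribed worked-example tables for acceptance tests.

    ``table1``: total effects (immune trait -> outcome, IVW);
    ``table2``: metabolite -> outcome effects (IVW);
    ``table3``: published mediated effects and proportions;
    ``step2``: immune trait -> metabolite odds ratios from the results text.
    """

    table1: pd.DataFrame
    table2: pd.DataFrame
    table3: pd.DataFrame
    step2: pd.DataFrame

    def step2_or(self, immune_trait: str, metabolite: str) -> float:
        return self._lookup(self.step2, immune_trait, metabolite)["or"]

    def total_beta(self, immune_trait: str) -> float:
        rows = self.table1[self.table1["exposure"] == immune_trait]
        if len(rows) != 1:
            raise KeyError(immune_trait)
        return float(rows.iloc[0]["b"])

    def total_or(self, immune_trait: str) -> float:
        rows = self.table1[self.table1["exposure"] == immune_trait]
        if len(rows) != 1:
            raise KeyError(immune_trait)
        return float(rows.iloc[0]["or"])

    def metabolite_beta(self, metabolite: str) -> float:
        rows = self.table2[
            self.table2["exposure"].str.lower() == metabolite.lower()
        ]
        if len(rows) != 1:
            raise KeyError(metabolite)
        return float(rows.iloc[0]["b"])

    @staticmethod
    def _lookup(df: pd.DataFrame, immune_trait: str, metabolite: str) -> pd.Series:
        rows = df[
            (df["immune_trait"] == immune_trait)
            & (df["metabolite"].str.lower() == metabolite.lower())
        ]
        if len(rows) != 1:
            raise KeyError((immune_trait, metabolite))
        return rows.iloc[0]


def make_paper_fixture() -> PaperFixture:
    """Parse the transcribed tables into DataFrames (no computation)."""
    read = lambda text: pd.read_csv(io.StringIO(text), sep="\t")
    return PaperFixture(
        table1=read(_TABLE1_TSV),
        table2=read(_TABLE2_TSV),
        table3=read(_TABLE3_TSV),
        step2=read(_STEP2_TSV),
    )


def config_from_dict(data: dict) -> SimulationConfig:
    """Build a :class:`SimulationConfig` from a parsed YAML/JSON mapping."""
    data = dict(data)
    if "pleiotropy" in data and isinstance(data["pleiotropy"], dict):
        data["pleiotropy"] = PleiotropyConfig(**data["pleiotropy"])
    if "maf_range" in data:
        data["maf_range"] = tuple(data["maf_range"])
    if "ld_blocks" in data and data["ld_blocks"] is not None:
        data["ld_blocks"] = [tuple(b) for b in data["ld_blocks"]]
    try:
        return SimulationConfig(**data)
    except TypeError as exc:
        raise ConfigurationError(str(exc)) from exc
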