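"""Instrument selection: p-value filter, greedy LD clumping, F-statistic filter."""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, NamedTuple

import pandas as pd

from .errors import ConfigurationError, NoInstrumentsError
from .sumstats import SummaryStatsTable, VariantAssociation

__all__ = [
    "LDPairTable",
    "InstrumentSelectionConfig",
    "SelectionLog",
    "SelectionResult",
    "f_statistic",
    "filter_by_pvalue",
    "filter_by_f",
    "ld_clump",
    "select_instruments",
]


@dataclass
class LDPairTable:
    """Symmetric lookup of pairwise r² between variants.

    Missing pairs are treated as r² = 0 (independent); ``lookup(a, a)`` is 1
    by convention.
    """

    _r2: dict[frozenset, float] = field(default_factory=dict)

    @classmethod
    def from_pairs(cls, pairs: Iterable[tuple[str, str, float]]) -> "LDPairTable":
        table = cls()
        for a, b, r2 in pairs:
            table.add(a, b, r2)
        return table

    @classmethod
    def from_tsv(cls, path: str | Path) -> "LDPairTable":
        df = pd.read_csv(path, sep="\t", dtype={"variant_a": str, "variant_b": str})
        return cls.from_pairs(
            zip(df["variant_a"], df["variant_b"], df["r2"].astype(float))
        )

    def add(self, a: str, b: str, r2: float) -> None:
        if not (0.0 <= r2 <= 1.0):
            raise ValueError(f"r2 {r2} outside [0, 1] for pair ({a}, {b})")
        if a == b:
            return
        self._r2[frozenset((a, b))] = r2

    def lookup(self, a: str, b: str) -> float:
        if a == b:
            return 1.0
        return self._r2.get(frozenset((a, b)), 0.0)

    def __len__(self) -> int:
        return len(self._r2)

    def to_tsv(self, path: str | Path) -> None:
        rows = [
            tuple(sorted(key)) + (r2,) for key, r2 in sorted(
                self._r2.items(), key=lambda kv: tuple(sorted(kv[0]))
            )
        ]
        pd.DataFrame(rows, columns=["variant_a", "variant_b", "r2"]).to_csv(
            path, sep="\t", index=False
        )


@dataclass(frozen=True)
class InstrumentSelectionConfig:
    """Thresholds for the three-stage instrument selection pipeline.

    ``f_formula`` selects how the per-SNP F-statistic is computed:
    ``"ratio_squared"`` for the conventional (beta/se)² (default) or
    ``"literal"`` for beta/se² (kept for auditability; not scale-invariant).
    """

    pval_threshold: float = 1e-5
    clump_r2: float = 0.001
    clump_window_kb: float = 10_000.0
    min_f: float = 10.0
    f_formula: str = "ratio_squared"

    def __post_init__(self) -> None:
        if not (0.0 < self.pval_threshold <= 1.0):
            raise ConfigurationError("pval_threshold must lie in (0, 1]")
        if not (0.0 < self.clump_r2 < 1.0):
            raise ConfigurationError("clump_r2 must lie in (0, 1)")
        if self.clump_window_kb <= 0:
            raise ConfigurationError("clump_window_kb must be positive")
        if self.min_f < 0:
            raise ConfigurationError("min_f must be nonnegative")
        if self.f_formula not in ("ratio_squared", "literal"):
            raise ConfigurationError(f"unknown f_formula {self.f_formula!r}")


def f_statistic(record: VariantAssociation, formula: str = "ratio_squared") -> float:
    """Single-SNP instrument-strength F-statistic.

    ``ratio_squared`` gives (beta/se)², sign-invariant in beta. The
    ``literal`` variant beta/se² is provided for auditing only.
    """
    if formula == "ratio_squared":
        return (record.beta / record.se) ** 2
    if formula == "literal":
        return record.beta / record.se**2
    raise ConfigurationError(f"unknown f_formula {formula!r}")


def filter_by_pvalue(table: SummaryStatsTable, threshold: float) -> SummaryStatsTable:
    """Keep records with pval strictly below ``threshold``; order preserved."""
    if not (0.0 < threshold <= 1.0):
        raise ConfigurationError("threshold must lie in (0, 1]")
    return SummaryStatsTable(
        table.trait_id,
        table.trait_label,
        [r for r in table if r.pval < threshold],
    )


def filter_by_f(
    table: SummaryStatsTable, min_f: float, formula: str = "ratio_squared"
) -> SummaryStatsTable:
    """Keep records whose F-statistic is >= ``min_f`` (exclusion is F < min_f)."""
    return SummaryStatsTable(
        table.trait_id,
        table.trait_label,
        [r for r in table if f_statistic(r, formula) >= min_f],
    )


def ld_clump(
    table: SummaryStatsTable,
    ld: LDPairTable,
    r2_thresh: float = 0.001,
    window_kb: float = 10_000.0,
) -> SummaryStatsTable:
    """Greedy LD clumping.

    Candidates are visited by ascending p-value (ties broken by
    ``variant_id``); each retained index SNP removes every remaining
    candidate on the same chromosome within ``window_kb`` whose r² with it
    is >= ``r2_thresh``. The result is returned in original table order and
    is therefore independent of input row order.
    """
    order = sorted(table, key=lambda r: (r.pval, r.variant_id))
    removed: set[str] = set()
    kept: set[str] = set()
    window_bp = window_kb * 1000.0
    for idx_snp in order:
        if idx_snp.variant_id in removed:
            continue
        kept.add(idx_snp.variant_id)
        for other in order:
            if other.variant_id in kept or other.variant_id in removed:
                continue
            if other.chrom != idx_snp.chrom:
                continue
            if abs(other.pos - idx_snp.pos) > window_bp:
                continue
            if ld.lookup(idx_snp.variant_id, other.variant_id) >= r2_thresh:
                removed.add(other.variant_id)
    return table.subset(kept)


@dataclass(frozen=True)
class SelectionLog:
    """Counts surviving each selection stage."""

    n_input: int
    n_after_pvalue: int
    n_after_clump: int
    n_after_f: int

    def counts(self) -> list[int]:
        return [self.n_input, self.n_after_pvalue, self.n_after_clump, self.n_after_f]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "stage": ["input", "pvalue", "clump", "fstat"],
                "n_retained": self.counts(),
            }
        )

    def write(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


class SelectionResult(NamedTuple):
    table: SummaryStatsTable
    log: SelectionLog


def select_instruments(
    table: SummaryStatsTable,
    ld: LDPairTable | None,
    cfg: InstrumentSelectionConfig = InstrumentSelectionConfig(),
) -> SelectionResult:
    """p-value filter, then LD clumping, then F-statistic filter.

    Raises
    ------
    NoInstrumentsError
        Naming the first stage that left zero survivors.
    """
    ld = ld if ld is not None else LDPairTable()
    after_p = filter_by_pvalue(table, cfg.pval_threshold)
    if len(after_p) == 0:
        raise NoInstrumentsError("pvalue")
    after_clump = ld_clump(after_p, ld, cfg.clump_r2, cfg.clump_window_kb)
    if len(after_clump) == 0:
        raise NoInstrumentsError("clump")
    after_f = filter_by_f(after_clump, cfg.min_f, cfg.f_formula)
    if len(after_f) == 0:
        raise NoInstrumentsError("fstat")
    log = SelectionLog(len(table), len(after_p), len(after_clump), len(after_f))
    return SelectionResult(after_f, log)
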