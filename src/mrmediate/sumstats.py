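"""GWAS summary-statistics data model, TSV I/O and allele harmonization.

The canonical file dialect is tab-separated with header::

    variant_id chrom pos effect_allele other_allele eaf beta se pval n

with ``NA`` as the missing token. Foreign headers are supported through a
``column_map`` passed to :func:`read_sumstats`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, NamedTuple

import pandas as pd

from .errors import ConfigurationError, NoSharedInstrumentsError

__all__ = [
    "VariantAssociation",
    "SummaryStatsTable",
    "HarmonizedInstrumentSet",
    "ReadResult",
    "CANONICAL_COLUMNS",
    "MISSING_TOKEN",
    "read_sumstats",
    "write_sumstats",
    "harmonize",
    "write_harmonized",
    "write_drop_log",
]

CANONICAL_COLUMNS = (
    "variant_id",
    "chrom",
    "pos",
    "effect_allele",
    "other_allele",
    "eaf",
    "beta",
    "se",
    "pval",
    "n",
)
MISSING_TOKEN = "NA"

_VALID_ALLELES = frozenset("ACGT")
_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}
_HARMONIZED_COLUMNS = (
    "variant_id",
    "beta_exp",
    "se_exp",
    "beta_out",
    "se_out",
    "eaf_exp",
    "eaf_out",
)


@dataclass(frozen=True)
class VariantAssociation:
    """One variant's association with one trait.

    Betas are per-effect-allele effects (log odds for binary traits).
    ``eaf`` and ``n`` may be ``None`` (missing).
    """

    variant_id: str
    chrom: str
    pos: int
    effect_allele: str
    other_allele: str
    eaf: float | None
    beta: float
    se: float
    pval: float
    n: int | None

    def __post_init__(self) -> None:
        if not self.variant_id:
            raise ValueError("empty variant_id")
        if self.pos < 1:
            raise ValueError(f"{self.variant_id}: pos must be >= 1")
        for name, allele in (
            ("effect_allele", self.effect_allele),
            ("other_allele", self.other_allele),
        ):
            if allele not in _VALID_ALLELES:
                raise ValueError(
                    f"{self.variant_id}: {name} {allele!r} is not a single "
                    "A/C/G/T base (indels and multi-allelic records rejected)"
                )
        if self.effect_allele == self.other_allele:
            raise ValueError(f"{self.variant_id}: effect_allele == other_allele")
        if self.eaf is not None and not (0.0 <= self.eaf <= 1.0):
            raise ValueError(f"{self.variant_id}: eaf outside [0, 1]")
        if not (self.se > 0):
            raise ValueError(f"{self.variant_id}: nonpositive se")
        if not (0.0 < self.pval <= 1.0):
            raise ValueError(f"{self.variant_id}: pval outside (0, 1]")
        if self.n is not None and self.n < 1:
            raise ValueError(f"{self.variant_id}: nonpositive n")

    def is_palindromic(self) -> bool:
        """True for strand-ambiguous A/T or C/G variants."""
        return self.other_allele == _COMPLEMENT[self.effect_allele]


@dataclass
class SummaryStatsTable:
    """Ordered collection of :class:`VariantAssociation` for one trait."""

    trait_id: str
    trait_label: str
    records: list[VariantAssociation] = field(default_factory=list)

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for rec in self.records:
            if rec.variant_id in seen:
                raise ValueError(f"duplicate variant_id {rec.variant_id!r}")
            seen.add(rec.variant_id)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[VariantAssociation]:
        return iter(self.records)

    def get(self, variant_id: str) -> VariantAssociation | None:
        for rec in self.records:
            if rec.variant_id == variant_id:
                return rec
        return None

    def subset(self, variant_ids: Iterable[str]) -> "SummaryStatsTable":
        """New table with only the named variants, original order preserved."""
        keep = set(variant_ids)
        return SummaryStatsTable(
            self.trait_id,
            self.trait_label,
            [r for r in self.records if r.variant_id in keep],
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "variant_id": r.variant_id,
                    "chrom": r.chrom,
                    "pos": r.pos,
                    "effect_allele": r.effect_allele,
                    "other_allele": r.other_allele,
                    "eaf": math.nan if r.eaf is None else r.eaf,
                    "beta": r.beta,
                    "se": r.se,
                    "pval": r.pval,
                    "n": math.nan if r.n is None else r.n,
                }
                for r in self.records
            ],
            columns=list(CANONICAL_COLUMNS),
        )


@dataclass
class HarmonizedInstrumentSet:
    """Allele-aligned per-SNP exposure and outcome effects ready for MR.

    ``rows`` is a DataFrame with columns
    ``variant_id beta_exp se_exp beta_out se_out eaf_exp eaf_out`` in which
    both betas refer to the exposure's effect allele. ``dropped`` records
    variants removed during harmonization with a reason each.
    """

    exposure_id: str
    outcome_id: str
    rows: pd.DataFrame
    dropped: list[tuple[str, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        missing = [c for c in _HARMONIZED_COLUMNS if c not in self.rows.columns]
        if missing:
            raise ValueError(f"harmonized rows missing columns {missing}")
        if len(self.rows) and not (
            (self.rows["se_exp"] > 0).all() and (self.rows["se_out"] > 0).all()
        ):
            raise ValueError("harmonized rows contain nonpositive standard errors")

    @property
    def nsnp(self) -> int:
        return len(self.rows)

    def subset(self, variant_ids: Iterable[str]) -> "HarmonizedInstrumentSet":
        keep = set(variant_ids)
        return HarmonizedInstrumentSet(
            self.exposure_id,
            self.outcome_id,
            self.rows[self.rows["variant_id"].isin(keep)].reset_index(drop=True),
            list(self.dropped),
        )


class ReadResult(NamedTuple):
    table: SummaryStatsTable
    rejected: list[tuple[int, str]]  # (1-based data-row number, reason)


def _parse_float(value: str, allow_missing: bool = False) -> float | None:
    if value == MISSING_TOKEN or value == "":
        if allow_missing:
            return None
        raise ValueError("missing value")
    return float(value)


def _parse_int(value: str, allow_missing: bool = False) -> int | None:
    if value == MISSING_TOKEN or value == "":
        if allow_missing:
            return None
        raise ValueError("missing value")
    f = float(value)
    i = int(f)
    if i != f:
        raise ValueError(f"not an integer: {value!r}")
    return i


def read_sumstats(
    path: str | Path,
    column_map: dict[str, str] | None = None,
    trait_id: str | None = None,
    trait_label: str | None = None,
    sep: str = "\t",
) -> ReadResult:
    """Read a summary-statistics table from delimited text.

    Parameters
    ----------
    path
        Delimited text file with a header row.
    column_map
        Optional mapping from file column names to canonical field names,
        e.g. ``{"b": "beta"}``. Unmapped canonical names are looked up
        verbatim.
    trait_id, trait_label
        Identifiers for the trait; default to the file stem.

    Returns
    -------
    ReadResult
        The table plus per-row rejection diagnostics. Rows failing numeric
        parsing or an invariant check are rejected individually; a missing
        mandatory column raises :class:`ConfigurationError`.
    """
    path = Path(path)
    column_map = dict(column_map or {})
    with path.open() as fh:
        header = fh.readline().rstrip("\n").split(sep)
        name_for = {column_map.get(col, col): idx for idx, col in enumerate(header)}
        mandatory = [c for c in CANONICAL_COLUMNS if c not in ("eaf", "n")]
        missing = [c for c in mandatory if c not in name_for]
        if missing:
            raise ConfigurationError(
                f"{path}: missing mandatory column(s) {missing}; "
                f"header was {header}"
            )
        has_eaf = "eaf" in name_for
        has_n = "n" in name_for

        records: list[VariantAssociation] = []
        rejected: list[tuple[int, str]] = []
        seen: set[str] = set()
        for row_no, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split(sep)
            try:
                vid = fields[name_for["variant_id"]]
                if vid in seen:
                    raise ValueError(f"{vid}: duplicate variant_id")
                rec = VariantAssociation(
                    variant_id=vid,
                    chrom=fields[name_for["chrom"]],
                    pos=_parse_int(fields[name_for["pos"]]),
                    effect_allele=fields[name_for["effect_allele"]].upper(),
                    other_allele=fields[name_for["other_allele"]].upper(),
                    eaf=_parse_float(fields[name_for["eaf"]], True) if has_eaf else None,
                    beta=_parse_float(fields[name_for["beta"]]),
                    se=_parse_float(fields[name_for["se"]]),
                    pval=_parse_float(fields[name_for["pval"]]),
                    n=_parse_int(fields[name_for["n"]], True) if has_n else None,
                )
            except (ValueError, IndexError) as exc:
                rejected.append((row_no, str(exc)))
                continue
            seen.add(rec.variant_id)
            records.append(rec)

    stem = path.stem
    table = SummaryStatsTable(trait_id or stem, trait_label or stem, records)
    return ReadResult(table, rejected)


def _fmt(value: float | int | str | None) -> str:
    if value is None:
        return MISSING_TOKEN
    if isinstance(value, float):
        return repr(value)  # shortest round-tripping representation
    return str(value)


def write_sumstats(table: SummaryStatsTable, path: str | Path) -> None:
    """Write a table in the canonical TSV dialect (round-trips exactly)."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write("\t".join(CANONICAL_COLUMNS) + "\n")
        for r in table:
            fh.write(
                "\t".join(
                    [
                        r.variant_id,
                        r.chrom,
                        str(r.pos),
                        r.effect_allele,
                        r.other_allele,
                        _fmt(r.eaf),
                        _fmt(r.beta),
                        _fmt(r.se),
                        _fmt(r.pval),
                        _fmt(r.n),
                    ]
                )
                + "\n"
            )


def _align_outcome(
    exp: VariantAssociation, out: VariantAssociation
) -> tuple[str, float, float | None] | None:
    """Work out how the outcome record maps onto the exposure's alleles.

    Returns ``(action, beta_out, eaf_out)`` with action ``"keep"`` or
    ``"flip"``, or ``None`` when the allele sets cannot be reconciled.
    Palindromic variants are handled by the caller.
    """
    ea, oa = exp.effect_allele, exp.other_allele
    pairs = {
        (ea, oa): "keep",
        (oa, ea): "flip",
        (_COMPLEMENT[ea], _COMPLEMENT[oa]): "keep",  # strand flip
        (_COMPLEMENT[oa], _COMPLEMENT[ea]): "flip",
    }
    action = pairs.get((out.effect_allele, out.other_allele))
    if action is None:
        return None
    if action == "keep":
        return "keep", out.beta, out.eaf
    eaf = None if out.eaf is None else 1.0 - out.eaf
    return "flip", -out.beta, eaf


def harmonize(
    exposure: SummaryStatsTable,
    outcome: SummaryStatsTable,
    palindrome_policy: str = "infer_by_eaf",
    eaf_threshold: float = 0.08,
) -> HarmonizedInstrumentSet:
    """Align outcome effects to the exposure's effect alleles.

    Only variants present in both tables are kept. When the outcome's
    alleles are swapped relative to the exposure (directly or after strand
    complementation) the outcome beta is negated and its eaf replaced by
    ``1 - eaf``. Strand-ambiguous (A/T, C/G) variants are dropped under
    ``palindrome_policy="drop_all"``; under ``"infer_by_eaf"`` they are
    oriented by comparing both eafs to 0.5 and dropped as ambiguous when
    either eaf lies within ``eaf_threshold`` of 0.5 or is missing.

    Raises
    ------
    NoSharedInstrumentsError
        When the two tables share no variant.
    """
    if palindrome_policy not in ("drop_all", "infer_by_eaf"):
        raise ConfigurationError(
            f"unknown palindrome_policy {palindrome_policy!r}"
        )
    out_by_id = {r.variant_id: r for r in outcome}
    shared = [r for r in exposure if r.variant_id in out_by_id]
    if not shared:
        raise NoSharedInstrumentsError(
            f"no shared instruments between {exposure.trait_id!r} "
            f"and {outcome.trait_id!r}"
        )

    rows: list[dict] = []
    dropped: list[tuple[str, str]] = []
    for exp in shared:
        out = out_by_id[exp.variant_id]
        if exp.is_palindromic() or out.is_palindromic():
            if palindrome_policy == "drop_all":
                dropped.append((exp.variant_id, "palindrome"))
                continue
            if exp.eaf is None or out.eaf is None:
                dropped.append((exp.variant_id, "palindrome missing eaf"))
                continue
            if (
                abs(exp.eaf - 0.5) < eaf_threshold
                or abs(out.eaf - 0.5) < eaf_threshold
            ):
                dropped.append((exp.variant_id, "ambiguous palindrome"))
                continue
            # Orient by allele-frequency agreement: matched sides of 0.5
            # mean the stated effect alleles refer to the same allele.
            if (exp.eaf < 0.5) == (out.eaf < 0.5):
                beta_out, eaf_out = out.beta, out.eaf
            else:
                beta_out, eaf_out = -out.beta, 1.0 - out.eaf
        else:
            aligned = _align_outcome(exp, out)
            if aligned is None:
                dropped.append((exp.variant_id, "allele mismatch"))
                continue
            _, beta_out, eaf_out = aligned
        rows.append(
            {
                "variant_id": exp.variant_id,
                "beta_exp": exp.beta,
                "se_exp": exp.se,
                "beta_out": beta_out,
                "se_out": out.se,
                "eaf_exp": math.nan if exp.eaf is None else exp.eaf,
                "eaf_out": math.nan if eaf_out is None else eaf_out,
            }
        )

    frame = pd.DataFrame(rows, columns=list(_HARMONIZED_COLUMNS))
    return HarmonizedInstrumentSet(exposure.trait_id, outcome.trait_id, frame, dropped)


def write_harmonized(hset: HarmonizedInstrumentSet, path: str | Path) -> None:
    hset.rows.to_csv(path, sep="\t", index=False, na_rep=MISSING_TOKEN)


def write_drop_log(hset: HarmonizedInstrumentSet, path: str | Path) -> None:
    pd.DataFrame(hset.dropped, columns=["variant_id", "reason"]).to_csv(
        path, sep="\t", index=False
    )
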