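"""SNP catalog ingest, locus assignment, LD pruning and time-point panels.

A genetic-risk panel at a time point is the set of genome-wide-significant
SNPs reported up to that date, grouped into loci (single-linkage chains of
SNPs within a base-pair window on one chromosome) and greedily pruned so
that no two retained SNPs at a locus are in strong linkage disequilibrium.
When the same SNP is reported more than once, the effective odds ratio at a
time point comes from the most significant report published by then.
"""

from __future__ import annotations

import datetime
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "GENOME_WIDE_ALPHA",
    "LOCUS_WINDOW_BP",
    "R2_PRUNE_DEFAULT",
    "SnpRecord",
    "Locus",
    "LdTable",
    "TimePointPanel",
    "CatalogFormatError",
    "CatalogValidationError",
    "read_catalog",
    "assign_loci",
    "prune_locus",
    "build_panels",
]

#: conventional genome-wide significance threshold for common-variant GWAS
GENOME_WIDE_ALPHA = 5e-8
#: SNPs within this distance of each other belong to the same locus
LOCUS_WINDOW_BP = 500_000
#: default r-squared ceiling for stepwise LD pruning
R2_PRUNE_DEFAULT = 0.75

REQUIRED_COLUMNS = (
    "rsid",
    "chrom",
    "pos",
    "risk_allele",
    "raf",
    "or",
    "pvalue",
    "report_date",
    "source",
)
OPTIONAL_COLUMNS = ("n_cases", "n_controls")


class CatalogFormatError(ValueError):
    """The catalog file does not conform to the expected column dialect."""


class CatalogValidationError(ValueError):
    """A catalog row violates a field invariant (bad frequency, OR, ...)."""


@dataclass(frozen=True)
class SnpRecord:
    """One published SNP-disease association.

    ``raf`` is the risk-allele frequency and ``odds_ratio`` the per-allele
    effect; ``beta`` is its natural log. Records are normally oriented at
    ingest so the stored odds ratio is >= 1 (see :meth:`oriented`).
    """

    rsid: str
    chromosome: str
    position_bp: int
    risk_allele: str
    raf: float
    odds_ratio: float
    p_value: float
    report_date: datetime.date
    source: str
    n_cases: int | None = None
    n_controls: int | None = None

    def __post_init__(self) -> None:
        if not (0.0 < self.raf < 1.0):
            raise CatalogValidationError(
                f"{self.rsid}: risk-allele frequency {self.raf} outside (0, 1)"
            )
        if not self.odds_ratio > 0.0:
            raise CatalogValidationError(
                f"{self.rsid}: odds ratio {self.odds_ratio} must be > 0"
            )
        if not (0.0 < self.p_value < 1.0):
            raise CatalogValidationError(
                f"{self.rsid}: p-value {self.p_value} outside (0, 1)"
            )
        if self.position_bp < 1:
            raise CatalogValidationError(
                f"{self.rsid}: position {self.position_bp} must be >= 1"
            )
        for name in ("n_cases", "n_controls"):
            value = getattr(self, name)
            if value is not None and value <= 0:
                raise CatalogValidationError(f"{self.rsid}: {name} must be positive")

    @property
    def beta(self) -> float:
        """Per-allele log odds ratio."""
        return math.log(self.odds_ratio)

    def oriented(self) -> "SnpRecord":
        """Return a copy oriented to the risk allele (odds ratio >= 1).

        A reported OR below 1 describes a protective allele; flipping to the
        other allele (OR -> 1/OR, frequency -> 1 - frequency) makes the
        genotype dosage count risk alleles, as the multiplicative odds model
        assumes.
        """
        if self.odds_ratio >= 1.0:
            return self
        return replace(
            self,
            risk_allele=f"not({self.risk_allele})",
            raf=1.0 - self.raf,
            odds_ratio=1.0 / self.odds_ratio,
        )


@dataclass(frozen=True)
class Locus:
    """A single-linkage chain of SNPs on one chromosome."""

    locus_id: str
    chromosome: str
    snps: tuple[SnpRecord, ...]

    def __post_init__(self) -> None:
        chroms = {s.chromosome for s in self.snps}
        if chroms and chroms != {self.chromosome}:
            raise ValueError(f"locus {self.locus_id}: members span chromosomes {chroms}")
        positions = [s.position_bp for s in self.snps]
        if positions != sorted(positions):
            object.__setattr__(
                self, "snps", tuple(sorted(self.snps, key=lambda s: s.position_bp))
            )

    @property
    def rsids(self) -> tuple[str, ...]:
        return tuple(s.rsid for s in self.snps)

    def __len__(self) -> int:
        return len(self.snps)


class LdTable:
    """Symmetric pairwise r² lookup for SNPs.

    Missing pairs raise ``KeyError`` rather than defaulting to zero: silently
    assuming linkage equilibrium would under-prune.
    """

    def __init__(self, pairs: Mapping[tuple[str, str], float] | None = None) -> None:
        self._r2: dict[frozenset, float] = {}
        if pairs:
            for (a, b), r2 in pairs.items():
                self.add(a, b, r2)

    def add(self, rsid_a: str, rsid_b: str, r2: float) -> None:
        if not (0.0 <= r2 <= 1.0):
            raise ValueError(f"r2({rsid_a},{rsid_b}) = {r2} outside [0, 1]")
        self._r2[frozenset((rsid_a, rsid_b))] = float(r2)

    def r2(self, rsid_a: str, rsid_b: str) -> float:
        if rsid_a == rsid_b:
            return 1.0
        key = frozenset((rsid_a, rsid_b))
        try:
            return self._r2[key]
        except KeyError:
            raise KeyError(
                f"no r2 value for pair ({rsid_a}, {rsid_b}); "
                "LD table must cover all within-locus pairs"
            ) from None

    def __len__(self) -> int:
        return len(self._r2)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "LdTable":
        df = pd.read_csv(path, sep="\t", dtype={"rsid_a": str, "rsid_b": str})
        missing = {"rsid_a", "rsid_b", "r2"} - set(df.columns)
        if missing:
            raise CatalogFormatError(f"LD table {path} missing columns: {sorted(missing)}")
        table = cls()
        for row in df.itertuples(index=False):
            table.add(row.rsid_a, row.rsid_b, float(row.r2))
        return table

    def to_tsv(self, path: str | Path) -> None:
        rows = []
        for key, r2 in sorted(self._r2.items(), key=lambda kv: sorted(kv[0])):
            a, b = sorted(key)
            rows.append((a, b, r2))
        pd.DataFrame(rows, columns=["rsid_a", "rsid_b", "r2"]).to_csv(
            path, sep="\t", index=False
        )


@dataclass(frozen=True)
class TimePointPanel:
    """The LD-pruned risk panel in effect at one time point.

    ``snps`` carry the effective odds ratio at this time point: the OR from
    the most significant report published on or before the panel date.
    """

    tag: str
    date: datetime.date
    snps: tuple[SnpRecord, ...]

    @property
    def k(self) -> int:
        """Number of SNPs in the panel."""
        return len(self.snps)

    @property
    def rsids(self) -> tuple[str, ...]:
        return tuple(s.rsid for s in self.snps)

    @property
    def betas(self) -> np.ndarray:
        return np.array([s.beta for s in self.snps], dtype=float)

    def __len__(self) -> int:
        return len(self.snps)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "rsid": [s.rsid for s in self.snps],
                "chrom": [s.chromosome for s in self.snps],
                "pos": [s.position_bp for s in self.snps],
                "risk_allele": [s.risk_allele for s in self.snps],
                "raf": [s.raf for s in self.snps],
                "or": [s.odds_ratio for s in self.snps],
                "pvalue": [s.p_value for s in self.snps],
                "report_date": [s.report_date.isoformat() for s in self.snps],
                "source": [s.source for s in self.snps],
                "n_cases": [s.n_cases for s in self.snps],
                "n_controls": [s.n_controls for s in self.snps],
            }
        )

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path, tag: str | None = None) -> "TimePointPanel":
        records = read_catalog(path, alpha=1.0 - 1e-16, orient_risk=False)
        date = max((r.report_date for r in records), default=datetime.date.today())
        return cls(tag=tag or str(path), date=date, snps=tuple(records))


def _parse_date(value) -> datetime.date:
    if isinstance(value, datetime.date):
        return value
    return datetime.date.fromisoformat(str(value))


def read_catalog(
    path: str | Path,
    alpha: float = GENOME_WIDE_ALPHA,
    orient_risk: bool = True,
) -> list[SnpRecord]:
    """Read a tab-separated SNP catalog, keeping rows with ``pvalue < alpha``.

    Parameters
    ----------
    path
        TSV with header columns
        ``rsid chrom pos risk_allele raf or pvalue report_date source``
        and optional ``n_cases``/``n_controls``.
    alpha
        Significance cutoff; rows at or above it are dropped.
    orient_risk
        Flip records with OR < 1 to the risk allele (see
        :meth:`SnpRecord.oriented`).

    Raises
    ------
    CatalogFormatError
        If a required column is absent.
    CatalogValidationError
        If a retained row violates a field invariant; the message names the
        offending rsid and row.
    """
    df = pd.read_csv(path, sep="\t", dtype={"rsid": str, "chrom": str})
    missing = set(REQUIRED_COLUMNS) - set(df.columns)
    if missing:
        raise CatalogFormatError(f"catalog {path} missing columns: {sorted(missing)}")
    # "or" is a Python keyword, which itertuples would mangle
    df = df.rename(columns={"or": "odds_ratio"})
    records: list[SnpRecord] = []
    for i, row in enumerate(df.itertuples(index=False)):
        pvalue = float(getattr(row, "pvalue"))
        if not pvalue < alpha:
            continue
        try:
            rec = SnpRecord(
                rsid=str(row.rsid),
                chromosome=str(row.chrom),
                position_bp=int(row.pos),
                risk_allele=str(row.risk_allele),
                raf=float(row.raf),
                odds_ratio=float(row.odds_ratio),
                p_value=pvalue,
                report_date=_parse_date(row.report_date),
                source=str(row.source),
                n_cases=_opt_int(getattr(row, "n_cases", None)),
                n_controls=_opt_int(getattr(row, "n_controls", None)),
            )
        except CatalogValidationError as exc:
            raise CatalogValidationError(f"row {i + 2} of {path}: {exc}") from exc
        records.append(rec.oriented() if orient_risk else rec)
    return records


def _opt_int(value) -> int | None:
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return None
    return int(value)


def assign_loci(
    records: Sequence[SnpRecord], window_bp: int = LOCUS_WINDOW_BP
) -> list[Locus]:
    """Partition SNPs into loci by single-linkage chaining.

    SNPs on the same chromosome whose sorted positions have adjacent gaps of
    at most ``window_bp`` form one locus. Loci are returned sorted by
    chromosome label then leftmost position.
    """
    by_chrom: dict[str, list[SnpRecord]] = {}
    for rec in records:
        by_chrom.setdefault(rec.chromosome, []).append(rec)
    loci: list[Locus] = []
    for chrom in sorted(by_chrom):
        members = sorted(by_chrom[chrom], key=lambda s: (s.position_bp, s.rsid))
        start = 0
        for i in range(1, len(members) + 1):
            if i == len(members) or (
                members[i].position_bp - members[i - 1].position_bp > window_bp
            ):
                chunk = members[start:i]
                loci.append(
                    Locus(
                        locus_id=f"{chrom}:{chunk[0].position_bp}",
                        chromosome=chrom,
                        snps=tuple(chunk),
                    )
                )
                start = i
    return loci


def prune_locus(
    locus: Locus, ld: LdTable, r2_max: float = R2_PRUNE_DEFAULT
) -> list[SnpRecord]:
    """Greedy stepwise LD pruning of one locus.

    Candidates are visited in order of ascending p-value (ties broken by
    position then rsid) and retained iff their r² with every already-retained
    SNP is strictly below ``r2_max``. ``r2_max >= 1`` retains every SNP
    (the no-pruning sensitivity endpoint); ``r2_max = 0`` retains exactly
    the top SNP.
    """
    ordered = sorted(locus.snps, key=lambda s: (s.p_value, s.position_bp, s.rsid))
    if r2_max >= 1.0:
        return ordered
    kept: list[SnpRecord] = []
    for cand in ordered:
        if all(ld.r2(cand.rsid, k.rsid) < r2_max for k in kept):
            kept.append(cand)
    return kept


def _effective_record(reports: list[SnpRecord]) -> SnpRecord:
    # most significant report wins; a tie in p keeps the earlier report
    return min(reports, key=lambda r: (r.p_value, r.report_date, r.source))


def build_panels(
    records: Sequence[SnpRecord],
    time_points: Sequence[datetime.date | str],
    ld: LdTable | None = None,
    r2_max: float = R2_PRUNE_DEFAULT,
    window_bp: int = LOCUS_WINDOW_BP,
) -> list[TimePointPanel]:
    """Assemble the cumulative, LD-pruned panel at each time point.

    At time point ``m`` the panel contains every SNP with at least one
    report dated on or before ``m``; its effective OR (and p-value, used for
    pruning order) comes from the most significant such report. Re-reports
    replace the OR only when strictly more significant.

    ``ld`` may be omitted when every locus is a single SNP.
    """
    dates = [_parse_date(t) for t in time_points]
    if any(b <= a for a, b in zip(dates, dates[1:])):
        raise ValueError("time points must be strictly increasing")
    seen: set[tuple[str, datetime.date, str]] = set()
    for rec in records:
        key = (rec.rsid, rec.report_date, rec.source)
        if key in seen:
            raise ValueError(f"duplicate catalog row for {key}")
        seen.add(key)
    by_rsid: dict[str, list[SnpRecord]] = {}
    for rec in records:
        by_rsid.setdefault(rec.rsid, []).append(rec)
    ld = ld if ld is not None else LdTable()

    panels: list[TimePointPanel] = []
    for date in dates:
        effective: list[SnpRecord] = []
        for reports in by_rsid.values():
            eligible = [r for r in reports if r.report_date <= date]
            if eligible:
                effective.append(_effective_record(eligible))
        loci = assign_loci(effective, window_bp=window_bp)
        retained: list[SnpRecord] = []
        for locus in loci:
            retained.extend(prune_locus(locus, ld, r2_max=r2_max))
        retained.sort(key=lambda s: (s.chromosome, s.position_bp, s.rsid))
        panels.append(TimePointPanel(tag=date.isoformat(), date=date, snps=tuple(retained)))
    return panels
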