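"""Shared builders and small brute-force oracles for the test suite."""

from __future__ import annotations

import datetime
import itertools
import math

import numpy as np

from riskdrift import SnpRecord, TimePointPanel


def make_snp(
    rsid: str,
    raf: float = 0.3,
    odds_ratio: float = 1.2,
    chrom: str = "1",
    pos: int = 1_000_000,
    p_value: float = 1e-9,
    report_date: str = "2013-01-01",
    source: str = "study",
    n_cases: int | None = None,
    n_controls: int | None = None,
) -> SnpRecord:
    return SnpRecord(
        rsid=rsid,
        chromosome=chrom,
        position_bp=pos,
        risk_allele="A",
        raf=raf,
        odds_ratio=odds_ratio,
        p_value=p_value,
        report_date=datetime.date.fromisoformat(report_date),
        source=source,
        n_cases=n_cases,
        n_controls=n_controls,
    )


def make_panel(specs, tag="panel", date="2013-12-31") -> TimePointPanel:
    """Panel from (rsid, raf, OR) triples; each SNP on its own chromosome."""
    snps = tuple(
        make_snp(rsid, raf=raf, odds_ratio=orr, chrom=str(i + 1), pos=1_000_000)
        for i, (rsid, raf, orr) in enumerate(specs)
    )
    return TimePointPanel(tag=tag, date=datetime.date.fromisoformat(date), snps=snps)


def brute_force_distribution(specs):
    """Enumerate normalised odds for independent HWE SNPs in plain Python.

    ``specs`` is a list of (raf, OR); returns (odds, control_pmf, case_pmf)
    sorted by odds value. Independent of the package's convolution path.
    """
    states = []
    for genotypes in itertools.product(range(3), repeat=len(specs)):
        prob = 1.0
        odds = 1.0
        for g, (q, orr) in zip(genotypes, specs):
            hwe = [(1 - q) ** 2, 2 * q * (1 - q), q * q][g]
            prob *= hwe
            odds *= orr**g
        states.append((odds, prob))
    mean = sum(o * p for o, p in states)
    collapsed: dict[float, float] = {}
    for o, p in states:
        key = round(o / mean, 10)
        collapsed[key] = collapsed.get(key, 0.0) + p
    odds = np.array(sorted(collapsed))
    control = np.array([collapsed[o] for o in odds])
    case = odds * control
    case = case / case.sum()
    return odds, control, case


def brute_force_joint(specs_a, specs_b, union):
    """Joint normalised odds under two OR maps over shared HWE genotypes.

    ``union`` is a list of (rsid, raf); ``specs_a``/``specs_b`` map rsid to
    OR (absent rsid = OR 1). Returns (odds_a, odds_b, prob) arrays over all
    genotype combinations, normalised by each panel's exact mean.
    """
    rows = []
    for genotypes in itertools.product(range(3), repeat=len(union)):
        prob, oa, ob = 1.0, 1.0, 1.0
        for g, (rsid, q) in zip(genotypes, union):
            prob *= [(1 - q) ** 2, 2 * q * (1 - q), q * q][g]
            oa *= specs_a.get(rsid, 1.0) ** g
            ob *= specs_b.get(rsid, 1.0) ** g
        rows.append((oa, ob, prob))
    oa = np.array([r[0] for r in rows])
    ob = np.array([r[1] for r in rows])
    p = np.array([r[2] for r in rows])
    return oa / (p @ oa), ob / (p @ ob), p
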