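"""Synthetic GWAS universes, discovery timelines, and LD fixtures.

Everything the real analysis would download is generated here instead: a
"true" universe of causal susceptibility SNPs with log odds ratios and
allele frequencies, a multi-time-point discovery timeline in which each
SNP is reported once a study has the power to detect it, and haplotype
fixtures with controllable linkage disequilibrium for multi-SNP loci.

The timeline emulates the accumulation of genome-wide-significant hits
over successive catalog snapshots: four time points with geometrically
growing sample sizes by default, so the later intervals sit in the
"tipping point" regime where many small-effect SNPs cross the
significance threshold at once. Reported effect sizes can optionally carry
winner's curse (the effect estimate resampled from its sampling
distribution truncated to significance), which biases early, underpowered
reports upward.
"""

from __future__ import annotations

import datetime
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .catalog import GENOME_WIDE_ALPHA
from .cohort import HaplotypeModel
from .projection import StudyDesign, detection_power

__all__ = [
    "SyntheticUniverse",
    "DiscoverySchedule",
    "make_universe",
    "default_schedule",
    "simulate_discovery",
    "make_ld_fixture",
    "write_catalog_tsv",
    "write_haplotype_fixture",
]

_CHROMOSOMES = [str(c) for c in range(1, 23)]
#: within-chromosome spacing of causal SNPs; > the 500 kb locus window, so
#: distinct causal SNPs land in distinct loci by default
_SPACING_BP = 2_000_000


@dataclass(frozen=True)
class SyntheticUniverse:
    """A true universe of causal SNPs with their effects and frequencies."""

    frame: pd.DataFrame
    params: dict
    seed: int | None

    @property
    def n(self) -> int:
        return len(self.frame)

    @property
    def betas(self) -> np.ndarray:
        return self.frame["beta"].to_numpy()

    @property
    def freqs(self) -> np.ndarray:
        return self.frame["q"].to_numpy()

    def to_manifest(self, path: str | Path) -> None:
        payload = {
            "params": self.params,
            "seed": self.seed,
            "snps": self.frame.to_dict(orient="records"),
        }
        Path(path).write_text(json.dumps(payload, indent=1))


@dataclass(frozen=True)
class DiscoverySchedule:
    """Ordered discovery time points with cumulative study designs."""

    time_points: tuple[tuple[datetime.date, StudyDesign], ...]
    alpha: float = GENOME_WIDE_ALPHA

    def __post_init__(self) -> None:
        dates = [d for d, _ in self.time_points]
        if any(b <= a for a, b in zip(dates, dates[1:])):
            raise ValueError("schedule dates must be strictly increasing")
        sizes = [(des.n_cases, des.n_controls) for _, des in self.time_points]
        if any(
            b[0] < a[0] or b[1] < a[1] for a, b in zip(sizes, sizes[1:])
        ):
            raise ValueError("cumulative sample sizes must be non-decreasing")

    @property
    def dates(self) -> list[datetime.date]:
        return [d for d, _ in self.time_points]


def default_schedule() -> DiscoverySchedule:
    """Four snapshots (end of 2007/2009/2011/2013) with geometric growth.

    Cumulative per-arm sizes 2,000 / 5,000 / 12,000 / 30,000 put the mean
    synthetic effect (OR around 1.1) near 50% power only at the last time
    point, so discoveries accelerate late — the regime in which panel
    growth and reclassification stay high.
    """
    sizes = (2_000, 5_000, 12_000, 30_000)
    years = (2007, 2009, 2011, 2013)
    return DiscoverySchedule(
        time_points=tuple(
            (datetime.date(y, 12, 31), StudyDesign(n_cases=s, n_controls=s))
            for y, s in zip(years, sizes)
        )
    )


def make_universe(
    n_causal: int = 300,
    effect_floor: float = math.log(1.03),
    effect_scale: float = 0.045,
    maf_range: tuple[float, float] = (0.05, 0.95),
    seed: int | None = None,
) -> SyntheticUniverse:
    """Draw a polygenic universe of causal SNPs.

    Log odds ratios are ``effect_floor`` plus an Exponential(effect_scale)
    tail — most ORs between 1.03 and 1.25, a thinning tail of larger
    effects, consistent with a polygenic architecture of many small
    effects. The defaults keep the cumulative log-odds spread of a
    discovered panel in the regime of published common-disease risk models
    (panel AUCs roughly 0.6-0.75), where widening the risk distribution
    still grows the extreme tiers. Risk-allele frequencies are uniform on
    ``maf_range``. Deterministic given the seed, with SNPs laid out in a
    fixed order on chromosomes 1-22 at 2 Mb spacing (each causal SNP its
    own locus).
    """
    if n_causal < 0:
        raise ValueError("n_causal must be >= 0")
    lo, hi = maf_range
    if not (0.0 < lo < hi < 1.0):
        raise ValueError("maf_range must satisfy 0 < lo < hi < 1")
    if effect_scale <= 0 or effect_floor < 0:
        raise ValueError("effect distribution parameters must be positive")
    rng = np.random.default_rng(seed)
    betas = effect_floor + rng.exponential(effect_scale, size=n_causal)
    qs = rng.uniform(lo, hi, size=n_causal)
    chroms = [_CHROMOSOMES[i % len(_CHROMOSOMES)] for i in range(n_causal)]
    positions = [
        1_000_000 + (i // len(_CHROMOSOMES)) * _SPACING_BP for i in range(n_causal)
    ]
    frame = pd.DataFrame(
        {
            "rsid": [f"rs{i + 1:06d}" for i in range(n_causal)],
            "chrom": chroms,
            "pos": positions,
            "beta": betas,
            "q": qs,
        }
    )
    return SyntheticUniverse(
        frame=frame,
        params={
            "n_causal": n_causal,
            "effect_floor": effect_floor,
            "effect_scale": effect_scale,
            "maf_range": list(maf_range),
        },
        seed=seed,
    )


def _truncated_z(
    ncp: np.ndarray, z_crit: float, rng: np.random.Generator
) -> np.ndarray:
    """Draw Wald z-statistics conditional on two-sided significance.

    z ~ Normal(ncp, 1) given |z| > z_crit: pick the tail with probability
    proportional to its mass, then draw from the one-sided truncation.
    """
    ncp = np.asarray(ncp, dtype=float)
    upper_mass = stats.norm.sf(z_crit - ncp)
    lower_mass = stats.norm.cdf(-z_crit - ncp)
    take_upper = rng.random(ncp.shape) < upper_mass / (upper_mass + lower_mass)
    z = np.empty(ncp.shape)
    if take_upper.any():
        a = z_crit - ncp[take_upper]
        z[take_upper] = stats.truncnorm.rvs(
            a, np.inf, loc=ncp[take_upper], scale=1.0, random_state=rng
        )
    if (~take_upper).any():
        b = -z_crit - ncp[~take_upper]
        z[~take_upper] = stats.truncnorm.rvs(
            -np.inf, b, loc=ncp[~take_upper], scale=1.0, random_state=rng
        )
    return z


def _beta_se(beta: np.ndarray, q: np.ndarray, design: StudyDesign) -> np.ndarray:
    orr = np.exp(beta)
    q_case = q * orr / (1.0 - q + q * orr)
    return np.sqrt(
        1.0 / (2.0 * design.n_cases * q_case * (1.0 - q_case))
        + 1.0 / (2.0 * design.n_controls * q * (1.0 - q))
    )


def simulate_discovery(
    universe: SyntheticUniverse,
    schedule: DiscoverySchedule | None = None,
    winners_curse: bool = False,
    seed: int | None = None,
) -> pd.DataFrame:
    """Simulate the catalog rows produced by the discovery timeline.

    At each time point, each not-yet-discovered causal SNP is reported with
    probability equal to its detection power under the cumulative design.
    The reported z-statistic is drawn from the Wald sampling distribution
    truncated to significance (so reported p-values always pass the
    genome-wide filter); the reported OR is the true ``exp(beta)`` unless
    ``winners_curse`` is on, in which case it is ``exp(z * SE)`` — upwardly
    biased for underpowered effects. Already-discovered SNPs are
    re-reported at every later time point under the larger design, so
    effect estimates are refreshed by the catalog's most-significant-report
    rule.

    Returns a catalog-dialect DataFrame of all report rows.
    """
    schedule = schedule or default_schedule()
    rng = np.random.default_rng(seed)
    betas = universe.betas
    qs = universe.freqs
    discovered = np.zeros(universe.n, dtype=bool)
    rows: list[dict] = []
    z_crit = float(stats.norm.isf(schedule.alpha / 2.0))
    for date, design in schedule.time_points:
        power = np.atleast_1d(detection_power(betas, qs, design)) if universe.n else np.array([])
        newly = (~discovered) & (rng.random(universe.n) < power)
        reporting = newly | discovered
        idx = np.flatnonzero(reporting)
        if idx.size:
            se = _beta_se(betas[idx], qs[idx], design)
            z = _truncated_z(betas[idx] / se, z_crit, rng)
            pvals = np.clip(2.0 * stats.norm.sf(np.abs(z)), 1e-300, None)
            reported_or = np.exp(z * se) if winners_curse else np.exp(betas[idx])
            for j, i in enumerate(idx):
                snp = universe.frame.iloc[i]
                rows.append(
                    {
                        "rsid": snp["rsid"],
                        "chrom": snp["chrom"],
                        "pos": int(snp["pos"]),
                        "risk_allele": "A",
                        "raf": float(snp["q"]),
                        "or": float(reported_or[j]),
                        "pvalue": float(pvals[j]),
                        "report_date": date.isoformat(),
                        "source": f"synth_gwas_{date.year}",
                        "n_cases": design.n_cases,
                        "n_controls": design.n_controls,
                    }
                )
        discovered |= newly
    return pd.DataFrame(
        rows,
        columns=[
            "rsid",
            "chrom",
            "pos",
            "risk_allele",
            "raf",
            "or",
            "pvalue",
            "report_date",
            "source",
            "n_cases",
            "n_controls",
        ],
    )


def write_catalog_tsv(catalog: pd.DataFrame, path: str | Path) -> None:
    """Write catalog rows in the tab-separated catalog dialect."""
    catalog.to_csv(path, sep="\t", index=False)


def make_ld_fixture(
    n_snps: int,
    r2_target: float,
    freqs: float | Sequence[float],
    snp_ids: Sequence[str] | None = None,
) -> HaplotypeModel:
    """Construct a haplotype model whose adjacent-pair r² hits a target.

    Haplotypes follow a first-order Markov chain along the ordered SNPs:
    each adjacent pair has allelic correlation ``sqrt(r2_target)``, so the
    implied adjacent r² equals the target exactly when feasible (non-
    adjacent pairs decay geometrically). ``r2_target = 0`` gives the
    linkage-equilibrium product model; ``r2_target = 1`` with equal
    frequencies gives the two perfectly coupled haplotypes.

    Raises ``ValueError`` when the target is infeasible for the given
    frequencies (the coupling D would push a haplotype frequency negative).
    """
    if n_snps < 1:
        raise ValueError("need at least one SNP")
    if not (0.0 <= r2_target <= 1.0):
        raise ValueError("r2 target must be in [0, 1]")
    q = np.full(n_snps, float(freqs)) if np.isscalar(freqs) else np.asarray(freqs, float)
    if q.shape != (n_snps,):
        raise ValueError("freqs must be scalar or one value per SNP")
    if np.any((q <= 0.0) | (q >= 1.0)):
        raise ValueError("allele frequencies must be in (0, 1)")
    r = math.sqrt(r2_target)
    # adjacent-pair coupling and feasibility
    cond: list[tuple[float, float]] = []  # P(next=1 | prev=1), P(next=1 | prev=0)
    for a in range(n_snps - 1):
        qa, qb = q[a], q[a + 1]
        d = r * math.sqrt(qa * (1 - qa) * qb * (1 - qb))
        pab = qa * qb + d
        if pab > min(qa, qb) + 1e-12:
            raise ValueError(
                f"r2={r2_target} infeasible for frequencies ({qa:.3g}, {qb:.3g}): "
                f"requires P(both risk alleles) = {pab:.3g} > min(q) = {min(qa, qb):.3g}"
            )
        cond.append((pab / qa, (qb - pab) / (1.0 - qa)))
    haps = np.array(
        [[(h >> (n_snps - 1 - i)) & 1 for i in range(n_snps)] for h in range(2**n_snps)],
        dtype=np.int8,
    )
    probs = np.where(haps[:, 0] == 1, q[0], 1.0 - q[0]).astype(float)
    for a, (p11, p01) in enumerate(cond):
        p_next_one = np.where(haps[:, a] == 1, p11, p01)
        probs *= np.where(haps[:, a + 1] == 1, p_next_one, 1.0 - p_next_one)
    keep = probs > 1e-15
    probs = probs[keep] / probs[keep].sum()
    ids = tuple(snp_ids) if snp_ids is not None else tuple(f"ld_snp{i}" for i in range(n_snps))
    return HaplotypeModel(snp_ids=ids, haplotypes=haps[keep], frequencies=probs)


def write_haplotype_fixture(
    models: dict[str, HaplotypeModel], path: str | Path
) -> None:
    """Write per-locus haplotype models in the fixture TSV dialect."""
    rows = []
    for locus_id, model in sorted(models.items()):
        for hap, freq in zip(model.haplotypes, model.frequencies):
            rows.append(
                {
                    "locus_id": locus_id,
                    "haplotype": "".join(str(int(b)) for b in hap),
                    "frequency": float(freq),
                }
            )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
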