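"""Projecting future GWAS discoveries and their effect on risk panels.

The number of detectable susceptibility SNPs is estimated by inflating each
observed SNP by the power to have detected it: a SNP with effect size
e = beta^2 * 2q(1-q) observed in a study with detection power p represents
an estimated M_T = 1/p SNPs of that effect size in total (Park's bin
method, with one bin per observed SNP by default). A hypothetical future
study with a multiplied sample size then detects ceil(p' * M_T) of them,
where p' is the power at the larger size; those SNPs — the observed one
plus newly simulated independent loci sharing its effect size and allele
frequency — form the future panel.

Detection power uses the normal approximation for the per-allele (1-df
trend) Wald test at significance level alpha, with the standard error of
the log odds ratio evaluated at the case and control allele frequencies
implied by the effect size.
"""

from __future__ import annotations

import datetime
import math
from dataclasses import dataclass, replace
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .catalog import GENOME_WIDE_ALPHA, Locus, SnpRecord, TimePointPanel
from .cohort import HaplotypeModel, simulate_genotypes
from .metrics import (
    AucResult,
    ReclassificationResult,
    analytic_auc,
    empirical_auc,
    nri,
    odds_change_summary,
    reclassification_metrics,
)
from .risk import RISK_THRESHOLDS, score_cohort

__all__ = [
    "StudyDesign",
    "EffectBin",
    "ProjectionResult",
    "effect_size",
    "detection_power",
    "bin_totals",
    "future_snp_count",
    "future_panel",
    "project_future",
]


@dataclass(frozen=True)
class StudyDesign:
    """Case-control GWAS design used for power calculations."""

    n_cases: int
    n_controls: int
    alpha: float = GENOME_WIDE_ALPHA
    multiplier: float = 2.0

    def __post_init__(self) -> None:
        if self.n_cases <= 0 or self.n_controls <= 0:
            raise ValueError("sample sizes must be positive")
        if not (0.0 < self.alpha < 1.0):
            raise ValueError("alpha must be in (0, 1)")
        if self.multiplier < 1.0:
            raise ValueError("sample-size multiplier must be >= 1")

    def scaled(self, factor: float | None = None) -> "StudyDesign":
        """The design with both arms multiplied by ``factor`` (default
        ``self.multiplier``)."""
        f = self.multiplier if factor is None else factor
        if f < 1.0:
            raise ValueError("sample-size multiplier must be >= 1")
        return replace(
            self,
            n_cases=int(round(self.n_cases * f)),
            n_controls=int(round(self.n_controls * f)),
        )


@dataclass(frozen=True)
class EffectBin:
    """One effect-size bin of the observed-to-total accounting."""

    effect: float
    beta: float
    q: float
    m_observed: float
    power: float
    m_total: float
    seed_snp: SnpRecord | None = None

    def __post_init__(self) -> None:
        if not (0.0 < self.power <= 1.0):
            raise ValueError("bin power must be in (0, 1]")
        if self.m_total < self.m_observed - 1e-12:
            raise ValueError("estimated total cannot be below the observed count")


def effect_size(beta, q):
    """Per-SNP effect size e = beta^2 * 2q(1-q); symmetric in q and 1-q."""
    beta = np.asarray(beta, dtype=float)
    q = np.asarray(q, dtype=float)
    if np.any((q <= 0.0) | (q >= 1.0)):
        raise ValueError("allele frequency must be in (0, 1)")
    out = beta**2 * 2.0 * q * (1.0 - q)
    return float(out) if out.ndim == 0 else out


def detection_power(beta, q, design: StudyDesign):
    """Power of the per-allele trend test to detect a log-OR ``beta``.

    Normal approximation: the Wald statistic beta_hat / SE is compared to
    the two-sided critical value at ``design.alpha``, with

        SE = sqrt( 1/(2 n_cases q_case (1-q_case))
                 + 1/(2 n_controls q (1-q)) )

    where ``q_case = q e^beta / (1 - q + q e^beta)`` is the case allele
    frequency implied by the per-allele odds ratio. Power is
    Phi(|beta|/SE - z) + Phi(-|beta|/SE - z); at beta = 0 it equals alpha,
    and it increases with |beta|, q(1-q) and sample size. Accepts scalars
    or arrays.
    """
    beta = np.asarray(beta, dtype=float)
    q = np.asarray(q, dtype=float)
    if np.any((q <= 0.0) | (q >= 1.0)):
        raise ValueError("allele frequency must be in (0, 1)")
    orr = np.exp(beta)
    q_case = q * orr / (1.0 - q + q * orr)
    se = np.sqrt(
        1.0 / (2.0 * design.n_cases * q_case * (1.0 - q_case))
        + 1.0 / (2.0 * design.n_controls * q * (1.0 - q))
    )
    z_crit = stats.norm.isf(design.alpha / 2.0)
    ncp = np.abs(beta) / se
    power = stats.norm.cdf(ncp - z_crit) + stats.norm.cdf(-ncp - z_crit)
    return float(power) if power.ndim == 0 else power


def bin_totals(
    snps: TimePointPanel | Sequence[SnpRecord],
    design: StudyDesign,
    min_power: float = 0.05,
    bin_width: float | None = None,
) -> tuple[list[EffectBin], float]:
    """Estimate per-bin and total counts of detectable susceptibility SNPs.

    By default each observed SNP is its own bin (M_j = 1, M_T,j = 1/p_j).
    ``bin_width`` switches to histogram bins on the effect size e, pooling
    SNPs whose e falls in the same bin. SNPs whose detection power under
    ``design`` is below ``min_power`` are excluded from the accounting —
    their 1/p inflation is numerically unstable and dominated by chance
    discoveries.

    Returns the bins and M_Total, the summed estimated totals.
    """
    records = list(snps.snps) if isinstance(snps, TimePointPanel) else list(snps)
    enriched = []
    for rec in records:
        p = detection_power(rec.beta, rec.raf, design)
        if p <= 0.0:
            raise ValueError(
                f"{rec.rsid}: detection power is numerically zero under the stated "
                "design; the SNP could not have been observed"
            )
        if p < min_power:
            continue
        enriched.append((rec, effect_size(rec.beta, rec.raf), p))

    bins: list[EffectBin] = []
    if bin_width is None:
        for rec, e, p in enriched:
            bins.append(
                EffectBin(
                    effect=e,
                    beta=rec.beta,
                    q=rec.raf,
                    m_observed=1.0,
                    power=p,
                    m_total=1.0 / p,
                    seed_snp=rec,
                )
            )
    else:
        groups: dict[int, list[tuple[SnpRecord, float, float]]] = {}
        for rec, e, p in enriched:
            groups.setdefault(int(e // bin_width), []).append((rec, e, p))
        for key in sorted(groups):
            members = groups[key]
            m = float(len(members))
            mean_e = float(np.mean([e for _, e, _ in members]))
            mean_p = float(np.mean([p for _, _, p in members]))
            rep = min(members, key=lambda t: t[0].p_value)[0]
            bins.append(
                EffectBin(
                    effect=mean_e,
                    beta=rep.beta,
                    q=rep.raf,
                    m_observed=m,
                    power=mean_p,
                    m_total=m / mean_p,
                    seed_snp=rep,
                )
            )
    m_total = float(sum(b.m_total for b in bins))
    return bins, m_total


def future_snp_count(m_total: float, power_future: float) -> int:
    """SNPs of a bin's effect size expected in the larger study.

    The expected count is ``power_future * m_total``; the ceiling is
    simulated so fractional expectations round up (an expectation of 7.2
    detectable SNPs yields 8 simulated ones).
    """
    if not (0.0 <= power_future <= 1.0):
        raise ValueError("power must be in [0, 1]")
    if m_total < 0:
        raise ValueError("m_total must be >= 0")
    return int(math.ceil(power_future * m_total - 1e-12))


def future_panel(
    panel: TimePointPanel,
    bins: Sequence[EffectBin],
    design: StudyDesign,
    include_observed: bool = True,
    tag: str = "future",
) -> TimePointPanel:
    """Construct the hypothetical panel after a sample-size-multiplied GWAS.

    For each bin, power is recomputed at ``design.scaled()`` and the panel
    receives ``ceil(p' * M_T)`` SNPs with the bin's log-OR and allele
    frequency. With ``include_observed`` (default) the bin's observed seed
    SNP is kept — so the future cohort shares its genotypes with the
    current one — and the remainder are newly simulated SNPs, each placed
    on its own synthetic chromosome (a unique locus). With
    ``include_observed=False`` every SNP in the panel is new.
    """
    scaled = design.scaled()
    new_date = panel.date + datetime.timedelta(days=365)
    snps: list[SnpRecord] = []
    sim_index = 0
    for b in bins:
        p_future = detection_power(b.beta, b.q, scaled)
        count = future_snp_count(b.m_total, p_future)
        if count == 0:
            continue
        n_new = count
        if include_observed and b.seed_snp is not None:
            snps.append(b.seed_snp)
            n_new = max(count - int(round(b.m_observed)), 0)
        template = b.seed_snp
        for _ in range(n_new):
            sim_index += 1
            snps.append(
                SnpRecord(
                    rsid=f"sim_{template.rsid if template else 'bin'}_{sim_index}",
                    chromosome=f"proj{sim_index}",
                    position_bp=1_000_000,
                    risk_allele="A",
                    raf=b.q,
                    odds_ratio=math.exp(abs(b.beta)),
                    p_value=min(template.p_value if template else 1e-9, 1e-9),
                    report_date=new_date,
                    source="projected",
                    n_cases=scaled.n_cases,
                    n_controls=scaled.n_controls,
                )
            )
    return TimePointPanel(tag=tag, date=new_date, snps=tuple(snps))


@dataclass(frozen=True)
class ProjectionResult:
    """Reclassification and discrimination between a panel and its future."""

    reclassification: ReclassificationResult
    auc_current: float
    auc_future: float
    auc_current_binormal: AucResult
    auc_future_binormal: AucResult
    odds_change: tuple[float, float]
    n_current: int
    n_future: int


def project_future(
    current: TimePointPanel,
    future: TimePointPanel,
    cohort_size: int = 100_000,
    seed: int | np.random.Generator | None = None,
    hap_models: Mapping[str, HaplotypeModel] | None = None,
    thresholds: tuple[float, float] = RISK_THRESHOLDS,
) -> ProjectionResult:
    """Measure projected reclassification on one shared simulated cohort.

    Genotypes are simulated once for the union of current and future SNPs
    (each future SNP a unique locus); both panels score the same cohort,
    each normalised by its own mean. Case weights for the NRI and AUC come
    from the rare-disease reweighting (cases at the current panel define
    the NRI's case population, matching one underlying population compared
    across panels).
    """
    union: dict[str, SnpRecord] = {s.rsid: s for s in (*current.snps, *future.snps)}
    hap_models = hap_models or {}
    covered = {sid for m in hap_models.values() for sid in m.snp_ids}
    loci = [
        Locus(locus_id=f"u:{rec.rsid}", chromosome=rec.chromosome, snps=(rec,))
        for rec in union.values()
        if rec.rsid not in covered
    ]
    if covered:
        raise NotImplementedError(
            "haplotype-modelled loci in projections are not supported; "
            "projections assume each SNP is an independent locus"
        )
    genotypes = simulate_genotypes(loci, n=cohort_size, seed=seed)
    prof_current = score_cohort(genotypes, current, thresholds)
    prof_future = score_cohort(genotypes, future, thresholds)
    result = reclassification_metrics(prof_current.categories, prof_future.categories)
    nri_value = nri(
        prof_current.categories,
        prof_future.categories,
        case_weights=prof_current.case_weights,
        control_weights=np.ones(cohort_size),
    )
    result = replace(result, nri_value=nri_value)
    auc_c = empirical_auc(
        prof_current.normalized, prof_current.case_weights, np.ones(cohort_size)
    )
    auc_f = empirical_auc(
        prof_future.normalized, prof_future.case_weights, np.ones(cohort_size)
    )
    return ProjectionResult(
        reclassification=result,
        auc_current=auc_c,
        auc_future=auc_f,
        auc_current_binormal=_binormal_from_profile(prof_current),
        auc_future_binormal=_binormal_from_profile(prof_future),
        odds_change=odds_change_summary(prof_current.normalized, prof_future.normalized),
        n_current=current.k,
        n_future=future.k,
    )


def _binormal_from_profile(profile) -> AucResult:
    log_o = np.log(profile.normalized)
    cw = profile.case_weights
    mu_case = float(cw @ log_o)
    sd_case = float(np.sqrt(cw @ (log_o - mu_case) ** 2))
    mu_ctrl = float(log_o.mean())
    sd_ctrl = float(log_o.std())
    return analytic_auc(mu_case, sd_case, mu_ctrl, sd_ctrl)
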