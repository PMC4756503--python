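"""Multiplicative genetic odds, risk tiers, and exact score distributions.

An individual's genetic odds under a panel is the product over panel SNPs of
the per-allele odds ratio raised to the risk-allele count:

    Odds_i = prod_j OR_j ** g_ij

computed as ``exp(sum_j g_ij * log OR_j)`` so hundred-SNP panels do not
overflow. Odds are normalised by the cohort (or population) mean, and
individuals fall into three tiers relative to the average: Lower (O < 0.5),
Average (0.5 <= O <= 2) and Higher (O > 2).

For small panels the full genotype space can be enumerated, giving the
exact population distribution of the normalised odds. Under the
rare-disease approximation the population distribution stands in for
controls, and the case distribution reweights each genotype class by its
normalised odds.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .catalog import TimePointPanel
from .cohort import CohortGenotypes, HaplotypeModel

__all__ = [
    "RiskCategory",
    "RISK_THRESHOLDS",
    "RiskProfile",
    "GeneticValueDistribution",
    "raw_odds",
    "normalize_odds",
    "classify",
    "score_cohort",
    "exact_distribution",
    "exact_joint_distribution",
    "control_dist_at_incidence",
]

#: (lo, hi) multiples of the average odds bounding the Average tier
RISK_THRESHOLDS = (0.5, 2.0)

# log-odds values are keyed after rounding to this many decimals when
# collapsing enumeration states; well below any OR resolution of interest
_LOG_DECIMALS = 10


class RiskCategory(enum.IntEnum):
    """Ordered risk tiers relative to the population average."""

    LOWER = 0
    AVERAGE = 1
    HIGHER = 2

    @property
    def label(self) -> str:
        return self.name.capitalize()


def raw_odds(
    genotypes: CohortGenotypes | np.ndarray,
    panel: TimePointPanel,
    snp_ids: Sequence[str] | None = None,
) -> np.ndarray:
    """Per-individual multiplicative odds under ``panel``.

    ``genotypes`` may be a :class:`CohortGenotypes` (columns looked up by
    rsid) or a bare matrix with ``snp_ids`` giving its column order. An
    individual with no risk alleles has odds 1 (empty product).
    """
    if isinstance(genotypes, CohortGenotypes):
        try:
            G = genotypes.columns(panel.rsids)
        except KeyError as exc:
            raise KeyError(f"panel SNP missing from genotype matrix: {exc}") from exc
    else:
        if snp_ids is None:
            raise ValueError("snp_ids required when passing a bare matrix")
        index = {s: i for i, s in enumerate(snp_ids)}
        missing = [s for s in panel.rsids if s not in index]
        if missing:
            raise KeyError(f"panel SNP missing from genotype matrix: {missing}")
        G = np.asarray(genotypes)[:, [index[s] for s in panel.rsids]]
    return np.exp(G.astype(float) @ panel.betas)


def normalize_odds(odds: np.ndarray) -> np.ndarray:
    """Divide by the arithmetic mean; the result averages to 1."""
    odds = np.asarray(odds, dtype=float)
    if odds.size == 0:
        raise ValueError("cannot normalise an empty odds vector")
    if np.any(odds <= 0.0):
        raise ValueError("odds must be strictly positive")
    return odds / odds.mean()


def classify(
    normalized: np.ndarray,
    lo: float = RISK_THRESHOLDS[0],
    hi: float = RISK_THRESHOLDS[1],
) -> np.ndarray:
    """Map normalised odds to ordered tier codes (0 Lower, 1 Average, 2 Higher).

    Both boundaries belong to the Average tier: Lower is O < lo, Higher is
    O > hi.
    """
    if not (0.0 < lo < hi):
        raise ValueError("thresholds must satisfy 0 < lo < hi")
    O = np.asarray(normalized, dtype=float)
    return np.where(O < lo, RiskCategory.LOWER, np.where(O > hi, RiskCategory.HIGHER, RiskCategory.AVERAGE)).astype(np.int8)


@dataclass(frozen=True)
class RiskProfile:
    """Scored cohort under one panel: raw odds, normalised odds, tiers."""

    panel_tag: str
    raw: np.ndarray
    normalized: np.ndarray
    categories: np.ndarray

    @property
    def n(self) -> int:
        return self.raw.shape[0]

    @property
    def case_weights(self) -> np.ndarray:
        """Rare-disease case weights, proportional to the normalised odds."""
        return self.normalized / self.normalized.sum()

    def category_proportions(self) -> np.ndarray:
        return np.bincount(self.categories, minlength=3) / self.n

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "individual_id": np.arange(self.n),
                "raw_odds": self.raw,
                "normalized_odds": self.normalized,
                "category": [RiskCategory(c).label for c in self.categories],
            }
        )


def score_cohort(
    genotypes: CohortGenotypes,
    panel: TimePointPanel,
    thresholds: tuple[float, float] = RISK_THRESHOLDS,
) -> RiskProfile:
    """Score a simulated cohort under a panel (raw -> normalised -> tiers)."""
    odds = raw_odds(genotypes, panel)
    normalized = normalize_odds(odds)
    return RiskProfile(
        panel_tag=panel.tag,
        raw=odds,
        normalized=normalized,
        categories=classify(normalized, *thresholds),
    )


@dataclass(frozen=True)
class GeneticValueDistribution:
    """Exact distribution of normalised genetic odds in controls and cases.

    ``odds`` holds the distinct normalised odds values O_g; ``control_pmf``
    the population/control probabilities Pr(g); ``case_pmf`` the
    case-reweighted probabilities proportional to O_g * Pr(g).
    """

    odds: np.ndarray
    control_pmf: np.ndarray
    case_pmf: np.ndarray

    def __post_init__(self) -> None:
        for name in ("odds", "control_pmf", "case_pmf"):
            object.__setattr__(self, name, np.asarray(getattr(self, name), dtype=float))
        if not (self.odds.shape == self.control_pmf.shape == self.case_pmf.shape):
            raise ValueError("odds and pmf vectors must align")
        for pmf in (self.control_pmf, self.case_pmf):
            if abs(pmf.sum() - 1.0) > 1e-8 or np.any(pmf < -1e-12):
                raise ValueError("probability vectors must be nonnegative and sum to 1")

    def _moments(self, pmf: np.ndarray) -> tuple[float, float]:
        log_o = np.log(self.odds)
        mu = float(pmf @ log_o)
        var = float(pmf @ (log_o - mu) ** 2)
        return mu, np.sqrt(max(var, 0.0))

    @property
    def mu_controls(self) -> float:
        return self._moments(self.control_pmf)[0]

    @property
    def sigma_controls(self) -> float:
        return self._moments(self.control_pmf)[1]

    @property
    def mu_cases(self) -> float:
        return self._moments(self.case_pmf)[0]

    @property
    def sigma_cases(self) -> float:
        return self._moments(self.case_pmf)[1]

    def log_moments(self) -> dict[str, float]:
        """All four log-odds moments (cases mu/sigma, controls mu/sigma)."""
        mu_c, sd_c = self._moments(self.case_pmf)
        mu_n, sd_n = self._moments(self.control_pmf)
        return {
            "mu_cases": mu_c,
            "sigma_cases": sd_c,
            "mu_controls": mu_n,
            "sigma_controls": sd_n,
        }

    def category_proportions(
        self,
        lo: float = RISK_THRESHOLDS[0],
        hi: float = RISK_THRESHOLDS[1],
        population: str = "controls",
    ) -> np.ndarray:
        pmf = self.control_pmf if population == "controls" else self.case_pmf
        cats = classify(self.odds, lo, hi)
        return np.array([pmf[cats == c].sum() for c in range(3)])


def _locus_log_odds(
    locus_snps: Sequence, betas: Mapping[str, float], hap_model: HaplotypeModel | None
) -> tuple[np.ndarray, np.ndarray]:
    """Distinct log-odds contributions of one locus with probabilities."""
    if hap_model is None:
        (snp,) = locus_snps
        q = snp.raf
        probs = np.array([(1 - q) ** 2, 2 * q * (1 - q), q**2])
        values = np.array([0.0, 1.0, 2.0]) * betas.get(snp.rsid, 0.0)
    else:
        genos, probs = hap_model.diplotype_distribution()
        b = np.array([betas.get(s, 0.0) for s in hap_model.snp_ids])
        values = genos.astype(float) @ b
    return _compress(values, probs)


def _compress(values: np.ndarray, probs: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    keys = np.round(values, _LOG_DECIMALS)
    uniq, inv = np.unique(keys, return_inverse=True)
    agg = np.zeros_like(uniq)
    np.add.at(agg, inv, probs)
    return uniq, agg


def _convolve_loci(
    parts: Sequence[tuple[np.ndarray, np.ndarray]], max_states: int
) -> tuple[np.ndarray, np.ndarray]:
    values = np.array([0.0])
    probs = np.array([1.0])
    for v, p in parts:
        if values.size * v.size > max_states:
            raise ValueError(
                f"genotype space exceeds {max_states} states; "
                "use the Monte-Carlo cohort path instead"
            )
        values = np.add.outer(values, v).ravel()
        probs = np.multiply.outer(probs, p).ravel()
        values, probs = _compress(values, probs)
    return values, probs


def _panel_loci(panel: TimePointPanel, hap_models: Mapping[str, HaplotypeModel] | None):
    """Group panel SNPs into independent enumeration units.

    SNPs covered by a haplotype model form one unit; the rest are
    independent single SNPs.
    """
    hap_models = hap_models or {}
    covered: set[str] = set()
    units: list[tuple[list, HaplotypeModel | None]] = []
    for model in hap_models.values():
        members = [s for s in panel.snps if s.rsid in model.snp_ids]
        if members:
            units.append((members, model))
            covered.update(s.rsid for s in members)
    for snp in panel.snps:
        if snp.rsid not in covered:
            units.append(([snp], None))
    return units


def exact_distribution(
    panel: TimePointPanel,
    hap_models: Mapping[str, HaplotypeModel] | None = None,
    max_states: int = 1_000_000,
) -> GeneticValueDistribution:
    """Enumerate the exact normalised-odds distribution under a panel.

    Per-locus genotype distributions (HWE for single SNPs, diplotype
    probabilities for haplotype-modelled loci) are convolved on the
    log-odds scale across independent loci, collapsing equal values as it
    goes. Odds are normalised by the exact population mean, so the result
    is seed-free. The case pmf reweights by the normalised odds
    (rare-disease approximation).
    """
    betas = {s.rsid: s.beta for s in panel.snps}
    parts = [_locus_log_odds(snps, betas, model) for snps, model in _panel_loci(panel, hap_models)]
    log_vals, probs = _convolve_loci(parts, max_states)
    odds = np.exp(log_vals)
    mean = float(probs @ odds)
    O = odds / mean
    case = O * probs
    case /= case.sum()
    return GeneticValueDistribution(odds=O, control_pmf=probs, case_pmf=case)


def exact_joint_distribution(
    panel_a: TimePointPanel,
    panel_b: TimePointPanel,
    hap_models: Mapping[str, HaplotypeModel] | None = None,
    max_states: int = 1_000_000,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Joint exact distribution of normalised odds under two panels.

    Returns ``(odds_a, odds_b, prob)`` over the union genotype space: each
    row is a distinct pair of normalised odds values with its population
    probability. Genotypes are shared — the same individual scored under
    both panels — which is what between-panel reclassification measures.
    """
    betas_a = {s.rsid: s.beta for s in panel_a.snps}
    betas_b = {s.rsid: s.beta for s in panel_b.snps}
    union_snps = {s.rsid: s for s in (*panel_a.snps, *panel_b.snps)}
    union_panel = TimePointPanel(
        tag="union", date=max(panel_a.date, panel_b.date), snps=tuple(union_snps.values())
    )

    pairs = np.zeros((1, 2))
    probs = np.array([1.0])
    for snps, model in _panel_loci(union_panel, hap_models):
        if model is None:
            (snp,) = snps
            q = snp.raf
            p_loc = np.array([(1 - q) ** 2, 2 * q * (1 - q), q**2])
            g = np.arange(3.0)
            v_loc = np.stack(
                [g * betas_a.get(snp.rsid, 0.0), g * betas_b.get(snp.rsid, 0.0)], axis=1
            )
        else:
            genos, p_loc = model.diplotype_distribution()
            ba = np.array([betas_a.get(s, 0.0) for s in model.snp_ids])
            bb = np.array([betas_b.get(s, 0.0) for s in model.snp_ids])
            v_loc = np.stack([genos.astype(float) @ ba, genos.astype(float) @ bb], axis=1)
        if pairs.shape[0] * v_loc.shape[0] > max_states:
            raise ValueError(f"joint genotype space exceeds {max_states} states")
        pairs = (pairs[:, None, :] + v_loc[None, :, :]).reshape(-1, 2)
        probs = np.multiply.outer(probs, p_loc).ravel()
        keys = np.round(pairs, _LOG_DECIMALS)
        uniq, inv = np.unique(keys, axis=0, return_inverse=True)
        agg = np.zeros(uniq.shape[0])
        np.add.at(agg, inv.ravel(), probs)
        pairs, probs = uniq, agg

    odds_a = np.exp(pairs[:, 0])
    odds_b = np.exp(pairs[:, 1])
    odds_a /= probs @ odds_a
    odds_b /= probs @ odds_b
    return odds_a, odds_b, probs


def control_dist_at_incidence(
    dist: GeneticValueDistribution, incidence: float
) -> GeneticValueDistribution:
    """Replace the rare-disease control pmf with one at a finite incidence.

    With disease probability Pr(D|g) = c * O_g and marginal incidence K,
    c = K because the normalised odds average to 1 over the population.
    Controls are then the non-diseased: Pr(g|control) proportional to
    (1 - c*O_g) * Pr(g). K = 0 returns the distribution unchanged.
    """
    if not (0.0 <= incidence <= 0.5):
        raise ValueError("incidence must be in [0, 0.5]")
    if incidence == 0.0:
        return dist
    mean_o = float(dist.control_pmf @ dist.odds)
    c = incidence / mean_o
    if c * dist.odds.max() > 1.0:
        raise ValueError(
            f"infeasible incidence: c * max(O_g) = {c * dist.odds.max():.4g} > 1; "
            "the linear risk scaling cannot exceed probability 1"
        )
    control = (1.0 - c * dist.odds) * dist.control_pmf
    control /= control.sum()
    return replace(dist, control_pmf=control)
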