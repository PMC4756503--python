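"""Model/Results facade over the reclassification pipeline.

:class:`GeneticRiskModel` is built from a SNP catalog plus a set of panel
dates; :meth:`GeneticRiskModel.fit` simulates one cohort for the union of
panel SNPs, scores every time-point panel on it, and returns a
:class:`GeneticRiskResults` carrying panel sizes, risk-tier proportions,
between-panel reclassification tables with NRI, per-panel AUCs, and
(optionally) the projection to a sample-size-doubled future GWAS, with a
``summary()`` table in the spirit of statsmodels results objects.
"""

from __future__ import annotations

import datetime
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import catalog as cat
from .catalog import LdTable, SnpRecord, TimePointPanel
from .cohort import CohortGenotypes, HaplotypeModel, simulate_genotypes
from .metrics import (
    AucResult,
    ReclassificationResult,
    analytic_auc,
    empirical_auc,
    nri,
    odds_change_summary,
    reclassification_metrics,
)
from .projection import (
    ProjectionResult,
    StudyDesign,
    bin_totals,
    future_panel,
    project_future,
)
from .risk import RISK_THRESHOLDS, RiskProfile, score_cohort

__all__ = ["GeneticRiskModel", "GeneticRiskResults", "PanelComparison"]


@dataclass(frozen=True)
class PanelComparison:
    """Reclassification summary between two scored panels."""

    tag_from: str
    tag_to: str
    reclassification: ReclassificationResult
    odds_change: tuple[float, float]


class GeneticRiskModel:
    """Multiplicative-odds genetic risk model over time-stamped SNP panels.

    Parameters
    ----------
    records
        Validated catalog records (all reports, including repeats).
    time_points
        Panel snapshot dates (ISO strings or dates), strictly increasing.
    ld
        Pairwise r² table covering within-locus pairs; may be omitted when
        every locus holds a single SNP.
    r2_max, window_bp
        LD-pruning threshold and locus chaining window.
    thresholds
        (lo, hi) normalised-odds boundaries of the Average tier.
    hap_models
        Haplotype models keyed by locus id for multi-SNP loci.
    """

    def __init__(
        self,
        records: Sequence[SnpRecord],
        time_points: Sequence[datetime.date | str],
        ld: LdTable | None = None,
        r2_max: float = cat.R2_PRUNE_DEFAULT,
        window_bp: int = cat.LOCUS_WINDOW_BP,
        thresholds: tuple[float, float] = RISK_THRESHOLDS,
        hap_models: Mapping[str, HaplotypeModel] | None = None,
    ) -> None:
        self.records = list(records)
        self.time_points = list(time_points)
        self.ld = ld
        self.r2_max = r2_max
        self.window_bp = window_bp
        self.thresholds = thresholds
        self.hap_models = dict(hap_models or {})
        self.panels: list[TimePointPanel] = cat.build_panels(
            self.records, self.time_points, ld=ld, r2_max=r2_max, window_bp=window_bp
        )

    @classmethod
    def from_catalog(
        cls,
        path: str | Path,
        time_points: Sequence[datetime.date | str],
        alpha: float = cat.GENOME_WIDE_ALPHA,
        **kwargs,
    ) -> "GeneticRiskModel":
        """Build from a catalog TSV (rows filtered at ``alpha``)."""
        return cls(cat.read_catalog(path, alpha=alpha), time_points, **kwargs)

    @classmethod
    def from_dataframe(
        cls,
        frame: pd.DataFrame,
        time_points: Sequence[datetime.date | str],
        alpha: float = cat.GENOME_WIDE_ALPHA,
        **kwargs,
    ) -> "GeneticRiskModel":
        """Build from a catalog-dialect DataFrame."""
        import io

        buf = io.StringIO()
        frame.to_csv(buf, sep="\t", index=False)
        buf.seek(0)
        return cls(cat.read_catalog(buf, alpha=alpha), time_points, **kwargs)

    def _union_loci(self):
        """One locus list covering every SNP appearing in any panel."""
        latest: dict[str, SnpRecord] = {}
        for panel in self.panels:
            for snp in panel.snps:
                latest[snp.rsid] = snp
        return cat.assign_loci(list(latest.values()), window_bp=self.window_bp)

    def fit(
        self,
        cohort_size: int = 100_000,
        seed: int | None = None,
        design: StudyDesign | None = None,
        project: bool = False,
        min_power: float = 0.05,
    ) -> "GeneticRiskResults":
        """Simulate the cohort, score all panels, and compare them.

        One cohort is simulated for the union of SNPs across every time
        point, so between-panel reclassification reflects panel change
        rather than genotype resampling. With ``project=True`` (requires a
        ``design`` or per-SNP study sizes in the last panel) the fit also
        builds the future panel at the design's sample-size multiplier and
        measures projected reclassification on a fresh shared cohort.
        """
        loci = self._union_loci()
        genotypes = simulate_genotypes(
            loci, n=cohort_size, seed=seed, hap_models=self.hap_models or None
        )
        profiles = [score_cohort(genotypes, p, self.thresholds) for p in self.panels]

        comparisons: list[PanelComparison] = []
        pairs = list(zip(range(len(profiles) - 1), range(1, len(profiles))))
        if len(profiles) > 2:
            pairs.append((0, len(profiles) - 1))
        ones = np.ones(cohort_size)
        for i, j in pairs:
            a, b = profiles[i], profiles[j]
            rec = reclassification_metrics(a.categories, b.categories)
            rec = replace(
                rec,
                nri_value=nri(a.categories, b.categories, a.case_weights, ones),
            )
            comparisons.append(
                PanelComparison(
                    tag_from=a.panel_tag,
                    tag_to=b.panel_tag,
                    reclassification=rec,
                    odds_change=odds_change_summary(a.normalized, b.normalized),
                )
            )

        aucs = []
        for prof in profiles:
            log_o = np.log(prof.normalized)
            cw = prof.case_weights
            mu_case = float(cw @ log_o)
            sd_case = float(np.sqrt(cw @ (log_o - mu_case) ** 2))
            binormal = analytic_auc(mu_case, sd_case, float(log_o.mean()), float(log_o.std()))
            empirical = empirical_auc(prof.normalized, cw, ones)
            aucs.append((empirical, binormal))

        projection = None
        if project:
            last = self.panels[-1]
            proj_design = design or _design_from_panel(last)
            bins, m_total = bin_totals(last, proj_design, min_power=min_power)
            fut = future_panel(last, bins, proj_design)
            proj_seed = None if seed is None else seed + 1
            projection = project_future(
                last,
                fut,
                cohort_size=cohort_size,
                seed=proj_seed,
                thresholds=self.thresholds,
            )
            projection_extra = {"m_total": m_total, "n_bins": len(bins)}
        else:
            projection_extra = {}

        return GeneticRiskResults(
            model=self,
            genotypes=genotypes,
            profiles=profiles,
            comparisons=comparisons,
            aucs=aucs,
            projection=projection,
            projection_info=projection_extra,
            seed=seed,
        )


def _design_from_panel(panel: TimePointPanel) -> StudyDesign:
    sizes = [
        (s.n_cases, s.n_controls)
        for s in panel.snps
        if s.n_cases is not None and s.n_controls is not None
    ]
    if not sizes:
        raise ValueError(
            "no study sizes available in the panel; pass an explicit StudyDesign"
        )
    n_cases = max(s for s, _ in sizes)
    n_controls = max(s for _, s in sizes)
    return StudyDesign(n_cases=n_cases, n_controls=n_controls)


@dataclass
class GeneticRiskResults:
    """Fitted reclassification analysis over the panel timeline."""

    model: GeneticRiskModel
    genotypes: CohortGenotypes
    profiles: list[RiskProfile]
    comparisons: list[PanelComparison]
    aucs: list[tuple[float, AucResult]]
    projection: ProjectionResult | None
    projection_info: dict
    seed: int | None

    @property
    def panel_sizes(self) -> list[int]:
        return [p.k for p in self.model.panels]

    @property
    def higher_risk_proportions(self) -> list[float]:
        return [float(p.category_proportions()[2]) for p in self.profiles]

    @property
    def tags(self) -> list[str]:
        return [p.tag for p in self.model.panels]

    def category_table(self) -> pd.DataFrame:
        """Tier proportions per time point (rows = time points)."""
        return pd.DataFrame(
            [p.category_proportions() for p in self.profiles],
            index=self.tags,
            columns=["Lower", "Average", "Higher"],
        )

    def reclassification_table(self) -> pd.DataFrame:
        rows = []
        for comp in self.comparisons:
            rec = comp.reclassification
            rows.append(
                {
                    "from": comp.tag_from,
                    "to": comp.tag_to,
                    "percent_reclassified": rec.percent_reclassified,
                    "collapsed_reclassified": rec.collapsed_reclassified,
                    "downward_from_high": rec.downward_from_high,
                    "nri": rec.nri_value,
                    "p_small_change": comp.odds_change[0],
                    "p_large_change": comp.odds_change[1],
                }
            )
        return pd.DataFrame(rows)

    def auc_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "panel": self.tags,
                "k_snps": self.panel_sizes,
                "auc_empirical": [a for a, _ in self.aucs],
                "auc_binormal": [b.auc for _, b in self.aucs],
            }
        )

    def summary(self) -> str:
        """Human-readable summary of the fitted analysis."""
        lines = [
            "Genetic risk reclassification analysis",
            "=" * 54,
            f"cohort size: {self.genotypes.n:,}   seed: {self.seed}",
            f"risk tiers: Lower < {self.model.thresholds[0]} <= Average <= "
            f"{self.model.thresholds[1]} < Higher (x population average odds)",
            "",
            "Panels and discrimination",
            "-" * 54,
            self.auc_table().to_string(
                index=False, float_format=lambda v: f"{v:.3f}"
            ),
            "",
            "Risk-tier proportions",
            "-" * 54,
            self.category_table().to_string(float_format=lambda v: f"{v:.3f}"),
            "",
            "Between-panel reclassification",
            "-" * 54,
            self.reclassification_table().to_string(
                index=False, float_format=lambda v: f"{v:.3f}"
            ),
        ]
        if self.projection is not None:
            proj = self.projection
            lines += [
                "",
                "Projection to a sample-size-doubled GWAS",
                "-" * 54,
                f"current panel SNPs: {proj.n_current}   future panel SNPs: {proj.n_future}",
                f"estimated detectable SNPs (M_total): "
                f"{self.projection_info.get('m_total', float('nan')):.1f}",
                f"percent reclassified: {proj.reclassification.percent_reclassified:.3f}",
                f"downward from Higher: {proj.reclassification.downward_from_high:.3f}",
                f"NRI: {proj.reclassification.nri_value:.3f}",
                f"AUC current -> future: {proj.auc_current:.3f} -> {proj.auc_future:.3f}",
            ]
        return "\n".join(lines)

    def plot_risk_distributions(self, ax=None, bins: int = 80):
        """Overlay normalised-odds histograms for every panel (log x-axis)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        for prof in self.profiles:
            ax.hist(
                np.log2(prof.normalized),
                bins=bins,
                histtype="step",
                density=True,
                label=prof.panel_tag,
            )
        for thr in self.model.thresholds:
            ax.axvline(np.log2(thr), color="grey", lw=0.8, ls="--")
        ax.set_xlabel("log2 normalised genetic odds")
        ax.set_ylabel("density")
        ax.legend(title="panel")
        return ax
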