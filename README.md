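# riskdrift

**How stable are polygenic risk classifications as GWAS catalogs grow?**

`riskdrift` is a Python package for quantifying the *reclassification* of
genetic risk predictions over time. As genome-wide association studies
(GWAS) accumulate, new genome-wide-significant SNPs enter risk panels and
effect estimates for known SNPs are revised; an individual labelled
"higher risk" under one panel may not be under the next. The package
builds time-stamped SNP panels from catalog files, simulates a cohort,
scores it under the multiplicative odds model, measures how classifications
move between panels, and projects how much more movement a future,
larger GWAS would cause. It is aimed at statistical geneticists and
methodologists studying the clinical readiness of common-variant risk
models; everything runs on synthetic catalogs, so no external data
services are needed.

## The model

An individual *i*'s genetic odds under the panel in effect at time *m* is
the product over the panel's k_m SNPs of the per-allele odds ratio raised
to the risk-allele count:

    Odds_{i,m} = ∏_{j=1}^{k_m} OR_{j,m}^{g_{i,j}},     O_{i,m} = Odds_{i,m} / mean(Odds_{·,m})

Normalised odds O define three tiers relative to the population average:
Lower (O < 0.5), Average (0.5 ≤ O ≤ 2), Higher (O > 2). Panels are
assembled by keeping SNPs with p < 5×10⁻⁸, chaining SNPs within 500 kb
into loci, and greedily retaining SNPs per locus in order of significance
while pairwise r² < 0.75. Between two panels the package reports the
percent reclassified (off-diagonal of the 3×3 tier table), the net
reclassification index NRI = (P_case↑ − P_case↓) + (P_ctrl↓ − P_ctrl↑)
under rare-disease case weights (w_i ∝ O_i), and the AUC — empirically by
weighted Mann–Whitney, or in closed form from the binormal model on log
odds, AUC = Φ(a/√(1+b²)) with a = (μ_D − μ_D̄)/σ_D and b = σ_D̄/σ_D.

Future discoveries are projected by the power-inflation ("bin") method:
each observed SNP with effect size e = β²·2q(1−q) and detection power p_j
at the reference study size represents M_T,j = 1/p_j detectable SNPs in
total; a study with multiplied sample size detects ceil(p′_j · M_T,j) of
them, simulated as independent loci with the same β and q.

## Worked example

```python
import riskdrift as rd

universe = rd.make_universe(n_causal=300, seed=7)        # true polygenic architecture
catalog = rd.simulate_discovery(universe, seed=8)        # four-snapshot discovery timeline
model = rd.GeneticRiskModel.from_dataframe(
    catalog, ["2007-12-31", "2009-12-31", "2011-12-31", "2013-12-31"]
)
results = model.fit(cohort_size=100_000, seed=9, project=True)
print(results.summary())
```

prints

```
Genetic risk reclassification analysis
======================================================
cohort size: 100,000   seed: 9
risk tiers: Lower < 0.5 <= Average <= 2.0 < Higher (x population average odds)

Panels and discrimination
------------------------------------------------------
     panel  k_snps  auc_empirical  auc_binormal
2007-12-31       4          0.597         0.597
2009-12-31      13          0.643         0.643
2011-12-31      48          0.690         0.690
2013-12-31     127          0.726         0.726

Risk-tier proportions
------------------------------------------------------
            Lower  Average  Higher
2007-12-31  0.021    0.955   0.024
2009-12-31  0.138    0.806   0.056
2011-12-31  0.263    0.646   0.091
2013-12-31  0.348    0.543   0.109

Between-panel reclassification
------------------------------------------------------
      from         to  percent_reclassified  collapsed_reclassified  downward_from_high    nri  p_small_change  p_large_change
2007-12-31 2009-12-31                 0.184                   0.055               0.485  0.037           0.440           0.168
2009-12-31 2011-12-31                 0.273                   0.082               0.423  0.017           0.402           0.236
2011-12-31 2013-12-31                 0.265                   0.085               0.367 -0.016           0.456           0.229
2007-12-31 2013-12-31                 0.451                   0.114               0.603  0.042           0.218           0.434

Projection to a sample-size-doubled GWAS
------------------------------------------------------
current panel SNPs: 127   future panel SNPs: 282
estimated detectable SNPs (M_total): 208.2
percent reclassified: 0.337
downward from Higher: 0.432
NRI: -0.061
AUC current -> future: 0.727 -> 0.782
```

Reading the output: discovery accelerates late (4 → 127 panel SNPs), the
risk distribution widens (Higher-tier share 2.4% → 10.9%, AUC 0.60 →
0.73), and between any two snapshots a large fraction of individuals
change tier — 26.5% between the last two panels, and over a third of the
Higher-tier individuals drop out of that tier each interval. The
projection says a doubled-sample-size GWAS would raise the panel to ~282
SNPs and reclassify another 34% of the cohort: classification churn does
not die down at current study sizes.

The same pipeline is scriptable from the shell:

```bash
riskdrift synth --n-causal 300 --seed 7 --out synth/
riskdrift panels --catalog synth/catalog.tsv \
    --dates 2007-12-31,2009-12-31,2011-12-31,2013-12-31 --out panels/
riskdrift simulate --panels panels/ --n 100000 --seed 17 --out genotypes.tsv
riskdrift score --genotypes genotypes.tsv --panel panels/panel_2013-12-31.tsv --out scores.tsv
riskdrift project --panel panels/panel_2013-12-31.tsv \
    --n-cases 30000 --n-controls 30000 --out projection.json
```

## Layout

- `riskdrift.catalog` — catalog parsing, locus chaining, LD pruning, panels
- `riskdrift.cohort` — genotype simulation, EM haplotype frequencies
- `riskdrift.risk` — odds scoring, tiers, exact genotype-space distributions
- `riskdrift.metrics` — reclassification tables, NRI, odds changes, AUC
- `riskdrift.projection` — effect bins, detection power, future panels
- `riskdrift.synthetic` — universes, discovery timelines, LD fixtures
- `riskdrift.model` — `GeneticRiskModel` / `GeneticRiskResults` facade
- `riskdrift.cli` — the `riskdrift` command

See `docs/methods.md` for modelling assumptions, parameter choices, and
known limitations.
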