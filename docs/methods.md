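# Methods

## Model and assumptions

The package scores genetic risk with the multiplicative per-allele odds
model: an individual's odds of disease is the product over panel SNPs of
OR_j raised to the risk-allele count g_ij, equivalent to an additive model
on the log-odds scale. Odds are normalised by the population mean, so a
normalised value O = 2 means "twice the average genetic odds". Three
assumptions do most of the work:

- **Rare disease.** Odds ratios approximate relative risks, and the
  general population approximates controls. The case distribution of the
  score is then the control distribution reweighted by O (each genotype
  class contributes in proportion to its odds). The explicit finite-
  incidence correction (`control_dist_at_incidence`) replaces the control
  weights with (1 − K·O_g)·Pr(g) for incidence K; on representative
  panels the tier proportions at K = 0.10 differ from the rare-disease
  limit by well under 0.02, so the approximation is used everywhere else.
- **Independence across loci, random mating within.** Genotypes at
  different loci are simulated independently (linkage equilibrium between
  loci); within a multi-SNP locus, two haplotypes are drawn independently
  from a haplotype model, preserving LD. Single-SNP loci are
  Hardy–Weinberg: risk-allele count ~ Binomial(2, q).
- **Catalog ORs taken at face value.** Effective ORs come from the most
  significant report to date, with no shrinkage for winner's curse. The
  synthetic generator can simulate cursed reports to study the effect, but
  the scoring pipeline never corrects for it — matching how published
  catalog values are used in practice.

## Panel construction

SNPs pass a significance filter (default α = 5×10⁻⁸, the conventional
genome-wide threshold) and records with OR < 1 are flipped to the other
allele at ingest (OR → 1/OR, q → 1−q) so dosage always counts risk
alleles. Loci are single-linkage chains: SNPs on one chromosome whose
adjacent gaps are ≤ 500 kb. Single-linkage is used because a pairwise
"all within 500 kb" rule is not well defined for chains; the window is
configurable. Within a locus, pruning is greedy stepwise: visit SNPs in
ascending p-value (ties broken by position, then rsid, for determinism)
and retain a candidate iff its r² with *every* retained SNP is strictly
below the threshold (default 0.75). The endpoints behave as expected:
r2_max = 0 retains exactly the top SNP per locus, r2_max ≥ 1 retains all.
Pruning is idempotent. Missing r² pairs are an error, never assumed 0 —
silently assuming equilibrium would under-prune. A repeat report replaces
a SNP's effective OR only when its p-value is strictly smaller; ties keep
the earlier report.

## Cohort simulation and EM

One cohort (default 100,000 individuals) is simulated for the union of
SNPs across every time point, so between-panel reclassification reflects
panel change, not genotype resampling. Simulation is bit-reproducible
given the seed. When only unphased genotypes are available for a
multi-SNP locus, haplotype frequencies are estimated with the standard
multinomial EM: E-step distributes each genotype over compatible ordered
haplotype pairs, M-step averages expected haplotype counts. The
log-likelihood is monotone; iteration stops when the improvement drops
below `tol` (default 1e-8) or at `max_iter` (default 1000), in which case
the result carries `em_converged = False` rather than failing silently.
Initialisation is the linkage-equilibrium product of observed allele
frequencies plus a small symmetric perturbation (1e-6) to avoid starting
exactly on a ridge. Enumeration is over all 2^k haplotypes and is capped
at k = 16 SNPs per locus.

## Exact distributions

For small panels, `exact_distribution` enumerates the score distribution
rather than simulating it: per-locus genotype distributions (HWE or
diplotype probabilities) are convolved across loci on the log-odds scale,
collapsing states whose log-odds agree after rounding to 10 decimals.
The state cap (default 10⁶) bounds memory; larger panels use the
Monte-Carlo cohort path. Normalisation uses the exact population mean,
so enumeration results are seed-free; the cohort path normalises by the
sample mean, as an analyst with simulated data would. Odds products are
always accumulated in log space — naive products overflow beyond ~100
SNPs. `exact_joint_distribution` applies the same convolution to a pair
of panels over the shared genotype space, which is what between-panel
reclassification needs.

## Reclassification metrics

Tier boundaries (0.5, 2.0) are benchmarks, not clinical thresholds; both
boundary values fall in the Average tier. Percent reclassified is the
off-diagonal mass of the 3×3 table; the collapsed version merges Lower
and Average first (Higher vs not-Higher). "Downward from high" is the
share of time-1 Higher individuals no longer Higher at time 2, and is
reported as missing (NaN) when nobody was Higher at time 1. The NRI
counts any category move once, including a two-tier jump. Cohort-path
NRIs use rare-disease case weights w_i ∝ O_i evaluated at the *earlier*
panel: the comparison is of one underlying population across two panels,
so the case population is defined once per comparison (weights at the
later panel are available by passing them explicitly). The empirical AUC
is the weighted Mann–Whitney probability that a case outscores a control
with ties counted half; the binormal formula Φ(a/√(1+b²)) is exact when
both log-score distributions are normal and is reported alongside it.

## Detection power and projection

Power for the per-allele (1-df trend) test uses the normal approximation
to the Wald statistic: power = Φ(|β|/SE − z_{1−α/2}) + Φ(−|β|/SE −
z_{1−α/2}), with the SE of the log-OR evaluated at the case and control
allele frequencies implied by the effect, SE² = 1/(2·n_cases·q_case(1−q_case))
+ 1/(2·n_controls·q(1−q)) and q_case = q·e^β/(1−q+q·e^β). Evaluating the
case arm at q_case rather than the pooled frequency matters: at OR = 1.1,
q = 0.1 and 20,000/20,000 the pooled approximation misses simulated
rejection rates by ~0.03, while this form tracks them within Monte-Carlo
error. At β = 0 the power is exactly α; it is monotone in |β|, q(1−q),
and sample size.

The projection inflates each observed SNP by its detection power: one
bin per SNP (M_j = 1, M_T,j = 1/p_j), summed to M_Total. Optional
histogram binning on e = β²·2q(1−q) pools SNPs instead. SNPs with power
below `min_power` (default 0.05) are excluded from the accounting — their
1/p inflation is dominated by chance discoveries and numerically
unstable. The future panel at a multiplied sample size contains
ceil(p′_j·M_T,j) SNPs per bin: the observed seed SNP (so the future
cohort shares genotypes with the current one, making individual-level
reclassification well defined) plus newly simulated SNPs, each an
independent unique locus with the seed's β and q. A fully-new-SNPs mode
(`include_observed=False`) is available; the default is the shared-
genotype mode, since reclassification of *the same individuals* is the
quantity of interest. Two-stage study designs are treated as single-stage
at the combined sample size.

## Synthetic data: what it emulates, and what it does not

The generator stands in for everything the real analysis would download.
A universe of causal SNPs draws log-ORs as ln(1.03) + Exponential(0.045)
and risk-allele frequencies uniform on (0.05, 0.95): many small effects
with a thinning tail, calibrated so that a fully discovered timeline
yields panel AUCs in the 0.6–0.75 range reported for common-disease risk
models — below the log-normal turning point σ² = 2·ln 2, where widening
the risk distribution still grows the extreme tiers. The default
discovery schedule has four snapshots (end of 2007/2009/2011/2013) with
cumulative per-arm sizes 2,000 / 5,000 / 12,000 / 30,000: geometric
growth that keeps the mean effect near 50% power only at the last
snapshot, so discovery accelerates late — the "tipping point" regime in
which reclassification stays high. Each undiscovered SNP is reported with
probability equal to its current detection power; reported test
statistics are drawn from the Wald sampling distribution truncated to
significance, so reported p-values always pass the filter, and with
`winners_curse=True` the reported OR is exp(z·SE) — upwardly biased
exactly as literature estimates from underpowered studies are. Discovered
SNPs are re-reported at later snapshots under the larger design,
exercising the OR-update rule. LD fixtures build haplotype models as
first-order Markov chains along the locus, hitting a target adjacent-pair
r² exactly when feasible (infeasible frequency/r² combinations raise an
error citing the coupling bound).

What passing tests on this generator do *not* show: real catalogs carry
curation noise, multi-ancestry frequencies, genuine LD between causal
variants, relatedness, and non-genetic covariates, none of which are
modelled. Causal SNPs default to one per locus at 2 Mb spacing (multi-SNP
loci are opt-in via fixtures), individuals are i.i.d. (no relatedness
filter is needed or implemented), and effect sizes are exactly constant
over time unless winner's curse is switched on. Quantitative results on
synthetic timelines characterise the method, not any particular disease.

## Problem sizes and numerical choices

The test suite and the acceptance script use the sizes the analyses were
designed at: 100,000-individual cohorts for Monte-Carlo/enumeration
agreement and the full timeline (300 causal SNPs, four snapshots,
projection included); 10⁶ draws per group for the binormal check; 10,000
individuals × 50 seeds for EM recovery; 200 replicates of a 200-SNP
universe for recovery of the total-SNP estimator (reference design
400,000/400,000 so every universe SNP has power ≥ 0.05); 10,000
replicates per cell of a 3×3 (OR, frequency) grid at 20,000/20,000 for
the power check. The whole suite runs in well under a minute on one core.
Degenerate inputs fail loudly: empty odds vectors, zero-mass weight
groups, missing LD pairs, q outside (0,1), infeasible incidence
(K·max O_g > 1), and enumeration beyond the state cap all raise errors
with the offending quantity named.

## Known limitations

- No confidence intervals for NRI/AUC; no continuous (category-free) NRI.
- No absolute-risk or lifetime-risk conversion and no calibration against
  observed outcomes — the normalised odds scale is relative throughout.
- The power formula is a normal approximation; it is validated against
  simulated Wald tests at realistic sizes but will drift for very rare
  alleles or tiny studies where counts are small.
- Projections inherit the face-value OR assumption; if published ORs are
  winner's-curse inflated, projected AUC gains are optimistic.
- Haplotype-modelled loci are supported in panel scoring and enumeration
  but not inside the future-panel projection, which assumes each SNP is
  an independent locus.
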