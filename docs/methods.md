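# Methods

This note records what `refstab` computes, the assumptions behind each
step, the defaults and why they were chosen, and what the synthetic-data
generator does and does not emulate. Nothing here states an empirical
result that the test suite or `scripts/acceptance.py` does not itself
compute.

## Data model and preprocessing

A `CqTable` is a genes × samples matrix of quantification cycles (Cq)
with per-sample annotations (region, genotype, biological and technical
replicate). Cq is the cycle at which amplification crosses the detection
threshold, so it is a *negative* log₂ expression scale: one cycle less
means twice the template, assuming perfect doubling. PCR efficiency is
fixed at 2 throughout; there is no efficiency-correction input, which
keeps every downstream formula on a single consistent scale
(2<sup>−ΔCq</sup> quantification, log₂ ratios as Cq differences).

**Technical replicates** are collapsed by the arithmetic mean of the
non-missing Cq values — the standard treatment, since averaging on the
cycle scale corresponds to a geometric mean of linear quantities. The
per-cell SD of the technical replicates is retained as `tech_spread`, and
cells exceeding `spread_warn` (default 0.5 cycles, a common lab rule of
thumb for acceptable triplicate scatter) are *flagged, never removed*:
no outlier-removal rule is imposed. A cell is missing only if all its
technical replicates are missing.

**Missing values** (non-detects) propagate as missing. The estimators use
pairwise-complete samples where that is mathematically valid (ΔCt and
geNorm pairwise SDs, BestKeeper per-gene statistics) and error rather than
impute when a precondition fails (a gene pair sharing fewer than three
samples, a gene with fewer than three complete samples). NormFinder
requires within-sample centering across all genes, so samples missing any
gene are dropped with a warning.

## The four stability estimators

All four return a per-gene value where lower = more stable, plus ranks
(1 = best; ties share the average rank, kept fractional downstream).

**Comparative ΔCt.** For each gene pair, the per-sample difference
Cq<sub>i</sub> − Cq<sub>j</sub> is a log₂ expression ratio up to a
constant; its SD across samples (ddof = 1) measures the pair's relative
instability. A gene's value is the mean of these SDs over all partners
(units: cycles).

**geNorm.** Relative quantities Q = 2^(min Cq − Cq) put each gene on a
log₂ scale where the pairwise variation V<sub>jk</sub> = SD of
log₂(Q<sub>j</sub>/Q<sub>k</sub>) reduces to the same pairwise Cq-difference
SD. M<sub>j</sub> is the mean of V<sub>jk</sub> over partners; the gene
with the highest M is excluded and M recomputed until two genes remain.
A gene's reported value is its M at exclusion; the final two genes carry
the final-step M and share rank 1.5, because the method cannot separate
its last pair. Ranks therefore follow the *exclusion order* (the method's
own semantics) rather than a re-sort of the recorded M values, which need
not be monotone in pathological tables. Ties on the worst M exclude the
alphabetically last symbol, for determinism. The V<sub>n/n+1</sub> series
(SD across samples of the log₂ ratio between normalization factors built
from the top n and top n + 1 genes) is reported as a diagnostic only; the
panel size is a fixed choice (k = 3 by default), not decided by the 0.15
V-threshold heuristic.

**BestKeeper.** The ranking statistic is the tool's "SD[±Cq]" — the mean
absolute deviation of a gene's Cq from its arithmetic mean — not the
Pearson r, since the original tool treats SD > 1 cycle as the
acceptability bound and the aggregation tools built on it do not document
using r. CV% (= SD/mean·100), the BestKeeper index (per-sample geometric
mean of all candidates' Cq) and each gene's Pearson r against the index
(with two-sided p) are carried in diagnostics. When a gene or the index is
constant, r is undefined and recorded as missing with a warning; the gene
is still ranked by SD.

**NormFinder.** On the log scale (−Cq; the sign does not affect the
result), each sample is centered across the k genes, removing per-sample
offsets (the invariance the tests assert). Within each group g with
n<sub>g</sub> samples, z<sub>ig</sub> is the mean and s²<sub>ig</sub> the
variance (ddof = 1) of the centered residuals of gene i. Because
centering mixes the genes' errors, s²<sub>ig</sub> estimates
(1 − 2/k)σ²<sub>ig</sub> + γ<sub>g</sub> with
γ<sub>g</sub> = Σσ²/k²; solving gives the bias-corrected intragroup
variance

    σ̂²_ig = max(0, (s²_ig − mean_i s²_ig / (k−1)) · k/(k−2)),

which is why at least three genes are required. Intergroup deviations
d<sub>ig</sub> = z<sub>ig</sub> − mean over groups of z<sub>ig</sub> sum
to zero across genes within each group; they are shrunk toward zero by
τ/(τ + Var(d<sub>ig</sub>)), with τ the truncated moment estimate of the
variance of the true deviations and Var(d<sub>ig</sub>) ≈
σ̂²<sub>ig</sub>/n<sub>g</sub>. The stability value is the mean over
groups of |d̃<sub>ig</sub>| + √(σ̂²<sub>ig</sub>/n<sub>g</sub>); with no
grouping it reduces to √σ̂²<sub>i</sub>. Ungrouped estimation is the
default for within-genotype/across-region assessments; the
within-region/across-genotype assessments pass genotype as the group
factor, so a gene shifting between genotypes is penalized through d.

## Rank aggregation and panel compilation

The comprehensive rank of a gene is the geometric mean of its four method
ranks, computed on the fractional tied ranks without rounding; the final
order sorts ascending with alphabetical tie-break.

The **condition sweep** evaluates two axes. Within-genotype/across-regions
yields one ranking per genotype; `pooled` mode estimates once from all of
the genotype's samples, while `per_cell_averaged` (the default for panel
compilation) computes a ranking per region and averages the per-region
rank positions arithmetically — the "average ranking position across the
regions" reading. Both modes are exposed because the two readings answer
slightly different questions (overall cross-region stability vs typical
within-region stability), and on regionally homogeneous data they agree
(asserted in the CLI tests). Within-region/across-genotypes yields one
ranking per region and always pools the region's samples of both
genotypes, since a single-genotype cell cannot contrast genotypes.

The initial **screen** of the candidate pool ranks within one genotype
*pooled across all regions*: across-region instability (large region
effects, high biological noise) is precisely what the screen must detect,
and the pooled estimation uses every sample. The `keep` best genes
survive.

**Panel compilation**: each axis score is the arithmetic mean (matching
"average rank"; a geometric alternative would compress large ranks) of
the per-condition comprehensive ranks; the combined score is the weighted
average of the two axes (weights non-negative, summing to 1, default
0.5/0.5); the panel is the k genes with the smallest combined score,
alphabetical on ties.

## Relative quantification and contrasts

ΔCq = Cq<sub>target</sub> − arithmetic mean of the panel genes' Cq;
relative expression is 2<sup>−ΔCq</sup> per biological replicate. The
arithmetic mean on the Cq scale equals the geometric mean of the panel's
linear quantities — the standard multi-reference normalization factor —
and makes the result invariant to any per-replicate offset common to all
genes (e.g. input-amount differences).

Genotype contrasts per region use the classical two-sided unpaired
Student t-test on the per-replicate relative expressions (equal-variance,
as conventional for balanced qPCR designs; Welch by flag — with equal n
the two share the t statistic and differ only in degrees of freedom).
Shapiro–Wilk normality p-values are attached per group when n ≥ 3;
failures produce a warning but never switch the test automatically, since
the normality check is a verification step, not a branch. Labels are
ns/*/**/*** at p ≤ 0.05/0.01/0.001. No multiple-testing correction is
applied by default — the stars are per-region descriptive labels; users
needing family-wise control should adjust the returned p-values
themselves.

Degenerate input (both groups zero-variance) yields p = 1 for equal
means, p = 0 otherwise, with a warning, instead of a NaN from the t
formula.

## Synthetic data

The generator draws

    Cq(g, s) = base_cq + region_effect + genotype_effect·[second genotype]
               + ε_bio + ε_tech

with Gaussian noise on the Cq scale (log-normal on the linear scale, the
standard qPCR error model): ε_bio ~ N(0, bio_sd²) shared by a biological
replicate's technical replicates, ε_tech ~ N(0, tech_sd²) per well,
independent dropouts with probability `dropout_p`. The genotype effect
may be region-dependent (a region → cycles map), giving true fold changes
2^(−effect) per (gene, region). Randomness is split from the root seed
into one child stream per gene, so editing one gene's spec does not
perturb the draws of the others.

`SimulationTruth` is a deterministic function of the configuration: the
designed stability order sorts genes by the composite instability score
√(bio_sd² + Var(region_effects) + mean(genotype_effect²)) (population
variance over all configured regions; the genotype term averaged over
regions when region-dependent). The score is declared ground truth for
tests only — no estimator consumes it.

The ready-made study configuration (`pws_brain_config`) emulates the
nine-region, WT vs mutant survey: 11 candidate reference genes — three
designed-unstable conventional housekeepers (bio SD 1.4–1.6 cycles plus
regional and genotype effects), five moderate survivors (bio SD
0.6–0.8), three designed panel genes (bio SD 0.1, no effects) —
technical SD 0.15 cycles everywhere, three biological replicates per cell
(six for WT hypothalamus) in technical triplicate, and optional target
genes with region-dependent genotype effects qualitatively matching the
studied expression differences (e.g. a 2-fold hypothalamic knock-down of
*Pcsk1*, a mild upregulation of all *Nlgn3* isoforms). The noise tiers
are chosen to represent a clearly separable screening problem (unstable
candidates ~2× the moderate tier, panel genes ~6× below it), which is
what a well-designed candidate pool looks like; recovery rates under
these conditions are computed by the acceptance script, not assumed.

What the generator does **not** emulate: amplification efficiency
variation between assays, fluorescence-curve artefacts, inter-plate
calibration shifts, correlated noise between genes sharing a plate or an
RNA extraction, and non-Gaussian contamination. Passing recovery tests on
this model therefore shows the pipeline's statistical machinery is
correct under the declared noise model — not that any particular lab
dataset satisfies that model.

## Numerical choices and problem sizes

* SDs use ddof = 1 throughout; ranks come from average-rank midranking.
* Geometric means are computed as exp(mean(log ·)); ranks are ≥ 1 so no
  underflow occurs.
* NormFinder's variance estimates and τ are truncated at zero.
* Tie-breaks (geNorm exclusion, final orders, panel membership) are
  alphabetical, making every pipeline output deterministic given data.
* The simulation studies run at the design's natural size: recovery over
  100 simulated studies of the full 9 × 2 × (3|6) × 3 design; power over
  1000 simulated two-group experiments at n = 8 per group with a 0.2
  cycle effect (chosen to sit in the informative mid-range of the power
  curve, where empirical and closed-form power can actually disagree);
  fold-change recovery at n = 100 biological replicates. The closed-form
  power uses the exact log-normal moments implied by the generator
  (collapsed Cq variance bio_sd² + tech_sd²/3, ΔCq variance inflated by
  1 + 1/3 for the three-gene panel mean) converted to a standardized
  effect size for the two-sample t power function.

## Known limitations

* No efficiency correction (Pfaffl-type E^ΔCt models are out of scope);
  assays with efficiencies far from 2 will bias fold changes.
* BestKeeper's regression diagnostics beyond Pearson r, NormFinder
  confidence intervals, and geNorm's V-based panel-size decision rule are
  not implemented.
* The t-test operates on the linear 2^−ΔCq scale to match the reporting
  convention of mean ± SD fold changes; for strongly noisy data a
  log-scale test would be more powerful.
* Stability estimation within a single design cell relies on few
  biological replicates (3–6); per-region rankings are correspondingly
  noisy, which is why the screen pools across regions.
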