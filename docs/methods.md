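# Methods

## Scope of the model

`droughtsel` operationalizes a screening protocol for paired-stress
yield trials: per-genotype mean yields under non-stress (YP) and stress
(YS) are reduced to nine scalar indices, the indices are screened by
correlation with yield, the survivors are combined into the composite
selection index (CSI), and multivariate structure is read off rank-2
SVD biplots. Everything operates on genotype-level means; plot-level
experimental design (blocking, replication, spatial adjustment) is
assumed to have been handled upstream and is out of scope.

## Indices and scopes

The nine indices (SSI, RSI, TOL, MP, YSI, HM, GMP, STI, YI) are exact
algebraic functions of (YP, YS, Ȳ_P, Ȳ_S). Population means Ȳ_P, Ȳ_S
include every entry in the table — lines, parents and checks — by
default, because check varieties are part of the population whose mean
defines stress intensity; an `entry_types` filter restricts them when a
lines-only convention is wanted.

Indices are computed per *scope*: a single year, or "pooled". Pooling
averages per-year genotype means with equal year weight (not a grand
mean of plots), so an unbalanced year cannot dominate the pooled value.
A genotype missing either condition within a scope is dropped from that
scope with a warning; YP = 0 leaves the ratio indices (SSI, RSI, YSI)
undefined for that genotype (reported as missing), and Ȳ_S = Ȳ_P makes
SSI globally undefined (hard error naming the degenerate denominator).

## Correlation screening and CSI

Each index column is correlated (Pearson) with YP and with YS across
genotypes; the p-value comes from the two-sided t test,
t = r·√(n−2)/√(1−r²) on n−2 degrees of freedom. An index is significant
when p < α under *both* conditions (default α = 0.05, any sign); a
`require_positive` option additionally demands positive correlations,
since a susceptibility index can in principle pass the two-sided gate
with negative r and then enters CSI with negative weight — the formula
allows it, so the default keeps the signed weight. No multiple-testing
correction is applied across the nine indices; the screen is
deliberately liberal and the weights, not the gate, carry the
information.

CSI_i = ½·Σ_j (r_YP,j + r_YS,j)·index_ij over the significant indices.
Weights are always taken from the same scope as the index values (a
year's CSI uses that year's correlations; pooled CSI uses pooled
correlations). Rankings sort descending with ties broken
lexicographically by genotype id, so results are deterministic.

When a scope yields no significant index, `select_significant` raises
(CSI is undefined there); the pipeline records the condition as a
warning for that scope and continues with the others rather than
aborting the whole run.

## Biplot engine

All modes column-center the two-way table. The genotype×trait (GT)
table holds YP, YS, the nine indices and optionally CSI; because these
columns have heterogeneous units the pipeline fits GT biplots with
unit-sd column scaling. The genotype×environment (GGE) table holds mean
yields per year×condition environment; its columns share units, so
scaling defaults to off. The PCA mode standardizes the index columns at
table-construction time.

Singular-value partitioning follows the two standard conventions:
column-metric preserving ("tester-focused": testers get V·S, genotypes
get U), used for tester comparison — tester vector lengths then equal
column standard deviations (times √(n−1)) and cosines approximate
column correlations — and symmetric (both sides get √S), used for the
which-won-where polygon. The full-rank coordinate product reproduces
the processed matrix identically under either partitioning.

Numerical conventions: axis signs are fixed by making the
largest-magnitude loading on each axis positive; a table whose second
singular value carries < 1e−12 of the total sum of squares is flagged
rank-1 with a warning; explained variance per axis is σ_k²/Σσ².

Which-won-where computes the convex hull of genotype points; sector
boundaries are the perpendiculars from the origin to the hull edges,
and the winner of each sector is its hull vertex. The implementation
assigns each tester to the hull vertex maximizing the inner product
with the tester vector, which is mathematically equivalent (a linear
functional on a convex polygon is maximized at a vertex) and is
verified against the geometric construction in tests. A tester exactly
on a boundary joins the counter-clockwise sector: among inner-product
ties the vertex with the smallest counter-clockwise angular distance
from the tester wins. The ideal tester lies on the normalized average-
tester axis at the length of the longest tester vector; testers are
ranked by Euclidean distance to it (stable sort, so exact ties keep
input order).

## Synthetic trial generator

The generator emulates the statistical structure the analysis assumes,
with known truth for every quantity the downstream modules estimate.

Genetics: each of `n_loci` independent biallelic loci is inherited from
either parent with probability ½ (lines are fully homozygous, as after
single-seed descent). The default parents are complementary — each
carries the plus-allele at half the loci — which gives both parents the
same non-stress genetic value and makes transgressive segregation in
both directions likely, the situation the screening method is designed
for. The stress genetic value is g_S = m + ρ_g·(g_P − m) + √(1−ρ_g²)·η
with η drawn at the segregation variance (fixed offsets for parents and
checks, so ρ_g = 1 forces g_S = g_P for every entry, a limit the tests
exploit).

Yields: yield_N = μ_P + year effect + g_P + G×E + error;
yield_D = (1 − δ_y)·(μ_P + year effect + g_S) + G×E + error. The stress
factor δ_y multiplies the genetic-plus-year component but not the
noise, so the population-level percent reduction recovers δ_y directly
from the N and D means — the simplest mechanism consistent with
reporting stress severity as a percent reduction. Yields truncate at
zero with a warning (the severe year otherwise produces negatives).

Defaults (one trial = 152 lines + 2 parents + 3 checks × 3 years × 2
conditions = 942 records): μ_P = 2.0 t ha⁻¹ base, 20 loci × 0.2 t ha⁻¹
effects (population mean yield ≈ 4 t ha⁻¹ non-stress, genetic sd
≈ 0.45 t ha⁻¹), year effects (0.3, −0.1, −0.2) t ha⁻¹, δ = (0.89,
0.58, 0.35) mimicking one severe and two moderate drought years,
ρ_g = 0.7 (stress tolerance heritable but not identical to yield
potential), G×E sd 0.25 and plot error sd 0.3 t ha⁻¹ — plausible
magnitudes for irrigated cereal trials with a CV near 10%.

What the generator does *not* emulate: linkage (loci are independent —
sufficient for transgressive-segregation structure, useless for
mapping), phenology and its correlation with escape, augmented-design
field adjustment, heteroscedastic or spatially correlated plot error.
Tests passing on this generator therefore validate the estimators'
algebra and statistical behaviour under the assumed structure, not
robustness to field artifacts.

## Numerical choices

- Transgressive-segregant comparisons are strict inequalities with an
  absolute tie tolerance of 1e−9 t ha⁻¹: a line equal to a parent
  (including equality up to float summation order, which arises exactly
  when a line inherits half the plus-alleles of complementary parents)
  is not a segregant. The generator's truth flags use the same
  tolerance so detection and truth agree in the zero-noise limit.
- Correlation r is clipped to [−1, 1] before the t transform; |r| = 1
  maps to p = 0.
- All rankings use stable sorts with lexicographic id tie-breaks.
- Human-readable outputs round to 3 decimals; CSVs keep full precision.

## Problem sizes

The test suite and the acceptance script run one default-size trial
(157 genotypes × 6 environments) per scenario, 20 seeds for the
stress-recovery check, 1000 random yield pairs for the index algebra
properties and 200 random geometries for the which-won-where
equivalence; the whole suite completes in a few seconds.

## Known limitations

- CSI weights are sample correlations; with few genotypes they are
  noisy and the index inherits that noise. No shrinkage is applied.
- The significance gate tests each index marginally; strongly collinear
  indices (MP/GMP/HM/STI typically correlate > 0.9) enter CSI jointly,
  so CSI effectively up-weights their shared signal. This mirrors the
  protocol it implements rather than an optimality claim.
- Biplot readings (angles ≈ correlations, sector winners) are exact
  only insofar as the rank-2 approximation is good; the explained-
  variance shares written alongside every biplot are the caveat to
  check.
- Reconstructed figures can differ from other software by axis
  rotation/reflection; the sign convention here is deterministic but
  arbitrary.
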