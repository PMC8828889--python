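# droughtsel

Yield-based drought-tolerance screening for plant-breeding trials.

Breeding programmes that screen a biparental population (for example a
rice recombinant-inbred-line population) under paired non-stress and
drought-stress conditions face the same recurring questions: which of
the classical tolerance/susceptibility indices actually track yield in
*both* regimes, how to combine them into a single selection score, which
lines win in which environment, and which lines transgress the parental
range. `droughtsel` packages that workflow: the nine standard indices, a
correlation-weighted composite selection index (CSI), a rank-2 SVD
biplot engine (genotype×trait and genotype×environment views, including
which-won-where sectors and ideal-tester ranking), transgressive-
segregant detection, and a seeded simulator of RIL multi-environment
trials for validation.

## The statistics

For a genotype with mean yield YP under non-stress and YS under stress,
and population means Ȳ_P, Ȳ_S over all entries:

| index | formula | high value means |
|-------|---------|------------------|
| SSI | (1 − YS/YP)/(1 − Ȳ_S/Ȳ_P) | susceptible |
| RSI | (YS/YP)/(Ȳ_S/Ȳ_P) | tolerant |
| TOL | YP − YS | susceptible |
| MP  | (YP + YS)/2 | productive |
| YSI | YS/YP | stable |
| HM  | 2·YP·YS/(YP + YS) | tolerant |
| GMP | √(YP·YS) | productive in both |
| STI | YP·YS/Ȳ_P² | productive in both |
| YI  | YS/Ȳ_S | suited to stress |

An index is *significant* when its Pearson correlation with yield is
significant under both conditions (two-sided t test at α). The composite
selection index weights each significant index j by its correlations:

    CSI_i = ½ · Σ_j (r_YP,j + r_YS,j) · index_ij

Biplots column-center (optionally column-scale) the two-way table and
take the SVD; tester-focused partitioning (columns get the singular
values) supports index comparison and ideal-tester ranking, symmetric
partitioning supports the which-won-where polygon, whose sector winners
provably maximize the inner product with every tester in their sector.

## Worked example

The composite index for a line whose pooled index values are
MP = 4.286, GMP = 3.553, HM = 2.945, STI = 0.788, using weights
r_YP = (0.96, 0.85, 0.72, 0.83) and r_YS = (0.79, 0.92, 0.98, 0.91):

```python
>>> import pandas as pd
>>> from droughtsel import composite_index
>>> from droughtsel.datasets import l53_index_values, pooled_weights
>>> composite_index(l53_index_values(), pooled_weights())
genotype
L53    10.083465
Name: csi, dtype: float64
```

CSI = ½[(0.96+0.79)·4.286 + (0.85+0.92)·3.553 + (0.72+0.98)·2.945 +
(0.83+0.91)·0.788] = 10.083 — the line scores high because it combines
large MP/GMP/HM (absolute productivity in both regimes) with a solid
STI.

A full screening run from the shell:

```sh
droughtsel simulate --out trial.csv --seed 1
droughtsel report --input trial.csv --out-dir results --parents P1,P2
```

which prints `report written to results (7 stages)` and writes, per
scope (each year and pooled): the index table, the correlation report
with significance flags, CSI scores and ranks, biplot coordinates,
which-won-where sector maps, the ideal-index ranking, the transgressive
segregant lists, and `report.json` tying it all together. On the default
simulation the per-year population yield reductions come out at 89.5%,
58.0% and 36.9% — recovering the generating stress severities (0.89,
0.58, 0.35) to within 0.02.

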