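# Methods

`proteoage` re-implements, as a tested and reusable pipeline, the
quantitative analysis by which a triple-SILAC *C. elegans* proteome
measured at three adult ages (day 1 = heavy, day 5 = medium, day 10 =
light) is turned into a set of significantly age-variant proteins, trend
clusters, gene-set shifts, localization profiles, a cross-strain scaling
classification, and reporter-foci measurements. This note records the
model assumptions, the free parameters and how their defaults were
chosen, and what the synthetic study conditions do and do not establish
about real data.

## The data model

A MaxQuant-style protein-groups table is assumed per biological
replicate: one row per protein group keyed by the lead protein of the
group, with per-channel intensities (H/M/L), evidence-weighted linear
SILAC ratios for the three pairs M/H (day 5 / day 1), L/M (day 10 /
day 5), and L/H (day 10 / day 1), razor + unique peptide counts, and
reverse/contaminant flags. Ratios are analyzed in log2. A protein is
quantifiable when it carries at least two sequence-unique peptides in
every replicate; the reverse and contaminant rows are dropped at the
same step. Missing cells are preserved as missing, never as zero, and a
protein enters a pair's statistics only when that pair is observed in
all replicates. The per-protein reference intensity is the median over
all available channel intensities and replicates.

## Age-variance detection

The core statistic treats each (protein, SILAC pair) separately. The
protein's replicate log2 ratios form one group; the pooled replicate
ratios of k = 20 randomly sampled age-invariant control proteins form
the other; a two-group one-way ANOVA yields F and a p value on (1, n-2)
degrees of freedom. Because measurement error grows as intensity falls,
controls are drawn without replacement from the tested protein's own
log10-reference-intensity decile (10 quantile bins, widened to adjacent
bins on shortage, with a warning). One control draw is made per protein
and reused across the three pairs; repeated-draw averaging is available
as an option. Per-pair p values are Benjamini-Hochberg corrected within
the pair's family (three families, matching the three volcano panels),
and the dataset-wide mean ± 1.96 SD band of per-protein mean ratios is
reported per pair as a descriptive flag, not as a gate.

Two parameters were deliberately calibrated against the method's own
required statistical properties rather than fixed a priori, and the
calibration is worth recording because the naive choices fail quietly:

* **Control definition τ.** A control candidate must keep its mean log2
  ratio within ±τ in all three pairs. A tight τ (0.2) sounds closer to
  "age-invariant", but with three replicates and realistic ratio noise
  (SD 0.15-0.3) it truncates the control pool at roughly 1.4 standard
  errors of the mean. The pooled control group then under-represents
  between-protein sampling variation, the ANOVA denominator shrinks, and
  null p-values become anticonservative (a Kolmogorov-Smirnov test
  against uniformity fails decisively at 5,000 null proteins, with
  P(p < 0.05) ≈ 0.064). The default is therefore **τ = 0.5**: wide
  enough that eligibility barely truncates measurement noise (null
  p-values are KS-uniform), tight enough to exclude genuine ~2-fold age
  changes from the null pool. τ remains a parameter.
* **Protein-level combination rule.** Declaring a protein significant
  when *any* pair's q falls below α (the "union" rule) does not control
  the protein-level false-discovery rate: with three correlated pair
  tests (L/H is approximately the sum of M/H and L/M), the realized FDP
  is 1.5-3x the nominal α in simulation. The default therefore combines
  the three pair p values by **Simes' method** and applies BH across
  proteins; the protein call is q_combined < α. This keeps empirical FDP
  near 0.03 at α = 0.05 with sensitivity ~1 for 2-fold planted changes.
  The union rule is retained as `protein_rule="union"` for comparison.

The significance level is α = 0.05 on corrected values, with volcano
tiers at 0.05/0.01/0.001. The band multiplier defaults to 1.96 ("mean ±
1.96 SD"); an even ±2 SD is a parameter away. Degenerate ANOVA inputs
follow explicit conventions: zero within-group variance with equal means
gives p = 1, with unequal means p = 0 (warned).

## Trend clustering

Each significant protein's mean (M/H, L/M, L/H) log2 changes are scaled
into [-1, +1] by dividing by the profile's own maximum absolute value
(-1 = maximum decrease, +1 = maximum increase; all-zero profiles stay
zero). Scaling is applied to log2 changes, not linear ratios, so
increases and decreases are symmetric. All three pairs, including the
redundant L/H, enter the Euclidean distance, mirroring the three heatmap
columns. Clustering is agglomerative Ward minimum-variance in the
Ward.D2 sense (scipy's `linkage(..., method="ward")`); the same tree is
cut at k = 2 (up vs down) and k = 6 (trend archetypes), so the k = 6
partition refines the k = 2 partition by construction. Clusters are
numbered by descending size with ties broken on the smallest member id,
making labels invariant to input row order. Cluster archetype
descriptors read the signs of the cluster-mean M/H and L/M components
with a dead zone at |mean| < 0.1 (e.g. "up-then-down" for a sharp rise
between days 1 and 5 followed by a fall between days 5 and 10).
Clustering uses mean-across-replicate changes (one column per pair),
not replicate-level profiles.

## Gene-set shift testing

The gene-set analysis formalizes a visual density comparison, so the
statistic is deliberately simple and robust: median(set changes) -
median(background changes), where the background is the full quantified
change table. Significance comes from a permutation null of random
same-size sets drawn without replacement from the non-set background,
with the smoothed two-sided p = (1 + #{|null| ≥ |observed|}) /
(n_perm + 1); a rank-sum standardized z accompanies the median shift.
Set members deviating more than 1.96 set-SDs from the set's own mean are
flagged as within-set outliers — the pattern of a pathway that shifts
coherently except for one or two biologically meaningful exceptions.
The permutation formalization (statistic, null, and smoothing) is this
package's construction; the original comparison was purely visual.

## Mutant scaling

For proteins with a known wild-type age direction, the mutant-vs-
wild-type log2 ratio at a chronologically matched age is classified as
younger / unchanged / older with threshold δ: for an age-increasing
protein, at least δ below wild type is "younger" and at least δ above is
"older"; for an age-decreasing protein the convention inverts. δ
defaults to 0.585 log2 units (1.5-fold) — the source analysis gives no
numeric cutoff, so the value is exposed and easy to scan. Cohorts are
summarized per (strain, direction) stratum as counts and proportions.
An intersection helper joins an external study's table by protein id and
keeps only direction-concordant proteins, reporting the discard count.

## Reporter imaging

Reporter z-stacks are partitioned into focal (punctate, import-positive)
and diffuse (cytoplasmic) components. Foci are segmented on one
designated z-section (default: the brightest): the local background is a
Gaussian blur at scale sigma = 8 px, and pixels exceeding it by
threshold_k = 4 robust SDs (median absolute deviation x 1.4826 of the
residual) form candidates, kept at ≥ 4 px area, optionally split by
marker-based watershed. Because the threshold scales with the residual
spread, counts are invariant under uniform intensity rescaling.
Intensities are summed over all sections; the focal component is the sum
under the 1-px-dilated mask projected through z, the cytoplasmic
component is the remainder, and the normalized cytoplasmic fraction is
cytoplasmic/total — the quantity compared between age groups with an
unpaired (pooled-variance, optionally Welch) t test. The foci count is
taken from the single designated section. No worm-body segmentation is
attempted; images are assumed cropped to the region of interest.

## The synthetic study conditions

The generator encodes the statistical structure the analysis assumes,
with defaults chosen once as the study conditions:

* **Abundance**: log10 intensity ~ Normal(7.0, 1.3), so the 1st-99.9th
  percentile span is ≈ 7 decades, the dynamic range a deep MS experiment
  shows.
* **Noise**: the SD of a log2 ratio is `floor + slope * max(0, cap -
  log10 I)` with floor 0.05, slope 0.05/decade, cap 9 — the simplest
  monotone form of "error grows as intensity falls", giving SD ≈ 0.15 at
  the median intensity and ≈ 0.3 for faint proteins. The source data do
  not quantify this relation; floor/slope are calibration choices.
* **Planted trends**: 8% of proteins are age-variant (matching the ~8%
  headline), drawn from six archetypes defined as sign patterns over
  (M/H, L/M): (+,+), (+,0), (+,-), (-,-), (-,0), (-,+), with magnitude
  `effect_size_log2` (default 1.0, i.e. 2-fold per changing interval).
  Truth satisfies L/H = M/H + L/M exactly; observed L/H is generated as
  observed M/H + L/M plus a small independent error, so additivity is
  soft in observations.
* **Missingness**: independent Bernoulli per ratio cell at rate 0.05;
  no intensity-dependent missingness is modeled.
* **Peptide counts**: Poisson with intensity-dependent mean, which
  makes the two-peptides-in-every-replicate filter remove ~20-30% of
  identifications, comparable to a real deep dataset.
* **Localization**: four-compartment proportions drawn from a flat
  Dirichlet; fraction intensities get unit-mean gamma noise (CV 0.2).
* **Mutant scaling**: planted younger/unchanged/older proportions per
  strain default to the long-lived-mutant up-stratum pattern
  (0.35/0.40/0.25) and the short-lived-mutant pattern (0.02/0.36/0.62),
  with offset ±1 log2 and noise SD 0.2 around the planted calls.
* **Reporter stacks**: well-separated 3D Gaussian foci (sigma 1.5 px
  in-plane, 2 sections axially, centered within one section of the
  middle plane, i.e. the focal plane of the cells being imaged) over a
  uniform diffuse background with additive Gaussian noise clipped at
  zero. When a target diffuse fraction is requested, foci amplitudes are
  rescaled so the noise-to-background ratio stays fixed. The recorded
  truth integrates the actual generated components.

What passing tests on these conditions show: the statistics are
calibrated and powerful when the generator's assumptions hold
(independent Gaussian log-ratio noise, independent missingness, clean
archetypes, homogeneous strain behaviour). What they do not show:
robustness to peptide-level interference, ratio compression,
intensity-dependent missingness, correlated replicates, batch structure,
or fractionation artifacts — none of which the generator emulates. The
headline numbers of the original deep dataset (9,398 reproducible
protein groups, 627 age-variant proteins, median replicate r = 0.85)
depend on the full MS dataset and are not reproduced at synthetic desk
scale; the pipeline reports the analogous quantities for whatever
dataset it is given.

## Numerical and determinism choices

All randomness flows through `numpy.random.default_rng` seeds carried in
parameter objects; identical inputs and seeds give byte-identical
outputs, including written TSVs. FDR correction delegates to
statsmodels' BH implementation; Ward linkage to scipy; both are checked
in the test suite against independent brute-force oracles (a literal
step-up formula; exhaustive pairwise agglomeration on ≤ 8 points), as
are the ANOVA (plain sums of squares) and the cumulative abundance curve
(sort-and-cumsum). Problem sizes in the acceptance script (5,000
simulated proteins, 999 permutations, twenty 15x128x128 stacks) were
chosen as the smallest scales at which the binomial/permutation errors
of the reported quantities are small relative to the effects they
measure.

## Known limitations

* The two-group ANOVA treats pooled control replicates as one group;
  with k = 20 controls the test is dominated by the target's deviation,
  but control-set heterogeneity beyond measurement noise (real datasets)
  would widen the null relative to this model.
* The gene-set permutation p is conditional on the observed background;
  it is not a competitive GSEA enrichment score and does not weight by
  rank.
* The foci/diffuse partition assigns diffuse signal under the dilated
  mask to the focal component; with the default spot sizes this biases
  the cytoplasmic fraction by well under 0.01 per focus percent-area,
  but images dense with large foci would need a background-corrected
  variant.
* Only identifier-level gene-set matching is supported; ortholog mapping
  and annotation-database enrichment are out of scope.
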