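# proteoage

Quantitative analysis of triple-SILAC aging proteomes in *C. elegans*.

Worms labeled with heavy, medium, and light isotopes at days 1, 5, and
10 of adulthood yield, per biological replicate, a MaxQuant-style
protein-groups table with three SILAC pair ratios per protein: M/H
(day 5 / day 1), L/M (day 10 / day 5), and L/H (day 10 / day 1).
`proteoage` turns such tables into:

1. a **quantifiable proteome** (≥ 2 sequence-unique peptides in every
   replicate, reverse/contaminant rows removed) and its QC profile —
   replicate Venn overlap, pairwise Pearson correlation, PCA, cumulative
   abundance curve, intensity dynamic range;
2. a set of **significantly age-variant proteins**: per protein and
   pair, a one-way ANOVA of the replicate log2 ratios against the pooled
   ratios of k intensity-matched, randomly sampled age-invariant control
   proteins, with Benjamini–Hochberg correction per pair, a Simes-
   combined protein-level call at FDR α = 0.05, and the dataset-wide
   mean ± 1.96 SD ratio band reported alongside;
3. **trend clusters**: profiles scaled to [−1, +1] and grouped by Ward's
   minimum-variance method at k = 2 (up/down) and k = 6 (archetypes such
   as "up-then-down");
4. **gene-set shifts**: the difference of medians between a named set
   (e.g. insulin/IGF-1 signaling) and the full quantified background,
   with a same-size-resampling permutation p and within-set outlier
   flags;
5. sub-cellular **localization profiles** from four-compartment
   fractionation intensities, with predominant-localization calls;
6. a **cross-strain scaling classification** — whether each age-variant
   protein looks *younger*, *unchanged*, or *older* in a long- or
   short-lived mutant at a chronologically matched age — with stacked
   cohort proportions per strain;
7. **reporter-foci quantification** of peroxisomal-import z-stacks:
   foci segmentation on a designated section, focal vs diffuse intensity
   partition summed over all sections, cytoplasmic fraction normalized
   to total intensity, and unpaired t tests between age groups.

A synthetic-data module generates every input artifact with known ground
truth (planted trends from six archetypes, intensity-dependent ratio
noise, missingness, fractionation profiles, strain scaling behaviour,
reporter stacks), so the whole pipeline is testable offline. See
`docs/methods.md` for the models, parameter defaults, and calibration
rationale.

## Worked example

Simulate a 2,000-protein experiment, ingest it, profile it, detect
age-variant proteins, and cluster their trends:

```sh
echo '{"n_proteins": 2000, "frac_age_variant": 0.08}' > params.json
proteoage simulate proteome --seed 1 --out-dir . --params params.json
proteoage ingest --replicates proteinGroups_rep1.txt \
    --replicates proteinGroups_rep2.txt --replicates proteinGroups_rep3.txt
proteoage qc --ratio-matrix ratio_matrix.tsv
proteoage detect --ratio-matrix ratio_matrix.tsv --seed 1
proteoage cluster --changes significant_changes.tsv --k 6
```

which prints:

```
input protein groups (union): 2040
removed reverse hits: 20
removed contaminants: 20
removed absent from required replicates: 0
removed below peptide threshold: 575
retained quantifiable: 1425
identified in all replicates: 2040
ratio matrix: 1425 proteins
median replicate Pearson r: 0.786
PC1/PC2 explained variance: [0.509, 0.491]
dynamic range: 7.09 decades (raw), 6.17 (0.1-99.9% trim)
significant age-variant proteins: 115 of 1425
direction  down  up
pair
MH           44  57
LM           32  29
LH           27  35
          n   mean_MH   mean_LM   mean_LH     archetype
cluster
1        12  0.488921  0.500829  1.000000         up-up
2        11 -0.498365 -0.500073 -1.000000     down-down
3        11 -0.922902  0.944792  0.026193  down-then-up
4        11  0.949225  0.013509  0.964762       up-flat
5         9  0.983651 -0.933110  0.048054  up-then-down
6         8 -0.964050 -0.009646 -0.977891     down-flat
```

Reading the output: 1,425 of 2,040 identified protein groups pass the
two-peptides-per-replicate filter; replicate agreement (median Pearson
r 0.79 on log2 ratios) and a ~7-decade intensity range match the
generator's study conditions; 115 proteins (8.1% of the quantified set)
are called age-variant at FDR 0.05, split into up/down movers per pair;
and the six trend clusters recover the planted archetypes — e.g.
cluster 5 holds proteins that rise sharply between days 1 and 5 and
fall back between days 5 and 10 ("up-then-down"). The same stages are
available as library functions (`proteoage.simulate_proteome`,
`build_ratio_matrix`, `detect_age_variant`, `ward_cluster`,
`density_shift`, `classify_scaling`, `quantify_stack`, ...).

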