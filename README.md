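# mzqpost

Post-processing for label-free quantitative proteomics, built on a
self-contained "mzq-lite" document model that mirrors the structures of
the PSI mzQuantML standard: assays, study variables, LC-MS feature lists,
run-aligned peptide consensus elements, protein lists and groups, and
quant layers (labelled matrices of abundances). The package is aimed at
people building or benchmarking quantification pipelines who need the
standard downstream steps as composable, scriptable routines:

* **idmapper** — transfer PSM identifications (from mzIdentML-style or
  TSV identification lists) onto quantified MS1 features by m/z and
  retention time, and propagate them to run-aligned peptide consensus
  elements with deterministic conflict resolution;
* **normalise** — global intensity normalisation against a reference
  run via iterative MAD-based outlier rejection, with automatic
  reference selection;
* **inference** — protein grouping from shared peptides (unique /
  common / conflicted classification, same-set and sub-set merging,
  anchor proteins) and peptide-to-group abundance aggregation;
* **anova** — per-row one-way ANOVA across assay groups on log
  abundances, plus a Bonferroni threshold helper;
* **export** — mzTab-lite and CSV output;
* **simulate** — synthetic studies with planted ground truth (scaling
  factors, group structure, differential expression, missing values) so
  every routine is testable end to end without external data.

## The statistics at the core

**Normalisation.** Assuming most peptides are not differentially
abundant, log ratios between the reference run A_r and another run A_n
centre on zero. Per run the routine computes r_i = log10(A_r,i / A_n,i)
over usable rows (Null/NaN/zero excluded), then repeats

1. m = median(r), MAD = median(|r − m|), σ = 1.4826 · MAD,
2. drop rows outside m ± 2σ (≈ the 95% interval),

until no row moves (or MAD = 0), and anti-logs the mean of the surviving
ratios: scaling factor = 10^mean(r). Multiplying A_n by this factor
aligns it with the reference. If no reference is given, every assay is
tried as reference; the one whose factor vector's standard deviation is
closest to the median of all such deviations is chosen.

**Protein inference.** A peptide mapping to one accession is *unique*;
one mapping to several accessions of which ≥ 2 own unique peptides is
*conflicted* and removed; the rest are *common*. Groups are seeded from
unique-peptide proteins and maximal same-set classes, sub-set proteins
are merged into their superset's group, and each group's *anchor* is the
member with the most peptides (ties: lexicographic). Group abundance is
the sum (or mean/median) of its peptides' values, with Null/NaN counted
as zero — for label-free data the sum is strongly recommended, for which
the replacement is exact.

**Differential expression.** Per row, a fixed-effects one-way ANOVA on
log10 abundances across k groups of assays: p = P(F_{k−1, N−k} ≥ F_obs).
Rows with any Null/NaN in the tested columns get p = NaN; zeros are
replaced by 0.5 before the log. Bonferroni: threshold = α / n_tests.

## Worked example

Simulate a 50-protein, 3 vs 3 label-free study with 10% of proteins
4-fold up in the second condition, then run the full pipeline:

```
$ printf 'n_proteins: 50\nde_fraction: 0.1\nde_fold_change: 4.0\nseed: 7\n' > sim.yaml
$ mzqpost simulate --config sim.yaml --out study.mzq --truth truth.json
$ mzqpost inference --mzq study.mzq --op sum \
    --in-ct MS:1001893 --out-ct MS:1002518 --out step1.mzq
50 protein groups
$ mzqpost normalise --mzq step1.mzq --level protein_group \
    --in-ct MS:1002518 --out-ct MS:1002519 --out step2.mzq
reference ass_2; factors: ass_0=0.8925 ass_1=1.947 ass_2=1 ass_3=0.8994 ass_4=1.796 ass_5=1.34
$ mzqpost anova --mzq step2.mzq --in-ct MS:1002519 \
    --groups "ass_0,ass_1,ass_2;ass_3,ass_4,ass_5" \
    --out-ct MS:1002520 --out step3.mzq
$ mzqpost export --mzq step3.mzq --format mztab --out result.mztab
```

The normalisation line reports the automatically selected reference run
and the per-assay scaling factors (the factor multiplies that assay's
column; ass_1's 1.947 says that run measured roughly half the reference's
intensity). Scoring the attached p-value layer against the planted truth:

```
Bonferroni threshold: 0.05/50 = 1.000e-03
significant groups: 5; planted DE proteins: 5
  PG_8 anchor=P0007 p=2.297e-05 planted=yes
  PG_22 anchor=P0021 p=2.314e-05 planted=yes
  PG_2 anchor=P0001 p=6.110e-05 planted=yes
  PG_29 anchor=P0028 p=3.476e-04 planted=yes
  PG_1 anchor=P0000 p=5.093e-04 planted=yes
```

All five planted 4-fold proteins pass the Bonferroni-corrected 0.05
cut-off, and nothing else does. `result.mztab` starts with the MTD
metadata block and carries one PRT row per protein group and one PEP row
per peptide, with per-assay abundance columns.

Every CLI subcommand is a thin wrapper over a library function
(`mzqpost.normalise_layer`, `mzqpost.infer_protein_abundance`,
`mzqpost.attach_pvalue_layer`, ...) that takes and returns
`QuantDocument` objects, so the same pipeline can be driven from Python.

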