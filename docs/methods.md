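# Methods

This note documents the models, conventions and numerical choices behind
mzqpost, in the order data flows through the pipeline, and what the
synthetic studies used for validation do and do not emulate.

## Document model and serialisation

The in-memory model is a faithful subset of mzQuantML: assays, study
variables, per-run feature lists, run-aligned `PeptideConsensus`
elements, a protein list, derived protein groups, and quant layers
(matrices of values typed by a PSI-MS CV term, rows = entities, columns
= assays). The on-disk dialect ("mzq-lite") mirrors the standard's
element names without namespaces or XSD validation: the goal is
structural fidelity, not schema compliance.

Missing values are three-way and the distinction is load-bearing:

* a **number** (zero included) — a measured value;
* **NaN** — a computed not-a-number (token `NaN`);
* **Null** — never measured (token `null`).

Normalisation ignores Null, NaN *and* zero when estimating factors but
passes all three through unchanged; protein aggregation replaces Null
and NaN by zero (exact for the recommended sum operator); the ANOVA sets
a row's p to NaN if any tested cell is Null or NaN, and replaces zeros
by 0.5 before the log. Empty matrix cells are a format error — a missing
value must be written deliberately.

Retention time is always seconds in the model; readers convert when a
unit attribute says minutes. Floats serialise with `repr` (shortest
round-trip decimal), elements in list order: writing is byte-stable and
`read(write(doc))` reproduces the document exactly, which the suite
checks over randomly generated studies. All invariants (unique ids,
resolvable references, matrix shapes, anchor membership) are enforced on
read and before any byte is written.

P-value layers are ordinary quant layers with an empty column-reference
list and one value per row, avoiding a second matrix type for the
single-column case.

## Identification mapping

Quantification (MS1 feature detection) and identification (MS2 database
search) come from different tools, so PSMs must be transferred onto
features afterwards. Step 1, per run: a PSM matches a feature when
|Δm/z| ≤ 0.05 Da (absolute, not ppm) and the PSM's RT falls inside the
feature's reported RT window — or within ±10 s of the centroid when no
window is present — and charges agree when both are known. A PSM
matching several features is assigned only to the best one (smallest
|Δm/z|, then |ΔRT|, then feature id), so one spectrum can never inflate
several features; a feature may accumulate several PSMs, of which the
best-scoring one provides its identification. Step 2: a consensus
element inherits an identification when ≥ 1 of its features has one;
across runs the identification carried by the most feature lists wins,
ties break to the lexicographically smallest (sequence, modifications)
pair, and any disagreement sets the conflict flag with the losing
candidates kept as user params. Both steps are order-independent, which
the suite checks against an exhaustive all-pairs oracle.

PSMs without RT are representable (`rt=None`) but unusable: mapping
raises rather than assuming RT 0, since the RT must be recovered
upstream from the spectrum files. Decoy PSMs are excluded by default.

## Normalisation

Per non-reference assay, log10(ref/target) ratios over usable rows
(both cells positive numbers) are trimmed by the iterative MAD rule:
median m, MAD, σ = 1.4826·MAD, drop rows outside m ± 2σ, repeat. The
interval is **median-centred** (the natural centre for a MAD-based
scale) and the median is recomputed each iteration. Convergence: an
iteration removing no rows, MAD = 0 (the constant-ratio fast path, which
makes exact ratios recover exact factors), or a 100-iteration cap; the
row count strictly decreases otherwise, so termination is guaranteed.
The factor is 10^mean of the survivors and multiplies the target column;
Ar/An orientation is fixed, so planted generator factors are recovered
directly when the reference's factor is 1.

Note the fixpoint over-trims relative to a single 2σ pass (each
iteration's MAD shrinks), typically discarding ~10% of rows on clean
data; this is the specified behaviour and costs a little efficiency, not
bias, on symmetric ratio distributions.

Automatic reference selection evaluates every assay as candidate
reference, takes the sample standard deviation (n−1) of each factor
vector, and picks the assay closest to the median stdev — a central
run, not an outlier. Distances that are mathematically equal (the two
middle stdevs of an even-length list are always equidistant from the
median) are compared with a 1e-9 relative tolerance so the lowest-id
tie-break is decided deterministically rather than by rounding noise.

Rows whose id contains the decoy tag, and (for peptide-level runs with
`identified_only`) rows without a sequence, are excluded from factor
estimation but appear, scaled, in the output layer. Fewer than two
usable rows is a hard error; a (theoretically unreachable) empty
surviving set yields factor 1 with a warning flag.

## Protein inference

Definitions: a peptide with one accession is unique; with several
accessions of which ≥ 2 own unique peptides, conflicted (removed from
quantification); otherwise common. "≥ 2" resolves the edge where exactly
one mapped protein has unique peptides: such peptides stay common and
join that protein's group. Same-set/sub-set relations are computed on
peptide sets *after* conflicted-peptide removal, keeping one consistent
peptide universe for classification, grouping and quantification.

Grouping: maximal peptide sets seed groups holding their exact owners
plus all strict-subset proteins; a subset of several maximal sets joins
the one whose exact owners include the smallest accession. One corner
case the definitions leave open: a common peptide whose proteins sit in
two different groups neither of which has a unique-peptide protein
(constructible in random bipartite graphs). To preserve the partition
invariant — every non-conflicted peptide in exactly one group — such a
peptide is assigned to the group with the lexicographically smallest
anchor. The anchor is the member with the most peptides, ties
lexicographic; this single rule reproduces all three stated cases
(singleton → the protein; same-set → first accession; sub-set → most
peptides). Group ids are `PG_<n>` in anchor order. The whole procedure
is checked against an independent set-algebra oracle on random graphs.

Aggregation: sum, mean or median over the group's peptide values with
Null/NaN → 0 applied first, uniformly across operators (it is a no-op
for sum, which is the recommended operator for label-free data; the CLI
warns otherwise). Unidentified consensus rows never participate — no
accession mapping exists for them. With sum, total group abundance
exactly equals total non-conflicted peptide abundance, a conservation
law the suite asserts to 1e-9 relative.

## ANOVA

Per row, cells of the spec'd assay columns only: Null/NaN anywhere →
p = NaN (this short-circuit wins over the zero rule); negative values →
p = NaN with a log message (log undefined; upstream tools occasionally
produce them); zeros → 0.5; then log10 and a fixed-effects one-way
ANOVA, p from the upper tail of F(k−1, N−k) via scipy. The log base
provably cancels in F — the suite verifies base-10 and base-e give
identical p — and with k = 2 the p equals the pooled two-sided t-test to
1e-10. Degenerate rows: SSW = 0 with SSB = 0 gives p = 1 (identical
values), SSW = 0 with SSB > 0 gives p = 0. N − k ≤ 0 yields NaN for every
row with a warning. No multiplicity adjustment happens inside the
routine; `bonferroni_threshold(alpha, n)` = α/n is applied by the
caller.

## Exporters

The mzTab exporter targets the mzTab 1.0 tabular shape: an MTD block
(version, mode, assay and study-variable declarations), PRH/PRT rows
keyed by each group's anchor with `ambiguity_members`, PEH/PEP peptide
rows, and one `*_abundance_assay[n]` column per assay per layer, n
following document assay order; single-column p-value layers become
`opt_global_*` columns. Missing values are the literal `null`;
unknowable metadata slots are `null` per the mzTab convention. The
exporter aims at structural fidelity (every value appears exactly once,
bit-equal after reparse) rather than repository-grade CV completeness.
The CSV exporter writes one layer as an RFC-4180 table (id column plus
one column per assay, named by assay names). Both are byte-deterministic.

## Synthetic studies

The generator emulates the statistical structure the routines assume:

* **Abundances are hierarchical**: a protein-level loading (log10 sd
  0.8 across proteins) plus a per-peptide ionisation-efficiency offset
  (log10 sd 0.15), so sibling peptides are correlated as in real LC-MS
  data and a protein's summed abundance is genuinely less noisy than a
  single peptide. Measurement noise is multiplicative log-normal, sd 0.1
  log10 units per peptide cell, independent across cells.
* **Run effects**: each assay's column is divided by its true scaling
  factor (given, or drawn log-normal with sd 0.15 log10), so
  normalisation should recover exactly those factors against a
  unit-factor reference.
* **Graph structure**: each seed protein gets 4–10 unique peptides;
  a configurable fraction of proteins receives a companion protein
  sharing a proper subset of its peptides (a planted sub-set/same-set
  group with no unique peptides of its own); conflicted edges optionally
  connect two unique-owning proteins. Expected classification, grouping
  and anchors are therefore known exactly.
* **Differential expression** multiplies all peptides of a chosen
  protein fraction by the fold change in the second condition's assays.
* **Contamination**: cells go missing (Null) completely at random;
  a small fraction of rows is perturbed by 1–2 orders of magnitude in
  one assay — outliers the MAD loop is expected to reject.
* One `numpy` Generator is seeded once per run; every draw flows from
  it, so a fixed seed reproduces the study byte-for-byte.

PSM sets are emitted at feature coordinates with configurable uniform
jitter, identification rate, decoy rate, and a conflict rate that swaps
the sequence reported in one run (planting consensus conflicts with a
known count). The planted feature assignment is returned alongside the
records.

What the generator does **not** emulate: retention-time drift and
alignment errors, chromatographic peak shapes, informative (intensity-
dependent) missingness, correlated noise between runs, and interference
between co-eluting analytes. Passing tests therefore demonstrate
algorithmic correctness under the stated statistical model, not
robustness to every pathology of real data.

## Validation experiment sizes

The acceptance checks run at desk scale, chosen to make the measured
properties statistically meaningful while keeping the whole suite in
seconds: factor recovery on a 6-assay study of ~2000–3500 peptide rows
with planted factors {1.0, 0.5, 2.0, 1.5, 0.8, 1.2}, 10% missing cells
and 5% outlier rows (recovered within 2% relative); oracle-equivalence
over 20 reference-selection instances, 200 random bipartite grouping
graphs and 100 random mapping instances; a 1000-row null simulation for
type-I calibration (fraction of p < 0.05 inside the exact binomial 99%
band); 100 generated documents for round-trip identity; and the
end-to-end pipeline (simulate → inference → normalise → ANOVA → mzTab)
on a 200-protein, 3 vs 3 study with 15% of proteins at fold change 4.
The differential-expression experiment uses well-covered proteins (6–12
peptides) and a complete matrix: it isolates statistical power of the
pipeline, while robustness to missing cells and outliers is exercised by
the factor-recovery and conservation experiments. With 3 replicates per
group the error degrees of freedom are only 4, so Bonferroni-level
p-values require protein-level replicate noise of ≲ 0.04 log10 units —
attainable when several correlated peptides are summed, which is exactly
what the hierarchical abundance model provides; a flat model with fully
independent peptide abundances would leave the sum dominated by its
largest term and cap power well below that, regardless of peptide count.

## Known limitations

* Only `AssayQuantLayer`-shaped input is normalised; ratio layers,
  quantile or loess normalisation are out of scope.
* Aggregation offers sum/mean/median only; no weighted or ratio-based
  schemes, and the Null/NaN → 0 convention — while exact for sum —
  biases mean and median downward for rows with missing cells.
* The Null→0 convention interacts badly with the downstream log-scale
  ANOVA when cells are missing: a dropped peptide dents one assay's sum
  and inflates within-group variance. This is inherent to the
  convention, not a defect; power figures assume complete matrices.
* m/z tolerance is absolute Da only (no ppm); MS2-level mapping and FDR
  estimation are out of scope.
* mzTab output is a structural "lite" dialect, not a fully validated
  repository submission.
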