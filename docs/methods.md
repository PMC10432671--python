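# Methods

This note documents the models, rules and numerical choices implemented in
`neovax`, what the synthetic-data generators do and do not emulate, and the
design decisions taken where the underlying procedure was open.

## Somatic variant filter

The filter consumes annotated, protein-level missense calls (TSV), not
VCF/BAM: read alignment, variant calling and transcript annotation are
upstream of this package. The six rules form a conjunction:

| rule | condition | default |
|---|---|---|
| tumor coverage | tumor depth strictly greater than `coverage_min` | 10 reads |
| normal coverage | normal depth strictly greater than `coverage_min` | 10 reads |
| normal VAF | alt/depth in normal < `normal_vaf_max` | 1% |
| tumor VAF | alt/depth in tumor > `tumor_vaf_min` | 15% |
| strand support | ≥ 1 variant read on each strand | — |
| population MAF | ≤ `pop_maf_max` (absent value = 0, novel) | 1% |

Choices: "greater than ×10 coverage" is read strictly (`> 10`); strand
presence is operationalized as ≥ 1 supporting read per strand (a presence
statement, not a count); VAF is recomputed from read counts rather than
trusting an upstream caller's field, so the filter is self-contained. Only
single-residue substitutions are accepted — the epitope machinery is
defined for amino-acid substitutions, and frameshifts/indels are rejected
at parse time. The audit names the *first* failing rule in the table order
above; rules are independent, so order affects only attribution, not
retention.

## Epitope enumeration

Coordinates are 1-based throughout (`aa_pos` is the residue index in the
named protein, matching protein-change notation such as Q61R). The mutation
context is `flank_len` = 10 native residues per side (a 21-mer for interior
mutations, mutant at offset 11). Contexts and windows are truncated at
protein termini and never padded: padding characters would create
non-biological peptides that a predictor cannot score. For window length L
and protein length n, the number of windows containing position p is
`max(0, min(p, n−L+1) − max(1, p−L+1) + 1)` — equal to L for interior
mutations. Windows containing `X` or other non-standard residues are
dropped; duplicate mutant peptides (possible in low-complexity sequence)
are collapsed to the first occurrence. Human runs enumerate 9-mers only;
mouse runs enumerate {8, 9, 10}; both are configurable.

## Selection rules

Anchor positions are {1, 2, C-terminus} uniformly across alleles and
lengths; no allele-specific anchor maps are used. Mutant-side thresholds
are strict (`<`), the wild-type floor strict (`>`), the mouse rank
boundary inclusive (`≤ 1.0`, "within the 1%").

Open points resolved here:

- The printed rules give only a mutant-side threshold for HLA-A\*24:02 and
  HLA-A\*03:01. The differential branch for these alleles requires the
  wild-type affinity to exceed the *same* allele threshold, symmetric with
  the HLA-A\*02:01 rule (whose wild-type floor is separately configurable
  as `wt_affinity_min_a0201`). This preserves the differential-binding
  intent and is configurable.
- "Similar" affinities are quantified as a max/min ratio ≤
  `similar_affinity_fold` (default 3) — the source procedure never
  quantifies similarity.
- A narrative aside about a 500 nM binding threshold is not implemented as
  a rule; the stated per-allele thresholds govern.
- The mouse rule takes the best rank per candidate over H2-Db/H2-Kb
  (per-allele best, not both-allele).
- `rule_path` labels the branch that fired: `anchor_differential` means the
  differential rule (mutant binds, wild type does not), whatever the
  position; `nonanchor_similar` the similar-pair rule at a TCR-facing
  position; `rejected_position` a similar pair whose mutation sits at an
  anchor (the similar rule only applies off-anchor).

The bundled `mock_affinity_predictor` is a deterministic hash of
(peptide, allele, seed) mapped log-uniformly onto [1, 50000] nM with rank a
fixed monotone transform of affinity. It exists so the pipeline runs and is
testable offline; its numbers carry no biology, and real runs should ingest
a prediction table from an external predictor via `read_affinity_table`.

## Binding assay quantification

Stabilization curves are modelled as a four-parameter logistic in log10
concentration, `MFI(c) = b + (p − b)/(1 + (EC50/c)^h)`; EC50 is the
concentration at the midpoint of the *fitted* baseline and plateau, which
resists single-point noise better than observed min/max. The fit
(`scipy.optimize.curve_fit`) uses σ ∝ signal, matching the multiplicative
error structure of flow-cytometry MFI; bounds keep the Hill slope in
[0.1, 10] and log-EC50 within ±2 decades of the tested range. If the fit
fails or is degenerate (plateau ≤ baseline, half-max not bracketed by the
observations, EC50 outside the tested range), a monotone log-linear
interpolation between the two observations bracketing the observed
half-max is used; flat curves (relative dynamic range < 0.2) or
non-bracketing curves yield no EC50. Competition assays fit inhibition
`1 − signal/reference` with the same machinery (unweighted — inhibition is
not multiplicative-noise scaled) and report IC50 at 50% inhibition; curves
never reaching 50% yield none.

The dilution series is 8 steps from 100 µM; the serial factor is not
stated by the source procedure, so the generator defaults to 3-fold
(spanning 0.046–100 µM, a typical stabilization-assay range). The fitters
never assume the factor — they read concentrations from the data.

The binder call — determinate EC50/IC50 within the tested range *and*
plateau ≥ `binder_plateau_fold` (1.5) × no-peptide control for
stabilization, or maximal inhibition ≥ 0.5 for competition — is this
package's own criterion: the source procedure reports binder counts
without stating one. 1.5× is the smallest fold that cleanly separates the
generator's binder and non-binder classes and is configurable.

## T-cell responder rule

`stim ≥ responder_fold × max(unstim, zero_floor)` with `responder_fold` =
2 (inclusive, "twice or higher") and `zero_floor_pct` = 0.1% so that a 0%
measured background cannot make every stimulated value a responder.

## Summary table

Per (sample, allele): `n_predicted` selected candidates, `n_bound` binder
calls among them, `n_immunogenic` binders with ≥ 1 responding subject,
`n_displayed` peptides with direct display evidence (ligandome overlap or
tumor-recognition); a totals row sums the columns. Rates are percentages
*truncated* (not rounded) to one decimal — 44/66 prints as 66.6 — matching
the convention of the summary statistics this table reproduces. The
invariant `n_immunogenic ≤ n_bound ≤ n_predicted` is enforced, and a
peptide appearing downstream without an upstream record is a consistency
error.

## Long-peptide design

The 31-mer LP is the native window of the mutated protein covering the
H2-Db epitope, the H2-Kb epitope and the mutation, centred on the mutation
as nearly as termini allow (ties toward the N-terminus). The source
procedure states only that each LP carries one Db and one Kb minimal
epitope; the native-window reading (no linkers, no concatenation) is this
package's choice, consistent with the flanking-context philosophy of the
enumeration stage, and pairs that cannot be covered by any native 31-mer
are reported as errors rather than forced. Since both epitopes contain the
mutation, two ≤10-mers always fit (span ≤ 19); the error path exists for
longer or externally supplied epitopes and for proteins shorter than 31
residues.

## Immunopeptidome matching

Exact string membership of the mutant peptide in the eluted list, with
wild-type-only hits reported separately. Optional I/L-equivalent matching
(leucine and isoleucine are isobaric in MS) is off by default so the
strict database-identity semantics govern; enabling it can only grow the
overlap.

## Synthetic data: what it emulates and what it does not

Generators are pure functions of (parameters, seed) using
`numpy.random.default_rng`. Decoy variants are *single-fault*: each fails
exactly one filter rule, making retention counts closed-form. Binding
curves use Hill slope 1 (EC50 as half-maximal point is slope-invariant)
with multiplicative Gaussian noise of coefficient of variation `noise_cv`
(MFI error scales with signal); default study-like conditions are baseline
20, plateau 400 MFI, CV 5% where noise is wanted. T-cell readouts place
planted responders at ≥ 2.5× background and non-responders ≤ 1.5×, so the
2× rule separates classes with margin. Ligandome backgrounds are uniform
random 9-mers over the 20-letter alphabet: candidate matching is exact
string comparison, so compositional realism is irrelevant to what the
tests establish.

The generators do **not** emulate read-level sequencing data, mass
spectra, flow-cytometry event data, linkage between mutations, peptide
chemistry (synthesizability, solubility), or predictor error. Passing
tests therefore demonstrate the correctness of the *rules and estimators*
on data satisfying their assumptions — not the biological accuracy of
external predictors or assays on real samples.

## Problem sizes and determinism

Default test and acceptance problem sizes: 5 true + 12 decoy variants per
bundle, 27 windows per variant, 100 Monte-Carlo curves for EC50 recovery,
200-peptide ligandome backgrounds. These sizes give closed-form or
tight-stochastic expectations while keeping runs fast. All randomness
flows from a single seed; pipeline reruns with identical inputs and seed
produce byte-identical outputs, recorded as SHA-256 digests in the run
manifest.

## Known limitations

- The filter's VAF is read-fraction based; an alternative reading of VAF
  (per-sample counting) exists in the source material's wording but is
  non-standard and not implemented.
- No proteasomal-cleavage or TAP-transport scoring, no expression-level
  confirmation rule (transcriptome support is treated as upstream
  evidence), no predictor re-implementation, and no flow-cytometry gating
  or survival statistics — these are out of scope by design.
- The anchor set {1, 2, C-terminus} is a uniform approximation; real
  allele-specific anchor maps differ (e.g. position 5 contributes for
  H2-Db) and could be added as configuration.
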