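# neovax

A Python package for neoantigen identification and validation in tumors:
from a table of somatic missense variants, through mutant epitope
enumeration and allele-specific MHC-I selection rules, to cell-based
binding-assay quantification (EC50/IC50), T-cell responder calling,
31-mer long-peptide (LP) vaccine design, immunopeptidome matching and
per-sample candidate-funnel summaries. It is aimed at immunoinformatics
practitioners who need a transparent, testable version of the candidate
funnel that sits between a variant caller and the wet lab.

## The method

**Somatic filter.** A protein-level missense call is kept iff

- tumor depth > 10 and normal depth > 10 reads (strict),
- normal VAF < 1% and tumor VAF > 15%, where VAF = alt reads / depth,
- at least one variant-supporting read on each DNA strand,
- population MAF ≤ 1% (common germline variants removed).

**Epitope enumeration.** Each retained substitution is applied to its
protein; a 21-mer context (10 native flanking residues per side, truncated
at termini, never padded) is extracted and every 8/9/10-mer window
containing the mutant residue is emitted with its wild-type counterpart.
An interior mutation yields exactly L windows per length L (27 for
{8,9,10}); human runs enumerate 9-mers only.

**Selection rules.** Peptide positions 1, 2 and the C-terminus are MHC
anchor positions; interior positions face the TCR. With predicted
affinities a(mut), a(wt) on an allele with threshold T (HLA-A\*02:01:
1000 nM, HLA-A\*03:01: 1500 nM, HLA-A\*24:02: 2500 nM):

- *differential*: a(mut) < T and a(wt) above its floor — selected at any
  position (the mutation itself creates the binder);
- *similar pair*: a(mut), a(wt) < T with ratio ≤ 3 — selected only if the
  mutation is TCR-facing.

Mouse (H2-Db/H2-Kb) candidates are selected when the best percentile rank
over the two alleles is ≤ 1% (inclusive).

**Assays.** Stabilization curves (TAP-deficient T2/RMA-S cells, 8 serial
dilutions from 100 µM) are fitted with a four-parameter logistic in
log-concentration, MFI = b + (p−b) / (1 + (EC50/c)^h), weighted for
multiplicative MFI noise; EC50 is the concentration at half-maximal MFI,
with a log-linear interpolation fallback. Competition assays report IC50 at
50% inhibition of a labelled reference peptide. A binder additionally needs
a plateau ≥ 1.5× the no-peptide control. A subject responds to a peptide
when stimulated %IFN-γ+ of CD8+ is at least twice the unstimulated
background.

**LP design.** For each variant with one H2-Db and one H2-Kb selected
epitope, the LP is the native 31-residue window of the mutated protein
covering both epitopes, centred on the mutation — always an exact
substring, never a concatenation.

Every stage has a synthetic-data generator with planted ground truth
(`neovax.simulate`), so the whole pipeline is testable offline; a
deterministic mock affinity predictor stands in for the external
neural-network predictor whose output the pipeline normally ingests.

## Worked example

```bash
python examples/08_full_pipeline.py
```

```
stage counts: {'variants_in': 17, 'variants_retained': 5, 'candidates': 135,
 'selected': 10, 'binders': 6, 'responder_calls': 3, 'long_peptides': 5, 'ms_overlap': 0}
somatic truth recovered  : True
selection truth recovered: True
MS overlap (expect 0)    : 0
sample allele  n_predicted  n_bound  n_immunogenic  n_displayed  binding_rate_pct  immunogenic_rate_pct
sample  H2-Kb            5        3              2            0              60.0                  66.6
sample  H2-Db            5        3              1            0              60.0                  33.3
 total                  10        6              3            0              60.0                  50.0
```

Seventeen simulated variants (5 true somatic, 12 single-fault decoys) are
filtered back to exactly the 5 planted calls; 135 mutant windows are
enumerated, the 10 planted peptides selected by the rank rule, 6 planted
binders and 3 responder pairs recovered, 5 LPs designed (one Db + one Kb
epitope each), and the MS ligandome query returns the expected empty
overlap. The other scripts in `examples/` demonstrate each capability in
isolation. The same stages are available as a CLI
(`neovax simulate|filter|enumerate|select|assay|design-lp|match-ms|summarize|run`).

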