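"""Epitope enumeration: windows of the mutated protein containing the mutation.

Applies a missense substitution to a protein, builds the 21-residue context
(10 native flanks per side) and enumerates all 8/9/10-mer mutant windows
paired with their wild-type counterparts.
"""

from neovax import apply_mutation, build_context_21mer, enumerate_mutant_windows

protein = (
    "MSDNGPQNQRNAPRITFGGPSDSTGSNQNGERSGARSKQRRPQGLPNNTASWFTALTQHGKEDLKFPRGQGV"
    "PINTNSSPDDQIGYYRRATRRIRGGDGKMKDLSPRWYFYYLGTGPEAGLPYGANKDGIIWVATEGALNTPKD"
)
ctx = apply_mutation(protein, aa_pos=84, ref_aa="I", alt_aa="T", protein_id="NCAP")
context, offset = build_context_21mer(ctx)

print(f"mutation          : {ctx.ref_aa}{ctx.aa_pos}{ctx.alt_aa} in a {len(protein)}-aa protein")
print(f"21-mer context    : {context} (mutant residue at offset {offset})")

candidates = enumerate_mutant_windows(ctx, lengths=(8, 9, 10))
print(f"candidate windows : {len(candidates)} (8 + 9 + 10 for an interior mutation)")
for c in [c for c in candidates if c.length == 9][:3]:
    print(f"  9-mer mut {c.mutant_peptide}  wt {c.wt_peptide}  mutation at position {c.mut_offset}")
# Each mutant/wild-type pair differs at exactly one residue - the substitution.
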