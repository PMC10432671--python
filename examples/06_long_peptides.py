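"""31-mer long-peptide design around a shared mutation.

Takes one H2-Db 9-mer and one H2-Kb 8-mer epitope from the same missense
variant and extracts the native 31-residue window of the mutated protein
that covers both, centred on the mutation.
"""

from neovax import apply_mutation, design_31mer, enumerate_mutant_windows

protein = (
    "MTEYKLVVVGAGGVGKSALTIQLIQNHFVDEYDPTIEDSYRKQVVIDGETCLLDILDTAGQEEYSAMRDQYM"
    "RTGEGFLCVFAINNTKSFEDIHQYREQIKRVKDSDDVPMVLVGNKCDLAARTVESRQAQDLARSYGIPYIET"
)
ctx = apply_mutation(protein, aa_pos=61, ref_aa="Q", alt_aa="R", protein_id="KRAS")
windows = enumerate_mutant_windows(ctx, (8, 9), source_variant="var61")
db = next(w for w in windows if w.length == 9 and w.mut_offset == 5)
kb = next(w for w in windows if w.length == 8 and w.mut_offset == 2)

lp = design_31mer(db, kb, ctx)
print(f"Db epitope : {db.mutant_peptide} (mutation at {db.mut_offset})")
print(f"Kb epitope : {kb.mutant_peptide} (mutation at {kb.mut_offset})")
print(f"31-mer LP  : {lp.sequence}")
print(f"offsets    : Db@{lp.db_offset}, Kb@{lp.kb_offset}, mutation@{lp.mut_offset}")
print(f"native     : {lp.sequence in ctx.mut_sequence}")
# The LP is an exact substring of the mutated protein (no linkers), with the
# mutation at offset 16 - dead centre of the 31-mer - when termini allow.
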