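"""Querying an MS-eluted ligandome for candidate neoantigens.

Builds a background ligandome of random 9-mers, queries the candidate list
(empty overlap - the structural null), then plants one candidate and shows
I/L-equivalent matching.
"""

from neovax import EpitopeCandidate, gen_ms_peptides, match_candidates

candidates = [
    EpitopeCandidate("NLAPYIKSV", "NLAPAIKSV", 5, "v1"),
    EpitopeCandidate("KLFEKVTAV", "KLFGKVTAV", 4, "v2"),
]

ligandome = gen_ms_peptides(n_background=500, seed=6)
report = match_candidates(ligandome, candidates)
print(f"background-only ligandome ({len(ligandome)} peptides): "
      f"{len(report.mutant_hits)} candidate hits")

planted = gen_ms_peptides(n_background=500, planted=["NLAPYIKSV"], seed=6)
report = match_candidates(planted, candidates)
print(f"after planting NLAPYIKSV: hits = {sorted(report.mutant_peptides)}")

il_lig = ["NLAPYLKSV"]  # MS cannot tell I from L
print(f"exact match vs NLAPYLKSV : {len(match_candidates(il_lig, candidates).mutant_hits)}")
print(
    "I/L-equivalent match     : "
    f"{sorted(match_candidates(il_lig, candidates, il_equivalent=True).mutant_peptides)}"
)
# Exact matching is the default; I/L equivalence only widens the overlap.
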