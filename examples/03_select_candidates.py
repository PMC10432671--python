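"""Allele-specific selection rules on mutant/wild-type affinity pairs.

Shows the two human selection branches (anchor differential vs TCR-facing
similar pair) and the mouse 1%-rank rule, including the inclusive boundary.
"""

from neovax import (
    AffinityPrediction,
    EpitopeCandidate,
    PipelineConfig,
    select_human_candidates,
    select_mouse_candidates,
)

cfg = PipelineConfig()
allele = "HLA-A*02:01"


def run_case(label, mut_offset, mut_nm, wt_nm):
    mut, wt = "KLFEKVTAV", None
    wt = mut[: mut_offset - 1] + "G" + mut[mut_offset:]
    cand = EpitopeCandidate(mut, wt, mut_offset, "var1", allele=allele)
    affinities = {
        (mut, allele): AffinityPrediction(mut, allele, mut_nm, 1.0),
        (wt, allele): AffinityPrediction(wt, allele, wt_nm, 1.0),
    }
    (d,) = select_human_candidates([cand], affinities, cfg)
    print(
        f"{label:34s} mut {mut_nm:6.0f} nM, wt {wt_nm:6.0f} nM, position {mut_offset}"
        f" -> {'selected' if d.selected else 'rejected'} ({d.rule_path.value})"
    )


run_case("anchor, mutation creates binder", 2, 800, 1500)
run_case("anchor, both bind similarly", 2, 300, 350)
run_case("TCR-facing, both bind similarly", 5, 300, 350)
run_case("mutant above threshold", 5, 1200, 5000)

mouse = EpitopeCandidate("SIINFEKL", "SIINFEKV", 8, "var2")
for rank in (0.5, 1.0, 1.5):
    preds = {("SIINFEKL", "H2-Kb"): AffinityPrediction("SIINFEKL", "H2-Kb", 100.0, rank)}
    (d,) = select_mouse_candidates([mouse], preds, cfg)
    print(f"mouse rank {rank:4.1f}% on H2-Kb -> {'selected' if d.selected else 'rejected'}")
# Rank 1.0 is selected: 'within the 1% percentile rank' is an inclusive cut-off.
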