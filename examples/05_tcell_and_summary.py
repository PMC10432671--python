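"""Responder calling and the per-sample candidate funnel table.

Calls T-cell responders with the twice-background rule on simulated
readouts, then tallies a published-style summary table of predicted /
bound / immunogenic counts per sample and allele.
"""

from neovax import PipelineConfig, call_responder, gen_tcell_assays, summarize_counts

cfg = PipelineConfig()
peptides = [f"pep{i}" for i in range(5)]
planted = {("D1", "pep0"), ("D2", "pep0"), ("D3", "pep4")}
records = gen_tcell_assays(peptides, planted, background_pct=0.4, seed=4, cfg=cfg)

called = {(r.subject_id, r.peptide_id) for r in records if call_responder(r, cfg)}
print(f"responder pairs called: {sorted(called)}")
print(f"matches planted truth : {called == planted}")

predicted = [("sampleA", "H2-Db", p) for p in peptides]
binders = {p: p != "pep3" for p in peptides}  # pep3 failed the binding assay
responders = [(s, p, True) for s, p in called]
table = summarize_counts(predicted, binders, responders, cfg=cfg)
print(table.to_string(index=False))
# n_immunogenic counts binder peptides with at least one responding subject;
# rates are percentages truncated to one decimal.
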