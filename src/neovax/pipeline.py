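"""End-to-end orchestration: filter -> enumerate -> predict -> select ->
assays -> LP design -> MS matching -> summary, with a reproducibility
manifest.

The external affinity predictor is integrated file-based only: either a
prediction table is supplied, or the bundled deterministic mock predictor
is used (``use_mock_predictor``).  The run never shells out.  Every stage
writes its TSV/FASTA output under the output directory; the manifest
(JSON, written last) records the config snapshot, SHA-256 digests of all
inputs and outputs, per-stage record counts, seed and package version.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

from . import io as nio
from .assays import AssayType, call_binder, call_responder, fit_ec50, fit_ic50, summarize_counts
from .config import PipelineConfig
from .epitopes import EpitopeCandidate, apply_mutation, enumerate_mutant_windows
from .errors import NotCoverableError, PipelineError
from .ligandome import match_candidates
from .lp import design_31mer
from .selection import (
    MOUSE_ALLELES,
    mock_affinity_predictor,
    select_human_candidates,
    select_mouse_candidates,
)
from .variants import apply_somatic_filters

__all__ = ["RunManifest", "run_pipeline", "HUMAN_LENGTHS", "MOUSE_LENGTHS"]

#: Minimal-epitope lengths enumerated per species (human candidates are
#: 9-mers; the mouse pipeline scores 8/9/10-mers).
HUMAN_LENGTHS = (9,)
MOUSE_LENGTHS = (8, 9, 10)

VERSION = "0.1.0"


@dataclass
class RunManifest:
    config: dict
    seed: int
    version: str
    species: str
    input_digests: dict[str, str] = field(default_factory=dict)
    output_digests: dict[str, str] = field(default_factory=dict)
    stage_counts: dict[str, int] = field(default_factory=dict)

    def write(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.__dict__, indent=2, sort_keys=True) + "\n")


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(
    cfg: PipelineConfig,
    inputs: Mapping[str, str | Path],
    out_dir: str | Path,
    species: str = "mouse",
    sample_id: str = "sample",
    use_mock_predictor: bool = False,
    alleles: tuple[str, ...] | None = None,
) -> RunManifest:
    """Run all stages in dependency order; any stage may be skipped by
    omitting its input.

    ``inputs`` keys: ``variants`` and ``proteins`` (required), and
    optionally ``affinities`` (else ``use_mock_predictor`` must be set),
    ``curves``, ``tcell``, ``ms``.  Partial outputs are retained on stage
    failure; the failing stage is named in the raised error.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for key in ("variants", "proteins"):
        if key not in inputs:
            raise PipelineError(f"required input {key!r} missing")
    for key, p in inputs.items():
        if not Path(p).exists():
            raise PipelineError(f"input {key!r}: file {p} does not exist")
    if species not in ("human", "mouse"):
        raise PipelineError(f"species must be 'human' or 'mouse', got {species!r}")

    manifest = RunManifest(
        config=cfg.to_dict(),
        seed=cfg.rng_seed,
        version=VERSION,
        species=species,
        input_digests={k: _sha256(Path(p)) for k, p in sorted(inputs.items())},
    )

    def stage(name: str):
        def wrap(fn):
            try:
                return fn()
            except Exception as exc:
                raise PipelineError(f"stage {name!r} failed: {exc}") from exc

        return wrap

    # 1. filter ------------------------------------------------------------
    def _filter():
        variants = nio.read_variant_table(inputs["variants"])
        retained, audit = apply_somatic_filters(variants, cfg)
        nio.write_variant_table(retained, out / "retained.tsv")
        nio.write_audit_table(audit, out / "audit.tsv")
        manifest.stage_counts["variants_in"] = len(variants)
        manifest.stage_counts["variants_retained"] = len(retained)
        return retained

    retained = stage("filter")(_filter)

    # 2. enumerate ---------------------------------------------------------
    lengths = HUMAN_LENGTHS if species == "human" else MOUSE_LENGTHS

    def _enumerate():
        proteins = nio.read_fasta(inputs["proteins"])
        contexts = {}
        candidates: list[EpitopeCandidate] = []
        for v in retained:
            if v.protein_id not in proteins:
                raise PipelineError(f"protein {v.protein_id!r} absent from FASTA")
            ctx = apply_mutation(proteins[v.protein_id], v.aa_pos, v.ref_aa, v.alt_aa, v.protein_id)
            contexts[v.id] = ctx
            candidates.extend(enumerate_mutant_windows(ctx, lengths, source_variant=v.id))
        nio.write_candidate_table(candidates, out / "candidates.tsv")
        nio.write_fasta(
            {f"mut_{i}": c.mutant_peptide for i, c in enumerate(candidates)},
            out / "mutant_peptides.fasta",
        )
        nio.write_fasta(
            {f"wt_{i}": c.wt_peptide for i, c in enumerate(candidates)},
            out / "wt_peptides.fasta",
        )
        manifest.stage_counts["candidates"] = len(candidates)
        return contexts, candidates

    contexts, candidates = stage("enumerate")(_enumerate)

    # 3. predict -----------------------------------------------------------
    allele_set = alleles or (
        tuple(cfg.allele_thresholds) if species == "human" else MOUSE_ALLELES
    )

    def _predict():
        if "affinities" in inputs:
            preds = nio.read_affinity_table(inputs["affinities"])
        elif use_mock_predictor:
            peptides = {c.mutant_peptide for c in candidates} | {
                c.wt_peptide for c in candidates
            }
            preds = [
                mock_affinity_predictor(p, a, cfg.rng_seed)
                for p in sorted(peptides)
                for a in allele_set
            ]
            nio.write_affinity_table(preds, out / "affinities.tsv")
        else:
            raise PipelineError(
                "no affinity table supplied and use_mock_predictor is unset; "
                "provide inputs['affinities'] or enable the mock predictor"
            )
        return {(p.peptide, p.allele): p for p in preds}

    affinity_map = stage("predict")(_predict)

    # 4. select ------------------------------------------------------------
    def _select():
        if species == "human":
            expanded = [
                c.with_allele(a)
                for c in candidates
                for a in allele_set
                if (c.mutant_peptide, a) in affinity_map
            ]
            decisions = select_human_candidates(expanded, affinity_map, cfg)
        else:
            decisions = select_mouse_candidates(candidates, affinity_map, cfg, allele_set)
        nio.write_decision_table(decisions, out / "decisions.tsv")
        manifest.stage_counts["selected"] = sum(d.selected for d in decisions)
        return decisions

    decisions = stage("select")(_select)
    selected = [d for d in decisions if d.selected]

    # 5. binding assays ----------------------------------------------------
    binder_flags: dict[str, bool] = {}
    if "curves" in inputs:

        def _assays():
            curves = nio.read_curve_table(inputs["curves"])
            results = []
            for curve in curves:
                res = (
                    fit_ec50(curve)
                    if curve.assay_type is AssayType.STABILIZATION
                    else fit_ic50(curve)
                )
                res = type(res)(**{**res.__dict__, "binder": call_binder(res, curve, cfg)})
                results.append(res)
                binder_flags[res.peptide_id] = res.binder
            nio.write_binding_results(results, out / "binding.tsv")
            manifest.stage_counts["binders"] = sum(r.binder for r in results)

        stage("assays")(_assays)

    # 6. T-cell assays -----------------------------------------------------
    responder_rows: list[tuple[str, str, bool]] = []
    if "tcell" in inputs:

        def _tcell():
            records = nio.read_tcell_table(inputs["tcell"])
            for rec in records:
                responder_rows.append(
                    (rec.subject_id, rec.peptide_id, call_responder(rec, cfg))
                )
            nio.write_tcell_table(records, out / "tcell.tsv")
            manifest.stage_counts["responder_calls"] = sum(r for *_, r in responder_rows)

        stage("tcell")(_tcell)

    # 7. LP design (mouse only: one Db + one Kb epitope per variant) -------
    if species == "mouse":

        def _lp():
            by_variant: dict[str, dict[str, list]] = {}
            for d in selected:
                if d.qualifying_allele is None:
                    continue
                by_variant.setdefault(d.candidate.source_variant, {}).setdefault(
                    d.qualifying_allele, []
                ).append(d)
            lps = {}
            id_to_ctx = contexts
            for var_id, per_allele in sorted(by_variant.items()):
                db = per_allele.get(MOUSE_ALLELES[0])
                kb = per_allele.get(MOUSE_ALLELES[1])
                if not db or not kb or var_id not in id_to_ctx:
                    continue
                best_db = min(db, key=lambda d: d.mutant_nm or float("inf"))
                best_kb = min(kb, key=lambda d: d.mutant_nm or float("inf"))
                try:
                    lp = design_31mer(best_db.candidate, best_kb.candidate, id_to_ctx[var_id], cfg)
                except NotCoverableError:
                    continue
                lps[
                    f"{var_id}|db@{lp.db_offset}|kb@{lp.kb_offset}"
                ] = lp.sequence
            nio.write_fasta(lps, out / "lp.fasta")
            manifest.stage_counts["long_peptides"] = len(lps)

        stage("design-lp")(_lp)

    # 8. MS matching -------------------------------------------------------
    ms_overlap: set[str] = set()
    if "ms" in inputs:

        def _ms():
            eluted = nio.read_ms_peptides(inputs["ms"])
            report = match_candidates(eluted, [d.candidate for d in selected])
            ms_overlap.update(report.mutant_peptides)
            nio.write_ms_peptides(sorted(ms_overlap), out / "ms_overlap.tsv")
            manifest.stage_counts["ms_overlap"] = len(ms_overlap)

        stage("ms")(_ms)

    # 9. summary -----------------------------------------------------------
    def _summary():
        pred_rows = []
        seen = set()
        for d in selected:
            key = (sample_id, d.candidate.allele or "", d.candidate.mutant_peptide)
            if key in seen:
                continue
            seen.add(key)
            pred_rows.append(key)
        universe = {p for *_, p in pred_rows}
        table = summarize_counts(
            pred_rows,
            {p: f for p, f in binder_flags.items() if p in universe},
            [r for r in responder_rows if r[1] in universe],
            ms_overlap & universe,
            cfg=cfg,
        )
        table.to_csv(out / "summary.tsv", sep="\t", index=False)
        return table

    stage("summary")(_summary)

    for p in sorted(out.iterdir()):
        if p.is_file() and p.name != "manifest.json":
            manifest.output_digests[p.name] = _sha256(p)
    manifest.write(out / "manifest.json")
    return manifest
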