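"""Synthetic inputs with planted ground truth for every pipeline stage.

Each generator is a pure function of its parameters and seed and emulates
the statistical structure the downstream analysis assumes:

* ``gen_variants`` — somatic calls that pass every filter rule, plus
  single-fault decoys that each violate exactly one of the six rules, so
  filter pass/fail counts are predictable in closed form.
* ``gen_binding_curves`` — four-parameter logistic stabilization curves
  (Hill slope 1) over the configured eight-step dilution series, with
  multiplicative Gaussian noise (flow-cytometry MFI error scales with
  signal) and a no-peptide control per curve.
* ``gen_tcell_assays`` — stimulated/unstimulated %IFN-gamma+ readouts where
  planted responders sit at >= 2.5x background and non-responders within
  1.5x, cleanly separated by the 2x responder rule.
* ``gen_ms_peptides`` — a background ligandome of random 9-mers, optionally
  with planted candidate peptides.

None of the generators emulates read-level sequencing data, spectra, or
event-level cytometry; see docs/methods.md for what that implies.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .assays import AssayType, BindingAssayCurve, TcellAssayRecord
from .config import PipelineConfig
from .epitopes import EpitopeCandidate
from .errors import FormatError
from .selection import AffinityPrediction
from .variants import FILTER_RULES, SomaticVariant

__all__ = [
    "SimulationTruth",
    "gen_variants",
    "gen_proteins",
    "gen_binding_curves",
    "gen_tcell_assays",
    "gen_ms_peptides",
    "gen_affinity_table",
    "gen_bundle",
]

_AA20 = "ACDEFGHIKLMNPQRSTVWY"


@dataclass
class SimulationTruth:
    """Ground truth planted by the generators."""

    true_somatic_ids: set[str] = field(default_factory=set)
    true_selected: set[str] = field(default_factory=set)  # mutant peptides
    true_ec50: dict[str, float] = field(default_factory=dict)  # peptide -> uM
    true_responders: set[tuple[str, str]] = field(default_factory=set)
    planted_ms_overlap: set[str] = field(default_factory=set)


def _random_protein(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list(_AA20), size=length))


def gen_variants(
    n_true: int,
    n_decoy_per_rule: int,
    seed: int,
    cfg: PipelineConfig | None = None,
    protein_len: int = 101,
) -> tuple[list[SomaticVariant], SimulationTruth]:
    """True somatic calls plus one-fault decoys for each of the six rules.

    Exactly ``n_true`` variants pass every filter; for each rule in
    :data:`~neovax.variants.FILTER_RULES` exactly ``n_decoy_per_rule``
    variants fail that rule and only that rule.  Deterministic per seed.
    """
    if n_true < 0 or n_decoy_per_rule < 0:
        raise FormatError("counts must be non-negative")
    cfg = cfg or PipelineConfig()
    rng = np.random.default_rng(seed)
    truth = SimulationTruth()
    variants: list[SomaticVariant] = []
    counter = 0

    def base_fields() -> dict:
        nonlocal counter
        counter += 1
        aa_pos = int(rng.integers(15, protein_len - 14))
        ref, alt = rng.choice(list(_AA20), size=2, replace=False)
        tumor_depth = int(rng.integers(40, 81))
        vaf = float(rng.uniform(0.25, 0.45))
        alt_reads = max(2, int(round(vaf * tumor_depth)))
        fwd = int(rng.integers(1, alt_reads))
        return dict(
            id=f"var{counter:04d}",
            gene=f"GENE{counter}",
            protein_id=f"PROT{counter}",
            aa_pos=aa_pos,
            ref_aa=str(ref),
            alt_aa=str(alt),
            tumor_depth=tumor_depth,
            normal_depth=int(rng.integers(40, 81)),
            tumor_alt_reads=alt_reads,
            normal_alt_reads=0,
            alt_fwd=fwd,
            alt_rev=alt_reads - fwd,
            pop_maf=0.0,
        )

    for _ in range(n_true):
        f = base_fields()
        v = SomaticVariant(**f)
        variants.append(v)
        truth.true_somatic_ids.add(v.id)

    for rule in FILTER_RULES:
        for _ in range(n_decoy_per_rule):
            f = base_fields()
            if rule == "tumor_coverage":
                depth = cfg.coverage_min  # fails strict '>'
                alt = max(2, int(math.ceil((cfg.tumor_vaf_min + 0.1) * depth)))
                f.update(
                    tumor_depth=depth,
                    tumor_alt_reads=alt,
                    alt_fwd=1,
                    alt_rev=alt - 1,
                )
            elif rule == "normal_coverage":
                f.update(normal_depth=cfg.coverage_min)
            elif rule == "normal_vaf":
                # normal VAF at 4x the ceiling, depth kept high
                f.update(
                    normal_alt_reads=max(
                        1, int(math.ceil(4 * cfg.normal_vaf_max * f["normal_depth"]))
                    )
                )
            elif rule == "tumor_vaf":
                alt = max(2, int(math.floor(0.6 * cfg.tumor_vaf_min * f["tumor_depth"])))
                f.update(tumor_alt_reads=alt, alt_fwd=1, alt_rev=alt - 1)
            elif rule == "strand_support":
                f.update(alt_fwd=f["tumor_alt_reads"], alt_rev=0)
            elif rule == "population_maf":
                f.update(pop_maf=5 * cfg.pop_maf_max)
            variants.append(SomaticVariant(**f))
    return variants, truth


def gen_proteins(
    variants: Sequence[SomaticVariant], seed: int, length: int = 101
) -> dict[str, str]:
    """Random protein per ``protein_id`` with the reference residue in place."""
    rng = np.random.default_rng(seed)
    proteins: dict[str, str] = {}
    for v in variants:
        if v.protein_id in proteins:
            continue
        seq = list(_random_protein(rng, length))
        if v.aa_pos > length:
            raise FormatError(f"{v.id}: aa_pos {v.aa_pos} exceeds protein length {length}")
        seq[v.aa_pos - 1] = v.ref_aa
        proteins[v.protein_id] = "".join(seq)
    return proteins


def gen_binding_curves(
    peptides: Sequence[str],
    true_ec50: Mapping[str, float],
    noise_cv: float,
    seed: int,
    cfg: PipelineConfig | None = None,
    baseline: float = 20.0,
    plateau: float = 400.0,
    hill: float = 1.0,
) -> list[BindingAssayCurve]:
    """Stabilization curves from a 4PL with multiplicative Gaussian noise.

    Peptides absent from ``true_ec50`` are non-binders (flat at baseline).
    With ``noise_cv = 0`` the signal at the true EC50 is exactly the
    midpoint of baseline and plateau.
    """
    cfg = cfg or PipelineConfig()
    rng = np.random.default_rng(seed)
    concs = cfg.concentrations_um()
    curves = []
    for pep in peptides:
        ec50 = true_ec50.get(pep)
        if ec50 is not None and not 0.001 < ec50 < 1000.0:
            raise FormatError(f"{pep}: true EC50 {ec50} uM outside (0.001, 1000)")
        sigs = []
        for c in concs:
            mean = (
                baseline
                if ec50 is None
                else baseline + (plateau - baseline) / (1.0 + (ec50 / c) ** hill)
            )
            noisy = mean * (1.0 + noise_cv * rng.standard_normal()) if noise_cv else mean
            sigs.append(max(0.0, noisy))
        control = (
            baseline * (1.0 + noise_cv * rng.standard_normal()) if noise_cv else baseline
        )
        curves.append(
            BindingAssayCurve(
                peptide_id=pep,
                assay_type=AssayType.STABILIZATION,
                concentrations=tuple(concs),
                signals=tuple(sigs),
                no_peptide_control=max(0.0, control),
            )
        )
    return curves


def gen_tcell_assays(
    peptides: Sequence[str],
    responder_pairs: Iterable[tuple[str, str]],
    background_pct: float,
    seed: int,
    subjects: Sequence[str] = ("D1", "D2", "D3"),
    cfg: PipelineConfig | None = None,
) -> list[TcellAssayRecord]:
    """Per subject x peptide IFN-gamma readouts with planted responders.

    Planted (subject, peptide) pairs get a stimulated signal >= 2.5x the
    effective background; all others stay within 1.5x, so the 2x responder
    rule recovers the planted set exactly.
    """
    if not 0.0 < background_pct < 5.0:
        raise FormatError(f"background_pct must be in (0, 5), got {background_pct}")
    cfg = cfg or PipelineConfig()
    responder_pairs = set(responder_pairs)
    subjects = list(subjects) or sorted({s for s, _ in responder_pairs})
    for s, p in responder_pairs:
        if s not in subjects or p not in peptides:
            raise FormatError(f"responder pair ({s}, {p}) outside subjects x peptides")
    rng = np.random.default_rng(seed)
    records = []
    for subject in subjects:
        for pep in peptides:
            unstim = background_pct * float(rng.uniform(0.7, 1.3))
            floor = max(unstim, cfg.zero_floor_pct)
            if (subject, pep) in responder_pairs:
                stim = floor * float(rng.uniform(2.5, 5.0))
            else:
                stim = floor * float(rng.uniform(0.3, 1.5))
            records.append(
                TcellAssayRecord(
                    subject_id=subject,
                    peptide_id=pep,
                    stim_pct=min(100.0, stim),
                    unstim_pct=min(100.0, unstim),
                )
            )
    return records


def gen_ms_peptides(
    n_background: int,
    planted: Iterable[str] = (),
    seed: int = 0,
    include_planted: bool = True,
) -> list[str]:
    """Background ligandome of random 9-mers, optionally with planted peptides.

    Background peptides never collide with the planted set; when
    ``include_planted`` the planted peptides are appended to the output.
    """
    planted = list(dict.fromkeys(planted))
    for p in planted:
        if not 8 <= len(p) <= 11:
            raise FormatError(f"planted peptide {p!r} must be 8-11 aa")
    rng = np.random.default_rng(seed)
    forbidden = set(planted)
    background: list[str] = []
    seen: set[str] = set()
    while len(background) < n_background:
        pep = _random_protein(rng, 9)
        if pep in forbidden or pep in seen:
            continue
        seen.add(pep)
        background.append(pep)
    return background + (planted if include_planted else [])


def gen_affinity_table(
    candidates: Sequence[EpitopeCandidate],
    selected_peptides: Iterable[str],
    cfg: PipelineConfig | None = None,
    species: str = "mouse",
    alleles: Sequence[str] | None = None,
    allele_of: Mapping[str, str] | None = None,
) -> tuple[list[AffinityPrediction], SimulationTruth]:
    """Affinity/rank table under which exactly the chosen peptides are selected.

    Planted peptides get strongly passing values (mutant well below the
    allele threshold and a clear differential over wild type for the human
    rules; rank well inside the 1% cut-off for the mouse rule); all others
    get clearly failing values.  The returned truth carries the planted
    selected set.
    """
    cfg = cfg or PipelineConfig()
    selected = set(selected_peptides)
    truth = SimulationTruth(true_selected=set(selected))
    preds: dict[tuple[str, str], AffinityPrediction] = {}

    def put(pep: str, allele: str, nm: float, rank: float) -> None:
        preds[(pep, allele)] = AffinityPrediction(pep, allele, nm, rank)

    if species == "human":
        for cand in candidates:
            if cand.allele is None:
                raise FormatError(f"candidate {cand.mutant_peptide} has no allele")
            thr = cfg.mutant_threshold(cand.allele)
            wt_floor = cfg.wt_floor(cand.allele)
            if cand.mutant_peptide in selected:
                put(cand.mutant_peptide, cand.allele, thr / 10.0, 0.5)
                put(cand.wt_peptide, cand.allele, wt_floor * 10.0, 50.0)
            else:
                put(cand.mutant_peptide, cand.allele, thr * 10.0, 50.0)
                put(cand.wt_peptide, cand.allele, wt_floor * 10.0, 50.0)
    elif species == "mouse":
        from .selection import MOUSE_ALLELES

        alleles = tuple(alleles or MOUSE_ALLELES)
        allele_of = dict(allele_of or {})
        for cand in candidates:
            hit = cand.mutant_peptide in selected
            # the qualifying allele for a planted hit (default: first allele)
            qual = allele_of.get(cand.mutant_peptide, alleles[0])
            for allele in alleles:
                qualifies = hit and allele == qual
                rank = 0.25 if qualifies else (2.5 if hit else 25.0)
                nm = 50.0 if qualifies else 5000.0
                put(cand.mutant_peptide, allele, nm, rank)
                put(cand.wt_peptide, allele, 5000.0, 25.0)
    else:
        raise FormatError(f"species must be 'human' or 'mouse', got {species!r}")
    return list(preds.values()), truth


def gen_bundle(
    out_dir,
    seed: int,
    cfg: PipelineConfig | None = None,
    n_true: int = 5,
    n_decoy_per_rule: int = 2,
    noise_cv: float = 0.0,
    n_ms_background: int = 200,
    plant_ms: Iterable[str] = (),
    subjects: Sequence[str] = ("D1", "D2", "D3"),
) -> SimulationTruth:
    """Write a complete synthetic input bundle for one mouse pipeline run.

    Files written under ``out_dir``: variants.tsv, proteins.fasta,
    affinities.tsv, curves.tsv, tcell.tsv, ms.tsv.  Ground truth is planted
    at every stage: for each true somatic variant one 9-mer (H2-Db) and one
    8-mer (H2-Kb) window are given qualifying ranks; two thirds of the
    selected peptides get a true EC50 (the rest are flat non-binders); the
    first subject responds to every second binder peptide.  With
    ``noise_cv = 0`` the pipeline recovers each truth set exactly.
    """
    from pathlib import Path

    from . import io as nio
    from .epitopes import apply_mutation, enumerate_mutant_windows

    cfg = cfg or PipelineConfig()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    variants, truth = gen_variants(n_true, n_decoy_per_rule, seed, cfg)
    proteins = gen_proteins(variants, seed + 1)

    candidates = []
    allele_of: dict[str, str] = {}
    for v in variants:
        if v.id not in truth.true_somatic_ids:
            continue
        ctx = apply_mutation(proteins[v.protein_id], v.aa_pos, v.ref_aa, v.alt_aa, v.protein_id)
        windows = enumerate_mutant_windows(ctx, (8, 9, 10), source_variant=v.id)
        candidates.extend(windows)
        db = next(w for w in windows if w.length == 9)
        kb = next(
            w for w in windows if w.length == 8 and w.mutant_peptide != db.mutant_peptide
        )
        allele_of[db.mutant_peptide] = "H2-Db"
        allele_of[kb.mutant_peptide] = "H2-Kb"

    preds, sel_truth = gen_affinity_table(
        candidates, set(allele_of), cfg, species="mouse", allele_of=allele_of
    )
    truth.true_selected = sel_truth.true_selected

    selected = sorted(truth.true_selected)
    binders = selected[: max(1, (2 * len(selected)) // 3)] if selected else []
    truth.true_ec50 = {p: 5.0 for p in binders}
    curves = gen_binding_curves(selected, truth.true_ec50, noise_cv, seed + 2, cfg)

    truth.true_responders = {(subjects[0], p) for p in binders[::2]}
    tcell = gen_tcell_assays(selected, truth.true_responders, 0.4, seed + 3, subjects, cfg)

    truth.planted_ms_overlap = set(plant_ms)
    ms = gen_ms_peptides(n_ms_background, sorted(truth.planted_ms_overlap), seed + 4)

    nio.write_variant_table(variants, out / "variants.tsv")
    nio.write_fasta(proteins, out / "proteins.fasta")
    nio.write_affinity_table(preds, out / "affinities.tsv")
    nio.write_curve_table(curves, out / "curves.tsv")
    nio.write_tcell_table(tcell, out / "tcell.tsv")
    nio.write_ms_peptides(ms, out / "ms.tsv")
    return truth
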