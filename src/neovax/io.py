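"""Tabular (TSV) and sequence (FASTA) readers/writers for every pipeline stage.

All tables are tab-separated with a header row and '.'-decimal numbers
regardless of locale; every reader/writer pair is a lossless round-trip on
valid data.  FASTA goes through Biopython.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Mapping, Sequence
import warnings

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .assays import AssayType, BindingAssayCurve, BindingResult, TcellAssayRecord
from .epitopes import EpitopeCandidate
from .errors import ConfigurationError, FormatError
from .selection import AffinityPrediction, RulePath, SelectionDecision
from .variants import FilterAudit, SomaticVariant

__all__ = [
    "read_variant_table",
    "write_variant_table",
    "read_fasta",
    "write_fasta",
    "read_affinity_table",
    "write_affinity_table",
    "read_candidate_table",
    "write_candidate_table",
    "read_curve_table",
    "write_curve_table",
    "read_tcell_table",
    "write_tcell_table",
    "read_ms_peptides",
    "write_ms_peptides",
    "write_decision_table",
    "read_decision_table",
    "write_audit_table",
    "write_binding_results",
]

_VARIANT_COLUMNS = [
    "id",
    "gene",
    "protein_id",
    "aa_pos",
    "ref_aa",
    "alt_aa",
    "tumor_depth",
    "normal_depth",
    "tumor_alt_reads",
    "normal_alt_reads",
    "alt_fwd",
    "alt_rev",
    "pop_maf",
]

_INT_VARIANT_FIELDS = {
    "aa_pos",
    "tumor_depth",
    "normal_depth",
    "tumor_alt_reads",
    "normal_alt_reads",
    "alt_fwd",
    "alt_rev",
}


def _read_tsv(path: str | Path, required: Sequence[str]) -> pd.DataFrame:
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    except pd.errors.ParserError as exc:
        raise FormatError(f"{path}: not a parseable TSV ({exc})") from exc
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ConfigurationError(f"{path}: missing required column(s) {missing}")
    return df


def _num(df_value: str, column: str, row: int, path: Path, as_int: bool):
    try:
        return int(df_value) if as_int else float(df_value)
    except ValueError:
        raise FormatError(
            f"{path}: row {row}: malformed numeric value {df_value!r} in column {column!r}"
        ) from None


# ---------------------------------------------------------------------------
# somatic variants
# ---------------------------------------------------------------------------


def read_variant_table(path: str | Path) -> list[SomaticVariant]:
    """Read a somatic variant TSV; malformed numeric fields name their row."""
    path = Path(path)
    df = _read_tsv(path, _VARIANT_COLUMNS)
    variants = []
    for i, row in enumerate(df.itertuples(index=False), start=2):  # 1 = header line
        kwargs = {}
        for col in _VARIANT_COLUMNS:
            raw = getattr(row, col)
            if col in _INT_VARIANT_FIELDS:
                kwargs[col] = _num(raw, col, i, path, as_int=True)
            elif col == "pop_maf":
                kwargs[col] = _num(raw, col, i, path, as_int=False) if raw != "" else 0.0
            else:
                kwargs[col] = str(raw)
        try:
            variants.append(SomaticVariant(**kwargs))
        except FormatError as exc:
            raise FormatError(f"{path}: row {i}: {exc}") from exc
    return variants


def write_variant_table(variants: Iterable[SomaticVariant], path: str | Path) -> None:
    df = pd.DataFrame([vars(v) for v in variants], columns=_VARIANT_COLUMNS)
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read protein FASTA into an id -> upper-cased sequence map.

    Duplicate ids are an error; an empty file returns an empty map with a
    warning.
    """
    path = Path(path)
    sequences: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in sequences:
            raise FormatError(f"{path}: duplicate FASTA id {rec.id!r}")
        sequences[rec.id] = str(rec.seq).upper()
    if not sequences:
        warnings.warn(f"{path}: FASTA file contains no records", stacklevel=2)
    return sequences


def write_fasta(sequences: Mapping[str, str], path: str | Path) -> None:
    records = [SeqRecord(Seq(seq), id=name, description="") for name, seq in sequences.items()]
    SeqIO.write(records, str(path), "fasta")


# ---------------------------------------------------------------------------
# affinity predictions
# ---------------------------------------------------------------------------

_AFFINITY_COLUMNS = ["peptide", "allele", "affinity_nm", "rank_pct"]


def read_affinity_table(path: str | Path) -> list[AffinityPrediction]:
    path = Path(path)
    df = _read_tsv(path, _AFFINITY_COLUMNS)
    preds = []
    for i, row in enumerate(df.itertuples(index=False), start=2):
        nm = _num(row.affinity_nm, "affinity_nm", i, path, as_int=False)
        rank = _num(row.rank_pct, "rank_pct", i, path, as_int=False)
        try:
            preds.append(AffinityPrediction(str(row.peptide), str(row.allele), nm, rank))
        except FormatError as exc:
            raise FormatError(f"{path}: row {i}: {exc}") from exc
    return preds


def write_affinity_table(preds: Iterable[AffinityPrediction], path: str | Path) -> None:
    df = pd.DataFrame([vars(p) for p in preds], columns=_AFFINITY_COLUMNS)
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# epitope candidates
# ---------------------------------------------------------------------------

_CANDIDATE_COLUMNS = ["mutant_peptide", "wt_peptide", "mut_offset", "source_variant", "allele"]


def read_candidate_table(path: str | Path) -> list[EpitopeCandidate]:
    path = Path(path)
    df = _read_tsv(path, _CANDIDATE_COLUMNS)
    out = []
    for i, row in enumerate(df.itertuples(index=False), start=2):
        try:
            out.append(
                EpitopeCandidate(
                    mutant_peptide=str(row.mutant_peptide),
                    wt_peptide=str(row.wt_peptide),
                    mut_offset=_num(row.mut_offset, "mut_offset", i, path, as_int=True),
                    source_variant=str(row.source_variant),
                    allele=str(row.allele) or None,
                )
            )
        except FormatError as exc:
            raise FormatError(f"{path}: row {i}: {exc}") from exc
    return out


def write_candidate_table(candidates: Iterable[EpitopeCandidate], path: str | Path) -> None:
    rows = [
        {
            "mutant_peptide": c.mutant_peptide,
            "wt_peptide": c.wt_peptide,
            "mut_offset": c.mut_offset,
            "source_variant": c.source_variant,
            "allele": c.allele or "",
        }
        for c in candidates
    ]
    pd.DataFrame(rows, columns=_CANDIDATE_COLUMNS).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# binding assay curves (long format; concentration 0 marks the control row)
# ---------------------------------------------------------------------------

_CURVE_COLUMNS = ["peptide_id", "assay_type", "concentration_um", "signal", "reference"]


def write_curve_table(curves: Iterable[BindingAssayCurve], path: str | Path) -> None:
    rows = []
    for c in curves:
        ref = "" if c.reference_no_competitor is None else repr(c.reference_no_competitor)
        for conc, sig in zip(c.concentrations, c.signals):
            rows.append(
                {
                    "peptide_id": c.peptide_id,
                    "assay_type": c.assay_type.value,
                    "concentration_um": repr(conc),
                    "signal": repr(sig),
                    "reference": ref,
                }
            )
        rows.append(  # no-peptide control row
            {
                "peptide_id": c.peptide_id,
                "assay_type": c.assay_type.value,
                "concentration_um": "0",
                "signal": repr(c.no_peptide_control),
                "reference": ref,
            }
        )
    pd.DataFrame(rows, columns=_CURVE_COLUMNS).to_csv(path, sep="\t", index=False)


def read_curve_table(path: str | Path) -> list[BindingAssayCurve]:
    """Rebuild curves from the long table; a 0-concentration row is the control."""
    path = Path(path)
    df = _read_tsv(path, _CURVE_COLUMNS)
    curves: list[BindingAssayCurve] = []
    for (pid, atype), grp in df.groupby(["peptide_id", "assay_type"], sort=False):
        concs, sigs, control = [], [], None
        ref: float | None = None
        for i, row in enumerate(grp.itertuples(index=False), start=2):
            conc = _num(row.concentration_um, "concentration_um", i, path, as_int=False)
            sig = _num(row.signal, "signal", i, path, as_int=False)
            if row.reference != "":
                ref = _num(row.reference, "reference", i, path, as_int=False)
            if conc == 0:
                control = sig
            else:
                concs.append(conc)
                sigs.append(sig)
        if control is None:
            raise FormatError(f"{path}: curve {pid!r} lacks a no-peptide control row")
        order = sorted(range(len(concs)), key=lambda k: -concs[k])
        curves.append(
            BindingAssayCurve(
                peptide_id=str(pid),
                assay_type=AssayType(atype),
                concentrations=tuple(concs[k] for k in order),
                signals=tuple(sigs[k] for k in order),
                no_peptide_control=control,
                reference_no_competitor=ref,
            )
        )
    return curves


# ---------------------------------------------------------------------------
# T-cell assay records
# ---------------------------------------------------------------------------

_TCELL_COLUMNS = ["subject_id", "peptide_id", "stim_pct", "unstim_pct"]


def read_tcell_table(path: str | Path) -> list[TcellAssayRecord]:
    path = Path(path)
    df = _read_tsv(path, _TCELL_COLUMNS)
    out = []
    for i, row in enumerate(df.itertuples(index=False), start=2):
        try:
            out.append(
                TcellAssayRecord(
                    subject_id=str(row.subject_id),
                    peptide_id=str(row.peptide_id),
                    stim_pct=_num(row.stim_pct, "stim_pct", i, path, as_int=False),
                    unstim_pct=_num(row.unstim_pct, "unstim_pct", i, path, as_int=False),
                )
            )
        except FormatError as exc:
            raise FormatError(f"{path}: row {i}: {exc}") from exc
    return out


def write_tcell_table(records: Iterable[TcellAssayRecord], path: str | Path) -> None:
    rows = [
        {
            "subject_id": r.subject_id,
            "peptide_id": r.peptide_id,
            "stim_pct": repr(r.stim_pct),
            "unstim_pct": repr(r.unstim_pct),
        }
        for r in records
    ]
    pd.DataFrame(rows, columns=_TCELL_COLUMNS).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# MS-eluted peptide lists
# ---------------------------------------------------------------------------


def read_ms_peptides(path: str | Path) -> list[str]:
    """Single-column 'peptide' TSV of MS-eluted peptide sequences."""
    df = _read_tsv(path, ["peptide"])
    return [str(p) for p in df["peptide"]]


def write_ms_peptides(peptides: Iterable[str], path: str | Path) -> None:
    pd.DataFrame({"peptide": list(peptides)}).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# selection decisions, filter audits, binding results
# ---------------------------------------------------------------------------

_DECISION_COLUMNS = _CANDIDATE_COLUMNS + [
    "selected",
    "rule_path",
    "mutant_nm",
    "wt_nm",
    "qualifying_allele",
]


def write_decision_table(decisions: Iterable[SelectionDecision], path: str | Path) -> None:
    rows = []
    for d in decisions:
        c = d.candidate
        rows.append(
            {
                "mutant_peptide": c.mutant_peptide,
                "wt_peptide": c.wt_peptide,
                "mut_offset": c.mut_offset,
                "source_variant": c.source_variant,
                "allele": c.allele or "",
                "selected": str(d.selected),
                "rule_path": d.rule_path.value,
                "mutant_nm": "" if d.mutant_nm is None else repr(d.mutant_nm),
                "wt_nm": "" if d.wt_nm is None else repr(d.wt_nm),
                "qualifying_allele": d.qualifying_allele or "",
            }
        )
    pd.DataFrame(rows, columns=_DECISION_COLUMNS).to_csv(path, sep="\t", index=False)


def read_decision_table(path: str | Path) -> list[SelectionDecision]:
    path = Path(path)
    df = _read_tsv(path, _DECISION_COLUMNS)
    out = []
    for i, row in enumerate(df.itertuples(index=False), start=2):
        cand = EpitopeCandidate(
            mutant_peptide=str(row.mutant_peptide),
            wt_peptide=str(row.wt_peptide),
            mut_offset=_num(row.mut_offset, "mut_offset", i, path, as_int=True),
            source_variant=str(row.source_variant),
            allele=str(row.allele) or None,
        )
        out.append(
            SelectionDecision(
                candidate=cand,
                selected=row.selected == "True",
                rule_path=RulePath(row.rule_path),
                mutant_nm=None
                if row.mutant_nm == ""
                else _num(row.mutant_nm, "mutant_nm", i, path, as_int=False),
                wt_nm=None
                if row.wt_nm == ""
                else _num(row.wt_nm, "wt_nm", i, path, as_int=False),
                qualifying_allele=str(row.qualifying_allele) or None,
            )
        )
    return out


def write_audit_table(audits: Iterable[FilterAudit], path: str | Path) -> None:
    rows = [
        {
            "variant_id": a.variant_id,
            "retained": str(a.retained),
            "failed_rule": a.failed_rule or "",
        }
        for a in audits
    ]
    pd.DataFrame(rows, columns=["variant_id", "retained", "failed_rule"]).to_csv(
        path, sep="\t", index=False
    )


def write_binding_results(results: Iterable[BindingResult], path: str | Path) -> None:
    rows = [
        {
            "peptide_id": r.peptide_id,
            "assay_type": r.assay_type.value,
            "ec50_um": "" if r.ec50_um is None else repr(r.ec50_um),
            "plateau_mfi": repr(r.plateau_mfi),
            "fit_method": r.fit_method.value,
            "binder": str(r.binder),
        }
        for r in results
    ]
    pd.DataFrame(
        rows,
        columns=["peptide_id", "assay_type", "ec50_um", "plateau_mfi", "fit_method", "binder"],
    ).to_csv(path, sep="\t", index=False)
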