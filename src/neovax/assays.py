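"""Cell-based binding assay quantification and T-cell responder calling.

Stabilization assays (TAP-deficient T2 / RMA-S cells): surface MHC is
stabilized only by exogenous peptide, so MFI rises with peptide
concentration.  The dose-response is modelled as a four-parameter logistic
in log10 concentration,

    MFI(c) = baseline + (plateau - baseline) / (1 + (EC50 / c)**h),

and EC50 is the concentration at half-maximal MFI, i.e. the midpoint of the
fitted baseline and plateau.  When the nonlinear fit fails, a monotone
linear interpolation in log-concentration between the two observations
bracketing half-max is used instead; flat or non-bracketing curves yield no
EC50.

Competition assays (HLA-A*24:02 on BRIP cells): inhibition(c) =
1 - signal(c)/reference, and IC50 is the competitor concentration at 50%
inhibition of the FITC-labelled reference peptide, fitted the same way.

Responder rule for T-cell assays: a subject responds to a peptide when the
stimulated %IFN-gamma+ of CD8+ is at least twice the unstimulated
background (inclusive), with a small floor on the background so a 0%
background cannot decide calls by itself.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .config import PipelineConfig
from .errors import ConsistencyError, FormatError, InsufficientDataError

__all__ = [
    "AssayType",
    "FitMethod",
    "BindingAssayCurve",
    "BindingResult",
    "TcellAssayRecord",
    "fit_ec50",
    "fit_ic50",
    "interpolate_ec50",
    "call_binder",
    "call_responder",
    "summarize_counts",
    "rate_pct",
    "four_pl",
]

#: Relative dynamic range below which a curve is treated as flat.
_FLAT_REL_RANGE = 0.2


class AssayType(str, Enum):
    STABILIZATION = "stabilization"
    COMPETITION = "competition"


class FitMethod(str, Enum):
    LOGISTIC_FIT = "logistic_fit"
    INTERPOLATION = "interpolation"
    NONE = "none"


@dataclass(frozen=True)
class BindingAssayCurve:
    """One peptide's dilution series (concentrations strictly descending, uM)."""

    peptide_id: str
    assay_type: AssayType
    concentrations: tuple[float, ...]
    signals: tuple[float, ...]
    no_peptide_control: float
    reference_no_competitor: float | None = None  # competition assays only

    def __post_init__(self) -> None:
        object.__setattr__(self, "concentrations", tuple(self.concentrations))
        object.__setattr__(self, "signals", tuple(self.signals))
        object.__setattr__(self, "assay_type", AssayType(self.assay_type))
        if len(self.concentrations) != len(self.signals):
            raise FormatError(f"{self.peptide_id}: concentrations/signals length mismatch")
        if any(c2 >= c1 for c1, c2 in zip(self.concentrations, self.concentrations[1:])):
            raise FormatError(f"{self.peptide_id}: concentrations must be strictly decreasing")
        if any(c <= 0 for c in self.concentrations):
            raise FormatError(f"{self.peptide_id}: concentrations must be positive")
        if any(s < 0 for s in self.signals):
            raise FormatError(f"{self.peptide_id}: signals must be non-negative")

    def sorted_ascending(self) -> tuple[np.ndarray, np.ndarray]:
        conc = np.asarray(self.concentrations, dtype=float)[::-1]
        sig = np.asarray(self.signals, dtype=float)[::-1]
        return conc, sig


@dataclass(frozen=True)
class BindingResult:
    peptide_id: str
    assay_type: AssayType
    ec50_um: float | None  # IC50 for competition assays
    plateau_mfi: float
    baseline_mfi: float
    max_inhibition: float | None
    fit_method: FitMethod
    binder: bool = False


@dataclass(frozen=True)
class TcellAssayRecord:
    """Stimulated vs unstimulated %IFN-gamma+ of CD8+ for one subject/peptide."""

    subject_id: str
    peptide_id: str
    stim_pct: float
    unstim_pct: float

    def __post_init__(self) -> None:
        for label, v in (("stim_pct", self.stim_pct), ("unstim_pct", self.unstim_pct)):
            if not 0.0 <= v <= 100.0:
                raise FormatError(
                    f"{self.subject_id}/{self.peptide_id}: {label} must be a "
                    f"percentage in [0,100], got {v}"
                )


def four_pl(log_c: np.ndarray, baseline: float, plateau: float, log_ec50: float, hill: float):
    """Four-parameter logistic in log10 concentration (ascending when plateau>baseline)."""
    return baseline + (plateau - baseline) / (1.0 + 10.0 ** (hill * (log_ec50 - log_c)))


def _fit_4pl(
    conc: np.ndarray, sig: np.ndarray, sigma: np.ndarray | None = None
) -> tuple[float, float, float, float] | None:
    log_c = np.log10(conc)
    lo, hi = float(sig.min()), float(sig.max())
    p0 = (lo, hi, float(np.median(log_c)), 1.0)
    span = hi - lo if hi > lo else 1.0
    bounds = (
        [lo - span, lo - span, log_c.min() - 2.0, 0.1],
        [hi + span, hi + span, log_c.max() + 2.0, 10.0],
    )
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            popt, _ = curve_fit(
                four_pl, log_c, sig, p0=p0, bounds=bounds, maxfev=5000, sigma=sigma
            )
    except (RuntimeError, ValueError):
        return None
    return tuple(float(p) for p in popt)  # type: ignore[return-value]


def _interpolate_crossing(conc: np.ndarray, sig: np.ndarray, half: float) -> float | None:
    """Linear-in-log10(c) crossing of ``half`` between adjacent observations."""
    for i in range(len(conc) - 1):
        s0, s1 = sig[i], sig[i + 1]
        if (s0 - half) * (s1 - half) <= 0 and s0 != s1:
            f = (half - s0) / (s1 - s0)
            log_c = math.log10(conc[i]) + f * (math.log10(conc[i + 1]) - math.log10(conc[i]))
            return 10.0**log_c
    return None


def fit_ec50(curve: BindingAssayCurve) -> BindingResult:
    """EC50 of a stabilization curve: concentration at half-maximal MFI.

    Prefers a 4PL fit (half-max from fitted baseline/plateau); falls back to
    monotone interpolation in log-concentration using observed extremes.
    Flat curves, or curves whose observations never bracket half-max, yield
    no EC50 (``fit_method`` ``none``).
    """
    if curve.assay_type is not AssayType.STABILIZATION:
        raise FormatError(f"{curve.peptide_id}: fit_ec50 requires a stabilization curve")
    if len(curve.concentrations) < 4:
        raise InsufficientDataError(
            f"{curve.peptide_id}: need >= 4 dilution points, got {len(curve.concentrations)}"
        )
    conc, sig = curve.sorted_ascending()
    obs_lo, obs_hi = float(sig.min()), float(sig.max())
    floor = max(curve.no_peptide_control, 1e-9)
    if obs_hi - obs_lo < _FLAT_REL_RANGE * max(obs_hi, floor):
        return BindingResult(
            curve.peptide_id, curve.assay_type, None, obs_hi, obs_lo, None, FitMethod.NONE
        )

    # sigma ~ signal: MFI error is multiplicative, so weight accordingly
    fit = _fit_4pl(conc, sig, sigma=np.maximum(np.abs(sig), 1e-6))
    if fit is not None:
        baseline, plateau, log_ec50, _h = fit
        half = (baseline + plateau) / 2.0
        ec50 = 10.0**log_ec50
        bracketed = obs_lo <= half <= obs_hi
        in_range = conc.min() <= ec50 <= conc.max()
        if plateau > baseline and bracketed and in_range:
            return BindingResult(
                curve.peptide_id,
                curve.assay_type,
                ec50,
                plateau,
                baseline,
                None,
                FitMethod.LOGISTIC_FIT,
            )

    ec50 = interpolate_ec50(curve)
    if ec50 is None:
        return BindingResult(
            curve.peptide_id, curve.assay_type, None, obs_hi, obs_lo, None, FitMethod.NONE
        )
    return BindingResult(
        curve.peptide_id, curve.assay_type, ec50, obs_hi, obs_lo, None, FitMethod.INTERPOLATION
    )


def interpolate_ec50(curve: BindingAssayCurve) -> float | None:
    """Half-max crossing from observed extremes, linear in log-concentration.

    The interpolation fallback of :func:`fit_ec50`: half-max is the midpoint
    of the observed minimum and maximum signal, and the crossing is located
    between the two adjacent dilution points bracketing it.
    """
    conc, sig = curve.sorted_ascending()
    half = (float(sig.min()) + float(sig.max())) / 2.0
    return _interpolate_crossing(conc, sig, half)


def fit_ic50(curve: BindingAssayCurve) -> BindingResult:
    """IC50 of a competition curve: concentration at 50% inhibition.

    ``inhibition(c) = 1 - signal(c)/reference``; fitted as an ascending 4PL
    of inhibition vs log-concentration with interpolation fallback.  Curves
    never reaching 50% inhibition yield no IC50.
    """
    if curve.assay_type is not AssayType.COMPETITION:
        raise FormatError(f"{curve.peptide_id}: fit_ic50 requires a competition curve")
    if curve.reference_no_competitor is None or not curve.reference_no_competitor > 0:
        raise FormatError(f"{curve.peptide_id}: positive reference_no_competitor required")
    if len(curve.concentrations) < 4:
        raise InsufficientDataError(
            f"{curve.peptide_id}: need >= 4 dilution points, got {len(curve.concentrations)}"
        )
    conc, sig = curve.sorted_ascending()
    inhibition = 1.0 - sig / curve.reference_no_competitor
    max_inh = float(inhibition.max())
    if max_inh < 0.5:
        return BindingResult(
            curve.peptide_id,
            curve.assay_type,
            None,
            float(sig.max()),
            float(sig.min()),
            max_inh,
            FitMethod.NONE,
        )

    fit = _fit_4pl(conc, inhibition)
    if fit is not None:
        base, top, log_x0, hill = fit
        # concentration where the fitted inhibition curve crosses 0.5
        if top > 0.5 > base and top > base:
            ratio = (top - base) / (0.5 - base) - 1.0
            if ratio > 0:
                ic50 = 10.0 ** (log_x0 - math.log10(ratio) / hill)
                if conc.min() <= ic50 <= conc.max():
                    return BindingResult(
                        curve.peptide_id,
                        curve.assay_type,
                        float(ic50),
                        float(sig.max()),
                        float(sig.min()),
                        max_inh,
                        FitMethod.LOGISTIC_FIT,
                    )

    ic50 = _interpolate_crossing(conc, inhibition, 0.5)
    if ic50 is None:
        return BindingResult(
            curve.peptide_id,
            curve.assay_type,
            None,
            float(sig.max()),
            float(sig.min()),
            max_inh,
            FitMethod.NONE,
        )
    return BindingResult(
        curve.peptide_id,
        curve.assay_type,
        ic50,
        float(sig.max()),
        float(sig.min()),
        max_inh,
        FitMethod.INTERPOLATION,
    )


def call_binder(result: BindingResult, curve: BindingAssayCurve, cfg: PipelineConfig) -> bool:
    """Binder call: determinate EC50/IC50 within the tested range, plus effect size.

    Stabilization: fitted plateau must reach ``binder_plateau_fold`` times the
    no-peptide control.  Competition: maximal inhibition must reach 50%.
    """
    if result.peptide_id != curve.peptide_id:
        raise ConsistencyError("result and curve describe different peptides")
    if result.ec50_um is None or result.ec50_um > cfg.top_concentration:
        return False
    if curve.assay_type is AssayType.STABILIZATION:
        return result.plateau_mfi >= cfg.binder_plateau_fold * max(
            curve.no_peptide_control, 1e-9
        )
    return result.max_inhibition is not None and result.max_inhibition >= 0.5


def call_responder(rec: TcellAssayRecord, cfg: PipelineConfig) -> bool:
    """Responder iff stimulated >= fold x max(background, floor), inclusive."""
    return rec.stim_pct >= cfg.responder_fold * max(rec.unstim_pct, cfg.zero_floor_pct)


# ---------------------------------------------------------------------------
# Summary table
# ---------------------------------------------------------------------------


def rate_pct(numerator: int, denominator: int) -> float:
    """Percentage truncated (not rounded) to one decimal; 0 when undefined.

    Truncation matches the convention of the summary statistics this table
    reproduces (44/66 -> 66.6).
    """
    if denominator == 0:
        return 0.0
    return math.floor(1000.0 * numerator / denominator + 1e-9) / 10.0


def summarize_counts(
    predicted: Iterable[tuple[str, str, str]],
    binder_flags: Mapping[str, bool],
    responders: Iterable[TcellAssayRecord] | Iterable[tuple[str, str, bool]] = (),
    ms_overlap: Iterable[str] = (),
    tumor_recognized: Iterable[str] = (),
    cfg: PipelineConfig | None = None,
) -> pd.DataFrame:
    """Per-(sample, allele) candidate funnel with a totals row.

    ``predicted`` lists the selected candidates as (sample, allele, peptide);
    ``binder_flags`` maps peptide -> binder call; ``responders`` carries
    per-subject T-cell records (or pre-made (subject, peptide, responder)
    triples); ``ms_overlap`` / ``tumor_recognized`` name peptides with direct
    display evidence.  A peptide referenced downstream but absent upstream is
    a consistency error.  Columns: n_predicted, n_bound (binders among
    predicted), n_immunogenic (binders with >= 1 responding subject),
    n_displayed, and rates truncated to one decimal.
    """
    cfg = cfg or PipelineConfig()
    pred_rows = [(s, a, p) for s, a, p in predicted]
    universe = {p for _, _, p in pred_rows}
    if len({(s, a, p) for s, a, p in pred_rows}) != len(pred_rows):
        raise ConsistencyError("duplicate (sample, allele, peptide) rows in predicted")

    for p in binder_flags:
        if p not in universe:
            raise ConsistencyError(f"binding result for unknown peptide {p!r}")

    responding: set[str] = set()
    for rec in responders:
        if isinstance(rec, TcellAssayRecord):
            pep, hit = rec.peptide_id, call_responder(rec, cfg)
        else:
            _subject, pep, hit = rec
        if pep not in universe:
            raise ConsistencyError(f"T-cell record for unknown peptide {pep!r}")
        if hit:
            responding.add(pep)

    displayed_univ = set(ms_overlap) | set(tumor_recognized)
    for p in displayed_univ:
        if p not in universe:
            raise ConsistencyError(f"display evidence for unknown peptide {p!r}")

    groups: dict[tuple[str, str], list[str]] = {}
    for s, a, p in pred_rows:
        groups.setdefault((s, a), []).append(p)

    rows = []
    for (sample, allele), peps in groups.items():
        bound = [p for p in peps if binder_flags.get(p, False)]
        immuno = [p for p in bound if p in responding]
        displayed = [p for p in peps if p in displayed_univ]
        rows.append(
            {
                "sample": sample,
                "allele": allele,
                "n_predicted": len(peps),
                "n_bound": len(bound),
                "n_immunogenic": len(immuno),
                "n_displayed": len(displayed),
            }
        )
    table = pd.DataFrame(
        rows,
        columns=["sample", "allele", "n_predicted", "n_bound", "n_immunogenic", "n_displayed"],
    )
    totals = {
        "sample": "total",
        "allele": "",
        **{c: int(table[c].sum()) if len(table) else 0 for c in table.columns[2:]},
    }
    table = pd.concat([table, pd.DataFrame([totals])], ignore_index=True)
    table["binding_rate_pct"] = [
        rate_pct(b, n) for b, n in zip(table["n_bound"], table["n_predicted"])
    ]
    table["immunogenic_rate_pct"] = [
        rate_pct(i, b) for i, b in zip(table["n_immunogenic"], table["n_bound"])
    ]
    bad = table[
        (table["n_bound"] > table["n_predicted"]) | (table["n_immunogenic"] > table["n_bound"])
    ]
    if len(bad):
        raise ConsistencyError("summary violates n_immunogenic <= n_bound <= n_predicted")
    return table
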