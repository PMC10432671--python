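"""EC50/IC50 fitting, binder/responder calls, and summary-table tallying."""

import math
import random

import pytest

from neovax import (
    AssayType,
    BindingAssayCurve,
    FitMethod,
    PipelineConfig,
    TcellAssayRecord,
    call_binder,
    call_responder,
    fit_ec50,
    fit_ic50,
    gen_binding_curves,
    interpolate_ec50,
    summarize_counts,
    rate_pct,
)
from neovax.errors import ConsistencyError, FormatError, InsufficientDataError


def stab_curve(concs, sigs, control=20.0, pid="p"):
    return BindingAssayCurve(pid, AssayType.STABILIZATION, tuple(concs), tuple(sigs), control)


# -- EC50 ------------------------------------------------------------------


@pytest.mark.parametrize("true_ec50", [0.5, 2.0, 10.0, 40.0])
def test_noiseless_4pl_recovered_within_one_percent(cfg, true_ec50):
    (curve,) = gen_binding_curves(["p"], {"p": true_ec50}, noise_cv=0.0, seed=0, cfg=cfg)
    res = fit_ec50(curve)
    assert res.fit_method is FitMethod.LOGISTIC_FIT
    assert res.ec50_um == pytest.approx(true_ec50, rel=0.01)


def test_ec50_is_midpoint_signal_concentration(cfg):
    """At c = EC50 the noiseless 4PL signal is exactly (baseline+plateau)/2."""
    (curve,) = gen_binding_curves(
        ["p"], {"p": 100.0 / 9.0}, noise_cv=0.0, seed=0, cfg=cfg,
        baseline=10.0, plateau=90.0,
    )
    # 100/9 uM is the third dilution point of the 3-fold series from 100 uM
    assert curve.concentrations[2] == pytest.approx(100.0 / 9.0)
    assert curve.signals[2] == pytest.approx(50.0)


def test_flat_curve_yields_no_ec50_and_non_binder(cfg):
    (curve,) = gen_binding_curves(["p"], {}, noise_cv=0.0, seed=0, cfg=cfg)
    res = fit_ec50(curve)
    assert res.ec50_um is None
    assert res.fit_method is FitMethod.NONE
    assert call_binder(res, curve, cfg) is False


def test_interpolation_crossing_matches_hand_arithmetic():
    # piecewise-linear curve: signals 10 at 3.7 uM, 70 at 11.1 uM, extremes 10/90
    concs = [100.0, 33.3, 11.1, 3.7, 1.2]
    sigs = [90.0, 80.0, 70.0, 10.0, 10.0]
    curve = stab_curve(concs, sigs, control=10.0)
    # half-max = (10+90)/2 = 50, crossed between 3.7 (10) and 11.1 (70):
    # f = (50-10)/(70-10) = 2/3; log-linear interpolation
    expected = 10 ** (math.log10(3.7) + (2 / 3) * (math.log10(11.1) - math.log10(3.7)))
    assert interpolate_ec50(curve) == pytest.approx(expected)


def test_fit_invariant_to_row_order(cfg):
    (curve,) = gen_binding_curves(["p"], {"p": 7.0}, noise_cv=0.05, seed=4, cfg=cfg)
    order = [3, 0, 7, 1, 5, 2, 6, 4]
    # canonical sorting happens at construction (strictly decreasing required)
    pairs = sorted(
        ((curve.concentrations[i], curve.signals[i]) for i in order), key=lambda t: -t[0]
    )
    shuffled = stab_curve([c for c, _ in pairs], [s for _, s in pairs], curve.no_peptide_control)
    assert fit_ec50(shuffled).ec50_um == pytest.approx(fit_ec50(curve).ec50_um)


def test_fewer_than_four_points_rejected():
    with pytest.raises(InsufficientDataError):
        fit_ec50(stab_curve([100.0, 10.0, 1.0], [90.0, 50.0, 10.0]))


def test_ec50_recovery_low_bias_under_noise(cfg):
    """Over 100 noisy curves (CV 5%), mean log-EC50 bias stays under 5%."""
    true = 8.0
    peptides = [f"p{i}" for i in range(100)]
    curves = gen_binding_curves(peptides, {p: true for p in peptides}, 0.05, seed=42, cfg=cfg)
    logs = []
    for curve in curves:
        res = fit_ec50(curve)
        assert res.ec50_um is not None
        logs.append(math.log(res.ec50_um))
    geo_mean = math.exp(sum(logs) / len(logs))
    assert abs(geo_mean - true) / true < 0.05


# -- IC50 ------------------------------------------------------------------


def comp_curve(ic50, ref=200.0, n=8, imax=1.0, pid="c"):
    cfg = PipelineConfig()
    concs = cfg.concentrations_um()[:n]
    sigs = [ref * (1.0 - imax / (1.0 + ic50 / c)) for c in concs]
    return BindingAssayCurve(
        pid, AssayType.COMPETITION, tuple(concs), tuple(sigs), 5.0, reference_no_competitor=ref
    )


@pytest.mark.parametrize("true_ic50", [1.0, 5.0, 25.0])
def test_noiseless_ic50_recovered_within_one_percent(cfg, true_ic50):
    curve = comp_curve(true_ic50)
    res = fit_ic50(curve)
    assert res.ec50_um == pytest.approx(true_ic50, rel=0.01)
    assert call_binder(res, curve, cfg) is True


def test_ic50_at_half_reference_signal(cfg):
    """Signal equal to reference/2 at 25 uM pins IC50 = 25 uM."""
    res = fit_ic50(comp_curve(25.0))
    assert res.ec50_um == pytest.approx(25.0, rel=0.01)


def test_no_inhibition_yields_absent_ic50(cfg):
    ref = 200.0
    concs = PipelineConfig().concentrations_um()
    curve = BindingAssayCurve(
        "c", AssayType.COMPETITION, tuple(concs), tuple([ref * 0.98] * 8), 5.0,
        reference_no_competitor=ref,
    )
    res = fit_ic50(curve)
    assert res.ec50_um is None
    assert call_binder(res, curve, cfg) is False


def test_zero_reference_is_an_error():
    curve = comp_curve(5.0)
    bad = BindingAssayCurve(
        "c", AssayType.COMPETITION, curve.concentrations, curve.signals, 5.0,
        reference_no_competitor=0.0,
    )
    with pytest.raises(FormatError):
        fit_ic50(bad)


# -- binder call -----------------------------------------------------------


def test_low_plateau_despite_crossing_is_non_binder(cfg):
    # formal half-max crossing but plateau only 1.2x control
    control = 100.0
    concs = PipelineConfig().concentrations_um()
    sigs = [100 + 20 / (1 + 5.0 / c) for c in concs]
    curve = stab_curve(concs, sigs, control=control)
    res = fit_ec50(curve)
    assert call_binder(res, curve, cfg) is False


def test_strong_plateau_with_determinate_ec50_is_binder(cfg):
    (curve,) = gen_binding_curves(["p"], {"p": 8.0}, 0.0, seed=0, cfg=cfg)
    res = fit_ec50(curve)
    assert res.plateau_mfi >= cfg.binder_plateau_fold * curve.no_peptide_control
    assert call_binder(res, curve, cfg) is True


def test_binder_call_requires_matching_curve(cfg):
    (c1,) = gen_binding_curves(["p1"], {"p1": 8.0}, 0.0, seed=0, cfg=cfg)
    (c2,) = gen_binding_curves(["p2"], {"p2": 8.0}, 0.0, seed=0, cfg=cfg)
    with pytest.raises(ConsistencyError):
        call_binder(fit_ec50(c1), c2, cfg)


# -- responder rule --------------------------------------------------------


@pytest.mark.parametrize(
    "stim,unstim,expected",
    [
        (1.2, 0.5, True),
        (0.9, 0.5, False),
        (1.0, 0.5, True),  # inclusive boundary: twice-or-higher
        (0.999, 0.5, False),
        (0.3, 0.0, True),  # 0% background floored at 0.1%
        (0.15, 0.0, False),
    ],
)
def test_responder_rule_hand_computed(cfg, stim, unstim, expected):
    rec = TcellAssayRecord("D1", "p", stim_pct=stim, unstim_pct=unstim)
    assert call_responder(rec, cfg) is expected


# -- summary ---------------------------------------------------------------


def test_rate_truncated_to_one_decimal():
    assert rate_pct(44, 66) == 66.6
    assert rate_pct(2, 3) == 66.6
    assert rate_pct(1, 2) == 50.0
    assert rate_pct(0, 0) == 0.0
    assert rate_pct(21, 27) == 77.7


def test_empty_inputs_give_zero_table(cfg):
    table = summarize_counts([], {}, [], set(), cfg=cfg)
    assert len(table) == 1  # totals row only
    assert table.iloc[0][["n_predicted", "n_bound", "n_immunogenic"]].tolist() == [0, 0, 0]


def test_downstream_only_peptide_is_consistency_error(cfg):
    with pytest.raises(ConsistencyError):
        summarize_counts([("s", "a", "PEP1")], {"PEP2": True}, cfg=cfg)


def test_random_flag_tables_match_counting_oracle(cfg):
    rng = random.Random(12)
    for _ in range(200):
        predicted, binder, resp, displayed = [], {}, [], set()
        expect = {}
        for g in range(rng.randint(1, 4)):
            sample, allele = f"s{g % 2}", f"a{g}"
            n = rng.randint(1, 8)
            n_b = n_i = n_d = 0
            for i in range(n):
                pep = f"{sample}:{allele}:{i}"
                predicted.append((sample, allele, pep))
                is_b = rng.random() < 0.6
                binder[pep] = is_b
                n_b += is_b
                responds = rng.random() < 0.4
                resp.append((f"D{rng.randint(1, 3)}", pep, responds))
                n_i += is_b and responds
                if rng.random() < 0.1:
                    displayed.add(pep)
                    n_d += 1
            expect[(sample, allele)] = (n, n_b, n_i, n_d)
        table = summarize_counts(predicted, binder, resp, displayed, cfg=cfg)
        body = table[table["sample"] != "total"]
        assert len(body) == len(expect)
        for _, row in body.iterrows():
            n, n_b, n_i, n_d = expect[(row["sample"], row["allele"])]
            assert (row["n_predicted"], row["n_bound"]) == (n, n_b)
            assert (row["n_immunogenic"], row["n_displayed"]) == (n_i, n_d)
            assert row["n_immunogenic"] <= row["n_bound"] <= row["n_predicted"]
        totals = table[table["sample"] == "total"].iloc[0]
        assert totals["n_predicted"] == sum(e[0] for e in expect.values())
        assert totals["n_bound"] == sum(e[1] for e in expect.values())
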