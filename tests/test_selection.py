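"""Selection rules vs an independent straight-line oracle; mock predictor."""

import itertools

import pytest

from neovax import (
    AffinityPrediction,
    EpitopeCandidate,
    MutationPosition,
    PipelineConfig,
    RulePath,
    classify_mutation_position,
    mock_affinity_predictor,
    select_human_candidates,
    select_mouse_candidates,
)
from neovax.errors import ConfigurationError, ConsistencyError, FormatError

MUT9 = "KLFEKVTAV"


def cand9(off, allele="HLA-A*02:01"):
    wt = MUT9[: off - 1] + ("G" if MUT9[off - 1] != "G" else "P") + MUT9[off:]
    return EpitopeCandidate(MUT9, wt, off, "v1", allele=allele)


def aff_map(cand, mut_nm, wt_nm, allele="HLA-A*02:01"):
    return {
        (cand.mutant_peptide, allele): AffinityPrediction(
            cand.mutant_peptide, allele, mut_nm, 1.0
        ),
        (cand.wt_peptide, allele): AffinityPrediction(cand.wt_peptide, allele, wt_nm, 1.0),
    }


@pytest.mark.parametrize(
    "length,offset,expected",
    [
        (9, 1, MutationPosition.ANCHOR),
        (9, 2, MutationPosition.ANCHOR),
        (9, 9, MutationPosition.ANCHOR),  # C-terminus
        (9, 5, MutationPosition.TCR_FACING),
        (8, 8, MutationPosition.ANCHOR),
        (10, 9, MutationPosition.TCR_FACING),
        (10, 10, MutationPosition.ANCHOR),
    ],
)
def test_anchor_classification(length, offset, expected):
    mut = "KLFEKVTAVL"[:length]
    wt = mut[: offset - 1] + ("G" if mut[offset - 1] != "G" else "P") + mut[offset:]
    cand = EpitopeCandidate(mut, wt, offset, "v")
    assert classify_mutation_position(cand) == expected


def test_anchor_differential_selected(cfg):
    cand = cand9(2)  # anchor
    (d,) = select_human_candidates([cand], aff_map(cand, 800.0, 1500.0), cfg)
    assert d.selected and d.rule_path is RulePath.ANCHOR_DIFFERENTIAL


def test_mutant_above_threshold_rejected(cfg):
    cand = cand9(2)
    (d,) = select_human_candidates([cand], aff_map(cand, 1200.0, 5000.0), cfg)
    assert not d.selected and d.rule_path is RulePath.REJECTED_AFFINITY


def test_tcr_facing_similar_pair_selected(cfg):
    cand = cand9(5)
    (d,) = select_human_candidates([cand], aff_map(cand, 300.0, 350.0), cfg)
    assert d.selected and d.rule_path is RulePath.NONANCHOR_SIMILAR


def test_anchor_similar_pair_rejected_for_position(cfg):
    cand = cand9(2)
    (d,) = select_human_candidates([cand], aff_map(cand, 300.0, 350.0), cfg)
    assert not d.selected and d.rule_path is RulePath.REJECTED_POSITION


def _human_oracle(mut_nm, wt_nm, is_anchor, thr, wt_floor, fold):
    """Literal restatement of the selection wording, independent of RulePath."""
    if not mut_nm < thr:
        return False
    if wt_nm > wt_floor:  # mutant binds, wild type does not: differential
        return True
    similar = wt_nm < thr and max(mut_nm, wt_nm) / min(mut_nm, wt_nm) <= fold
    return similar and not is_anchor


@pytest.mark.parametrize("allele", ["HLA-A*02:01", "HLA-A*03:01", "HLA-A*24:02"])
def test_exhaustive_affinity_position_grid_matches_oracle(cfg, allele):
    thr = cfg.mutant_threshold(allele)
    wt_floor = cfg.wt_floor(allele)
    # affinities straddling the threshold and similarity fold from both sides
    levels = [thr / 20, thr / 2, thr / 1.01, thr * 1.01, thr * 2, thr * 20]
    offsets = [1, 2, 5, 9]
    for mut_nm, wt_nm, off in itertools.product(levels, levels, offsets):
        cand = cand9(off, allele)
        (d,) = select_human_candidates([cand], aff_map(cand, mut_nm, wt_nm, allele), cfg)
        expected = _human_oracle(
            mut_nm, wt_nm, off in (1, 2, 9), thr, wt_floor, cfg.similar_affinity_fold
        )
        assert d.selected == expected, (allele, mut_nm, wt_nm, off)


def test_loosening_threshold_never_shrinks_selection():
    base = PipelineConfig()
    loose = PipelineConfig(similar_affinity_fold=10.0)
    loose.allele_thresholds = {k: v * 2 for k, v in base.allele_thresholds.items()}
    levels = [100.0, 600.0, 1200.0, 3000.0]
    for mut_nm, wt_nm, off in itertools.product(levels, levels, [2, 5]):
        cand = cand9(off)
        sel_base = select_human_candidates([cand], aff_map(cand, mut_nm, wt_nm), base)[0]
        sel_loose = select_human_candidates([cand], aff_map(cand, mut_nm, wt_nm), loose)[0]
        assert sel_loose.selected >= sel_base.selected


def test_missing_wt_prediction_is_an_error(cfg):
    cand = cand9(5)
    preds = {
        (cand.mutant_peptide, cand.allele): AffinityPrediction(
            cand.mutant_peptide, cand.allele, 100.0, 0.5
        )
    }
    with pytest.raises(ConsistencyError, match="no affinity prediction"):
        select_human_candidates([cand], preds, cfg)


def test_unconfigured_allele_is_an_error(cfg):
    cand = cand9(5, allele="HLA-B*07:02")
    with pytest.raises(ConfigurationError):
        select_human_candidates([cand], aff_map(cand, 100.0, 100.0, "HLA-B*07:02"), cfg)


# -- mouse rule ------------------------------------------------------------


def mouse_cand():
    return EpitopeCandidate("SIINFEKL", "SIINFEKV", 8, "v1")


def mouse_aff(db_rank, kb_rank):
    c = mouse_cand()
    out = {}
    for allele, rank in (("H2-Db", db_rank), ("H2-Kb", kb_rank)):
        if rank is not None:
            out[(c.mutant_peptide, allele)] = AffinityPrediction(
                c.mutant_peptide, allele, 500.0, rank
            )
    return out


@pytest.mark.parametrize(
    "db_rank,kb_rank,selected,qualifying",
    [
        (5.0, 0.5, True, "H2-Kb"),
        (1.5, 1.5, False, None),
        (1.0, 2.0, True, "H2-Db"),  # inclusive boundary
        (None, 0.3, True, "H2-Kb"),  # single-allele prediction suffices
        (1.0001, None, False, None),
    ],
)
def test_mouse_rank_rule(cfg, db_rank, kb_rank, selected, qualifying):
    (d,) = select_mouse_candidates([mouse_cand()], mouse_aff(db_rank, kb_rank), cfg)
    assert d.selected == selected
    assert d.qualifying_allele == qualifying


def test_mouse_rank_boundary_matches_oracle(cfg):
    """Sweep ranks across the cut-off; decision equals `min rank <= 1.0`."""
    for db in [0.1, 0.99, 1.0, 1.01, 3.0]:
        for kb in [0.5, 1.0, 1.5, 50.0]:
            (d,) = select_mouse_candidates([mouse_cand()], mouse_aff(db, kb), cfg)
            assert d.selected == (min(db, kb) <= cfg.mouse_rank_max)


def test_mouse_without_any_prediction_is_error(cfg):
    with pytest.raises(ConsistencyError):
        select_mouse_candidates([mouse_cand()], {}, cfg)


# -- mock predictor --------------------------------------------------------


def test_mock_predictor_is_deterministic():
    a = mock_affinity_predictor("SIINFEKL", "H2-Kb", 7)
    b = mock_affinity_predictor("SIINFEKL", "H2-Kb", 7)
    assert a == b
    c = mock_affinity_predictor("SIINFEKL", "H2-Kb", 8)
    assert c != a  # seed changes the prediction


def test_mock_predictor_bounds_and_rank_monotonicity():
    import random

    rng = random.Random(0)
    aa = "ACDEFGHIKLMNPQRSTVWY"
    preds = [
        mock_affinity_predictor("".join(rng.choices(aa, k=9)), "HLA-A*02:01", 1)
        for _ in range(1000)
    ]
    assert all(1.0 <= p.affinity_nm <= 50000.0 for p in preds)
    assert all(0.0 <= p.rank_pct <= 100.0 for p in preds)
    by_affinity = sorted(preds, key=lambda p: p.affinity_nm)
    ranks = [p.rank_pct for p in by_affinity]
    assert ranks == sorted(ranks)  # rank strictly increases with affinity
    assert len(set(ranks)) == len(ranks)


def test_mock_predictor_length_contract():
    with pytest.raises(FormatError):
        mock_affinity_predictor("ACDEFGHIKLMN", "H2-Kb", 0)  # 12-mer
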