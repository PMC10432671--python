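"""Somatic filter: arithmetic, boundary grid vs brute-force oracle, properties."""

import itertools

import pytest

from neovax import (
    FILTER_RULES,
    PipelineConfig,
    SomaticVariant,
    apply_somatic_filters,
    gen_variants,
    normal_vaf,
    tumor_vaf,
)
from neovax.errors import FormatError, UndefinedVafError


def make_variant(**over):
    base = dict(
        id="v1",
        gene="G",
        protein_id="P",
        aa_pos=50,
        ref_aa="D",
        alt_aa="Y",
        tumor_depth=50,
        normal_depth=40,
        tumor_alt_reads=10,
        normal_alt_reads=0,
        alt_fwd=4,
        alt_rev=6,
        pop_maf=0.0,
    )
    base.update(over)
    return SomaticVariant(**base)


@pytest.mark.parametrize(
    "alt,depth,expected",
    [(10, 50, 0.20), (0, 50, 0.0), (50, 50, 1.0)],
)
def test_tumor_vaf_arithmetic(alt, depth, expected):
    v = make_variant(tumor_alt_reads=alt, alt_fwd=alt, alt_rev=0, tumor_depth=depth)
    assert tumor_vaf(v) == pytest.approx(expected)


def test_zero_depth_vaf_is_an_error():
    v = make_variant(tumor_depth=0, tumor_alt_reads=0, alt_fwd=0, alt_rev=0)
    with pytest.raises(UndefinedVafError):
        tumor_vaf(v)
    w = make_variant(normal_depth=0)
    with pytest.raises(UndefinedVafError):
        normal_vaf(w)


@pytest.mark.parametrize(
    "bad",
    [
        dict(ref_aa="D", alt_aa="D"),  # not missense
        dict(tumor_alt_reads=60),  # exceeds depth
        dict(alt_fwd=3, alt_rev=3),  # strand counts don't sum
        dict(pop_maf=1.5),
    ],
)
def test_variant_invariants_enforced(bad):
    with pytest.raises(FormatError):
        make_variant(**bad)


def test_textbook_passing_variant_is_retained(cfg):
    # depths 50/40, normal VAF 0.5%, tumor VAF 20%, both strands, novel variant
    v = make_variant(
        tumor_depth=50,
        normal_depth=40,
        tumor_alt_reads=10,
        normal_alt_reads=0,
        alt_fwd=4,
        alt_rev=6,
        pop_maf=0.0,
    )
    retained, audit = apply_somatic_filters([v], cfg)
    assert retained == [v]
    assert audit[0].retained and audit[0].failed_rule is None


def test_empty_input_allowed(cfg):
    assert apply_somatic_filters([], cfg) == ([], [])


def _oracle_pass(v, cfg):
    """Independent straight-line restatement of the filter conjunction."""
    return (
        v.tumor_depth > cfg.coverage_min
        and v.normal_depth > cfg.coverage_min
        and (v.normal_alt_reads / v.normal_depth) < cfg.normal_vaf_max
        and (v.tumor_alt_reads / v.tumor_depth) > cfg.tumor_vaf_min
        and v.alt_fwd >= 1
        and v.alt_rev >= 1
        and v.pop_maf <= cfg.pop_maf_max
    )


def boundary_grid(cfg):
    """64 variants crossing each rule's boundary (one fail/pass value per rule)."""
    tumor_depth_opts = (cfg.coverage_min, cfg.coverage_min + 40)  # fail / pass
    normal_depth_opts = (cfg.coverage_min, 100)
    normal_alt_opts = (2, 0)  # 2/100 = 2% fails; 0 passes
    tumor_vaf_opts = (0.10, 0.40)
    strand_opts = (False, True)  # all-forward vs both strands
    maf_opts = (5 * cfg.pop_maf_max, 0.0)
    grid = []
    for i, (td, nd, na, tv, strand, maf) in enumerate(
        itertools.product(
            tumor_depth_opts,
            normal_depth_opts,
            normal_alt_opts,
            tumor_vaf_opts,
            strand_opts,
            maf_opts,
        )
    ):
        alt = max(2, round(tv * td))
        fwd = alt if not strand else 1
        grid.append(
            make_variant(
                id=f"g{i:02d}",
                tumor_depth=td,
                normal_depth=nd,
                normal_alt_reads=min(na, nd),
                tumor_alt_reads=alt,
                alt_fwd=fwd,
                alt_rev=alt - fwd,
                pop_maf=maf,
            )
        )
    return grid


def test_boundary_grid_matches_brute_force_oracle(cfg):
    grid = boundary_grid(cfg)
    assert len(grid) == 64
    retained, audit = apply_somatic_filters(grid, cfg)
    expected = [v for v in grid if _oracle_pass(v, cfg)]
    assert retained == expected
    # exactly one cell of the grid passes everything
    assert len(retained) == 1
    for v, a in zip(grid, audit):
        assert a.retained == _oracle_pass(v, cfg)
        if not a.retained:
            assert a.failed_rule in FILTER_RULES


def test_tightening_any_threshold_never_increases_retention(cfg):
    grid = boundary_grid(cfg) + gen_variants(10, 2, seed=3)[0]
    base_n = len(apply_somatic_filters(grid, cfg)[0])
    tighter = [
        PipelineConfig(coverage_min=cfg.coverage_min + 50),
        PipelineConfig(normal_vaf_max=cfg.normal_vaf_max / 10),
        PipelineConfig(tumor_vaf_min=0.5),
        PipelineConfig(pop_maf_max=cfg.pop_maf_max / 100),
    ]
    for tcfg in tighter:
        assert len(apply_somatic_filters(grid, tcfg)[0]) <= base_n


def test_filter_is_idempotent_and_order_preserving(cfg):
    variants, _ = gen_variants(8, 3, seed=11)
    retained, _ = apply_somatic_filters(variants, cfg)
    again, _ = apply_somatic_filters(retained, cfg)
    assert again == retained
    ids = [v.id for v in variants]
    assert [v.id for v in retained] == [i for i in ids if i in {v.id for v in retained}]


def test_generator_truth_recovered_exactly(cfg):
    variants, truth = gen_variants(12, 4, seed=23, cfg=cfg)
    retained, _ = apply_somatic_filters(variants, cfg)
    assert {v.id for v in retained} == truth.true_somatic_ids


def test_absent_pop_maf_treated_as_novel(tmp_path, cfg):
    from neovax import io as nio

    path = tmp_path / "v.tsv"
    v = make_variant()
    nio.write_variant_table([v], path)
    text = path.read_text().splitlines()
    text[1] = text[1].rsplit("\t", 1)[0] + "\t"  # blank pop_maf cell
    path.write_text("\n".join(text) + "\n")
    (loaded,) = nio.read_variant_table(path)
    assert loaded.pop_maf == 0.0
    assert apply_somatic_filters([loaded], cfg)[0] == [loaded]
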