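"""Instrument-selection filters, LD clumping and the F statistic."""

import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy import stats as sps

from pqtlmr.instruments import (
    LDMatrix,
    LDMatrixError,
    SelectionConfig,
    exclude_mhc,
    exclude_outcome_associated,
    f_statistic,
    filter_cis,
    filter_f,
    ld_clump,
    select_instruments,
    select_significant,
)
from pqtlmr.sumstats import GeneAnnotation

from conftest import make_sumstats, random_sumstats

CFG = SelectionConfig()


def test_significance_threshold_is_strict():
    stats = make_sumstats(
        variant_id=["a", "b"], beta=[0.1, 0.1], se=[0.01, 0.01],
        pvalue=[4.9e-8, 5e-8],
    )
    kept = select_significant(stats, CFG)
    assert list(kept.table["variant_id"]) == ["a"]  # p == 5e-8 exactly is dropped


def test_significance_all_null_gives_empty():
    stats = make_sumstats(variant_id=list("abc"), beta=[0.1] * 3, se=[0.01] * 3, pvalue=[0.5] * 3)
    assert len(select_significant(stats, CFG)) == 0


@pytest.mark.parametrize(
    "chrom,pos,kept",
    [
        ("6", 30_000_000, False),
        ("6", 28_477_897, False),  # inclusive lower bound
        ("6", 33_448_354, False),  # inclusive upper bound
        ("6", 28_477_896, True),
        ("6", 33_448_355, True),
        ("7", 30_000_000, True),
    ],
)
def test_mhc_exclusion_boundaries(chrom, pos, kept):
    stats = make_sumstats(
        variant_id=["v"], chromosome=[chrom], position=[pos],
        beta=[0.1], se=[0.01], pvalue=[0.5],
    )
    assert (len(exclude_mhc(stats, CFG)) == 1) is kept


@pytest.mark.parametrize(
    "pos,kept",
    [
        (500_000, True),        # 500 kb upstream of gene start
        (1, True),              # within window (start - 1 Mb floor-clips below 1)
        (2_010_000, True),      # exactly gene end + 1 Mb
        (2_010_001, False),     # one bp beyond
    ],
)
def test_cis_window_boundaries(pos, kept):
    gene = GeneAnnotation("G", "1", 1_000_000, 1_010_000)
    stats = make_sumstats(
        variant_id=["v"], chromosome=["1"], position=[pos],
        beta=[0.1], se=[0.01], pvalue=[0.5],
    )
    assert (len(filter_cis(stats, gene, CFG)) == 1) is kept


def test_cis_requires_same_chromosome():
    gene = GeneAnnotation("G", "2", 1_000_000, 1_010_000)
    stats = make_sumstats(
        variant_id=["v"], chromosome=["1"], position=[1_000_000],
        beta=[0.1], se=[0.01], pvalue=[0.5],
    )
    assert len(filter_cis(stats, gene, CFG)) == 0


def test_independent_filters_commute_and_match_bruteforce(rng):
    stats = random_sumstats(rng, 300)
    gene = GeneAnnotation("G", "6", 30_000_000, 30_010_000)
    a = filter_cis(exclude_mhc(select_significant(stats, CFG), CFG), gene, CFG)
    b = select_significant(exclude_mhc(filter_cis(stats, gene, CFG), CFG), CFG)
    assert list(a.table["variant_id"]) == list(b.table["variant_id"])

    t = stats.table
    brute = (
        (t["pvalue"] < CFG.p_threshold)
        & ~((t["chromosome"] == "6") & t["position"].between(CFG.mhc_start, CFG.mhc_end))
        & (t["chromosome"] == "6")
        & t["position"].between(gene.start - CFG.cis_window, gene.end + CFG.cis_window)
    )
    assert set(a.table["variant_id"]) == set(t.loc[brute, "variant_id"])


def test_filters_idempotent(rng):
    stats = random_sumstats(rng, 200)
    gene = GeneAnnotation("G", "3", 50_000_000, 50_010_000)
    for op in (
        lambda s: select_significant(s, CFG),
        lambda s: exclude_mhc(s, CFG),
        lambda s: filter_cis(s, gene, CFG),
        lambda s: filter_f(s, CFG),
    ):
        once = op(stats)
        twice = op(once)
        assert list(once.table["variant_id"]) == list(twice.table["variant_id"])


# ---------------------------------------------------------------------------
# LD clumping


def _clump_stats(pvals, positions=None, chrom="1"):
    k = len(pvals)
    return make_sumstats(
        variant_id=[f"v{i}" for i in range(k)],
        chromosome=[chrom] * k,
        position=positions if positions is not None else np.arange(k) * 1000 + 1,
        beta=[0.1] * k, se=[0.01] * k, pvalue=pvals,
    )


def test_clump_single_block_keeps_min_p():
    stats = _clump_stats([1e-10, 1e-9, 1e-8])
    ld = LDMatrix.from_blocks({"b": ["v0", "v1", "v2"]}, 0.9)
    kept = ld_clump(stats, ld, CFG)
    assert list(kept.table["variant_id"]) == ["v0"]


def test_clump_uncorrelated_keeps_all():
    stats = _clump_stats([1e-10, 1e-9, 1e-8])
    kept = ld_clump(stats, LDMatrix(), CFG)
    assert len(kept) == 3


def test_clump_block_diagonal_keeps_per_block_minimum(rng):
    k_blocks, per_block = 6, 4
    n = k_blocks * per_block
    pvals = rng.uniform(1e-12, 1e-8, size=n)
    stats = _clump_stats(pvals)
    blocks = {
        f"b{b}": [f"v{b * per_block + j}" for j in range(per_block)]
        for b in range(k_blocks)
    }
    kept = ld_clump(stats, LDMatrix.from_blocks(blocks, 0.8), CFG)
    expected = {
        members[int(np.argmin([pvals[int(m[1:])] for m in members]))]
        for members in blocks.values()
    }
    assert set(kept.table["variant_id"]) == expected
    # pairwise independence of the kept set
    ld = LDMatrix.from_blocks(blocks, 0.8)
    kept_ids = list(kept.table["variant_id"])
    for i, a in enumerate(kept_ids):
        for b in kept_ids[i + 1 :]:
            assert ld.r2_between(a, b) <= CFG.clump_r2


def test_clump_respects_window():
    # correlated pair but 20 Mb apart: both kept
    stats = _clump_stats([1e-10, 1e-9], positions=[1, 20_000_001])
    ld = LDMatrix.from_blocks({"b": ["v0", "v1"]}, 0.9)
    assert len(ld_clump(stats, ld, CFG)) == 2


def test_clump_tie_break_lexicographic():
    stats = _clump_stats([1e-9, 1e-9])
    ld = LDMatrix.from_blocks({"b": ["v0", "v1"]}, 0.9)
    assert list(ld_clump(stats, ld, CFG).table["variant_id"]) == ["v0"]


def test_asymmetric_dense_matrix_rejected():
    r2 = np.array([[1.0, 0.5], [0.4, 1.0]])
    with pytest.raises(LDMatrixError, match="symmetric"):
        LDMatrix.from_dense(["a", "b"], r2)


def test_ld_pair_and_block_files_roundtrip(tmp_path):
    ld = LDMatrix.from_blocks({"b1": ["a", "b", "c"], "b2": ["d", "e"]}, 0.7)
    path = tmp_path / "ld.tsv"
    ld.to_pairs_tsv(path)
    again = LDMatrix.from_pairs_tsv(path)
    assert again.r2_between("a", "c") == pytest.approx(0.7)
    assert again.r2_between("a", "d") == 0.0

    block_file = tmp_path / "blocks.tsv"
    block_file.write_text("b1\ta\t0.7\nb1\tb\t0.7\nb2\td\t0.5\nb2\te\t0.5\n")
    from_blocks = LDMatrix.from_blocks_tsv(block_file)
    assert from_blocks.r2_between("d", "e") == pytest.approx(0.5)


# ---------------------------------------------------------------------------
# F statistic and composition


def test_f_statistic_exact_and_domain():
    assert f_statistic(0.1, 0.01) == pytest.approx(100.0)
    assert f_statistic(0.0, 0.5) == 0.0
    with pytest.raises(ValueError):
        f_statistic(0.1, 0.0)


def test_f_matches_z_from_pvalue(rng):
    beta = rng.normal(0, 0.3, size=100)
    se = rng.uniform(0.01, 0.1, size=100)
    z = beta / se
    p = 2 * sps.norm.sf(np.abs(z))
    f = f_statistic(beta, se)
    z_back = sps.norm.isf(p / 2)
    np.testing.assert_allclose(f, z_back**2, rtol=1e-2)


def test_select_instruments_composed_fixture():
    # one strong cis variant, one strong MHC variant, one weak cis variant
    gene = GeneAnnotation("G", "6", 34_000_000, 34_010_000)
    stats = make_sumstats(
        "G",
        variant_id=["cis_strong", "mhc_strong", "cis_weak"],
        chromosome=["6", "6", "6"],
        position=[34_005_000, 30_000_000, 34_006_000],
        beta=[0.5, 0.5, 0.01],
        se=[0.05, 0.05, 0.05],
        pvalue=[1e-20, 1e-20, 0.5],
    )
    kept, counts = select_instruments(stats, gene, LDMatrix(), CFG)
    assert list(kept.table["variant_id"]) == ["cis_strong"]
    assert counts["dropped_mhc"] == 1 and counts["dropped_significance"] == 1


def test_select_instruments_no_significant_variants():
    gene = GeneAnnotation("G", "1", 1_000_000, 1_010_000)
    stats = make_sumstats(
        "G", variant_id=["a"], chromosome=["1"], position=[1_005_000],
        beta=[0.1], se=[0.05], pvalue=[0.5],
    )
    kept, counts = select_instruments(stats, gene, LDMatrix(), CFG)
    assert len(kept) == 0 and counts["kept"] == 0


def test_outcome_overlap_exclusion():
    instruments = make_sumstats(
        variant_id=["a", "b", "c"], beta=[0.3] * 3, se=[0.01] * 3, pvalue=[1e-10] * 3
    )
    outcome = make_sumstats(
        "out", variant_id=["a", "b"], beta=[0.1, 0.0], se=[0.01, 0.01],
        pvalue=[1e-9, 0.3],
    )
    kept = exclude_outcome_associated(instruments, outcome, CFG)
    # a: outcome-significant, dropped; c: absent from outcome, dropped
    assert list(kept.table["variant_id"]) == ["b"]


@given(st.integers(0, 2**31 - 1))
def test_outcome_overlap_matches_bruteforce(seed):
    rng = np.random.default_rng(seed)
    instruments = random_sumstats(rng, 50, "exp")
    outcome = random_sumstats(rng, 50, "out")
    # force id overlap
    outcome.table["variant_id"] = instruments.table["variant_id"].sample(
        frac=1.0, random_state=0
    ).to_numpy()
    outcome._indexed = None
    kept = exclude_outcome_associated(instruments, outcome, CFG)
    out_p = dict(zip(outcome.table["variant_id"], outcome.table["pvalue"]))
    expected = [
        v for v in instruments.table["variant_id"]
        if v in out_p and not out_p[v] < CFG.outcome_p_exclusion
    ]
    assert list(kept.table["variant_id"]) == expected


def test_selection_config_validation_and_yaml(tmp_path):
    with pytest.raises(ValueError):
        SelectionConfig(clump_r2=1.5)
    with pytest.raises(ValueError):
        SelectionConfig(p_threshold=0)
    path = tmp_path / "cfg.yaml"
    path.write_text("p_threshold: 1.0e-6\nclump_r2: 0.01\n")
    cfg = SelectionConfig.from_yaml(path)
    assert cfg.p_threshold == 1e-6 and cfg.clump_r2 == 0.01 and cfg.f_min == 10.0
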