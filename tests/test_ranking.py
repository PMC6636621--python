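"""Direction-aware ranking, ASR aggregation and ordering."""

import numpy as np
import pandas as pd
import pytest

import stressidx as sx
from stressidx.indices import RANKED_VARIABLES


def test_toy_ranks_and_asr(toy_trial):
    """B beats A everywhere except the tied Yp column."""
    table = sx.compute_indices(toy_trial)
    ranks = sx.rank_all(table, toy_trial)
    assert ranks.ranks.loc["A", "Yp"] == ranks.ranks.loc["B", "Yp"] == 1.5
    for col in RANKED_VARIABLES[1:]:
        assert ranks.ranks.loc["B", col] == 1.0
        assert ranks.ranks.loc["A", col] == 2.0
    assert ranks.asr["B"] == pytest.approx((1.5 + 10) / 11)
    assert ranks.asr["A"] == pytest.approx((1.5 + 20) / 11)
    assert sx.sort_by_asr(ranks) == ["B", "A"]


def test_rank_columns_sum_to_triangular_number(indices20, trial20):
    ranks = sx.rank_all(indices20, trial20)
    n = trial20.n
    for col in RANKED_VARIABLES:
        assert ranks.ranks[col].sum() == pytest.approx(n * (n + 1) / 2)


def test_full_tie_column_gets_midrank():
    trial = sx.TrialTable(tuple("abcde"), [3.0] * 5, [2.0, 1.0, 1.5, 0.5, 2.5])
    ranks = sx.rank_all(sx.compute_indices(trial))
    assert (ranks.ranks["Yp"] == 3.0).all()


def test_ysi_rsi_and_ssi_rank_columns_coincide(indices20):
    """RSI is a positive multiple of YSI; SSI a decreasing affine map of it."""
    ranks = sx.rank_all(indices20).ranks
    np.testing.assert_array_equal(ranks["YSI"], ranks["RSI"])
    assert indices20.means.ys_bar < indices20.means.yp_bar
    np.testing.assert_array_equal(ranks["SSI"], ranks["YSI"])


def test_label_equivariance_under_row_permutation(trial20):
    ranks = sx.rank_all(sx.compute_indices(trial20))
    rng = np.random.default_rng(3)
    perm = rng.permutation(trial20.n)
    shuffled = sx.TrialTable(
        tuple(trial20.genotypes[i] for i in perm),
        trial20.yp[perm],
        trial20.ys[perm],
    )
    ranks_perm = sx.rank_all(sx.compute_indices(shuffled))
    for genotype in trial20.genotypes:
        np.testing.assert_allclose(
            ranks_perm.ranks.loc[genotype], ranks.ranks.loc[genotype], rtol=1e-12
        )


def test_nine_column_variant_excludes_yields(indices20):
    r11 = sx.rank_all(indices20, asr_columns=11)
    r9 = sx.rank_all(indices20, asr_columns=9)
    index_cols = [c for c in RANKED_VARIABLES if c not in ("Yp", "Ys")]
    np.testing.assert_allclose(r9.asr, r9.ranks[index_cols].mean(axis=1))
    assert not np.allclose(r9.asr, r11.asr)
    # rank columns themselves are identical either way
    np.testing.assert_array_equal(r9.ranks, r11.ranks)


def test_undefined_column_excluded_from_asr():
    trial = sx.TrialTable(("a", "b", "c"), [4.0, 2.0, 3.0], [2.0, 4.0, 3.0])  # Ȳs = Ȳp
    with pytest.warns(UserWarning):
        table = sx.compute_indices(trial)
        ranks = sx.rank_all(table)
    assert ranks.excluded == ("SSI",)
    assert ranks.ranks["SSI"].isna().all()
    remaining = [c for c in RANKED_VARIABLES if c != "SSI"]
    np.testing.assert_allclose(ranks.asr, ranks.ranks[remaining].mean(axis=1))


def test_sort_by_asr_breaks_ties_by_sd_then_input_order():
    ranks = sx.RankTable(
        ranks=sx.rank_all(sx.compute_indices(sx.TrialTable(("x", "y", "z"), [1.0, 2, 3], [1.0, 2, 3]))).ranks,
        rank_sum=pd.Series([4.0, 4.0, 4.0], index=["x", "y", "z"]),
        asr=pd.Series([2.0, 2.0, 2.0], index=["x", "y", "z"]),
        rank_sd=pd.Series([1.0, 0.5, 1.0], index=["x", "y", "z"]),
        excluded=(),
        asr_columns=11,
    )
    assert sx.sort_by_asr(ranks) == ["y", "x", "z"]
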