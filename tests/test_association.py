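"""Pearson/Spearman association matrices, p-values and heat-map specs."""

import numpy as np
import pytest

import stressidx as sx


def brute_force_ranks(values: np.ndarray, minimum_is_best: bool) -> np.ndarray:
    """Independent tie-averaging ranker: sort, then average tied positions."""
    keyed = values if minimum_is_best else -values
    order = sorted(range(len(keyed)), key=lambda i: keyed[i])
    ranks = np.empty(len(keyed))
    pos = 0
    while pos < len(order):
        end = pos
        while end + 1 < len(order) and keyed[order[end + 1]] == keyed[order[pos]]:
            end += 1
        avg = (pos + end) / 2 + 1  # positions are 0-based
        for idx in order[pos : end + 1]:
            ranks[idx] = avg
        pos = end + 1
    return ranks


def test_matrix_structure(indices20):
    mat = sx.pearson_matrix(indices20)
    r = mat.r.to_numpy()
    assert r.shape == (11, 11)
    np.testing.assert_array_equal(np.diag(r), np.ones(11))
    np.testing.assert_allclose(r, r.T, rtol=1e-15)
    assert np.nanmax(np.abs(r)) <= 1.0 + 1e-12


def test_two_points_give_unit_correlation():
    trial = sx.TrialTable(("A", "B"), [4.0, 5.0], [1.0, 3.0])
    mat = sx.pearson_matrix(sx.compute_indices(trial))
    off_diag = mat.r.loc["Yp", "Ys"]
    assert abs(off_diag) == pytest.approx(1.0)


def test_ysi_rsi_exactly_collinear(indices20):
    mat = sx.pearson_matrix(indices20)
    assert mat.r.loc["YSI", "RSI"] == pytest.approx(1.0, abs=1e-12)


def test_spearman_of_identical_and_reversed_columns(indices20):
    ranks = sx.rank_all(indices20)
    mat = sx.spearman_matrix(ranks)
    assert mat.r.loc["YSI", "RSI"] == pytest.approx(1.0, abs=1e-15)
    # a rank column against its exact reversal
    col = ranks.ranks["Yp"].to_numpy()
    reversed_col = len(col) + 1 - col
    rho = np.corrcoef(col, reversed_col)[0, 1]
    assert rho == pytest.approx(-1.0, abs=1e-12)


def test_spearman_equals_brute_force_rank_then_pearson(trial20):
    """Cross-check against an independent sort-and-average ranker."""
    table = sx.compute_indices(trial20)
    ranks = sx.rank_all(table, trial20)
    mat = sx.spearman_matrix(ranks)
    meta = {m.id: m for m in sx.index_metadata()}
    oracle_ranks = {
        col: brute_force_ranks(
            table.frame[col].to_numpy(), meta[col].direction == "min"
        )
        for col in mat.variables
    }
    for i, a in enumerate(mat.variables):
        for b in mat.variables[i + 1 :]:
            expected = np.corrcoef(oracle_ranks[a], oracle_ranks[b])[0, 1]
            assert mat.r.loc[a, b] == pytest.approx(expected, abs=1e-12)


def test_direction_flip_absorbed_into_ranks():
    """TOL (min-is-best) vs MP (max-is-best): with constant Yp the two are
    exactly antitone in values yet identical in favourability, so the
    direction-aware Spearman coefficient is +1 where a textbook Spearman
    on raw values would be -1."""
    trial = sx.TrialTable(tuple("abcde"), [10.0] * 5, [2.0, 4.0, 6.0, 8.0, 9.0])
    with pytest.warns(UserWarning, match="zero variance"):
        table = sx.compute_indices(trial)
        ranks = sx.rank_all(table)
        value_r = np.corrcoef(table.frame["TOL"], table.frame["MP"])[0, 1]
        rank_r = sx.spearman_matrix(ranks).r.loc["TOL", "MP"]
    assert value_r == pytest.approx(-1.0, abs=1e-12)
    assert rank_r == pytest.approx(1.0, abs=1e-12)


def test_pvalues_match_t_transform(indices20):
    from scipy import stats

    mat = sx.pearson_matrix(indices20)
    n = mat.n
    r = mat.r.loc["Yp", "MP"]
    t = r * np.sqrt((n - 2) / (1 - r**2))
    expected = 2 * stats.t.sf(abs(t), df=n - 2)
    assert mat.p.loc["Yp", "MP"] == pytest.approx(expected, rel=1e-12)
    assert (np.diag(mat.p.to_numpy()) == 0).all()


def test_zero_variance_column_flagged():
    trial = sx.TrialTable(("a", "b", "c"), [4.0, 4.0, 4.0], [1.0, 2.0, 3.0])
    with pytest.warns(UserWarning, match="zero variance"):
        mat = sx.pearson_matrix(sx.compute_indices(trial))
    assert np.isnan(mat.r.loc["Yp", "Ys"])
    assert mat.r.loc["Ys", "MP"] == pytest.approx(1.0)


def test_heatmap_spec_styles_and_stars(indices20):
    mat = sx.pearson_matrix(indices20)
    for style in ("square", "circle", "mixed"):
        spec = sx.heatmap_data(mat, style=style)
        assert spec.style == style
        assert spec.vmin == -1 and spec.vmax == 1 and spec.center == 0
    spec = sx.heatmap_data(mat)
    stars = spec.stars.to_numpy()
    pv = mat.p.to_numpy()
    off = ~np.eye(11, dtype=bool)
    assert ((stars == "**") == (pv < 0.01))[off].all()
    with pytest.raises(ValueError):
        sx.heatmap_data(mat, style="hexagon")


def test_bonferroni_adjustment(indices20):
    mat = sx.pearson_matrix(indices20)
    adj = mat.bonferroni_p()
    off = ~np.eye(11, dtype=bool)
    raw = mat.p.to_numpy()[off]
    corrected = adj.to_numpy()[off]
    np.testing.assert_allclose(corrected, np.minimum(raw * 55, 1.0), rtol=1e-12)
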