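"""Index formulas, metadata, algebraic identities and degeneracies."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import stressidx as sx
from stressidx.indices import ALL_VARIABLES, RANKED_VARIABLES


def test_environment_means(toy_trial):
    means = sx.compute_environment_means(toy_trial)
    assert means == (4.0, 2.0)


def test_toy_values_match_hand_derivation(toy_trial):
    frame = sx.compute_indices(toy_trial).frame
    expected_a = {
        "TOL": 3.0, "MP": 2.5, "GMP": 2.0, "HM": 1.6, "SSI": 1.5,
        "STI": 0.25, "YI": 0.5, "YSI": 0.25, "RSI": 0.5, "RC": 75.0,
    }
    for key, value in expected_a.items():
        assert frame.loc["A", key] == value, key
    # second genotype, same population means
    assert frame.loc["B", "SSI"] == 0.5
    assert frame.loc["B", "STI"] == 0.75
    assert frame.loc["B", "YI"] == 1.5


def test_equal_yields_degeneracy():
    trial = sx.TrialTable(("X", "Y"), [5.0, 7.0], [5.0, 7.0])
    frame = sx.compute_indices(trial).frame
    assert (frame["TOL"] == 0).all()
    assert (frame["RC"] == 0).all()
    assert (frame["YSI"] == 1).all()
    for col in ("MP", "GMP", "HM"):
        np.testing.assert_allclose(frame[col], frame["Yp"], rtol=1e-15)


def test_column_order_fixed(indices20):
    assert tuple(indices20.frame.columns) == ALL_VARIABLES
    assert ALL_VARIABLES == (
        "Yp", "Ys", "RC", "TOL", "MP", "GMP", "HM", "SSI", "STI", "YI", "YSI", "RSI",
    )


def test_metadata_directions():
    meta = {m.id: m for m in sx.index_metadata()}
    assert len(meta) == 12
    for worse_is_more in ("TOL", "SSI"):
        assert meta[worse_is_more].direction == "min"
    for better_is_more in ("Yp", "Ys", "MP", "GMP", "HM", "STI", "YI", "YSI", "RSI"):
        assert meta[better_is_more].direction == "max"
    assert not meta["RC"].ranked
    assert all(meta[v].ranked for v in RANKED_VARIABLES)


positive_yield = st.floats(min_value=0.01, max_value=1e4)


@given(
    yp=st.lists(positive_yield, min_size=2, max_size=12),
    ys=st.lists(positive_yield, min_size=2, max_size=12),
)
@settings(max_examples=150, derandomize=True)
def test_identities_hold_on_random_tables(yp, ys):
    """AM-GM-HM chain and the exact algebraic relations among indices."""
    k = min(len(yp), len(ys))
    trial = sx.TrialTable(tuple(f"g{i}" for i in range(k)), yp[:k], ys[:k])
    table = sx.compute_indices(trial)
    f, means = table.frame, table.means

    assert (f["HM"] <= f["GMP"] * (1 + 1e-12)).all()
    assert (f["GMP"] <= f["MP"] * (1 + 1e-12)).all()
    np.testing.assert_allclose(f["STI"], f["GMP"] ** 2 / means.yp_bar**2, rtol=1e-12)
    np.testing.assert_allclose(f["TOL"], f["Yp"] * (1 - f["YSI"]), rtol=1e-10, atol=1e-10)
    np.testing.assert_allclose(f["RSI"], f["YSI"] * means.yp_bar / means.ys_bar, rtol=1e-12)
    loss = 1 - means.ys_bar / means.yp_bar
    if loss != 0:
        np.testing.assert_allclose(f["SSI"], (1 - f["YSI"]) / loss, rtol=1e-12)
    assert f["YI"].mean() == pytest.approx(1.0, rel=1e-12)


@given(
    yp=st.lists(positive_yield, min_size=3, max_size=8),
    c=st.floats(min_value=0.01, max_value=100),
)
@settings(max_examples=100, derandomize=True)
def test_scale_equivariance(yp, c):
    """Rescaling all yields by c scales TOL/MP/GMP/HM and fixes the ratios."""
    rng = np.random.default_rng(0)
    ys = np.array(yp) * rng.uniform(0.3, 1.1, len(yp))
    names = tuple(f"g{i}" for i in range(len(yp)))
    base = sx.compute_indices(sx.TrialTable(names, yp, ys)).frame
    scaled = sx.compute_indices(sx.TrialTable(names, np.array(yp) * c, ys * c)).frame
    for col in ("TOL", "MP", "GMP", "HM"):
        np.testing.assert_allclose(scaled[col], base[col] * c, rtol=1e-9)
    for col in ("SSI", "STI", "YI", "YSI", "RSI", "RC"):
        np.testing.assert_allclose(scaled[col], base[col], rtol=1e-9)


def test_ssi_undefined_when_means_equal():
    trial = sx.TrialTable(("a", "b"), [4.0, 2.0], [2.0, 4.0])  # Ȳs = Ȳp = 3
    with pytest.warns(UserWarning, match="SSI is undefined"):
        frame = sx.compute_indices(trial).frame
    assert frame["SSI"].isna().all()
    assert frame[["TOL", "MP", "GMP", "HM", "STI", "YI", "YSI", "RSI"]].notna().all().all()


def test_ssi_computed_with_warning_on_stress_benefit():
    trial = sx.TrialTable(("a", "b"), [2.0, 3.0], [4.0, 5.0])
    with pytest.warns(UserWarning, match="selection direction inverts"):
        frame = sx.compute_indices(trial).frame
    assert np.isfinite(frame["SSI"]).all()


def test_yi_rsi_undefined_when_all_stressed_yields_zero():
    trial = sx.TrialTable(("a", "b"), [2.0, 3.0], [0.0, 0.0])
    with pytest.warns(UserWarning, match="YI and RSI"):
        frame = sx.compute_indices(trial).frame
    assert frame["YI"].isna().all() and frame["RSI"].isna().all()
    assert np.isfinite(frame["TOL"]).all()
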