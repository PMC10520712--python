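import math

import numpy as np
import pandas as pd
import pytest

from geoconverge.index import (
    IndicatorSpec,
    composite_index,
    entropy_weights,
    standardize,
)


def tidy(values: dict[str, list], years=None) -> pd.DataFrame:
    n = len(next(iter(values.values())))
    return pd.DataFrame(
        {"region": [f"r{i}" for i in range(n)], "year": years or [2000] * n, **values}
    )


def entropy_weights_oracle(cols: list[list[float]]):
    """Independent brute-force of the proportions->entropy->divergence chain."""
    n = len(cols[0])
    divs = []
    for col in cols:
        s = sum(col)
        e = 0.0
        for v in col:
            q = v / s
            if q > 0:
                e -= q * math.log(q)
        e /= math.log(n)
        divs.append(1.0 - e)
    total = sum(divs)
    return [d / total for d in divs]


class TestStandardize:
    def test_positive_extremes_map_to_unit_interval(self):
        panel = tidy({"a": [2.0, 4.0, 6.0]})
        std = standardize(panel, [IndicatorSpec("a", "positive")])
        assert np.allclose(std["a"], [0.0, 0.5, 1.0])

    def test_negative_polarity_reverses(self):
        panel = tidy({"a": [2.0, 4.0, 6.0]})
        std = standardize(panel, [IndicatorSpec("a", "negative")])
        assert np.allclose(std["a"], [1.0, 0.5, 0.0])

    def test_per_year_scope_uses_yearly_extrema(self):
        panel = tidy({"a": [1.0, 3.0, 10.0, 30.0]}, years=[2000, 2000, 2001, 2001])
        std = standardize(panel, [IndicatorSpec("a", "positive")], scope="per_year")
        assert np.allclose(std["a"], [0, 1, 0, 1])

    def test_degenerate_year_maps_to_midpoint_with_warning(self):
        panel = tidy({"a": [5.0, 5.0, 5.0]})
        with pytest.warns(UserWarning, match="degenerate"):
            std = standardize(panel, [IndicatorSpec("a", "positive")])
        assert np.allclose(std["a"], 0.5)

    def test_missing_value_names_offending_cell(self):
        panel = tidy({"a": [1.0, np.nan, 3.0]})
        with pytest.raises(ValueError, match="region='r1'"):
            standardize(panel, [IndicatorSpec("a", "positive")])

    def test_scale_invariance_under_affine_rescaling(self):
        rng = np.random.default_rng(0)
        vals = rng.normal(size=12)
        panel = tidy({"a": list(vals)}, years=[2000] * 6 + [2001] * 6)
        rescaled = tidy({"a": list(3.5 * vals + 7.0)}, years=[2000] * 6 + [2001] * 6)
        spec = [IndicatorSpec("a", "positive")]
        assert np.allclose(standardize(panel, spec)["a"], standardize(rescaled, spec)["a"])

    def test_bound_attainment_each_year(self):
        rng = np.random.default_rng(1)
        panel = tidy({"a": list(rng.normal(size=10))}, years=[2000] * 5 + [2001] * 5)
        std = standardize(panel, [IndicatorSpec("a", "positive")])
        for _, grp in std.groupby("year"):
            assert grp["a"].min() == 0.0 and grp["a"].max() == 1.0

    def test_bad_polarity_rejected(self):
        with pytest.raises(ValueError):
            IndicatorSpec("a", "upward")


class TestEntropyWeights:
    def test_identical_columns_share_weight(self):
        std = tidy({"a": [0.0, 0.5, 1.0], "b": [0.0, 0.5, 1.0]})
        w = entropy_weights(std)
        assert np.allclose(w.weights, [0.5, 0.5])

    def test_constant_column_gets_zero_weight(self):
        std = tidy({"a": [0.3, 0.3, 0.3], "b": [0.0, 0.5, 1.0]})
        w = entropy_weights(std)
        assert np.allclose(w.weights, [0.0, 1.0])

    def test_matches_brute_force_oracle(self):
        cols = {"a": [0.0, 0.5, 1.0], "b": [0.0, 1.0, 1.0]}
        w = entropy_weights(tidy(cols))
        expected = entropy_weights_oracle([cols["a"], cols["b"]])
        assert np.allclose(w.weights, expected, atol=1e-12)
        # frozen values from the oracle, for the record
        assert np.allclose(w.weights, [0.53264, 0.46736], atol=1e-5)

    def test_all_constant_rejected(self):
        std = tidy({"a": [0.5, 0.5], "b": [0.2, 0.2]})
        with pytest.raises(ValueError, match="no discriminating information"):
            entropy_weights(std)

    def test_weights_sum_to_one_on_random_panels(self):
        rng = np.random.default_rng(2)
        for _ in range(20):
            std = tidy({f"v{j}": list(rng.random(8)) for j in range(4)})
            w = entropy_weights(std)
            assert abs(w.weights.sum() - 1.0) < 1e-12
            assert (w.weights >= 0).all()

    def test_shift_changes_weights_explicitly(self):
        std = tidy({"a": [0.0, 0.5, 1.0], "b": [0.1, 0.2, 0.9]})
        w0 = entropy_weights(std)
        w1 = entropy_weights(std, shift=1e-3)
        assert not np.allclose(w0.weights, w1.weights)


class TestCompositeIndex:
    def test_projection_and_bounds(self):
        std = tidy({"a": [1.0, 0.2], "b": [1.0, 0.9], "c": [1.0, 0.4]})
        w = entropy_weights(tidy({"a": [0.0, 1.0], "b": [0.0, 1.0], "c": [0.0, 1.0]}))
        out = composite_index(std, w)
        assert out["health"].iloc[0] == pytest.approx(1.0)
        assert ((out["health"] >= 0) & (out["health"] <= 1)).all()

    def test_known_dot_product(self):
        import pandas as pd

        from geoconverge.index import EntropyWeights

        w = EntropyWeights(
            weights=pd.Series([0.2, 0.3, 0.5], index=["a", "b", "c"]),
            entropies=pd.Series([0.0] * 3, index=["a", "b", "c"]),
            divergences=pd.Series([1.0] * 3, index=["a", "b", "c"]),
        )
        std = tidy({"a": [1.0], "b": [0.0], "c": [0.5]})
        out = composite_index(std, w)
        assert out["health"].iloc[0] == pytest.approx(0.45)

    def test_dimension_mismatch_rejected(self):
        std = tidy({"a": [0.1, 0.9]})
        w = entropy_weights(tidy({"a": [0.0, 1.0], "b": [0.0, 1.0]}))
        with pytest.raises(ValueError):
            composite_index(std, w)

    def test_monotone_in_improving_indicator(self):
        raw = tidy({"a": [1.0, 2.0, 3.0], "b": [4.0, 5.0, 6.0]})
        specs = [IndicatorSpec("a", "positive"), IndicatorSpec("b", "negative")]
        std = standardize(raw, specs)
        w = entropy_weights(std)
        base = composite_index(std, w)["health"]
        better = raw.copy()
        better.loc[1, "a"] = 2.5  # improve a positive indicator for r1
        std2 = standardize(better, specs)
        assert composite_index(std2, w)["health"].iloc[1] >= base.iloc[1]
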