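"""Unit and property tests for the encoding-model regressor builders."""

import math

import numpy as np
import pytest
import sympy
from hypothesis import given, settings
from hypothesis import strategies as st

from cueuse.encoding_models import (
    MODEL_IDS,
    SPATIAL_PROBS,
    VALUE_LABELS,
    LossInputs,
    ValueConfig,
    build_regressor_table,
    counterfactual_loss,
    hick_hyman,
    median_abs_dev,
    motivational_p,
    relative_value_p,
)


class TestHickHyman:
    @pytest.mark.parametrize(
        "p, expected",
        [
            (0.0, 0.0),
            (0.5, math.log(3)),
            (0.8, math.log(2.25)),
            (0.2, math.log(6)),
            (1.0, math.log(2)),
        ],
    )
    def test_values(self, p, expected):
        assert hick_hyman(p) == pytest.approx(expected, abs=1e-12)

    @pytest.mark.parametrize("bad", [-0.1, float("nan"), float("inf")])
    def test_rejects_bad_input(self, bad):
        with pytest.raises(ValueError):
            hick_hyman(bad)

    @given(st.floats(min_value=1e-6, max_value=1e6), st.floats(min_value=1e-6, max_value=1e6))
    @settings(max_examples=200, derandomize=True)
    def test_strictly_decreasing(self, a, b):
        if a == b:
            assert hick_hyman(a) == hick_hyman(b)
        else:
            lo, hi = sorted((a, b))
            assert hick_hyman(lo) > hick_hyman(hi)


class TestMedianAbsDev:
    @pytest.mark.parametrize(
        "values, expected",
        [([100, 10], 45.0), ([7, 7, 7], 0.0), ([0, 1], 0.5), ([1, 2, 3, 4], 1.0)],
    )
    def test_values(self, values, expected):
        assert median_abs_dev(values) == pytest.approx(expected)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            median_abs_dev([])


class TestCounterfactualLoss:
    def test_zero_when_outcomes_coincide(self):
        assert counterfactual_loss(LossInputs(x=42, x_cf=42, y_des=42, mad=45)) == 0.0

    def test_low_target_high_distractor(self):
        # counterfactual equals the desired outcome: only the distance term
        assert counterfactual_loss(
            LossInputs(x=10, x_cf=100, y_des=100, mad=45)
        ) == pytest.approx(2.0)

    def test_high_target_low_distractor(self):
        # squared term dominates: (10 - 100)^2 + 90/45
        assert counterfactual_loss(
            LossInputs(x=100, x_cf=10, y_des=100, mad=45)
        ) == pytest.approx(8102.0)

    def test_zero_mad_with_distinct_outcomes_rejected(self):
        with pytest.raises(ZeroDivisionError):
            counterfactual_loss(LossInputs(x=1, x_cf=2, y_des=2, mad=0))

    @given(
        st.floats(min_value=0.5, max_value=1e3),
        st.floats(min_value=0.5, max_value=1e3),
        st.floats(min_value=0.5, max_value=1e3),
        st.floats(min_value=0.1, max_value=1e3),
    )
    @settings(max_examples=100, derandomize=True)
    def test_distance_term_symmetric_squared_term_not(self, x, x_cf, y_des, mad):
        forward = counterfactual_loss(LossInputs(x=x, x_cf=x_cf, y_des=y_des, mad=mad))
        swapped = counterfactual_loss(LossInputs(x=x_cf, x_cf=x, y_des=y_des, mad=mad))
        d = 0.0 if x == x_cf else abs(x - x_cf) / mad
        # distance part identical in both directions
        assert forward - (x_cf - y_des) ** 2 == pytest.approx(d)
        assert swapped - (x - y_des) ** 2 == pytest.approx(d)
        if (x_cf - y_des) ** 2 != (x - y_des) ** 2:
            assert forward != swapped


class TestAnticipatoryProbabilities:
    @pytest.mark.parametrize(
        "v_tgt, values, expected",
        [(100, [100, 10], 100 / 110), (10, [100, 10], 10 / 110), (5, [5, 5], 0.5)],
    )
    def test_relative_value(self, v_tgt, values, expected):
        assert relative_value_p(v_tgt, values) == pytest.approx(expected, abs=1e-12)

    def test_relative_value_rejects_nonpositive(self):
        with pytest.raises(ValueError):
            relative_value_p(1, [1, 0])

    @pytest.mark.parametrize(
        "probs, values, expected",
        [([0.5, 0.5], [100, 100], 100.0), ([0.5, 0.5], [10, 10], 10.0),
         ([0.5, 0.5], [100, 10], 55.0), ([0.8, 0.2], [100, 10], 82.0)],
    )
    def test_motivational(self, probs, values, expected):
        assert motivational_p(probs, values) == pytest.approx(expected, abs=1e-12)

    def test_motivational_rejects_mismatched_lengths(self):
        with pytest.raises(ValueError):
            motivational_p([0.5, 0.5], [1, 2, 3])


class TestRegressorTables:
    def test_selection_history_table(self):
        table = build_regressor_table("sh")
        assert table[0.8] == pytest.approx(0.81093, abs=1e-4)
        assert table[0.5] == pytest.approx(1.09861, abs=1e-4)
        assert table[0.2] == pytest.approx(1.79176, abs=1e-4)

    def test_counterfactual_table(self):
        table = build_regressor_table("cf")
        assert table["hT/hD"] == 0.0
        assert table["lT/lD"] == 0.0
        assert table["lT/hD"] == pytest.approx(math.log(1.5), abs=1e-12)
        assert table["hT/lD"] == pytest.approx(math.log(1 + 1 / 8102), abs=1e-12)

    def test_relative_value_table(self):
        table = build_regressor_table("rv")
        assert table["hT/lD"] == pytest.approx(math.log(2.1), abs=1e-12)
        assert table["hT/hD"] == pytest.approx(math.log(3), abs=1e-12)
        assert table["lT/lD"] == pytest.approx(math.log(3), abs=1e-12)
        assert table["lT/hD"] == pytest.approx(math.log(12), abs=1e-12)

    def test_spatial_counterfactual_null_table(self):
        table = build_regressor_table("sh_cf_null")
        assert table[0.5] == 0.0
        assert table[0.8] == pytest.approx(math.log(4 / 3), abs=1e-12)
        assert table[0.2] == pytest.approx(math.log(1.5), abs=1e-12)

    @given(
        st.floats(min_value=0.01, max_value=1e4),
        st.floats(min_value=1.01, max_value=100.0),
    )
    @settings(max_examples=100, derandomize=True)
    def test_counterfactual_ordering_any_value_pair(self, low, ratio):
        """Selective slowing for lT/hD; the equal-value cells are exactly 0."""
        high = low * ratio
        t = build_regressor_table("cf", high_points=high, low_points=low)
        assert t["lT/hD"] > t["hT/lD"] > t["hT/hD"] == t["lT/lD"] == 0.0

    @given(
        st.floats(min_value=0.01, max_value=1e4),
        st.floats(min_value=1.01, max_value=100.0),
    )
    @settings(max_examples=100, derandomize=True)
    def test_relative_value_equal_cells(self, low, ratio):
        t = build_regressor_table("rv", high_points=low * ratio, low_points=low)
        assert t["hT/hD"] == pytest.approx(t["lT/lD"], abs=1e-12)
        assert t["hT/lD"] < t["hT/hD"] < t["lT/hD"]

    def test_motivational_ordering(self):
        t = build_regressor_table("mot")
        assert t["hT/hD"] < t["hT/lD"] == t["lT/hD"] < t["lT/lD"]

    def test_unknown_model_rejected(self):
        with pytest.raises(ValueError):
            build_regressor_table("sticky")

    def test_incomplete_condition_set_rejected(self):
        with pytest.raises(ValueError):
            build_regressor_table("sh", conditions=[0.8, 0.5])
        with pytest.raises(ValueError):
            build_regressor_table("cf", conditions=["hT/hD", "lT/hD"])

    def test_value_config_label_consistency(self):
        with pytest.raises(ValueError):
            ValueConfig(v_tgt=10, v_dst=100, label="hT/lD")
        vc = ValueConfig.from_label("lT/hD")
        assert (vc.v_tgt, vc.v_dst) == (10.0, 100.0)

    def test_serialises_long_format(self):
        frame = build_regressor_table("cf").to_frame()
        assert list(frame.columns) == ["model_id", "condition", "value"]
        assert set(frame["condition"]) == set(VALUE_LABELS)


def _sympy_tables(high, low):
    """Independent symbolic oracle composing the encoding equations.

    Works in exact rational arithmetic and evaluates the final log at 50
    digits; shares no code with the implementation.
    """
    high, low = sympy.Rational(high), sympy.Rational(low)
    hh = lambda p: sympy.log(1 / p + 1) if p != 0 else sympy.Integer(0)
    mad = sympy.Rational(1, 2) * sympy.Abs(high - low)  # MAD of {high, low}
    configs = {
        "hT/hD": (high, high), "hT/lD": (high, low),
        "lT/hD": (low, high), "lT/lD": (low, low),
    }
    tables = {"sh": {}, "sh_cf_null": {}, "rv": {}, "mot": {}, "cf": {}}
    for p in (sympy.Rational(4, 5), sympy.Rational(1, 2), sympy.Rational(1, 5)):
        tables["sh"][float(p)] = hh(p)
        if p == sympy.Rational(1, 2):
            loss = sympy.Integer(0)
        else:
            # counterfactual of the match indicator is its complement,
            # desired outcome 1, MAD of {0,1} = 1/2
            match = sympy.Integer(1 if p > sympy.Rational(1, 2) else 0)
            loss = ((1 - match) - 1) ** 2 + sympy.Abs(match - (1 - match)) / sympy.Rational(1, 2)
        tables["sh_cf_null"][float(p)] = hh(loss)
    for label, (vt, vd) in configs.items():
        tables["rv"][label] = hh(vt / (vt + vd))
        tables["mot"][label] = hh(vt / 2 + vd / 2)
        d = sympy.Integer(0) if vt == vd else sympy.Abs(vt - vd) / mad
        tables["cf"][label] = hh((vd - sympy.Max(vt, vd)) ** 2 + d)
    return {
        m: {c: float(sympy.N(v, 50)) for c, v in tbl.items()} for m, tbl in tables.items()
    }


@pytest.mark.parametrize("high, low", [(100, 10), (50, 5), (7, 3)])
def test_all_models_match_symbolic_oracle(high, low):
    oracle = _sympy_tables(high, low)
    for model_id in MODEL_IDS:
        table = build_regressor_table(model_id, high_points=high, low_points=low)
        for cond, value in table.entries.items():
            assert value == pytest.approx(oracle[model_id][cond], abs=1e-12), (
                model_id, cond)
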