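"""Response index, index tables, fitted curves, critical point."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import hippostereo as hs
from hippostereo import indices


def _table(volume_means, density_means):
    means = pd.DataFrame(
        [volume_means, density_means],
        index=list(indices.INDEX_NAMES),
        columns=list(hs.GROUPS),
        dtype=float,
    )
    return indices.ResponseIndexTable(means=means, sds=means * np.nan, mode="ratio_of_means")


class TestResponseIndex:
    def test_control_density_ratio(self):
        assert round(hs.response_index(945, 613), 2) == 1.54

    def test_diabetic_density_ratio(self):
        assert round(hs.response_index(9615, 18055), 2) == 0.53

    def test_identity(self):
        assert hs.response_index(3.7, 3.7) == pytest.approx(1.0)

    @pytest.mark.parametrize("den", [0.0, -1.0])
    def test_nonpositive_denominator_rejected(self, den):
        with pytest.raises(ValueError):
            hs.response_index(1.0, den)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(
        num=st.floats(0.1, 1e4),
        den=st.floats(0.1, 1e4),
        c=st.floats(1e-3, 1e3),
    )
    def test_scale_invariance(self, num, den, c):
        assert hs.response_index(c * num, c * den) == pytest.approx(
            hs.response_index(num, den), rel=1e-9
        )


class TestIndexTable:
    @staticmethod
    def _measurements():
        rows = []
        for g, (vdg, vca3, nddg, ndca3) in {
            "Con": (2.00, 3.15, 945, 613),
            "Ins": (1.99, 3.08, 1074, 616),
            "VitC": (1.64, 2.06, 1119, 798),
            "Dia": (1.58, 1.98, 9615, 18055),
        }.items():
            for i, scale in enumerate((0.9, 1.0, 1.1)):
                rows.append(
                    {
                        "animal_id": f"{g}{i}",
                        "group": g,
                        "V_DG": vdg * scale,
                        "V_CA3": vca3 * scale,
                        "ND_DG": nddg * scale,
                        "ND_CA3": ndca3 * scale,
                    }
                )
        return pd.DataFrame(rows)

    def test_ratio_of_means_reproduces_printed_control_volume(self):
        t = indices.index_table(self._measurements(), mode="ratio_of_means")
        assert t.cell("volume", "Con", 2) == 0.63
        assert t.cell("density", "VitC", 2) == 1.40

    def test_per_animal_equal_ratios_have_zero_sd(self):
        t = indices.index_table(self._measurements(), mode="per_animal")
        # every animal in a group shares the same ratio by construction
        assert t.sds.loc["volume", "Con"] == pytest.approx(0.0, abs=1e-12)
        assert t.cell("volume", "Con") == pytest.approx(2.00 / 3.15)

    def test_empty_group_rejected(self):
        df = self._measurements()
        with pytest.raises(ValueError):
            indices.index_table(df[df["group"] != "Dia"])

    def test_zero_denominator_rejected_per_animal(self):
        df = self._measurements()
        df.loc[df.index[0], "V_CA3"] = 0.0
        with pytest.raises(ValueError):
            indices.index_table(df, mode="per_animal")


class TestFitIndexCurve:
    def test_perfect_line(self):
        t = _table([1, 2, 3, 4], [1, 1, 1, 1])
        c = indices.fit_index_curve(t, "volume", degree=1)
        assert c.coeffs[1] == pytest.approx(1.0, abs=1e-12)
        assert c.coeffs[0] == pytest.approx(0.0, abs=1e-12)

    def test_constant_points(self):
        t = _table([1, 2, 3, 4], [0.7, 0.7, 0.7, 0.7])
        c = indices.fit_index_curve(t, "density", degree=1)
        assert c.coeffs[1] == pytest.approx(0.0, abs=1e-12)
        assert c.coeffs[0] == pytest.approx(0.7)

    def test_published_volume_cells_match_normal_equations(self):
        # closed-form least squares on (1..4, [.63,.64,.81,.80]):
        # slope = 0.34/5 = 0.068, intercept = 0.72 - 0.068*2.5 = 0.55
        t = _table([0.63, 0.64, 0.81, 0.80], [1.54, 1.74, 1.40, 0.53])
        cv = indices.fit_index_curve(t, "volume", degree=1)
        assert cv.coeffs[1] == pytest.approx(0.068, abs=1e-12)
        assert cv.coeffs[0] == pytest.approx(0.55, abs=1e-12)
        cn = indices.fit_index_curve(t, "density", degree=1)
        assert cn.coeffs[1] == pytest.approx(-0.337, abs=1e-12)
        assert cn.coeffs[0] == pytest.approx(2.145, abs=1e-12)

    def test_excess_degree_rejected(self):
        t = _table([1, 2, 3, 4], [1, 1, 1, 1])
        with pytest.raises(ValueError):
            indices.fit_index_curve(t, "volume", degree=4)


class TestCriticalPoint:
    def test_closed_form_crossing(self):
        a = indices.IndexCurve("volume", (0.0, 1.0))  # y = x
        b = indices.IndexCurve("density", (2.0, -1.0))  # y = -x + 2
        cp = indices.critical_point(a, b)
        assert cp.x_star == pytest.approx(1.0, abs=1e-12)
        assert cp.y_star == pytest.approx(1.0, abs=1e-12)

    def test_parallel_lines_have_no_intersection(self):
        a = indices.IndexCurve("volume", (0.0, 1.0))
        b = indices.IndexCurve("density", (1.0, 1.0))
        with pytest.raises(indices.NoIntersectionError):
            indices.critical_point(a, b)

    def test_identical_curves_rejected(self):
        a = indices.IndexCurve("volume", (0.5, 0.3))
        with pytest.raises(ValueError):
            indices.critical_point(a, indices.IndexCurve("density", (0.5, 0.3)))

    def test_out_of_range_crossing_raises(self):
        a = indices.IndexCurve("volume", (0.0, 1.0))
        b = indices.IndexCurve("density", (-20.0, 2.0))  # crosses at x = 20
        with pytest.raises(indices.NoIntersectionError):
            indices.critical_point(a, b)

    def test_quadratic_crossing(self):
        # y = x^2 - 3 and y = 2x - 3 meet at x = 0 and x = 2; range starts at 1
        a = indices.IndexCurve("volume", (-3.0, 0.0, 1.0))
        b = indices.IndexCurve("density", (-3.0, 2.0))
        cp = indices.critical_point(a, b, x_range=(1.0, 6.0))
        assert cp.x_star == pytest.approx(2.0, abs=1e-9)
        assert cp.y_star == pytest.approx(1.0, abs=1e-9)

    def test_published_cells_match_two_line_oracle(self):
        # hand-derived normal equations give the two lines
        # y_v = 0.55 + 0.068 x and y_nd = 2.145 - 0.337 x, meeting at
        # x* = 1.595/0.405 = 319/81, y* = 66.242/81
        t = _table([0.63, 0.64, 0.81, 0.80], [1.54, 1.74, 1.40, 0.53])
        cv = indices.fit_index_curve(t, "volume")
        cn = indices.fit_index_curve(t, "density")
        cp = indices.critical_point(cv, cn)
        assert cp.x_star == pytest.approx(319 / 81, abs=1e-9)
        assert cp.y_star == pytest.approx(66.242 / 81, abs=1e-9)
        # intersection satisfies both curve equations
        assert abs(cv(cp.x_star) - cp.y_star) < 1e-9
        assert abs(cn(cp.x_star) - cp.y_star) < 1e-9
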