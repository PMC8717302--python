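"""gdi formula, classification, trace scoring and replicate aggregation."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import constant_trace
from mscdelim.gdi import (
    classify_gdi,
    compute_gdi,
    gdi_from_trace,
    gdi_matrix,
    subset_distribution_summary,
)


def theta_for(tau, g):
    """theta giving gdi exactly g at divergence tau."""
    return -2.0 * tau / math.log(1.0 - g)


class TestComputeGdi:
    @pytest.mark.parametrize(
        "tau, theta, expected",
        [
            (0.0, 0.01, 0.0),
            (0.00003, 0.0001, 0.451188),  # the analysis prior means
            (0.002, 0.004, 0.632121),  # the naive-analysis values
            (1.0, 1e-6, 1.0),  # asymptote
        ],
    )
    def test_reference_points(self, tau, theta, expected):
        assert compute_gdi(tau, theta) == pytest.approx(expected, abs=1e-6)

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            compute_gdi(0.001, 0.0)
        with pytest.raises(ValueError):
            compute_gdi(-0.001, 0.01)

    def test_matches_independent_arithmetic_on_grid(self):
        taus = np.linspace(1e-6, 0.01, 10)
        thetas = np.linspace(1e-5, 0.02, 10)
        for tau in taus:
            for theta in thetas:
                direct = 1.0 - math.exp(-2.0 * tau / theta)
                assert abs(compute_gdi(tau, theta) - direct) < 1e-12

    @settings(deadline=None, derandomize=True, max_examples=60)
    @given(
        tau=st.floats(1e-8, 1e-3),
        theta=st.floats(1e-3, 0.1),
        bump=st.floats(1e-6, 1e-3),
    )
    def test_monotone_increasing_in_tau_decreasing_in_theta(self, tau, theta, bump):
        # bounded to 2*tau/theta <= ~4 so strictness survives float rounding
        g = compute_gdi(tau, theta)
        assert compute_gdi(tau + bump, theta) > g
        assert compute_gdi(tau, theta + bump) < g


class TestClassifyGdi:
    @pytest.mark.parametrize(
        "value, expected",
        [
            (0.15, "single"),
            (0.85, "distinct"),
            (0.2, "ambiguous"),  # boundaries inclusive to ambiguous
            (0.7, "ambiguous"),
            (0.45, "ambiguous"),
            (0.0, "single"),
            (1.0, "distinct"),
        ],
    )
    def test_thresholds(self, value, expected):
        assert classify_gdi(value) == expected

    def test_out_of_range(self):
        with pytest.raises(ValueError):
            classify_gdi(1.2)


def two_tip_trace(tau, theta_a, theta_b):
    return constant_trace(
        f"(A[&theta={theta_a}]:{tau},B[&theta={theta_b}]:{tau})"
        f"[&theta={(theta_a + theta_b) / 2},tau={tau}];"
    )


class TestGdiFromTrace:
    def test_constant_trace_direct_value(self):
        tr = two_tip_trace(0.0005, 0.001, 0.001)
        s = gdi_from_trace(tr, ("A", "B"))
        assert s.gdi_ab == pytest.approx(1 - math.exp(-1), abs=1e-9)

    def test_equal_thetas_symmetric(self):
        tr = two_tip_trace(0.0004, 0.002, 0.002)
        s = gdi_from_trace(tr, ("A", "B"))
        assert s.gdi_ab == pytest.approx(s.gdi_ba)
        assert s.mean == pytest.approx(s.gdi_ab)

    def test_directional_uses_each_groups_theta(self):
        tr = two_tip_trace(0.001, 0.001, 0.004)
        s = gdi_from_trace(tr, ("A", "B"))
        assert s.gdi_ab == pytest.approx(compute_gdi(0.001, 0.001))
        assert s.gdi_ba == pytest.approx(compute_gdi(0.001, 0.004))

    def test_per_sample_equals_mean_params_on_constant_trace(self):
        tr = two_tip_trace(0.0006, 0.0015, 0.0015)
        a = gdi_from_trace(tr, ("A", "B"), mode="mean-params")
        b = gdi_from_trace(tr, ("A", "B"), mode="per-sample")
        assert a.mean == pytest.approx(b.mean, abs=1e-12)
        assert b.ci_ab[0] == pytest.approx(b.ci_ab[1], abs=1e-12)

    def test_missing_group_named(self):
        tr = two_tip_trace(0.001, 0.001, 0.001)
        with pytest.raises(KeyError, match="Z"):
            gdi_from_trace(tr, ("A", "Z"))


class TestGdiMatrix:
    def traces_with_gdi(self, values, tau=0.001):
        return [two_tip_trace(tau, theta_for(tau, v), theta_for(tau, v)) for v in values]

    def test_replicate_mean_sd_classification(self):
        traces = self.traces_with_gdi([0.4, 0.6])
        mat = gdi_matrix(traces, [("A", "B")])
        e = mat.entry("A", "B")
        assert e.mean == pytest.approx(0.5, abs=1e-9)
        assert e.sd == pytest.approx(0.1414, abs=1e-3)
        assert e.classification == "ambiguous"

    def test_single_replicate_sd_zero(self):
        mat = gdi_matrix(self.traces_with_gdi([0.35]), [("A", "B")])
        e = mat.entry("A", "B")
        assert e.sd == 0.0 and e.mean == pytest.approx(0.35, abs=1e-9)

    def test_all_high_classified_distinct(self):
        mat = gdi_matrix(self.traces_with_gdi([0.8, 0.9, 0.75]), [("A", "B")])
        assert mat.entry("A", "B").classification == "distinct"

    def test_replicate_order_invariant(self):
        a = gdi_matrix(self.traces_with_gdi([0.3, 0.5, 0.7]), [("A", "B")])
        b = gdi_matrix(self.traces_with_gdi([0.7, 0.3, 0.5]), [("A", "B")])
        assert a.entry("A", "B").mean == pytest.approx(b.entry("A", "B").mean)
        assert a.entry("A", "B").sd == pytest.approx(b.entry("A", "B").sd)


class TestSubsetDistributionSummary:
    def mat(self, values):
        traces = [
            two_tip_trace(0.001, theta_for(0.001, v), theta_for(0.001, v))
            for v in values
        ]
        comps = [("A", "B")]
        # one comparison per matrix is too degenerate; use per-value entries
        from mscdelim.gdi import GdiEntry, GdiMatrix, classify_gdi

        entries = {
            ("A", f"B{k}"): GdiEntry("A", f"B{k}", v, 0.0, 1, classify_gdi(v))
            for k, v in enumerate(values)
        }
        return GdiMatrix(entries=entries)

    def test_identical_subsets_identical_summaries(self):
        mats = {"s1": self.mat([0.2, 0.5, 0.8]), "s2": self.mat([0.2, 0.5, 0.8])}
        df = subset_distribution_summary(mats)
        a, b = df.iloc[0], df.iloc[1]
        assert a["mean_gdi"] == b["mean_gdi"]
        assert a["normalized"] == b["normalized"]

    def test_minmax_normalization(self):
        mats = {"s1": self.mat([0.1, 0.4, 0.9]), "s2": self.mat([0.3, 0.6, 0.65])}
        df = subset_distribution_summary(mats)
        for norm in df["normalized"]:
            assert min(norm) == 0.0 and max(norm) == 1.0
            assert all(0.0 <= x <= 1.0 for x in norm)

    def test_ordering_reported(self):
        mats = {"low": self.mat([0.1, 0.2]), "high": self.mat([0.7, 0.9])}
        df = subset_distribution_summary(mats)
        assert list(df["subset"]) == ["low", "high"]
        assert list(df["rank"]) == [1, 2]

    def test_needs_two_subsets(self):
        with pytest.raises(ValueError):
            subset_distribution_summary({"only": self.mat([0.5])})
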