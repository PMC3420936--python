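"""Colony-count statistics, censoring, MIF and aggregate reproduction."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from supercoil import (aggregate_positions, censor_low,
                       efficiency_from_counts, format_mif, mif, rif_rebound)
from supercoil.resolution import (ResolutionMeasurement, ResolutionReplicate,
                                  measurements_from_counts,
                                  render_table_report)


def reps(*pairs):
    return [ResolutionReplicate(w, t) for w, t in pairs]


class TestCounts:
    def test_triplicate_mean_and_sd(self):
        mean, sd = efficiency_from_counts(reps((162, 200), (158, 200),
                                               (166, 200)))
        assert mean == pytest.approx(0.810)
        assert sd == pytest.approx(0.020)

    def test_all_zero_counts(self):
        mean, sd = efficiency_from_counts(reps((0, 200), (0, 200), (0, 200)))
        assert mean == 0.0 and sd == 0.0

    def test_single_replicate_warns(self):
        with pytest.warns(UserWarning, match="1 replicates"):
            mean, sd = efficiency_from_counts(reps((200, 200)))
        assert mean == 1.0 and np.isnan(sd)

    def test_invalid_counts_rejected(self):
        with pytest.raises(ValueError):
            ResolutionReplicate(10, 0)
        with pytest.raises(ValueError):
            ResolutionReplicate(300, 200)

    def test_undersized_plating_warns(self):
        with pytest.warns(UserWarning, match="colonies"):
            ResolutionReplicate(50, 100)

    def test_estimator_unbiased_at_p04(self):
        rng = np.random.default_rng(20120816)
        whites = rng.binomial(200, 0.4, size=(1000, 3))
        means = [efficiency_from_counts(reps(*((w, 200) for w in row)))[0]
                 for row in whites]
        assert np.mean(means) == pytest.approx(0.4, abs=0.01)


class TestCensoring:
    @pytest.mark.parametrize("eff,value,censored", [
        (0.007, 0.005, True), (0.02, 0.02, False), (0.0, 0.005, True),
    ])
    def test_detection_limit_rule(self, eff, value, censored):
        cv = censor_low(eff)
        assert cv.value == value and cv.censored == censored

    @settings(derandomize=True, max_examples=40)
    @given(eff=st.floats(0.0, 1.0))
    def test_idempotent(self, eff):
        once = censor_low(eff)
        twice = censor_low(once.value)
        assert twice.value == once.value


class TestMif:
    def test_printed_examples(self):
        value, bound = mif(0.81, 0.07)
        assert not bound and format_mif(value) == "12"
        value, bound = mif(0.81, 0.56)
        assert format_mif(value) == "1.4"
        value, bound = mif(0.5, 0.5)
        assert value == 1.0

    def test_censored_mutant_gives_lower_bound(self):
        value, bound = mif(0.82, None, mut_censored=True)
        assert bound and value == pytest.approx(82.0)
        assert format_mif(value, bound) == ">82"

    def test_zero_mutant_uses_detection_limit(self):
        value, bound = mif(0.45, 0.0)
        assert bound and value == pytest.approx(45.0)

    def test_nonpositive_wt_rejected(self):
        with pytest.raises(ValueError):
            mif(0.0, 0.5)

    @settings(derandomize=True, max_examples=40)
    @given(a=st.floats(0.02, 1.0), b=st.floats(0.02, 1.0))
    def test_reciprocal_product_is_one(self, a, b):
        assert mif(a, b)[0] * mif(b, a)[0] == pytest.approx(1.0)

    def test_two_significant_figure_display(self):
        assert format_mif(40.5) == "40"
        assert format_mif(0.4058) == "0.41"
        assert format_mif(2.816) == "2.8"


class TestAggregates:
    def test_wt_seven_position_summary(self, tables):
        wt = tables["table1"].query("genotype == 'WT'")
        summ = aggregate_positions(wt)
        assert round(summ.mean_efficiency * 100) == 81
        assert summ.mean_sigma == pytest.approx(-0.038, abs=0.0005)
        assert summ.n_positions == 7

    def test_gyrb652_censored_mean(self, tables, curve):
        g = tables["table1"].query("genotype == 'gyrB652'")
        summ = aggregate_positions(g, curve)
        assert round(summ.mean_efficiency * 100) == 2
        # 5 censored rows in the table; the Ter-proximal one is excluded
        assert summ.n_censored == 4

    def test_pare206_mean(self, tables):
        g = tables["table1"].query("genotype == 'parE206'")
        assert round(aggregate_positions(g).mean_efficiency * 100) == 60

    def test_empty_after_exclusion_is_an_error(self, tables, curve):
        wt = tables["table1"].query("position_cs == 33.0")
        with pytest.raises(ValueError):
            aggregate_positions(wt, curve)


class TestRifRebound:
    def _measurement(self, eff_frac, condition):
        w = int(round(eff_frac * 200))
        return ResolutionMeasurement(
            strain_id="NH6037", position=85.0, genotype="gyrB1820",
            condition=condition,
            replicates=reps((w, 200), (w, 200), (w, 200)))

    def test_sevenfold_rebound(self, curve):
        fold, dsig = rif_rebound(self._measurement(0.08, "none"),
                                 self._measurement(0.56, "rif"), curve)
        assert fold == pytest.approx(7.0)
        assert dsig == pytest.approx(-0.020, abs=0.003)

    def test_identical_conditions(self, curve):
        fold, dsig = rif_rebound(self._measurement(0.4, "none"),
                                 self._measurement(0.4, "rif"), curve)
        assert fold == pytest.approx(1.0) and dsig == 0.0

    def test_mismatched_position_rejected(self, curve):
        a = self._measurement(0.1, "none")
        b = ResolutionMeasurement(
            strain_id="NH6037", position=58.0, genotype="gyrB1820",
            condition="rif", replicates=reps((100, 200), (100, 200),
                                             (100, 200)))
        with pytest.raises(ValueError, match="matched"):
            rif_rebound(a, b, curve)


def test_report_round_trip(curve):
    sheet = pd.DataFrame({
        "strain_id": ["A"] * 3 + ["B"] * 3,
        "position_cs": [85.0] * 6,
        "genotype": ["WT"] * 3 + ["gyrB652"] * 3,
        "condition": ["none"] * 6,
        "replicate_id": [1, 2, 3] * 2,
        "white_count": [162, 158, 166, 1, 0, 2],
        "total_count": [200] * 6,
    })
    ms = measurements_from_counts(sheet)
    wt = {m.position: m.efficiency_mean for m in ms if m.genotype == "WT"}
    report = render_table_report(ms, curve, wt_by_position=wt)
    assert list(report["censored"]) == [False, True]
    assert report.loc[1, "efficiency"] == "<1%"
    assert report.loc[1, "mif"].startswith(">")
    assert report.loc[0, "mif"] == "1"
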