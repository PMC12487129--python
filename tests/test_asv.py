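"""ASV log-linear growth fits, isolate matching, candidate selection."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from bloomics import (
    fit_max_growth,
    match_isolates_to_asvs,
    select_bloomer_isolates,
)
from bloomics.asv import fit_asv_table, pseudoabundance, reverse_complement
from bloomics.types import Thresholds, ValidationError


def brute_force_best_window(times, pseudo, alpha=0.05):
    """Independent oracle: closed-form OLS over every contiguous window of
    the positive points, slope t-test from the residual variance."""
    t = np.asarray(times, float)
    y = np.asarray(pseudo, float)
    keep = y > 0
    t, y = t[keep], np.log(y[keep])
    best = None
    for i in range(len(t)):
        for j in range(i + 3, len(t) + 1):
            tw, yw = t[i:j], y[i:j]
            slope, intercept = np.polyfit(tw, yw, 1)
            resid = yw - (slope * tw + intercept)
            df = len(tw) - 2
            sxx = np.sum((tw - tw.mean()) ** 2)
            s2 = np.sum(resid**2) / df if df else 0.0
            se = math.sqrt(s2 / sxx) if sxx else math.inf
            if se == 0:
                p = 0.0
            elif math.isinf(se):
                p = 1.0
            else:
                p = 2 * sps.t.sf(abs(slope / se), df)
            if p < alpha:
                cand = (slope, -p, -i)
                if best is None or cand > best[0]:
                    best = (cand, i, j - 1, slope, p)
    return best


class TestFitMaxGrowth:
    def test_exact_exponential_line(self):
        t = np.array([0.0, 12.0, 24.0, 36.0])
        fit = fit_max_growth(t, np.exp(0.1 * t))
        assert fit.slope_per_h == pytest.approx(0.1)
        assert fit.doubling_time_h == pytest.approx(math.log(2) / 0.1)
        assert fit.p_value < 0.05

    def test_growth_then_decline_picks_rising_window(self):
        fit = fit_max_growth([0, 12, 24, 36], np.exp([0.0, 1.2, 2.4, 2.0]))
        assert (fit.start_index, fit.end_index) == (0, 2)
        assert fit.slope_per_h == pytest.approx(0.1)

    def test_all_zero_series_none(self):
        assert fit_max_growth([0, 12, 24], [0.0, 0.0, 0.0]) is None

    def test_zero_points_excluded(self):
        t = [0.0, 6.0, 12.0, 24.0, 36.0]
        y = [0.0, math.exp(0.6), math.exp(1.2), math.exp(2.4), math.exp(3.6)]
        fit = fit_max_growth(t, y)
        assert fit.slope_per_h == pytest.approx(0.1)

    def test_null_series_significant_at_about_alpha(self):
        # a three-point series has a single candidate window, so the rate
        # of significant fits under the null is the nominal level itself
        rng = np.random.default_rng(0)
        n = 400
        hits = sum(
            fit_max_growth([0.0, 12.0, 24.0], np.exp(rng.normal(0, 1, 3))) is not None
            for _ in range(n)
        )
        assert 0.01 < hits / n < 0.12

    def test_matches_brute_force_on_random_series(self):
        rng = np.random.default_rng(12)
        for _ in range(100):
            n = rng.integers(3, 9)
            t = np.sort(rng.choice(np.arange(1, 50), size=n, replace=False)).astype(float)
            y = np.exp(rng.normal(0, 1, n))
            y[rng.uniform(size=n) < 0.1] = 0.0
            fit = fit_max_growth(t, y)
            oracle = brute_force_best_window(t, y)
            if oracle is None:
                assert fit is None
            else:
                assert fit is not None
                assert fit.slope_per_h == pytest.approx(oracle[3], rel=1e-9)
                assert (fit.start_index, fit.end_index) == (oracle[1], oracle[2])

    def test_negative_slope_reported_with_nan_doubling(self):
        t = np.array([0.0, 12.0, 24.0, 36.0])
        fit = fit_max_growth(t, np.exp(-0.1 * t))
        assert fit.slope_per_h == pytest.approx(-0.1)
        assert math.isnan(fit.doubling_time_h)


class TestPseudoabundance:
    def test_product(self):
        out = pseudoabundance([1.0, 2.0], [1e6, 2e6])
        assert out.tolist() == [1e6, 4e6]

    def test_nonpositive_totals_rejected(self):
        with pytest.raises(ValidationError):
            pseudoabundance([1.0], [0.0])

    def test_table_driver(self):
        t = np.array([0.0, 12.0, 24.0, 36.0])
        asv = pd.DataFrame(
            {
                "asv_id": "A1",
                "experiment": "summer_VL",
                "time_h": t,
                "rel_abundance_pct": np.exp(0.1 * t),
            }
        )
        cyto = pd.DataFrame(
            {"experiment": "summer_VL", "time_h": t, "total_cells": 1e6}
        )
        fits = fit_asv_table(asv, cyto)
        assert fits["slope_per_h"].iloc[0] == pytest.approx(0.1)


class TestIsolateMatching:
    def test_exact_match_and_mismatch(self):
        asvs = {"A1": "ACGTACGTAC", "A2": "TTTTTTTTTT"}
        isolates = {
            "I_exact": "GG" + "ACGTACGTAC" + "CC",
            "I_miss": "GG" + "ACGTACGTAA" + "CC",
        }
        matches = match_isolates_to_asvs(isolates, asvs, region=(2, 12))
        assert matches.values.tolist() == [["I_exact", "A1"]]

    def test_reverse_complement_orientation(self):
        seq = "ACGTACGTAC"
        asvs = {"A1": seq}
        isolates = {"I_rc": reverse_complement(seq)}
        with_rc = match_isolates_to_asvs(isolates, asvs)
        without = match_isolates_to_asvs(isolates, asvs, check_reverse_complement=False)
        assert len(with_rc) == 1 and without.empty

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValidationError):
            match_isolates_to_asvs({"I": ""}, {"A": "ACGT"})


class TestSelection:
    def _fits(self, doubling):
        return pd.DataFrame(
            {
                "asv_id": ["A1"],
                "experiment": ["summer_VL"],
                "doubling_time_h": [doubling],
            }
        )

    def _abund(self, t0=0.4, tf=2.1):
        return pd.DataFrame(
            {
                "asv_id": ["A1"],
                "experiment": ["summer_VL"],
                "abund_t0_pct": [t0],
                "abund_tf_pct": [tf],
            }
        )

    def _matches(self):
        return pd.DataFrame({"isolate_id": ["I1"], "asv_id": ["A1"]})

    def test_qualifying_asv_selects_isolate(self):
        out = select_bloomer_isolates(self._matches(), self._abund(), self._fits(9.0))
        assert out == {"I1"}

    def test_slow_doubling_rejected(self):
        out = select_bloomer_isolates(self._matches(), self._abund(), self._fits(30.0))
        assert out == set()

    def test_abundant_start_rejected(self):
        out = select_bloomer_isolates(
            self._matches(), self._abund(t0=1.5), self._fits(9.0)
        )
        assert out == set()

    def test_unmatched_isolate_never_selected(self):
        matches = pd.DataFrame({"isolate_id": [], "asv_id": []})
        out = select_bloomer_isolates(matches, self._abund(), self._fits(9.0))
        assert out == set()

    def test_monotone_in_doubling_threshold(self):
        matches = pd.DataFrame(
            {"isolate_id": ["I1", "I2"], "asv_id": ["A1", "A2"]}
        )
        abund = pd.DataFrame(
            {
                "asv_id": ["A1", "A2"],
                "experiment": "summer_VL",
                "abund_t0_pct": [0.4, 0.5],
                "abund_tf_pct": [2.0, 3.0],
            }
        )
        fits = pd.DataFrame(
            {
                "asv_id": ["A1", "A2"],
                "experiment": "summer_VL",
                "doubling_time_h": [9.0, 20.0],
            }
        )
        previous = None
        for cutoff in (30.0, 24.0, 15.0, 8.0):
            selected = select_bloomer_isolates(
                matches, abund, fits, Thresholds(asv_min_doubling_h=cutoff)
            )
            if previous is not None:
                assert selected <= previous
            previous = selected
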