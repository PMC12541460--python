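"""Fractions, dwell medians, survival curves, and the E_FRET heat map."""

import numpy as np
import pytest

from orctether import (
    fraction_se,
    median_se,
    survival_curve,
    time_to_formation,
    tether_vs_cdt1_offsets,
    retention_after_cdt1,
    efret_heatmap,
)
from orctether.kinetics import interaction_duration
from orctether.preprocess import EventRecord
from orctether.state_calling import StateCall


def make_call(
    spot_id="s0",
    efret=None,
    high=(),
    stable=True,
    copresence=None,
    dt=2.6,
    n=60,
):
    e = np.full(n, np.nan) if efret is None else np.asarray(efret, float)
    return StateCall(
        spot_id=spot_id,
        efret=e,
        threshold=0.5,
        high_intervals=list(high),
        stable_recruitment=stable,
        copresence=copresence,
        dt=dt,
    )


class TestFractionSe:
    @pytest.mark.parametrize(
        "k,n,expected",
        [
            (58, 147, "39 ± 4%"),
            (66, 104, "63 ± 5%"),
            (13, 104, "13 ± 3%"),
            (0, 10, "0 ± 0%"),
        ],
    )
    def test_integer_percent_strings(self, k, n, expected):
        assert fraction_se(k, n).as_string(0) == expected

    def test_pct_and_se_are_exact_binomial(self):
        fs = fraction_se(85, 106)
        assert fs.pct == pytest.approx(100 * 85 / 106)
        p = 85 / 106
        assert fs.se_pct == pytest.approx(100 * np.sqrt(p * (1 - p) / 106))

    def test_invalid_counts_rejected(self):
        with pytest.raises(ValueError):
            fraction_se(5, 4)
        with pytest.raises(ValueError):
            fraction_se(0, 0)


class TestMedianSe:
    def test_trivial_median(self):
        assert median_se([1.0, 2.0, 3.0]).median == 2.0

    def test_constant_sample_has_zero_se(self):
        s = median_se([4.0] * 20)
        assert s.se_median == 0.0
        assert (s.ci_low, s.ci_high) == (4.0, 4.0)

    def test_bootstrap_se_matches_asymptotic_for_exponential(self):
        """SE of the median ~ 1/(2 f(m) sqrt(n)) for Exp(1): 1/sqrt(n)."""
        rng = np.random.default_rng(12)
        n = 2000
        values = rng.exponential(1.0, n)
        s = median_se(values, n_boot=2000, rng=rng)
        assert s.se_median == pytest.approx(1.0 / np.sqrt(n), rel=0.20)


class TestSurvivalCurve:
    def test_uncensored_steps(self):
        sc = survival_curve([1.0, 2.0, 3.0, 4.0], n_boot=50)
        assert np.allclose(sc.time, [0, 1, 2, 3, 4])
        assert np.allclose(sc.survival, [1.0, 0.75, 0.5, 0.25, 0.0])

    def test_all_censored_stays_at_one(self):
        sc = survival_curve([5.0, 5.0, 5.0], censored=[True] * 3, n_boot=50)
        assert np.allclose(sc.survival, 1.0)

    def test_km_equals_empirical_without_censoring(self):
        rng = np.random.default_rng(4)
        times = rng.exponential(10.0, 100)
        sc = survival_curve(times, n_boot=50)
        empirical = np.array([(times > t).sum() / len(times) for t in sc.time])
        assert np.allclose(sc.survival, empirical)

    def test_monotone_and_ci_brackets_estimate(self):
        rng = np.random.default_rng(5)
        times = rng.exponential(5.0, 60)
        cens = rng.random(60) < 0.3
        sc = survival_curve(times, cens, n_boot=200, rng=1)
        assert np.all(np.diff(sc.survival) <= 1e-12)
        assert np.all(sc.ci_low <= sc.survival + 1e-12)
        assert np.all(sc.survival <= sc.ci_high + 1e-12)


class TestEventSummaries:
    def test_time_to_formation_arithmetic(self):
        """Formation 3 cycles after arrival at 2.6 s/cycle is 7.8 s."""
        call = make_call(high=[(13, 20, False)], copresence=(10, 30))
        ev = EventRecord(
            spot_id="s0", mcm_arrival_s=26.0, mcm_interval=(10, 30), orc_interval=(5, 40)
        )
        s = time_to_formation([call], [ev], n_boot=100)
        assert s.median == pytest.approx(7.8)

    def test_unformed_events_are_excluded(self):
        formed = make_call("a", high=[(12, 20, False)])
        unformed = make_call("b", high=[])
        evs = [
            EventRecord(spot_id="a", mcm_arrival_s=26.0),
            EventRecord(spot_id="b", mcm_arrival_s=26.0),
        ]
        s = time_to_formation([formed, unformed], evs, n_boot=100)
        assert s.n == 1

    def test_duration_arithmetic_and_censor_tally(self):
        # [10 s, 36.4 s) lasts 26.4 s
        a = make_call("a", high=[(10, 24, False)], dt=26.4 / 14)
        b = make_call("b", high=[(5, 10, True)], dt=26.4 / 14)
        s = interaction_duration([a, b], n_boot=100)
        assert sorted(np.round(s.values, 10)) == [
            pytest.approx(5 * 26.4 / 14),
            pytest.approx(26.4),
        ]
        assert s.n_censored == 1
        s2 = interaction_duration([a, b], include_censored=False, n_boot=100)
        assert s2.n == 1

    def test_offsets_signs(self):
        """Formation at 20 s with release at 36.9 s is a -16.9 s offset."""
        dt = 2.0
        early = make_call("a", high=[(10, 30, False)], dt=dt)
        late = make_call("b", high=[(25, 30, False)], dt=dt)
        evs = [
            EventRecord(spot_id="a", cdt1_release_s=36.9),
            EventRecord(spot_id="b", cdt1_release_s=36.9),
        ]
        out = tether_vs_cdt1_offsets([early, late], evs, n_boot=100)
        assert out.offsets[0] == pytest.approx(20.0 - 36.9)
        assert out.offsets[1] == pytest.approx(50.0 - 36.9)
        assert out.n_tether_first == 1

    def test_missing_release_counted_as_excluded(self):
        call = make_call("a", high=[(10, 30, False)])
        ev = EventRecord(spot_id="a", cdt1_release_s=None)
        call2 = make_call("b", high=[(10, 30, False)])
        ev2 = EventRecord(spot_id="b", cdt1_release_s=26.0)
        out = tether_vs_cdt1_offsets([call, call2], [ev, ev2], n_boot=100)
        assert out.n_excluded == 1
        assert len(out.offsets) == 1


class TestRetention:
    def _pair(self, spot_id, release_cycle, depart_cycle, high, censored=False, dt=2.6):
        call = make_call(
            spot_id,
            high=[(release_cycle - 2, release_cycle + 3, False)] if high else [],
            dt=dt,
        )
        ev = EventRecord(
            spot_id=spot_id,
            orc_arrival_s=0.0,
            orc_departure_s=depart_cycle * dt,
            orc_censored=censored,
            cdt1_release_s=release_cycle * dt,
        )
        return call, ev

    def test_three_cycle_retention_counts_in_released_within_three(self):
        call, ev = self._pair("a", 10, 13, high=True)
        out = retention_after_cdt1([call], [ev], n_boot=50)
        assert out.released_within_3_cycles.k == 1
        assert out.released_within_1_cycle.k == 0
        assert "high" in out.groups
        assert out.groups["high"][1].values[0] == pytest.approx(7.8)

    def test_censored_event_not_in_released_numerators(self):
        call, ev = self._pair("a", 10, 11, high=False, censored=True)
        out = retention_after_cdt1([call], [ev], n_boot=50)
        assert out.released_within_1_cycle.k == 0
        assert out.released_within_3_cycles.k == 0
        assert out.groups["low"][0].survival[-1] > 0  # right-censored in KM

    def test_orc_absent_at_release_excluded(self):
        call, ev = self._pair("a", 10, 13, high=True)
        ev.orc_departure_s = 5 * 2.6  # departed before release
        out = retention_after_cdt1([call], [ev], n_boot=50)
        assert out is None or out.n_excluded == 1

    def test_long_retention_fraction(self):
        pairs = [self._pair(f"s{i}", 10, 10 + 50 * (i + 1), high=True) for i in range(3)]
        calls, evs = zip(*pairs)
        out = retention_after_cdt1(list(calls), list(evs), n_boot=50)
        # retentions 130, 260, 390 s: all beyond 100 s
        assert out.retained_over_100s.k == 3


class TestHeatmap:
    def test_constant_efret_cohort(self):
        n = 20
        calls, evs = [], []
        for i in range(4):
            e = np.full(n, np.nan)
            e[2:12] = 0.5
            calls.append(make_call(f"s{i}", efret=e, copresence=(2, 12), n=n))
            evs.append(EventRecord(spot_id=f"s{i}", mcm_interval=(2, 12)))
        hm = efret_heatmap(calls, evs, n_boot=50)
        assert hm.remaining_fraction[0] == 1.0
        assert np.all(hm.remaining_fraction == 1.0)
        bin_of_half = np.digitize(0.5, hm.e_edges) - 1
        col = hm.density[:, 0]
        assert col[bin_of_half] == 1.0
        assert np.nansum(col) == pytest.approx(1.0)

    def test_matches_bruteforce_histogram(self):
        rng = np.random.default_rng(6)
        n = 40
        calls, evs = [], []
        spans = {}
        for i in range(8):
            lo, hi = 3, int(rng.integers(15, 35))
            e = np.full(n, np.nan)
            e[lo:hi] = rng.normal(0.5, 0.2, hi - lo)
            sid = f"s{i}"
            calls.append(make_call(sid, efret=e, copresence=(lo, hi), n=n))
            evs.append(EventRecord(spot_id=sid, mcm_interval=(lo, hi)))
            spans[sid] = e[lo:hi]
        hm = efret_heatmap(calls, evs, n_boot=50)
        for j in range(hm.density.shape[1]):
            vals = [s[j] for s in spans.values() if len(s) > j]
            vals = [v for v in vals if np.isfinite(v)]
            if not vals:
                assert np.all(np.isnan(hm.density[:, j]))
                continue
            hist, _ = np.histogram(vals, bins=hm.e_edges)
            assert np.allclose(hm.density[:, j], hist / hist.sum())
            # remaining fraction is nonincreasing from 1
        assert hm.remaining_fraction[0] == 1.0
        assert np.all(np.diff(hm.remaining_fraction) <= 1e-12)
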