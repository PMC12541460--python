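"""Kinetic-scheme validation, Gillespie paths, and trace rendering."""

import numpy as np
import pytest
from scipy import stats

from orctether import (
    AcquisitionConfig,
    ConfigurationError,
    KineticScheme,
    generate_cohort,
    render_trace,
    simulate_state_path,
)
from orctether.presets import TETHERED_STATES, build_loading_scheme, get_preset
from orctether.scheme import StatePath


def single_state_scheme(efret=None, green=1, red=1):
    return KineticScheme(
        state_names=("a",),
        exit_rate={"a": 0.0},
        transition_probs={},
        fret_efficiency={"a": efret},
        green_dyes={"a": green},
        red_dyes={"a": red},
        initial_state="a",
    )


def two_state_scheme(k=0.1):
    return KineticScheme(
        state_names=("A", "B"),
        exit_rate={"A": k, "B": 0.0},
        transition_probs={"A": {"B": 1.0}},
        fret_efficiency={"A": 0.5, "B": None},
        green_dyes={"A": 1, "B": 0},
        red_dyes={"A": 1, "B": 1},
        initial_state="A",
    )


class TestSchemeValidation:
    def test_unnormalized_transition_row_rejected(self):
        with pytest.raises(ConfigurationError, match="sums to"):
            KineticScheme(
                state_names=("A", "B"),
                exit_rate={"A": 1.0, "B": 0.0},
                transition_probs={"A": {"B": 0.7}},
                fret_efficiency={"A": None, "B": None},
                green_dyes={"A": 0, "B": 0},
                red_dyes={"A": 0, "B": 0},
                initial_state="A",
            )

    def test_fret_on_single_dye_state_rejected(self):
        with pytest.raises(ConfigurationError, match="fret_efficiency must be None"):
            single_state_scheme(efret=0.5, green=0)

    def test_unknown_preset_rejected(self):
        with pytest.raises(ConfigurationError, match="unknown preset"):
            generate_cohort("nonexistent", 2, 0)


class TestStatePathSimulation:
    def test_absorbing_state_spans_whole_window(self):
        path = simulate_state_path(single_state_scheme(), 100.0, 0)
        assert path.segments == [("a", 0.0, 100.0)]
        assert path.total_duration == 100.0

    def test_zero_duration_gives_empty_path(self):
        path = simulate_state_path(single_state_scheme(), 0.0, 0)
        assert path.segments == []
        assert path.total_duration == 0.0

    def test_mean_dwell_matches_rate_constant(self):
        """Monte Carlo mean dwell in A equals 1/k within sampling error."""
        k, n = 0.1, 10_000
        scheme = two_state_scheme(k)
        rng = np.random.default_rng(42)
        dwells = [
            simulate_state_path(scheme, 1e6, rng).segments[0][2] for _ in range(n)
        ]
        # SE of the mean is (1/k)/sqrt(n); allow 4 sigma
        assert np.mean(dwells) == pytest.approx(1.0 / k, abs=4 * (1.0 / k) / np.sqrt(n))

    def test_dwell_distribution_is_exponential(self):
        """KS test of simulated dwell times against Exp(k) at alpha = 0.01."""
        k, n = 0.1, 10_000
        scheme = two_state_scheme(k)
        rng = np.random.default_rng(7)
        dwells = [
            simulate_state_path(scheme, 1e6, rng).segments[0][2] for _ in range(n)
        ]
        assert stats.kstest(dwells, "expon", args=(0, 1.0 / k)).pvalue > 0.01

    def test_path_segments_are_contiguous(self):
        scheme = build_loading_scheme()
        rng = np.random.default_rng(3)
        for _ in range(50):
            path = simulate_state_path(scheme, 300.0, rng)
            t = 0.0
            for _, start, end in path.segments:
                assert start == pytest.approx(t)
                assert end >= start
                t = end
            assert t == pytest.approx(300.0)


class TestRendering:
    def test_zero_fret_leaves_acceptor_channel_at_background(self, noiseless_emission):
        scheme = single_state_scheme(efret=0.0)
        path = StatePath([("a", 0.0, 26.0)], 26.0, scheme)
        tr = render_trace(path, AcquisitionConfig(n_cycles=10), noiseless_emission, 0)
        assert np.allclose(tr.I_DexAem, 100.0)
        assert np.allclose(tr.I_DexDem, 1100.0)

    def test_cdt1_release_halves_red_signal(self, noiseless_emission):
        """Two red dyes then one: red-excited signal above background drops 50%."""
        scheme = KineticScheme(
            state_names=("two", "one"),
            exit_rate={"two": 1.0, "one": 0.0},
            transition_probs={"two": {"one": 1.0}},
            fret_efficiency={"two": None, "one": None},
            green_dyes={"two": 0, "one": 0},
            red_dyes={"two": 2, "one": 1},
            initial_state="two",
        )
        path = StatePath([("two", 0.0, 26.0), ("one", 26.0, 52.0)], 52.0, scheme)
        tr = render_trace(path, AcquisitionConfig(n_cycles=20), noiseless_emission, 0)
        above_bg = tr.I_AexAem - 100.0
        assert np.allclose(above_bg[:10], 2000.0)
        assert np.allclose(above_bg[10:], 1000.0)
        assert above_bg[10] / above_bg[9] == pytest.approx(0.5)

    def test_total_donor_emission_conserved_across_fret_change(self, noiseless_emission):
        """FRET moves donor photons between channels; the sum is invariant."""
        scheme = KineticScheme(
            state_names=("low", "high"),
            exit_rate={"low": 1.0, "high": 0.0},
            transition_probs={"low": {"high": 1.0}},
            fret_efficiency={"low": 0.33, "high": 0.71},
            green_dyes={"low": 1, "high": 1},
            red_dyes={"low": 1, "high": 1},
            initial_state="low",
        )
        path = StatePath([("low", 0.0, 26.0), ("high", 26.0, 52.0)], 52.0, scheme)
        tr = render_trace(path, AcquisitionConfig(n_cycles=20), noiseless_emission, 0)
        assert np.allclose(tr.donor_total, tr.donor_total[0])

    def test_dye_contributes_nothing_after_bleaching(self):
        emission = EmissionParamsNoNoiseFastBleach()
        scheme = KineticScheme(
            state_names=("a",),
            exit_rate={"a": 0.0},
            transition_probs={},
            fret_efficiency={"a": 0.0},
            green_dyes={"a": 1},
            red_dyes={"a": 1},
            initial_state="a",
        )
        path = StatePath([("a", 0.0, 520.0)], 520.0, scheme)
        tr = render_trace(path, AcquisitionConfig(n_cycles=200), emission, 1)
        for dye, channel in [("green0", tr.I_DexDem), ("red0", tr.I_AexAem)]:
            tb = tr.bleach_times[dye]
            assert np.isfinite(tb)
            # every cycle whose exposure starts after the bleach is background
            after = [i for i in range(200) if i * 2.6 > tb + 2.6]
            assert np.allclose(channel[after], 100.0)
            before = [i for i in range(200) if (i + 1) * 2.6 < tb]
            assert np.all(channel[before] > 500.0)


def EmissionParamsNoNoiseFastBleach():
    from orctether import EmissionParams

    return EmissionParams(
        background_mean=(100.0, 100.0, 100.0),
        background_sd=(0.0, 0.0, 0.0),
        bleach_rate_green=0.01,
        bleach_rate_red=0.01,
    )


class TestCohorts:
    def test_identical_seeds_give_bit_identical_cohorts(self):
        a = generate_cohort("wt", 10, 1, n_cycles=60)
        b = generate_cohort("wt", 10, 1, n_cycles=60)
        for ta, tb in zip(a.traces, b.traces):
            assert np.array_equal(ta.I_DexDem, tb.I_DexDem)
            assert np.array_equal(ta.I_DexAem, tb.I_DexAem)
            assert np.array_equal(ta.I_AexAem, tb.I_AexAem)
            assert ta.truth.segments == tb.truth.segments

    def test_cdt1_labeled_preset_has_two_red_dyes_before_release(self):
        scheme = get_preset("cdt1_labeled_wt").scheme
        assert scheme.red_dyes["occm"] == 2
        assert scheme.red_dyes["tethered_occm"] == 2
        assert scheme.red_dyes["tethered_postcdt1"] == 1
        assert scheme.red_dyes["untethered_postcdt1"] == 1

    def test_double_mutant_rarely_reaches_tether_state(self):
        """Ground-truth tether visits: dN+lnk1scr preset << wild type."""

        def tether_fraction(preset, n=300):
            cohort = generate_cohort(preset, n, 11, n_cycles=150)
            hits = sum(
                t.truth.visits(lambda s: s in TETHERED_STATES) for t in cohort.traces
            )
            return hits / n

        wt = tether_fraction("wt")
        double = tether_fraction("orc6dN_lnk1scr")
        assert double < 0.15 < 0.5 < wt

    def test_recording_opens_with_empty_dna(self):
        cohort = generate_cohort("wt", 5, 2, n_cycles=80)
        for t in cohort.traces:
            label, start, end = t.truth.segments[0]
            assert label == "empty"
            assert start == 0.0 and end >= 30.0
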