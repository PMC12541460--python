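"""Background correction, presence intervals, and per-spot event extraction.

Intervals are half-open ``[start, end)`` in frame-cycle indices, and event
times are reported at the start of the cycle in which the change is first
observed.  Presence of the green-labeled species (ORC) is detected on total
donor-excited emission (``I_DexDem + I_DexAem``), which is conserved across
FRET transitions, so tether formation never masquerades as an ORC departure;
presence of red-labeled species (Mcm2-7, optionally Cdt1) is detected on the
directly excited acceptor channel.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .trace import CHANNELS, SpotTrace

__all__ = [
    "EventRecord",
    "correct_background",
    "detect_presence",
    "extract_events",
    "detect_cdt1_release",
]


@dataclass
class EventRecord:
    """Detected arrival/departure/release times for one spot (seconds).

    Missing events are ``None``.  ``orc_censored`` / ``mcm_censored`` mark
    species still bound at the final cycle (``censored_end`` is their OR);
    ``bleach_suspected`` marks a second halving of the red signal after the
    Cdt1-release step.  ``orc_interval`` / ``mcm_interval`` retain the
    half-open cycle-index intervals the times were derived from.
    """

    spot_id: str
    orc_arrival_s: float | None = None
    orc_departure_s: float | None = None
    mcm_arrival_s: float | None = None
    mcm_departure_s: float | None = None
    cdt1_release_s: float | None = None
    second_mcm_arrival_s: float | None = None
    censored_end: bool = False
    orc_censored: bool = False
    mcm_censored: bool = False
    bleach_suspected: bool = False
    orc_interval: tuple[int, int] | None = None
    mcm_interval: tuple[int, int] | None = None

    def copresence_interval(self) -> tuple[int, int] | None:
        """Overlap of the ORC and Mcm2-7 presence intervals, in cycles."""
        if self.orc_interval is None or self.mcm_interval is None:
            return None
        lo = max(self.orc_interval[0], self.mcm_interval[0])
        hi = min(self.orc_interval[1], self.mcm_interval[1])
        return (lo, hi) if hi > lo else None


def _lowest_window(x: np.ndarray, w: int) -> tuple[int, np.ndarray]:
    """Start index and values of the length-``w`` window with the lowest mean."""
    means = np.convolve(x, np.ones(w) / w, mode="valid")
    i = int(np.argmin(means))
    return i, x[i : i + w]


def _half_sample_mode(x: np.ndarray) -> float:
    """Robust mode estimate by iterated shortest-half reduction."""
    x = np.sort(np.asarray(x, float))
    while len(x) > 3:
        h = len(x) // 2
        widths = x[h:] - x[: len(x) - h]
        i = int(np.argmin(widths))
        x = x[i : i + h + 1]
    return float(np.median(x))


def _diff_noise_sd(x: np.ndarray) -> float:
    """Noise sd from the MAD of successive differences.

    Robust to binding steps (which contribute only isolated large diffs) and,
    unlike statistics of a selected low window, not biased by the selection.
    """
    if len(x) < 3:
        return 0.0
    d = np.diff(x)
    return 1.4826 * float(np.median(np.abs(d - np.median(d)))) / np.sqrt(2.0)


def correct_background(trace: SpotTrace, baseline_window: int = 10) -> SpotTrace:
    """Subtract a robust per-channel baseline from each channel.

    The baseline is the median of the lowest-mean contiguous window of
    ``baseline_window`` cycles (the unbound stretch of the recording); the
    per-channel noise estimate used by presence detection comes from the
    scaled MAD of successive differences over the whole series.  Traces
    shorter than the window fall back to a global half-sample mode and are
    flagged ``baseline_fallback``.
    """
    baselines, noise_sd, fallback = {}, {}, False
    channels = {ch: getattr(trace, ch).astype(float) for ch in CHANNELS}
    corrected = {}
    for ch, x in channels.items():
        if len(x) >= baseline_window >= 1:
            _, win = _lowest_window(x, baseline_window)
            base = float(np.median(win))
        else:
            base = _half_sample_mode(x) if len(x) else 0.0
            fallback = True
        baselines[ch] = base
        noise_sd[ch] = _diff_noise_sd(x)
        corrected[ch] = x - base
    out = SpotTrace(
        spot_id=trace.spot_id,
        time_s=trace.time_s,
        I_DexDem=corrected["I_DexDem"],
        I_DexAem=corrected["I_DexAem"],
        I_AexAem=corrected["I_AexAem"],
        truth=trace.truth,
        bleach_times=trace.bleach_times,
        meta=dict(trace.meta),
    )
    out.meta.update(
        baseline=baselines,
        noise_sd=noise_sd,
        baseline_fallback=fallback,
        background_corrected=True,
    )
    return out


def detect_presence(
    series: np.ndarray,
    noise_sd: float,
    threshold_sd: float = 3.0,
    bridge_gaps: int = 1,
) -> list[tuple[int, int]]:
    """Contiguous runs where a corrected series exceeds ``threshold_sd * sd``.

    Single-cycle dropouts inside a run (fluorophore blinking) are bridged;
    gaps longer than ``bridge_gaps`` cycles split intervals.
    """
    series = np.asarray(series, float)
    if series.size == 0:
        return []
    above = series > threshold_sd * noise_sd
    if bridge_gaps > 0 and above.any():
        idx = np.flatnonzero(above)
        filled = above.copy()
        for a, b in zip(idx[:-1], idx[1:]):
            if 1 < b - a <= bridge_gaps + 1:
                filled[a:b] = True
        above = filled
    intervals = []
    padded = np.r_[False, above, False]
    starts = np.flatnonzero(~padded[:-1] & padded[1:])
    ends = np.flatnonzero(padded[:-1] & ~padded[1:])
    for s, e in zip(starts, ends):
        intervals.append((int(s), int(e)))
    return intervals


def prune_spurious_intervals(
    intervals: list[tuple[int, int]],
    series: np.ndarray,
    noise_sd: float,
    min_cycles: int = 2,
    strong_sd: float = 5.0,
) -> list[tuple[int, int]]:
    """Drop presence intervals that look like isolated noise excursions.

    Intervals shorter than ``min_cycles`` are kept only if their peak clears
    ``strong_sd`` noise sds — a genuine one-frame binding event is many sigma
    above background, while a noise spike barely crosses the 3-sigma presence
    threshold.
    """
    out = []
    for a, b in intervals:
        if b - a >= min_cycles or np.max(series[a:b]) >= strong_sd * noise_sd:
            out.append((a, b))
    return out


def extract_events(
    trace: SpotTrace,
    green_intervals: list[tuple[int, int]],
    red_intervals: list[tuple[int, int]],
) -> EventRecord:
    """Build an :class:`EventRecord` from presence intervals.

    The first green interval defines ORC arrival/departure.  The first red
    interval overlapping it defines Mcm2-7 recruitment; a subsequent red
    interval overlapping the green one is recorded as a second Mcm2-7
    arrival.  With no green/red co-occurrence the Mcm fields stay absent (a
    red-only spot yields no ORC fields at all).
    """
    n = trace.n_cycles
    ev = EventRecord(spot_id=trace.spot_id)
    if green_intervals:
        g0 = green_intervals[0]
        ev.orc_interval = g0
        ev.orc_arrival_s = trace.cycle_time(g0[0])
        ev.orc_departure_s = trace.cycle_time(g0[1])
        ev.orc_censored = g0[1] >= n
        overlapping = [r for r in red_intervals if r[0] < g0[1] and r[1] > g0[0]]
        if overlapping:
            m0 = overlapping[0]
            ev.mcm_interval = m0
            ev.mcm_arrival_s = trace.cycle_time(m0[0])
            ev.mcm_departure_s = trace.cycle_time(m0[1])
            ev.mcm_censored = m0[1] >= n
            if len(overlapping) > 1:
                ev.second_mcm_arrival_s = trace.cycle_time(overlapping[1][0])
    ev.censored_end = ev.orc_censored or ev.mcm_censored
    return ev


def detect_cdt1_release(
    trace: SpotTrace,
    mcm_interval: tuple[int, int],
    half_tolerance: float = 0.25,
    min_segment: int = 2,
) -> tuple[float | None, bool]:
    """Find the Cdt1-release step: a halving of red-excited fluorescence.

    Exhaustive single-changepoint least-squares scan of ``I_AexAem`` within
    the Mcm2-7 presence interval, accepted only if the post-step level is
    within ``half_tolerance`` of half the pre-step level (both measured above
    background), which distinguishes release of one of two dyes from full
    departure.  Returns ``(time_s or None, bleach_suspected)``; the flag is
    set when a second, later halving (acceptor photobleach) is also present.
    """
    lo, hi = mcm_interval
    hi = min(hi, trace.n_cycles)
    y = np.asarray(trace.I_AexAem, float)[lo:hi]
    c = _best_changepoint(y, min_segment)
    if c is None:
        return None, False
    pre = float(np.mean(y[:c]))
    post = float(np.mean(y[c:]))
    if pre <= 0 or post >= pre or abs(post - 0.5 * pre) > half_tolerance * pre:
        return None, False
    bleach = False
    c2 = _best_changepoint(y[c:], min_segment)
    if c2 is not None:
        pre2 = float(np.mean(y[c : c + c2]))
        post2 = float(np.mean(y[c + c2 :]))
        if pre2 > 0 and post2 < pre2 and abs(post2 - 0.5 * pre2) <= half_tolerance * pre2:
            bleach = True
    return trace.cycle_time(lo + c), bleach


def _best_changepoint(y: np.ndarray, min_segment: int) -> int | None:
    """Breakpoint minimizing two-segment squared error; None if trivial.

    The candidate must beat the no-step model; a flat series therefore
    returns None.
    """
    n = len(y)
    if n < 2 * min_segment:
        return None
    best_c, best_sse = None, None
    for c in range(min_segment, n - min_segment + 1):
        a, b = y[:c], y[c:]
        sse = float(np.sum((a - a.mean()) ** 2) + np.sum((b - b.mean()) ** 2))
        if best_sse is None or sse < best_sse:
            best_sse, best_c = sse, c
    sse0 = float(np.sum((y - y.mean()) ** 2))
    if best_sse is None or sse0 <= best_sse + 1e-12:
        return None
    return best_c
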