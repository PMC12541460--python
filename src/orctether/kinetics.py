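"""Cohort-level kinetic summaries: fractions, dwell medians, survival, heat maps.

Conventions shared by all summaries:

* fractions are binomial: pct = 100 k/n with SE = 100 sqrt(p(1-p)/n);
* reported percentages use two-stage round-half-up (to two decimals, then to
  the reporting precision), the convention that reproduces the reference
  fraction table in :mod:`orctether.worked_examples`;
* dwell medians carry a bootstrap SE (seeded, 1000 resamples by default);
* survival curves are Kaplan-Meier with bootstrap 95% CIs over spots;
* frame-to-seconds conversions use the acquisition cycle duration
  (1 cycle = 2.6 s, 3 cycles = 7.8 s by default).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from lifelines import KaplanMeierFitter

from .preprocess import EventRecord
from .state_calling import StateCall

__all__ = [
    "FractionSummary",
    "DwellSummary",
    "SurvivalCurve",
    "OffsetSummary",
    "RetentionSummary",
    "EfretHeatmap",
    "fraction_se",
    "median_se",
    "survival_curve",
    "formation_fraction",
    "time_to_formation",
    "interaction_duration",
    "tether_vs_cdt1_offsets",
    "retention_after_cdt1",
    "efret_heatmap",
]


# ---------------------------------------------------------------------------
# rounding helpers (reporting convention)

def _round_half_up(x: float, decimals: int = 0) -> float:
    m = 10**decimals
    return math.floor(x * m + 0.5 + 1e-9) / m


def _pct_hundredths(k: int, n: int) -> int:
    """round-half-up of 100*k/n to two decimals, in integer hundredths."""
    return (20000 * k + n) // (2 * n)


def display_pct(k: int, n: int, decimals: int = 0) -> float:
    """Reported percentage for k successes of n: exact two-stage rounding."""
    h = _pct_hundredths(k, n)
    if decimals >= 2:
        return h / 100
    if decimals == 1:
        return ((h + 5) // 10) / 10
    return float((h + 50) // 100)


@dataclass(frozen=True)
class FractionSummary:
    """k-of-n fraction with binomial standard error."""

    k: int
    n: int

    def __post_init__(self) -> None:
        if not (0 <= self.k <= self.n) or self.n <= 0:
            raise ValueError("need 0 <= k <= n with n > 0")

    @property
    def pct(self) -> float:
        return 100.0 * self.k / self.n

    @property
    def se_pct(self) -> float:
        p = self.k / self.n
        return 100.0 * math.sqrt(p * (1.0 - p) / self.n)

    def pct_display(self, decimals: int = 0) -> float:
        return display_pct(self.k, self.n, decimals)

    def se_display(self, decimals: int = 0) -> float:
        return _round_half_up(_round_half_up(self.se_pct, 2), decimals)

    def as_string(self, decimals: int = 0, with_se: bool = True) -> str:
        pct = self.pct_display(decimals)
        if with_se:
            return f"{pct:g} ± {self.se_display(decimals):g}%"
        return f"{pct:g}%"


def fraction_se(k: int, n: int) -> FractionSummary:
    """Binomial fraction summary; the SE model behind every reported pct."""
    return FractionSummary(k=k, n=n)


# ---------------------------------------------------------------------------
# dwell summaries

@dataclass
class DwellSummary:
    """List of dwell times with median, bootstrap SE, and 95% CI (seconds)."""

    values: np.ndarray
    median: float
    se_median: float
    ci_low: float
    ci_high: float
    n: int
    n_censored: int = 0
    note: str = ""


def median_se(
    values, n_boot: int = 1000, rng: int | np.random.Generator = 0
) -> DwellSummary:
    """Sample median with bootstrap SE and percentile 95% CI."""
    values = np.asarray(values, float)
    if values.size == 0:
        raise ValueError("median_se needs at least one value")
    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    med = float(np.median(values))
    if values.size == 1:
        return DwellSummary(values, med, 0.0, med, med, 1)
    idx = rng.integers(0, values.size, size=(n_boot, values.size))
    boots = np.median(values[idx], axis=1)
    lo, hi = np.percentile(boots, [2.5, 97.5])
    return DwellSummary(
        values=values,
        median=med,
        se_median=float(np.std(boots, ddof=1)),
        ci_low=float(lo),
        ci_high=float(hi),
        n=int(values.size),
    )


def _km_median_summary(
    times: np.ndarray,
    censored: np.ndarray,
    n_boot: int,
    rng: np.random.Generator,
) -> DwellSummary:
    """Kaplan-Meier median with bootstrap SE (censoring-aware)."""
    kmf = KaplanMeierFitter().fit(times, event_observed=~censored)
    med = float(kmf.median_survival_time_)
    boots = []
    for _ in range(n_boot):
        idx = rng.integers(0, len(times), size=len(times))
        t, c = times[idx], censored[idx]
        if (~c).sum() == 0:
            boots.append(np.inf)
            continue
        boots.append(float(KaplanMeierFitter().fit(t, event_observed=~c).median_survival_time_))
    boots = np.asarray(boots)
    finite = boots[np.isfinite(boots)]
    note = ""
    if len(finite) < len(boots):
        note = f"{len(boots) - len(finite)} bootstrap medians undefined (heavy censoring)"
    if len(finite) >= 2:
        se = float(np.std(finite, ddof=1))
        lo, hi = np.percentile(finite, [2.5, 97.5])
    else:  # pragma: no cover - degenerate censoring
        se, lo, hi = np.nan, np.nan, np.nan
    return DwellSummary(
        values=times,
        median=med,
        se_median=se,
        ci_low=float(lo),
        ci_high=float(hi),
        n=len(times),
        n_censored=int(censored.sum()),
        note=note,
    )


# ---------------------------------------------------------------------------
# survival curves

@dataclass
class SurvivalCurve:
    """Kaplan-Meier curve on the event-time grid with bootstrap 95% CI."""

    time: np.ndarray
    survival: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray
    n_at_risk: np.ndarray
    n: int
    n_censored: int


def survival_curve(
    times,
    censored=None,
    n_boot: int = 1000,
    rng: int | np.random.Generator = 0,
) -> SurvivalCurve:
    """Kaplan-Meier estimator with seeded nonparametric bootstrap CI.

    With no censoring the estimator equals the empirical survival function.
    ``censored[i]`` True means the spot was still bound when observation
    ended (right-censoring).
    """
    times = np.asarray(times, float)
    if times.size == 0:
        raise ValueError("survival_curve needs at least one time")
    censored = (
        np.zeros(times.size, bool) if censored is None else np.asarray(censored, bool)
    )
    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    grid = np.unique(np.r_[0.0, times])
    kmf = KaplanMeierFitter().fit(times, event_observed=~censored)
    surv = kmf.survival_function_at_times(grid).to_numpy(float)
    boots = np.empty((n_boot, grid.size))
    for b in range(n_boot):
        idx = rng.integers(0, times.size, size=times.size)
        bk = KaplanMeierFitter().fit(times[idx], event_observed=~censored[idx])
        boots[b] = bk.survival_function_at_times(grid).to_numpy(float)
    lo, hi = np.percentile(boots, [2.5, 97.5], axis=0)
    return SurvivalCurve(
        time=grid,
        survival=surv,
        ci_low=np.minimum(lo, surv),
        ci_high=np.maximum(hi, surv),
        n_at_risk=np.array([(times >= t).sum() for t in grid]),
        n=int(times.size),
        n_censored=int(censored.sum()),
    )


# ---------------------------------------------------------------------------
# per-cohort operations

def _paired(calls: list[StateCall], events: list[EventRecord]):
    ev = {e.spot_id: e for e in events}
    return [(c, ev[c.spot_id]) for c in calls if c.spot_id in ev]


def formation_fraction(calls: list[StateCall]) -> FractionSummary | None:
    """Fraction of stably recruited events that ever reached the high state.

    Returns None when no event passes the stable-recruitment filter.
    """
    stable = [c for c in calls if c.stable_recruitment]
    if not stable:
        return None
    return FractionSummary(k=sum(c.formed for c in stable), n=len(stable))


def time_to_formation(
    calls: list[StateCall],
    events: list[EventRecord],
    n_boot: int = 1000,
    rng: int | np.random.Generator = 0,
) -> DwellSummary | None:
    """Time from Mcm2-7 arrival to first entry into the high-FRET state.

    Only stably recruited events that formed the tether contribute (events
    that never reached the high state are excluded by construction).
    """
    vals = []
    for call, ev in _paired(calls, events):
        if call.stable_recruitment and call.formed and ev.mcm_arrival_s is not None:
            first_start_s = call.high_intervals_s[0][0]
            vals.append(first_start_s - ev.mcm_arrival_s)
    if not vals:
        return None
    return median_se(np.asarray(vals), n_boot=n_boot, rng=rng)


def interaction_duration(
    calls: list[StateCall],
    include_censored: bool = True,
    n_boot: int = 1000,
    rng: int | np.random.Generator = 0,
) -> DwellSummary | None:
    """Durations of the first high-FRET interval per spot.

    Censored intervals (high at species departure or recording end) are
    included as observed durations by default, with the censoring tally
    reported on the summary; pass ``include_censored=False`` to drop them.
    """
    vals, cens = [], 0
    for call in calls:
        if not (call.stable_recruitment and call.formed):
            continue
        a, b, censored = call.high_intervals_s[0]
        if censored:
            cens += 1
            if not include_censored:
                continue
        vals.append(b - a)
    if not vals:
        return None
    out = median_se(np.asarray(vals), n_boot=n_boot, rng=rng)
    out.n_censored = cens
    out.note = (
        f"{cens} censored interval(s) included as observed"
        if include_censored
        else f"{cens} censored interval(s) excluded"
    )
    return out


@dataclass
class OffsetSummary:
    """Signed offsets of tether formation relative to Cdt1 release (s).

    Negative offsets mean the tether formed first.
    """

    offsets: np.ndarray
    summary: DwellSummary
    n_tether_first: int
    n_excluded: int


def tether_vs_cdt1_offsets(
    calls: list[StateCall],
    events: list[EventRecord],
    n_boot: int = 1000,
    rng: int | np.random.Generator = 0,
) -> OffsetSummary | None:
    """Per-event (first tether formation - Cdt1 release) offsets.

    Events without a detected Cdt1 release or without a high interval are
    excluded and tallied.
    """
    offsets, excluded = [], 0
    for call, ev in _paired(calls, events):
        if not call.stable_recruitment:
            continue
        if ev.cdt1_release_s is None or not call.formed:
            excluded += 1
            continue
        offsets.append(call.high_intervals_s[0][0] - ev.cdt1_release_s)
    if not offsets:
        return None
    offsets = np.asarray(offsets)
    return OffsetSummary(
        offsets=offsets,
        summary=median_se(offsets, n_boot=n_boot, rng=rng),
        n_tether_first=int((offsets < 0).sum()),
        n_excluded=excluded,
    )


@dataclass
class RetentionSummary:
    """ORC retention after Cdt1 release, segregated by tether state.

    ``groups`` maps 'high'/'low' (E_FRET state at the release cycle) to a
    (survival curve, KM median summary) pair.  The release-within-one-cycle,
    release-within-three-cycles, and retained-beyond-100-s fractions are
    pooled over both groups, as are the exclusion tallies.
    """

    groups: dict[str, tuple[SurvivalCurve, DwellSummary]]
    released_within_1_cycle: FractionSummary | None
    released_within_3_cycles: FractionSummary | None
    retained_over_100s: FractionSummary | None
    n_excluded: int
    cycle_s: float


def retention_after_cdt1(
    calls: list[StateCall],
    events: list[EventRecord],
    n_boot: int = 1000,
    rng: int | np.random.Generator = 0,
    long_retention_s: float = 100.0,
) -> RetentionSummary | None:
    """ORC retention time after Cdt1 release, by tether state at release.

    Retention is ``orc_departure - cdt1_release``; spots where ORC was not
    detected at the time of Cdt1 release are excluded (tallied).  Spots with
    ORC still bound at the recording end are right-censored in the survival
    curves and never counted in a "released within" numerator.
    """
    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    rows = []  # (retention_s, censored, state_at_release)
    excluded = 0
    for call, ev in _paired(calls, events):
        if ev.cdt1_release_s is None:
            continue
        t_rel = ev.cdt1_release_s
        if (
            ev.orc_arrival_s is None
            or ev.orc_departure_s is None
            or not (ev.orc_arrival_s <= t_rel < ev.orc_departure_s)
        ):
            excluded += 1
            continue
        retention = ev.orc_departure_s - t_rel
        rel_cycle = int(round((t_rel - call.t0) / call.dt))
        rows.append((retention, ev.orc_censored, call.state_at_cycle(rel_cycle)))
    if not rows:
        return None
    ret = np.array([r[0] for r in rows])
    cens = np.array([r[1] for r in rows])
    state = np.array([r[2] for r in rows])
    dt = calls[0].dt

    groups = {}
    for g in ("high", "low"):
        mask = state == g
        if mask.any():
            curve = survival_curve(ret[mask], cens[mask], n_boot=n_boot, rng=rng)
            med = _km_median_summary(ret[mask], cens[mask], n_boot, rng)
            groups[g] = (curve, med)

    eps = 1e-9
    n = len(rows)
    within = lambda w: int(((ret <= w + eps) & ~cens).sum())
    return RetentionSummary(
        groups=groups,
        released_within_1_cycle=FractionSummary(within(dt), n),
        released_within_3_cycles=FractionSummary(within(3 * dt), n),
        retained_over_100s=FractionSummary(int((ret > long_retention_s).sum()), n),
        n_excluded=excluded,
        cycle_s=dt,
    )


# ---------------------------------------------------------------------------
# E_FRET heat map

@dataclass
class EfretHeatmap:
    """E_FRET probability density vs time since Mcm2-7 arrival.

    Column ``j`` of ``density`` is the normalized E histogram over the
    molecules still co-present ``j`` cycles after their Mcm2-7 arrival
    (NaN where none remain); ``remaining_fraction`` is the companion
    remaining-complexes curve with bootstrap 95% CI.
    """

    e_edges: np.ndarray
    time_edges_s: np.ndarray
    density: np.ndarray  # shape (n_e_bins, n_time_bins)
    remaining_fraction: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray
    n_spots: int


def efret_heatmap(
    calls: list[StateCall],
    events: list[EventRecord],
    e_edges: np.ndarray | None = None,
    max_offset_cycles: int | None = None,
    n_boot: int = 1000,
    rng: int | np.random.Generator = 0,
) -> EfretHeatmap | None:
    """Cohort E_FRET heat map aligned at Mcm2-7 arrival.

    Uses only stably recruited spots, and at each time bin only the
    molecules whose ORC/Mcm2-7 co-presence still covers that cycle (so the
    density tracks surviving complexes, not departures).  Default bins are
    0.05 E units by one frame cycle.
    """
    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    pairs = [
        (c, e)
        for c, e in _paired(calls, events)
        if c.stable_recruitment and e.mcm_interval is not None and c.copresence
    ]
    if not pairs:
        return None
    if e_edges is None:
        e_edges = np.arange(-0.2, 1.2001, 0.05)
    dt = pairs[0][0].dt
    spans = []  # (aligned E array from arrival to copresence end)
    for call, ev in pairs:
        m0 = ev.mcm_interval[0]
        _, co_end = call.copresence
        spans.append(call.efret[m0:co_end])
    max_len = max(len(s) for s in spans)
    if max_offset_cycles is not None:
        max_len = min(max_len, max_offset_cycles)
    n_spots = len(spans)

    remain_mat = np.zeros((n_spots, max_len), bool)
    density = np.full((len(e_edges) - 1, max_len), np.nan)
    for j in range(max_len):
        vals = [s[j] for s in spans if len(s) > j]
        for i, s in enumerate(spans):
            remain_mat[i, j] = len(s) > j
        finite = np.asarray([v for v in vals if np.isfinite(v)])
        if finite.size:
            hist, _ = np.histogram(finite, bins=e_edges)
            density[:, j] = hist / hist.sum()
    remaining = remain_mat.mean(axis=0)
    idx = rng.integers(0, n_spots, size=(n_boot, n_spots))
    boots = remain_mat[idx].mean(axis=1)
    lo, hi = np.percentile(boots, [2.5, 97.5], axis=0)
    return EfretHeatmap(
        e_edges=np.asarray(e_edges, float),
        time_edges_s=np.arange(max_len + 1) * dt,
        density=density,
        remaining_fraction=remaining,
        ci_low=np.minimum(lo, remaining),
        ci_high=np.maximum(hi, remaining),
        n_spots=n_spots,
    )
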