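"""E_FRET computation, threshold determination, and high-state calling.

The apparent FRET efficiency per frame cycle is

    E = I(Dex, Aem) / (I(Dex, Dem) + I(Dex, Aem)),

defined only while both labeled species are on the DNA and the total
donor-excited emission is above a floor.  A cohort-wide threshold separating
the low (OCCM) and high (Orc6 tether) states is placed at the
equal-posterior point of a two-component Gaussian mixture fitted to the
pooled E values.  Tether intervals are then called with a symmetric
two-consecutive-frame hysteresis rule: a high interval starts at the first
of two consecutive frames above threshold and ends at the first of two
consecutive frames below it; single-frame excursions in either direction do
not change the state.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq
from scipy.stats import norm
from sklearn.mixture import GaussianMixture

from .errors import ThresholdFitError
from .preprocess import EventRecord
from .trace import SpotTrace

__all__ = [
    "StateCall",
    "compute_efret",
    "determine_threshold",
    "call_high_state",
    "stable_recruitment_filter",
]

#: Minimum co-presence duration, in frame cycles, for an event to count as a
#: "stable recruitment" (5 cycles = 13 s at the default 2.6 s cycle).
STABLE_RECRUITMENT_CYCLES = 5


@dataclass
class StateCall:
    """Per-spot E_FRET series and called high (tether) intervals.

    ``efret`` has one entry per cycle of the trace, NaN outside the
    co-presence interval or where the donor-excited total is below the
    floor.  ``high_intervals`` are half-open cycle-index intervals with a
    censored flag (interval truncated by species departure or recording
    end).  Interval seconds are available through ``high_intervals_s``.
    """

    spot_id: str
    efret: np.ndarray
    threshold: float
    high_intervals: list[tuple[int, int, bool]]
    stable_recruitment: bool
    copresence: tuple[int, int] | None
    dt: float
    t0: float = 0.0
    meta: dict = field(default_factory=dict)

    @property
    def formed(self) -> bool:
        return len(self.high_intervals) > 0

    @property
    def high_intervals_s(self) -> list[tuple[float, float, bool]]:
        return [
            (self.t0 + a * self.dt, self.t0 + b * self.dt, c)
            for a, b, c in self.high_intervals
        ]

    def state_at_cycle(self, cycle: int) -> str:
        """'high' if the cycle lies inside a called tether interval."""
        for a, b, _ in self.high_intervals:
            if a <= cycle < b:
                return "high"
        return "low"


def compute_efret(
    trace: SpotTrace,
    copresence_interval: tuple[int, int] | None,
    total_floor: float = 0.0,
) -> np.ndarray:
    """Per-cycle apparent FRET efficiency inside the co-presence interval.

    Cycles whose donor-excited total is at or below ``total_floor`` are NaN
    rather than computed (the ratio is meaningless near zero denominator).
    Values are deliberately not clipped to [0, 1]: noise-driven excursions
    carry information for the mixture fit and the histograms.
    """
    e = np.full(trace.n_cycles, np.nan)
    if copresence_interval is None:
        return e
    lo, hi = copresence_interval
    lo, hi = max(lo, 0), min(hi, trace.n_cycles)
    total = trace.I_DexDem[lo:hi] + trace.I_DexAem[lo:hi]
    with np.errstate(divide="ignore", invalid="ignore"):
        vals = np.where(total > total_floor, trace.I_DexAem[lo:hi] / total, np.nan)
    e[lo:hi] = vals
    return e


def determine_threshold(
    efret_pool: np.ndarray,
    min_pool: int = 200,
    random_state: int = 0,
) -> float:
    """Low/high E_FRET threshold from a two-Gaussian mixture fit.

    The mixture is initialized deterministically at the pool's 25th/75th
    percentiles and the threshold is placed where the two components'
    posterior responsibilities are equal, between the two means.  A fit
    whose means are closer than half the larger component sd raises
    :class:`ThresholdFitError` (supply a manual threshold instead).
    """
    pool = np.asarray(efret_pool, float)
    pool = pool[np.isfinite(pool)]
    if pool.size < min_pool:
        raise ValueError(
            f"need at least {min_pool} defined E values to fit a threshold "
            f"(got {pool.size})"
        )
    x = pool.reshape(-1, 1)
    q25, q75 = np.percentile(pool, [25, 75])
    gmm = GaussianMixture(
        n_components=2,
        covariance_type="full",
        means_init=[[q25], [q75]],
        weights_init=[0.5, 0.5],
        max_iter=500,
        n_init=1,
        random_state=random_state,
    )
    gmm.fit(x)
    means = gmm.means_.ravel()
    sds = np.sqrt(gmm.covariances_.ravel())
    weights = gmm.weights_.ravel()
    order = np.argsort(means)
    (m1, m2), (s1, s2), (w1, w2) = means[order], sds[order], weights[order]
    if (m2 - m1) < max(s1, s2) / 2:
        raise ThresholdFitError(
            f"mixture components collapsed (means {m1:.3f}, {m2:.3f}, "
            f"sds {s1:.3f}, {s2:.3f}); set the threshold manually"
        )
    # A unimodal pool splits into two heavily overlapping halves whose
    # mixture density has no dip between the means; require real bimodality.
    def mixture_pdf(x):
        return w1 * norm.pdf(x, m1, s1) + w2 * norm.pdf(x, m2, s2)

    between = np.linspace(m1, m2, 200)
    dip = mixture_pdf(between).min()
    if dip >= 0.9 * min(mixture_pdf(m1), mixture_pdf(m2)):
        raise ThresholdFitError(
            "pooled E values look unimodal (no density dip between the fitted "
            "components); set the threshold manually"
        )

    def log_posterior_diff(x0: float) -> float:
        return (np.log(w1) + norm.logpdf(x0, m1, s1)) - (
            np.log(w2) + norm.logpdf(x0, m2, s2)
        )

    # The crossing normally lies between the means; with very unequal
    # weights or spreads it can sit just outside, so widen the bracket on a
    # fine grid and take the crossing closest to the midpoint of the means.
    grid = np.linspace(m1 - 3 * s1, m2 + 3 * s2, 2001)
    diffs = np.array([log_posterior_diff(x) for x in grid])
    sign_flips = np.flatnonzero(np.sign(diffs[:-1]) != np.sign(diffs[1:]))
    if sign_flips.size == 0:
        raise ThresholdFitError("no equal-posterior crossing between the components")
    mid = 0.5 * (m1 + m2)
    i = sign_flips[np.argmin(np.abs(grid[sign_flips] - mid))]
    return float(brentq(log_posterior_diff, grid[i], grid[i + 1]))


def call_high_state(
    efret: np.ndarray, threshold: float
) -> list[tuple[int, int, bool]]:
    """Hysteresis calling of high-FRET (tether) intervals.

    Operates on the defined (finite) entries of ``efret``; NaN cycles are
    skipped and never advance the entry or exit counter.  Returns half-open
    cycle-index intervals; an interval still high when the defined series
    ends (species departure or recording end) is censored, with its end at
    one past the last defined cycle.
    """
    efret = np.asarray(efret, float)
    pos = np.flatnonzero(np.isfinite(efret))
    above = efret[pos] > threshold
    intervals: list[tuple[int, int, bool]] = []
    m = len(pos)
    i = 0
    start = None
    while i < m:
        if start is None:
            if above[i] and i + 1 < m and above[i + 1]:
                start = int(pos[i])
                i += 2
            else:
                i += 1
        else:
            if not above[i] and i + 1 < m and not above[i + 1]:
                intervals.append((start, int(pos[i]), False))
                start = None
                i += 2
            else:
                i += 1
    if start is not None:
        intervals.append((start, int(pos[-1]) + 1, True))
    return intervals


def stable_recruitment_filter(
    events: EventRecord, min_cycles: int = STABLE_RECRUITMENT_CYCLES
) -> bool:
    """True iff ORC and Mcm2-7 were co-present for at least ``min_cycles``.

    Downstream per-event statistics (formation fraction, formation time,
    durations) consider only events passing this filter.
    """
    co = events.copresence_interval()
    return co is not None and (co[1] - co[0]) >= min_cycles
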