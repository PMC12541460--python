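"""Kinetic schemes and state paths for helicase-loading simulations.

A :class:`KineticScheme` is a continuous-time Markov chain over labeled
intermediates of the origin-licensing reaction (ORC binding, Mcm2-7-Cdt1
recruitment, Orc6-tether formation, Cdt1 release, ORC release, ...).  Each
state carries the observables needed to render a two-color alternating
excitation measurement: a true FRET efficiency (meaningful only while both a
donor- and an acceptor-labeled species are present), and counts of donor
(green) and acceptor (red) fluorophores.  A :class:`StatePath` is one
stochastic realization of the chain, used both as simulation ground truth and
as the input to trace rendering.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigurationError

__all__ = ["KineticScheme", "StatePath", "simulate_state_path"]

_PROB_TOL = 1e-9


@dataclass(frozen=True)
class KineticScheme:
    """CTMC over licensing intermediates plus per-state observables.

    Parameters
    ----------
    state_names
        Ordered state labels.
    exit_rate
        Per-state exit rate constant in 1/s; 0 marks an absorbing state.
    transition_probs
        Per-state categorical distribution over successor states.  States
        with ``exit_rate == 0`` may omit their row.
    fret_efficiency
        True FRET efficiency in [0, 1] for states where both dyes are
        present; ``None`` marks FRET as inapplicable (required whenever
        either dye count is zero).
    green_dyes, red_dyes
        Nonnegative fluorophore counts per state (donor on ORC; acceptor on
        Mcm2-7, plus one extra acceptor on Cdt1 in Cdt1-labeled schemes).
    initial_state
        Label of the state every path starts in.
    """

    state_names: tuple[str, ...]
    exit_rate: dict[str, float]
    transition_probs: dict[str, dict[str, float]]
    fret_efficiency: dict[str, float | None]
    green_dyes: dict[str, int]
    red_dyes: dict[str, int]
    initial_state: str

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        states = set(self.state_names)
        if self.initial_state not in states:
            raise ConfigurationError(
                f"initial_state {self.initial_state!r} not among states"
            )
        for mapping, what in [
            (self.exit_rate, "exit_rate"),
            (self.fret_efficiency, "fret_efficiency"),
            (self.green_dyes, "green_dyes"),
            (self.red_dyes, "red_dyes"),
        ]:
            missing = states - set(mapping)
            if missing:
                raise ConfigurationError(f"{what} missing for states {sorted(missing)}")
        for s in self.state_names:
            k = self.exit_rate[s]
            if not (k >= 0) or not math.isfinite(k):
                raise ConfigurationError(f"exit_rate[{s!r}] must be finite and >= 0")
            for mapping, what in [(self.green_dyes, "green"), (self.red_dyes, "red")]:
                c = mapping[s]
                if not isinstance(c, (int, np.integer)) or c < 0:
                    raise ConfigurationError(
                        f"{what}_dyes[{s!r}] must be a nonnegative integer"
                    )
            e = self.fret_efficiency[s]
            if e is not None and not (0.0 <= e <= 1.0):
                raise ConfigurationError(f"fret_efficiency[{s!r}] must lie in [0, 1]")
            if (self.green_dyes[s] == 0 or self.red_dyes[s] == 0) and e is not None:
                raise ConfigurationError(
                    f"state {s!r} lacks one dye species; fret_efficiency must be None"
                )
            if k > 0:
                row = self.transition_probs.get(s)
                if not row:
                    raise ConfigurationError(f"state {s!r} has exit rate but no successors")
                if set(row) - states:
                    raise ConfigurationError(f"unknown successor(s) in row {s!r}")
                if any(p < 0 for p in row.values()):
                    raise ConfigurationError(f"negative probability in row {s!r}")
                if abs(sum(row.values()) - 1.0) > _PROB_TOL:
                    raise ConfigurationError(
                        f"transition_probs[{s!r}] sums to {sum(row.values())}, not 1"
                    )

    def is_absorbing(self, state: str) -> bool:
        return self.exit_rate[state] == 0.0

    def fret_applicable(self, state: str) -> bool:
        return self.fret_efficiency[state] is not None

    def max_green_dyes(self) -> int:
        return max(self.green_dyes.values())

    def max_red_dyes(self) -> int:
        return max(self.red_dyes.values())

    def to_dict(self) -> dict:
        """Plain-data dump for metadata files."""
        return {
            "state_names": list(self.state_names),
            "exit_rate": dict(self.exit_rate),
            "transition_probs": {s: dict(r) for s, r in self.transition_probs.items()},
            "fret_efficiency": dict(self.fret_efficiency),
            "green_dyes": dict(self.green_dyes),
            "red_dyes": dict(self.red_dyes),
            "initial_state": self.initial_state,
        }


@dataclass
class StatePath:
    """One realization of a kinetic scheme: contiguous labeled segments.

    ``segments`` is an ordered list of ``(state_label, start_s, end_s)``
    covering [0, total_duration) without gaps or overlap.  ``scheme`` is kept
    so downstream rendering can look up per-state observables.
    """

    segments: list[tuple[str, float, float]]
    total_duration: float
    scheme: KineticScheme | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        t = 0.0
        for label, start, end in self.segments:
            if not math.isclose(start, t, abs_tol=1e-9) or end < start:
                raise ConfigurationError("segments must be contiguous and ordered")
            t = end
        if self.segments and not math.isclose(t, self.total_duration, abs_tol=1e-9):
            raise ConfigurationError("segments must end at total_duration")

    def state_at(self, t: float) -> str | None:
        """State occupied at time ``t``; None beyond the end of the path."""
        for label, start, end in self.segments:
            if start <= t < end:
                return label
        return None

    def pieces(self, a: float, b: float) -> list[tuple[str | None, float, float]]:
        """Piecewise-constant decomposition of [a, b] by state occupancy.

        Times after the path end are reported with state ``None`` (empty DNA,
        no fluorophores).
        """
        out: list[tuple[str | None, float, float]] = []
        for label, start, end in self.segments:
            lo, hi = max(a, start), min(b, end)
            if hi > lo:
                out.append((label, lo, hi))
        tail = max(a, self.total_duration)
        if b > tail:
            out.append((None, tail, b))
        return out

    def occupancy(self, a: float, b: float) -> dict[str | None, float]:
        """Total time spent in each state within [a, b]."""
        occ: dict[str | None, float] = {}
        for label, lo, hi in self.pieces(a, b):
            occ[label] = occ.get(label, 0.0) + (hi - lo)
        return occ

    def first_entry(self, predicate) -> float | None:
        """Time of first entry into a state satisfying ``predicate(label)``."""
        for label, start, _ in self.segments:
            if predicate(label):
                return start
        return None

    def visits(self, predicate) -> bool:
        return any(predicate(label) for label, _, _ in self.segments)


def simulate_state_path(
    scheme: KineticScheme,
    duration: float,
    rng_seed: int | np.random.Generator,
) -> StatePath:
    """Gillespie realization of ``scheme`` truncated at ``duration`` seconds.

    Dwell times are exponential with the state's exit rate; successors are
    drawn from its categorical row.  Absorbing states (exit rate 0) persist to
    the end of the window.  ``duration == 0`` yields an empty path.
    """
    if duration < 0:
        raise ConfigurationError("duration must be >= 0")
    scheme.validate()
    rng = (
        rng_seed
        if isinstance(rng_seed, np.random.Generator)
        else np.random.default_rng(rng_seed)
    )
    segments: list[tuple[str, float, float]] = []
    t = 0.0
    state = scheme.initial_state
    while t < duration:
        k = scheme.exit_rate[state]
        if k == 0.0:
            segments.append((state, t, duration))
            break
        dwell = rng.exponential(1.0 / k)
        end = min(t + dwell, duration)
        segments.append((state, t, end))
        t = end
        if t >= duration:
            break
        row = scheme.transition_probs[state]
        succ = list(row)
        state = succ[rng.choice(len(succ), p=[row[s] for s in succ])]
    return StatePath(segments=segments, total_duration=float(duration), scheme=scheme)
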