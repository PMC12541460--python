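"""Ground-truth readouts from simulated state paths.

These functions compute, directly from a :class:`~orctether.scheme.StatePath`
and its kinetic scheme, the same event times the trace pipeline estimates
from intensities: species presence windows, tether formation/end, and Cdt1
release.  They serve as the independent reference in end-to-end checks and
in the pipeline's ground-truth comparison mode.
"""

from __future__ import annotations

from dataclasses import dataclass

from .presets import TETHERED_STATES
from .scheme import KineticScheme, StatePath

__all__ = ["TruthEvents", "ground_truth_events"]


@dataclass
class TruthEvents:
    """True event times (seconds) for one simulated spot; None if absent."""

    orc_arrival_s: float | None = None
    orc_departure_s: float | None = None
    mcm_arrival_s: float | None = None
    mcm_departure_s: float | None = None
    tether_start_s: float | None = None
    tether_end_s: float | None = None
    cdt1_release_s: float | None = None
    copresence_s: float = 0.0


def _first_run(path: StatePath, member) -> tuple[float, float] | None:
    """First maximal run of consecutive segments satisfying ``member``."""
    start = None
    end = None
    for label, s, e in path.segments:
        if member(label):
            if start is None:
                start = s
            end = e
        elif start is not None:
            return (start, end)
    return (start, end) if start is not None else None


def ground_truth_events(
    path: StatePath,
    scheme: KineticScheme | None = None,
    tethered_states: frozenset[str] = TETHERED_STATES,
) -> TruthEvents:
    """True arrival/departure/tether/release times for one state path.

    ORC (green) and Mcm2-7 (red) presence follow the scheme's dye counts;
    Cdt1 release is the first drop of the red-dye count from 2 to 1 in
    Cdt1-labeled schemes, otherwise the first entry into a post-release
    state (state labels containing ``postcdt1`` or ``loaded``).
    """
    scheme = scheme or path.scheme
    if scheme is None:
        raise ValueError("need a kinetic scheme to interpret the path")
    out = TruthEvents()
    green = _first_run(path, lambda s: scheme.green_dyes[s] > 0)
    if green:
        out.orc_arrival_s, out.orc_departure_s = green
    red = _first_run(path, lambda s: scheme.red_dyes[s] > 0)
    if red:
        out.mcm_arrival_s, out.mcm_departure_s = red
    tether = _first_run(path, lambda s: s in tethered_states)
    if tether:
        out.tether_start_s, out.tether_end_s = tether
    if green and red:
        out.copresence_s = max(
            0.0, min(green[1], red[1]) - max(green[0], red[0])
        )
    # Cdt1 release: red dye count 2 -> 1, or entry into a post-release state.
    if scheme.max_red_dyes() >= 2:
        prev = None
        for label, s, _ in path.segments:
            if prev is not None and scheme.red_dyes[prev] >= 2 and scheme.red_dyes[label] == 1:
                out.cdt1_release_s = s
                break
            prev = label
    else:
        for label, s, _ in path.segments:
            if "postcdt1" in label or label == "loaded":
                out.cdt1_release_s = s
                break
    return out
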