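"""Render ground-truth state paths into noisy three-channel traces.

The rendering model: during a green (donor-excitation) exposure each
unbleached donor emits ``donor_brightness`` counts/s split between the donor
and acceptor channels as ``(1 - E)`` and ``E``, where ``E`` is the occupied
state's true FRET efficiency (0 whenever FRET is inapplicable or the FRET
acceptor has bleached).  During a red exposure each unbleached acceptor emits
``acceptor_brightness_direct`` counts/s into the AexAem channel — so a
Cdt1-labeled complex shows double red signal until Cdt1 release halves it.
Exposure windows straddling a state boundary integrate occupancy, per-channel
Gaussian background noise is added, and every dye photobleaches on an
independent exponential clock started at its first appearance.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigurationError
from .scheme import KineticScheme, StatePath, simulate_state_path
from .trace import AcquisitionConfig, EmissionParams, SpotTrace

__all__ = ["render_trace", "generate_cohort", "Cohort"]

#: Red dye slot that acts as the FRET acceptor (the Mcm2-7 N-tier label).
#: Slot 1, when present, is the Cdt1 label, which does not FRET with the
#: ORC donor.
FRET_PARTNER_SLOT = 0


def _slot_schedule(
    path: StatePath, counts: dict[str, int], n_slots: int
) -> list[float | None]:
    """First-appearance time of each dye slot along the path (None = never)."""
    first: list[float | None] = [None] * n_slots
    for label, start, _ in path.segments:
        c = counts[label]
        for j in range(min(c, n_slots)):
            if first[j] is None:
                first[j] = start
    return first


def render_trace(
    path: StatePath,
    acq: AcquisitionConfig,
    emission: EmissionParams,
    rng_seed: int | np.random.Generator,
    spot_id: str = "spot0",
) -> SpotTrace:
    """Render one state path into a :class:`SpotTrace`.

    The path may end before the recording does; later cycles show empty-DNA
    (background-only) emission.  The returned trace carries the ground-truth
    path and per-dye bleach times.
    """
    scheme = path.scheme
    if scheme is None:
        raise ConfigurationError("path must carry its kinetic scheme for rendering")
    rng = (
        rng_seed
        if isinstance(rng_seed, np.random.Generator)
        else np.random.default_rng(rng_seed)
    )

    n_green = scheme.max_green_dyes()
    n_red = scheme.max_red_dyes()
    green_on = _slot_schedule(path, scheme.green_dyes, n_green)
    red_on = _slot_schedule(path, scheme.red_dyes, n_red)

    def _dye_fates(first, rate, label_eff, prefix):
        labeled, bleach, names = [], [], []
        for j, t_on in enumerate(first):
            names.append(f"{prefix}{j}")
            labeled.append(bool(rng.random() < label_eff))
            if t_on is None or rate == 0.0:
                bleach.append(np.inf)
            else:
                bleach.append(t_on + rng.exponential(1.0 / rate))
        return labeled, bleach, names

    g_lab, g_bleach, g_names = _dye_fates(
        green_on, emission.bleach_rate_green, emission.label_efficiency_green, "green"
    )
    r_lab, r_bleach, r_names = _dye_fates(
        red_on, emission.bleach_rate_red, emission.label_efficiency_red, "red"
    )
    bleach_times = {
        name: (float(t) if np.isfinite(t) else np.inf)
        for name, t in zip(g_names + r_names, g_bleach + r_bleach)
    }

    def _active(j, t, counts_of_state, labeled, bleach):
        return labeled[j] and t < bleach[j] and j < counts_of_state

    def _pieces(a, b, extra_breaks):
        """State pieces of [a, b], further split at bleach times."""
        breaks = sorted({a, b, *(t for t in extra_breaks if a < t < b)})
        out = []
        for lo, hi in zip(breaks[:-1], breaks[1:]):
            for label, plo, phi in path.pieces(lo, hi):
                out.append((label, plo, phi))
        return out

    all_bleach = [t for t in g_bleach + r_bleach if np.isfinite(t)]
    n = acq.n_cycles
    dem = np.zeros(n)
    aem = np.zeros(n)
    red = np.zeros(n)

    for i in range(n):
        ga, gb = acq.green_window(i)
        for label, lo, hi in _pieces(ga, gb, all_bleach):
            if label is None:
                continue
            tmid = 0.5 * (lo + hi)
            n_don = sum(
                _active(j, tmid, scheme.green_dyes[label], g_lab, g_bleach)
                for j in range(n_green)
            )
            if n_don == 0:
                continue
            e = scheme.fret_efficiency[label]
            partner = _active(
                FRET_PARTNER_SLOT, tmid, scheme.red_dyes[label], r_lab, r_bleach
            )
            e_eff = e if (e is not None and partner) else 0.0
            flux = n_don * emission.donor_brightness * (hi - lo)
            dem[i] += flux * (1.0 - e_eff)
            aem[i] += flux * e_eff
        ra, rb = acq.red_window(i)
        for label, lo, hi in _pieces(ra, rb, all_bleach):
            if label is None:
                continue
            tmid = 0.5 * (lo + hi)
            n_acc = sum(
                _active(j, tmid, scheme.red_dyes[label], r_lab, r_bleach)
                for j in range(n_red)
            )
            red[i] += n_acc * emission.acceptor_brightness_direct * (hi - lo)

    bg_mean, bg_sd = emission.background_mean, emission.background_sd
    for arr, m, sd in zip((dem, aem, red), bg_mean, bg_sd):
        arr += m
        if sd > 0:
            arr += rng.normal(0.0, sd, size=n)

    return SpotTrace(
        spot_id=spot_id,
        time_s=np.arange(n) * acq.cycle_duration,
        I_DexDem=dem,
        I_DexAem=aem,
        I_AexAem=red,
        truth=path,
        bleach_times=bleach_times,
        meta={"cycle_duration": acq.cycle_duration},
    )


@dataclass
class Cohort:
    """A simulated set of spots plus everything needed to reproduce it."""

    traces: list[SpotTrace]
    scheme: KineticScheme
    acquisition: AcquisitionConfig
    emission: EmissionParams
    preset: str
    seed: int
    cdt1_labeled: bool = False
    meta: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.traces)

    def metadata(self) -> dict:
        return {
            "preset": self.preset,
            "seed": self.seed,
            "n_spots": len(self.traces),
            "cdt1_labeled": self.cdt1_labeled,
            "scheme": self.scheme.to_dict(),
            "acquisition": self.acquisition.to_dict(),
            "emission": self.emission.to_dict(),
            **self.meta,
        }


def generate_cohort(
    preset_name: str,
    n_spots: int,
    rng_seed: int,
    *,
    n_cycles: int | None = None,
    emission: EmissionParams | None = None,
    acquisition: AcquisitionConfig | None = None,
    scheme: KineticScheme | None = None,
    cdt1_labeled: bool | None = None,
    reaction_start_s: float = 30.0,
) -> Cohort:
    """Simulate a reproducible cohort of spots under a named preset.

    Each spot gets an independent child seed spawned from ``rng_seed``, so
    cohorts are bit-identical across runs with the same arguments.
    ``reaction_start_s`` models the protein flow-in delay: every recording
    opens with that much empty-DNA time (as in the experiment, where DNA
    positions are mapped before the loading reaction starts), which also
    guarantees a baseline stretch for background estimation.  The keyword
    overrides exist for custom schemes in tests and parameter studies;
    presets themselves differ only in kinetic rates and labeling.
    """
    from .presets import get_preset  # local import to avoid a cycle

    if n_spots <= 0:
        raise ConfigurationError("n_spots must be > 0")
    preset = get_preset(preset_name)
    scheme = scheme if scheme is not None else preset.scheme
    acq = acquisition if acquisition is not None else preset.acquisition
    emi = emission if emission is not None else preset.emission
    labeled = preset.cdt1_labeled if cdt1_labeled is None else cdt1_labeled
    if n_cycles is not None:
        acq = AcquisitionConfig(
            exposure_green=acq.exposure_green,
            exposure_red=acq.exposure_red,
            dead_time=acq.dead_time,
            cycle_duration=acq.cycle_duration,
            n_cycles=n_cycles,
        )

    if not (0.0 <= reaction_start_s < acq.total_duration):
        raise ConfigurationError("reaction_start_s must lie within the recording")
    seeds = np.random.SeedSequence(rng_seed).spawn(n_spots)
    traces = []
    for i, ss in enumerate(seeds):
        rng = np.random.default_rng(ss)
        path = simulate_state_path(
            scheme, acq.total_duration - reaction_start_s, rng
        )
        if reaction_start_s > 0:
            segments = [(scheme.initial_state, 0.0, reaction_start_s)] + [
                (s, a + reaction_start_s, b + reaction_start_s)
                for s, a, b in path.segments
            ]
            path = StatePath(
                segments=segments,
                total_duration=acq.total_duration,
                scheme=scheme,
            )
        traces.append(render_trace(path, acq, emi, rng, spot_id=f"spot{i:04d}"))
    return Cohort(
        traces=traces,
        scheme=scheme,
        acquisition=acq,
        emission=emi,
        preset=preset_name,
        seed=rng_seed,
        cdt1_labeled=labeled,
        meta={"description": preset.description},
    )
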