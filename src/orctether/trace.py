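"""Per-spot trace containers and acquisition/emission parameter sets."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigurationError
from .scheme import StatePath

__all__ = ["AcquisitionConfig", "EmissionParams", "SpotTrace", "CHANNELS"]

#: Channel column names: donor-excited donor emission, donor-excited acceptor
#: emission (FRET channel), acceptor-excited acceptor emission.
CHANNELS = ("I_DexDem", "I_DexAem", "I_AexAem")


@dataclass(frozen=True)
class AcquisitionConfig:
    """Timing of the alternating-excitation acquisition.

    One frame cycle is a green (donor-excitation) exposure, then a red
    (acceptor-excitation) exposure, separated by dead time.  The default
    cycle duration is 2.6 s: 1 s green + 1 s red + 2 x 0.2 s dead time plus
    0.2 s of per-cycle overhead, so that three cycles span 7.8 s, the
    frame-to-seconds conversion used throughout the kinetic summaries.
    """

    exposure_green: float = 1.0
    exposure_red: float = 1.0
    dead_time: float = 0.2
    cycle_duration: float = 2.6
    n_cycles: int = 200

    def __post_init__(self) -> None:
        if min(self.exposure_green, self.exposure_red, self.cycle_duration) <= 0:
            raise ConfigurationError("all durations must be > 0")
        if self.dead_time < 0:
            raise ConfigurationError("dead_time must be >= 0")
        core = self.exposure_green + self.exposure_red + 2 * self.dead_time
        if self.cycle_duration + 1e-9 < core:
            raise ConfigurationError(
                f"cycle_duration {self.cycle_duration} shorter than exposures + dead time ({core})"
            )
        if self.n_cycles < 0:
            raise ConfigurationError("n_cycles must be >= 0")

    @property
    def total_duration(self) -> float:
        return self.n_cycles * self.cycle_duration

    def green_window(self, cycle: int) -> tuple[float, float]:
        t0 = cycle * self.cycle_duration
        return t0, t0 + self.exposure_green

    def red_window(self, cycle: int) -> tuple[float, float]:
        t0 = cycle * self.cycle_duration + self.exposure_green + self.dead_time
        return t0, t0 + self.exposure_red

    def to_dict(self) -> dict:
        return {
            "exposure_green": self.exposure_green,
            "exposure_red": self.exposure_red,
            "dead_time": self.dead_time,
            "cycle_duration": self.cycle_duration,
            "n_cycles": self.n_cycles,
        }


@dataclass(frozen=True)
class EmissionParams:
    """Photophysics of trace rendering.

    Brightnesses are expected counts per second per fluorophore; background
    mean/sd are counts per exposure per channel (order: DexDem, DexAem,
    AexAem); noise is additive Gaussian.  Each fluorophore photobleaches on
    an independent exponential clock started when it first appears on the
    DNA, and contributes nothing afterward.  Labeling efficiencies give the
    probability that a dye slot carries a functional fluorophore at all.
    """

    donor_brightness: float = 1000.0
    acceptor_brightness_direct: float = 1000.0
    background_mean: tuple[float, float, float] = (100.0, 100.0, 100.0)
    background_sd: tuple[float, float, float] = (50.0, 50.0, 50.0)
    bleach_rate_green: float = 0.001
    bleach_rate_red: float = 0.001
    label_efficiency_green: float = 1.0
    label_efficiency_red: float = 1.0

    def __post_init__(self) -> None:
        bg_mean = tuple(float(v) for v in np.broadcast_to(self.background_mean, (3,)))
        bg_sd = tuple(float(v) for v in np.broadcast_to(self.background_sd, (3,)))
        object.__setattr__(self, "background_mean", bg_mean)
        object.__setattr__(self, "background_sd", bg_sd)
        if min(self.donor_brightness, self.acceptor_brightness_direct) <= 0:
            raise ConfigurationError("brightnesses must be > 0")
        if any(sd < 0 for sd in bg_sd):
            raise ConfigurationError("background sds must be >= 0")
        if min(self.bleach_rate_green, self.bleach_rate_red) < 0:
            raise ConfigurationError("bleach rates must be >= 0")
        for p in (self.label_efficiency_green, self.label_efficiency_red):
            if not (0.0 <= p <= 1.0):
                raise ConfigurationError("label efficiencies must lie in [0, 1]")

    def to_dict(self) -> dict:
        return {
            "donor_brightness": self.donor_brightness,
            "acceptor_brightness_direct": self.acceptor_brightness_direct,
            "background_mean": list(self.background_mean),
            "background_sd": list(self.background_sd),
            "bleach_rate_green": self.bleach_rate_green,
            "bleach_rate_red": self.bleach_rate_red,
            "label_efficiency_green": self.label_efficiency_green,
            "label_efficiency_red": self.label_efficiency_red,
        }


@dataclass
class SpotTrace:
    """Three-channel intensity time series for one DNA molecule.

    ``time_s[i]`` is the start of frame cycle ``i``; spacing is the cycle
    duration.  Simulated traces optionally carry their ground-truth state
    path and per-dye bleach times; analysis results accumulate in ``meta``
    (baselines, noise estimates, warning flags).
    """

    spot_id: str
    time_s: np.ndarray
    I_DexDem: np.ndarray
    I_DexAem: np.ndarray
    I_AexAem: np.ndarray
    truth: StatePath | None = field(default=None, repr=False)
    bleach_times: dict[str, float] | None = field(default=None, repr=False)
    meta: dict = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        n = len(self.time_s)
        if not (len(self.I_DexDem) == len(self.I_DexAem) == len(self.I_AexAem) == n):
            raise ConfigurationError("all channels must have the same length")
        if n >= 2:
            dt = np.diff(self.time_s)
            if np.any(dt <= 0) or not np.allclose(dt, dt[0], rtol=1e-6, atol=1e-9):
                raise ConfigurationError("time_s must increase with constant spacing")

    @property
    def n_cycles(self) -> int:
        return len(self.time_s)

    @property
    def dt(self) -> float:
        if len(self.time_s) < 2:
            return float(self.meta.get("cycle_duration", np.nan))
        return float(self.time_s[1] - self.time_s[0])

    @property
    def donor_total(self) -> np.ndarray:
        """Total donor-excited emission (conserved across FRET changes)."""
        return self.I_DexDem + self.I_DexAem

    def cycle_time(self, cycle: int) -> float:
        """Start-of-cycle time for ``cycle`` (may extrapolate past the end)."""
        return float(self.time_s[0] + cycle * self.dt)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "spot_id": self.spot_id,
                "cycle_index": np.arange(self.n_cycles),
                "time_s": self.time_s,
                "I_DexDem": self.I_DexDem,
                "I_DexAem": self.I_DexAem,
                "I_AexAem": self.I_AexAem,
            }
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame, spot_id: str | None = None) -> "SpotTrace":
        if spot_id is None:
            ids = df["spot_id"].unique()
            if len(ids) != 1:
                raise ConfigurationError("frame holds multiple spots; pass spot_id")
            spot_id = str(ids[0])
        else:
            df = df[df["spot_id"].astype(str) == str(spot_id)]
        df = df.sort_values("cycle_index")
        return cls(
            spot_id=str(spot_id),
            time_s=df["time_s"].to_numpy(float),
            I_DexDem=df["I_DexDem"].to_numpy(float),
            I_DexAem=df["I_DexAem"].to_numpy(float),
            I_AexAem=df["I_AexAem"].to_numpy(float),
        )
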