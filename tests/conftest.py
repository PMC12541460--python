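import numpy as np
import pytest

from orctether import EmissionParams, SpotTrace


def rle_high_state_oracle(efret, thr):
    """Run-length-encoding formulation of the 2-in/2-out hysteresis rule.

    Independent of the production caller: encodes the defined above/below
    sequence into runs, enters high at the first above-run of length >= 2,
    exits at the first below-run of length >= 2.
    """
    pos = [i for i, v in enumerate(efret) if np.isfinite(v)]
    ab = [efret[i] > thr for i in pos]
    runs = []  # [is_above, start_index_into_pos, length]
    for k, b in enumerate(ab):
        if runs and runs[-1][0] == b:
            runs[-1][2] += 1
        else:
            runs.append([b, k, 1])
    high, out, start = False, [], None
    for b, k0, ln in runs:
        if not high and b and ln >= 2:
            high, start = True, pos[k0]
        elif high and not b and ln >= 2:
            out.append((start, pos[k0], False))
            high = False
    if high:
        out.append((start, pos[-1] + 1, True))
    return out


@pytest.fixture
def high_state_oracle():
    return rle_high_state_oracle


@pytest.fixture
def noiseless_emission():
    """Rendering parameters with background but no noise and no bleaching."""
    return EmissionParams(
        background_mean=(100.0, 100.0, 100.0),
        background_sd=(0.0, 0.0, 0.0),
        bleach_rate_green=0.0,
        bleach_rate_red=0.0,
    )


@pytest.fixture
def trace_factory():
    """Build a SpotTrace directly from per-channel arrays (dt = 1 s)."""

    def make(dem, aem, red, dt=1.0, spot_id="s0"):
        dem = np.asarray(dem, float)
        n = len(dem)
        return SpotTrace(
            spot_id=spot_id,
            time_s=np.arange(n) * dt,
            I_DexDem=dem,
            I_DexAem=np.asarray(aem, float),
            I_AexAem=np.asarray(red, float),
        )

    return make
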