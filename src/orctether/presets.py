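"""Named simulation presets for the helicase-loading tether assay.

Each preset is a kinetic scheme over the licensing pathway

    empty DNA -> ORC bound -> OCCM (ORC-Cdc6-Cdt1-Mcm2-7, low FRET)
    -> Orc6 tether formed (high FRET) -> Cdt1 released (tether retained)
    -> double-hexamer path or ORC release -> lone Mcm2-7 -> empty

plus a branch in which Cdt1 is released before any tether forms, after which
ORC leaves quickly.  Exit rates are parameterized as ln2 / median so that the
stage medians equal the measured dwell medians for each construct; mutant and
phosphorylated-ORC presets alter only rates and branch probabilities (and,
for the Orc6 dN construct, the high-FRET efficiency), never the emission
physics.  Cdt1-labeled presets carry one extra acceptor before Cdt1 release,
so release halves the red-excited signal.

The MO-complex preset models the alternative labeling geometry (donor on the
Orc6 C-terminus, acceptor on the Mcm3 N-terminus): low FRET in the OCCM and
a high-FRET state only once ORC flips onto the Mcm2-7 N-tier.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from .errors import ConfigurationError
from .scheme import KineticScheme
from .trace import AcquisitionConfig, EmissionParams

__all__ = ["Preset", "PRESET_NAMES", "get_preset", "build_loading_scheme"]

LN2 = math.log(2.0)

#: FRET efficiencies of the two observed states in the tether assay.
E_LOW = 0.33
E_HIGH = 0.71

#: Median single-Mcm2-7 lifetime on DNA after ORC release, seconds.
LONE_MCM_MEDIAN_S = 11.2


def build_loading_scheme(
    *,
    tether_prob: float = 0.92,
    occm_median_s: float = 7.2,
    tether_pre_release_median_s: float = 16.9,
    retention_median_s: float = 23.8,
    untethered_retention_median_s: float = 3.8,
    dh_prob: float = 0.25,
    e_low: float = E_LOW,
    e_high: float = E_HIGH,
    cdt1_labeled: bool = False,
    orc_arrival_median_s: float = 10.0,
    orc_alone_median_s: float = 14.0,
    mcm_recruit_prob: float = 0.8,
) -> KineticScheme:
    """Assemble the tether-assay kinetic scheme from stage medians.

    ``occm_median_s`` sets the waiting time in the low-FRET OCCM, after which
    the event branches: with ``tether_prob`` the Orc6 tether (high FRET)
    forms; otherwise Cdt1 is released without a tether and ORC departs with
    median ``untethered_retention_median_s``.  Tethered events release Cdt1
    after ``tether_pre_release_median_s`` and then either go on to a stable
    loaded state (probability ``dh_prob``; signals persist to the end of the
    recording) or release ORC with median ``retention_median_s``.
    """
    if not (0.0 <= tether_prob <= 1.0 and 0.0 <= dh_prob <= 1.0):
        raise ConfigurationError("branch probabilities must lie in [0, 1]")
    red_pre = 2 if cdt1_labeled else 1  # Mcm label + optional Cdt1 label

    states = [
        "empty",
        "orc_dna",
        "occm",
        "tethered_occm",
        "tethered_postcdt1",
        "untethered_postcdt1",
        "loaded",
        "lone_mcm",
        "empty_end",
    ]
    return KineticScheme(
        state_names=tuple(states),
        exit_rate={
            "empty": LN2 / orc_arrival_median_s,
            "orc_dna": LN2 / orc_alone_median_s,
            "occm": LN2 / occm_median_s,
            "tethered_occm": LN2 / tether_pre_release_median_s,
            "tethered_postcdt1": LN2 / retention_median_s,
            "untethered_postcdt1": LN2 / untethered_retention_median_s,
            "loaded": 0.0,
            "lone_mcm": LN2 / LONE_MCM_MEDIAN_S,
            "empty_end": 0.0,
        },
        transition_probs={
            "empty": {"orc_dna": 1.0},
            "orc_dna": {"occm": mcm_recruit_prob, "empty": 1.0 - mcm_recruit_prob},
            "occm": {
                "tethered_occm": tether_prob,
                "untethered_postcdt1": 1.0 - tether_prob,
            },
            "tethered_occm": {"tethered_postcdt1": 1.0},
            "tethered_postcdt1": {"loaded": dh_prob, "lone_mcm": 1.0 - dh_prob},
            "untethered_postcdt1": {"lone_mcm": 1.0},
            "lone_mcm": {"empty_end": 1.0},
        },
        fret_efficiency={
            "empty": None,
            "orc_dna": None,
            "occm": e_low,
            "tethered_occm": e_high,
            "tethered_postcdt1": e_high,
            "untethered_postcdt1": e_low,
            "loaded": e_high,
            "lone_mcm": None,
            "empty_end": None,
        },
        green_dyes={s: (1 if s in _GREEN_STATES else 0) for s in states},
        red_dyes={
            "empty": 0,
            "orc_dna": 0,
            "occm": red_pre,
            "tethered_occm": red_pre,
            "tethered_postcdt1": 1,
            "untethered_postcdt1": 1,
            "loaded": 1,
            "lone_mcm": 1,
            "empty_end": 0,
        },
        initial_state="empty",
    )


_GREEN_STATES = {
    "orc_dna",
    "occm",
    "tethered_occm",
    "tethered_postcdt1",
    "untethered_postcdt1",
    "loaded",
    "mo_search",
    "mo",
}

#: States in which the Orc6 tether (high-FRET interaction) is present;
#: used by ground-truth oracles in tests and reports.
TETHERED_STATES = frozenset({"tethered_occm", "tethered_postcdt1", "loaded", "tether"})

#: States in which Mcm2-7 (the red-labeled helicase) is on the DNA.
MCM_STATES = frozenset(
    {
        "occm",
        "tethered_occm",
        "tethered_postcdt1",
        "untethered_postcdt1",
        "loaded",
        "lone_mcm",
        "mo_search",
        "mo",
    }
)


def build_validation_scheme(
    *,
    formation_median_s: float = 30.0,
    duration_median_s: float = 40.0,
    post_low_median_s: float = 60.0,
) -> KineticScheme:
    """Idealized linear chain for parameter-recovery validation.

    One exponential stage per recovered quantity — time to tether formation
    is the OCCM dwell, tether duration is a single tether state — with no
    branching, so each pipeline median has the closed form ln2/k.  After the
    tether a long low-FRET state keeps both species bound: the high interval
    therefore ends by a FRET drop rather than a departure, and the
    stable-recruitment filter (co-presence >= 5 frames) conditions on the
    long total co-presence instead of on the dwells being measured, which
    would otherwise bias the conditional medians upward.  Stage medians
    default to many frame cycles so quantization is small against the
    sampling error of a 200-spot cohort.
    """
    states = ("empty", "orc_dna", "occm", "tether", "post_low", "lone_mcm", "empty_end")
    both_bound = ("occm", "tether", "post_low")
    return KineticScheme(
        state_names=states,
        exit_rate={
            "empty": LN2 / 15.0,
            "orc_dna": LN2 / 12.0,
            "occm": LN2 / formation_median_s,
            "tether": LN2 / duration_median_s,
            "post_low": LN2 / post_low_median_s,
            "lone_mcm": LN2 / LONE_MCM_MEDIAN_S,
            "empty_end": 0.0,
        },
        transition_probs={
            "empty": {"orc_dna": 1.0},
            "orc_dna": {"occm": 1.0},
            "occm": {"tether": 1.0},
            "tether": {"post_low": 1.0},
            "post_low": {"lone_mcm": 1.0},
            "lone_mcm": {"empty_end": 1.0},
        },
        fret_efficiency={
            "empty": None,
            "orc_dna": None,
            "occm": E_LOW,
            "tether": E_HIGH,
            "post_low": E_LOW,
            "lone_mcm": None,
            "empty_end": None,
        },
        green_dyes={s: int(s in ("orc_dna",) + both_bound) for s in states},
        red_dyes={s: int(s in both_bound + ("lone_mcm",)) for s in states},
        initial_state="empty",
    )


def build_mo_scheme(
    *,
    mo_prob: float = 0.7,
    mo_formation_median_s: float = 8.3,
    mo_lifetime_median_s: float = 30.0,
    dh_prob: float = 0.4,
    e_low: float = 0.20,
    e_high: float = 0.80,
) -> KineticScheme:
    """MO-complex assay scheme (Orc6C donor / Mcm3N acceptor labeling).

    FRET is low through the OCCM and the post-Cdt1 search, and high only in
    the MO complex, which forms with median ``mo_formation_median_s`` after
    Cdt1 release.  The high-FRET efficiency of the MO state is not pinned by
    the tether-assay calibration and is configurable.
    """
    states = [
        "empty",
        "orc_dna",
        "occm",
        "mo_search",
        "mo",
        "loaded",
        "lone_mcm",
        "empty_end",
    ]
    return KineticScheme(
        state_names=tuple(states),
        exit_rate={
            "empty": LN2 / 10.0,
            "orc_dna": LN2 / 14.0,
            "occm": LN2 / 7.2,
            "mo_search": LN2 / mo_formation_median_s,
            "mo": LN2 / mo_lifetime_median_s,
            "loaded": 0.0,
            "lone_mcm": LN2 / LONE_MCM_MEDIAN_S,
            "empty_end": 0.0,
        },
        transition_probs={
            "empty": {"orc_dna": 1.0},
            "orc_dna": {"occm": 0.8, "empty": 0.2},
            "occm": {"mo_search": 1.0},
            "mo_search": {"mo": mo_prob, "lone_mcm": 1.0 - mo_prob},
            "mo": {"loaded": dh_prob, "lone_mcm": 1.0 - dh_prob},
            "lone_mcm": {"empty_end": 1.0},
        },
        fret_efficiency={
            "empty": None,
            "orc_dna": None,
            "occm": e_low,
            "mo_search": e_low,
            "mo": e_high,
            "loaded": e_high,
            "lone_mcm": None,
            "empty_end": None,
        },
        green_dyes={s: (1 if s in _GREEN_STATES or s == "loaded" else 0) for s in states},
        red_dyes={
            s: (1 if s in ("occm", "mo_search", "mo", "loaded", "lone_mcm") else 0)
            for s in states
        },
        initial_state="empty",
    )


@dataclass(frozen=True)
class Preset:
    name: str
    scheme: KineticScheme
    cdt1_labeled: bool
    description: str
    labeling: dict = field(default_factory=dict)
    acquisition: AcquisitionConfig = field(default_factory=AcquisitionConfig)
    emission: EmissionParams = field(default_factory=EmissionParams)


def _tether_labeling() -> dict:
    return {"donor": "ORC(Orc6N)-550", "acceptor": "Mcm2-7(Mcm6N)-650"}


def _make_presets() -> dict[str, Preset]:
    presets: dict[str, Preset] = {}

    def add(name, scheme, cdt1_labeled, description, labeling):
        presets[name] = Preset(
            name=name,
            scheme=scheme,
            cdt1_labeled=cdt1_labeled,
            description=description,
            labeling=labeling,
        )

    add(
        "wt",
        build_loading_scheme(),
        False,
        "Wild-type ORC and Mcm2-7; tether forms in ~92% of events with the "
        "measured stage medians (7.2 s to form, 16.9 s tethered before Cdt1 "
        "release, 23.8 s ORC retention after release).",
        _tether_labeling(),
    )
    add(
        "orc6dN",
        build_loading_scheme(
            tether_prob=0.82, retention_median_s=3.4, dh_prob=0.01, e_high=0.62
        ),
        False,
        "Orc6 N-domain deletion: slightly fewer tether events, lower "
        "high-FRET efficiency (0.62), rapid ORC release after Cdt1 release.",
        _tether_labeling(),
    )
    add(
        "orc6lnk1scr",
        build_loading_scheme(
            tether_prob=0.75,
            occm_median_s=14.4,
            tether_pre_release_median_s=6.0,
            retention_median_s=5.4,
            dh_prob=0.13,
        ),
        False,
        "Orc6 lnk1 scramble: twofold slower tether formation, shorter "
        "tether dwells, intermediate long-retention subpopulation.",
        _tether_labeling(),
    )
    add(
        "orc6dN_lnk1scr",
        build_loading_scheme(
            tether_prob=0.044,
            tether_pre_release_median_s=3.0,
            retention_median_s=3.1,
            dh_prob=0.0,
        ),
        False,
        "Orc6 dN + lnk1 scramble: tether formation nearly abolished.",
        _tether_labeling(),
    )
    add(
        "orc_cdk",
        build_loading_scheme(
            tether_prob=0.539,
            occm_median_s=16.0,
            tether_pre_release_median_s=5.0,
            retention_median_s=4.7,
            dh_prob=0.05,
        ),
        False,
        "CDK-phosphorylated ORC: delayed formation, shortened tether "
        "lifetime, about half of recruitments ever reach high FRET.",
        _tether_labeling(),
    )
    add(
        "cdt1_labeled_wt",
        build_loading_scheme(cdt1_labeled=True),
        True,
        "Wild type with Cdt1 carrying a second acceptor: red-excited signal "
        "starts at two dyes and halves at Cdt1 release.",
        {**_tether_labeling(), "extra_acceptor": "Cdt1(C)-650"},
    )
    add(
        "mo_assay",
        build_mo_scheme(),
        False,
        "MO-complex assay labeling (Orc6C donor, Mcm3N acceptor): high FRET "
        "reports MO formation rather than the Orc6 tether.",
        {"donor": "ORC(Orc6C)-550", "acceptor": "Mcm2-7(Mcm3N)-650"},
    )
    return presets


_PRESETS = _make_presets()
PRESET_NAMES = tuple(_PRESETS)


def get_preset(name: str) -> Preset:
    try:
        return _PRESETS[name]
    except KeyError:
        raise ConfigurationError(
            f"unknown preset {name!r}; choose one of {', '.join(PRESET_NAMES)}"
        ) from None
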