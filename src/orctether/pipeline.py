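"""Run orchestration: simulate -> preprocess -> call states -> summarize.

A :class:`RunConfig` (usually loaded from YAML) drives the whole pipeline;
the seed is mandatory and every stochastic step (simulation, bootstraps)
derives its generator from it, so identical configs produce byte-identical
output files.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .errors import ConfigurationError
from . import io as oio
from .kinetics import (
    efret_heatmap,
    formation_fraction,
    interaction_duration,
    retention_after_cdt1,
    tether_vs_cdt1_offsets,
    time_to_formation,
)
from .oracle import ground_truth_events
from .preprocess import (
    correct_background,
    detect_cdt1_release,
    detect_presence,
    extract_events,
    prune_spurious_intervals,
)
from .simulate import Cohort, generate_cohort
from .state_calling import (
    StateCall,
    call_high_state,
    compute_efret,
    determine_threshold,
    stable_recruitment_filter,
)
from .trace import SpotTrace
from .worked_examples import reproduce_worked_examples

__all__ = [
    "RunConfig",
    "AnalysisResult",
    "analyze_traces",
    "run_simulate",
    "run_analyze",
    "render_report",
    "reproduce_worked_examples",
]


@dataclass
class RunConfig:
    """Configuration of one simulate/analyze run."""

    seed: int
    preset: str = "wt"
    n_spots: int = 50
    n_cycles: int | None = None
    traces: str | None = None  # analyze an existing trace table instead
    cdt1_labeled: bool | None = None
    threshold: float | None = None
    threshold_sd: float = 3.0
    baseline_window: int = 10
    min_stable_cycles: int = 5
    n_boot: int = 1000
    outdir: str = "orctether_out"
    emission: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if "seed" not in raw:
            raise ConfigurationError("config must set an explicit seed")
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ConfigurationError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**raw)

    def hash(self) -> str:
        """Digest of every numerics-affecting field (output location excluded)."""
        d = asdict(self)
        d.pop("outdir", None)
        blob = json.dumps(d, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


@dataclass
class AnalysisResult:
    """Everything the analysis stage produces for one cohort."""

    events: list
    calls: list[StateCall]
    threshold: float
    summaries: dict
    exclusions: dict[str, str]
    cdt1_labeled: bool


def _preprocess_spot(trace: SpotTrace, cfg: RunConfig):
    corr = correct_background(trace, baseline_window=cfg.baseline_window)
    sd = corr.meta["noise_sd"]
    sd_green = float(np.hypot(sd["I_DexDem"], sd["I_DexAem"]))
    green = detect_presence(corr.donor_total, sd_green, cfg.threshold_sd)
    green = prune_spurious_intervals(green, corr.donor_total, sd_green)
    red = detect_presence(corr.I_AexAem, sd["I_AexAem"], cfg.threshold_sd)
    red = prune_spurious_intervals(red, corr.I_AexAem, sd["I_AexAem"])
    ev = extract_events(corr, green, red)
    return corr, ev, sd_green


def analyze_traces(
    traces: list[SpotTrace],
    cfg: RunConfig,
    cdt1_labeled: bool = False,
) -> AnalysisResult:
    """Run preprocessing, state calling, and kinetic summaries on a cohort.

    The E_FRET threshold is fitted once per cohort from the pooled defined E
    values (or taken from ``cfg.threshold``); all bootstraps are seeded from
    ``cfg.seed``.
    """
    corrected, events, floors = [], [], []
    exclusions: dict[str, str] = {}
    for t in traces:
        corr, ev, sd_green = _preprocess_spot(t, cfg)
        if cdt1_labeled and ev.mcm_interval is not None:
            t_rel, bleach = detect_cdt1_release(corr, ev.mcm_interval)
            ev.cdt1_release_s = t_rel
            ev.bleach_suspected = bleach
        corrected.append(corr)
        events.append(ev)
        floors.append(5.0 * sd_green)
        if ev.orc_interval is None:
            exclusions[t.spot_id] = "no ORC presence detected"
        elif ev.mcm_interval is None:
            exclusions[t.spot_id] = "no Mcm2-7 co-occurrence with ORC"

    efrets = [
        compute_efret(corr, ev.copresence_interval(), total_floor=floor)
        for corr, ev, floor in zip(corrected, events, floors)
    ]
    if cfg.threshold is not None:
        threshold = float(cfg.threshold)
    else:
        pool = np.concatenate([e[np.isfinite(e)] for e in efrets]) if efrets else np.array([])
        threshold = determine_threshold(pool)

    calls = []
    for corr, ev, e in zip(corrected, events, efrets):
        stable = stable_recruitment_filter(ev, cfg.min_stable_cycles)
        if ev.copresence_interval() is not None and not stable:
            exclusions.setdefault(
                corr.spot_id, "co-presence shorter than stable-recruitment filter"
            )
        calls.append(
            StateCall(
                spot_id=corr.spot_id,
                efret=e,
                threshold=threshold,
                high_intervals=call_high_state(e, threshold),
                stable_recruitment=stable,
                copresence=ev.copresence_interval(),
                dt=corr.dt,
                t0=float(corr.time_s[0]) if corr.n_cycles else 0.0,
            )
        )

    seeds = np.random.SeedSequence(cfg.seed).spawn(5)
    rngs = [np.random.default_rng(s) for s in seeds]
    summaries = {
        "n_spots": len(traces),
        "n_recruitment_events": sum(ev.mcm_interval is not None for ev in events),
        "n_stable": sum(c.stable_recruitment for c in calls),
        "threshold": threshold,
        "formation": formation_fraction(calls),
        "time_to_formation": time_to_formation(calls, events, cfg.n_boot, rngs[0]),
        "duration": interaction_duration(calls, True, cfg.n_boot, rngs[1]),
        "offsets": (
            tether_vs_cdt1_offsets(calls, events, cfg.n_boot, rngs[2])
            if cdt1_labeled
            else None
        ),
        "retention": (
            retention_after_cdt1(calls, events, cfg.n_boot, rngs[3])
            if cdt1_labeled
            else None
        ),
        "heatmap": efret_heatmap(calls, events, n_boot=cfg.n_boot, rng=rngs[4]),
    }
    return AnalysisResult(
        events=events,
        calls=calls,
        threshold=threshold,
        summaries=summaries,
        exclusions=exclusions,
        cdt1_labeled=cdt1_labeled,
    )


def truth_deltas(result: AnalysisResult, cohort: Cohort) -> dict[str, float]:
    """Median |detected - true| per event time, in seconds (oracle mode)."""
    truths = {
        t.spot_id: ground_truth_events(t.truth, cohort.scheme)
        for t in cohort.traces
        if t.truth is not None
    }
    pairs = {
        "mcm_arrival_s": lambda ev, c: ev.mcm_arrival_s,
        "orc_arrival_s": lambda ev, c: ev.orc_arrival_s,
        "cdt1_release_s": lambda ev, c: ev.cdt1_release_s,
        "tether_start_s": lambda ev, c: (
            c.high_intervals_s[0][0] if c.formed else None
        ),
    }
    deltas: dict[str, float] = {}
    for name, getter in pairs.items():
        ds = []
        for ev, call in zip(result.events, result.calls):
            tru = truths.get(ev.spot_id)
            if tru is None:
                continue
            true_val = getattr(tru, {"tether_start_s": "tether_start_s"}.get(name, name))
            est = getter(ev, call)
            if est is not None and true_val is not None:
                ds.append(abs(est - true_val))
        if ds:
            deltas[name] = float(np.median(ds))
    return deltas


def _fmt_dwell(d) -> str:
    if d is None:
        return "n/a (no qualifying events)"
    s = f"median {d.median:.1f} ± {d.se_median:.1f} s (n={d.n}"
    if d.n_censored:
        s += f", {d.n_censored} censored"
    return s + ")"


def render_report(result: AnalysisResult) -> str:
    """Human-readable run report covering every summary section."""
    s = result.summaries
    lines = [
        "orctether run report",
        "====================",
        f"spots analyzed:            {s['n_spots']}",
        f"Mcm2-7 recruitment events: {s['n_recruitment_events']}",
        f"stably recruited (>=5 cycles co-presence): {s['n_stable']}",
        f"E_FRET threshold:          {s['threshold']:.3f}",
        "",
        "Tether formation",
        "----------------",
    ]
    f = s["formation"]
    if f is None:
        lines.append("n/a (no stably recruited events)")
    else:
        lines.append(f"formed high-FRET state: {f.as_string(1, with_se=False)} ({f.k}/{f.n})")
    lines += [
        "",
        "Time to tether formation (from Mcm2-7 arrival)",
        "----------------------------------------------",
        _fmt_dwell(s["time_to_formation"]),
        "",
        "Tether interaction duration (first interval)",
        "--------------------------------------------",
        _fmt_dwell(s["duration"]),
        "",
        "Tether formation vs Cdt1 release",
        "--------------------------------",
    ]
    off = s["offsets"]
    if off is None:
        lines.append("n/a (Cdt1 not labeled in this cohort)")
    else:
        lines.append(
            f"offset (formation - release): {_fmt_dwell(off.summary)}; "
            f"tether first in {off.n_tether_first}/{len(off.offsets)} events "
            f"({off.n_excluded} excluded)"
        )
    lines += ["", "ORC retention after Cdt1 release", "--------------------------------"]
    ret = s["retention"]
    if ret is None:
        lines.append("n/a (Cdt1 not labeled in this cohort)")
    else:
        for g, (curve, med) in ret.groups.items():
            lines.append(f"{g}-FRET at release: {_fmt_dwell(med)}")
        for label, fs in [
            (f"released within 1 cycle ({ret.cycle_s:.1f} s)", ret.released_within_1_cycle),
            (f"released within 3 cycles ({3 * ret.cycle_s:.1f} s)", ret.released_within_3_cycles),
            ("retained > 100 s", ret.retained_over_100s),
        ]:
            if fs is not None:
                lines.append(f"{label}: {fs.as_string(0)} ({fs.k}/{fs.n})")
        lines.append(f"excluded (ORC absent at release): {ret.n_excluded}")
    hm = s["heatmap"]
    lines += ["", "E_FRET heat map", "---------------"]
    if hm is None:
        lines.append("n/a (no stable events)")
    else:
        lines.append(
            f"{hm.n_spots} molecules, {hm.density.shape[1]} time bins x "
            f"{hm.density.shape[0]} E bins"
        )
    if result.exclusions:
        lines += ["", "Per-spot exclusions", "-------------------"]
        for sid in sorted(result.exclusions):
            lines.append(f"{sid}: {result.exclusions[sid]}")
    return "\n".join(lines) + "\n"


def summary_json(result: AnalysisResult) -> dict:
    """Machine-readable summary (numbers only) for the run report."""
    s = result.summaries
    out: dict = {
        "n_spots": s["n_spots"],
        "n_recruitment_events": s["n_recruitment_events"],
        "n_stable": s["n_stable"],
        "threshold": s["threshold"],
    }
    if s["formation"] is not None:
        f = s["formation"]
        out["formation"] = {"k": f.k, "n": f.n, "pct": f.pct, "se_pct": f.se_pct}
    for key in ("time_to_formation", "duration"):
        d = s[key]
        if d is not None:
            out[key] = {
                "median_s": d.median,
                "se_median_s": d.se_median,
                "n": d.n,
                "n_censored": d.n_censored,
            }
    if s["offsets"] is not None:
        off = s["offsets"]
        out["offsets"] = {
            "median_s": off.summary.median,
            "se_median_s": off.summary.se_median,
            "n": len(off.offsets),
            "n_tether_first": off.n_tether_first,
        }
    if s["retention"] is not None:
        ret = s["retention"]
        out["retention"] = {
            g: {"km_median_s": med.median, "se_median_s": med.se_median, "n": med.n}
            for g, (curve, med) in ret.groups.items()
        }
        for name, fs in [
            ("released_within_1_cycle", ret.released_within_1_cycle),
            ("released_within_3_cycles", ret.released_within_3_cycles),
            ("retained_over_100s", ret.retained_over_100s),
        ]:
            if fs is not None:
                out["retention"][name] = {"k": fs.k, "n": fs.n, "pct": fs.pct}
        out["retention"]["n_excluded"] = ret.n_excluded
    return out


def run_simulate(cfg: RunConfig, outdir=None) -> Cohort:
    """Simulate the configured cohort and write traces + ground truth."""
    from .trace import EmissionParams

    emission = EmissionParams(**cfg.emission) if cfg.emission else None
    cohort = generate_cohort(
        cfg.preset,
        cfg.n_spots,
        cfg.seed,
        n_cycles=cfg.n_cycles,
        emission=emission,
        cdt1_labeled=cfg.cdt1_labeled,
    )
    out = Path(outdir or cfg.outdir)
    out.mkdir(parents=True, exist_ok=True)
    header = {"config_hash": cfg.hash(), "seed": cfg.seed, "preset": cfg.preset}
    oio.write_traces(cohort.traces, out / "traces.tsv", header)
    oio.write_truth(cohort.traces, out / "truth_states.tsv", out / "truth_bleach.tsv")
    meta = cohort.metadata()
    meta["config_hash"] = cfg.hash()
    (out / "metadata.yaml").write_text(yaml.safe_dump(meta, sort_keys=True))
    return cohort


def run_analyze(
    cfg: RunConfig,
    traces: list[SpotTrace] | None = None,
    cohort: Cohort | None = None,
    outdir=None,
) -> AnalysisResult:
    """Analyze a cohort (in memory or from ``cfg.traces``) and write results."""
    cdt1_labeled = cfg.cdt1_labeled
    if traces is None:
        if cohort is not None:
            traces = cohort.traces
            if cdt1_labeled is None:
                cdt1_labeled = cohort.cdt1_labeled
        elif cfg.traces is not None:
            traces = oio.read_traces(cfg.traces)
        else:
            raise ConfigurationError("no traces: set cfg.traces or pass a cohort")
    if cdt1_labeled is None and cfg.preset is not None:
        from .presets import get_preset

        cdt1_labeled = get_preset(cfg.preset).cdt1_labeled
    result = analyze_traces(traces, cfg, cdt1_labeled=bool(cdt1_labeled))
    out = Path(outdir or cfg.outdir)
    out.mkdir(parents=True, exist_ok=True)
    header = {"config_hash": cfg.hash(), "seed": cfg.seed}
    oio.write_events(result.events, out / "events.tsv", header)
    oio.write_calls(result.calls, out / "calls.tsv", header)
    report = render_report(result)
    if cohort is not None and any(t.truth is not None for t in cohort.traces):
        deltas = truth_deltas(result, cohort)
        report += "\nGround-truth comparison (median |delta|, s)\n"
        report += "-------------------------------------------\n"
        for k in sorted(deltas):
            report += f"{k}: {deltas[k]:.2f}\n"
    (out / "summary.txt").write_text(report)
    (out / "summary.json").write_text(
        json.dumps(
            {"config_hash": cfg.hash(), "seed": cfg.seed, **summary_json(result)},
            indent=2,
            sort_keys=True,
        )
        + "\n"
    )
    hm = result.summaries["heatmap"]
    if hm is not None:
        import pandas as pd

        df = pd.DataFrame(
            hm.density,
            index=[f"{e:.2f}" for e in hm.e_edges[:-1]],
            columns=[f"{t:.1f}" for t in hm.time_edges_s[:-1]],
        )
        oio.write_table(
            df.reset_index().rename(columns={"index": "e_bin_low"}),
            out / "heatmap.tsv",
            {**header, "e_bin_width": "0.05", "time_bin_s": f"{hm.time_edges_s[1]:.1f}"},
        )
    return result
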