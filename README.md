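# orctether

Simulation and analysis of single-molecule colocalization/FRET recordings of
eukaryotic helicase loading — specifically, the transient "Orc6 tether"
between the Orc6 N-terminal region of ORC and the N-tier of the Mcm2-7
helicase that keeps ORC at the loading site while it switches binding sites
between the OCCM and MO intermediates.

The package is for people who work with CoSMoS/smFRET trace data of this
kind: it turns per-spot, three-channel intensity time series into binding
events, FRET-state calls, and cohort kinetics, and it ships a synthetic
trace generator that simulates the full loading pathway so every stage of
the analysis can be validated against ground truth without raw microscope
data.

## The measurement and the statistics it yields

Acquisition alternates donor (532 nm) and acceptor (633 nm) excitation,
~2.6 s per frame cycle, giving three channels per DNA spot: donor-excited
donor emission `I(Dex,Dem)`, donor-excited acceptor emission `I(Dex,Aem)`,
and acceptor-excited acceptor emission `I(Aex,Aem)`.  Per frame, the
apparent FRET efficiency is

    E_FRET = I(Dex,Aem) / (I(Dex,Dem) + I(Dex,Aem))

Low (`E ≈ 0.33`) and high (`E ≈ 0.71`) states are separated by a per-cohort
threshold at the equal-posterior point of a two-Gaussian mixture fit, and a
tether interval is called by two-frame hysteresis: it starts at the first of
two consecutive frames above threshold and ends at the first of two
consecutive frames below.  On top of the calls the package computes:

* fraction of stably recruited Mcm2-7 (≥ 5 frames ORC/Mcm co-presence) that
  form the tether, with binomial SE `100·sqrt(p(1−p)/n)`;
* time to tether formation after Mcm2-7 arrival, and tether duration
  (median ± bootstrap SE);
* Cdt1-release times from the 2:1 halving of the red-excited signal when
  Cdt1 carries a second acceptor (exhaustive least-squares changepoint with
  a 2:1 level constraint);
* tether-vs-release offsets, and ORC retention after Cdt1 release as
  Kaplan–Meier curves segregated by tether state at release;
* the cohort E_FRET heat map over time since Mcm2-7 arrival, normalized per
  time bin over molecules still co-present.

## Worked example

Simulate a 100-spot wild-type cohort with Cdt1 labeled and analyze it:

```
$ cat demo.yaml
preset: cdt1_labeled_wt
n_spots: 100
n_cycles: 200
seed: 11
outdir: wt_demo

$ orctether simulate -c demo.yaml
wrote 100 spots to wt_demo
$ orctether analyze -c demo.yaml -i wt_demo/traces.tsv
orctether run report
====================
spots analyzed:            100
Mcm2-7 recruitment events: 84
stably recruited (>=5 cycles co-presence): 79
E_FRET threshold:          0.573

Tether formation
----------------
formed high-FRET state: 91.1% (72/79)

Time to tether formation (from Mcm2-7 arrival)
----------------------------------------------
median 7.8 ± 1.3 s (n=72)

Tether formation vs Cdt1 release
--------------------------------
offset (formation - release): median -20.8 ± 3.1 s (n=69); tether first in 62/69 events (10 excluded)

ORC retention after Cdt1 release
--------------------------------
high-FRET at release: median 44.2 ± 13.5 s (n=64, 15 censored)
low-FRET at release: median 7.8 ± 6.7 s (n=14)
released within 1 cycle (2.6 s): 5 ± 3% (4/78)
released within 3 cycles (7.8 s): 21 ± 5% (16/78)
retained > 100 s: 28 ± 5% (22/78)
excluded (ORC absent at release): 2
```

Reading it: 91.1% of stably recruited helicases formed the high-FRET tether,
with a median 7.8 s (three frames) after recruitment — the generator's
formation median is 7.2 s, and the report recovers it to frame resolution.
The tether formed a median 20.8 s before Cdt1 release (negative offset =
tether first), and ORC retention after release is far longer when the tether
was present at release (44.2 s vs 7.8 s), the signature of the tether
holding ORC at the loading site.  `orctether report -c demo.yaml` produces
the same numbers plus figures (per-spot trace panels, the E_FRET heat map,
retention survival curves), and every output embeds the config hash and
seed; identical configs give byte-identical tables.

Mutant and phospho-ORC presets (`orc6dN`, `orc6lnk1scr`, `orc6dN_lnk1scr`,
`orc_cdk`) and the MO-complex labeling geometry (`mo_assay`) differ only in
kinetic rates and labeling; `orctether reproduce` recomputes the package's
reference table of per-construct fractions from raw counts and checks the
formatted output of the binomial-SE model against each expected string.

As a library:

```python
import orctether as ot
cohort = ot.generate_cohort("cdt1_labeled_wt", 100, rng_seed=11)
result = ot.analyze_traces(cohort.traces, ot.RunConfig(seed=11), cdt1_labeled=True)
print(result.summaries["formation"].as_string(1, with_se=False))  # e.g. 91.1%
```

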