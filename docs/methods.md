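# Methods

`orctether` simulates and analyzes two-color, alternating-excitation
single-molecule recordings of helicase loading: a donor fluorophore on the
Orc6 N-terminal region of ORC, an acceptor on the Mcm2-7 N-tier (and
optionally a second acceptor on Cdt1).  The quantity of interest is the
"Orc6 tether" — a transient Orc6N–Mcm2-7N interaction read out as a high
apparent FRET efficiency — and its kinetics relative to Mcm2-7 recruitment
and Cdt1 release.  This note records the model, the conventions, and the
design choices, in enough detail to reproduce or audit any number the
package emits.

## Generative model

### Kinetic scheme

Loading events are modeled as a continuous-time Markov chain over labeled
intermediates.  Each state has an exponential exit rate (1/s; 0 = absorbing),
a categorical successor distribution, a true FRET efficiency `E` (defined
only when both labeled species are present), and integer donor/acceptor dye
counts.  The default pathway is

    empty → ORC bound → OCCM (E = 0.33) → tether formed (E = 0.71)
          → Cdt1 released, tether retained (E = 0.71)
          → stably loaded (absorbing) or ORC released → lone Mcm2-7 → empty

with a minor branch in which Cdt1 release precedes tether formation and ORC
then leaves quickly.  Dwell times in every state are exponential.  The data
do not constrain the dwell-shape beyond the medians, so single-exponential
stages are an assumption, made explicit here; multi-step (peaked) dwells
would be conservative for the recovery checks but are not modeled.

Stage rates are parameterized as `ln2 / median`, using the measured stage
medians for the wild-type system:

| stage                        | median (s) | rate (1/s) |
|------------------------------|-----------|------------|
| tether formation after Mcm2-7 recruitment | 7.2  | 0.0963 |
| tether dwell before Cdt1 release          | 16.9 | 0.0410 |
| ORC retention after Cdt1 release (tethered) | 23.8 | 0.0291 |
| ORC retention after Cdt1 release (untethered) | 3.8 | 0.182 |
| lone Mcm2-7 lifetime                      | 11.2 | 0.0619 |

Note these stage medians imply a simulated total tether duration
(formation → ORC release) with median near 40 s; the package makes no claim
that this equals any independently measured total-duration median, and no
test compares against one.

Mutant and phosphorylated-ORC presets change only branch probabilities and
rates (and, for the Orc6 ΔN construct, the high-FRET value, 0.62):
`orc6dN`, `orc6lnk1scr`, `orc6dN_lnk1scr` (tether probability 0.044),
`orc_cdk`, `cdt1_labeled_wt` (one extra acceptor before Cdt1 release), and
`mo_assay` (Orc6C-donor / Mcm3N-acceptor geometry, where high FRET reports
the MO complex instead; its high-state E is not pinned by the tether-assay
calibration and defaults to 0.80, configurable).  The fraction of events
entering the long-lived loaded state (0.25 for wild type, near 0 for the
ΔN-containing mutants) produces the long-retention subpopulation.

Every simulated recording opens with 30 s of empty DNA — the protein
flow-in delay of the experiment — which also guarantees a signal-free
stretch for baseline estimation.

### Acquisition and emission

One frame cycle is a 1 s donor-excitation exposure and a 1 s
acceptor-excitation exposure with 0.2 s dead times.  The cycle clock is
2.6 s (0.2 s per-cycle overhead beyond the 2.4 s core), chosen so that one
frame = 2.6 s and three frames = 7.8 s, the frame-to-seconds conversion used
by all summaries.  Default recordings are 200 cycles (520 s).

Noiseless expected intensities per cycle:

* `I(Dex,Dem) = n_donors · B_D · (1 − E)` and `I(Dex,Aem) = n_donors · B_D · E`,
  so total donor-excited emission is conserved across FRET changes;
* `I(Aex,Aem) = n_acceptors · B_A` — with Cdt1 labeled, release halves the
  red-excited signal (2 dyes → 1).

Defaults: `B_D = B_A = 1000` counts/s per dye; per-channel background
100 counts with additive Gaussian noise (sd 50, i.e. 5% of a one-dye
signal); dye photobleaching on independent exponential clocks
(0.001 s⁻¹, started at first appearance); labeling efficiency 1.0.  Frames
straddling a state boundary integrate occupancy over the exposure window.
The second acceptor (Cdt1) does not act as FRET partner; only the Mcm2-7
dye does.  Direct excitation of the acceptor by the donor laser and
spectral bleed-through are omitted (the measured quantity is apparent, not
corrected, FRET); a constant detection efficiency is absorbed into the
brightnesses.

What the generator does **not** emulate: signal-dependent (shot) noise,
spot drift and overlapping spots, multi-step or non-Markovian dwells,
dye blinking beyond one-frame gaps, day-to-day illumination drift.
Passing tests therefore validate the pipeline's correctness and
calibration under these idealized conditions, not its robustness to every
artifact of real recordings.

## Analysis pipeline

1. **Background correction.** Per channel, subtract the median of the
   lowest-mean contiguous 10-cycle window (the unbound stretch).  Noise sd
   is estimated as `1.4826 · MAD(diff)/√2` of successive differences over
   the whole series — robust to steps and, unlike statistics of the selected
   low window, not biased low by the selection.  Traces shorter than the
   window fall back to a global half-sample mode and carry a warning flag.
2. **Presence intervals.** Runs of cycles above 3 noise sds; one-cycle gaps
   (blinking) are bridged, longer gaps split intervals.  ORC presence uses
   total donor-excited emission (`Dem + Aem`), which is FRET-invariant, so
   tether formation cannot masquerade as an ORC departure; Mcm2-7 (and
   Cdt1) presence uses the directly excited acceptor channel.  The pipeline
   additionally discards intervals shorter than 2 cycles unless their peak
   clears 5 sds: a genuine one-frame binding event is ≥ 10 sd, while noise
   excursions barely cross 3 sd, and without this veto a few-hundred-frame
   recording has a substantial chance of a spurious "first interval".
3. **Events.** First green interval = ORC arrival/departure; first red
   interval overlapping it = Mcm2-7 recruitment; a later overlapping red
   interval = second Mcm2-7 arrival.  All intervals are half-open
   `[start, end)` in cycles; times are reported at the start of the cycle in
   which a change is first observed; species bound at the last cycle are
   right-censored.
4. **Cdt1 release.** Exhaustive single-changepoint least-squares scan of the
   red-excited signal within the Mcm2-7 interval, accepted only if the
   post-step level is within ±25% of half the pre-step level (the 2:1
   two-dye/one-dye constraint); a second, later halving marks suspected
   acceptor photobleach.  The exhaustive scan is exact for the
   single-breakpoint model, so no approximate changepoint machinery is
   needed at these trace lengths.
5. **E_FRET and threshold.** `E = Aem/(Dem + Aem)` per cycle inside the
   ORC/Mcm co-presence interval; cycles whose donor-excited total is below
   5× the combined noise sd are undefined (NaN), and E is deliberately not
   clipped to [0, 1] (clipping would bias the mixture fit).  The low/high
   threshold is fitted once per cohort: a two-component Gaussian mixture,
   deterministically initialized at the pooled 25th/75th percentiles, with
   the threshold at the equal-posterior crossing between the means
   (root-found; bracket widened if unequal weights push the crossing
   slightly outside the means).  Fits whose means are closer than half the
   larger sd, or whose mixture density has no dip between the means
   (unimodal pool), raise an error asking for a manual threshold.
6. **State calling.** Symmetric two-frame hysteresis: a high (tether)
   interval starts at the first of ≥ 2 consecutive frames above threshold
   and ends at the first of ≥ 2 consecutive frames below; single-frame
   excursions never switch the state; undefined frames advance neither
   counter.  The entry rule is the published two-consecutive-frames
   criterion; the symmetric exit rule is this package's choice, stated here
   because only entry was specified.  An interval still high when the
   co-presence ends is censored.
7. **Stable recruitment.** Only events with ≥ 5 cycles (13 s) of ORC/Mcm2-7
   co-presence enter per-event statistics.

## Statistics

* **Fractions** are binomial: `pct = 100·k/n`,
  `SE = 100·sqrt(p(1−p)/n)`.  Reported percentages use two-stage
  round-half-up — to two decimals, then to the reporting precision (one
  decimal for formation fractions, integers elsewhere).  This convention
  reproduces the package's reference fraction table exactly, including the
  cases where one-stage rounding would differ in the last digit; the first
  stage is computed in exact integer arithmetic to avoid binary-float
  round-half artifacts.
* **Medians** carry a bootstrap SE and percentile 95% CI (1000 seeded
  resamples).  Whether a "± SE" on a median should be bootstrap-derived is
  itself a convention; it is flagged as such rather than assumed to match
  any external computation.
* **Survival** is Kaplan–Meier (lifelines) with seeded nonparametric
  bootstrap 95% CIs over spots; with no censoring KM equals the empirical
  survival function exactly.  Censored dwell durations are included as
  observed values in median summaries by default, with the censoring count
  reported alongside (the alternative — excluding them — is a flag away);
  KM medians are used wherever a survival curve is reported.
* **Retention after Cdt1 release** is `ORC departure − release`, grouped by
  the called FRET state at the release cycle; spots where ORC was absent at
  release are excluded and tallied; censored spots never count in a
  "released within N frames" numerator; "released within one/three frames"
  means retention ≤ 2.6 s / 7.8 s.
* **Heat map**: E histograms in 0.05 × one-cycle bins, each time column
  normalized over the molecules still co-present at that time (so the
  density tracks surviving complexes), with a bootstrap-CI remaining
  fraction curve.  The 0.05 bin resolves the 0.33/0.71 peaks without
  overbinning.

## Validation design

The parameter-recovery checks simulate 200-spot cohorts from an idealized
linear chain (`build_validation_scheme`) with one exponential stage per
recovered quantity, and require the pipeline median to fall inside the
bootstrap 95% CI of `ln2/k`.  Two deliberate features of that scheme:

* **Stage medians of 30/40/30 s (≥ 11 frames).**  Event times are quantized
  to the 2.6 s frame clock, and arrival (detected at the first frame with
  any occupancy) and formation (detected at the first fully-high frame)
  quantize in opposite directions, leaving a net bias of roughly one frame
  on a time difference.  At ≥ 11-frame medians this is well inside the CI
  of a 200-spot cohort; at few-frame medians it is not, and no analysis of
  frame-clock data could honestly recover them to that precision.
* **A long low-FRET co-bound state after the tether.**  The
  stable-recruitment filter conditions on co-presence ≥ 5 frames; if
  co-presence ended with the tether, the filter would condition on the very
  dwells being measured and inflate their conditional medians (an ~15%
  effect at these rates).  With co-presence extended past the tether, the
  filter selects on total residence instead and the measured dwells stay
  exponential with the nominal rates.  The same consideration applies to
  real data whenever the filter length is comparable to the measured dwell.

Ground-truth equivalence is checked on noiseless cohorts: detected event
times match the simulation sidecar within one frame (boundaries that fall
entirely inside dead time are invisible by construction, so agreement is
required for ≥ 95% of boundaries), and a tether visit can only be missed
by the caller when it is shorter than the three frames needed for two
consecutive high measurements.

## Numerical choices and degenerate inputs

* All randomness flows from a single run seed through `numpy` seed
  sequences; identical configs give byte-identical outputs.
* Mixture fit: `sklearn` GaussianMixture, `n_init=1`, fixed means/weights
  init, fixed random state — deterministic given the pool.
* Empty inputs return explicit empty results (`None`) rather than raising,
  except where a precondition is violated (unnormalized scheme rows,
  missing seed, unknown preset, missing trace columns → configuration
  errors naming the problem).
* Changepoint scan requires ≥ 2 cycles per segment and must beat the
  no-step model, so flat series return "absent".
* A zero-exit-rate state absorbs; a zero-duration simulation is an empty
  path; traces shorter than the baseline window use the fallback baseline.

## Known limitations

* Two-state FRET only; the MO-assay preset reuses the two-state caller, and
  no hidden-Markov or Bayesian state inference is attempted.
* Single 2:1 halving only; multi-step photobleach counting is out of scope.
* The binomial SE and the bootstrap median SE are conventions chosen for
  transparency; other SE models would give slightly different uncertainty
  bands without changing any point estimate.
* Exponential dwells everywhere; if the real formation step is multi-step,
  time-to-formation histograms would be peaked rather than monotone, which
  the presets cannot produce.
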