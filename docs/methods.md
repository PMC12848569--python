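# Methods

This note documents the models, parameter choices and numerical
conventions behind `chorusloop`, and what the synthetic components do and
do not emulate.

## Stimulus synthesis

Calls are synthesized as a whine followed by optional chucks.  The whine
is an exponential frequency sweep — `f(t) = f_start · (f_end/f_start)^(t/T)`
— with an amplitude envelope following the same exponential law down to
`whine_amp_decay` (default 0.25) of peak, reflecting the concurrent
amplitude/frequency descent of natural whines.  An exponential (rather
than linear) law was chosen for its perceptually smooth descent; both are
available via `sweep_law`.  Chucks are band-limited Gaussian-noise bursts
(1.2–3.6 kHz, capped below Nyquist at low rates) with a 2 ms attack and a
decay to 30% of peak, generated from a per-call seed so every render is
bit-reproducible.

The three stimulus calls are synthetic stand-ins for field recordings;
only their total durations are anchored to measured values (low OP
0.428 s < intermediate OP 0.484 s < high OP 0.519 s), and the additional
duration of the longer calls comes from additional chuck notes (low OP
carries one chuck, the other two carry two), matching how duration and
elaboration covary in the originals.  Chuck duration is 60 ms with a
10 ms inter-chuck gap, so the short-latency responses triggered by an
initial chuck's offset (minimum latency 60 ms, below) land inside the
second chuck — the mechanism behind the "restricted" overlap definition.
The interim call (whine 0.31 s + two chucks, 0.44 s total) doubles as the
motif building block once its second chuck is removed (0.37 s, exactly
the synchronous-motif span).

Peak calibration is digital: a scalar gain setting the absolute peak to
0.9 full scale stands in for speaker SPL calibration.  Motifs built by
summing identical call copies are renormalized to the calibration peak
*after* summation.  A consequence worth noting: because identical copies
sum coherently, renormalization makes the overlapping and the
overlapping+synchronous motifs nearly equivalent in integrated
stimulation, and their behavioral effects in the simulation are a
statistical tie (tests treat them as such).

## Motif assembly and the crossfade

Only each motif's composition and total span are specified, so internal
offsets are solved from the span (e.g. the second overlapping copy starts
at 610 − 370 = 240 ms).  Motifs join stimulus calls through a 10 ms
equal-power cos/sin crossfade; this keeps the junction free of
low-amplitude dips, which matters mechanistically — a dip would be a
release from inhibition and would itself trigger calls.  With the
crossfade, a 610 ms motif leads the stimulus onset by exactly 600 ms.

## Trial scheduling

The enumerable design is 3 stimulus calls × 8 silence delays (0.45–1.5 s
in 0.15 s steps) plus 3 × 5 motifs × the 4 delays ≥ 1.05 s (motifs extend
up to 600 ms before the stimulus and must not collide with the trigger
call), i.e. 84 conditions × 5 repetitions = 420 presentations.  Orders
are seeded permutations; per-subject seeds are derived by hashing
(subject id, master seed), so one master seed yields distinct but
reproducible orders across subjects.

## The closed-loop engine

The engine is a four-state machine (warmup → await trigger → await
response → await interim response).  All scheduling is sample-quantized
against the transport clock, so on the deterministic simulated transport
realized stimulus onsets sit exactly at trigger + commanded delay and
interim onsets exactly 0.75 s after response onsets.  The online onset
detector is a windowed-RMS threshold crossing (4 ms windows, threshold
0.05 full scale) with a 0.55 s refractory — longer than any single call,
so chuck notes cannot retrigger it.  Engine timestamps are treated as
provisional; definitive timing comes from offline extraction.

Offline extraction segments each channel into activity regions (fine-hop
RMS above threshold, regions merged across silences shorter than 150 ms,
so within-call gaps never split a call), then refines each region start
to the first supra-threshold sample.  On simulated sessions this recovers
ground-truth onsets to well under a millisecond.  Playback onsets are
aligned to plan directives by order (a count mismatch raises an
alignment error rather than guessing); subject onsets are labeled
trigger/response by replaying the protocol over the aligned times.

## The virtual frog

The virtual caller is a functional model built from qualitative
ingredients: gap detection, a refractory period, an endogenous rhythm,
stimulation-dependent permissiveness, and arousal-driven elaboration.
All functional forms are deliberately minimal and monotone; none is a
fitted sensory model.  Per 5 ms frame the frog receives intensity
(absolute windowed RMS), inhibition (intensity weighted by the
frequency-sensitivity curve), and a conspecific flag (voiced f0 inside
300–950 Hz), and it updates:

* **Stimulation integrals.**  A *generic* integral of intensity (with a
  1.5× weight on conspecific frames) and a *conspecific-only* integral,
  both reset at each of the frog's own calls.
* **Release triggering.**  A call is committed when the per-frame release
  (drop rate of inhibition) exceeds
  `θ·ε / (1 + g_m·stim_generic + g_p·phase)`, where phase is time beyond
  the 0.45 s refractory and ε is a per-cycle lognormal jitter.  Committed
  calls are emitted after a latency `min_latency + scale·σ(...)·jitter`,
  where the logistic σ switches steeply (threshold 0.17 stimulation
  units, width 0.02) on the *conspecific* integral.  This single switch
  produces the two observed response modes: isolated calls and tones get
  ~0.5–0.6 s latencies, conspecific motifs push latency toward the 60 ms
  floor.
* **Endogenous rhythm.**  Absent stimulation the frog calls at
  `N(1.71, 0.12)` s intervals.  During stimulation the endogenous event
  is normally vetoed (the release will trigger instead), but it breaks
  through with probability `0.08 + 0.4·g_m·stim_generic` — the generic
  (tone-inclusive) pathway by which intense stimulation raises overlap.
  A forward-masking envelope (50 ms decay) defines "during stimulation",
  so 10 ms chuck gaps do not count as stimulation offsets.
* **Arousal and elaboration.**  Arousal integrates conspecific intensity
  and decays at 0.15/s in silence; below a floor the frog stops calling
  (mirroring the defensive silence of real males).  Each emitted call's
  elaboration is `inertia·previous + (1−inertia)·f(arousal)` with
  inertia 0.8, giving the strong trigger-to-response elaboration
  correlation, slow escalation under sustained conspecific stimulation,
  and decline over silent stretches.

**Calibration.**  Two parameters were calibrated once against the study
conditions the toolkit is meant to reproduce, using the default stimulus
library: the latency scale (0.50 s) so that dyadic alternation with
interim playback has a median call period of 1.71 s, and the
breakthrough base (0.08) so that the pooled overlap fraction across the
full silence-condition schedule is ≈3.5%.  All other defaults were set
by the mechanistic considerations above and held fixed.

**What the simulation does not emulate.**  Real males vary widely in
baseline overlap propensity, elaboration level and period; the virtual
frog is one "median male" with within-cycle jitter only.  The published
interaction structure on the logit scale (random-effects GLMMs over 39
males) is therefore out of reach by design: recovery tests check the
*signs* of the simulated permissiveness gains (motif and delay main
effects) and the widening of motif–silence differences with delay on the
probability scale, not mixed-model coefficients.  Passing tests show the
pipeline measures what the generator put in — not that the generator is
the animal.

## Trajectories and the sensitivity stand-in

Amplitude trajectories are windowed RMS (10 ms window, 5 ms hop —
resolving 60 ms latencies with ≥10 frames); f0 is estimated per window
by unbiased autocorrelation with parabolic lag refinement.  Among
autocorrelation local maxima within 25% of the global peak the shortest
lag is preferred, which prevents octave-down locking and makes the
tracker follow the fresher, higher-frequency whine where two calls
overlap.  Windows with weak periodicity or low energy are unvoiced
(broadband chucks, silence).

Relative inhibition is `amp(t) · S(f0(t))` rescaled to maximum 1, with
unvoiced frames evaluated at the band-pass centre (broadband sounds
inhibit at full weight).  `S` is the single pluggable stand-in for the
species' fitted sensory model, which is not reproduced here: the default
is a log-Gaussian band-pass centred at 850 Hz with width 0.4 octaves.
Centred near the whine's start, it makes inhibition fall faster than
amplitude as the sweep descends — yielding the moderate release shortly
after whine onsets that gap detection requires — and it weights 1000 Hz
tones at ≈0.84, so tones inhibit strongly.  The release rate is the
negative finite-difference slope clipped at zero.  Inside the virtual
frog's front-end (not in the public trajectory operations) the filled f0
track and the inhibition track are median-filtered (5 and 3 frames) to
suppress single-frame tracker glitches while preserving multi-frame
note-offset releases.

## Response metrics conventions

* Overlap uses the half-open interval `[S, S + duration)`: an onset at
  the exact stimulus offset is alternation (offset-triggered responses
  *are* the alternation mechanism).
* Restricted overlap requires the onset before the end of the initial
  chuck and is defined only for multi-chuck stimuli (it equals the plain
  definition otherwise); it isolates whine-triggered stereotyped overlap
  from chuck-offset-triggered responses landing in the second chuck.
* Chuck amplitude in the elaboration score is the segment *peak*
  relative to the whine peak (a peak-to-peak ratio, gain-invariant).
* Responses preceding the stimulus onset are flagged spontaneous and
  excluded from delay curves but retained in the records.
* Response curves are per-delay medians with seeded bootstrap intervals;
  the period curve is delay + delay-curve by construction, making the
  period − delay identity exact.  This descriptive estimator stands in
  for additive-model smoothing, which is routine and left to external
  tools via `export_model_table`.

## Numerical and testing choices

Simulations run at 8 kHz, where every designed delay, crossfade and
motif duration is an integer number of samples and call energy (< 4 kHz)
is fully representable; synthesis examples and DSP checks use 44.1 kHz.
Closed-loop audio sessions in the tests use shortened warmup blocks and
small plans (tens of presentations); calibration and recovery statistics
use the frame/event-level simulation path (~4000 presentations in a few
seconds), with the audio and event paths sharing the same per-frame frog
update.  The live-device transport is specified as a contract
(`read`/`schedule`/`now`) only; the deterministic simulated transport is
the tested implementation, and real-device jitter is out of scope.

## Known limitations

* Single-male simulation only; no chorus of interacting virtual callers.
* The f0 tracker is a single-source estimator; where two whines overlap
  it follows the dominant/higher source, and the median smoothing hides
  residual ambiguity rather than resolving it.
* The sensitivity curve, latency switch and breakthrough channel are
  caricatures chosen for monotonicity and testability; their parameter
  values are not estimates of any animal's physiology.
* Motif renormalization makes the two 610 ms conspecific motifs nearly
  equivalent; distinguishing them would require an amplitude-calibration
  convention other than post-sum peak normalization.
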