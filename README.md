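# chorusloop

Closed-loop acoustic playback for call-timing experiments with chorusing
frogs — stimulus synthesis, trial scheduling, an onset-triggered playback
engine, a virtual gap-detection caller to close the loop, and the full
response-metrics pipeline.

## The scientific problem

Male túngara frogs (*Physalaemus pustulosus*) advertise with a call that
begins with a "whine" (a descending frequency sweep, roughly 900 → 400 Hz,
with amplitude falling alongside frequency) optionally followed by short
broadband "chuck" notes; more chucks means a more *elaborate* (and more
attractive) call.  Males call about every 1.7 s.  In small choruses rivals
alternate their calls; in large choruses they increasingly *overlap* each
other in a stereotyped way, with the follower's whine starting just before
the leader's chucks.

Call timing is governed by **gap detection**: calling is suppressed by
acoustic inhibition, and a call is triggered by an abrupt *release* from
inhibition — the offset of a rival's call being the starkest release.  The
shift from alternation to overlap can then be understood as a change in
**permissiveness**: how small a release suffices to trigger a call.  The
experimental question this toolkit serves is what cues drive that shift —
specifically, how the *pattern* of conspecific stimulation heard between a
male's own calls (motifs of overlapping calls, synchronous calls, or plain
tones) interacts with *when* in his call cycle a rival's call arrives (the
stimulus delay).

The toolkit implements the complete experimental loop:

* **callsynth** — parametric whine+chuck calls, pure tones, a library of
  three stimulus calls whose total durations (0.428 / 0.484 / 0.519 s)
  grade with chuck number, and the fixed two-chuck "interim" call played
  between presentations.
* **motifbuild** — the six pre-stimulus motifs (silence; two overlapping
  calls, 610 ms; two synchronous calls, 370 ms; overlapping+synchronous,
  610 ms; 1000 Hz tones of 610 and 310 ms) crossfaded onto stimulus calls
  over 10 ms, so a 610 ms motif leads the stimulus onset by 600 ms.
* **scheduler** — the crossed design (3 stimulus calls × 8 delays under
  silence + 3 × 5 motifs × 4 late delays = 84 conditions, 5 repetitions
  each) in a seeded per-subject random order with interim interleaving.
* **looper** — the event-driven engine: the subject's call onset triggers
  a stimulus at the commanded delay; his response triggers an interim call
  0.75 s later; his response to that triggers the next stimulus.
* **virtualfrog** — a simulated gap-detection caller (median period
  1.71 s, refractory 0.45 s, ~60 ms minimum latency, stimulation- and
  phase-dependent permissiveness, arousal-driven call elaboration) that
  closes the loop for testing and generates ground-truth data.
* **inhibition** — windowed RMS-amplitude and fundamental-frequency
  trajectories, their projection through a frequency-sensitivity curve
  into relative inhibition, and the release rate.
* **respmetrics / analysis** — offline onset extraction from two-channel
  session recordings, per-presentation response metrics (stimulus delay,
  response delay, response period = delay + response delay, two overlap
  definitions, call elaboration = summed chuck peaks relative to whine
  peak), binned response curves, overlap tables, and a fixed-effects
  interaction logistic model for recovery tests.

## Worked example

Simulate a small closed-loop session against the virtual frog and measure
its responses from the session recording:

```python
import numpy as np
from chorusloop import (Condition, EngineConfig, randomize_plan,
                        run_simulated_session, extract_onsets,
                        compute_delays, build_stimulus_library,
                        records_to_frame)

conds = [Condition("highOP", 1.05, "silence"),
         Condition("lowOP", 0.45, "silence"),
         Condition("intOP", 1.5, "overlap_sync"),
         Condition("highOP", 1.2, "tone_long"),
         Condition("lowOP", 1.35, "synchronous")]
plan = randomize_plan(conds, reps=2, seed=5, subject_id="M01",
                      warmup_duration=8.0, warmup_interval=2.0)
log, transport = run_simulated_session(
    plan, seed=2, config=EngineConfig(silent_timeout=30.0))

onsets = extract_onsets(transport.recording(), plan)
records = compute_delays(onsets, plan,
                         library=build_stimulus_library(transport.rate))
df = records_to_frame(records)
print(df[["stimulus_id", "motif_kind", "stimulus_delay",
          "response_delay", "overlapped"]].head(6).round(3))
```

prints

```
  stimulus_id    motif_kind  stimulus_delay  response_delay  overlapped
0      highOP       silence           1.052           0.891       False
1       lowOP   synchronous           1.350           0.462       False
2      highOP     tone_long           1.200           0.760       False
3       lowOP   synchronous           1.349           0.505       False
4      highOP       silence           1.053           0.960       False
5       intOP  overlap_sync           1.499           0.290        True
```

Each row is one stimulus presentation: the stimulus arrived
`stimulus_delay` seconds after the frog's trigger-call onset (measured
from the session recording, hence 1.052 for a commanded 1.05), and the
frog's next call followed `response_delay` seconds after the stimulus
onset; their sum is the realized response period for that cycle.  The
two response modes are visible: isolated or tone-preceded stimuli get
long-latency answers after the call has ended (rows 0, 2, 4), conspecific
motifs switch the frog into short latencies (rows 1, 3), and in row 5 the
overlapping+synchronous motif at the latest delay produced an overlap —
the response began only 290 ms into the 484 ms stimulus call.

The same pipeline is scriptable from the shell:

```
chorusloop schedule --subject M01 --seed 7 --out plan.json
chorusloop simulate --plan plan.json --seed 3 --out session/
chorusloop analyze overlap --records records.csv
```

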