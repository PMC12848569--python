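"""Experimental design enumeration and per-subject trial plans.

The full design crosses three stimulus calls (lowOP / intOP / highOP)
with eight stimulus delays under silence (0.45-1.5 s in 0.15 s steps)
and, because motifs extend up to 600 ms before stimulus onsets, only the
four latest delays (1.05-1.5 s) under each of the five non-silent
motifs: 3x8 + 3x5x4 = 84 conditions.  Each condition is presented
``reps`` times (5 by default) in a seeded per-subject random order, with
a fixed-delay interim call interleaved between presentations and a
one-minute interim warmup block at the start.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import List, Optional, Sequence

import numpy as np

from .motifbuild import DEFAULT_CROSSFADE, MOTIF_DURATIONS

__all__ = ["SILENCE_DELAYS", "MOTIF_DELAYS", "STIMULUS_IDS", "NONSILENT_MOTIFS",
           "Condition", "TrialPlan", "Directive", "enumerate_conditions",
           "randomize_plan", "plan_to_sequence", "subject_seed"]

SILENCE_DELAYS = (0.45, 0.60, 0.75, 0.90, 1.05, 1.20, 1.35, 1.50)
MOTIF_DELAYS = (1.05, 1.20, 1.35, 1.50)
STIMULUS_IDS = ("lowOP", "intOP", "highOP")
NONSILENT_MOTIFS = ("overlapping", "synchronous", "overlap_sync",
                    "tone_long", "tone_short")


@dataclass(frozen=True)
class Condition:
    stimulus_id: str
    stimulus_delay: float
    motif_kind: str


@dataclass
class TrialPlan:
    subject_id: str
    seed: int
    entries: List[Condition]
    interim_delay: float = 0.75
    warmup_duration: float = 60.0
    warmup_interval: float = 1.8

    def to_json(self, path=None) -> str:
        d = dict(subject_id=self.subject_id, seed=self.seed,
                 interim_delay=self.interim_delay,
                 warmup_duration=self.warmup_duration,
                 warmup_interval=self.warmup_interval,
                 entries=[asdict(e) for e in self.entries])
        text = json.dumps(d, indent=1)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source) -> "TrialPlan":
        text = (Path(source).read_text() if isinstance(source, (str, Path))
                and str(source).endswith(".json") else source)
        d = json.loads(text)
        d["entries"] = [Condition(**e) for e in d["entries"]]
        return cls(**d)


def enumerate_conditions(delays_silence: Sequence[float] = SILENCE_DELAYS,
                         delays_motif: Sequence[float] = MOTIF_DELAYS,
                         stimulus_ids: Sequence[str] = STIMULUS_IDS,
                         motif_kinds: Sequence[str] = NONSILENT_MOTIFS,
                         ) -> List[Condition]:
    """Cartesian design: silence at every silence delay, each non-silent
    motif at the (later) motif delays.  Defaults give 84 conditions."""
    if len(delays_silence) == 0:
        raise ValueError("silence delay set is empty")
    if len(motif_kinds) and len(delays_motif) == 0:
        raise ValueError("motif delay set is empty")
    for name, ds in (("silence", delays_silence), ("motif", delays_motif)):
        if len(set(ds)) != len(ds):
            raise ValueError(f"duplicate {name} delays")
    out = []
    for sid in stimulus_ids:
        for d in delays_silence:
            out.append(Condition(sid, float(d), "silence"))
        for kind in motif_kinds:
            for d in delays_motif:
                out.append(Condition(sid, float(d), kind))
    return out


def subject_seed(subject_id: str, master_seed: int) -> int:
    """Stable per-subject seed below 2**31, derived by hashing."""
    digest = hashlib.sha256(f"{subject_id}:{master_seed}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


def randomize_plan(conditions: Sequence[Condition], reps: int, seed: int,
                   subject_id: str = "subject", **plan_kw) -> TrialPlan:
    """Repeat every condition ``reps`` times in a seeded random order.

    The permutation is reproducible from (subject_id, seed); different
    subjects get different orders under the same master seed.
    """
    if reps < 1:
        raise ValueError("reps must be >= 1")
    sseed = subject_seed(subject_id, seed)
    rng = np.random.default_rng(sseed)
    entries = [c for c in conditions for _ in range(reps)]
    order = rng.permutation(len(entries))
    entries = [entries[i] for i in order]
    return TrialPlan(subject_id, seed, entries, **plan_kw)


@dataclass(frozen=True)
class Directive:
    """One playback event in protocol order.

    ``kind`` is "interim" or "stimulus"; warmup interims carry
    ``ref = -1``, all other directives the plan-entry index.  For
    stimulus directives ``lead`` is the motif lead time (render onset to
    stimulus onset, 0 for silence motifs).
    """

    kind: str
    ref: int
    stimulus_id: Optional[str] = None
    stimulus_delay: Optional[float] = None
    motif_kind: Optional[str] = None
    lead: float = 0.0


def plan_to_sequence(plan: TrialPlan,
                     crossfade: float = DEFAULT_CROSSFADE) -> List[Directive]:
    """Expand a plan into ordered playback directives.

    A warmup block of interim calls, then each entry as a stimulus
    directive followed by one palette-cleansing interim directive.
    """
    n_warm = max(1, int(round(plan.warmup_duration / plan.warmup_interval)))
    seq = [Directive("interim", -1) for _ in range(n_warm)]
    for i, e in enumerate(plan.entries):
        dur = MOTIF_DURATIONS[e.motif_kind]
        lead = max(0.0, dur - crossfade) if dur > 0 else 0.0
        seq.append(Directive("stimulus", i, e.stimulus_id, e.stimulus_delay,
                             e.motif_kind, lead))
        seq.append(Directive("interim", i))
    return seq
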