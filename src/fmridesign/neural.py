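"""Graded neural-input trains with transient temporal profiles (TTPs).

Delay-period activity — preparatory activity in attention cueing,
maintenance activity in working memory — keeps the neural drive above
baseline between events.  This is modelled by inserting sub-impulse
amplitudes (0.66 of the event amplitude) on the TR grid after each
stimulus, following one of six profiles:

=======  ==========================  ==============================
profile  shape (event amplitude 1)   intended regime
=======  ==========================  ==============================
1        [1, 0.66]                   attention, short L/U bounds
2        [1, 0.66 x4]                attention, short L, long U
3        profile 1 after a delay     attention, long L, short U
4        profile 2 after a delay     attention, long L, long U
5        [1, 0.66 ... next event]    working memory, short L
6        profile 5 after a delay     working memory, long L
=======  ==========================  ==============================

The delay in profiles 3, 4 and 6 is half the lower ISI bound, floored
to whole TR steps: it mimics a subject relaxing before re-engaging when
the interval is known to be long.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np

from .design import EventSequence, InvalidDesignError, PARADIGMS

__all__ = [
    "TTProfile",
    "NeuralInput",
    "ttp_profile",
    "select_ttp_profile",
    "build_neural_input",
]

logger = logging.getLogger(__name__)

#: Relative amplitude of delay-period (sub-impulse) activity.
SUB_AMPLITUDE = 0.66

#: L_ISI above this (seconds) counts as "long" in the profile usage map.
L_LONG_THRESHOLD = 6.0

#: U_ISI above this (seconds) counts as "long" in the profile usage map.
#: 7.5 s is the length of profile 2's grading (5 TR steps at TR 1.5 s):
#: the longer grading must fit inside the typical gap it serves.
U_LONG_THRESHOLD = 7.5

_ATTENTION_PROFILES = {
    (False, False): 1,
    (False, True): 2,
    (True, False): 3,
    (True, True): 4,
}

_DELAYED_PROFILES = (3, 4, 6)
_SUSTAINED_PROFILES = (5, 6)
_TAIL_LENGTH = {1: 1, 2: 4, 3: 1, 4: 4}


@dataclass(frozen=True)
class TTProfile:
    """One transient temporal profile, resolved onto the TR grid.

    ``delay_scans`` is the quiet period between the unit impulse and the
    first sub-impulse; ``tail_scans`` is the number of sub-impulses, or
    ``None`` for sustained profiles (5, 6) that grade until the next
    event.
    """

    profile_id: int
    delay_scans: int = 0
    tail_scans: int | None = None
    sub_amplitude: float = SUB_AMPLITUDE

    def __post_init__(self) -> None:
        if self.profile_id not in range(1, 7):
            raise ValueError(f"profile_id must be 1..6, got {self.profile_id}")
        if not 0 < self.sub_amplitude <= 1:
            raise ValueError(
                f"sub_amplitude must lie in (0, 1], got {self.sub_amplitude}"
            )
        if self.delay_scans < 0:
            raise ValueError("delay_scans must be >= 0")

    @property
    def sustained(self) -> bool:
        """Whether the grading extends until the next event."""
        return self.tail_scans is None


def ttp_profile(
    profile_id: int,
    l_isi: float,
    tr: float = 1.5,
    sub_amplitude: float = SUB_AMPLITUDE,
) -> TTProfile:
    """Instantiate profile ``profile_id`` for the given ISI lower bound.

    Profiles 3, 4 and 6 carry a leading delay of ``floor(l_isi / (2*tr))``
    TR steps; the floor keeps the delay on the grid and never longer than
    half the minimum gap.
    """
    delay = (
        int(math.floor(l_isi / (2.0 * tr))) if profile_id in _DELAYED_PROFILES else 0
    )
    tail = None if profile_id in _SUSTAINED_PROFILES else _TAIL_LENGTH[profile_id]
    return TTProfile(
        profile_id=profile_id,
        delay_scans=delay,
        tail_scans=tail,
        sub_amplitude=sub_amplitude,
    )


def select_ttp_profile(
    l_isi: float,
    u_isi: float,
    paradigm: str,
    tr: float = 1.5,
    l_long_threshold: float = L_LONG_THRESHOLD,
    u_long_threshold: float = U_LONG_THRESHOLD,
) -> TTProfile:
    """Pick the profile serving an (L_ISI, U_ISI) cell of the usage map.

    Attention designs use profiles 1–4 over the short/long quadrants of
    (L_ISI, U_ISI); working-memory designs use profile 5 for short L_ISI
    and 6 for long.  A bound exactly at a threshold counts as "short"
    (closed-left convention).
    """
    if paradigm not in PARADIGMS:
        raise InvalidDesignError(f"paradigm must be one of {PARADIGMS}")
    l_long = l_isi > l_long_threshold
    if paradigm == "attention":
        u_long = u_isi > u_long_threshold
        pid = _ATTENTION_PROFILES[(l_long, u_long)]
    else:
        pid = 6 if l_long else 5
    return ttp_profile(pid, l_isi, tr=tr)


@dataclass(frozen=True)
class NeuralInput:
    """Per-event-type neural amplitude trains on the TR grid.

    ``trains`` maps each event type to a vector of length ``n_scans``
    with values in [0, 1]; 0 marks baseline, 1 a stimulus, and
    intermediate values delay-period activity.  The summed train drives
    the hemodynamic forward model.
    """

    trains: dict[str, np.ndarray]
    tr: float
    profile: TTProfile | None = None

    @property
    def n_scans(self) -> int:
        return len(next(iter(self.trains.values())))

    @property
    def combined(self) -> np.ndarray:
        """Sum of the per-type trains, u(t) = u_1(t) + ... + u_n(t)."""
        return np.sum(list(self.trains.values()), axis=0)


def build_neural_input(
    seq: EventSequence,
    profile: TTProfile | None = None,
    enable_ttp: bool = True,
) -> NeuralInput:
    """Turn an event sequence into graded neural-input trains.

    Each non-null event emits its amplitude for one TR, followed (when
    ``enable_ttp`` and a profile are given) by the profile's
    sub-impulses at ``sub_amplitude`` times the event amplitude.
    Sub-impulses are truncated at the next delivered event's onset, so
    delay activity never crosses an event boundary; null targets emit
    nothing, and a sustained profile runs on through the vacated slot.
    With ``enable_ttp`` off the result is the bare stimulus train.
    """
    n = seq.n_scans
    trains = {etype: np.zeros(n) for etype in seq.event_types}
    active = [e for e in seq.events if not e.is_null]
    for i, event in enumerate(active):
        s = event.onset_scan
        trains[event.event_type][s] = event.amplitude
        if not enable_ttp or profile is None:
            continue
        next_onset = active[i + 1].onset_scan if i + 1 < len(active) else n
        start = s + 1 + profile.delay_scans
        if profile.sustained:
            stop = next_onset
        else:
            stop = min(s + 1 + profile.delay_scans + profile.tail_scans, next_onset)
        stop = min(stop, n)
        if start >= next_onset and profile.delay_scans > 0 and i + 1 < len(active):
            logger.warning(
                "profile %d delay (%d scans) consumes the whole gap after scan "
                "%d; emitting the unit impulse only",
                profile.profile_id,
                profile.delay_scans,
                s,
            )
            continue
        if start < stop:
            trains[event.event_type][start:stop] = (
                profile.sub_amplitude * event.amplitude
            )
    return NeuralInput(trains=trains, tr=seq.tr, profile=profile if enable_ttp else None)
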