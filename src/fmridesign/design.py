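"""Alternating cue–target event sequences on a TR grid.

Cue–target paradigms (trial-by-trial attention cueing, working memory)
impose a fixed event order — a cue is always followed by its target — so
the usual randomization tricks for event-related fMRI designs are
unavailable.  The only timing freedom is the inter-stimulus interval
(ISI): the onset-to-onset spacing between consecutive events is jittered
uniformly between a lower bound ``l_isi`` and an upper bound ``u_isi``,
and a proportion of targets may be replaced by null events ("partial
trials").

Events live on the scanner's TR grid: onsets are drawn in continuous
time and snapped to the nearest TR index, and each stimulus occupies one
TR step.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "PARADIGMS",
    "DesignSpec",
    "Event",
    "EventSequence",
    "InvalidDesignError",
    "EventsTableError",
    "generate_alternating_sequence",
    "insert_partial_trials",
    "uniform_event_train",
    "read_events_tsv",
    "write_events_tsv",
]

PARADIGMS = ("attention", "working_memory")

#: Column order of a BIDS-style events table.
EVENTS_COLUMNS = ("onset", "duration", "trial_type", "amplitude")

#: Suffix marking an omitted (null) event in an events table.
NULL_SUFFIX = "_null"


class InvalidDesignError(ValueError):
    """A design specification that cannot produce a valid sequence."""


class EventsTableError(ValueError):
    """An events table that violates the expected format."""


@dataclass(frozen=True)
class DesignSpec:
    """All user-chosen parameters of one alternating design.

    Parameters
    ----------
    l_isi, u_isi
        Lower and upper bound of the uniformly jittered inter-stimulus
        interval, in seconds.  The onset-to-onset gap between every pair
        of consecutive events is drawn independently from
        ``Uniform(l_isi, u_isi)``.
    tr
        Repetition time (seconds per scan).
    n_scans
        Number of TR steps; total duration is ``tr * n_scans`` seconds
        (441 s with the defaults).
    paradigm
        ``"attention"`` or ``"working_memory"``; selects the family of
        transient temporal profiles used downstream.
    n_pairs
        Number of distinct cue–target pairs.  With one pair the event
        types are ``"cue"`` and ``"target"``; with more they are
        ``"cue1"``, ``"target1"``, ... and pairs cycle deterministically
        (C1 T1 C2 T2 ...) unless ``random_pair_order`` is set.
    partial_fraction
        Proportion of targets replaced by null events, in [0, 0.5].
    amplitudes
        Optional mapping from event type to stimulus amplitude
        (default 1.0 for every type).
    seed
        RNG seed used when no generator is passed explicitly.
    """

    l_isi: float
    u_isi: float
    tr: float = 1.5
    n_scans: int = 294
    paradigm: str = "attention"
    n_pairs: int = 1
    partial_fraction: float = 0.0
    amplitudes: dict[str, float] | None = None
    random_pair_order: bool = False
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.tr <= 0:
            raise InvalidDesignError(f"tr must be positive, got {self.tr}")
        if self.n_scans < 1:
            raise InvalidDesignError(f"n_scans must be >= 1, got {self.n_scans}")
        if not 0 < self.l_isi <= self.u_isi:
            raise InvalidDesignError(
                f"need 0 < l_isi <= u_isi, got l_isi={self.l_isi}, u_isi={self.u_isi}"
            )
        if not 0 <= self.partial_fraction <= 0.5:
            raise InvalidDesignError(
                f"partial_fraction must lie in [0, 0.5], got {self.partial_fraction}"
            )
        if self.paradigm not in PARADIGMS:
            raise InvalidDesignError(
                f"paradigm must be one of {PARADIGMS}, got {self.paradigm!r}"
            )
        if self.n_pairs < 1:
            raise InvalidDesignError(f"n_pairs must be >= 1, got {self.n_pairs}")

    @property
    def duration(self) -> float:
        """Total sequence duration in seconds."""
        return self.tr * self.n_scans

    @property
    def event_types(self) -> tuple[str, ...]:
        if self.n_pairs == 1:
            return ("cue", "target")
        types: list[str] = []
        for p in range(1, self.n_pairs + 1):
            types.extend((f"cue{p}", f"target{p}"))
        return tuple(types)

    def amplitude_of(self, event_type: str) -> float:
        if self.amplitudes is None:
            return 1.0
        return float(self.amplitudes.get(event_type, 1.0))


@dataclass(frozen=True)
class Event:
    """A single stimulus slot on the TR grid."""

    onset_scan: int
    event_type: str
    amplitude: float = 1.0
    is_null: bool = False

    @property
    def is_target(self) -> bool:
        return self.event_type.startswith("target")


@dataclass(frozen=True)
class EventSequence:
    """An ordered, TR-gridded train of typed events.

    ``isis`` stores the continuous-time gaps (seconds) drawn between
    consecutive event slots before snapping to the TR grid; it is
    provenance, excluded from equality, as is ``spec``.
    """

    events: tuple[Event, ...]
    n_scans: int
    tr: float
    spec: DesignSpec | None = field(default=None, compare=False)
    isis: tuple[float, ...] = field(default=(), compare=False)

    def __post_init__(self) -> None:
        scans = [e.onset_scan for e in self.events]
        if any(s < 0 or s >= self.n_scans for s in scans):
            raise InvalidDesignError("event onset outside [0, n_scans)")
        if any(b <= a for a, b in zip(scans, scans[1:])):
            raise InvalidDesignError("event onsets must be strictly increasing")

    def __len__(self) -> int:
        return len(self.events)

    @property
    def event_types(self) -> tuple[str, ...]:
        """Distinct event types in order of first appearance."""
        seen: dict[str, None] = {}
        for e in self.events:
            seen.setdefault(e.event_type, None)
        return tuple(seen)

    @property
    def onsets_s(self) -> np.ndarray:
        """Snapped onset times in seconds."""
        return np.array([e.onset_scan * self.tr for e in self.events])

    @property
    def n_trials(self) -> int:
        """Number of trials (targets, whether delivered or null)."""
        return sum(1 for e in self.events if e.is_target)

    @property
    def n_partial_trials(self) -> int:
        return sum(1 for e in self.events if e.is_target and e.is_null)

    def is_alternating(self) -> bool:
        """True when every target slot is immediately preceded by a cue."""
        for prev, cur in zip(self.events, self.events[1:]):
            if cur.is_target and prev.is_target:
                return False
        return bool(self.events) and not self.events[0].is_target


def _draw_onsets(
    l_isi: float,
    u_isi: float,
    tr: float,
    n_scans: int,
    rng: np.random.Generator,
) -> tuple[list[int], list[float]]:
    """Draw uniformly jittered onsets and snap them to the TR grid.

    Returns the snapped scan indices and the drawn gaps (seconds).
    Generation starts at t = 0 and stops at the first event whose
    snapped index would fall at or beyond ``n_scans``.  When two onsets
    snap to the same TR index the later one is pushed forward one TR.
    """
    duration = tr * n_scans
    if l_isi > duration:
        raise InvalidDesignError(
            f"l_isi={l_isi} exceeds the total duration {duration}; no events possible"
        )
    if u_isi < tr:
        warnings.warn(
            f"u_isi={u_isi} is shorter than tr={tr}: the jitter cannot be "
            "resolved on the TR grid and consecutive events collapse onto "
            "adjacent scans",
            stacklevel=3,
        )
    scans: list[int] = []
    gaps: list[float] = []
    t = 0.0
    while True:
        s = int(round(t / tr))
        if scans and s <= scans[-1]:
            s = scans[-1] + 1
        if s >= n_scans:
            break
        scans.append(s)
        g = float(rng.uniform(l_isi, u_isi))
        gaps.append(g)
        t += g
    # the last drawn gap leads nowhere
    if gaps:
        gaps.pop()
    return scans, gaps


def generate_alternating_sequence(
    spec: DesignSpec, rng: np.random.Generator | None = None
) -> EventSequence:
    """Generate a cue–target alternating sequence with uniform ISI jitter.

    Onset-to-onset gaps are drawn independently from
    ``Uniform(l_isi, u_isi)`` (both cue→target and target→cue gaps),
    onsets are snapped to the nearest TR index, and each event occupies
    one TR step.  Trials are whole units: a trailing cue whose target
    does not fit inside ``n_scans`` is dropped.
    """
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    scans, gaps = _draw_onsets(spec.l_isi, spec.u_isi, spec.tr, spec.n_scans, rng)

    types = spec.event_types
    n_pairs = spec.n_pairs
    if spec.random_pair_order and n_pairs > 1:
        pair_order = [int(rng.integers(n_pairs)) for _ in range((len(scans) + 1) // 2)]
    else:
        pair_order = [i % n_pairs for i in range((len(scans) + 1) // 2)]

    events: list[Event] = []
    for i, s in enumerate(scans):
        pair = pair_order[i // 2]
        etype = types[2 * pair + (i % 2)]
        events.append(Event(s, etype, spec.amplitude_of(etype)))

    # end on a complete trial
    while events and not events[-1].is_target:
        events.pop()
        if gaps:
            gaps.pop()

    seq = EventSequence(
        events=tuple(events),
        n_scans=spec.n_scans,
        tr=spec.tr,
        spec=spec,
        isis=tuple(gaps),
    )
    if spec.partial_fraction > 0:
        seq = insert_partial_trials(seq, spec.partial_fraction, rng)
    return seq


def insert_partial_trials(
    seq: EventSequence,
    partial_fraction: float,
    rng: np.random.Generator,
) -> EventSequence:
    """Replace a fixed proportion of targets by null events.

    Exactly ``round(partial_fraction * n_targets)`` targets, chosen
    uniformly at random, are flagged null: the stimulus is omitted
    (amplitude 0) but the slot's timing is preserved, so the preceding
    cue's delay period extends to the next cue.
    """
    if not 0 <= partial_fraction <= 0.5:
        raise InvalidDesignError(
            f"partial_fraction must lie in [0, 0.5], got {partial_fraction}"
        )
    target_idx = [
        i for i, e in enumerate(seq.events) if e.is_target and not e.is_null
    ]
    n_null = int(np.floor(partial_fraction * len(target_idx) + 0.5))
    if n_null == 0:
        return seq
    chosen = set(rng.choice(target_idx, size=n_null, replace=False).tolist())
    events = tuple(
        replace(e, is_null=True, amplitude=0.0) if i in chosen else e
        for i, e in enumerate(seq.events)
    )
    return EventSequence(
        events=events, n_scans=seq.n_scans, tr=seq.tr, spec=seq.spec, isis=seq.isis
    )


def uniform_event_train(
    l_isi: float,
    u_isi: float,
    tr: float,
    n_scans: int,
    rng: np.random.Generator,
    amplitude: float = 1.0,
) -> np.ndarray:
    """Binary single-event-type train with uniform ISI jitter.

    Same timing rules as :func:`generate_alternating_sequence` but with
    a single, untyped event stream; used for integrated-response
    diagnostics of the nonlinear forward model.
    """
    scans, _ = _draw_onsets(l_isi, u_isi, tr, n_scans, rng)
    u = np.zeros(n_scans)
    u[scans] = amplitude
    return u


def write_events_tsv(seq: EventSequence, path: str | Path) -> None:
    """Write a sequence as a BIDS-style events table.

    Columns are onset (s), duration (s), trial_type and amplitude.
    Null events are written with the ``_null`` suffix on their trial
    type and amplitude 0, so the table round-trips exactly.
    """
    rows = []
    for e in seq.events:
        trial_type = e.event_type + NULL_SUFFIX if e.is_null else e.event_type
        rows.append(
            {
                "onset": e.onset_scan * seq.tr,
                "duration": seq.tr,
                "trial_type": trial_type,
                "amplitude": e.amplitude,
            }
        )
    pd.DataFrame(rows, columns=list(EVENTS_COLUMNS)).to_csv(
        path, sep="\t", index=False
    )


def read_events_tsv(path: str | Path, tr: float, n_scans: int) -> EventSequence:
    """Read a BIDS-style events table onto the TR grid.

    Onsets (seconds) are quantized to the nearest TR index.  Raises
    :class:`EventsTableError` naming the offending row for missing
    columns, negative onsets or non-monotone onsets.
    """
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in EVENTS_COLUMNS if c not in df.columns]
    if missing:
        raise EventsTableError(f"events table {path} is missing columns: {missing}")
    onsets = df["onset"].to_numpy(dtype=float)
    for i, onset in enumerate(onsets):
        if onset < 0:
            raise EventsTableError(f"row {i}: negative onset {onset}")
        if i > 0 and onset <= onsets[i - 1]:
            raise EventsTableError(
                f"row {i}: onset {onset} is not strictly after the previous "
                f"onset {onsets[i - 1]}"
            )
    events: list[Event] = []
    for i, row in df.iterrows():
        scan = int(round(float(row["onset"]) / tr))
        if events and scan <= events[-1].onset_scan:
            scan = events[-1].onset_scan + 1
        if scan >= n_scans:
            raise EventsTableError(
                f"row {i}: onset {row['onset']} falls beyond scan {n_scans - 1}"
            )
        trial_type = str(row["trial_type"])
        is_null = trial_type.endswith(NULL_SUFFIX)
        if is_null:
            trial_type = trial_type[: -len(NULL_SUFFIX)]
        events.append(
            Event(scan, trial_type, float(row["amplitude"]), is_null=is_null)
        )
    gaps = tuple(np.diff(onsets).tolist())
    return EventSequence(
        events=tuple(events), n_scans=n_scans, tr=tr, isis=gaps
    )
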