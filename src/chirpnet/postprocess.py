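"""From probability tracks to discrete detections, passes, and text output.

The sliding detector produces a smooth per-frame probability track; actual
call starts are recovered by non-maximum suppression (each peak keeps only
its local maximum).  For monitoring statistics, individual calls are then
grouped into *bat passes*: calls in the same 3.84 s sound clip belong to one
pass, and a pass continues across a clip boundary whenever the adjacent
clip also contains calls.

Detections are exported as TSV with both file-time and real-time
coordinates (file time = real time x expansion factor).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "DetectionEvent",
    "BatPass",
    "nonmax_suppress",
    "apply_threshold",
    "group_passes",
    "export_detections",
    "read_detections",
]


@dataclass(frozen=True)
class DetectionEvent:
    """A predicted call start: real-time seconds plus classifier probability."""

    time: float
    probability: float
    source_id: str = ""

    def __post_init__(self) -> None:
        if not (-1e-9 <= self.probability <= 1 + 1e-9):
            raise ValueError("probability must be in [0, 1]")
        object.__setattr__(self, "probability", float(np.clip(self.probability, 0, 1)))
        object.__setattr__(self, "time", float(self.time))


@dataclass(frozen=True)
class BatPass:
    """A sequence of calls attributed to one transit of a bat past the sensor."""

    events: tuple[DetectionEvent, ...]
    first_clip: int
    last_clip: int

    @property
    def start_time(self) -> float:
        return self.events[0].time

    @property
    def end_time(self) -> float:
        return self.events[-1].time

    def __len__(self) -> int:
        return len(self.events)


def nonmax_suppress(
    track,
    neighborhood: float = 11.5e-3,
    floor: float = 0.05,
    source_id: str | None = None,
) -> list[DetectionEvent]:
    """Reduce a probability track to its local maxima.

    A frame is kept iff its probability is at least ``floor`` and is the
    maximum over all frames within ``+-neighborhood`` seconds; on an exact
    tie (plateau) only the earliest frame of the plateau is kept.  The
    default neighbourhood of 11.5 ms is half the 23 ms detection window —
    search-phase calls essentially never repeat faster than that.
    """
    probs = np.asarray(track.probs, float)
    times = np.asarray(track.times, float)
    sid = source_id if source_id is not None else getattr(track, "model_id", "")
    events = []
    for i in range(probs.size):
        p = probs[i]
        if p < floor:
            continue
        in_nbhd = np.abs(times - times[i]) <= neighborhood
        neigh = probs[in_nbhd]
        if p < neigh.max():
            continue
        # plateau tie-break: skip if an earlier in-neighbourhood frame ties
        earlier = in_nbhd & (np.arange(probs.size) < i)
        if earlier.any() and probs[earlier].max() >= p:
            continue
        events.append(DetectionEvent(time=float(times[i]), probability=float(p), source_id=sid))
    return events


def apply_threshold(events: list[DetectionEvent], p_min: float) -> list[DetectionEvent]:
    """Keep events with probability >= ``p_min`` (order preserved).

    The monitoring application uses a conservative 0.90 so that only
    high-precision predictions are counted.
    """
    if not (0.0 <= p_min <= 1.0):
        raise ValueError("p_min must be in [0, 1]")
    return [e for e in events if e.probability >= p_min]


def group_passes(
    events: list[DetectionEvent],
    clip_length: float = 3.84,
    expansion_factor: int = 10,
) -> list[BatPass]:
    """Group calls into bat passes by the clip-adjacency heuristic.

    Calls in the same ``clip_length``-second sound clip (file time) share a
    pass; the pass extends across a clip boundary iff the neighbouring clip
    also contains at least one call.  Equivalently, passes are maximal runs
    of consecutive occupied clips.
    """
    if not events:
        return []
    ordered = sorted(events, key=lambda e: e.time)
    clip_of = [int(e.time * expansion_factor / clip_length) for e in ordered]
    passes: list[BatPass] = []
    group: list[DetectionEvent] = [ordered[0]]
    for ev, clip, prev_clip in zip(ordered[1:], clip_of[1:], clip_of[:-1]):
        if clip - prev_clip <= 1:
            group.append(ev)
        else:
            passes.append(_make_pass(group, clip_length, expansion_factor))
            group = [ev]
    passes.append(_make_pass(group, clip_length, expansion_factor))
    return passes


def _make_pass(group, clip_length, expansion_factor) -> BatPass:
    clips = [int(e.time * expansion_factor / clip_length) for e in group]
    return BatPass(events=tuple(group), first_clip=min(clips), last_clip=max(clips))


_HEADER = "source_id\tfile_time_s\treal_time_s\tprobability"


def export_detections(
    events: list[DetectionEvent], path, expansion_factor: int = 10
) -> None:
    """Write detections as TSV: id, file time, real time, probability.

    Floats are written with ``repr`` so a parse round-trips exactly; rows
    are ordered by (source_id, time) for determinism.
    """
    ordered = sorted(events, key=lambda e: (e.source_id, e.time))
    with open(path, "w") as fh:
        fh.write(_HEADER + "\n")
        for e in ordered:
            fh.write(
                f"{e.source_id}\t{e.time * expansion_factor!r}\t"
                f"{e.time!r}\t{e.probability!r}\n"
            )


def read_detections(path) -> list[DetectionEvent]:
    """Parse a detection TSV written by :func:`export_detections`."""
    events = []
    with open(path) as fh:
        header = fh.readline().strip()
        if header != _HEADER:
            raise ValueError(f"unrecognised detection file header: {header!r}")
        for line in fh:
            sid, _file_t, real_t, prob = line.rstrip("\n").split("\t")
            events.append(
                DetectionEvent(time=float(real_t), probability=float(prob), source_id=sid)
            )
    return events
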