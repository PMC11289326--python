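"""Construction of the 10-second analysis windows.

Seated trials are driven by the instruction schedule: the first 2 s after each
instruction are discarded and the following 10 s (250 frames at 25 fps) form
the analysis window.  Walking trials are driven by scene visibility: each walk
ends approximately when the carpet leaves the camera view, and the window is
the preceding 10 s.
"""

from __future__ import annotations

import logging

import numpy as np

from .core import DomainError, InstructionSchedule, Interval, TargetTrack

__all__ = ["onsets_from_audio", "seated_intervals", "walking_intervals"]

log = logging.getLogger(__name__)


def onsets_from_audio(
    t: np.ndarray,
    envelope: np.ndarray,
    threshold: float,
    refractory_s: float = 5.0,
) -> np.ndarray:
    """Onset times of instruction bursts from a non-negative audio envelope.

    An onset is a rising crossing of ``threshold`` at least ``refractory_s``
    after the previous accepted onset.
    """
    t = np.asarray(t, dtype=float)
    envelope = np.asarray(envelope, dtype=float)
    if np.any(envelope < 0):
        raise DomainError("envelope must be non-negative")
    above = envelope >= threshold
    rising = np.nonzero(above[1:] & ~above[:-1])[0] + 1
    if above.size and above[0]:
        rising = np.concatenate([[0], rising])
    onsets: list[float] = []
    for i in rising:
        if not onsets or t[i] - onsets[-1] >= refractory_s:
            onsets.append(float(t[i]))
    return np.asarray(onsets)


def seated_intervals(
    schedule: InstructionSchedule,
    skip_s: float = 2.0,
    window_s: float = 10.0,
) -> list[Interval]:
    """One analysis window per instruction: ``[onset + skip, onset + skip + window]``.

    If the next instruction arrives before the window completes, the window is
    truncated at that onset (with a logged warning).
    """
    if len(schedule) == 0:
        raise DomainError("empty instruction schedule")
    intervals: list[Interval] = []
    onsets = list(schedule.onsets_s) + [np.inf]
    for k, (onset, label) in enumerate(schedule):
        start = onset + skip_s
        end = onset + skip_s + window_s
        nxt = onsets[k + 1]
        if end > nxt:
            log.warning(
                "interval for %r at %.2f s truncated to %.2f s by the next onset",
                label,
                onset,
                nxt - start,
            )
            end = nxt
        if end <= start:
            log.warning("instruction %r at %.2f s leaves no analysis window", label, onset)
            continue
        intervals.append(Interval(start_t=start, end_t=end, label=label, kind="seated"))
    return intervals


def _fill_short_gaps(visible: np.ndarray, max_gap: int) -> np.ndarray:
    """Treat invisible runs of at most ``max_gap`` frames as visible (dropouts)."""
    visible = visible.copy()
    n = visible.size
    i = 0
    while i < n:
        if not visible[i]:
            j = i
            while j < n and not visible[j]:
                j += 1
            if i > 0 and j < n and (j - i) <= max_gap:
                visible[i:j] = True
            i = j
        else:
            i += 1
    return visible


def walking_intervals(
    track: TargetTrack,
    window_s: float = 10.0,
    sustained_gap_s: float = 2.0,
    dropout_frames: int = 2,
    max_walks: int = 2,
) -> list[Interval]:
    """Up to ``max_walks`` windows, each ending when the carpet leaves the view.

    A walk end is the last visible frame before a sustained (> ``sustained_gap_s``)
    invisible run; single-frame detection dropouts do not end a walk.  With no
    visibility transition at all, a single fallback window ends at the last
    visible frame.
    """
    if track.visible is None:
        raise DomainError("walking segmentation requires per-frame visibility flags")
    fps = track.frame_rate_hz
    visible = _fill_short_gaps(np.asarray(track.visible, dtype=bool), dropout_frames)
    if not np.any(visible):
        raise DomainError("carpet never visible in the recording")
    gap_frames = int(round(sustained_gap_s * fps))
    n = visible.size
    ends: list[int] = []
    i = 0
    while i < n:
        if visible[i]:
            j = i
            while j < n and visible[j]:
                j += 1
            # run [i, j); ends at j-1 if followed by a sustained gap or recording end
            run_end = j - 1
            gap_len = 0
            k = j
            while k < n and not visible[k]:
                gap_len += 1
                k += 1
            # a walk ends on a sustained gap, or when the carpet never returns
            if j >= n or k >= n or gap_len > gap_frames:
                ends.append(run_end)
            i = k
        else:
            i += 1
    if not ends:
        ends = [int(np.nonzero(visible)[0][-1])]
        log.warning("no visibility transitions; falling back to the last visible frame")
    intervals: list[Interval] = []
    for end_f in ends[:max_walks]:
        end_t = (end_f + 1) / fps
        start_t = max(end_t - window_s, 0.0)
        if end_t <= start_t:
            continue
        intervals.append(
            Interval(start_t=start_t, end_t=end_t, label="bullseye", kind="walking")
        )
    return intervals
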