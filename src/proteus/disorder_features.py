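"""Disorder-track features: segment descriptors and disorder topography.

Feature group 6 describes the predicted disorder landscape around a residue:
the window-averaged disorder probability plus the length and relative
boundary positions of the contiguous disordered (score >= 0.5) or ordered
(score < 0.5) segment containing the residue. Exactly one of the two
segment triplets is nonzero for any residue.

Feature group 7 classifies each residue as part of a peak (+1), a valley
(-1) or neither (0) of the disorder-score graph: a residue sits on a peak if
somewhere to its left AND somewhere to its right there is a residue scoring
at least 10% lower, and in a valley if both sides hold a residue scoring at
least 10% higher. The second feature is the length of the contiguous run of
residues sharing the same class (0 for class "neither").
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io_tracks import DisorderProfile


@dataclass(frozen=True)
class DisorderConfig:
    """Tunables for groups 6-7.

    delta: the "at least 10%" criterion of the topography classifier.
    delta_mode: "relative" treats delta multiplicatively (<= (1-delta)*s);
        "absolute" as an offset (<= s - delta).
    disorder_threshold: score at or above which a residue counts as
        disordered.
    segment_position_mode: "position" reports segment boundaries as 1-based
        positions divided by L; "distance" reports the distance from the
        current residue to each boundary divided by L.
    """

    delta: float = 0.10
    delta_mode: str = "relative"
    disorder_threshold: float = 0.5
    segment_position_mode: str = "position"


DEFAULT_CONFIG = DisorderConfig()


@dataclass(frozen=True)
class SegmentDescriptor:
    kind: str  # "disordered" | "ordered"
    length: int
    start_rel: float
    stop_rel: float
    start: int  # 1-based
    stop: int  # 1-based inclusive


@dataclass(frozen=True)
class TopographyAnnotation:
    klass: int  # 1 peak, -1 valley, 0 neither
    run_length: int  # 0 when klass == 0


def _scores(diso: DisorderProfile | np.ndarray) -> np.ndarray:
    if isinstance(diso, DisorderProfile):
        return diso.scores
    return np.asarray(diso, dtype=float)


def _segment_bounds(mask: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """For each position, the 0-based start/stop of its maximal same-mask run."""
    L = mask.shape[0]
    change = np.empty(L, dtype=bool)
    change[0] = True
    change[1:] = mask[1:] != mask[:-1]
    seg_id = np.cumsum(change) - 1
    starts = np.flatnonzero(change)
    stops = np.append(starts[1:] - 1, L - 1)
    return starts[seg_id], stops[seg_id]


def segment_of(
    diso: DisorderProfile | np.ndarray,
    pos: int,
    threshold: float = 0.5,
    position_mode: str = "position",
) -> SegmentDescriptor:
    """Maximal contiguous disordered/ordered segment containing residue pos (1-based)."""
    s = _scores(diso)
    L = s.shape[0]
    if not 1 <= pos <= L:
        raise IndexError(f"position {pos} outside [1, {L}]")
    mask = s >= threshold
    starts, stops = _segment_bounds(mask)
    i = pos - 1
    start, stop = int(starts[i]) + 1, int(stops[i]) + 1
    if position_mode == "position":
        start_rel, stop_rel = start / L, stop / L
    else:  # distance of the current residue to each boundary, relative to L
        start_rel, stop_rel = (pos - start) / L, (stop - pos) / L
    return SegmentDescriptor(
        kind="disordered" if mask[i] else "ordered",
        length=stop - start + 1,
        start_rel=start_rel,
        stop_rel=stop_rel,
        start=start,
        stop=stop,
    )


def windowed_disorder(diso: DisorderProfile | np.ndarray, window: int = 15) -> np.ndarray:
    """Mean disorder score over a truncated centred window, for every residue."""
    s = _scores(diso)
    L = s.shape[0]
    half = window // 2
    csum = np.concatenate([[0.0], np.cumsum(s)])
    idx = np.arange(L)
    lo = np.maximum(idx - half, 0)
    hi = np.minimum(idx + half, L - 1)
    return (csum[hi + 1] - csum[lo]) / (hi - lo + 1)


def disorder_segment_features(
    diso: DisorderProfile | np.ndarray,
    pos: int,
    window: int = 15,
    config: DisorderConfig = DEFAULT_CONFIG,
) -> np.ndarray:
    """The 7 group-6 values for one residue (1-based pos)."""
    return disorder_segment_matrix(diso, window=window, config=config)[pos - 1]


def disorder_segment_matrix(
    diso: DisorderProfile | np.ndarray,
    window: int = 15,
    config: DisorderConfig = DEFAULT_CONFIG,
) -> np.ndarray:
    """L x 7 group-6 feature block, vectorised over residues.

    Columns: windowed mean score; (length, start_rel, stop_rel) of the
    disordered segment when the residue is disordered, else zeros; the same
    triplet for the ordered segment when the residue is ordered, else zeros.
    """
    s = _scores(diso)
    L = s.shape[0]
    mask = s >= config.disorder_threshold
    starts, stops = _segment_bounds(mask)
    starts1, stops1 = starts + 1.0, stops + 1.0
    length = stops1 - starts1 + 1
    if config.segment_position_mode == "position":
        start_rel, stop_rel = starts1 / L, stops1 / L
    else:
        pos1 = np.arange(1, L + 1, dtype=float)
        start_rel, stop_rel = (pos1 - starts1) / L, (stops1 - pos1) / L
    out = np.zeros((L, 7))
    out[:, 0] = windowed_disorder(s, window)
    out[mask, 1] = length[mask]
    out[mask, 2] = start_rel[mask]
    out[mask, 3] = stop_rel[mask]
    out[~mask, 4] = length[~mask]
    out[~mask, 5] = start_rel[~mask]
    out[~mask, 6] = stop_rel[~mask]
    return out


def topography_classes(
    diso: DisorderProfile | np.ndarray, config: DisorderConfig = DEFAULT_CONFIG
) -> np.ndarray:
    """Peak/valley/neither class for every residue, via prefix extrema (O(L))."""
    s = _scores(diso)
    L = s.shape[0]
    if L == 0:
        return np.zeros(0, dtype=np.int64)
    # extrema over the strict left/right of each position
    left_min = np.concatenate([[np.inf], np.minimum.accumulate(s)[:-1]])
    left_max = np.concatenate([[-np.inf], np.maximum.accumulate(s)[:-1]])
    right_min = np.concatenate([np.minimum.accumulate(s[::-1])[:-1][::-1], [np.inf]])
    right_max = np.concatenate([np.maximum.accumulate(s[::-1])[:-1][::-1], [-np.inf]])
    if config.delta_mode == "relative":
        lo_thr = (1.0 - config.delta) * s
        hi_thr = (1.0 + config.delta) * s
    else:
        lo_thr = s - config.delta
        hi_thr = s + config.delta
    peak = (left_min <= lo_thr) & (right_min <= lo_thr)
    valley = (left_max >= hi_thr) & (right_max >= hi_thr)
    klass = np.zeros(L, dtype=np.int64)
    klass[peak] = 1
    klass[valley & ~peak] = -1
    return klass


def topography_class(
    diso: DisorderProfile | np.ndarray,
    pos: int,
    delta: float = 0.10,
    config: DisorderConfig | None = None,
) -> int:
    """Topography class of one residue (1-based pos)."""
    cfg = config or DisorderConfig(delta=delta)
    s = _scores(diso)
    if not 1 <= pos <= s.shape[0]:
        raise IndexError(f"position {pos} outside [1, {s.shape[0]}]")
    return int(topography_classes(s, cfg)[pos - 1])


def topography_matrix(
    diso: DisorderProfile | np.ndarray, config: DisorderConfig = DEFAULT_CONFIG
) -> np.ndarray:
    """L x 2 group-7 block: (class, same-class run length; 0 for class 0)."""
    klass = topography_classes(diso, config)
    L = klass.shape[0]
    out = np.zeros((L, 2))
    out[:, 0] = klass
    if L:
        starts, stops = _segment_bounds(klass)
        run = stops - starts + 1.0
        nz = klass != 0
        out[nz, 1] = run[nz]
    return out


def topography_features(
    diso: DisorderProfile | np.ndarray,
    pos: int,
    config: DisorderConfig = DEFAULT_CONFIG,
) -> tuple[int, int]:
    """(class, run length) of one residue (1-based pos)."""
    mat = topography_matrix(diso, config)
    if not 1 <= pos <= mat.shape[0]:
        raise IndexError(f"position {pos} outside [1, {mat.shape[0]}]")
    klass, run = mat[pos - 1]
    return int(klass), int(run)
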