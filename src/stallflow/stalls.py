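"""Capillary stall detection from angiogram frame stacks.

A stalled capillary transiently loses its flowing red blood cells, which in an
angiogram time series appears as an intensity dropout in that segment lasting
one or more frames, followed by recovery.  The detection pipeline is:

1. flatten a 4-D (T, Z, H, W) angiogram volume series to 2-D frames by maximum
   intensity projection along Z (:func:`flatten_mip`);
2. enhance tubular structures in the time-mean image with a multiscale
   vesselness (ridge) filter (:func:`enhance_vessels`);
3. binarize, skeletonize, cut the skeleton at branch points, and grow each
   branch back onto the vessel mask to obtain labeled capillary segments
   (:func:`segment_capillaries`);
4. extract per-segment mean-intensity time series (:func:`extract_traces`);
5. call stall events per segment with an individual threshold — a fraction
   ``alpha`` of that segment's temporal median — and a minimum-duration rule
   (default 3 frames; at ~9 s/frame that is ~27 s) (:func:`detect_stalls`);
6. summarize as the proportion of segments with at least one true event and
   the pooled event-duration statistics (:func:`stall_metrics`).

Segmentation runs on the time-mean image so that segments which vanish in
individual frames (the stalls we are looking for) are still delineated.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import tifffile
from scipy import ndimage
from skimage.filters import frangi, threshold_otsu
from skimage.morphology import skeletonize
from skimage.segmentation import watershed

__all__ = [
    "AngiogramStack",
    "SegmentMap",
    "SegmentTraces",
    "StallEvent",
    "StallRecord",
    "StallMetrics",
    "flatten_mip",
    "enhance_vessels",
    "segment_capillaries",
    "extract_traces",
    "detect_stalls",
    "stall_metrics",
    "detect_stalls_in_stack",
]

DEFAULT_FRAME_INTERVAL_S = 9.0
DEFAULT_ALPHA = 0.5
DEFAULT_MIN_DURATION_FRAMES = 3
#: Frangi scales (pixels) spanning expected capillary half-widths.
VESSELNESS_SIGMAS = (1.0, 1.5, 2.0, 3.0)
MIN_SKELETON_LENGTH_PX = 5


@dataclass
class AngiogramStack:
    """T x H x W stack of non-negative angiogram intensities."""

    frames: np.ndarray
    frame_interval_s: float = DEFAULT_FRAME_INTERVAL_S

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 3:
            raise ValueError(f"frames must be T x H x W, got shape {self.frames.shape}")
        if self.frames.shape[0] < 1:
            raise ValueError("stack needs at least one frame")
        if self.frame_interval_s <= 0:
            raise ValueError("frame_interval_s must be positive")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    def mean_image(self) -> np.ndarray:
        return self.frames.mean(axis=0)

    def to_tiff(self, path) -> None:
        tifffile.imwrite(path, self.frames.astype(np.float32))

    @classmethod
    def from_tiff(cls, path, frame_interval_s: float = DEFAULT_FRAME_INTERVAL_S) -> "AngiogramStack":
        arr = tifffile.imread(path)
        if arr.ndim == 4:
            return flatten_mip(arr, frame_interval_s=frame_interval_s)
        return cls(arr, frame_interval_s=frame_interval_s)


@dataclass
class SegmentMap:
    """Labeled capillary segments: 0 = background, k = segment k (1-based)."""

    labels: np.ndarray

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 2:
            raise ValueError("labels must be a 2-D image")
        present = np.unique(self.labels)
        present = present[present > 0]
        n = int(self.labels.max(initial=0))
        if len(present) != n:
            raise ValueError("labels must be consecutive 1..n_segments, all non-empty")

    @property
    def n_segments(self) -> int:
        return int(self.labels.max(initial=0))

    @property
    def pixel_counts(self) -> np.ndarray:
        return np.bincount(self.labels.ravel(), minlength=self.n_segments + 1)[1:]

    def to_tiff(self, path) -> None:
        if self.n_segments > np.iinfo(np.uint16).max:
            raise ValueError("too many segments for 16-bit label TIFF")
        tifffile.imwrite(path, self.labels.astype(np.uint16))

    @classmethod
    def from_tiff(cls, path) -> "SegmentMap":
        return cls(tifffile.imread(path).astype(np.int64))


@dataclass
class SegmentTraces:
    """n_segments x T matrix of per-frame segment mean intensities."""

    values: np.ndarray
    frame_interval_s: float = DEFAULT_FRAME_INTERVAL_S

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("traces must be n_segments x T")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("traces must be finite")

    @property
    def n_segments(self) -> int:
        return self.values.shape[0]

    @property
    def n_frames(self) -> int:
        return self.values.shape[1]


@dataclass(frozen=True)
class StallEvent:
    segment_id: int
    start_frame: int
    duration_frames: int

    def __post_init__(self) -> None:
        if self.duration_frames < 1:
            raise ValueError("duration_frames must be >= 1")
        if self.start_frame < 0:
            raise ValueError("start_frame must be >= 0")


@dataclass
class StallRecord:
    """True stall events per segment plus the per-segment thresholds used."""

    events: list[StallEvent]
    thresholds: np.ndarray
    n_segments: int
    min_duration_frames: int = DEFAULT_MIN_DURATION_FRAMES
    alpha: float = DEFAULT_ALPHA

    def events_for(self, segment_id: int) -> list[StallEvent]:
        return [e for e in self.events if e.segment_id == segment_id]

    @property
    def stalled_segments(self) -> set[int]:
        return {e.segment_id for e in self.events}

    def to_json(self, path) -> None:
        payload = {
            "n_segments": self.n_segments,
            "min_duration_frames": self.min_duration_frames,
            "alpha": self.alpha,
            "thresholds": [float(t) for t in self.thresholds],
            "events": [
                {"segment_id": e.segment_id, "start_frame": e.start_frame, "duration_frames": e.duration_frames}
                for e in self.events
            ],
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "StallRecord":
        with open(path) as fh:
            d = json.load(fh)
        return cls(
            events=[StallEvent(e["segment_id"], e["start_frame"], e["duration_frames"]) for e in d["events"]],
            thresholds=np.asarray(d["thresholds"], dtype=float),
            n_segments=d["n_segments"],
            min_duration_frames=d["min_duration_frames"],
            alpha=d["alpha"],
        )


@dataclass
class StallMetrics:
    """Stall summary: proportion of stalled segments and event durations.

    ``proportion_stalled`` counts segments with at least one true event in the
    numerator (an ``n_events``-based rate is available as ``event_rate``);
    duration statistics pool all true events, so a segment stalling twice
    contributes two durations.
    """

    proportion_stalled: float
    durations_frames: list[int] = field(default_factory=list)
    mean_duration_frames: float = float("nan")
    mean_duration_s: float = float("nan")
    n_segments: int = 0
    n_events: int = 0
    frame_interval_s: float = DEFAULT_FRAME_INTERVAL_S

    @property
    def event_rate(self) -> float:
        """Number of true events divided by the number of segments."""
        return self.n_events / self.n_segments if self.n_segments else float("nan")


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def flatten_mip(volume_series: np.ndarray, frame_interval_s: float = DEFAULT_FRAME_INTERVAL_S) -> AngiogramStack:
    """Flatten a T x Z x H x W angiogram volume series by per-frame maximum
    intensity projection along Z."""
    volume_series = np.asarray(volume_series)
    if volume_series.ndim != 4:
        raise ValueError(f"expected a 4-D (T, Z, H, W) stack, got shape {volume_series.shape}")
    return AngiogramStack(volume_series.max(axis=1), frame_interval_s=frame_interval_s)


def enhance_vessels(mean_image: np.ndarray, sigmas=VESSELNESS_SIGMAS) -> np.ndarray:
    """Multiscale vesselness (bright-ridge) response, rescaled to [0, 1].

    A constant image has no ridges and maps to an all-zero response.
    """
    mean_image = np.asarray(mean_image, dtype=float)
    if mean_image.ndim != 2:
        raise ValueError("expected a 2-D image")
    if np.ptp(mean_image) == 0:
        return np.zeros_like(mean_image)
    resp = frangi(mean_image, sigmas=sigmas, black_ridges=False)
    top = resp.max()
    if top > 0:
        resp = resp / top
    return np.clip(resp, 0.0, 1.0)


def _branch_points(skel: np.ndarray) -> np.ndarray:
    """Skeleton pixels with more than two 8-connected skeleton neighbours."""
    kernel = np.ones((3, 3), dtype=int)
    kernel[1, 1] = 0
    nbrs = ndimage.convolve(skel.astype(int), kernel, mode="constant")
    return skel & (nbrs > 2)


def _prune_spurs(skel: np.ndarray, prune_len: int, n_iter: int = 2) -> np.ndarray:
    """Remove short terminal skeleton spurs so they do not split long branches.

    A spur is a branch that ends in a skeleton endpoint and is shorter than
    ``prune_len`` pixels; removing it turns the spurious branch point back
    into a regular path pixel.
    """
    kernel = np.ones((3, 3), dtype=int)
    kernel[1, 1] = 0
    eight = np.ones((3, 3), dtype=int)
    skel = skel.copy()
    for _ in range(n_iter):
        nbrs = ndimage.convolve(skel.astype(int), kernel, mode="constant")
        endpoints = skel & (nbrs <= 1)
        branches = skel & ~_branch_points(skel)
        labels, n = ndimage.label(branches, structure=eight)
        if n == 0:
            break
        sizes = np.bincount(labels.ravel(), minlength=n + 1)
        # branches with exactly one endpoint hang off a branch point (true
        # spurs); two endpoints means an isolated segment, which is kept
        n_endpoints = np.bincount(labels[endpoints & (labels > 0)], minlength=n + 1)
        # never prune the longest branch of a skeleton component, so a small
        # tube whose skeleton splits into two short spurs is not erased
        comp_labels, _ = ndimage.label(skel, structure=eight)
        keeper: dict[int, int] = {}
        for lab in range(1, n + 1):
            comp = int(comp_labels[labels == lab][0])
            if comp not in keeper or sizes[lab] > sizes[keeper[comp]]:
                keeper[comp] = lab
        protected = set(keeper.values())
        removed = False
        for lab in range(1, n + 1):
            if lab not in protected and n_endpoints[lab] == 1 and sizes[lab] < prune_len:
                skel[labels == lab] = False
                removed = True
        if not removed:
            break
    return skel


def segment_capillaries(
    enhanced: np.ndarray,
    threshold: float | None = None,
    min_length_px: int = MIN_SKELETON_LENGTH_PX,
) -> SegmentMap:
    """Delineate labeled capillary segments from a vesselness image.

    Binarize (Otsu by default), skeletonize, prune short terminal spurs, cut
    the skeleton at branch points, discard branches shorter than
    ``min_length_px`` skeleton pixels, and grow each remaining branch back
    onto the binary mask (watershed on the inverted vesselness) to form the
    labeled segments.
    """
    enhanced = np.asarray(enhanced, dtype=float)
    if threshold is None:
        if np.ptp(enhanced) == 0:
            raise ValueError("no capillaries detected: constant vesselness image")
        threshold = threshold_otsu(enhanced)
    mask = enhanced > threshold
    if not mask.any():
        raise ValueError("no capillaries detected: empty binary mask")

    skel = _prune_spurs(skeletonize(mask), prune_len=2 * min_length_px)
    branches = skel & ~_branch_points(skel)
    branch_labels, _ = ndimage.label(branches, structure=np.ones((3, 3), dtype=int))
    sizes = np.bincount(branch_labels.ravel())
    keep = np.flatnonzero(sizes >= min_length_px)
    keep = keep[keep > 0]
    if keep.size == 0:
        raise ValueError("no capillaries detected: all skeleton branches too short")
    remap = np.zeros(sizes.size, dtype=np.int64)
    remap[keep] = np.arange(1, keep.size + 1)
    markers = remap[branch_labels]

    labels = watershed(-enhanced, markers=markers, mask=mask)
    # watershed can leave mask islands unreached by any marker; drop them
    present = np.unique(labels)
    present = present[present > 0]
    if present.size != keep.size:
        remap2 = np.zeros(int(labels.max()) + 1, dtype=np.int64)
        remap2[present] = np.arange(1, present.size + 1)
        labels = remap2[labels]
    return SegmentMap(labels)


def extract_traces(stack: AngiogramStack, seg: SegmentMap) -> SegmentTraces:
    """Per-frame mean intensity of each segment: entry (k, t)."""
    if stack.frames.shape[1:] != seg.labels.shape:
        raise ValueError("stack frames and segment map shapes differ")
    n = seg.n_segments
    if n == 0:
        raise ValueError("segment map has no segments")
    idx = np.arange(1, n + 1)
    traces = np.empty((n, stack.n_frames), dtype=float)
    for t in range(stack.n_frames):
        traces[:, t] = ndimage.mean(stack.frames[t], labels=seg.labels, index=idx)
    return SegmentTraces(traces, frame_interval_s=stack.frame_interval_s)


def _runs_below(flags: np.ndarray) -> list[tuple[int, int]]:
    """(start, length) of maximal runs of True in a boolean vector."""
    padded = np.diff(np.concatenate(([0], flags.astype(int), [0])))
    starts = np.flatnonzero(padded == 1)
    ends = np.flatnonzero(padded == -1)
    return [(int(s), int(e - s)) for s, e in zip(starts, ends)]


def detect_stalls(
    traces: SegmentTraces,
    alpha: float = DEFAULT_ALPHA,
    min_duration: int = DEFAULT_MIN_DURATION_FRAMES,
) -> StallRecord:
    """Call stall events with a per-capillary threshold.

    For each segment the threshold is ``alpha`` times the median of its own
    trace; frames strictly below threshold are stall-flagged, and maximal
    flagged runs of at least ``min_duration`` frames become true events.
    """
    if not 0 < alpha < 1:
        raise ValueError(f"alpha must be in (0, 1), got {alpha}")
    if traces.n_frames < min_duration:
        raise ValueError("trace shorter than the minimum stall duration")
    thresholds = alpha * np.median(traces.values, axis=1)
    events: list[StallEvent] = []
    for k in range(traces.n_segments):
        flagged = traces.values[k] < thresholds[k]
        for start, length in _runs_below(flagged):
            if length >= min_duration:
                events.append(StallEvent(segment_id=k + 1, start_frame=start, duration_frames=length))
    return StallRecord(
        events=events,
        thresholds=thresholds,
        n_segments=traces.n_segments,
        min_duration_frames=min_duration,
        alpha=alpha,
    )


def stall_metrics(
    record: StallRecord,
    n_segments: int | None = None,
    frame_interval_s: float = DEFAULT_FRAME_INTERVAL_S,
) -> StallMetrics:
    """Stall proportion and duration summary from a stall record."""
    n = record.n_segments if n_segments is None else n_segments
    if n < 1:
        raise ValueError("n_segments must be >= 1")
    durations = [e.duration_frames for e in record.events]
    mean_frames = float(np.mean(durations)) if durations else float("nan")
    return StallMetrics(
        proportion_stalled=len(record.stalled_segments) / n,
        durations_frames=durations,
        mean_duration_frames=mean_frames,
        mean_duration_s=mean_frames * frame_interval_s,
        n_segments=n,
        n_events=len(record.events),
        frame_interval_s=frame_interval_s,
    )


def detect_stalls_in_stack(
    stack: AngiogramStack,
    alpha: float = DEFAULT_ALPHA,
    min_duration: int = DEFAULT_MIN_DURATION_FRAMES,
    threshold: float | None = None,
    min_length_px: int = MIN_SKELETON_LENGTH_PX,
) -> tuple[SegmentMap, StallRecord, StallMetrics]:
    """Full detection pipeline on one angiogram stack."""
    enhanced = enhance_vessels(stack.mean_image())
    seg = segment_capillaries(enhanced, threshold=threshold, min_length_px=min_length_px)
    traces = extract_traces(stack, seg)
    record = detect_stalls(traces, alpha=alpha, min_duration=min_duration)
    metrics = stall_metrics(record, frame_interval_s=stack.frame_interval_s)
    if not record.events and min_duration > stack.n_frames:
        warnings.warn("minimum duration exceeds stack length; no events can be detected")
    return seg, record, metrics
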