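"""Longitudinal lesion linking and trajectory extraction.

Lesions segmented on each weekly scan are chained across consecutive
timepoints when their 3D masks overlap by at least 4 voxels, yielding one
track per lesion. Each track carries a full per-timepoint trajectory of
volume (µL) and mean normalized PDw intensity: before first detection, and
after a lesion disappears, statistics are measured in a propagated region
of interest of the lesion's maximum extent, so the pre-lesion baseline and
the post-recovery plateau are always defined.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .imgproc import (
    LabelMap,
    Volume,
    detect_enhancement,
    t1_subtraction,
)

logger = logging.getLogger(__name__)

#: Minimum 3D overlap (voxels) for two components at consecutive timepoints
#: to be identified as the same lesion.
DEFAULT_MIN_OVERLAP_VOXELS = 4


def voxel_count_to_ul(count: int, voxel_size_mm: Sequence[float]) -> float:
    """Convert a voxel count to a volume in µL (1 mm^3 = 1 µL).

    At the default 0.15 x 0.15 x 1.0 mm spacing one voxel is 0.0225 µL.
    """
    if count < 0:
        raise ValueError(f"voxel count must be >= 0, got {count}")
    return float(count) * float(np.prod(np.asarray(voxel_size_mm, dtype=float)))


@dataclass
class StudyTimeline:
    """Serial multicontrast volumes for one subject.

    ``volumes`` maps a contrast tag (e.g. ``"PDw"``, ``"T1w_pre"``) to a list
    of :class:`~remyetrack.imgproc.Volume`, one per week, ordered like
    ``weeks``. ``label_maps`` (one per week) are filled in by segmentation.
    """

    subject_id: str
    weeks: np.ndarray
    volumes: Dict[str, List[Volume]]
    gm_mask: np.ndarray
    wm_mask: np.ndarray
    voxel_size_mm: Tuple[float, float, float]
    label_maps: Optional[List[LabelMap]] = None

    def __post_init__(self) -> None:
        self.weeks = np.asarray(self.weeks, dtype=float)
        if self.weeks.ndim != 1 or len(self.weeks) < 1:
            raise ValueError("weeks must be a non-empty 1D sequence")
        if np.any(np.diff(self.weeks) <= 0):
            raise ValueError("weeks must be strictly increasing")
        for tag, vols in self.volumes.items():
            if len(vols) != len(self.weeks):
                raise ValueError(
                    f"contrast {tag!r} has {len(vols)} volumes for {len(self.weeks)} weeks"
                )

    @property
    def n_timepoints(self) -> int:
        return len(self.weeks)

    @property
    def terminal_week(self) -> float:
        return float(self.weeks[-1])

    def contrast(self, tag: str, week_index: int) -> Volume:
        try:
            vols = self.volumes[tag]
        except KeyError:
            raise KeyError(
                f"contrast {tag!r} missing for week {self.weeks[week_index]}"
            ) from None
        return vols[week_index]


@dataclass
class TrajectoryPoint:
    """One timepoint of a lesion trajectory."""

    week: float
    volume_ul: float
    mean_norm_intensity: float
    sd_norm_intensity: float
    roi_propagated: bool
    enhancing: Optional[bool] = None

    def __post_init__(self) -> None:
        if self.volume_ul == 0 and not self.roi_propagated:
            raise ValueError("volume_ul = 0 is only allowed for propagated-ROI points")


@dataclass
class LesionTrack:
    """One lesion's linked masks and per-timepoint statistics."""

    track_id: int
    first_detection_week: float
    points: List[TrajectoryPoint]
    max_roi: np.ndarray  # boolean mask, maximum lesion extent
    terminal_enhancing: Optional[bool] = None
    events: List[str] = field(default_factory=list)

    @property
    def weeks(self) -> np.ndarray:
        return np.array([p.week for p in self.points])

    @property
    def intensities(self) -> np.ndarray:
        return np.array([p.mean_norm_intensity for p in self.points])

    def peak_volume_ul(self) -> float:
        """Maximum measured (non-propagated) lesion volume in µL."""
        vols = [p.volume_ul for p in self.points if not p.roi_propagated]
        if not vols:
            raise ValueError("track has no directly segmented timepoints")
        return max(vols)

    def baseline_points(self) -> List[TrajectoryPoint]:
        """Pre-lesion propagated points (weeks before first detection)."""
        return [
            p for p in self.points
            if p.roi_propagated and p.week < self.first_detection_week
        ]


@dataclass
class LinkResult:
    """Outcome of linking two consecutive label maps.

    ``links`` holds the resolved (label_t, label_t1, overlap) assignments;
    ``candidates`` every pair meeting the overlap criterion; ``merges``
    labels at t+1 with multiple qualifying predecessors; ``splits`` labels
    at t with multiple qualifying successors.
    """

    links: List[Tuple[int, int, int]]
    candidates: List[Tuple[int, int, int]]
    merges: List[int] = field(default_factory=list)
    splits: List[int] = field(default_factory=list)


def link_timepoints(
    labels_t: LabelMap,
    labels_t1: LabelMap,
    min_overlap_voxels: int = DEFAULT_MIN_OVERLAP_VOXELS,
) -> LinkResult:
    """Link lesion components across consecutive timepoints by 3D overlap.

    A component ``b`` at t+1 is identified with component ``a`` at t when
    their masks share at least ``min_overlap_voxels`` voxels. If several
    predecessors qualify, ``b`` is linked to the one with maximal overlap
    (ties go to the smaller label id) and the event is recorded as a merge.
    """
    if labels_t.labels.shape != labels_t1.labels.shape:
        raise ValueError(
            f"grid mismatch: {labels_t.labels.shape} vs {labels_t1.labels.shape}"
        )
    a = labels_t.labels
    b = labels_t1.labels
    both = (a > 0) & (b > 0)
    candidates: List[Tuple[int, int, int]] = []
    if both.any():
        pair_index = a[both].astype(np.int64) * (b.max() + 1) + b[both].astype(np.int64)
        pairs, counts = np.unique(pair_index, return_counts=True)
        for p, c in zip(pairs, counts):
            la = int(p // (b.max() + 1))
            lb = int(p % (b.max() + 1))
            if c >= min_overlap_voxels:
                candidates.append((la, lb, int(c)))

    links: List[Tuple[int, int, int]] = []
    merges: List[int] = []
    by_successor: Dict[int, List[Tuple[int, int]]] = {}
    for la, lb, c in candidates:
        by_successor.setdefault(lb, []).append((la, c))
    for lb, preds in sorted(by_successor.items()):
        if len(preds) > 1:
            merges.append(lb)
        best = max(preds, key=lambda t: (t[1], -t[0]))
        links.append((best[0], lb, best[1]))

    succ_count: Dict[int, int] = {}
    for la, _, _ in links:
        succ_count[la] = succ_count.get(la, 0) + 1
    splits = sorted(la for la, n in succ_count.items() if n > 1)
    return LinkResult(links=links, candidates=candidates, merges=merges, splits=splits)


def _roi_stats(volume: Volume, roi: np.ndarray) -> Tuple[float, float]:
    vals = volume.data[roi]
    return float(np.mean(vals)), float(np.std(vals))


def build_tracks(
    timeline: StudyTimeline,
    min_overlap_voxels: int = DEFAULT_MIN_OVERLAP_VOXELS,
    enhancement_k_sigma: float = 3.0,
) -> List[LesionTrack]:
    """Chain per-week segmentations into lesion tracks with full trajectories.

    Consecutive timepoints are linked by :func:`link_timepoints`. For weeks
    before a track's first detection, and for weeks after it disappears, the
    track's maximum-extent ROI is propagated and statistics are measured
    inside it (``roi_propagated`` points, volume recorded as 0). A track
    that disappears may re-link to a later component overlapping its
    maximum-extent ROI by at least ``min_overlap_voxels`` voxels; the event
    is recorded.

    PDw volumes in the timeline are assumed GM-normalized. Terminal
    enhancement status is read off the terminal pre/post-gadolinium T1
    subtraction with :func:`~remyetrack.imgproc.detect_enhancement`, using
    lesion-free white matter as background.
    """
    if timeline.label_maps is None or any(lm is None for lm in timeline.label_maps):
        raise ValueError("timeline.label_maps must be populated for every week")
    n_t = timeline.n_timepoints

    # active[label at current week] -> track index
    comps_by_track: List[Dict[int, np.ndarray]] = []  # track -> week_idx -> mask
    track_events: List[List[str]] = []
    prev_assign: Dict[int, int] = {}

    for ti in range(n_t):
        lm = timeline.label_maps[ti]
        labels_here = sorted(set(np.unique(lm.labels)) - {0})
        assign: Dict[int, int] = {}
        if ti > 0:
            res = link_timepoints(
                timeline.label_maps[ti - 1], lm, min_overlap_voxels
            )
            # components at ti linked to a predecessor's track
            claimed: Dict[int, List[Tuple[int, int]]] = {}
            for la, lb, c in res.links:
                claimed.setdefault(prev_assign[la], []).append((lb, c))
            for tr, lbs in claimed.items():
                lbs.sort(key=lambda t: (-t[1], t[0]))
                assign[lbs[0][0]] = tr
                for lb, _ in lbs[1:]:
                    # split: extra successor starts its own track below
                    track_events[tr].append(
                        f"split at week {timeline.weeks[ti]}: component {lb} detached"
                    )
            for lb in res.merges:
                tr = assign.get(lb)
                if tr is not None:
                    track_events[tr].append(
                        f"merge at week {timeline.weeks[ti]}: component {lb} had "
                        f"multiple predecessors"
                    )
        # components not linked week-to-week: re-attach by overlap with an
        # existing track's full-extent ROI (a lesion that disappeared and
        # reappeared, or transiently split at the threshold); else new track
        for lb in labels_here:
            if lb in assign:
                continue
            mask = lm.labels == lb
            best_tr, best_ov = None, 0
            for tr, comps in enumerate(comps_by_track):
                roi = np.zeros_like(mask)
                for m in comps.values():
                    roi |= m
                ov = int(np.count_nonzero(roi & mask))
                if ov >= min_overlap_voxels and ov > best_ov:
                    best_tr, best_ov = tr, ov
            if best_tr is not None:
                assign[lb] = best_tr
                track_events[best_tr].append(
                    f"re-attached by max-extent overlap at week {timeline.weeks[ti]}"
                )
            else:
                comps_by_track.append({})
                track_events.append([])
                assign[lb] = len(comps_by_track) - 1
        for lb, tr in assign.items():
            mask = lm.labels == lb
            if ti in comps_by_track[tr]:
                comps_by_track[tr][ti] |= mask  # split pieces rejoin the track
            else:
                comps_by_track[tr][ti] = mask
        prev_assign = assign

    # assemble tracks with propagated-ROI statistics
    pdw = timeline.volumes["PDw"]
    voxvol = float(np.prod(timeline.voxel_size_mm))
    all_lesion_voxels = np.zeros(timeline.gm_mask.shape, dtype=bool)
    max_rois: List[np.ndarray] = []
    for comps in comps_by_track:
        best_ti = min(comps, key=lambda t: (-int(np.count_nonzero(comps[t])), t))
        max_rois.append(comps[best_ti])
        for m in comps.values():
            all_lesion_voxels |= m
    background = timeline.wm_mask & ~all_lesion_voxels

    terminal_sub: Optional[Volume] = None
    if "T1w_pre" in timeline.volumes and "T1w_post" in timeline.volumes:
        terminal_sub = t1_subtraction(
            timeline.contrast("T1w_pre", n_t - 1),
            timeline.contrast("T1w_post", n_t - 1),
        )

    tracks: List[LesionTrack] = []
    order = sorted(
        range(len(comps_by_track)), key=lambda tr: min(comps_by_track[tr])
    )
    for new_id, tr in enumerate(order, start=1):
        comps = comps_by_track[tr]
        max_roi = max_rois[tr]
        first_ti = min(comps)
        points: List[TrajectoryPoint] = []
        for ti in range(n_t):
            if ti in comps:
                mask = comps[ti]
                mean, sd = _roi_stats(pdw[ti], mask)
                points.append(TrajectoryPoint(
                    week=float(timeline.weeks[ti]),
                    volume_ul=voxel_count_to_ul(int(np.count_nonzero(mask)),
                                                timeline.voxel_size_mm),
                    mean_norm_intensity=mean,
                    sd_norm_intensity=sd,
                    roi_propagated=False,
                ))
            else:
                mean, sd = _roi_stats(pdw[ti], max_roi)
                points.append(TrajectoryPoint(
                    week=float(timeline.weeks[ti]),
                    volume_ul=0.0,
                    mean_norm_intensity=mean,
                    sd_norm_intensity=sd,
                    roi_propagated=True,
                ))
        terminal_enhancing: Optional[bool] = None
        if terminal_sub is not None and background.any():
            terminal_mask = comps.get(n_t - 1, max_roi)
            enhancing, mean_enh = detect_enhancement(
                terminal_sub, terminal_mask, background, enhancement_k_sigma
            )
            terminal_enhancing = enhancing
            points[-1].enhancing = enhancing
        tracks.append(LesionTrack(
            track_id=new_id,
            first_detection_week=float(timeline.weeks[first_ti]),
            points=points,
            max_roi=max_roi,
            terminal_enhancing=terminal_enhancing,
            events=track_events[tr],
        ))
    return tracks


def tracks_to_dataframe(tracks: List[LesionTrack], subject_id: str):
    """Tidy one-row-per-track-per-week table of trajectories."""
    import pandas as pd

    rows = []
    for tr in tracks:
        for p in tr.points:
            rows.append({
                "subject": subject_id,
                "track_id": tr.track_id,
                "week": p.week,
                "volume_ul": p.volume_ul,
                "mean_norm_intensity": p.mean_norm_intensity,
                "sd_norm_intensity": p.sd_norm_intensity,
                "roi_propagated": p.roi_propagated,
                "enhancing": p.enhancing,
            })
    return pd.DataFrame(rows)
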