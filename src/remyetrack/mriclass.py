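"""Rule-based categorization of lesion tracks from PDw intensity trajectories.

Lesions are assigned to one of three classes from their serial normalized
PDw signal and terminal gadolinium enhancement status, mirroring the
rater criteria used with serial marmoset EAE MRI:

1. *early active* — hyperintense at the terminal scan and enhancing after
   gadolinium;
2. *chronic, at least partially demyelinated* — hyperintense at the
   terminal scan, not enhancing;
3. *remyelinated* — hyperintense at some earlier timepoint, isointense at
   the terminal scan, not enhancing.

"Hyperintense" is operationalized against the track's own pre-lesion
baseline: a timepoint is hyperintense when its mean normalized intensity
exceeds the baseline mean by more than max(min_hyper_margin,
k_sigma * baseline SD). The module also implements the peak-size rule
(lesions above 0.5 µL at peak do not remyelinate) and estimates the
remyelination window from the downward intensity slope and its plateau.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional

import numpy as np

from .core import LesionClass
from .tracking import LesionTrack, TrajectoryPoint

MriCategory = LesionClass


@dataclass
class ClassificationRuleConfig:
    """Thresholds for the trajectory classification rules.

    isointensity_k_sigma
        Multiplier on the pre-lesion baseline SD for the hyperintensity
        margin (default 2).
    min_hyper_margin
        Floor on that margin in normalized units (default 0.05), so a
        near-noiseless baseline does not make the rule degenerate.
    size_rule_threshold_ul
        Peak-volume boundary of the size rule (default 0.5 µL, inclusive:
        remyelination is considered possible at exactly 0.5 µL).
    """

    isointensity_k_sigma: float = 2.0
    min_hyper_margin: float = 0.05
    size_rule_threshold_ul: float = 0.5

    def __post_init__(self) -> None:
        if (self.isointensity_k_sigma <= 0 or self.min_hyper_margin <= 0
                or self.size_rule_threshold_ul <= 0):
            raise ValueError("all classification thresholds must be positive")


def _baseline_stats(track: LesionTrack) -> tuple:
    base = track.baseline_points()
    if len(base) < 2:
        raise ValueError(
            f"track {track.track_id}: need >= 2 pre-lesion baseline points to "
            f"estimate the isointensity band, found {len(base)}"
        )
    vals = np.array([p.mean_norm_intensity for p in base])
    return float(vals.mean()), float(vals.std())


def hyper_margin(track: LesionTrack, cfg: ClassificationRuleConfig) -> float:
    """The track's hyperintensity margin above its baseline mean."""
    _, sd = _baseline_stats(track)
    return max(cfg.min_hyper_margin, cfg.isointensity_k_sigma * sd)


def _is_hyper(point: TrajectoryPoint, mu_b: float, margin: float) -> bool:
    return point.mean_norm_intensity > mu_b + margin


def classify_track(
    track: LesionTrack,
    cfg: Optional[ClassificationRuleConfig] = None,
) -> MriCategory:
    """Assign one of the three MRI classes to a lesion track.

    Enhancement takes precedence: any terminal-hyperintense track that
    enhances at the terminal scan is early active, even if shrinking.

    Raises
    ------
    ValueError
        If the track has fewer than 2 pre-lesion baseline points, lacks a
        terminal enhancement status, or is never hyperintense at any
        timepoint ("not a lesion track").
    """
    cfg = cfg or ClassificationRuleConfig()
    mu_b, sd_b = _baseline_stats(track)
    margin = max(cfg.min_hyper_margin, cfg.isointensity_k_sigma * sd_b)
    if track.terminal_enhancing is None:
        raise ValueError(
            f"track {track.track_id}: terminal enhancement status is required"
        )
    hyper = [_is_hyper(p, mu_b, margin) for p in track.points]
    if not any(hyper):
        raise ValueError(f"track {track.track_id}: not a lesion track "
                         f"(never hyperintense)")
    if hyper[-1]:
        if track.terminal_enhancing:
            return LesionClass.EARLY_ACTIVE
        return LesionClass.CHRONIC_DEMYELINATED
    if track.terminal_enhancing:
        # isointense but enhancing: treat as early active inflammation
        return LesionClass.EARLY_ACTIVE
    return LesionClass.REMYELINATED


def predict_by_peak_size(
    track: LesionTrack,
    threshold_ul: float = 0.5,
) -> bool:
    """Size-rule prediction: can this lesion remyelinate?

    True iff the maximum directly-segmented volume never exceeded
    ``threshold_ul`` (inclusive boundary). Lesions larger than 0.5 µL at
    peak do not return to isointensity.
    """
    return track.peak_volume_ul() <= threshold_ul


@dataclass
class RemyelinationWindow:
    """Estimated demyelination/remyelination timing for one track (weeks)."""

    demyelination_start_week: float
    remyelination_start_week: float
    plateau_week: float

    @property
    def remyelination_duration_weeks(self) -> float:
        return self.plateau_week - self.remyelination_start_week


def estimate_remyelination_window(
    track: LesionTrack,
    cfg: Optional[ClassificationRuleConfig] = None,
) -> Optional[RemyelinationWindow]:
    """Estimate the remyelination window of a remyelinated track.

    Demyelination starts at the first hyperintense timepoint; remyelination
    starts at the timepoint of maximal mean intensity (the downward slope
    begins there); the plateau is the first later timepoint that is
    isointense and stays isointense for all subsequent directly-segmented
    points. Returns None for tracks that do not classify as remyelinated or
    never reach a stable isointense plateau.
    """
    cfg = cfg or ClassificationRuleConfig()
    try:
        if classify_track(track, cfg) is not LesionClass.REMYELINATED:
            return None
    except ValueError:
        return None
    mu_b, sd_b = _baseline_stats(track)
    margin = max(cfg.min_hyper_margin, cfg.isointensity_k_sigma * sd_b)
    pts = track.points
    hyper = [_is_hyper(p, mu_b, margin) for p in pts]
    demyel_start = next(p.week for p, h in zip(pts, hyper) if h)
    peak_idx = int(np.argmax([p.mean_norm_intensity for p in pts]))
    plateau_week: Optional[float] = None
    for i in range(peak_idx + 1, len(pts)):
        if hyper[i]:
            continue
        later_ok = all(
            not hyper[j]
            for j in range(i + 1, len(pts))
            if not pts[j].roi_propagated
        ) and not any(hyper[i:])
        if later_ok:
            plateau_week = pts[i].week
            break
    if plateau_week is None:
        return None
    return RemyelinationWindow(
        demyelination_start_week=float(demyel_start),
        remyelination_start_week=float(pts[peak_idx].week),
        plateau_week=float(plateau_week),
    )
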