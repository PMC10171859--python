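"""Shared fixtures: tiny synthetic studies and hand-built lesion tracks."""

from __future__ import annotations

from typing import List, Optional, Sequence

import numpy as np
import pytest

from remyetrack import SimulationConfig, simulate_study
from remyetrack.tracking import LesionTrack, TrajectoryPoint


def make_track(
    intensities: Sequence[float],
    n_baseline: int = 2,
    terminal_enhancing: Optional[bool] = False,
    volumes: Optional[Sequence[float]] = None,
    detected: Optional[Sequence[bool]] = None,
    track_id: int = 1,
) -> LesionTrack:
    """Build a LesionTrack from a weekly intensity series.

    The first ``n_baseline`` points are pre-lesion propagated-ROI points;
    the rest are directly segmented unless ``detected`` says otherwise.
    """
    n = len(intensities)
    if detected is None:
        detected = [i >= n_baseline for i in range(n)]
    if volumes is None:
        volumes = [0.2 if d else 0.0 for d in detected]
    points = [
        TrajectoryPoint(
            week=float(i),
            volume_ul=float(volumes[i]) if detected[i] else 0.0,
            mean_norm_intensity=float(intensities[i]),
            sd_norm_intensity=0.0,
            roi_propagated=not detected[i],
        )
        for i in range(n)
    ]
    first_det = next((p.week for p in points if not p.roi_propagated),
                     float("nan"))
    return LesionTrack(
        track_id=track_id,
        first_detection_week=first_det,
        points=points,
        max_roi=np.ones((2, 2, 2), dtype=bool),
        terminal_enhancing=terminal_enhancing,
    )


def _segmented(cfg):
    from remyetrack.imgproc import segment_lesions

    timeline, lesions = simulate_study(cfg)
    timeline.label_maps = [
        segment_lesions(v, timeline.wm_mask) for v in timeline.volumes["PDw"]
    ]
    return cfg, timeline, lesions


@pytest.fixture(scope="session")
def noiseless_study():
    """Small noiseless study (label maps populated) with mixed lesion classes."""
    return _segmented(SimulationConfig(n_lesions=5, noise_sd=0.0, seed=11))


@pytest.fixture(scope="session")
def noisy_study():
    return _segmented(SimulationConfig(n_lesions=5, noise_sd=0.01, seed=12))
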