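"""Synthetic longitudinal MRI studies and terminal histology with known truth.

The generator emulates the imaging phenotype of focal inflammatory
demyelinating white-matter lesions in marmoset EAE followed with weekly
multicontrast 7T MRI:

* a GM-normalized proton density-weighted (PDw) series in which normal
  white matter sits in a 0.65-0.75 intensity band and lesions appear as
  hyperintense ellipsoids that grow to a peak volume during a 4-7 week
  demyelination phase;
* for the remyelinating class, a subsequent convex decay of the lesion
  signal back to the pre-lesion baseline over 4-9 weeks (lesions with peak
  volume above 0.5 µL do not remyelinate);
* pre/post-gadolinium T1w pairs encoding transient blood-brain-barrier
  enhancement at lesion appearance (and persistent terminal enhancement
  for early-active lesions);
* MT-on/MT-off pairs encoding a demyelination-dependent drop in the
  magnetization transfer ratio;
* terminal histology endpoints per lesion (PLP/LFB unstained fraction,
  oligodendrocyte and OPC counts, Iba1 density) drawn from class-conditional
  distributions, renderable as 2D stain images whose quantification
  reproduces the truth.

Every stage of the analysis pipeline can thus be tested at desk scale
against exact ground truth, without any imaging download.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict, replace
from typing import Dict, List, Optional, Sequence, Set, Tuple

import numpy as np

from .core import LesionClass
from .imgproc import DEFAULT_VOXEL_SIZE_MM, Volume
from .tracking import StudyTimeline

__all__ = [
    "SimulationConfig",
    "GroundTruthLesion",
    "HistoTruth",
    "StainImageSet",
    "HISTO_CLASS_MOMENTS",
    "NAWM_HISTO_MOMENTS",
    "simulate_study",
    "sample_ground_truth",
    "sample_histo_truth",
    "render_histology",
]


# --------------------------------------------------------------------------
# Configuration and ground-truth containers
# --------------------------------------------------------------------------

@dataclass
class SimulationConfig:
    """Study conditions for one synthetic subject.

    Defaults reproduce the reference study setting: weekly scans at
    150 µm in-plane / 1 mm slice resolution (0.0225 µL voxels), lesion class
    mix of 30% early active / 25% chronic demyelinated / 45% remyelinated,
    normal-appearing white matter at 0.65-0.75 normalized PDw intensity,
    demyelination lasting 4-7 weeks and remyelination 4-9 weeks, and peak
    lesion volumes log-uniform around the 0.5 µL remyelination decision
    boundary.
    """

    grid_shape: Tuple[int, int, int] = (64, 64, 24)
    voxel_size_mm: Tuple[float, float, float] = DEFAULT_VOXEL_SIZE_MM
    n_timepoints: int = 22
    scan_interval_weeks: float = 1.0
    n_lesions: int = 8
    class_proportions: Tuple[float, float, float] = (0.30, 0.25, 0.45)
    nawm_intensity_band: Tuple[float, float] = (0.65, 0.75)
    lesion_peak_intensity_range: Tuple[float, float] = (0.85, 1.00)
    demyelination_duration_weeks_range: Tuple[int, int] = (4, 7)
    remyelination_duration_weeks_range: Tuple[int, int] = (4, 9)
    peak_volume_ul_range: Tuple[float, float] = (0.02, 3.0)
    size_rule_threshold_ul: float = 0.5
    noise_sd: float = 0.01
    enhancement_offset: float = 0.2
    enhancement_probability: float = 0.82
    min_contrast: float = 0.15
    scanner_gain: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if abs(sum(self.class_proportions) - 1.0) > 1e-9:
            raise ValueError("class_proportions must sum to 1 within 1e-9")
        if any(p < 0 for p in self.class_proportions):
            raise ValueError("class_proportions must be non-negative")
        for name in ("demyelination_duration_weeks_range",
                     "remyelination_duration_weeks_range"):
            lo, hi = getattr(self, name)
            if lo <= 0 or hi < lo:
                raise ValueError(f"{name} must be positive and ordered, got ({lo}, {hi})")
        if self.scan_interval_weeks <= 0:
            raise ValueError("scan_interval_weeks must be > 0")
        if self.n_timepoints < 5:
            raise ValueError("n_timepoints must be >= 5 (>=2 baseline scans plus "
                             "a lesion trajectory)")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        lo, hi = self.peak_volume_ul_range
        if lo <= 0 or hi < lo:
            raise ValueError("peak_volume_ul_range must be positive and ordered")

    @property
    def voxel_volume_ul(self) -> float:
        """Volume of one voxel in µL; 0.0225 at the default spacing."""
        return float(np.prod(self.voxel_size_mm))

    @property
    def weeks(self) -> np.ndarray:
        return np.arange(self.n_timepoints) * self.scan_interval_weeks


# Class-conditional terminal-histology endpoints.
# PLP/LFB unstained-area percentages (mean, sd) follow the reference values
# for marmoset EAE lesion categories; oligodendrocyte (ASPA+/Olig2+) and OPC
# (ASPA-/Olig2+) counts and Iba1 positive-pixel density encode the
# qualitative ordering (oligodendrocyte repopulation in remyelinated lesions,
# OPC excess in young early-active lesions, prominent microglial infiltration
# only in early-active lesions).
HISTO_CLASS_MOMENTS: Dict[LesionClass, Dict[str, Tuple[float, float]]] = {
    LesionClass.EARLY_ACTIVE: {
        "plp_unstained_pct": (58.0, 25.0),
        "lfb_unstained_pct": (63.0, 26.0),
        "oligo_count": (8.0, 4.0),
        "opc_count": (15.0, 5.0),
        "iba1_density": (0.50, 0.10),
    },
    LesionClass.CHRONIC_DEMYELINATED: {
        "plp_unstained_pct": (38.0, 25.0),
        "lfb_unstained_pct": (43.0, 26.0),
        "oligo_count": (5.0, 3.0),
        "opc_count": (4.0, 2.0),
        "iba1_density": (0.15, 0.05),
    },
    LesionClass.REMYELINATED: {
        "plp_unstained_pct": (4.5, 1.1),
        "lfb_unstained_pct": (15.0, 25.0),
        "oligo_count": (25.0, 6.0),
        "opc_count": (6.0, 2.0),
        "iba1_density": (0.08, 0.03),
    },
}

#: Normal-appearing white matter endpoints (mean, sd).
NAWM_HISTO_MOMENTS: Dict[str, Tuple[float, float]] = {
    "plp_unstained_pct": (2.6, 0.3),
    "lfb_unstained_pct": (3.0, 0.4),
    "oligo_count": (35.0, 5.0),
    "opc_count": (5.0, 2.0),
    "iba1_density": (0.05, 0.02),
}


@dataclass
class HistoTruth:
    """Per-lesion terminal histology ground truth."""

    plp_unstained_pct: float
    lfb_unstained_pct: float
    oligo_count: int
    opc_count: int
    iba1_density: float

    def __post_init__(self) -> None:
        for name in ("plp_unstained_pct", "lfb_unstained_pct"):
            v = getattr(self, name)
            if not 0 <= v <= 100:
                raise ValueError(f"{name} must be in [0, 100], got {v}")
        if self.oligo_count < 0 or self.opc_count < 0:
            raise ValueError("cell counts must be >= 0")
        if self.iba1_density < 0:
            raise ValueError("iba1_density must be >= 0")


@dataclass
class GroundTruthLesion:
    """Everything the generator knows about one simulated lesion."""

    lesion_id: int
    true_class: LesionClass
    onset_week: float
    peak_volume_ul: float
    peak_intensity: float
    demyelination_duration_weeks: float
    remyelination_onset_week: Optional[float]
    remyelination_duration_weeks: Optional[float]
    center_voxel: Tuple[int, int, int]
    enhancement_weeks: Set[float]
    histo_truth: HistoTruth
    # voxel-level geometry (not serialized in the JSON manifest)
    peak_voxels: Optional[np.ndarray] = field(default=None, repr=False)
    voxel_order: Optional[np.ndarray] = field(default=None, repr=False)

    def __post_init__(self) -> None:
        is_remyel = self.true_class is LesionClass.REMYELINATED
        if is_remyel != (self.remyelination_onset_week is not None):
            raise ValueError(
                "remyelination_onset_week must be present iff class is remyelinated"
            )

    @property
    def age_at_week(self):
        return lambda week: week - self.onset_week

    def to_manifest_dict(self) -> dict:
        d = {
            "lesion_id": self.lesion_id,
            "true_class": self.true_class.value,
            "onset_week": self.onset_week,
            "peak_volume_ul": self.peak_volume_ul,
            "peak_intensity": self.peak_intensity,
            "demyelination_duration_weeks": self.demyelination_duration_weeks,
            "remyelination_onset_week": self.remyelination_onset_week,
            "remyelination_duration_weeks": self.remyelination_duration_weeks,
            "center_voxel": list(self.center_voxel),
            "enhancement_weeks": sorted(self.enhancement_weeks),
            "histo_truth": asdict(self.histo_truth),
        }
        return d


@dataclass
class StainImageSet:
    """2D stain channels for one lesion's terminal histology section.

    Channels are uint16 images sharing shape and pixel size; a value of
    exactly 0 encodes "unstained" (the null-pixel convention used by
    threshold-based demyelination quantification).
    """

    channels: Dict[str, np.ndarray]
    pixel_size_um: float
    lesion_center_px: Tuple[int, int]

    def __post_init__(self) -> None:
        shapes = {c.shape for c in self.channels.values()}
        if len(shapes) > 1:
            raise ValueError("all stain channels must share one shape")
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be > 0")


# --------------------------------------------------------------------------
# Anatomy and ground-truth sampling
# --------------------------------------------------------------------------

def reference_masks(grid_shape: Sequence[int]) -> Tuple[np.ndarray, np.ndarray]:
    """Gray- and white-matter reference masks for the synthetic brain.

    White matter is a central box (half the in-plane extent, interior
    slices); gray matter is everything else. No realistic anatomy is
    attempted: the masks exist to define the normalization reference and
    the lesion placement domain.
    """
    nx, ny, nz = grid_shape
    wm = np.zeros(tuple(grid_shape), dtype=bool)
    wm[nx // 4: nx - nx // 4, ny // 4: ny - ny // 4, 2: max(3, nz - 2)] = True
    gm = ~wm
    return gm, wm


def _ellipsoid_voxels(
    center: Tuple[int, int, int],
    radii_mm: np.ndarray,
    grid_shape: Sequence[int],
    voxel_size_mm: Sequence[float],
) -> Tuple[np.ndarray, np.ndarray]:
    """Voxels inside an axis-aligned ellipsoid plus their normalized distance.

    Returns (indices [n, 3], u [n]) with u the ellipsoidal norm in [0, 1],
    sorted by increasing u (stable order for deterministic growth).
    """
    vs = np.asarray(voxel_size_mm, dtype=float)
    lo = [max(0, int(np.floor(center[i] - radii_mm[i] / vs[i])) ) for i in range(3)]
    hi = [min(grid_shape[i] - 1, int(np.ceil(center[i] + radii_mm[i] / vs[i])))
          for i in range(3)]
    ranges = [np.arange(lo[i], hi[i] + 1) for i in range(3)]
    gx, gy, gz = np.meshgrid(*ranges, indexing="ij")
    dx = (gx - center[0]) * vs[0] / radii_mm[0]
    dy = (gy - center[1]) * vs[1] / radii_mm[1]
    dz = (gz - center[2]) * vs[2] / radii_mm[2]
    u = np.sqrt(dx * dx + dy * dy + dz * dz)
    inside = u <= 1.0
    idx = np.stack([gx[inside], gy[inside], gz[inside]], axis=1)
    uu = u[inside]
    order = np.argsort(uu, kind="stable")
    return idx[order], uu[order]


_MIN_PEAK_VOXELS = 5  # every lesion must survive the 4-voxel minimum filter
_MIN_ONSET_VOXELS = 5


def _sample_lesion_geometry(
    rng: np.random.Generator,
    target_volume_ul: float,
    wm_mask: np.ndarray,
    occupied: np.ndarray,
    grid_shape: Sequence[int],
    voxel_size_mm: Sequence[float],
    lesion_index: int,
    max_retries: int = 200,
) -> Tuple[Tuple[int, int, int], np.ndarray, np.ndarray]:
    """Place an ellipsoidal lesion inside white matter, avoiding collisions.

    Lesions must not touch each other even diagonally (else they would fuse
    into one 26-connected component); a 1-voxel Chebyshev margin around
    already-occupied voxels is enforced.
    """
    from scipy import ndimage

    vs = np.asarray(voxel_size_mm, dtype=float)
    r0 = (3.0 * target_volume_ul / (4.0 * np.pi)) ** (1.0 / 3.0)
    jitter = rng.uniform(0.85, 1.18, size=3)
    jitter /= np.prod(jitter) ** (1.0 / 3.0)  # keep target volume
    radii = np.maximum(r0 * jitter, 0.55 * vs)  # at least one voxel each axis

    forbidden = ndimage.binary_dilation(occupied, structure=np.ones((3, 3, 3)))
    wm_idx = np.argwhere(wm_mask)
    for _ in range(max_retries):
        cx, cy, cz = wm_idx[rng.integers(len(wm_idx))]
        center = (int(cx), int(cy), int(cz))
        idx, u = _ellipsoid_voxels(center, radii, grid_shape, voxel_size_mm)
        scale = 1.0
        while len(idx) < _MIN_PEAK_VOXELS and scale < 4.0:
            scale *= 1.15
            idx, u = _ellipsoid_voxels(center, radii * scale, grid_shape,
                                       voxel_size_mm)
        if len(idx) < _MIN_PEAK_VOXELS:
            continue
        if not wm_mask[idx[:, 0], idx[:, 1], idx[:, 2]].all():
            continue
        if forbidden[idx[:, 0], idx[:, 1], idx[:, 2]].any():
            continue
        return center, idx, u
    raise RuntimeError(
        f"could not place lesion {lesion_index} after {max_retries} retries: "
        f"grid too small or too crowded for a {target_volume_ul:.3g} µL lesion"
    )


def sample_histo_truth(
    lesion_class: Optional[LesionClass],
    rng: np.random.Generator,
) -> HistoTruth:
    """Draw terminal histology endpoints for a lesion class (None = NAWM)."""
    moments = (NAWM_HISTO_MOMENTS if lesion_class is None
               else HISTO_CLASS_MOMENTS[lesion_class])

    def draw(name: str) -> float:
        mu, sd = moments[name]
        return float(rng.normal(mu, sd))

    return HistoTruth(
        plp_unstained_pct=float(np.clip(draw("plp_unstained_pct"), 0.0, 100.0)),
        lfb_unstained_pct=float(np.clip(draw("lfb_unstained_pct"), 0.0, 100.0)),
        oligo_count=int(max(0, round(draw("oligo_count")))),
        opc_count=int(max(0, round(draw("opc_count")))),
        iba1_density=float(np.clip(draw("iba1_density"), 0.0, 1.0)),
    )


def _log_uniform(rng: np.random.Generator, lo: float, hi: float) -> float:
    return float(np.exp(rng.uniform(np.log(lo), np.log(hi))))


def sample_ground_truth(
    config: SimulationConfig,
    rng: Optional[np.random.Generator] = None,
    place_geometry: bool = True,
) -> Tuple[float, List[GroundTruthLesion]]:
    """Sample the subject baseline and all ground-truth lesions.

    Returns (baseline_wm_intensity, lesions). With ``place_geometry=False``
    only classes, timings, sizes and histology endpoints are sampled — no
    voxel geometry — which is enough for cohort-level statistics and is much
    cheaper than a full volume simulation.

    Onset weeks are drawn on the scan grid so that each class's trajectory
    fits the study: remyelinated lesions complete demyelination plus
    remyelination before the terminal scan; chronic lesions appear at least
    3 scans before the end (their transient enhancement resolves); early
    active lesions appear within the last 2 scan intervals and are still
    enhancing at the terminal scan.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    classes = [LesionClass.EARLY_ACTIVE, LesionClass.CHRONIC_DEMYELINATED,
               LesionClass.REMYELINATED]
    t_idx = config.n_timepoints - 1
    interval = config.scan_interval_weeks
    band_lo, band_hi = config.nawm_intensity_band
    baseline = float(rng.uniform(band_lo, band_hi))

    gm_mask, wm_mask = reference_masks(config.grid_shape)
    occupied = np.zeros(tuple(config.grid_shape), dtype=bool)
    lesions: List[GroundTruthLesion] = []
    for i in range(config.n_lesions):
        cls = classes[int(rng.choice(3, p=list(config.class_proportions)))]
        d_lo, d_hi = config.demyelination_duration_weeks_range
        r_lo, r_hi = config.remyelination_duration_weeks_range
        demyel = float(rng.integers(int(d_lo), int(d_hi) + 1))
        remyel: Optional[float] = None

        vol_lo, vol_hi = config.peak_volume_ul_range
        min_vol = _MIN_PEAK_VOXELS * config.voxel_volume_ul
        if cls is LesionClass.REMYELINATED:
            remyel = float(rng.integers(int(r_lo), int(r_hi) + 1))
            peak_vol = float(np.clip(_log_uniform(rng, vol_lo, vol_hi),
                                     min_vol, config.size_rule_threshold_ul))
            latest = t_idx - int(np.ceil((demyel + remyel) / interval))
        elif cls is LesionClass.CHRONIC_DEMYELINATED:
            peak_vol = float(max(_log_uniform(rng, vol_lo, vol_hi), min_vol))
            latest = t_idx - 3
        else:  # early active: young lesion, still enhancing at terminal
            peak_vol = float(max(_log_uniform(rng, vol_lo, vol_hi), min_vol))
            latest = t_idx - 1
        earliest = 2  # >= 2 lesion-free baseline scans
        if cls is LesionClass.EARLY_ACTIVE:
            earliest = max(2, t_idx - 2)
        if latest < earliest:
            raise ValueError(
                f"timeline too short for a {cls.value} lesion trajectory: "
                f"need onset index in [{earliest}, {latest}] with "
                f"{config.n_timepoints} timepoints"
            )
        onset_idx = int(rng.integers(earliest, latest + 1))
        onset_week = onset_idx * interval

        peak_lo = max(config.lesion_peak_intensity_range[0],
                      baseline + config.min_contrast)
        peak_hi = config.lesion_peak_intensity_range[1]
        if peak_hi < peak_lo:
            raise ValueError(
                "lesion_peak_intensity_range incompatible with NAWM band and "
                "minimum contrast"
            )
        peak_intensity = float(rng.uniform(peak_lo, peak_hi))

        # enhancement at first detection (always, for terminal early-active)
        enh_weeks: Set[float] = set()
        if cls is LesionClass.EARLY_ACTIVE:
            enh_weeks = {w * interval for w in range(onset_idx, t_idx + 1)}
        elif rng.random() < config.enhancement_probability:
            n_enh = int(rng.integers(1, 4))  # up to 2 timepoints after detection
            enh_weeks = {w * interval for w in range(onset_idx,
                                                     min(onset_idx + n_enh, t_idx))}

        histo = sample_histo_truth(cls, rng)

        center = (0, 0, 0)
        peak_voxels = voxel_order = None
        if place_geometry:
            center, peak_voxels, voxel_order = _sample_lesion_geometry(
                rng, peak_vol, wm_mask, occupied, config.grid_shape,
                config.voxel_size_mm, lesion_index=i,
            )
            if cls is LesionClass.REMYELINATED:
                # keep the discretized peak within the size-rule boundary:
                # drop outermost voxels (largest ellipsoidal distance) first
                n_max = max(_MIN_PEAK_VOXELS,
                            int(config.size_rule_threshold_ul
                                / config.voxel_volume_ul))
                peak_voxels = peak_voxels[:n_max]
                voxel_order = voxel_order[:n_max]
            occupied[peak_voxels[:, 0], peak_voxels[:, 1], peak_voxels[:, 2]] = True
            peak_vol = len(peak_voxels) * config.voxel_volume_ul

        lesions.append(GroundTruthLesion(
            lesion_id=i + 1,
            true_class=cls,
            onset_week=onset_week,
            peak_volume_ul=peak_vol,
            peak_intensity=peak_intensity,
            demyelination_duration_weeks=demyel,
            remyelination_onset_week=(onset_week + demyel
                                      if cls is LesionClass.REMYELINATED else None),
            remyelination_duration_weeks=remyel,
            center_voxel=center,
            enhancement_weeks=enh_weeks,
            histo_truth=histo,
            peak_voxels=peak_voxels,
            voxel_order=voxel_order,
        ))
    return baseline, lesions


# --------------------------------------------------------------------------
# Trajectory model
# --------------------------------------------------------------------------

_DECAY_EXPONENT = 4.0  # convex remyelination decay: slow initial drop, then
#                        a rapid return into the isointensity band, matching
#                        a downward slope followed by a plateau


def lesion_intensity(lesion: GroundTruthLesion, baseline: float, week: float) -> float:
    """Noiseless mean lesion intensity at a given week (normalized units)."""
    if week < lesion.onset_week:
        return baseline
    d = lesion.demyelination_duration_weeks
    p = lesion.peak_intensity
    entry = max(baseline + 0.1, min(p, 0.85))  # hyperintense at first scan
    t = week - lesion.onset_week
    if t <= d:
        return entry + (p - entry) * (t / d)
    if lesion.true_class is not LesionClass.REMYELINATED:
        return p
    r = lesion.remyelination_duration_weeks
    s = (t - d) / r
    if s >= 1.0:
        return baseline
    return p - (p - baseline) * s ** _DECAY_EXPONENT


def lesion_volume_fraction(lesion: GroundTruthLesion, week: float) -> float:
    """Noiseless lesion volume as a fraction of peak volume."""
    if week < lesion.onset_week:
        return 0.0
    d = lesion.demyelination_duration_weeks
    t = week - lesion.onset_week
    if t >= d:
        return 1.0
    start = max(0.15, _MIN_ONSET_VOXELS / max(_MIN_ONSET_VOXELS,
                                              lesion.peak_volume_ul / 0.0225))
    return start + (1.0 - start) * (t / d)


def _current_voxels(lesion: GroundTruthLesion, week: float) -> np.ndarray:
    """Indices of the voxels the lesion occupies at a given week."""
    frac = lesion_volume_fraction(lesion, week)
    if frac <= 0:
        return lesion.peak_voxels[:0]
    n_total = len(lesion.peak_voxels)
    # fraction of volume -> fraction of ellipsoidal radius cubed
    u_cut = frac ** (1.0 / 3.0)
    n = int(np.count_nonzero(lesion.voxel_order <= u_cut))
    n = max(n, min(_MIN_ONSET_VOXELS, n_total))
    return lesion.peak_voxels[:n]


# --------------------------------------------------------------------------
# Volume rendering
# --------------------------------------------------------------------------

# Tissue values for the auxiliary contrasts (normalized units).
_T1_GM, _T1_WM, _T1_LESION = 0.90, 1.00, 0.95
_M0_VALUE = 1.0
_MTR_GM, _MTR_WM = 0.30, 0.40
_MTR_LESION_DROP = 0.25  # maximal MTR decrease in a fully demyelinated lesion


def simulate_study(
    config: SimulationConfig,
    subject_id: str = "synthetic",
) -> Tuple[StudyTimeline, List[GroundTruthLesion]]:
    """Generate one serial multicontrast study with known ground truth.

    Returns a :class:`~remyetrack.tracking.StudyTimeline` holding PDw,
    pre/post-gadolinium T1w and MT-on/MT-off series (all on one grid, with
    GM/WM reference masks) plus the list of ground-truth lesions. With
    ``scanner_gain`` = 1 the PDw series is emitted already GM-normalized;
    a different gain rescales all PDw volumes, which downstream
    normalization must undo.
    """
    rng = np.random.default_rng(config.seed)
    baseline, lesions = sample_ground_truth(config, rng, place_geometry=True)
    gm_mask, wm_mask = reference_masks(config.grid_shape)
    weeks = config.weeks
    shape = tuple(config.grid_shape)

    def noisy(arr: np.ndarray) -> np.ndarray:
        if config.noise_sd > 0:
            arr = arr + rng.normal(0.0, config.noise_sd, size=shape)
        return arr.astype(np.float32)

    pdw_base = np.where(wm_mask, baseline, 1.0)
    t1_base = np.where(wm_mask, _T1_WM, _T1_GM)
    mtr_base = np.where(wm_mask, _MTR_WM, _MTR_GM)

    volumes: Dict[str, List[Volume]] = {t: [] for t in
                                        ("PDw", "T1w_pre", "T1w_post",
                                         "MT_on", "MT_off")}
    for wi, week in enumerate(weeks):
        pdw = pdw_base.copy()
        t1_pre = t1_base.copy()
        t1_post = t1_base.copy()
        mtr = mtr_base.copy()
        for les in lesions:
            vox = _current_voxels(les, week)
            if len(vox) == 0:
                continue
            ii, jj, kk = vox[:, 0], vox[:, 1], vox[:, 2]
            intensity = lesion_intensity(les, baseline, week)
            pdw[ii, jj, kk] = intensity
            t1_pre[ii, jj, kk] = _T1_LESION
            t1_post[ii, jj, kk] = _T1_LESION
            if week in les.enhancement_weeks:
                t1_post[ii, jj, kk] = _T1_LESION + config.enhancement_offset
            severity = np.clip((intensity - baseline) / _MTR_LESION_DROP, 0.0, 1.0)
            mtr[ii, jj, kk] = _MTR_WM - _MTR_LESION_DROP * severity
        m0 = np.full(shape, _M0_VALUE)
        msat = m0 * (1.0 - mtr)

        def vol(data: np.ndarray, tag: str) -> Volume:
            return Volume(noisy(data), voxel_size_mm=config.voxel_size_mm,
                          contrast_tag=tag, week=float(week))

        volumes["PDw"].append(vol(pdw * config.scanner_gain, "PDw"))
        volumes["T1w_pre"].append(vol(t1_pre, "T1w_pre"))
        volumes["T1w_post"].append(vol(t1_post, "T1w_post"))
        volumes["MT_off"].append(vol(m0, "MT_off"))
        volumes["MT_on"].append(vol(msat, "MT_on"))

    timeline = StudyTimeline(
        subject_id=subject_id,
        weeks=weeks,
        volumes=volumes,
        gm_mask=gm_mask,
        wm_mask=wm_mask,
        voxel_size_mm=config.voxel_size_mm,
    )
    return timeline, lesions


def manifest_dict(
    config: SimulationConfig,
    baseline: float,
    lesions: List[GroundTruthLesion],
    subject_id: str = "synthetic",
) -> dict:
    """JSON-serializable ground-truth manifest for one simulated subject."""
    return {
        "subject_id": subject_id,
        "config": {**asdict(config)},
        "baseline_wm_intensity": baseline,
        "lesions": [l.to_manifest_dict() for l in lesions],
    }


# --------------------------------------------------------------------------
# Histology rendering
# --------------------------------------------------------------------------

_STAIN_LO, _STAIN_HI = 20000, 60000  # uint16 range of "stained" pixel values
_CELL_VALUE = 60000
_CELL_RADIUS_PX = 2


def _disc_offsets(radius: int) -> np.ndarray:
    r = np.arange(-radius, radius + 1)
    gx, gy = np.meshgrid(r, r, indexing="ij")
    inside = gx * gx + gy * gy <= radius * radius
    return np.stack([gx[inside], gy[inside]], axis=1)


def _demyelinated_region(shape: Tuple[int, int], n_null: int,
                         rng: np.random.Generator) -> np.ndarray:
    """Boolean mask of exactly n_null pixels forming a center-weighted blob."""
    h, w = shape
    gx, gy = np.meshgrid(np.arange(h), np.arange(w), indexing="ij")
    dist = np.hypot(gx - (h - 1) / 2.0, gy - (w - 1) / 2.0)
    dist = dist + rng.uniform(0.0, 1.0, size=shape)  # irregular edge
    cut = np.partition(dist.ravel(), n_null - 1)[n_null - 1] if n_null > 0 else -1.0
    mask = dist <= cut
    # resolve ties at the cut to the exact count
    extra = int(mask.sum()) - n_null
    if extra > 0:
        tie_idx = np.argwhere(dist == cut)
        for i in range(extra):
            mask[tuple(tie_idx[i])] = False
    return mask


def render_histology(
    truth: HistoTruth,
    roi_um: float = 1500.0,
    pixel_size_um: float = 4.0,
    seed: int = 0,
) -> StainImageSet:
    """Render 2D stain channels that quantify back to the given truth.

    The PLP and LFB channels contain a center-weighted null-pixel (value 0)
    region whose pixel count matches the unstained percentage exactly (up to
    one pixel of rounding); the Iba1 channel has a positive-pixel fraction
    equal to ``iba1_density``; the ASPA and Olig2 channels contain
    non-touching disc-shaped cells such that exactly ``oligo_count`` cells
    are double positive and ``opc_count`` are Olig2-only.
    """
    if roi_um <= 0 or pixel_size_um <= 0:
        raise ValueError("roi_um and pixel_size_um must be > 0")
    rng = np.random.default_rng(seed)
    # even side so a centered square ROI of the same physical size tiles
    # the image exactly
    side = max(8, 2 * int(round(roi_um / pixel_size_um / 2.0)))
    shape = (side, side)
    npix = side * side

    def stained(n: int) -> np.ndarray:
        return rng.integers(_STAIN_LO, _STAIN_HI, size=n, dtype=np.uint16)

    channels: Dict[str, np.ndarray] = {}
    for name, pct in (("PLP", truth.plp_unstained_pct),
                      ("LFB", truth.lfb_unstained_pct)):
        img = np.zeros(shape, dtype=np.uint16)
        img[:] = stained(npix).reshape(shape)
        n_null = int(round(pct / 100.0 * npix))
        if n_null > 0:
            img[_demyelinated_region(shape, n_null, rng)] = 0
        channels[name] = img

    iba1 = np.zeros(shape, dtype=np.uint16)
    n_pos = int(round(truth.iba1_density * npix))
    pos_idx = rng.choice(npix, size=n_pos, replace=False)
    iba1.ravel()[pos_idx] = stained(n_pos)
    channels["Iba1"] = iba1

    # cells on a jittered grid with guaranteed separation
    spacing = 2 * _CELL_RADIUS_PX + 2
    margin = _CELL_RADIUS_PX + 1
    grid_pts = [
        (x, y)
        for x in range(margin, side - margin, spacing)
        for y in range(margin, side - margin, spacing)
    ]
    n_cells = truth.oligo_count + truth.opc_count
    if n_cells > len(grid_pts):
        raise ValueError(
            f"cannot pack {n_cells} cells into a {side}x{side} px image "
            f"(capacity {len(grid_pts)})"
        )
    chosen = rng.choice(len(grid_pts), size=n_cells, replace=False)
    offsets = _disc_offsets(_CELL_RADIUS_PX)
    aspa = np.zeros(shape, dtype=np.uint16)
    olig2 = np.zeros(shape, dtype=np.uint16)
    for rank, ci in enumerate(chosen):
        cx, cy = grid_pts[int(ci)]
        xs, ys = cx + offsets[:, 0], cy + offsets[:, 1]
        olig2[xs, ys] = _CELL_VALUE
        if rank < truth.oligo_count:  # double positive = mature oligodendrocyte
            aspa[xs, ys] = _CELL_VALUE
    channels["ASPA"] = aspa
    channels["Olig2"] = olig2

    center = (side // 2, side // 2)
    return StainImageSet(channels=channels, pixel_size_um=pixel_size_um,
                         lesion_center_px=center)
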