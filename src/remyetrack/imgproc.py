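"""Voxelwise image computations and lesion segmentation on single timepoints.

All operations act on aligned 3D grids: gray-matter normalization of PDw
volumes, magnetization transfer ratio (MTR) maps from MT-on/MT-off pairs,
pre/post-gadolinium T1 subtraction with enhancement detection, and a
transparent threshold + connected-component white-matter lesion segmenter
with the standard 4-voxel minimum size filter.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Optional, Tuple

import numpy as np
from scipy import ndimage

logger = logging.getLogger(__name__)

#: Valid contrast tags for a :class:`Volume`.
CONTRAST_TAGS = (
    "PDw",
    "T1w_pre",
    "T1w_post",
    "MT_on",
    "MT_off",
    "MTR",
    "T1_subtraction",
)

#: Default per-voxel size in mm (150 µm in-plane, 1 mm slices).
DEFAULT_VOXEL_SIZE_MM = (0.15, 0.15, 1.0)


@dataclass
class Volume:
    """A single 3D scalar image with acquisition metadata.

    Parameters
    ----------
    data
        3D array of voxel values.
    voxel_size_mm
        Physical voxel edge lengths in mm; their product is the voxel volume
        in mm^3 (equivalently µL).
    contrast_tag
        One of :data:`CONTRAST_TAGS`.
    week
        Acquisition time in weeks post-immunization.
    """

    data: np.ndarray
    voxel_size_mm: Tuple[float, float, float] = DEFAULT_VOXEL_SIZE_MM
    contrast_tag: str = "PDw"
    week: float = 0.0

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"Volume data must be 3D, got ndim={self.data.ndim}")
        if any(s <= 0 for s in self.voxel_size_mm):
            raise ValueError(f"voxel_size_mm must be positive, got {self.voxel_size_mm}")
        if self.contrast_tag not in CONTRAST_TAGS:
            raise ValueError(
                f"unknown contrast_tag {self.contrast_tag!r}; expected one of {CONTRAST_TAGS}"
            )

    @property
    def voxel_volume_ul(self) -> float:
        """Volume of one voxel in µL (= mm^3)."""
        return float(np.prod(self.voxel_size_mm))

    def with_data(self, data: np.ndarray, contrast_tag: Optional[str] = None) -> "Volume":
        """Copy of this volume with new data (and optionally a new tag)."""
        out = replace(self, data=data)
        if contrast_tag is not None:
            out.contrast_tag = contrast_tag
        return out


@dataclass
class LabelMap:
    """Connected-component labels aligned to a volume grid.

    Labels are positive integers 1..n_components; 0 is background. After
    size filtering every surviving component has at least the configured
    minimum voxel count.
    """

    labels: np.ndarray
    n_components: int
    voxel_size_mm: Tuple[float, float, float] = DEFAULT_VOXEL_SIZE_MM

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3:
            raise ValueError("LabelMap labels must be 3D")
        if self.labels.min() < 0:
            raise ValueError("labels must be non-negative")

    def component_mask(self, label: int) -> np.ndarray:
        return self.labels == label

    def component_sizes(self) -> dict:
        """Map label -> voxel count for every nonzero label."""
        labs, counts = np.unique(self.labels[self.labels > 0], return_counts=True)
        return {int(l): int(c) for l, c in zip(labs, counts)}


def _as_bool_mask(mask: np.ndarray, shape: Tuple[int, ...], name: str) -> np.ndarray:
    mask = np.asarray(mask).astype(bool)
    if mask.shape != shape:
        raise ValueError(f"{name} shape {mask.shape} does not match volume shape {shape}")
    return mask


def normalize_to_gm(pdw: Volume, gm_mask: np.ndarray) -> Volume:
    """Normalize a PDw volume so mean gray-matter intensity equals 1.

    Dividing by the mean signal over the gray-matter reference mask puts
    all timepoints of a serial study on a common intensity scale; normal
    white matter then sits at a characteristic 0.65-0.75 band and lesions
    become comparably hyperintense across weeks.

    Raises
    ------
    ValueError
        If the mask is empty or the mean gray-matter intensity is not
        strictly positive.
    """
    mask = _as_bool_mask(gm_mask, pdw.data.shape, "gm_mask")
    if not mask.any():
        raise ValueError("gm_mask is empty")
    gm_mean = float(np.mean(pdw.data[mask]))
    if gm_mean <= 0:
        raise ValueError(f"mean gray-matter intensity must be > 0, got {gm_mean}")
    return pdw.with_data(pdw.data / gm_mean)


def compute_mtr(m0: Volume, msat: Volume, eps: float = 1e-6) -> Volume:
    """Magnetization transfer ratio map, voxelwise (M0 - MSAT) / M0.

    Voxels with |M0| <= eps are masked out (set to NaN): the ratio is
    undefined where there is no reference signal.
    """
    if m0.data.shape != msat.data.shape:
        raise ValueError(
            f"shape mismatch: M0 {m0.data.shape} vs MSAT {msat.data.shape}"
        )
    if eps <= 0:
        raise ValueError("eps must be > 0")
    m0d = np.asarray(m0.data, dtype=float)
    out = np.full_like(m0d, np.nan)
    valid = np.abs(m0d) > eps
    out[valid] = (m0d[valid] - msat.data[valid]) / m0d[valid]
    return m0.with_data(out, contrast_tag="MTR")


def t1_subtraction(pre: Volume, post: Volume) -> Volume:
    """Voxelwise post-gadolinium minus pre-gadolinium T1w subtraction."""
    if pre.data.shape != post.data.shape:
        raise ValueError(
            f"shape mismatch: pre {pre.data.shape} vs post {post.data.shape}"
        )
    return pre.with_data(
        np.asarray(post.data, dtype=float) - np.asarray(pre.data, dtype=float),
        contrast_tag="T1_subtraction",
    )


def detect_enhancement(
    subtraction: Volume,
    lesion_mask: np.ndarray,
    background_mask: np.ndarray,
    k_sigma: float = 3.0,
) -> Tuple[bool, float]:
    """Decide whether a lesion enhances on the T1 subtraction image.

    A lesion is called enhancing when its mean subtraction signal exceeds
    the background mean by more than ``k_sigma`` background standard
    deviations — i.e. the post-contrast signal increase inside the lesion
    is not explainable by noise.

    Returns
    -------
    (enhancing, mean_enhancement)
        ``mean_enhancement`` is the mean subtraction value over the lesion.
    """
    les = _as_bool_mask(lesion_mask, subtraction.data.shape, "lesion_mask")
    bg = _as_bool_mask(background_mask, subtraction.data.shape, "background_mask")
    if not les.any():
        raise ValueError("lesion_mask is empty")
    if not bg.any():
        raise ValueError("background_mask is empty")
    lesion_mean = float(np.mean(subtraction.data[les]))
    bg_mean = float(np.mean(subtraction.data[bg]))
    bg_sd = float(np.std(subtraction.data[bg]))
    return lesion_mean > bg_mean + k_sigma * bg_sd, lesion_mean


def _connectivity_structure(connectivity: int) -> np.ndarray:
    if connectivity == 26:
        return np.ones((3, 3, 3), dtype=bool)
    if connectivity == 6:
        return ndimage.generate_binary_structure(3, 1)
    if connectivity == 18:
        return ndimage.generate_binary_structure(3, 2)
    raise ValueError(f"connectivity must be 6, 18 or 26, got {connectivity}")


def segment_lesions(
    pdw_norm: Volume,
    wm_mask: np.ndarray,
    intensity_threshold: float = 0.80,
    min_voxels: int = 4,
    connectivity: int = 26,
    gm_mask: Optional[np.ndarray] = None,
    norm_tolerance: float = 0.05,
) -> LabelMap:
    """Segment hyperintense white-matter lesions on a GM-normalized PDw volume.

    Thresholds the normalized PDw image inside the white-matter mask (the
    default 0.80 sits between the normal-appearing white-matter band ceiling,
    0.75, and typical lesion peaks, 0.85-1.00), extracts connected components
    (26-connectivity by default), and removes any component smaller than
    ``min_voxels`` voxels (default 4, the conventional minimum lesion size).

    Surviving components are relabeled 1..n deterministically: by descending
    voxel count, ties broken by lexicographically smallest centroid.

    If ``gm_mask`` is provided and the mean normalized gray-matter intensity
    deviates from 1 by more than ``norm_tolerance``, a warning is logged —
    the input is probably not normalized.
    """
    if min_voxels < 1:
        raise ValueError("min_voxels must be >= 1")
    wm = _as_bool_mask(wm_mask, pdw_norm.data.shape, "wm_mask")
    if gm_mask is not None:
        gm = _as_bool_mask(gm_mask, pdw_norm.data.shape, "gm_mask")
        if gm.any():
            gm_mean = float(np.mean(pdw_norm.data[gm]))
            if abs(gm_mean - 1.0) > norm_tolerance:
                logger.warning(
                    "segment_lesions: input does not look GM-normalized "
                    "(GM mean = %.4f)", gm_mean,
                )

    supra = (np.asarray(pdw_norm.data) > intensity_threshold) & wm
    structure = _connectivity_structure(connectivity)
    raw_labels, n_raw = ndimage.label(supra, structure=structure)

    out = np.zeros_like(raw_labels, dtype=np.int32)
    if n_raw == 0:
        return LabelMap(out, 0, voxel_size_mm=pdw_norm.voxel_size_mm)

    sizes = ndimage.sum_labels(supra, raw_labels, index=np.arange(1, n_raw + 1))
    keep = [i + 1 for i, s in enumerate(sizes) if s >= min_voxels]
    if not keep:
        return LabelMap(out, 0, voxel_size_mm=pdw_norm.voxel_size_mm)

    centroids = ndimage.center_of_mass(supra, raw_labels, index=keep)
    order = sorted(
        range(len(keep)),
        key=lambda i: (-sizes[keep[i] - 1], tuple(np.round(centroids[i], 9))),
    )
    for new_label, i in enumerate(order, start=1):
        out[raw_labels == keep[i]] = new_label
    return LabelMap(out, len(keep), voxel_size_mm=pdw_norm.voxel_size_mm)
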