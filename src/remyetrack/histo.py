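"""Stain-image quantification and histological lesion categorization.

Demyelination is measured as the percentage of null-valued (unstained)
pixels inside a region of interest centered on the lesion core, on myelin
protein (PLP) and myelin lipid (LFB) channels. Oligodendrocyte-lineage
cells are counted as connected components of Olig2-positive pixels:
double-positive (ASPA+/Olig2+) components are mature oligodendrocytes,
Olig2-only components are oligodendrocyte precursor cells (OPC). A
three-level histological category is then assigned from the unstained
percentages, the oligodendrocyte count and the Iba1 (microglia) density.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np
from scipy import ndimage

from .core import LesionClass

logger = logging.getLogger(__name__)

HistoCategory = LesionClass


@dataclass
class HistoMetrics:
    """Per-lesion stain quantification inside the core ROI."""

    plp_unstained_pct: float
    lfb_unstained_pct: float
    oligo_count: int
    opc_count: int
    iba1_density: float
    roi_area_um2: float

    def __post_init__(self) -> None:
        for name in ("plp_unstained_pct", "lfb_unstained_pct"):
            v = getattr(self, name)
            if not 0 <= v <= 100:
                raise ValueError(f"{name} must be in [0, 100], got {v}")
        if self.oligo_count < 0 or self.opc_count < 0:
            raise ValueError("cell counts must be >= 0")


@dataclass
class HistoThresholds:
    """Cutoffs for histological categorization.

    remyel_max_unstained_pct
        Maximum PLP unstained percentage for a remyelinated call (default 6:
        remyelinated lesions show less than 6% unstained area).
    oligo_min_count
        Minimum mature-oligodendrocyte count for a remyelinated call
        (default 12, above the chronic-lesion level: remyelination requires
        oligodendrocyte repopulation).
    iba1_inflammation_density
        Iba1 positive-pixel fraction at or above which a demyelinated lesion
        is called early active (prominent microglial infiltration).
    lfb_demyelinated_pct
        LFB unstained percentage above which the lipid stain reads
        "demyelinated" (default 20); PLP/LFB disagreement is flagged.
    """

    remyel_max_unstained_pct: float = 6.0
    oligo_min_count: int = 12
    iba1_inflammation_density: float = 0.30
    lfb_demyelinated_pct: float = 20.0


@dataclass
class HistoClassification:
    category: HistoCategory
    plp_lfb_discordant: bool


@dataclass
class RoiSpec:
    """ROI convention for the lesion-core region.

    ``kind="side"`` (default) reads the configured value as the side length
    of a square in µm; ``kind="area"`` reads it as the square's area in µm²
    (the literal small-ROI convention: 1500 µm² is a ~38.7 µm square).
    """

    kind: str = "side"
    value_um: float = 1500.0

    def side_um(self) -> float:
        if self.kind == "side":
            return self.value_um
        if self.kind == "area":
            return float(np.sqrt(self.value_um))
        raise ValueError(f"RoiSpec.kind must be 'side' or 'area', got {self.kind!r}")


def roi_from_center(
    center_px: Tuple[int, int],
    image_shape: Tuple[int, int],
    pixel_size_um: float,
    roi_spec: Optional[RoiSpec] = None,
) -> np.ndarray:
    """Boolean mask of a square ROI of configured physical size.

    The square is centered on ``center_px`` and clipped to the image; a
    clipped (smaller-than-nominal) ROI is logged as a warning. Raises if
    the region is degenerate after clipping or the center lies outside the
    image.
    """
    roi_spec = roi_spec or RoiSpec()
    h, w = image_shape
    cx, cy = center_px
    if not (0 <= cx < h and 0 <= cy < w):
        raise ValueError(f"center {center_px} outside image of shape {image_shape}")
    half = max(1, int(round(roi_spec.side_um() / pixel_size_um / 2.0)))
    x0, x1 = max(0, cx - half), min(h, cx + half)
    y0, y1 = max(0, cy - half), min(w, cy + half)
    if x1 <= x0 or y1 <= y0:
        raise ValueError("ROI degenerate after clipping to the image")
    nominal = (2 * half) ** 2
    actual = (x1 - x0) * (y1 - y0)
    if actual < nominal:
        logger.warning(
            "ROI clipped at image border: %d of %d nominal pixels", actual, nominal
        )
    mask = np.zeros(image_shape, dtype=bool)
    mask[x0:x1, y0:y1] = True
    return mask


def quantify_unstained(channel: np.ndarray, roi: np.ndarray) -> float:
    """Percentage of null-valued (value exactly 0) pixels inside the ROI.

    This is the threshold-based demyelinated-area measure:
    ``100 * n_null / n_total`` over the ROI.
    """
    channel = np.asarray(channel)
    roi = np.asarray(roi).astype(bool)
    if channel.shape != roi.shape:
        raise ValueError("channel and roi shapes differ")
    n_total = int(np.count_nonzero(roi))
    if n_total == 0:
        raise ValueError("ROI is empty")
    n_null = int(np.count_nonzero(channel[roi] == 0))
    return 100.0 * n_null / n_total


def count_cells(
    aspa: np.ndarray,
    olig2: np.ndarray,
    roi: np.ndarray,
    positivity_threshold: float = 0.0,
) -> Tuple[int, int]:
    """Count mature oligodendrocytes and OPC inside the ROI.

    Connected components (8-connectivity) of Olig2-positive pixels within
    the ROI are cells; a cell whose pixels are at least 50% ASPA-positive is
    a mature oligodendrocyte (ASPA+/Olig2+), otherwise an OPC
    (ASPA-/Olig2+). Pixels are positive when strictly above
    ``positivity_threshold``.

    Returns (oligo_count, opc_count).
    """
    aspa = np.asarray(aspa)
    olig2 = np.asarray(olig2)
    roi = np.asarray(roi).astype(bool)
    if aspa.shape != olig2.shape or aspa.shape != roi.shape:
        raise ValueError("ASPA, Olig2 and ROI must share one shape")
    lo = min(float(aspa.min()), float(olig2.min()))
    hi = max(float(aspa.max()), float(olig2.max()))
    if not (lo <= positivity_threshold <= hi):
        raise ValueError(
            f"positivity_threshold {positivity_threshold} outside channel range "
            f"[{lo}, {hi}]"
        )
    olig2_pos = (olig2 > positivity_threshold) & roi
    aspa_pos = aspa > positivity_threshold
    labels, n = ndimage.label(olig2_pos, structure=np.ones((3, 3), dtype=bool))
    oligo = opc = 0
    for lab in range(1, n + 1):
        cell = labels == lab
        frac_aspa = np.count_nonzero(aspa_pos & cell) / np.count_nonzero(cell)
        if frac_aspa >= 0.5:
            oligo += 1
        else:
            opc += 1
    return oligo, opc


def quantify_stains(
    channels: dict,
    roi: np.ndarray,
    pixel_size_um: float,
    positivity_threshold: float = 0.0,
) -> HistoMetrics:
    """Full per-lesion quantification of a stain channel set inside an ROI."""
    plp = quantify_unstained(channels["PLP"], roi)
    lfb = quantify_unstained(channels["LFB"], roi)
    oligo, opc = count_cells(channels["ASPA"], channels["Olig2"], roi,
                             positivity_threshold)
    iba1 = np.asarray(channels["Iba1"])
    iba1_density = float(
        np.count_nonzero(iba1[roi] > positivity_threshold) / np.count_nonzero(roi)
    )
    roi_area = float(np.count_nonzero(roi)) * pixel_size_um ** 2
    return HistoMetrics(
        plp_unstained_pct=plp,
        lfb_unstained_pct=lfb,
        oligo_count=oligo,
        opc_count=opc,
        iba1_density=iba1_density,
        roi_area_um2=roi_area,
    )


def classify_histology(
    metrics: HistoMetrics,
    iba1_density: Optional[float] = None,
    thresholds: Optional[HistoThresholds] = None,
) -> HistoClassification:
    """Assign the three-level histological category.

    A lesion is *remyelinated* when its PLP unstained area is at most
    ``remyel_max_unstained_pct`` AND mature oligodendrocytes have
    repopulated (count >= ``oligo_min_count``). Otherwise it is *early
    active* when Iba1 density indicates prominent inflammation, else
    *chronic, at least partially demyelinated*. A lesion remyelinated on
    PLP but demyelinated on LFB (> ``lfb_demyelinated_pct``) is classified
    by PLP and flagged discordant — myelin protein and lipid can
    reconstitute on different timelines.
    """
    thresholds = thresholds or HistoThresholds()
    if iba1_density is None:
        iba1_density = metrics.iba1_density
    plp_remyel = metrics.plp_unstained_pct <= thresholds.remyel_max_unstained_pct
    if plp_remyel and metrics.oligo_count >= thresholds.oligo_min_count:
        discordant = metrics.lfb_unstained_pct > thresholds.lfb_demyelinated_pct
        return HistoClassification(LesionClass.REMYELINATED, discordant)
    if iba1_density >= thresholds.iba1_inflammation_density:
        return HistoClassification(LesionClass.EARLY_ACTIVE, False)
    return HistoClassification(LesionClass.CHRONIC_DEMYELINATED, False)
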