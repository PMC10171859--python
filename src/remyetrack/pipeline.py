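"""End-to-end pipeline driver: simulate → segment → track → classify →
histology → concordance evaluation.

A :class:`PipelineConfig` fixes every stage's parameters plus one master
seed; two runs with equal configuration are bit-identical. The driver
simulates a multi-subject cohort (alternate subjects corticosteroid
treated), runs the full MRI analysis per subject, renders and quantifies
terminal histology per lesion, assembles the lesion label table, and writes
the evaluation report (MRI vs histology, and MRI vs generator ground
truth).
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd

from . import io as rio
from .core import LesionClass
from .histo import (
    HistoThresholds,
    RoiSpec,
    classify_histology,
    quantify_stains,
    roi_from_center,
)
from .imgproc import normalize_to_gm, segment_lesions
from .mriclass import (
    ClassificationRuleConfig,
    classify_track,
    estimate_remyelination_window,
    predict_by_peak_size,
)
from .stats import concordance_report, sensitivity_specificity, binarize_and_tabulate
from .synthgen import (
    GroundTruthLesion,
    SimulationConfig,
    manifest_dict,
    render_histology,
    simulate_study,
)
from .tracking import LesionTrack, build_tracks, tracks_to_dataframe

logger = logging.getLogger(__name__)


@dataclass
class SegmentationConfig:
    intensity_threshold: float = 0.80
    min_voxels: int = 4
    connectivity: int = 26
    min_overlap_voxels: int = 4


@dataclass
class HistologyConfig:
    roi_spec: RoiSpec = field(default_factory=RoiSpec)
    pixel_size_um: float = 4.0
    thresholds: HistoThresholds = field(default_factory=HistoThresholds)


@dataclass
class PipelineConfig:
    """Nested configuration for a full reproducible run."""

    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    segmentation: SegmentationConfig = field(default_factory=SegmentationConfig)
    classification: ClassificationRuleConfig = field(
        default_factory=ClassificationRuleConfig)
    histology: HistologyConfig = field(default_factory=HistologyConfig)
    n_subjects: int = 5
    seed: int = 0
    out_dir: Optional[str] = None
    write_volumes: bool = False
    log_level: str = "INFO"

    _KNOWN_KEYS = None  # set below

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        """Build a config from nested dictionaries, rejecting unknown keys."""
        def build(dc_cls, sub: dict):
            names = {f.name: f for f in dataclasses.fields(dc_cls)}
            unknown = set(sub) - set(names)
            if unknown:
                raise ValueError(
                    f"unknown key(s) {sorted(unknown)} for {dc_cls.__name__}"
                )
            kwargs = {}
            for k, v in sub.items():
                f = names[k]
                if dataclasses.is_dataclass(f.type) and isinstance(v, dict):
                    kwargs[k] = build(f.type, v)
                elif k == "simulation":
                    kwargs[k] = SimulationConfig(**{
                        kk: (tuple(vv) if isinstance(vv, list) else vv)
                        for kk, vv in v.items()
                    })
                elif k == "segmentation":
                    kwargs[k] = SegmentationConfig(**v)
                elif k == "classification":
                    kwargs[k] = ClassificationRuleConfig(**v)
                elif k == "histology":
                    hv = dict(v)
                    if "roi_spec" in hv and isinstance(hv["roi_spec"], dict):
                        hv["roi_spec"] = RoiSpec(**hv["roi_spec"])
                    if "thresholds" in hv and isinstance(hv["thresholds"], dict):
                        hv["thresholds"] = HistoThresholds(**hv["thresholds"])
                    kwargs[k] = HistologyConfig(**hv)
                else:
                    kwargs[k] = v
            return dc_cls(**kwargs)

        return build(cls, d)


def _subject_seed(master_seed: int, subject_index: int) -> int:
    ss = np.random.SeedSequence([master_seed, subject_index])
    return int(ss.generate_state(1)[0] % (2 ** 31))


def analyze_timeline(timeline, seg_cfg: SegmentationConfig,
                     cls_cfg: ClassificationRuleConfig):
    """Normalize, segment every week, and build classified lesion tracks.

    Returns (tracks, per-track classification records). PDw volumes are
    GM-normalized in place on the returned timeline.
    """
    timeline.volumes["PDw"] = [
        normalize_to_gm(v, timeline.gm_mask) for v in timeline.volumes["PDw"]
    ]
    timeline.label_maps = [
        segment_lesions(
            v, timeline.wm_mask,
            intensity_threshold=seg_cfg.intensity_threshold,
            min_voxels=seg_cfg.min_voxels,
            connectivity=seg_cfg.connectivity,
            gm_mask=timeline.gm_mask,
        )
        for v in timeline.volumes["PDw"]
    ]
    tracks = build_tracks(timeline, min_overlap_voxels=seg_cfg.min_overlap_voxels)
    records = []
    for tr in tracks:
        category = classify_track(tr, cls_cfg)
        window = estimate_remyelination_window(tr, cls_cfg)
        records.append({
            "track_id": tr.track_id,
            "mri_category": category.value,
            "first_detection_week": tr.first_detection_week,
            "peak_volume_ul": tr.peak_volume_ul(),
            "size_rule_remyelination_possible": predict_by_peak_size(
                tr, cls_cfg.size_rule_threshold_ul),
            "terminal_enhancing": tr.terminal_enhancing,
            "remyelination_duration_weeks": (
                window.remyelination_duration_weeks if window else None),
        })
    return tracks, records


def match_tracks_to_truth(
    tracks: List[LesionTrack],
    lesions: List[GroundTruthLesion],
) -> Dict[int, int]:
    """Map track_id -> lesion_id by maximal overlap with ground-truth voxels."""
    matches: Dict[int, int] = {}
    for tr in tracks:
        best, best_ov = None, 0
        for les in lesions:
            if les.peak_voxels is None:
                continue
            vox = les.peak_voxels
            ov = int(np.count_nonzero(
                tr.max_roi[vox[:, 0], vox[:, 1], vox[:, 2]]))
            if ov > best_ov:
                best, best_ov = les.lesion_id, ov
        if best is not None:
            matches[tr.track_id] = best
    return matches


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the full synthetic-cohort pipeline.

    Returns the evaluation report as a dict; when ``config.out_dir`` is set,
    tracks/labels/metrics CSVs, the ground-truth manifest and the report
    JSON are written there (and, optionally, all volumes as NIfTI).
    """
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    out = Path(config.out_dir) if config.out_dir else None
    if out:
        out.mkdir(parents=True, exist_ok=True)

    label_rows = []
    track_frames = []
    window_errors = []
    manifests = []
    histo_rows = []
    for s in range(config.n_subjects):
        subject = f"S{s + 1:02d}"
        sim_cfg = dataclasses.replace(
            config.simulation, seed=_subject_seed(config.seed, s))
        try:
            timeline, lesions = simulate_study(sim_cfg, subject_id=subject)
        except Exception as exc:
            raise RuntimeError(f"stage 'simulate' failed for {subject}: {exc}") from exc
        # subject baseline: median white-matter intensity at the first scan
        baseline_est = float(np.median(
            timeline.volumes["PDw"][0].data[timeline.wm_mask]))
        manifests.append(manifest_dict(sim_cfg, baseline_est, lesions, subject))
        steroid_treated = s % 2 == 0

        try:
            tracks, records = analyze_timeline(
                timeline, config.segmentation, config.classification)
        except Exception as exc:
            raise RuntimeError(
                f"stage 'segment/track/classify' failed for {subject}: {exc}"
            ) from exc
        track_frames.append(tracks_to_dataframe(tracks, subject))
        matches = match_tracks_to_truth(tracks, lesions)
        lesions_by_id = {l.lesion_id: l for l in lesions}

        hcfg = config.histology
        for rec in records:
            lesion_id = matches.get(rec["track_id"])
            truth = lesions_by_id.get(lesion_id)
            row = {
                "subject": subject,
                "lesion_id": f"{subject}:{lesion_id}" if lesion_id else None,
                "track_id": rec["track_id"],
                "mri_category": rec["mri_category"],
                "histo_category": None,
                "steroid_treated": steroid_treated,
                "lesion_age_weeks": None,
                "opc_count": None,
                "true_class": truth.true_class.value if truth else None,
                "peak_volume_ul": rec["peak_volume_ul"],
                "size_rule_remyelination_possible":
                    rec["size_rule_remyelination_possible"],
                "remyelination_duration_weeks":
                    rec["remyelination_duration_weeks"],
            }
            if truth is not None:
                row["lesion_age_weeks"] = timeline.terminal_week - truth.onset_week
                try:
                    stains = render_histology(
                        truth.histo_truth,
                        roi_um=hcfg.roi_spec.side_um(),
                        pixel_size_um=hcfg.pixel_size_um,
                        seed=_subject_seed(config.seed, 1000 + 100 * s
                                           + truth.lesion_id),
                    )
                except Exception as exc:
                    raise RuntimeError(
                        f"stage 'histology' failed for {subject} lesion "
                        f"{truth.lesion_id}: {exc}") from exc
                roi = roi_from_center(
                    stains.lesion_center_px,
                    next(iter(stains.channels.values())).shape,
                    stains.pixel_size_um, hcfg.roi_spec)
                metrics = quantify_stains(stains.channels, roi,
                                          stains.pixel_size_um)
                cls = classify_histology(metrics, thresholds=hcfg.thresholds)
                row["histo_category"] = cls.category.value
                row["plp_lfb_discordant"] = cls.plp_lfb_discordant
                row["opc_count"] = metrics.opc_count
                histo_rows.append({
                    "subject": subject, "lesion_id": row["lesion_id"],
                    **dataclasses.asdict(metrics),
                })
                if (truth.true_class is LesionClass.REMYELINATED
                        and rec["remyelination_duration_weeks"] is not None):
                    window_errors.append(
                        rec["remyelination_duration_weeks"]
                        - truth.remyelination_duration_weeks)
            label_rows.append(row)

    table = pd.DataFrame(label_rows)
    report = concordance_report(table.dropna(subset=["histo_category"]))
    # concordance against generator ground truth (the known answer)
    matched = table.dropna(subset=["true_class"])
    truth_table = matched.drop(columns=["histo_category"]).rename(
        columns={"true_class": "histo_category"})
    cm_truth = binarize_and_tabulate(truth_table)
    try:
        sens_t, spec_t = sensitivity_specificity(cm_truth)
    except ValueError:  # degenerate cohort (a class absent from the truth)
        sens_t = spec_t = float("nan")
    report["vs_ground_truth"] = {
        "n_lesions": cm_truth.total,
        "confusion_matrix": {"tp": cm_truth.tp, "fn": cm_truth.fn,
                             "fp": cm_truth.fp, "tn": cm_truth.tn},
        "sensitivity": sens_t,
        "specificity": spec_t,
        "classification_accuracy": float(
            (matched["mri_category"] == matched["true_class"]).mean()),
    }
    if window_errors:
        report["remyelination_window"] = {
            "n": len(window_errors),
            "max_abs_error_weeks": float(np.max(np.abs(window_errors))),
            "mean_error_weeks": float(np.mean(window_errors)),
        }
    report["n_tracks"] = int(sum(len(f["track_id"].unique())
                                 for f in track_frames))
    report["n_true_lesions"] = int(sum(len(m["lesions"]) for m in manifests))

    if out:
        rio.write_table(pd.concat(track_frames, ignore_index=True),
                        out / "tracks.csv")
        rio.write_table(table, out / "labels.csv")
        if histo_rows:
            rio.write_table(pd.DataFrame(histo_rows), out / "histo_metrics.csv")
        rio.write_json({"subjects": manifests}, out / "ground_truth.json")
        rio.write_json(report, out / "report.json")
        _write_markdown_report(report, out / "report.md")
    return report


def _write_markdown_report(report: dict, path: Path) -> None:
    cm = report["confusion_matrix"]
    lines = [
        "# Radiological-pathological concordance report",
        "",
        f"Lesions evaluated: {report['n_lesions']}",
        "",
        "|              | MRI demyelinated | MRI remyelinated |",
        "|--------------|------------------|------------------|",
        f"| histo demyelinated | {cm['tn']} | {cm['fp']} |",
        f"| histo remyelinated | {cm['fn']} | {cm['tp']} |",
        "",
        f"Sensitivity for remyelination: {report['sensitivity_pct']:.1f}%",
        f"Specificity for remyelination: {report['specificity_pct']:.1f}%",
        f"Accuracy: {report['accuracy_pct']:.1f}%",
    ]
    vt = report.get("vs_ground_truth")
    if vt:
        lines += [
            "",
            "## Against generator ground truth",
            f"Three-class accuracy: {100 * vt['classification_accuracy']:.1f}%",
            f"Sensitivity {100 * vt['sensitivity']:.1f}% / "
            f"specificity {100 * vt['specificity']:.1f}%",
        ]
    path.write_text("\n".join(lines) + "\n")
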