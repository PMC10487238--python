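"""Batch orchestration: calibrate -> segment -> measure -> aggregate -> compare.

`run_pipeline` consumes a directory laid out as images/, rois/, a control
image and a metadata table (exactly what the synthetic generator writes), and
produces the glomerulus table, case table, group-comparison and correlation
tables, the threshold record and a machine-readable run manifest.  Rerunning
with identical inputs reproduces all numeric outputs byte-identically.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import __version__
from .calibration import DEFAULT_QUANTILE, ThresholdSet, calibrate_thresholds
from .features import (
    CaseFeatures,
    GlomerulusFeatures,
    aggregate_case,
    case_table,
    glomerulus_table,
    measure_glomerulus,
)
from .io import (
    CaseMetadata,
    ChannelMap,
    GlomerulusROI,
    MultiplexImage,
    read_case_metadata,
    read_multiplex_image,
    read_roi_annotations,
)
from .segmentation import (
    SegmentationParams,
    classify_podocyte_nuclei,
    segment_nqo1_area,
    segment_nuclei,
)
from .stats import (
    comparison_table,
    compare_cohort,
    correlate_features,
    correlation_table,
)

logger = logging.getLogger(__name__)

#: Case-level features compared across disease groups by default.
DEFAULT_COMPARED_FEATURES = (
    "nfe2l1_nuclear",
    "nfe2l2_nuclear",
    "nqo1_pct_positivity",
    "nqo1_intensity",
)

#: Feature pairs correlated by default (nuclear NFE2L1 against the two
#: glomerular NQO1 readouts).
DEFAULT_CORRELATED_PAIRS = (
    ("nfe2l1_nuclear", "nqo1_pct_positivity"),
    ("nfe2l1_nuclear", "nqo1_intensity"),
)


class DataError(Exception):
    """Input data is missing or inconsistent (exit code 2 in the CLI)."""


@dataclass
class RunConfig:
    """Everything needed to reproduce one analysis run."""

    images_dir: str = "images"
    rois_dir: str = "rois"
    control_image: str | None = "control/control.tiff"
    thresholds_file: str | None = None
    metadata: str = "metadata.csv"
    output_dir: str = "results"
    channel_map: dict[str, int] | None = None  # None = canonical order
    pixel_size_um: float = 0.25
    calibration_quantile: float = DEFAULT_QUANTILE
    segmentation: SegmentationParams = field(default_factory=SegmentationParams)
    test: str = "ranksum"
    correlation_level: str = "case"  # or "glomerulus"
    reference_group: str = "normal"
    compared_features: tuple[str, ...] = DEFAULT_COMPARED_FEATURES
    seed: int = 0
    base_dir: str = "."

    def path(self, rel: str | None) -> Path | None:
        if rel is None:
            return None
        p = Path(rel)
        return p if p.is_absolute() else Path(self.base_dir) / p

    def resolved_channel_map(self) -> ChannelMap:
        if self.channel_map is None:
            return ChannelMap.identity()
        return ChannelMap(dict(self.channel_map))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        payload = yaml.safe_load(Path(path).read_text()) or {}
        seg = payload.pop("segmentation", None)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(payload) - known
        if unknown:
            raise DataError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**payload)
        if seg is not None:
            cfg.segmentation = SegmentationParams(**seg)
        if "compared_features" in payload:
            cfg.compared_features = tuple(payload["compared_features"])
        cfg.base_dir = str(Path(path).parent)
        return cfg

    def to_yaml(self, path: str | Path) -> None:
        payload = dataclasses.asdict(self)
        payload["compared_features"] = list(self.compared_features)
        Path(path).write_text(yaml.safe_dump(payload, sort_keys=True))


def analyze_tile(
    image: MultiplexImage,
    roi: GlomerulusROI,
    thresholds: ThresholdSet,
    params: SegmentationParams | None = None,
) -> GlomerulusFeatures:
    """Run the per-glomerulus analysis chain on one tile."""
    params = params or SegmentationParams()
    nuclei = segment_nuclei(image, roi, params)
    nuclei = classify_podocyte_nuclei(nuclei, thresholds)
    nqo1 = segment_nqo1_area(image, roi, thresholds, params)
    return measure_glomerulus(image, roi, nuclei, nqo1)


def analyze_cohort_in_memory(cohort, scene, seed) -> "pd.DataFrame":
    """Simulate and analyze a whole cohort tile-by-tile without touching disk.

    Renders the control tile, calibrates thresholds, then streams every
    glomerulus tile through the analysis chain and aggregates per case.
    Returns the case-level feature table.  Memory stays flat: tiles are
    discarded after measurement.
    """
    import numpy as np

    from .simulate import generate_control_tile, iter_cohort_tiles

    rng = np.random.default_rng(seed)
    thresholds = calibrate_thresholds(generate_control_tile(scene, rng))
    rows_by_case: dict[str, list[GlomerulusFeatures]] = {}
    metas: dict[str, CaseMetadata] = {}
    for meta, roi, image, _truth in iter_cohort_tiles(cohort, scene, rng):
        rows_by_case.setdefault(meta.case_id, []).append(analyze_tile(image, roi, thresholds))
        metas[meta.case_id] = meta
    cases = [aggregate_case(rows, metas[cid]) for cid, rows in rows_by_case.items()]
    return case_table(cases)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full batch workflow and write all result tables.

    Returns a summary dictionary (also written as ``manifest.json``).  Cases
    with no analyzable glomeruli are listed in the manifest, never silently
    dropped; a missing calibration source is a hard error.
    """
    outdir = Path(config.path(config.output_dir))
    outdir.mkdir(parents=True, exist_ok=True)
    cmap = config.resolved_channel_map()

    meta_path = config.path(config.metadata)
    if meta_path is None or not meta_path.exists():
        raise DataError(f"metadata table not found: {meta_path}")
    cases = read_case_metadata(meta_path)
    if not cases:
        raise DataError("metadata table contains no cases")

    checksums: dict[str, str] = {str(config.metadata): _sha256(meta_path)}

    # -- calibration -------------------------------------------------------
    if config.thresholds_file:
        thr_path = config.path(config.thresholds_file)
        if not thr_path.exists():
            raise DataError(f"thresholds file not found: {thr_path}")
        thresholds = ThresholdSet.from_yaml(thr_path)
        checksums[str(config.thresholds_file)] = _sha256(thr_path)
    elif config.control_image:
        ctrl_path = config.path(config.control_image)
        if not ctrl_path.exists():
            raise DataError(f"control image not found: {ctrl_path}")
        control = read_multiplex_image(ctrl_path, cmap, config.pixel_size_um)
        thresholds = calibrate_thresholds(control, quantile=config.calibration_quantile)
        checksums[str(config.control_image)] = _sha256(ctrl_path)
    else:
        raise DataError(
            "no calibration source: provide either control_image or thresholds_file"
        )
    thresholds.to_yaml(outdir / "thresholds.yaml")

    # -- per-glomerulus segmentation and measurement -----------------------
    glom_rows: list[GlomerulusFeatures] = []
    case_rows: list[CaseFeatures] = []
    skipped_cases: list[str] = []
    for meta in cases:
        roi_path = config.path(config.rois_dir) / f"{meta.case_id}.geojson"
        if not roi_path.exists():
            logger.warning("case %s: ROI file missing (%s)", meta.case_id, roi_path)
            skipped_cases.append(meta.case_id)
            continue
        checksums[f"{config.rois_dir}/{meta.case_id}.geojson"] = _sha256(roi_path)
        rois = read_roi_annotations(roi_path)
        rows_for_case: list[GlomerulusFeatures] = []
        for roi in rois:
            img_path = (
                config.path(config.images_dir)
                / f"{meta.case_id}_{roi.glomerulus_id}.tiff"
            )
            if not img_path.exists():
                raise DataError(
                    f"case {meta.case_id}, glomerulus {roi.glomerulus_id}: "
                    f"image not found at {img_path}"
                )
            image = read_multiplex_image(img_path, cmap, config.pixel_size_um)
            try:
                row = analyze_tile(image, roi, thresholds, config.segmentation)
            except Exception as exc:
                raise DataError(
                    f"case {meta.case_id}, glomerulus {roi.glomerulus_id}: {exc}"
                ) from exc
            rows_for_case.append(row)
            logger.info(
                "case %s glomerulus %s: %d nuclei, %d podocytes",
                meta.case_id, roi.glomerulus_id, row.n_nuclei, row.n_podocytes,
            )
        if not rows_for_case:
            skipped_cases.append(meta.case_id)
            continue
        glom_rows.extend(rows_for_case)
        case_rows.append(aggregate_case(rows_for_case, meta))

    if not case_rows:
        raise DataError("no case produced any analyzable glomerulus")

    glom_df = glomerulus_table(glom_rows)
    case_df = case_table(case_rows)
    glom_df.to_csv(outdir / "glomeruli.csv", index=False)
    case_df.to_csv(outdir / "cases.csv", index=False)

    # -- cohort statistics -------------------------------------------------
    comparisons = []
    groups_present = set(case_df["group"])
    if config.reference_group in groups_present and len(groups_present) > 1:
        for feat in config.compared_features:
            comparisons.extend(
                compare_cohort(
                    case_df, feat,
                    reference_group=config.reference_group, test=config.test,
                )
            )
    corr_frame = glom_df if config.correlation_level == "glomerulus" else case_df
    correlations = [
        correlate_features(corr_frame, fx, fy) for fx, fy in DEFAULT_CORRELATED_PAIRS
    ]
    comparison_table(comparisons).to_csv(outdir / "comparisons.csv", index=False)
    correlation_table(correlations).to_csv(outdir / "correlations.csv", index=False)

    manifest = {
        "version": __version__,
        "config": json.loads(json.dumps(dataclasses.asdict(config), default=str)),
        "thresholds": thresholds.thresholds,
        "n_cases_analyzed": len(case_rows),
        "n_glomeruli": len(glom_rows),
        "skipped_cases": skipped_cases,
        "input_checksums": dict(sorted(checksums.items())),
        "outputs": [
            "glomeruli.csv", "cases.csv", "comparisons.csv",
            "correlations.csv", "thresholds.yaml",
        ],
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
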