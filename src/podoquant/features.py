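"""Per-glomerulus measurements and their per-case aggregation.

The 13 reported features follow one uniform three-level convention: per
object/compartment, the mean raw pixel intensity; per glomerulus, the mean
over objects; per case, the unweighted mean over glomeruli ("mean of means").
Counts aggregate as sums, and podocytes-per-glomerulus as the ratio of totals.

Empty compartments yield missing values (NaN), never zero: a glomerulus with
no podocytes must not fabricate zero marker expression, which would conflate
podocyte loss with expression loss.  Case aggregation skips missing values
pairwise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, fields
from typing import Sequence

import numpy as np
import pandas as pd

from .io import CaseMetadata, GlomerulusROI, MultiplexImage
from .segmentation import CompartmentMask, NucleusObject


@dataclass
class GlomerulusFeatures:
    """Measurements of one annotated glomerulus."""

    case_id: str
    glomerulus_id: str
    glomerulus_area_um2: float
    n_nuclei: int
    n_podocytes: int
    nqo1_pos_area_um2: float
    nqo1_pct_positivity: float
    nqo1_intensity: float
    nfe2l1_in_nqo1: float
    nfe2l2_in_nqo1: float
    podocyte_nuclear_area_um2: float
    p57_nuclear: float
    nfe2l1_nuclear: float
    nfe2l2_nuclear: float


@dataclass
class CaseFeatures:
    """Case-level aggregation of per-glomerulus measurements."""

    case_id: str
    group: str
    n_glomeruli: int
    glomerulus_area_um2: float
    n_podocytes: int
    podocytes_per_glomerulus: float
    nqo1_pos_area_um2: float
    nqo1_pct_positivity: float
    nqo1_intensity: float
    nfe2l1_in_nqo1: float
    nfe2l2_in_nqo1: float
    podocyte_nuclear_area_um2: float
    p57_nuclear: float
    nfe2l1_nuclear: float
    nfe2l2_nuclear: float


#: Continuous per-glomerulus features that aggregate as unweighted means.
MEAN_FEATURES = (
    "glomerulus_area_um2",
    "nqo1_pos_area_um2",
    "nqo1_pct_positivity",
    "nqo1_intensity",
    "nfe2l1_in_nqo1",
    "nfe2l2_in_nqo1",
    "podocyte_nuclear_area_um2",
    "p57_nuclear",
    "nfe2l1_nuclear",
    "nfe2l2_nuclear",
)

#: The 13 case-level reported features (counts, ratio, and mean-of-means).
CASE_FEATURE_NAMES = ("n_glomeruli", "n_podocytes", "podocytes_per_glomerulus") + MEAN_FEATURES


def _masked_mean(plane: np.ndarray, mask: np.ndarray) -> float:
    return float(plane[mask].mean()) if mask.any() else math.nan


def measure_glomerulus(
    image: MultiplexImage,
    roi: GlomerulusROI,
    nuclei: Sequence[NucleusObject],
    nqo1: CompartmentMask,
) -> GlomerulusFeatures:
    """Compute all per-glomerulus features.

    Intensity-in-compartment features are means of raw pixel intensities over
    the compartment mask; nuclear features average the per-podocyte mean
    intensities (one value per podocyte nucleus, then the mean over podocytes).
    """
    roi_mask = roi.mask(image.shape)
    n_px = int(roi_mask.sum())
    if n_px == 0:
        raise ValueError(
            f"ROI {roi.glomerulus_id} of case {roi.case_id} has zero interior area"
        )
    px_area = image.pixel_size_um**2
    glom_area = n_px * px_area

    podos = [n for n in nuclei if n.is_podocyte]

    def podo_mean(values: list[float]) -> float:
        return float(np.mean(values)) if values else math.nan

    return GlomerulusFeatures(
        case_id=roi.case_id,
        glomerulus_id=roi.glomerulus_id,
        glomerulus_area_um2=float(glom_area),
        n_nuclei=len(nuclei),
        n_podocytes=len(podos),
        nqo1_pos_area_um2=float(nqo1.area_um2),
        nqo1_pct_positivity=float(100.0 * nqo1.area_um2 / glom_area),
        nqo1_intensity=_masked_mean(image.plane("nqo1"), nqo1.mask),
        nfe2l1_in_nqo1=_masked_mean(image.plane("nfe2l1"), nqo1.mask),
        nfe2l2_in_nqo1=_masked_mean(image.plane("nfe2l2"), nqo1.mask),
        podocyte_nuclear_area_um2=podo_mean([n.area_um2 for n in podos]),
        p57_nuclear=podo_mean([n.mean_intensity["p57"] for n in podos]),
        nfe2l1_nuclear=podo_mean([n.mean_intensity["nfe2l1"] for n in podos]),
        nfe2l2_nuclear=podo_mean([n.mean_intensity["nfe2l2"] for n in podos]),
    )


def aggregate_case(rows: Sequence[GlomerulusFeatures], meta: CaseMetadata) -> CaseFeatures:
    """Aggregate per-glomerulus rows into one case row.

    Counts are summed, podocytes_per_glomerulus is total podocytes over total
    glomeruli, continuous features are unweighted means over glomeruli with
    missing values excluded pairwise.  Row order is irrelevant.
    """
    rows = list(rows)
    if not rows:
        raise ValueError(f"case {meta.case_id}: no glomerulus rows to aggregate")
    ids = {r.case_id for r in rows}
    if ids != {meta.case_id}:
        raise ValueError(f"mixed or mismatched case_ids {sorted(ids)} for case {meta.case_id}")

    n_glom = len(rows)
    n_podo = int(sum(r.n_podocytes for r in rows))

    def feature_mean(name: str) -> float:
        vals = [getattr(r, name) for r in rows]
        vals = [v for v in vals if not math.isnan(v)]
        return float(np.mean(vals)) if vals else math.nan

    return CaseFeatures(
        case_id=meta.case_id,
        group=meta.group,
        n_glomeruli=n_glom,
        n_podocytes=n_podo,
        podocytes_per_glomerulus=n_podo / n_glom,
        **{name: feature_mean(name) for name in MEAN_FEATURES},
    )


def case_table(cases: Sequence[CaseFeatures]) -> pd.DataFrame:
    """Case rows as a DataFrame with columns in declaration order."""
    cols = [f.name for f in fields(CaseFeatures)]
    return pd.DataFrame.from_records(
        [{c: getattr(r, c) for c in cols} for r in cases], columns=cols
    )


def glomerulus_table(rows: Sequence[GlomerulusFeatures]) -> pd.DataFrame:
    cols = [f.name for f in fields(GlomerulusFeatures)]
    return pd.DataFrame.from_records(
        [{c: getattr(r, c) for c in cols} for r in rows], columns=cols
    )
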