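"""Positivity-threshold calibration from a no-primary-antibody control image.

A section stained without primary antibody carries only autofluorescence in the
marker channels; any intensity above that background is treated as positive
signal.  The rule is implemented as a high empirical quantile (inverted-CDF
order statistic) of the pooled control pixels, per channel: the maximum would
be unstable to single hot pixels, while a high quantile approximates
"above autofluorescence" robustly.  Thresholds apply to raw intensities — the
positivity rule is a cut-off, not a background subtraction.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import yaml

from .io import MARKER_CHANNELS, GlomerulusROI, MultiplexImage

#: Default control-pixel quantile defining the positivity threshold.
DEFAULT_QUANTILE = 0.995


@dataclass
class ThresholdSet:
    """Per-marker-channel positivity thresholds in raw intensity units.

    The Hoechst counterstain is excluded: nuclei are segmented with their own
    foreground threshold, not an antibody-positivity rule.
    """

    thresholds: dict[str, float]
    quantile: float = DEFAULT_QUANTILE
    source: str = ""

    def __post_init__(self) -> None:
        missing = set(MARKER_CHANNELS) - set(self.thresholds)
        if missing:
            raise ValueError(f"thresholds missing for channels {sorted(missing)}")
        if any(v < 0 for v in self.thresholds.values()):
            raise ValueError("thresholds must be nonnegative")
        if not 0 < self.quantile <= 1:
            raise ValueError(f"quantile must be in (0, 1], got {self.quantile}")
        self.thresholds = {ch: float(self.thresholds[ch]) for ch in MARKER_CHANNELS}

    def __getitem__(self, channel: str) -> float:
        return self.thresholds[channel]

    def to_yaml(self, path: str | Path) -> None:
        payload = {
            "thresholds": self.thresholds,
            "quantile": float(self.quantile),
            "source": self.source,
        }
        Path(path).write_text(yaml.safe_dump(payload, sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ThresholdSet":
        payload = yaml.safe_load(Path(path).read_text())
        return cls(
            thresholds=payload["thresholds"],
            quantile=payload["quantile"],
            source=payload.get("source", ""),
        )


def calibrate_thresholds(
    control: MultiplexImage,
    rois: Sequence[GlomerulusROI] | None = None,
    quantile: float = DEFAULT_QUANTILE,
) -> ThresholdSet:
    """Derive per-channel positivity thresholds from a control image.

    Parameters
    ----------
    control
        No-primary-antibody control tile; its marker channels contain only
        autofluorescence (plus noise).
    rois
        If given, control pixels are pooled only from inside these regions;
        otherwise the whole tile is used.  Whether autofluorescence should be
        sampled tissue-wide or within glomeruli is a user choice.
    quantile
        Empirical quantile in (0, 1] of the pooled control pixels; computed as
        the inverted-CDF order statistic, so the threshold is always an
        observed pixel value.
    """
    if not 0 < quantile <= 1:
        raise ValueError(f"quantile must be in (0, 1], got {quantile}")
    if rois is not None:
        pool_mask = np.zeros(control.shape, dtype=bool)
        for roi in rois:
            pool_mask |= roi.mask(control.shape)
        if not pool_mask.any():
            raise ValueError("control pixel pool is empty: ROIs do not overlap the image")
    else:
        pool_mask = None

    thresholds = {}
    for ch in MARKER_CHANNELS:
        plane = control.plane(ch)
        vals = plane[pool_mask] if pool_mask is not None else plane.ravel()
        thresholds[ch] = float(np.quantile(vals, quantile, method="inverted_cdf"))
    return ThresholdSet(thresholds=thresholds, quantile=quantile, source="control")
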