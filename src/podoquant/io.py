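"""Readers and writers for the pipeline's external artifacts.

Images are multi-page TIFF stacks with one plane per fluorescence channel;
glomerulus annotations are GeoJSON polygon FeatureCollections in the dialect
exported by common annotation tools (x = column, y = row, 0-based, pixel-centre
coordinates); measurement tables are plain comma-separated text with a '.'
decimal separator regardless of locale.

Intensities are carried as raw integer counts and are never rescaled, because
positivity thresholds are calibrated in raw units.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import tifffile
from shapely.geometry import Polygon

logger = logging.getLogger(__name__)

#: Canonical channel order used throughout the package.
CHANNELS = ("hoechst", "p57", "nfe2l2", "nfe2l1", "nqo1")

#: Antibody-dependent marker channels (everything except the Hoechst counterstain).
MARKER_CHANNELS = ("p57", "nfe2l2", "nfe2l1", "nqo1")

#: Recognised disease-group vocabulary for case metadata.
GROUPS = ("normal", "MCD", "DN", "FSGS", "MesIgA", "MCGN")


@dataclass(frozen=True)
class ChannelMap:
    """Mapping from channel name to 0-based plane index in a stored TIFF."""

    entries: dict[str, int]

    def __post_init__(self) -> None:
        names = set(self.entries)
        if names != set(CHANNELS):
            raise ValueError(
                f"channel map must name exactly {sorted(CHANNELS)}, got {sorted(names)}"
            )
        indices = list(self.entries.values())
        if len(set(indices)) != len(indices):
            raise ValueError(f"channel map indices must be distinct, got {indices}")
        if any((not isinstance(i, (int, np.integer))) or i < 0 for i in indices):
            raise ValueError(f"channel map indices must be nonnegative integers, got {indices}")

    @classmethod
    def identity(cls) -> "ChannelMap":
        """Channel map for files already stored in canonical order."""
        return cls({name: i for i, name in enumerate(CHANNELS)})

    @property
    def max_index(self) -> int:
        return max(self.entries.values())


@dataclass
class MultiplexImage:
    """A registered stack of the five named channels over one tile.

    ``planes`` is always held in canonical :data:`CHANNELS` order,
    shape ``(5, rows, cols)``, unsigned-integer counts.
    """

    planes: np.ndarray
    pixel_size_um: float

    def __post_init__(self) -> None:
        self.planes = np.asarray(self.planes)
        if self.planes.ndim != 3 or self.planes.shape[0] != len(CHANNELS):
            raise ValueError(
                f"planes must have shape (5, rows, cols), got {self.planes.shape}"
            )
        if self.planes.dtype.kind not in "ui":
            raise ValueError(
                f"sample format must be integer counts, got dtype {self.planes.dtype}"
            )
        if self.planes.dtype.kind == "i" and self.planes.min() < 0:
            raise ValueError("intensities must be nonnegative")
        if not self.pixel_size_um > 0:
            raise ValueError(f"pixel_size_um must be positive, got {self.pixel_size_um}")

    def plane(self, name: str) -> np.ndarray:
        return self.planes[CHANNELS.index(name)]

    @property
    def shape(self) -> tuple[int, int]:
        return self.planes.shape[1], self.planes.shape[2]


@dataclass
class GlomerulusROI:
    """One annotated glomerulus outline in pixel coordinates.

    Vertices are an open ring of (x, y) = (column, row) pairs; the closing
    duplicate vertex of the GeoJSON ring is not stored.
    """

    case_id: str
    glomerulus_id: str
    vertices: list[tuple[float, float]]

    def __post_init__(self) -> None:
        verts = [(float(x), float(y)) for x, y in self.vertices]
        if len(verts) >= 2 and verts[0] == verts[-1]:
            verts = verts[:-1]
        if len(verts) < 3:
            raise ValueError(f"ROI ring needs >= 3 vertices, got {len(verts)}")
        poly = Polygon(verts)
        if not poly.is_simple:
            raise ValueError("ROI ring is self-intersecting")
        if not poly.area > 0:
            raise ValueError("ROI encloses zero area")
        self.vertices = verts

    def polygon(self) -> Polygon:
        return Polygon(self.vertices)

    def mask(self, shape: tuple[int, int]) -> np.ndarray:
        """Boolean interior mask: a pixel belongs iff its centre is inside the ring.

        Pixel (row r, col c) has its centre at (x=c, y=r); boundary pixels are
        excluded (open interior), which is the even-odd rule for a simple ring.
        """
        import shapely

        h, w = shape
        poly = self.polygon()
        minx, miny, maxx, maxy = poly.bounds
        c0 = max(0, int(np.floor(minx)))
        c1 = min(w - 1, int(np.ceil(maxx)))
        r0 = max(0, int(np.floor(miny)))
        r1 = min(h - 1, int(np.ceil(maxy)))
        out = np.zeros(shape, dtype=bool)
        if c1 < c0 or r1 < r0:
            return out
        cols = np.arange(c0, c1 + 1)
        rows = np.arange(r0, r1 + 1)
        cc, rr = np.meshgrid(cols, rows)
        inside = shapely.contains_xy(poly, cc.ravel(), rr.ravel()).reshape(cc.shape)
        out[r0 : r1 + 1, c0 : c1 + 1] = inside
        return out


@dataclass
class CaseMetadata:
    """One cohort case: identifier, disease group and free clinical covariates."""

    case_id: str
    group: str
    covariates: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise ValueError(f"unknown group {self.group!r}; expected one of {GROUPS}")


def read_multiplex_image(
    path: str | Path, channel_map: ChannelMap, pixel_size_um: float
) -> MultiplexImage:
    """Read a multi-plane TIFF and reorder planes to canonical channel order.

    Intensities are preserved bit-exactly; the file may store channels in any
    order described by ``channel_map``.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"image file not found: {path}")
    arr = tifffile.imread(path)
    if arr.ndim == 2:
        arr = arr[None]
    if arr.ndim != 3:
        raise ValueError(f"expected a plane stack, got array of shape {arr.shape}")
    needed = channel_map.max_index + 1
    if arr.shape[0] < needed:
        raise ValueError(
            f"TIFF at {path} has {arr.shape[0]} planes but the channel map "
            f"requires at least {needed}"
        )
    if arr.dtype.kind != "u":
        raise ValueError(
            f"sample format must be unsigned integer, got dtype {arr.dtype} in {path}"
        )
    planes = np.stack([arr[channel_map.entries[name]] for name in CHANNELS])
    return MultiplexImage(planes=planes, pixel_size_um=pixel_size_um)


def write_multiplex_image(image: MultiplexImage, path: str | Path) -> None:
    """Write an image as a multi-page TIFF in canonical channel order."""
    tifffile.imwrite(Path(path), image.planes)


def read_roi_annotations(path: str | Path) -> list[GlomerulusROI]:
    """Read a GeoJSON FeatureCollection of glomerulus polygons.

    Non-polygon geometries and malformed rings are skipped with a logged
    warning; unreadable JSON is a hard error.  Polygon holes are ignored —
    glomerulus annotations are simple outlines.
    """
    data = json.loads(Path(path).read_text())
    rois: list[GlomerulusROI] = []
    for i, feat in enumerate(data.get("features", [])):
        geom = feat.get("geometry") or {}
        if geom.get("type") != "Polygon":
            logger.warning(
                "skipping feature %d in %s: geometry type %r is not Polygon",
                i, path, geom.get("type"),
            )
            continue
        ring = geom["coordinates"][0]
        props = feat.get("properties") or {}
        case_id = str(props.get("case_id", props.get("name", "unknown")))
        glom_id = str(props.get("glomerulus_id", f"g{i}"))
        try:
            rois.append(GlomerulusROI(case_id=case_id, glomerulus_id=glom_id, vertices=ring))
        except ValueError as exc:
            logger.warning("skipping feature %d in %s: %s", i, path, exc)
    return rois


def write_roi_annotations(rois: Sequence[GlomerulusROI], path: str | Path) -> None:
    """Write ROIs as a GeoJSON FeatureCollection (closing vertex re-appended)."""
    features = []
    for roi in rois:
        ring = [[x, y] for x, y in roi.vertices]
        ring.append(ring[0])
        features.append(
            {
                "type": "Feature",
                "geometry": {"type": "Polygon", "coordinates": [ring]},
                "properties": {
                    "case_id": roi.case_id,
                    "glomerulus_id": roi.glomerulus_id,
                    "classification": {"name": "Glomerulus"},
                },
            }
        )
    Path(path).write_text(json.dumps({"type": "FeatureCollection", "features": features}))


def write_measurements(rows: Iterable, path: str | Path, kind: type | None = None) -> None:
    """Write measurement dataclass rows as a CSV table.

    ``kind`` supplies the column schema when ``rows`` is empty; otherwise it is
    inferred from the first row, and all rows must be of that one type.
    Output always uses '.' decimals and ',' separators (locale independent).
    """
    rows = list(rows)
    if rows:
        kind = type(rows[0])
        if any(type(r) is not kind for r in rows):
            raise TypeError("rows must be homogeneous in type")
    elif kind is None:
        raise ValueError("kind is required to write an empty table")
    columns = [f.name for f in dataclasses.fields(kind)]
    records = [dataclasses.asdict(r) for r in rows]
    df = pd.DataFrame.from_records(records, columns=columns)
    df.to_csv(Path(path), index=False)


def read_measurements(path: str | Path) -> pd.DataFrame:
    """Read a measurement CSV back into a DataFrame."""
    return pd.read_csv(Path(path))


def read_case_metadata(path: str | Path) -> list[CaseMetadata]:
    """Read the case metadata table (columns case_id, group + free covariates)."""
    df = pd.read_csv(Path(path), dtype={"case_id": str})
    if df["case_id"].duplicated().any():
        dupes = df.loc[df["case_id"].duplicated(), "case_id"].tolist()
        raise ValueError(f"duplicate case_id values: {dupes}")
    extra = [c for c in df.columns if c not in ("case_id", "group")]
    return [
        CaseMetadata(
            case_id=str(row["case_id"]),
            group=str(row["group"]),
            covariates={c: row[c] for c in extra},
        )
        for _, row in df.iterrows()
    ]


def write_case_metadata(cases: Sequence[CaseMetadata], path: str | Path) -> None:
    records = []
    for c in cases:
        rec = {"case_id": c.case_id, "group": c.group}
        rec.update(c.covariates)
        records.append(rec)
    pd.DataFrame.from_records(records).to_csv(Path(path), index=False)
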