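"""Synthetic multiplexed-immunofluorescence glomerulus tiles and cohorts.

Each tile holds one glomerulus, modelled as an ellipse, containing 8–16
non-overlapping nuclei of which a fixed fraction are podocytes.  Channel
content mirrors the compartment structure of the stains:

* hoechst — every nucleus,
* p57 — podocyte nuclei only (the podocyte-defining marker),
* nfe2l1 — podocyte nuclei at a nuclear level plus a diffuse level over the
  NQO1-positive area (nuclear localisation with diffuse cytoplasmic staining),
* nfe2l2 — diffuse over the whole glomerulus,
* nqo1 — a cytoplasmic annulus around each podocyte nucleus (the cell body,
  with no process-like signal).

Signals are uniform compartment levels softened by a small Gaussian blur, on
top of a per-channel autofluorescence background, with Poisson shot noise and
Gaussian read noise.  Ground-truth masks are the hard pre-blur compartment
sets, so recovery can be scored exactly.

Cohorts draw per-case latent multipliers for nuclear NFE2L1 and NQO1 from a
Gaussian copula with configurable rank correlation, then apply per-group
multiplicative effect factors (default: disease nuclear NFE2L1 at 1/3 of
normal).  Everything is deterministic under a fixed seed.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from .io import (
    CHANNELS,
    CaseMetadata,
    GlomerulusROI,
    MultiplexImage,
    write_case_metadata,
    write_multiplex_image,
    write_roi_annotations,
)

#: Disease-cohort group sizes (the normal group is a control set of needle
#: biopsies / tumour-distant nephrectomy parenchyma).
DEFAULT_GROUP_SIZES = {
    "normal": 11,
    "MCD": 13,
    "DN": 27,
    "FSGS": 37,
    "MesIgA": 37,
    "MCGN": 12,
}

#: Default disease effect: nuclear NFE2L1 reduced 3-fold relative to normal.
DEFAULT_NFE2L1_FACTORS = {
    "normal": 1.0,
    "MCD": 1 / 3,
    "DN": 1 / 3,
    "FSGS": 1 / 3,
    "MesIgA": 1 / 3,
    "MCGN": 1 / 3,
}


@dataclass
class SceneParams:
    """Geometry, staining levels and noise model of one synthetic tile.

    Lengths are micrometres unless the name says px.  Marker levels are the
    uniform signal amplitudes *added on top of* the channel background.
    """

    tile_size_px: int = 256
    pixel_size_um: float = 0.25
    glom_semi_axes_um: tuple[float, float] = (30.0, 26.0)
    glom_jitter_um: float = 1.0
    n_nuclei: tuple[int, int] = (8, 16)  # inclusive uniform range
    podocyte_fraction: float = 0.3
    nucleus_radius_um: tuple[float, float] = (2.8, 0.2)  # mean, sd
    nucleus_radius_bounds_um: tuple[float, float] = (2.5, 3.1)
    min_separation_um: float = 7.0
    ring_width_um: float = 2.0
    background: dict[str, float] = field(
        default_factory=lambda: {
            "hoechst": 50.0, "p57": 30.0, "nfe2l2": 35.0, "nfe2l1": 30.0, "nqo1": 45.0,
        }
    )
    hoechst_level: float = 1500.0
    p57_level: float = 600.0
    nfe2l1_nuclear_level: float = 1200.0
    nfe2l1_cyto_level: float = 150.0
    nfe2l2_diffuse_level: float = 120.0
    nqo1_level: float = 800.0
    render_sigma_px: float = 1.0
    poisson_noise: bool = True
    read_noise_sd: float = 3.0

    def __post_init__(self) -> None:
        if not 0 <= self.podocyte_fraction <= 1:
            raise ValueError("podocyte_fraction must be in [0, 1]")
        for name in ("hoechst_level", "p57_level", "nfe2l1_nuclear_level",
                     "nfe2l1_cyto_level", "nfe2l2_diffuse_level", "nqo1_level"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")
        if any(v < 0 for v in self.background.values()):
            raise ValueError("background levels must be nonnegative")


@dataclass
class CohortParams:
    """Cohort composition and the case-level effect/coupling model."""

    group_sizes: dict[str, int] = field(default_factory=lambda: dict(DEFAULT_GROUP_SIZES))
    glomeruli_per_case: tuple[int, int] = (3, 8)  # inclusive uniform range
    nfe2l1_factors: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_NFE2L1_FACTORS)
    )
    nqo1_level_factors: dict[str, float] = field(default_factory=dict)  # default 1.0
    nqo1_area_factors: dict[str, float] = field(default_factory=dict)  # default 1.0
    rho: float = 0.7
    latent_sigma: float = 0.15
    glom_sigma: float = 0.08  # between-glomerulus lognormal jitter within a case

    def __post_init__(self) -> None:
        from .io import GROUPS

        unknown = set(self.group_sizes) - set(GROUPS)
        if unknown:
            raise ValueError(f"unknown groups {sorted(unknown)}; expected subset of {GROUPS}")
        if any(n < 1 for n in self.group_sizes.values()):
            raise ValueError("group sizes must be >= 1")
        if not -1 <= self.rho <= 1:
            raise ValueError("rho must be in [-1, 1]")

    def factor(self, table: str, group: str) -> float:
        return {
            "nfe2l1": self.nfe2l1_factors,
            "nqo1_level": self.nqo1_level_factors,
            "nqo1_area": self.nqo1_area_factors,
        }[table].get(group, 1.0)


@dataclass
class TileGroundTruth:
    """Exact pre-noise truth for one rendered tile."""

    centres_px: np.ndarray  # (n, 2) as (x, y)
    radii_um: np.ndarray
    is_podocyte: np.ndarray
    nucleus_labels: np.ndarray  # (H, W) uint16, 0 = background
    nqo1_mask: np.ndarray
    glom_mask: np.ndarray
    levels: dict[str, float]  # effective per-compartment signal amplitudes
    background: dict[str, float]


def _as_rng(seed) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


def _ellipse_roi(
    scene: SceneParams, rng: np.random.Generator, case_id: str, glomerulus_id: str
) -> GlomerulusROI:
    px = scene.pixel_size_um
    half = scene.tile_size_px / 2.0
    jitter = scene.glom_jitter_um / px
    cx = half + rng.uniform(-jitter, jitter)
    cy = half + rng.uniform(-jitter, jitter)
    a = scene.glom_semi_axes_um[0] / px
    b = scene.glom_semi_axes_um[1] / px
    t = np.linspace(0, 2 * np.pi, 97)[:-1]
    verts = [(cx + a * np.cos(v), cy + b * np.sin(v)) for v in t]
    return GlomerulusROI(case_id=case_id, glomerulus_id=glomerulus_id, vertices=verts)


def _place_nuclei(
    scene: SceneParams, rng: np.random.Generator, roi: GlomerulusROI
) -> tuple[np.ndarray, np.ndarray]:
    """Rejection-sample non-overlapping nucleus centres inside the ellipse."""
    px = scene.pixel_size_um
    n = int(rng.integers(scene.n_nuclei[0], scene.n_nuclei[1] + 1))
    mean_r, sd_r = scene.nucleus_radius_um
    lo_r, hi_r = scene.nucleus_radius_bounds_um
    radii = np.clip(rng.normal(mean_r, sd_r, size=n), lo_r, hi_r)
    min_sep_px = scene.min_separation_um / px

    xs = np.array([v[0] for v in roi.vertices])
    ys = np.array([v[1] for v in roi.vertices])
    cx, cy = xs.mean(), ys.mean()
    a = (xs.max() - xs.min()) / 2.0
    b = (ys.max() - ys.min()) / 2.0

    for _restart in range(50):
        centres: list[tuple[float, float]] = []
        ok = True
        for i in range(n):
            r_px = radii[i] / px
            ea, eb = a - r_px - 1.0, b - r_px - 1.0
            for _attempt in range(1000):
                x = rng.uniform(cx - ea, cx + ea)
                y = rng.uniform(cy - eb, cy + eb)
                if ((x - cx) / ea) ** 2 + ((y - cy) / eb) ** 2 > 1.0:
                    continue
                if all(np.hypot(x - px0, y - py0) >= min_sep_px for px0, py0 in centres):
                    centres.append((x, y))
                    break
            else:
                ok = False
                break
        if ok:
            return np.array(centres), radii
    raise ValueError(
        f"could not place {n} nuclei at minimum separation "
        f"{scene.min_separation_um} um inside the glomerulus ellipse"
    )


def _paint_disks(
    shape: tuple[int, int], centres: np.ndarray, radii_px: np.ndarray
) -> np.ndarray:
    """Label image with disk i+1 at each centre (disks must not overlap)."""
    labels = np.zeros(shape, dtype=np.uint16)
    h, w = shape
    for i, ((x, y), r) in enumerate(zip(centres, radii_px)):
        r0 = max(0, int(np.floor(y - r - 1)))
        r1 = min(h, int(np.ceil(y + r + 2)))
        c0 = max(0, int(np.floor(x - r - 1)))
        c1 = min(w, int(np.ceil(x + r + 2)))
        rr, cc = np.mgrid[r0:r1, c0:c1]
        disk = (cc - x) ** 2 + (rr - y) ** 2 <= r**2
        labels[r0:r1, c0:c1][disk] = i + 1
    return labels


def _within_distance(
    shape: tuple[int, int], centres: np.ndarray, dists_px: np.ndarray
) -> np.ndarray:
    mask = np.zeros(shape, dtype=bool)
    h, w = shape
    for (x, y), d in zip(centres, dists_px):
        r0 = max(0, int(np.floor(y - d - 1)))
        r1 = min(h, int(np.ceil(y + d + 2)))
        c0 = max(0, int(np.floor(x - d - 1)))
        c1 = min(w, int(np.ceil(x + d + 2)))
        rr, cc = np.mgrid[r0:r1, c0:c1]
        mask[r0:r1, c0:c1] |= (cc - x) ** 2 + (rr - y) ** 2 <= d**2
    return mask


def generate_tile(
    scene: SceneParams,
    seed,
    *,
    case_id: str = "case",
    glomerulus_id: str = "g1",
    nfe2l1_factor: float = 1.0,
    nqo1_level_factor: float = 1.0,
    nqo1_area_factor: float = 1.0,
    markers_off: bool = False,
) -> tuple[MultiplexImage, GlomerulusROI, TileGroundTruth]:
    """Render one glomerulus tile with full ground truth.

    ``seed`` may be an integer or a ``numpy.random.Generator``; identical seed
    and parameters give bit-identical output.  The multiplicative factors scale
    the nuclear NFE2L1 level, the NQO1 level, and the NQO1 ring width (hence
    its area), modelling per-case / per-group expression differences.
    ``markers_off`` renders a no-primary-antibody tile: marker channels carry
    only background and noise while Hoechst still stains nuclei.
    """
    from scipy import ndimage as ndi

    rng = _as_rng(seed)
    px = scene.pixel_size_um
    shape = (scene.tile_size_px, scene.tile_size_px)

    roi = _ellipse_roi(scene, rng, case_id, glomerulus_id)
    glom_mask = roi.mask(shape)
    centres, radii_um = _place_nuclei(scene, rng, roi)
    n = len(centres)

    n_podo = int(round(n * scene.podocyte_fraction))
    podo_idx = rng.choice(n, size=n_podo, replace=False) if n_podo else np.array([], int)
    is_podo = np.zeros(n, dtype=bool)
    is_podo[podo_idx] = True

    radii_px = radii_um / px
    labels = _paint_disks(shape, centres, radii_px)
    nucleus_mask = labels > 0
    podo_mask = np.isin(labels, np.flatnonzero(is_podo) + 1)

    ring_w_px = scene.ring_width_um * max(nqo1_area_factor, 0.0) / px
    if n_podo and ring_w_px > 0:
        outer = _within_distance(
            shape, centres[is_podo], radii_px[is_podo] + ring_w_px
        )
        nqo1_mask = outer & ~nucleus_mask & glom_mask
    else:
        nqo1_mask = np.zeros(shape, dtype=bool)

    levels = {
        "hoechst": scene.hoechst_level,
        "p57": 0.0 if markers_off else scene.p57_level,
        "nfe2l1_nuclear": 0.0 if markers_off else scene.nfe2l1_nuclear_level * nfe2l1_factor,
        "nfe2l1_cyto": 0.0 if markers_off else scene.nfe2l1_cyto_level,
        "nfe2l2": 0.0 if markers_off else scene.nfe2l2_diffuse_level,
        "nqo1": 0.0 if markers_off else scene.nqo1_level * nqo1_level_factor,
    }

    signal = {ch: np.zeros(shape, dtype=np.float64) for ch in CHANNELS}
    signal["hoechst"][nucleus_mask] = levels["hoechst"]
    signal["p57"][podo_mask] = levels["p57"]
    signal["nfe2l1"][nqo1_mask] = levels["nfe2l1_cyto"]
    signal["nfe2l1"][podo_mask] = levels["nfe2l1_nuclear"]
    signal["nfe2l2"][glom_mask] = levels["nfe2l2"]
    signal["nqo1"][nqo1_mask] = levels["nqo1"]

    planes = np.empty((len(CHANNELS), *shape), dtype=np.uint16)
    for k, ch in enumerate(CHANNELS):
        expected = signal[ch]
        if scene.render_sigma_px > 0:
            expected = ndi.gaussian_filter(expected, scene.render_sigma_px)
        expected = expected + scene.background[ch]
        if scene.poisson_noise:
            vals = rng.poisson(expected).astype(np.float64)
        else:
            vals = expected.copy()
        if scene.read_noise_sd > 0:
            vals += rng.normal(0.0, scene.read_noise_sd, size=shape)
        planes[k] = np.clip(np.rint(vals), 0, np.iinfo(np.uint16).max).astype(np.uint16)

    image = MultiplexImage(planes=planes, pixel_size_um=px)
    truth = TileGroundTruth(
        centres_px=centres,
        radii_um=radii_um,
        is_podocyte=is_podo,
        nucleus_labels=labels,
        nqo1_mask=nqo1_mask,
        glom_mask=glom_mask,
        levels=levels,
        background=dict(scene.background),
    )
    return image, roi, truth


def generate_control_tile(scene: SceneParams, seed) -> MultiplexImage:
    """Render a no-primary-antibody control tile (background + noise markers)."""
    image, _roi, _truth = generate_tile(scene, seed, markers_off=True)
    return image


def draw_case_latents(cohort: CohortParams, seed) -> pd.DataFrame:
    """Draw per-case latent NFE2L1/NQO1 multipliers from a Gaussian copula.

    The bivariate-normal correlation is chosen as 2 sin(pi * rho / 6) so the
    lognormal multipliers have Spearman rank correlation exactly ``rho``.
    Returns one row per case with the applicable group effect factors.
    """
    rng = _as_rng(seed)
    r = 2.0 * np.sin(np.pi * cohort.rho / 6.0)
    rows = []
    for group, size in cohort.group_sizes.items():
        z1 = rng.standard_normal(size)
        z2 = r * z1 + np.sqrt(max(0.0, 1.0 - r**2)) * rng.standard_normal(size)
        lat1 = np.exp(cohort.latent_sigma * z1)
        lat2 = np.exp(cohort.latent_sigma * z2)
        for i in range(size):
            rows.append(
                {
                    "case_id": f"{group}_{i + 1:02d}",
                    "group": group,
                    "nfe2l1_latent": lat1[i],
                    "nqo1_latent": lat2[i],
                    "nfe2l1_factor": cohort.factor("nfe2l1", group),
                    "nqo1_level_factor": cohort.factor("nqo1_level", group),
                    "nqo1_area_factor": cohort.factor("nqo1_area", group),
                }
            )
    return pd.DataFrame(rows)


def iter_cohort_tiles(cohort: CohortParams, scene: SceneParams, seed):
    """Yield (CaseMetadata, GlomerulusROI, MultiplexImage, TileGroundTruth)
    tile-by-tile for a whole cohort, without touching disk.

    Per-case latents multiply the group effect factors; all tiles of one case
    share its latent multipliers.  The sequence is deterministic given seed.
    """
    rng = _as_rng(seed)
    latents = draw_case_latents(cohort, rng)
    yield from _iter_tiles(latents, cohort, scene, rng)


def _iter_tiles(
    latents: pd.DataFrame, cohort: CohortParams, scene: SceneParams, rng: np.random.Generator
):
    lo, hi = cohort.glomeruli_per_case
    for row in latents.itertuples(index=False):
        meta = CaseMetadata(case_id=row.case_id, group=row.group)
        n_glom = int(rng.integers(lo, hi + 1))
        for g in range(1, n_glom + 1):
            jit = np.exp(rng.normal(0.0, cohort.glom_sigma, size=3))
            image, roi, truth = generate_tile(
                scene,
                rng,
                case_id=row.case_id,
                glomerulus_id=f"g{g}",
                nfe2l1_factor=row.nfe2l1_factor * row.nfe2l1_latent * jit[0],
                nqo1_level_factor=row.nqo1_level_factor * row.nqo1_latent * jit[1],
                nqo1_area_factor=row.nqo1_area_factor * jit[2],
            )
            yield meta, roi, image, truth


def generate_cohort(
    cohort: CohortParams, scene: SceneParams, outdir: str | Path, seed: int
) -> pd.DataFrame:
    """Write a full synthetic cohort to ``outdir`` in pipeline-ready layout.

    Layout: ``images/<case>_<glom>.tiff``, ``rois/<case>.geojson``,
    ``control/control.tiff``, ``metadata.csv``, ``ground_truth/`` (per-tile
    nucleus-label and NQO1-mask TIFFs, case latents CSV, parameter YAML) and a
    ``config.yaml`` consumable by the analysis pipeline with no further input.
    Returns the case-latent table.  One control tile is shared by the cohort
    (single staining batch).
    """
    outdir = Path(outdir)
    for sub in ("images", "rois", "control", "ground_truth"):
        (outdir / sub).mkdir(parents=True, exist_ok=True)

    rng = np.random.default_rng(seed)
    latents = draw_case_latents(cohort, rng)
    control = generate_control_tile(scene, rng)
    write_multiplex_image(control, outdir / "control" / "control.tiff")

    metas: list[CaseMetadata] = []
    rois_by_case: dict[str, list[GlomerulusROI]] = {}
    for meta, roi, image, truth in _iter_tiles(latents, cohort, scene, rng):
        if meta.case_id not in rois_by_case:
            metas.append(meta)
            rois_by_case[meta.case_id] = []
        rois_by_case[meta.case_id].append(roi)
        stem = f"{meta.case_id}_{roi.glomerulus_id}"
        write_multiplex_image(image, outdir / "images" / f"{stem}.tiff")
        tifffile.imwrite(
            outdir / "ground_truth" / f"{stem}_nuclei.tiff", truth.nucleus_labels
        )
        tifffile.imwrite(
            outdir / "ground_truth" / f"{stem}_nqo1.tiff",
            truth.nqo1_mask.astype(np.uint8),
        )
    for case_id, rois in rois_by_case.items():
        write_roi_annotations(rois, outdir / "rois" / f"{case_id}.geojson")
    write_case_metadata(metas, outdir / "metadata.csv")
    latents.to_csv(outdir / "ground_truth" / "cases.csv", index=False)

    params = {
        "seed": int(seed),
        "scene": dataclasses.asdict(scene),
        "cohort": dataclasses.asdict(cohort),
    }
    (outdir / "ground_truth" / "params.yaml").write_text(yaml.safe_dump(params))

    config = {
        "images_dir": "images",
        "rois_dir": "rois",
        "control_image": "control/control.tiff",
        "metadata": "metadata.csv",
        "pixel_size_um": scene.pixel_size_um,
        "output_dir": "results",
        "seed": int(seed),
    }
    (outdir / "config.yaml").write_text(yaml.safe_dump(config))
    return latents


def simulate_case_features(
    cohort: CohortParams,
    seed,
    scene: SceneParams | None = None,
    glom_noise_sd: float | None = None,
    boundary_dilution: float = 0.93,
) -> pd.DataFrame:
    """Case-level feature table from the cohort's statistical skeleton.

    Draws the same latent copula and effect model as the image path and maps
    them through the measurement model (background + diluted compartment level,
    lognormal between-glomerulus variation, mean over the case's glomeruli)
    without rendering pixels.  Used for Monte-Carlo studies of the cohort
    statistics where rendering hundreds of image cohorts would be pointless —
    the rendering-and-recovery fidelity is validated separately.
    """
    scene = scene or SceneParams()
    if glom_noise_sd is None:
        glom_noise_sd = cohort.glom_sigma
    rng = _as_rng(seed)
    latents = draw_case_latents(cohort, rng)
    lo, hi = cohort.glomeruli_per_case
    b = scene.background
    d = boundary_dilution
    # mean NQO1-annulus share of the ellipse for the default geometry
    mean_r = scene.nucleus_radius_um[0]
    ring_area = np.pi * ((mean_r + scene.ring_width_um) ** 2 - mean_r**2)
    n_podo = scene.podocyte_fraction * np.mean(scene.n_nuclei)
    glom_area = np.pi * scene.glom_semi_axes_um[0] * scene.glom_semi_axes_um[1]
    base_pct = 100.0 * n_podo * ring_area / glom_area

    rows = []
    for row in latents.itertuples(index=False):
        m = int(rng.integers(lo, hi + 1))
        noise = np.exp(rng.normal(0.0, glom_noise_sd, size=(3, m)))
        nfe2l1 = b["nfe2l1"] + d * scene.nfe2l1_nuclear_level * row.nfe2l1_factor \
            * row.nfe2l1_latent * noise[0]
        nqo1_int = b["nqo1"] + d * scene.nqo1_level * row.nqo1_level_factor \
            * row.nqo1_latent * noise[1]
        pct = np.clip(base_pct * row.nqo1_area_factor * noise[2], 0.0, 100.0)
        rows.append(
            {
                "case_id": row.case_id,
                "group": row.group,
                "n_glomeruli": m,
                "nfe2l1_nuclear": float(nfe2l1.mean()),
                "nqo1_intensity": float(nqo1_int.mean()),
                "nqo1_pct_positivity": float(pct.mean()),
            }
        )
    return pd.DataFrame(rows)
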