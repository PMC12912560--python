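"""Ground-truthed synthetic inputs: lung-like histology renders, stripe
masks with analytic mean linear intercept, and correlation-controlled
paired data.

The image generator emulates a 20x field of H&E-stained distal lung:
dark-staining parenchyma (low green-channel intensity) surrounding bright
airspace lumina. Airspaces are non-overlapping ellipses with sinusoidal
boundary perturbation — near-circular for alveoli, strongly elongated and
irregular for alveolar ducts (the perturbation amplitude and axis ratio
are the levers that push duct circularity below the 0.5 gate). Two presets
encode the study phenotypes:

* ``normoxia``  — many small airspaces (normal alveolarization);
* ``hyperoxia`` — fewer, larger airspaces (arrested alveolarization after
  neonatal 95% O₂, the BPD model), with larger and more numerous ducts.

Every render carries its ground truth (label map, per-object class, area,
circularity, exclusion mask), so the segmentation pipeline, classifier and
intercept scorer can all be checked against construction. All randomness
flows from one explicit seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage import draw

__all__ = [
    "PhenotypeParams",
    "ClassSpec",
    "GroundTruth",
    "PRESETS",
    "TISSUE_RGB",
    "AIRSPACE_RGB",
    "SYNTHETIC_THRESHOLD",
    "generate_lung_image",
    "stripe_mask",
    "generate_correlated_pairs",
    "generate_cohort",
]

# H&E-like palette: tissue dark in the green channel, lumina bright.
TISSUE_RGB = (168, 70, 150)
AIRSPACE_RGB = (242, 238, 244)
VESSEL_WALL_RGB = (150, 55, 135)

#: Grayscale threshold separating the two palettes on the green channel.
SYNTHETIC_THRESHOLD = 150


@dataclass(frozen=True)
class ClassSpec:
    """Object-count range and log-normal area distribution for one class.

    Areas are drawn log-normally around ``area_median_um2`` with log-SD
    ``area_sigma`` and clipped to ``area_clip_um2`` — the clip band is kept
    at least 10% inside the classification gates so noiseless class
    recovery is well-posed.
    """

    n_range: tuple[int, int]
    area_median_um2: float
    area_sigma: float
    area_clip_um2: tuple[float, float]
    axis_ratio_range: tuple[float, float]
    boundary_amp: float
    boundary_lobes: tuple[int, int] = (4, 7)


@dataclass(frozen=True)
class PhenotypeParams:
    """Full parameterization of one synthetic phenotype."""

    name: str
    alveoli: ClassSpec
    intermediates: ClassSpec
    ducts: ClassSpec
    wall_um: float = 8.0
    n_vessels: int = 0
    vessel_lumen_um2: tuple[float, float] = (800.0, 2000.0)
    vessel_wall_um: float = 10.0
    n_exudates: int = 0
    exudate_area_um2: tuple[float, float] = (8.0, 30.0)
    noise_sigma: float = 0.0


PRESETS: dict[str, PhenotypeParams] = {
    "normoxia": PhenotypeParams(
        name="normoxia",
        alveoli=ClassSpec((35, 45), 420.0, 0.35, (200.0, 1300.0), (1.0, 1.4), 0.05),
        intermediates=ClassSpec((5, 8), 2400.0, 0.25, (1700.0, 3600.0), (1.5, 2.5), 0.08),
        ducts=ClassSpec((2, 3), 6000.0, 0.25, (4500.0, 9000.0), (5.0, 6.0), 0.12),
    ),
    "hyperoxia": PhenotypeParams(
        name="hyperoxia",
        alveoli=ClassSpec((12, 18), 750.0, 0.35, (250.0, 1300.0), (1.0, 1.4), 0.05),
        intermediates=ClassSpec((4, 6), 2800.0, 0.25, (1700.0, 3600.0), (1.5, 2.5), 0.08),
        ducts=ClassSpec((3, 5), 8500.0, 0.25, (5000.0, 12000.0), (5.0, 6.0), 0.12),
    ),
}


@dataclass
class GroundTruth:
    """Construction-time truth paired with a rendered field."""

    label_map: np.ndarray
    classes: list[str]  # classes[k] is the class of label k+1
    areas_um2: list[float]  # rasterized pixel areas
    exclusion_mask: np.ndarray
    tissue_area_um2: float
    scale_um_per_px: float
    phenotype: str = ""

    @property
    def n_objects(self) -> int:
        return len(self.classes)


# ---------------------------------------------------------------------------
# Shape rasterization and placement
# ---------------------------------------------------------------------------

def _perturbed_ellipse(
    center: tuple[float, float],
    area_px: float,
    axis_ratio: float,
    angle: float,
    amp: float,
    lobes: int,
    phase: float,
    shape: tuple[int, int],
) -> tuple[np.ndarray, np.ndarray]:
    """Pixel coordinates of an ellipse with sinusoidal boundary perturbation."""
    b = math.sqrt(area_px / (math.pi * axis_ratio))
    a = axis_ratio * b
    phi = np.linspace(0, 2 * math.pi, 256, endpoint=False)
    radial = 1.0 + amp * np.sin(lobes * phi + phase)
    ex = a * np.cos(phi) * radial
    ey = b * np.sin(phi) * radial
    ca, sa = math.cos(angle), math.sin(angle)
    xs = center[0] + ca * ex - sa * ey
    ys = center[1] + sa * ex + ca * ey
    return draw.polygon(ys, xs, shape=shape)


def _place_objects(
    rng: np.random.Generator,
    spec: ClassSpec,
    n: int,
    occupancy: np.ndarray,
    blocked: np.ndarray,
    scale: float,
    wall_px: int,
    margin: int,
    label_map: np.ndarray,
    next_label: int,
    max_tries: int = 300,
) -> tuple[int, int]:
    """Rasterize ``n`` non-overlapping objects of one class; returns
    (placed, next_label). ``blocked`` is the wall-dilated occupancy."""
    h, w = occupancy.shape
    wall_struct = _disk_struct(wall_px)
    placed = 0
    for _ in range(n):
        area = float(
            np.clip(
                spec.area_median_um2 * math.exp(spec.area_sigma * rng.standard_normal()),
                *spec.area_clip_um2,
            )
        )
        area_px = area / scale**2
        ok = False
        for _try in range(max_tries):
            ratio = rng.uniform(*spec.axis_ratio_range)
            angle = rng.uniform(0, math.pi)
            lobes = int(rng.integers(spec.boundary_lobes[0], spec.boundary_lobes[1] + 1))
            phase = rng.uniform(0, 2 * math.pi)
            cx = rng.uniform(margin, w - 1 - margin)
            cy = rng.uniform(margin, h - 1 - margin)
            rr, cc = _perturbed_ellipse(
                (cx, cy), area_px, ratio, angle, spec.boundary_amp, lobes, phase, (h, w)
            )
            if rr.size == 0:
                continue
            if (
                rr.min() < margin
                or cc.min() < margin
                or rr.max() >= h - margin
                or cc.max() >= w - margin
            ):
                continue
            if blocked[rr, cc].any():
                continue
            ok = True
            break
        if not ok:
            return placed, next_label
        label_map[rr, cc] = next_label
        occupancy[rr, cc] = True
        # block a wall-thick neighbourhood around the new object
        r0 = max(0, rr.min() - wall_px - 1)
        r1 = min(h, rr.max() + wall_px + 2)
        c0 = max(0, cc.min() - wall_px - 1)
        c1 = min(w, cc.max() + wall_px + 2)
        window = np.zeros((r1 - r0, c1 - c0), dtype=bool)
        window[rr - r0, cc - c0] = True
        blocked[r0:r1, c0:c1] |= ndimage.binary_dilation(window, structure=wall_struct)
        next_label += 1
        placed += 1
    return placed, next_label


def _disk_struct(radius: int) -> np.ndarray:
    if radius < 1:
        return np.ones((1, 1), dtype=bool)
    yy, xx = np.mgrid[-radius : radius + 1, -radius : radius + 1]
    return (xx**2 + yy**2) <= radius**2


def generate_lung_image(
    phenotype: str | PhenotypeParams = "normoxia",
    size_px: tuple[int, int] = (512, 512),
    scale_um_per_px: float = 1.0,
    seed: int | np.random.Generator = 0,
    counts: dict[str, int] | None = None,
    border_margin_px: int = 4,
    strict: bool = True,
) -> tuple[np.ndarray, GroundTruth]:
    """Render one synthetic 20x field and its ground truth.

    Ducts are placed first (largest), then intermediates, then alveoli; a
    wall-thick exclusion zone keeps every pair of airspaces separated by
    parenchyma. ``counts`` overrides the per-class object counts (keys
    ``alveolus``/``intermediate``/``duct``). With ``strict=True`` a field
    where the requested objects cannot be placed after bounded retries
    raises, reporting the achieved count. Deterministic per seed.
    """
    params = PRESETS[phenotype] if isinstance(phenotype, str) else phenotype
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    h, w = size_px
    scale = scale_um_per_px
    wall_px = max(1, int(round(params.wall_um / scale)))

    label_map = np.zeros((h, w), dtype=np.int32)
    occupancy = np.zeros((h, w), dtype=bool)
    blocked = np.zeros((h, w), dtype=bool)
    exclusion = np.zeros((h, w), dtype=bool)
    classes: list[str] = []
    next_label = 1

    plan = [
        ("duct", params.ducts),
        ("intermediate", params.intermediates),
        ("alveolus", params.alveoli),
    ]
    for cls_name, spec in plan:
        if counts is not None and cls_name in counts:
            n = int(counts[cls_name])
        else:
            n = int(rng.integers(spec.n_range[0], spec.n_range[1] + 1))
        placed, next_label = _place_objects(
            rng, spec, n, occupancy, blocked, scale, wall_px,
            border_margin_px + wall_px, label_map, next_label,
        )
        classes.extend([cls_name] * placed)
        if placed < n and strict:
            raise RuntimeError(
                f"could not place {n} {cls_name} objects without overlap "
                f"(achieved {placed}); reduce counts or areas"
            )

    # vessels: bright lumen inside a thick dark wall, whole structure excluded
    for _ in range(params.n_vessels):
        lum_area = rng.uniform(*params.vessel_lumen_um2) / scale**2
        wall_extra = max(2, int(round(params.vessel_wall_um / scale)))
        for _try in range(300):
            r = math.sqrt(lum_area / math.pi)
            cx = rng.uniform(border_margin_px + r + wall_extra, w - 1 - border_margin_px - r - wall_extra)
            cy = rng.uniform(border_margin_px + r + wall_extra, h - 1 - border_margin_px - r - wall_extra)
            rr, cc = draw.disk((cy, cx), r, shape=(h, w))
            out_rr, out_cc = draw.disk((cy, cx), r + wall_extra, shape=(h, w))
            if blocked[out_rr, out_cc].any():
                continue
            occupancy[rr, cc] = True  # lumen is bright
            exclusion[out_rr, out_cc] = True
            window = np.zeros((h, w), dtype=bool)
            window[out_rr, out_cc] = True
            blocked |= ndimage.binary_dilation(window, structure=_disk_struct(wall_px))
            break

    # disconnected exudates: tissue-coloured specks inside airspace lumina
    lumen_free = occupancy & ~exclusion
    speck_candidates = np.flatnonzero(ndimage.binary_erosion(lumen_free, _disk_struct(4)))
    exudate_px = np.zeros((h, w), dtype=bool)
    for _ in range(params.n_exudates):
        if speck_candidates.size == 0:
            break
        idx = int(rng.choice(speck_candidates))
        cy, cx = divmod(idx, w)
        area = rng.uniform(*params.exudate_area_um2) / scale**2
        rr, cc = draw.disk((cy, cx), max(1.0, math.sqrt(area / math.pi)), shape=(h, w))
        keep = lumen_free[rr, cc]
        exudate_px[rr[keep], cc[keep]] = True

    # render
    rgb = np.empty((h, w, 3), dtype=np.uint8)
    rgb[...] = TISSUE_RGB
    lumen = occupancy.copy()
    rgb[lumen] = AIRSPACE_RGB
    wall_ring = exclusion & ~lumen
    rgb[wall_ring] = VESSEL_WALL_RGB
    rgb[exudate_px] = TISSUE_RGB

    if params.noise_sigma > 0:
        noise = rng.normal(0.0, params.noise_sigma, size=rgb.shape)
        rgb = np.clip(rgb.astype(float) + noise, 0, 255).astype(np.uint8)

    areas = [
        float(np.count_nonzero(label_map == k) * scale**2)
        for k in range(1, len(classes) + 1)
    ]
    # exudate specks render as tissue but are debris, not parenchyma
    tissue_px = np.count_nonzero(~occupancy & ~exclusion)
    truth = GroundTruth(
        label_map=label_map,
        classes=classes,
        areas_um2=areas,
        exclusion_mask=exclusion,
        tissue_area_um2=float(tissue_px * scale**2),
        scale_um_per_px=scale,
        phenotype=params.name,
    )
    return rgb, truth


# ---------------------------------------------------------------------------
# Analytic fixtures
# ---------------------------------------------------------------------------

def stripe_mask(
    period_um: float,
    wall_um: float,
    size_px: tuple[int, int] = (200, 1000),
    scale_um_per_px: float = 1.0,
) -> np.ndarray:
    """Vertical tissue stripes with exact geometry (analytic L_M oracle).

    Columns x with (x·scale mod period) < wall are tissue, the rest
    airspace, so a horizontal line spanning k periods crosses exactly k
    walls and its L_M equals the period.
    """
    if not 0 < wall_um < period_um:
        raise ValueError("require 0 < wall_um < period_um")
    h, w = size_px
    x_um = np.arange(w) * scale_um_per_px
    tissue_cols = np.mod(x_um, period_um) < wall_um
    return np.tile(tissue_cols, (h, 1))


def generate_correlated_pairs(
    n: int,
    target_r: float,
    seed: int | np.random.Generator = 0,
    exact: bool = True,
) -> tuple[np.ndarray, np.ndarray]:
    """Paired vectors with controlled Pearson correlation.

    With ``exact=True`` the *sample* correlation equals ``target_r`` to
    floating-point accuracy, by the orthogonalization construction: mix a
    centred unit vector with a residual-orthogonal unit complement at the
    angle whose cosine is ``target_r``. With ``exact=False`` the pairs are
    drawn from a bivariate normal with *population* correlation
    ``target_r`` (sample r then fluctuates as ~1/sqrt(n)).
    """
    if abs(target_r) > 1:
        raise ValueError(f"|target_r| must be <= 1, got {target_r}")
    if n < 3:
        raise ValueError(f"need n >= 3 pairs, got {n}")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    x = rng.standard_normal(n)
    if not exact:
        y = target_r * x + math.sqrt(1.0 - target_r**2) * rng.standard_normal(n)
        return x, y
    for _ in range(100):
        e = rng.standard_normal(n)
        xc = x - x.mean()
        ec = e - e.mean()
        ec = ec - (ec @ xc) / (xc @ xc) * xc
        norm_e = np.linalg.norm(ec)
        if norm_e > 1e-12:
            break
    else:  # pragma: no cover - probability zero
        raise RuntimeError("failed to construct an orthogonal complement")
    xu = xc / np.linalg.norm(xc)
    eu = ec / norm_e
    y = target_r * xu + math.sqrt(1.0 - target_r**2) * eu
    return x, y


# ---------------------------------------------------------------------------
# Cohorts
# ---------------------------------------------------------------------------

def generate_cohort(
    out_dir: str | Path,
    n_animals_per_group: tuple[int, int] = (3, 4),
    phenotypes: tuple[str, str] = ("normoxia", "hyperoxia"),
    fields_per_animal: int = 6,
    seed: int = 0,
    size_px: tuple[int, int] = (512, 512),
    scale_um_per_px: float = 1.0,
    image_format: str = "tif",
    n_vessels: int = 0,
) -> pd.DataFrame:
    """Write a two-group image cohort plus manifest CSV to ``out_dir``.

    Emulates the study layout: six 20x fields per animal, two exposure
    groups. Returns the manifest (animal_id, group, field_id, image, mask)
    whose paths are relative to ``out_dir``. Deterministic per seed.
    """
    import imageio.v3 as iio

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    root_seq = np.random.SeedSequence(seed)
    rows = []
    for g, (n_animals, pheno) in enumerate(zip(n_animals_per_group, phenotypes)):
        params = PRESETS[pheno]
        if n_vessels:
            params = replace(params, n_vessels=n_vessels)
        for a in range(n_animals):
            animal_id = f"{pheno[:3]}{a + 1:02d}"
            for f in range(fields_per_animal):
                child = root_seq.spawn(1)[0]
                rng = np.random.default_rng(child)
                rgb, truth = generate_lung_image(
                    params, size_px=size_px, scale_um_per_px=scale_um_per_px, seed=rng
                )
                img_name = f"{animal_id}_f{f + 1}.{image_format}"
                iio.imwrite(out_dir / img_name, rgb)
                mask_name = ""
                if truth.exclusion_mask.any():
                    mask_name = f"{animal_id}_f{f + 1}_mask.png"
                    iio.imwrite(
                        out_dir / mask_name,
                        (truth.exclusion_mask.astype(np.uint8) * 255),
                    )
                rows.append(
                    {
                        "animal_id": animal_id,
                        "group": pheno,
                        "field_id": f + 1,
                        "image": img_name,
                        "mask": mask_name,
                    }
                )
    manifest = pd.DataFrame(rows)
    manifest.to_csv(out_dir / "manifest.csv", index=False)
    return manifest
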