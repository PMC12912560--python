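"""Mean linear intercept (L_M): chord-based scoring of distal airspace size.

L_M = AB / N_intersection, where AB is the length of a test line overlaid
on the parenchyma and N_intersection is the number of times the line
crosses a respiratory airway wall. The manual protocol places two lines
per 20x field, six fields per animal (12 measurements), and averages them;
here the manual placement can be replaced by seeded uniform-random lines
that reject excluded regions.

An *intersection* is operationalized as one maximal run of tissue pixels
crossed along the line profile, sampled at sub-pixel steps with
nearest-pixel lookup. A line lying entirely inside tissue therefore counts
one intersection; a line inside a single airspace counts zero and is
flagged invalid (L_M undefined, excluded from averaging — never silently
infinite).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .pipeline import CalibrationSettings

__all__ = [
    "LmMeasurement",
    "LineRejected",
    "compute_lm",
    "count_intersections",
    "auto_lm",
    "mean_lm",
    "read_manual_lm",
    "manual_lm_per_animal",
]


class LineRejected(ValueError):
    """Raised when a test line violates placement constraints."""


@dataclass
class LmMeasurement:
    """One test line: geometry, intersection count and the resulting L_M."""

    line_length_um: float
    n_intersections: int
    lm_um: float  # NaN when invalid
    p0: tuple[float, float] = (0.0, 0.0)  # (x, y) pixels
    p1: tuple[float, float] = (0.0, 0.0)

    @property
    def valid(self) -> bool:
        return self.n_intersections > 0


def compute_lm(line_length_um: float, n_intersections: int) -> float:
    """L_M = line length / intersection count; NaN when the count is zero."""
    if line_length_um <= 0:
        raise ValueError(f"line_length_um must be > 0, got {line_length_um}")
    if n_intersections < 0:
        raise ValueError(f"n_intersections must be >= 0, got {n_intersections}")
    if n_intersections == 0:
        return math.nan
    return line_length_um / n_intersections


def count_intersections(
    tissue_mask: np.ndarray,
    p0: tuple[float, float],
    p1: tuple[float, float],
    exclusion_mask: np.ndarray | None = None,
    step_px: float = 0.25,
) -> int:
    """Number of maximal tissue runs (walls) crossed along the line p0->p1.

    Points are (x, y) in pixel coordinates; the profile is sampled every
    ``step_px`` pixels with nearest-pixel lookup. A line touching an
    excluded region is rejected (mirroring the manual rule of avoiding
    bronchioles and vascular structures).
    """
    tissue_mask = np.asarray(tissue_mask, dtype=bool)
    h, w = tissue_mask.shape
    (x0, y0), (x1, y1) = p0, p1
    length = math.hypot(x1 - x0, y1 - y0)
    if length == 0:
        raise LineRejected("zero-length line")
    n_steps = max(2, int(math.ceil(length / step_px)) + 1)
    t = np.linspace(0.0, 1.0, n_steps)
    xs = np.rint(x0 + t * (x1 - x0)).astype(int)
    ys = np.rint(y0 + t * (y1 - y0)).astype(int)
    if xs.min() < 0 or ys.min() < 0 or xs.max() >= w or ys.max() >= h:
        raise LineRejected("line leaves the image bounds")
    if exclusion_mask is not None:
        exclusion_mask = np.asarray(exclusion_mask, dtype=bool)
        if exclusion_mask[ys, xs].any():
            raise LineRejected("line crosses an excluded region")
    profile = tissue_mask[ys, xs]
    # count rising edges of the tissue profile = maximal tissue runs
    runs = int(profile[0]) + int(np.count_nonzero(~profile[:-1] & profile[1:]))
    return runs


def auto_lm(
    tissue_mask: np.ndarray,
    calibration: CalibrationSettings,
    n_lines: int = 2,
    seed: int | np.random.Generator = 0,
    exclusion_mask: np.ndarray | None = None,
    line_length_um: float | None = None,
    border_margin_px: int = 2,
    max_tries_per_line: int = 200,
) -> list[LmMeasurement]:
    """Cast ``n_lines`` seeded random test lines over the field.

    Each line has fixed length (default 60% of the smaller field dimension)
    at uniform-random position and orientation; lines that leave the field,
    touch the border margin, or cross an excluded region are rejected and
    redrawn. After ``max_tries_per_line`` failures the line is dropped with
    a warning, so fewer measurements than requested may be returned. A line
    with zero intersections yields an invalid measurement (kept, flagged).
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    tissue_mask = np.asarray(tissue_mask, dtype=bool)
    h, w = tissue_mask.shape
    scale = calibration.scale_um_per_px
    if line_length_um is None:
        line_length_um = 0.6 * min(h, w) * scale
    length_px = line_length_um / scale

    out: list[LmMeasurement] = []
    for _ in range(n_lines):
        placed = False
        for _try in range(max_tries_per_line):
            theta = rng.uniform(0, math.pi)
            dx, dy = length_px * math.cos(theta), length_px * math.sin(theta)
            m = border_margin_px
            x0 = rng.uniform(m + max(0, -dx), w - 1 - m - max(0, dx))
            y0 = rng.uniform(m + max(0, -dy), h - 1 - m - max(0, dy))
            if not (m <= x0 <= w - 1 - m and m <= y0 <= h - 1 - m):
                continue
            x1, y1 = x0 + dx, y0 + dy
            try:
                n = count_intersections(
                    tissue_mask, (x0, y0), (x1, y1), exclusion_mask=exclusion_mask
                )
            except LineRejected:
                continue
            out.append(
                LmMeasurement(
                    line_length_um=line_length_um,
                    n_intersections=n,
                    lm_um=compute_lm(line_length_um, n),
                    p0=(x0, y0),
                    p1=(x1, y1),
                )
            )
            placed = True
            break
        if not placed:
            warnings.warn(
                f"could not place a valid test line after {max_tries_per_line} tries; "
                f"returning {len(out)} of {n_lines} measurements",
                stacklevel=2,
            )
    if out and not any(m.valid for m in out):
        warnings.warn("all test lines have zero intersections (no tissue crossed)", stacklevel=2)
    return out


def mean_lm(measurements: list[LmMeasurement]) -> float:
    """Mean L_M over valid measurements; NaN if none are valid."""
    vals = [m.lm_um for m in measurements if m.valid]
    return float(np.mean(vals)) if vals else math.nan


# ---------------------------------------------------------------------------
# Manual-score ingestion
# ---------------------------------------------------------------------------

MANUAL_COLUMNS = ["animal_id", "field_id", "line_length_um", "n_intersections"]


def read_manual_lm(path) -> pd.DataFrame:
    """Read manually counted intercepts (CSV) and compute per-line L_M.

    Expected columns: animal_id, field_id, line_length_um, n_intersections.
    Rows with zero intersections get L_M = NaN and are excluded from
    animal averages.
    """
    df = pd.read_csv(path)
    missing = [c for c in MANUAL_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"manual L_M table is missing columns: {missing}")
    df = df.copy()
    df["lm_um"] = [
        compute_lm(l, int(n)) for l, n in zip(df["line_length_um"], df["n_intersections"])
    ]
    return df


def manual_lm_per_animal(df: pd.DataFrame) -> pd.Series:
    """Average per-line L_M scores to one score per animal (NaN rows dropped)."""
    return df.dropna(subset=["lm_um"]).groupby("animal_id")["lm_um"].mean()
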