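"""Gate-parameter sweep with leave-one-out Pearson stability selection.

The area/circularity gates that define "alveolar duct" and "alveolus" are
not known a priori; they are chosen by sweeping a small grid of candidate
gates, correlating the resulting per-animal mean airspace area with the
manual mean linear intercept (L_M), and preferring gates whose correlation
is *stable* under leave-one-out (LOO) resampling — each of the n animals is
excluded in turn and Pearson's r is recomputed on the remaining n−1, so a
gate whose full-sample r leans on a single animal shows a wide LOO range.

Candidate grids (minimum area × circularity range):

* ducts:   {3000, 4000, 5000, 6000} µm² × {[0, 0.5], [0, 1]}   (8 combos)
* alveoli: {50, 100, 150} µm² × {[0.01, 1], [0.1, 1], [0.25, 1]} (9 combos)

Gates here are minimum-area + circularity only (no upper area bound); the
buffer band is applied afterwards during classification. Selection is
advisory: the full ranking is always returned so a human can override.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .morphometry import AirspaceMeasurement
from .stats import pearson_r_p

__all__ = [
    "DUCT_AREAS_UM2",
    "DUCT_CIRC_RANGES",
    "ALVEOLUS_AREAS_UM2",
    "ALVEOLUS_CIRC_RANGES",
    "GateCombo",
    "ParamGrid",
    "SweepResult",
    "build_param_grid",
    "loo_correlations",
    "gate_mean_area",
    "sweep_table_from_measurements",
    "run_sweep",
    "select_optimal",
    "sweep_results_to_frame",
]

DUCT_AREAS_UM2 = (3000.0, 4000.0, 5000.0, 6000.0)
DUCT_CIRC_RANGES = ((0.0, 0.5), (0.0, 1.0))
ALVEOLUS_AREAS_UM2 = (50.0, 100.0, 150.0)
ALVEOLUS_CIRC_RANGES = ((0.01, 1.0), (0.1, 1.0), (0.25, 1.0))


@dataclass(frozen=True)
class GateCombo:
    """One candidate gate: minimum area plus a closed circularity range."""

    kind: str
    min_area_um2: float
    circ: tuple[float, float]

    def passes(self, area_um2: float, circularity: float) -> bool:
        lo, hi = self.circ
        return area_um2 >= self.min_area_um2 and lo <= circularity <= hi


@dataclass(frozen=True)
class ParamGrid:
    kind: str
    combos: tuple[GateCombo, ...]


@dataclass
class SweepResult:
    """Full-sample and leave-one-out Pearson statistics for one gate."""

    combo: GateCombo
    full_r: float
    full_p: float
    loo_r: list[float]
    loo_median_r: float
    loo_min_r: float
    loo_max_r: float
    n: int
    warnings: list[str] = field(default_factory=list)

    @property
    def loo_range(self) -> float:
        return self.loo_max_r - self.loo_min_r


def build_param_grid(kind: str) -> ParamGrid:
    """The candidate gate grid for one airway kind (``duct`` or ``alveolus``)."""
    if kind == "duct":
        areas, circs = DUCT_AREAS_UM2, DUCT_CIRC_RANGES
    elif kind == "alveolus":
        areas, circs = ALVEOLUS_AREAS_UM2, ALVEOLUS_CIRC_RANGES
    else:
        raise ValueError(f"unknown airway kind {kind!r}; expected 'duct' or 'alveolus'")
    combos = tuple(GateCombo(kind, a, c) for a in areas for c in circs)
    return ParamGrid(kind=kind, combos=combos)


def loo_correlations(x, y) -> dict:
    """Full-sample and leave-one-out Pearson statistics for paired vectors.

    Iteration i recomputes r over the n−1 pairs excluding pair i. Subsets
    with zero variance are flagged and excluded from the median/min/max.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("x and y must be paired")
    n = x.size
    if n < 4:
        raise ValueError(f"need at least 4 pairs for leave-one-out, got {n}")
    full_r, full_p, _ = pearson_r_p(x, y)
    loo_r: list[float] = []
    warns: list[str] = []
    for i in range(n):
        xi = np.delete(x, i)
        yi = np.delete(y, i)
        if np.std(xi) == 0 or np.std(yi) == 0:
            warns.append(f"LOO iteration {i}: zero variance, excluded")
            continue
        r, _, _ = pearson_r_p(xi, yi)
        loo_r.append(r)
    if not loo_r:
        raise ValueError("every leave-one-out subset had zero variance")
    return {
        "full_r": full_r,
        "full_p": full_p,
        "loo_r": loo_r,
        "loo_median_r": float(np.median(loo_r)),
        "loo_min_r": float(min(loo_r)),
        "loo_max_r": float(max(loo_r)),
        "n": n,
        "warnings": warns,
    }


def gate_mean_area(measurements: list[AirspaceMeasurement], combo: GateCombo) -> float:
    """Mean area (µm²) over the airspaces passing one candidate gate; NaN if none."""
    areas = [m.area_um2 for m in measurements if combo.passes(m.area_um2, m.circularity)]
    return float(np.mean(areas)) if areas else float("nan")


def sweep_table_from_measurements(
    measurements_by_animal: dict[str, list[AirspaceMeasurement]],
    grid: ParamGrid,
) -> pd.DataFrame:
    """Per-animal mean gated area for every grid combination (long format).

    Measurements for one animal are pooled across its fields of view before
    averaging, so the per-animal value is the mean area of all gated
    airspaces that animal contributed.
    """
    rows = []
    for animal, ms in measurements_by_animal.items():
        for combo in grid.combos:
            rows.append(
                {
                    "animal_id": animal,
                    "kind": combo.kind,
                    "min_area_um2": combo.min_area_um2,
                    "circ_low": combo.circ[0],
                    "circ_high": combo.circ[1],
                    "mean_area_um2": gate_mean_area(ms, combo),
                }
            )
    return pd.DataFrame(rows)


def run_sweep(
    per_animal_areas: pd.DataFrame,
    lm_by_animal: pd.Series | dict,
    grid: ParamGrid,
) -> list[SweepResult]:
    """Correlate per-animal gated mean areas against L_M for every combo.

    ``per_animal_areas`` is the long table from
    :func:`sweep_table_from_measurements`; every animal must appear for
    every combination and have an L_M score.
    """
    lm = pd.Series(lm_by_animal, dtype=float)
    results: list[SweepResult] = []
    for combo in grid.combos:
        sub = per_animal_areas[
            (per_animal_areas["min_area_um2"] == combo.min_area_um2)
            & (per_animal_areas["circ_low"] == combo.circ[0])
            & (per_animal_areas["circ_high"] == combo.circ[1])
        ].set_index("animal_id")["mean_area_um2"]
        missing_area = set(lm.index) - set(sub.index)
        if missing_area:
            raise ValueError(
                f"no gated area for animal(s) {sorted(missing_area)} "
                f"under combo {combo}"
            )
        missing_lm = set(sub.index) - set(lm.index)
        if missing_lm:
            raise ValueError(f"no L_M score for animal(s) {sorted(missing_lm)}")
        animals = sorted(sub.index)
        stats = loo_correlations(sub.loc[animals].to_numpy(), lm.loc[animals].to_numpy())
        results.append(SweepResult(combo=combo, **stats))
    return results


def select_optimal(
    results: list[SweepResult], loo_range_cap: float = 0.25
) -> tuple[SweepResult, pd.DataFrame]:
    """Advisory gate selection: highest LOO median r among stable combos.

    A combo is *stable* when its LOO range (max − min r) is within
    ``loo_range_cap``; ties break by full-sample r, then by smaller minimum
    area. If no combo passes the cap the cap is relaxed with a warning —
    the ranking table is always returned for human override.
    """
    if not results:
        raise ValueError("empty sweep: nothing to select")
    stable = [s for s in results if s.loo_range <= loo_range_cap]
    if not stable:
        warnings.warn(
            f"no combination has a LOO range within {loo_range_cap}; "
            "relaxing the stability cap",
            stacklevel=2,
        )
        stable = list(results)
    best = max(
        stable,
        key=lambda s: (s.loo_median_r, s.full_r, -s.combo.min_area_um2),
    )
    return best, sweep_results_to_frame(results)


def sweep_results_to_frame(results: list[SweepResult]) -> pd.DataFrame:
    """Long-format sweep report, ranked by LOO median r (descending)."""
    df = pd.DataFrame(
        {
            "kind": s.combo.kind,
            "min_area_um2": s.combo.min_area_um2,
            "circ_low": s.combo.circ[0],
            "circ_high": s.combo.circ[1],
            "full_r": s.full_r,
            "full_p": s.full_p,
            "loo_median_r": s.loo_median_r,
            "loo_min_r": s.loo_min_r,
            "loo_max_r": s.loo_max_r,
            "loo_range": s.loo_range,
            "n": s.n,
        }
        for s in results
    )
    return df.sort_values("loo_median_r", ascending=False).reset_index(drop=True)
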