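"""Batch execution, configuration, logging and report/overlay writing.

One :class:`RunConfig` drives a whole batch; it is serialized (with a
content hash) into every output directory so any table can be traced back
to the exact thresholds and gates that produced it. CSV is the canonical
table format (written at full float precision so re-reading reproduces
in-memory values exactly); XLSX mirrors it when enabled. Overlay renders
follow the visual-inspection convention: classified airways cyan, excluded
structures orange.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .intercept import auto_lm, manual_lm_per_animal, mean_lm, read_manual_lm
from .morphometry import (
    CLASSES,
    CLASSIFIED,
    ClassificationParams,
    animal_summaries_to_frame,
    classify_all,
    image_summaries_to_frame,
    measure_airspaces,
    measurements_to_frame,
    summarize_animal,
    summarize_image,
)
from .paramopt import (
    build_param_grid,
    run_sweep,
    select_optimal,
    sweep_results_to_frame,
)
from .pipeline import (
    CalibrationSettings,
    PipelineParams,
    load_exclusion_mask,
    load_rgb,
    process_image,
)
from .stats import bland_altman_z, compare_groups, pearson_with_gate

__all__ = [
    "RunConfig",
    "process_batch",
    "optimize_from_measurements",
    "compare_animal_groups",
    "render_overlay",
    "write_table",
]

CYAN = np.array([0, 255, 255], dtype=np.uint8)
ORANGE = np.array([255, 165, 0], dtype=np.uint8)


@dataclass
class RunConfig:
    """Declarative configuration for a batch run.

    The spatial scale and grayscale threshold have no defaults: both must
    be user-calibrated before any batch is processed.
    """

    scale_um_per_px: float
    threshold: float
    duct_min_area_um2: float = 4000.0
    duct_circ: tuple[float, float] = (0.0, 0.5)
    alv_min_area_um2: float = 150.0
    alv_max_area_um2: float = 1500.0
    alv_circ: tuple[float, float] = (0.01, 1.0)
    debris_min_um2: float = 50.0
    hole_max_um2: float = 50.0
    connectivity: int = 2
    exclude_edge: bool = False
    lm_auto: bool = True
    lm_lines_per_field: int = 2
    lm_line_length_um: float | None = None
    loo_range_cap: float = 0.25
    expected_fields: int = 6
    seed: int = 0
    write_xlsx: bool = False
    write_overlays: bool = True

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "scale_um_per_px" not in raw:
            raise ValueError(
                "config is missing 'scale_um_per_px': a user-defined scale "
                "must be set globally prior to use"
            )
        if "threshold" not in raw:
            raise ValueError("config is missing 'threshold' (grayscale calibration value)")
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("duct_circ", "alv_circ"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["duct_circ"] = list(self.duct_circ)
        d["alv_circ"] = list(self.alv_circ)
        return d

    @property
    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]

    @property
    def calibration(self) -> CalibrationSettings:
        return CalibrationSettings(self.scale_um_per_px, self.threshold)

    @property
    def pipeline_params(self) -> PipelineParams:
        return PipelineParams(
            debris_min_um2=self.debris_min_um2,
            hole_max_um2=self.hole_max_um2,
            airspace_connectivity=self.connectivity,
            exclude_edge=self.exclude_edge,
        )

    @property
    def classification(self) -> ClassificationParams:
        return ClassificationParams(
            duct_min_area_um2=self.duct_min_area_um2,
            duct_circ=self.duct_circ,
            alv_min_area_um2=self.alv_min_area_um2,
            alv_max_area_um2=self.alv_max_area_um2,
            alv_circ=self.alv_circ,
        )


def write_table(df: pd.DataFrame, path: Path, xlsx: bool = False) -> None:
    """Write a table as CSV (canonical, full precision) and optionally XLSX.

    Floats are written as shortest round-trip representations; re-read with
    :func:`read_table` (round-trip float parsing) to reproduce in-memory
    values bit-exactly.
    """
    df.to_csv(path.with_suffix(".csv"), index=False)
    if xlsx:
        df.to_excel(path.with_suffix(".xlsx"), index=False)


def read_table(path: str | Path) -> pd.DataFrame:
    """Re-read a table written by :func:`write_table` without float drift."""
    return pd.read_csv(path, float_precision="round_trip")


def render_overlay(green: np.ndarray, label_map, measurements, exclusion_mask) -> np.ndarray:
    """Inspection overlay: classified airways cyan, excluded structures orange."""
    rgb = np.stack([green] * 3, axis=-1).astype(np.uint8)
    classified_labels = [m.label for m in measurements if m.assigned_class in CLASSIFIED]
    if classified_labels:
        sel = np.isin(label_map.labels, classified_labels)
        rgb[sel] = CYAN
    if exclusion_mask is not None and exclusion_mask.any():
        rgb[exclusion_mask.astype(bool)] = ORANGE
    return rgb


def _load_manifest(input_dir: Path, manifest_path: Path | None) -> pd.DataFrame:
    """Manifest of the batch; without one, every image is its own animal."""
    if manifest_path is None:
        manifest_path = input_dir / "manifest.csv"
    if manifest_path.exists():
        mf = pd.read_csv(manifest_path, keep_default_na=False)
        required = {"animal_id", "image"}
        if not required <= set(mf.columns):
            raise ValueError(f"manifest must contain columns {sorted(required)}")
        if "group" not in mf.columns:
            mf["group"] = ""
        if "field_id" not in mf.columns:
            mf["field_id"] = mf.groupby("animal_id").cumcount() + 1
        if "mask" not in mf.columns:
            mf["mask"] = ""
        return mf
    images = sorted(
        p.name
        for p in input_dir.iterdir()
        if p.suffix.lower() in {".tif", ".tiff", ".png", ".jpg", ".jpeg"}
        and not p.stem.endswith("_mask")
    )
    if not images:
        raise FileNotFoundError(f"no images found in {input_dir}")
    rows = []
    for name in images:
        stem = Path(name).stem
        mask = ""
        for suffix in (".png", ".tif", ".tiff"):
            cand = input_dir / f"{stem}_mask{suffix}"
            if cand.exists():
                mask = cand.name
                break
        rows.append(
            {"animal_id": stem, "group": "", "field_id": 1, "image": name, "mask": mask}
        )
    return pd.DataFrame(rows)


def process_batch(
    config: RunConfig,
    input_dir: str | Path,
    output_dir: str | Path,
    manifest: str | Path | None = None,
) -> dict:
    """Run the full pipeline over a batch of images.

    Writes per-airspace, per-image and per-animal tables, inspection
    overlays, a structured per-image run log and the serialized config to
    ``output_dir``. Unreadable images are skipped with a logged error; the
    batch fails only if every image fails.
    """
    input_dir = Path(input_dir)
    output_dir = Path(output_dir)
    output_dir.mkdir(parents=True, exist_ok=True)
    mf = _load_manifest(input_dir, Path(manifest) if manifest else None)

    calibration = config.calibration
    params = config.pipeline_params
    cls_params = config.classification
    rng = np.random.default_rng(config.seed)

    per_airspace: list[pd.DataFrame] = []
    image_summaries: dict[str, list] = {}
    groups: dict[str, str] = {}
    lm_values: dict[str, list[float]] = {}
    log: list[dict] = []
    overlay_dir = output_dir / "overlays"
    mask_dir = output_dir / "labels"
    if config.write_overlays:
        overlay_dir.mkdir(exist_ok=True)
        mask_dir.mkdir(exist_ok=True)

    n_failed = 0
    for row in mf.itertuples(index=False):
        record: dict = {"image": row.image, "animal_id": row.animal_id}
        try:
            rgb = load_rgb(input_dir / row.image)
            excl = None
            if getattr(row, "mask", ""):
                excl = load_exclusion_mask(input_dir / row.mask, rgb.shape[:2])
            result = process_image(rgb, calibration, params, exclusion_mask=excl, name=row.image)
            measurements = classify_all(
                measure_airspaces(result.label_map, calibration), cls_params
            )
            summary = summarize_image(
                measurements,
                tissue_area_um2=result.tissue_area_um2,
                excluded_area_um2=result.excluded_area_um2,
                airspace_area_um2=result.airspace_area_um2,
                image_id=row.image,
                animal_id=str(row.animal_id),
            )
            per_airspace.append(
                measurements_to_frame(measurements, image_id=row.image, animal_id=str(row.animal_id))
            )
            image_summaries.setdefault(str(row.animal_id), []).append(summary)
            groups[str(row.animal_id)] = str(getattr(row, "group", ""))
            if config.lm_auto:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    lm_ms = auto_lm(
                        result.tissue_mask,
                        calibration,
                        n_lines=config.lm_lines_per_field,
                        seed=rng,
                        exclusion_mask=excl,
                        line_length_um=config.lm_line_length_um,
                    )
                lm_values.setdefault(str(row.animal_id), []).extend(
                    m.lm_um for m in lm_ms if m.valid
                )
            if config.write_overlays:
                import imageio.v3 as iio

                overlay = render_overlay(
                    result.green, result.label_map, measurements, result.exclusion_mask
                )
                iio.imwrite(overlay_dir / f"{Path(row.image).stem}_overlay.png", overlay)
                iio.imwrite(
                    mask_dir / f"{Path(row.image).stem}_tissue.png",
                    (result.tissue_mask.astype(np.uint8) * 255),
                )
            record.update(
                status="ok",
                steps=result.steps_applied,
                n_airspaces=result.label_map.n_labels,
                warnings=result.warnings,
            )
        except Exception as exc:  # noqa: BLE001 - batch must continue
            n_failed += 1
            record.update(status="error", error=str(exc))
        log.append(record)

    if not image_summaries:
        raise RuntimeError(f"all {len(mf)} image(s) failed to process; see run log")

    animal_summaries = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for animal, summaries in image_summaries.items():
            lm = float(np.mean(lm_values[animal])) if lm_values.get(animal) else None
            animal_summaries.append(
                summarize_animal(
                    summaries, lm_um=lm, group=groups.get(animal),
                    expected_fields=config.expected_fields,
                )
            )

    airspace_df = (
        pd.concat(per_airspace, ignore_index=True) if per_airspace else pd.DataFrame()
    )
    image_df = image_summaries_to_frame(
        [s for lst in image_summaries.values() for s in lst]
    )
    animal_df = animal_summaries_to_frame(animal_summaries)

    write_table(airspace_df, output_dir / "per_airspace", config.write_xlsx)
    write_table(image_df, output_dir / "per_image", config.write_xlsx)
    write_table(animal_df, output_dir / "per_animal", config.write_xlsx)
    run_log = {
        "tool_version": __version__,
        "config_hash": config.config_hash,
        "n_images": int(len(mf)),
        "n_failed": int(n_failed),
        "images": log,
    }
    (output_dir / "run_log.json").write_text(json.dumps(run_log, indent=2))
    (output_dir / "config.json").write_text(json.dumps(self_describing(config), indent=2))
    return {
        "per_airspace": airspace_df,
        "per_image": image_df,
        "per_animal": animal_df,
        "run_log": run_log,
    }


def self_describing(config: RunConfig) -> dict:
    d = config.to_dict()
    d["config_hash"] = config.config_hash
    d["tool_version"] = __version__
    return d


# ---------------------------------------------------------------------------
# Optimization and comparison runners
# ---------------------------------------------------------------------------

def optimize_from_measurements(
    per_airspace: pd.DataFrame,
    lm_by_animal: pd.Series | dict,
    kinds: tuple[str, ...] = ("duct", "alveolus"),
    loo_range_cap: float = 0.25,
) -> dict:
    """Gate sweep from a per-airspace table (as written by process_batch).

    Re-gating a measurement table is cheap, so the sweep reuses the
    measured geometry instead of re-segmenting images.
    """
    from .morphometry import AirspaceMeasurement
    from .paramopt import sweep_table_from_measurements

    by_animal: dict[str, list[AirspaceMeasurement]] = {}
    for row in per_airspace.itertuples(index=False):
        by_animal.setdefault(str(row.animal_id), []).append(
            AirspaceMeasurement(
                label=int(row.label),
                area_um2=float(row.area_um2),
                perimeter_um=float(row.perimeter_um),
                circularity=float(row.circularity),
                centroid_xy=(float(row.centroid_x), float(row.centroid_y)),
                touches_edge=bool(row.touches_edge),
            )
        )
    out: dict = {}
    for kind in kinds:
        grid = build_param_grid(kind)
        table = sweep_table_from_measurements(by_animal, grid)
        results = run_sweep(table, lm_by_animal, grid)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            best, ranking = select_optimal(results, loo_range_cap=loo_range_cap)
        out[kind] = {"results": results, "best": best, "ranking": ranking}
    return out


def compare_animal_groups(
    animal_df: pd.DataFrame,
    group_a: str,
    group_b: str,
    variance_alpha: float = 0.05,
) -> pd.DataFrame:
    """Group comparison rows for every per-animal metric, plus agreement
    statistics (Pearson r, Bland–Altman bias/LOA) of mean area vs L_M."""
    rows = []
    metrics = [f"{c}_{q}" for c in CLASSES for q in
               ("count", "mean_area_um2", "total_area_um2", "percent_area")]
    metrics += ["tissue_area_um2", "airspace_area_um2", "lm_um"]
    a_df = animal_df[animal_df["group"] == group_a]
    b_df = animal_df[animal_df["group"] == group_b]
    if len(a_df) < 2 or len(b_df) < 2:
        raise ValueError("each group needs at least 2 animals")
    for metric in metrics:
        if metric not in animal_df.columns:
            continue
        a = a_df[metric].dropna().to_numpy(dtype=float)
        b = b_df[metric].dropna().to_numpy(dtype=float)
        if a.size < 2 or b.size < 2 or (a.var() == 0 and b.var() == 0):
            continue
        cmp = compare_groups(a, b, variance_alpha=variance_alpha)
        rows.append(
            {
                "metric": metric,
                "group_a": group_a,
                "group_b": group_b,
                "mean_a": cmp.mean_a,
                "sd_a": cmp.sd_a,
                "n_a": cmp.n_a,
                "mean_b": cmp.mean_b,
                "sd_b": cmp.sd_b,
                "n_b": cmp.n_b,
                "f_p": cmp.f_p,
                "welch": cmp.welch,
                "t_stat": cmp.t_stat,
                "p": cmp.p,
            }
        )
    report = pd.DataFrame(rows)

    # agreement of automated area readouts with L_M, across all animals
    agreement_rows = []
    if "lm_um" in animal_df.columns and animal_df["lm_um"].notna().sum() >= 3:
        for c in ("duct", "alveolus"):
            col = f"{c}_mean_area_um2"
            if col not in animal_df.columns:
                continue
            sub = animal_df.dropna(subset=[col, "lm_um"])
            if len(sub) < 3:
                continue
            x = sub[col].to_numpy(dtype=float)
            y = sub["lm_um"].to_numpy(dtype=float)
            pr = pearson_with_gate(x, y)
            ba = bland_altman_z(x, y)
            agreement_rows.append(
                {
                    "comparison": f"{c}_mean_area_vs_lm",
                    "n": pr.n,
                    "r": pr.r,
                    "p": pr.p,
                    "bias": ba.bias,
                    "loa_low": ba.loa_low,
                    "loa_high": ba.loa_high,
                    "outside_loa": ";".join(map(str, ba.outside_loa.tolist())),
                }
            )
    agreement = pd.DataFrame(agreement_rows)
    if not agreement.empty:
        report = pd.concat([report, agreement], ignore_index=True)
    return report


# ---------------------------------------------------------------------------
# Optional plots (lazy matplotlib)
# ---------------------------------------------------------------------------

def plot_sweep(ranking: pd.DataFrame, path: str | Path) -> None:
    """Dot-and-range plot of full-sample r and LOO median/range per combo."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    labels = [
        f"{int(r.min_area_um2)}/{r.circ_low:g}-{r.circ_high:g}"
        for r in ranking.itertuples(index=False)
    ]
    x = np.arange(len(ranking))
    fig, ax = plt.subplots(figsize=(1.2 * len(ranking) + 2, 4))
    ax.errorbar(
        x,
        ranking["loo_median_r"],
        yerr=[
            ranking["loo_median_r"] - ranking["loo_min_r"],
            ranking["loo_max_r"] - ranking["loo_median_r"],
        ],
        fmt="ko",
        capsize=3,
        label="LOO median (range)",
    )
    ax.plot(x, ranking["full_r"], "ro", label="full-sample r")
    ax.set_xticks(x, labels, rotation=45, ha="right")
    ax.set_ylabel("Pearson r vs $L_M$")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_bland_altman(result, path: str | Path) -> None:
    """Bland–Altman plot of z-scored pairs with bias and 95% LOA lines."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    ax.scatter(result.means, result.differences, color="k", s=20)
    ax.axhline(result.bias, color="r", label="bias")
    for y in (result.loa_low, result.loa_high):
        ax.axhline(y, color="k", linestyle="--")
    ax.set_xlabel("mean of z-scores")
    ax.set_ylabel("difference of z-scores")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
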