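"""End-to-end study orchestration: colonies in, summary and effect tables out.

``run_colony`` takes one DEM (path or raster) plus an optional benthic
mask, brings the DEM to the working grid, applies the consistent edge
trim, and returns the metric battery together with the benthic
composition record.  ``run_study`` maps that over a set of colonies and
closes with the compositional robust regressions of the five response
variables (fractal dimension, surface rugosity, IQR slope, IQR planform
curvature, IQR profile curvature) on benthic composition.
"""

from __future__ import annotations

import hashlib
import logging
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import coda, metrics
from .errors import AlignmentError
from .rasters import (
    BenthicMask,
    CompositionRecord,
    ElevationRaster,
    aggregate_clip,
    check_aligned,
    quantify_areas,
    read_dem,
    read_mask,
    resample_to_grid,
)

logger = logging.getLogger("reefstruct")

RESPONSE_VARIABLES = (
    "Fractal Dimension",
    "Surface Rugosity",
    "IQR Slope",
    "IQR Planform Curvature",
    "IQR Profile Curvature",
)


@dataclass
class StudyConfig:
    """All pipeline settings; defaults are the analysis's standard choices."""

    working_cell_size: float = 0.01
    factors: tuple[int, ...] = (1, 2, 4, 8, 16, 32)
    linearity_threshold: float = 0.98
    curvature_method: str = "zevenbergen_thorne"
    zero_alpha: float = 0.05
    zero_mode: str = "simple_substitution"
    trim_fraction: float | None = None
    seed: int = 0
    output_dir: str | None = None
    category_metrics: bool = False

    def to_yaml(self, path: str | Path) -> Path:
        path = Path(path)
        data = asdict(self)
        data["factors"] = list(self.factors)
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=False)
        return path

    @classmethod
    def from_yaml(cls, path: str | Path) -> "StudyConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        if "factors" in data:
            data["factors"] = tuple(data["factors"])
        return cls(**data)


def _array_hash(a: np.ndarray) -> str:
    return hashlib.sha256(np.ascontiguousarray(a).tobytes()).hexdigest()[:16]


def _prepare_raster(raster: ElevationRaster, config: StudyConfig) -> ElevationRaster:
    """Bring a DEM to the working grid and apply the consistent edge trim."""
    if raster.cell_size < config.working_cell_size - 1e-12:
        raster = resample_to_grid(raster, config.working_cell_size)
    return aggregate_clip(raster, max(config.factors))


def run_colony(
    dem: str | Path | ElevationRaster,
    mask: str | Path | BenthicMask | None = None,
    config: StudyConfig | None = None,
    colony_id: str | None = None,
) -> tuple[metrics.MetricSet, CompositionRecord | None]:
    """Metrics plus composition for one colony.

    Stages: read → resample to the working grid → aggregation-based edge
    trim (largest factor, so all metrics share one footprint) → metric
    battery → per-category area quantification.  Provenance (input hashes
    and config) is logged per stage.
    """
    config = config or StudyConfig()
    if isinstance(dem, (str, Path)):
        colony_id = colony_id or Path(dem).stem
        dem = read_dem(dem)
    colony_id = colony_id or "colony"
    logger.info("%s: dem hash=%s config=%s", colony_id, _array_hash(dem.values), config)

    if isinstance(mask, (str, Path)):
        mask = read_mask(mask, like=dem)
    if mask is not None:
        check_aligned(dem, mask)

    work = _prepare_raster(dem, config)
    mset = metrics.colony_metrics(
        work,
        colony_id=colony_id,
        factors=config.factors,
        linearity_threshold=config.linearity_threshold,
        curvature_method=config.curvature_method,
    )

    record = None
    if mask is None:
        warnings.warn(f"{colony_id}: no benthic mask; composition not quantified",
                      stacklevel=2)
    else:
        gsd = dem.gsd if dem.gsd else dem.cell_size
        record = quantify_areas(mask, colony_id, detection_limit_area=gsd**2)
        logger.info("%s: mask hash=%s", colony_id, _array_hash(mask.labels))
    return mset, record


def _records_frame(records: list[CompositionRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "colony_id": [r.colony_id for r in records],
            "live_m2": [r.live_area for r in records],
            "dead_m2": [r.dead_area for r in records],
            "other_m2": [r.other_area for r in records],
            "detection_limit_m2": [r.detection_limit_area for r in records],
            "total_m2": [r.total_area for r in records],
        }
    )


def summary_table(metrics_df: pd.DataFrame, records_df: pd.DataFrame) -> pd.DataFrame:
    """Across-colony summary of DEM properties and benthic areas.

    Mean / SD / median / min / max of GSD (reported both as pixel length in
    m and pixel area in m²), planform area, and the three category areas.
    """
    merged = metrics_df.merge(records_df, on="colony_id", how="left")
    gsd_len = np.sqrt(merged["detection_limit_m2"]) if "detection_limit_m2" in merged else pd.Series(dtype=float)
    rows = {
        "gsd_m_per_pixel": gsd_len,
        "gsd_m2_per_pixel": merged.get("detection_limit_m2", pd.Series(dtype=float)),
        "planform_area_m2": merged["planform_area_m2"],
        "other_m2": merged.get("other_m2", pd.Series(dtype=float)),
        "dead_m2": merged.get("dead_m2", pd.Series(dtype=float)),
        "live_m2": merged.get("live_m2", pd.Series(dtype=float)),
    }
    out = []
    for name, series in rows.items():
        s = pd.to_numeric(series, errors="coerce").dropna()
        if s.empty:
            continue
        out.append(
            {
                "quantity": name,
                "mean": s.mean(),
                "sd": s.std(ddof=1) if len(s) > 1 else 0.0,
                "median": s.median(),
                "min": s.min(),
                "max": s.max(),
            }
        )
    return pd.DataFrame(out)


def run_study(
    colonies: list,
    config: StudyConfig | None = None,
) -> dict:
    """Run the full analysis over a set of colonies.

    ``colonies`` holds (colony_id, dem, mask) triples, where dem/mask may
    be paths or in-memory objects; masks may be None.  Returns a dict with
    ``metrics`` (per-colony rows), ``records``, ``summary`` (Table-1-style)
    and, when at least 6 colonies carry compositions, ``effects`` (one
    ComponentEffectTable per response variable) and ``report``.
    """
    config = config or StudyConfig()
    ids = [c[0] for c in colonies]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate colony_id in study inputs")

    msets, records = [], []
    for colony_id, dem, mask in colonies:
        mset, record = run_colony(dem, mask, config, colony_id=colony_id)
        msets.append(mset)
        if record is not None:
            records.append(record)

    metrics_df = pd.DataFrame([m.to_row() for m in msets])
    records_df = _records_frame(records) if records else pd.DataFrame(columns=["colony_id"])
    result = {
        "metrics": metrics_df,
        "records": records_df,
        "summary": summary_table(metrics_df, records_df),
    }

    if len(records) < 6:
        logger.warning(
            "regression skipped: %d colonies with compositions (need >= 6)",
            len(records),
        )
        return result

    zcfg = coda.ZeroReplacementConfig(alpha=config.zero_alpha, mode=config.zero_mode)
    replaced = coda.replace_rounded_zeros(records_df, zcfg)
    merged = metrics_df.merge(replaced, on="colony_id", how="inner")
    responses = {
        "Fractal Dimension": merged["fractal_d"],
        "Surface Rugosity": merged["surface_rugosity"],
        "IQR Slope": merged["slope_iqr"],
        "IQR Planform Curvature": merged["planform_curv_iqr"],
        "IQR Profile Curvature": merged["profile_curv_iqr"],
    }
    effects = {}
    for name in RESPONSE_VARIABLES:
        y = responses[name].to_numpy(dtype=float)
        if np.ptp(y[np.isfinite(y)]) == 0.0:
            logger.warning("%s: zero-variance response; effects degenerate", name)
        effects[name] = coda.coda_metric_regression(
            merged, y, trim_fraction=config.trim_fraction, seed=config.seed
        )
    result["effects"] = effects
    result["report"] = coda.effects_report(effects)
    return result


def write_outputs(result: dict, output_dir: str | Path) -> list[Path]:
    """Write study tables as CSV (and the effects report as markdown)."""
    outdir = Path(output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    written = []

    def dump(df: pd.DataFrame, name: str) -> None:
        path = outdir / name
        df.to_csv(path, index=False, float_format="%.10g")
        written.append(path)

    dump(result["metrics"], "colony_metrics.csv")
    if len(result["records"]):
        dump(result["records"], "compositions.csv")
    dump(result["summary"], "study_summary.csv")
    if "report" in result:
        dump(result["report"], "effects.csv")
        md = outdir / "effects.md"
        md.write_text(coda.effects_markdown(result["report"]))
        written.append(md)
    return written


def make_figures(effects: dict[str, pd.DataFrame], output_dir: str | Path) -> list[Path]:
    """Bar plot of per-part effects with SEM whiskers, one file per metric."""
    if not effects:
        raise ValueError("no effects to plot")
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    outdir = Path(output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = []
    for name, table in effects.items():
        fig, ax = plt.subplots(figsize=(4, 3))
        xs = np.arange(len(table))
        ax.bar(xs, table["delta_y_per_m2"], yerr=table["se"], capsize=4,
               color=["#2a9d8f", "#7f675b", "#e9c46a"])
        for x, (_, row) in zip(xs, table.iterrows()):
            mark = coda._sig_mark(row["p_value"])
            if mark:
                ax.annotate(mark, (x, row["delta_y_per_m2"]),
                            ha="center", va="bottom", fontsize=14)
        ax.set_xticks(xs, table["part"])
        ax.axhline(0.0, color="k", lw=0.5)
        ax.set_ylabel("predicted change per m$^2$")
        ax.set_title(name)
        fig.tight_layout()
        path = outdir / f"effects_{name.lower().replace(' ', '_')}.png"
        fig.savefig(path, dpi=150)
        plt.close(fig)
        paths.append(path)
    return paths
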