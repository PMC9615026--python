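"""Batch orchestration: blinding, per-cell quantification, statistics, provenance.

A run is driven by a single structured config (YAML or JSON) listing per-cell
stack/geometry paths with condition labels plus segmentation, enrichment,
shell and statistics settings. Cells failing the inclusion criterion — a
non-empty construct-positive organelle mask on at least one slice, the
pixel-level analog of "only cells with visible construct signal on
organelles" — are excluded and reported with reasons, never silently
dropped. Every output table can be regenerated from the provenance JSON
plus the inputs.
"""
from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .counts import roi_object_counts
from .enrichment import peroxisomal_enrichment
from .errors import ConfigError, EnrichmentError, PunctaError
from .io import read_geometry, read_stack, write_results
from .radial import aggregate_distributions, radial_distribution, shape_scaled_shells
from .segment import cell_region, double_positive_mask, segment_marker
from .stats import dunnett_t3, mann_whitney_test, rout_outliers, welch_t_test

logger = logging.getLogger(__name__)

_VALID_TESTS = ("welch_t", "mann_whitney", "dunnett_t3")
_VALID_OUTLIER_RULES = ("none", "rout", "tukey")


@dataclass
class CellEntry:
    stack: str
    geometry: str
    condition: str
    cell_id: str = ""


@dataclass
class PipelineConfig:
    cells: list[CellEntry]
    channel_roles: dict[int, str]
    output_dir: str = "results"
    z_step_um: float = 0.3
    pixel_size_um: float = 0.2
    segmentation: dict = field(default_factory=lambda: {"method": "otsu", "min_size_px": 2})
    enrichment: dict = field(
        default_factory=lambda: {
            "slice_weighting": "unweighted", "normalization": "ratio_of_means"
        }
    )
    n_shells: int = 10
    statistics: dict = field(
        default_factory=lambda: {
            "test": "dunnett_t3", "outlier_rule": "none", "Q": 1.0,
            "mc_reps": 100_000, "seed": 0,
        }
    )

    def __post_init__(self) -> None:
        if not self.cells:
            raise ConfigError("config lists no cells")
        for i, c in enumerate(self.cells):
            if isinstance(c, dict):
                self.cells[i] = c = CellEntry(**c)
            if not c.condition:
                raise ConfigError(f"cell {i}: empty condition label")
            if not c.cell_id:
                c.cell_id = f"cell_{i:03d}"
        self.channel_roles = {int(k): v for k, v in self.channel_roles.items()}
        if self.statistics.get("test", "dunnett_t3") not in _VALID_TESTS:
            raise ConfigError(f"statistics.test must be one of {_VALID_TESTS}")
        if self.statistics.get("outlier_rule", "none") not in _VALID_OUTLIER_RULES:
            raise ConfigError(f"statistics.outlier_rule must be one of {_VALID_OUTLIER_RULES}")
        if self.n_shells < 1:
            raise ConfigError("n_shells must be >= 1")

    def validate_paths(self) -> None:
        for c in self.cells:
            for p in (c.stack, c.geometry):
                if not Path(p).exists():
                    raise ConfigError(f"input path does not exist: {p}")


def load_config(path: str | Path) -> PipelineConfig:
    text = Path(path).read_text()
    doc = yaml.safe_load(text)
    if not isinstance(doc, dict):
        raise ConfigError(f"{path}: config must be a mapping")
    try:
        return PipelineConfig(**doc)
    except TypeError as exc:
        raise ConfigError(f"{path}: {exc}") from exc


# ---------------------------------------------------------------------------
# Blinding


@dataclass
class BlindingMap:
    """Bijection between original paths and opaque codes."""

    codes: dict[str, str]
    seed: int

    def unblind(self, code: str) -> str:
        inverse = {v: k for k, v in self.codes.items()}
        return inverse[code]

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps({"seed": self.seed, "codes": self.codes}, indent=1))

    @classmethod
    def load(cls, path: str | Path) -> "BlindingMap":
        doc = json.loads(Path(path).read_text())
        return cls(codes=doc["codes"], seed=doc["seed"])


def blind_filenames(manifest: list[str], seed: int) -> BlindingMap:
    """Assign opaque, order-scrambled codes to unique paths.

    Codes carry no condition information; the stored map is the only way to
    unblind after quantification.
    """
    paths = [str(p) for p in manifest]
    if len(set(paths)) != len(paths):
        raise ConfigError("duplicate paths in manifest")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(paths))
    codes = {p: f"blind_{order[i]:04d}" for i, p in enumerate(paths)}
    return BlindingMap(codes=codes, seed=seed)


# ---------------------------------------------------------------------------
# Per-cell quantification


def _load_cell(entry: CellEntry, config: PipelineConfig):
    stack = read_stack(
        entry.stack, config.channel_roles,
        z_step_um=config.z_step_um, pixel_size_um=config.pixel_size_um,
    )
    geometry = read_geometry(entry.geometry)
    return stack, geometry


def quantify_cell_enrichment(stack, geometry, seg_params: dict, enr_params: dict, cell_id=""):
    """Segment, restrict to construct-positive pixels, and score one cell."""
    marker_mask, _ = segment_marker(
        stack,
        method=seg_params.get("method", "otsu"),
        min_size_px=seg_params.get("min_size_px", 2),
    )
    analysis = double_positive_mask(
        marker_mask, stack, seg_params.get("construct_threshold")
    )
    region = cell_region(stack, geometry)
    return peroxisomal_enrichment(
        stack, marker_mask, analysis, region, cell_id=cell_id, **enr_params
    )


def _apply_outlier_rule(df: pd.DataFrame, column: str, stats_cfg: dict) -> pd.DataFrame:
    rule = stats_cfg.get("outlier_rule", "none")
    if rule == "none":
        return df
    keep_mask = pd.Series(True, index=df.index)
    for _, grp in df.groupby("condition"):
        vals = grp[column].to_numpy()
        if rule == "rout" and len(vals) >= 3:
            res = rout_outliers(vals, Q=stats_cfg.get("Q", 1.0))
            bad = set(np.round(res.flagged, 12))
            keep_mask[grp.index] = [round(v, 12) not in bad for v in vals]
        elif rule == "tukey" and len(vals) >= 4:
            from .stats import tukey_box_summary

            box = tukey_box_summary(vals)
            bad = set(np.round(box.outliers, 12))
            keep_mask[grp.index] = [round(v, 12) not in bad for v in vals]
    flagged = df[~keep_mask]
    if len(flagged):
        logger.warning("%d value(s) flagged as outliers by rule %r", len(flagged), rule)
    out = df.copy()
    out["outlier"] = ~keep_mask
    return out


def _run_statistics(df: pd.DataFrame, column: str, stats_cfg: dict) -> dict:
    if "outlier" in df.columns:
        df = df[~df["outlier"]]
    groups = {
        label: grp[column].to_numpy() for label, grp in df.groupby("condition")
    }
    test = stats_cfg.get("test", "dunnett_t3")
    if test == "dunnett_t3":
        table = dunnett_t3(
            groups,
            mc_reps=stats_cfg.get("mc_reps", 100_000),
            seed=stats_cfg.get("seed", 0),
        )
        return {"test": test, "comparisons": table.comparisons,
                "anova_f": table.anova_f, "anova_p": table.anova_p,
                "mc_reps": table.mc_reps, "seed": table.seed}
    labels = sorted(groups)
    if len(labels) != 2:
        raise ConfigError(f"{test} requires exactly 2 conditions, got {len(labels)}")
    fn = welch_t_test if test == "welch_t" else mann_whitney_test
    res = fn(groups[labels[0]], groups[labels[1]])
    return {"test": res.method, "group_a": labels[0], "group_b": labels[1],
            "statistic": res.statistic, "df": res.df, "p_value": res.p_value}


def _provenance(config: PipelineConfig, extra: dict) -> dict:
    doc = {"puncta_version": __version__, "config": _config_dict(config)}
    doc.update(extra)
    return doc


def _config_dict(config: PipelineConfig) -> dict:
    d = asdict(config)
    d["channel_roles"] = {str(k): v for k, v in d["channel_roles"].items()}
    return d


def run_colocalization(config: PipelineConfig, output_dir: str | Path | None = None) -> dict:
    """End-to-end enrichment quantification for every cell in the config.

    Writes ``enrichment.csv`` (included cells), ``exclusions.csv`` (cells
    failing the inclusion criterion, with reasons), ``comparisons.json``
    (statistics block) and ``provenance.json``; returns the same objects.
    """
    config.validate_paths()
    outdir = Path(output_dir or config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    rows, exclusions = [], []
    for entry in config.cells:
        try:
            stack, geometry = _load_cell(entry, config)
            res = quantify_cell_enrichment(
                stack, geometry, config.segmentation, config.enrichment, entry.cell_id
            )
        except (EnrichmentError, PunctaError) as exc:
            logger.warning("cell %s excluded: %s", entry.cell_id, exc)
            exclusions.append(
                {"cell_id": entry.cell_id, "condition": entry.condition, "reason": str(exc)}
            )
            continue
        logger.info("cell %s quantified", entry.cell_id)
        rows.append(
            {
                "cell_id": entry.cell_id, "condition": entry.condition,
                "raw_enrichment": res.raw_enrichment,
                "construct_intensity": res.construct_intensity,
                "normalized_enrichment": res.normalized_enrichment,
                "background": res.background,
                "n_slices_used": res.n_slices_used,
                "analysis_mask_px": res.analysis_mask_px,
            }
        )
    if not rows:
        raise ConfigError("zero cells passed the inclusion criterion")
    df = pd.DataFrame(rows)
    df = _apply_outlier_rule(df, "normalized_enrichment", config.statistics)
    stats_block = _run_statistics(df, "normalized_enrichment", config.statistics)
    write_results(df, outdir / "enrichment.csv")
    write_results(
        exclusions, outdir / "exclusions.csv", columns=["cell_id", "condition", "reason"]
    )
    (outdir / "comparisons.json").write_text(json.dumps(stats_block, indent=1))
    prov = _provenance(config, {"n_included": len(df), "n_excluded": len(exclusions)})
    (outdir / "provenance.json").write_text(json.dumps(prov, indent=1))
    return {"results": df, "exclusions": exclusions, "statistics": stats_block}


def run_radial(config: PipelineConfig, output_dir: str | Path | None = None) -> dict:
    """Radial shell distributions per cell plus per-condition mean/SD tables."""
    config.validate_paths()
    outdir = Path(output_dir or config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    n = config.n_shells
    shell_cols = [f"shell_{k}" for k in range(1, n + 1)]
    per_cell, by_condition = [], {}
    for entry in config.cells:
        stack, geometry = _load_cell(entry, config)
        _, objects = segment_marker(
            stack,
            method=config.segmentation.get("method", "otsu"),
            min_size_px=config.segmentation.get("min_size_px", 2),
        )
        shells = shape_scaled_shells(geometry, n)
        dist = radial_distribution(objects, shells, outline=geometry.outline)
        row = {"cell_id": entry.cell_id, "condition": entry.condition,
               "n_objects": dist.n_objects_included,
               "n_excluded": dist.n_objects_excluded}
        row.update(dict(zip(shell_cols, dist.frequencies)))
        per_cell.append(row)
        by_condition.setdefault(entry.condition, []).append(dist)
    df = pd.DataFrame(per_cell)
    agg_rows = []
    for label, dists in by_condition.items():
        agg = aggregate_distributions(dists)
        for stat in ("mean", "sd"):
            row = {"condition": label, "statistic": stat, "n_cells": agg["n_cells"]}
            row.update(dict(zip(shell_cols, agg[stat])))
            agg_rows.append(row)
    agg_df = pd.DataFrame(agg_rows)
    write_results(df, outdir / "radial_per_cell.csv")
    write_results(agg_df, outdir / "radial_aggregate.csv")
    (outdir / "provenance.json").write_text(
        json.dumps(_provenance(config, {"n_cells": len(df)}), indent=1)
    )
    return {"per_cell": df, "aggregate": agg_df}


def run_counts(
    config: PipelineConfig,
    roi_names: tuple[str, ...] = ("soma", "growth_cone"),
    output_dir: str | Path | None = None,
) -> dict:
    """ROI object counts and growth-cone/soma ratios for neuron geometries."""
    config.validate_paths()
    outdir = Path(output_dir or config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    rows = []
    for entry in config.cells:
        stack, geometry = _load_cell(entry, config)
        _, objects = segment_marker(
            stack,
            method=config.segmentation.get("method", "otsu"),
            min_size_px=config.segmentation.get("min_size_px", 2),
        )
        res = roi_object_counts(objects, geometry, roi_names, cell_id=entry.cell_id)
        row = {"cell_id": entry.cell_id, "condition": entry.condition,
               "gc_soma_ratio": res.gc_soma_ratio}
        row.update({f"count_{k}": v for k, v in res.counts.items()})
        rows.append(row)
    df = pd.DataFrame(rows)
    write_results(df, outdir / "roi_counts.csv")
    (outdir / "provenance.json").write_text(
        json.dumps(_provenance(config, {"n_cells": len(df)}), indent=1)
    )
    return {"results": df}
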