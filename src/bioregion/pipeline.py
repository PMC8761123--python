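"""Configuration-driven orchestration of the full regionalization pipeline.

Stage order mirrors the analysis workflow: harmonize rasters → prune
collinear variables (VIF) → choose K (silhouette) → k-means + hill-climb →
majority filter → subclusters → cluster profiling → endemism analysis.
Every stage logs its parameters and wall time into ``report.txt`` and each
output is a plain CSV / Newick / GeoTIFF file, so any stage can be re-run
from saved intermediates.
"""

from __future__ import annotations

import logging
import os
import time
from dataclasses import dataclass, field, fields

import numpy as np
import pandas as pd
import yaml

from . import endemism as endm
from . import profiles as prof
from . import regionalize as regio
from .raster import build_pixel_table, read_manifest, write_cluster_map
from .vif import iterative_vif_prune

__all__ = ["PipelineConfig", "run_pipeline", "load_config"]

logger = logging.getLogger("bioregion")


class ConfigError(ValueError):
    """Invalid or unknown pipeline configuration."""


class StageError(RuntimeError):
    """A pipeline stage failed; partial outputs are retained."""


@dataclass
class PipelineConfig:
    manifest: str | None = None
    checklist: str | None = None
    out_dir: str = "bioregion_out"
    vif_threshold: float = 5.0
    k: int | None = None  # fixed K; otherwise chosen from k_scan
    k_scan: tuple[int, int] = (2, 12)
    seed: int = 42
    n_init: int = 10
    silhouette_subsample: int = 10_000
    majority_window: int = 3
    majority_passes: int = 1
    min_area_pixels: int = 25
    unit_level: str = "cluster"  # or "subcluster"
    n_perm: int = 1000
    linkage: str = "complete"
    distance_metric: str = "euclidean"
    drop_empty_units: bool = True

    def __post_init__(self) -> None:
        if self.manifest is None and self.checklist is None:
            raise ConfigError("config needs a raster manifest, a checklist, or both")
        if self.unit_level not in ("cluster", "subcluster"):
            raise ConfigError(f"unit_level must be cluster|subcluster, got {self.unit_level!r}")
        if self.k is not None and self.k < 2:
            raise ConfigError("k must be >= 2")
        k0, k1 = self.k_scan
        if not (2 <= k0 <= k1):
            raise ConfigError(f"invalid k_scan range {self.k_scan}")


def load_config(path: str) -> PipelineConfig:
    """Load a YAML config; unknown keys are rejected outright."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    known = {f.name for f in fields(PipelineConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ConfigError(f"unknown config key(s): {sorted(unknown)}")
    if "k_scan" in raw:
        raw["k_scan"] = tuple(raw["k_scan"])
    return PipelineConfig(**raw)


def _stage(report: list, name: str, func, *args, **kwargs):
    t0 = time.perf_counter()
    logger.info("stage %s: starting", name)
    try:
        result = func(*args, **kwargs)
    except Exception as exc:
        report.append(f"[{name}] FAILED after {time.perf_counter() - t0:.2f}s: {exc}")
        raise StageError(f"stage {name!r} failed: {exc}") from exc
    dt = time.perf_counter() - t0
    report.append(f"[{name}] ok in {dt:.2f}s")
    logger.info("stage %s: done in %.2fs", name, dt)
    return result


def run_pipeline(config: PipelineConfig) -> dict[str, str]:
    """Run all configured stages; returns a map of output name → path.

    Deterministic given the config and seeds.  A stage failure aborts with
    a stage-named error; outputs written before the failure are retained.
    """
    out = config.out_dir
    os.makedirs(out, exist_ok=True)
    paths: dict[str, str] = {}
    report: list[str] = [f"bioregion pipeline report", f"config: {config}"]

    def save(name: str, fname: str):
        paths[name] = os.path.join(out, fname)
        return paths[name]

    cluster_map = None
    env_dendro = None
    stack = None
    try:
        if config.manifest:
            stack = _stage(report, "read_rasters", read_manifest, config.manifest)
            table = _stage(report, "pixel_table", build_pixel_table, stack)

            vif_report = _stage(report, "vif_prune", iterative_vif_prune, table, config.vif_threshold)
            vif_report.to_frame().to_csv(save("vif_trace", "vif_trace.csv"), index=False)
            report.append(f"[vif_prune] retained {len(vif_report.retained)}/{len(table.variable_codes)}: {vif_report.retained}")

            pruned = table.subset(vif_report.retained)
            Z, _, _ = regio.standardize(pruned)

            if config.k is None:
                k0, k1 = config.k_scan
                profile = _stage(
                    report, "silhouette_scan", regio.silhouette_profile,
                    Z, k0, min(k1, Z.shape[0] - 1), config.seed, config.silhouette_subsample, config.n_init,
                )
                profile.to_frame().to_csv(save("silhouette", "silhouette.csv"), index=False)
                K = profile.argmax
                report.append(f"[silhouette_scan] argmax K={K}, local peaks {profile.local_peaks}")
            else:
                K = config.k

            fit = _stage(report, "kmeans", regio.kmeans, Z, K, config.seed, config.n_init)
            fit = _stage(report, "hill_climb", regio.hill_climb_refine, Z, fit)
            report.append(f"[kmeans] K={K} sse={fit.sse:.4f} iterations={fit.iterations}")

            raw_map = regio.labels_to_map(pruned, fit.labels)
            cluster_map = _stage(report, "majority_filter", regio.majority_filter, raw_map, config.majority_window, config.majority_passes)
            write_cluster_map(cluster_map, save("clusters", "clusters.tif"))

            submap = _stage(report, "subclusters", regio.split_subclusters, cluster_map, 8, config.min_area_pixels)
            areas = prof.cluster_area(cluster_map)
            sub_rows = [
                {"subcluster": submap.names[i], "parent": submap.parent[i], "pixels": submap.sizes[i]}
                for i in sorted(submap.names)
            ]
            pd.DataFrame(sub_rows).to_csv(save("subclusters", "subclusters.csv"), index=False)

            shared = _stage(report, "shared_values", prof.shared_value_table, stack, cluster_map)
            shared.to_csv(save("shared_values", "shared_values.csv"))
            summary = _stage(report, "cluster_means", prof.cluster_means, stack, cluster_map)
            summary.to_csv(save("cluster_summary", "cluster_summary.csv"))
            norm = prof.normalize_profile(summary)
            env_dendro = _stage(report, "env_dendrogram", prof.hierarchical_cluster, norm, config.linkage)
            with open(save("env_dendrogram", "env_dendrogram.nwk"), "w") as fh:
                fh.write(env_dendro.to_newick() + "\n")

        if config.checklist:
            checklist = _stage(report, "load_checklist", endm.load_checklist, config.checklist)
            matrix = _stage(report, "occurrence_matrix", endm.build_occurrence_matrix, checklist, config.drop_empty_units)
            matrix.to_csv(save("occurrence_matrix", "occurrence_matrix.csv"))

            dist = endm.occurrence_distance(matrix, config.distance_metric)
            flor_dendro = _stage(report, "floristic_dendrogram", prof.hierarchical_cluster, dist, config.linkage)
            with open(save("floristic_dendrogram", "floristic_dendrogram.nwk"), "w") as fh:
                fh.write(flor_dendro.to_newick() + "\n")
            if env_dendro is not None:
                coph = prof.compare_dendrograms(flor_dendro, env_dendro)
                report.append(f"[dendrogram_comparison] cophenetic correlation = {coph:.4f}")

            iv = _stage(report, "indval", endm.indval, matrix, None, config.n_perm, config.seed)
            iv.table.to_csv(save("indval", "indval.csv"))
            report.append(f"[indval] {int((iv.table['p_value'] < 0.05).sum())} taxa with p < 0.05 of {len(iv.table)}")

            rich = _stage(report, "richness", endm.richness_summary, matrix, checklist)
            rich.to_csv(save("richness", "richness.csv"))

            if cluster_map is not None:
                areas = prof.cluster_area(cluster_map)
                units_df = pd.DataFrame(
                    {
                        "area_km2": [areas.get(int(u), np.nan) for u in matrix.index],
                        "endemics": rich["total_taxa"].to_numpy(),
                    },
                    index=matrix.index,
                ).dropna()
                if (units_df["endemics"] > 0).sum() >= 3:
                    fit = _stage(report, "arrhenius", endm.arrhenius_fit, units_df)
                    alpha = endm.alpha_index(fit, units_df)
                    alpha.to_csv(save("alpha", "alpha.csv"))
                    r2 = endm.area_richness_r2(units_df)
                    report.append(
                        f"[arrhenius] c={fit.c:.4f} z={fit.z:.4f} r2_loglog={fit.r2_loglog:.4f}; linear area-richness R2={r2:.4f}"
                    )
    finally:
        with open(save("report", "report.txt"), "w") as fh:
            fh.write("\n".join(report) + "\n")
    return paths
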