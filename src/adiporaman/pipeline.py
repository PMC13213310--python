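"""Configuration-driven end-to-end orchestration.

``run_pipeline`` executes generate/ingest -> preprocess -> per-region EMSC ->
per-partition random-forest ranking -> UMAP + silhouette (before vs after
top-k selection), writes every artifact as CSV/PNG under the output
directory, and records a run manifest (config snapshot, package version,
artifact hashes, timestamps, warnings) sufficient to reproduce the
deterministic artifacts bit-exactly.

Partitions follow the analysis design: the full cohort plus the NW-only and
OW-only strata, each NA vs CAA, crossed with the fingerprint and
high-wavenumber regions.  All stages after region cutting run independently
per region.  One global seed drives the synthetic cohort; the supervised and
embedding stages use their conventional fixed seeds (random forest 42, UMAP
seeds 42-51).
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

from . import __version__
from .dataset import (
    REGIONS,
    MapGeometry,
    SpectralDataset,
    cut_region,
    mean_spectrum,
    read_dataset,
    write_dataset,
)
from .embedding import UMAPConfig, embed_and_score
from .emsc import correct_dataset_with_pca
from .exceptions import ParameterError
from .preprocessing import PreprocessConfig, preprocess_dataset
from .ranking import RFConfig, rank_wavenumbers, select_top_k, train_rf_cv
from .synthetic import GeneratorConfig, generate_cohort

logger = logging.getLogger(__name__)

SUBSETS = ("all", "NW", "OW")
DEFAULT_PARTITIONS = tuple(
    (subset, region) for subset in SUBSETS for region in ("fingerprint", "high_wavenumber")
)


@dataclass
class PipelineConfig:
    """Validated pipeline configuration (usually loaded from YAML)."""

    synth: GeneratorConfig | None = None
    input_path: str | None = None
    meta_path: str | None = None
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    emsc: dict = field(default_factory=dict)
    rf: RFConfig = field(default_factory=RFConfig)
    umap: UMAPConfig = field(default_factory=UMAPConfig)
    partitions: tuple[tuple[str, str], ...] = DEFAULT_PARTITIONS
    output_dir: str = "pipeline_out"
    seed: int = 0
    make_plots: bool = True

    def __post_init__(self) -> None:
        if not self.partitions:
            raise ParameterError("partitions list must be non-empty")
        for subset, region in self.partitions:
            if subset not in SUBSETS or region not in REGIONS:
                raise ParameterError(f"unknown partition ({subset!r}, {region!r})")
        if self.synth is None and (self.input_path is None or self.meta_path is None):
            raise ParameterError("either a synth block or input paths are required")


def config_from_dict(raw: dict[str, Any]) -> PipelineConfig:
    """Build a PipelineConfig from a plain (YAML-loaded) dictionary."""
    kwargs: dict[str, Any] = {}
    if "synth" in raw:
        synth = dict(raw["synth"])
        if "grid" in synth:
            synth["grid"] = MapGeometry(**synth["grid"])
        if "regions" in synth:
            synth["regions"] = tuple(tuple(r) for r in synth["regions"])
        kwargs["synth"] = GeneratorConfig(**synth)
    for key in ("input_path", "meta_path", "output_dir", "seed", "make_plots"):
        if key in raw:
            kwargs[key] = raw[key]
    if "preprocess" in raw:
        kwargs["preprocess"] = PreprocessConfig(**raw["preprocess"])
    if "emsc" in raw:
        kwargs["emsc"] = dict(raw["emsc"])
    if "rf" in raw:
        kwargs["rf"] = RFConfig(**raw["rf"])
    if "umap" in raw:
        umap_raw = dict(raw["umap"])
        if "seeds" in umap_raw:
            umap_raw["seeds"] = tuple(umap_raw["seeds"])
        kwargs["umap"] = UMAPConfig(**umap_raw)
    if "partitions" in raw:
        kwargs["partitions"] = tuple((p["subset"], p["region"]) for p in raw["partitions"])
    return PipelineConfig(**kwargs)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _config_snapshot(cfg: PipelineConfig) -> dict:
    snap: dict[str, Any] = {
        "input_path": cfg.input_path,
        "meta_path": cfg.meta_path,
        "preprocess": asdict(cfg.preprocess),
        "emsc": cfg.emsc,
        "rf": asdict(cfg.rf),
        "umap": {**asdict(cfg.umap), "seeds": list(cfg.umap.seeds)},
        "partitions": [list(p) for p in cfg.partitions],
        "output_dir": cfg.output_dir,
        "seed": cfg.seed,
    }
    if cfg.synth is not None:
        synth = asdict(cfg.synth)
        synth["grid"] = asdict(cfg.synth.grid)
        synth["bands"] = [asdict(b) for b in cfg.synth.bands]
        synth["class_profiles"] = {
            f"{t}/{w}": asdict(p) for (t, w), p in cfg.synth.class_profiles.items()
        }
        synth["regions"] = [list(r) for r in cfg.synth.regions]
        snap["synth"] = synth
    return snap


def _subset_mask(ds: SpectralDataset, subset: str) -> np.ndarray:
    if subset == "all":
        return np.ones(ds.n_spectra, dtype=bool)
    return (ds.meta["weight_class"] == subset).to_numpy()


def _plot_partition(
    out: Path, tag: str, ds: SpectralDataset,
    coords_before: np.ndarray, coords_after: np.ndarray,
    top_wavenumbers: np.ndarray,
) -> list[str]:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    written = []
    labels = ds.meta["tissue_class"].to_numpy()
    fig, axes = plt.subplots(1, 2, figsize=(10, 4))
    for ax, coords, stage in ((axes[0], coords_before, "all channels"),
                              (axes[1], coords_after, "top-k channels")):
        for tissue, color in (("NA", "tab:blue"), ("CAA", "tab:orange")):
            m = labels == tissue
            ax.scatter(coords[m, 0], coords[m, 1], s=6, c=color, label=tissue, alpha=0.7)
        ax.set_title(f"{tag}: {stage}")
        ax.legend()
    fig.tight_layout()
    path = out / f"umap_{tag}.png"
    fig.savefig(path, dpi=120)
    plt.close(fig)
    written.append(path.name)

    fig, ax = plt.subplots(figsize=(8, 4))
    for label, spec in mean_spectrum(ds, "tissue_class").items():
        ax.plot(ds.axis, spec, label=label)
    for wn in top_wavenumbers:
        ax.axvline(wn, color="grey", alpha=0.3, lw=0.8)
    ax.set_xlabel("wavenumber (cm$^{-1}$)")
    ax.set_ylabel("intensity (a.u.)")
    ax.set_title(f"{tag}: class mean spectra with top-k wavenumbers")
    ax.legend()
    fig.tight_layout()
    path = out / f"mean_spectra_{tag}.png"
    fig.savefig(path, dpi=120)
    plt.close(fig)
    written.append(path.name)
    return written


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Execute the full pipeline; returns the run manifest (also written to disk)."""
    t0 = time.time()
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    warnings_log: list[str] = []

    if cfg.synth is not None:
        synth_cfg = cfg.synth if cfg.synth.seed == cfg.seed else (
            GeneratorConfig(**{**asdict_shallow(cfg.synth), "seed": cfg.seed})
        )
        ds, truth = generate_cohort(synth_cfg)
        truth.to_csv(out / "ground_truth.csv", index=False)
        write_dataset(ds, out / "raw_spectra.tsv", out / "raw_metadata.csv")
        logger.info("generated synthetic cohort: %d spectra", ds.n_spectra)
    else:
        ds = read_dataset(cfg.input_path, cfg.meta_path)
        logger.info("read %d spectra from %s", ds.n_spectra, cfg.input_path)

    pre = preprocess_dataset(ds, cfg.preprocess)

    summary_rows = []
    artifacts: dict[str, str] = {}
    for region_name in sorted({r for _, r in cfg.partitions}):
        region_ds = cut_region(pre, REGIONS[region_name])
        corrected, coeff_table, model = correct_dataset_with_pca(region_ds, **cfg.emsc)
        coeff_path = out / f"emsc_coefficients_{region_name}.csv"
        coeff_table.to_csv(coeff_path, index=False, float_format="%.9g")
        loadings = pd.DataFrame(
            model.interference.components.T,
            columns=[f"pc{j + 1}" for j in range(model.n_interference)],
        )
        loadings.insert(0, "wavenumber_cm-1", corrected.axis)
        loadings.to_csv(out / f"interference_loadings_{region_name}.csv",
                        index=False, float_format="%.9g")
        write_dataset(
            corrected, out / f"corrected_{region_name}.tsv",
            out / f"corrected_{region_name}_metadata.csv",
        )

        for subset, region in cfg.partitions:
            if region != region_name:
                continue
            tag = f"{subset}_{region_name}"
            part = corrected.subset(_subset_mask(corrected, subset))
            labels = part.meta["tissue_class"].to_numpy()
            try:
                ranker, metrics = train_rf_cv(part.matrix, labels, cfg.rf)
            except Exception as exc:
                raise type(exc)(f"partition {tag}: {exc}") from exc
            ranking = rank_wavenumbers(ranker, part.axis)
            rank_path = out / f"feature_ranking_{tag}.csv"
            ranking.to_frame().to_csv(rank_path, index=False, float_format="%.9g")
            pd.DataFrame(
                {"fold": np.arange(1, len(ranking.cv_fold_accuracies) + 1),
                 "accuracy": ranking.cv_fold_accuracies}
            ).to_csv(out / f"cv_metrics_{tag}.csv", index=False, float_format="%.9g")

            k = min(cfg.rf.top_k, part.n_channels)
            top = select_top_k(ranking, k)
            before = embed_and_score(part.matrix, labels, cfg.umap)
            after = embed_and_score(part.matrix[:, np.isin(part.axis, top)], labels, cfg.umap)
            record = {
                "subset": subset, "region": region_name,
                "n_spectra": int(part.n_spectra),
                "n_channels_before": int(part.n_channels),
                "n_channels_after": int(k),
                "silhouette_before": before.silhouette,
                "silhouette_after": after.silhouette,
                "silhouette_delta": after.silhouette - before.silhouette,
                "seed_before": before.seed, "seed_after": after.seed,
                "cv_accuracy_mean": metrics["cv_accuracy_mean"],
                "cv_accuracy_sd": metrics["cv_accuracy_sd"],
            }
            summary_rows.append(record)
            for stage, res in (("before", before), ("after", after)):
                emb = pd.DataFrame(
                    {"spectrum_id": part.meta["spectrum_id"], "x": res.coords[:, 0],
                     "y": res.coords[:, 1], "label": labels}
                )
                emb.to_csv(out / f"embedding_{tag}_{stage}.csv", index=False,
                           float_format="%.9g")
            if cfg.make_plots:
                _plot_partition(out, tag, part, before.coords, after.coords, top)

    summary = pd.DataFrame(summary_rows)
    summary.to_csv(out / "silhouette_summary.csv", index=False, float_format="%.9g")

    for path in sorted(out.glob("*.csv")) + sorted(out.glob("*.tsv")):
        artifacts[path.name] = _sha256(path)
    manifest = {
        "package_version": __version__,
        "config": _config_snapshot(cfg),
        "artifacts": artifacts,
        "warnings": warnings_log,
        "started_unix": t0,
        "elapsed_s": time.time() - t0,
    }
    (out / "run_manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest


def asdict_shallow(cfg: GeneratorConfig) -> dict:
    """GeneratorConfig fields without deep conversion (keeps dataclass values)."""
    return {f: getattr(cfg, f) for f in cfg.__dataclass_fields__}


def write_report(output_dir: str | Path) -> Path:
    """Render a markdown report over a completed run's artifacts.

    Missing artifacts are listed as absent; the report is still produced, and
    regeneration is idempotent.
    """
    out = Path(output_dir)
    lines = ["# Adipocyte Raman pipeline report", ""]
    manifest_path = out / "run_manifest.json"
    if manifest_path.exists():
        manifest = json.loads(manifest_path.read_text())
        lines += [f"Package version: {manifest['package_version']}",
                  f"Elapsed: {manifest['elapsed_s']:.1f} s", ""]
    summary_path = out / "silhouette_summary.csv"
    lines.append("## Silhouette before vs after top-k selection\n")
    if summary_path.exists():
        summary = pd.read_csv(summary_path)
        cols = ["subset", "region", "silhouette_before", "silhouette_after",
                "silhouette_delta", "cv_accuracy_mean"]
        lines.append(summary[cols].to_markdown(index=False, floatfmt=".3f"))
        lines.append("")
    else:
        lines.append("*silhouette_summary.csv absent*\n")
    lines.append("## Artifacts\n")
    expected_prefixes = ("feature_ranking_", "cv_metrics_", "embedding_",
                         "emsc_coefficients_", "interference_loadings_")
    found = sorted(p.name for p in out.glob("*.csv"))
    for name in found:
        lines.append(f"- `{name}`")
    rankings = [n for n in found if n.startswith("feature_ranking_")]
    if not rankings:
        lines.append("- *ranking panels absent (RF stage did not run)*")
    pngs = sorted(p.name for p in out.glob("*.png"))
    for name in pngs:
        lines.append(f"- `{name}`")
    report = out / "report.md"
    report.write_text("\n".join(lines) + "\n")
    return report
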