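"""End-to-end orchestration: simulate -> segment -> extract -> explore -> train.

One :class:`RunConfig` (constructible in code or from YAML) drives a fully
reproducible run: synthetic scenes are rendered and written as ENVI cubes, the
contrast-optimal band pair is found once on a calibration cube and reused
batch-wide, regions are segmented, matched to ground-truth objects, ratioed
against each scan's reference panel, assembled into a spectra table, explored
(group means, PCA), and classified with the tuned rLDA repeated-holdout
protocol.  A manifest records every stage's outputs and seeds; numeric outputs
are bit-identical under a fixed config.

The single config seed fans out to fixed per-stage offsets so stages can be
rerun in isolation without perturbing one another.
"""

from __future__ import annotations

import json
import time
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import discriminant, explore, io, segment, simulate, spectra

__all__ = ["RunConfig", "Scenario", "run_pipeline", "scenario_matrix"]

# Seed offsets per stage (scenes get scene-index offsets on top of SIMULATE).
_SEED_OFFSETS = {"simulate": 1000, "segment": 2000, "train": 3000}


@dataclass
class RunConfig:
    """Everything one pipeline run needs.

    Scene/design block: which cultivars, stages, organs to simulate, how many
    organs per (cultivar, stage, organ) cell, scene geometry and noise.
    Segmentation block: band-search stride and mask refinement settings.
    Classification block: the label column (cultivar | stage | organ),
    optional organ/stage subset filters (the study's modeling scenarios),
    replicate count, split ratio, and tuning budget.
    """

    out_dir: str = "run"
    seed: int = 0
    # --- scene / design ---
    cultivars: tuple = ("CW", "BX")
    stages: tuple = ("wk02", "wk04")
    organs: tuple = ("leaf", "flower")
    samples_per_cell: int = 4
    replicates: int = 4
    n_bands: int = 110
    n_lines: int = 150
    n_pixels: int = 190
    object_radius: float = 9.0
    illumination_amplitude: float = 0.15
    spectral_response_amplitude: float = 0.15
    additive_noise_sd: float = 0.005
    multiplicative_noise_sd: float = 0.01
    # --- segmentation ---
    band_stride: int = 8
    min_area: int = 50
    morphology_radius: int = 1
    histogram_bins: int = 256
    reference_mode: str = "flatness"
    # --- classification ---
    label_column: str = "organ"
    organ_filter: str | None = None
    stage_filter: str | None = None
    reps: int = 30
    train_fraction: float = 0.75
    tune_budget: int = 30
    cv_folds: int = 10
    tune_strategy: str = "bayes"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(raw) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key, value in raw.items():
            if isinstance(value, list):
                raw[key] = tuple(value)
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        d = asdict(self)
        for k, v in d.items():
            if isinstance(v, tuple):
                d[k] = list(v)
        Path(path).write_text(yaml.safe_dump(d, sort_keys=False))

    def validate(self) -> None:
        if self.label_column not in ("cultivar", "stage", "organ"):
            raise ValueError(
                f"label column {self.label_column!r} not in the metadata schema "
                "(cultivar | stage | organ)"
            )
        if self.organ_filter is not None and self.organ_filter not in self.organs:
            raise ValueError(f"organ filter {self.organ_filter!r} not simulated")
        if self.stage_filter is not None and self.stage_filter not in self.stages:
            raise ValueError(f"stage filter {self.stage_filter!r} not simulated")
        if not 0 < self.train_fraction < 1:
            raise ValueError("train_fraction must lie in (0, 1)")


@dataclass(frozen=True)
class Scenario:
    """One classification run: a label column plus metadata subset filters."""

    name: str
    label_column: str
    filters: tuple  # ((column, value), ...)

    def select(self, table: io.SpectraTable) -> io.SpectraTable:
        mask = np.ones(len(table), dtype=bool)
        for col, val in self.filters:
            mask &= (table.metadata[col] == val).to_numpy()
        return table.subset(mask)


def scenario_matrix(table: io.SpectraTable, min_classes: int = 2) -> list[Scenario]:
    """Enumerate the study's modeling scenarios for a spectra table.

    Cultivar models per (stage x organ), per stage with organs combined, and
    pooled across stages (leaf / flower / both); stage models per
    (cultivar x organ); organ models per (cultivar x stage).  Scenarios left
    with fewer than ``min_classes`` classes after filtering are skipped with
    a warning.
    """
    meta = table.metadata
    stages = sorted(meta["stage"].unique())
    cultivars = sorted(meta["cultivar"].unique())
    organs = sorted(meta["organ"].unique())
    out: list[Scenario] = []

    def add(name, label, filters):
        sc = Scenario(name=name, label_column=label, filters=tuple(filters))
        sub = sc.select(table)
        if sub.metadata[label].nunique() < min_classes:
            warnings.warn(f"scenario {name!r}: < {min_classes} classes, skipped")
            return
        out.append(sc)

    for s in stages:
        for o in organs:
            add(f"cultivar__{s}__{o}", "cultivar", [("stage", s), ("organ", o)])
        add(f"cultivar__{s}__both", "cultivar", [("stage", s)])
    for o in organs:
        add(f"cultivar__pooled__{o}", "cultivar", [("organ", o)])
    add("cultivar__pooled__both", "cultivar", [])
    for c in cultivars:
        for o in organs:
            add(f"stage__{c}__{o}", "stage", [("cultivar", c), ("organ", o)])
    for c in cultivars:
        for s in stages:
            add(f"organ__{c}__{s}", "organ", [("cultivar", c), ("stage", s)])
    return out


# ---------------------------------------------------------------------------
# Stages
# ---------------------------------------------------------------------------


def _stage_simulate(cfg: RunConfig, out: Path, classes) -> dict:
    """Render one scene per (cultivar, stage) holding that cell's organs."""
    wl = simulate.default_wavelengths(cfg.n_bands)
    scans = []
    scene_index = 0
    for c in cfg.cultivars:
        for s in cfg.stages:
            labels = [
                (c, s, o) for o in cfg.organs for _ in range(cfg.samples_per_cell)
            ]
            design = simulate.build_scene_design(
                labels,
                n_lines=cfg.n_lines,
                n_pixels=cfg.n_pixels,
                object_radius=cfg.object_radius,
                seed=cfg.seed + _SEED_OFFSETS["simulate"] + scene_index,
                illumination_amplitude=cfg.illumination_amplitude,
                spectral_response_amplitude=cfg.spectral_response_amplitude,
                additive_noise_sd=cfg.additive_noise_sd,
                multiplicative_noise_sd=cfg.multiplicative_noise_sd,
            )
            cube, gt, meta = simulate.render_scene(design, classes, wl)
            cube.scan_id = f"scan_{c}_{s}"
            stem = out / cube.scan_id
            io.write_cube(cube, stem.with_suffix(".hdr"))
            io.write_label_image(gt, stem.with_suffix(".labels.tif"))
            meta = meta.copy()
            meta["sample_id"] = [
                f"{c}_{s}_{row.organ}_{row.object_id:03d}" if row.kind != "reference" else ""
                for row in meta.itertuples()
            ]
            meta["replicate"] = [
                (row.object_id - 1) % cfg.replicates + 1 if row.kind != "reference" else 0
                for row in meta.itertuples()
            ]
            meta.to_csv(stem.with_suffix(".objects.csv"), index=False)
            scans.append(cube.scan_id)
            scene_index += 1
    return {"scans": scans, "n_bands": cfg.n_bands}


def _match_regions(seg_labels: np.ndarray, gt_labels: np.ndarray) -> dict[int, int]:
    """Map each segmented region to the ground-truth object covering most of
    it; regions mostly on background are dropped (warned)."""
    mapping: dict[int, int] = {}
    for rid in np.unique(seg_labels):
        if rid == 0:
            continue
        gt_under = gt_labels[seg_labels == rid]
        ids, counts = np.unique(gt_under, return_counts=True)
        best = int(ids[np.argmax(counts)])
        if best == 0 or counts.max() < 0.5 * gt_under.size:
            warnings.warn(f"segmented region {rid} matches no ground-truth object")
            continue
        mapping[int(rid)] = best
    return mapping


def _stage_segment(cfg: RunConfig, out: Path, scans: list[str]) -> dict:
    seg_cfg = segment.SegmentationConfig(
        bins=cfg.histogram_bins,
        min_area=cfg.min_area,
        morphology_radius=cfg.morphology_radius,
    )
    calibration = io.read_cube(out / f"{scans[0]}.hdr")
    pair, contrast, _ = segment.select_band_pair(calibration, stride=cfg.band_stride)
    report = {
        "pair": {"lambda1": pair.lambda1, "lambda2": pair.lambda2},
        "contrast_score": contrast.score,
        "calibration_scan": scans[0],
        "scans": {},
    }
    for scan in scans:
        cube = io.read_cube(out / f"{scan}.hdr")
        result = segment.segment_scene(cube, segment.make_band_pair(cube, pair.lambda1, pair.lambda2), seg_cfg)
        ref = segment.locate_reference(cube, result, mode=cfg.reference_mode)
        if ref is None:
            raise RuntimeError(f"segment stage: no reference panel found in {scan}")
        io.write_label_image(result.regions, out / f"{scan}.segmented.tif")
        np.save(out / f"{scan}.refmask.npy", ref.mask)
        report["scans"][scan] = {
            "threshold": result.threshold,
            "smoothing_iterations": result.smoothing_iterations,
            "n_regions": int(result.regions.max()),
            "reference_cv": ref.cv,
        }
    (out / "segmentation.json").write_text(json.dumps(report, indent=2))
    return report


def _stage_extract(cfg: RunConfig, out: Path, scans: list[str]) -> dict:
    assembled = []
    for scan in scans:
        cube = io.read_cube(out / f"{scan}.hdr")
        seg_labels = io.read_label_image(out / f"{scan}.segmented.tif")
        gt_labels = io.read_label_image(out / f"{scan}.labels.tif")
        ref_mask = np.load(out / f"{scan}.refmask.npy")
        objects = pd.read_csv(out / f"{scan}.objects.csv")

        mapping = _match_regions(seg_labels, gt_labels)
        region_specs = [
            spectra.mean_spectrum(cube, seg_labels == rid, region_id=rid)
            for rid in sorted(mapping)
        ]
        ref_spec = spectra.reference_spectrum(
            cube, segment.ReferenceRegion(mask=ref_mask, region_id=None, cv=None)
        )
        ratios = spectra.ratio_to_reference(region_specs, ref_spec)
        meta = objects[objects["kind"] != "reference"].copy()
        meta["region_id"] = meta["object_id"]
        # Rewire: segmented region rid corresponds to gt object mapping[rid].
        remapped = meta.set_index("object_id")
        rows = []
        for r in ratios:
            obj = remapped.loc[mapping[r.region_id]]
            rows.append(
                {
                    "region_id": r.region_id,
                    "sample_id": obj["sample_id"],
                    "cultivar": obj["cultivar"],
                    "stage": obj["stage"],
                    "organ": obj["organ"],
                    "replicate": obj["replicate"],
                }
            )
        assembled.append((cube, ratios, pd.DataFrame(rows)))
    table = spectra.assemble_spectra_table(assembled)
    io.write_spectra_table(table, out / "spectra.csv")
    return {"n_samples": len(table), "path": "spectra.csv"}


def _stage_explore(cfg: RunConfig, out: Path) -> dict:
    table = io.read_spectra_table(out / "spectra.csv")
    n_comp = min(3, len(table) - 1, len(table.wavelengths))
    pca = explore.pca_explore(table, n_components=n_comp)
    scores = table.metadata.copy()
    for i in range(n_comp):
        scores[f"PC{i+1}"] = pca.scores[:, i]
    scores.to_csv(out / "pca_scores.csv", index=False)
    gm = explore.group_mean_spectra(table, [cfg.label_column])
    gm.mean.to_csv(out / "group_mean_spectra.csv")
    return {
        "variance_percent": [round(float(v), 6) for v in pca.variance_percent],
        "groups": [str(g) for g in gm.mean.index],
    }


def _stage_train(cfg: RunConfig, out: Path) -> dict:
    table = io.read_spectra_table(out / "spectra.csv")
    mask = np.ones(len(table), dtype=bool)
    if cfg.organ_filter is not None:
        mask &= (table.metadata["organ"] == cfg.organ_filter).to_numpy()
    if cfg.stage_filter is not None:
        mask &= (table.metadata["stage"] == cfg.stage_filter).to_numpy()
    sub = table.subset(mask)
    y = sub.metadata[cfg.label_column].to_numpy()
    report = discriminant.repeated_holdout(
        sub.values,
        y,
        reps=cfg.reps,
        train_fraction=cfg.train_fraction,
        base_seed=cfg.seed + _SEED_OFFSETS["train"],
        tune_budget=cfg.tune_budget,
        cv_folds=cfg.cv_folds,
        tune_strategy=cfg.tune_strategy,
    )
    confusion = discriminant.pooled_confusion(report)
    confusion.to_frame().to_csv(out / "confusion.csv")
    payload = {
        "label_column": cfg.label_column,
        "classes": [str(c) for c in report.classes],
        "n_samples": int(len(sub)),
        "replicates": report.n_replicates,
        "accuracies": [round(a, 10) for a in report.accuracies.tolist()],
        "mean_accuracy": round(report.mean_accuracy, 10),
        "se_accuracy": None
        if report.se_accuracy is None
        else round(report.se_accuracy, 10),
        "hyperparams": [
            {"gamma": p.gamma, "delta": p.delta} for p in report.hyperparams
        ],
    }
    (out / "classification.json").write_text(json.dumps(payload, indent=2))
    return {
        "mean_accuracy": payload["mean_accuracy"],
        "se_accuracy": payload["se_accuracy"],
        "n_samples": payload["n_samples"],
    }


def run_pipeline(config: RunConfig) -> dict:
    """Execute all five stages; returns (and writes) the run manifest.

    Any stage failure aborts the run with an error naming the stage.
    Re-running with an identical config reproduces identical numeric outputs.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    classes = simulate.default_class_models(
        config.cultivars, config.stages, config.organs
    )
    manifest: dict = {"config": asdict(config), "stages": {}}
    stage_fns = [
        ("simulate", lambda: _stage_simulate(config, out, classes)),
        ("segment", lambda: _stage_segment(config, out, manifest["stages"]["simulate"]["output"]["scans"])),
        ("extract", lambda: _stage_extract(config, out, manifest["stages"]["simulate"]["output"]["scans"])),
        ("explore", lambda: _stage_explore(config, out)),
        ("train", lambda: _stage_train(config, out)),
    ]
    for name, fn in stage_fns:
        t0 = time.perf_counter()
        try:
            result = fn()
        except Exception as exc:
            raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc
        manifest["stages"][name] = {
            "output": result,
            "seconds": round(time.perf_counter() - t0, 3),
        }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return manifest
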