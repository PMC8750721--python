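"""End-to-end study orchestration.

One call runs: simulate (or ingest) scenes → reflectance calibration → ROI
extraction in one of three modes (automatic calyx circle, manual 10×10
rectangle, whole-fruit mean spectrum) → preprocessing chain → Kennard–Stone
70/30 split → PCA → classifier bank with 5-fold CV → optional forward
wavelength selection — writing reports, tables, figures, the resolved config
and a log into a run directory.  Every random draw derives from the master
seed, so a config reproduces its artifacts byte-identically.

Note on ordering: Kennard–Stone distances are computed on the preprocessed
spectra before mean centering.  Subtracting one constant vector from every
row leaves all pairwise Euclidean distances unchanged, so the split is
identical to one computed after centering while the centering statistics can
still be fitted on the training partition only.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import roi as roi_mod
from .calibration import calibrate
from .errors import CalyxScanError, ParameterError
from .hypercube import Hypercube, ReferencePair, read_envi
from .modeling import (cross_validate, evaluate, fit_pca, train_classifier,
                       transform_pca)
from .preprocessing import PreprocessConfig, fit_preprocessor
from .roi import acquire_roi, extract_pixel_spectra, mean_spectrum, rect_roi
from .selection import sfs_select, subset_report
from .simulate import SceneConfig, generate_study
from .split import assemble_dataset, kennard_stone
from .table import PixelSpectraTable

log = logging.getLogger("calyxscan")

MODES = ("auto-roi", "manual-roi", "mean-spectra")


@dataclass
class RunConfig:
    """Fully explicit configuration of one study run."""

    mode: str = "auto-roi"
    n_control: int = 2
    n_infested: int = 4
    scene: SceneConfig = field(default_factory=SceneConfig)
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    seg_nm: float = 1084.0
    roi_diameter_px: int = 50
    selem_radius: int = 2
    rect_size: int = 10
    train_fraction: float = 0.7
    classifiers: list = field(default_factory=lambda: ["gtb", "rf", "knn", "lda"])
    pca_components: int = 3
    feature_inputs: list = field(default_factory=lambda: ["pca"])  # + "raw"
    cv_folds: int = 5
    run_sfs: bool = False
    sfs_max_k: int = 10
    sfs_classifier: str = "gtb"
    sfs_subset_sizes: list = field(default_factory=lambda: [5, 15, 22, 30])
    jitter: float = 1.0
    seed: int = 0
    input_dir: str = ""   # when set, ENVI scenes are read instead of simulated
    out_dir: str = "runs/study"
    make_plots: bool = True

    def __post_init__(self):
        if self.mode not in MODES:
            raise ParameterError(f"mode must be one of {MODES}")
        if isinstance(self.scene, dict):
            self.scene = SceneConfig(**self.scene)
        if isinstance(self.preprocess, dict):
            self.preprocess = PreprocessConfig(**self.preprocess)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls(**(yaml.safe_load(fh) or {}))

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(_plain(dataclasses.asdict(self)), fh, sort_keys=False)


def _plain(obj):
    if isinstance(obj, dict):
        return {k: _plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_plain(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj


def _ingest_scenes(input_dir: str) -> list:
    """Read (raw, white, dark) ENVI triples named *_raw.hdr etc."""
    scenes = []
    for raw_hdr in sorted(Path(input_dir).glob("*_raw.hdr")):
        stem = raw_hdr.name[: -len("_raw.hdr")]
        raw = read_envi(raw_hdr)
        refs = ReferencePair(
            read_envi(raw_hdr.with_name(f"{stem}_white.hdr")),
            read_envi(raw_hdr.with_name(f"{stem}_dark.hdr")),
        )
        scenes.append((raw, refs, None))
    if not scenes:
        raise ParameterError(f"no *_raw.hdr scenes found in {input_dir}")
    return scenes


def _scene_table(config: RunConfig, cube: Hypercube, label: str) -> PixelSpectraTable:
    """Mode-specific spectra extraction from one calibrated cube."""
    meta = cube.meta
    prov = dict(sample_id=meta.get("sample_id", cube.name),
                cultivar=meta.get("cultivar", ""),
                orientation=meta.get("orientation", ""))
    if config.mode == "mean-spectra":
        img = cube.band_image(config.seg_nm)
        fruit = img > roi_mod._otsu(img.ravel())
        spec = mean_spectrum(cube, fruit)
        return PixelSpectraTable(
            spec[None, :], cube.wavelengths,
            np.array([label], dtype=object),
            pd.DataFrame([{**prov, "row": -1, "col": -1}]),
        )
    result = acquire_roi(cube, seg_nm=config.seg_nm,
                         diameter_px=config.roi_diameter_px,
                         selem_radius=config.selem_radius)
    if config.mode == "manual-roi":
        mask = rect_roi(result.centroid, config.rect_size, config.rect_size,
                        cube.data.shape[:2])
    else:
        mask = result.mask
    return extract_pixel_spectra(cube, mask, label, **prov)


def run_pipeline(config: RunConfig) -> Path:
    """Execute the full study; returns the run directory."""
    out = Path(config.out_dir)
    (out / "reports").mkdir(parents=True, exist_ok=True)
    (out / "tables").mkdir(exist_ok=True)
    handler = logging.FileHandler(out / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)
    stage = "configure"
    try:
        config.to_yaml(out / "resolved_config.yaml")

        stage = "simulate" if not config.input_dir else "ingest"
        if config.input_dir:
            scenes = _ingest_scenes(config.input_dir)
        else:
            scene = dataclasses.replace(config.scene, seed=config.seed)
            scenes = generate_study(config.n_control, config.n_infested,
                                    template=scene, seed=config.seed,
                                    jitter=config.jitter)
        log.info("stage=%s scenes=%d", stage, len(scenes))

        stage = "calibrate+roi"
        tables = []
        for raw, refs, _truth in scenes:
            cal = calibrate(raw, refs)
            label = raw.meta.get("label", "healthy")
            tables.append(_scene_table(config, cal, label))
        dataset = assemble_dataset(tables)
        log.info("stage=%s pixels=%d bands=%d", stage, dataset.n, dataset.n_bands)

        stage = "preprocess"
        pre_cfg = config.preprocess
        # row-wise steps first; centering is refitted on train below
        no_center = dataclasses.replace(pre_cfg, center="none")
        _, rowwise = fit_preprocessor(dataset, no_center)

        stage = "split"
        split = kennard_stone(rowwise.spectra, config.train_fraction)
        split.to_csv(out / "tables" / "split.csv")
        train_tbl = rowwise.subset_rows(split.train_idx)
        val_tbl = rowwise.subset_rows(split.val_idx)
        if pre_cfg.center == "train-mean":
            from .preprocessing import mean_center
            train_tbl, train_mean = mean_center(train_tbl, "fit")
            val_tbl, _ = mean_center(val_tbl, train_mean)
        log.info("stage=split train=%d val=%d", train_tbl.n, val_tbl.n)

        stage = "pca"
        features = {}
        if "pca" in config.feature_inputs:
            pca = fit_pca(train_tbl.spectra, config.pca_components)
            features["pca"] = (transform_pca(pca, train_tbl.spectra),
                               transform_pca(pca, val_tbl.spectra))
            pd.DataFrame({
                "component": np.arange(1, len(pca.explained_variance_ratio) + 1),
                "explained_variance_ratio": pca.explained_variance_ratio,
            }).to_csv(out / "tables" / "pca_variance.csv", index=False)
        if "raw" in config.feature_inputs:
            features["raw"] = (train_tbl.spectra, val_tbl.spectra)

        stage = "classify"
        rows = []
        reports = []
        for feat_name, (ftr, fva) in features.items():
            for tag in config.classifiers:
                model = train_classifier(tag, ftr, train_tbl.labels,
                                         seed=config.seed)
                for part, f, lab in (("train", ftr, train_tbl.labels),
                                     ("validation", fva, val_tbl.labels)):
                    rep = evaluate(model, f, lab, partition=part,
                                   classifier_tag=tag)
                    rep.config = {"features": feat_name, "seed": config.seed}
                    reports.append(rep)
                cv = cross_validate(tag, ftr, train_tbl.labels,
                                    folds=config.cv_folds, seed=config.seed)
                rows.append({"classifier": tag, "features": feat_name,
                             "cv_mean_accuracy": cv["mean_accuracy"],
                             "cv_sd_accuracy": cv["sd_accuracy"]})
                log.info("classifier=%s features=%s cv=%.4f±%.4f", tag,
                         feat_name, cv["mean_accuracy"], cv["sd_accuracy"])
        _write_reports(out, reports, rows)

        if config.run_sfs:
            stage = "sfs"
            sfs = sfs_select(train_tbl.spectra, train_tbl.labels,
                             classifier_tag=config.sfs_classifier,
                             max_k=config.sfs_max_k, folds=config.cv_folds,
                             seed=config.seed, wavelengths=train_tbl.wavelengths)
            sfs.to_json(out / "reports" / "sfs.json")
            sfs.to_csv(out / "tables" / "sfs_curve.csv")
            subset_rows = []
            for k in config.sfs_subset_sizes:
                if k > len(sfs.selected_band_indices):
                    continue
                rep = subset_report(rowwise.spectra, rowwise.labels,
                                    sfs.selected_band_indices[:k],
                                    classifier_tag=config.sfs_classifier,
                                    split=split, seed=config.seed)
                subset_rows.append({"k": k, "validation_accuracy": rep.accuracy})
            pd.DataFrame(subset_rows).to_csv(out / "tables" / "sfs_subsets.csv",
                                             index=False)
            if config.make_plots:
                _plot_curve(sfs, out / "sfs_curve.png")
        return out
    except CalyxScanError:
        log.exception("pipeline aborted at stage '%s'", stage)
        raise
    finally:
        log.removeHandler(handler)
        handler.close()


def _write_reports(out: Path, reports: list, cv_rows: list) -> None:
    with open(out / "reports" / "classification.json", "w") as fh:
        json.dump([r.to_dict() for r in reports], fh, indent=2)
    flat = []
    for r in reports:
        for cls, m in r.per_class.items():
            flat.append({
                "classifier": r.classifier,
                "features": r.config.get("features", ""),
                "partition": r.partition, "class": cls,
                "precision": m["precision"], "recall": m["recall"],
                "f1": m["f1"], "accuracy": r.accuracy,
                "n": r.n_observations,
            })
    pd.DataFrame(flat).to_csv(out / "tables" / "classification.csv", index=False)
    pd.DataFrame(cv_rows).to_csv(out / "tables" / "cross_validation.csv",
                                 index=False)


def _plot_curve(sfs, path) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 3.2))
    ax.plot(range(1, len(sfs.accuracy_curve) + 1), sfs.accuracy_curve, "o-")
    ax.set_xlabel("number of selected wavelengths")
    ax.set_ylabel(f"CV {sfs.criterion}")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
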