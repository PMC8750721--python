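"""Canonical synthetic-study experiments.

These functions pin the study conditions used to validate the pipeline on
synthetic apples: an end-to-end classification study at a given infestation
effect size (including the null condition, effect = 1.0), and a wavelength-
recovery experiment in which the class signal is confined to a known set of
narrow bands and forward selection must find them.  Both are deterministic
given their seed and are what `scripts/acceptance.py` and the test suite run.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .calibration import calibrate
from .modeling import evaluate, fit_pca, train_classifier, transform_pca
from .preprocessing import PreprocessConfig, fit_preprocessor, mean_center
from .roi import acquire_roi, extract_pixel_spectra
from .selection import sfs_select
from .simulate import (SceneConfig, _illumination, endmember_spectrum,
                       generate_study, sample_pixel_spectra)
from .split import assemble_dataset, kennard_stone


def run_classification_study(effect: float, seed: int, n_control: int = 2,
                             n_infested: int = 2,
                             classifiers: tuple = ("gtb", "lda"),
                             pca_components: int = 3,
                             template: SceneConfig | None = None) -> dict:
    """Full pipeline on a synthetic study; returns validation accuracies.

    Scenes → calibration → automatic calyx ROI → preprocessing chain →
    Kennard–Stone 70/30 split → PCA → classifiers.  The null condition is
    ``effect=1.0`` with balanced groups: infested apples then carry no
    spectral difference, and validation accuracy should sit in the binomial
    band around 0.5.
    """
    tmpl = dataclasses.replace(template or SceneConfig(),
                               infestation_effect=effect)
    scenes = generate_study(n_control, n_infested, template=tmpl, seed=seed)
    tables = []
    for raw, refs, _truth in scenes:
        cal = calibrate(raw, refs)
        roi = acquire_roi(cal)
        tables.append(extract_pixel_spectra(
            cal, roi.mask, raw.meta["label"],
            sample_id=raw.meta["sample_id"]))
    dataset = assemble_dataset(tables)
    cfg = PreprocessConfig()
    _, rowwise = fit_preprocessor(dataset,
                                  dataclasses.replace(cfg, center="none"))
    split = kennard_stone(rowwise.spectra, 0.7)
    train = rowwise.subset_rows(split.train_idx)
    val = rowwise.subset_rows(split.val_idx)
    train, train_mean = mean_center(train, "fit")
    val, _ = mean_center(val, train_mean)
    pca = fit_pca(train.spectra, pca_components)
    f_train = transform_pca(pca, train.spectra)
    f_val = transform_pca(pca, val.spectra)
    accuracies, reports = {}, {}
    for tag in classifiers:
        model = train_classifier(tag, f_train, train.labels, seed=seed)
        rep = evaluate(model, f_val, val.labels, classifier_tag=tag)
        accuracies[tag] = rep.accuracy
        reports[tag] = rep
    return {
        "accuracies": accuracies,
        "reports": reports,
        "n_train": train.n,
        "n_validation": val.n,
        "explained_variance_ratio": pca.explained_variance_ratio,
    }


def band_confined_config(centers_nm=(980.0, 1120.0, 1260.0, 1420.0, 1580.0),
                         effect: float = 0.89, noise_sd: float = 0.033,
                         width_nm: float = 2.5, n_bands: int = 128) -> tuple:
    """Scene config whose infestation signal lives in exactly the given bands.

    The Gaussian depression at each centre is much narrower than the band
    spacing, and its amplitude is scaled inversely to the local
    reflectance×illumination product so every configured band carries equal
    discriminative strength.  Returns ``(config, known_band_indices)``.
    """
    base = SceneConfig(n_bands=n_bands, noise_additive_sd=noise_sd)
    wl = base.wavelengths
    healthy = endmember_spectrum("healthy", base)
    env = _illumination(wl, 1.0)
    idx = [int(np.argmin(np.abs(wl - c))) for c in centers_nm]
    amps = np.array([1.0 / (healthy[i] * env[i]) for i in idx])
    amps /= amps.max()
    cfg = SceneConfig(
        n_bands=n_bands, noise_additive_sd=noise_sd, infestation_effect=effect,
        infestation_bands=[(c, a, width_nm) for c, a in zip(centers_nm, amps)],
    )
    return cfg, sorted(idx)


def band_recovery_experiment(seed: int, n_per_class: int = 1500,
                             max_k: int = 5, folds: int = 5,
                             classifier_tag: str = "lda") -> dict:
    """Forward selection against a known band-confined signal.

    Pixel spectra are drawn directly from the endmember + noise model (no ROI
    geometry in the loop, so the signal support is exact), max-normalized,
    and fed to SFS.  Returns the selected path, the ground-truth band set and
    the recovered count.
    """
    cfg, known = band_confined_config()
    x = np.vstack([
        sample_pixel_spectra(cfg, "healthy", n_per_class, seed),
        sample_pixel_spectra(cfg, "infested", n_per_class, seed + 10_000),
    ])
    y = np.array(["healthy"] * n_per_class + ["infested"] * n_per_class,
                 dtype=object)
    x = x / x.max(axis=1, keepdims=True)
    result = sfs_select(x, y, classifier_tag=classifier_tag, max_k=max_k,
                        folds=folds, seed=seed, wavelengths=cfg.wavelengths)
    recovered = len(set(result.selected_band_indices) & set(known))
    return {
        "result": result,
        "known_bands": known,
        "recovered": recovered,
        "n": 2 * n_per_class,
    }


def binomial_band(n: int, confidence_z: float = 2.5758) -> float:
    """Half-width of the normal-approximation band around 0.5 for n trials."""
    return confidence_z * 0.5 / np.sqrt(n)
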