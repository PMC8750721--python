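"""Synthetic apple-scene hypercubes with ground truth.

The generator emulates the structure of push-broom NIR (900–1700 nm)
hyperspectral images of apples viewed from the calyx end:

* smooth reflectance curves with water/CH absorption valleys near 950, 1200
  and 1400 nm;
* a bright fruit disk on a dark background with a darker calyx cavity;
* infested tissue around the calyx with depressed reflectance — the
  depression is weighted toward the absorption valleys (plus a flat floor),
  so infested spectra sit below healthy ones at every band while a shape
  difference survives max-normalization;
* per-pixel scalar gain (path-length proxy), additive sensor noise, dark
  current, and a mildly non-flat illumination envelope, so reflectance
  calibration against the white/dark references is non-trivial.

White/dark references are emitted as single-line (1×W×B) cubes following the
push-broom line-average convention.  All randomness flows from the config
seed; identical configs give bit-identical scenes.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

from .errors import ParameterError
from .hypercube import Hypercube, ReferencePair


@dataclass
class SceneConfig:
    """All knobs of one synthetic apple scene."""

    image_size: tuple = (200, 200)
    n_bands: int = 128
    wl_low_nm: float = 900.0
    wl_high_nm: float = 1700.0
    apple_center: Optional[tuple] = None     # default: image centre
    apple_radius: float = 70.0
    calyx_offset: tuple = (-10.0, 8.0)       # relative to apple centre
    calyx_radius: float = 8.0
    calyx_darkening: float = 0.3             # calyx = healthy × this
    infestation_effect: float = 0.85         # depression at profile max; 1 = null
    lesion_radius: float = 30.0              # infested disk around the calyx
    infestation_floor: float = 0.3           # flat share of the depression profile
    infestation_bands: Optional[list] = None  # [(center_nm, width_nm)] → confined signal
    absorption_valleys: list = field(default_factory=lambda: [
        (950.0, 0.12, 35.0), (1200.0, 0.20, 55.0), (1400.0, 0.30, 65.0)
    ])
    background_reflectance: float = 0.03
    reflectance_gain: float = 1.0            # per-apple brightness factor
    noise_additive_sd: float = 0.01          # counts, as a fraction of full scale
    noise_multiplicative_sd: float = 0.02    # per-pixel gain sd
    dark_current: float = 100.0
    dark_noise_sd: float = 1.0
    illumination_scale: float = 3000.0
    label: str = "infested"
    cultivar: str = "Fuji"
    orientation: str = "calyx"
    sample_id: str = "scene_0"
    seed: int = 0

    def __post_init__(self):
        if self.calyx_radius <= 0 or self.apple_radius <= 0 or self.lesion_radius <= 0:
            raise ParameterError("all radii must be positive")
        for _, depth, _ in self.absorption_valleys:
            if not 0 <= depth < 1:
                raise ParameterError(f"valley depth {depth} outside [0, 1)")
        if not 0 < self.infestation_effect <= 1:
            raise ParameterError("infestation_effect must be in (0, 1]")
        off = float(np.hypot(*self.calyx_offset))
        if off + self.calyx_radius > self.apple_radius:
            raise ParameterError("calyx disk must lie inside the apple disk")

    @property
    def wavelengths(self) -> np.ndarray:
        return np.linspace(self.wl_low_nm, self.wl_high_nm, self.n_bands)


@dataclass
class SceneTruth:
    """Ground-truth masks, per-pixel labels and noiseless endmembers."""

    background_mask: np.ndarray
    fruit_mask: np.ndarray
    calyx_mask: np.ndarray
    infested_mask: np.ndarray
    pixel_labels: np.ndarray           # (H, W) object array
    endmembers: dict                   # kind → noiseless reflectance spectrum
    calyx_center: tuple = (0.0, 0.0)   # (row, col) of the true calyx centre


def _gaussians(wl: np.ndarray, bands) -> np.ndarray:
    out = np.zeros_like(wl)
    for center, *rest in bands:
        width = rest[-1]
        amp = rest[0] if len(rest) == 2 else 1.0
        out += amp * np.exp(-0.5 * ((wl - center) / width) ** 2)
    return out


def _depression_profile(config: SceneConfig) -> np.ndarray:
    """Spectral weight of the infestation depression, max exactly 1."""
    wl = config.wavelengths
    if config.infestation_bands is not None:
        prof = np.minimum(_gaussians(wl, config.infestation_bands), 1.0)
    else:
        valleys = [(c, w) for c, _, w in config.absorption_valleys]
        bump = np.minimum(_gaussians(wl, valleys), 1.0)
        prof = config.infestation_floor + (1 - config.infestation_floor) * bump
    m = prof.max()
    return prof / m if m > 0 else prof


def endmember_spectrum(kind: str, config: SceneConfig) -> np.ndarray:
    """Noiseless reflectance spectrum of one scene constituent."""
    wl = config.wavelengths
    u = (wl - config.wl_low_nm) / max(config.wl_high_nm - config.wl_low_nm, 1e-9)
    baseline = 0.55 + 0.50 * u - 0.30 * u ** 2
    healthy = baseline - _gaussians(wl, config.absorption_valleys)
    healthy = np.clip(healthy, 0.02, None) * config.reflectance_gain
    if kind == "healthy":
        return healthy
    if kind == "infested":
        depression = (1.0 - config.infestation_effect) * _depression_profile(config)
        return healthy * (1.0 - depression)
    if kind == "calyx":
        return healthy * config.calyx_darkening
    if kind == "background":
        return np.full_like(wl, config.background_reflectance)
    raise ParameterError(f"unknown endmember kind '{kind}'")


def _illumination(wl: np.ndarray, scale: float) -> np.ndarray:
    return scale * (1.0 - 0.15 * ((wl - 1300.0) / 400.0) ** 2)


def generate_scene(config: SceneConfig):
    """Build one raw scene: returns ``(raw_cube, references, truth)``.

    The forward model is ``counts = dark + illumination(λ)·R·g + noise`` with
    a per-pixel gain ``g``; the white reference sees ``R = 1``, so reflectance
    calibration approximately inverts to the endmember reflectances.
    """
    h, w = config.image_size
    wl = config.wavelengths
    rng = np.random.default_rng(config.seed)
    ac = (np.array(config.apple_center, float)
          if config.apple_center is not None else np.array([(h - 1) / 2, (w - 1) / 2]))
    cc = ac + np.asarray(config.calyx_offset, float)

    rr, col = np.ogrid[:h, :w]
    fruit = (rr - ac[0]) ** 2 + (col - ac[1]) ** 2 <= config.apple_radius ** 2
    calyx = (rr - cc[0]) ** 2 + (col - cc[1]) ** 2 <= config.calyx_radius ** 2
    calyx &= fruit
    infested = np.zeros((h, w), dtype=bool)
    if config.label == "infested":
        lesion = (rr - cc[0]) ** 2 + (col - cc[1]) ** 2 <= config.lesion_radius ** 2
        infested = lesion & fruit & ~calyx
    background = ~fruit

    ends = {k: endmember_spectrum(k, config)
            for k in ("healthy", "infested", "calyx", "background")}
    refl = np.empty((h, w, len(wl)))
    refl[:] = ends["background"]
    refl[fruit] = ends["healthy"]
    refl[infested] = ends["infested"]
    refl[calyx] = ends["calyx"]

    labels = np.full((h, w), "background", dtype=object)
    labels[fruit] = "healthy"
    labels[infested] = "infested"
    labels[calyx] = "calyx"

    illum = _illumination(wl, config.illumination_scale)
    gain = 1.0 + config.noise_multiplicative_sd * rng.standard_normal((h, w, 1))
    gain = np.clip(gain, 0.5, None)
    counts_sd = config.noise_additive_sd * config.illumination_scale
    raw = (config.dark_current
           + illum * refl * gain
           + counts_sd * rng.standard_normal(refl.shape))
    raw = np.clip(raw, 0.0, None)

    meta = {"label": config.label, "cultivar": config.cultivar,
            "orientation": config.orientation, "sample_id": config.sample_id,
            "dtype": "float32", "interleave": "bil"}
    raw_cube = Hypercube(raw, wl, name=config.sample_id, meta=dict(meta))

    white = (config.dark_current + illum * np.ones((1, w, len(wl)))
             + counts_sd * rng.standard_normal((1, w, len(wl))))
    dark = (config.dark_current
            + config.dark_noise_sd * rng.standard_normal((1, w, len(wl))))
    refs = ReferencePair(
        Hypercube(np.clip(white, 0, None), wl, name="white", meta=dict(meta)),
        Hypercube(np.clip(dark, 0, None), wl, name="dark", meta=dict(meta)),
    )
    truth = SceneTruth(background, fruit, calyx, infested, labels, ends,
                       calyx_center=(float(cc[0]), float(cc[1])))
    return raw_cube, refs, truth


def generate_study(n_control: int, n_infested: int,
                   template: SceneConfig | None = None, seed: int = 0,
                   jitter: float = 1.0) -> list:
    """Generate a labelled study of apples with between-apple variability.

    Control apples carry no lesion and label ``healthy``; infested apples use
    the template's effect size.  Per-apple geometry and brightness are
    jittered (``jitter`` scales the magnitudes; 0 = identical apples up to
    noise seed); each apple's seed derives deterministically from ``seed``.
    Default study ratio follows the 1:2 control:infested design.
    """
    if n_control < 1 or n_infested < 1:
        raise ParameterError("need at least one apple per group")
    template = template or SceneConfig()
    children = np.random.SeedSequence(seed).spawn(n_control + n_infested)
    scenes = []
    labels = ["healthy"] * n_control + ["infested"] * n_infested
    for i, (lab, child) in enumerate(zip(labels, children)):
        rng = np.random.default_rng(child)
        group = "control" if lab == "healthy" else "infested"
        idx = i if lab == "healthy" else i - n_control
        cfg = replace(
            template,
            label=lab,
            sample_id=f"{group}_{idx:02d}",
            apple_radius=template.apple_radius + jitter * rng.uniform(-5, 5),
            calyx_offset=tuple(np.asarray(template.calyx_offset)
                               + jitter * rng.uniform(-3, 3, size=2)),
            reflectance_gain=template.reflectance_gain
            * (1.0 + jitter * rng.uniform(-0.05, 0.05)),
            seed=int(rng.integers(0, 2 ** 31 - 1)),
        )
        scenes.append(generate_scene(cfg))
    return scenes


def sample_pixel_spectra(config: SceneConfig, kind: str, n: int,
                         seed: int = 0) -> np.ndarray:
    """Draw ``n`` noisy calibrated-domain pixel spectra of one endmember.

    Applies the scene noise model directly in reflectance space: per-pixel
    scalar gain plus additive noise scaled by the inverse illumination
    envelope (edge bands are noisier, as in a real push-broom instrument).
    Useful for table-level experiments that need exact control over where
    the class signal lives, without the ROI geometry in the loop.
    """
    rng = np.random.default_rng(seed)
    base = endmember_spectrum(kind, config)
    illum = _illumination(config.wavelengths, config.illumination_scale)
    refl_sd = config.noise_additive_sd * config.illumination_scale / illum
    gain = np.clip(1.0 + config.noise_multiplicative_sd
                   * rng.standard_normal((n, 1)), 0.5, None)
    return base * gain + refl_sd * rng.standard_normal((n, len(base)))


_PRESETS = {
    # strong, well-separated infestation signal at low noise
    "strong": dict(infestation_effect=0.85, noise_additive_sd=0.01),
    # no infestation effect at all: the null condition
    "null": dict(infestation_effect=1.0),
    # full-resolution spectral axis
    "paper-scale": dict(image_size=(200, 200), n_bands=256),
}


def preset_config(name: str, **overrides) -> SceneConfig:
    """Named scene presets; extra keyword overrides win."""
    if name not in _PRESETS:
        raise ParameterError(f"unknown preset '{name}' (have {sorted(_PRESETS)})")
    kw = dict(_PRESETS[name])
    kw.update(overrides)
    return SceneConfig(**kw)
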