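"""Synthetic hyperspectral scenes and design responses with known ground truth.

No public hypercubes exist for the sausage/ATP study system, so every
imaging stage is exercised on synthetic scenes that emulate its essential
structure: a 151-band visible/NIR wavelength grid, elongated sausage
footprints on a dark background separable by a single red-band threshold,
and a reflectance spectrum that rises with ATP content (spoilage raises
both).  Pixel spectra are a convex mixture of two smooth endmembers
weighted by the sausage's ATP value, corrupted by the three disturbances a
push-broom rig actually produces: per-pixel multiplicative scatter,
per-pixel additive baseline offset, and band-wise sensor noise.  Raw
counts, dark frames and white frames are emitted so the dark/white
calibration step is tested end to end.

The module also simulates central-composite-design response vectors from a
known quadratic model, for parameter-recovery checks of the
response-surface fit.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .cube import Hypercube, write_envi
from .rsm import CCDesign, model_matrix

__all__ = [
    "SceneConfig",
    "GroundTruth",
    "generate_scene",
    "generate_ccd_responses",
    "endmember_low",
    "endmember_high",
    "write_scene",
    "ATP_SCALE",
]

# ATP range (log10 mol/L) the mixture weight is scaled over: spans the
# levels observed across heavily spoiled to well-preserved sausages, so any
# realistic per-sausage value maps inside [0, 1].
ATP_SCALE = (-10.0, -4.0)

BACKGROUND_REFLECTANCE = 0.02
SEGMENTATION_WAVELENGTH = 695.0
SEGMENTATION_THRESHOLD = 0.075


def endmember_low(wavelengths: np.ndarray) -> np.ndarray:
    """Endmember of the lowest-ATP (freshest) surface: dim, blue-peaked.

    Smooth Gaussian-on-baseline shapes peaking in the 350-450 nm and
    600-750 nm regions, where spoilage-driven spectral variation
    concentrates (myoglobin chemistry in the red, general brightness loss
    in the blue).
    """
    w = np.asarray(wavelengths, dtype=float)
    return 0.18 + 0.20 * np.exp(-((w - 410.0) ** 2) / (2 * 45.0**2))


def endmember_high(wavelengths: np.ndarray) -> np.ndarray:
    """Endmember of the highest-ATP (most spoiled) surface: bright, red-peaked."""
    w = np.asarray(wavelengths, dtype=float)
    return 0.40 + 0.35 * np.exp(-((w - 680.0) ** 2) / (2 * 60.0**2))


@dataclass(frozen=True)
class SceneConfig:
    """Geometry, spectral grid, ATP assignments and noise levels of a scene.

    Noise defaults describe a careful bench acquisition in which
    multiplicative scatter is by far the dominant corruption: gain sd 0.15
    (curvature/illumination scatter across the casing surface), baseline
    stray-light offset sd 0.001 and band-wise sensor noise sd 0.001, all in
    reflectance units.  Gain and offset vary smoothly across the image
    (correlation length ``scatter_correlation_px``), as scatter from a
    curved glossy surface does.  The 350-1100 nm / 5 nm grid gives the
    camera's 151 bands and contains every wavelength the workflow names
    (450, 550, 600, 695 nm); the true range of the instrument is not
    published, so this grid is an assumption of the generator.
    """

    image_height: int = 96
    image_width: int = 128
    n_bands: int = 151
    wavelength_start: float = 350.0
    wavelength_step: float = 5.0
    n_sausages: int = 2
    atp_values: tuple = (-9.33, -4.37)
    scatter_multiplicative_sd: float = 0.15
    baseline_offset_sd: float = 0.001
    noise_sd: float = 0.001
    scatter_correlation_px: float = 12.0
    seed: int = 0

    def __post_init__(self):
        if self.n_bands < 3:
            raise ValueError("n_bands must be >= 3")
        if self.wavelength_step <= 0:
            raise ValueError("wavelength_step must be positive (increasing axis)")
        if len(self.atp_values) != self.n_sausages:
            raise ValueError("atp_values must list one ATP value per sausage")
        lo, hi = ATP_SCALE
        if any(not (lo <= a <= hi) for a in self.atp_values):
            raise ValueError(f"atp_values must lie within {ATP_SCALE} log10 mol/L")
        if min(self.scatter_multiplicative_sd, self.baseline_offset_sd, self.noise_sd) < 0:
            raise ValueError("noise standard deviations must be non-negative")

    @property
    def wavelengths(self) -> np.ndarray:
        return self.wavelength_start + self.wavelength_step * np.arange(self.n_bands)


@dataclass
class GroundTruth:
    """Everything the generator knows that downstream stages must recover."""

    mask: np.ndarray                 # foreground, all sausages
    sausage_ids: np.ndarray          # 0 background, 1..n per sausage
    atp_map: np.ndarray              # per-pixel ATP, NaN on background
    atp_values: dict                 # sausage id -> ATP
    endmembers: dict                 # {"low": spectrum, "high": spectrum}
    reflectance: np.ndarray          # noise-free mixture reflectance cube
    config: SceneConfig = None

    def sausage_mask(self, sausage_id: int) -> np.ndarray:
        return self.sausage_ids == sausage_id


def _smooth_field(
    rng: np.random.Generator, shape: tuple[int, int], sd: float, correlation_px: float
) -> np.ndarray:
    """Spatially smooth Gaussian random field with per-pixel sd ``sd``.

    Scatter on a curved sausage surface varies smoothly (illumination
    geometry, casing curvature), so the multiplicative gain and baseline
    offset are modelled as low-frequency fields rather than white noise —
    smooth enough to survive segment-mean averaging, which is exactly why
    scatter correction matters for segment spectra.  ``correlation_px = 0``
    degrades to independent per-pixel noise.
    """
    if sd == 0:
        return np.zeros(shape)
    white = rng.normal(size=shape)
    if correlation_px <= 0:
        return sd * white
    from scipy.ndimage import gaussian_filter

    field = gaussian_filter(white, sigma=correlation_px, mode="reflect")
    field_sd = field.std()
    if field_sd == 0:  # pathological tiny image
        return np.zeros(shape)
    return sd * field / field_sd


def _sausage_footprints(config: SceneConfig) -> np.ndarray:
    """Axis-aligned elliptical footprints stacked vertically, long axis horizontal."""
    H, W, n = config.image_height, config.image_width, config.n_sausages
    rr, cc = np.mgrid[0:H, 0:W]
    ids = np.zeros((H, W), dtype=int)
    for k in range(n):
        cy = (k + 0.5) * H / n
        cx = W / 2.0
        semi_minor = 0.30 * H / n
        semi_major = 0.38 * W
        inside = ((rr - cy) / semi_minor) ** 2 + ((cc - cx) / semi_major) ** 2 <= 1.0
        ids[inside] = k + 1
    return ids


def generate_scene(
    config: SceneConfig,
) -> tuple[Hypercube, np.ndarray, np.ndarray, GroundTruth]:
    """Generate (raw cube, dark frame, white frame, ground truth).

    Construction, in reflectance space first: the foreground mixture is
    ``(1 - t) * low + t * high`` with ``t`` the sausage's ATP rescaled to
    [0, 1] over :data:`ATP_SCALE` (so the map from ATP to spectrum is
    injective and increasing); each pixel's spectrum is then multiplied by
    ``1 + m`` (m ~ N(0, scatter_sd)), shifted by a per-pixel constant
    offset ~ N(0, offset_sd), and perturbed band-wise by N(0, noise_sd).
    Raw counts are ``dark + R * (white - dark)``, inverting the
    calibration identity exactly when all noise terms are zero.

    Raises ``ValueError`` if the realised noise makes foreground and
    background overlap at the 695 nm segmentation band — such a scene could
    not be segmented and is an unusable fixture.
    """
    rng = np.random.default_rng(config.seed)
    w = config.wavelengths
    H, W, B = config.image_height, config.image_width, config.n_bands

    sausage_ids = _sausage_footprints(config)
    mask = sausage_ids > 0
    for k in range(1, config.n_sausages + 1):
        if not np.any(sausage_ids == k):
            raise ValueError(f"image too small: sausage {k} has no pixels")

    e_low = endmember_low(w)
    e_high = endmember_high(w)
    lo, hi = ATP_SCALE
    atp_map = np.full((H, W), np.nan)
    reflectance = np.full((H, W, B), BACKGROUND_REFLECTANCE)
    for k in range(1, config.n_sausages + 1):
        atp = float(config.atp_values[k - 1])
        t = (atp - lo) / (hi - lo)
        reflectance[sausage_ids == k] = (1.0 - t) * e_low + t * e_high
        atp_map[sausage_ids == k] = atp

    gain = 1.0 + _smooth_field(rng, (H, W), config.scatter_multiplicative_sd,
                               config.scatter_correlation_px)[:, :, None]
    offset = _smooth_field(rng, (H, W), config.baseline_offset_sd,
                           config.scatter_correlation_px)[:, :, None]
    band_noise = rng.normal(0.0, config.noise_sd, size=(H, W, B))
    observed = reflectance * gain + offset + band_noise

    dark_spectrum = 100.0 + 0.02 * (w - w[0])
    white_spectrum = 3500.0 + 800.0 * np.exp(-((w - 650.0) ** 2) / (2 * 300.0**2))
    dark = np.broadcast_to(dark_spectrum, (H, W, B)).copy()
    white = np.broadcast_to(white_spectrum, (H, W, B)).copy()
    raw = Hypercube(dark + observed * (white - dark), w, kind="raw")

    seg_band = int(np.argmin(np.abs(w - SEGMENTATION_WAVELENGTH)))
    plane = observed[:, :, seg_band]
    fg_min = plane[mask].min()
    bg_max = plane[~mask].max() if np.any(~mask) else -np.inf
    thr = SEGMENTATION_THRESHOLD
    if not (fg_min > thr and bg_max <= thr):
        raise ValueError(
            "unusable fixture: foreground/background overlap at the 695 nm "
            f"segmentation band (foreground min {fg_min:.4f}, background max "
            f"{bg_max:.4f}, threshold {thr}); lower the noise levels"
        )

    truth = GroundTruth(
        mask=mask,
        sausage_ids=sausage_ids,
        atp_map=atp_map,
        atp_values={k: float(config.atp_values[k - 1]) for k in range(1, config.n_sausages + 1)},
        endmembers={"low": e_low, "high": e_high},
        reflectance=reflectance,
        config=config,
    )
    return raw, dark, white, truth


def recovery_benchmark_config(seed: int = 0) -> SceneConfig:
    """The standard parameter-recovery scene: ten sausages spanning the ATP range.

    Ten elongated sausages with ATP levels evenly spaced over
    -9.4..-4.4 log10 mol/L under the default (scatter-dominant) noise —
    the study conditions used for full-pipeline calibration/prediction
    benchmarks.  One scene yields 150 segment spectra (10 sausages x 15
    cross-sections).
    """
    atps = tuple(np.round(np.linspace(-9.4, -4.4, 10), 2))
    return SceneConfig(
        image_height=220, image_width=160, n_sausages=10, atp_values=atps, seed=seed
    )


def generate_ccd_responses(
    design: CCDesign,
    coefficients: np.ndarray,
    noise_sd: float,
    seed: int,
) -> np.ndarray:
    """Simulate response values from a known coded quadratic model.

    ``y = M(coded) @ coefficients + N(0, noise_sd)`` per run, where M is the
    21-term quadratic model matrix.  Used to check that refitting recovers
    the generating coefficients.
    """
    coefficients = np.asarray(coefficients, dtype=float).ravel()
    M = model_matrix(design.coded)
    if design.n_runs != 32:
        raise ValueError(f"expected the 32-run design (16 cube + 10 axial + 6 centre), "
                         f"got {design.n_runs} runs")
    if coefficients.size != M.shape[1]:
        raise ValueError(
            f"coefficient vector has {coefficients.size} terms, design model has {M.shape[1]}"
        )
    rng = np.random.default_rng(seed)
    return M @ coefficients + rng.normal(0.0, noise_sd, size=design.n_runs)


def write_scene(
    config: SceneConfig, out_dir: str | Path
) -> dict[str, Path]:
    """Generate a scene and write it to disk (ENVI cubes + ground-truth CSV)."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    raw, dark, white, truth = generate_scene(config)
    w = config.wavelengths
    paths = {
        "raw": write_envi(raw, out_dir / "scene_raw"),
        "dark": write_envi(Hypercube(dark, w, kind="raw"), out_dir / "scene_dark"),
        "white": write_envi(Hypercube(white, w, kind="raw"), out_dir / "scene_white"),
    }
    rr, cc = np.nonzero(truth.mask)
    gt = pd.DataFrame(
        {
            "row": rr,
            "col": cc,
            "sausage_id": truth.sausage_ids[rr, cc],
            "atp_log10_molL": truth.atp_map[rr, cc],
        }
    )
    paths["ground_truth"] = out_dir / "ground_truth.csv"
    gt.to_csv(paths["ground_truth"], index=False)
    cfg = dataclasses.asdict(config)
    cfg["atp_values"] = list(cfg["atp_values"])
    paths["config"] = out_dir / "scene_config.json"
    import json

    paths["config"].write_text(json.dumps(cfg, indent=1))
    return paths
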