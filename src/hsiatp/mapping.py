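"""Pixel-wise ATP distribution maps.

The payoff of imaging over point spectroscopy: the masked hypercube is
unfolded into a pixels x bands table (coordinates retained), the fitted
pre-treatment chain and PLSR regression vector are applied to every pixel
exactly as they were to the calibration spectra, and the predictions are
refolded into image coordinates and rendered beside the RGB
reconstruction on a linear colour scale.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .chemometrics import PLSRModel
from .cube import Hypercube, write_envi
from .preprocess import Preprocessor

__all__ = ["ATPMap", "predict_pixels", "render_map", "export_map"]

log = logging.getLogger("hsiatp")


@dataclass
class ATPMap:
    """Per-pixel predicted ATP (log10 mol/L); NaN outside the foreground."""

    values: np.ndarray
    mask: np.ndarray
    scale_limits: tuple[float, float] | None = None
    n_rejected_pixels: int = 0

    def foreground_values(self) -> np.ndarray:
        return self.values[self.mask]

    def sausage_mean(self, sausage_mask: np.ndarray) -> float:
        v = self.values[sausage_mask & self.mask]
        return float(np.nanmean(v))


def predict_pixels(
    cube: Hypercube,
    mask: np.ndarray,
    preprocessor: Preprocessor,
    model: PLSRModel,
    scale_limits: tuple[float, float] | None = None,
) -> ATPMap:
    """Predict ATP for every masked pixel of a reflectance cube.

    The chain is applied with its calibration-time state (e.g. the MSC
    reference) — never refit on pixels.  Pixels a pre-treatment guard
    rejects (flat spectra that cannot be SNV-scaled) are demoted to
    background and counted.  Raises if the cube's band axis does not match
    what the model was trained on (e.g. derivative shrinkage mismatch).
    """
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != cube.shape[:2]:
        raise ValueError("mask does not align with cube")
    if not mask.any():
        raise ValueError("empty foreground mask")
    if preprocessor.input_bands_ is not None and preprocessor.input_bands_ != cube.n_bands:
        raise ValueError(
            f"preprocessor expects {preprocessor.input_bands_} bands, cube has {cube.n_bands}"
        )
    rr, cc = np.nonzero(mask)
    spectra = cube.data[rr, cc, :]          # unfold, coordinates kept in (rr, cc)
    transformed, ok = preprocessor.transform_safe(spectra)
    if transformed.shape[1] != model.b.size:
        raise ValueError(
            f"band-axis mismatch: pre-treated pixels have {transformed.shape[1]} bands, "
            f"regression vector has {model.b.size}"
        )
    pred = model.predict(transformed)
    values = np.full(mask.shape, np.nan)
    values[rr[ok], cc[ok]] = pred[ok]       # refold
    out_mask = np.zeros_like(mask)
    out_mask[rr[ok], cc[ok]] = True
    n_rejected = int((~ok).sum())
    if n_rejected:
        log.info("distribution map: %d pixel(s) rejected by pre-treatment guards", n_rejected)
    return ATPMap(values=values, mask=out_mask, scale_limits=scale_limits,
                  n_rejected_pixels=n_rejected)


def render_map(
    atp_map: ATPMap,
    rgb: np.ndarray,
    path: str | Path,
    scale_limits: tuple[float, float] | None = None,
    cmap: str = "jet",
) -> Path:
    """Side-by-side panel: RGB reconstruction | ATP map with colour bar.

    The colour scale is linear; limits come from the argument, the map's
    stored limits, or the foreground min/max, in that order.  Out-of-range
    pixels clamp to the endpoint colours; background renders neutral grey.
    """
    if rgb.shape[:2] != atp_map.values.shape:
        raise ValueError("RGB image and map dimensions differ")
    fg = atp_map.foreground_values()
    if fg.size == 0:
        raise ValueError("empty foreground: nothing to render")
    limits = scale_limits or atp_map.scale_limits
    if limits is None:
        limits = (float(np.nanmin(fg)), float(np.nanmax(fg)))
    vmin, vmax = limits
    fig, axes = plt.subplots(1, 2, figsize=(9, 4))
    axes[0].imshow(rgb)
    axes[0].set_title("RGB reconstruction")
    axes[0].axis("off")
    masked = np.ma.masked_invalid(atp_map.values)
    cm = plt.get_cmap(cmap).copy()
    cm.set_bad("0.85")
    im = axes[1].imshow(masked, cmap=cm, vmin=vmin, vmax=vmax)
    axes[1].set_title("ATP distribution (log10 mol/L)")
    axes[1].axis("off")
    fig.colorbar(im, ax=axes[1], shrink=0.85)
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fig.savefig(path, dpi=120, bbox_inches="tight")
    plt.close(fig)
    return path


def export_map(atp_map: ATPMap, base_path: str | Path) -> dict[str, Path]:
    """Write the raw map as single-band ENVI and as a long-form CSV."""
    base_path = Path(base_path)
    base_path.parent.mkdir(parents=True, exist_ok=True)
    cube = Hypercube(np.nan_to_num(atp_map.values)[:, :, None], np.array([0.0]), kind="raw")
    envi_path = write_envi(cube, base_path)
    rr, cc = np.nonzero(atp_map.mask)
    csv_path = base_path.with_suffix(".csv")
    pd.DataFrame(
        {"row": rr, "col": cc, "atp_log10_molL": atp_map.values[rr, cc]}
    ).to_csv(csv_path, index=False)
    return {"envi": envi_path, "csv": csv_path}
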