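"""Hypercube container, ENVI I/O, reflectance calibration and spatial operations.

A hyperspectral measurement is a 3-D array (rows x cols x bands) with a
wavelength axis.  This module covers the image-side half of the workflow:
dark/white reflectance calibration, threshold segmentation of the sausage
foreground, equal-area partitioning of each sausage into cross-section
segments, per-segment mean-spectrum extraction, and RGB reconstruction for
visualisation.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage

__all__ = [
    "Hypercube",
    "ReferenceFrames",
    "SegmentLabels",
    "CalibrationError",
    "read_envi",
    "write_envi",
    "calibrate",
    "segment_foreground",
    "partition_segments",
    "extract_mean_spectra",
    "reconstruct_rgb",
]

KINDS = ("raw", "reflectance", "absorbance")


class CalibrationError(ValueError):
    """Raised when dark/white references cannot calibrate a cube."""


@dataclass
class Hypercube:
    """A rows x cols x bands spectral image with its wavelength axis.

    ``kind`` records the radiometric state: camera counts (``raw``),
    dark/white-normalised ``reflectance``, or ``absorbance`` (log10 1/R).
    """

    data: np.ndarray
    wavelengths: np.ndarray
    kind: str = "raw"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        if self.data.ndim != 3:
            raise ValueError(f"data must be 3-D (rows, cols, bands), got {self.data.shape}")
        if self.data.shape[2] != self.wavelengths.size:
            raise ValueError(
                f"bands ({self.data.shape[2]}) != wavelengths ({self.wavelengths.size})"
            )
        if self.wavelengths.size > 1 and not np.all(np.diff(self.wavelengths) > 0):
            raise ValueError("wavelengths must be strictly increasing")
        if self.kind not in KINDS:
            raise ValueError(f"kind must be one of {KINDS}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def n_bands(self) -> int:
        return self.data.shape[2]

    def band_index(self, wavelength_nm: float) -> int:
        """Index of the band nearest to ``wavelength_nm``.

        The band grid of the camera is not assumed to contain the named
        wavelengths exactly; nearest-band lookup is used throughout, but a
        request outside the covered range is an error.
        """
        w = self.wavelengths
        if not (w[0] <= wavelength_nm <= w[-1]):
            raise ValueError(
                f"wavelength {wavelength_nm} nm outside axis range [{w[0]}, {w[-1]}] nm"
            )
        return int(np.argmin(np.abs(w - wavelength_nm)))

    def band(self, wavelength_nm: float) -> np.ndarray:
        """The 2-D image plane at the band nearest to ``wavelength_nm``."""
        return self.data[:, :, self.band_index(wavelength_nm)]


@dataclass
class ReferenceFrames:
    """Dark-current and 100%-white reference measurements.

    Either may be a full cube, a single frame, or a per-band spectrum;
    anything broadcastable against the target cube is accepted, since
    whether references are recorded as frames or cubes varies by setup.
    """

    dark: np.ndarray
    white: np.ndarray

    def __post_init__(self) -> None:
        self.dark = np.asarray(self.dark, dtype=float)
        self.white = np.asarray(self.white, dtype=float)


@dataclass
class SegmentLabels:
    """Per-pixel segment (1..n per sausage, 0 = background) and sausage ids."""

    labels: np.ndarray
    sausage_ids: np.ndarray
    n_segments: int = 15
    segment_order_axes: dict = field(default_factory=dict)

    def sausages(self) -> list[int]:
        ids = np.unique(self.sausage_ids)
        return [int(i) for i in ids if i != 0]


# ---------------------------------------------------------------------------
# ENVI I/O (text header + band-sequential binary)
# ---------------------------------------------------------------------------

_ENVI_DTYPES = {1: np.uint8, 2: np.int16, 4: np.float32, 5: np.float64, 12: np.uint16}
_DTYPE_CODES = {np.dtype(np.float32): 4, np.dtype(np.float64): 5}


def write_envi(cube: Hypercube, path: str | Path, dtype=np.float32) -> Path:
    """Write ``cube`` as an ENVI pair: ``<path>.hdr`` + ``<path>.img`` (BSQ)."""
    path = Path(path)
    if path.suffix in (".hdr", ".img"):
        path = path.with_suffix("")
    dtype = np.dtype(dtype)
    code = _DTYPE_CODES[dtype]
    rows, cols, bands = cube.shape
    wl = ", ".join(f"{w:g}" for w in cube.wavelengths)
    header = (
        "ENVI\n"
        f"description = {{hsiatp hypercube, kind = {cube.kind}}}\n"
        f"samples = {cols}\n"
        f"lines = {rows}\n"
        f"bands = {bands}\n"
        "header offset = 0\n"
        "file type = ENVI Standard\n"
        f"data type = {code}\n"
        "interleave = bsq\n"
        "byte order = 0\n"
        "wavelength units = Nanometers\n"
        f"wavelength = {{{wl}}}\n"
    )
    path.with_suffix(".hdr").write_text(header)
    # BSQ: band-major on disk
    np.ascontiguousarray(np.moveaxis(cube.data, 2, 0)).astype(dtype).tofile(
        path.with_suffix(".img")
    )
    return path


def _parse_envi_header(text: str) -> dict:
    fields: dict[str, str] = {}
    # brace-valued entries may span lines
    text = re.sub(r"\{[^}]*\}", lambda m: m.group(0).replace("\n", " "), text)
    for line in text.splitlines():
        if "=" not in line:
            continue
        key, value = line.split("=", 1)
        fields[key.strip().lower()] = value.strip()
    return fields


def read_envi(path: str | Path) -> Hypercube:
    """Read an ENVI header/binary pair written by :func:`write_envi`.

    Supports BSQ/BIL/BIP interleaves and little-endian data.
    """
    path = Path(path)
    if path.suffix in (".hdr", ".img"):
        path = path.with_suffix("")
    fields = _parse_envi_header(path.with_suffix(".hdr").read_text())
    rows = int(fields["lines"])
    cols = int(fields["samples"])
    bands = int(fields["bands"])
    dtype = _ENVI_DTYPES[int(fields["data type"])]
    interleave = fields.get("interleave", "bsq").lower()
    offset = int(fields.get("header offset", 0))
    raw = np.fromfile(path.with_suffix(".img"), dtype=dtype, offset=offset)
    if raw.size != rows * cols * bands:
        raise ValueError(f"binary size {raw.size} != lines*samples*bands for {path}")
    if interleave == "bsq":
        data = np.moveaxis(raw.reshape(bands, rows, cols), 0, 2)
    elif interleave == "bil":
        data = np.moveaxis(raw.reshape(rows, bands, cols), 1, 2)
    elif interleave == "bip":
        data = raw.reshape(rows, cols, bands)
    else:
        raise ValueError(f"unknown interleave {interleave!r}")
    m = re.search(r"wavelength\s*=\s*\{([^}]*)\}", path.with_suffix(".hdr").read_text())
    if m:
        wavelengths = np.array([float(v) for v in m.group(1).split(",")])
    else:
        wavelengths = np.arange(bands, dtype=float)
    kind = "raw"
    km = re.search(r"kind\s*=\s*(\w+)", fields.get("description", ""))
    if km and km.group(1) in KINDS:
        kind = km.group(1)
    return Hypercube(data=np.array(data, dtype=float), wavelengths=wavelengths, kind=kind)


def write_mask_envi(mask: np.ndarray, path: str | Path) -> Path:
    """Write a 2-D mask or label map as a single-band ENVI image."""
    cube = Hypercube(mask.astype(float)[:, :, None], np.array([0.0]), kind="raw")
    return write_envi(cube, path)


# ---------------------------------------------------------------------------
# Reflectance calibration
# ---------------------------------------------------------------------------


def calibrate(raw: Hypercube, refs: ReferenceFrames) -> Hypercube:
    """Dark/white reflectance calibration: R = (r1 - dark) / (white - dark).

    Reflectance is deliberately not clipped to [0, 1] — specular pixels can
    legitimately exceed the white reference, and clipping would bias the
    scatter-correction pre-treatments downstream.

    Raises
    ------
    CalibrationError
        If ``white - dark`` vanishes anywhere, naming the offending bands.
    """
    dark = np.broadcast_to(refs.dark, raw.shape)
    white = np.broadcast_to(refs.white, raw.shape)
    denom = white - dark
    bad = denom == 0
    if np.any(bad):
        bands = sorted(set(np.nonzero(bad)[2].tolist()))
        wl = ", ".join(f"{raw.wavelengths[b]:g} nm" for b in bands[:5])
        raise CalibrationError(
            f"white == dark in {len(bands)} band(s) ({wl}{'...' if len(bands) > 5 else ''})"
        )
    reflectance = (raw.data - dark) / denom
    return Hypercube(reflectance, raw.wavelengths.copy(), kind="reflectance")


def segment_foreground(
    cube: Hypercube, wavelength_nm: float = 695.0, threshold: float = 0.075
) -> np.ndarray:
    """Foreground mask: pixels with reflectance at ~695 nm strictly above 0.075.

    The sausage surface reflects far more than the black background sheet in
    the red band, so a single-band threshold separates them; the inequality
    is strict (a pixel exactly at the threshold is background).
    """
    if cube.kind != "reflectance":
        raise ValueError(f"segmentation requires a reflectance cube, got kind={cube.kind!r}")
    return cube.band(wavelength_nm) > threshold


# ---------------------------------------------------------------------------
# Equal-area cross-section partitioning
# ---------------------------------------------------------------------------

_CONN8 = np.ones((3, 3), dtype=int)


def _principal_axis(coords: np.ndarray) -> np.ndarray:
    """Unit principal axis of an (n, 2) pixel-coordinate cloud, sign-fixed."""
    centred = coords - coords.mean(axis=0)
    cov = centred.T @ centred / max(len(coords) - 1, 1)
    eigvals, eigvecs = np.linalg.eigh(cov)
    axis = eigvecs[:, np.argmax(eigvals)]
    # deterministic orientation: first nonzero component positive
    for comp in axis:
        if abs(comp) > 1e-12:
            if comp < 0:
                axis = -axis
            break
    return axis


def partition_segments(mask: np.ndarray, n_segments: int = 15) -> SegmentLabels:
    """Slice each connected sausage into ``n_segments`` equal-area cross-sections.

    Each connected component is treated as one sausage.  Its pixels are
    ordered by projection onto the component's principal axis (the sausage's
    long axis) and split into contiguous groups whose sizes differ by at
    most one pixel — equal *area* cross-sections rather than equal length,
    so tapered ends are not under-represented.

    Ties in projection are broken by (row, col) so the labelling is
    deterministic.
    """
    mask = np.asarray(mask, dtype=bool)
    comp_map, n_comp = ndimage.label(mask, structure=_CONN8)
    if n_comp == 0:
        raise ValueError("mask has no foreground component")
    labels = np.zeros(mask.shape, dtype=int)
    sausage_ids = np.zeros(mask.shape, dtype=int)
    axes: dict[int, np.ndarray] = {}
    for comp in range(1, n_comp + 1):
        rr, cc = np.nonzero(comp_map == comp)
        if rr.size < n_segments:
            raise ValueError(
                f"component {comp} has {rr.size} pixels; cannot form {n_segments} segments"
            )
        coords = np.column_stack([rr, cc]).astype(float)
        axis = _principal_axis(coords)
        proj = coords @ axis
        order = np.lexsort((cc, rr, proj))  # projection first, then row/col ties
        groups = np.array_split(order, n_segments)
        for seg, grp in enumerate(groups, start=1):
            labels[rr[grp], cc[grp]] = seg
        sausage_ids[rr, cc] = comp
        axes[comp] = axis
    return SegmentLabels(labels=labels, sausage_ids=sausage_ids,
                         n_segments=n_segments, segment_order_axes=axes)


def extract_mean_spectra(
    cube: Hypercube,
    labels: SegmentLabels,
    reference: dict[int, float] | pd.Series | None = None,
    treatments: dict[int, object] | None = None,
) -> pd.DataFrame:
    """Per-segment mean spectra with sausage/treatment/ATP metadata.

    Returns one row per (sausage, segment): columns ``sausage_id``,
    ``segment_id``, ``treatment_id``, ``atp_log10_molL`` then one column per
    wavelength.  Every segment of a sausage carries that sausage's single
    reference ATP value — the reference assay measures the whole sausage, so
    segments are replicate spectra of one response value.
    """
    if labels.labels.shape != cube.shape[:2]:
        raise ValueError("label map does not align with cube")
    if reference is not None:
        reference = dict(reference)
        missing = [s for s in labels.sausages() if s not in reference]
        if missing:
            raise KeyError(f"sausage id(s) {missing} missing from reference table")
    rows = []
    flat = cube.data.reshape(-1, cube.n_bands)
    lab_flat = labels.labels.ravel()
    sid_flat = labels.sausage_ids.ravel()
    for sid in labels.sausages():
        for seg in range(1, labels.n_segments + 1):
            sel = (sid_flat == sid) & (lab_flat == seg)
            spectrum = flat[sel].mean(axis=0)
            meta = {
                "sausage_id": sid,
                "segment_id": seg,
                "treatment_id": (treatments or {}).get(sid, sid),
                "atp_log10_molL": reference[sid] if reference is not None else np.nan,
            }
            rows.append({**meta, **dict(zip((f"{w:g}" for w in cube.wavelengths), spectrum))})
    return pd.DataFrame(rows)


def spectra_matrix(table: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    """Split a spectra table into (X, wavelengths); metadata columns dropped."""
    meta = {"sausage_id", "segment_id", "treatment_id", "atp_log10_molL"}
    bands = [c for c in table.columns if c not in meta]
    return table[bands].to_numpy(dtype=float), np.array([float(c) for c in bands])


def reconstruct_rgb(cube: Hypercube, mask: np.ndarray | None = None) -> np.ndarray:
    """RGB reconstruction from the 600 / 550 / 450 nm bands, scaled to [0, 1].

    Each channel is min-max scaled over the foreground (or the whole image
    if no mask is given) so the sausage occupies the full dynamic range.
    """
    channels = []
    for wl in (600.0, 550.0, 450.0):
        plane = cube.band(wl).astype(float)
        region = plane[mask] if mask is not None else plane
        lo, hi = float(region.min()), float(region.max())
        if hi == lo:  # degenerate range: keep the (clipped) raw level
            scaled = np.full_like(plane, lo)
        else:
            scaled = (plane - lo) / (hi - lo)
        channels.append(np.clip(scaled, 0.0, 1.0))
    return np.dstack(channels)
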