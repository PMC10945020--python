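"""Spectral pre-treatments and ordered fit/apply chains.

Spectra are 2-D arrays of shape (n_spectra, n_bands); every transform is
row-independent so the same fitted chain can be applied to segment-mean
spectra and, later, to every masked pixel of a hypercube.

Available steps: absorbance conversion, standard normal variate (SNV),
multiplicative scatter correction (MSC), min-max normalisation,
Savitzky-Golay smoothing and increment derivatives.  A chain is fitted on
the calibration subset only (MSC learns its reference spectrum there) and
then applied unchanged to prediction spectra and pixels.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np
from scipy.signal import savgol_coeffs

__all__ = [
    "absorbance",
    "snv",
    "msc_fit",
    "msc_apply",
    "normalise",
    "sg_smoothing_matrix",
    "sg_smooth",
    "derivative",
    "PreprocessSpec",
    "Preprocessor",
    "PreprocessError",
    "STANDARD_CHAINS",
]

ABSORBANCE_EPS = 1e-6  # reflectance clamp keeping log10(1/R) finite


class PreprocessError(ValueError):
    """A pre-treatment step failed on the given spectra."""


def _as2d(spectra: np.ndarray) -> np.ndarray:
    x = np.asarray(spectra, dtype=float)
    return x[None, :] if x.ndim == 1 else x


def absorbance(spectra: np.ndarray) -> np.ndarray:
    """Reflectance to absorbance: A = log10(1 / max(R, eps)).

    The clamp keeps shadowed or negative-calibrated pixels finite instead of
    raising; with eps = 1e-6 a fully dark pixel maps to A = 6.
    """
    x = _as2d(spectra)
    return np.log10(1.0 / np.maximum(x, ABSORBANCE_EPS))


def snv(spectra: np.ndarray) -> np.ndarray:
    """Standard normal variate: centre and scale each spectrum to sd 1.

    Uses the sample (n-1) standard deviation.  Removes per-spectrum
    multiplicative scatter and baseline offset.
    """
    x = _as2d(spectra)
    if x.shape[1] < 2:
        raise PreprocessError("SNV needs at least 2 bands")
    sd = x.std(axis=1, ddof=1)
    zero = np.nonzero(sd == 0)[0]
    if zero.size:
        raise PreprocessError(f"zero-variance spectrum in row(s) {zero.tolist()}")
    return (x - x.mean(axis=1, keepdims=True)) / sd[:, None]


def snv_safe(spectra: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """SNV with a validity flag instead of an error for zero-variance rows.

    Used for pixel-wise application, where a flat spectrum should be dropped
    to background rather than aborting the whole map.  Returns (out, ok).
    """
    x = _as2d(spectra)
    sd = x.std(axis=1, ddof=1)
    ok = sd > 0
    out = np.zeros_like(x)
    out[ok] = (x[ok] - x[ok].mean(axis=1, keepdims=True)) / sd[ok, None]
    return out, ok


def msc_fit(calibration_spectra: np.ndarray) -> np.ndarray:
    """MSC reference spectrum: the band-wise mean of the calibration set."""
    return _as2d(calibration_spectra).mean(axis=0)


def msc_apply(spectra: np.ndarray, reference: np.ndarray) -> np.ndarray:
    """Multiplicative scatter correction against a reference spectrum.

    Each spectrum is regressed (OLS) on the reference, x ~ a + b*ref, and
    corrected to (x - a) / b.
    """
    x = _as2d(spectra)
    ref = np.asarray(reference, dtype=float)
    if ref.size != x.shape[1]:
        raise PreprocessError("MSC reference length does not match spectra bands")
    refc = ref - ref.mean()
    denom = refc @ refc
    if denom == 0:
        raise PreprocessError("MSC reference spectrum is constant")
    b = (x - x.mean(axis=1, keepdims=True)) @ refc / denom
    small = np.nonzero(np.abs(b) < 1e-12)[0]
    if small.size:
        raise PreprocessError(f"MSC slope ~ 0 in row(s) {small.tolist()}")
    a = x.mean(axis=1) - b * ref.mean()
    return (x - a[:, None]) / b[:, None]


def normalise(spectra: np.ndarray) -> np.ndarray:
    """Per-spectrum min-max scaling to [0, 1]."""
    x = _as2d(spectra)
    lo = x.min(axis=1, keepdims=True)
    hi = x.max(axis=1, keepdims=True)
    rng = hi - lo
    flat = np.nonzero(rng.ravel() == 0)[0]
    if flat.size:
        raise PreprocessError(f"constant spectrum in row(s) {flat.tolist()}")
    return (x - lo) / rng


def sg_smoothing_matrix(n_bands: int, window: int = 5, degree: int = 2) -> np.ndarray:
    """Savitzky-Golay smoothing as an explicit (n_bands x n_bands) linear map.

    Interior bands use the standard centred SG coefficients; bands within
    half a window of either edge are smoothed by a least-squares polynomial
    fitted on the window truncated at the array boundary.  Because the
    filter is linear, building the matrix once lets whole pixel tables be
    smoothed with a single matmul.
    """
    if window % 2 == 0 or window < 3:
        raise PreprocessError(f"window must be odd and >= 3, got {window}")
    if degree >= window:
        raise PreprocessError(f"degree ({degree}) must be < window ({window})")
    if n_bands < window:
        raise PreprocessError(f"need at least {window} bands, got {n_bands}")
    half = window // 2
    S = np.zeros((n_bands, n_bands))
    centre_coeffs = savgol_coeffs(window, degree)[::-1]  # convolution order -> dot order
    for i in range(n_bands):
        lo = max(0, i - half)
        hi = min(n_bands, i + half + 1)
        if hi - lo == window:
            S[i, lo:hi] = centre_coeffs
        else:  # truncated one-sided edge window: local polynomial LS fit
            t = np.arange(lo, hi) - i
            deg = min(degree, hi - lo - 1)
            V = np.vander(t, deg + 1, increasing=True)
            # smoothed value at t=0 is the fitted intercept
            S[i, lo:hi] = np.linalg.pinv(V)[0]
    return S


def sg_smooth(spectra: np.ndarray, window: int = 5, degree: int = 2) -> np.ndarray:
    """Savitzky-Golay least-squares polynomial smoothing along the band axis."""
    x = _as2d(spectra)
    return x @ sg_smoothing_matrix(x.shape[1], window, degree).T


def derivative(
    spectra: np.ndarray,
    wavelengths: np.ndarray | None = None,
    order: int = 1,
    smooth_window: int | None = 5,
    smooth_degree: int = 2,
) -> tuple[np.ndarray, np.ndarray | None]:
    """Increment derivative: difference between consecutive (smoothed) bands.

    Each application first Savitzky-Golay smooths the spectrum (disable with
    ``smooth_window=None``), then takes the first difference, shrinking the
    band axis by one; the wavelength axis moves to interval midpoints.  The
    increment is not divided by the band spacing — on an even grid this is a
    constant factor absorbed by the regression.
    """
    if order not in (1, 2):
        raise PreprocessError(f"derivative order must be 1 or 2, got {order}")
    x = _as2d(spectra)
    w = None if wavelengths is None else np.asarray(wavelengths, dtype=float)
    for _ in range(order):
        if x.shape[1] < 2:
            raise PreprocessError("too few bands for a derivative")
        if smooth_window is not None:
            x = sg_smooth(x, smooth_window, smooth_degree)
        x = np.diff(x, axis=1)
        if w is not None:
            w = 0.5 * (w[:-1] + w[1:])
    return x, w


# ---------------------------------------------------------------------------
# Ordered chains with fit/apply semantics
# ---------------------------------------------------------------------------

STEP_NAMES = ("absorbance", "snv", "msc", "normalise", "sg_smooth", "derivative")


@dataclass(frozen=True)
class PreprocessSpec:
    """An ordered, serialisable list of pre-treatment steps.

    Each step is ``(name, params)`` with name in ``STEP_NAMES``; e.g. the
    chain found best for ATP spectra is
    ``[("absorbance", {}), ("snv", {}), ("derivative", {"order": 1})]``.
    """

    steps: tuple = ()
    name: str = ""

    @staticmethod
    def from_list(items, name: str = "") -> "PreprocessSpec":
        steps = []
        for item in items:
            if isinstance(item, str):
                step_name, params = item, {}
            else:
                step_name, params = item[0], dict(item[1] or {})
            if step_name not in STEP_NAMES:
                raise PreprocessError(f"unknown step {step_name!r}")
            steps.append((step_name, tuple(sorted(params.items()))))
        return PreprocessSpec(steps=tuple(steps), name=name)

    def to_list(self) -> list:
        return [[name, dict(params)] for name, params in self.steps]


@dataclass
class Preprocessor:
    """A pre-treatment chain with learned state, fitted once and reusable.

    ``fit`` runs the chain over the calibration spectra, learning any
    stateful step (the MSC reference) from them alone; ``transform`` then
    replays the identical chain on new spectra or unfolded pixels.  This
    separation prevents information from prediction rows leaking into the
    model and keeps pixel-wise maps on the same footing as the calibration.
    """

    spec: PreprocessSpec
    fitted_: list = dc_field(default_factory=list)
    input_bands_: int | None = None
    output_wavelengths_: np.ndarray | None = None

    def fit(self, calibration_spectra: np.ndarray, wavelengths: np.ndarray) -> "Preprocessor":
        x = _as2d(calibration_spectra)
        w = np.asarray(wavelengths, dtype=float)
        self.input_bands_ = x.shape[1]
        self.fitted_ = []
        for idx, (name, params) in enumerate(self.spec.steps):
            p = dict(params)
            try:
                if name == "msc":
                    ref = msc_fit(x)
                    self.fitted_.append(("msc", {"reference": ref}))
                    x = msc_apply(x, ref)
                else:
                    self.fitted_.append((name, p))
                    x, w = self._apply_stateless(name, p, x, w)
            except PreprocessError as err:
                raise PreprocessError(f"step {idx} ({name}): {err}") from err
        self.output_wavelengths_ = w
        return self

    def transform(self, spectra: np.ndarray) -> np.ndarray:
        if self.input_bands_ is None:
            raise PreprocessError("Preprocessor not fitted")
        x = _as2d(spectra)
        if x.shape[1] != self.input_bands_:
            raise PreprocessError(
                f"expected {self.input_bands_} bands, got {x.shape[1]}"
            )
        w = None
        for idx, (name, state) in enumerate(self.fitted_):
            try:
                if name == "msc":
                    x = msc_apply(x, state["reference"])
                else:
                    x, w = self._apply_stateless(name, state, x, w)
            except PreprocessError as err:
                raise PreprocessError(f"step {idx} ({name}): {err}") from err
        return x

    def transform_safe(self, spectra: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Like ``transform`` but flags rows a guard rejects instead of raising.

        A pixel whose spectrum is constant (zero variance under SNV,
        zero range under normalise, ~zero MSC slope) gets ``ok=False`` and a
        zero row; used by the distribution-map path.
        """
        x = _as2d(spectra)
        ok = np.ones(x.shape[0], dtype=bool)
        w = None
        for name, state in self.fitted_:
            if name == "snv":
                x, good = snv_safe(x)
                ok &= good
            elif name == "msc":
                ref = state["reference"]
                refc = ref - ref.mean()
                b = (x - x.mean(axis=1, keepdims=True)) @ refc / (refc @ refc)
                good = np.abs(b) >= 1e-12
                ok &= good
                # rows the slope guard rejects are replaced by the reference
                # itself (a fixed point of MSC) so the batch call cannot raise
                x = msc_apply(np.where(good[:, None], x, ref[None, :]), ref)
            elif name == "normalise":
                rng = x.max(axis=1) - x.min(axis=1)
                good = rng > 0
                ok &= good
                filler = np.linspace(0.0, 1.0, x.shape[1])
                x = normalise(np.where(good[:, None], x, filler[None, :]))
            else:
                x, w = self._apply_stateless(name, state, x, w)
        x[~ok] = 0.0
        return x, ok

    @staticmethod
    def _apply_stateless(name, params, x, w):
        if name == "absorbance":
            return absorbance(x), w
        if name == "snv":
            return snv(x), w
        if name == "normalise":
            return normalise(x), w
        if name == "sg_smooth":
            return sg_smooth(x, params.get("window", 5), params.get("degree", 2)), w
        if name == "derivative":
            return derivative(
                x,
                w,
                order=params.get("order", 1),
                smooth_window=params.get("smooth_window", 5),
                smooth_degree=params.get("smooth_degree", 2),
            )
        raise PreprocessError(f"unknown step {name!r}")


def chain_fit_apply(
    spec: PreprocessSpec,
    calibration_spectra: np.ndarray,
    other_spectra: np.ndarray | None,
    wavelengths: np.ndarray,
) -> tuple[np.ndarray, np.ndarray | None, "Preprocessor"]:
    """Fit a chain on calibration spectra and apply it to both sets.

    Returns (transformed calibration, transformed other, fitted chain).
    """
    pp = Preprocessor(spec).fit(calibration_spectra, wavelengths)
    cal_t = pp.transform(calibration_spectra)
    other_t = None if other_spectra is None else pp.transform(other_spectra)
    return cal_t, other_t, pp


# The nine pre-treatment chains compared when sweeping models: raw
# reflectance, then everything else on absorbance spectra.
STANDARD_CHAINS: dict[str, PreprocessSpec] = {
    "raw_reflectance": PreprocessSpec.from_list([], name="raw_reflectance"),
    "raw_absorbance": PreprocessSpec.from_list(["absorbance"], name="raw_absorbance"),
    "msc": PreprocessSpec.from_list(["absorbance", "msc"], name="msc"),
    "derivative_1st": PreprocessSpec.from_list(
        ["absorbance", ("derivative", {"order": 1})], name="derivative_1st"
    ),
    "snv": PreprocessSpec.from_list(["absorbance", "snv"], name="snv"),
    "derivative_2nd": PreprocessSpec.from_list(
        ["absorbance", ("derivative", {"order": 2})], name="derivative_2nd"
    ),
    "normalisation": PreprocessSpec.from_list(["absorbance", "normalise"], name="normalisation"),
    "snv_deriv1": PreprocessSpec.from_list(
        ["absorbance", "snv", ("derivative", {"order": 1})], name="snv_deriv1"
    ),
    "deriv1_snv": PreprocessSpec.from_list(
        ["absorbance", ("derivative", {"order": 1}), "snv"], name="deriv1_snv"
    ),
}
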