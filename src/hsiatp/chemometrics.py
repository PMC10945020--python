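"""Calibration/prediction splitting, PLSR fitting and model metrics.

The regression side of the workflow: Kennard-Stone sample-set partitioning
(two thirds calibration, one third prediction), partial least squares
regression collapsed to a single regression vector plus intercept, latent
variable selection by full (leave-one-out) cross-validation, and the usual
R^2 / RMSE triples for calibration, prediction and cross-validation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.spatial.distance import cdist
from sklearn.cross_decomposition import PLSRegression

__all__ = [
    "SplitResult",
    "PLSRModel",
    "ModelMetrics",
    "kennard_stone",
    "fit_plsr",
    "cross_validate",
    "select_components",
    "evaluate",
]


@dataclass(frozen=True)
class SplitResult:
    """Row indices chosen for calibration and prediction."""

    calibration: np.ndarray
    prediction: np.ndarray
    metric: str = "euclidean"


def kennard_stone(X: np.ndarray, calibration_fraction: float = 2.0 / 3.0) -> SplitResult:
    """Kennard-Stone selection of a maximally spread calibration subset.

    The classic deterministic greedy: seed with the two most mutually
    distant samples, then repeatedly add the sample whose minimum Euclidean
    distance to the already-selected set is largest.  Ties are broken by the
    lowest row index, so duplicated rows never raise.  The calibration size
    is ``round(fraction * n)``.
    """
    X = np.asarray(X, dtype=float)
    n = X.shape[0]
    if n < 3:
        raise ValueError(f"need at least 3 samples, got {n}")
    n_cal = int(np.rint(calibration_fraction * n))
    n_cal = min(max(n_cal, 2), n)
    D = cdist(X, X)
    if not np.all(np.isfinite(D)):
        raise ValueError("non-finite distances in X")
    # seed: the most distant pair; argmax returns the first (lowest-index) max
    i, j = np.unravel_index(np.argmax(D), D.shape)
    selected = [min(i, j), max(i, j)]
    mask = np.ones(n, dtype=bool)
    mask[selected] = False
    mindist = np.minimum(D[selected[0]], D[selected[1]])
    while len(selected) < n_cal:
        cand = np.where(mask, mindist, -np.inf)
        nxt = int(np.argmax(cand))
        selected.append(nxt)
        mask[nxt] = False
        mindist = np.minimum(mindist, D[nxt])
    calibration = np.array(sorted(selected))
    prediction = np.array([k for k in range(n) if mask[k]])
    return SplitResult(calibration=calibration, prediction=prediction)


@dataclass
class PLSRModel:
    """A fitted PLS regression reduced to prediction form.

    Whatever the latent decomposition, prediction of a pre-treated spectrum
    ``x`` is ``b0 + x @ b``; that pair (plus the band axis it was trained
    on) is all the distribution-map stage needs.
    """

    n_components: int
    b0: float
    b: np.ndarray
    wavelengths: np.ndarray | None = None
    spec_name: str = ""
    metadata: dict = field(default_factory=dict)

    def predict(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[None, :]
        if X.shape[1] != self.b.size:
            raise ValueError(f"expected {self.b.size} bands, got {X.shape[1]}")
        return self.b0 + X @ self.b

    def to_json(self, path: str | Path) -> Path:
        path = Path(path)
        payload = {
            "n_components": self.n_components,
            "b0": self.b0,
            "b": self.b.tolist(),
            "wavelengths": None if self.wavelengths is None else self.wavelengths.tolist(),
            "spec_name": self.spec_name,
            "metadata": self.metadata,
        }
        path.write_text(json.dumps(payload, indent=1))
        return path

    @staticmethod
    def from_json(path: str | Path) -> "PLSRModel":
        d = json.loads(Path(path).read_text())
        return PLSRModel(
            n_components=d["n_components"],
            b0=d["b0"],
            b=np.array(d["b"]),
            wavelengths=None if d["wavelengths"] is None else np.array(d["wavelengths"]),
            spec_name=d.get("spec_name", ""),
            metadata=d.get("metadata", {}),
        )


@dataclass
class ModelMetrics:
    """R^2 and RMSE for calibration / prediction / cross-validation subsets."""

    r2_c: float = np.nan
    rmsec: float = np.nan
    r2_p: float = np.nan
    rmsep: float = np.nan
    r2_cv: float = np.nan
    rmsecv: float = np.nan

    def as_dict(self) -> dict:
        return {
            "R2_c": self.r2_c, "RMSEC": self.rmsec,
            "R2_p": self.r2_p, "RMSEP": self.rmsep,
            "R2_cv": self.r2_cv, "RMSECV": self.rmsecv,
        }


def fit_plsr(
    X: np.ndarray,
    y: np.ndarray,
    n_components: int,
    wavelengths: np.ndarray | None = None,
    spec_name: str = "",
) -> PLSRModel:
    """Fit a PLS regression and collapse it to (intercept, regression vector).

    X is centred internally (no variance scaling).  ``n_components`` may not
    exceed the rank of the centred X nor n - 1.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n, p = X.shape
    if y.size != n:
        raise ValueError("X and y lengths differ")
    rank = np.linalg.matrix_rank(X - X.mean(axis=0))
    max_ok = min(rank, n - 1, p)
    if not (1 <= n_components <= max_ok):
        raise ValueError(
            f"n_components={n_components} invalid: must be in [1, {max_ok}] "
            f"(rank {rank}, n {n}, bands {p})"
        )
    pls = PLSRegression(n_components=n_components, scale=False)
    pls.fit(X, y)
    # PLS prediction is affine in x; probe the map at 0 and the unit vectors
    # so the collapsed (b0, b) form is exact regardless of how the library
    # parameterises centring internally.
    b0 = float(np.asarray(pls.predict(np.zeros((1, p)))).ravel()[0])
    b = np.asarray(pls.predict(np.eye(p))).ravel() - b0
    return PLSRModel(
        n_components=n_components,
        b0=b0,
        b=b,
        wavelengths=None if wavelengths is None else np.asarray(wavelengths, dtype=float),
        spec_name=spec_name,
    )


def evaluate(model: PLSRModel, X: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """(R^2, RMSE) of a model on a subset.

    R^2 = 1 - SS_res / SS_tot with the subset's own mean; RMSE in response
    units (log10 mol/L here).
    """
    y = np.asarray(y, dtype=float).ravel()
    yhat = model.predict(X)
    return r2_rmse(y, yhat)


def r2_rmse(y: np.ndarray, yhat: np.ndarray) -> tuple[float, float]:
    y = np.asarray(y, dtype=float).ravel()
    yhat = np.asarray(yhat, dtype=float).ravel()
    sst = float(((y - y.mean()) ** 2).sum())
    if sst == 0:
        raise ValueError("zero-variance response; R^2 undefined")
    ssr = float(((y - yhat) ** 2).sum())
    return 1.0 - ssr / sst, float(np.sqrt(ssr / y.size))


def cross_validate(X: np.ndarray, y: np.ndarray, n_components: int) -> tuple[float, float]:
    """Leave-one-out cross-validation: (R^2_cv, RMSECV).

    Each sample is predicted by a model fitted on the remaining n - 1
    samples with the same number of latent variables (capped by the fold's
    rank when a deflated fold cannot support it).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n = X.shape[0]
    if n < 3:
        raise ValueError("LOO cross-validation needs n >= 3")
    yhat = np.empty(n)
    for k in range(n):
        keep = np.ones(n, dtype=bool)
        keep[k] = False
        Xk, yk = X[keep], y[keep]
        rank = np.linalg.matrix_rank(Xk - Xk.mean(axis=0))
        nc = min(n_components, rank, Xk.shape[0] - 1)
        model = fit_plsr(Xk, yk, nc)
        yhat[k] = model.predict(X[k])[0]
    return r2_rmse(y, yhat)


def select_components(
    X_cal: np.ndarray, y_cal: np.ndarray, max_components: int | None = None
) -> int:
    """Number of latent variables minimising RMSECV over 1..max_components.

    Ties (within 1e-12) go to the smaller model.  The default cap is
    min(20, n // 3, rank) — enough latitude for ~150-band spectra without
    letting tiny calibration sets overfit.
    """
    X_cal = np.asarray(X_cal, dtype=float)
    n = X_cal.shape[0]
    rank = np.linalg.matrix_rank(X_cal - X_cal.mean(axis=0))
    cap = min(rank, n - 2)
    if max_components is None:
        max_components = min(20, max(n // 3, 1))
    max_components = max(1, min(max_components, cap))
    rmsecvs = np.array(
        [cross_validate(X_cal, y_cal, nc)[1] for nc in range(1, max_components + 1)]
    )
    best = float(rmsecvs.min())
    return int(np.nonzero(rmsecvs <= best + 1e-12)[0][0]) + 1
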