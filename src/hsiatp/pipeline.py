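"""End-to-end orchestration: simulate -> calibrate -> extract -> train -> map.

A run is fully described by a :class:`RunConfig` (serialised into the
output directory alongside the results) and a single seed, so every
artefact in a run directory can be regenerated exactly.  The trained-model
sweep produces one metrics row per configured pre-treatment chain
(R^2 / RMSE for calibration, prediction and cross-validation) and marks
the chain with the best prediction R^2; that chain's model then drives the
pixel-wise distribution map.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import chemometrics, cube as cube_mod, mapping, preprocess, rsm
from .synthetic_data import SceneConfig, generate_scene

log = logging.getLogger("hsiatp")

__all__ = ["RunConfig", "run_pipeline", "train_chain", "sweep_chains"]


@dataclass
class RunConfig:
    """Everything a reproducible run needs.

    Either a synthetic ``scene`` is generated or ENVI inputs are read from
    ``input_dir`` (scene_raw/scene_dark/scene_white plus a
    ``reference.csv`` with sausage_id, atp_log10_molL).  ``chains`` names
    pre-treatment chains from :data:`preprocess.STANDARD_CHAINS`; the default
    sweeps all nine.
    """

    out_dir: str = "run"
    seed: int = 0
    scene: SceneConfig | None = None
    input_dir: str | None = None
    chains: tuple = tuple(preprocess.STANDARD_CHAINS)
    ks_fraction: float = 2.0 / 3.0
    max_components: int | None = None
    n_segments: int = 15
    split_level: str = "segment"     # or "sausage": replicates stay together
    cv_refit_chain: bool = False     # refit MSC state inside each LOO fold
    map_chain: str | None = None  # default: best by prediction R^2

    def validate(self) -> None:
        if (self.scene is None) == (self.input_dir is None):
            raise ValueError("exactly one of scene / input_dir must be set")
        if self.input_dir is not None:
            root = Path(self.input_dir)
            for name in ("scene_raw.hdr", "scene_dark.hdr", "scene_white.hdr", "reference.csv"):
                if not (root / name).exists():
                    raise FileNotFoundError(f"missing input {root / name}")
        unknown = [c for c in self.chains if c not in preprocess.STANDARD_CHAINS]
        if unknown:
            raise ValueError(f"unknown pre-treatment chain(s) {unknown}")

    def to_yaml(self, path: str | Path) -> None:
        d = dataclasses.asdict(self)
        if self.scene is not None:
            d["scene"] = dataclasses.asdict(self.scene)
            d["scene"]["atp_values"] = list(d["scene"]["atp_values"])
        d["chains"] = list(d["chains"])
        Path(path).write_text(yaml.safe_dump(d, sort_keys=False))

    @staticmethod
    def from_yaml(path: str | Path) -> "RunConfig":
        d = yaml.safe_load(Path(path).read_text())
        if d.get("scene") is not None:
            scene = d["scene"]
            scene["atp_values"] = tuple(scene["atp_values"])
            d["scene"] = SceneConfig(**scene)
        if "chains" in d:
            d["chains"] = tuple(d["chains"])
        return RunConfig(**d)


def _grouped_split(
    X_t: np.ndarray, groups: np.ndarray, fraction: float
) -> chemometrics.SplitResult:
    """Kennard-Stone over group-mean spectra, expanded back to row indices.

    Keeps all replicate rows of a sausage on one side of the split, so the
    prediction set contains only unseen sausages.
    """
    ids = np.unique(groups)
    means = np.vstack([X_t[groups == g].mean(axis=0) for g in ids])
    gsplit = chemometrics.kennard_stone(means, fraction)
    cal_ids = set(ids[gsplit.calibration].tolist())
    cal = np.nonzero([g in cal_ids for g in groups])[0]
    pred = np.nonzero([g not in cal_ids for g in groups])[0]
    return chemometrics.SplitResult(calibration=cal, prediction=pred)


def _loo_with_chain_refit(
    spec: preprocess.PreprocessSpec,
    spectra_cal: np.ndarray,
    y_cal: np.ndarray,
    wavelengths: np.ndarray,
    n_comp: int,
) -> tuple[float, float]:
    """Leave-one-out CV refitting the whole pre-treatment chain per fold.

    Stricter than reusing the calibration-fitted matrix: stateful steps
    (the MSC reference) are relearned without the held-out row.
    """
    n = len(y_cal)
    yhat = np.empty(n)
    for k in range(n):
        keep = np.ones(n, dtype=bool)
        keep[k] = False
        pp_k = preprocess.Preprocessor(spec).fit(spectra_cal[keep], wavelengths)
        Xk = pp_k.transform(spectra_cal[keep])
        rank = np.linalg.matrix_rank(Xk - Xk.mean(axis=0))
        model_k = chemometrics.fit_plsr(Xk, y_cal[keep], min(n_comp, rank, n - 2))
        yhat[k] = model_k.predict(pp_k.transform(spectra_cal[k : k + 1]))[0]
    return chemometrics.r2_rmse(y_cal, yhat)


def train_chain(
    spec: preprocess.PreprocessSpec,
    spectra: np.ndarray,
    atp: np.ndarray,
    wavelengths: np.ndarray,
    ks_fraction: float = 2.0 / 3.0,
    max_components: int | None = None,
    split_level: str = "segment",
    groups: np.ndarray | None = None,
    cv_refit_chain: bool = False,
) -> tuple[chemometrics.PLSRModel, chemometrics.ModelMetrics, preprocess.Preprocessor,
           chemometrics.SplitResult]:
    """Fit one pre-treatment chain + PLSR model with a Kennard-Stone split.

    The split runs on pre-treated spectra (a provisional chain fitted on
    all rows supplies any MSC reference for splitting only); the modelling
    chain is then refit on the calibration subset alone, so no prediction
    information enters the fitted state.  Latent variables are chosen by
    leave-one-out cross-validation on the calibration set.

    ``split_level='segment'`` (default) splits individual cross-section
    rows, mirroring how the calibration population is expanded;
    ``'sausage'`` keeps each sausage's replicates together (requires
    ``groups``, one id per row) for a split with no replicate leakage.
    ``cv_refit_chain=True`` refits stateful pre-treatment steps inside
    every LOO fold instead of reusing the calibration-fitted matrix.
    """
    spectra = np.asarray(spectra, dtype=float)
    atp = np.asarray(atp, dtype=float).ravel()
    provisional = preprocess.Preprocessor(spec).fit(spectra, wavelengths)
    X_prov = provisional.transform(spectra)
    if split_level == "segment":
        split = chemometrics.kennard_stone(X_prov, ks_fraction)
    elif split_level == "sausage":
        if groups is None:
            raise ValueError("split_level='sausage' requires per-row group ids")
        split = _grouped_split(X_prov, np.asarray(groups), ks_fraction)
    else:
        raise ValueError(f"unknown split_level {split_level!r}")
    pp = preprocess.Preprocessor(spec).fit(spectra[split.calibration], wavelengths)
    X_cal = pp.transform(spectra[split.calibration])
    X_pred = pp.transform(spectra[split.prediction])
    y_cal, y_pred = atp[split.calibration], atp[split.prediction]
    n_comp = chemometrics.select_components(X_cal, y_cal, max_components)
    model = chemometrics.fit_plsr(
        X_cal, y_cal, n_comp, wavelengths=pp.output_wavelengths_, spec_name=spec.name
    )
    metrics = chemometrics.ModelMetrics()
    metrics.r2_c, metrics.rmsec = chemometrics.evaluate(model, X_cal, y_cal)
    metrics.r2_p, metrics.rmsep = chemometrics.evaluate(model, X_pred, y_pred)
    if cv_refit_chain:
        metrics.r2_cv, metrics.rmsecv = _loo_with_chain_refit(
            spec, spectra[split.calibration], y_cal, wavelengths, n_comp
        )
    else:
        metrics.r2_cv, metrics.rmsecv = chemometrics.cross_validate(X_cal, y_cal, n_comp)
    model.metadata.update(
        {"n_calibration": len(y_cal), "n_prediction": len(y_pred), **metrics.as_dict()}
    )
    return model, metrics, pp, split


def sweep_chains(
    chain_names,
    spectra: np.ndarray,
    atp: np.ndarray,
    wavelengths: np.ndarray,
    ks_fraction: float = 2.0 / 3.0,
    max_components: int | None = None,
    split_level: str = "segment",
    groups: np.ndarray | None = None,
    cv_refit_chain: bool = False,
):
    """Train every named chain; returns (metrics table, {name: (model, pp)})."""
    rows = []
    fitted = {}
    for name in chain_names:
        spec = preprocess.STANDARD_CHAINS[name]
        model, metrics, pp, _ = train_chain(
            spec, spectra, atp, wavelengths, ks_fraction, max_components,
            split_level=split_level, groups=groups, cv_refit_chain=cv_refit_chain,
        )
        rows.append({"chain": name, "n_components": model.n_components, **metrics.as_dict()})
        fitted[name] = (model, pp)
    table = pd.DataFrame(rows)
    table["best"] = table["R2_p"] == table["R2_p"].max()
    return table, fitted


def run_pipeline(config: RunConfig) -> Path:
    """Execute all stages; returns the run directory.

    Deterministic given the config (which includes the seed): two runs with
    the same config produce byte-identical metrics tables.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)
    config.to_yaml(out / "config.yaml")
    t_start = time.perf_counter()

    def stage(name):
        log.info("stage %-10s t=%.2fs", name, time.perf_counter() - t_start)

    try:
        stage("acquire")
        if config.scene is not None:
            scene_cfg = dataclasses.replace(config.scene, seed=config.seed)
            raw, dark, white, truth = generate_scene(scene_cfg)
            reference = truth.atp_values
        else:
            root = Path(config.input_dir)
            raw = cube_mod.read_envi(root / "scene_raw")
            dark = cube_mod.read_envi(root / "scene_dark").data
            white = cube_mod.read_envi(root / "scene_white").data
            ref_df = pd.read_csv(root / "reference.csv")
            reference = dict(zip(ref_df["sausage_id"].astype(int), ref_df["atp_log10_molL"]))
            truth = None

        stage("calibrate")
        refl = cube_mod.calibrate(raw, cube_mod.ReferenceFrames(dark=dark, white=white))

        stage("segment")
        mask = cube_mod.segment_foreground(refl)
        labels = cube_mod.partition_segments(mask, config.n_segments)

        stage("extract")
        table = cube_mod.extract_mean_spectra(refl, labels, reference=reference)
        table.to_csv(out / "spectra.csv", index=False)
        X, wavelengths = cube_mod.spectra_matrix(table)
        atp = table["atp_log10_molL"].to_numpy()

        stage("train")
        metrics, fitted = sweep_chains(
            config.chains, X, atp, wavelengths, config.ks_fraction,
            config.max_components, split_level=config.split_level,
            groups=table["sausage_id"].to_numpy(), cv_refit_chain=config.cv_refit_chain,
        )
        metrics.to_csv(out / "metrics.csv", index=False)
        best = config.map_chain or metrics.loc[metrics["best"], "chain"].iloc[0]
        model, pp = fitted[best]
        model.to_json(out / "model_best.json")
        log.info("best chain by R2_p: %s", best)

        stage("map")
        atp_range = (float(np.min(list(reference.values()))),
                     float(np.max(list(reference.values()))))
        atp_map = mapping.predict_pixels(refl, mask, pp, model, scale_limits=atp_range)
        rgb = cube_mod.reconstruct_rgb(refl, mask)
        mapping.render_map(atp_map, rgb, out / "distribution_map.png")
        mapping.export_map(atp_map, out / "distribution_map")

        stage("done")
    except Exception as err:  # annotate with run context, then re-raise
        log.error("pipeline failed: %s", err)
        raise
    finally:
        log.removeHandler(handler)
        handler.close()
    return out


def run_rsm(out_dir: str | Path, table: pd.DataFrame | None = None) -> Path:
    """Fit the response-surface model (packaged design by default), export tables."""
    out_dir = Path(out_dir)
    design = rsm.build_design(table if table is not None else rsm.load_packaged_design())
    model = rsm.fit_quadratic(design)
    rsm.export_tables(model, out_dir)
    summary = {
        "r_squared_pct": 100.0 * model.r_squared,
        "sse": model.sse,
        "sst": model.sst,
        "constant_coded": float(model.coefficients[0]),
    }
    (out_dir / "rsm_summary.json").write_text(json.dumps(summary, indent=1))
    return out_dir
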