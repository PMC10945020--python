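import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import hsiatp
from hsiatp.cube import ReferenceFrames, spectra_matrix
from hsiatp.pipeline import train_chain
from hsiatp.preprocess import STANDARD_CHAINS
from hsiatp.synthetic_data import SceneConfig, generate_scene, recovery_benchmark_config

settings.register_profile(
    "suite",
    deadline=None,
    derandomize=True,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def noise_free_scene():
    """Two-sausage scene with every noise term off: exact oracles apply."""
    cfg = SceneConfig(
        image_height=60,
        image_width=90,
        n_sausages=2,
        atp_values=(-9.33, -4.37),
        scatter_multiplicative_sd=0.0,
        baseline_offset_sd=0.0,
        noise_sd=0.0,
        seed=7,
    )
    return generate_scene(cfg)


@pytest.fixture(scope="session")
def noisy_scene():
    """Two-sausage scene under the default (scatter-dominant) noise."""
    cfg = SceneConfig(
        image_height=60, image_width=90, n_sausages=2, atp_values=(-8.66, -4.37), seed=3
    )
    return generate_scene(cfg)


def _run_imaging(scene):
    raw, dark, white, truth = scene
    refl = hsiatp.calibrate(raw, ReferenceFrames(dark=dark, white=white))
    mask = hsiatp.segment_foreground(refl)
    labels = hsiatp.partition_segments(mask)
    table = hsiatp.extract_mean_spectra(refl, labels, reference=truth.atp_values)
    X, wavelengths = spectra_matrix(table)
    return {
        "truth": truth,
        "reflectance": refl,
        "mask": mask,
        "labels": labels,
        "table": table,
        "X": X,
        "wavelengths": wavelengths,
        "atp": table["atp_log10_molL"].to_numpy(),
    }


@pytest.fixture(scope="session")
def noise_free_run(noise_free_scene):
    return _run_imaging(noise_free_scene)


@pytest.fixture(scope="session")
def benchmark_run():
    """The ten-sausage parameter-recovery scene, imaged and trained.

    Trains the raw-reflectance and absorbance->SNV->1st-derivative chains
    once for the whole session; several tests compare their metrics.
    """
    scene = generate_scene(recovery_benchmark_config(seed=0))
    run = _run_imaging(scene)
    run["trained"] = {}
    for name in ("raw_reflectance", "snv_deriv1"):
        model, metrics, pp, split = train_chain(
            STANDARD_CHAINS[name], run["X"], run["atp"], run["wavelengths"], max_components=10
        )
        run["trained"][name] = {"model": model, "metrics": metrics, "pp": pp, "split": split}
    return run


@pytest.fixture(scope="session")
def fitted_rsm():
    design = hsiatp.build_design(hsiatp.load_packaged_design())
    return hsiatp.fit_quadratic(design)


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
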