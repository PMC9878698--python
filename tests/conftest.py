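import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from phenotray import synthetic as syn
from phenotray.imaging import TrayPipelineConfig

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


def tray_pipeline_config(spec, **overrides):
    kwargs = dict(
        tray_filter=syn.reference_tray_filter(spec),
        plant_filter=syn.reference_plant_filter(spec),
        rows=spec.rows,
        cols=spec.cols,
        cell_px=spec.cell_px,
    )
    kwargs.update(overrides)
    return TrayPipelineConfig(**kwargs)


@pytest.fixture(scope="session")
def small_tray():
    """Unwarped noiseless 12x12 tray with rosettes in every cell."""
    rng = np.random.default_rng(101)
    spec = syn.TraySpec(cell_px=40)
    rosettes = syn.random_rosettes(spec, rng, area_range=(50, 700))
    image, manifest = syn.render_tray(spec, rosettes)
    return spec, rosettes, image, manifest


@pytest.fixture(scope="session")
def warped_tray():
    """Projectively warped noisy tray with rosettes in every cell."""
    rng = np.random.default_rng(202)
    base = syn.TraySpec(cell_px=40, noise_sd=2.0, rng_seed=7)
    corners = syn.corner_warp(base, rng, max_frac=0.05)
    spec = syn.TraySpec(cell_px=40, noise_sd=2.0, rng_seed=7, warp=corners)
    rosettes = syn.random_rosettes(spec, rng, area_range=(50, 700))
    image, manifest = syn.render_tray(spec, rosettes)
    return spec, rosettes, image, manifest
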