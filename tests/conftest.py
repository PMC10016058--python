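import numpy as np
import pytest

from tonomap import pipeline, synthetic
from tonomap.registration import ReferenceMarks


@pytest.fixture
def rng():
    return np.random.default_rng(0)


def gaussian_bump(shape, center, sigma_px, amplitude=1.0):
    """Sampled isotropic Gaussian, peak ``amplitude`` at ``center`` (x, y)."""
    ys, xs = np.mgrid[: shape[0], : shape[1]]
    return amplitude * np.exp(
        -((xs - center[0]) ** 2 + (ys - center[1]) ** 2) / (2 * sigma_px**2)
    )


@pytest.fixture(scope="session")
def noisy_session():
    """One default-condition synthetic session, processed end to end."""
    layouts = synthetic.sample_population_layouts(
        synthetic.PopulationParams(), 1, np.random.default_rng(0)
    )
    layout = layouts[0]
    config = synthetic.AcquisitionConfig()
    rng = np.random.default_rng(1)
    maps = pipeline.process_layout_maps(layout, config, rng)
    placement = synthetic.place_reference_marks(layout, 100.0, rng)
    marks = ReferenceMarks(pixels=placement.pixels, bldist_mm=layout.bldist_mm)
    analysis = pipeline.analyze_session(maps, marks)
    return layout, config, analysis


@pytest.fixture(scope="session")
def recovery_run_50():
    """The 50-mouse default-condition recovery study (noise and 100-um
    human-error jitter on)."""
    return pipeline.run_synthetic_population(50, seed=0)


@pytest.fixture(scope="session")
def identity_transform():
    """theta = 0, 10 um/px, bregma at pixel (0, 0)."""
    from tonomap.coords import StereotaxicTransform

    return StereotaxicTransform(
        theta_rad=0.0, scale_ap_um=10.0, scale_dv_um=10.0, bregma_px=np.zeros(2)
    )
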