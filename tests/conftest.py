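import numpy as np
import pytest

from mitofoci.synthetic import CohortSimParams, simulate_cohort


ZERO_NOISE = {"DAPI": 0.0, "SDHA": 0.0, "MTCOI": 0.0}


@pytest.fixture(scope="session")
def zero_noise_cohort():
    """A small noise-free cohort with mixed perinuclear enrichment."""
    params = CohortSimParams(
        n_fibers=12, enrichment_rho=0.5, seed=42, noise_sd=dict(ZERO_NOISE)
    )
    return simulate_cohort(params)


@pytest.fixture()
def circle_section():
    """A plain circular fiber on a uniform raster (no nuclei, no focus)."""
    from mitofoci.io import FiberSection

    theta = np.linspace(0, 2 * np.pi, 64, endpoint=False)
    boundary = np.column_stack([64 + 40 * np.cos(theta), 64 + 40 * np.sin(theta)])
    channels = {
        ch: np.full((128, 128), v, dtype=np.uint16)
        for ch, v in (("DAPI", 40), ("SDHA", 100), ("MTCOI", 100))
    }
    return FiberSection("P1", "S1", "C1", boundary, channels)
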