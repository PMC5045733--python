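import numpy as np
import pytest

from secsaxs.peak_shapes import PeakKind, PeakModel
from secsaxs.synthetic import (
    SpeciesSpec,
    SyntheticSpec,
    aldolase_like_spec,
    generate,
    generate_blanks,
)

TEST_SEED = 20260929


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(TEST_SEED)


@pytest.fixture(scope="session")
def demo_spec():
    """The four-species EMG+GMG demo layout (1% noise, no fouling)."""
    return aldolase_like_spec(seed=TEST_SEED)


@pytest.fixture(scope="session")
def demo_data(demo_spec):
    return generate(demo_spec)


@pytest.fixture(scope="session")
def fouled_single_species():
    """One Gaussian species with fouling gamma=2e-3 plus matching blanks."""
    q = np.linspace(0.004, 0.05, 40)
    species = [
        SpeciesSpec(
            rg=20.0, i0=10.0, conc_area=0.0,
            peak=PeakModel(PeakKind.GAUSS, 500.0, 150.0, 20.0),
        )
    ]
    spec = SyntheticSpec(
        q=q, n_frames=400, species=species, gamma=2e-3,
        noise_fraction=0.01, noise_floor=5e-4, n_buffer_frames=50,
        seed=TEST_SEED,
    )
    ds, truth = generate(spec)
    blanks = generate_blanks(spec)
    return spec, ds, truth, blanks


@pytest.fixture(scope="session")
def fitted_demo_model(demo_data):
    """Global EMG+GMG fit of the demo surface, shared across tests.

    Runs the full interactive protocol: single-chromatogram fit, linear
    amplitude initialisation on every third q, variable-projection global
    fit with a deterministic grid of distortion starts, then
    amplitude-only extension to all q.
    """
    from secsaxs import decomposition as dc

    ds, truth = demo_data
    peaks, report = dc.fit_single(
        ds.chromatogram(2), 4, PeakKind.EMG_GMG,
        init_centers=[245.0, 320.0, 395.0, 500.0], init_distortion=30.0,
    )
    q_indices = np.arange(0, ds.n_q, 3)[:40]
    model0 = dc.init_global(peaks, ds, q_indices=q_indices)
    starts = [(d1, d2) for d1 in (20.0, 50.0, 90.0) for d2 in (20.0, 50.0, 90.0)]
    model, fit_report = dc.global_fit(model0, ds, distortion_starts=starts)
    full = dc.fit_all_amplitudes(model, ds)
    return model, full, fit_report
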