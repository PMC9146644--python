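import numpy as np
import pytest

import prostasm as pa


@pytest.fixture(scope="session")
def ball_mask():
    """Analytic ball, radius 10 mm, on an anisotropic grid with 3 mm slices."""
    shape = (40, 40, 14)
    spacing = (1.0, 1.0, 3.0)
    grids = np.meshgrid(*[np.arange(s) for s in shape], indexing="ij")
    center = [(s - 1) / 2 * sp for s, sp in zip(shape, spacing)]
    d2 = sum(((g * sp - c) ** 2) for g, sp, c in zip(grids, spacing, center))
    return pa.BinaryMask(d2 <= 10.0**2, spacing)


@pytest.fixture(scope="session")
def sphere_mask_iso():
    """Ball radius 20 mm phantom mask resampled to the 0.5 mm working grid."""
    spec = pa.PhantomSpec(base_radii=(20, 20, 20), noise_sd=0, bias_range=(1, 1), seed=0)
    _, mask = pa.make_phantom(spec)
    return pa.resample_isotropic(mask, 0.5, mode="nearest")


@pytest.fixture(scope="session")
def default_cohort():
    """Shared phantom cohort: 12 members under the default study conditions."""
    return pa.make_cohort(12, seed=42)


@pytest.fixture(scope="session")
def trained_archive(default_cohort):
    """Shape + appearance archive built from the first 9 cohort members."""
    train = [(v, m) for v, m, _ in default_cohort[:9]]
    return pa.build_models(train, pa.PipelineConfig())
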