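import numpy as np
import pytest

from dceflow.protocol import AcquisitionProtocol, BiexponentialBolus, generate_aif
from dceflow.phantom import PhantomSpec, TumorGeometry


@pytest.fixture(scope="session")
def protocol():
    return AcquisitionProtocol()


@pytest.fixture(scope="session")
def aif(protocol):
    return generate_aif(protocol)


@pytest.fixture(scope="session")
def small_phantom_spec():
    """Noiseless lesion on a coarse grid; quick to generate and fit."""
    return PhantomSpec(
        grid_shape=(14, 14, 12),
        voxel_size_mm=(2.5, 2.5, 2.5),
        tumor=TumorGeometry.sphere((17.5, 17.5, 15.0), 6.0),
        ktrans_mean=0.3,
        ktrans_spatial_sd=0.08,
        ktrans_correlation_length=3.0,
        noise_sd=0.0,
        seed=42,
    )


def sphere_domain(radius_mm, margin_mm, spacing_mm, spherical_boundary=False):
    """Voxelized spherical tumor centered in a cubic extended domain."""
    from dceflow.flow import SimulationDomain

    half = int(np.ceil((radius_mm + margin_mm) / spacing_mm)) + 1
    n = 2 * half + 1
    idx = (np.indices((n, n, n)) - half) * spacing_mm
    r = np.sqrt((idx**2).sum(axis=0))
    labels = (r <= radius_mm).astype(np.uint8)
    fixed = (r >= radius_mm + margin_mm) if spherical_boundary else None
    dom = SimulationDomain(labels=labels, spacing_mm=spacing_mm, fixed_mask=fixed)
    return dom, r, half
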