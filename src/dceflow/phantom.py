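"""Digital DCE phantoms with known ground-truth pharmacokinetic maps.

A phantom is a rectangular grid of (possibly anisotropic) voxels holding an
ellipsoidal "tumor" whose Ktrans field is a spatially correlated Gaussian
random field; v_e and v_p are uniform inside the lesion.  The 4D signal is
synthesized by running the extended Tofts forward model voxelwise and
converting concentration to SPGR signal, optionally with measurement noise.
Everything is reproducible from the spec's seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.ndimage import gaussian_filter

from .protocol import AcquisitionProtocol, AIFCurve, BiexponentialBolus, generate_aif
from .spgr import concentration_to_signal
from .tofts import forward_etm, forward_etm_many

__all__ = ["TumorGeometry", "PhantomSpec", "Phantom", "generate_phantom", "ground_truth_maps"]

# quiescent background tissue (intact blood-brain barrier): negligible
# leakage, small plasma fraction
BACKGROUND_KTRANS = 0.002
BACKGROUND_VE = 0.2
BACKGROUND_VP = 0.01


@dataclass(frozen=True)
class TumorGeometry:
    """Ellipsoid lesion: center and semi-axes in mm (grid coordinates)."""

    center_mm: tuple[float, float, float]
    radii_mm: tuple[float, float, float]

    def __post_init__(self) -> None:
        if any(r <= 0 for r in self.radii_mm):
            raise ValueError("radii must be positive")

    @classmethod
    def sphere(cls, center_mm, radius_mm) -> "TumorGeometry":
        return cls(tuple(center_mm), (radius_mm,) * 3)


@dataclass(frozen=True)
class PhantomSpec:
    """Full recipe for one synthetic lesion.

    ``ktrans_mean`` / ``ktrans_spatial_sd`` (1/min) set the level and
    heterogeneity of the tumor Ktrans field, spatially correlated over
    ``ktrans_correlation_length`` mm.  ``necrotic_core_fraction`` carves a
    concentric core (radius as a fraction of the lesion radii) whose Ktrans
    is multiplied by ``necrotic_core_level`` — a poorly perfused center.
    ``noise_sd`` is the SD of additive Gaussian noise on the magnitude
    signal (``rician=True`` makes it Rician instead).
    """

    grid_shape: tuple[int, int, int] = (24, 24, 12)
    voxel_size_mm: tuple[float, float, float] = (2.0, 2.0, 5.0)
    tumor: TumorGeometry = field(
        default_factory=lambda: TumorGeometry.sphere((24.0, 24.0, 30.0), 6.0)
    )
    ktrans_mean: float = 0.3
    ktrans_spatial_sd: float = 0.1
    ktrans_correlation_length: float = 3.0
    ve_mean: float = 0.3
    vp_mean: float = 0.03
    necrotic_core_fraction: float = 0.0
    necrotic_core_level: float = 1.0
    noise_sd: float = 0.0
    rician: bool = False
    m0: float = 1000.0
    t10: float | None = None
    protocol: AcquisitionProtocol = field(default_factory=AcquisitionProtocol)
    bolus: BiexponentialBolus = field(default_factory=BiexponentialBolus)
    seed: int = 0
    # the random field has its own seed so a rescan of the same lesion
    # (same vasculature, fresh measurement noise) can share it; defaults to
    # ``seed`` when None
    field_seed: int | None = None

    def __post_init__(self) -> None:
        if not (0.0 <= self.ktrans_mean <= 5.0):
            raise ValueError("ktrans_mean must lie in [0, 5] 1/min")
        if not (0.0 <= self.ve_mean <= 1.0 and 0.0 <= self.vp_mean <= 1.0):
            raise ValueError("ve_mean and vp_mean must lie in [0, 1]")
        if self.ktrans_spatial_sd < 0 or self.noise_sd < 0:
            raise ValueError("spreads must be non-negative")
        if not (0.0 <= self.necrotic_core_fraction < 1.0):
            raise ValueError("necrotic_core_fraction must lie in [0, 1)")
        if self.necrotic_core_level < 0:
            raise ValueError("necrotic_core_level must be >= 0")
        # lesion must fit strictly inside the grid
        extent = np.array(self.grid_shape) * np.array(self.voxel_size_mm)
        c = np.array(self.tumor.center_mm)
        r = np.array(self.tumor.radii_mm)
        if np.any(c - r <= 0) or np.any(c + r >= extent):
            raise ValueError("tumor does not fit strictly inside the grid")

    def replace(self, **kwargs) -> "PhantomSpec":
        return replace(self, **kwargs)

    @property
    def affine(self) -> np.ndarray:
        aff = np.diag(list(self.voxel_size_mm) + [1.0])
        return aff


@dataclass
class Phantom:
    """Generated phantom: 4D signal plus the ground truth that made it."""

    signal: np.ndarray  # (x, y, z, t)
    mask: np.ndarray  # bool, lesion voxels
    ktrans: np.ndarray  # 1/min, ground truth
    ve: np.ndarray
    vp: np.ndarray
    aif: AIFCurve
    affine: np.ndarray
    spec: PhantomSpec

    @property
    def times(self) -> np.ndarray:
        return self.aif.times


def _radial_coordinate(spec: PhantomSpec) -> np.ndarray:
    """Normalized ellipsoidal radius (1.0 on the lesion surface) per voxel."""
    idx = np.indices(spec.grid_shape, dtype=float)
    # voxel centers in mm
    for ax in range(3):
        idx[ax] = (idx[ax] + 0.5) * spec.voxel_size_mm[ax]
    c = np.array(spec.tumor.center_mm).reshape(3, 1, 1, 1)
    r = np.array(spec.tumor.radii_mm).reshape(3, 1, 1, 1)
    return np.sqrt(np.sum(((idx - c) / r) ** 2, axis=0))


def correlated_field(
    shape: tuple[int, int, int],
    voxel_size_mm: tuple[float, float, float],
    correlation_length_mm: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Zero-mean, unit-variance Gaussian random field.

    White noise smoothed with a Gaussian kernel of width
    ``correlation_length_mm`` (per-axis sigma in voxels), then restandardized
    so the marginal SD is 1 regardless of the smoothing.
    """
    if correlation_length_mm <= 0:
        return rng.standard_normal(shape)
    sigma = [correlation_length_mm / vs for vs in voxel_size_mm]
    # generate on a padded grid and crop so edge voxels have the same
    # (stationary) statistics as the interior; standardize by the exact
    # discrete kernel norm rather than the sample SD
    pad = [int(np.ceil(4 * s)) + 1 for s in sigma]
    padded = tuple(n + 2 * p for n, p in zip(shape, pad))
    smooth = gaussian_filter(rng.standard_normal(padded), sigma=sigma,
                             mode="constant")
    crop = tuple(slice(p, p + n) for p, n in zip(pad, shape))
    norm = 1.0
    for s in sigma:
        impulse = np.zeros(8 * int(np.ceil(4 * s)) + 9)
        impulse[impulse.size // 2] = 1.0
        k = gaussian_filter(impulse, sigma=s, mode="constant")
        norm *= float(np.sum(k**2))
    return smooth[crop] / np.sqrt(norm)


def ground_truth_maps(spec: PhantomSpec):
    """Lesion mask and ground-truth (Ktrans, v_e, v_p) maps of a spec.

    The tumor Ktrans field is ``mean + sd * G`` with G a unit-variance
    correlated Gaussian field, optionally multiplied by the necrotic-core
    factor, and clipped to the physiologic box [0, 5] 1/min.  Voxels outside
    the lesion get quiescent background values.
    """
    field_seed = spec.field_seed if spec.field_seed is not None else spec.seed
    field_rng = np.random.default_rng(field_seed)
    rho = _radial_coordinate(spec)
    mask = rho <= 1.0
    if not mask.any():
        raise ValueError("degenerate geometry: no voxel center falls inside the lesion")

    g = correlated_field(spec.grid_shape, spec.voxel_size_mm,
                         spec.ktrans_correlation_length, field_rng)
    ktrans = np.full(spec.grid_shape, BACKGROUND_KTRANS)
    kt_tumor = spec.ktrans_mean + spec.ktrans_spatial_sd * g
    if spec.necrotic_core_fraction > 0:
        core = rho <= spec.necrotic_core_fraction
        kt_tumor = np.where(core, kt_tumor * spec.necrotic_core_level, kt_tumor)
    ktrans[mask] = np.clip(kt_tumor[mask], 0.0, 5.0)

    ve = np.full(spec.grid_shape, BACKGROUND_VE)
    vp = np.full(spec.grid_shape, BACKGROUND_VP)
    ve[mask] = spec.ve_mean
    vp[mask] = spec.vp_mean
    return mask, ktrans, ve, vp


def generate_phantom(spec: PhantomSpec) -> Phantom:
    """Build the 4D DCE signal volume and its ground-truth maps.

    Identical specs (including seed) produce bit-identical phantoms.
    """
    noise_rng = np.random.default_rng(spec.seed)
    mask, ktrans, ve, vp = ground_truth_maps(spec)
    aif = generate_aif(spec.protocol, spec.bolus)
    t10 = spec.t10 if spec.t10 is not None else spec.protocol.t10_default

    # all background voxels share one parameter triple -> one curve
    conc = np.empty(spec.grid_shape + (len(aif),))
    conc[~mask] = forward_etm(BACKGROUND_KTRANS, BACKGROUND_VE, BACKGROUND_VP, aif)
    conc[mask] = forward_etm_many(ktrans[mask], ve[mask], vp[mask], aif)
    signal = concentration_to_signal(conc, spec.protocol, t10, m0=spec.m0)

    if spec.noise_sd > 0:
        if spec.rician:
            re_ = signal + noise_rng.normal(0.0, spec.noise_sd, signal.shape)
            im_ = noise_rng.normal(0.0, spec.noise_sd, signal.shape)
            signal = np.sqrt(re_**2 + im_**2)
        else:
            signal = signal + noise_rng.normal(0.0, spec.noise_sd, signal.shape)

    return Phantom(
        signal=signal, mask=mask, ktrans=ktrans, ve=ve, vp=vp,
        aif=aif, affine=spec.affine, spec=spec,
    )
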