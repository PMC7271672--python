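"""Steady-state interstitial fluid pressure (IFP) and velocity (IFV).

The interstitium is a porous medium: bulk flow obeys Darcy's law
``u = -K_H grad(p)`` and, at steady state with zero lymphatic clearance
(brain), mass balance gives a linear reaction-diffusion equation for the
interstitial pressure p:

    -div(K_H grad p) + c p = c P_eff,      c = (Ktrans/<Ktrans>) * L_p * S/V

Fluid filters out of the microvasculature at a rate proportional to the
Starling driving pressure, lumped here into the single effective pressure
P_eff; the local Ktrans map, normalized by its tumor mean, modulates the
filtration source to reflect heterogeneous vascular leakiness.  Pressure is
clamped to a Dirichlet value (zero, normal brain) on the outer boundary of
an extended domain of normal tissue surrounding the lesion.

Discretization: 7-point finite-volume stencil on an isotropic grid with
harmonic averaging of K_H across voxel faces (flux continuity at the
tumor/normal interface).  The system is symmetric positive definite and is
solved directly (sparse LU) for small problems or by Jacobi-preconditioned
conjugate gradients for large ones.

The characteristic pressure decay length is sqrt(K_H / (L_p S/V)); with the
default tumor parameters this is about 6 mm, so lesions much larger than
that plateau at P_eff in their interior.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla
from scipy.ndimage import zoom as ndzoom

__all__ = [
    "TissueProperties",
    "NORMAL_TISSUE",
    "TUMOR_TISSUE",
    "FlowParameters",
    "SimulationDomain",
    "build_domain",
    "make_ktrans_ratio",
    "FlowSystem",
    "assemble_system",
    "PressureField",
    "VelocityField",
    "solve_ifp",
    "compute_ifv",
    "conservation_balance",
    "InterstitialFlowModel",
    "FlowResults",
]

NORMAL_LABEL = 0
TUMOR_LABEL = 1


@dataclass(frozen=True)
class TissueProperties:
    """Physical constants of one tissue class (SI units).

    k_h : interstitial hydraulic conductivity, m^2/(Pa s)
    l_p : vascular wall hydraulic conductivity, m/(Pa s)
    s_over_v : microvascular exchange area per unit volume, 1/m
    p_eff : lumped Starling effective pressure p_V - sigma_T (pi_V - pi_i), Pa

    The lymphatic clearance term is identically zero (no brain lymphatics),
    so it carries no field here.
    """

    k_h: float
    l_p: float
    s_over_v: float
    p_eff: float

    def __post_init__(self) -> None:
        if self.k_h <= 0 or self.l_p <= 0 or self.s_over_v <= 0:
            raise ValueError("conductivities and S/V must be positive")
        if self.p_eff < 0:
            raise ValueError("effective pressure must be >= 0")

    @property
    def filtration_coefficient(self) -> float:
        """c = L_p S/V in 1/(Pa s)."""
        return self.l_p * self.s_over_v

    @property
    def decay_length_m(self) -> float:
        """sqrt(K_H / (L_p S/V)): e-folding length of pressure variations."""
        return float(np.sqrt(self.k_h / self.filtration_coefficient))


# literature parameter set for brain tissue and brain metastases
NORMAL_TISSUE = TissueProperties(k_h=5.65e-15, l_p=8e-14, s_over_v=1.0e4, p_eff=400.0)
TUMOR_TISSUE = TissueProperties(k_h=4.9e-13, l_p=6.4e-13, s_over_v=2.0e4, p_eff=1550.0)


@dataclass(frozen=True)
class FlowParameters:
    """Per-tissue physical parameters plus source-activation switches.

    ``source_in_normal`` keeps the normal-tissue filtration source active in
    the extended domain (both tissues carry literature values, so both are
    sourced by default); turning it off sources only the tumor.
    """

    normal: TissueProperties = NORMAL_TISSUE
    tumor: TissueProperties = TUMOR_TISSUE
    source_in_normal: bool = True
    source_in_tumor: bool = True

    def replace(self, **kwargs) -> "FlowParameters":
        return replace(self, **kwargs)


@dataclass
class SimulationDomain:
    """Isotropic simulation grid: tissue labels plus the Ktrans source ratio.

    ``labels`` is 0 for normal tissue, 1 for tumor; ``spacing_mm`` is the
    (equal) voxel edge length; ``ktrans_ratio`` is Ktrans normalized by its
    tumor mean (1 in normal tissue), attached by :func:`make_ktrans_ratio`.
    The tumor must sit strictly inside the grid and the outer voxel layer is
    the Dirichlet boundary at ``boundary_pressure``.
    """

    labels: np.ndarray
    spacing_mm: float
    boundary_pressure: float = 0.0
    ktrans_ratio: np.ndarray | None = None
    # extra voxels clamped to boundary_pressure (beyond the outer layer),
    # for non-cubic extended domains such as a spherical shell
    fixed_mask: np.ndarray | None = None
    # reslice bookkeeping so parameter maps can follow the mask's transform
    zoom_factors: tuple[float, float, float] | None = None
    pad_voxels: int = 0
    core_shape: tuple[int, int, int] | None = None

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3:
            raise ValueError("labels must be a 3D volume")
        if self.spacing_mm <= 0:
            raise ValueError("spacing must be positive")
        tumor = self.labels == TUMOR_LABEL
        if not tumor.any():
            raise ValueError("domain contains no tumor voxels")
        # tumor strictly interior: none on the outer voxel layer
        for ax in range(3):
            if tumor.take(0, axis=ax).any() or tumor.take(-1, axis=ax).any():
                raise ValueError("tumor touches the domain boundary")
        if self.fixed_mask is not None:
            fm = np.asarray(self.fixed_mask, dtype=bool)
            if fm.shape != self.labels.shape:
                raise ValueError("fixed_mask shape must match labels")
            if (fm & tumor).any():
                raise ValueError("tumor voxels cannot be Dirichlet-fixed")
            self.fixed_mask = fm
        if self.ktrans_ratio is not None:
            self._check_ratio()

    def _check_ratio(self) -> None:
        r = np.asarray(self.ktrans_ratio, dtype=float)
        if r.shape != self.labels.shape:
            raise ValueError("ktrans_ratio shape must match labels")
        if np.any(r < 0) or not np.all(np.isfinite(r)):
            raise ValueError("ktrans_ratio must be finite and >= 0")
        m = r[self.labels == TUMOR_LABEL].mean()
        if abs(m - 1.0) > 1e-6:
            raise ValueError(f"tumor-mean ktrans_ratio must be 1, got {m}")

    @property
    def tumor_mask(self) -> np.ndarray:
        return self.labels == TUMOR_LABEL

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.labels.shape

    @property
    def spacing_m(self) -> float:
        return self.spacing_mm * 1e-3


def build_domain(
    mask: np.ndarray,
    voxel_size_mm,
    target_spacing_mm: float = 1.0,
    margin_mm: float = 20.0,
    boundary_pressure: float = 0.0,
) -> SimulationDomain:
    """Reslice a lesion mask to an isotropic grid and pad with normal tissue.

    The mask is resampled by nearest neighbour to ``target_spacing_mm``
    (1 mm isotropic by default) and surrounded by ``margin_mm`` of normal
    tissue on every side, forming the extended domain whose outer surface
    carries the zero-pressure boundary condition.
    """
    mask = np.asarray(mask).astype(bool)
    if mask.ndim != 3:
        raise ValueError("mask must be 3D")
    if not mask.any():
        raise ValueError("mask is empty")
    if target_spacing_mm <= 0:
        raise ValueError("target_spacing_mm must be positive")
    pad = int(round(margin_mm / target_spacing_mm))
    if pad < 2:
        raise ValueError(
            f"margin of {margin_mm} mm is under 2 voxels at "
            f"{target_spacing_mm} mm spacing"
        )
    voxel_size_mm = np.broadcast_to(np.asarray(voxel_size_mm, dtype=float), (3,))
    if np.any(voxel_size_mm <= 0):
        raise ValueError("voxel sizes must be positive")
    zoomf = tuple(vs / target_spacing_mm for vs in voxel_size_mm)
    if np.allclose(zoomf, 1.0):
        resliced = mask.copy()
    else:
        # linear interpolation of the indicator + 0.5 threshold gives a far
        # smoother surface than nearest neighbour at strongly anisotropic
        # zoom factors while preserving volume to the same order
        resliced = ndzoom(mask.astype(float), zoomf, order=1) > 0.5
    labels = np.pad(resliced.astype(np.uint8), pad, constant_values=NORMAL_LABEL)
    return SimulationDomain(
        labels=labels,
        spacing_mm=target_spacing_mm,
        boundary_pressure=boundary_pressure,
        zoom_factors=zoomf,
        pad_voxels=pad,
        core_shape=resliced.shape,
    )


def make_ktrans_ratio(ktrans: np.ndarray, domain: SimulationDomain) -> SimulationDomain:
    """Attach the normalized Ktrans source-modulation field to the domain.

    The Ktrans map (acquisition grid, same grid as the mask passed to
    :func:`build_domain`) is linearly resampled onto the isotropic grid;
    inside the tumor the ratio is Ktrans divided by its tumor mean, outside
    it is 1 (the map is only defined in the lesion).  The tumor mean of the
    ratio is exactly 1 by construction.
    """
    ktrans = np.asarray(ktrans, dtype=float)
    if domain.zoom_factors is None or domain.core_shape is None:
        raise ValueError("domain lacks reslice bookkeeping; use build_domain")
    if np.allclose(domain.zoom_factors, 1.0) and ktrans.shape == domain.core_shape:
        resliced = ktrans.copy()
    else:
        resliced = ndzoom(ktrans, domain.zoom_factors, order=1)
    if resliced.shape != domain.core_shape:
        raise ValueError("ktrans map does not cover the domain tumor grid")
    full = np.pad(resliced, domain.pad_voxels, constant_values=0.0)
    tumor = domain.tumor_mask
    mean_kt = full[tumor].mean()
    if mean_kt <= 0:
        raise ValueError("tumor-mean Ktrans is zero: ratio undefined")
    ratio = np.ones_like(full)
    ratio[tumor] = full[tumor] / mean_kt
    ratio[tumor] /= ratio[tumor].mean()  # exact renormalization
    return SimulationDomain(
        labels=domain.labels,
        spacing_mm=domain.spacing_mm,
        boundary_pressure=domain.boundary_pressure,
        ktrans_ratio=ratio,
        zoom_factors=domain.zoom_factors,
        pad_voxels=domain.pad_voxels,
        core_shape=domain.core_shape,
    )


@dataclass
class FlowSystem:
    """Assembled sparse system A p = b on the interior unknowns."""

    A: sp.csr_matrix
    b: np.ndarray
    interior: np.ndarray  # bool, full grid
    kh: np.ndarray  # full grid, m^2/(Pa s)
    c: np.ndarray  # full grid filtration coefficient, 1/(Pa s)
    p_eff: np.ndarray  # full grid, Pa
    domain: SimulationDomain

    @property
    def n_unknowns(self) -> int:
        return self.b.size


def _face_transmissibility(kh: np.ndarray, axis: int, h: float) -> np.ndarray:
    sl_a = [slice(None)] * 3
    sl_b = [slice(None)] * 3
    sl_a[axis] = slice(None, -1)
    sl_b[axis] = slice(1, None)
    ka, kb = kh[tuple(sl_a)], kh[tuple(sl_b)]
    return (2.0 * ka * kb / (ka + kb)) / h**2


def assemble_system(domain: SimulationDomain, props: FlowParameters) -> FlowSystem:
    """Finite-volume discretization of -div(K_H grad p) + c p = c P_eff.

    Face conductivities are harmonic means of the adjacent voxel K_H values;
    outer-layer voxels are Dirichlet at ``domain.boundary_pressure`` and are
    eliminated from the unknowns, keeping A symmetric positive definite.
    """
    if domain.ktrans_ratio is None:
        ratio = np.ones(domain.shape)
    else:
        ratio = domain.ktrans_ratio
    labels = domain.labels
    tumor = labels == TUMOR_LABEL
    h = domain.spacing_m

    kh = np.where(tumor, props.tumor.k_h, props.normal.k_h)
    c = np.where(
        tumor,
        props.tumor.filtration_coefficient if props.source_in_tumor else 0.0,
        props.normal.filtration_coefficient if props.source_in_normal else 0.0,
    ) * ratio
    p_eff = np.where(tumor, props.tumor.p_eff, props.normal.p_eff)

    interior = np.ones(domain.shape, dtype=bool)
    for ax in range(3):
        sl = [slice(None)] * 3
        sl[ax] = 0
        interior[tuple(sl)] = False
        sl[ax] = -1
        interior[tuple(sl)] = False
    if domain.fixed_mask is not None:
        interior &= ~domain.fixed_mask

    n = labels.size
    g = np.arange(n).reshape(domain.shape)
    int_flat = interior.ravel()
    unk = -np.ones(n, dtype=np.int64)
    unk[int_flat] = np.arange(int_flat.sum())

    diag_full = np.zeros(n)
    b_bc = np.zeros(n)
    rows, cols, vals = [], [], []
    pb = domain.boundary_pressure
    for ax in range(3):
        t = _face_transmissibility(kh, ax, h).ravel()
        sl_a = [slice(None)] * 3
        sl_b = [slice(None)] * 3
        sl_a[ax] = slice(None, -1)
        sl_b[ax] = slice(1, None)
        ga = g[tuple(sl_a)].ravel()
        gb = g[tuple(sl_b)].ravel()
        ia, ib = int_flat[ga], int_flat[gb]
        np.add.at(diag_full, ga[ia], t[ia])
        np.add.at(diag_full, gb[ib], t[ib])
        both = ia & ib
        rows.append(unk[ga[both]])
        cols.append(unk[gb[both]])
        vals.append(-t[both])
        rows.append(unk[gb[both]])
        cols.append(unk[ga[both]])
        vals.append(-t[both])
        if pb != 0.0:
            a_only = ia & ~ib
            b_only = ib & ~ia
            np.add.at(b_bc, ga[a_only], t[a_only] * pb)
            np.add.at(b_bc, gb[b_only], t[b_only] * pb)

    n_int = int(int_flat.sum())
    diag = diag_full[int_flat] + c.ravel()[int_flat]
    A = sp.coo_matrix(
        (
            np.concatenate(vals + [diag]),
            (
                np.concatenate(rows + [np.arange(n_int)]),
                np.concatenate(cols + [np.arange(n_int)]),
            ),
        ),
        shape=(n_int, n_int),
    ).tocsr()
    b = (c * p_eff).ravel()[int_flat] + b_bc[int_flat]
    return FlowSystem(A=A, b=b, interior=interior, kh=kh, c=c, p_eff=p_eff, domain=domain)


@dataclass
class PressureField:
    """Solved interstitial fluid pressure on the full grid (Pa)."""

    p: np.ndarray
    residual: float
    iterations: int

    @property
    def p_kpa(self) -> np.ndarray:
        return self.p / 1000.0


@dataclass
class VelocityField:
    """Darcy velocity u = -K_H grad(p): components and magnitude, m/s."""

    u: np.ndarray  # (3, x, y, z)
    magnitude: np.ndarray


class SolverError(RuntimeError):
    def __init__(self, message: str, residual: float):
        super().__init__(message)
        self.residual = residual


def solve_ifp(
    system: FlowSystem,
    tolerance: float = 1e-10,
    method: str = "auto",
    maxiter: int = 20000,
) -> PressureField:
    """Solve the assembled system to the requested relative residual.

    ``method='auto'`` uses a direct sparse factorization for small systems
    and Jacobi-preconditioned conjugate gradients otherwise (3D LU fill-in
    makes direct solves uncompetitive well before memory runs out);
    ``'direct'`` and ``'cg'`` force the choice.  Non-convergence raises
    :class:`SolverError` carrying the achieved residual.
    """
    A, b = system.A, system.b
    if method == "auto":
        method = "direct" if A.shape[0] < 20_000 else "cg"
    it = 0
    if method == "direct":
        x = spla.spsolve(A.tocsc(), b)
    elif method == "cg":
        d = A.diagonal()
        M = sp.diags(1.0 / d)
        count = [0]

        def cb(_):
            count[0] += 1

        x, info = spla.cg(A, b, rtol=tolerance * 0.1, atol=0.0, M=M,
                          maxiter=maxiter, callback=cb)
        it = count[0]
        if info != 0:
            res = np.linalg.norm(A @ x - b) / np.linalg.norm(b)
            raise SolverError(f"CG did not converge (info={info})", res)
    else:
        raise ValueError(f"unknown method {method!r}")
    nb = np.linalg.norm(b)
    residual = float(np.linalg.norm(A @ x - b) / nb) if nb > 0 else 0.0
    if residual > tolerance and nb > 0:
        raise SolverError("solution residual exceeds tolerance", residual)
    p = np.full(system.domain.shape, system.domain.boundary_pressure, dtype=float)
    p[system.interior] = x
    return PressureField(p=p, residual=residual, iterations=it)


def compute_ifv(
    pressure: PressureField,
    domain: SimulationDomain,
    props: FlowParameters,
) -> VelocityField:
    """Darcy velocity from the pressure field.

    Central differences in the interior, one-sided at the domain faces;
    K_H is the voxelwise (tissue-class) conductivity.
    """
    h = domain.spacing_m
    kh = np.where(domain.tumor_mask, props.tumor.k_h, props.normal.k_h)
    grads = np.gradient(pressure.p, h)
    u = np.stack([-kh * gr for gr in grads])
    mag = np.sqrt(np.sum(u**2, axis=0))
    return VelocityField(u=u, magnitude=mag)


def conservation_balance(system: FlowSystem, pressure: PressureField) -> tuple[float, float]:
    """(net interior source, outward boundary flux), both in m^3/s.

    The finite-volume identity: summing the discrete equations over all
    interior cells telescopes the interior fluxes, leaving
    sum c (P_eff - p) h^3 = flux through faces adjacent to boundary voxels.
    """
    dom = system.domain
    h = dom.spacing_m
    p = pressure.p
    interior = system.interior
    source = float(np.sum((system.c * (system.p_eff - p))[interior]) * h**3)
    flux = 0.0
    pb = dom.boundary_pressure
    for ax in range(3):
        t = _face_transmissibility(system.kh, ax, h)
        sl_a = [slice(None)] * 3
        sl_b = [slice(None)] * 3
        sl_a[ax] = slice(None, -1)
        sl_b[ax] = slice(1, None)
        pa, pbv = p[tuple(sl_a)], p[tuple(sl_b)]
        ia, ib = interior[tuple(sl_a)], interior[tuple(sl_b)]
        a_only = ia & ~ib  # flux leaving through the b-side boundary voxel
        b_only = ib & ~ia
        flux += float(np.sum(t[a_only] * (pa[a_only] - pb)) * h**3)
        flux += float(np.sum(t[b_only] * (pbv[b_only] - pb)) * h**3)
    return source, flux


class InterstitialFlowModel:
    """Steady-state porous-medium model of a lesion and its surroundings.

    Parameters
    ----------
    domain : SimulationDomain
        Isotropic labeled grid, optionally carrying the Ktrans ratio field.
    props : FlowParameters
        Per-tissue physical constants (literature defaults).

    ``solve()`` returns a :class:`FlowResults` with the pressure and
    velocity fields, solver diagnostics and a ``summary()`` table.
    """

    def __init__(self, domain: SimulationDomain, props: FlowParameters | None = None):
        self.domain = domain
        self.props = props if props is not None else FlowParameters()
        self._system: FlowSystem | None = None

    @property
    def system(self) -> FlowSystem:
        if self._system is None:
            self._system = assemble_system(self.domain, self.props)
        return self._system

    def solve(self, tolerance: float = 1e-10, method: str = "auto") -> "FlowResults":
        pressure = solve_ifp(self.system, tolerance=tolerance, method=method)
        velocity = compute_ifv(pressure, self.domain, self.props)
        return FlowResults(self, pressure, velocity)


@dataclass
class FlowResults:
    """Solved IFP/IFV fields with diagnostics."""

    model: InterstitialFlowModel
    pressure: PressureField
    velocity: VelocityField

    @property
    def domain(self) -> SimulationDomain:
        return self.model.domain

    def conservation(self) -> tuple[float, float]:
        return conservation_balance(self.model.system, self.pressure)

    def summary(self) -> "pd.DataFrame":
        import pandas as pd

        dom = self.domain
        tumor = dom.tumor_mask
        src, flux = self.conservation()
        rows = [
            ("n_voxels", dom.labels.size, ""),
            ("n_tumor_voxels", int(tumor.sum()), ""),
            ("spacing_mm", dom.spacing_mm, "mm"),
            ("ifp_tumor_mean", self.pressure.p[tumor].mean(), "Pa"),
            ("ifp_tumor_max", self.pressure.p[tumor].max(), "Pa"),
            ("ifv_tumor_mean", self.velocity.magnitude[tumor].mean(), "m/s"),
            ("ifv_tumor_max", self.velocity.magnitude[tumor].max(), "m/s"),
            ("solver_residual", self.pressure.residual, ""),
            ("solver_iterations", self.pressure.iterations, ""),
            ("source_minus_boundary_flux_rel", abs(src - flux) / max(abs(src), 1e-300), ""),
        ]
        return pd.DataFrame(rows, columns=["quantity", "value", "units"])

    def plot_slice(self, axis: int = 2, index: int | None = None, ax=None):
        """Pressure map on one grid slice with the tumor contour."""
        import matplotlib.pyplot as plt

        if index is None:
            index = self.domain.shape[axis] // 2
        if ax is None:
            _, ax = plt.subplots()
        sl = [slice(None)] * 3
        sl[axis] = index
        im = ax.imshow(self.pressure.p_kpa[tuple(sl)].T, origin="lower", cmap="magma")
        ax.contour(self.domain.tumor_mask[tuple(sl)].T, levels=[0.5], colors="cyan")
        plt.colorbar(im, ax=ax, label="IFP (kPa)")
        return ax
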