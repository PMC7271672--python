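"""Extended Tofts model (ETM) kinetics.

Two-compartment pharmacokinetic model of contrast agent exchange between
blood plasma and the extravascular extracellular space (EES):

    C_t(t) = Ktrans * int_0^t exp(-k_ep (t - tau)) C_p(tau) dtau + v_p C_p(t)

with k_ep = Ktrans / v_e.  Ktrans (1/min) is the plasma-to-EES volume
transfer constant, v_e and v_p are the EES and plasma volume fractions.
The convolution is evaluated by trapezoidal quadrature on the acquisition
time grid; tests bound the quadrature error against a fine-grid reference.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import least_squares

from .protocol import AIFCurve

__all__ = [
    "KTRANS_BOUNDS",
    "VE_BOUNDS",
    "VP_BOUNDS",
    "forward_etm",
    "forward_etm_many",
    "fit_etm_voxel",
    "fit_etm_curves_profiled",
]

# fit box constraints for (Ktrans [1/min], v_e, v_p)
KTRANS_BOUNDS = (0.0, 5.0)
VE_BOUNDS = (0.0, 1.0)
VP_BOUNDS = (0.0, 1.0)

_VE_FLOOR = 1e-9  # avoids k_ep = Ktrans/v_e blowing up inside the optimizer


def trapezoid_weights(times: np.ndarray) -> np.ndarray:
    """Lower-triangular matrix W with W[i] = trapezoid weights on [t0, t_i].

    Row i integrates a sampled function over tau in [times[0], times[i]]:
    ``integral_i = W[i] @ f``.  Supports non-uniform grids.
    """
    n = times.size
    w = np.zeros((n, n))
    dt = np.diff(times)
    for i in range(1, n):
        w[i, : i + 1] = w[i - 1, : i + 1]
        w[i, i - 1] += 0.5 * dt[i - 1]
        w[i, i] += 0.5 * dt[i - 1]
    return w


def _conv_kernel(kep_per_s: float, times: np.ndarray, weights: np.ndarray, cp: np.ndarray) -> np.ndarray:
    # int_0^{t_i} exp(-kep (t_i - tau)) cp(tau) dtau, trapezoid on the grid
    lag = times[:, None] - times[None, :]
    with np.errstate(over="ignore"):
        kernel = np.exp(-kep_per_s * np.maximum(lag, 0.0))
    return (weights * kernel) @ cp


def forward_etm(ktrans: float, ve: float, vp: float, aif: AIFCurve) -> np.ndarray:
    """Tissue concentration C_t(t) in mM for one parameter triple.

    Parameters are in the conventional units: ``ktrans`` 1/min, ``ve`` and
    ``vp`` fractions.  Raises if ``ve == 0`` while ``ktrans > 0`` (k_ep is
    then undefined).
    """
    if not (KTRANS_BOUNDS[0] <= ktrans <= KTRANS_BOUNDS[1]):
        raise ValueError(f"ktrans {ktrans} outside {KTRANS_BOUNDS} 1/min")
    if not (VE_BOUNDS[0] <= ve <= VE_BOUNDS[1] and VP_BOUNDS[0] <= vp <= VP_BOUNDS[1]):
        raise ValueError("ve and vp must lie in [0, 1]")
    if ktrans > 0 and ve == 0:
        raise ValueError("ve = 0 with ktrans > 0: k_ep undefined")
    times, cp = aif.times, aif.cp
    weights = trapezoid_weights(times)
    if ktrans == 0:
        return vp * cp
    kep_per_s = (ktrans / ve) / 60.0
    return (ktrans / 60.0) * _conv_kernel(kep_per_s, times, weights, cp) + vp * cp


def forward_etm_many(
    ktrans: np.ndarray,
    ve: np.ndarray,
    vp: np.ndarray,
    aif: AIFCurve,
    chunk: int = 2048,
) -> np.ndarray:
    """Vectorized :func:`forward_etm` over flat parameter arrays.

    Returns an array of shape ``(n_voxels, n_times)``.  Used by the phantom
    generator where every voxel carries its own parameter triple.
    """
    ktrans = np.asarray(ktrans, dtype=float).ravel()
    ve = np.asarray(ve, dtype=float).ravel()
    vp = np.asarray(vp, dtype=float).ravel()
    times, cp = aif.times, aif.cp
    weights = trapezoid_weights(times)
    lag = np.maximum(times[:, None] - times[None, :], 0.0)
    out = np.empty((ktrans.size, times.size))
    for lo in range(0, ktrans.size, chunk):
        hi = min(lo + chunk, ktrans.size)
        kt = ktrans[lo:hi]
        kep = np.where(ve[lo:hi] > 0, kt / np.maximum(ve[lo:hi], _VE_FLOOR), 0.0) / 60.0
        with np.errstate(over="ignore"):
            kern = np.exp(-kep[:, None, None] * lag[None, :, :])
        conv = np.einsum("vij,ij,j->vi", kern, weights, cp)
        out[lo:hi] = (kt / 60.0)[:, None] * conv + vp[lo:hi, None] * cp[None, :]
    return out


def fit_etm_voxel(
    curve: np.ndarray,
    aif: AIFCurve,
    init: tuple[float, float, float] = (0.1, 0.2, 0.05),
    bounds: tuple | None = None,
    multistart: bool = False,
) -> dict:
    """Bounded nonlinear least-squares ETM fit of one concentration curve.

    Minimizes the sum of squared errors between the model and ``curve``
    over (Ktrans, v_e, v_p) inside the physiologic box Ktrans in [0, 5]
    1/min, v_e and v_p in [0, 1].

    Returns a dict with keys ``ktrans, ve, vp, kep, sse, success``.  A fit
    that fails to converge is flagged ``success=False`` with ``sse = inf``
    rather than raising, so volume fits can skip bad voxels.
    """
    curve = np.asarray(curve, dtype=float)
    if curve.shape != aif.times.shape:
        raise ValueError("curve and AIF must share the time grid")
    if bounds is None:
        bounds = (
            np.array([KTRANS_BOUNDS[0], VE_BOUNDS[0], VP_BOUNDS[0]]),
            np.array([KTRANS_BOUNDS[1], VE_BOUNDS[1], VP_BOUNDS[1]]),
        )
    lo, hi = np.asarray(bounds[0], float), np.asarray(bounds[1], float)
    lo = np.maximum(lo, [0.0, _VE_FLOOR, 0.0])  # keep k_ep finite

    times, cp = aif.times, aif.cp
    weights = trapezoid_weights(times)
    lag = np.maximum(times[:, None] - times[None, :], 0.0)

    def model(x):
        kt, ve, vp = x
        kep = (kt / max(ve, _VE_FLOOR)) / 60.0
        with np.errstate(over="ignore"):
            kern = np.exp(-kep * lag)
        return (kt / 60.0) * ((weights * kern) @ cp) + vp * cp

    def resid(x):
        return model(x) - curve

    starts = [np.clip(np.asarray(init, float), lo, hi)]
    if multistart:
        starts += [
            np.clip(np.array([0.02, 0.1, 0.01]), lo, hi),
            np.clip(np.array([0.8, 0.4, 0.08]), lo, hi),
        ]

    best = None
    for x0 in starts:
        try:
            sol = least_squares(
                resid, x0, bounds=(lo, hi), method="trf",
                xtol=1e-12, ftol=1e-14, gtol=1e-12, max_nfev=400,
            )
        except Exception:
            continue
        sse = float(np.sum(sol.fun**2))
        if best is None or sse < best[1]:
            best = (sol, sse)
    if best is None:
        return dict(ktrans=np.nan, ve=np.nan, vp=np.nan, kep=np.nan,
                    sse=np.inf, success=False)
    sol, sse = best
    kt, ve, vp = sol.x
    kep = kt / ve if ve > _VE_FLOOR else (0.0 if kt == 0 else np.nan)
    return dict(ktrans=float(kt), ve=float(ve), vp=float(vp),
                kep=float(kep), sse=sse, success=bool(sol.success))


def _bounded_2x2_lsq(g11, g12, g22, r1, r2, a1_max, a2_max):
    """Non-negative, box-bounded least squares for two basis coefficients.

    Solves min ||a1 b1 + a2 b2 - y||^2 with 0 <= a1 <= a1_max,
    0 <= a2 <= a2_max, given the Gram entries g_ij = b_i . b_j and
    projections r_i = b_i . y (vectorized over the trailing axes).  The
    active-set structure of a 2-variable box QP is enumerated explicitly.
    """
    det = g11 * g22 - g12**2
    det = np.where(det <= 0, np.inf, det)
    a1 = (g22 * r1 - g12 * r2) / det
    a2 = (g11 * r2 - g12 * r1) / det
    # clamp each variable and re-optimize the other on each face
    candidates = []
    for f1 in (None, 0.0, a1_max):
        for f2 in (None, 0.0, a2_max):
            if f1 is None and f2 is None:
                c1, c2 = a1, a2
            elif f1 is None:
                c2 = np.broadcast_to(f2, np.shape(a1))
                c1 = (r1 - g12 * f2) / g11
                c1 = np.clip(c1, 0.0, a1_max)
            elif f2 is None:
                c1 = np.broadcast_to(f1, np.shape(a1))
                c2 = (r2 - g12 * f1) / g22
                c2 = np.clip(c2, 0.0, a2_max)
            else:
                c1 = np.broadcast_to(f1, np.shape(a1))
                c2 = np.broadcast_to(f2, np.shape(a1))
            candidates.append((np.clip(c1, 0.0, a1_max), np.clip(c2, 0.0, a2_max)))
    # objective up to the constant ||y||^2
    best_obj = None
    best = None
    for c1, c2 in candidates:
        obj = c1**2 * g11 + 2 * c1 * c2 * g12 + c2**2 * g22 - 2 * (c1 * r1 + c2 * r2)
        if best_obj is None:
            best_obj, best = obj, (c1.copy(), c2.copy())
        else:
            better = obj < best_obj
            best_obj = np.where(better, obj, best_obj)
            best = (np.where(better, c1, best[0]), np.where(better, c2, best[1]))
    return best[0], best[1], best_obj


def fit_etm_curves_profiled(
    curves: np.ndarray,
    aif: AIFCurve,
    n_kep: int = 64,
    kep_max: float = 50.0,
    refine: bool = True,
) -> dict:
    """Fast vectorized ETM fit of many curves by profiling out k_ep.

    For fixed k_ep the model C = (Ktrans/60) conv(k_ep) + v_p C_p is linear
    in its two coefficients, so the SSE can be minimized in closed form per
    candidate k_ep; a geometric k_ep grid (plus k_ep = 0) is scanned and the
    winner optionally refined by parabolic interpolation on log k_ep.  The
    box constraints (Ktrans in [0, 5] 1/min, v_e, v_p in [0, 1]) are
    enforced: v_e = Ktrans/k_ep <= 1 restricts the admissible Ktrans range
    per k_ep candidate.

    This is the same SSE objective as :func:`fit_etm_voxel` minimized over a
    restricted k_ep set — a fast path for whole-volume fitting.

    Returns dict of arrays ``ktrans, ve, vp, kep, sse, success`` over the
    leading axis of ``curves`` (n_curves, n_times).
    """
    curves = np.atleast_2d(np.asarray(curves, dtype=float))
    times, cp = aif.times, aif.cp
    if curves.shape[1] != times.size:
        raise ValueError("curves and AIF must share the time grid")
    weights = trapezoid_weights(times)
    lag = np.maximum(times[:, None] - times[None, :], 0.0)
    kep_grid = np.concatenate([[0.0], np.geomspace(1e-3, kep_max, n_kep - 1)])  # 1/min

    def basis(kep_per_min):
        return _conv_kernel(kep_per_min / 60.0, times, weights, cp)

    b2 = cp
    g22 = float(b2 @ b2)
    r2 = curves @ b2  # (V,)
    yy = np.einsum("vt,vt->v", curves, curves)

    def scan(keps):
        nk, nv = len(keps), curves.shape[0]
        obj = np.empty((nk, nv))
        coef = np.empty((2, nk, nv))
        for j, kep in enumerate(keps):
            b1 = basis(kep)
            g11 = float(b1 @ b1)
            g12 = float(b1 @ b2)
            r1 = curves @ b1
            # ve = ktrans/kep <= 1 caps the ktrans coefficient a1 = ktrans/60
            a1_cap = KTRANS_BOUNDS[1] / 60.0 if kep == 0 else min(KTRANS_BOUNDS[1], kep) / 60.0
            if g11 <= 0:  # degenerate basis (kep huge): vascular-only
                a1 = np.zeros(nv)
                a2 = np.clip(r2 / g22, 0.0, VP_BOUNDS[1])
                o = a2**2 * g22 - 2 * a2 * r2
            else:
                a1, a2, o = _bounded_2x2_lsq(g11, g12, g22, r1, r2, a1_cap, VP_BOUNDS[1])
            obj[j], coef[0, j], coef[1, j] = o, a1, a2
        return obj, coef

    obj, coef = scan(kep_grid)
    jbest = np.argmin(obj, axis=0)
    nv = curves.shape[0]
    vidx = np.arange(nv)

    kep_best = kep_grid[jbest]
    if refine:
        # parabolic refinement on log(kep) where the winner is interior
        interior = (jbest >= 2) & (jbest < len(kep_grid) - 1)
        if interior.any():
            jl = np.maximum(jbest - 1, 1)  # grid index 0 is kep=0; log-safe
            jc = np.maximum(jbest, 1)
            jr = np.minimum(jbest + 1, len(kep_grid) - 1)
            xl, xc, xr = (np.log(kep_grid[j]) for j in (jl, jc, jr))
            yl, yc, yr = obj[jl, vidx], obj[jc, vidx], obj[jr, vidx]
            denom = (yl - 2 * yc + yr)
            with np.errstate(divide="ignore", invalid="ignore"):
                shift = 0.5 * (yl - yr) / denom
            good = interior & np.isfinite(shift) & (np.abs(shift) < 1.0) & (denom > 0)
            kep_ref = np.exp(xc + np.clip(shift, -1, 1) * (xr - xc))
            kep_cand = np.where(good, kep_ref, kep_best)
            # rescore candidates voxel-by-voxel in small groups
            refine_idx = np.where(good)[0]
            if refine_idx.size:
                for v in refine_idx:
                    b1 = basis(kep_cand[v])
                    g11 = float(b1 @ b1)
                    g12 = float(b1 @ b2)
                    r1v = float(curves[v] @ b1)
                    cap = min(KTRANS_BOUNDS[1], kep_cand[v]) / 60.0
                    a1, a2, o = _bounded_2x2_lsq(
                        np.array(g11), np.array(g12), np.array(g22),
                        np.array(r1v), np.array(r2[v]), cap, VP_BOUNDS[1])
                    if o < obj[jbest[v], v]:
                        kep_best[v] = kep_cand[v]
                        coef[0, jbest[v], v] = a1
                        coef[1, jbest[v], v] = a2
                        obj[jbest[v], v] = o

    a1 = coef[0, jbest, vidx]
    a2 = coef[1, jbest, vidx]
    ktrans = a1 * 60.0
    vp = a2
    with np.errstate(divide="ignore", invalid="ignore"):
        ve = np.where(kep_best > 0, ktrans / kep_best, 0.0)
    ve = np.clip(ve, 0.0, 1.0)
    sse = obj[jbest, vidx] + yy
    sse = np.maximum(sse, 0.0)
    return dict(
        ktrans=ktrans, ve=ve, vp=vp, kep=kep_best, sse=sse,
        success=np.ones(nv, dtype=bool),
    )
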