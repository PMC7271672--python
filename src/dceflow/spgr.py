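"""Spoiled gradient-echo (SPGR) steady-state signal model.

Links longitudinal relaxation rate R1 to measured signal, and back.  The
forward direction generates synthetic DCE signal; the exact inverse turns a
measured dynamic series into R1(t) and hence contrast concentration.
"""

from __future__ import annotations

import numpy as np

from .protocol import AcquisitionProtocol

__all__ = ["spgr_signal", "spgr_r1", "baseline_m0", "concentration_to_signal"]


def spgr_signal(r1, protocol: AcquisitionProtocol, m0=1.0):
    """SPGR steady-state signal for relaxation rate ``r1`` (1/s).

    S = M0 sin(a) (1 - E1) / (1 - cos(a) E1),  E1 = exp(-TR * R1).
    """
    r1 = np.asarray(r1, dtype=float)
    a = np.deg2rad(protocol.flip_angle)
    e1 = np.exp(-protocol.repetition_time * r1)
    return m0 * np.sin(a) * (1.0 - e1) / (1.0 - np.cos(a) * e1)


def spgr_r1(signal, protocol: AcquisitionProtocol, m0):
    """Exact inversion of :func:`spgr_signal`.

    Returns ``(r1, valid)``: voxels whose signal is outside the invertible
    range of the SPGR equation (E1 outside (0, 1]) are flagged invalid and
    get r1 = NaN rather than raising.
    """
    signal = np.asarray(signal, dtype=float)
    a = np.deg2rad(protocol.flip_angle)
    y = signal / (np.asarray(m0, dtype=float) * np.sin(a))
    with np.errstate(divide="ignore", invalid="ignore"):
        e1 = (1.0 - y) / (1.0 - np.cos(a) * y)
        valid = np.isfinite(e1) & (e1 > 0.0) & (e1 <= 1.0)
        r1 = np.where(valid, -np.log(np.where(valid, e1, 1.0)) / protocol.repetition_time, np.nan)
    return r1, valid


def concentration_to_signal(conc, protocol: AcquisitionProtocol, t10: float, m0=1.0):
    """SPGR signal for a contrast concentration curve/volume (mM).

    R1(t) = 1/T10 + r1 C(t); deterministic and linear in ``m0``.  The exact
    inverse is :func:`dceflow.pk.signal_to_concentration`.
    """
    if t10 <= 0:
        raise ValueError("t10 must be positive")
    r1 = 1.0 / t10 + protocol.relaxivity_r1 * np.asarray(conc, dtype=float)
    return spgr_signal(r1, protocol, m0=m0)


def baseline_m0(s0, protocol: AcquisitionProtocol, t10: float):
    """Equilibrium magnetization implied by baseline signal ``s0`` at ``t10``."""
    if t10 <= 0:
        raise ValueError("t10 must be positive")
    a = np.deg2rad(protocol.flip_angle)
    e10 = np.exp(-protocol.repetition_time / t10)
    return np.asarray(s0, dtype=float) * (1.0 - np.cos(a) * e10) / (np.sin(a) * (1.0 - e10))
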