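"""Acquisition protocol and arterial input function (AIF) containers.

The DCE acquisition is an axial 3D spoiled gradient-echo (SPGR) dynamic
series: a block of pre-injection baseline phases followed by dynamic phases
during and after bolus injection of a gadolinium contrast agent.  The
protocol object carries the handful of acquisition constants every stage
needs (TR, flip angle, phase timing, relaxivity, baseline T1).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "AcquisitionProtocol",
    "AIFCurve",
    "BiexponentialBolus",
    "generate_aif",
]


@dataclass(frozen=True)
class AcquisitionProtocol:
    """Constants of the dynamic SPGR acquisition.

    Parameters
    ----------
    repetition_time : float
        Sequence TR in seconds (typical dynamic SPGR: 4-5 ms).
    flip_angle : float
        Excitation flip angle in degrees, in (0, 90].
    n_baseline_phases : int
        Number of pre-injection phases (used to estimate the baseline signal).
    n_total_phases : int
        Total number of dynamic phases acquired.
    temporal_resolution : float
        Time between successive phases, seconds.
    field_strength_label : str
        ``"1.5T"`` or ``"3T"``; informational label only.
    relaxivity_r1 : float
        Longitudinal relaxivity of the contrast agent in 1/(s*mM)
        (gadopentetate is near 4.5 at clinical field strengths).
    t10_default : float
        Pre-contrast tissue T1 in seconds assumed when no T1 map is
        available.  0.8 s and 1.0 s are both in conventional use depending
        on field strength; which applies is a user choice.
    """

    repetition_time: float = 4.5e-3
    flip_angle: float = 25.0
    n_baseline_phases: int = 10
    n_total_phases: int = 40
    temporal_resolution: float = 5.5
    field_strength_label: str = "3T"
    relaxivity_r1: float = 4.5
    t10_default: float = 1.0

    def __post_init__(self) -> None:
        if not (0 < self.n_baseline_phases < self.n_total_phases):
            raise ValueError(
                "need 0 < n_baseline_phases < n_total_phases, got "
                f"{self.n_baseline_phases} / {self.n_total_phases}"
            )
        if self.repetition_time <= 0 or self.temporal_resolution <= 0:
            raise ValueError("all times must be positive")
        if not (0 < self.flip_angle <= 90):
            raise ValueError("flip_angle must lie in (0, 90] degrees")
        if self.relaxivity_r1 <= 0 or self.t10_default <= 0:
            raise ValueError("relaxivity and T10 must be positive")

    @property
    def times(self) -> np.ndarray:
        """Phase acquisition times in seconds (phase 0 at t = 0)."""
        return np.arange(self.n_total_phases) * self.temporal_resolution

    @property
    def baseline_duration(self) -> float:
        """End of the pre-injection block, seconds."""
        return self.n_baseline_phases * self.temporal_resolution

    @property
    def scan_duration(self) -> float:
        return (self.n_total_phases - 1) * self.temporal_resolution

    def replace(self, **kwargs) -> "AcquisitionProtocol":
        return replace(self, **kwargs)


@dataclass(frozen=True)
class AIFCurve:
    """Plasma contrast concentration time course C_p(t).

    ``times`` are seconds on the acquisition grid, ``cp`` is plasma
    concentration in mM.  Concentration is zero before bolus arrival and
    non-negative everywhere.
    """

    times: np.ndarray
    cp: np.ndarray

    def __post_init__(self) -> None:
        times = np.asarray(self.times, dtype=float)
        cp = np.asarray(self.cp, dtype=float)
        if times.ndim != 1 or times.shape != cp.shape:
            raise ValueError("times and cp must be matching 1-D arrays")
        if times.size >= 2 and np.any(np.diff(times) <= 0):
            raise ValueError("times must be strictly increasing")
        if not np.all(np.isfinite(cp)):
            raise ValueError("cp must be finite")
        if np.any(cp < 0):
            raise ValueError("cp must be non-negative")
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "cp", cp)

    def __len__(self) -> int:
        return self.times.size


@dataclass(frozen=True)
class BiexponentialBolus:
    """Population bolus model C_p(t) = A (e^{-m_slow dt} - e^{-m_fast dt}).

    ``dt`` is time since bolus arrival.  ``m_fast`` sets the wash-in rate,
    ``m_slow`` the washout; the curve rises on a 1/m_fast timescale and
    decays on 1/m_slow.  ``amplitude`` (mM) scales the whole curve; the peak
    concentration is amplitude * (e^{-m_slow t*} - e^{-m_fast t*}) attained
    at t* = ln(m_fast/m_slow) / (m_fast - m_slow).
    """

    amplitude: float = 6.0
    m_fast: float = 0.25
    m_slow: float = 0.01

    def __post_init__(self) -> None:
        if self.amplitude < 0:
            raise ValueError("amplitude must be >= 0")
        if not (0 < self.m_slow < self.m_fast):
            raise ValueError("need 0 < m_slow < m_fast")

    def peak(self) -> tuple[float, float]:
        """Closed-form (time since arrival, concentration) of the maximum."""
        tstar = np.log(self.m_fast / self.m_slow) / (self.m_fast - self.m_slow)
        return tstar, float(self(np.array([tstar]))[0])

    def __call__(self, dt: np.ndarray) -> np.ndarray:
        dt = np.asarray(dt, dtype=float)
        out = self.amplitude * (np.exp(-self.m_slow * dt) - np.exp(-self.m_fast * dt))
        return np.where(dt >= 0, np.maximum(out, 0.0), 0.0)


def generate_aif(
    protocol: AcquisitionProtocol,
    bolus: BiexponentialBolus | None = None,
    bolus_arrival: float | None = None,
) -> AIFCurve:
    """Sample a population AIF on the protocol's acquisition time grid.

    Parameters
    ----------
    protocol : AcquisitionProtocol
        Supplies the phase time grid and baseline duration.
    bolus : BiexponentialBolus, optional
        Bolus shape parameters; defaults to the package's population curve.
    bolus_arrival : float, optional
        Arrival time in seconds.  Must fall at or after the end of the
        baseline block and inside the scan window.  Defaults to the end of
        the baseline block.

    Returns
    -------
    AIFCurve
        Plasma concentration, zero before arrival, on ``protocol.times``.
    """
    if bolus is None:
        bolus = BiexponentialBolus()
    if bolus_arrival is None:
        bolus_arrival = protocol.baseline_duration
    if bolus_arrival < protocol.baseline_duration - 1e-9:
        raise ValueError(
            f"bolus_arrival {bolus_arrival:g}s precedes the end of the "
            f"baseline block ({protocol.baseline_duration:g}s)"
        )
    if bolus_arrival > protocol.scan_duration:
        raise ValueError("bolus_arrival lies outside the scan window")
    times = protocol.times
    cp = bolus(times - bolus_arrival)
    return AIFCurve(times=times, cp=cp)
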