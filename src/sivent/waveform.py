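"""Volume-controlled breath waveforms and the single-compartment pressure model.

The respiratory system is modelled as a single linear compartment,

    P_aw(t) = E_rs * V(t) + R_rs * Vdot(t) + PEEP,

where ``P_aw`` is airway pressure (cmH2O), ``V`` delivered volume (L),
``Vdot`` flow (L/s), ``E_rs`` respiratory elastance (cmH2O/L), ``R_rs``
respiratory resistance (cmH2O.s/L) and PEEP the ventilator-applied offset
pressure (cmH2O).  During volume-controlled (VC) ventilation the clinician
sets the flow profile, so pressure is the dependent output and can be
forward-simulated for any candidate combination of settings.

This module synthesises VC inspiratory flow/volume profiles (square and
descending-ramp waveforms), simulates the resulting pressure, and computes
the safety-relevant outcomes — peak pressure P_MAX, plateau pressure P_PLAT,
driving pressure dP = E_rs * V_T, and the I:E timing — both in closed form
and from sampled waveforms.

Internal units are L, L/s, s and cmH2O throughout; peak flow is converted
from the clinical L/min at the interface.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.integrate import cumulative_trapezoid

__all__ = [
    "RespiratoryMechanics",
    "VCSettings",
    "BreathWaveform",
    "VentilationOutcomes",
    "build_vc_profile",
    "simulate_pressure",
    "compute_outcomes",
    "sampled_outcomes",
    "DEFAULT_DT",
]

#: default sample period (s); 50 Hz, the rate of the bedside recordings the
#: breath-definition criteria (8 samples = 0.16 s) are phrased in.
DEFAULT_DT = 0.02

#: numerical slack used when comparing against strict/inclusive limits
EPS = 1e-9

WAVEFORMS = ("square", "ramp")


@dataclass(frozen=True)
class RespiratoryMechanics:
    """Patient-specific parameters of the single-compartment model.

    Parameters
    ----------
    E_rs : float
        Respiratory elastance, cmH2O/L.  Reciprocal of compliance; higher
        means a stiffer lung.
    R_rs : float
        Respiratory resistance, cmH2O.s/L.
    PEEP : float
        Positive end-expiratory pressure, cmH2O.
    """

    E_rs: float
    R_rs: float
    PEEP: float

    def __post_init__(self) -> None:
        if self.E_rs < 0 or self.R_rs < 0 or self.PEEP < 0:
            raise ValueError(
                f"mechanics must be nonnegative, got E_rs={self.E_rs}, "
                f"R_rs={self.R_rs}, PEEP={self.PEEP}"
            )


@dataclass(frozen=True)
class VCSettings:
    """One combination of clinician-adjustable VC ventilation settings.

    Parameters
    ----------
    RR : float
        Respiratory rate, breaths/min.
    VT_perkg : float
        Tidal volume indexed to body weight, mL/kg.
    peak_flow : float
        Peak inspiratory flow Vdot_MAX, L/min.
    T_plat : float
        Inspiratory plateau (zero-flow hold) time, s.
    waveform : str
        ``"square"`` (constant flow) or ``"ramp"`` (linear descent from the
        peak flow to zero).
    """

    RR: float
    VT_perkg: float
    peak_flow: float
    T_plat: float
    waveform: str

    def __post_init__(self) -> None:
        if self.waveform not in WAVEFORMS:
            raise ValueError(f"waveform must be one of {WAVEFORMS}, got {self.waveform!r}")
        if self.RR <= 0 or self.VT_perkg <= 0 or self.peak_flow <= 0 or self.T_plat < 0:
            raise ValueError(f"invalid VC settings: {self}")

    def tidal_volume(self, weight: float) -> float:
        """Tidal volume in litres for a patient of ``weight`` kg."""
        return self.VT_perkg * weight / 1000.0

    def flow_time(self, weight: float) -> float:
        """Duration of the inspiratory flow phase, s.

        Square delivers V_T at constant peak flow (T = V_T/Vdot_max); the
        descending ramp spans twice that so both the set peak flow and the
        set tidal volume are honoured (triangle area = V_T).
        """
        vmax = self.peak_flow / 60.0
        t = self.tidal_volume(weight) / vmax
        return t if self.waveform == "square" else 2.0 * t


@dataclass
class BreathWaveform:
    """Uniformly sampled breath signals.

    ``volume`` is the running trapezoidal integral of ``flow`` with V(0)=0;
    ``pressure`` is absent until simulated.
    """

    t: np.ndarray
    flow: np.ndarray
    volume: np.ndarray
    dt: float
    pressure: np.ndarray | None = None

    def __post_init__(self) -> None:
        n = len(self.t)
        if len(self.flow) != n or len(self.volume) != n:
            raise ValueError("time, flow and volume grids must share one length")
        if self.pressure is not None and len(self.pressure) != n:
            raise ValueError("pressure grid length mismatch")

    def to_frame(self) -> pd.DataFrame:
        """Export as a DataFrame with the documented CSV columns."""
        data = {"t_s": self.t, "flow_Lps": self.flow, "volume_L": self.volume}
        if self.pressure is not None:
            data["pressure_cmH2O"] = self.pressure
        return pd.DataFrame(data)


@dataclass(frozen=True)
class VentilationOutcomes:
    """Safety-relevant outcomes of one setting combination.

    ``IE_denom`` is the E-side of the clinical 1:x I:E ratio, i.e.
    T_exp / T_insp.  ``feasible`` is False when the inspiratory phase does
    not fit inside the breath period (T_exp <= 0).
    """

    P_MAX: float
    P_PLAT: float
    dP: float
    IE_denom: float
    T_insp: float
    T_exp: float
    feasible: bool


def build_vc_profile(
    settings: VCSettings, weight: float, dt: float = DEFAULT_DT
) -> BreathWaveform:
    """Synthesise the inspiratory flow/volume profile for one VC setting.

    The grid covers inspiration only (flow phase plus plateau hold);
    expiration is not modelled beyond its timing.  Delivered volume at the
    end of the flow phase equals ``settings.tidal_volume(weight)`` to
    quadrature accuracy.

    Parameters
    ----------
    settings : VCSettings
    weight : float
        Patient weight, kg (converts mL/kg to L).
    dt : float
        Sample period, s.
    """
    if weight <= 0:
        raise ValueError("weight must be positive")
    if dt <= 0:
        raise ValueError("dt must be positive")
    vmax = settings.peak_flow / 60.0
    t_flow = settings.flow_time(weight)
    t_insp = t_flow + settings.T_plat
    t = np.arange(0.0, t_insp + dt / 2, dt)
    if t[-1] < t_insp - EPS:  # make sure end-inspiration is on the grid
        t = np.append(t, t_insp)
    if settings.waveform == "square":
        flow = np.where(t <= t_flow + EPS, vmax, 0.0)
    else:
        flow = np.where(t <= t_flow + EPS, vmax * np.clip(1.0 - t / t_flow, 0.0, 1.0), 0.0)
    volume = cumulative_trapezoid(flow, t, initial=0.0)
    return BreathWaveform(t=t, flow=flow, volume=volume, dt=dt)


def simulate_pressure(mech: RespiratoryMechanics, wf: BreathWaveform) -> BreathWaveform:
    """Simulate airway pressure for a waveform via the compartment model.

    Returns a new :class:`BreathWaveform` with
    ``pressure = E_rs*volume + R_rs*flow + PEEP`` sample-by-sample.
    """
    pressure = mech.E_rs * wf.volume + mech.R_rs * wf.flow + mech.PEEP
    return replace(wf, pressure=pressure)


def _ramp_peak_pressure(mech: RespiratoryMechanics, vmax: float, t_flow: float, vt: float) -> float:
    """Peak pressure of a descending-ramp inspiration, in closed form.

    Pressure along the ramp is quadratic in time; the maximum lies at the
    flow onset, at the end of the flow phase, or at the interior stationary
    point t* = T_flow - R_rs/E_rs when that falls inside the phase.
    """
    candidates = [mech.R_rs * vmax + mech.PEEP, mech.E_rs * vt + mech.PEEP]
    if mech.E_rs > 0:
        t_star = t_flow - mech.R_rs / mech.E_rs
        if 0.0 < t_star < t_flow:
            vol = vmax * (t_star - t_star**2 / (2.0 * t_flow))
            flo = vmax * (1.0 - t_star / t_flow)
            candidates.append(mech.E_rs * vol + mech.R_rs * flo + mech.PEEP)
    return max(candidates)


def compute_outcomes(
    mech: RespiratoryMechanics, settings: VCSettings, weight: float
) -> VentilationOutcomes:
    """Closed-form ventilation outcomes for one setting combination.

    P_PLAT = E_rs*V_T + PEEP (pressure during the zero-flow hold),
    dP = E_rs*V_T, and P_MAX is the analytic maximum of the simulated
    pressure over inspiration.  T_insp counts the flow phase plus the
    plateau hold; T_exp is the remainder of the 60/RR breath period.
    An infeasible combination (T_exp <= 0) is flagged, never raised.
    """
    if weight <= 0:
        raise ValueError("weight must be positive")
    vt = settings.tidal_volume(weight)
    vmax = settings.peak_flow / 60.0
    t_flow = settings.flow_time(weight)
    t_insp = t_flow + settings.T_plat
    t_exp = 60.0 / settings.RR - t_insp
    p_plat = mech.E_rs * vt + mech.PEEP
    if settings.waveform == "square":
        p_max = p_plat + mech.R_rs * vmax
    else:
        p_max = _ramp_peak_pressure(mech, vmax, t_flow, vt)
    feasible = t_exp > EPS
    return VentilationOutcomes(
        P_MAX=p_max,
        P_PLAT=p_plat,
        dP=mech.E_rs * vt,
        IE_denom=t_exp / t_insp,
        T_insp=t_insp,
        T_exp=t_exp,
        feasible=feasible,
    )


def sampled_outcomes(
    mech: RespiratoryMechanics,
    settings: VCSettings,
    weight: float,
    dt: float = DEFAULT_DT,
) -> VentilationOutcomes:
    """Outcomes measured from a sampled, simulated waveform.

    Independent of :func:`compute_outcomes` — used to cross-check the
    closed forms; they agree to within one sample's pressure increment.
    """
    wf = simulate_pressure(mech, build_vc_profile(settings, weight, dt))
    assert wf.pressure is not None
    p_max = float(np.max(wf.pressure))
    p_plat = float(wf.pressure[-1])  # end-inspiration, zero flow, full volume
    t_insp = settings.flow_time(weight) + settings.T_plat
    t_exp = 60.0 / settings.RR - t_insp
    feasible = t_exp > EPS
    return VentilationOutcomes(
        P_MAX=p_max,
        P_PLAT=p_plat,
        dP=p_plat - mech.PEEP,
        IE_denom=t_exp / t_insp,
        T_insp=t_insp,
        T_exp=t_exp,
        feasible=feasible,
    )
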