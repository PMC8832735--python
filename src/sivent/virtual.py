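"""Virtual mechanically ventilated patients.

Real bedside pressure–flow recordings are not publicly redistributable, so
every pipeline stage is exercised against synthetic patients instead.  A
virtual patient is a slowly drifting elastance trajectory (multiplicative
log-normal walk reflected at physiological bounds) plus a VC breath stream
generated by the same single-compartment model the pipeline identifies:
square/ramp inspirations from the waveform engine, a passive exponential
expiration (time constant R_rs/E_rs), additive Gaussian pressure sensor
noise, and a configurable fraction of asynchronous breaths.  Asynchrony is
modelled as an effort-like negative pressure deflection in mid-inspiration,
the simplest distortion that drives the model-fit APE above the 15%
true-breath threshold.

Default study conditions: a 65 kg patient ventilated at RR 15, V_T
6 mL/kg, square flow 40 L/min with a 0.3 s plateau, PEEP 10 cmH2O; baseline
elastance 33.8 cmH2O/L and resistance 9.8 cmH2O.s/L (cohort-median adult
ICU mechanics); per-interval log-walk SD 0.05 (a few percent drift per
10 min); sensor noise SD 0.5 cmH2O; 50 Hz sampling.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .waveform import RespiratoryMechanics, VCSettings, build_vc_profile, simulate_pressure

__all__ = ["VirtualPatientConfig", "simulate_ers_trajectory", "generate_patient_stream"]

DEFAULT_SETTINGS = VCSettings(RR=15, VT_perkg=6, peak_flow=40, T_plat=0.3, waveform="square")


@dataclass(frozen=True)
class VirtualPatientConfig:
    """Study conditions for one virtual patient."""

    weight: float = 65.0
    E0: float = 33.8
    R: float = 9.8
    PEEP: float = 10.0
    settings: VCSettings = DEFAULT_SETTINGS
    log_walk_sd: float = 0.05
    noise_sd: float = 0.5
    asynchrony_rate: float = 0.05
    fs: float = 50.0
    seed: int = 0
    E_bounds: tuple = (8.0, 73.0)

    def __post_init__(self) -> None:
        if not (0.0 <= self.asynchrony_rate <= 1.0):
            raise ValueError("asynchrony_rate must be in [0, 1]")
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        lo, hi = self.E_bounds
        if not (0 < lo < hi):
            raise ValueError(f"invalid elastance bounds {self.E_bounds}")
        if not (lo <= self.E0 <= hi):
            raise ValueError(f"E0={self.E0} outside bounds {self.E_bounds}")


def simulate_ers_trajectory(config: VirtualPatientConfig, n_intervals: int) -> np.ndarray:
    """Per-interval elastance: a reflected multiplicative log-normal walk.

    log E steps by N(0, log_walk_sd^2) each interval and reflects at the
    configured physiological bounds, so all values stay inside them.
    Deterministic given the config seed.
    """
    rng = np.random.default_rng(config.seed)
    lo, hi = np.log(config.E_bounds[0]), np.log(config.E_bounds[1])
    vals = np.empty(n_intervals)
    x = np.log(config.E0)
    for i in range(n_intervals):
        vals[i] = np.exp(x)
        x += rng.normal(0.0, config.log_walk_sd)
        # reflect into [lo, hi]
        period = 2.0 * (hi - lo)
        x = (x - lo) % period
        x = lo + min(x, period - x)
    return vals


def _expiration(vt: float, tau: float, t_exp: float, dt: float) -> np.ndarray:
    """Passive expiratory flow profile returning exactly -vt of volume."""
    t = np.arange(dt, t_exp + dt / 2, dt)
    flow = -(vt / tau) * np.exp(-t / tau)
    # rescale so the trapezoidal volume excursion is exactly -vt and the
    # breath ends at zero volume
    vol = np.concatenate([[0.0], np.cumsum((flow[1:] + flow[:-1]) / 2 * dt)])
    if vol[-1] != 0:
        flow *= vt / -vol[-1]
    return flow


def generate_patient_stream(
    config: VirtualPatientConfig,
    trajectory: np.ndarray | None = None,
    n_intervals: int = 18,
    interval_len: float = 600.0,
) -> tuple[dict, dict]:
    """Generate a continuous pressure–flow stream plus its ground truth.

    Returns ``(stream, truth)``: ``stream`` has uniform arrays ``t_s``,
    ``pressure_cmH2O``, ``flow_Lps``; ``truth`` records the elastance
    trajectory, mechanics, settings and the injected asynchronous breath
    indices, for round-trip validation.
    """
    if trajectory is None:
        trajectory = simulate_ers_trajectory(config, n_intervals)
    trajectory = np.asarray(trajectory, dtype=float)
    rng = np.random.default_rng(config.seed + 1)
    st = config.settings
    dt = 1.0 / config.fs
    t_cycle = 60.0 / st.RR
    t_insp = st.flow_time(config.weight) + st.T_plat
    if t_insp >= t_cycle:
        raise ValueError("infeasible settings schedule: inspiration exceeds the breath period")
    vt = st.tidal_volume(config.weight)
    n_cycle = int(round(t_cycle / dt))
    breaths_per_interval = int(round(interval_len / t_cycle))

    insp = build_vc_profile(st, config.weight, dt)
    n_insp = len(insp.t)
    exp_flow = _expiration(vt, max(config.R / max(trajectory.min(), 1e-6), 0.05),
                           t_cycle - t_insp, dt)
    n_insp = min(n_insp, n_cycle)
    flow_cycle = np.zeros(n_cycle)
    flow_cycle[:n_insp] = insp.flow[:n_insp]
    n_exp = min(len(exp_flow), n_cycle - n_insp)
    flow_cycle[n_insp : n_insp + n_exp] = exp_flow[:n_exp]

    pressures, flows = [], []
    async_breaths: list[int] = []
    breath_idx = 0
    for E in trajectory:
        mech = RespiratoryMechanics(E_rs=E, R_rs=config.R, PEEP=config.PEEP)
        # volume over one cycle from the shared flow profile
        vol_cycle = np.concatenate(
            [[0.0], np.cumsum((flow_cycle[1:] + flow_cycle[:-1]) / 2 * dt)]
        )
        p_cycle = mech.E_rs * vol_cycle + mech.R_rs * flow_cycle + mech.PEEP
        for _ in range(breaths_per_interval):
            p = p_cycle.copy()
            if rng.uniform() < config.asynchrony_rate:
                async_breaths.append(breath_idx)
                # effort-like mid-inspiration negative deflection
                a, b = n_insp // 5, n_insp
                amp = 0.8 * (p_cycle[:n_insp].max() - config.PEEP)
                p[a:b] -= amp * np.sin(np.pi * np.arange(b - a) / (b - a))
            if config.noise_sd > 0:
                p += rng.normal(0.0, config.noise_sd, size=n_cycle)
            pressures.append(p)
            flows.append(flow_cycle)
            breath_idx += 1
    pressure = np.concatenate(pressures)
    flow = np.concatenate(flows)
    t = np.arange(len(pressure)) * dt
    stream = {"t_s": t, "pressure_cmH2O": pressure, "flow_Lps": flow}
    truth = {
        "trajectory": trajectory.tolist(),
        "E0": config.E0,
        "R": config.R,
        "PEEP": config.PEEP,
        "weight": config.weight,
        "settings": {
            "RR": st.RR,
            "VT_perkg": st.VT_perkg,
            "peak_flow": st.peak_flow,
            "T_plat": st.T_plat,
            "waveform": st.waveform,
        },
        "interval_len": interval_len,
        "breaths_per_interval": breaths_per_interval,
        "asynchrony_indices": async_breaths,
        "seed": config.seed,
    }
    return stream, truth
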