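"""Integral-based identification of respiratory mechanics from one breath.

Integrating the single-compartment model P = E_rs*V + R_rs*dV/dt + PEEP
from the breath start t0 to each inspiratory sample t_i turns the pointwise
model into one linear equation per sample,

    [ int_{t0}^{t_i} V dt,  V_i - V_0 ] . [E_rs, R_rs]^T
        = int_{t0}^{t_i} (P - PEEP) dt,

which is solved for nonnegative E_rs and R_rs by Lawson–Hanson nonnegative
least squares.  Cumulative integration low-pass filters the sensor noise
that would dominate a derivative-based fit.  Fit quality is summarised by
the median absolute percentage error (APE) between the fitted and measured
inspiratory pressure; breaths with APE above threshold are typically
asynchronous and are rejected upstream.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.integrate import cumulative_trapezoid
from scipy.optimize import nnls

logger = logging.getLogger(__name__)

__all__ = ["MechanicsEstimate", "identify_inspiration", "identify_breath", "compute_ape"]


@dataclass(frozen=True)
class MechanicsEstimate:
    """Per-breath mechanics estimate with its fit statistic.

    ``valid`` is False when the regression system is rank-deficient (e.g.
    zero flow) and the estimate is meaningless.
    """

    E_rs: float
    R_rs: float
    APE: float
    n_equations: int
    valid: bool


def compute_ape(P_sim: np.ndarray, P_mea: np.ndarray) -> float:
    """Median absolute percentage error between fitted and measured pressure.

    APE = median(|(P_sim - P_mea) / P_sim|) * 100 over the compared samples.
    Samples where P_sim is exactly zero cannot be normalised and are
    excluded (logged).
    """
    P_sim = np.asarray(P_sim, dtype=float)
    P_mea = np.asarray(P_mea, dtype=float)
    if P_sim.shape != P_mea.shape:
        raise ValueError("P_sim and P_mea must have equal lengths")
    mask = P_sim != 0.0
    if not mask.all():
        logger.info("compute_ape: excluded %d samples with P_sim == 0", (~mask).sum())
    if not mask.any():
        return float("nan")
    rel = np.abs((P_sim[mask] - P_mea[mask]) / P_sim[mask])
    return float(np.median(rel) * 100.0)


def identify_inspiration(
    t: np.ndarray,
    pressure: np.ndarray,
    flow: np.ndarray,
    PEEP: float,
) -> MechanicsEstimate:
    """Identify (E_rs, R_rs) from the inspiratory samples of one breath.

    ``t``, ``pressure`` and ``flow`` run from the very beginning of the
    breath (t0) to end-inspiration.  Volume is reconstructed as the running
    trapezoidal integral of flow, so only pressure–flow data are required.
    One equation is built per sample from the second sample onward.
    """
    t = np.asarray(t, dtype=float)
    pressure = np.asarray(pressure, dtype=float)
    flow = np.asarray(flow, dtype=float)
    if len(t) < 3:
        raise ValueError("need at least 3 inspiratory samples")
    volume = cumulative_trapezoid(flow, t, initial=0.0)
    if np.any(volume < -1e-6):
        raise ValueError("negative inspiratory volume — not a VC inspiration")

    int_v = cumulative_trapezoid(volume, t, initial=0.0)
    rhs = cumulative_trapezoid(pressure - PEEP, t, initial=0.0)
    A = np.column_stack([int_v[1:], volume[1:] - volume[0]])
    b = rhs[1:]

    # rank check: a zero (or numerically zero) column means E and R are not
    # jointly identifiable from this breath
    scale = max(np.abs(A).max(), 1.0)
    if np.linalg.matrix_rank(A / scale, tol=1e-10) < 2:
        return MechanicsEstimate(0.0, 0.0, float("nan"), len(b), valid=False)

    coef, _ = nnls(A, b)
    E_rs, R_rs = float(coef[0]), float(coef[1])
    p_fit = E_rs * volume + R_rs * flow + PEEP
    ape = compute_ape(p_fit, pressure)
    return MechanicsEstimate(E_rs, R_rs, ape, len(b), valid=True)


def identify_breath(breath, PEEP: float | None = None) -> MechanicsEstimate:
    """Identify mechanics from a segmented breath (inspiration only).

    ``breath`` is a :class:`sivent.breaths.SegmentedBreath`; ``PEEP``
    defaults to the breath's own PEEP estimate.
    """
    if PEEP is None:
        PEEP = breath.PEEP_est
    if PEEP is None:
        raise ValueError("breath has no PEEP estimate and none was given")
    t, p, f = breath.inspiration()
    return identify_inspiration(t, p, f, PEEP)
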