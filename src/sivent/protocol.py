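"""The VENT / SiVENT setting-recommendation protocol.

Given a patient's identified mechanics, the protocol walks four stages:

* **V** (virtually ventilate): every combination of VC settings on the
  clinical grid is forward-simulated through the single-compartment model
  to predict its pressure outcomes;
* **E** (eliminate): combinations whose predicted outcomes violate
  literature safety thresholds (P_MAX < 40 cmH2O, P_PLAT < 30 cmH2O,
  I:E between 1:1 and 1:3, feasible timing) are removed;
* **N** (narrow): a clinician objective — here minimising driving pressure
  dP = E_rs * V_T — keeps only the best surviving tier;
* **T** (tabulate): survivors are listed with their predicted outcomes.

VENT simulates at the current elastance alone.  SiVENT simulates each
combination twice, at the 5th and 95th percentile of the forecast
next-interval elastance from the transition model, and a combination
survives only if its whole forecast outcome range is safe.  Because
pressures are monotone in elastance, SiVENT can only be more conservative.

The engine is fully vectorised over the grid (189,000 combinations at the
default resolution) and each run carries a boundary-sensitivity audit:
the number of combinations whose survival flips when the input elastance
moves by +/-0.05 cmH2O/L, the precision at which identified elastances are
typically reported.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .breaths import IntervalSummary
from .stochastic import ErsTransitionModel, forecast_percentiles
from .waveform import EPS, RespiratoryMechanics

logger = logging.getLogger(__name__)

__all__ = [
    "GridSpec",
    "SettingGrid",
    "SafetyThresholds",
    "ProtocolResult",
    "enumerate_grid",
    "grid_outcomes",
    "e_stage",
    "n_stage",
    "run_vent",
    "run_sivent",
    "evaluate_performance",
    "DEFAULT_GRID",
    "DEFAULT_THRESHOLDS",
]

#: elastance perturbation (cmH2O/L) used by the boundary-sensitivity audit
AUDIT_DELTA = 0.05


@dataclass(frozen=True)
class GridSpec:
    """Inclusive range and resolution of each VC setting axis.

    Defaults are the clinical grid: RR 6–35 by 1 breath/min, V_T 4–8 by
    1 mL/kg, peak flow 5–150 by 5 L/min, plateau time 0–2 by 0.1 s, and
    both waveforms — 30*5*30*21*2 = 189,000 combinations.
    """

    RR: tuple = (6, 35, 1)
    VT: tuple = (4, 8, 1)
    flow: tuple = (5, 150, 5)
    T_plat: tuple = (0.0, 2.0, 0.1)
    waveforms: tuple = ("square", "ramp")

    @staticmethod
    def _axis(lo: float, hi: float, step: float) -> np.ndarray:
        if step <= 0 or hi < lo:
            raise ValueError(f"empty or inconsistent axis ({lo}, {hi}, {step})")
        n_steps = (hi - lo) / step
        if abs(n_steps - round(n_steps)) > 1e-9:
            raise ValueError(f"axis range ({lo}, {hi}) is not a multiple of step {step}")
        vals = lo + step * np.arange(int(round(n_steps)) + 1)
        return np.round(vals, 10)

    def axes(self) -> dict:
        if len(self.waveforms) == 0:
            raise ValueError("waveform axis is empty")
        return {
            "RR": self._axis(*self.RR),
            "VT": self._axis(*self.VT),
            "flow": self._axis(*self.flow),
            "T_plat": self._axis(*self.T_plat),
            "waveform": np.asarray(self.waveforms, dtype=object),
        }


@dataclass(frozen=True)
class SettingGrid:
    """Enumerated setting combinations as flat parallel arrays.

    Order is the Cartesian product with RR as the outermost axis and the
    waveform innermost: (RR, VT, flow, T_plat, waveform).
    ``is_ramp`` encodes the waveform axis as a boolean.
    """

    RR: np.ndarray
    VT: np.ndarray
    flow: np.ndarray
    T_plat: np.ndarray
    is_ramp: np.ndarray

    @property
    def n(self) -> int:
        return len(self.RR)

    def waveform_labels(self) -> np.ndarray:
        return np.where(self.is_ramp, "ramp", "square")


@dataclass(frozen=True)
class SafetyThresholds:
    """Literature-recommended outcome limits applied in the E-stage.

    Pressure limits are strict (<); the I:E denominator range and the
    RR / V_T setting ranges are inclusive.  PEEP has no threshold — it is
    specified by the clinician and enters only the pressure simulation.
    """

    RR_range: tuple = (6.0, 35.0)
    VT_range: tuple = (4.0, 8.0)
    Pmax_limit: float = 40.0
    Pplat_limit: float = 30.0
    IE_range: tuple = (1.0, 3.0)


DEFAULT_GRID = GridSpec()
DEFAULT_THRESHOLDS = SafetyThresholds()

#: thresholds with every limit disabled (useful as a null control)
UNRESTRICTED = SafetyThresholds(
    RR_range=(-np.inf, np.inf),
    VT_range=(-np.inf, np.inf),
    Pmax_limit=np.inf,
    Pplat_limit=np.inf,
    IE_range=(-np.inf, np.inf),
)


@dataclass
class ProtocolResult:
    """Stage counts, survivor table and audit of one protocol run."""

    protocol: str
    stage_counts: dict
    survivors: pd.DataFrame
    pct_reduction: float
    boundary_flips: int = 0
    forecast: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        counts = list(self.stage_counts.values())
        if any(b > a for a, b in zip(counts, counts[1:])):
            raise ValueError(f"stage counts must be nonincreasing: {self.stage_counts}")


def enumerate_grid(grid: GridSpec = DEFAULT_GRID) -> SettingGrid:
    """Enumerate the full Cartesian setting grid in documented order."""
    ax = grid.axes()
    rr, vt, fl, tp, wf = np.meshgrid(
        ax["RR"], ax["VT"], ax["flow"], ax["T_plat"],
        np.arange(len(ax["waveform"])), indexing="ij",
    )
    is_ramp = np.asarray(
        [w == "ramp" for w in ax["waveform"]], dtype=bool
    )[wf.ravel()]
    return SettingGrid(
        RR=rr.ravel().astype(float),
        VT=vt.ravel().astype(float),
        flow=fl.ravel().astype(float),
        T_plat=tp.ravel().astype(float),
        is_ramp=is_ramp,
    )


def grid_outcomes(
    E_rs: float, R_rs: float, PEEP: float, weight: float, grid: SettingGrid
) -> dict:
    """V-stage: closed-form outcomes for every combination, vectorised.

    Returns arrays keyed ``Pmax, Pplat, dP, T_insp, T_exp, IE, feasible``.
    Mirrors :func:`sivent.waveform.compute_outcomes` exactly (tested by
    brute-force equivalence).
    """
    if weight <= 0:
        raise ValueError("weight must be positive")
    vt = grid.VT * weight / 1000.0
    vmax = grid.flow / 60.0
    t_flow = np.where(grid.is_ramp, 2.0, 1.0) * vt / vmax
    t_insp = t_flow + grid.T_plat
    t_exp = 60.0 / grid.RR - t_insp
    feasible = t_exp > EPS
    # IE <= 0 marks infeasible timing; the default IE range [1, 3]
    # eliminates those combinations without a separate feasibility rule
    ie = t_exp / t_insp
    p_plat = E_rs * vt + PEEP
    p_max_sq = p_plat + R_rs * vmax
    # ramp: pressure max over {onset, interior stationary point, end of flow}
    p_onset = R_rs * vmax + PEEP
    p_ramp = np.maximum(p_onset, p_plat)
    if E_rs > 0:
        t_star = t_flow - R_rs / E_rs
        interior = (t_star > 0) & (t_star < t_flow)
        with np.errstate(invalid="ignore"):
            vol = vmax * (t_star - t_star**2 / (2.0 * t_flow))
            flo = vmax * (1.0 - t_star / t_flow)
            p_int = E_rs * vol + R_rs * flo + PEEP
        p_ramp = np.where(interior, np.maximum(p_ramp, p_int), p_ramp)
    p_max = np.where(grid.is_ramp, p_ramp, p_max_sq)
    return {
        "Pmax": p_max,
        "Pplat": p_plat,
        "dP": E_rs * vt,
        "T_insp": t_insp,
        "T_exp": t_exp,
        "IE": ie,
        "feasible": feasible,
    }


def e_stage(
    outcome_sets,
    grid: SettingGrid,
    thresholds: SafetyThresholds = DEFAULT_THRESHOLDS,
) -> np.ndarray:
    """E-stage survivor mask; all outcome sets must pass every threshold.

    ``outcome_sets`` is one :func:`grid_outcomes` dict or a sequence of
    them (SiVENT passes the 5th- and 95th-percentile simulations so the
    whole forecast range must be safe).  An empty survivor set is a valid
    result, not an error.
    """
    if isinstance(outcome_sets, dict):
        outcome_sets = [outcome_sets]
    mask = np.ones(grid.n, dtype=bool)
    mask &= (grid.RR >= thresholds.RR_range[0] - EPS) & (
        grid.RR <= thresholds.RR_range[1] + EPS
    )
    mask &= (grid.VT >= thresholds.VT_range[0] - EPS) & (
        grid.VT <= thresholds.VT_range[1] + EPS
    )
    for out in outcome_sets:
        mask &= out["Pmax"] < thresholds.Pmax_limit - EPS
        mask &= out["Pplat"] < thresholds.Pplat_limit - EPS
        mask &= (out["IE"] >= thresholds.IE_range[0] - EPS) & (
            out["IE"] <= thresholds.IE_range[1] + EPS
        )
    return mask


def n_stage(
    mask: np.ndarray, dP: np.ndarray, objective: str | None = "min_dP"
) -> np.ndarray:
    """N-stage: keep survivors meeting the narrowing objective.

    ``min_dP`` keeps every combination whose driving pressure ties the
    minimum among survivors; since dP = E_rs * V_T this is exactly the
    lowest surviving tidal-volume tier.  ``None`` applies no narrowing.
    An empty mask passes through empty.
    """
    if objective is None:
        return mask.copy()
    if objective != "min_dP":
        raise ValueError(f"unknown narrowing objective {objective!r}")
    if not mask.any():
        return mask.copy()
    best = dP[mask].min()
    return mask & (dP <= best + EPS)


def _as_mechanics(summary, PEEP=None) -> tuple[float, float, float]:
    """Accept an IntervalSummary, RespiratoryMechanics or (E, R, PEEP)."""
    if isinstance(summary, IntervalSummary):
        return summary.Ers_N, summary.Rrs_N, summary.PEEP_N
    if isinstance(summary, RespiratoryMechanics):
        return summary.E_rs, summary.R_rs, summary.PEEP
    E, R, P = summary
    return float(E), float(R), float(P)


def _survivor_table(
    grid: SettingGrid, mask: np.ndarray, outcome_sets: list
) -> pd.DataFrame:
    """T-stage table: surviving settings with (ranges of) outcomes."""
    idx = np.flatnonzero(mask)
    cols = {
        "RR": grid.RR[idx],
        "waveform": grid.waveform_labels()[idx],
        "VT_mL_per_kg": grid.VT[idx],
        "peak_flow_Lpm": grid.flow[idx],
        "T_plat_s": grid.T_plat[idx],
    }
    for key in ("Pmax", "Pplat", "dP"):
        vals = np.stack([o[key][idx] for o in outcome_sets])
        cols[f"{key}_lo"] = vals.min(axis=0)
        cols[f"{key}_hi"] = vals.max(axis=0)
    cols["IE"] = outcome_sets[0]["IE"][idx]
    return pd.DataFrame(cols)


def _run(
    protocol: str,
    E_values: list,
    R_rs: float,
    PEEP: float,
    weight: float,
    thresholds: SafetyThresholds,
    objective: str | None,
    grid_spec: GridSpec,
    audit: bool,
    forecast: dict | None = None,
) -> ProtocolResult:
    grid = enumerate_grid(grid_spec)

    def final_mask(e_vals) -> tuple[np.ndarray, np.ndarray, list]:
        outs = [grid_outcomes(e, R_rs, PEEP, weight, grid) for e in e_vals]
        em = e_stage(outs, grid, thresholds)
        # conservative narrowing: the largest forecast dP (dP is linear in
        # E_rs, so any percentile selects the same tidal-volume tier)
        dp_hi = np.stack([o["dP"] for o in outs]).max(axis=0)
        return n_stage(em, dp_hi, objective), em, outs

    nmask, emask, outs = final_mask(E_values)
    flips = 0
    if audit:
        lo_mask, _, _ = final_mask([max(e - AUDIT_DELTA, 0.0) for e in E_values])
        hi_mask, _, _ = final_mask([e + AUDIT_DELTA for e in E_values])
        flips = int((lo_mask != hi_mask).sum())
    counts = {
        "initial": grid.n,
        "V": grid.n,
        "E": int(emask.sum()),
        "N": int(nmask.sum()),
    }
    if counts["N"] == 0:
        logger.warning("%s: no setting combination survived the protocol", protocol)
    table = _survivor_table(grid, nmask, outs)
    return ProtocolResult(
        protocol=protocol,
        stage_counts=counts,
        survivors=table,
        pct_reduction=100.0 * (1.0 - counts["N"] / grid.n),
        boundary_flips=flips,
        forecast=forecast or {},
    )


def run_vent(
    summary,
    weight: float,
    thresholds: SafetyThresholds = DEFAULT_THRESHOLDS,
    objective: str | None = "min_dP",
    grid_spec: GridSpec = DEFAULT_GRID,
    audit: bool = True,
) -> ProtocolResult:
    """Run the VENT protocol at the current interval mechanics.

    ``summary`` is an :class:`IntervalSummary`, a
    :class:`RespiratoryMechanics`, or an (E_rs, R_rs, PEEP) triple.
    """
    E, R, PEEP = _as_mechanics(summary)
    if not np.isfinite([E, R, PEEP]).all() or E < 0 or R < 0:
        raise ValueError(f"invalid interval mechanics (E={E}, R={R}, PEEP={PEEP})")
    return _run("VENT", [E], R, PEEP, weight, thresholds, objective, grid_spec, audit)


def run_sivent(
    summary,
    model: ErsTransitionModel,
    weight: float,
    thresholds: SafetyThresholds = DEFAULT_THRESHOLDS,
    objective: str | None = "min_dP",
    grid_spec: GridSpec = DEFAULT_GRID,
    audit: bool = True,
    levels=(5.0, 95.0),
) -> ProtocolResult:
    """Run the SiVENT protocol against the forecast elastance range.

    The transition model forecasts the 5th/95th percentile of next-interval
    elastance given the current one; each combination is simulated at both
    and must be safe across the whole range.
    """
    E, R, PEEP = _as_mechanics(summary)
    fc = forecast_percentiles(model, E, levels=levels)
    return _run(
        "SiVENT",
        list(fc.values),
        R,
        PEEP,
        weight,
        thresholds,
        objective,
        grid_spec,
        audit,
        forecast={"Ers_N": E, **{f"p{g:g}": v for g, v in fc.as_dict().items()}},
    )


def evaluate_performance(
    summaries,
    model: ErsTransitionModel,
    weight: float,
    thresholds: SafetyThresholds = DEFAULT_THRESHOLDS,
    objective: str | None = "min_dP",
    grid_spec: GridSpec = DEFAULT_GRID,
) -> tuple[pd.DataFrame, dict]:
    """Run VENT and SiVENT at every usable interval and aggregate.

    Parameters
    ----------
    summaries : list of IntervalSummary
        Per-interval median mechanics (e.g. from
        :func:`sivent.breaths.process_stream`); one protocol run per entry.

    Returns
    -------
    (table, aggregates)
        ``table`` has one row per interval (mechanics, survivor counts and
        percentage reductions for both protocols); ``aggregates`` holds the
        cohort-style median [IQR] of each count/reduction column.
    """
    summaries = list(summaries)
    if not summaries:
        raise ValueError("no usable intervals")
    rows = []
    for s in summaries:
        E, R, PEEP = _as_mechanics(s)
        vent = run_vent((E, R, PEEP), weight, thresholds, objective, grid_spec, audit=False)
        siv = run_sivent(
            (E, R, PEEP), model, weight, thresholds, objective, grid_spec, audit=False
        )
        rows.append(
            {
                "interval": getattr(s, "N", len(rows) + 1),
                "Ers_N": E,
                "Rrs_N": R,
                "PEEP_N": PEEP,
                "vent_count": vent.stage_counts["N"],
                "sivent_count": siv.stage_counts["N"],
                "vent_pct_reduction": vent.pct_reduction,
                "sivent_pct_reduction": siv.pct_reduction,
            }
        )
    table = pd.DataFrame(rows)
    aggregates = {}
    for col in (
        "vent_count",
        "sivent_count",
        "vent_pct_reduction",
        "sivent_pct_reduction",
    ):
        q25, q50, q75 = np.percentile(table[col], [25, 50, 75])
        aggregates[col] = {"median": float(q50), "iqr": (float(q25), float(q75))}
    return table, aggregates
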