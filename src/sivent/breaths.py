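"""Breath segmentation, true-breath filtering and interval summaries.

A continuous airway pressure–flow recording is cut into breaths using
threshold-plus-persistence rules phrased at the 50 Hz recording rate:

* inspiration onset: flow > 0.1 L/s and pressure > PEEP + 2 cmH2O, with
  positive flow sustained over the next 8 samples (0.16 s);
* expiration onset: flow < -0.1 L/s sustained over 8 samples;
* a candidate breath is kept only if its peak inspiratory volume exceeds
  40 mL, its peak inspiratory pressure exceeds PEEP + 1 cmH2O inside the
  inspiratory phase, and expiration is detected within 4.125 s of the
  inspiration onset.

Breaths passing segmentation are then screened as "true breaths": the
model fit must have APE <= 15%, the estimated elastance must be positive,
and the elastance must lie inside the 5th–95th percentile of the patient's
previously accepted estimates (an expanding patient-specific window).
Asynchronous breaths — waveforms distorted by patient effort — fail the
APE screen because passive single-compartment mechanics no longer explain
the measured pressure.

Interval summaries (default 10 min) are medians over the true breaths in
the interval, the granularity at which the elastance transition model and
the setting-recommendation protocol operate.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import cumulative_trapezoid

from .identify import MechanicsEstimate, identify_inspiration

logger = logging.getLogger(__name__)

__all__ = [
    "SegmentedBreath",
    "IntervalSummary",
    "segment_breaths",
    "estimate_peep",
    "filter_true_breaths",
    "summarize_interval",
    "process_stream",
]

FLOW_ON = 0.1  # L/s, inspiration-onset flow threshold
FLOW_OFF = -0.1  # L/s, expiration-onset flow threshold
PRESSURE_MARGIN = 2.0  # cmH2O above PEEP at inspiration onset
PERSIST = 8  # samples of sustained flow sign (0.16 s at 50 Hz)
MIN_PEAK_VOLUME = 0.040  # L
PIP_MARGIN = 1.0  # cmH2O above PEEP
MAX_INSP_TO_EXP = 4.125  # s, expiration must start within this of onset
APE_THRESHOLD = 15.0  # percent
PERCENTILE_BAND = (5.0, 95.0)
MIN_HISTORY = 10  # accepted breaths before the percentile screen engages
#: minimal relative half-width of the percentile band.  A nearly constant
#: accepted history (regular ventilation, synthetic data) collapses the
#: empirical 5th-95th band to zero width and would reject genuine small
#: drift; real histories are far wider, so this floor never binds there.
MIN_BAND_REL = 0.05


@dataclass
class SegmentedBreath:
    """One breath cut from the stream, with a short pre-inspiratory tail.

    Indices are into the original stream; the stored arrays cover
    ``[slice_start, end)`` so the pre-inspiratory pause is available for
    PEEP estimation.
    """

    insp_start: int
    exp_start: int
    end: int
    slice_start: int
    t: np.ndarray
    pressure: np.ndarray
    flow: np.ndarray
    PIP: float
    peak_insp_volume: float
    PEEP_est: float | None = None
    quality_flags: set = field(default_factory=set)
    estimate: MechanicsEstimate | None = None

    def inspiration(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """(t, pressure, flow) from breath start to end-inspiration."""
        i0 = self.insp_start - self.slice_start
        i1 = self.exp_start - self.slice_start
        return self.t[i0:i1], self.pressure[i0:i1], self.flow[i0:i1]

    @property
    def onset_time(self) -> float:
        return float(self.t[self.insp_start - self.slice_start])


@dataclass(frozen=True)
class IntervalSummary:
    """Median mechanics over the true breaths of one interval."""

    N: int
    Ers_N: float
    Rrs_N: float
    PEEP_N: float
    n_true_breaths: int
    interval_len: float


def _sustained(mask: np.ndarray, n: int) -> np.ndarray:
    """True where ``mask`` holds at every one of the next ``n`` samples."""
    out = np.zeros(len(mask), dtype=bool)
    if len(mask) > n:
        windows = np.lib.stride_tricks.sliding_window_view(mask[1:], n)
        out[: len(windows)] = windows.all(axis=1)
    return out


def estimate_peep(breath: SegmentedBreath, lookback_s: float = 0.5) -> float:
    """PEEP from the pre-inspiratory pause, rounded to integer cmH2O.

    Median airway pressure over the near-zero-flow samples preceding the
    inspiration onset; falls back to the minimum pressure in the breath if
    no pre-inspiratory samples exist.
    """
    i0 = breath.insp_start - breath.slice_start
    pre_p = breath.pressure[:i0]
    pre_f = breath.flow[:i0]
    if len(pre_p):
        dt = float(breath.t[1] - breath.t[0]) if len(breath.t) > 1 else 0.02
        n = max(1, int(round(lookback_s / dt)))
        pre_p, pre_f = pre_p[-n:], pre_f[-n:]
        quiet = np.abs(pre_f) < FLOW_ON
        if quiet.any():
            return float(np.round(np.median(pre_p[quiet])))
        return float(np.round(np.median(pre_p)))
    return float(np.round(np.min(breath.pressure)))


def segment_breaths(
    t: np.ndarray,
    pressure: np.ndarray,
    flow: np.ndarray,
    peep_hint: float | None = None,
    keep_rejected: bool = False,
) -> list[SegmentedBreath]:
    """Segment a uniformly sampled pressure–flow stream into breaths.

    Parameters
    ----------
    t, pressure, flow : arrays
        Uniform time grid (s), airway pressure (cmH2O), flow (L/s).
    peep_hint : float, optional
        PEEP value entering the onset criterion.  Defaults to the global
        pressure minimum, a safe underestimate before PEEP is known; in
        streaming use pass the previous interval's PEEP estimate.
    keep_rejected : bool
        When True, breaths failing the definition criteria are returned
        too, with their ``quality_flags`` set.
    """
    t = np.asarray(t, dtype=float)
    pressure = np.asarray(pressure, dtype=float)
    flow = np.asarray(flow, dtype=float)
    if len(t) == 0:
        raise ValueError("empty stream")
    if np.isnan(pressure).any() or np.isnan(flow).any():
        raise ValueError("stream contains NaN samples")
    if peep_hint is None:
        peep_hint = float(np.min(pressure))

    onset = (
        (flow > FLOW_ON)
        & (pressure > peep_hint + PRESSURE_MARGIN)
        & _sustained(flow > 0.0, PERSIST)
    )
    exp_onset = (flow < FLOW_OFF) & _sustained(flow < 0.0, PERSIST)
    onset_idx = np.flatnonzero(onset)
    exp_idx = np.flatnonzero(exp_onset)

    # collapse runs of onset candidates: a new breath may only start once an
    # expiration has begun after the previous onset
    starts: list[int] = []
    for i in onset_idx:
        if starts:
            nxt_exp = exp_idx[exp_idx > starts[-1]]
            if len(nxt_exp) == 0 or i <= nxt_exp[0]:
                continue
        starts.append(int(i))

    breaths: list[SegmentedBreath] = []
    dt = float(t[1] - t[0]) if len(t) > 1 else 0.02
    lookback = int(round(2.0 / dt))
    for k, i in enumerate(starts):
        end = starts[k + 1] if k + 1 < len(starts) else len(t)
        nxt = exp_idx[(exp_idx > i) & (exp_idx < end)]
        flags: set = set()
        if len(nxt) == 0:
            if k + 1 == len(starts):
                continue  # trailing partial breath, no expiration recorded
            flags.add("no_expiration")
            j = end
        else:
            j = int(nxt[0])
        sl = max(0, i - lookback, starts[k - 1] if k else 0)
        insp_vol = cumulative_trapezoid(flow[i:j], t[i:j], initial=0.0)
        peak_vol = float(insp_vol.max()) if len(insp_vol) else 0.0
        pip = float(pressure[i:j].max()) if j > i else float("-inf")
        br = SegmentedBreath(
            insp_start=i,
            exp_start=j,
            end=end,
            slice_start=sl,
            t=t[sl:end],
            pressure=pressure[sl:end],
            flow=flow[sl:end],
            PIP=pip,
            peak_insp_volume=peak_vol,
            quality_flags=flags,
        )
        br.PEEP_est = estimate_peep(br)
        if j >= len(t) or t[j] - t[i] > MAX_INSP_TO_EXP:
            br.quality_flags.add("late_expiration")
        if peak_vol <= MIN_PEAK_VOLUME:
            br.quality_flags.add("low_volume")
        if pip <= br.PEEP_est + PIP_MARGIN:
            br.quality_flags.add("low_pip")
        if keep_rejected or not br.quality_flags:
            breaths.append(br)
    return breaths


def filter_true_breaths(
    breaths: list[SegmentedBreath],
    history: list[float] | None = None,
    ape_threshold: float = APE_THRESHOLD,
    min_history: int = MIN_HISTORY,
) -> list[SegmentedBreath]:
    """Screen segmented breaths as 'true breaths'; flags the rest.

    Attaches a mechanics estimate to every breath (identified at the
    breath's own PEEP estimate when missing) and flags:

    * ``ape_exceeded`` — median model-fit error above ``ape_threshold`` %;
    * ``nonpositive_elastance`` — E_rs <= 0 or an unidentifiable breath;
    * ``percentile_outlier`` — E_rs outside the 5th–95th percentile of this
      patient's previously accepted estimates (expanding window, skipped
      with a warning until ``min_history`` breaths have accrued).

    Returns the full list; true breaths are those with empty
    ``quality_flags``.  ``history`` is mutated in place when provided.
    """
    if history is None:
        history = []
    warned = False
    for br in breaths:
        if br.estimate is None:
            t, p, f = br.inspiration()
            if len(t) < 3:
                br.quality_flags.add("nonpositive_elastance")
                continue
            br.estimate = identify_inspiration(t, p, f, br.PEEP_est)
        est = br.estimate
        if not est.valid or est.E_rs <= 0.0:
            br.quality_flags.add("nonpositive_elastance")
        if est.valid and est.APE > ape_threshold:
            br.quality_flags.add("ape_exceeded")
        if not br.quality_flags:
            if len(history) >= min_history:
                lo, hi = np.percentile(history, PERCENTILE_BAND)
                med = float(np.median(history))
                lo = min(lo, (1.0 - MIN_BAND_REL) * med)
                hi = max(hi, (1.0 + MIN_BAND_REL) * med)
                if not (lo <= est.E_rs <= hi):
                    br.quality_flags.add("percentile_outlier")
            elif not warned:
                logger.warning(
                    "elastance history has %d < %d accepted breaths; "
                    "percentile criterion skipped",
                    len(history),
                    min_history,
                )
                warned = True
        if not br.quality_flags:
            history.append(est.E_rs)
    return breaths


def summarize_interval(
    true_breaths: list[SegmentedBreath],
    N: int = 0,
    interval_len: float = 600.0,
) -> IntervalSummary:
    """Median mechanics over the true breaths of one interval."""
    if not true_breaths:
        raise ValueError("interval has no true breaths")
    ests = [b.estimate for b in true_breaths]
    if any(e is None for e in ests):
        raise ValueError("breaths must carry mechanics estimates")
    return IntervalSummary(
        N=N,
        Ers_N=float(np.median([e.E_rs for e in ests])),
        Rrs_N=float(np.median([e.R_rs for e in ests])),
        PEEP_N=float(np.median([b.PEEP_est for b in true_breaths])),
        n_true_breaths=len(true_breaths),
        interval_len=interval_len,
    )


def process_stream(
    t: np.ndarray,
    pressure: np.ndarray,
    flow: np.ndarray,
    interval_len: float = 600.0,
    peep_hint: float | None = None,
) -> list[IntervalSummary]:
    """Full per-interval pipeline: segment, identify, filter, summarise.

    Intervals with no true breaths are skipped (their index is absent from
    the returned list).
    """
    breaths = segment_breaths(t, pressure, flow, peep_hint=peep_hint)
    filter_true_breaths(breaths)
    summaries: list[IntervalSummary] = []
    if not breaths:
        return summaries
    t0 = float(t[0])
    n_intervals = int(np.floor((float(t[-1]) - t0) / interval_len)) + 1
    for n in range(n_intervals):
        lo, hi = t0 + n * interval_len, t0 + (n + 1) * interval_len
        group = [
            b for b in breaths if not b.quality_flags and lo <= b.onset_time < hi
        ]
        if not group:
            logger.info("interval %d skipped: no true breaths", n)
            continue
        summaries.append(summarize_interval(group, N=n, interval_len=interval_len))
    return summaries
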