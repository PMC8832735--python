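"""Stochastic model of respiratory elastance transitions.

Elastance drifts with patient condition, so a setting that is safe now may
not be in the next monitoring interval.  The transition model captures
P(E_rs,N+1 | E_rs,N) nonparametrically: each observed transition pair
(y_i = E_rs,N, x_i = E_rs,N+1) contributes a bivariate Gaussian kernel
truncated to the physically meaningful nonnegative quadrant,

    P(x | y) = sum_i w_i(y) * phi(x; x_i, sigma2_x_i) / p_x_i,
    w_i(y) = [phi(y; y_i, sigma2_y_i) / p_y_i] / sum_j phi(y; y_j, sigma2_y_j) / p_y_j,

where p = integral of the kernel over [0, inf) renormalises each truncated
kernel to unit mass.  By construction the conditional density integrates to
one on [0, inf) for every supported y.  Quantiles of this conditional law
(5th/95th by default) give the forecast elastance range the setting
recommendation protocol simulates against.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.integrate import cumulative_trapezoid
from scipy.stats import norm

__all__ = [
    "ErsTransitionModel",
    "PercentileForecast",
    "fit_transition_model",
    "conditional_density",
    "forecast_percentiles",
    "validate_coverage",
    "percentile_table",
]

GRID_POINTS = 1000
GRID_SPAN = 1.5  # x-grid upper bound as a multiple of max observed E_rs,N+1


@dataclass(frozen=True)
class PercentileForecast:
    """Forecast elastance at the requested percentile levels."""

    levels: tuple
    values: tuple

    def __post_init__(self) -> None:
        if any(b < a for a, b in zip(self.values, self.values[1:])):
            raise ValueError("forecast values must be nondecreasing in level")

    def as_dict(self) -> dict:
        return dict(zip(self.levels, self.values))


@dataclass(frozen=True)
class ErsTransitionModel:
    """Truncated-Gaussian kernel mixture over elastance transition pairs.

    Attributes
    ----------
    y, x : arrays
        Current-interval (E_rs,N) and next-interval (E_rs,N+1) elastances of
        each training pair, cmH2O/L.
    sigma2_y, sigma2_x : arrays
        Per-kernel variances on each axis.
    p_y, p_x : arrays
        Mass of each kernel on [0, inf) — the truncation normalisers.
    bandwidth_rule : str
        Name of the rule the variances came from (for provenance).
    """

    y: np.ndarray
    x: np.ndarray
    sigma2_y: np.ndarray
    sigma2_x: np.ndarray
    p_y: np.ndarray
    p_x: np.ndarray
    bandwidth_rule: str = "silverman"

    @property
    def n(self) -> int:
        return len(self.x)

    def default_grid(self) -> np.ndarray:
        return np.linspace(0.0, GRID_SPAN * float(self.x.max()), GRID_POINTS)

    def to_dict(self) -> dict:
        return {
            "pairs": np.column_stack([self.y, self.x]).tolist(),
            "sigma2_y": self.sigma2_y.tolist(),
            "sigma2_x": self.sigma2_x.tolist(),
            "p_y": self.p_y.tolist(),
            "p_x": self.p_x.tolist(),
            "bandwidth_rule": self.bandwidth_rule,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ErsTransitionModel":
        pairs = np.asarray(d["pairs"], dtype=float)
        return cls(
            y=pairs[:, 0],
            x=pairs[:, 1],
            sigma2_y=np.asarray(d["sigma2_y"], dtype=float),
            sigma2_x=np.asarray(d["sigma2_x"], dtype=float),
            p_y=np.asarray(d["p_y"], dtype=float),
            p_x=np.asarray(d["p_x"], dtype=float),
            bandwidth_rule=d.get("bandwidth_rule", "custom"),
        )

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict()))

    @classmethod
    def load(cls, path: str | Path) -> "ErsTransitionModel":
        return cls.from_dict(json.loads(Path(path).read_text()))


def _loo_conditional_loglik(y: np.ndarray, x: np.ndarray, s_y: float, s_x: float) -> float:
    """Leave-one-out conditional log-likelihood of the training pairs."""
    ky = norm.pdf(y[:, None], loc=y[None, :], scale=s_y) / norm.cdf(y / s_y)[None, :]
    kx = norm.pdf(x[:, None], loc=x[None, :], scale=s_x) / norm.cdf(x / s_x)[None, :]
    np.fill_diagonal(ky, 0.0)
    num = (ky * kx).sum(axis=1)
    den = ky.sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        ll = np.log(num / den)
    ll = ll[np.isfinite(ll)]
    if len(ll) == 0:
        return -np.inf
    return float(ll.sum())


def _cv_sigmas(y: np.ndarray, x: np.ndarray) -> tuple[float, float]:
    """Bandwidths maximising the leave-one-out conditional likelihood.

    Scans a multiplier grid around the Silverman pilot on each axis.
    Rule-of-thumb marginal bandwidths systematically oversmooth a
    conditional density, widening the forecast bands past their nominal
    coverage; the conditional likelihood targets exactly the quantity the
    model is used for.
    """
    h_y = _rule_sigma(y, "silverman")
    h_x = _rule_sigma(x, "silverman")
    mult = np.geomspace(0.1, 1.5, 12)
    best = (-np.inf, h_y, h_x)
    for a in mult:
        for b in mult:
            ll = _loo_conditional_loglik(y, x, h_y * a, h_x * b)
            if ll > best[0]:
                best = (ll, h_y * a, h_x * b)
    return best[1], best[2]


def _rule_sigma(values: np.ndarray, rule: str) -> float:
    """Global rule-of-thumb kernel SD for one axis."""
    n = len(values)
    sd = float(np.std(values, ddof=1)) if n > 1 else 0.0
    if rule == "silverman":
        iqr = float(np.subtract(*np.percentile(values, [75, 25])))
        spread = min(sd, iqr / 1.34) if iqr > 0 else sd
        h = 0.9 * spread * n ** (-1 / 5)
    elif rule == "scott":
        h = 1.06 * sd * n ** (-1 / 5)
    else:
        raise ValueError(f"unknown bandwidth rule {rule!r}")
    if h <= 0:
        raise ValueError(
            f"bandwidth rule {rule!r} gave nonpositive bandwidth "
            f"(degenerate data, n={n}); pass an explicit bandwidth"
        )
    return h


def fit_transition_model(
    pairs,
    bandwidth_rule: str | float | tuple = "cv",
) -> ErsTransitionModel:
    """Fit the transition model on (E_rs,N, E_rs,N+1) pairs.

    Parameters
    ----------
    pairs : array-like, shape (n, 2)
        Columns are (E_rs,N, E_rs,N+1) in cmH2O/L; all values positive.
    bandwidth_rule : str, float or (float, float)
        ``"cv"`` (default): leave-one-out conditional-likelihood selection,
        which calibrates the forecast bands; ``"silverman"`` or ``"scott"``
        rule-of-thumb applied per axis; or an explicit kernel SD (one value
        for both axes, or a (sigma_y, sigma_x) pair).  ``"cv"`` needs at
        least 10 pairs and falls back to ``"silverman"`` below that.
    """
    pairs = np.atleast_2d(np.asarray(pairs, dtype=float))
    if pairs.shape[0] == 0:
        raise ValueError("need at least one transition pair")
    if pairs.shape[1] != 2:
        raise ValueError("pairs must have two columns (E_rs,N, E_rs,N+1)")
    if np.any(pairs <= 0):
        raise ValueError("elastance values must be positive")
    y, x = pairs[:, 0].copy(), pairs[:, 1].copy()
    if isinstance(bandwidth_rule, str):
        rule_name = bandwidth_rule
        if bandwidth_rule == "cv" and len(y) < 10:
            rule_name = "silverman"
        if rule_name == "cv":
            s_y, s_x = _cv_sigmas(y, x)
        else:
            s_y = _rule_sigma(y, rule_name)
            s_x = _rule_sigma(x, rule_name)
    else:
        try:
            s_y, s_x = (float(bandwidth_rule[0]), float(bandwidth_rule[1]))
        except (TypeError, IndexError):
            s_y = s_x = float(bandwidth_rule)
        if s_y <= 0 or s_x <= 0:
            raise ValueError("explicit bandwidths must be positive")
        rule_name = "fixed"
    n = len(x)
    sigma2_y = np.full(n, s_y**2)
    sigma2_x = np.full(n, s_x**2)
    # kernel mass on [0, inf): 1 - Phi(-mu/sigma) = Phi(mu/sigma)
    p_y = norm.cdf(y / s_y)
    p_x = norm.cdf(x / s_x)
    return ErsTransitionModel(
        y=y, x=x, sigma2_y=sigma2_y, sigma2_x=sigma2_x, p_y=p_y, p_x=p_x,
        bandwidth_rule=rule_name,
    )


def _weights(model: ErsTransitionModel, y: float) -> np.ndarray:
    """Normalised kernel weights at the conditioning value y."""
    if y <= 0:
        raise ValueError("E_rs,N must be positive")
    s = np.sqrt(model.sigma2_y)
    logw = norm.logpdf(y, loc=model.y, scale=s) - np.log(model.p_y)
    m = logw.max()
    if not np.isfinite(m) or m < -700.0:
        raise ValueError(f"no support at y={y}: all kernel weights underflow")
    w = np.exp(logw - m)
    return w / w.sum()


def conditional_density(
    model: ErsTransitionModel,
    y: float,
    x_grid: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Conditional density of E_rs,N+1 given E_rs,N = y on ``x_grid``.

    Returns ``(x_grid, density)``.  The density is a weight-mixture of the
    truncated x-kernels and integrates to 1 on [0, inf).
    """
    if x_grid is None:
        x_grid = model.default_grid()
    x_grid = np.asarray(x_grid, dtype=float)
    w = _weights(model, y)
    s_x = np.sqrt(model.sigma2_x)
    # (grid, kernel) broadcast; truncated kernels renormalised by p_x
    pdf = norm.pdf(x_grid[:, None], loc=model.x[None, :], scale=s_x[None, :])
    dens = (pdf / model.p_x[None, :]) @ w
    dens = np.where(x_grid < 0, 0.0, dens)
    return x_grid, dens


def conditional_cdf(
    model: ErsTransitionModel, y: float, x: np.ndarray
) -> np.ndarray:
    """Exact conditional CDF (closed form, no quadrature)."""
    x = np.asarray(x, dtype=float)
    w = _weights(model, y)
    s_x = np.sqrt(model.sigma2_x)
    lo = norm.cdf(0.0, loc=model.x[None, :], scale=s_x[None, :])
    cdf = (norm.cdf(x[:, None], loc=model.x[None, :], scale=s_x[None, :]) - lo)
    return np.clip((cdf / model.p_x[None, :]) @ w, 0.0, 1.0)


def forecast_percentiles(
    model: ErsTransitionModel,
    Ers_N: float,
    levels=(5.0, 95.0),
    x_grid: np.ndarray | None = None,
) -> PercentileForecast:
    """Invert the conditional CDF at the requested percentile levels.

    The CDF is the cumulative trapezoid of the conditional density over the
    x-grid; quantiles come from linear interpolation, so they are monotone
    in level by construction.
    """
    levels = tuple(sorted(float(v) for v in levels))
    if not levels or not all(0.0 < v < 100.0 for v in levels):
        raise ValueError("levels must lie strictly between 0 and 100")
    x_grid, dens = conditional_density(model, Ers_N, x_grid)
    cdf = cumulative_trapezoid(dens, x_grid, initial=0.0)
    total = cdf[-1]
    if total <= 0:
        raise ValueError("degenerate conditional density on the grid")
    cdf = cdf / total
    values = tuple(float(np.interp(v / 100.0, cdf, x_grid)) for v in levels)
    return PercentileForecast(levels=levels, values=values)


def validate_coverage(model: ErsTransitionModel, test_pairs) -> dict:
    """Empirical coverage of the model's forecast bands on held-out pairs.

    Returns the fraction of next-interval elastances falling inside the
    [5, 95] and [25, 75] percentile bands forecast at the corresponding
    current-interval elastance.
    """
    test_pairs = np.atleast_2d(np.asarray(test_pairs, dtype=float))
    if test_pairs.shape[0] == 0:
        raise ValueError("empty test set")
    inside_wide = inside_narrow = 0
    for y_i, x_i in test_pairs:
        fc = forecast_percentiles(model, y_i, levels=(5.0, 25.0, 75.0, 95.0))
        q5, q25, q75, q95 = fc.values
        inside_wide += q5 <= x_i <= q95
        inside_narrow += q25 <= x_i <= q75
    n = test_pairs.shape[0]
    return {
        "n": int(n),
        "coverage_5_95": inside_wide / n,
        "coverage_25_75": inside_narrow / n,
    }


def percentile_table(
    model: ErsTransitionModel,
    y_values: np.ndarray | None = None,
    levels=(5.0, 25.0, 50.0, 75.0, 95.0),
):
    """Look-up table of forecast percentiles over a span of E_rs,N values.

    Returns a DataFrame (one row per y, one column per level) suitable for
    CSV export and bedside look-up use.
    """
    import pandas as pd

    if y_values is None:
        y_values = np.linspace(float(model.y.min()), float(model.y.max()), 50)
    rows = [forecast_percentiles(model, float(y), levels).values for y in y_values]
    cols = [f"p{g:g}" for g in sorted(float(v) for v in levels)]
    out = pd.DataFrame(rows, columns=cols)
    out.insert(0, "Ers_N", np.asarray(y_values, dtype=float))
    return out
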