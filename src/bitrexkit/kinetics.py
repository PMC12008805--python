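"""Second-order contraction kinetics of a tandem gene array.

Array contraction is modeled as homologous recombination between pairs of
repeat units: with X the unit copy number and k the recombination rate
constant (per copy^2 per time unit),

    dX/dt = -k X^2          =>          X(t) = X0 / (1 + k X0 t).

The copy-number alteration per generation over an exposure window of
duration T spanning G generations is then

    CNA/G = (X(T) - X0) / G = -(1/G) * X0^2 / (X0 + 1/(kT)),

which decreases with X0 along the sum of a line and a rectangular
hyperbola, approaching the line -(X0 - 1/(kT))/G for large X0.

The X^2 rate is the model as published; note it is nonzero at X = 1, where
contraction is physically impossible (no partner unit).  A pairwise variant
using X(X-1) is available via ``pairwise=True`` and closes to
X(t) = 1 / (1 - (1 - 1/X0) e^{-kt}).
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit


@dataclass(frozen=True)
class KineticParams:
    """Model symbols: rate constant k, window T, generations G, initial X0."""

    k: float
    T: float
    G: float
    X0: float

    def __post_init__(self):
        for name in ("k", "T", "G", "X0"):
            v = getattr(self, name)
            if not math.isfinite(v):
                raise ValueError(f"{name} must be finite")
        if self.k < 0:
            raise ValueError("k must be >= 0")
        if self.T <= 0:
            raise ValueError("T must be > 0")
        if self.G <= 0:
            raise ValueError("G must be > 0")
        if self.X0 < 1:
            raise ValueError("X0 must be >= 1")


@dataclass
class Trajectory:
    """A measured copy-number time series (times in days)."""

    times: np.ndarray
    mean_copy: np.ndarray
    sd_copy: np.ndarray | None = None
    n_replicates: int = 1

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.mean_copy = np.asarray(self.mean_copy, dtype=float)
        if self.sd_copy is not None:
            self.sd_copy = np.asarray(self.sd_copy, dtype=float)
            if self.sd_copy.shape != self.times.shape:
                raise ValueError("sd_copy length must match times")
            if np.any(self.sd_copy < 0):
                raise ValueError("sd_copy must be >= 0")
        if self.times.shape != self.mean_copy.shape:
            raise ValueError("times and mean_copy must have equal length")
        if self.times.size and np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if np.any(self.mean_copy < 0):
            raise ValueError("mean_copy must be >= 0")

    @classmethod
    def from_series(cls, df: pd.DataFrame) -> "Trajectory":
        """Collapse a (day, replicate, copy_number) frame to a mean series."""
        g = df.groupby("day")["copy_number"]
        days = np.array(sorted(g.groups))
        return cls(
            times=days,
            mean_copy=g.mean().loc[days].to_numpy(),
            sd_copy=g.std(ddof=0).loc[days].to_numpy(),
            n_replicates=int(df["replicate"].nunique()),
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"day": self.times, "mean_copy": self.mean_copy, "sd_copy": self.sd_copy}
        )


@dataclass
class GrowthRecord:
    """Optical-density bookkeeping for division counting."""

    od_inoculum: float
    od_final: float
    span_days: float = 1.0

    def __post_init__(self):
        if self.od_inoculum <= 0 or self.od_final <= 0 or self.span_days <= 0:
            raise ValueError("GrowthRecord fields must be positive")


def closed_form_x(X0, k, t, *, pairwise: bool = False):
    """Copy number at time t under second-order contraction (vectorized).

    Default: X0/(1 + k X0 t).  With ``pairwise=True``, the X(X-1) rate law
    solution 1/(1 - (1 - 1/X0) e^{-kt}) (requires X0 >= 1).
    """
    X0a = np.asarray(X0, dtype=float)
    ka = np.asarray(k, dtype=float)
    ta = np.asarray(t, dtype=float)
    if np.any(X0a < 0) or np.any(ka < 0) or np.any(ta < 0):
        raise ValueError("X0, k and t must be non-negative")
    if pairwise:
        if np.any(X0a < 1):
            raise ValueError("pairwise form requires X0 >= 1")
        with np.errstate(divide="ignore"):
            out = 1.0 / (1.0 - (1.0 - 1.0 / X0a) * np.exp(-ka * ta))
    else:
        out = X0a / (1.0 + ka * X0a * ta)
    if np.isscalar(X0) and np.isscalar(k) and np.isscalar(t):
        return float(out)
    return out


def cna_g_model(params: KineticParams, *, pairwise: bool = False) -> float:
    """Model-predicted CNA/G: -(1/G) X0^2/(X0 + 1/(kT)); 0 when k = 0."""
    if params.k == 0:
        return 0.0
    if pairwise:
        return float((closed_form_x(params.X0, params.k, params.T, pairwise=True) - params.X0) / params.G)
    c = 1.0 / (params.k * params.T)
    return float(-(1.0 / params.G) * params.X0**2 / (params.X0 + c))


def cna_g_empirical(copy_T: float, copy_0: float, divisions: float) -> float:
    """Measured CNA/G = (copy number at day T - at day 0) / division number."""
    if divisions <= 0:
        raise ValueError("divisions must be > 0")
    return (copy_T - copy_0) / divisions


def divisions_from_od(record: GrowthRecord) -> float:
    """Division number over a growth window: log2 of the OD fold change."""
    return float(np.log2(record.od_final / record.od_inoculum))


@dataclass
class KFitResult:
    """Least-squares fit of the closed-form hyperbola to a trajectory."""

    k: float  # per copy^2 per day
    k_ci: tuple[float, float]
    x0: float
    k_per_generation: float
    residuals: np.ndarray = field(repr=False)
    n_bootstrap: int = 0
    warning: str | None = None
    co_estimated_x0: bool = True


def _fit_once(t: np.ndarray, y: np.ndarray, x0_fixed: float | None):
    k_guess = max((1.0 / y[-1] - 1.0 / y[0]) / max(t[-1] - t[0], 1e-12), 0.0)
    tols = dict(xtol=1e-15, ftol=1e-15, gtol=1e-15, maxfev=20000)
    if x0_fixed is None:
        popt, _ = curve_fit(
            lambda tt, k, x0: x0 / (1.0 + k * x0 * tt),
            t,
            y,
            p0=[max(k_guess, 1e-10), max(y[0], 1.0)],
            bounds=([0.0, 1e-9], [np.inf, np.inf]),
            **tols,
        )
        return float(popt[0]), float(popt[1])
    popt, _ = curve_fit(
        lambda tt, k: x0_fixed / (1.0 + k * x0_fixed * tt),
        t,
        y,
        p0=[max(k_guess, 1e-10)],
        bounds=([0.0], [np.inf]),
        **tols,
    )
    return float(popt[0]), float(x0_fixed)


def fit_k(
    traj: Trajectory,
    g_per_day: float = 6.0,
    *,
    co_estimate_x0: bool = True,
    n_bootstrap: int = 1000,
    seed: int = 0,
) -> KFitResult:
    """Fit the contraction rate constant k (per day) with a bootstrap CI.

    X0 is co-estimated by default, or pinned to the earliest measurement.
    The CI is a case-resampling bootstrap over time points (percentile
    2.5/97.5).  A non-decreasing series yields k = 0 with a warning flag.
    """
    t = traj.times
    y = traj.mean_copy
    if t.size < 3:
        raise ValueError("need at least 3 time points")
    if np.any(y <= 0):
        raise ValueError("mean_copy must be positive for fitting")
    x0_fixed = None if co_estimate_x0 else float(y[0])
    k_hat, x0_hat = _fit_once(t, y, x0_fixed)
    resid = y - closed_form_x(x0_hat, k_hat, t)

    warning = None
    if y[-1] >= y[0] and k_hat <= 1e-12:
        warning = "series non-decreasing; k constrained to 0"

    ks = []
    if n_bootstrap > 0:
        rng = np.random.default_rng(seed)
        n = t.size
        for _ in range(n_bootstrap):
            idx = np.sort(rng.integers(0, n, size=n))
            tb, yb = t[idx], y[idx]
            # collapse duplicate times (strictly increasing not required for
            # least squares, but degenerate draws can stall the optimizer)
            if np.unique(tb).size < 3:
                continue
            try:
                kb, _ = _fit_once(tb, yb, x0_fixed)
            except RuntimeError:
                continue
            ks.append(kb)
    if ks:
        lo, hi = np.percentile(ks, [2.5, 97.5])
        ci = (float(lo), float(hi))
    else:
        ci = (k_hat, k_hat)

    return KFitResult(
        k=k_hat,
        k_ci=ci,
        x0=x0_hat,
        k_per_generation=k_hat / g_per_day,
        residuals=resid,
        n_bootstrap=len(ks),
        warning=warning,
        co_estimated_x0=co_estimate_x0,
    )


def predict_cna_curve(k: float, T: float, G: float, x0_grid) -> pd.DataFrame:
    """CNA/G over a grid of initial copy numbers (Fig-style theory curve)."""
    grid = np.asarray(x0_grid, dtype=float)
    if grid.size == 0:
        return pd.DataFrame({"X0": [], "cna_g": []})
    if np.any(grid <= 0):
        raise ValueError("X0 grid must be positive")
    if k == 0:
        vals = np.zeros_like(grid)
    else:
        c = 1.0 / (k * T)
        vals = -(1.0 / G) * grid**2 / (grid + c)
    return pd.DataFrame({"X0": grid, "cna_g": vals})


def predict_fragment_size(n_units: int, unit_length_kb: float, extra_kb: float = 0.0) -> float:
    """Restriction-fragment size in Mb, rounded half-away-from-zero to 0.1.

    For an enzyme with no site inside the repeat unit, the array-containing
    fragment is n_units * unit_length plus any flanking distance to the
    nearest sites (``extra_kb``).
    """
    if n_units < 0 or unit_length_kb < 0 or extra_kb < 0:
        raise ValueError("inputs must be non-negative")
    mb = (n_units * unit_length_kb + extra_kb) / 1000.0
    return math.floor(mb * 10.0 + 0.5) / 10.0
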