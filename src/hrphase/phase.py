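"""Heart-rate phase (HRP) extraction.

A participant's raw heart-rate samples are aggregated into a weekly
profile of up to 2016 five-minute bins (288 per day x 7 days, Sunday to
Sunday) and fit to a fixed-period 24 h sinusoid

    HR(t) = A * sin(pi/720 * (t - 60*phi)) + b

with t in minutes of week.  This is a single-component cosinor with a
sine (mean-crossing) phase convention: phi in hours is the ascending
mean-crossing time, and the heart-rate peak (acrophase) falls at
phi + 6 h.  The fit is linear in the basis {sin, cos, 1}, so the least
squares solution is closed-form; A >= 0 and phi in [0, 24) are obtained
by canonicalising the two linear coefficients.

Cohort-level goodness-of-fit thresholding follows a Youden-style rule:
the retention rate at an R^2 threshold plus the threshold minus one,
maximised over a grid.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "SineFitResult",
    "ThresholdScan",
    "aggregate_weekly_profile",
    "fit_sine",
    "fit_cohort",
    "select_r2_threshold",
    "apply_inclusion_filters",
]

_OMEGA = np.pi / 720.0  # radians per minute, 24 h period
_BIN_MIN = 5
_WEEK_MIN = 7 * 1440


@dataclass
class SineFitResult:
    """Canonical parameters of the fixed-period sine fit.

    Attributes
    ----------
    amplitude : float
        A in bpm, >= 0.
    phi : float
        Phase in hours, in [0, 24); ascending mean-crossing time.
    baseline : float
        Vertical shift b in bpm.
    r_squared : float
        1 - SS_res/SS_tot over the profile bins; 0 for a constant
        profile (flagged).
    n_bins : int
        Number of profile bins used.
    ok : bool
        False when the fit is degenerate (too few bins, constant
        profile, or a singular design).
    reason : str
        Empty when ok, otherwise why the fit was flagged.
    """

    amplitude: float
    phi: float
    baseline: float
    r_squared: float
    n_bins: int
    ok: bool = True
    reason: str = ""

    def predict(self, t_minutes: np.ndarray) -> np.ndarray:
        """Model heart rate at time-of-week ``t_minutes``."""
        return (self.amplitude * np.sin(_OMEGA * (np.asarray(t_minutes, float)
                                                  - 60.0 * self.phi))
                + self.baseline)


@dataclass
class ThresholdScan:
    """Youden-index scan over R^2 thresholds."""

    grid: np.ndarray
    retention: np.ndarray
    youden: np.ndarray
    selected: float
    n_at_zero: int = 0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"threshold": self.grid, "retention": self.retention,
                             "youden": self.youden})


def aggregate_weekly_profile(samples: pd.DataFrame) -> pd.DataFrame:
    """Aggregate one participant's raw samples to a weekly 5-min profile.

    Each sample is mapped to minutes since the most recent Sunday 00:00
    and floored to its 5-minute bin; the bin value is the mean bpm over
    all the participant's dates.  Bins with no samples are omitted, so
    the profile has at most 2016 rows.

    Parameters
    ----------
    samples : DataFrame with columns timestamp (datetime-like) and bpm.

    Returns
    -------
    DataFrame with columns bin_start (minutes of week, multiple of 5),
    mean_hr (bpm) and n_samples, sorted by bin_start.
    """
    if len(samples) == 0:
        return pd.DataFrame(columns=["bin_start", "mean_hr", "n_samples"])
    ts = pd.to_datetime(samples["timestamp"])
    bpm = pd.to_numeric(samples["bpm"])
    if not np.isfinite(bpm).all() or (bpm <= 0).any():
        raise ValueError("bpm values must be finite and positive")
    # pandas dayofweek: Monday=0 ... Sunday=6; shift so Sunday=0
    day = (ts.dt.dayofweek + 1) % 7
    minutes = day * 1440 + ts.dt.hour * 60 + ts.dt.minute
    bins = (minutes // _BIN_MIN) * _BIN_MIN
    grouped = bpm.groupby(bins.to_numpy()).agg(["mean", "size"])
    out = grouped.reset_index()
    out.columns = ["bin_start", "mean_hr", "n_samples"]
    return out.sort_values("bin_start", ignore_index=True)


def _canonicalise(a: float, c: float) -> tuple[float, float]:
    """Map linear coefficients a*sin + c*cos to (A >= 0, phi hours)."""
    amplitude = float(np.hypot(a, c))
    phi_min = np.arctan2(-c, a) / _OMEGA
    phi = float(np.mod(phi_min / 60.0, 24.0))
    return amplitude, phi


def fit_sine(profile: pd.DataFrame) -> SineFitResult:
    """Least-squares 24 h sine fit to a weekly profile.

    The model is linear in {sin(omega*t), cos(omega*t), 1}; bins are
    unweighted regardless of per-bin sample counts.  Requires at least
    3 bins with distinct time-of-day values; a constant profile gets
    r_squared = 0 and is flagged.
    """
    t = np.asarray(profile["bin_start"], dtype=float)
    y = np.asarray(profile["mean_hr"], dtype=float)
    n = t.size
    if n < 3 or np.unique(np.mod(t, 1440.0)).size < 3:
        return SineFitResult(0.0, 0.0, float(y.mean()) if n else np.nan,
                             0.0, n, ok=False, reason="too_few_bins")
    X = np.column_stack([np.sin(_OMEGA * t), np.cos(_OMEGA * t), np.ones(n)])
    coef, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    if rank < 3:
        return SineFitResult(0.0, 0.0, float(y.mean()), 0.0, n,
                             ok=False, reason="singular_design")
    a, c, b = coef
    amplitude, phi = _canonicalise(a, c)
    resid = y - X @ coef
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot == 0.0:
        return SineFitResult(amplitude, phi, float(b), 0.0, n,
                             ok=False, reason="constant_profile")
    r2 = 1.0 - float(np.sum(resid ** 2)) / ss_tot
    return SineFitResult(amplitude, phi, float(b), r2, n)


def fit_cohort(hr: pd.DataFrame) -> pd.DataFrame:
    """Aggregate and fit every participant in a raw heart-rate table.

    Returns one row per participant: phi, r_squared, amplitude,
    baseline, n_bins, days_with_data (distinct calendar dates with at
    least one sample) and fit_ok.
    """
    ts = pd.to_datetime(hr["timestamp"])
    work = pd.DataFrame({
        "participant_id": hr["participant_id"].to_numpy(),
        "bpm": pd.to_numeric(hr["bpm"]).to_numpy(),
        "date": ts.dt.normalize().to_numpy(),
        "bin": (((ts.dt.dayofweek + 1) % 7) * 1440 + ts.dt.hour * 60
                + ts.dt.minute).to_numpy() // _BIN_MIN * _BIN_MIN,
    })
    days = work.groupby("participant_id")["date"].nunique()
    binned = (work.groupby(["participant_id", "bin"])["bpm"]
              .agg(["mean", "size"]).reset_index())
    rows = []
    for pid, grp in binned.groupby("participant_id", sort=True):
        profile = grp.rename(columns={"bin": "bin_start", "mean": "mean_hr",
                                      "size": "n_samples"})
        fit = fit_sine(profile)
        rows.append({
            "participant_id": pid,
            "phi": fit.phi,
            "r_squared": fit.r_squared,
            "amplitude": fit.amplitude,
            "baseline": fit.baseline,
            "n_bins": fit.n_bins,
            "days_with_data": int(days.loc[pid]),
            "fit_ok": fit.ok,
        })
    return pd.DataFrame(rows)


def select_r2_threshold(r_squared: np.ndarray | pd.Series,
                        grid_step: float = 0.1) -> ThresholdScan:
    """Pick the R^2 cutoff maximising retention(theta) + theta - 1.

    retention(theta) is the cohort size at threshold theta (r_squared
    strictly greater than theta) divided by the cohort size at
    threshold 0.0.  Ties are broken toward the lowest threshold.
    """
    r2 = np.asarray(r_squared, dtype=float)
    if r2.size == 0:
        raise ValueError("empty cohort")
    grid = np.round(np.arange(0.0, 1.0 - 1e-9, grid_step), 10)
    n_zero = int(np.sum(r2 > 0.0))
    if n_zero == 0:
        retention = np.zeros_like(grid)
    else:
        retention = np.array([np.sum(r2 > th) for th in grid], dtype=float) / n_zero
    youden = retention + grid - 1.0
    selected = float(grid[int(np.argmax(youden))])  # argmax takes first max
    return ThresholdScan(grid=grid, retention=retention, youden=youden,
                         selected=selected, n_at_zero=n_zero)


def apply_inclusion_filters(fits: pd.DataFrame, threshold: float,
                            min_days: int = 30,
                            sd_limit: float = 3.0) -> pd.DataFrame:
    """Apply the three cohort inclusion filters in order.

    1. days_with_data strictly greater than ``min_days``;
    2. r_squared strictly greater than ``threshold``;
    3. on the survivors of 1+2, compute the linear mean and SD of phi
       (hours) once and exclude |phi - mean| >= sd_limit * SD.  A zero
       SD excludes nobody (degenerate guard).

    Returns the input with boolean ``included`` and string
    ``exclusion_reason`` columns ('' when included).
    """
    out = fits.copy()
    reason = np.full(len(out), "", dtype=object)
    days_ok = out["days_with_data"].to_numpy() > min_days
    reason[~days_ok] = "days"
    r2_ok = out["r_squared"].to_numpy() > threshold
    reason[days_ok & ~r2_ok] = "r_squared"
    survivors = days_ok & r2_ok
    if survivors.any():
        phi = out.loc[survivors, "phi"].to_numpy()
        mu, sd = float(phi.mean()), float(phi.std(ddof=0))
        if sd > 0.0:
            outlier = np.zeros(len(out), dtype=bool)
            outlier[survivors] = np.abs(out.loc[survivors, "phi"].to_numpy() - mu) >= sd_limit * sd
            reason[outlier] = "phase_outlier"
            survivors &= ~outlier
    out["included"] = survivors
    out["exclusion_reason"] = reason
    return out
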