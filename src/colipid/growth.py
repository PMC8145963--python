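"""Microplate growth phenotyping: maximum specific growth rate, steady-state
OD600, quality control, and construct-vs-control classification.

The maximum specific growth rate mu_max (h^-1) is the largest slope of a
fixed-width sliding least-squares fit to ln(OD600) versus time, the standard
log-linear estimate for batch cultures read every few minutes.  Steady-state
OD600 is the median over the longest trailing segment whose windowed specific
slope stays below a plateau threshold.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from numpy.lib.stride_tricks import sliding_window_view
from scipy import stats

DEFAULT_WINDOW_POINTS = 13      # 1 h at 5-min sampling
DEFAULT_OD_FLOOR = 0.02         # below this, readings are noise-dominated
DEFAULT_PLATEAU_SLOPE = 0.02    # h^-1; windowed |slope| below this = plateau
DEFAULT_MIN_OD = 0.2            # QC: cultures never reaching this are excluded


def _window_slopes(t_h: np.ndarray, ln_od: np.ndarray, w: int) -> np.ndarray:
    """Least-squares slope of ln(OD) vs time for every length-w window."""
    tw = sliding_window_view(t_h, w)
    yw = sliding_window_view(ln_od, w)
    tm = tw.mean(axis=1, keepdims=True)
    ym = yw.mean(axis=1, keepdims=True)
    denom = ((tw - tm) ** 2).sum(axis=1)
    return ((tw - tm) * (yw - ym)).sum(axis=1) / denom


def mu_max(
    times_min: np.ndarray,
    od: np.ndarray,
    window_points: int = DEFAULT_WINDOW_POINTS,
    od_floor: float = DEFAULT_OD_FLOOR,
    blank: float = 0.0,
) -> tuple[float, tuple[float, float] | None]:
    """Maximum specific growth rate (h^-1) and the time window attaining it.

    Only windows whose readings all exceed ``od_floor`` (after blank
    subtraction) enter the search; if no such window exists, (nan, None) is
    returned and QC is expected to handle the culture downstream.
    """
    t = np.asarray(times_min, float) / 60.0
    y = np.asarray(od, float) - blank
    if len(t) < window_points:
        return float("nan"), None
    valid = y > od_floor
    ln_od = np.where(valid, np.log(np.where(valid, y, 1.0)), np.nan)
    ok_windows = sliding_window_view(valid, window_points).all(axis=1)
    if not ok_windows.any():
        return float("nan"), None
    slopes = _window_slopes(t, np.nan_to_num(ln_od), window_points)
    slopes = np.where(ok_windows, slopes, -np.inf)
    i = int(np.argmax(slopes))
    return float(slopes[i]), (float(times_min[i]), float(times_min[i + window_points - 1]))


def steady_state_od(
    times_min: np.ndarray,
    od: np.ndarray,
    window_points: int = DEFAULT_WINDOW_POINTS,
    slope_threshold: float = DEFAULT_PLATEAU_SLOPE,
    od_floor: float = DEFAULT_OD_FLOOR,
) -> tuple[float, bool]:
    """Steady-state OD600 and a flag marking the no-plateau fallback.

    Returns the median OD over the longest trailing run of windows whose
    specific (ln) slope magnitude is below ``slope_threshold``.  Cultures that
    never plateau fall back to the median of the final window, flagged True.
    """
    t = np.asarray(times_min, float) / 60.0
    y = np.asarray(od, float)
    if len(y) < window_points:
        return float(np.median(y)), True
    safe = np.clip(y, max(od_floor / 10.0, 1e-6), None)
    slopes = _window_slopes(t, np.log(safe), window_points)
    flat = np.abs(slopes) < slope_threshold
    # longest trailing run of flat windows
    n_flat = 0
    for f in flat[::-1]:
        if not f:
            break
        n_flat += 1
    if n_flat == 0:
        return float(np.median(y[-window_points:])), True
    start = len(y) - (n_flat + window_points - 1)
    return float(np.median(y[start:])), False


@dataclass
class GrowthSummary:
    table: pd.DataFrame  # per sample: mu_max, steady_state_od, max_od, qc_pass, flags


def summarize_growth(
    od_table: pd.DataFrame,
    window_points: int = DEFAULT_WINDOW_POINTS,
    od_floor: float = DEFAULT_OD_FLOOR,
    blank: float = 0.0,
    min_od: float = DEFAULT_MIN_OD,
) -> pd.DataFrame:
    """Growth summary for a wide OD table (column ``time_min`` + one per well)."""
    if "time_min" not in od_table.columns:
        raise ValueError("OD table must have a 'time_min' column")
    t = od_table["time_min"].to_numpy(float)
    rows = []
    for well in od_table.columns:
        if well == "time_min":
            continue
        y = od_table[well].to_numpy(float)
        mu, win = mu_max(t, y, window_points, od_floor, blank)
        ss, fallback = steady_state_od(t, y, window_points)
        rows.append(
            {
                "sample_id": well,
                "mu_max": mu,
                "fit_start_min": win[0] if win else np.nan,
                "fit_end_min": win[1] if win else np.nan,
                "steady_state_od": ss,
                "plateau_fallback": fallback,
                "max_od": float(np.max(y)) - blank,
            }
        )
    out = pd.DataFrame(rows).set_index("sample_id")
    out["qc_pass"] = out["max_od"] >= min_od
    return out


def qc_filter(summaries: pd.DataFrame, min_od: float = DEFAULT_MIN_OD):
    """Split cultures into kept / excluded by maximum OD (inclusive boundary)."""
    keep = summaries["max_od"] >= min_od
    return summaries.index[keep].tolist(), summaries.index[~keep].tolist()


def compare_to_controls(
    summaries: pd.DataFrame,
    metadata: pd.DataFrame,
    alpha: float = 0.05,
    value: str = "mu_max",
) -> pd.DataFrame:
    """Welch-test classification of each construct against its matched control.

    Knock-outs are compared to wild type, overexpressors to the empty-vector
    control, separately per butanol condition.  Two-sided, uncorrected p
    versus ``alpha``; the sign of the difference gives 'higher' / 'lower',
    otherwise 'ns'.  Constructs with fewer than two replicates are flagged.
    """
    meta = metadata.loc[summaries.index]
    rows = []
    for butanol in sorted(meta["butanol"].astype(int).unique()):
        cond = meta["butanol"].astype(int) == butanol
        for ctype, control in (("KO", "WT"), ("OV", "EV")):
            ctl_ids = meta.index[cond & (meta["construct_type"] == control)]
            ctl = summaries.loc[ctl_ids, value].dropna()
            sub = meta[cond & (meta["construct_type"] == ctype)]
            for gene, grp in sub.groupby("gene"):
                vals = summaries.loc[grp.index, value].dropna()
                rec = {
                    "gene": gene,
                    "construct_type": ctype,
                    "butanol": butanol,
                    "n": len(vals),
                    "mean": vals.mean() if len(vals) else np.nan,
                    "control_mean": ctl.mean(),
                }
                if len(vals) < 2 or len(ctl) < 2:
                    rec.update(p=np.nan, classification="ns", flagged=True)
                else:
                    t, p = stats.ttest_ind(vals, ctl, equal_var=False)
                    cls = "ns"
                    if p < alpha:
                        cls = "higher" if vals.mean() > ctl.mean() else "lower"
                    rec.update(p=float(p), classification=cls, flagged=False)
                rows.append(rec)
    return pd.DataFrame(rows)
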