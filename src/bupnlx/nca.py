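"""Non-compartmental analysis: Cmax, Tmax, AUC by linear up-log-down.

BQL records are excluded before computing metrics (M1-consistent handling);
subjects whose profile retains fewer than two quantifiable points are
flagged and skipped with a log entry.

The AUC uses the linear trapezoid on rising or flat segments (or when either
endpoint is zero) and the logarithmic trapezoid on declining segments with
both endpoints positive.  Window endpoints that fall between samples are
interpolated with the same convention (linear on the way up, log on the way
down).  Extrapolation to infinity uses a terminal log-linear regression on
the last points (>= 3, chosen by best adjusted R^2).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .dataset import PKDataset

logger = logging.getLogger(__name__)


def _interp_at(times: np.ndarray, conc: np.ndarray, t: float) -> float:
    """Concentration at t with linear-up / log-down segment interpolation."""
    if t <= times[0]:
        return float(conc[0]) if t == times[0] else 0.0
    if t >= times[-1]:
        return float(conc[-1])
    j = int(np.searchsorted(times, t, side="right")) - 1
    t1, t2, c1, c2 = times[j], times[j + 1], conc[j], conc[j + 1]
    w = (t - t1) / (t2 - t1)
    if c2 < c1 and c1 > 0 and c2 > 0:
        return float(c1 * (c2 / c1) ** w)
    return float(c1 + w * (c2 - c1))


def auc_linuplogdown(times, conc, window: tuple | None = None) -> float:
    """AUC (ng·h/L) over ``window`` by the linear up-log-down method."""
    times = np.asarray(times, dtype=float)
    conc = np.asarray(conc, dtype=float)
    if len(times) < 2:
        raise ValueError("need at least two points for an AUC")
    if np.any(np.diff(times) <= 0):
        raise ValueError("times must be strictly increasing")
    if np.any(conc < 0):
        raise ValueError("concentrations must be >= 0")
    if window is not None:
        lo, hi = window
        if hi <= lo:
            raise ValueError("empty window")
        keep = (times > lo) & (times < hi)
        t = np.concatenate([[lo], times[keep], [hi]])
        c = np.concatenate([[_interp_at(times, conc, lo)], conc[keep],
                            [_interp_at(times, conc, hi)]])
    else:
        t, c = times, conc
    auc = 0.0
    for t1, t2, c1, c2 in zip(t, t[1:], c, c[1:]):
        dt = t2 - t1
        if c2 < c1 and c1 > 0 and c2 > 0:
            auc += dt * (c1 - c2) / np.log(c1 / c2)
        else:
            auc += dt * (c1 + c2) / 2.0
    return float(auc)


def terminal_slope(times, conc, min_points: int = 3):
    """Terminal elimination rate lambda_z by best-adjusted-R^2 log-linear fit.

    Candidate fits use the last k points (k >= min_points) after Cmax,
    excluding zeros.  Returns (lambda_z, intercept, n_points) or None when no
    admissible fit exists.
    """
    times = np.asarray(times, dtype=float)
    conc = np.asarray(conc, dtype=float)
    pos = conc > 0
    times, conc = times[pos], conc[pos]
    if len(conc) < min_points + 1:
        return None
    imax = int(np.argmax(conc))
    t_tail, c_tail = times[imax + 1:], conc[imax + 1:]
    best = None
    for k in range(min_points, len(t_tail) + 1):
        t, c = t_tail[-k:], np.log(c_tail[-k:])
        slope, intercept = np.polyfit(t, c, 1)
        if slope >= 0:
            continue
        pred = slope * t + intercept
        ss_res = np.sum((c - pred) ** 2)
        ss_tot = np.sum((c - c.mean()) ** 2)
        if ss_tot == 0:
            continue
        r2adj = 1 - (1 - (1 - ss_res / ss_tot)) * (k - 1) / (k - 2)
        if best is None or r2adj > best[0]:
            best = (r2adj, -slope, intercept, k)
    if best is None:
        return None
    return best[1], best[2], best[3]


@dataclass
class NcaResult:
    """Per-subject NCA metrics plus group summaries."""

    table: pd.DataFrame                       # one row per subject x analyte
    summaries: pd.DataFrame = field(default=None)
    excluded: list = field(default_factory=list)

    def summary(self, by=("ARM", "CMT")) -> pd.DataFrame:
        rows = []
        for key, g in self.table.groupby(list(by)):
            row = dict(zip(by, key if isinstance(key, tuple) else (key,)))
            for col in g.columns:
                if col in by or g[col].dtype == object:
                    continue
                v = g[col].dropna()
                if v.empty:
                    continue
                row[f"{col}_median"] = v.median()
                row[f"{col}_min"] = v.min()
                row[f"{col}_max"] = v.max()
                row[f"{col}_mean"] = v.mean()
                row[f"{col}_sd"] = v.std(ddof=1)
            rows.append(row)
        return pd.DataFrame(rows)


def nca_table(dataset: PKDataset, windows: dict | None = None,
              analytes=("BUP", "NORBUP", "NLX")) -> NcaResult:
    """Per-subject NCA over the requested windows.

    ``windows`` maps a label to a (lo, hi) time window; the special label
    ``"inf"`` (always included) requests AUC to infinity via terminal-slope
    extrapolation.  Dose-normalized variants divide by the subject's labelled
    dose-group amount in mg.
    """
    windows = dict(windows or {})
    rows = []
    excluded = []
    for sid in dataset.subjects:
        sub = dataset.subject_data(sid)
        dose_mg = float(sub.DOSEGRP.iloc[0])
        for analyte in analytes:
            obs = sub[(sub.EVID == 0) & (sub.CMT == analyte) & (sub.BQL == 0)]
            if len(obs) < 2:
                excluded.append((sid, analyte))
                logger.info("subject %s analyte %s: <2 quantifiable points, excluded",
                            sid, analyte)
                continue
            t = obs.TIME.to_numpy(dtype=float)
            c = obs.DV.to_numpy(dtype=float)
            imax = int(np.argmax(c))      # earliest time at the maximum
            cmax, tmax = float(c[imax]), float(t[imax])
            row = dict(ID=sid, CMT=analyte, ARM=sub.ARM.iloc[0],
                       DOSEGRP=dose_mg, Cmax=cmax, Tmax=tmax,
                       Cmax_dn=cmax / dose_mg)
            row["AUClast"] = auc_linuplogdown(t, c)
            row["AUClast_dn"] = row["AUClast"] / dose_mg
            fit = terminal_slope(t, c)
            if fit is not None:
                lz = fit[0]
                row["lambda_z"] = lz
                row["AUCinf"] = row["AUClast"] + float(c[-1]) / lz
                row["AUCinf_dn"] = row["AUCinf"] / dose_mg
            for label, (lo, hi) in windows.items():
                try:
                    row[f"AUC{label}"] = auc_linuplogdown(t, c, (lo, hi))
                    row[f"AUC{label}_dn"] = row[f"AUC{label}"] / dose_mg
                except ValueError:
                    row[f"AUC{label}"] = np.nan
            rows.append(row)
    if not rows:
        raise ValueError("no subject has >= 2 quantifiable points")
    result = NcaResult(pd.DataFrame(rows), excluded=excluded)
    result.summaries = result.summary()
    return result


def accumulation_check(dataset: PKDataset,
                       multi_arm: str = "8mg-multi",
                       single_arm: str = "8mg-single",
                       analytes=("BUP", "NORBUP", "NLX")) -> pd.DataFrame:
    """Accumulation ratio: AUC(168-192 h, multiple dose) / AUC(0-24 h, single 8 mg).

    A ratio near 1 means no accumulation under once-daily dosing.  Returns
    per-analyte group medians and the ratio of medians.
    """
    rows = []
    for analyte in analytes:
        aucs = {}
        for arm, window in ((multi_arm, (168.0, 192.0)), (single_arm, (0.0, 24.0))):
            obs = dataset.observations(analyte, arm=arm, include_bql=False)
            if obs.empty:
                raise ValueError(f"arm {arm!r} missing from dataset")
            vals = []
            for sid, g in obs.groupby("ID"):
                t = g.TIME.to_numpy(dtype=float)
                c = g.DV.to_numpy(dtype=float)
                if ((t > window[0]) & (t < window[1])).sum() >= 2:
                    vals.append(auc_linuplogdown(t, c, window))
            if not vals:
                raise ValueError(f"arm {arm!r}: no evaluable subjects for {analyte}")
            aucs[arm] = np.median(vals)
        rows.append(dict(CMT=analyte, AUC_multi=aucs[multi_arm],
                         AUC_single=aucs[single_arm],
                         ratio=aucs[multi_arm] / aucs[single_arm]))
    return pd.DataFrame(rows)
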