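"""Simulation-based model diagnostics: GOF residuals, VPC/pcVPC, NPC.

All diagnostics work from a fitted model (theta/omega/sigma) and the dataset
it was fitted to.  Simulated replicates redraw the random effects and
residual errors under the original design and censor at the same LLOQ as the
observations, so observed and simulated summaries are compared on equal
footing.  When the fit used the M3 censored likelihood, CWRES is replaced by
a simulation-based NPDE (rank-transformed, then inverse-normal) in the
residual table.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm

from .dataset import PKDataset
from .estimation import FitResult, SubjectData, _residual_sd, subjects_from_dataset
from .nca import auc_linuplogdown

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# simulation engine
# ---------------------------------------------------------------------------

def simulate_replicates(fit: FitResult, model, subjects: list[SubjectData],
                        nsim: int, seed: int, censor: bool = True):
    """Simulate ``nsim`` datasets under the fitted model and original design.

    Returns (sims, bql) arrays of shape (nsim, n_records) where ``sims``
    holds the simulated concentration (NaN where censored) and ``bql`` the
    censoring indicator, records ordered as the concatenated subjects.
    """
    rng = np.random.default_rng(seed)
    n_rec = sum(len(s.times) for s in subjects)
    sims = np.empty((nsim, n_rec))
    bql = np.zeros((nsim, n_rec), dtype=int)
    eta_names = [k for k, v in fit.omega.items() if v > 0]
    for r in range(nsim):
        pos = 0
        for sub in subjects:
            eta = {k: rng.normal(0.0, fit.omega[k]) for k in eta_names}
            ipred = model.predict(fit.theta, eta, sub)
            sd = _residual_sd(model, fit.sigma, sub.cmt, ipred)
            y = ipred + sd * rng.normal(0.0, 1.0, len(ipred))
            k = len(y)
            if censor:
                c = y < sub.lloq
                bql[r, pos:pos + k] = c
                sims[r, pos:pos + k] = np.where(c, np.nan, y)
            else:
                sims[r, pos:pos + k] = y
            pos += k
    return sims, bql


def _records_frame(subjects: list[SubjectData]) -> pd.DataFrame:
    rows = []
    for sub in subjects:
        for i in range(len(sub.times)):
            rows.append(dict(ID=sub.id, TIME=sub.times[i], CMT=sub.cmt[i],
                             DV=sub.dv[i], BQL=sub.bql[i], LLOQ=sub.lloq[i]))
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# goodness of fit
# ---------------------------------------------------------------------------

def gof(fit: FitResult, dataset: PKDataset, model, nsim: int = 1000,
        seed: int = 12345, eta_step: float = 1e-4) -> pd.DataFrame:
    """Residual tables: DV, PRED, IPRED, IWRES and CWRES (or NPDE under M3).

    CWRES uses the first-order conditional linearization around the
    empirical Bayes estimates; NPDE uses simulation ranks transformed by the
    inverse normal (simplified, no decorrelation across records).
    """
    subjects = subjects_from_dataset(dataset, model.analytes)
    table = _records_frame(subjects)
    use_npde = fit.bql_method == "M3"
    pred = np.empty(len(table))
    ipred = np.empty(len(table))
    iwres = np.full(len(table), np.nan)
    cwres = np.full(len(table), np.nan)
    eta_names = [k for k, v in fit.omega.items() if v > 0]
    pos = 0
    for sub in subjects:
        k = len(sub.times)
        ehat = fit.ebes.get(sub.id, {})
        p0 = model.predict(fit.theta, {}, sub)
        pi = model.predict(fit.theta, ehat, sub)
        pred[pos:pos + k] = p0
        ipred[pos:pos + k] = pi
        sd_i = _residual_sd(model, fit.sigma, sub.cmt, pi)
        quant = sub.bql == 0
        with np.errstate(divide="ignore", invalid="ignore"):
            iw = (sub.dv - pi) / sd_i
        iwres[pos:pos + k] = np.where(quant & (sd_i > 0), iw, np.nan)
        if not use_npde and eta_names and quant.any():
            evec = np.array([ehat.get(n, 0.0) for n in eta_names])
            G = np.zeros((k, len(eta_names)))
            for a, name in enumerate(eta_names):
                up, dn = dict(ehat), dict(ehat)
                up[name] = up.get(name, 0.0) + eta_step
                dn[name] = dn.get(name, 0.0) - eta_step
                G[:, a] = (model.predict(fit.theta, up, sub)
                           - model.predict(fit.theta, dn, sub)) / (2 * eta_step)
            mean = pi - G @ evec
            omega = np.diag([fit.omega[n] ** 2 for n in eta_names])
            cov = G @ omega @ G.T + np.diag(sd_i ** 2)
            idx = np.where(quant)[0]
            L = np.linalg.cholesky(cov[np.ix_(idx, idx)])
            cwres[pos + idx] = np.linalg.solve(L, sub.dv[idx] - mean[idx])
        pos += k
    table["PRED"] = pred
    table["IPRED"] = ipred
    table["IWRES"] = iwres
    if use_npde:
        sims, _ = simulate_replicates(fit, model, subjects, nsim, seed, censor=False)
        dv = table.DV.to_numpy()
        frac = (np.sum(sims < dv[None, :], axis=0) + 0.5) / (nsim + 1)
        npde = norm.ppf(frac)
        table["NPDE"] = np.where(table.BQL == 0, npde, np.nan)
        table["RESIDUAL_TYPE"] = "NPDE"
    else:
        table["CWRES"] = cwres
        table["RESIDUAL_TYPE"] = "CWRES"
    return table


# ---------------------------------------------------------------------------
# visual predictive check
# ---------------------------------------------------------------------------

@dataclass
class VpcResult:
    """Per-bin observed percentiles with simulation CIs and BQL fractions."""

    table: pd.DataFrame         # CMT, bin time, obs 5/50/95, CI bounds
    bql_table: pd.DataFrame     # CMT, bin time, observed/simulated BQL fraction
    pred_corrected: bool = False
    nsim: int = 0

    def percentile_ordering_ok(self) -> bool:
        t = self.table.dropna(subset=["obs_p5", "obs_p50", "obs_p95"])
        return bool(((t.obs_p5 <= t.obs_p50 + 1e-12)
                     & (t.obs_p50 <= t.obs_p95 + 1e-12)).all())


PCTS = (5, 50, 95)


def vpc(fit: FitResult, dataset: PKDataset, model, nsim: int = 1000,
        pred_correct: bool = False, seed: int = 12345,
        min_bin: int = 2) -> VpcResult:
    """Visual predictive check binned on the nominal protocol times.

    Observed 5/50/95th percentiles per bin against the 95% CI of the same
    percentiles across ``nsim`` simulated replicates; with ``pred_correct``
    every observation and simulation is scaled by bin-median PRED divided by
    the record's own population prediction.  A BQL-fraction-versus-time
    panel is always produced; simulated values are censored at the LLOQ
    before percentile computation, matching the observed handling.
    """
    subjects = subjects_from_dataset(dataset, model.analytes)
    table = _records_frame(subjects)
    sims, sim_bql = simulate_replicates(fit, model, subjects, nsim, seed)
    pred = np.concatenate([model.predict(fit.theta, {}, s) for s in subjects])
    table["PRED"] = pred

    # protocol-time bins, merged forward until each holds >= min_bin records
    table["BIN"] = table.TIME
    for cmt, g in table.groupby("CMT"):
        counts = g.BIN.value_counts()
        times = sorted(counts.index)
        merged = {}
        i = 0
        while i < len(times):
            members = [times[i]]
            total = counts[times[i]]
            while total < min_bin and i + 1 < len(times):
                i += 1
                members.append(times[i])
                total += counts[times[i]]
            for t in members:
                merged[t] = float(np.median(members))
            i += 1
        sel = table.CMT == cmt
        table.loc[sel, "BIN"] = table.loc[sel, "BIN"].map(merged)

    obs_vals = table.DV.to_numpy(dtype=float)
    sim_vals = sims.copy()
    if pred_correct:
        factor = np.ones(len(table))
        for (_, _), idx in table.groupby(["CMT", "BIN"]).groups.items():
            idx = np.asarray(idx)
            med = np.median(pred[idx])
            with np.errstate(divide="ignore", invalid="ignore"):
                factor[idx] = np.where(pred[idx] > 0, med / pred[idx], 1.0)
        obs_vals = obs_vals * factor
        sim_vals = sim_vals * factor[None, :]

    rows, bql_rows = [], []
    for (cmt, b), idx in table.groupby(["CMT", "BIN"]).groups.items():
        idx = np.asarray(idx)
        quant = table.BQL.to_numpy()[idx] == 0
        row = dict(CMT=cmt, bin=b, n_obs=int(quant.sum()))
        if quant.any():
            for p in PCTS:
                row[f"obs_p{p}"] = np.percentile(obs_vals[idx][quant], p)
        sim_block = sim_vals[:, idx]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            per_rep = np.nanpercentile(sim_block, PCTS, axis=1)  # (3, nsim)
        for j, p in enumerate(PCTS):
            v = per_rep[j][np.isfinite(per_rep[j])]
            if len(v):
                row[f"sim_p{p}_lo"] = np.percentile(v, 2.5)
                row[f"sim_p{p}_med"] = np.percentile(v, 50)
                row[f"sim_p{p}_hi"] = np.percentile(v, 97.5)
        rows.append(row)
        sim_frac = sim_bql[:, idx].mean(axis=1)
        bql_rows.append(dict(
            CMT=cmt, bin=b,
            obs_bql_frac=float((table.BQL.to_numpy()[idx] == 1).mean()),
            sim_bql_frac_med=float(np.median(sim_frac)),
            sim_bql_frac_lo=float(np.percentile(sim_frac, 2.5)),
            sim_bql_frac_hi=float(np.percentile(sim_frac, 97.5))))
    out = VpcResult(pd.DataFrame(rows).sort_values(["CMT", "bin"]).reset_index(drop=True),
                    pd.DataFrame(bql_rows).sort_values(["CMT", "bin"]).reset_index(drop=True),
                    pred_corrected=pred_correct, nsim=nsim)
    return out


# ---------------------------------------------------------------------------
# numerical predictive check
# ---------------------------------------------------------------------------

def npc(fit: FitResult, dataset: PKDataset, model, nsim: int = 1000,
        metrics=("concentration", "AUC", "Cmax"), seed: int = 12345) -> pd.DataFrame:
    """Tabular predictive check of concentration, AUC and Cmax medians.

    Observed median of each metric per analyte against the median and 95% CI
    of the corresponding medians across simulated replicates.  AUC and Cmax
    are computed per subject from quantifiable records.
    """
    subjects = subjects_from_dataset(dataset, model.analytes)
    table = _records_frame(subjects)
    sims, _ = simulate_replicates(fit, model, subjects, nsim, seed)
    if nsim < 2:
        warnings.warn("npc with nsim < 2 cannot form confidence intervals",
                      stacklevel=2)

    def metric_values(dv: np.ndarray) -> dict:
        out = {}
        for cmt in model.analytes:
            sel = (table.CMT == cmt).to_numpy()
            vals = dv[sel]
            quant = np.isfinite(vals)
            if "concentration" in metrics and quant.any():
                out[("concentration", cmt)] = float(np.median(vals[quant]))
            aucs, cmaxs = [], []
            for sid in table.ID.unique():
                s = sel & (table.ID == sid).to_numpy()
                v, t = dv[s], table.TIME.to_numpy()[s]
                q = np.isfinite(v)
                if q.sum() >= 2:
                    aucs.append(auc_linuplogdown(t[q], np.maximum(v[q], 0.0)))
                    cmaxs.append(float(np.max(v[q])))
            if "AUC" in metrics and aucs:
                out[("AUC", cmt)] = float(np.median(aucs))
            if "Cmax" in metrics and cmaxs:
                out[("Cmax", cmt)] = float(np.median(cmaxs))
        return out

    dv_obs = np.where(table.BQL.to_numpy() == 0, table.DV.to_numpy(), np.nan)
    observed = metric_values(dv_obs)
    sim_results: dict = {k: [] for k in observed}
    for r in range(nsim):
        for k, v in metric_values(sims[r]).items():
            if k in sim_results:
                sim_results[k].append(v)
    rows = []
    for (metric, cmt), obs_val in observed.items():
        v = np.asarray(sim_results[(metric, cmt)])
        row = dict(metric=metric, CMT=cmt, observed=obs_val,
                   sim_median=float(np.median(v)) if len(v) else np.nan)
        if nsim >= 2 and len(v) >= 2:
            row["sim_lo"] = float(np.percentile(v, 2.5))
            row["sim_hi"] = float(np.percentile(v, 97.5))
        rows.append(row)
    return pd.DataFrame(rows)
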