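"""Structural PK models: BUP->norBUP with transit absorption, one-compartment NLX.

Both systems are linear and time-invariant for a given subject, so they are
solved exactly: the BUP/norBUP system by piecewise matrix-exponential
propagation between dose events (doses are impulses into the first transit
compartment), naloxone by closed-form Bateman superposition.

Convention: when an output time coincides with a dose event the concentration
reported is the *pre-dose* (trough) value.

State layout of the BUP/norBUP system (n = number of transit compartments)::

    0 .. n-1   transit chain, each draining at ktr = (n+1)/MTT
    n          depot, draining at ka into the BUP central compartment
    n+1, n+2   BUP central / peripheral
    n+3, n+4   norBUP central / peripheral
    n+5        cumulative norBUP elimination (mass-balance accounting)

All amounts in ng, concentrations in ng/L (central amount / V).
"""

from __future__ import annotations

import numpy as np
from scipy.linalg import expm

from .params import (NG_PER_MG, BUP_ETA_NAMES, NLX_ETA_NAMES,
                     BupParams, NlxParams, OccupancyParams)
from .regimen import Regimen

__all__ = [
    "covariate_f_bup", "covariate_fm", "covariate_f_nlx", "mu_oro",
    "individual_bup", "individual_nlx", "bup_system_matrix",
    "solve_bup_norbup", "solve_bup_norbup_grid", "solve_nlx", "solve_nlx_batch",
]


# ---------------------------------------------------------------------------
# covariate functions
# ---------------------------------------------------------------------------

def covariate_f_bup(nos, params: BupParams):
    """Relative BUP bioavailability for a given number of swallows.

    Linear in NOS centered at the overall median: 1 + theta_nos*(NOS - ref),
    floored at ``params.f_floor`` so extreme extrapolation cannot produce a
    non-positive bioavailability.
    """
    nos = np.asarray(nos, dtype=float)
    if np.any(nos < 0):
        raise ValueError("NOS must be >= 0")
    f = 1.0 + params.theta_nos * (nos - params.nos_ref)
    out = np.maximum(f, params.f_floor)
    return out.item() if out.ndim == 0 else out

def covariate_fm(dose_bup: float, params: BupParams) -> float:
    """Fm multiplier for the dose tier (16 mg tier has a higher Fm).

    Default is the linear-categorical form, multiplier 1 + fm_inc16 for the
    16 mg tier; with ``params.fm_absolute`` the multiplier is fm_inc16 itself.
    """
    if dose_bup <= 0:
        raise ValueError("dose must be > 0")
    if dose_bup < 16.0:
        return 1.0
    return params.fm_inc16 if params.fm_absolute else 1.0 + params.fm_inc16

def covariate_f_nlx(dose_nlx, params: NlxParams):
    """NLX bioavailability, power function of dose: F_ref*(dose/ref)**theta."""
    dose = np.asarray(dose_nlx, dtype=float)
    if np.any(dose <= 0):
        raise ValueError("dose must be > 0")
    out = params.f_ref * (dose / params.dose_ref) ** params.theta_dose
    return out.item() if out.ndim == 0 else out

def mu_oro(cp_ng_ml, params: OccupancyParams | None = None):
    """Mu-opioid receptor occupancy (%) from BUP plasma concentration (ng/mL)."""
    params = params or OccupancyParams()
    cp = np.asarray(cp_ng_ml, dtype=float)
    if np.any(cp < 0):
        raise ValueError("concentration must be >= 0")
    out = params.emax * cp / (params.ec50 + cp)
    return out.item() if out.ndim == 0 else out


# ---------------------------------------------------------------------------
# individualization (exponential IIV)
# ---------------------------------------------------------------------------

def individual_bup(params: BupParams, eta: dict | None = None) -> dict:
    """Subject-level BUP/norBUP parameters, P_i = theta*exp(eta).

    No random effect exists for ka (hard structural constraint).
    """
    eta = eta or {}
    unknown = set(eta) - set(BUP_ETA_NAMES)
    if unknown:
        raise ValueError(f"unknown eta entries: {sorted(unknown)}")
    e = {k: np.exp(eta.get(k, 0.0)) for k in BUP_ETA_NAMES}
    return {
        "cl": params.cl_f * e["CL"], "vc": params.vc_f * e["VC"],
        "vp": params.vp_f * e["VP"], "q": params.q_f * e["Q"],
        "mtt": params.mtt * e["MTT"], "ka": params.ka,
        "clm": params.clm_fm * e["CLM"], "vcm": params.vcm_fm * e["VCM"],
        "vpm": params.vpm_fm * e["VPM"], "qm": params.qm_fm * e["QM"],
    }

def individual_nlx(params: NlxParams, eta: dict | None = None) -> dict:
    eta = eta or {}
    unknown = set(eta) - set(NLX_ETA_NAMES)
    if unknown:
        raise ValueError(f"unknown eta entries: {sorted(unknown)}")
    return {
        "cl": params.cl * np.exp(eta.get("CL", 0.0)),
        "vc": params.vc * np.exp(eta.get("VC", 0.0)),
        "ka": params.ka,
    }


# ---------------------------------------------------------------------------
# BUP/norBUP linear system
# ---------------------------------------------------------------------------

def bup_system_matrix(params: BupParams, eta: dict | None = None,
                      fm: float = 1.0) -> np.ndarray:
    """Rate matrix A of the BUP/norBUP system for one subject (dx/dt = A x)."""
    p = individual_bup(params, eta)
    n = params.n_transit
    ktr = (n + 1) / p["mtt"]
    k = n + 6
    A = np.zeros((k, k))
    # transit chain -> depot
    for i in range(n):
        A[i, i] = -ktr
        A[i + 1, i] = ktr
    idep, ibc, ibp, imc, imp, iel = n, n + 1, n + 2, n + 3, n + 4, n + 5
    A[idep, idep] += -p["ka"]
    A[ibc, idep] = p["ka"]
    k10, k12, k21 = p["cl"] / p["vc"], p["q"] / p["vc"], p["q"] / p["vp"]
    A[ibc, ibc] += -(k10 + k12)
    A[ibc, ibp] = k21
    A[ibp, ibc] = k12
    A[ibp, ibp] = -k21
    # parent elimination flux feeds the metabolite (apparent scale, x Fm)
    A[imc, ibc] = fm * k10
    km10, km12, km21 = p["clm"] / p["vcm"], p["qm"] / p["vcm"], p["qm"] / p["vpm"]
    A[imc, imc] = -(km10 + km12)
    A[imc, imp] = km21
    A[imp, imc] = km12
    A[imp, imp] = -km21
    A[iel, imc] = km10
    if not np.all(np.isfinite(A)):
        raise ValueError("non-finite rate constants")
    return A


def _dose_vector(params: BupParams, regimen: Regimen, event) -> np.ndarray:
    """Impulse added to the state by one dose event (ng into transit 1/depot)."""
    k = params.n_transit + 6
    v = np.zeros(k)
    f = covariate_f_bup(event.nos, params)
    v[0] = event.bup_mg * NG_PER_MG * f
    return v


def solve_bup_norbup(params: BupParams, regimen: Regimen, times,
                     eta: dict | None = None, return_amounts: bool = False):
    """Exact BUP and norBUP concentration-time curves for one subject.

    Returns ``(c_bup, c_norbup)`` in ng/L at ``times`` (hours since first
    dose); with ``return_amounts=True`` also the full state matrix
    (len(times), n_states) for mass-balance checks.
    """
    times = np.asarray(times, dtype=float)
    if times.ndim != 1:
        raise ValueError("times must be one-dimensional")
    n = params.n_transit
    k = n + 6
    if not regimen.events:
        z = np.zeros(len(times))
        return (z, z.copy(), np.zeros((len(times), k))) if return_amounts else (z, z.copy())
    fm = params.fm * covariate_fm(regimen.dose_group, params)
    A = bup_system_matrix(params, eta, fm=fm)
    p = individual_bup(params, eta)

    order = np.argsort(times, kind="stable")
    sorted_times = times[order]
    events = list(regimen.events)
    states = np.zeros((len(times), k))
    x = np.zeros(k)
    t_cur = 0.0
    ev_i = 0
    cache: dict[float, np.ndarray] = {}

    def step(dt: float) -> np.ndarray:
        key = round(dt, 12)
        if key not in cache:
            cache[key] = expm(A * dt)
        return cache[key]

    for j in order:
        t_obs = times[j]
        if t_obs < 0:
            raise ValueError("times must be >= 0")
        # apply doses strictly before t_obs (pre-dose convention at ties)
        while ev_i < len(events) and events[ev_i].time < t_obs:
            ev = events[ev_i]
            if ev.time > t_cur:
                x = step(ev.time - t_cur) @ x
                t_cur = ev.time
            x = x + _dose_vector(params, regimen, ev)
            ev_i += 1
        if t_obs > t_cur:
            x = step(t_obs - t_cur) @ x
            t_cur = t_obs
        states[j] = x
    c_bup = states[:, n + 1] / p["vc"]
    c_nor = states[:, n + 3] / p["vcm"]
    if return_amounts:
        return c_bup, c_nor, states
    return c_bup, c_nor


def solve_bup_norbup_grid(params: BupParams, regimen: Regimen,
                          etas: np.ndarray | None, t_end: float, dt: float = 0.05,
                          t_start: float = 0.0):
    """Batched BUP/norBUP solution on a uniform grid for many subjects.

    ``etas`` is an (n_subjects, 9) array ordered as ``BUP_ETA_NAMES`` (or
    None for a single typical subject).  Dose times must fall on the grid.
    Returns ``(t, c_bup, c_norbup)`` with concentrations shaped
    (n_subjects, n_times) restricted to ``t_start <= t <= t_end`` (pre-dose
    convention at dose times).
    """
    if etas is None:
        etas = np.zeros((1, len(BUP_ETA_NAMES)))
    etas = np.atleast_2d(np.asarray(etas, dtype=float))
    m = etas.shape[0]
    n = params.n_transit
    k = n + 6
    fm = params.fm * covariate_fm(regimen.dose_group, params)
    A = np.stack([
        bup_system_matrix(params, dict(zip(BUP_ETA_NAMES, e)), fm=fm)
        for e in etas
    ])
    P = expm(A * dt)                      # (m, k, k) one-step propagators
    n_steps = int(round(t_end / dt))
    if abs(n_steps * dt - t_end) > 1e-9:
        raise ValueError("t_end must be a multiple of dt")
    dose_idx = {}
    for ev in regimen.events:
        i = int(round(ev.time / dt))
        if abs(i * dt - ev.time) > 1e-9:
            raise ValueError("dose times must fall on the simulation grid")
        dose_idx[i] = ev
    vcs = params.vc_f * np.exp(etas[:, BUP_ETA_NAMES.index("VC")])
    vcms = params.vcm_fm * np.exp(etas[:, BUP_ETA_NAMES.index("VCM")])
    i0 = int(np.ceil(t_start / dt - 1e-9))
    t_out = np.arange(i0, n_steps + 1) * dt
    c_bup = np.empty((m, len(t_out)))
    c_nor = np.empty((m, len(t_out)))
    x = np.zeros((m, k))
    for i in range(n_steps + 1):
        if i >= i0:
            c_bup[:, i - i0] = x[:, n + 1] / vcs
            c_nor[:, i - i0] = x[:, n + 3] / vcms
        if i in dose_idx:
            ev = dose_idx[i]
            x[:, 0] += ev.bup_mg * NG_PER_MG * covariate_f_bup(ev.nos, params)
        if i < n_steps:
            x = np.einsum("mij,mj->mi", P, x)
    return t_out, c_bup, c_nor


# ---------------------------------------------------------------------------
# naloxone (closed-form Bateman superposition)
# ---------------------------------------------------------------------------

def solve_nlx_batch(params: NlxParams, regimen: Regimen, times,
                    etas: np.ndarray | None = None) -> np.ndarray:
    """NLX concentrations (ng/L), shape (n_subjects, n_times).

    One-compartment first-order absorption/elimination; each dose event
    contributes a Bateman term with its own dose-dependent bioavailability.
    """
    times = np.asarray(times, dtype=float)
    if etas is None:
        etas = np.zeros((1, len(NLX_ETA_NAMES)))
    etas = np.atleast_2d(np.asarray(etas, dtype=float))
    cl = params.cl * np.exp(etas[:, 0])[:, None]
    vc = params.vc * np.exp(etas[:, 1])[:, None]
    ka = params.ka
    ke = cl / vc
    conc = np.zeros((etas.shape[0], len(times)))
    for ev in regimen.events:
        tau = times[None, :] - ev.time
        pos = tau > 0
        tau = np.where(pos, tau, 0.0)
        f = covariate_f_nlx(ev.nlx_mg, params)
        dose_ng = ev.nlx_mg * NG_PER_MG * f
        diff = ka - ke
        near = np.abs(diff) < 1e-10 * ka
        with np.errstate(divide="ignore", invalid="ignore"):
            bate = dose_ng * ka / (vc * diff) * (np.exp(-ke * tau) - np.exp(-ka * tau))
        limit = dose_ng / vc * ka * tau * np.exp(-ka * tau)
        conc += np.where(pos, np.where(near, limit, bate), 0.0)
    return conc


def solve_nlx(params: NlxParams, regimen: Regimen, times,
              eta: dict | None = None) -> np.ndarray:
    """NLX concentration curve (ng/L) for a single subject."""
    eta = eta or {}
    ev = np.array([[eta.get("CL", 0.0), eta.get("VC", 0.0)]])
    unknown = set(eta) - set(NLX_ETA_NAMES)
    if unknown:
        raise ValueError(f"unknown eta entries: {sorted(unknown)}")
    return solve_nlx_batch(params, regimen, times, ev)[0]
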