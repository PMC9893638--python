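"""Nonlinear mixed-effects estimation with M1/M3 BQL handling.

The marginal likelihood is approximated subject-by-subject with the Laplace
method: the joint -2 log-likelihood J(eta) (residual terms plus the normal
eta prior) is minimized over each subject's random effects and

    -2 log L_i  =  J(eta_hat) - q log(2 pi) + log |J''(eta_hat) / 2|

FOCE-I is the same construction with the Gauss-Newton/expected-information
approximation of J'' (model second derivatives dropped, the residual-variance
dependence on eta retained - the "interaction").  Censored (BQL) records
contribute the censored-normal mass Phi((LLOQ - IPRED)/sd) under M3 and are
discarded under M1; the M1/M3 choice follows the 10% BQL-fraction rule.

Fixed effects, variance components and residual SDs are estimated by a
derivative-free outer optimization on a log scale (positivity), with
covariate coefficients unconstrained.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.stats import norm

from .dataset import PKDataset
from .params import NG_PER_MG, BupParams, NlxParams
from .regimen import DoseEvent, Regimen
from .structural import solve_bup_norbup, solve_nlx

logger = logging.getLogger(__name__)

LOG2PI = float(np.log(2 * np.pi))


# ---------------------------------------------------------------------------
# BQL strategy
# ---------------------------------------------------------------------------

def choose_bql_method(dataset: PKDataset, analyte: str, arm: str | None = None) -> str:
    """M1 (discard) when the BQL fraction is < 10%, M3 (censored likelihood) otherwise."""
    frac = dataset.bql_fraction(analyte, arm)
    return "M1" if frac < 0.10 else "M3"


# ---------------------------------------------------------------------------
# data containers
# ---------------------------------------------------------------------------

@dataclass
class SubjectData:
    """One subject's dosing history, observations and covariates."""

    id: object
    regimen: Regimen
    times: np.ndarray          # observation times, h
    dv: np.ndarray             # observed concentration (nan for BQL)
    bql: np.ndarray            # 0/1
    lloq: np.ndarray
    cmt: np.ndarray            # analyte per record
    covariates: dict


def subjects_from_dataset(dataset: PKDataset, analytes) -> list[SubjectData]:
    out = []
    for sid in dataset.subjects:
        sub = dataset.subject_data(sid)
        doses = sub[sub.EVID == 1]
        events = [DoseEvent(r.TIME, r.AMT / NG_PER_MG, r.NOS) for r in doses.itertuples()]
        reg = Regimen(events, dose_group=float(sub.DOSEGRP.iloc[0]))
        obs = sub[(sub.EVID == 0) & sub.CMT.isin(analytes)]
        if obs.empty:
            continue
        out.append(SubjectData(
            id=sid, regimen=reg,
            times=obs.TIME.to_numpy(dtype=float),
            dv=obs.DV.to_numpy(dtype=float),
            bql=obs.BQL.to_numpy(dtype=int),
            lloq=obs.LLOQ.to_numpy(dtype=float),
            cmt=obs.CMT.to_numpy(dtype=object),
            covariates=dict(NOS=float(sub.NOS.iloc[0]),
                            DOSEGRP=float(sub.DOSEGRP.iloc[0]),
                            STATE=str(sub.STATE.iloc[0]),
                            AGE=float(sub.AGE.iloc[0]),
                            WT=float(sub.WT.iloc[0]),
                            HT=float(sub.HT.iloc[0])),
        ))
    if not out:
        raise ValueError("dataset contains no observations for the requested analytes")
    return out


# ---------------------------------------------------------------------------
# covariate effects (SCM candidates)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CovariateEffect:
    """A parameter-covariate relation in one of the three canonical forms.

    linear:       P = theta1 * (1 + theta2 * (cov - center))
    power:        P = theta1 * (cov / center) ** theta2
    categorical:  P = theta1 * (1 + theta2 * indicator)
    """

    parameter: str            # model theta the effect multiplies (e.g. "CL")
    covariate: str            # covariate name in SubjectData.covariates
    form: str                 # linear | power | categorical
    center: float = 0.0
    init: float = 0.01

    def __post_init__(self):
        if self.form not in ("linear", "power", "categorical"):
            raise ValueError(f"unknown covariate form {self.form!r}")
        if self.form in ("linear", "power") and self.center <= 0 and self.form == "power":
            raise ValueError("power form requires a positive center")

    @property
    def theta_name(self) -> str:
        return f"BETA_{self.parameter}_{self.covariate}"

    def factor(self, theta2: float, cov_value) -> float:
        if self.form == "linear":
            return 1.0 + theta2 * (float(cov_value) - self.center)
        if self.form == "power":
            return (float(cov_value) / self.center) ** theta2
        return 1.0 + theta2 * float(cov_value)


# ---------------------------------------------------------------------------
# model wrappers around the structural solvers
# ---------------------------------------------------------------------------

class BupModel:
    """Estimable view of the BUP/norBUP structural model.

    ``theta`` entries map onto BupParams fields; ``THETA_NOS`` and
    ``FM_INC16`` are unconstrained covariate coefficients, everything else is
    positive.  Additional SCM covariate effects multiply the mapped theta
    per subject.
    """

    THETA_FIELDS = {"CL": "cl_f", "VC": "vc_f", "VP": "vp_f", "Q": "q_f",
                    "KA": "ka", "MTT": "mtt", "CLM": "clm_fm", "VCM": "vcm_fm",
                    "VPM": "vpm_fm", "QM": "qm_fm",
                    "THETA_NOS": "theta_nos", "FM_INC16": "fm_inc16"}
    UNCONSTRAINED = {"THETA_NOS", "FM_INC16"}
    ETA_NAMES = ("CL", "VC", "VP", "Q", "MTT", "CLM", "VCM", "VPM", "QM")
    RESIDUALS = {"BUP": ("sigma_bup", None), "NORBUP": ("sigma_norbup", None)}

    def __init__(self, template: BupParams | None = None,
                 analytes=("BUP", "NORBUP"),
                 covariate_effects: tuple = ()):
        self.template = template or BupParams()
        self.analytes = tuple(analytes)
        self.covariate_effects = tuple(covariate_effects)

    def default_theta(self) -> dict:
        t = {k: getattr(self.template, f) for k, f in self.THETA_FIELDS.items()}
        t.update({ce.theta_name: ce.init for ce in self.covariate_effects})
        return t

    def unconstrained(self) -> set:
        return self.UNCONSTRAINED | {ce.theta_name for ce in self.covariate_effects}

    def _params_for(self, theta: dict, subject: SubjectData) -> BupParams:
        fields = {f: theta.get(k, getattr(self.template, f))
                  for k, f in self.THETA_FIELDS.items()}
        for ce in self.covariate_effects:
            f = self.THETA_FIELDS[ce.parameter]
            fields[f] = fields[f] * ce.factor(theta[ce.theta_name],
                                              subject.covariates[ce.covariate])
        return self.template.replace(**fields)

    def predict(self, theta: dict, eta: dict, subject: SubjectData) -> np.ndarray:
        params = self._params_for(theta, subject)
        c_bup, c_nor = solve_bup_norbup(params, subject.regimen, subject.times, eta)
        ipred = np.where(subject.cmt == "BUP", c_bup, c_nor)
        return ipred


class NlxModel:
    """Estimable view of the one-compartment naloxone model."""

    THETA_FIELDS = {"CL": "cl", "VC": "vc", "KA": "ka", "THETA_DOSE": "theta_dose"}
    UNCONSTRAINED = {"THETA_DOSE"}
    ETA_NAMES = ("CL", "VC")
    RESIDUALS = {"NLX": ("sigma_prop", "sigma_add")}

    def __init__(self, template: NlxParams | None = None,
                 covariate_effects: tuple = ()):
        self.template = template or NlxParams()
        self.analytes = ("NLX",)
        self.covariate_effects = tuple(covariate_effects)

    def default_theta(self) -> dict:
        t = {k: getattr(self.template, f) for k, f in self.THETA_FIELDS.items()}
        t.update({ce.theta_name: ce.init for ce in self.covariate_effects})
        return t

    def unconstrained(self) -> set:
        return self.UNCONSTRAINED | {ce.theta_name for ce in self.covariate_effects}

    def _params_for(self, theta: dict, subject: SubjectData) -> NlxParams:
        fields = {f: theta.get(k, getattr(self.template, f))
                  for k, f in self.THETA_FIELDS.items()}
        for ce in self.covariate_effects:
            f = self.THETA_FIELDS[ce.parameter]
            fields[f] = fields[f] * ce.factor(theta[ce.theta_name],
                                              subject.covariates[ce.covariate])
        return self.template.replace(**fields)

    def predict(self, theta: dict, eta: dict, subject: SubjectData) -> np.ndarray:
        params = self._params_for(theta, subject)
        return solve_nlx(params, subject.regimen, subject.times, eta)


# ---------------------------------------------------------------------------
# likelihood
# ---------------------------------------------------------------------------

def _residual_sd(model, theta_sigma: dict, cmt: np.ndarray, ipred: np.ndarray) -> np.ndarray:
    sd2 = np.zeros_like(ipred)
    for analyte, (prop, add) in model.RESIDUALS.items():
        mask = cmt == analyte
        if not mask.any():
            continue
        v = np.zeros(mask.sum())
        if prop is not None:
            v += (theta_sigma[prop] * ipred[mask]) ** 2
        if add is not None:
            v += theta_sigma[add] ** 2
        sd2[mask] = v
    return np.sqrt(sd2)


def individual_joint_neg2ll(theta: dict, eta: dict, subject: SubjectData,
                            model, omega: dict, sigma: dict,
                            bql_method: str = "M3") -> float:
    """Joint -2 log-likelihood of one subject's data and random effects.

    Quantifiable records contribute the normal density at IPRED with the
    residual-model variance; BQL records contribute log Phi((LLOQ-IPRED)/sd)
    under M3 and nothing under M1; the eta prior adds eta^2/omega^2 plus
    normalizing constants.
    """
    ipred = model.predict(theta, eta, subject)
    sd = _residual_sd(model, sigma, subject.cmt, ipred)
    if np.any(sd[subject.bql == 0] <= 0):
        raise ValueError("non-positive residual SD at a quantifiable record")
    j = 0.0
    quant = subject.bql == 0
    if quant.any():
        r = subject.dv[quant] - ipred[quant]
        v = sd[quant] ** 2
        j += float(np.sum(np.log(2 * np.pi * v) + r * r / v))
    cens = subject.bql == 1
    if cens.any() and bql_method == "M3":
        # IPRED can be exactly 0 (pre-dose) making sd 0; the censored mass is 1
        sd_c = np.maximum(sd[cens], 1e-12)
        z = (subject.lloq[cens] - ipred[cens]) / sd_c
        j += float(-2.0 * np.sum(norm.logcdf(z)))
    for name, om in omega.items():
        if om > 0:
            e = eta.get(name, 0.0)
            j += e * e / (om * om) + np.log(2 * np.pi * om * om)
    return j


def _fd_grad_hess(J, x, f0, h=1e-4):
    """Central finite-difference gradient and Hessian of J at x."""
    q = len(x)
    g = np.zeros(q)
    H = np.zeros((q, q))
    fp, fm = np.zeros(q), np.zeros(q)
    for a in range(q):
        e = np.zeros(q)
        e[a] = h
        fp[a], fm[a] = J(x + e), J(x - e)
        g[a] = (fp[a] - fm[a]) / (2 * h)
        H[a, a] = (fp[a] - 2 * f0 + fm[a]) / (h * h)
    for a in range(q):
        for b in range(a + 1, q):
            ea, eb = np.zeros(q), np.zeros(q)
            ea[a] = h
            eb[b] = h
            H[a, b] = H[b, a] = (J(x + ea + eb) - J(x + ea - eb)
                                 - J(x - ea + eb) + J(x - ea - eb)) / (4 * h * h)
    return g, H


def _newton_minimize(J, x0, tol=1e-8, max_iter=15):
    """Damped Newton minimization (small q); returns (x, f, Hessian at x)."""
    x = np.asarray(x0, dtype=float)
    f = J(x)
    if not np.isfinite(f):
        x = np.zeros_like(x)
        f = J(x)
    g = H = None
    for _ in range(max_iter):
        g, H = _fd_grad_hess(J, x, f)
        # regularize indefinite curvature toward the descent direction
        w, V = np.linalg.eigh(H)
        w = np.maximum(np.abs(w), 1e-8)
        step = -V @ ((V.T @ g) / w)
        t = 1.0
        for _ in range(8):
            f_new = J(x + t * step)
            if f_new < f:
                break
            t *= 0.5
        else:
            break
        x = x + t * step
        gain, f = f - f_new, f_new
        if gain < tol:
            break
    if H is None:
        g, H = _fd_grad_hess(J, x, f)
    return x, f, H


def _subject_marginal(theta, subject, model, omega, sigma, bql_method, method,
                      eta0=None, h=1e-4):
    """Laplace/FOCE-I -2 log marginal likelihood of one subject.

    Returns (neg2ll, eta_hat dict).
    """
    eta_names = [k for k, v in omega.items() if v > 0]
    q = len(eta_names)

    def J(evec):
        return individual_joint_neg2ll(theta, dict(zip(eta_names, evec)),
                                       subject, model, omega, sigma, bql_method)

    if q == 0:
        return J(np.zeros(0)), {}

    x0 = np.array([eta0.get(k, 0.0) for k in eta_names]) if eta0 else np.zeros(q)
    ehat, jhat, H = _newton_minimize(J, x0)

    if method == "laplace":
        pass          # Newton's final Hessian of J is the Laplace curvature
    else:  # foce-i: Gauss-Newton / expected information with interaction
        eta_hat = dict(zip(eta_names, ehat))
        f0 = model.predict(theta, eta_hat, subject)
        sd0 = _residual_sd(model, sigma, subject.cmt, f0)
        G = np.zeros((len(f0), q))
        S = np.zeros((len(f0), q))
        for a in range(q):
            ea = dict(eta_hat)
            eb = dict(eta_hat)
            ea[eta_names[a]] += h
            eb[eta_names[a]] -= h
            fa = model.predict(theta, ea, subject)
            fb = model.predict(theta, eb, subject)
            G[:, a] = (fa - fb) / (2 * h)
            S[:, a] = (_residual_sd(model, sigma, subject.cmt, fa) ** 2
                       - _residual_sd(model, sigma, subject.cmt, fb) ** 2) / (2 * h)
        quant = subject.bql == 0
        v = sd0[quant] ** 2
        Gq, Sq = G[quant], S[quant]
        H = 2 * (Gq / v[:, None]).T @ Gq + (Sq / v[:, None]).T @ (Sq / v[:, None])
        H += 2 * np.diag([1.0 / omega[k] ** 2 for k in eta_names])

    sign, logdet = np.linalg.slogdet(H / 2.0)
    if sign <= 0:      # indefinite curvature: fall back to prior curvature
        logdet = float(np.sum(np.log([1.0 / omega[k] ** 2 for k in eta_names])))
    neg2ll = jhat - q * LOG2PI + logdet
    return neg2ll, dict(zip(eta_names, ehat))


def marginal_neg2ll(theta, subjects, model, omega, sigma, bql_method, method,
                    eta_cache=None):
    """Total -2 log marginal likelihood (OFV) over all subjects."""
    total = 0.0
    ebes = {}
    for sub in subjects:
        eta0 = eta_cache.get(sub.id) if eta_cache else None
        n2, ehat = _subject_marginal(theta, sub, model, omega, sigma,
                                     bql_method, method, eta0=eta0)
        total += n2
        ebes[sub.id] = ehat
        if eta_cache is not None:
            eta_cache[sub.id] = ehat
    return total, ebes


# ---------------------------------------------------------------------------
# FitResult and the outer optimization
# ---------------------------------------------------------------------------

@dataclass
class FitResult:
    theta: dict
    omega: dict
    sigma: dict
    ofv: float
    converged: bool
    ebes: dict = field(default_factory=dict)          # subject -> eta dict
    rse: dict | None = None                           # name -> %RSE
    condition_number: float | None = None
    eta_shrinkage: dict = field(default_factory=dict)  # %, per eta
    eps_shrinkage: float | None = None                 # %
    method: str = "foce-i"
    bql_method: str = "M1"
    trace: list = field(default_factory=list)
    message: str = ""

    @property
    def estimates(self) -> dict:
        return {**self.theta, **{f"omega_{k}": v for k, v in self.omega.items()},
                **{f"sigma_{k.removeprefix('sigma_')}": v for k, v in self.sigma.items()}}


class _Transform:
    """Flat-vector <-> named-dict transform; positives on the log scale."""

    def __init__(self, theta0, omega0, sigma0, unconstrained, fixed):
        self.names = []
        self.kinds = []       # (group, name)
        self.logscale = []
        self.fixed = {("theta", k): v for k, v in theta0.items() if k in fixed}
        self.fixed.update({("omega", k): v for k, v in omega0.items()
                           if f"omega_{k}" in fixed or v == 0})
        self.fixed.update({("sigma", k): v for k, v in sigma0.items() if k in fixed})
        x0 = []
        for k, v in theta0.items():
            if ("theta", k) in self.fixed:
                continue
            self.kinds.append(("theta", k))
            if k in unconstrained:
                self.logscale.append(False)
                x0.append(v)
            else:
                self.logscale.append(True)
                x0.append(np.log(v))
        for k, v in omega0.items():
            if ("omega", k) in self.fixed:
                continue
            self.kinds.append(("omega", k))
            self.logscale.append(True)
            x0.append(np.log(v))
        for k, v in sigma0.items():
            if ("sigma", k) in self.fixed:
                continue
            self.kinds.append(("sigma", k))
            self.logscale.append(True)
            x0.append(np.log(v))
        self.x0 = np.array(x0, dtype=float)

    def unpack(self, x):
        theta, omega, sigma = {}, {}, {}
        for (group, name), val in self.fixed.items():
            {"theta": theta, "omega": omega, "sigma": sigma}[group][name] = val
        for (group, name), log, v in zip(self.kinds, self.logscale, x):
            {"theta": theta, "omega": omega, "sigma": sigma}[group][name] = (
                float(np.exp(v)) if log else float(v))
        return theta, omega, sigma


def fit(dataset: PKDataset, model, theta_init: dict | None = None,
        omega_init: dict | None = None, sigma_init: dict | None = None,
        fixed: set | None = None, method: str | None = None,
        bql_method: str | None = None, compute_se: bool = False,
        maxfev: int = 2000, tol: float = 1e-4) -> FitResult:
    """Maximum (approximate) marginal-likelihood fit of a population PK model.

    ``fixed`` names parameters held at their initial value (use the
    ``omega_<name>`` prefix for variance components).  Omega entries absent
    from ``omega_init`` are structurally zero (no IIV).  ``bql_method`` is
    chosen per the 10% rule when None, and the default estimation method
    pairs with it (FOCE-I with M1, Laplace with M3).  Deterministic given
    data and inits; non-convergence is flagged on the result, not raised.
    """
    if method not in ("foce-i", "laplace", None):
        raise ValueError("method must be 'foce-i' or 'laplace'")
    subjects = subjects_from_dataset(dataset, model.analytes)
    theta0 = model.default_theta()
    theta0.update(theta_init or {})
    omega0 = dict(omega_init or {})
    sigma0 = {}
    for prop, add in model.RESIDUALS.values():
        if prop:
            sigma0.setdefault(prop, 0.2)
        if add:
            sigma0.setdefault(add, 1.0)
    sigma0.update(sigma_init or {})
    if bql_method is None:
        fracs = [dataset.bql_fraction(a) for a in model.analytes]
        bql_method = "M1" if max(fracs) < 0.10 else "M3"
    if method is None:
        method = "foce-i" if bql_method == "M1" else "laplace"
    if bql_method == "M1":
        subjects = [SubjectData(s.id, s.regimen, s.times[s.bql == 0],
                                s.dv[s.bql == 0], s.bql[s.bql == 0],
                                s.lloq[s.bql == 0], s.cmt[s.bql == 0],
                                s.covariates)
                    for s in subjects]
        subjects = [s for s in subjects if len(s.times)]

    tr = _Transform(theta0, omega0, sigma0, model.unconstrained(), fixed or set())
    eta_cache: dict = {}
    trace: list = []
    best = {"x": tr.x0.copy(), "f": np.inf}

    def objective(x):
        theta, omega, sigma = tr.unpack(x)
        try:
            ofv, _ = marginal_neg2ll(theta, subjects, model, omega, sigma,
                                     bql_method, method, eta_cache)
        except (ValueError, FloatingPointError, np.linalg.LinAlgError):
            return 1e12
        if not np.isfinite(ofv):
            return 1e12
        if ofv < best["f"]:
            best["f"], best["x"] = ofv, x.copy()
            trace.append(ofv)
        return ofv

    converged = True
    message = "no free parameters"
    if len(tr.x0):
        res = minimize(objective, tr.x0, method="Nelder-Mead",
                       options={"xatol": tol, "fatol": tol,
                                "maxfev": maxfev, "adaptive": len(tr.x0) > 6})
        converged = bool(res.success) and np.isfinite(best["f"])
        message = res.message
    else:
        best["f"] = objective(tr.x0)

    theta, omega, sigma = tr.unpack(best["x"])
    ofv, ebes = marginal_neg2ll(theta, subjects, model, omega, sigma,
                                bql_method, method, eta_cache)
    result = FitResult(theta=theta, omega=omega, sigma=sigma, ofv=float(ofv),
                       converged=converged, ebes=ebes, method=method,
                       bql_method=bql_method, trace=trace, message=str(message))

    # shrinkage diagnostics
    for name, om in omega.items():
        if om > 0 and len(ebes) > 1:
            sd = np.std([e.get(name, 0.0) for e in ebes.values()], ddof=1)
            result.eta_shrinkage[name] = 100.0 * (1.0 - sd / om)
    iwres = []
    for sub in subjects:
        ipred = model.predict(theta, ebes.get(sub.id, {}), sub)
        sd = _residual_sd(model, sigma, sub.cmt, ipred)
        quant = (sub.bql == 0) & (sd > 0)
        iwres.extend(((sub.dv[quant] - ipred[quant]) / sd[quant]).tolist())
    if len(iwres) > 1:
        result.eps_shrinkage = 100.0 * (1.0 - float(np.std(iwres, ddof=1)))

    if compute_se and len(tr.x0):
        result.rse, result.condition_number = _standard_errors(
            best["x"], tr, subjects, model, bql_method, method)
    return result


def _standard_errors(x, tr, subjects, model, bql_method, method, h=1e-3):
    """%RSE and condition number from a finite-difference Hessian of the OFV."""
    n = len(x)

    def f(xv):
        theta, omega, sigma = tr.unpack(xv)
        ofv, _ = marginal_neg2ll(theta, subjects, model, omega, sigma,
                                 bql_method, method)
        return ofv

    H = np.zeros((n, n))
    for a in range(n):
        for b in range(a, n):
            ea, eb = np.zeros(n), np.zeros(n)
            ea[a] = h
            eb[b] = h
            H[a, b] = H[b, a] = (f(x + ea + eb) - f(x + ea - eb)
                                 - f(x - ea + eb) + f(x - ea - eb)) / (4 * h * h)
    eig = np.linalg.eigvalsh(H)
    cond = float(eig.max() / eig.min()) if eig.min() > 0 else float("inf")
    try:
        cov = 2.0 * np.linalg.inv(H)
    except np.linalg.LinAlgError:
        return None, cond
    theta, omega, sigma = tr.unpack(x)
    rse = {}
    for i, ((group, name), log) in enumerate(zip(tr.kinds, tr.logscale)):
        var = cov[i, i]
        if var < 0:
            continue
        value = {"theta": theta, "omega": omega, "sigma": sigma}[group][name]
        label = name if group == "theta" else f"{group}_{name}"
        if log:
            rse[label] = 100.0 * float(np.sqrt(var))      # SE of log ~ relative SE
        elif value != 0:
            rse[label] = 100.0 * float(np.sqrt(var)) / abs(value)
    return rse, cond


# ---------------------------------------------------------------------------
# sequential parent-metabolite fitting (PPPD)
# ---------------------------------------------------------------------------

@dataclass
class SequentialResult:
    parent: FitResult
    joint_fixed_parent: FitResult
    final: FitResult

    @property
    def stage_ofvs(self) -> tuple:
        return (self.parent.ofv, self.joint_fixed_parent.ofv, self.final.ofv)


def sequential_pppd(dataset: PKDataset, template: BupParams | None = None,
                    parent_free=("CL", "VC", "VP", "Q", "KA", "MTT"),
                    metabolite_free=("CLM", "VCM", "VPM", "QM"),
                    omega_init: dict | None = None,
                    covariate_effects: tuple = (),
                    method: str | None = None, maxfev: int = 2000,
                    fixed: set | None = None, **fit_kwargs) -> SequentialResult:
    """Three-stage sequential fit of the parent-metabolite model.

    Stage 1 fits the parent (BUP) model alone; stage 2 fixes the parent
    typical values and estimates the metabolite parameters against both
    analytes; stage 3 re-estimates everything from the stage-2 optimum.
    """
    template = template or BupParams()
    omega_init = dict(omega_init or {})
    user_fixed = set(fixed or set())
    user_sigma = dict(fit_kwargs.pop("sigma_init", {}) or {})
    all_names = set(BupModel.THETA_FIELDS)

    parent_model = BupModel(template, analytes=("BUP",),
                            covariate_effects=covariate_effects)
    fixed1 = (all_names - set(parent_free)) | {f"omega_{k}" for k in omega_init
                                               if k not in parent_free} | user_fixed
    om1 = {k: v for k, v in omega_init.items() if k in parent_free or
           f"omega_{k}" not in fixed1}
    stage1 = fit(dataset, parent_model, omega_init=om1, fixed=fixed1,
                 sigma_init=user_sigma, method=method, maxfev=maxfev,
                 **fit_kwargs)
    if not np.isfinite(stage1.ofv):
        raise RuntimeError("PPPD stage 1 (parent) failed")
    logger.info("PPPD stage 1 done, OFV=%.3f (parent params frozen hereafter "
                "for stage 2)", stage1.ofv)

    joint_model = BupModel(template, analytes=("BUP", "NORBUP"),
                           covariate_effects=covariate_effects)
    fixed2 = (all_names - set(metabolite_free)) | user_fixed
    stage2 = fit(dataset, joint_model, theta_init=stage1.theta,
                 omega_init=omega_init, sigma_init={**user_sigma, **stage1.sigma},
                 fixed=fixed2, method=method, maxfev=maxfev, **fit_kwargs)
    if not np.isfinite(stage2.ofv):
        raise RuntimeError("PPPD stage 2 (metabolite, parent fixed) failed")
    logger.info("PPPD stage 2 done, OFV=%.3f", stage2.ofv)

    fixed3 = (all_names - set(parent_free) - set(metabolite_free)) | user_fixed
    stage3 = fit(dataset, joint_model, theta_init=stage2.theta,
                 omega_init=stage2.omega, sigma_init=stage2.sigma,
                 fixed=fixed3, method=method, maxfev=maxfev, **fit_kwargs)
    if not np.isfinite(stage3.ofv):
        raise RuntimeError("PPPD stage 3 (joint refinement) failed")
    logger.info("PPPD stage 3 done, OFV=%.3f", stage3.ofv)
    return SequentialResult(stage1, stage2, stage3)


# ---------------------------------------------------------------------------
# stepwise covariate modelling
# ---------------------------------------------------------------------------

@dataclass
class ScmResult:
    selected: tuple
    ledger: pd.DataFrame     # step, phase, candidate, ofv, delta, decision


def scm(candidates, ofv_fn, forward_dofv: float = 6.64,
        backward_dofv: float = 10.83) -> ScmResult:
    """Greedy forward-inclusion / backward-elimination covariate search.

    ``ofv_fn(frozenset_of_candidates) -> OFV`` evaluates a model containing
    the given covariate effects.  Forward: add the candidate with the largest
    OFV drop while the drop is >= 6.64; backward: remove any covariate whose
    deletion raises the OFV by < 10.83.  Returns the selected set and the
    full delta-OFV ledger.
    """
    candidates = list(candidates)
    cache: dict = {}

    def ofv(included) -> float:
        key = frozenset(included)
        if key not in cache:
            cache[key] = float(ofv_fn(key))
        return cache[key]

    rows = []
    included: list = []
    step = 0
    base = ofv(included)
    while True:
        step += 1
        best_cand, best_drop = None, -np.inf
        for cand in candidates:
            if cand in included:
                continue
            delta = base - ofv(included + [cand])
            rows.append(dict(step=step, phase="forward", candidate=str(cand),
                             ofv=ofv(included + [cand]), delta=delta,
                             decision="candidate"))
            if delta > best_drop:
                best_cand, best_drop = cand, delta
        if best_cand is None or best_drop < forward_dofv:
            break
        included.append(best_cand)
        base = ofv(included)
        rows.append(dict(step=step, phase="forward", candidate=str(best_cand),
                         ofv=base, delta=best_drop, decision="included"))
    while True:
        step += 1
        worst_cand, worst_rise = None, np.inf
        for cand in included:
            rest = [c for c in included if c is not cand]
            rise = ofv(rest) - base
            rows.append(dict(step=step, phase="backward", candidate=str(cand),
                             ofv=ofv(rest), delta=rise, decision="candidate"))
            if rise < worst_rise:
                worst_cand, worst_rise = cand, rise
        if worst_cand is None or worst_rise >= backward_dofv:
            break
        included.remove(worst_cand)
        base = ofv(included)
        rows.append(dict(step=step, phase="backward", candidate=str(worst_cand),
                         ofv=base, delta=worst_rise, decision="removed"))
    return ScmResult(tuple(included), pd.DataFrame(rows))


def univariate_prescreen(dataset: PKDataset, fit_result: FitResult,
                         eta_name: str, covariates, alpha: float = 0.05) -> list:
    """Screen covariates against the EBEs of one random effect (p < alpha).

    Continuous covariates use a linear regression F-test, categorical ones a
    one-way ANOVA.  A screening heuristic, not a model comparison.
    """
    from scipy.stats import f_oneway, linregress
    ebes = fit_result.ebes
    subs = sorted(ebes)
    y = np.array([ebes[s].get(eta_name, 0.0) for s in subs])
    passed = []
    for cov, values in covariates.items():
        x = np.asarray([values[s] for s in subs])
        if np.issubdtype(np.asarray(x).dtype, np.number) and len(np.unique(x)) > 3:
            p = linregress(x.astype(float), y).pvalue
        else:
            groups = [y[x == g] for g in np.unique(x)]
            groups = [g for g in groups if len(g) > 0]
            p = f_oneway(*groups).pvalue if len(groups) > 1 else 1.0
        if p < alpha:
            passed.append(cov)
    return passed


# ---------------------------------------------------------------------------
# bootstrap
# ---------------------------------------------------------------------------

@dataclass
class BootstrapResult:
    estimates: pd.DataFrame   # one row per successful replicate
    summary: pd.DataFrame     # parameter, median, ci_lo, ci_hi
    success_rate: float


def bootstrap(dataset: PKDataset, fit_fn, n: int = 1000,
              stratify: str = "DOSEGRP", seed: int | None = None) -> BootstrapResult:
    """Stratified nonparametric bootstrap of a population fit.

    Subjects are resampled with replacement within each stratum, preserving
    per-stratum counts; ``fit_fn(PKDataset) -> FitResult`` refits each
    replicate.  Failed replicates count against the success rate and are
    excluded from the percentile CIs.
    """
    if seed is None:
        raise ValueError("a seed is required")
    rng = np.random.default_rng(seed)
    df = dataset.df
    strata = {s: df[df[stratify] == s].ID.unique()
              for s in df[stratify].unique()}
    rows = []
    n_ok = 0
    for rep in range(n):
        pieces = []
        new_id = 0
        for ids in strata.values():
            for sid in rng.choice(ids, size=len(ids), replace=True):
                new_id += 1
                g = df[df.ID == sid].copy()
                g["ID"] = new_id
                pieces.append(g)
        boot = PKDataset(pd.concat(pieces, ignore_index=True), validate=False)
        try:
            res = fit_fn(boot)
            ok = res.converged and np.isfinite(res.ofv)
        except Exception as exc:       # noqa: BLE001 - replicate failure is data
            logger.warning("bootstrap replicate %d failed: %s", rep, exc)
            ok = False
        if ok:
            n_ok += 1
            rows.append({"replicate": rep, **res.estimates})
    est = pd.DataFrame(rows)
    summary_rows = []
    for col in est.columns:
        if col == "replicate":
            continue
        v = est[col].dropna()
        summary_rows.append(dict(parameter=col, median=v.median(),
                                 ci_lo=v.quantile(0.025), ci_hi=v.quantile(0.975)))
    return BootstrapResult(est, pd.DataFrame(summary_rows),
                           success_rate=n_ok / n if n else float("nan"))


# ---------------------------------------------------------------------------
# deterministic least-squares refits (structural self-consistency)
# ---------------------------------------------------------------------------

def refit_bup_least_squares(profiles, template: BupParams | None = None,
                            free=("CL", "VC", "VP", "Q", "KA", "MTT"),
                            init: dict | None = None) -> dict:
    """Least-squares refit of the parent BUP structural model.

    ``profiles`` is a sequence of (regimen, times, conc) tuples (BUP
    concentrations, ng/L).  Parameters are optimized on the log scale with
    log-concentration residuals (robust across the orders of magnitude a
    72 h profile spans); returns the recovered theta dict.
    """
    from scipy.optimize import least_squares

    template = template or BupParams()
    free = list(free)
    theta0 = {k: getattr(template, BupModel.THETA_FIELDS[k]) for k in free}
    theta0.update(init or {})
    x0 = np.log([theta0[k] for k in free])

    def residuals(x):
        vals = dict(zip(free, np.exp(x)))
        params = template.replace(**{BupModel.THETA_FIELDS[k]: v
                                     for k, v in vals.items()})
        r = []
        for reg, times, conc in profiles:
            pred, _ = solve_bup_norbup(params, reg, times)
            mask = conc > 0
            r.extend(np.log(np.maximum(pred[mask], 1e-300) / conc[mask]).tolist())
        return np.array(r)

    sol = least_squares(residuals, x0, method="lm", xtol=1e-14, ftol=1e-14)
    return dict(zip(free, np.exp(sol.x)))


def refit_nlx_least_squares(profiles, template: NlxParams | None = None,
                            free=("CL", "VC", "KA"),
                            init: dict | None = None) -> dict:
    """Least-squares refit of the one-compartment NLX model.

    The Bateman curve is invariant under swapping the absorption and
    elimination rates (flip-flop); the result is canonicalized to the
    absorption-limited branch (ka < CL/VC) when both rates are free.
    """
    from scipy.optimize import least_squares

    template = template or NlxParams()
    free = list(free)
    theta0 = {k: getattr(template, NlxModel.THETA_FIELDS[k]) for k in free}
    theta0.update(init or {})
    x0 = np.log([theta0[k] for k in free])

    def residuals(x):
        vals = dict(zip(free, np.exp(x)))
        params = template.replace(**{NlxModel.THETA_FIELDS[k]: v
                                     for k, v in vals.items()})
        r = []
        for reg, times, conc in profiles:
            pred = solve_nlx(params, reg, times)
            mask = conc > 0
            r.extend(np.log(np.maximum(pred[mask], 1e-300) / conc[mask]).tolist())
        return np.array(r)

    sol = least_squares(residuals, x0, method="lm", xtol=1e-14, ftol=1e-14)
    out = dict(zip(free, np.exp(sol.x)))
    if {"CL", "VC", "KA"} <= set(out):
        ke = out["CL"] / out["VC"]
        if out["KA"] > ke:      # mirror solution: swap to the flip-flop branch
            out["VC"] = out["CL"] / out["KA"]
            out["KA"] = ke
    return out
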