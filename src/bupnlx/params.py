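"""Model parameter containers for the buprenorphine/naloxone population PK models.

Defaults are the published typical values, inter-individual variability (IIV)
magnitudes and residual-error magnitudes of the final sublingual BUP/NLX
models in Chinese subjects.  All disposition parameters are *apparent*
(scaled by bioavailability F or by the fraction metabolized Fm), so no
salt-to-base or molar corrections are applied anywhere.

Unit conventions
----------------
* amounts: ng internally (doses given in mg, converted at 1e6 ng/mg)
* volumes: L, clearances: L/h, times: h
* concentrations: ng/L internally; pharmacodynamic thresholds quoted in
  ng/mL are converted (x1000) at module boundaries.
* IIV entries are standard deviations of the log-normal ``eta`` terms
  (the percent-CV reporting convention, CV/100).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

NG_PER_MG = 1_000_000.0
NG_L_PER_NG_ML = 1000.0

#: order of the BUP/norBUP random effects wherever a plain vector is used
BUP_ETA_NAMES = ("CL", "VC", "VP", "Q", "MTT", "CLM", "VCM", "VPM", "QM")
#: order of the NLX random effects
NLX_ETA_NAMES = ("CL", "VC")


def _require_positive(**kwargs: float) -> None:
    for name, value in kwargs.items():
        if not value > 0:
            raise ValueError(f"{name} must be > 0, got {value!r}")


@dataclass
class BupParams:
    """Typical values and variability of the BUP -> norBUP model.

    Two-compartment disposition for both parent and metabolite, a chain of
    ``n_transit`` transit compartments plus a depot for sublingual
    absorption (transit rate ktr = (n_transit + 1) / mtt), 100% of parent
    elimination feeding the metabolite on the apparent (/Fm) scale.
    """

    cl_f: float = 270.0        # apparent clearance CL/F, L/h
    vc_f: float = 377.0        # central volume VC/F, L
    vp_f: float = 5879.0       # peripheral volume VP/F, L
    ka: float = 0.397          # absorption rate, 1/h (no IIV)
    q_f: float = 404.0         # intercompartmental clearance Q/F, L/h
    mtt: float = 0.234         # mean transit time, h
    n_transit: int = 3         # structural constant, not estimated
    theta_nos: float = -0.035  # per-swallow linear effect on F
    nos_ref: float = 2.0       # centering value (overall median NOS)
    f_floor: float = 0.05      # lower bound on covariate-adjusted F
    fm: float = 1.0            # fraction metabolized (fixed; apparent scale)
    fm_inc16: float = 1.98     # Fm increment for the 16 mg tier
    fm_absolute: bool = False  # True: 16 mg tier Fm = fm_inc16 (not 1 + fm_inc16)
    clm_fm: float = 22.2       # norBUP CL/Fm, L/h
    vcm_fm: float = 264.0      # norBUP VC/Fm, L
    vpm_fm: float = 5170.0     # norBUP VP/Fm, L
    qm_fm: float = 705.0       # norBUP Q/Fm, L/h
    omega: dict = field(default_factory=lambda: {
        "CL": 0.332, "VC": 1.356, "VP": 0.414, "Q": 0.494, "MTT": 0.375,
        "CLM": 1.196, "VCM": 0.505, "VPM": 0.451, "QM": 0.567,
    })
    sigma_prop_bup: float = 0.281     # proportional residual SD, BUP
    sigma_prop_norbup: float = 0.22   # proportional residual SD, norBUP

    def __post_init__(self) -> None:
        _require_positive(cl_f=self.cl_f, vc_f=self.vc_f, vp_f=self.vp_f,
                          ka=self.ka, q_f=self.q_f, mtt=self.mtt)
        if self.n_transit < 0 or int(self.n_transit) != self.n_transit:
            raise ValueError("n_transit must be a non-negative integer")
        self.n_transit = int(self.n_transit)
        unknown = set(self.omega) - set(BUP_ETA_NAMES)
        if unknown:
            raise ValueError(f"unknown omega entries: {sorted(unknown)}")
        if any(v < 0 for v in self.omega.values()):
            raise ValueError("omega entries must be >= 0")
        if self.sigma_prop_bup < 0 or self.sigma_prop_norbup < 0:
            raise ValueError("residual SDs must be >= 0")
        if not 0 < self.f_floor <= 1:
            raise ValueError("f_floor must lie in (0, 1]")

    @property
    def ktr(self) -> float:
        """Transit rate constant, (n_transit + 1) / MTT per hour."""
        return (self.n_transit + 1) / self.mtt

    def replace(self, **changes) -> "BupParams":
        return replace(self, **changes)


@dataclass
class NlxParams:
    """Typical values and variability of the one-compartment naloxone model.

    Sublingual bioavailability is fixed at 0.01 at the 2 mg reference dose
    and scales with dose through a power covariate with a negative exponent
    (higher NLX doses dissolve less completely, lowering F).
    """

    cl: float = 205.0          # clearance CL_NLX, L/h
    vc: float = 104.0          # central volume, L
    ka: float = 0.585          # absorption rate, 1/h
    f_ref: float = 0.01        # bioavailability at the reference dose (fixed)
    theta_dose: float = -0.36  # exponent of dose on F
    dose_ref: float = 2.0      # reference NLX dose, mg
    omega: dict = field(default_factory=lambda: {"CL": 0.312, "VC": 1.025})
    sigma_prop: float = 0.208  # proportional residual SD
    sigma_add: float = 9.24    # additive residual SD, ng/L

    def __post_init__(self) -> None:
        _require_positive(cl=self.cl, vc=self.vc, ka=self.ka,
                          f_ref=self.f_ref, dose_ref=self.dose_ref)
        if not 0 < self.f_ref <= 1:
            raise ValueError("f_ref must lie in (0, 1]")
        unknown = set(self.omega) - set(NLX_ETA_NAMES)
        if unknown:
            raise ValueError(f"unknown omega entries: {sorted(unknown)}")
        if any(v < 0 for v in self.omega.values()):
            raise ValueError("omega entries must be >= 0")
        if self.sigma_prop < 0 or self.sigma_add < 0:
            raise ValueError("residual SDs must be >= 0")

    def replace(self, **changes) -> "NlxParams":
        return replace(self, **changes)


@dataclass
class OccupancyParams:
    """Emax model linking BUP plasma concentration to mu-opioid receptor occupancy."""

    emax: float = 91.4   # maximum receptor occupancy, %
    ec50: float = 0.67   # BUP concentration at half-maximal occupancy, ng/mL

    def __post_init__(self) -> None:
        if not 0 < self.emax <= 100:
            raise ValueError("emax must lie in (0, 100]")
        if not self.ec50 > 0:
            raise ValueError("ec50 must be > 0")
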