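"""Virtual clinical trials with the statistical structure of the BUP/NLX study.

The default design reproduces the study layout: three single-dose arms
(4 mg n=12, 8 mg n=12, 16 mg n=10, healthy volunteers) with rich sampling to
72 h, and one multiple-dose arm (8 mg QD for 8 days, n=12, OUD subjects)
with trough samples on days 6-8 and rich sampling after the day-8 dose.
Number-of-swallows (NOS) is drawn per arm from a shifted binomial calibrated
to the published median and range; the multiple-dose arm has no NOS record
and is imputed with the single-dose 8 mg median (2).

Simulation follows the published random-effect structure: log-normal IIV per
parameter (constant across occasions), proportional residual error for BUP
and norBUP, combined proportional+additive error for NLX.  Observations
below the analyte LLOQ are emitted as censored (BQL) records; the uncensored
value is retained in-memory in ``DV_TRUE`` for oracle tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .dataset import LLOQ_DEFAULT, PKDataset
from .params import BUP_ETA_NAMES, NLX_ETA_NAMES, NG_PER_MG, BupParams, NlxParams
from .regimen import Regimen, repeated_regimen, single_dose_regimen
from .structural import covariate_f_bup, solve_bup_norbup, solve_nlx

SINGLE_DOSE_TIMES = (0.25, 0.5, 0.75, 1, 1.5, 2, 3, 4, 6, 8, 10, 12,
                     24, 36, 48, 60, 72)
MULTI_POSTDOSE_TIMES = (0.25, 0.5, 1, 1.5, 2, 4, 8, 12, 24)
MULTI_TROUGH_DAYS = (6, 7, 8)   # pre-dose trough samples on these days


@dataclass(frozen=True)
class NosDistribution:
    """Shifted-binomial swallow-count distribution matching median and range."""

    low: int
    high: int
    median: float

    def sample(self, rng: np.random.Generator, size=None):
        if self.high == self.low:
            return np.full(size, self.low) if size else self.low
        p = (self.median - self.low) / (self.high - self.low)
        return self.low + rng.binomial(self.high - self.low, p, size=size)


@dataclass(frozen=True)
class Arm:
    name: str
    dose_mg: float
    n: int
    multiple: bool = False          # 8-day once-daily arm if True
    state: str = "healthy"
    nos: NosDistribution | None = None
    age_range: tuple = (20.0, 30.0)
    wt_range: tuple = (53.0, 88.0)
    ht_range: tuple = (1.60, 1.88)


@dataclass
class TrialDesign:
    """Arms, sampling schedules and LLOQs of the (virtual) trial."""

    arms: list = field(default_factory=lambda: [
        Arm("4mg-single", 4, 12, nos=NosDistribution(0, 8, 3.5),
            age_range=(21, 30), wt_range=(54, 88), ht_range=(1.67, 1.88)),
        Arm("8mg-single", 8, 12, nos=NosDistribution(0, 3, 2.0),
            age_range=(20, 30), wt_range=(60, 78), ht_range=(1.67, 1.83)),
        Arm("16mg-single", 16, 10, nos=NosDistribution(2, 12, 6.5),
            age_range=(22, 30), wt_range=(53, 70), ht_range=(1.60, 1.74)),
        Arm("8mg-multi", 8, 12, multiple=True, state="OUD",
            nos=NosDistribution(2, 2, 2.0),      # imputed, constant
            age_range=(27, 44), wt_range=(53, 70.2), ht_range=(1.64, 1.82)),
    ])
    lloq: dict = field(default_factory=lambda: dict(LLOQ_DEFAULT))
    days_multiple: int = 8

    def sampling_times(self, arm: Arm) -> np.ndarray:
        if not arm.multiple:
            return np.array((0.0,) + SINGLE_DOSE_TIMES)
        last = (self.days_multiple - 1) * 24.0
        troughs = [(d - 1) * 24.0 for d in MULTI_TROUGH_DAYS]
        return np.array(sorted(set(troughs) | {last + t for t in MULTI_POSTDOSE_TIMES}))

    def regimen_for(self, arm: Arm, nos: float) -> Regimen:
        if arm.multiple:
            return repeated_regimen([arm.dose_mg], self.days_multiple, nos=nos)
        return single_dose_regimen(arm.dose_mg, nos=nos)


def sample_nos(arm: Arm, rng_or_seed) -> int:
    """Draw a number of swallows for one subject of the given arm."""
    rng = (rng_or_seed if isinstance(rng_or_seed, np.random.Generator)
           else np.random.default_rng(rng_or_seed))
    return int(arm.nos.sample(rng))


def generate_trial(design: TrialDesign | None = None,
                   bup: BupParams | None = None,
                   nlx: NlxParams | None = None,
                   seed: int | None = None,
                   iiv: bool = True,
                   residual: bool = True,
                   censor: bool = True) -> PKDataset:
    """Simulate one complete virtual trial.

    Deterministic for a fixed seed.  ``iiv``/``residual``/``censor`` toggle
    the corresponding layers for degenerate-noise oracle tests.  The returned
    dataset's ``meta`` records scheduled and post-censoring record counts and
    the achieved BQL fraction per analyte and arm.
    """
    if seed is None:
        raise ValueError("a seed is required (reproducibility is mandatory)")
    design = design or TrialDesign()
    bup = bup or BupParams()
    nlx = nlx or NlxParams()
    rng = np.random.default_rng(seed)

    rows = []
    sid = 0
    for arm in design.arms:
        times = design.sampling_times(arm)
        for _ in range(arm.n):
            sid += 1
            nos = sample_nos(arm, rng)
            age = rng.uniform(*arm.age_range)
            wt = rng.uniform(*arm.wt_range)
            ht = rng.uniform(*arm.ht_range)
            if iiv:
                eta_b = {k: rng.normal(0.0, bup.omega.get(k, 0.0)) for k in BUP_ETA_NAMES}
                eta_n = {k: rng.normal(0.0, nlx.omega.get(k, 0.0)) for k in NLX_ETA_NAMES}
            else:
                eta_b, eta_n = {}, {}
            reg = design.regimen_for(arm, nos)
            c_bup, c_nor = solve_bup_norbup(bup, reg, times, eta_b)
            c_nlx = solve_nlx(nlx, reg, times, eta_n)
            common = dict(NOS=nos, DOSEGRP=arm.dose_mg, ARM=arm.name,
                          STATE=arm.state, AGE=round(age, 1), WT=round(wt, 1),
                          HT=round(ht, 2))
            for ev in reg.events:
                rows.append(dict(ID=sid, TIME=ev.time, AMT=ev.bup_mg * NG_PER_MG,
                                 EVID=1, CMT="DOSE", DV=np.nan, BQL=0,
                                 LLOQ=np.nan, DV_TRUE=np.nan, **common))
            for analyte, ipred in (("BUP", c_bup), ("NORBUP", c_nor), ("NLX", c_nlx)):
                lloq = design.lloq[analyte]
                sig_prop = {"BUP": bup.sigma_prop_bup,
                            "NORBUP": bup.sigma_prop_norbup,
                            "NLX": nlx.sigma_prop}[analyte]
                if residual:
                    y = ipred * (1.0 + rng.normal(0.0, sig_prop, len(times)))
                    if analyte == "NLX":
                        y = y + rng.normal(0.0, nlx.sigma_add, len(times))
                else:
                    y = ipred.copy()
                for t, yv, ip in zip(times, y, ipred):
                    bql = 1 if (censor and yv < lloq) else 0
                    rows.append(dict(ID=sid, TIME=t, AMT=np.nan, EVID=0,
                                     CMT=analyte, DV=np.nan if bql else yv,
                                     BQL=bql, LLOQ=lloq, DV_TRUE=yv, **common))

    df = pd.DataFrame(rows).sort_values(["ID", "TIME", "EVID", "CMT"],
                                        ascending=[True, True, False, True])
    ds = PKDataset(df, validate=False)
    meta = {"seed": seed, "scheduled_records": {}, "bql_fraction": {}}
    for analyte in ("BUP", "NORBUP", "NLX"):
        obs = ds.observations(analyte)
        meta["scheduled_records"][analyte] = int(len(obs))
        meta["bql_fraction"][analyte] = {
            "all": float((obs.BQL == 1).mean()),
            **{arm.name: float((obs[obs.ARM == arm.name].BQL == 1).mean())
               for arm in design.arms},
        }
    ds.meta = meta
    ds.validate()
    return ds
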