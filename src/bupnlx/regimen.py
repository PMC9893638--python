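"""Dosing regimens for the sublingual BUP/NLX combination tablet.

Each tablet carries a 4:1 BUP:NLX ratio (2 mg buprenorphine per 0.5 mg
naloxone), so naloxone dose events are always implied as one quarter of the
buprenorphine amount.  Doses are administered at 08:00; multiple daily doses
are spaced evenly (q12h for two, q8h for three), with the larger dose first
for mixed regimens.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

#: per-dose-group median number of swallows, used to adjust F in simulations
NOS_GROUP_MEDIAN = {4: 3.5, 8: 2.0, 16: 6.5}


@dataclass(frozen=True)
class DoseEvent:
    """A single sublingual administration."""

    time: float      # h since first dose
    bup_mg: float    # buprenorphine amount, mg
    nos: float = 2.0  # number of swallows recorded/assigned for this event

    @property
    def nlx_mg(self) -> float:
        """Implied naloxone amount (4:1 tablet ratio)."""
        return self.bup_mg / 4.0

    def __post_init__(self):
        if self.time < 0:
            raise ValueError("dose time must be >= 0")
        if self.bup_mg <= 0:
            raise ValueError("dose amount must be > 0")
        if self.nos < 0:
            raise ValueError("NOS must be >= 0")


@dataclass
class Regimen:
    """An ordered sequence of dose events plus metadata.

    ``dose_group`` is the labelled dose tier (4, 8 or 16 mg) that determines
    the Fm covariate tier and the default NOS; it defaults to the largest
    per-event amount.
    """

    events: Sequence[DoseEvent]
    label: str = ""
    dose_group: float | None = None

    def __post_init__(self) -> None:
        self.events = tuple(self.events)
        times = [e.time for e in self.events]
        if any(t2 <= t1 for t1, t2 in zip(times, times[1:])):
            raise ValueError("dose event times must be strictly increasing")
        if self.dose_group is None and self.events:
            self.dose_group = max(e.bup_mg for e in self.events)

    @property
    def total_daily_bup_mg(self) -> float:
        """Total BUP over the first 24 h of the cycle."""
        return sum(e.bup_mg for e in self.events if e.time < 24.0)

    def last_dose_time(self) -> float:
        return self.events[-1].time if self.events else 0.0


def _nos_for(amount_mg: float) -> float:
    tier = min(NOS_GROUP_MEDIAN, key=lambda d: abs(d - amount_mg))
    return NOS_GROUP_MEDIAN[tier]


def repeated_regimen(daily_amounts_mg: Sequence[float], days: int,
                     label: str = "", nos: float | None = None) -> Regimen:
    """Build a multi-day regimen from the amounts given each day.

    Amounts within a day are evenly spaced over 24 h starting at time 0
    (08:00): one dose daily at 0 h, two at 0/12 h, three at 0/8/16 h.
    ``nos`` overrides the per-dose-group median number of swallows.
    """
    amounts = list(daily_amounts_mg)
    if not amounts or days < 1:
        raise ValueError("need at least one dose amount and one day")
    interval = 24.0 / len(amounts)
    events = []
    for day in range(days):
        for k, amt in enumerate(amounts):
            t = day * 24.0 + k * interval
            events.append(DoseEvent(t, amt, nos if nos is not None else _nos_for(amt)))
    return Regimen(events, label=label or "+".join(f"{a:g}" for a in amounts),
                   dose_group=max(amounts))


def single_dose_regimen(bup_mg: float, nos: float | None = None) -> Regimen:
    """One sublingual dose at time zero."""
    return Regimen([DoseEvent(0.0, bup_mg, nos if nos is not None else _nos_for(bup_mg))],
                   label=f"{bup_mg:g} mg single", dose_group=bup_mg)


def standard_regimens(days: int = 8) -> dict[str, Regimen]:
    """The six candidate maintenance regimens evaluated for dose optimization."""
    return {
        "16 mg QD": repeated_regimen([16], days, "16 mg QD"),
        "8 mg BID": repeated_regimen([8, 8], days, "8 mg BID"),
        "16+8 mg": repeated_regimen([16, 8], days, "16+8 mg"),
        "8 mg TID": repeated_regimen([8, 8, 8], days, "8 mg TID"),
        "16 mg BID": repeated_regimen([16, 16], days, "16 mg BID"),
        "16+8+8 mg": repeated_regimen([16, 8, 8], days, "16+8+8 mg"),
    }
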