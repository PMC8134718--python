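"""Scaling network-level reductions to the national incidence baseline.

The hospital-network counts cover roughly a fifth of national cancer
incidence. Extrapolation multiplies the network's monthly reduction
*fractions* (not its raw counts) by the national monthly incidence
baseline, which reproduces the published nationwide per-month excess
deaths. The externally observed nationwide reduction (-23.3% as of
24 Nov 2020) is carried as a config constant with provenance, never
recomputed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

from .cohort import ReductionSeries
from .errors import ValidationError
from .model import MonthLabel


@dataclass(frozen=True)
class NationalBaseline:
    """National incidence and mortality constants.

    Defaults are the 2018 national figures: 382 000 new solid-tumor
    diagnoses and 157 400 cancer deaths per year (41% death rate), hence
    31 833 new diagnoses per month. ``national_observed_reduction`` is the
    nationwide new-diagnosis reduction reported on the national social
    security platform, used only as a scenario offset.
    """

    monthly_new_cases: float = 31833.0
    annual_new_cases: float = 382000.0
    annual_deaths: float = 157400.0
    national_observed_reduction: float | None = 0.233
    sources: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if min(self.monthly_new_cases, self.annual_new_cases, self.annual_deaths) <= 0:
            raise ValidationError("baseline counts must be positive")
        if abs(self.monthly_new_cases * 12 - self.annual_new_cases) > 0.01 * self.annual_new_cases:
            raise ValidationError(
                "monthly_new_cases x 12 must match annual_new_cases within 1%"
            )

    @property
    def death_rate(self) -> float:
        return self.annual_deaths / self.annual_new_cases


def national_missing(
    series: ReductionSeries, baseline: NationalBaseline
) -> dict[MonthLabel, float]:
    """Per-month national missing patients: ``monthly_new_cases * f_m``.

    Months with a net increase (negative fraction) contribute zero.
    The result feeds :func:`oncodelay.model.build_schedule` directly.
    """
    return {
        label: max(baseline.monthly_new_cases * float(f), 0.0)
        for label, f in zip(series.month_labels(), series.fractions)
    }


def network_share(series: ReductionSeries, baseline: NationalBaseline) -> float:
    """Mean monthly reference-year count as a share of national incidence.

    Reporting only: situates the network within national case volume.
    """
    mean_monthly = float(series.ref_counts.mean())
    return mean_monthly / baseline.monthly_new_cases
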