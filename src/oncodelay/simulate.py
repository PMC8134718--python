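"""Synthetic multi-center cohort generator and parameter-recovery checks.

The generator emulates the statistical structure the descriptive analysis
assumes: several centers with comparable volume, a few percent annual
growth in new diagnoses, independent Poisson counts per center, month and
stratum cell, and in one "dip year" a configurable lockdown dip profile
``d_m`` that removes a fraction of expected new patients in the affected
months. Stratum cells (sex x stage, optionally tumor group) modulate the
dip multiplicatively -- deeper for women and for nonmetastatic disease,
as observed -- while their share-weighted mean modifier is kept at 1 so
the aggregate monthly dip equals ``d_m`` and parameter recovery is
well-defined.

Determinism: one integer seed drives a ``numpy`` ``SeedSequence`` that is
split per center (spawn key = center index), so adding or reordering
strata within a center does not perturb other centers' streams.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .cohort import CohortRecord, CohortTable, Stratum, monthly_reduction
from .errors import ConfigError

#: Dip profile matching the observed March-July reductions.
DEFAULT_DIP = {3: 0.014, 4: 0.206, 5: 0.218, 6: 0.018, 7: 0.113}


@dataclass(frozen=True)
class GeneratorConfig:
    """Parameters of the synthetic cohort generator.

    ``baseline_mean`` is the expected number of new patients per center and
    month in ``first_year`` (the reference year); volumes grow by
    ``annual_growth`` per year. ``dip_profile`` maps calendar months of
    ``dip_year`` to dip depths ``d_m`` (fraction of expected patients
    removed). ``sex_effects``/``stage_effects`` multiply the dip per
    stratum cell; with the default shares their weighted means are 1.
    """

    n_centers: int = 17
    baseline_mean: float = 395.0
    annual_growth: float = 0.035
    first_year: int = 2019
    dip_year: int = 2020
    months: tuple[int, ...] = tuple(range(1, 8))
    dip_profile: Mapping[int, float] = field(default_factory=lambda: dict(DEFAULT_DIP))
    sex_shares: Mapping[str, float] = field(
        default_factory=lambda: {"male": 0.5, "female": 0.5}
    )
    sex_effects: Mapping[str, float] = field(
        default_factory=lambda: {"male": 0.8, "female": 1.2}
    )
    stage_shares: Mapping[str, float] = field(
        default_factory=lambda: {"metastatic": 0.25, "nonmetastatic": 0.75}
    )
    stage_effects: Mapping[str, float] = field(
        default_factory=lambda: {"metastatic": 0.7, "nonmetastatic": 1.1}
    )
    noise: str = "poisson"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.baseline_mean <= 0:
            raise ConfigError("baseline_mean must be positive")
        if self.n_centers < 1:
            raise ConfigError("need at least one center")
        if self.noise not in ("poisson", "none"):
            raise ConfigError(f"unknown noise model {self.noise!r}")
        for shares, name in ((self.sex_shares, "sex_shares"),
                             (self.stage_shares, "stage_shares")):
            if abs(sum(shares.values()) - 1.0) > 1e-9:
                raise ConfigError(f"{name} must sum to 1")
        for m, d in self.dip_profile.items():
            if not 0.0 <= d < 1.0:
                raise ConfigError(f"dip depth for month {m} outside [0, 1)")
            for sx, st in itertools.product(self.sex_effects, self.stage_effects):
                eff = d * self.sex_effects[sx] * self.stage_effects[st]
                if eff >= 1.0:
                    raise ConfigError(
                        f"dip x modifier >= 1 for month {m}, cell ({sx}, {st})"
                    )

    def cell_iter(self):
        """Stratum cells with (share, dip modifier) products."""
        for sx, st in itertools.product(self.sex_shares, self.stage_shares):
            share = self.sex_shares[sx] * self.stage_shares[st]
            modifier = self.sex_effects.get(sx, 1.0) * self.stage_effects.get(st, 1.0)
            yield sx, st, share, modifier


def _cell_mean(config: GeneratorConfig, year: int, month: int,
               share: float, modifier: float) -> float:
    mean = config.baseline_mean * (1.0 + config.annual_growth) ** (
        year - config.first_year
    ) * share
    if year == config.dip_year and month in config.dip_profile:
        mean *= 1.0 - config.dip_profile[month] * modifier
    return mean


def generate_cohort(config: GeneratorConfig, years: Sequence[int] | None = None) -> CohortTable:
    """Draw a synthetic :class:`CohortTable` for the given years.

    Counts per (center, month, sex x stage cell) are Poisson around the
    configured means (or the exact means with ``noise="none"``, in which
    case counts are generally non-integral). ``all``-stratum rows are sums
    of their cells by construction. Deterministic under a fixed seed.
    """
    years = list(years) if years is not None else [config.first_year, config.dip_year]
    root = np.random.SeedSequence(config.seed)
    center_seeds = root.spawn(config.n_centers)
    records: list[CohortRecord] = []
    for c in range(config.n_centers):
        center_id = f"S{c + 1:02d}"
        rng = np.random.default_rng(center_seeds[c])
        for year in years:
            for month in config.months:
                total = 0.0
                for sx, st, share, modifier in config.cell_iter():
                    mean = _cell_mean(config, year, month, share, modifier)
                    count = float(rng.poisson(mean)) if config.noise == "poisson" else mean
                    total += count
                    records.append(
                        CohortRecord(
                            center_id=center_id,
                            year=year,
                            month=month,
                            stratum=Stratum(patient_status="new", sex=sx, stage=st),
                            count=count,
                        )
                    )
                records.append(
                    CohortRecord(
                        center_id=center_id,
                        year=year,
                        month=month,
                        stratum=Stratum(patient_status="new"),
                        count=total,
                    )
                )
    return CohortTable(records, source=f"synthetic(seed={config.seed})")


def _replicate_config(config: GeneratorConfig, rep: int) -> GeneratorConfig:
    # distinct, reproducible stream per replicate; stays below 2**31
    derived = int(
        np.random.SeedSequence([config.seed, rep]).generate_state(1)[0] % (2**31)
    )
    return GeneratorConfig(
        **{**config.__dict__, "seed": derived}
    )


def recovery_report(
    config: GeneratorConfig,
    replicates: int,
    confidence: float = 0.95,
) -> pd.DataFrame:
    """Bias and interval coverage of the monthly reduction estimator.

    For each replicate a fresh table is generated and
    :func:`~oncodelay.cohort.monthly_reduction` is applied (dip year versus
    reference year). The raw year-over-year fraction confounds the dip with
    the configured secular growth, so the estimator de-trends with the known
    growth factor ``G = (1 + annual_growth)**(dip_year - first_year)``:
    ``d_hat = 1 - (obs/ref) / G``, which is exactly ``d_m`` in expectation
    terms when noise is off. For every dip month the report gives the true
    depth, the mean and Monte-Carlo standard error of the estimates, the
    bias, and the coverage of a per-replicate binomial (Wilson) interval:
    conditional on the two monthly totals R and O, O is binomial with
    probability q = O/(R+O); the interval for q is mapped to the dip scale
    through ``d = 1 - (q/(1-q)) / G``.
    """
    if replicates < 2:
        raise ConfigError("need at least two replicates")
    z = float(sps.norm.ppf(0.5 + confidence / 2.0))
    growth = (1.0 + config.annual_growth) ** (config.dip_year - config.first_year)
    months = sorted(config.dip_profile)
    est = np.empty((replicates, len(months)))
    covered = np.zeros((replicates, len(months)), dtype=bool)
    for rep in range(replicates):
        table = generate_cohort(_replicate_config(config, rep))
        series = monthly_reduction(
            table, config.first_year, config.dip_year, window=months
        )
        est[rep] = 1.0 - (series.obs_counts / series.ref_counts) / growth
        for j, (r, o) in enumerate(zip(series.ref_counts, series.obs_counts)):
            total = r + o
            if total == 0:
                continue
            q = o / total
            center = (q + z**2 / (2 * total)) / (1 + z**2 / total)
            half = (
                z
                * math.sqrt(q * (1 - q) / total + z**2 / (4 * total**2))
                / (1 + z**2 / total)
            )
            lo_q, hi_q = max(center - half, 0.0), min(center + half, 1.0 - 1e-12)
            # d = 1 - (q/(1-q))/G is decreasing in q
            lo_f = 1 - (hi_q / (1 - hi_q)) / growth
            hi_f = 1 - (lo_q / (1 - lo_q)) / growth
            d = config.dip_profile[months[j]]
            covered[rep, j] = lo_f <= d <= hi_f
    truth = np.array([config.dip_profile[m] for m in months])
    mean = est.mean(axis=0)
    se = est.std(axis=0, ddof=1) / math.sqrt(replicates)
    return pd.DataFrame(
        {
            "month": months,
            "true_dip": truth,
            "mean_estimate": mean,
            "bias": mean - truth,
            "mc_se": se,
            "coverage": covered.mean(axis=0),
        }
    )
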