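"""Embedded observed data: the network's published monthly counts.

Two cohort tables are shipped as package data. ``unicancer_centers()``
holds the per-center monthly new-patient counts for January-July of the
reference (2019) and observation (2020) years, with each center's
epidemic-incidence zone. ``unicancer_network()`` holds the published
network-level monthly totals for the same window.

The two are deliberately separate: in the published table the seventeen
per-center rows sum to 45 649 (2019) and 42 008 (2020), while the printed
network totals -- which all narrative figures use -- read 47 159 and
43 947. Each series is internally consistent; the gap between them is a
documented inconsistency of the source, frozen here as
``CENTER_SUM_GAP`` so that validation can distinguish it from ingest bugs.

Window aggregates that exist only as published totals (multi-year
January-July volumes, per-tumor March-July counts, the previously
diagnosed patient totals) are module constants.
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path

import yaml

from .cohort import CohortTable, read_cohort_csv
from .extrapolation import NationalBaseline
from .model import MonthLabel, RiskParams, TumorSpec

#: Centers located in high epidemic-incidence zones (the other twelve are low).
HIGH_INCIDENCE_CENTERS = frozenset({"C04", "C07", "C09", "C11", "C12"})

#: Published monthly reduction fractions of new diagnoses, March-July of the
#: observation year, as printed (1.4%, 20.6%, 21.8%, 1.8%, 11.3%). These
#: drive the national extrapolation; the unrounded fixture-derived values
#: differ only in the fourth decimal.
PUBLISHED_DIP_PROFILE: dict[MonthLabel, float] = {
    (2020, 3): 0.014,
    (2020, 4): 0.206,
    (2020, 5): 0.218,
    (2020, 6): 0.018,
    (2020, 7): 0.113,
}

#: Month by which all delayed patients are assumed treated (base scenario).
DEFAULT_RESOLUTION: MonthLabel = (2020, 8)

#: Total patients treated, January-July, network-wide (all statuses).
TOTAL_PATIENTS_JAN_JUL = {2016: 81666, 2017: 83877, 2018: 86493, 2019: 90432, 2020: 89161}

#: Newly diagnosed patients, January-July, network-wide.
NEW_PATIENTS_JAN_JUL = {2019: 47159, 2020: 43947}

#: Previously diagnosed patients, January-July, network-wide. The source
#: text quotes the change as +4.5% although these counts give +4.15%; the
#: counts are authoritative here.
PREVIOUS_PATIENTS_JAN_JUL = {2019: 44938, 2020: 46802}

#: Known gap between per-center sums and printed network totals (see module
#: docstring): printed total minus per-center sum, per year, Jan-Jul.
CENTER_SUM_GAP = {2019: 47159 - 45649, 2020: 43947 - 42008}

#: Per-tumor-group March-July new-patient totals (reference year, observation
#: year) from the narrative text. The breast counts here (10 525 / 8428)
#: differ from the five-tumor comparison table's (10 115 / 8194); both are
#: published and both are kept.
TUMOR_WINDOW_TOTALS: dict[str, tuple[int, int]] = {
    "breast": (10525, 8428),
    "digestive": (4153, 3736),
    "urological": (2498, 2247),
    "gynecological": (2949, 2673),
    "head_and_neck": (2038, 1889),
    "thoracic/lung": (2999, 2800),
    "hematological": (2058, 2133),
    "other": (6227, 5714),
}


def _data_path(name: str) -> Path:
    return Path(resources.files("oncodelay") / "data" / name)


def unicancer_centers() -> CohortTable:
    """Per-center monthly new-patient counts with epidemic-zone metadata."""
    table = read_cohort_csv(_data_path("unicancer_new_patients.csv"),
                            source="unicancer-percenter-counts")
    zone = {
        c: ("high" if c in HIGH_INCIDENCE_CENTERS else "low") for c in table.centers
    }
    return CohortTable(table.records, source=table.source, covid_zone=zone)


def unicancer_network() -> CohortTable:
    """Published network-level monthly totals of new patients."""
    return read_cohort_csv(_data_path("unicancer_network_monthly.csv"),
                           source="unicancer-network-totals")


def load_constants(path: str | Path | None = None) -> dict:
    """Raw constants mapping from the embedded (or a user) YAML file."""
    p = Path(path) if path is not None else _data_path("national_constants.yaml")
    with open(p, encoding="utf-8") as fh:
        return yaml.safe_load(fh)


def national_baseline(constants: dict | None = None) -> NationalBaseline:
    cfg = (constants or load_constants())["baseline"]
    return NationalBaseline(
        monthly_new_cases=cfg["monthly_new_cases"],
        annual_new_cases=cfg["annual_new_cases"],
        annual_deaths=cfg["annual_deaths"],
        national_observed_reduction=cfg.get("national_observed_reduction"),
        sources=cfg.get("sources", {}),
    )


def uniform_risk(constants: dict | None = None) -> RiskParams:
    cfg = (constants or load_constants())["risk"]
    return RiskParams(rd=cfg["rd"], hr=cfg["hr"])


def tumor_specs(constants: dict | None = None) -> list[TumorSpec]:
    cfg = (constants or load_constants())["tumors"]
    return [
        TumorSpec(
            label=t["label"],
            annual_incidence=t["annual_incidence"],
            annual_deaths=t["annual_deaths"],
            hr=t["hr"],
            missing_ref=t["missing_ref"],
            missing_obs=t["missing_obs"],
        )
        for t in cfg
    ]
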