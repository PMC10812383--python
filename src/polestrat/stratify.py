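"""Four-group taxonomy of POLE-mutated tumors and Table-style summaries.

Tumors carrying at least one POLE variant are split on tumor mutational
burden (TMB, mutations/Mb; high means >= 10 by default) and on whether any
variant is an established exonuclease-domain (ExoD) proofreading driver:

* Group 1 (G1): TMB-low, POLE variant(s) only.
* Group 2 (G2): TMB-high, ExoD driver(s) and nothing else.
* Group 3 (G3): TMB-high, ExoD driver(s) plus additional POLE variant(s).
* Group 4 (G4): TMB-high, POLE variant(s) without any ExoD driver.

Each group carries an MSS/MSI substatus from microsatellite testing. A
TMB-low profile that nevertheless contains a catalog driver stays in G1
and is flagged as an anomaly rather than reclassified.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import pandas as pd

from .stats import median_range
from .variants import DriverCatalog, PoleVariant, flag_drivers

__all__ = [
    "CANCER_TYPES",
    "GROUPS",
    "TumorProfile",
    "GroupAssignment",
    "normalize_msi",
    "assign_group",
    "assign_groups",
    "summarize_groups",
    "pole_mutation_frequency",
]

CANCER_TYPES = ("CRC", "EC", "OC", "other")
GROUPS = ("G1", "G2", "G3", "G4")
DEFAULT_TMB_THRESHOLD = 10.0


def normalize_msi(raw: Optional[str]) -> str:
    """Collapse assay vocabulary onto {MSS, MSI-H, unknown}.

    MSI-low is collapsed into MSS (group tables dichotomize). Unrecognized
    strings map to ``unknown`` and are treated as MSS downstream, with a
    warning at assignment time.
    """
    if raw is None:
        return "unknown"
    t = raw.strip().upper().replace("_", "-")
    if t in {"MSI", "MSI-H", "MSI-HIGH"}:
        return "MSI-H"
    if t in {"MSS", "MS-STABLE", "MSI-L", "MSI-LOW", "STABLE"}:
        return "MSS"
    return "unknown"


@dataclass(frozen=True)
class TumorProfile:
    """One tumor's clinical/molecular row: TMB, MSI, POLE variant calls."""

    tumor_id: str
    cancer_type: str
    tmb: float
    msi_status: str = "unknown"
    age: Optional[float] = None
    sex: str = "unknown"
    pole_variants: tuple[PoleVariant, ...] = ()
    comutations: tuple[tuple[str, str, str], ...] = ()
    pdl1: Optional[str] = None

    def __post_init__(self) -> None:
        if self.cancer_type not in CANCER_TYPES:
            raise ValueError(f"unknown cancer type {self.cancer_type!r}")
        if self.tmb is None or self.tmb != self.tmb:
            raise ValueError(f"tumor {self.tumor_id}: TMB is required")
        if self.tmb < 0:
            raise ValueError(f"tumor {self.tumor_id}: negative TMB")
        if self.msi_status not in {"MSS", "MSI-H", "unknown"}:
            raise ValueError(f"tumor {self.tumor_id}: bad MSI status {self.msi_status!r}")
        if self.sex not in {"F", "M", "unknown"}:
            raise ValueError(f"tumor {self.tumor_id}: bad sex {self.sex!r}")


@dataclass(frozen=True)
class GroupAssignment:
    group: str
    substatus: str  # MSS or MSI
    n_drivers: int
    n_additional_variants: int
    anomaly_flags: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise ValueError(f"unknown group {self.group!r}")
        if self.substatus not in {"MSS", "MSI"}:
            raise ValueError(f"substatus must be MSS or MSI")
        if self.group == "G2" and not (self.n_drivers >= 1 and self.n_additional_variants == 0):
            raise ValueError("G2 requires driver(s) and no additional variants")
        if self.group == "G3" and not (self.n_drivers >= 1 and self.n_additional_variants >= 1):
            raise ValueError("G3 requires driver(s) plus additional variant(s)")
        if self.group == "G4" and self.n_drivers != 0:
            raise ValueError("G4 excludes catalog drivers")


def assign_group(
    profile: TumorProfile,
    catalog: DriverCatalog,
    tmb_threshold: float = DEFAULT_TMB_THRESHOLD,
) -> GroupAssignment:
    """Place one profile in the four-group taxonomy.

    The threshold is inclusive on the high side (TMB == threshold is
    TMB-high). Driver status is recomputed here against the catalog, so
    upstream flags need not be trusted.
    """
    if not profile.pole_variants:
        raise ValueError(
            f"tumor {profile.tumor_id}: no POLE variants; not a cohort member"
        )
    flagged = flag_drivers(profile.pole_variants, catalog)
    n_drivers = sum(1 for v in flagged if v.is_exod_driver)
    n_additional = len(flagged) - n_drivers

    if profile.msi_status == "unknown":
        warnings.warn(
            f"tumor {profile.tumor_id}: unknown MSI status treated as MSS",
            stacklevel=2,
        )
    substatus = "MSI" if profile.msi_status == "MSI-H" else "MSS"

    flags: set[str] = set()
    if profile.tmb < tmb_threshold:
        group = "G1"
        if n_drivers > 0:
            flags.add("driver_with_low_tmb")
        # G1 invariant mirrors the taxonomy: driver count is reported but
        # the anomaly flag carries the contradiction.
        return GroupAssignment(
            group="G1", substatus=substatus, n_drivers=n_drivers,
            n_additional_variants=n_additional, anomaly_flags=frozenset(flags),
        )
    if n_drivers == 0:
        group = "G4"
    elif n_additional == 0:
        group = "G2"
    else:
        group = "G3"
    return GroupAssignment(
        group=group, substatus=substatus, n_drivers=n_drivers,
        n_additional_variants=n_additional, anomaly_flags=frozenset(),
    )


def assign_groups(
    profiles: Sequence[TumorProfile],
    catalog: DriverCatalog,
    tmb_threshold: float = DEFAULT_TMB_THRESHOLD,
) -> dict[str, GroupAssignment]:
    return {
        p.tumor_id: assign_group(p, catalog, tmb_threshold) for p in profiles
    }


def pole_mutation_frequency(n_pole_mutated: int, n_profiled: int) -> float:
    """Percentage of profiled tumors carrying a POLE mutation, to 1 decimal."""
    if n_profiled <= 0:
        raise ValueError("profiled count must be positive")
    if not (0 <= n_pole_mutated <= n_profiled):
        raise ValueError("mutated count must lie in [0, profiled]")
    return round(100.0 * n_pole_mutated / n_profiled, 1)


def summarize_groups(
    profiles: Sequence[TumorProfile],
    assignments: dict[str, GroupAssignment],
) -> pd.DataFrame:
    """Per (cancer_type, group) cohort summary.

    Columns: n, median_tmb (midpoint convention), tmb_min, tmb_max, MSS/MSI
    counts, age buckets (<50 vs >=50) and sex counts. Empty groups appear
    with n = 0 and NA summary fields.
    """
    missing = [p.tumor_id for p in profiles if p.tumor_id not in assignments]
    if missing:
        raise ValueError(f"profiles without assignment: {missing[:5]}")
    rows = []
    by_key: dict[tuple[str, str], list[TumorProfile]] = {}
    for p in profiles:
        by_key.setdefault((p.cancer_type, assignments[p.tumor_id].group), []).append(p)
    cancer_types = sorted({p.cancer_type for p in profiles})
    for ct in cancer_types:
        for g in GROUPS:
            members = by_key.get((ct, g), [])
            row: dict = {"cancer_type": ct, "group": g, "n": len(members)}
            if members:
                med, lo, hi = median_range([p.tmb for p in members])
                row.update(median_tmb=med, tmb_min=lo, tmb_max=hi)
                row["n_MSS"] = sum(
                    1 for p in members if assignments[p.tumor_id].substatus == "MSS"
                )
                row["n_MSI"] = len(members) - row["n_MSS"]
                ages = [p.age for p in members if p.age is not None]
                row["n_under_50"] = sum(1 for a in ages if a < 50)
                row["n_50_plus"] = sum(1 for a in ages if a >= 50)
                row["n_female"] = sum(1 for p in members if p.sex == "F")
                row["n_male"] = sum(1 for p in members if p.sex == "M")
            rows.append(row)
    return pd.DataFrame(rows)
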