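"""Rule-based annotation layers: protein stability, neoantigens, exclusivity.

Three small, fully specified rules applied to externally computed scores:

* ΔΔG stability classes with an inclusive +/-1.45 kcal/mol cutoff
  (positive ΔΔG destabilizes the fold, negative stabilizes it). The
  structure/energy computation itself is upstream; only its declared
  outputs are consumed here.
* Neoantigen categories from dual MHC-binding / T-cell-reactivity scores
  with an inclusive 0.5 threshold on each axis; the modified neoantigen
  burden is the per-tumor count of immunogenic calls.
* Group-3-exclusive mutation selection: keep mutations seen at most once
  in Group 2 and at least twice in Group 3.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .variants import DomainMap

__all__ = [
    "STABILITY_CLASSES",
    "NEOANTIGEN_CATEGORIES",
    "DdgRecord",
    "NeoantigenScore",
    "classify_stability",
    "categorize_neoantigen",
    "neoantigen_burden",
    "select_group3_exclusive",
    "stability_census",
]

DEFAULT_DDG_CUTOFF = 1.45  # kcal/mol
DEFAULT_NEO_THRESHOLD = 0.5

STABILITY_CLASSES = ("stabilizing", "destabilizing", "neutral")
NEOANTIGEN_CATEGORIES = (
    "immunogenic",
    "nonimmunogenic",
    "no_biological_significance",
    "none",
)


def classify_stability(ddg: float, cutoff: float = DEFAULT_DDG_CUTOFF) -> str:
    """Stability class of a ΔΔG value (kcal/mol), inclusive boundaries.

    ddg >= +cutoff -> destabilizing; ddg <= -cutoff -> stabilizing;
    otherwise neutral.
    """
    if not math.isfinite(ddg):
        raise ValueError(f"non-finite ddg {ddg!r}")
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    if ddg >= cutoff:
        return "destabilizing"
    if ddg <= -cutoff:
        return "stabilizing"
    return "neutral"


@dataclass(frozen=True)
class DdgRecord:
    """One mutant-vs-wildtype stability prediction."""

    variant_label: str
    position: int
    ddg: float
    model: str  # dna_bound or dna_unbound
    stability_class: str = ""

    def __post_init__(self) -> None:
        if self.model not in {"dna_bound", "dna_unbound"}:
            raise ValueError(f"unknown model {self.model!r}")

    @classmethod
    def build(
        cls, variant_label: str, position: int, ddg: float, model: str,
        cutoff: float = DEFAULT_DDG_CUTOFF,
    ) -> "DdgRecord":
        return cls(
            variant_label=variant_label, position=position, ddg=ddg,
            model=model, stability_class=classify_stability(ddg, cutoff),
        )


def categorize_neoantigen(
    mhc: float, tcr: float, threshold: float = DEFAULT_NEO_THRESHOLD
) -> str:
    """Category from (MHC binding, T-cell reactivity) scores in [0, 1].

    Both >= threshold -> immunogenic; MHC only -> nonimmunogenic; TCR only
    -> no_biological_significance; neither -> none. The four categories
    partition the unit square; boundaries are inclusive.
    """
    for name, s in (("mhc", mhc), ("tcr", tcr)):
        if not (0.0 <= s <= 1.0):
            raise ValueError(f"{name} score {s!r} outside [0, 1]")
    if mhc >= threshold:
        return "immunogenic" if tcr >= threshold else "nonimmunogenic"
    return "no_biological_significance" if tcr >= threshold else "none"


@dataclass(frozen=True)
class NeoantigenScore:
    gene: str
    aa_change: str
    hla_class: str
    peptide: str
    mhc_binding: float
    tcell_reactivity: float
    category: str = ""

    @classmethod
    def build(
        cls, gene: str, aa_change: str, hla_class: str, peptide: str,
        mhc_binding: float, tcell_reactivity: float,
        threshold: float = DEFAULT_NEO_THRESHOLD,
    ) -> "NeoantigenScore":
        return cls(
            gene=gene, aa_change=aa_change, hla_class=hla_class,
            peptide=peptide, mhc_binding=mhc_binding,
            tcell_reactivity=tcell_reactivity,
            category=categorize_neoantigen(mhc_binding, tcell_reactivity, threshold),
        )


def neoantigen_burden(scores: Iterable[NeoantigenScore]) -> int:
    """Modified neoantigen burden: count of immunogenic calls per tumor."""
    return sum(1 for s in scores if s.category == "immunogenic")


def select_group3_exclusive(
    mutation_counts_g2: Mapping[tuple[str, str], int],
    mutation_counts_g3: Mapping[tuple[str, str], int],
) -> list[tuple[str, str]]:
    """Mutations effectively exclusive to Group 3.

    Keep (gene, aa-change) keys appearing at most once in Group 2 and at
    least twice in Group 3.
    """
    for counts in (mutation_counts_g2, mutation_counts_g3):
        for key, n in counts.items():
            if n < 0 or n != int(n):
                raise ValueError(f"count for {key} must be a non-negative integer")
    return sorted(
        key
        for key, n3 in mutation_counts_g3.items()
        if n3 >= 2 and mutation_counts_g2.get(key, 0) <= 1
    )


def stability_census(
    records: Sequence[DdgRecord], domain_map: DomainMap
) -> pd.DataFrame:
    """Cross-tabulate stability classes by lobe and structural model.

    Rows: (model, lobe); columns: stabilizing / destabilizing / neutral
    counts plus the row total. Totals per model equal the record count for
    that model (conservation).
    """
    rows = []
    for r in records:
        if not r.stability_class:
            raise ValueError(f"record {r.variant_label} not classified")
        rows.append(
            {
                "model": r.model,
                "lobe": domain_map.lobe_of(r.position),
                "stability_class": r.stability_class,
            }
        )
    df = pd.DataFrame(rows, columns=["model", "lobe", "stability_class"])
    if df.empty:
        return pd.DataFrame(
            columns=["stabilizing", "destabilizing", "neutral", "total"]
        )
    tab = (
        df.groupby(["model", "lobe", "stability_class"]).size().unstack(fill_value=0)
    )
    for cls in STABILITY_CLASSES:
        if cls not in tab.columns:
            tab[cls] = 0
    tab = tab[list(STABILITY_CLASSES)]
    tab["total"] = tab.sum(axis=1)
    return tab
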