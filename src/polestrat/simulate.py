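"""Synthetic POLE-mutated tumor cohorts with known ground truth.

The generator emulates the statistical structure the analysis assumes so
every pipeline stage runs — and parameter recovery can be asserted —
without any external data:

* group-structured TMB: per (cancer type, group) target median and range,
  sampled by default from a median-anchored two-piece log-uniform (half
  the mass on [min, median], half on [median, max], log-uniform within
  each piece), so the configured median is the distribution median;
* driver prevalence concentrated on P286R and V411L (together ~67% of
  driver-bearing tumors by default), remainder spread over the other 18
  catalog alleles;
* passenger POLE variants drawn from a mixture of the bundled
  POLE-proofreading signature vectors (SBS10a/10b/14/28) plus a uniform
  noise component, realized as concrete coding changes on the bundled
  transcript and re-sampled when synonymous;
* MSI fractions, age buckets and sex composition per group.

Every draw flows through one explicitly threaded NumPy generator, so an
identical (config, seed) pair reproduces the cohort record-for-record.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional

import numpy as np
from Bio.Seq import Seq

from .signatures import (
    SbsChannel,
    SignatureVector,
    all_channels,
    load_default_signatures,
    normalize_to_pyrimidine,
)
from .stratify import TumorProfile
from .variants import (
    CodingChange,
    DriverCatalog,
    PoleVariant,
    load_default_driver_catalog,
    parse_hgvs_protein,
)

__all__ = [
    "GroupSpec",
    "SyntheticCohortConfig",
    "SyntheticTruth",
    "default_config",
    "simulate_cohort",
    "simulate_variants_from_signature",
    "transcript_channel_index",
    "load_default_transcript",
]

NOISE = "uniform_noise"
_MAX_RETRIES = 200


def load_default_transcript() -> str:
    """The bundled synthetic 2,286-codon coding sequence (plus stop)."""
    from importlib import resources

    from Bio import SeqIO

    with resources.files("polestrat.data").joinpath("pole_cds_synthetic.fasta").open() as fh:
        record = next(SeqIO.parse(fh, "fasta"))
    return str(record.seq).upper()


@dataclass(frozen=True)
class GroupSpec:
    """Sampling targets for one (cancer type, group) cell."""

    n: int
    tmb_median: float
    tmb_min: float
    tmb_max: float
    msi_fraction: float = 0.0
    under_50_fraction: float = 0.3
    female_fraction: float = 1.0
    tmb_distribution: str = "two_piece_log_uniform"  # or "log_normal"

    def __post_init__(self) -> None:
        if self.n < 0:
            raise ValueError("group size must be >= 0")
        if not (0 < self.tmb_min <= self.tmb_median <= self.tmb_max):
            raise ValueError("need 0 < min <= median <= max for TMB targets")
        for name in ("msi_fraction", "under_50_fraction", "female_fraction"):
            if not (0.0 <= getattr(self, name) <= 1.0):
                raise ValueError(f"{name} outside [0, 1]")
        if self.tmb_distribution not in {"two_piece_log_uniform", "log_uniform", "log_normal"}:
            raise ValueError(f"unknown TMB distribution {self.tmb_distribution!r}")


# Default per-group targets: cohort sizes, TMB medians/ranges and MSI
# fractions of the discovery cohort this generator emulates.
_DEFAULT_GROUPS: dict[tuple[str, str], GroupSpec] = {
    ("CRC", "G1"): GroupSpec(36, 6.0, 3, 9, msi_fraction=0 / 36, under_50_fraction=6 / 36, female_fraction=19 / 36),
    ("CRC", "G2"): GroupSpec(11, 115, 61, 216, msi_fraction=0 / 11, under_50_fraction=5 / 11, female_fraction=1 / 11),
    ("CRC", "G3"): GroupSpec(24, 264.5, 114, 414, msi_fraction=3 / 24, under_50_fraction=14 / 24, female_fraction=6 / 24),
    ("CRC", "G4"): GroupSpec(21, 33, 10, 461, msi_fraction=10 / 21, under_50_fraction=8 / 21, female_fraction=8 / 21),
    ("EC", "G1"): GroupSpec(95, 7, 3, 9, msi_fraction=5 / 95, under_50_fraction=6 / 95),
    ("EC", "G2"): GroupSpec(37, 52, 21, 314, msi_fraction=2 / 37, under_50_fraction=6 / 37),
    ("EC", "G3"): GroupSpec(57, 219, 53, 520, msi_fraction=16 / 57, under_50_fraction=10 / 57),
    ("EC", "G4"): GroupSpec(118, 17.5, 10, 273, msi_fraction=95 / 118, under_50_fraction=5 / 118),
    ("OC", "G1"): GroupSpec(24, 5.0, 4, 9, msi_fraction=0 / 24, under_50_fraction=4 / 24),
    ("OC", "G2"): GroupSpec(12, 69, 31, 379, msi_fraction=0 / 12, under_50_fraction=4 / 12),
    ("OC", "G3"): GroupSpec(8, 145, 51, 394, msi_fraction=2 / 8, under_50_fraction=5 / 8),
    ("OC", "G4"): GroupSpec(4, 14.5, 10, 21, msi_fraction=2 / 4, under_50_fraction=3 / 4),
}

# Driver allele weights: P286R + V411L carry ~67% of driver-bearing
# tumors; the other 18 catalog alleles share the rest equally.
_P286R_WEIGHT = 0.40
_V411L_WEIGHT = 0.27

_DEFAULT_N_ADDITIONAL = {1: 0.55, 2: 0.25, 3: 0.12, 4: 0.05, 5: 0.03}
_DEFAULT_N_PASSENGERS = {1: 0.70, 2: 0.20, 3: 0.10}  # G1/G4 variant counts

_DEFAULT_MIXTURE = {
    "SBS10a": 0.20,
    "SBS10b": 0.35,
    "SBS14": 0.15,
    "SBS28": 0.08,
    NOISE: 0.22,
}


@dataclass(frozen=True)
class SyntheticCohortConfig:
    seed: int
    groups: Mapping[tuple[str, str], GroupSpec]
    driver_frequencies: Mapping[str, float]
    signature_mixture: Mapping[str, float] = field(
        default_factory=lambda: dict(_DEFAULT_MIXTURE)
    )
    n_additional_variants_distribution: Mapping[int, float] = field(
        default_factory=lambda: dict(_DEFAULT_N_ADDITIONAL)
    )
    n_passenger_variants_distribution: Mapping[int, float] = field(
        default_factory=lambda: dict(_DEFAULT_N_PASSENGERS)
    )
    tmb_threshold: float = 10.0
    p_second_driver: float = 0.01

    def __post_init__(self) -> None:
        for weights, what in (
            (self.driver_frequencies, "driver frequencies"),
            (self.signature_mixture, "signature mixture"),
            (self.n_additional_variants_distribution, "additional-variant counts"),
            (self.n_passenger_variants_distribution, "passenger counts"),
        ):
            total = sum(weights.values())
            if abs(total - 1.0) > 1e-9:
                raise ValueError(f"{what} must sum to 1, got {total}")
            if any(w < 0 for w in weights.values()):
                raise ValueError(f"{what} must be non-negative")
        if any(k < 1 for k in self.n_additional_variants_distribution):
            raise ValueError("G3 tumors need at least one additional variant")
        if any(k < 1 for k in self.n_passenger_variants_distribution):
            raise ValueError("cohort tumors carry at least one POLE variant")
        for (ct, g), spec in self.groups.items():
            if g == "G1" and spec.tmb_max >= self.tmb_threshold:
                raise ValueError(
                    f"{ct}/G1: TMB range reaches {spec.tmb_max} >= threshold "
                    f"{self.tmb_threshold}; Group 1 must stay TMB-low"
                )
            if g in {"G2", "G3", "G4"} and spec.tmb_min < self.tmb_threshold:
                raise ValueError(
                    f"{ct}/{g}: TMB range starts below the threshold "
                    f"{self.tmb_threshold}"
                )


@dataclass
class SyntheticTruth:
    """Ground truth recorded for every generated entity."""

    seed: int
    group_labels: dict[str, str]
    variant_components: dict[str, list[str]]  # tumor -> component per passenger
    mixture_weights: dict[str, float]


def default_config(seed: int, catalog: Optional[DriverCatalog] = None) -> SyntheticCohortConfig:
    """Config with the default group targets and driver weights."""
    catalog = catalog or load_default_driver_catalog()
    others = sorted(
        f"{r}{p}{a}" for (r, p, a) in catalog.entries
        if f"{r}{p}{a}" not in {"P286R", "V411L"}
    )
    rest = 1.0 - _P286R_WEIGHT - _V411L_WEIGHT
    freqs = {"P286R": _P286R_WEIGHT, "V411L": _V411L_WEIGHT}
    freqs.update({lab: rest / len(others) for lab in others})
    return SyntheticCohortConfig(
        seed=seed, groups=dict(_DEFAULT_GROUPS), driver_frequencies=freqs
    )


def transcript_channel_index(
    transcript: str,
) -> dict[SbsChannel, list[tuple[int, str]]]:
    """Map each channel to the (CDS position, alt base) pairs realizing it.

    A position realizes a channel either directly (coding-strand reference
    is the channel's pyrimidine) or through the reverse complement, in
    which case the concrete alternate base is complemented.
    """
    seq = transcript.upper()
    index: dict[SbsChannel, list[tuple[int, str]]] = {c: [] for c in all_channels()}
    for pos in range(2, len(seq)):  # 1-based, interior only
        five, ref, three = seq[pos - 2], seq[pos - 1], seq[pos]
        for alt in "ACGT":
            if alt == ref:
                continue
            ch = normalize_to_pyrimidine(five, ref, alt, three)
            index[ch].append((pos, alt))
    return index


def _protein_change(transcript: str, change: CodingChange) -> tuple[str, int, str]:
    codon_i = (change.position - 1) // 3
    offset = (change.position - 1) % 3
    codon = transcript[codon_i * 3: codon_i * 3 + 3]
    mutant = codon[:offset] + change.alt + codon[offset + 1:]
    ref_aa = str(Seq(codon).translate())
    alt_aa = str(Seq(mutant).translate())
    return ref_aa, codon_i + 1, alt_aa


def simulate_variants_from_signature(
    k: int,
    mixture: Mapping[str, float],
    signatures: Mapping[str, SignatureVector],
    transcript: str,
    rng: np.random.Generator,
    channel_index: Optional[dict[SbsChannel, list[tuple[int, str]]]] = None,
    catalog: Optional[DriverCatalog] = None,
    require_protein_altering: bool = True,
) -> tuple[list[PoleVariant], list[str]]:
    """Draw k passenger variants from a signature/noise mixture.

    Each draw picks a mixture component, then a channel from that
    signature's 96-channel vector (uniform over channels for the noise
    component), then a CDS position realizing that channel, uniformly.
    Synonymous changes — and changes that would collide with a catalog
    driver allele — are re-sampled. Returns the variants (protein label
    plus coding change) and the generating component per variant.
    """
    total = sum(mixture.values())
    if abs(total - 1.0) > 1e-9:
        raise ValueError(f"mixture weights sum to {total}, expected 1")
    for name in mixture:
        if name != NOISE and name not in signatures:
            raise ValueError(f"mixture component {name!r} has no signature vector")
    index = channel_index if channel_index is not None else transcript_channel_index(transcript)
    channels = all_channels()
    comp_names = sorted(mixture)
    comp_w = np.array([mixture[c] for c in comp_names])
    comp_w = comp_w / comp_w.sum()
    channel_probs = {
        name: np.array([signatures[name].probs[c] for c in channels])
        for name in comp_names
        if name != NOISE
    }

    variants: list[PoleVariant] = []
    components: list[str] = []
    for _ in range(k):
        for attempt in range(_MAX_RETRIES):
            comp = comp_names[int(rng.choice(len(comp_names), p=comp_w))]
            if comp == NOISE:
                ch = channels[int(rng.integers(len(channels)))]
            else:
                probs = channel_probs[comp]
                ch = channels[int(rng.choice(len(channels), p=probs / probs.sum()))]
            sites = index.get(ch, [])
            if not sites:
                continue  # channel unrealizable on this transcript; redraw
            pos, alt = sites[int(rng.integers(len(sites)))]
            change = CodingChange(position=pos, ref=transcript[pos - 1], alt=alt)
            ref_aa, res, alt_aa = _protein_change(transcript, change)
            if require_protein_altering and ref_aa == alt_aa:
                continue
            if ref_aa == "*":  # stop-codon position; redraw
                continue
            if catalog is not None and (ref_aa, res, alt_aa) in catalog.entries:
                continue
            if ref_aa == alt_aa:  # synonymous; kept only when requested
                variant = PoleVariant(
                    raw_label=f"{ref_aa}{res}=", kind="other", position=res,
                    ref_aa=ref_aa, coding_change=change,
                )
            elif alt_aa == "*":
                variant = PoleVariant(
                    raw_label=f"{ref_aa}{res}X", kind="nonsense", position=res,
                    ref_aa=ref_aa, alt_aa="*", coding_change=change,
                )
            else:
                variant = PoleVariant(
                    raw_label=f"{ref_aa}{res}{alt_aa}", kind="missense",
                    position=res, ref_aa=ref_aa, alt_aa=alt_aa,
                    coding_change=change,
                )
            variants.append(variant)
            components.append(comp)
            break
        else:
            raise RuntimeError("could not realize a mixture draw on the transcript")
    return variants, components


def _sample_tmb(spec: GroupSpec, rng: np.random.Generator) -> float:
    lo, med, hi = np.log(spec.tmb_min), np.log(spec.tmb_median), np.log(spec.tmb_max)
    if spec.tmb_distribution == "log_uniform":
        value = float(np.exp(rng.uniform(lo, hi)))
    elif spec.tmb_distribution == "log_normal":
        sigma = max((hi - lo) / 4.0, 1e-6)
        for _ in range(_MAX_RETRIES):
            value = float(np.exp(rng.normal(med, sigma)))
            if spec.tmb_min <= value <= spec.tmb_max:
                break
        else:
            value = spec.tmb_median
    else:  # median-anchored two-piece log-uniform
        if rng.random() < 0.5:
            value = float(np.exp(rng.uniform(lo, med)))
        else:
            value = float(np.exp(rng.uniform(med, hi)))
    return round(min(max(value, spec.tmb_min), spec.tmb_max), 1)


def _sample_count(dist: Mapping[int, float], rng: np.random.Generator) -> int:
    ks = sorted(dist)
    w = np.array([dist[k] for k in ks])
    return int(ks[int(rng.choice(len(ks), p=w / w.sum()))])


def simulate_cohort(
    config: SyntheticCohortConfig,
    catalog: Optional[DriverCatalog] = None,
    signatures: Optional[Mapping[str, SignatureVector]] = None,
    transcript: Optional[str] = None,
) -> tuple[list[TumorProfile], SyntheticTruth]:
    """Generate a cohort honoring the group taxonomy by construction.

    G1 tumors get sub-threshold TMB and passenger variants only; G2 a
    driver (occasionally two) and nothing else; G3 a driver plus k >= 1
    passengers; G4 supra-threshold TMB and passengers only. Reproducible:
    identical (config, seed) yields identical records.
    """
    catalog = catalog or load_default_driver_catalog()
    signatures = signatures or load_default_signatures()
    transcript = transcript or load_default_transcript()
    rng = np.random.default_rng(config.seed)
    index = transcript_channel_index(transcript)

    driver_labels = sorted(config.driver_frequencies)
    driver_w = np.array([config.driver_frequencies[d] for d in driver_labels])
    driver_w = driver_w / driver_w.sum()

    profiles: list[TumorProfile] = []
    truth = SyntheticTruth(
        seed=config.seed, group_labels={}, variant_components={},
        mixture_weights=dict(config.signature_mixture),
    )

    def draw_driver() -> PoleVariant:
        label = driver_labels[int(rng.choice(len(driver_labels), p=driver_w))]
        return parse_hgvs_protein(label)

    def draw_passengers(k: int, tumor_id: str) -> list[PoleVariant]:
        vs, comps = simulate_variants_from_signature(
            k, config.signature_mixture, signatures, transcript, rng,
            channel_index=index, catalog=catalog,
        )
        truth.variant_components[tumor_id] = comps
        return vs

    for (ct, group) in sorted(config.groups):
        spec = config.groups[(ct, group)]
        for i in range(spec.n):
            tumor_id = f"{ct}-{group}-{i + 1:03d}"
            tmb = _sample_tmb(spec, rng)
            msi = "MSI-H" if rng.random() < spec.msi_fraction else "MSS"
            if rng.random() < spec.under_50_fraction:
                age = float(rng.integers(28, 50))
            else:
                age = float(rng.integers(50, 86))
            sex = "F" if rng.random() < spec.female_fraction else "M"

            variants: list[PoleVariant]
            if group in {"G2", "G3"}:
                drivers = [draw_driver()]
                if rng.random() < config.p_second_driver:
                    for _ in range(_MAX_RETRIES):
                        second = draw_driver()
                        if second.allele != drivers[0].allele:
                            drivers.append(second)
                            break
                if group == "G2":
                    variants = drivers
                    truth.variant_components[tumor_id] = []
                else:
                    k = _sample_count(config.n_additional_variants_distribution, rng)
                    variants = drivers + draw_passengers(k, tumor_id)
            else:
                k = _sample_count(config.n_passenger_variants_distribution, rng)
                variants = draw_passengers(k, tumor_id)

            profiles.append(
                TumorProfile(
                    tumor_id=tumor_id, cancer_type=ct, tmb=tmb,
                    msi_status=msi, age=age, sex=sex,
                    pole_variants=tuple(variants),
                )
            )
            truth.group_labels[tumor_id] = group
    return profiles, truth
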