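"""96-channel trinucleotide (SBS) context classification for POLE variants.

A single-base substitution is typed by its pyrimidine-normalized reference
base plus the 5' and 3' flanking bases — one of 96 channels, written
``T[C>A]T``. POLE proofreading deficiency concentrates mutations in a small
set of channels described by the COSMIC signatures SBS10a, SBS10b, SBS14
and SBS28, each with a primary "hotspot" channel (SBS10a: T[C>A]T, SBS10b:
T[C>T]G, SBS14: any N[C>A]T, SBS28: T[T>G]T).

A signature's *context set* is the set of channels whose probability
exceeds an inclusion threshold (default 1% of the signature mass); the sum
of the included probabilities is the set's coverage. A variant "falls in a
POLE ExoD context" when its channel belongs to at least one of the four
context sets.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

from .variants import CodingChange, PoleVariant

__all__ = [
    "SbsChannel",
    "SignatureVector",
    "SignatureContextSet",
    "ContextCall",
    "ContextFraction",
    "COMPLEMENT",
    "HOTSPOT_CHANNELS",
    "all_channels",
    "normalize_to_pyrimidine",
    "channel_of",
    "build_context_set",
    "classify_variant_context",
    "fraction_in_context",
    "load_signature_table",
    "load_default_signatures",
]

COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}
_BASES = "ACGT"
_PYRIMIDINES = "CT"

POLE_SIGNATURES = ("SBS10a", "SBS10b", "SBS14", "SBS28")


@dataclass(frozen=True, order=True)
class SbsChannel:
    """One of the 96 pyrimidine-normalized substitution channels."""

    ref: str
    alt: str
    five_prime: str
    three_prime: str

    def __post_init__(self) -> None:
        for b in (self.ref, self.alt, self.five_prime, self.three_prime):
            if b not in _BASES:
                raise ValueError(f"base must be A/C/G/T, got {b!r}")
        if self.ref not in _PYRIMIDINES:
            raise ValueError(f"channel reference must be a pyrimidine, got {self.ref!r}")
        if self.alt == self.ref:
            raise ValueError("alternate equals reference")

    def __str__(self) -> str:
        return f"{self.five_prime}[{self.ref}>{self.alt}]{self.three_prime}"

    @classmethod
    def from_string(cls, text: str) -> "SbsChannel":
        """Parse the COSMIC channel notation, e.g. ``T[C>A]T``."""
        t = text.strip().upper()
        if len(t) == 7 and t[1] == "[" and t[3] == ">" and t[5] == "]":
            return cls(ref=t[2], alt=t[4], five_prime=t[0], three_prime=t[6])
        if len(t) == 7 and t[3] == ">" and t[0] == t[4] and t[2] == t[6]:
            # trio notation "TCG>TTG": flanks repeat, middle base changes
            return normalize_to_pyrimidine(t[0], t[1], t[5], t[2])
        raise ValueError(f"bad channel notation {text!r}")


def all_channels() -> list[SbsChannel]:
    """The 96 channels in canonical COSMIC order."""
    out = []
    for ref in _PYRIMIDINES:
        for alt in _BASES:
            if alt == ref:
                continue
            for five in _BASES:
                for three in _BASES:
                    out.append(SbsChannel(ref=ref, alt=alt, five_prime=five, three_prime=three))
    return out


def normalize_to_pyrimidine(five: str, ref: str, alt: str, three: str) -> SbsChannel:
    """Map a stranded substitution onto its pyrimidine-reference channel.

    If the reference base is a purine the whole context is
    reverse-complemented (flanks swap and complement; ref and alt
    complement), so the same genomic event matches the same channel
    regardless of the strand it was reported on. Idempotent for
    pyrimidine-reference input.
    """
    for b in (five, ref, alt, three):
        if b not in _BASES:
            raise ValueError(f"base must be A/C/G/T, got {b!r}")
    if ref == alt:
        raise ValueError("alternate equals reference")
    if ref in _PYRIMIDINES:
        return SbsChannel(ref=ref, alt=alt, five_prime=five, three_prime=three)
    return SbsChannel(
        ref=COMPLEMENT[ref],
        alt=COMPLEMENT[alt],
        five_prime=COMPLEMENT[three],
        three_prime=COMPLEMENT[five],
    )


# Primary ("hotspot") channels per POLE-proofreading signature. SBS14's
# hotspot is C>A in NCT for any 5' base, hence four channels.
HOTSPOT_CHANNELS: dict[str, frozenset[SbsChannel]] = {
    "SBS10a": frozenset({SbsChannel("C", "A", "T", "T")}),
    "SBS10b": frozenset({SbsChannel("C", "T", "T", "G")}),
    "SBS14": frozenset(
        SbsChannel("C", "A", five, "T") for five in _BASES
    ),
    "SBS28": frozenset({SbsChannel("T", "G", "T", "T")}),
}


@dataclass(frozen=True)
class SignatureVector:
    """A 96-channel probability vector for one SBS signature."""

    signature_id: str
    probs: Mapping[SbsChannel, float]

    def __post_init__(self) -> None:
        if len(self.probs) != 96:
            raise ValueError(
                f"{self.signature_id}: expected 96 channels, got {len(self.probs)}"
            )
        total = 0.0
        for ch, p in self.probs.items():
            if p < 0:
                raise ValueError(f"{self.signature_id}: negative probability at {ch}")
            total += p
        if abs(total - 1.0) > 1e-6:
            raise ValueError(f"{self.signature_id}: probabilities sum to {total}")


@dataclass(frozen=True)
class SignatureContextSet:
    """Channels above the inclusion threshold for one signature."""

    signature_id: str
    included_channels: frozenset[SbsChannel]
    coverage: float
    primary_channels: frozenset[SbsChannel]
    inclusion_threshold: float

    def __contains__(self, channel: SbsChannel) -> bool:
        return channel in self.included_channels


def build_context_set(
    sig: SignatureVector, inclusion_threshold: float = 0.01
) -> SignatureContextSet:
    """Apply the >threshold rule: keep channels with prob strictly above it.

    Coverage is the exact sum of the included probabilities; the hotspot
    channels are attached from the fixed per-signature table (empty for
    signatures outside it).
    """
    if not (0.0 < inclusion_threshold < 1.0):
        raise ValueError(f"inclusion threshold must be in (0, 1), got {inclusion_threshold}")
    included = frozenset(ch for ch, p in sig.probs.items() if p > inclusion_threshold)
    coverage = sum(sig.probs[ch] for ch in included)
    primary = HOTSPOT_CHANNELS.get(sig.signature_id, frozenset())
    return SignatureContextSet(
        signature_id=sig.signature_id,
        included_channels=included,
        coverage=coverage,
        primary_channels=primary,
        inclusion_threshold=inclusion_threshold,
    )


def channel_of(
    coding_change: Optional[CodingChange], transcript: str
) -> Optional[SbsChannel]:
    """Trinucleotide channel of a coding SNV on the given CDS, or None.

    The flanks are read from the transcript at position-1/position+1
    (1-based) and the context is pyrimidine-normalized. Returns None for a
    missing coding change (non-SNV events carry none). The stated reference
    base must match the transcript; a mismatch is an integrity error.
    """
    if coding_change is None:
        return None
    seq = transcript.upper()
    pos = coding_change.position
    if pos < 2 or pos > len(seq) - 1:
        raise ValueError(
            f"position {pos} has no flanking bases on a CDS of length {len(seq)}"
        )
    ref = seq[pos - 1]
    if ref != coding_change.ref:
        raise ValueError(
            f"reference mismatch at CDS position {pos}: "
            f"transcript has {ref}, variant states {coding_change.ref}"
        )
    return normalize_to_pyrimidine(
        seq[pos - 2], ref, coding_change.alt, seq[pos]
    )


@dataclass(frozen=True)
class ContextCall:
    """Signature-context classification of one variant."""

    variant: PoleVariant
    channel: Optional[SbsChannel]
    in_pole_context: bool
    matching_signatures: frozenset[str]
    hotspot_hit: frozenset[str]

    def __post_init__(self) -> None:
        if self.in_pole_context != bool(self.matching_signatures):
            raise ValueError("in_pole_context must mirror matching_signatures")
        if self.channel is None and self.in_pole_context:
            raise ValueError("non-SNV cannot be in a signature context")


def classify_variant_context(
    v: PoleVariant,
    sets: Sequence[SignatureContextSet],
    transcript: str,
) -> ContextCall:
    """Place one variant's channel against the signature context sets."""
    channel = channel_of(v.coding_change, transcript)
    if channel is None:
        return ContextCall(
            variant=v, channel=None, in_pole_context=False,
            matching_signatures=frozenset(), hotspot_hit=frozenset(),
        )
    matching = frozenset(s.signature_id for s in sets if channel in s)
    hotspot = frozenset(s.signature_id for s in sets if channel in s.primary_channels)
    return ContextCall(
        variant=v, channel=channel, in_pole_context=bool(matching),
        matching_signatures=matching, hotspot_hit=hotspot,
    )


@dataclass(frozen=True)
class ContextFraction:
    """Aggregate of context calls over a cohort subset.

    ``fraction`` uses SNV-resolvable calls as the denominator (non-SNVs are
    excluded and counted separately); ``fraction_all_variants`` keeps them
    in the denominator so both conventions are always reported.
    """

    n_calls: int
    n_with_channel: int
    n_in_context: int
    n_non_snv: int
    fraction: Optional[float]
    fraction_all_variants: Optional[float]
    per_channel: dict[str, tuple[int, float]]


def fraction_in_context(calls: Iterable[ContextCall]) -> ContextFraction:
    """Fraction of variants whose channel lies in any POLE ExoD context set.

    Per-channel counts and percentages (of the channel-resolvable calls)
    are returned alongside; an empty denominator yields an undefined
    (None) fraction rather than a silent zero.
    """
    calls = list(calls)
    with_channel = [c for c in calls if c.channel is not None]
    n_in = sum(1 for c in with_channel if c.in_pole_context)
    n_non_snv = len(calls) - len(with_channel)
    per_channel: dict[str, tuple[int, float]] = {}
    if with_channel:
        counts: dict[str, int] = {}
        for c in with_channel:
            key = str(c.channel)
            counts[key] = counts.get(key, 0) + 1
        per_channel = {
            k: (n, 100.0 * n / len(with_channel)) for k, n in sorted(counts.items())
        }
    return ContextFraction(
        n_calls=len(calls),
        n_with_channel=len(with_channel),
        n_in_context=n_in,
        n_non_snv=n_non_snv,
        fraction=(n_in / len(with_channel)) if with_channel else None,
        fraction_all_variants=(n_in / len(calls)) if calls else None,
        per_channel=per_channel,
    )


def load_signature_table(path_or_buffer) -> dict[str, SignatureVector]:
    """Read a COSMIC-format signature TSV (Type column + one per signature)."""
    df = pd.read_csv(path_or_buffer, sep="\t", comment="#")
    if "Type" not in df.columns:
        raise ValueError("signature table needs a 'Type' column")
    channels = [SbsChannel.from_string(t) for t in df["Type"]]
    out = {}
    for col in df.columns:
        if col == "Type":
            continue
        probs = dict(zip(channels, df[col].astype(float)))
        out[col] = SignatureVector(signature_id=col, probs=probs)
    return out


def load_default_signatures() -> dict[str, SignatureVector]:
    """The bundled POLE-proofreading signature vectors.

    The shipped table (``data/sbs_pole_synthetic.tsv``) is a synthetic
    stand-in for the COSMIC v3 vectors, constructed to reproduce their
    documented structure: the per-signature hotspot channel dominates,
    the known minor channels (G[C>T]G for SBS10a/10b, C[C>T]G for SBS14)
    exceed the 1% rule, and the >1% channels jointly carry 88-89% of each
    signature's mass.
    """
    with resources.files("polestrat.data").joinpath("sbs_pole_synthetic.tsv").open() as fh:
        return load_signature_table(fh)
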