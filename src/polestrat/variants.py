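"""Protein-level POLE variant parsing, domain annotation and driver matching.

Variant calls arrive as short-form protein HGVS labels ("P286R", "R1125X",
"F285_P286delinsLR"). This module parses them into :class:`PoleVariant`
records, places each on the POLE domain architecture (N-terminal lobe with
exonuclease and polymerase subdomains; C-terminal lobe), and flags the
established exonuclease-domain (ExoD) proofreading drivers by exact
(ref, position, alt) allele match against a curated catalog.

The driver catalog ships as shorthand ("S297F/Y" means both S297F and
S297Y) and expands to exactly 20 alleles with the default list.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, replace
from importlib import resources
from typing import Iterable, Optional, Sequence

__all__ = [
    "VariantKind",
    "CodingChange",
    "PoleVariant",
    "DomainMap",
    "DriverCatalog",
    "VariantParseError",
    "parse_hgvs_protein",
    "format_variant",
    "expand_driver_catalog",
    "load_default_driver_catalog",
    "load_default_domain_map",
    "annotate_domain",
    "flag_drivers",
]

AMINO_ACIDS = set("ACDEFGHIKLMNPQRSTVWY")
STOP = "*"

# Supported variant kinds (protein level).
VariantKind = str
KINDS = (
    "missense",
    "nonsense",
    "frameshift",
    "inframe_deletion",
    "inframe_insertion",
    "delins",
    "duplication",
    "splice",
    "other",
)


class VariantParseError(ValueError):
    """Raised when a protein-change label cannot be interpreted."""


@dataclass(frozen=True)
class CodingChange:
    """A single-nucleotide coding change, 1-based on the transcript CDS."""

    position: int
    ref: str
    alt: str

    def __post_init__(self) -> None:
        if self.position < 1:
            raise ValueError(f"coding position must be >= 1, got {self.position}")
        for b in (self.ref, self.alt):
            if b not in "ACGT":
                raise ValueError(f"base must be one of A/C/G/T, got {b!r}")
        if self.ref == self.alt:
            raise ValueError("ref and alt base are identical")


@dataclass(frozen=True)
class PoleVariant:
    """One parsed POLE variant call.

    ``position`` is the (start) residue, 1-based. Multi-residue events
    (delins, deletions, insertions, duplications) carry ``end_position``.
    ``alt_aa`` holds the single alternate residue for substitutions, ``*``
    for stops, or the replacement peptide for delins.
    """

    raw_label: str
    kind: VariantKind
    position: Optional[int] = None
    end_position: Optional[int] = None
    ref_aa: Optional[str] = None
    alt_aa: Optional[str] = None
    coding_change: Optional[CodingChange] = None
    domain: Optional[str] = None
    lobe: Optional[str] = None
    is_exod_driver: bool = False

    def __post_init__(self) -> None:
        if self.kind not in KINDS:
            raise ValueError(f"unknown variant kind {self.kind!r}")
        if self.position is not None and self.position < 1:
            raise ValueError(
                f"residue position must be >= 1 in {self.raw_label!r}"
            )
        if self.end_position is not None and self.position is not None:
            if self.end_position < self.position:
                raise ValueError(f"inverted interval in {self.raw_label!r}")
        if self.kind == "missense":
            if self.ref_aa not in AMINO_ACIDS or self.alt_aa not in AMINO_ACIDS:
                raise ValueError(
                    f"missense requires standard residues: {self.raw_label!r}"
                )
            if self.ref_aa == self.alt_aa:
                raise ValueError(f"synonymous label is not missense: {self.raw_label!r}")
        if self.kind == "nonsense" and self.alt_aa != STOP:
            raise ValueError(f"nonsense requires a stop alternate: {self.raw_label!r}")

    @property
    def allele(self) -> Optional[tuple[str, int, str]]:
        """(ref, position, alt) triplet for single-residue substitutions."""
        if self.kind in ("missense", "nonsense") and self.position is not None:
            return (self.ref_aa, self.position, self.alt_aa)
        return None


_RE_SUB = re.compile(r"^([A-Z])(\d+)([A-Z*])$")
_RE_FS = re.compile(r"^([A-Z])(\d+)([A-Z*]?)FS(?:\*?\d*)?$")
_RE_DELINS = re.compile(r"^([A-Z])(\d+)(?:_([A-Z])(\d+))?DELINS([A-Z]+)$")
_RE_DEL = re.compile(r"^([A-Z])(\d+)(?:_([A-Z])(\d+))?DEL$")
_RE_INS = re.compile(r"^([A-Z])(\d+)_([A-Z])(\d+)INS([A-Z]+)$")
_RE_DUP = re.compile(r"^([A-Z])(\d+)(?:_([A-Z])(\d+))?DUP$")
_RE_SPLICE_POS = re.compile(r"(\d+)")


def _check_aa(aa: str, label: str) -> str:
    if aa == "X":
        return STOP
    if aa != STOP and aa not in AMINO_ACIDS:
        raise VariantParseError(f"unknown residue code {aa!r} in {label!r}")
    return aa


def parse_hgvs_protein(label: str) -> PoleVariant:
    """Parse a short-form protein HGVS label into a :class:`PoleVariant`.

    Accepts an optional ``p.`` prefix and either ``X`` or ``*`` for stop
    codons (normalized to ``*``). Parsing is case-insensitive; residues are
    reported upper-case.

    Raises
    ------
    VariantParseError
        If the label matches no supported form or fails validation.
    """
    if not label or not label.strip():
        raise VariantParseError("empty variant label")
    raw = label.strip()
    body = raw.upper()
    if body.startswith("P."):
        body = body[2:]

    if "SPLICE" in body:
        m = _RE_SPLICE_POS.search(body)
        pos = int(m.group(1)) if m else None
        return PoleVariant(raw_label=raw, kind="splice", position=pos)

    m = _RE_DELINS.match(body)
    if m:
        ref1, pos1, ref2, pos2, repl = m.groups()
        start = int(pos1)
        end = int(pos2) if pos2 else start
        _check_aa(ref1, raw)
        if ref2:
            _check_aa(ref2, raw)
        return PoleVariant(
            raw_label=raw, kind="delins", position=start, end_position=end,
            ref_aa=ref1, alt_aa=repl,
        )

    m = _RE_FS.match(body)
    if m:
        ref, pos, _alt = m.groups()
        return PoleVariant(
            raw_label=raw, kind="frameshift", position=int(pos),
            ref_aa=_check_aa(ref, raw),
        )

    m = _RE_SUB.match(body)
    if m:
        ref, pos, alt = m.groups()
        ref = _check_aa(ref, raw)
        alt = _check_aa(alt, raw)
        if int(pos) < 1:
            raise VariantParseError(f"residue position must be positive: {raw!r}")
        if alt == STOP:
            return PoleVariant(
                raw_label=raw, kind="nonsense", position=int(pos),
                ref_aa=ref, alt_aa=STOP,
            )
        if ref == STOP:
            raise VariantParseError(f"stop codon as reference residue: {raw!r}")
        if ref == alt:
            raise VariantParseError(f"synonymous label not supported: {raw!r}")
        return PoleVariant(
            raw_label=raw, kind="missense", position=int(pos),
            ref_aa=ref, alt_aa=alt,
        )

    m = _RE_DEL.match(body)
    if m:
        ref1, pos1, ref2, pos2 = m.groups()
        start = int(pos1)
        end = int(pos2) if pos2 else start
        _check_aa(ref1, raw)
        return PoleVariant(
            raw_label=raw, kind="inframe_deletion", position=start,
            end_position=end, ref_aa=ref1,
        )

    m = _RE_INS.match(body)
    if m:
        ref1, pos1, ref2, pos2, ins = m.groups()
        _check_aa(ref1, raw)
        _check_aa(ref2, raw)
        return PoleVariant(
            raw_label=raw, kind="inframe_insertion", position=int(pos1),
            end_position=int(pos2), ref_aa=ref1, alt_aa=ins,
        )

    m = _RE_DUP.match(body)
    if m:
        ref1, pos1, ref2, pos2 = m.groups()
        start = int(pos1)
        end = int(pos2) if pos2 else start
        _check_aa(ref1, raw)
        return PoleVariant(
            raw_label=raw, kind="duplication", position=start,
            end_position=end, ref_aa=ref1,
        )

    raise VariantParseError(f"cannot parse variant label {raw!r}")


def format_variant(v: PoleVariant) -> str:
    """Render a canonical short-form label; parse(format(v)) round-trips."""
    if v.kind == "missense" or v.kind == "nonsense":
        alt = "X" if v.alt_aa == STOP else v.alt_aa
        return f"{v.ref_aa}{v.position}{alt}"
    if v.kind == "frameshift":
        return f"{v.ref_aa}{v.position}fs"
    if v.kind == "delins":
        if v.end_position and v.end_position != v.position:
            return f"{v.ref_aa}{v.position}_?{v.end_position}delins{v.alt_aa}"
        return f"{v.ref_aa}{v.position}delins{v.alt_aa}"
    if v.kind == "splice":
        return f"{v.position or ''}splice"
    return v.raw_label


@dataclass(frozen=True)
class DomainMap:
    """POLE domain architecture as two interval tiers.

    ``lobes`` is the coarse tier and must tile residues 1..protein_length
    exactly (N-terminal lobe NTL and C-terminal lobe CTL by default, split
    at residue 1,183). ``domains`` is the fine tier (ExoD, polymerase
    palm/fingers/thumb, CTD ...); intervals may leave gaps but must not
    overlap. Domain lookup returns the innermost (shortest) match.
    """

    protein_length: int
    lobes: tuple[tuple[str, int, int], ...]
    domains: tuple[tuple[str, int, int], ...]

    def __post_init__(self) -> None:
        covered = []
        for name, start, end in self.lobes:
            if not (1 <= start <= end <= self.protein_length):
                raise ValueError(f"lobe {name} outside protein 1..{self.protein_length}")
            covered.append((start, end))
        covered.sort()
        cursor = 1
        for start, end in covered:
            if start != cursor:
                raise ValueError("lobe tier must tile the protein exactly once")
            cursor = end + 1
        if cursor != self.protein_length + 1:
            raise ValueError("lobe tier must cover the full protein")
        spans = sorted((s, e) for _, s, e in self.domains)
        for (s1, e1), (s2, e2) in zip(spans, spans[1:]):
            if s2 <= e1:
                raise ValueError("domain intervals overlap")

    def lobe_of(self, position: int) -> str:
        self._check_pos(position)
        for name, start, end in self.lobes:
            if start <= position <= end:
                return name
        raise AssertionError("unreachable: lobes tile the protein")

    def domain_of(self, position: int) -> Optional[str]:
        """Innermost fine-tier domain containing ``position`` (or None)."""
        self._check_pos(position)
        hits = [
            (end - start, name)
            for name, start, end in self.domains
            if start <= position <= end
        ]
        return min(hits)[1] if hits else None

    def _check_pos(self, position: int) -> None:
        if not (1 <= position <= self.protein_length):
            raise ValueError(
                f"residue {position} outside protein 1..{self.protein_length}"
            )


@dataclass(frozen=True)
class DriverCatalog:
    """Curated ExoD proofreading-driver alleles, matched exactly."""

    entries: frozenset[tuple[str, int, str]]
    source_shorthand: tuple[str, ...] = ()

    def __contains__(self, allele: tuple[str, int, str]) -> bool:
        return allele in self.entries

    def __len__(self) -> int:
        return len(self.entries)


_RE_SHORTHAND = re.compile(r"^([A-Z])(\d+)([A-Z])((?:/[A-Z])*)$")


def expand_driver_catalog(shorthand: Sequence[str]) -> DriverCatalog:
    """Expand multi-allele shorthand ("S297F/Y") into explicit alleles.

    Every slash-separated alternate becomes its own (ref, pos, alt) entry.
    Duplicate expanded entries are rejected.
    """
    entries: set[tuple[str, int, str]] = set()
    for item in shorthand:
        m = _RE_SHORTHAND.match(item.strip().upper())
        if not m:
            raise VariantParseError(f"bad driver shorthand {item!r}")
        ref, pos, first_alt, rest = m.groups()
        alts = [first_alt] + [a for a in rest.split("/") if a]
        for alt in alts:
            if alt not in AMINO_ACIDS or ref not in AMINO_ACIDS:
                raise VariantParseError(f"non-standard residue in {item!r}")
            key = (ref, int(pos), alt)
            if key in entries:
                raise ValueError(f"duplicate driver allele {ref}{pos}{alt}")
            entries.add(key)
    return DriverCatalog(entries=frozenset(entries), source_shorthand=tuple(shorthand))


def _load_data_json(name: str) -> dict:
    with resources.files("polestrat.data").joinpath(name).open() as fh:
        return json.load(fh)


def load_default_driver_catalog() -> DriverCatalog:
    """The 20-allele ExoD driver catalog shipped with the package."""
    payload = _load_data_json("drivers.json")
    return expand_driver_catalog(payload["drivers"])


def load_default_domain_map() -> DomainMap:
    payload = _load_data_json("domain_map.json")
    return DomainMap(
        protein_length=payload["protein_length"],
        lobes=tuple((d["name"], d["start"], d["end"]) for d in payload["lobes"]),
        domains=tuple((d["name"], d["start"], d["end"]) for d in payload["domains"]),
    )


def annotate_domain(v: PoleVariant, domain_map: DomainMap) -> PoleVariant:
    """Assign lobe and (if any) fine domain from the variant's start residue.

    Multi-residue events are placed by their start residue. A position past
    the protein end is a validation error.
    """
    if v.position is None:
        raise ValueError(f"variant {v.raw_label!r} has no resolvable residue")
    lobe = domain_map.lobe_of(v.position)
    domain = domain_map.domain_of(v.position)
    return replace(v, lobe=lobe, domain=domain)


def flag_drivers(
    variants: Iterable[PoleVariant], catalog: DriverCatalog
) -> list[PoleVariant]:
    """Set ``is_exod_driver`` by exact allele match against the catalog.

    Only single-residue missense substitutions can match; truncating,
    delins and other multi-residue events are never drivers even when they
    overlap a driver residue.
    """
    out = []
    for v in variants:
        allele = v.allele if v.kind == "missense" else None
        out.append(replace(v, is_exod_driver=allele in catalog.entries if allele else False))
    return out
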