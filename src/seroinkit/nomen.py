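"""Seroin nomenclature: species abbreviations, name building and parsing.

A seroin name concatenates the genus/species abbreviation (e.g. ``Bm`` for
Bombyx mori, extended to ``Has`` for Helicoverpa assulta to avoid clashing
with ``Ha``), the class tag ``Sn1``/``Sn2``/``Sn3``, an optional hyphenated
serial gene number for species with two paralogs of a class (``BmSn1-2``),
an optional capital splice-version letter (``GmSn1B``) and an optional
minor-variant digit starting at 2 (``GmSn1B2``).
"""

from __future__ import annotations

import re
import unicodedata
from dataclasses import dataclass
from typing import Iterable, Optional


class NameParseError(ValueError):
    """Name does not match the nomenclature grammar; message gives position."""


@dataclass(frozen=True)
class NameParts:
    """Decomposed seroin name."""

    abbrev: str
    seroin_class: int  # 1 | 2 | 3
    gene_number: Optional[int] = None  # 1 | 2, only for two-gene species
    splice_letter: Optional[str] = None  # 'A'..'Z'
    minor_variant: Optional[int] = None  # >= 2, requires splice_letter

    def __post_init__(self) -> None:
        if not re.fullmatch(r"[A-Z][a-z]+", self.abbrev):
            raise ValueError(f"abbrev {self.abbrev!r} must match [A-Z][a-z]+ (length >= 2)")
        if self.seroin_class not in (1, 2, 3):
            raise ValueError("seroin_class must be 1, 2 or 3")
        if self.gene_number is not None and self.gene_number not in (1, 2):
            raise ValueError("gene_number must be 1 or 2")
        if self.splice_letter is not None and not re.fullmatch(r"[A-Z]", self.splice_letter):
            raise ValueError("splice_letter must be a single capital letter")
        if self.minor_variant is not None:
            if self.splice_letter is None:
                raise ValueError("minor_variant requires a splice_letter")
            if self.minor_variant < 2:
                raise ValueError("minor_variant digits start at 2")


class AbbrevRegistry:
    """Bijective (genus, species) <-> abbreviation registry.

    Collisions are resolved by extending the species-epithet part of the
    abbreviation, never by reusing an existing code.
    """

    def __init__(self) -> None:
        self.by_species: dict[tuple[str, str], str] = {}
        self.by_abbrev: dict[str, tuple[str, str]] = {}

    def register(self, genus: str, species: str, abbrev: str) -> None:
        key = (genus, species)
        if abbrev in self.by_abbrev and self.by_abbrev[abbrev] != key:
            raise ValueError(f"abbreviation {abbrev!r} already in use")
        self.by_species[key] = abbrev
        self.by_abbrev[abbrev] = key

    def __contains__(self, abbrev: str) -> bool:
        return abbrev in self.by_abbrev


def species_abbrev(genus: str, species: str,
                   registry: Optional[AbbrevRegistry] = None) -> str:
    """Abbreviate a binomial: genus initial + species-epithet letters.

    Default is a two-letter code (``Bm``); on collision the epithet part
    is extended letter by letter until unique (``Ha`` vs ``Has``).  The
    registry, if given, is updated.
    """
    if not (genus.isalpha() and species.isalpha()):
        raise ValueError("genus and species must be alphabetic")
    registry = registry if registry is not None else AbbrevRegistry()
    key = (genus, species.lower())
    if key in registry.by_species:
        return registry.by_species[key]
    epithet = species.lower()
    for n in range(1, len(epithet) + 1):
        abbrev = genus[0].upper() + epithet[:n]
        if abbrev not in registry:
            registry.register(genus, epithet, abbrev)
            return abbrev
    raise ValueError(
        f"cannot derive a unique abbreviation for {genus} {species}"
    )


def build_name(parts: NameParts) -> str:
    """Serialize NameParts to a seroin name (ASCII hyphen-minus)."""
    name = f"{parts.abbrev}Sn{parts.seroin_class}"
    if parts.gene_number is not None:
        name += f"-{parts.gene_number}"
    if parts.splice_letter is not None:
        name += parts.splice_letter
        if parts.minor_variant is not None:
            name += str(parts.minor_variant)
    return name


_NAME_RE = re.compile(
    r"(?P<abbrev>[A-Z][a-z]+)Sn(?P<cls>[123])"
    r"(?:-(?P<gene>[12]))?"
    r"(?:(?P<letter>[A-Z])(?P<minor>[2-9]\d*)?)?$"
)


def parse_name(name: str, registry: Optional[AbbrevRegistry] = None) -> NameParts:
    """Exact inverse of :func:`build_name`.

    Unicode dashes (the en-dash that sometimes creeps into typeset names)
    are normalized to ASCII hyphen-minus before parsing.  Errors report
    the position where the grammar match fails.
    """
    if not name:
        raise NameParseError("empty name")
    normalized = "".join(
        "-" if unicodedata.category(ch) == "Pd" else ch for ch in name
    )
    m = _NAME_RE.match(normalized)
    if not m:
        # locate the failure point for the error message
        sn = re.search(r"Sn[123]", normalized)
        if not re.match(r"[A-Z][a-z]+", normalized):
            raise NameParseError(
                f"position 0: expected species abbreviation in {name!r}"
            )
        if not sn:
            raise NameParseError(
                f"position {len(re.match(r'[A-Z][a-z]+', normalized).group())}: "
                f"expected class tag Sn1/Sn2/Sn3 in {name!r}"
            )
        raise NameParseError(
            f"position {sn.end()}: trailing {normalized[sn.end():]!r} does not "
            f"match the gene/splice-variant grammar in {name!r}"
        )
    parts = NameParts(
        abbrev=m.group("abbrev"),
        seroin_class=int(m.group("cls")),
        gene_number=int(m.group("gene")) if m.group("gene") else None,
        splice_letter=m.group("letter"),
        minor_variant=int(m.group("minor")) if m.group("minor") else None,
    )
    if registry is not None and parts.abbrev not in registry:
        raise NameParseError(f"unknown species abbreviation {parts.abbrev!r}")
    return parts


def assign_names(rows: Iterable[dict], registry: Optional[AbbrevRegistry] = None
                 ) -> dict[str, str]:
    """Assign seroin names to annotated records.

    Each row needs: id, genus, species, seroin_class ('Sn1'...), version
    code and gene_number plus the total number of genes of that class in
    the species (``n_genes``).  Splice letters are handed out per gene in
    descending version-group size (ties by smallest member id); a gene
    with a single isoform gets no letter; additional members of the same
    version group get minor-variant digits starting at 2.
    """
    registry = registry if registry is not None else AbbrevRegistry()
    rows = list(rows)
    names: dict[str, str] = {}
    by_gene: dict[tuple, list[dict]] = {}
    for row in rows:
        key = (row["genus"], row["species"], row["seroin_class"], row["gene_number"])
        by_gene.setdefault(key, []).append(row)
    for (genus, species, cls, gene_number), members in sorted(by_gene.items()):
        abbrev = species_abbrev(genus, species, registry)
        cls_num = int(cls[-1])
        n_genes = max(r.get("n_genes", 1) for r in members)
        gene_field = gene_number if n_genes > 1 else None
        if len(members) == 1:
            parts = NameParts(abbrev, cls_num, gene_field)
            names[members[0]["id"]] = build_name(parts)
            continue
        versions: dict[str, list[dict]] = {}
        for r in members:
            versions.setdefault(r["version"], []).append(r)
        ordered = sorted(versions.values(),
                         key=lambda ms: (-len(ms), min(r["id"] for r in ms)))
        for vi, group in enumerate(ordered):
            letter = chr(ord("A") + vi)
            for mi, r in enumerate(sorted(group, key=lambda r: r["id"])):
                minor = None if mi == 0 else mi + 1
                parts = NameParts(abbrev, cls_num, gene_field, letter, minor)
                names[r["id"]] = build_name(parts)
    return names
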