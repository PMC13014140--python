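"""Species namespaces of the Alliance of Genome Resources member databases.

The Alliance aggregates nine model-organism knowledgebases, each with its own
gene-identifier namespace (``WB:WBGene…``, ``FBgn…``, ``HGNC:…`` …).  This
module maps raw gene identifiers and ortholog-column headers onto canonical
species codes so the rest of the pipeline can reason about which species a
gene belongs to without ever touching identifier syntax itself.

Two lookups are exposed:

* :meth:`SpeciesRegistry.infer_species` — identifier prefix → species.  Total:
  it never raises and returns :attr:`Species.UNKNOWN` for unrecognised input.
* :meth:`SpeciesRegistry.species_for_ortholog_column` — table header →
  species, used to assign a species to each per-species ortholog column of a
  SimpleMine export.

Xenbase is a single database serving two species (*Xenopus laevis* and
*Xenopus tropicalis*) whose gene IDs share one ``XB-GENE`` namespace, so a
bare Xenbase identifier is ambiguous.  Ortholog columns disambiguate via
their header text; for row genes the registry applies a configurable default
(``XB_XT``).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Union

import yaml

__all__ = [
    "Species",
    "ALLIANCE_SPECIES",
    "LATIN_NAMES",
    "PrefixRule",
    "SpeciesRegistry",
    "DEFAULT_REGISTRY",
]


class Species(enum.Enum):
    """Canonical species codes, one per Alliance member-database namespace."""

    SGD = "Saccharomyces Genome Database"
    WB = "WormBase"
    FB = "FlyBase"
    XB_XL = "Xenbase (Xenopus laevis)"
    XB_XT = "Xenbase (Xenopus tropicalis)"
    ZFIN = "Zebrafish Information Network"
    MGI = "Mouse Genome Informatics"
    RGD = "Rat Genome Database"
    HGNC = "HUGO Gene Nomenclature Committee"
    UNKNOWN = "unknown"

    @property
    def code(self) -> str:
        return self.name

    @property
    def display_name(self) -> str:
        return self.value

    def __lt__(self, other: "Species") -> bool:  # stable sort key for output
        if not isinstance(other, Species):
            return NotImplemented
        return self.name < other.name


#: The nine real species codes (everything except the UNKNOWN sentinel).
ALLIANCE_SPECIES: tuple[Species, ...] = tuple(
    s for s in Species if s is not Species.UNKNOWN
)

#: Binomial species names, used in ortholog-column headers.
LATIN_NAMES: dict[Species, str] = {
    Species.SGD: "Saccharomyces cerevisiae",
    Species.WB: "Caenorhabditis elegans",
    Species.FB: "Drosophila melanogaster",
    Species.XB_XL: "Xenopus laevis",
    Species.XB_XT: "Xenopus tropicalis",
    Species.ZFIN: "Danio rerio",
    Species.MGI: "Mus musculus",
    Species.RGD: "Rattus norvegicus",
    Species.HGNC: "Homo sapiens",
}

#: The shared Xenbase identifier prefixes that cannot name a single species.
_XENBASE_AMBIGUOUS = "XB"

#: Default identifier-prefix table.  Values are species codes, or the special
#: token ``XB`` meaning "Xenbase, species resolved by the registry default".
DEFAULT_PREFIXES: dict[str, str] = {
    "SGD:": "SGD",
    "WB:": "WB",
    "WBGene": "WB",
    "FB:": "FB",
    "FBgn": "FB",
    "ZFIN:": "ZFIN",
    "ZDB-GENE": "ZFIN",
    "MGI:": "MGI",
    "RGD:": "RGD",
    "HGNC:": "HGNC",
    "Xenbase:": _XENBASE_AMBIGUOUS,
    "XB-GENE": _XENBASE_AMBIGUOUS,
}


@dataclass(frozen=True)
class PrefixRule:
    """One identifier-prefix → species rule; matching is case-sensitive and
    anchored at the start of the identifier."""

    prefix: str
    species: Species

    def matches(self, gene_id: str) -> bool:
        return gene_id.startswith(self.prefix)


def _default_aliases() -> tuple[tuple[str, Species], ...]:
    aliases: list[tuple[str, Species]] = []
    for sp in ALLIANCE_SPECIES:
        aliases.append((LATIN_NAMES[sp], sp))
        aliases.append((sp.display_name, sp))
    return tuple(aliases)


@dataclass(frozen=True)
class SpeciesRegistry:
    """Prefix and header-alias rules resolving identifiers to species.

    Parameters
    ----------
    rules
        Prefix rules.  No rule's prefix may be a prefix of another rule's
        prefix, so at most one rule matches any identifier.
    header_aliases
        ``(alias, species)`` pairs; an ortholog-column header is resolved to
        the species of the longest alias it contains (case-insensitive).
    ortholog_marker
        Substring that must occur in a header for it to count as an ortholog
        column at all.
    xenbase_default
        Species assigned to a bare Xenbase identifier seen outside any
        ortholog column.
    """

    rules: tuple[PrefixRule, ...]
    header_aliases: tuple[tuple[str, Species], ...] = field(
        default_factory=_default_aliases
    )
    ortholog_marker: str = "Ortholog"
    xenbase_default: Species = Species.XB_XT

    def __post_init__(self) -> None:
        prefixes = [r.prefix for r in self.rules]
        for i, p in enumerate(prefixes):
            for q in prefixes[i + 1 :]:
                if p.startswith(q) or q.startswith(p):
                    raise ValueError(
                        f"overlapping identifier prefixes: {p!r} and {q!r}"
                    )
        if self.xenbase_default not in (Species.XB_XL, Species.XB_XT):
            raise ValueError("xenbase_default must be XB_XL or XB_XT")

    # -- identifier lookup -------------------------------------------------

    def infer_species(self, gene_id: str) -> Species:
        """Species of ``gene_id`` by anchored, case-sensitive prefix match.

        Total over all strings: unmatched (or empty) input yields
        :attr:`Species.UNKNOWN`, never an exception.
        """
        token = gene_id.strip()
        if not token:
            return Species.UNKNOWN
        for rule in self.rules:
            if rule.matches(token):
                return rule.species
        return Species.UNKNOWN

    # -- header lookup -----------------------------------------------------

    def species_for_ortholog_column(self, column_header: str) -> Species:
        """Species encoded in an ortholog-column header, else UNKNOWN.

        The header must contain :attr:`ortholog_marker`; among aliases
        occurring in it, the longest wins (so "Xenopus tropicalis" is never
        shadowed by a shorter overlapping alias).
        """
        header = column_header.lower()
        if self.ortholog_marker.lower() not in header:
            return Species.UNKNOWN
        best: tuple[int, Species] | None = None
        for alias, sp in self.header_aliases:
            if alias.lower() in header:
                cand = (len(alias), sp)
                if best is None or cand[0] > best[0]:
                    best = cand
        return best[1] if best is not None else Species.UNKNOWN

    # -- construction ------------------------------------------------------

    @classmethod
    def default(cls, xenbase_default: Species = Species.XB_XT) -> "SpeciesRegistry":
        return cls.from_prefix_map(DEFAULT_PREFIXES, xenbase_default=xenbase_default)

    @classmethod
    def from_prefix_map(
        cls,
        prefixes: Mapping[str, str],
        aliases: Mapping[str, str] | None = None,
        xenbase_default: Species = Species.XB_XT,
        ortholog_marker: str = "Ortholog",
    ) -> "SpeciesRegistry":
        """Build a registry from plain-text config maps (prefix → code,
        alias → code).  The code ``XB`` marks the ambiguous Xenbase namespace
        and resolves to ``xenbase_default``."""

        def resolve(code: str) -> Species:
            if code == _XENBASE_AMBIGUOUS:
                return xenbase_default
            return Species[code]

        rules = tuple(
            PrefixRule(prefix, resolve(code)) for prefix, code in prefixes.items()
        )
        if aliases is None:
            header_aliases = _default_aliases()
        else:
            header_aliases = tuple(
                (alias, resolve(code)) for alias, code in aliases.items()
            )
        return cls(
            rules=rules,
            header_aliases=header_aliases,
            ortholog_marker=ortholog_marker,
            xenbase_default=xenbase_default,
        )

    @classmethod
    def from_yaml(cls, path: Union[str, Path]) -> "SpeciesRegistry":
        """Load a registry from a YAML config file with keys ``prefixes``,
        ``aliases`` (optional), ``xenbase_default`` and ``ortholog_marker``."""
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_prefix_map(
            data.get("prefixes", DEFAULT_PREFIXES),
            aliases=data.get("aliases"),
            xenbase_default=Species[data.get("xenbase_default", "XB_XT")],
            ortholog_marker=data.get("ortholog_marker", "Ortholog"),
        )


#: Module-level registry with the shipped default rules.
DEFAULT_REGISTRY = SpeciesRegistry.default()


def parse_species_code(token: str) -> Species | None:
    """Parse a CLI species token: ``ALL`` → None (no filter), else a code."""
    tok = token.strip().upper()
    if tok == "ALL":
        return None
    try:
        sp = Species[tok]
    except KeyError:
        raise ValueError(
            f"unknown species code {token!r}; expected ALL or one of "
            + ", ".join(s.code for s in ALLIANCE_SPECIES)
        ) from None
    if sp is Species.UNKNOWN:
        raise ValueError("UNKNOWN is not a selectable species")
    return sp
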