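"""Configuration blocks: TSV dialect, column schema, endpoint, registry.

SimpleMine exports are tab-separated with multi-valued cells; the exact
intra-cell delimiters and header spellings are deployment details of the
Alliance service, so everything here is configuration with documented
defaults rather than hard-coded syntax.  The same dialect is used to write
fixture files, results tables and statistics tables, which is what makes the
parse/write round-trip exact.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Union

import yaml

from .registry import DEFAULT_REGISTRY, Species, SpeciesRegistry

__all__ = ["TsvDialect", "ColumnSchema", "EndpointConfig", "ToolConfig"]


@dataclass(frozen=True)
class TsvDialect:
    """Separators and missing-value tokens of the tabular format.

    ``field_separator`` splits cells, ``value_separator`` splits values
    within a cell, and ``subfield_separator`` splits the parts of one value
    (e.g. gene ID vs symbol inside an ortholog entry).  The three must be
    pairwise distinct.
    """

    field_separator: str = "\t"
    value_separator: str = "|"
    subfield_separator: str = ";"
    missing_tokens: frozenset[str] = frozenset({"", "N.A.", "NA"})

    def __post_init__(self) -> None:
        seps = (self.field_separator, self.value_separator, self.subfield_separator)
        if len(set(seps)) != 3:
            raise ValueError(f"separators must be pairwise distinct, got {seps!r}")

    def is_missing(self, cell: str) -> bool:
        return cell.strip() in self.missing_tokens

    def split_values(self, cell: str) -> list[str]:
        """Split a multi-valued cell: trim, drop missing tokens, de-duplicate
        preserving first-seen order."""
        if self.is_missing(cell):
            return []
        seen: dict[str, None] = {}
        for raw in cell.split(self.value_separator):
            tok = raw.strip()
            if tok and tok not in self.missing_tokens:
                seen.setdefault(tok)
        return list(seen)

    def join_values(self, values) -> str:
        """Render a set-valued cell: lexicographically sorted, or the first
        missing token when empty (keeps output cells visibly non-blank)."""
        vals = sorted(values)
        if not vals:
            return "N.A." if "N.A." in self.missing_tokens else ""
        return self.value_separator.join(vals)


@dataclass(frozen=True)
class ColumnSchema:
    """Header names of the mandatory columns in a SimpleMine export."""

    gene_id: str = "Gene ID"
    symbol: str = "Gene Symbol"
    genetic: str = "Genetic Interaction"
    ppi: str = "Protein-Protein Interaction"

    def mandatory(self) -> tuple[str, ...]:
        return (self.gene_id, self.symbol, self.genetic, self.ppi)


@dataclass(frozen=True)
class EndpointConfig:
    """Where the live SimpleMine service lives and how gene pages are linked."""

    url: str = "https://www.alliancegenome.org/agr_simplemine.cgi"
    gene_page_template: str = "https://www.alliancegenome.org/gene/{gene_id}"


@dataclass(frozen=True)
class ToolConfig:
    """Bundle of all configuration consumed by parsing, analysis and output.

    ``interactor_id_pattern`` optionally extracts the gene ID from decorated
    interactor values such as ``"symbol (WB:WBGene00000001)"``; when None the
    cell tokens are taken to be bare IDs (the fixture convention).
    """

    dialect: TsvDialect = field(default_factory=TsvDialect)
    columns: ColumnSchema = field(default_factory=ColumnSchema)
    endpoint: EndpointConfig = field(default_factory=EndpointConfig)
    registry: SpeciesRegistry = DEFAULT_REGISTRY
    interactor_id_pattern: str | None = None

    def extract_interactor_id(self, token: str) -> str:
        if self.interactor_id_pattern is None:
            return token
        m = re.search(self.interactor_id_pattern, token)
        return m.group(1) if m else token

    def with_(self, **kwargs) -> "ToolConfig":
        return replace(self, **kwargs)

    @classmethod
    def from_yaml(cls, path: Union[str, Path]) -> "ToolConfig":
        """Load overrides from a YAML file; absent keys keep their defaults.

        Recognised top-level keys: ``dialect`` (field_separator,
        value_separator, subfield_separator, missing_tokens), ``columns``
        (gene_id, symbol, genetic, ppi), ``endpoint`` (url,
        gene_page_template), ``registry`` (prefixes, aliases,
        xenbase_default, ortholog_marker), ``interactor_id_pattern``.
        """
        data = yaml.safe_load(Path(path).read_text()) or {}
        dialect = TsvDialect()
        if "dialect" in data:
            d = dict(data["dialect"])
            if "missing_tokens" in d:
                d["missing_tokens"] = frozenset(d["missing_tokens"])
            dialect = replace(dialect, **d)
        columns = ColumnSchema(**data.get("columns", {}))
        endpoint = EndpointConfig(**data.get("endpoint", {}))
        registry = DEFAULT_REGISTRY
        if "registry" in data:
            r = data["registry"]
            registry = SpeciesRegistry.from_prefix_map(
                r.get("prefixes", {}),
                aliases=r.get("aliases"),
                xenbase_default=Species[r.get("xenbase_default", "XB_XT")],
                ortholog_marker=r.get("ortholog_marker", "Ortholog"),
            )
        return cls(
            dialect=dialect,
            columns=columns,
            endpoint=endpoint,
            registry=registry,
            interactor_id_pattern=data.get("interactor_id_pattern"),
        )


DEFAULT_CONFIG = ToolConfig()
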