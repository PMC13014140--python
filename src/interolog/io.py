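"""Reading and writing SimpleMine-format gene tables and result tables.

The Alliance SimpleMine bulk-query service exports one row per gene with
multi-valued cells for curated genetic interactors, curated protein-protein
interactors and per-species ortholog lists, preceded by a free-text preamble.
This module parses such a file into an in-memory :class:`GeneDataset` keyed
by gene ID, and writes the two output tables of the pipeline (per-query
results, genome-wide statistics) in the same dialect so that every table
round-trips exactly.
"""

from __future__ import annotations

import enum
import html as _html
import io as _io
import logging
import urllib.error
import urllib.parse
import urllib.request
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Iterable, Iterator, Mapping, Sequence, Union

from .config import DEFAULT_CONFIG, ToolConfig
from .registry import Species

logger = logging.getLogger(__name__)

__all__ = [
    "InteractionType",
    "OrthologEntry",
    "GeneRecord",
    "GeneDataset",
    "ParseReport",
    "SimpleMineFormatError",
    "parse_simplemine_tsv",
    "RequestSpec",
    "build_download_request",
    "fetch_simplemine",
    "TransportError",
    "NotTsvError",
    "RESULT_COLUMNS",
    "STATS_COLUMNS",
    "write_results_tsv",
    "read_results_tsv",
    "write_genome_stats_tsv",
    "render_results_html",
]

#: Symbol-cell marker for queries absent from the dataset; chosen so that an
#: unknown-query row survives the results round-trip unambiguously.
NOT_FOUND_MARKER = "NOT_FOUND"


class InteractionType(enum.Enum):
    """Which curated interactor set of a gene record is read."""

    PPI = "ppi"
    GENETIC = "genetic"


@dataclass(frozen=True, order=True)
class OrthologEntry:
    """One ortholog of a gene: species (from the column header), ID, symbol."""

    species: Species
    gene_id: str
    symbol: str = ""

    def __post_init__(self) -> None:
        if not self.gene_id:
            raise ValueError("ortholog gene_id must be non-empty")
        if self.species is Species.UNKNOWN:
            raise ValueError("ortholog species must be known")


@dataclass(frozen=True)
class GeneRecord:
    """One parsed SimpleMine row."""

    gene_id: str
    symbol: str
    species: Species
    genetic_interactors: frozenset[str] = frozenset()
    ppi_interactors: frozenset[str] = frozenset()
    orthologs: tuple[OrthologEntry, ...] = ()

    def interactors(self, itype: InteractionType) -> frozenset[str]:
        if itype is InteractionType.PPI:
            return self.ppi_interactors
        return self.genetic_interactors


class GeneDataset:
    """Associative index of :class:`GeneRecord` keyed by gene ID, with a
    per-species secondary index.  Lookup is exact-match on the stored key."""

    def __init__(
        self,
        records: Iterable[GeneRecord],
        provenance: str = "",
    ) -> None:
        self.by_id: dict[str, GeneRecord] = {}
        self.by_species: dict[Species, set[str]] = {}
        self.provenance = provenance
        for rec in records:
            if rec.gene_id in self.by_id:
                raise ValueError(f"duplicate gene_id {rec.gene_id!r}")
            self.by_id[rec.gene_id] = rec
            self.by_species.setdefault(rec.species, set()).add(rec.gene_id)

    def get(self, gene_id: str) -> GeneRecord | None:
        return self.by_id.get(gene_id)

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self.by_id

    def __len__(self) -> int:
        return len(self.by_id)

    def genes_of(self, species: Species) -> tuple[str, ...]:
        return tuple(sorted(self.by_species.get(species, ())))

    def species_present(self) -> tuple[Species, ...]:
        return tuple(
            sorted((s for s in self.by_species if s is not Species.UNKNOWN))
        )


@dataclass
class ParseReport:
    """Bookkeeping from one parse: what was read, skipped or malformed."""

    rows: int = 0
    rows_skipped: int = 0
    preamble_lines: int = 0
    ragged_rows: int = 0
    unparseable_cells: int = 0
    duplicate_ids: list[str] = field(default_factory=list)

    def summary(self) -> str:
        return (
            f"{self.rows} gene rows parsed "
            f"({self.preamble_lines} preamble lines, "
            f"{self.rows_skipped} rows skipped, "
            f"{len(self.duplicate_ids)} duplicate IDs, "
            f"{self.ragged_rows} ragged rows, "
            f"{self.unparseable_cells} unparseable cells)"
        )


class SimpleMineFormatError(ValueError):
    """The input lacks a mandatory column or a recognisable header row."""


def _iter_lines(source: Union[str, Path, IO[str], Iterable[str]]) -> Iterator[str]:
    if isinstance(source, (str, Path)):
        with open(source, "r", encoding="utf-8") as fh:
            yield from fh
    else:
        yield from source


def parse_simplemine_tsv(
    source: Union[str, Path, IO[str], Iterable[str]],
    config: ToolConfig = DEFAULT_CONFIG,
    provenance: str = "",
) -> tuple[GeneDataset, ParseReport]:
    """Parse a SimpleMine-format TSV into a :class:`GeneDataset`.

    Leading preamble lines are skipped until the first line containing the
    configured gene-ID column name; that line is the header.  Mandatory
    columns are located by their configured names, ortholog columns by the
    species named in their headers.  Ragged data rows are padded/truncated
    and counted, never fatal; duplicate gene IDs keep the first occurrence.

    Raises
    ------
    SimpleMineFormatError
        If no header row is found or a mandatory column is absent.
    """
    dialect = config.dialect
    cols = config.columns
    registry = config.registry
    fs = dialect.field_separator

    report = ParseReport()
    lines = _iter_lines(source)

    header_cells: list[str] | None = None
    for line in lines:
        cells = [c.strip() for c in line.rstrip("\r\n").split(fs)]
        if cols.gene_id in cells:
            header_cells = cells
            break
        report.preamble_lines += 1
    if header_cells is None:
        raise SimpleMineFormatError(
            f"no header row containing column {cols.gene_id!r} found"
        )

    index: dict[str, int] = {}
    for name in cols.mandatory():
        try:
            index[name] = header_cells.index(name)
        except ValueError:
            raise SimpleMineFormatError(f"mandatory column {name!r} missing") from None
    ortholog_cols: dict[int, Species] = {}
    for i, cell in enumerate(header_cells):
        sp = registry.species_for_ortholog_column(cell)
        if sp is not Species.UNKNOWN:
            ortholog_cols[i] = sp

    n_cols = len(header_cells)
    records: dict[str, GeneRecord] = {}

    def interactor_set(cell: str) -> frozenset[str]:
        return frozenset(
            config.extract_interactor_id(tok) for tok in dialect.split_values(cell)
        )

    for line in lines:
        raw = line.rstrip("\r\n")
        if not raw.strip():
            report.rows_skipped += 1
            continue
        cells = raw.split(fs)
        if len(cells) != n_cols:
            report.ragged_rows += 1
            cells = (cells + [""] * n_cols)[:n_cols]
        gene_id = cells[index[cols.gene_id]].strip()
        if not gene_id or dialect.is_missing(gene_id):
            report.rows_skipped += 1
            continue
        if gene_id in records:
            report.duplicate_ids.append(gene_id)
            logger.debug("duplicate gene ID %s: keeping first occurrence", gene_id)
            continue

        orthologs: list[OrthologEntry] = []
        seen_orth: set[tuple[Species, str]] = set()
        for col_i, sp in ortholog_cols.items():
            cell = cells[col_i] if col_i < len(cells) else ""
            for value in dialect.split_values(cell):
                parts = value.split(dialect.subfield_separator)
                oid = parts[0].strip()
                osym = parts[1].strip() if len(parts) > 1 else ""
                if not oid or dialect.is_missing(oid):
                    report.unparseable_cells += 1
                    continue
                key = (sp, oid)
                if key not in seen_orth:
                    seen_orth.add(key)
                    orthologs.append(OrthologEntry(sp, oid, osym))

        records[gene_id] = GeneRecord(
            gene_id=gene_id,
            symbol=cells[index[cols.symbol]].strip(),
            species=registry.infer_species(gene_id),
            genetic_interactors=interactor_set(cells[index[cols.genetic]]),
            ppi_interactors=interactor_set(cells[index[cols.ppi]]),
            orthologs=tuple(orthologs),
        )
        report.rows += 1

    return GeneDataset(records.values(), provenance=provenance), report


# ---------------------------------------------------------------------------
# Download request
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class RequestSpec:
    """A fully-specified SimpleMine bulk query: endpoint plus parameters."""

    url: str
    parameters: tuple[tuple[str, str], ...]

    def full_url(self) -> str:
        return self.url + "?" + urllib.parse.urlencode(list(self.parameters))


class TransportError(RuntimeError):
    """The network call itself failed (DNS, connect, HTTP status)."""


class NotTsvError(RuntimeError):
    """The endpoint answered, but not with a tab-separated table."""


def build_download_request(config: ToolConfig = DEFAULT_CONFIG) -> RequestSpec:
    """The preset bulk query: symbol, both interaction sets and every
    ortholog field, for all genes of all species."""
    cols = config.columns
    params: tuple[tuple[str, str], ...] = (
        ("species", "all"),
        ("genes", "all genes"),
        ("field", cols.symbol),
        ("field", cols.genetic),
        ("field", cols.ppi),
        ("field", "All Orthologs"),
    )
    return RequestSpec(url=config.endpoint.url, parameters=params)


def fetch_simplemine(
    request: RequestSpec,
    dest: Union[str, Path] = "simplemine_results.tsv",
    timeout: float = 600.0,
) -> Path:
    """Execute a :class:`RequestSpec` and save the response bytes verbatim.

    Network access is entirely optional to the rest of the package; this is
    the one function that performs it.
    """
    try:
        with urllib.request.urlopen(request.full_url(), timeout=timeout) as resp:
            data = resp.read()
    except (urllib.error.URLError, OSError, ValueError) as exc:
        raise TransportError(f"SimpleMine request failed: {exc}") from exc

    head = data[:4096]
    try:
        text = head.decode("utf-8")
    except UnicodeDecodeError as exc:
        raise NotTsvError("response is not UTF-8 text") from exc
    if "<html" in text.lower() or (text.strip() and "\t" not in text):
        raise NotTsvError("response does not look like a tab-separated table")

    dest = Path(dest)
    dest.write_bytes(data)
    return dest


# ---------------------------------------------------------------------------
# Results table
# ---------------------------------------------------------------------------

RESULT_COLUMNS: tuple[str, ...] = (
    "Gene Symbol",
    "Gene ID",
    "Orthologs",
    "Ortholog Interactors",
    "Predicted Interologs",
    "Reported Interactors",
    "Overlap",
)


def _open_sink(sink: Union[str, Path, IO[str]]):
    if isinstance(sink, (str, Path)):
        return open(sink, "w", encoding="utf-8", newline=""), True
    return sink, False


def write_results_tsv(
    reports: Sequence,
    sink: Union[str, Path, IO[str]],
    config: ToolConfig = DEFAULT_CONFIG,
) -> int:
    """Write one row per :class:`~interolog.engine.GeneReport`.

    Set-valued cells are sorted lexicographically and joined with the value
    separator; ortholog entries are written ``CODE;gene_id;symbol`` and the
    ortholog-interactor map groups each ortholog with its interactors as
    ``ortholog_id;partner1;partner2…``, so the table re-parses losslessly
    with :func:`read_results_tsv`.  Returns the number of data rows written.
    """
    d = config.dialect
    fs, sub = d.field_separator, d.subfield_separator
    fh, close = _open_sink(sink)
    try:
        fh.write(fs.join(RESULT_COLUMNS) + "\n")
        n = 0
        for rep in reports:
            if rep.unknown:
                row = [NOT_FOUND_MARKER, rep.query_id] + [d.join_values(())] * 5
            else:
                orth_cells = [
                    f"{e.species.code}{sub}{e.gene_id}{sub}{e.symbol}"
                    for e in rep.orthologs_used
                ]
                oi_cells = [
                    sub.join([oid] + sorted(partners))
                    for oid, partners in rep.ortholog_interactors.items()
                ]
                row = [
                    rep.query_symbol,
                    rep.query_id,
                    d.join_values(orth_cells),
                    d.join_values(oi_cells),
                    d.join_values(rep.predicted_interologs),
                    d.join_values(rep.reported_interactors),
                    d.join_values(rep.overlap),
                ]
            fh.write(fs.join(row) + "\n")
            n += 1
        return n
    finally:
        if close:
            fh.close()


def read_results_tsv(
    source: Union[str, Path, IO[str], Iterable[str]],
    config: ToolConfig = DEFAULT_CONFIG,
):
    """Inverse of :func:`write_results_tsv`; returns a list of GeneReports."""
    from .engine import GeneReport  # local import avoids a module cycle

    d = config.dialect
    fs, sub = d.field_separator, d.subfield_separator
    lines = _iter_lines(source)
    try:
        header = next(lines).rstrip("\r\n").split(fs)
    except StopIteration:
        raise SimpleMineFormatError("empty results table") from None
    if tuple(header) != RESULT_COLUMNS:
        raise SimpleMineFormatError(f"unexpected results header: {header!r}")

    reports = []
    for line in lines:
        raw = line.rstrip("\r\n")
        if not raw.strip():
            continue
        cells = (raw.split(fs) + [""] * len(RESULT_COLUMNS))[: len(RESULT_COLUMNS)]
        symbol, gene_id = cells[0], cells[1]
        if symbol == NOT_FOUND_MARKER:
            reports.append(
                GeneReport(
                    query_id=gene_id,
                    query_symbol="",
                    query_species=Species.UNKNOWN,
                    unknown=True,
                )
            )
            continue
        orthologs = []
        for value in d.split_values(cells[2]):
            parts = value.split(sub)
            orthologs.append(
                OrthologEntry(
                    Species[parts[0]],
                    parts[1],
                    parts[2] if len(parts) > 2 else "",
                )
            )
        oi: dict[str, frozenset[str]] = {}
        for value in d.split_values(cells[3]):
            parts = value.split(sub)
            oi[parts[0]] = frozenset(p for p in parts[1:] if p)
        reports.append(
            GeneReport(
                query_id=gene_id,
                query_symbol=symbol,
                query_species=config.registry.infer_species(gene_id),
                unknown=False,
                orthologs_used=tuple(orthologs),
                ortholog_interactors=dict(sorted(oi.items())),
                predicted_interologs=frozenset(d.split_values(cells[4])),
                reported_interactors=frozenset(d.split_values(cells[5])),
                overlap=frozenset(d.split_values(cells[6])),
            )
        )
    return reports


# ---------------------------------------------------------------------------
# Genome-wide statistics table
# ---------------------------------------------------------------------------

STATS_COLUMNS: tuple[str, ...] = (
    "Species",
    "Interaction Type",
    "Curated Pairs",
    "Predicted Pairs",
    "Fold Ratio",
)


def write_genome_stats_tsv(
    stats: Sequence,
    sink: Union[str, Path, IO[str]],
    config: ToolConfig = DEFAULT_CONFIG,
) -> int:
    """One row per (species, interaction type): curated count, predicted
    count, predicted/curated fold ratio (empty cell when curated is zero)."""
    fs = config.dialect.field_separator
    fh, close = _open_sink(sink)
    try:
        fh.write(fs.join(STATS_COLUMNS) + "\n")
        n = 0
        for st in stats:
            ratio = "" if st.fold_ratio is None else str(float(st.fold_ratio))
            fh.write(
                fs.join(
                    [
                        st.species.code,
                        st.itype.name,
                        str(st.curated_count),
                        str(st.predicted_count),
                        ratio,
                    ]
                )
                + "\n"
            )
            n += 1
        return n
    finally:
        if close:
            fh.close()


# ---------------------------------------------------------------------------
# Optional HTML rendering (gene IDs linked to their Alliance gene pages)
# ---------------------------------------------------------------------------


def render_results_html(
    reports: Sequence,
    config: ToolConfig = DEFAULT_CONFIG,
) -> str:
    """Render reports as a minimal HTML table with gene-page hyperlinks."""

    def link(gene_id: str) -> str:
        if config.registry.infer_species(gene_id) is Species.UNKNOWN:
            return _html.escape(gene_id)
        url = config.endpoint.gene_page_template.format(gene_id=gene_id)
        return f'<a href="{_html.escape(url)}">{_html.escape(gene_id)}</a>'

    def id_set_cell(ids) -> str:
        return ", ".join(link(i) for i in sorted(ids)) or "&mdash;"

    out = _io.StringIO()
    out.write("<table>\n<tr>")
    for col in RESULT_COLUMNS:
        out.write(f"<th>{_html.escape(col)}</th>")
    out.write("</tr>\n")
    for rep in reports:
        if rep.unknown:
            cells = [_html.escape(NOT_FOUND_MARKER), link(rep.query_id)] + ["&mdash;"] * 5
        else:
            orth = ", ".join(
                f"{e.species.code}:{link(e.gene_id)}" for e in rep.orthologs_used
            ) or "&mdash;"
            oi = "; ".join(
                f"{link(oid)} &rarr; {id_set_cell(p) if p else '&mdash;'}"
                for oid, p in rep.ortholog_interactors.items()
            ) or "&mdash;"
            cells = [
                _html.escape(rep.query_symbol),
                link(rep.query_id),
                orth,
                oi,
                id_set_cell(rep.predicted_interologs),
                id_set_cell(rep.reported_interactors),
                id_set_cell(rep.overlap),
            ]
        out.write("<tr>" + "".join(f"<td>{c}</td>" for c in cells) + "</tr>\n")
    out.write("</table>\n")
    return out.getvalue()
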