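"""Interolog inference by relational composition over orthology.

An interolog is an interaction predicted in one species because the
orthologs of the two partners are known to interact in another species.
Given a query gene *g*, the engine composes three curated relations:

    orthologs of g  →  curated interactors of each ortholog  →
    orthologs of each interactor that lie in g's own species

The species filter restricts which orthologs may serve as evidence donors;
predictions are always mapped back into the query gene's own species so that
they share a namespace with the query's curated interactors and the overlap
between predicted and reported sets is well-defined.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

from .io import GeneDataset, InteractionType, OrthologEntry
from .registry import Species

logger = logging.getLogger(__name__)

__all__ = [
    "InteractionType",
    "GeneReport",
    "UnknownGeneError",
    "clean_query_ids",
    "get_filtered_orthologs",
    "collect_ortholog_interactors",
    "predict_interologs",
    "compute_overlap",
    "analyze",
]

#: A species filter is either None (all species) or a single species code.
SpeciesFilter = Optional[Species]

_QUERY_SPLIT = re.compile(r"[,\n\r;]+")


class UnknownGeneError(KeyError):
    """A gene ID was looked up that is not present in the dataset."""


@dataclass(frozen=True)
class GeneReport:
    """Everything the pipeline derived for one query gene.

    Invariants: ``overlap == predicted_interologs ∩ reported_interactors``;
    every predicted interolog lies in ``query_species``; an ``unknown``
    report carries only empty collections.
    """

    query_id: str
    query_symbol: str
    query_species: Species
    unknown: bool = False
    orthologs_used: tuple[OrthologEntry, ...] = ()
    ortholog_interactors: Mapping[str, frozenset[str]] = field(default_factory=dict)
    predicted_interologs: frozenset[str] = frozenset()
    reported_interactors: frozenset[str] = frozenset()
    overlap: frozenset[str] = frozenset()


def clean_query_ids(raw: str) -> list[str]:
    """Split user query text into gene IDs.

    Commas are the documented separator; newlines and semicolons are also
    accepted.  Tokens are whitespace-trimmed, empties dropped, duplicates
    removed preserving first-seen order.
    """
    seen: dict[str, None] = {}
    for tok in _QUERY_SPLIT.split(raw):
        tok = tok.strip()
        if tok:
            seen.setdefault(tok)
    return list(seen)


def get_filtered_orthologs(
    dataset: GeneDataset,
    gene_id: str,
    species_filter: SpeciesFilter = None,
) -> list[OrthologEntry]:
    """Orthologs of ``gene_id``, optionally restricted to one species.

    Ordered by (species code, gene ID); the query's own ID never appears.
    Raises :class:`UnknownGeneError` when the gene is not in the dataset.
    """
    rec = dataset.get(gene_id)
    if rec is None:
        raise UnknownGeneError(gene_id)
    entries = [
        e
        for e in rec.orthologs
        if e.gene_id != gene_id
        and (species_filter is None or e.species is species_filter)
    ]
    entries.sort(key=lambda e: (e.species.code, e.gene_id))
    return entries


def collect_ortholog_interactors(
    dataset: GeneDataset,
    orthologs: Sequence[OrthologEntry],
    itype: InteractionType,
) -> dict[str, frozenset[str]]:
    """Curated interactors (of the requested type) of each ortholog.

    Orthologs absent from the dataset map to the empty set; that is logged
    but never fatal (truncated files must not crash the analysis).
    """
    out: dict[str, frozenset[str]] = {}
    for entry in orthologs:
        rec = dataset.get(entry.gene_id)
        if rec is None:
            logger.debug("ortholog %s not in dataset; no evidence", entry.gene_id)
            out[entry.gene_id] = frozenset()
        else:
            out[entry.gene_id] = rec.interactors(itype)
    return out


def predict_interologs(
    dataset: GeneDataset,
    query_species: Species,
    ortholog_interactors: Mapping[str, frozenset[str]],
    query_id: str = "",
) -> frozenset[str]:
    """Map ortholog interactors back into the query species.

    For every interactor *x* in the evidence map, every ortholog of *x*
    whose species equals ``query_species`` becomes a predicted interolog
    (paralog fan-out: all such orthologs are kept).  Interactors absent from
    the dataset contribute nothing; the query's own ID is excluded.
    """
    predicted: set[str] = set()
    for partners in ortholog_interactors.values():
        for x in partners:
            rec = dataset.get(x)
            if rec is None:
                continue
            for entry in rec.orthologs:
                if entry.species is query_species:
                    predicted.add(entry.gene_id)
    predicted.discard(query_id)
    return frozenset(predicted)


def compute_overlap(predicted: frozenset[str], reported: frozenset[str]) -> frozenset[str]:
    """Exact intersection of predicted interologs and curated interactors."""
    return frozenset(predicted) & frozenset(reported)


def analyze(
    dataset: GeneDataset,
    raw_query: str,
    itype: InteractionType,
    species_filter: SpeciesFilter = None,
) -> list[GeneReport]:
    """Run the full per-gene pipeline for every ID in ``raw_query``.

    Unknown genes yield a flagged, empty report rather than an error;
    output order follows cleaned input order.  Deterministic given
    (dataset, query, parameters).
    """
    reports: list[GeneReport] = []
    for gene_id in clean_query_ids(raw_query):
        rec = dataset.get(gene_id)
        if rec is None:
            reports.append(
                GeneReport(
                    query_id=gene_id,
                    query_symbol="",
                    query_species=Species.UNKNOWN,
                    unknown=True,
                )
            )
            continue
        orthologs = get_filtered_orthologs(dataset, gene_id, species_filter)
        evidence = collect_ortholog_interactors(dataset, orthologs, itype)
        evidence = dict(sorted(evidence.items()))
        predicted = predict_interologs(dataset, rec.species, evidence, gene_id)
        reported = rec.interactors(itype)
        reports.append(
            GeneReport(
                query_id=gene_id,
                query_symbol=rec.symbol,
                query_species=rec.species,
                unknown=False,
                orthologs_used=tuple(orthologs),
                ortholog_interactors=evidence,
                predicted_interologs=predicted,
                reported_interactors=reported,
                overlap=compute_overlap(predicted, reported),
            )
        )
    return reports
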