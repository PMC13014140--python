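"""Genome-wide curated-vs-predicted interactome comparison.

For each species, count the unique curated interaction pairs recorded in
the dataset and the unique pairs the engine predicts by orthology transfer,
then express the expansion as a fold ratio.  Pairs are unordered and
canonicalised (lexicographically smaller ID first) so mirrored storage of
the same interaction counts once; partners resolving to a different species
have no home in a per-species tally and are excluded (and logged).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

from .engine import (
    SpeciesFilter,
    collect_ortholog_interactors,
    get_filtered_orthologs,
    predict_interologs,
)
from .io import GeneDataset, InteractionType
from .registry import Species

logger = logging.getLogger(__name__)

__all__ = [
    "InteractionPair",
    "SpeciesStats",
    "make_pair",
    "unique_curated_pairs",
    "unique_predicted_pairs",
    "compute_species_stats",
]


@dataclass(frozen=True, order=True)
class InteractionPair:
    """Canonical unordered same-species gene pair (a ≤ b lexicographically)."""

    a: str
    b: str
    itype: InteractionType

    def __post_init__(self) -> None:
        if self.a > self.b:
            raise ValueError("InteractionPair endpoints must be canonically ordered")


def make_pair(x: str, y: str, itype: InteractionType) -> InteractionPair:
    return InteractionPair(min(x, y), max(x, y), itype)


@dataclass(frozen=True)
class SpeciesStats:
    """Per-species expansion summary; fold_ratio is undefined (None) exactly
    when no curated pair exists."""

    species: Species
    itype: InteractionType
    curated_count: int
    predicted_count: int
    fold_ratio: Optional[float]


def _partner_species(dataset: GeneDataset, gene_id: str) -> Species:
    rec = dataset.get(gene_id)
    if rec is not None:
        return rec.species
    # Partner rows can be missing from truncated files; fall back to syntax.
    return Species.UNKNOWN


def unique_curated_pairs(
    dataset: GeneDataset,
    species: Species,
    itype: InteractionType,
) -> set[InteractionPair]:
    """Unique curated pairs among genes of one species.

    Every interactor of every gene of the species contributes the canonical
    pair {gene, interactor} provided the partner also resolves to the same
    species; symmetric duplicates collapse.  Self-pairs are kept if the file
    records them.
    """
    pairs: set[InteractionPair] = set()
    cross_species = 0
    for gene_id in dataset.genes_of(species):
        rec = dataset.by_id[gene_id]
        for partner in rec.interactors(itype):
            if partner == gene_id:
                pairs.add(make_pair(gene_id, partner, itype))
                continue
            if _partner_species(dataset, partner) is species:
                pairs.add(make_pair(gene_id, partner, itype))
            else:
                cross_species += 1
    if cross_species:
        logger.debug(
            "%s/%s: %d interactor references outside the species excluded",
            species.code,
            itype.name,
            cross_species,
        )
    return pairs


def unique_predicted_pairs(
    dataset: GeneDataset,
    species: Species,
    itype: InteractionType,
    species_filter: SpeciesFilter = None,
) -> set[InteractionPair]:
    """Unique pairs predicted by running the engine over every gene of the
    species; each predicted partner p of gene g contributes {g, p}."""
    pairs: set[InteractionPair] = set()
    for gene_id in dataset.genes_of(species):
        orthologs = get_filtered_orthologs(dataset, gene_id, species_filter)
        evidence = collect_ortholog_interactors(dataset, orthologs, itype)
        for partner in predict_interologs(dataset, species, evidence, gene_id):
            pairs.add(make_pair(gene_id, partner, itype))
    return pairs


def compute_species_stats(
    dataset: GeneDataset,
    species_list: Sequence[Species],
    itype: InteractionType,
    species_filter: SpeciesFilter = None,
    novel_only: bool = True,
) -> list[SpeciesStats]:
    """Curated vs predicted unique-pair counts per species.

    With ``novel_only`` the predicted count excludes pairs already curated
    ("newly predicted"); otherwise the full predicted set is counted.
    """
    out: list[SpeciesStats] = []
    for species in species_list:
        curated = unique_curated_pairs(dataset, species, itype)
        predicted = unique_predicted_pairs(dataset, species, itype, species_filter)
        if novel_only:
            predicted = predicted - curated
        ratio = len(predicted) / len(curated) if curated else None
        out.append(
            SpeciesStats(
                species=species,
                itype=itype,
                curated_count=len(curated),
                predicted_count=len(predicted),
                fold_ratio=ratio,
            )
        )
    return out
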