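"""Shared builders for hand-crafted datasets and inline TSV text."""

from __future__ import annotations

import interolog as il
from interolog import GeneDataset, GeneRecord, OrthologEntry, Species

HEADER = "\t".join(
    [
        "Gene ID",
        "Gene Symbol",
        "Genetic Interaction",
        "Protein-Protein Interaction",
        "Caenorhabditis elegans Ortholog",
        "Drosophila melanogaster Ortholog",
    ]
)

PREAMBLE = ("! synthetic preamble line 1", "! synthetic preamble line 2")


def make_tsv(*rows: tuple[str, ...], header: str = HEADER, preamble=PREAMBLE) -> list[str]:
    """Inline SimpleMine-style table as a list of lines."""
    return list(preamble) + [header] + ["\t".join(r) for r in rows]


def rec(
    gene_id: str,
    species: Species,
    symbol: str = "",
    ppi=(),
    genetic=(),
    orthologs=(),
) -> GeneRecord:
    return GeneRecord(
        gene_id=gene_id,
        symbol=symbol or gene_id.split(":")[-1].lower(),
        species=species,
        ppi_interactors=frozenset(ppi),
        genetic_interactors=frozenset(genetic),
        orthologs=tuple(orthologs),
    )


def orth(species: Species, gene_id: str, symbol: str = "") -> OrthologEntry:
    return OrthologEntry(species, gene_id, symbol)


def two_species_chain() -> GeneDataset:
    """Minimal worm/fly dataset: a1~b1, b1–b2 (PPI), b2~a2.

    The canonical interolog example: the fly interaction b1–b2 transfers to
    the worm as a predicted a1–a2 interaction.
    """
    W, F = Species.WB, Species.FB
    return GeneDataset(
        [
            rec("WB:a1", W, orthologs=[orth(F, "FB:b1")], ppi={"WB:a3"}),
            rec("WB:a2", W, orthologs=[orth(F, "FB:b2")]),
            rec("WB:a3", W),
            rec("FB:b1", F, ppi={"FB:b2"}, orthologs=[orth(W, "WB:a1")]),
            rec("FB:b2", F, ppi={"FB:b1"}, orthologs=[orth(W, "WB:a2")]),
        ]
    )
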