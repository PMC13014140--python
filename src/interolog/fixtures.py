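"""Synthetic SimpleMine-style datasets with planted ground truth.

The generator emulates the structure of an Alliance SimpleMine export —
multi-species gene sets, ortholog groups linking them, and per-species
curated interaction networks — with a tunable fraction of interactions
conserved across orthologous partners.  Because the exact planted relations
are returned alongside the file bytes, an independent brute-force oracle can
recompute every quantity the pipeline produces, which is how the package is
tested without any download.

Construction, in order, all driven by one seeded pseudo-random stream:

1. Each species gets ``genes_per_species`` genes with identifiers
   synthesised in that database's real namespace (``WB:WBGene…``,
   ``FBgn…`` …), so identifier→species inference is exercised authentically.
2. Ortholog groups are cliques: each group independently includes each
   species with ``group_span_probability`` and draws one unused gene from
   it; every cross-species member pair becomes an ortholog relation.
3. Each species samples a base interaction network per interaction type
   (``interaction_density`` expected partners per gene).
4. Every base interaction is replicated onto the orthologous gene pair of
   every other species with ``conservation_probability``; final curated
   networks are the union of base and replicated edges.

X. laevis is excluded from the generator's species pool: bare Xenbase gene
identifiers cannot encode the laevis/tropicalis distinction, so a generated
X. laevis row gene could never be re-identified from its ID alone.  The
registry and engine still handle X. laevis fully via ortholog-column headers.

The oracle functions below intentionally share no prediction code with
:mod:`interolog.engine`; they work directly on the planted relations with
exhaustive loops.
"""

from __future__ import annotations

import random
from dataclasses import dataclass
from pathlib import Path
from typing import IO, Mapping, Optional, Sequence, Union

from .config import DEFAULT_CONFIG, ToolConfig
from .io import GeneDataset, InteractionType, ParseReport, parse_simplemine_tsv
from .registry import LATIN_NAMES, Species
from .stats import SpeciesStats

__all__ = [
    "SPECIES_POOL",
    "FixtureSpec",
    "GroundTruth",
    "generate",
    "generate_dataset",
    "write_ground_truth",
    "oracle_predict",
    "oracle_predict_all",
    "oracle_species_stats",
    "conservation_observations",
]

#: Species available to the generator, in deterministic inclusion order.
SPECIES_POOL: tuple[Species, ...] = (
    Species.WB,
    Species.FB,
    Species.SGD,
    Species.ZFIN,
    Species.MGI,
    Species.RGD,
    Species.HGNC,
    Species.XB_XT,
)

_ID_TEMPLATES: dict[Species, str] = {
    Species.WB: "WB:WBGene{:08d}",
    Species.FB: "FB:FBgn{:07d}",
    Species.SGD: "SGD:S{:09d}",
    Species.ZFIN: "ZFIN:ZDB-GENE-{:06d}",
    Species.MGI: "MGI:{:07d}",
    Species.RGD: "RGD:{:07d}",
    Species.HGNC: "HGNC:{:05d}",
    Species.XB_XT: "Xenbase:XB-GENE-{:07d}",
}

Pair = tuple[str, str]


def _canon(x: str, y: str) -> Pair:
    return (x, y) if x <= y else (y, x)


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of one synthetic dataset; identical spec + seed gives
    byte-identical output."""

    n_species: int = 3
    genes_per_species: int = 50
    n_ortholog_groups: int = 30
    group_span_probability: float = 0.9
    interaction_density: float = 2.0
    conservation_probability: float = 0.5
    symmetric_storage: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if not 2 <= self.n_species <= len(SPECIES_POOL):
            raise ValueError(
                f"n_species must be in [2, {len(SPECIES_POOL)}], got {self.n_species}"
            )
        if self.genes_per_species < 1:
            raise ValueError("genes_per_species must be positive")
        if self.n_ortholog_groups < 1:
            raise ValueError("n_ortholog_groups must be positive")
        for name in ("group_span_probability", "conservation_probability"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {p}")
        if self.interaction_density < 0:
            raise ValueError("interaction_density must be non-negative")

    @property
    def species(self) -> tuple[Species, ...]:
        return SPECIES_POOL[: self.n_species]


@dataclass(frozen=True)
class GroundTruth:
    """The exact planted relations behind one generated file."""

    species: tuple[Species, ...]
    genes: Mapping[str, tuple[Species, str]]  # gene_id -> (species, symbol)
    groups: tuple[Mapping[Species, str], ...]
    ortholog_relation: frozenset[Pair]  # cross-species, canonical
    base_interactions: Mapping[InteractionType, frozenset[Pair]]
    interactions: Mapping[InteractionType, frozenset[Pair]]  # base ∪ conserved

    def species_of(self, gene_id: str) -> Species:
        return self.genes[gene_id][0]

    def genes_of(self, species: Species) -> tuple[str, ...]:
        return tuple(
            sorted(g for g, (sp, _) in self.genes.items() if sp is species)
        )


def _gene_ids(spec: FixtureSpec) -> dict[Species, list[str]]:
    out: dict[Species, list[str]] = {}
    for sp in spec.species:
        tmpl = _ID_TEMPLATES[sp]
        out[sp] = [tmpl.format(i) for i in range(1, spec.genes_per_species + 1)]
    return out


def generate(
    spec: FixtureSpec,
    config: ToolConfig = DEFAULT_CONFIG,
) -> tuple[GroundTruth, bytes]:
    """Build the planted relations and render them as SimpleMine-format TSV.

    Returns the ground truth and the file bytes (UTF-8).  Deterministic:
    the same spec always yields the same bytes.
    """
    rng = random.Random(spec.seed)
    species = spec.species
    ids = _gene_ids(spec)

    genes: dict[str, tuple[Species, str]] = {}
    for sp in species:
        for i, gid in enumerate(ids[sp], start=1):
            genes[gid] = (sp, f"{sp.code.lower()}-{i}")

    # Ortholog groups: draw members from shuffled per-species pools so group
    # membership is random but each gene joins at most one group.
    available = {sp: list(ids[sp]) for sp in species}
    for sp in species:
        rng.shuffle(available[sp])
    groups: list[dict[Species, str]] = []
    for _ in range(spec.n_ortholog_groups):
        members: dict[Species, str] = {}
        for sp in species:
            if available[sp] and rng.random() < spec.group_span_probability:
                members[sp] = available[sp].pop()
        groups.append(members)

    ortholog_relation: set[Pair] = set()
    member_of: dict[str, dict[Species, str]] = {}
    for members in groups:
        for gid in members.values():
            member_of[gid] = members
        mm = list(members.values())
        for i, x in enumerate(mm):
            for y in mm[i + 1 :]:
                ortholog_relation.add(_canon(x, y))

    # Base curated networks, one per species and interaction type.
    base: dict[InteractionType, set[Pair]] = {
        InteractionType.PPI: set(),
        InteractionType.GENETIC: set(),
    }
    n = spec.genes_per_species
    max_pairs = n * (n - 1) // 2
    m = min(round(n * spec.interaction_density / 2), max_pairs)
    for itype in (InteractionType.PPI, InteractionType.GENETIC):
        for sp in species:
            pool = ids[sp]
            pairs: set[Pair] = set()
            while len(pairs) < m:
                a, b = rng.sample(pool, 2)
                pairs.add(_canon(a, b))
            base[itype] |= pairs

    # Cross-species replication of each base interaction.
    final: dict[InteractionType, set[Pair]] = {
        it: set(ps) for it, ps in base.items()
    }
    for itype in (InteractionType.PPI, InteractionType.GENETIC):
        for a, b in sorted(base[itype]):
            src = genes[a][0]
            for tgt in species:
                if tgt is src:
                    continue
                ga, gb = member_of.get(a), member_of.get(b)
                if ga is None or gb is None:
                    continue
                at, bt = ga.get(tgt), gb.get(tgt)
                if at is None or bt is None or at == bt:
                    continue
                if rng.random() < spec.conservation_probability:
                    final[itype].add(_canon(at, bt))

    truth = GroundTruth(
        species=species,
        genes=genes,
        groups=tuple(groups),
        ortholog_relation=frozenset(ortholog_relation),
        base_interactions={it: frozenset(ps) for it, ps in base.items()},
        interactions={it: frozenset(ps) for it, ps in final.items()},
    )
    return truth, _render_tsv(spec, truth, config)


def _render_tsv(spec: FixtureSpec, truth: GroundTruth, config: ToolConfig) -> bytes:
    d = config.dialect
    cols = config.columns
    fs, vs, sub = d.field_separator, d.value_separator, d.subfield_separator

    adjacency: dict[InteractionType, dict[str, set[str]]] = {}
    for itype, pairs in truth.interactions.items():
        adj: dict[str, set[str]] = {}
        for a, b in pairs:
            if spec.symmetric_storage:
                adj.setdefault(a, set()).add(b)
                adj.setdefault(b, set()).add(a)
            else:
                adj.setdefault(a, set()).add(b)  # stored on the smaller ID only
        adjacency[itype] = adj

    def cell(values: Sequence[str]) -> str:
        return vs.join(values) if values else "N.A."

    lines = [
        "! Synthetic SimpleMine-style export with planted ortholog groups",
        f"! spec: n_species={spec.n_species} genes_per_species={spec.genes_per_species}"
        f" n_ortholog_groups={spec.n_ortholog_groups}"
        f" group_span_probability={spec.group_span_probability}"
        f" interaction_density={spec.interaction_density}"
        f" conservation_probability={spec.conservation_probability}"
        f" symmetric_storage={spec.symmetric_storage} seed={spec.seed}",
    ]
    header = [cols.gene_id, cols.symbol, cols.genetic, cols.ppi] + [
        f"{LATIN_NAMES[sp]} Ortholog" for sp in truth.species
    ]
    lines.append(fs.join(header))

    member_of: dict[str, Mapping[Species, str]] = {}
    for members in truth.groups:
        for gid in members.values():
            member_of[gid] = members

    for sp in truth.species:
        for gid in truth.genes_of(sp):
            row = [
                gid,
                truth.genes[gid][1],
                cell(sorted(adjacency[InteractionType.GENETIC].get(gid, ()))),
                cell(sorted(adjacency[InteractionType.PPI].get(gid, ()))),
            ]
            members = member_of.get(gid)
            for tgt in truth.species:
                if tgt is sp or members is None or tgt not in members:
                    row.append("N.A.")
                else:
                    oid = members[tgt]
                    row.append(f"{oid}{sub}{truth.genes[oid][1]}")
            lines.append(fs.join(row))
    return ("\n".join(lines) + "\n").encode("utf-8")


def generate_dataset(
    spec: FixtureSpec,
    config: ToolConfig = DEFAULT_CONFIG,
) -> tuple[GroundTruth, GeneDataset, ParseReport]:
    """Generate and immediately parse a fixture (the common test path)."""
    truth, data = generate(spec, config)
    dataset, report = parse_simplemine_tsv(
        data.decode("utf-8").splitlines(), config, provenance=f"fixture seed={spec.seed}"
    )
    return truth, dataset, report


def write_ground_truth(truth: GroundTruth, sink: Union[str, Path, IO[str]]) -> int:
    """Write the planted relations as a tagged tabular text sidecar."""
    lines: list[str] = []
    for gid in sorted(truth.genes):
        sp, sym = truth.genes[gid]
        lines.append(f"GENE\t{gid}\t{sp.code}\t{sym}")
    for a, b in sorted(truth.ortholog_relation):
        lines.append(f"ORTHOLOG\t{a}\t{b}")
    for tag, rel in (("BASE_", truth.base_interactions), ("", truth.interactions)):
        for itype in (InteractionType.PPI, InteractionType.GENETIC):
            for a, b in sorted(rel[itype]):
                lines.append(f"{tag}{itype.name}\t{a}\t{b}")
    text = "\n".join(lines) + "\n"
    if isinstance(sink, (str, Path)):
        Path(sink).write_text(text, encoding="utf-8")
    else:
        sink.write(text)
    return len(lines)


# ---------------------------------------------------------------------------
# Brute-force oracle (no shared code with interolog.engine)
# ---------------------------------------------------------------------------


def _oracle_indexes(truth: GroundTruth, itype: InteractionType):
    orth: dict[str, list[str]] = {}
    for a, b in truth.ortholog_relation:
        orth.setdefault(a, []).append(b)
        orth.setdefault(b, []).append(a)
    inter: dict[str, set[str]] = {}
    for a, b in truth.interactions[itype]:
        inter.setdefault(a, set()).add(b)
        inter.setdefault(b, set()).add(a)
    return orth, inter


def oracle_predict(
    truth: GroundTruth,
    gene_id: str,
    itype: InteractionType,
    species_filter: Optional[Species] = None,
) -> frozenset[str]:
    """Exhaustive relational composition over the planted relations:
    (ortholog of g passing the filter) × (its interactors) × (their
    orthologs in g's species), minus g itself."""
    if gene_id not in truth.genes:
        raise KeyError(gene_id)
    orth, inter = _oracle_indexes(truth, itype)
    return _oracle_one(truth, orth, inter, gene_id, species_filter)


def _oracle_one(truth, orth, inter, gene_id, species_filter) -> frozenset[str]:
    g_sp = truth.species_of(gene_id)
    result: set[str] = set()
    for o in orth.get(gene_id, ()):
        if species_filter is not None and truth.species_of(o) is not species_filter:
            continue
        for x in inter.get(o, ()):
            for a in orth.get(x, ()):
                if truth.species_of(a) is g_sp:
                    result.add(a)
    result.discard(gene_id)
    return frozenset(result)


def oracle_predict_all(
    truth: GroundTruth,
    itype: InteractionType,
    species_filter: Optional[Species] = None,
) -> dict[str, frozenset[str]]:
    """Oracle predictions for every planted gene (indexes built once)."""
    orth, inter = _oracle_indexes(truth, itype)
    return {
        gid: _oracle_one(truth, orth, inter, gid, species_filter)
        for gid in truth.genes
    }


def oracle_species_stats(
    truth: GroundTruth,
    species: Species,
    itype: InteractionType,
    species_filter: Optional[Species] = None,
    novel_only: bool = True,
) -> SpeciesStats:
    """Genome-wide oracle counterpart of
    :func:`interolog.stats.compute_species_stats` for one species."""
    curated = {
        (a, b)
        for a, b in truth.interactions[itype]
        if truth.species_of(a) is species
    }
    predictions = oracle_predict_all(truth, itype, species_filter)
    predicted: set[Pair] = set()
    for gid in truth.genes_of(species):
        for p in predictions[gid]:
            predicted.add(_canon(gid, p))
    if novel_only:
        predicted -= curated
    ratio = len(predicted) / len(curated) if curated else None
    return SpeciesStats(
        species=species,
        itype=itype,
        curated_count=len(curated),
        predicted_count=len(predicted),
        fold_ratio=ratio,
    )


def conservation_observations(truth: GroundTruth) -> tuple[int, int]:
    """Empirical cross-species replication (successes, trials).

    One trial per (base interaction, other species) where both endpoints map
    to a distinct orthologous pair; a success when that pair exists in the
    final network.  Trials whose target pair is already in the target
    species' own base network are excluded as confounded — the copy would
    exist regardless of the replication draw.
    """
    member_of: dict[str, Mapping[Species, str]] = {}
    for members in truth.groups:
        for gid in members.values():
            member_of[gid] = members

    successes = trials = 0
    for itype in (InteractionType.PPI, InteractionType.GENETIC):
        base = truth.base_interactions[itype]
        final = truth.interactions[itype]
        for a, b in base:
            src = truth.species_of(a)
            ga, gb = member_of.get(a), member_of.get(b)
            if ga is None or gb is None:
                continue
            for tgt in truth.species:
                if tgt is src:
                    continue
                at, bt = ga.get(tgt), gb.get(tgt)
                if at is None or bt is None or at == bt:
                    continue
                pair_t = _canon(at, bt)
                if pair_t in base:
                    continue
                trials += 1
                if pair_t in final:
                    successes += 1
    return successes, trials
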