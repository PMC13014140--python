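# interolog

Orthology-based transfer of curated gene interactions across species, driven
by Alliance of Genome Resources SimpleMine gene tables.

## The problem

Curated interaction networks are deep for a handful of intensively studied
organisms (human, mouse, yeast) and sparse for others (zebrafish, *Xenopus*),
even for genes that are well conserved. Because orthologs — genes descended
from a common ancestor through speciation — tend to retain their functions
and interaction partners, a curated interaction in one species is evidence
for the corresponding interaction between the orthologous genes of another.
Such transferred interactions are called **interologs**.

This package predicts interologs from a single SimpleMine export: a
tab-separated table with one row per gene carrying its symbol, curated
genetic interactors, curated protein–protein interactors (PPI), and
per-species ortholog lists across the nine Alliance member databases (SGD,
WB, FB, Xenbase ×2, ZFIN, MGI, RGD, HGNC). It is aimed at researchers who
want to expand a thin interactome by borrowing evidence from better-studied
species, and at anyone who wants the genome-wide curated-vs-predicted
expansion statistics per species.

## The method

For a query gene *g* in species *S* with interaction type *t* ∈ {PPI,
genetic}, the predicted interolog set is the relational composition

```
pred_t(g) = { a : o ∈ orth(g) ∩ filter,  x ∈ int_t(o),  a ∈ orth(x),
              species(a) = S }  \  { g }
```

i.e. take the orthologs of *g* (optionally restricted to one evidence
species), collect their curated interactors, and map each interactor back
into *S* through its own orthologs. The overlap `pred_t(g) ∩ reported_t(g)`
with the query's curated interactors measures how much of the known network
the transfer re-derives. Genome-wide, interactions are counted as canonical
unordered same-species pairs, and the per-species expansion is the fold
ratio `|predicted| / |curated|` (with predicted optionally restricted to
pairs not already curated).

A seeded synthetic-data generator plants multi-species gene sets, ortholog
groups and partially conserved interaction networks in the same file format,
together with an independent brute-force oracle, so the whole pipeline is
testable without any download. See `docs/methods.md` for the model, its
parameters and its limitations.

## Worked example

Generate a small 3-species dataset with known ground truth, predict PPI
partners for two worm genes, then compute genome-wide statistics:

```sh
$ interolog fixture --out demo.tsv --seed 7 --n-species 3 \
      --genes-per-species 20 --n-groups 12
wrote fixture demo.tsv and ground truth demo.tsv.truth.tsv (358 relations)

$ interolog analyze --input demo.tsv \
      --query "WB:WBGene00000001,WB:WBGene00000002" --type ppi \
      --out demo_results.tsv
wrote 2 result rows to demo_results.tsv
```

The first result row (columns abridged) reads:

```
Gene Symbol  Gene ID            Orthologs                 Predicted Interologs              Overlap
wb-1         WB:WBGene00000001  FB;FB:FBgn0000001;fb-1|…  WB:WBGene00000002|WB:WBGene00000003|…  WB:WBGene00000002|WB:WBGene00000006|WB:WBGene00000010|WB:WBGene00000015
```

`wb-1` has orthologs in fly and yeast; mapping their curated PPI partners
back into the worm predicts five interologs, four of which coincide with
`wb-1`'s own curated partners (the Overlap column) — the transfer re-derived
most of the known local network and proposed one new candidate partner.

```sh
$ interolog stats --input demo.tsv --out demo_stats.tsv
wrote 6 statistics rows to demo_stats.tsv
$ head -3 demo_stats.tsv
Species  Interaction Type  Curated Pairs  Predicted Pairs  Fold Ratio
FB       GENETIC           24             6                0.25
FB       PPI               24             3                0.125
```

One row per species and interaction type: unique curated pairs, unique
*newly* predicted pairs (use `--total` to count all predicted pairs), and
their fold ratio. On a real genome-wide SimpleMine export the predicted
counts typically dwarf the curated ones for sparsely annotated species; on
this small half-conserved fixture the expansion is modest by construction.

`interolog fetch` downloads the live genome-wide SimpleMine table (network
required); every other command works entirely offline. All dialect details
(separators, column names, identifier prefixes, endpoint) are overridable
via `--config config.yaml`.

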