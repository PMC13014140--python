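# Methods

## Prediction model

The package treats a SimpleMine export as three relations over genes:
`orth` (cross-species orthology, from the per-species ortholog columns),
`int_t` (curated interaction of type *t* ∈ {PPI, genetic}, from the two
interactor columns), and `species` (from identifier syntax). For a query
gene *g* the predicted interolog set is the composition
`orth ∘ int_t ∘ orth` restricted at the far end to `species(g)`, minus *g*
itself. Assumptions built into this model:

- **Evidence filter vs destination.** The single species parameter filters
  which orthologs may donate evidence; predictions are always mapped back
  into the query gene's own species. This is the only reading under which
  predicted and reported interactors share a namespace, so their overlap —
  the headline per-gene output — is well defined.
- **Paralog fan-out.** When an interactor has several orthologs in the
  query species, all of them are predicted. Orthology here is a relation,
  not a bijection, and the permissive union is the documented choice.
- **Self-predictions are dropped.** An ortholog round trip (g → o → x → g)
  would otherwise mint trivial self-interologs. Curated self-interactions
  in the input are retained in the reported set and in curated pair counts;
  predicted pair sets never contain self-pairs. This is a deliberate,
  documented asymmetry.
- **Stored adjacency is the source of truth.** Interactor cells are read as
  directed adjacency; no symmetric closure is imposed at the record level.
  Genome-wide counting canonicalises to unordered pairs instead, which makes
  the counts invariant to whether a file stores each interaction once or
  mirrored on both rows (a property the tests check explicitly).
- **Single hop.** No ortholog-of-ortholog chaining, no confidence scoring,
  no evidence weighting.

Genome-wide, `unique_curated_pairs` counts canonical same-species pairs
from the stored cells (partners resolving to a different species are
excluded from per-species tallies and logged), and
`unique_predicted_pairs` runs the engine over every gene of the species.
The fold ratio is predicted/curated, undefined (empty output cell) when the
curated count is zero. The default for expansion tables is
`novel_only=True` — predicted pairs already curated are excluded, matching
the "newly predicted" reading; the total is available via a flag because
either convention is defensible.

## Species resolution

Gene identifiers are mapped to species by case-sensitive, start-anchored
prefix rules covering the nine Alliance member-database namespaces; the
table ships as editable config because identifier syntax is a property of
the databases, not of this package. Ortholog-column headers are resolved by
alias lookup (binomial or database name, longest match wins, and only in
headers containing the configured "Ortholog" marker). Xenbase identifiers
are shared by *X. laevis* and *X. tropicalis*: the species of an ortholog
entry comes from its column header, while a Xenbase row gene receives a
configurable default (XB_XT). Both lookups are total — unrecognised input
yields an in-band UNKNOWN, never an exception.

## TSV dialect

The SimpleMine file is "tab-separated" but its intra-cell syntax is a
deployment detail, so it is configuration: values within a cell are split
on `|`, subfields of one value (ortholog `gene_id;symbol`) on `;`, and
`""`/`N.A.`/`NA` are missing tokens. Header detection skips preamble lines
until the first line containing the configured gene-ID column name, which
handles preambles of any length. Duplicate gene IDs keep the first
occurrence and are recorded; ragged rows are padded and counted; neither is
fatal. A configurable regex can extract IDs from decorated interactor cells
(`symbol (ID)`). All set-valued output cells are sorted lexicographically,
which makes every output byte-stable and lets the round-trip tests compare
files by equality. Unknown queries are written with a `NOT_FOUND` symbol
marker so result tables re-parse losslessly.

## Synthetic data generator

`FixtureSpec` plants a dataset from one seeded random stream:

| parameter | default | meaning |
|---|---|---|
| `n_species` | 3 | species drawn in fixed order from an 8-code pool |
| `genes_per_species` | 50 | genes per species, IDs in each database's real namespace |
| `n_ortholog_groups` | 30 | ortholog cliques; each gene joins at most one |
| `group_span_probability` | 0.9 | chance a group includes each species |
| `interaction_density` | 2.0 | expected curated partners per gene, per type |
| `conservation_probability` | 0.5 | chance a base interaction is replicated onto the orthologous pair of each other species |
| `symmetric_storage` | true | store each pair on both rows, or on one |

Each species samples `round(genes × density / 2)` distinct base pairs per
interaction type; each base pair is then replicated into every other
species where both endpoints have group members, with the conservation
probability; final curated networks are the union. The defaults model a
moderately conserved multi-species panel: ~90% group span and 50%
interaction conservation are in the range reported for well-conserved
eukaryotic modules, and density 2–3 keeps per-gene neighbourhoods sparse,
as curated networks are for most genes.

What the generator does *not* emulate: scale-free degree distributions,
correlated annotation depth between species (real curation is heavily
biased toward a few organisms), many-to-many ortholog groups beyond one
gene per species per group, decorated cell syntax, and cross-species
interaction records. Passing tests therefore demonstrate correctness of
the relational machinery on structurally faithful input, not calibration
on real Alliance data — the real-data expansion ratios depend on a large,
version-dependent download and are deliberately outside the test surface.

*X. laevis* is excluded from the generator pool because a bare Xenbase
identifier cannot encode which *Xenopus* species it belongs to; including
it would make generated row genes unrecoverable from their own IDs. The
registry and engine still handle *X. laevis* fully via ortholog-column
headers.

## The oracle

`oracle_predict` re-derives predictions by exhaustive loops directly over
the planted relations and shares no code with the engine, so the central
equivalence test (engine output = oracle output, field by field, across
many seeds at 5 species × 200 genes) is a genuine dual-route check. The
genome-wide oracle counts pairs the same way. Oracle independence is
enforced by module boundary: `fixtures.py` imports nothing from
`engine.py`.

Conservation recovery is measured from generated data as the fraction of
(base interaction, other species) trials whose orthologous pair exists in
the final network, excluding trials whose target pair is already in the
target species' own base network — those successes occur regardless of the
replication draw and would otherwise bias the estimate upward. Replication
from a third species remains a small residual inflation (≤ ~0.5 percentage
points at the test densities), well inside the 99% binomial band used for
the check.

## Numerical and procedural choices

- Canonical pairs order endpoints lexicographically; all iteration in the
  generator runs over sorted structures so one seed gives one byte stream.
- Determinism: identical inputs give byte-identical output files; the CLI
  exposes the generator seed.
- Degenerate inputs (empty query, header-only dataset, missing-value
  cells, duplicate rows, one-sided storage) complete under the documented
  policies rather than raising.
- Exit-code policy: structural faults (missing file, missing mandatory
  column, invalid spec) are nonzero; per-gene issues (unknown query IDs)
  are encoded in the output table with exit 0.
- Problem sizes in the test suite (up to 5 species × 200 genes × 50 seeds)
  were chosen as the smallest at which ortholog groups, conservation and
  both interaction types are all simultaneously exercised with thousands
  of trials; the whole suite runs in well under a minute.

## Known limitations

- No confidence model: every composed path counts equally, though real
  interolog transfer quality varies strongly with orthology confidence and
  evolutionary distance.
- Per-species expansion ratios from one file reflect that file's curation
  snapshot; they are not comparable across SimpleMine versions.
- The live SimpleMine dialect (exact headers, preamble, cell decoration)
  must be matched via config if it differs from the shipped defaults; the
  package makes no attempt to auto-detect it.
- Files are loaded fully into memory; streaming larger-than-memory exports
  is out of scope.
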