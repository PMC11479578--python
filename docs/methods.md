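# Methods

## Scope and model of the data

`sbmlflat` treats an SBML document as three parallel entity sequences —
compartments, species, reactions — and flattens each entity's three data
channels into text:

* **attributes**: the XML attributes of the entity element, preserved
  verbatim (names and values) in document order;
* **notes**: the XHTML `notes` container, reduced to one plain-text
  paragraph per top-level block element, markup stripped, internal
  whitespace collapsed to single spaces;
* **annotation**: the RDF `annotation` container, reduced to an ordered
  mapping from qualifier local name to URI list.

Everything else in the file (unit/function definitions, rules, events,
kinetic laws, Level 3 package extensions) is skipped: the package targets
structural pathway analysis, not simulation, and the three core components
are the part of SBML that has been stable since Level 1. Unrecognized
child elements inside core components are ignored; the parser logs what it
skipped at info level.

### Namespace handling

Elements are matched by local name within the root's namespace. The known
SBML core namespaces (Level 1; Level 2 versions 1–5; Level 3 versions 1–2)
map to their (level, version) pair; root `level`/`version` attributes take
precedence when present. An SBML-like namespace not on the list (e.g. a
future version) is accepted with a logged warning rather than a hard
error, since exporters vary and the document structure is recognizable
regardless. A non-SBML root namespace is a hard `UnsupportedFormatError`.
Level 1's archaic `specie` spellings (element and attribute) are accepted.

The whole document is parsed in memory with `xml.etree.ElementTree`;
pathway-scale files are small, so streaming would add complexity for no
benefit. Parsing is deterministic and order-preserving: the i-th record of
a component corresponds to the i-th element in the file.

### Annotation flattening rules

Within each `rdf:Description`, qualifier elements are dispatched by
namespace:

* biology qualifiers (`bqbiol:*`) keep their local name (`is`, `hasPart`,
  `isHomologTo`, `isDescribedBy`, ...);
* model qualifiers (`bqmodel:*`) are prefixed `bqmodel_` so that e.g.
  `bqmodel:is` can never silently merge with `bqbiol:is`;
* `dcterms:created` / `dcterms:modified` are flattened to their W3CDTF
  text under `created` / `modified`; `dcterms:creator` vCard entries are
  flattened to one string per creator, joining family name, given name,
  email and organization with `", "`. These appear under the same
  `annotation_*` column convention as the biology qualifiers, which keeps
  the "one column per characteristic" rule uniform; note that creator
  strings contain spaces, so the split-on-space inverse applies to URI
  qualifiers only.

URIs are collected recursively below each qualifier element (any
`rdf:resource` attribute, including a bare one on the qualifier itself),
in document order, because exporters disagree on bag nesting depth. A
`rdf:resource` value containing whitespace is dropped with a warning:
the downstream cell convention joins URIs with single spaces, and a
whitespace-bearing value would corrupt the split-inverts-join guarantee
for every other URI in the cell. Qualifiers with zero surviving values
produce no mapping entry, hence no column.

## Table construction

Tables are pandas DataFrames, all cells text (`object` dtype); no type
inference is performed, so stoichiometries and sizes stay strings exactly
as written. The column set of a table is the union of tags observed
across its entities, in first-appearance order: attribute columns first,
then `notes` (if any entity has a paragraph), then `annotation_*` columns.
A tag never defined creates no column; an entity lacking a tag that others
define gets `pandas.NA`, which is distinct from a genuinely empty
attribute value (`""`) and is rendered as an empty field by the CSV/TSV
writers.

Joining conventions: paragraphs with `|`, URIs with a single space. A
pipe character inside a notes paragraph is not escaped; notes joining is
therefore lossy in that corner case (URI joining is not, because URIs
cannot contain whitespace).

`df_species_in_reactions` is built from the concatenation of every
reaction's species references, reaction order first, then within-reaction
list order (reactants, products, modifiers). Each row keeps all observed
reference attributes (a `species` column is guaranteed), then two
appended columns: `reaction_id` and `role`. `role` is exactly one of
`Reactant`, `Product`, `Modifier`, assigned from the enclosing list
element; a species appearing in several lists yields one row per
appearance. `reaction_id` is the owning reaction's `id`, falling back to
its `metaid`, then to a generated `reaction_<ordinal>` label with a
warning — the join key against `df_reactions` must never be missing.

## MIRIAM URI parsing

Three URI shapes are recognized with regular expressions:

| shape | example |
|---|---|
| identifiers.org path | `http://identifiers.org/uniprot/P35869` |
| identifiers.org CURIE | `http://identifiers.org/chebi:CHEBI:17234` |
| legacy URN | `urn:miriam:chebi:CHEBI:17234` |

The collection is lower-cased; the identifier is kept verbatim, including
a namespace prefix like `CHEBI:` (downstream tools disagree on whether
they want it, and keeping it is lossless). CURIE and URN shapes split at
the first colon after the collection. `parse_uri` is total: an
unrecognized string comes back with `collection`/`identifier` unset and
the raw text preserved — a value, not an error. `collect_ids` filters
case-insensitively on the collection and deduplicates keeping first
occurrence, since the resulting vector is used set-like as a filter for
external conversion services.

## Network construction

Two builders operate on `df_species_in_reactions`:

* `bipartite_edges` — one edge per row; reactants and modifiers point
  into the reaction node, products point out of it. This reproduces the
  generic SBML-import graph shape.
* `species_projection` — species as nodes, one directed edge from every
  reactant to every product of each reaction (modifier→product edges
  optional). The direction choice (rather than an undirected "co-occur in
  a reaction" clique) preserves the causal reading of a pathway as a
  digraph; an undirected rendering is a writer concern, not a different
  builder.

Node identity defaults to the species id. Since an SBML species element
belongs to exactly one compartment, distinct ids already encode
compartment separation. With `merge_compartments=True`, species sharing a
display name are collapsed onto one node (the first member's id). The
merge key is the species `name` with a trailing bracketed
`"[compartment]"` suffix stripped — the convention pathway exporters use
to distinguish the same chemical across compartments — falling back to
the id for unnamed species. Merging requires the species table, because
reference rows carry only the species id. A transport reaction (same
chemical, two compartments) therefore yields two nodes and one edge with
compartments preserved, and one node with a self-loop when merged.
Self-loops are always emitted when source equals target.

Parallel edges from distinct reactions are kept, each carrying its
`reaction_id` provenance; `write_edgelist(deduplicate=True)` collapses
them at write time. `relabel_nodes` swaps species ids for any species
column (`name`, `annotation_is`, ...); nodes without a value keep their
id with a warning, and labels never change the edge multiset. GraphML
export goes through networkx `MultiDiGraph` with node `label` and edge
provenance attributes.

Degenerate input: a model without reactions produces a zero-row,
zero-column reference table; both builders return an empty edge list
rather than complaining about absent columns.

## Synthetic data generator

`FixtureSpec`/`make_sbml` emulate pathway-database exports: Level 2/3
namespaces, per-level attribute sets, XHTML notes, RDF annotations whose
qualifiers hold identifiers.org URIs in all three recognized shapes,
drawn from the uniprot/chebi/reactome/pubmed collections (`is` from
uniprot/chebi, `hasPart` from uniprot, `isHomologTo` from reactome,
`isDescribedBy` from pubmed, matching how curated exports use the
qualifiers). Defaults — 2 compartments, 8 species, 4 reactions, 1–3
reactants / 1–2 products / 0–1 modifiers per reaction, 90% of species
carrying a `bqbiol:is` cross-reference, up to 2 note paragraphs, and a
25% transport-reaction rate — are sized after small curated pathway
exports of the kind the converter targets.

The generator builds the ground-truth document first and serializes it,
so the truth record is by construction what a correct parse must return;
the same spec and seed always produce byte-identical XML. Transport
reactions rewrite a claimed pair of species to share a name across two
compartments, exercising the merge behaviour with known truth.

What the generator does *not* emulate: kinetic laws and math, SBO terms,
Level 3 package extensions, vendor-specific annotation dialects, notes
containing pipes or heavy markup, and realistic pathway topology
(reaction participants are sampled uniformly). Passing tests therefore
demonstrate faithful flattening of well-formed Reactome-style structure,
not robustness to every exporter quirk in the wild; the annotation
parser's recursive resource search and the unknown-namespace tolerance
are the two deliberate concessions to dialect variation.

A deterministic hand-written miniature (`data/synthetic_ahr_like.sbml`,
synthetic data) ships with the package: a ligand–receptor–chaperone
complex present in cytosol and nucleoplasm with the transport reaction
between them, plus binding, dimerization and a modifier-carrying
reaction, so the merge-versus-preserve contrast and every role literal
are exercised without randomness.

## Verification sizes

The test suite and `scripts/acceptance.py` use 100 seeded fixtures
(4–12 species, 0–5 reactions each) for ground-truth, round-trip and
convention checks, 20–100 fixtures for the projection edge-count law
against brute-force enumeration, and the shipped miniature for the exact
merge/preserve counts; these sizes make the whole verification run in
seconds while covering every generator code path, and all agreement
rates they report are computed at run time, not asserted constants.

## Known limitations

* Notes joining is lossy if a paragraph contains `|`.
* dcterms creator cells contain spaces and are not split-safe.
* Attribute values are not validated against SBML schemas (non-goal).
* Compartment merging trusts display names; two unrelated species that
  share a name would merge.
* The CLI `convert` command removes partial outputs on failure but does
  not write atomically.
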