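# sbmlflat

Flatten SBML models into tidy tables, MIRIAM identifier vectors and
network edge lists.

## The problem

SBML (Systems Biology Markup Language) is the standard XML format for
exchanging biochemical models, used by pathway databases such as
Reactome. Its three core components — `listOfCompartments`,
`listOfSpecies`, `listOfReactions` — have been stable since Level 1 and
carry the structural description of a pathway, but their deeply nested
XML (attributes, XHTML notes, RDF annotation blocks with
identifiers.org cross-references) is awkward to query directly.

`sbmlflat` converts an SBML document (Levels 1–3) into four tidy
tables, one row per entity and one column per characteristic:

| table | contents |
|---|---|
| `df_compartments` | one row per compartment |
| `df_species` | one row per species |
| `df_reactions` | one row per reaction |
| `df_species_in_reactions` | one row per species appearance in a reaction, plus `reaction_id` and `role` (Reactant / Product / Modifier) |

Column conventions: attribute columns keep the XML attribute name and
verbatim value; a `notes` column joins an entity's XHTML paragraphs
with `|`; each `annotation_<qualifier>` column (e.g. `annotation_is`,
`annotation_hasPart` for the `bqbiol:is` / `bqbiol:hasPart` qualifiers)
joins its URIs with a single space. A column is created only if at
least one entity defines the tag. Because MIRIAM URIs never contain
whitespace, splitting an annotation cell on spaces recovers the URI
list exactly.

From the tables, the package derives:

* **identifier vectors** — parse identifiers.org / `urn:miriam` URIs
  into (collection, identifier) pairs and collect deduplicated
  accessions for one collection (e.g. all UniProt ids in
  `annotation_is`), ready for external conversion services;
* **network edge lists** — the bipartite species–reaction graph, or a
  species–species digraph with one arc per reactant→product pair of
  each reaction, with optional compartment merging (a transport
  reaction moving one chemical between two compartments becomes a
  self-loop) and node relabeling by any species column.

A seeded generator of synthetic Reactome-style SBML documents with
known ground truth makes every step testable offline, and a small
hand-written pathway fixture ships with the package.

Intended users: bioinformaticians who want pathway-database SBML
content in pandas/networkx form without a full SBML simulation stack.
Kinetic laws, units, rules and events are out of scope.

## Worked example

```python
import sbmlflat as sf

tables = sf.as_tables(sf.ahr_like_path())     # shipped synthetic pathway
print(tables.df_species[["id", "name", "compartment"]].to_string(index=False))
```

```
        id                                            name compartment
     s_rec                              receptor [cytosol]       c_cyt
     s_lig                                ligand [cytosol]       c_cyt
s_cplx_cyt     receptor:ligand:chaperone complex [cytosol]       c_cyt
s_cplx_nuc receptor:ligand:chaperone complex [nucleoplasm]       c_nuc
    s_arnt                   nuclear partner [nucleoplasm]       c_nuc
   s_dimer active transcription factor dimer [nucleoplasm]       c_nuc
   s_metab                   oxidized metabolite [cytosol]       c_cyt
```

The complex appears twice — once per compartment. Projecting species
onto a reactant→product digraph keeps the two nodes distinct; merging
compartments collapses them and the transport reaction becomes a
self-loop:

```python
preserved = sf.species_projection(tables.df_species_in_reactions)
merged = sf.species_projection(tables.df_species_in_reactions,
                               tables.df_species, merge_compartments=True)
print([(e.source, e.target) for e in preserved if e.reaction_id == "r_transport"])
print([(e.source, e.target) for e in merged if e.reaction_id == "r_transport"])
```

```
[('s_cplx_cyt', 's_cplx_nuc')]
[('s_cplx_cyt', 's_cplx_cyt')]
```

Extracting the UniProt accessions referenced by `bqbiol:is`:

```python
print(sf.collect_ids(tables.df_species, "annotation_is", "uniprot"))
```

```
['P35869', 'P27540']
```

The same operations are available from the shell:

```sh
sbmlflat convert model.sbml --outdir tables --component all --format csv
sbmlflat edgelist model.sbml --out net.graphml --mode projection \
    --merge-compartments --label name --graph-format graphml
sbmlflat ids model.sbml --qualifier is --collection uniprot --out ids.txt
sbmlflat make-fixture --out synthetic.sbml --n-species 20 --seed 7
```

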