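"""Convert parsed entity records into tidy tables.

A full extraction yields four tables, mirroring the dataframe-per-component
convention common in the R systems-biology ecosystem:

* ``df_compartments`` — one row per compartment;
* ``df_species`` — one row per species;
* ``df_reactions`` — one row per reaction;
* ``df_species_in_reactions`` — one row per species appearance inside a
  reaction, with two additional columns ``reaction_id`` and ``role``.

Column rules
------------
One row per entity, one column per characteristic.  A column exists if
and only if at least one entity defines the corresponding tag:

* attribute columns are named after the attribute and hold its verbatim
  text value;
* a single ``notes`` column joins an entity's paragraphs with ``|``;
* one ``annotation_<qualifier>`` column per observed qualifier joins the
  entity's URIs with a single space (URIs never contain whitespace, so
  splitting on spaces recovers them exactly).

Entities lacking a tag that others define get a missing value
(:data:`MISSING`, rendered as an empty field on write).  Column order is
first-appearance order: attributes, then ``notes``, then ``annotation_*``.
Everything stays text; no type inference is performed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, fields as dataclass_fields
from pathlib import Path
from typing import Iterable, Sequence, Union

import pandas as pd

from .parse import EntityRecord, SbmlDocument, SpeciesRef, read_sbml

logger = logging.getLogger(__name__)

__all__ = ["MISSING", "TableSet", "tabulate_entities", "tabulate_reactions",
           "as_tables", "write_tables"]

#: Missing-value sentinel used in table cells; distinct from the empty
#: string and written as an empty field in CSV/TSV output.
MISSING = pd.NA


@dataclass
class TableSet:
    """The four tables of a full extraction."""

    df_compartments: pd.DataFrame
    df_species: pd.DataFrame
    df_reactions: pd.DataFrame
    df_species_in_reactions: pd.DataFrame

    def __iter__(self):
        return iter(
            (name.name, getattr(self, name.name)) for name in dataclass_fields(self)
        )


def _rows_to_frame(rows: list[dict[str, str]], columns: list[str]) -> pd.DataFrame:
    if not columns:
        return pd.DataFrame()
    df = pd.DataFrame(
        [[row.get(c, MISSING) for c in columns] for row in rows],
        columns=columns,
        dtype="object",
    )
    return df


def _flatten(
    items: Sequence[EntityRecord] | Sequence[SpeciesRef],
) -> tuple[list[str], list[dict[str, str]]]:
    """Shared column-union / cell-join logic for entities and references."""
    attr_cols: list[str] = []
    ann_cols: list[str] = []
    has_notes = False
    rows: list[dict[str, str]] = []
    for item in items:
        row: dict[str, str] = {}
        for name, value in item.attributes.items():
            if name not in attr_cols:
                attr_cols.append(name)
            row[name] = value
        if item.notes:
            has_notes = True
            row["notes"] = "|".join(item.notes)
        for qualifier, uris in item.annotation.items():
            col = f"annotation_{qualifier}"
            if col not in ann_cols:
                ann_cols.append(col)
            row[col] = " ".join(uris)
        rows.append(row)
    columns = attr_cols + (["notes"] if has_notes else []) + ann_cols
    return columns, rows


def tabulate_entities(entities: Sequence[EntityRecord]) -> pd.DataFrame:
    """One row per entity, one column per observed characteristic.

    All entities must share one component kind.  An empty input yields a
    table with zero rows and zero columns ("if the tag is never defined,
    the column is not created" applies to every column).
    """
    kinds = {e.component for e in entities}
    if len(kinds) > 1:
        raise ValueError(f"mixed component kinds in one table: {sorted(kinds)}")
    columns, rows = _flatten(entities)
    return _rows_to_frame(rows, columns)


def _reaction_label(reaction: EntityRecord, ordinal: int) -> str:
    """Join key for species-in-reactions rows; never missing."""
    rid = reaction.attributes.get("id") or reaction.attributes.get("metaid")
    if rid:
        return rid
    logger.warning("reaction #%d lacks id and metaid; generating a label", ordinal)
    return f"reaction_{ordinal}"


def tabulate_reactions(
    reactions: Sequence[EntityRecord],
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Build ``df_reactions`` and ``df_species_in_reactions``.

    The reactions table covers the reaction elements themselves.  The
    species-in-reactions table has one row per species reference, in
    reaction order then within-reaction list order (reactants, products,
    modifiers), with ``reaction_id`` and ``role`` appended after the
    reference's own attribute columns.  The reference's ``species``
    column is always present, so every row identifies its species.
    """
    if any(r.component != "reaction" for r in reactions):
        raise ValueError("tabulate_reactions expects reaction records only")
    reactions_table = tabulate_entities(reactions)

    refs: list[SpeciesRef] = []
    owners: list[str] = []
    for ordinal, reaction in enumerate(reactions):
        label = _reaction_label(reaction, ordinal)
        for ref in reaction.refs:
            attrs = dict(ref.attributes)
            if "species" not in attrs:
                attrs["species"] = ref.species_id
            refs.append(
                SpeciesRef(ref.species_id, ref.role, attrs, ref.notes, ref.annotation)
            )
            owners.append(label)
    columns, rows = _flatten(refs)
    if refs:
        columns = columns + ["reaction_id", "role"]
        for row, owner, ref in zip(rows, owners, refs):
            row["reaction_id"] = owner
            row["role"] = ref.role
    return reactions_table, _rows_to_frame(rows, columns)


def as_tables(doc_or_path: Union[SbmlDocument, str, Path]) -> TableSet:
    """Full extraction: one SBML document → the four tables.

    Components absent from the file yield tables with zero rows and zero
    columns.
    """
    doc = (
        doc_or_path
        if isinstance(doc_or_path, SbmlDocument)
        else read_sbml(doc_or_path)
    )
    df_reactions, df_sir = tabulate_reactions(doc.reactions)
    return TableSet(
        df_compartments=tabulate_entities(doc.compartments),
        df_species=tabulate_entities(doc.species),
        df_reactions=df_reactions,
        df_species_in_reactions=df_sir,
    )


def write_tables(
    tables: TableSet,
    outdir: Union[str, Path],
    fmt: str = "csv",
    components: Iterable[str] = ("compartments", "species", "reactions"),
) -> list[Path]:
    """Write tables to ``<outdir>/df_<name>.<fmt>``; returns written paths.

    ``fmt`` is ``csv`` (RFC 4180 quoting) or ``tsv``.  Missing cells
    become empty fields.  ``components`` selects which tables to write;
    ``reactions`` writes both the reactions and species-in-reactions
    files.
    """
    if fmt not in ("csv", "tsv"):
        raise ValueError(f"unknown table format {fmt!r}; expected 'csv' or 'tsv'")
    sep = "," if fmt == "csv" else "\t"
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    names = {
        "compartments": ["df_compartments"],
        "species": ["df_species"],
        "reactions": ["df_reactions", "df_species_in_reactions"],
    }
    written: list[Path] = []
    for component in components:
        if component not in names:
            raise ValueError(f"unknown component {component!r}")
        for table_name in names[component]:
            df: pd.DataFrame = getattr(tables, table_name)
            path = outdir / f"{table_name}.{fmt}"
            df.to_csv(path, sep=sep, index=False, na_rep="")
            written.append(path)
            logger.info("wrote %s (%d rows, %d columns)", path, len(df), df.shape[1])
    return written
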