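"""Parse and filter MIRIAM / identifiers.org URIs from annotation cells.

SBML annotations cross-reference public databases through URIs that
follow the MIRIAM guidelines.  Three shapes are recognized:

* path style  — ``http://identifiers.org/uniprot/P35869``
* CURIE style — ``http://identifiers.org/chebi:CHEBI:17234``
* legacy URN  — ``urn:miriam:chebi:CHEBI:17234``

Each decomposes into a *collection* (the registry namespace, e.g.
``uniprot``, ``chebi``, ``reactome``, ``pubmed``) and an *identifier*
(the trailing accession, kept verbatim including any ``CHEBI:``-style
prefix).  Anything else is preserved as an opaque reference.  The
resulting clean identifier vectors are what external conversion tools
(Ensembl/biomaRt-style services) take as input.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence, Union

import pandas as pd

__all__ = ["MiriamRef", "split_annotation_cell", "parse_uri", "collect_ids",
           "write_ids"]

_PATH_RE = re.compile(r"^[A-Za-z][A-Za-z0-9+.-]*://identifiers\.org/([^/:]+)/(.+)$")
_CURIE_RE = re.compile(r"^[A-Za-z][A-Za-z0-9+.-]*://identifiers\.org/([^/:]+):(.+)$")
_URN_RE = re.compile(r"^urn:miriam:([^:]+):(.+)$")


@dataclass(frozen=True)
class MiriamRef:
    """One cross-reference URI, decomposed when its shape is recognized.

    ``collection`` is lower-cased; ``identifier`` is verbatim.  For an
    unrecognized shape both are ``None`` and only ``raw`` is kept.
    """

    raw: str
    collection: str | None = None
    identifier: str | None = None


def split_annotation_cell(cell: object) -> list[str]:
    """Split a space-joined annotation cell back into its URI list.

    Missing or empty cells yield ``[]``.  This is the exact inverse of
    the single-space join used when building annotation columns, because
    URIs never contain whitespace.
    """
    if cell is None or pd.isna(cell) or cell == "":
        return []
    return [item for item in str(cell).split(" ") if item]


def parse_uri(uri: str) -> MiriamRef:
    """Decompose one whitespace-free URI; never raises.

    The legacy URN and CURIE shapes split at the first colon after the
    collection, so a namespaced accession like ``CHEBI:17234`` keeps its
    prefix in the identifier.
    """
    for pattern in (_PATH_RE, _CURIE_RE, _URN_RE):
        match = pattern.match(uri)
        if match:
            return MiriamRef(
                raw=uri,
                collection=match.group(1).lower(),
                identifier=match.group(2),
            )
    return MiriamRef(raw=uri)


def collect_ids(
    table: pd.DataFrame, column: str, collection: str
) -> list[str]:
    """Clean identifier vector for one collection from one table column.

    Splits and parses every cell of ``column`` in row order, keeps URIs
    whose collection matches (case-insensitively), and returns their
    identifiers with duplicates removed, first occurrence kept.
    """
    if column not in table.columns:
        raise KeyError(
            f"column {column!r} not in table (have: {list(table.columns)})"
        )
    wanted = collection.lower()
    seen: dict[str, None] = {}
    for cell in table[column]:
        for uri in split_annotation_cell(cell):
            ref = parse_uri(uri)
            if ref.collection == wanted and ref.identifier is not None:
                seen.setdefault(ref.identifier, None)
    return list(seen)


def write_ids(identifiers: Sequence[str], path: Union[str, Path]) -> Path:
    """Write one identifier per line, for hand-off to conversion tools."""
    path = Path(path)
    path.write_text("".join(f"{i}\n" for i in identifiers), encoding="utf-8")
    return path
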