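"""Read SBML XML and materialize its three core components as entity records.

SBML (the Systems Biology Markup Language) organizes a biochemical model
into "components", each a list of entities of one kind.  The three that
have been stable since Level 1 — ``listOfCompartments``, ``listOfSpecies``
and ``listOfReactions`` — carry the structural information of a pathway:
where things are, what they are, and how they transform into each other.
This module parses exactly those three; kinetic laws, unit and function
definitions, rules and events are intentionally skipped.

Each entity contributes three kinds of data:

* *attributes* — XML attributes such as ``id``, ``name``, ``metaid``;
* *notes* — an optional XHTML container with human-readable paragraphs;
* *annotation* — an optional RDF container mapping biology qualifiers
  (``bqbiol:is``, ``bqbiol:hasPart``, ...) to identifiers.org / MIRIAM URIs.

Reactions additionally carry species references: one record per appearance
of a species in the reaction's reactant, product or modifier lists.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Union
import xml.etree.ElementTree as ET

from .annotations import parse_annotation, parse_notes

logger = logging.getLogger(__name__)

__all__ = [
    "SbmlDocument",
    "EntityRecord",
    "SpeciesRef",
    "SbmlError",
    "SbmlParseError",
    "UnsupportedFormatError",
    "read_sbml",
    "extract_component",
]


class SbmlError(Exception):
    """Base class for SBML reading failures."""


class SbmlParseError(SbmlError):
    """The file is not well-formed XML."""


class UnsupportedFormatError(SbmlError):
    """The root element is not ``sbml`` in a recognized SBML namespace."""


#: Known SBML core namespace URIs mapped to (level, version).
SBML_NAMESPACES: dict[str, tuple[int, int]] = {
    "http://www.sbml.org/sbml/level1": (1, 2),
    "http://www.sbml.org/sbml/level2": (2, 1),
    "http://www.sbml.org/sbml/level2/version2": (2, 2),
    "http://www.sbml.org/sbml/level2/version3": (2, 3),
    "http://www.sbml.org/sbml/level2/version4": (2, 4),
    "http://www.sbml.org/sbml/level2/version5": (2, 5),
    "http://www.sbml.org/sbml/level3/version1/core": (3, 1),
    "http://www.sbml.org/sbml/level3/version2/core": (3, 2),
}

_COMPONENTS = ("compartment", "species", "reaction")

#: role literal per enclosing reaction sub-list.
_ROLE_BY_LIST = {
    "listOfReactants": "Reactant",
    "listOfProducts": "Product",
    "listOfModifiers": "Modifier",
}


def _local(tag: str) -> str:
    """Local name of a possibly namespace-qualified ElementTree tag."""
    return tag.rsplit("}", 1)[-1]


def _attributes(elem: ET.Element) -> dict[str, str]:
    # attribute order in ElementTree follows source order; namespaced
    # attributes (rare on core elements) are reduced to their local name.
    return {_local(k): v for k, v in elem.attrib.items()}


@dataclass
class SpeciesRef:
    """A species' participation in one reaction.

    ``role`` is one of the literals ``Reactant``, ``Product`` or
    ``Modifier``, assigned from the enclosing list element.  A species
    appearing in more than one list yields one record per appearance.
    """

    species_id: str
    role: str
    attributes: dict[str, str] = field(default_factory=dict)
    notes: list[str] = field(default_factory=list)
    annotation: dict[str, list[str]] = field(default_factory=dict)


@dataclass
class EntityRecord:
    """One compartment, species or reaction, flattened.

    ``attributes`` preserves XML attribute names and values verbatim in
    document order.  ``notes`` holds one string per XHTML block paragraph.
    ``annotation`` maps qualifier local names (``is``, ``hasPart``, ...)
    to their URI lists in document order.  ``refs`` is populated for
    reactions only.
    """

    component: str
    attributes: dict[str, str] = field(default_factory=dict)
    notes: list[str] = field(default_factory=list)
    annotation: dict[str, list[str]] = field(default_factory=dict)
    refs: list[SpeciesRef] = field(default_factory=list)


@dataclass
class SbmlDocument:
    """Parsed in-memory representation of one SBML file."""

    level: int
    version: int
    model_id: str | None = None
    model_name: str | None = None
    compartments: list[EntityRecord] = field(default_factory=list)
    species: list[EntityRecord] = field(default_factory=list)
    reactions: list[EntityRecord] = field(default_factory=list)


def _find_child(elem: ET.Element, local_names: tuple[str, ...]) -> ET.Element | None:
    for child in elem:
        if _local(child.tag) in local_names:
            return child
    return None


def _parse_entity(elem: ET.Element, component: str) -> EntityRecord:
    rec = EntityRecord(component=component, attributes=_attributes(elem))
    notes_elem = _find_child(elem, ("notes",))
    if notes_elem is not None:
        rec.notes = parse_notes(notes_elem)
    ann_elem = _find_child(elem, ("annotation", "annotations"))
    if ann_elem is not None:
        rec.annotation = parse_annotation(ann_elem)
    return rec


def _parse_species_ref(elem: ET.Element, role: str) -> SpeciesRef:
    attrs = _attributes(elem)
    # Level 1 Version 1 used the attribute name "specie".
    species_id = attrs.get("species") or attrs.get("specie") or ""
    ref = SpeciesRef(species_id=species_id, role=role, attributes=attrs)
    notes_elem = _find_child(elem, ("notes",))
    if notes_elem is not None:
        ref.notes = parse_notes(notes_elem)
    ann_elem = _find_child(elem, ("annotation", "annotations"))
    if ann_elem is not None:
        ref.annotation = parse_annotation(ann_elem)
    return ref


def _parse_reaction(elem: ET.Element) -> EntityRecord:
    rec = _parse_entity(elem, "reaction")
    for child in elem:
        role = _ROLE_BY_LIST.get(_local(child.tag))
        if role is None:
            continue
        for ref_elem in child:
            if _local(ref_elem.tag) in (
                "speciesReference",
                "specieReference",
                "modifierSpeciesReference",
            ):
                rec.refs.append(_parse_species_ref(ref_elem, role))
    return rec


def read_sbml(path: Union[str, Path]) -> SbmlDocument:
    """Parse one SBML file into an :class:`SbmlDocument`.

    Elements are matched by local name within the root's SBML namespace,
    which accommodates exporter dialects across Levels 1-3.  An SBML-like
    namespace not on the known list is accepted with a warning.  Elements
    outside the three core components are skipped.

    Raises
    ------
    FileNotFoundError
        If ``path`` does not exist.
    SbmlParseError
        If the file is not well-formed XML (the message names the line).
    UnsupportedFormatError
        If the root element is not ``sbml`` in an SBML namespace.
    """
    path = Path(path)
    if not path.is_file():
        raise FileNotFoundError(f"no such SBML file: {path}")
    try:
        tree = ET.parse(str(path))
    except ET.ParseError as exc:
        line, col = exc.position
        raise SbmlParseError(
            f"{path}: malformed XML at line {line}, column {col}: {exc}"
        ) from exc
    root = tree.getroot()
    if _local(root.tag) != "sbml":
        raise UnsupportedFormatError(
            f"{path}: root element is <{_local(root.tag)}>, expected <sbml>"
        )
    ns = root.tag[1:].rsplit("}", 1)[0] if root.tag.startswith("{") else ""
    level_version = SBML_NAMESPACES.get(ns)
    if level_version is None:
        if ns.startswith("http://www.sbml.org/sbml"):
            logger.warning("unknown SBML namespace %r, attempting parse anyway", ns)
            level_version = (0, 0)
        else:
            raise UnsupportedFormatError(
                f"{path}: root namespace {ns!r} is not a recognized SBML namespace"
            )
    # root attributes take precedence over the namespace-implied edition
    level = int(root.get("level", level_version[0]))
    version = int(root.get("version", level_version[1]))

    model = _find_child(root, ("model",))
    doc = SbmlDocument(level=level, version=version)
    if model is None:
        logger.warning("%s: no <model> element; document is empty", path)
        return doc
    doc.model_id = model.get("id") or model.get("name")
    doc.model_name = model.get("name")

    skipped: dict[str, int] = {}
    for child in model:
        name = _local(child.tag)
        if name == "listOfCompartments":
            doc.compartments = [
                _parse_entity(e, "compartment")
                for e in child
                if _local(e.tag) == "compartment"
            ]
        elif name == "listOfSpecies":
            doc.species = [
                _parse_entity(e, "species")
                for e in child
                if _local(e.tag) in ("species", "specie")
            ]
        elif name == "listOfReactions":
            doc.reactions = [
                _parse_reaction(e) for e in child if _local(e.tag) == "reaction"
            ]
        elif name in ("notes", "annotation"):
            continue  # model-level metadata, not an entity component
        else:
            skipped[name] = skipped.get(name, 0) + 1
    if skipped:
        logger.info(
            "%s: skipped non-core model children: %s",
            path,
            ", ".join(sorted(skipped)),
        )
    logger.info(
        "%s: SBML L%dV%d, %d compartments, %d species, %d reactions",
        path,
        level,
        version,
        len(doc.compartments),
        len(doc.species),
        len(doc.reactions),
    )
    return doc


def extract_component(
    doc_or_path: Union[SbmlDocument, str, Path], which: str = "all"
) -> SbmlDocument:
    """Restrict a document to one component, or keep all three.

    ``which`` is one of ``all``, ``compartments``, ``species``,
    ``reactions``.  With ``all`` the document is returned unchanged; the
    operation is idempotent.
    """
    if which not in ("all", "compartments", "species", "reactions"):
        raise ValueError(
            f"unknown component {which!r}; expected one of "
            "'all', 'compartments', 'species', 'reactions'"
        )
    doc = (
        doc_or_path
        if isinstance(doc_or_path, SbmlDocument)
        else read_sbml(doc_or_path)
    )
    if which == "all":
        return doc
    restricted = SbmlDocument(
        level=doc.level,
        version=doc.version,
        model_id=doc.model_id,
        model_name=doc.model_name,
    )
    setattr(restricted, which, list(getattr(doc, which)))
    return restricted
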