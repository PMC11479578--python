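"""Flatten SBML Notes (XHTML) and Annotation (RDF) subtrees.

Notes become an ordered list of plain-text paragraphs, one per top-level
XHTML block element, with markup stripped and whitespace normalized.

Annotations follow the MIRIAM convention: an ``rdf:RDF`` element whose
``rdf:Description`` children hold qualifier elements from the biomodels
biology- and model-qualifier namespaces (``bqbiol:is``, ``bqbiol:hasPart``,
``bqbiol:isHomologTo``, ``bqbiol:isDescribedBy``, ``bqmodel:is``, ...),
each wrapping a bag of ``rdf:li`` resources pointing at identifiers.org
URIs.  Document metadata (``dcterms:creator`` / ``created`` / ``modified``)
is flattened to text values under its local names.
"""

from __future__ import annotations

import logging
import xml.etree.ElementTree as ET

logger = logging.getLogger(__name__)

__all__ = ["parse_notes", "parse_annotation"]

RDF_NS = "http://www.w3.org/1999/02/22-rdf-syntax-ns#"
BQBIOL_NS = "http://biomodels.net/biology-qualifiers/"
BQMODEL_NS = "http://biomodels.net/model-qualifiers/"
DCTERMS_NS = "http://purl.org/dc/terms/"
DC_NS = "http://purl.org/dc/elements/1.1/"
VCARD_NS = "http://www.w3.org/2001/vcard-rdf/3.0#"
VCARD4_NS = "http://www.w3.org/2006/vcard/ns#"

_RDF_RESOURCE = f"{{{RDF_NS}}}resource"


def _local(tag: str) -> str:
    return tag.rsplit("}", 1)[-1]


def _ns(tag: str) -> str:
    return tag[1:].rsplit("}", 1)[0] if tag.startswith("{") else ""


def _collapse(text: str) -> str:
    return " ".join(text.split())


def parse_notes(notes_subtree: ET.Element | None) -> list[str]:
    """Flatten a ``notes`` subtree into ordered text paragraphs.

    One item is produced per top-level XHTML block element (each ``p``,
    ``div``, ... — for a ``body`` wrapper, its direct children), in
    document order.  Inline markup is stripped and internal whitespace
    collapsed to single spaces.  Absent or empty notes yield ``[]``.
    """
    if notes_subtree is None:
        return []
    blocks = list(notes_subtree)
    # a single <body> (or <html>) wrapper is transparent
    while len(blocks) == 1 and _local(blocks[0].tag) in ("body", "html"):
        blocks = list(blocks[0])
    paragraphs: list[str] = []
    if not blocks:
        # bare text directly inside <notes>: tolerated, one paragraph
        text = _collapse("".join(notes_subtree.itertext()))
        if text:
            logger.warning("notes element holds bare text without XHTML blocks")
            paragraphs.append(text)
        return paragraphs
    for block in blocks:
        text = _collapse("".join(block.itertext()))
        if text:
            paragraphs.append(text)
    return paragraphs


def _resources(qualifier_elem: ET.Element) -> list[str]:
    """All rdf:resource URIs under a qualifier element, document order.

    Searches recursively, so bags nested deeper than one RDF level are
    still found (exporter dialects vary).  Skips empty or whitespace-
    containing values, which would not survive the space-joined cell
    convention downstream.
    """
    uris: list[str] = []
    for elem in qualifier_elem.iter():
        uri = elem.get(_RDF_RESOURCE)
        if uri is None:
            continue
        if not uri or any(ch.isspace() for ch in uri):
            logger.warning("ignoring malformed rdf:resource %r", uri)
            continue
        uris.append(uri)
    return uris


def _flatten_creator(creator_elem: ET.Element) -> list[str]:
    """Flatten dcterms:creator vCard entries to one string per creator."""
    entries = [
        li for li in creator_elem.iter() if li.tag == f"{{{RDF_NS}}}li"
    ] or [creator_elem]
    values = []
    for entry in entries:
        parts: dict[str, str] = {}
        for elem in entry.iter():
            name = _local(elem.tag)
            if name in ("Family", "Given", "Orgname") and elem.text:
                parts[name] = _collapse(elem.text)
            elif name in ("EMAIL", "Email") and elem.text:
                parts["EMAIL"] = _collapse(elem.text)
        ordered = [parts[k] for k in ("Family", "Given", "EMAIL", "Orgname") if k in parts]
        if not ordered:
            text = _collapse("".join(entry.itertext()))
            ordered = [text] if text else []
        if ordered:
            values.append(", ".join(ordered))
    return values


def parse_annotation(annotation_subtree: ET.Element | None) -> dict[str, list[str]]:
    """Flatten an ``annotation`` subtree into qualifier → URI-list mapping.

    Keys are qualifier local names; a ``bqmodel`` qualifier is prefixed
    ``bqmodel_`` so it cannot silently merge with the ``bqbiol`` qualifier
    of the same local name.  ``dcterms`` creator/created/modified content
    is collected as text values under ``creator`` / ``created`` /
    ``modified``.  Qualifiers that yield zero values are omitted; an
    absent annotation yields ``{}``.
    """
    if annotation_subtree is None:
        return {}
    mapping: dict[str, list[str]] = {}

    def add(key: str, values: list[str]) -> None:
        if values:
            mapping.setdefault(key, []).extend(values)

    rdf_roots = [e for e in annotation_subtree.iter(f"{{{RDF_NS}}}RDF")]
    non_rdf = [c for c in annotation_subtree if _local(c.tag) != "RDF"]
    if non_rdf and not rdf_roots:
        logger.warning(
            "annotation holds no RDF content; skipping %d non-RDF children",
            len(non_rdf),
        )
    for rdf in rdf_roots:
        for desc in rdf:
            if _local(desc.tag) != "Description":
                continue
            for qualifier in desc:
                qns, qname = _ns(qualifier.tag), _local(qualifier.tag)
                if qns == BQBIOL_NS:
                    add(qname, _resources(qualifier))
                elif qns == BQMODEL_NS:
                    add(f"bqmodel_{qname}", _resources(qualifier))
                elif qns in (DCTERMS_NS, DC_NS):
                    if qname == "creator":
                        add("creator", _flatten_creator(qualifier))
                    elif qname in ("created", "modified"):
                        text = _collapse("".join(qualifier.itertext()))
                        add(qname, [text] if text else [])
                    else:
                        logger.debug("skipping dcterms qualifier %r", qname)
                else:
                    logger.debug("skipping unrecognized qualifier %r", qualifier.tag)
    return mapping
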