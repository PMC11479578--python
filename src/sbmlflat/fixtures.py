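"""Seeded generator of valid synthetic SBML documents with known ground truth.

Emulates pathway-database exports (Reactome-style): nested
``listOfCompartments`` / ``listOfSpecies`` / ``listOfReactions``, RDF
annotations whose biology qualifiers hold identifiers.org URIs, and
XHTML notes.  The generator returns both the serialized XML text and
the exact :class:`~sbmlflat.parse.SbmlDocument` a parse of that text
must reproduce, so every downstream module is testable without network
access.  The same spec and seed always yield byte-identical output.

Cross-compartment transport — the situation where one chemical species
is represented by two SBML species elements with the same display name
in different compartments, linked by a reaction — is generated at a
configurable rate, since it drives the merge-versus-preserve behaviour
of the species projection.

A small deterministic hand-written pathway fixture with the same shape
(a receptor complex present in cytosol and nucleoplasm plus the
transport reaction between them) ships with the package; see
:func:`ahr_like_path`.  It is synthetic data, not a database export.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Union
from xml.sax.saxutils import escape, quoteattr

from .parse import EntityRecord, SbmlDocument, SpeciesRef

__all__ = ["FixtureSpec", "make_sbml", "write_fixture", "ahr_like_path"]

_SBML_NS = {
    (2, 1): "http://www.sbml.org/sbml/level2",
    (2, 2): "http://www.sbml.org/sbml/level2/version2",
    (2, 3): "http://www.sbml.org/sbml/level2/version3",
    (2, 4): "http://www.sbml.org/sbml/level2/version4",
    (2, 5): "http://www.sbml.org/sbml/level2/version5",
    (3, 1): "http://www.sbml.org/sbml/level3/version1/core",
    (3, 2): "http://www.sbml.org/sbml/level3/version2/core",
}

_COMPARTMENT_NAMES = [
    "cytosol",
    "nucleoplasm",
    "extracellular region",
    "plasma membrane",
    "endoplasmic reticulum lumen",
    "mitochondrial matrix",
]

_SPECIES_STEMS = [
    "receptor complex",
    "ligand",
    "chaperone",
    "kinase",
    "transcription factor",
    "metabolite",
    "adaptor protein",
    "enzyme",
]

#: qualifier → collections its URIs are drawn from
_QUALIFIER_COLLECTIONS = {
    "is": ["uniprot", "chebi"],
    "hasPart": ["uniprot"],
    "isHomologTo": ["reactome"],
    "isDescribedBy": ["pubmed"],
}

#: default per-qualifier (probability, (min URIs, max URIs)) for species
_DEFAULT_ANNOTATION_PROFILE = {
    "is": (0.9, (1, 2)),
    "hasPart": (0.35, (2, 3)),
    "isHomologTo": (0.15, (1, 1)),
    "isDescribedBy": (0.3, (1, 2)),
}


@dataclass
class FixtureSpec:
    """Parameters of one synthetic SBML document.

    ``annotation_profile`` maps qualifier local names to a (probability,
    (min, max) URI count) pair applied per species; compartments and
    reactions receive fixed modest annotation rates.  ``notes_profile``
    is the (min, max) paragraph count per species/reaction (0 allowed).
    ``roles_profile`` gives (min, max) counts of reactants, products and
    modifiers per reaction.  ``cross_compartment_rate`` is the
    probability that a reaction is generated as a transport: same-named
    species in two compartments, reactant in one and product in the
    other.
    """

    level: int = 3
    version: int = 1
    n_compartments: int = 2
    n_species: int = 8
    n_reactions: int = 4
    annotation_profile: dict[str, tuple[float, tuple[int, int]]] = field(
        default_factory=lambda: dict(_DEFAULT_ANNOTATION_PROFILE)
    )
    notes_profile: tuple[int, int] = (0, 2)
    roles_profile: dict[str, tuple[int, int]] = field(
        default_factory=lambda: {
            "reactants": (1, 3),
            "products": (1, 2),
            "modifiers": (0, 1),
        }
    )
    cross_compartment_rate: float = 0.25
    seed: int = 0

    def validate(self) -> None:
        if self.level not in (2, 3):
            raise ValueError(f"level must be 2 or 3, got {self.level}")
        if (self.level, self.version) not in _SBML_NS:
            raise ValueError(
                f"no SBML namespace for Level {self.level} Version {self.version}"
            )
        for name in ("n_compartments", "n_species", "n_reactions"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0.0 <= self.cross_compartment_rate <= 1.0:
            raise ValueError("cross_compartment_rate must be in [0, 1]")
        for qualifier, (prob, (lo, hi)) in self.annotation_profile.items():
            if qualifier not in _QUALIFIER_COLLECTIONS:
                raise ValueError(f"unknown annotation qualifier {qualifier!r}")
            if not 0.0 <= prob <= 1.0 or lo < 0 or lo > hi:
                raise ValueError(f"bad annotation profile for {qualifier!r}")
        lo, hi = self.notes_profile
        if lo < 0 or lo > hi:
            raise ValueError("bad notes_profile range")
        for role, (lo, hi) in self.roles_profile.items():
            if role not in ("reactants", "products", "modifiers"):
                raise ValueError(f"unknown role key {role!r}")
            if lo < 0 or lo > hi:
                raise ValueError(f"bad roles_profile range for {role!r}")


def _identifier(rng: random.Random, collection: str) -> str:
    if collection == "uniprot":
        return "P" + "".join(rng.choices("0123456789", k=5))
    if collection == "chebi":
        return "CHEBI:" + str(rng.randint(10000, 99999))
    if collection == "reactome":
        return "R-HSA-" + str(rng.randint(1000000, 9999999))
    return str(rng.randint(10000000, 99999999))  # pubmed


def _uri(rng: random.Random, collection: str) -> str:
    identifier = _identifier(rng, collection)
    shape = rng.randrange(3)
    if shape == 0:
        return f"http://identifiers.org/{collection}/{identifier}"
    if shape == 1:
        return f"http://identifiers.org/{collection}:{identifier}"
    return f"urn:miriam:{collection}:{identifier}"


def _annotation(
    rng: random.Random,
    profile: dict[str, tuple[float, tuple[int, int]]],
) -> dict[str, list[str]]:
    mapping: dict[str, list[str]] = {}
    for qualifier, (prob, (lo, hi)) in profile.items():
        if rng.random() < prob:
            count = rng.randint(lo, hi)
            collections = _QUALIFIER_COLLECTIONS[qualifier]
            uris = [_uri(rng, rng.choice(collections)) for _ in range(count)]
            if uris:
                mapping[qualifier] = uris
    return mapping


def _notes(rng: random.Random, profile: tuple[int, int], context: str) -> list[str]:
    count = rng.randint(*profile)
    return [
        f"Synthetic note paragraph {i + 1} about the {context}."
        for i in range(count)
    ]


def make_sbml(spec: FixtureSpec) -> tuple[str, SbmlDocument]:
    """Generate one synthetic SBML document.

    Returns ``(sbml_text, truth)`` where ``truth`` is the exact document
    :func:`~sbmlflat.parse.read_sbml` must produce from ``sbml_text``.
    """
    spec.validate()
    rng = random.Random(spec.seed)
    level, version = spec.level, spec.version
    doc = SbmlDocument(level=level, version=version)
    doc.model_id = f"model_{spec.seed}"
    doc.model_name = "synthetic pathway"

    compartment_ids = [f"c{i}" for i in range(spec.n_compartments)]
    for i, cid in enumerate(compartment_ids):
        attrs = {
            "metaid": f"metaid_{cid}",
            "id": cid,
            "name": _COMPARTMENT_NAMES[i % len(_COMPARTMENT_NAMES)],
            "size": "1",
        }
        if level == 3:
            attrs["spatialDimensions"] = "3"
            attrs["constant"] = "true"
        rec = EntityRecord(component="compartment", attributes=attrs)
        if rng.random() < 0.5:
            rec.annotation = {"is": [_uri(rng, "reactome")]}
        doc.compartments.append(rec)

    species_ids = [f"s{i}" for i in range(spec.n_species)]
    for i, sid in enumerate(species_ids):
        stem = _SPECIES_STEMS[i % len(_SPECIES_STEMS)]
        attrs = {
            "metaid": f"metaid_{sid}",
            "id": sid,
            "name": f"{stem} {i}",
        }
        if compartment_ids:
            attrs["compartment"] = rng.choice(compartment_ids)
        if level == 3:
            attrs["hasOnlySubstanceUnits"] = "false"
            attrs["boundaryCondition"] = "false"
            attrs["constant"] = "false"
        rec = EntityRecord(component="species", attributes=attrs)
        rec.notes = _notes(rng, spec.notes_profile, f"{stem} {i}")
        rec.annotation = _annotation(rng, spec.annotation_profile)
        doc.species.append(rec)

    # decide transport reactions up front: each claims a species pair that
    # is rewritten to share a name across two different compartments
    transports: dict[int, tuple[str, str]] = {}
    if spec.n_compartments >= 2 and spec.n_species >= 2:
        free = list(range(spec.n_species))
        for r in range(spec.n_reactions):
            if len(free) >= 2 and rng.random() < spec.cross_compartment_rate:
                a, b = rng.sample(free, 2)
                free.remove(a)
                free.remove(b)
                rec_a, rec_b = doc.species[a], doc.species[b]
                rec_b.attributes["name"] = rec_a.attributes["name"]
                c_from = rec_a.attributes.get("compartment", compartment_ids[0])
                c_to = rng.choice([c for c in compartment_ids if c != c_from])
                rec_a.attributes["compartment"] = c_from
                rec_b.attributes["compartment"] = c_to
                transports[r] = (species_ids[a], species_ids[b])

    def _ref(sid: str, role: str) -> SpeciesRef:
        attrs = {"species": sid}
        if role != "Modifier":
            attrs["stoichiometry"] = "1"
            if level == 3:
                attrs["constant"] = "true"
        return SpeciesRef(species_id=sid, role=role, attributes=attrs)

    for r in range(spec.n_reactions):
        rid = f"r{r}"
        attrs = {
            "metaid": f"metaid_{rid}",
            "id": rid,
            "name": f"reaction {r}",
            "reversible": "false",
        }
        if (level, version) == (3, 1):
            attrs["fast"] = "false"
        rec = EntityRecord(component="reaction", attributes=attrs)
        rec.notes = _notes(rng, spec.notes_profile, f"reaction {r}")
        if rng.random() < 0.5:
            rec.annotation = {"isDescribedBy": [_uri(rng, "pubmed")]}
        if r in transports:
            source, target = transports[r]
            rec.refs = [_ref(source, "Reactant"), _ref(target, "Product")]
        elif species_ids:
            counts = {
                role: min(rng.randint(lo, hi), len(species_ids))
                for role, (lo, hi) in spec.roles_profile.items()
            }
            for role_key, literal in (
                ("reactants", "Reactant"),
                ("products", "Product"),
                ("modifiers", "Modifier"),
            ):
                for sid in rng.sample(species_ids, counts.get(role_key, 0)):
                    rec.refs.append(_ref(sid, literal))
        doc.reactions.append(rec)

    return _serialize(doc), doc


def _serialize(doc: SbmlDocument) -> str:
    ns = _SBML_NS[(doc.level, doc.version)]
    out: list[str] = ['<?xml version="1.0" encoding="UTF-8"?>\n']
    out.append(
        f'<sbml xmlns={quoteattr(ns)} level="{doc.level}" version="{doc.version}">\n'
    )
    out.append(
        f"  <model id={quoteattr(doc.model_id or 'model')}"
        f" name={quoteattr(doc.model_name or 'model')}>\n"
    )

    def attrs_str(attributes: dict[str, str]) -> str:
        return "".join(f" {k}={quoteattr(v)}" for k, v in attributes.items())

    def entity_body(rec: EntityRecord, indent: str) -> list[str]:
        parts: list[str] = []
        if rec.notes:
            parts.append(
                f'{indent}<notes><body xmlns="http://www.w3.org/1999/xhtml">'
            )
            for paragraph in rec.notes:
                parts.append(f"<p>{escape(paragraph)}</p>")
            parts.append("</body></notes>\n")
        if rec.annotation:
            metaid = rec.attributes.get("metaid", "")
            parts.append(
                f"{indent}<annotation>\n"
                f'{indent}  <rdf:RDF xmlns:rdf="http://www.w3.org/1999/02/22-rdf-syntax-ns#"'
                ' xmlns:bqbiol="http://biomodels.net/biology-qualifiers/">\n'
                f"{indent}    <rdf:Description rdf:about={quoteattr('#' + metaid)}>\n"
            )
            for qualifier, uris in rec.annotation.items():
                parts.append(f"{indent}      <bqbiol:{qualifier}><rdf:Bag>")
                for uri in uris:
                    parts.append(f"<rdf:li rdf:resource={quoteattr(uri)}/>")
                parts.append(f"</rdf:Bag></bqbiol:{qualifier}>\n")
            parts.append(
                f"{indent}    </rdf:Description>\n"
                f"{indent}  </rdf:RDF>\n"
                f"{indent}</annotation>\n"
            )
        return parts

    def emit_entities(
        tag: str, list_tag: str, records: list[EntityRecord]
    ) -> None:
        if not records:
            return
        out.append(f"    <{list_tag}>\n")
        for rec in records:
            body = entity_body(rec, "        ")
            if body or rec.refs:
                out.append(f"      <{tag}{attrs_str(rec.attributes)}>\n")
                out.extend(body)
                if rec.refs:
                    for role_list, literal, ref_tag in (
                        ("listOfReactants", "Reactant", "speciesReference"),
                        ("listOfProducts", "Product", "speciesReference"),
                        ("listOfModifiers", "Modifier", "modifierSpeciesReference"),
                    ):
                        refs = [r for r in rec.refs if r.role == literal]
                        if refs:
                            out.append(f"        <{role_list}>\n")
                            for ref in refs:
                                out.append(
                                    f"          <{ref_tag}{attrs_str(ref.attributes)}/>\n"
                                )
                            out.append(f"        </{role_list}>\n")
                out.append(f"      </{tag}>\n")
            else:
                out.append(f"      <{tag}{attrs_str(rec.attributes)}/>\n")
        out.append(f"    </{list_tag}>\n")

    emit_entities("compartment", "listOfCompartments", doc.compartments)
    emit_entities("species", "listOfSpecies", doc.species)
    emit_entities("reaction", "listOfReactions", doc.reactions)
    out.append("  </model>\n</sbml>\n")
    return "".join(out)


def write_fixture(spec: FixtureSpec, path: Union[str, Path]) -> SbmlDocument:
    """Write a generated fixture to ``path``; returns its ground truth."""
    text, truth = make_sbml(spec)
    Path(path).write_text(text, encoding="utf-8")
    return truth


def ahr_like_path() -> Path:
    """Path of the shipped deterministic synthetic pathway fixture.

    A hand-written miniature modelled on a receptor-signalling pathway:
    a ligand-receptor-chaperone complex exists in both the cytosol and
    the nucleoplasm (two species elements sharing one display name) and
    a transport reaction links them — the input that distinguishes the
    compartment-preserving and compartment-merging projections.
    """
    return Path(
        str(resources.files("sbmlflat").joinpath("data/synthetic_ahr_like.sbml"))
    )
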