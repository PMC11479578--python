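"""Shared fixtures and the independent raw-text oracle.

The oracle deliberately avoids the package's XML machinery: it counts
element starts and extracts rdf:resource values with regular expressions
over the raw bytes, so structural assertions are checked against a
source the parser cannot influence.
"""

from __future__ import annotations

import re
from pathlib import Path

import pytest

from sbmlflat import FixtureSpec, ahr_like_path, as_tables, make_sbml, read_sbml

ELEMENT_RE = {
    "compartments": re.compile(r"<compartment[\s/>]"),
    "species": re.compile(r"<species[\s/>]"),
    "reactions": re.compile(r"<reaction[\s/>]"),
    "refs": re.compile(r"<(?:speciesReference|modifierSpeciesReference)[\s/>]"),
}

RESOURCE_RE = re.compile(r'rdf:resource="([^"]*)"')


def raw_counts(sbml_text: str) -> dict[str, int]:
    """Entity counts per component from a plain-text element scan."""
    return {name: len(rx.findall(sbml_text)) for name, rx in ELEMENT_RE.items()}


def raw_resources(sbml_text: str) -> list[str]:
    """All rdf:resource attribute values in document order."""
    return RESOURCE_RE.findall(sbml_text)


@pytest.fixture(scope="session")
def ahr_path() -> Path:
    return ahr_like_path()


@pytest.fixture(scope="session")
def ahr_doc(ahr_path):
    return read_sbml(ahr_path)


@pytest.fixture(scope="session")
def ahr_tables(ahr_doc):
    return as_tables(ahr_doc)


@pytest.fixture
def fixture_file(tmp_path):
    """Factory writing a generated SBML fixture; returns (path, text, truth)."""

    def _make(spec: FixtureSpec | None = None, **kwargs):
        spec = spec or FixtureSpec(**kwargs)
        text, truth = make_sbml(spec)
        path = tmp_path / f"fixture_{spec.seed}.sbml"
        path.write_text(text, encoding="utf-8")
        return path, text, truth

    return _make
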