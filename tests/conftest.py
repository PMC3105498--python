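"""Shared fixtures and seeded random-object generators for the suite."""

from __future__ import annotations

import importlib.resources

import numpy as np
import pytest

from chemrdf.chembl_synth import random_smiles
from chemrdf.chemgraph import Molecule, parse_smiles
from chemrdf.nmr_derep import Peak, Spectrum
from chemrdf.rdf_core import BlankNode, IRI, Literal, TripleStore, parse_rdf

XSD = "http://www.w3.org/2001/XMLSchema#"

# Charged/bracket SMILES mixed into round-trip tests so that formal charges
# and explicit hydrogen counts are exercised, not just the neutral grammar.
CHARGED_SMILES = [
    "C[OH2+]",
    "[NH3+]CC(=O)[O-]",
    "[NH4+]",
    "CC(=O)[O-]",
    "C[N+](C)(C)C",
    "[OH-]",
]


def fixture_text(name: str) -> str:
    return (
        importlib.resources.files("chemrdf") / "data" / name
    ).read_text(encoding="utf-8")


@pytest.fixture(scope="session")
def methoxymethane_store() -> TripleStore:
    return parse_rdf(fixture_text("methoxymethane.ttl"))


@pytest.fixture(scope="session")
def protonated_methanol_store() -> TripleStore:
    return parse_rdf(fixture_text("protonated_methanol.ttl"))


@pytest.fixture(scope="session")
def tpsa_result_store() -> TripleStore:
    return parse_rdf(fixture_text("tpsa_result.ttl"))


@pytest.fixture(scope="session")
def nmr_spectrum_store() -> TripleStore:
    return parse_rdf(fixture_text("nmr_spectrum.ttl"))


# --- random RDF stores -------------------------------------------------------


def random_store(
    rng: np.random.Generator, n_triples: int = 12, n_bnodes: int = 3
) -> TripleStore:
    iris = [IRI(f"http://ex.org/r{i}") for i in range(6)]
    preds = [IRI(f"http://ex.org/p{i}") for i in range(4)]
    bnodes = [BlankNode(f"b{i}") for i in range(n_bnodes)]

    def subject_node():
        if bnodes and rng.random() < 0.3:
            return bnodes[rng.integers(len(bnodes))]
        return iris[rng.integers(len(iris))]

    def object_node():
        r = rng.random()
        if r < 0.4:
            return iris[rng.integers(len(iris))]
        if r < 0.6 and bnodes:
            return bnodes[rng.integers(len(bnodes))]
        choice = rng.random()
        value = str(rng.integers(100))
        if choice < 0.4:
            return Literal(value)
        if choice < 0.7:
            return Literal(value, datatype=f"{XSD}integer")
        return Literal("text" + value, lang="en")

    store = TripleStore(prefixes={"ex": "http://ex.org/"})
    for _ in range(n_triples):
        store.add(subject_node(), preds[rng.integers(len(preds))], object_node())
    return store


def relabel_bnodes(store: TripleStore, prefix: str = "x") -> TripleStore:
    mapping: dict[BlankNode, BlankNode] = {}

    def m(node):
        if isinstance(node, BlankNode):
            if node not in mapping:
                mapping[node] = BlankNode(f"{prefix}{len(mapping)}")
            return mapping[node]
        return node

    return TripleStore(
        ((m(s), p, m(o)) for s, p, o in store.triples),
        prefixes=store.prefixes,
    )


# --- random molecules and spectra -------------------------------------------


def random_molecule(rng: np.random.Generator) -> Molecule:
    if rng.random() < 0.2:
        smiles = CHARGED_SMILES[rng.integers(len(CHARGED_SMILES))]
    else:
        smiles = random_smiles(rng)
    mol = parse_smiles(smiles)
    if rng.random() < 0.5:
        mol.name = f"molecule {rng.integers(1000)}"
    return mol


def random_spectrum(rng: np.random.Generator, index: int = 0) -> Spectrum:
    n_peaks = int(rng.integers(0, 8))
    peaks = [
        Peak(
            shift=round(float(rng.uniform(0, 220)), 2),
            intensity=(round(float(rng.uniform(0, 1)), 3)
                       if rng.random() < 0.5 else None),
        )
        for _ in range(n_peaks)
    ]
    return Spectrum(
        id=f"http://ex.org/spectrum/{index}",
        molecule_ref=f"http://ex.org/molecule/{index}",
        peaks=peaks,
    )
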