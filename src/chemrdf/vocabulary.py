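"""Namespace IRIs and term names used across the package's RDF output.

The chemical-graph ontology mirrors the class/property names of the CDK-style
data model (Molecule, Atom, AtomType, Element, Bond, hasAtom, hasBond, symbol,
order); the descriptor-provenance terms follow the Blue Obelisk Descriptor
Ontology pattern (``instanceOf`` pointing into a descriptor dictionary); the
bioactivity vocabulary is this package's own ChEMBL-like schema, shaped so the
shipped extraction queries bind the conventional variable names (act, ass, mol,
smiles, val, unit, conf; target, type, pubmed, l4, l5, l6, seq).  None of
these term names are normative outside this package; they are documented here
and in ``data/descriptor_dictionary.ttl``.
"""

from .rdf_core import IRI

# Well-known external namespaces
RDF_TYPE = IRI("http://www.w3.org/1999/02/22-rdf-syntax-ns#type")
RDFS_SEEALSO = IRI("http://www.w3.org/2000/01/rdf-schema#seeAlso")
OWL_SAMEAS = IRI("http://www.w3.org/2002/07/owl#sameAs")
DC_TITLE = IRI("http://purl.org/dc/elements/1.1/title")
XSD_INTEGER = "http://www.w3.org/2001/XMLSchema#integer"
XSD_DECIMAL = "http://www.w3.org/2001/XMLSchema#decimal"
XSD_BOOLEAN = "http://www.w3.org/2001/XMLSchema#boolean"

# Default InChI resolver (the linked-data hub pattern)
OPENMOLECULES_BASE = "http://rdf.openmolecules.net/"

# --- chemical-graph ontology -------------------------------------------------
CG = "http://chemrdf.example.org/ont/chemgraph#"


def cg(name: str) -> IRI:
    return IRI(CG + name)


CG_MOLECULE = cg("Molecule")
CG_ATOM = cg("Atom")
CG_BOND = cg("Bond")
CG_HAS_ATOM = cg("hasAtom")
CG_HAS_BOND = cg("hasBond")
CG_SYMBOL = cg("symbol")
CG_ORDER = cg("order")
CG_BINDS_ATOM = cg("bindsAtom")
CG_FORMAL_CHARGE = cg("formalCharge")
CG_IMPLICIT_H = cg("implicitHydrogenCount")
CG_ATOM_INDEX = cg("atomIndex")
CG_AROMATIC = cg("aromatic")
CG_SMILES = cg("smiles")

# --- descriptor provenance (Blue Obelisk Descriptor Ontology pattern) -------
BODO = "http://www.blueobelisk.org/ontologies/cheminformatics-algorithms/#"


def bodo(name: str) -> IRI:
    return IRI(BODO + name)


BODO_DESCRIPTOR_RESULT = bodo("DescriptorResult")
BODO_INSTANCE_OF = bodo("instanceOf")
BODO_HAS_PARAMETER = bodo("hasParameter")
BODO_PARAMETER = bodo("Parameter")
BODO_PARAM_NAME = bodo("parameterName")
BODO_PARAM_VALUE = bodo("parameterValue")
BODO_VALUE = bodo("hasValue")
BODO_SOFTWARE = bodo("software")
BODO_SOFTWARE_TITLE = bodo("softwareTitle")
BODO_SOFTWARE_VERSION = bodo("softwareVersion")
BODO_FOR_MOLECULE = bodo("forMolecule")

# Descriptor dictionary entries live under their own namespace
BODO_DICT = "http://chemrdf.example.org/dict/descriptors#"

# --- ChEMBL-like bioactivity schema -----------------------------------------
CHEMBL = "http://chemrdf.example.org/ont/chembl#"


def chembl(name: str) -> IRI:
    return IRI(CHEMBL + name)


CH_TARGET = chembl("Target")
CH_ASSAY = chembl("Assay")
CH_ACTIVITY = chembl("Activity")
CH_MOLECULE = chembl("Molecule")
CH_TITLE = chembl("title")
CH_TARGET_TYPE = chembl("targetType")
CH_ORGANISM = chembl("organism")
CH_SEQUENCE = chembl("sequence")
CH_CLASS_LEVEL = {i: chembl(f"classL{i}") for i in range(1, 8)}
CH_HAS_TARGET = chembl("hasTarget")
CH_CONF_SCORE = chembl("hasConfScore")
CH_ON_ASSAY = chembl("onAssay")
CH_FOR_MOLECULE = chembl("forMolecule")
CH_ACTIVITY_TYPE = chembl("activityType")
CH_STANDARD_VALUE = chembl("standardValue")
CH_STANDARD_UNITS = chembl("standardUnits")
CH_PUBMED = chembl("pubmedId")
CH_SMILES = chembl("smiles")

# --- NMR spectra -------------------------------------------------------------
NMR = "http://chemrdf.example.org/ont/nmr#"


def nmr(name: str) -> IRI:
    return IRI(NMR + name)


NMR_SPECTRUM = nmr("Spectrum")
NMR_PEAK = nmr("Peak")
NMR_HAS_PEAK = nmr("hasPeak")
NMR_SHIFT = nmr("shift")
NMR_INTENSITY = nmr("intensity")
NMR_NUCLEUS = nmr("nucleus")
NMR_OF_MOLECULE = nmr("ofMolecule")

PREFIXES = {
    "rdf": "http://www.w3.org/1999/02/22-rdf-syntax-ns#",
    "rdfs": "http://www.w3.org/2000/01/rdf-schema#",
    "owl": "http://www.w3.org/2002/07/owl#",
    "xsd": "http://www.w3.org/2001/XMLSchema#",
    "dc": "http://purl.org/dc/elements/1.1/",
    "cg": CG,
    "bodo": BODO,
    "bodod": BODO_DICT,
    "chembl": CHEMBL,
    "nmr": NMR,
}
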