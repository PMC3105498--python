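"""Chemical graphs: SMILES parsing, implicit hydrogens, RDF and SDF export.

The molecule model is a plain labelled graph — atoms with element, formal
charge and an implicit-hydrogen count, bonds with one of four orders — the
unit that is converted between SMILES line notation, the CDK-style RDF
vocabulary in :mod:`chemrdf.vocabulary`, and MDL SD files.

Implicit hydrogens follow standard SMILES semantics: organic-subset atoms are
filled up to their default valence (B3 C4 N3 O2 P3 S2, halogens 1), counting
aromatic bonds as 1.5 and rounding the remaining valence down; bracket atoms
carry exactly the hydrogen count written in the brackets (so ``[OH2+]`` has
two hydrogens and charge +1, however many bonds it makes).  Stereochemistry,
isotopes and atom maps are outside the supported grammar and rejected with a
positioned parse error.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Optional, Sequence
from urllib.parse import quote, unquote

from . import vocabulary as voc
from .rdf_core import IRI, Literal, TripleStore

__all__ = [
    "Atom",
    "Bond",
    "Molecule",
    "SmilesError",
    "MoleculeRdfError",
    "parse_smiles",
    "molecule_to_rdf",
    "molecule_from_rdf",
    "inchi_to_uri",
    "uri_to_inchi",
    "molecular_formula",
    "molecular_weight",
    "write_sdf",
    "sdf_string",
]

# Default valences for the organic subset; used for implicit-H filling.
DEFAULT_VALENCE = {
    "B": 3, "C": 4, "N": 3, "O": 2, "F": 1,
    "P": 3, "S": 2, "Cl": 1, "Br": 1, "I": 1, "H": 1,
}

# IUPAC 2021 standard atomic weights, abridged.
ATOMIC_WEIGHT = {
    "H": 1.008, "B": 10.81, "C": 12.011, "N": 14.007, "O": 15.999,
    "F": 18.998, "P": 30.974, "S": 32.06, "Cl": 35.45, "Br": 79.904,
    "I": 126.904,
}

SUPPORTED_ELEMENTS = set(DEFAULT_VALENCE)
AROMATIC_SYMBOLS = {"b": "B", "c": "C", "n": "N", "o": "O", "p": "P", "s": "S"}
ORGANIC_SUBSET = ["Cl", "Br", "B", "C", "N", "O", "P", "S", "F", "I"]

BOND_ORDERS = ("single", "double", "triple", "aromatic")
ORDER_VALUE = {"single": 1.0, "double": 2.0, "triple": 3.0, "aromatic": 1.5}
_BOND_SYMBOL = {"-": "single", "=": "double", "#": "triple", ":": "aromatic"}


class SmilesError(ValueError):
    """SMILES syntax/semantics error, carrying token and position."""

    def __init__(self, message: str, position: int, token: str = ""):
        super().__init__(f"{message} (token {token!r} at position {position})")
        self.position = position
        self.token = token


class MoleculeRdfError(ValueError):
    """Structural problem while reading a molecule from RDF."""


@dataclass
class Atom:
    element: str
    formal_charge: int = 0
    implicit_h: int = 0
    aromatic: bool = False
    index: int = 0
    # True when the hydrogen count was written explicitly (bracket atom);
    # such atoms are exempt from valence-based H filling.
    h_explicit: bool = False

    def key(self):
        return (self.element, self.formal_charge, self.implicit_h, self.aromatic)


@dataclass
class Bond:
    atom1: int
    atom2: int
    order: str = "single"

    def __post_init__(self):
        if self.order not in BOND_ORDERS:
            raise ValueError(f"unknown bond order: {self.order}")
        if self.atom1 == self.atom2:
            raise ValueError("bond endpoints must differ")

    @property
    def pair(self) -> frozenset:
        return frozenset((self.atom1, self.atom2))


@dataclass
class Molecule:
    """A chemical graph; may be disconnected, hydrogens implicit."""

    atoms: list[Atom] = field(default_factory=list)
    bonds: list[Bond] = field(default_factory=list)
    name: Optional[str] = None
    smiles: Optional[str] = None
    inchi: Optional[str] = None

    def add_atom(self, atom: Atom) -> int:
        atom.index = len(self.atoms)
        self.atoms.append(atom)
        return atom.index

    def add_bond(self, bond: Bond) -> None:
        if bond.atom1 >= len(self.atoms) or bond.atom2 >= len(self.atoms):
            raise ValueError("bond endpoint does not exist")
        if any(b.pair == bond.pair for b in self.bonds):
            raise ValueError(
                f"duplicate bond between atoms {bond.atom1} and {bond.atom2}")
        self.bonds.append(bond)

    def neighbors(self, index: int) -> list[int]:
        out = []
        for b in self.bonds:
            if b.atom1 == index:
                out.append(b.atom2)
            elif b.atom2 == index:
                out.append(b.atom1)
        return out

    def bonds_of(self, index: int) -> list[Bond]:
        return [b for b in self.bonds if index in (b.atom1, b.atom2)]

    def net_charge(self) -> int:
        return sum(a.formal_charge for a in self.atoms)

    def n_components(self) -> int:
        n = len(self.atoms)
        parent = list(range(n))

        def find(i):
            while parent[i] != i:
                parent[i] = parent[parent[i]]
                i = parent[i]
            return i

        for b in self.bonds:
            ra, rb = find(b.atom1), find(b.atom2)
            if ra != rb:
                parent[ra] = rb
        return len({find(i) for i in range(n)})

    def structurally_equal(self, other: "Molecule") -> bool:
        """Same atoms (in order), bonds, and name; identifiers not compared."""
        if len(self.atoms) != len(other.atoms) or len(self.bonds) != len(other.bonds):
            return False
        if any(a.key() != b.key() for a, b in zip(self.atoms, other.atoms)):
            return False
        mine = {(b.pair, b.order) for b in self.bonds}
        theirs = {(b.pair, b.order) for b in other.bonds}
        return mine == theirs and self.name == other.name


# --- SMILES parsing ----------------------------------------------------------

_BRACKET_RE = re.compile(
    r"^(?P<symbol>[A-Z][a-z]?|[bcnops])"
    r"(?P<hcount>H\d*)?"
    r"(?P<charge>\+{1,3}|-{1,3}|\+\d|-\d)?$"
)


def _parse_bracket(body: str, pos: int) -> Atom:
    if re.match(r"^\d", body):
        raise SmilesError("isotopes are not supported", pos, body)
    if "@" in body:
        raise SmilesError("stereochemistry is not supported", pos, body)
    if ":" in body:
        raise SmilesError("atom maps are not supported", pos, body)
    m = _BRACKET_RE.match(body)
    if not m:
        raise SmilesError("cannot parse bracket atom", pos, f"[{body}]")
    symbol = m.group("symbol")
    aromatic = symbol in AROMATIC_SYMBOLS
    element = AROMATIC_SYMBOLS.get(symbol, symbol)
    if element not in SUPPORTED_ELEMENTS:
        raise SmilesError("unknown element", pos, symbol)
    hcount = 0
    if m.group("hcount"):
        digits = m.group("hcount")[1:]
        hcount = int(digits) if digits else 1
    charge = 0
    cs = m.group("charge")
    if cs:
        if cs[-1].isdigit():
            charge = int(cs[-1]) * (1 if cs[0] == "+" else -1)
        else:
            charge = len(cs) * (1 if cs[0] == "+" else -1)
    return Atom(element=element, formal_charge=charge,
                implicit_h=hcount, aromatic=aromatic, h_explicit=True)


def parse_smiles(smiles: str) -> Molecule:
    """Parse a SMILES string into a :class:`Molecule`.

    Supported grammar: organic-subset atoms, bracket atoms with explicit H
    count and charge, bond symbols ``- = # :``, branches, ring closures
    ``1``–``9`` and ``%nn``, dot disconnection, lowercase aromatic atoms.
    """
    mol = Molecule(smiles=smiles)
    prev: Optional[int] = None
    pending_bond: Optional[str] = None
    stack: list[Optional[int]] = []
    ring: dict[int, tuple[int, Optional[str], int]] = {}
    i, n = 0, len(smiles)

    def close_ring(num: int, pos: int):
        nonlocal pending_bond
        if num in ring:
            other, other_bond, _ = ring.pop(num)
            if other == prev:
                raise SmilesError("ring closure to same atom", pos, str(num))
            if pending_bond and other_bond and pending_bond != other_bond:
                raise SmilesError("conflicting ring-closure bond orders",
                                  pos, str(num))
            order = pending_bond or other_bond
            if order is None:
                a, b = mol.atoms[prev], mol.atoms[other]
                order = "aromatic" if (a.aromatic and b.aromatic) else "single"
            mol.add_bond(Bond(prev, other, order))
            pending_bond = None
        else:
            ring[num] = (prev, pending_bond, pos)
            pending_bond = None

    def attach(atom: Atom, pos: int):
        nonlocal prev, pending_bond
        idx = mol.add_atom(atom)
        if prev is not None:
            order = pending_bond
            if order is None:
                a, b = mol.atoms[prev], atom
                order = "aromatic" if (a.aromatic and b.aromatic) else "single"
            mol.add_bond(Bond(prev, idx, order))
        prev = idx
        pending_bond = None
        return idx

    while i < n:
        ch = smiles[i]
        if ch == "[":
            end = smiles.find("]", i)
            if end == -1:
                raise SmilesError("unterminated bracket atom", i, "[")
            attach(_parse_bracket(smiles[i + 1:end], i), i)
            i = end + 1
        elif ch in _BOND_SYMBOL:
            if pending_bond is not None:
                raise SmilesError("two bond symbols in a row", i, ch)
            pending_bond = _BOND_SYMBOL[ch]
            i += 1
        elif ch in "/\\":
            raise SmilesError("stereo bonds are not supported", i, ch)
        elif ch == "(":
            if prev is None:
                raise SmilesError("branch before any atom", i, ch)
            stack.append(prev)
            i += 1
        elif ch == ")":
            if not stack:
                raise SmilesError("unbalanced parentheses", i, ch)
            prev = stack.pop()
            i += 1
        elif ch == ".":
            if pending_bond is not None:
                raise SmilesError("bond symbol before dot", i, ch)
            prev = None
            i += 1
        elif ch.isdigit():
            if prev is None:
                raise SmilesError("ring closure before any atom", i, ch)
            close_ring(int(ch), i)
            i += 1
        elif ch == "%":
            if i + 2 >= n or not smiles[i + 1:i + 3].isdigit():
                raise SmilesError("malformed %nn ring closure", i, ch)
            if prev is None:
                raise SmilesError("ring closure before any atom", i, ch)
            close_ring(int(smiles[i + 1:i + 3]), i)
            i += 3
        else:
            matched = None
            for sym in ORGANIC_SUBSET:
                if smiles.startswith(sym, i):
                    matched = sym
                    break
            if matched is None and ch in AROMATIC_SYMBOLS:
                matched = ch
            if matched is None:
                raise SmilesError("unknown element or token", i, ch)
            aromatic = matched in AROMATIC_SYMBOLS
            element = AROMATIC_SYMBOLS.get(matched, matched)
            attach(Atom(element=element, aromatic=aromatic), i)
            i += len(matched)

    if stack:
        raise SmilesError("unbalanced parentheses", n - 1, "(")
    if ring:
        num, (_, _, pos) = next(iter(ring.items()))
        raise SmilesError("unmatched ring closure", pos, str(num))
    if pending_bond is not None:
        raise SmilesError("dangling bond symbol", n - 1, "")

    # Fill implicit hydrogens for non-bracket atoms.
    for atom in mol.atoms:
        if atom.h_explicit:
            continue  # explicit H count (possibly 0) is authoritative
        valence = DEFAULT_VALENCE[atom.element]
        degree = sum(ORDER_VALUE[b.order] for b in mol.bonds_of(atom.index))
        atom.implicit_h = max(0, int(valence - degree))
    return mol


# --- RDF serialization -------------------------------------------------------


def _int_lit(value: int) -> Literal:
    return Literal(str(value), datatype=voc.XSD_INTEGER)


def molecule_to_rdf(mol: Molecule, base: str) -> TripleStore:
    """Serialize the chemical graph under the CDK-style vocabulary.

    One resource per molecule, atom and bond; the molecule name goes out under
    the Dublin Core ``title`` predicate, and a known InChI becomes an
    ``owl:sameAs`` identity link to the InChI resolver URI.  Atom indices are
    written explicitly so reading the graph back is order-deterministic.
    """
    store = TripleStore(prefixes=dict(voc.PREFIXES))
    mol_iri = IRI(base)
    store.add(mol_iri, voc.RDF_TYPE, voc.CG_MOLECULE)
    if mol.name is not None:
        store.add(mol_iri, voc.DC_TITLE, Literal(mol.name))
    if mol.smiles is not None:
        store.add(mol_iri, voc.CG_SMILES, Literal(mol.smiles))
    if mol.inchi is not None:
        store.add(mol_iri, voc.OWL_SAMEAS, inchi_to_uri(mol.inchi))
    atom_iris = []
    for atom in mol.atoms:
        a = IRI(f"{base}/atom{atom.index}")
        atom_iris.append(a)
        store.add(mol_iri, voc.CG_HAS_ATOM, a)
        store.add(a, voc.RDF_TYPE, voc.CG_ATOM)
        store.add(a, voc.CG_SYMBOL, Literal(atom.element))
        store.add(a, voc.CG_ATOM_INDEX, _int_lit(atom.index))
        store.add(a, voc.CG_IMPLICIT_H, _int_lit(atom.implicit_h))
        if atom.formal_charge != 0:
            store.add(a, voc.CG_FORMAL_CHARGE, _int_lit(atom.formal_charge))
        if atom.aromatic:
            store.add(a, voc.CG_AROMATIC,
                      Literal("true", datatype=voc.XSD_BOOLEAN))
    for j, bond in enumerate(mol.bonds):
        b = IRI(f"{base}/bond{j}")
        store.add(mol_iri, voc.CG_HAS_BOND, b)
        store.add(b, voc.RDF_TYPE, voc.CG_BOND)
        store.add(b, voc.CG_BINDS_ATOM, atom_iris[bond.atom1])
        store.add(b, voc.CG_BINDS_ATOM, atom_iris[bond.atom2])
        store.add(b, voc.CG_ORDER, Literal(bond.order))
    return store


def molecule_from_rdf(store: TripleStore, molecule_iri: IRI) -> Molecule:
    """Reconstruct a molecule serialized by :func:`molecule_to_rdf`."""
    if (molecule_iri, voc.RDF_TYPE, voc.CG_MOLECULE) not in store:
        raise MoleculeRdfError(
            f"no molecule-typed resource at {molecule_iri}")
    mol = Molecule()
    title = store.object(molecule_iri, voc.DC_TITLE)
    if title is not None:
        mol.name = str(title)
    smiles = store.object(molecule_iri, voc.CG_SMILES)
    if smiles is not None:
        mol.smiles = str(smiles)
    same = store.object(molecule_iri, voc.OWL_SAMEAS)
    if isinstance(same, IRI) and same.value.startswith(voc.OPENMOLECULES_BASE):
        mol.inchi = uri_to_inchi(same)

    atom_nodes = store.objects(molecule_iri, voc.CG_HAS_ATOM)
    indexed = []
    for node in atom_nodes:
        sym = store.object(node, voc.CG_SYMBOL)
        if sym is None or str(sym) not in SUPPORTED_ELEMENTS:
            raise MoleculeRdfError(f"unknown or missing element on {node}")
        idx_lit = store.object(node, voc.CG_ATOM_INDEX)
        if idx_lit is None:
            raise MoleculeRdfError(f"atom {node} lacks an index annotation")
        charge = store.object(node, voc.CG_FORMAL_CHARGE)
        hcount = store.object(node, voc.CG_IMPLICIT_H)
        aromatic = store.object(node, voc.CG_AROMATIC)
        indexed.append((int(str(idx_lit)), node, Atom(
            element=str(sym),
            formal_charge=int(str(charge)) if charge is not None else 0,
            implicit_h=int(str(hcount)) if hcount is not None else 0,
            aromatic=aromatic is not None and str(aromatic) == "true",
        )))
    indexed.sort(key=lambda t: t[0])
    node_to_idx = {}
    for serial_idx, node, atom in indexed:
        node_to_idx[node] = mol.add_atom(atom)

    for bond_node in store.objects(molecule_iri, voc.CG_HAS_BOND):
        endpoints = store.objects(bond_node, voc.CG_BINDS_ATOM)
        if len(endpoints) != 2:
            raise MoleculeRdfError(
                f"bond {bond_node} has {len(endpoints)} endpoints, expected 2")
        try:
            a, b = (node_to_idx[e] for e in endpoints)
        except KeyError as exc:
            raise MoleculeRdfError(
                f"bond {bond_node} references a missing atom") from exc
        order = store.object(bond_node, voc.CG_ORDER)
        mol.add_bond(Bond(min(a, b), max(a, b),
                          str(order) if order is not None else "single"))
    mol.bonds.sort(key=lambda b: (b.atom1, b.atom2))
    return mol


# --- InChI <-> URI -----------------------------------------------------------

_INCHI_SAFE = "/,;+?=()"


def inchi_to_uri(inchi: str, resolver_base: str = voc.OPENMOLECULES_BASE) -> IRI:
    """Map an InChI string to its resolver URI (one-to-one).

    ``InChI=1/CH4/h1H4`` maps to
    ``http://rdf.openmolecules.net/?InChI=1/CH4/h1H4``.
    """
    if not inchi.startswith("InChI="):
        raise ValueError(f"not an InChI (missing 'InChI=' prefix): {inchi!r}")
    body = inchi[len("InChI="):]
    return IRI(resolver_base + "?InChI=" + quote(body, safe=_INCHI_SAFE))


def uri_to_inchi(uri: IRI | str, resolver_base: str = voc.OPENMOLECULES_BASE) -> str:
    """Inverse of :func:`inchi_to_uri`."""
    text = uri.value if isinstance(uri, IRI) else uri
    marker = resolver_base + "?InChI="
    if not text.startswith(marker):
        raise ValueError(f"not a resolver URI for base {resolver_base}: {text}")
    return "InChI=" + unquote(text[len(marker):])


# --- formula and weight ------------------------------------------------------


def _element_counts(mol: Molecule) -> dict[str, int]:
    counts: dict[str, int] = {}
    for atom in mol.atoms:
        counts[atom.element] = counts.get(atom.element, 0) + 1
        if atom.implicit_h:
            counts["H"] = counts.get("H", 0) + atom.implicit_h
    return counts


def molecular_formula(mol: Molecule) -> str:
    """Hill-order molecular formula including implicit hydrogens."""
    counts = _element_counts(mol)
    if not counts:
        return ""

    def fmt(el: str) -> str:
        c = counts[el]
        return el if c == 1 else f"{el}{c}"

    parts = []
    if "C" in counts:
        parts.append(fmt("C"))
        if "H" in counts:
            parts.append(fmt("H"))
        parts += [fmt(el) for el in sorted(counts) if el not in ("C", "H")]
    else:
        parts = [fmt(el) for el in sorted(counts)]
    return "".join(parts)


def molecular_weight(mol: Molecule) -> float:
    """Molecular mass in Da from standard atomic weights."""
    return sum(ATOMIC_WEIGHT[el] * c for el, c in _element_counts(mol).items())


# --- MDL SD file export ------------------------------------------------------

_MOLFILE_BOND_TYPE = {"single": 1, "double": 2, "triple": 3, "aromatic": 4}


def _molblock(mol: Molecule) -> str:
    if len(mol.atoms) > 999 or len(mol.bonds) > 999:
        raise ValueError("molecule exceeds the V2000 limit of 999 atoms/bonds")
    lines = [
        mol.name or "",
        "  chemrdf",
        "",
        f"{len(mol.atoms):>3d}{len(mol.bonds):>3d}  0  0  0  0  0  0  0  0999 V2000",
    ]
    for atom in mol.atoms:
        lines.append(
            f"{0.0:>10.4f}{0.0:>10.4f}{0.0:>10.4f} {atom.element:<3s}"
            " 0  0  0  0  0  0  0  0  0  0  0  0"
        )
    for bond in mol.bonds:
        lines.append(
            f"{bond.atom1 + 1:>3d}{bond.atom2 + 1:>3d}"
            f"{_MOLFILE_BOND_TYPE[bond.order]:>3d}  0"
        )
    charged = [(a.index + 1, a.formal_charge)
               for a in mol.atoms if a.formal_charge != 0]
    for start in range(0, len(charged), 8):
        chunk = charged[start:start + 8]
        line = f"M  CHG{len(chunk):>3d}"
        for idx, chg in chunk:
            line += f"{idx:>4d}{chg:>4d}"
        lines.append(line)
    lines.append("M  END")
    return "\n".join(lines)


def sdf_string(
    molecules: Sequence[Molecule],
    properties: Optional[Sequence[dict]] = None,
) -> str:
    """Build an MDL SD file (V2000) with per-molecule property blocks."""
    if properties is None:
        properties = [{} for _ in molecules]
    if len(properties) != len(molecules):
        raise ValueError("one property map per molecule required")
    blocks = []
    for mol, props in zip(molecules, properties):
        block = _molblock(mol)
        for key, value in props.items():
            block += f"\n> <{key}>\n{value}\n"
        block += "\n$$$$\n"
        blocks.append(block)
    return "".join(blocks)


def write_sdf(
    molecules: Sequence[Molecule],
    properties: Optional[Sequence[dict]],
    path: str,
) -> None:
    """Write molecules (with activity scores etc. as properties) to an SD file."""
    with open(path, "w") as fh:
        fh.write(sdf_string(molecules, properties))
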