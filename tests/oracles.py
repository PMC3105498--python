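"""Independent brute-force oracles used by the test suite.

These deliberately avoid the code paths they check: the BGP join oracle
enumerates all triple-to-pattern assignments instead of using any SPARQL
engine; the isomorphism oracle tries every blank-node permutation; the
dataset-scan oracles walk the generator's record tables instead of the RDF
store.
"""

from __future__ import annotations

import itertools
import re

from chemrdf.chembl_synth import DATA_BASE, ChemblRecords
from chemrdf.rdf_core import BlankNode, TripleStore


def bgp_solutions(triples, patterns) -> set[frozenset]:
    """All solutions of a basic graph pattern by exhaustive enumeration.

    ``patterns`` is a list of (s, p, o) where a string starting with '?' is a
    variable and anything else must match the triple term exactly.  Returns
    the set of full variable bindings, each as a frozenset of (var, term).
    """
    triples = list(triples)
    solutions = set()
    for combo in itertools.product(triples, repeat=len(patterns)):
        binding: dict = {}
        ok = True
        for pattern, triple in zip(patterns, combo):
            for slot, term in zip(pattern, triple):
                if isinstance(slot, str) and slot.startswith("?"):
                    if slot in binding and binding[slot] != term:
                        ok = False
                        break
                    binding[slot] = term
                elif slot != term:
                    ok = False
                    break
            if not ok:
                break
        if ok:
            solutions.add(frozenset(binding.items()))
    return solutions


def isomorphic_by_permutation(a: TripleStore, b: TripleStore) -> bool:
    """Graph isomorphism by trying every blank-node permutation (<= ~7)."""
    if len(a.triples) != len(b.triples):
        return False

    def bnodes(store):
        out = set()
        for s, _, o in store.triples:
            for n in (s, o):
                if isinstance(n, BlankNode):
                    out.add(n)
        return sorted(out, key=lambda n: n.label)

    na, nb = bnodes(a), bnodes(b)
    if len(na) != len(nb):
        return False
    for perm in itertools.permutations(nb):
        mapping = dict(zip(na, perm))

        def mapped(node):
            return mapping.get(node, node)

        if {(mapped(s), p, mapped(o)) for s, p, o in a.triples} == b.triples:
            return True
    return not na and a.triples == b.triples


def qsar_scan(records: ChemblRecords, target_id: int, activity_type: str):
    """Direct table scan standing in for the QSAR extraction query."""
    assays = {a.id: a for a in records.assays}
    rows = []
    for act in records.activities:
        assay = assays[act.assay]
        if assay.target == target_id and act.type == activity_type:
            rows.append((
                f"{DATA_BASE}activity/{act.id}",
                f"{DATA_BASE}assay/{act.assay}",
                f"{DATA_BASE}molecule/{act.molecule}",
                records.molecule_smiles[act.molecule],
                act.value,
                act.unit,
                assay.confidence,
            ))
    return sorted(rows)


def pcm_scan(records: ChemblRecords, level6_pattern: str):
    """Direct table scan standing in for the PCM extraction query."""
    targets = {t.id: t for t in records.targets}
    assays = {a.id: a for a in records.assays}
    rows = []
    for act in records.activities:
        if act.type not in ("Ki", "IC50"):
            continue
        target = targets[assays[act.assay].target]
        if not re.search(level6_pattern, target.classification[5]):
            continue
        rows.append((
            f"{DATA_BASE}target/{target.id}",
            act.type,
            act.pubmed,
            target.classification[3],
            target.classification[4],
            target.classification[5],
            records.molecule_smiles[act.molecule],
            act.value,
            target.sequence,
        ))
    return sorted(rows)


def activity_type_scan(records: ChemblRecords, target_id: int):
    assays = {a.id: a for a in records.assays}
    return sorted({
        act.type for act in records.activities
        if assays[act.assay].target == target_id
    })


def peak_near_scan(spectra, shift: float, tol: float):
    """Linear scan over every (molecule, peak) pair."""
    best = {}
    for spectrum in spectra:
        for peak in spectrum.peaks:
            dev = abs(peak.shift - shift)
            if dev <= tol:
                mol = spectrum.molecule_ref
                if mol not in best or dev < best[mol]:
                    best[mol] = dev
    return sorted(best, key=lambda m: (best[m], m))
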