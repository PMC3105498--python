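# Small RDF network for a molecule resource recognized by its ontological
# type, with an InChI-based identity link into the linked-data resolver hub
# and onward links to three external repositories (NMRShiftDB, ChEBI,
# DBPedia).  The resource is titled "Methanol" and carries the SMILES "CO";
# both texts are reproduced verbatim from the source material, which labels
# the compound methoxymethane in the surrounding prose — the discrepancy is
# preserved, not resolved.
@prefix rdf:  <http://www.w3.org/1999/02/22-rdf-syntax-ns#> .
@prefix rdfs: <http://www.w3.org/2000/01/rdf-schema#> .
@prefix owl:  <http://www.w3.org/2002/07/owl#> .
@prefix dc:   <http://purl.org/dc/elements/1.1/> .
@prefix sdb:  <http://chemrdf.example.org/ont/chemgraph#> .
@prefix ex:   <http://example.com/> .

ex:mol1 a sdb:Molecule ;
    dc:title "Methanol" ;
    sdb:smiles "CO" ;
    owl:sameAs <http://rdf.openmolecules.net/?InChI=1/CH4O/c1-2/h2H,1H3> .

<http://rdf.openmolecules.net/?InChI=1/CH4O/c1-2/h2H,1H3>
    rdfs:seeAlso <http://www.ebi.ac.uk/chebi/searchId.do?chebiId=CHEBI:17790> ;
    rdfs:seeAlso <http://nmrshiftdb.org/molecule/234215> ;
    rdfs:seeAlso <http://dbpedia.org/resource/Methanol> .
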