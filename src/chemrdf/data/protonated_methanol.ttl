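# CDK-style chemical-graph serialization of protonated methanol:
# two heavy atoms, one bond, in one molecule; the oxygen is positively
# charged and carries two implicit hydrogens.  Hydrogens are implicit, as in
# SMILES.  The molecule links out to the InChI resolver via owl:sameAs.
@prefix rdf: <http://www.w3.org/1999/02/22-rdf-syntax-ns#> .
@prefix owl: <http://www.w3.org/2002/07/owl#> .
@prefix dc:  <http://purl.org/dc/elements/1.1/> .
@prefix xsd: <http://www.w3.org/2001/XMLSchema#> .
@prefix cg:  <http://chemrdf.example.org/ont/chemgraph#> .

<http://example.com/methanol> a cg:Molecule ;
    dc:title "protonated methanol" ;
    cg:smiles "C[OH2+]" ;
    cg:hasAtom <http://example.com/methanol/atom0> , <http://example.com/methanol/atom1> ;
    cg:hasBond <http://example.com/methanol/bond0> ;
    owl:sameAs <http://rdf.openmolecules.net/?InChI=1/CH4O/c1-2/h2H,1H3/p+1> .

<http://example.com/methanol/atom0> a cg:Atom ;
    cg:symbol "C" ;
    cg:atomIndex "0"^^xsd:integer ;
    cg:implicitHydrogenCount "3"^^xsd:integer .

<http://example.com/methanol/atom1> a cg:Atom ;
    cg:symbol "O" ;
    cg:atomIndex "1"^^xsd:integer ;
    cg:implicitHydrogenCount "2"^^xsd:integer ;
    cg:formalCharge "1"^^xsd:integer .

<http://example.com/methanol/bond0> a cg:Bond ;
    cg:bindsAtom <http://example.com/methanol/atom0> , <http://example.com/methanol/atom1> ;
    cg:order "single" .
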