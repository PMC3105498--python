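# Descriptor-provenance example following the Blue Obelisk Descriptor
# Ontology pattern: a TPSA calculation result, classified against the
# descriptor dictionary entry via bodo:instanceOf, with the one algorithm
# parameter (aromaticity was not detected before calculation), the software
# that produced it, the decimal value, and the molecule it describes
# (methanol, TPSA = one hydroxyl contribution = 20.23 Å²).
@prefix rdf:   <http://www.w3.org/1999/02/22-rdf-syntax-ns#> .
@prefix xsd:   <http://www.w3.org/2001/XMLSchema#> .
@prefix bodo:  <http://www.blueobelisk.org/ontologies/cheminformatics-algorithms/#> .
@prefix bodod: <http://chemrdf.example.org/dict/descriptors#> .

<http://example.com/descriptor/result1> a bodo:DescriptorResult ;
    bodo:instanceOf bodod:tpsa ;
    bodo:forMolecule <http://example.com/methanol> ;
    bodo:hasValue "20.23"^^xsd:decimal ;
    bodo:hasParameter <http://example.com/descriptor/result1/param0> ;
    bodo:software <http://example.com/descriptor/result1/software> .

<http://example.com/descriptor/result1/param0> a bodo:Parameter ;
    bodo:parameterName "checkAromaticity" ;
    bodo:parameterValue "false"^^xsd:boolean .

<http://example.com/descriptor/result1/software>
    bodo:softwareTitle "chemrdf" ;
    bodo:softwareVersion "0.1.0" .
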