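# Descriptor dictionary and ontology terms in one small OWL/Turtle document:
# the ontology half declares the provenance classes and properties used for
# descriptor results; the dictionary half lists the descriptor algorithms
# this package implements.  The bodo: term names follow the Blue Obelisk
# Descriptor Ontology pattern (a result node classified against a dictionary
# entry via bodo:instanceOf); their exact IRIs are this package's own
# reconstruction of that pattern and are normative only within this package.
@prefix rdf:   <http://www.w3.org/1999/02/22-rdf-syntax-ns#> .
@prefix rdfs:  <http://www.w3.org/2000/01/rdf-schema#> .
@prefix owl:   <http://www.w3.org/2002/07/owl#> .
@prefix bodo:  <http://www.blueobelisk.org/ontologies/cheminformatics-algorithms/#> .
@prefix bodod: <http://chemrdf.example.org/dict/descriptors#> .

# --- ontology ---------------------------------------------------------------

bodo:DescriptorResult a owl:Class ;
    rdfs:comment "The outcome of one descriptor calculation on one molecule." .

bodo:Parameter a owl:Class ;
    rdfs:comment "A named algorithm parameter with the value actually used." .

bodo:instanceOf a rdf:Property ;
    rdfs:comment "Classifies a result against a descriptor dictionary entry." .

bodo:hasParameter a rdf:Property .
bodo:parameterName a rdf:Property .
bodo:parameterValue a rdf:Property .
bodo:hasValue a rdf:Property .
bodo:software a rdf:Property .
bodo:softwareTitle a rdf:Property .
bodo:softwareVersion a rdf:Property .
bodo:forMolecule a rdf:Property .

# --- dictionary of descriptor algorithms ------------------------------------

bodod:heavyAtomCount a owl:NamedIndividual ;
    rdfs:label "heavy atom count" ;
    rdfs:comment "Number of non-hydrogen atoms." .

bodod:bondCount a owl:NamedIndividual ;
    rdfs:label "bond count" ;
    rdfs:comment "Number of bonds between heavy atoms." .

bodod:ringCount a owl:NamedIndividual ;
    rdfs:label "ring count" ;
    rdfs:comment "Cyclomatic number: bonds - atoms + connected components." .

bodod:molecularWeight a owl:NamedIndividual ;
    rdfs:label "molecular weight" ;
    rdfs:comment "Sum of standard atomic weights, implicit hydrogens included (Da)." .

bodod:tpsa a owl:NamedIndividual ;
    rdfs:label "topological polar surface area" ;
    rdfs:comment "Sum of fragment surface contributions over N/O environments (A^2); parameter checkAromaticity selects whether lowercase-SMILES aromaticity marks are trusted (false) or recomputed from the bond graph (true)." .
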