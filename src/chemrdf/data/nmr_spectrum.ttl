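# RDF graph of a 13C NMR spectrum with three peaks, linked to its molecule.
# Shift values are chemical shifts in ppm, stored as decimal literals.
@prefix rdf: <http://www.w3.org/1999/02/22-rdf-syntax-ns#> .
@prefix xsd: <http://www.w3.org/2001/XMLSchema#> .
@prefix nmr: <http://chemrdf.example.org/ont/nmr#> .

<http://example.com/spectrum1> a nmr:Spectrum ;
    nmr:nucleus "13C" ;
    nmr:ofMolecule <http://example.com/mol1> ;
    nmr:hasPeak <http://example.com/spectrum1/peak0> ,
                <http://example.com/spectrum1/peak1> ,
                <http://example.com/spectrum1/peak2> .

<http://example.com/spectrum1/peak0> a nmr:Peak ;
    nmr:shift "18.9"^^xsd:decimal .

<http://example.com/spectrum1/peak1> a nmr:Peak ;
    nmr:shift "42.2"^^xsd:decimal .

<http://example.com/spectrum1/peak2> a nmr:Peak ;
    nmr:shift "207.1"^^xsd:decimal .
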