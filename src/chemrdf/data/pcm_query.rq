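# Extraction query for a proteochemometrics data set: retrieves nine
# properties — target id (?target), activity type (?type), PubMed id
# (?pubmed), three target classification levels (?l4 ?l5 ?l6), the
# molecule's SMILES (?smiles, which doubles as the molecule reference in
# this store: one molecule resource per SMILES), the activity value (?val,
# nM) and the target's aligned protein sequence (?seq).  Only Ki and IC50
# activities qualify, and the level-6 classification restricts the target
# family (the "Sodium" pattern below is the default the extraction API
# substitutes per request).
PREFIX chembl: <http://chemrdf.example.org/ont/chembl#>
SELECT ?target ?type ?pubmed ?l4 ?l5 ?l6 ?smiles ?val ?seq
WHERE {
  ?target a chembl:Target ;
          chembl:classL4 ?l4 ;
          chembl:classL5 ?l5 ;
          chembl:classL6 ?l6 ;
          chembl:sequence ?seq .
  ?ass chembl:hasTarget ?target .
  ?act chembl:onAssay ?ass ;
       chembl:activityType ?type ;
       chembl:forMolecule ?mol ;
       chembl:standardValue ?val ;
       chembl:pubmedId ?pubmed .
  ?mol chembl:smiles ?smiles .
  FILTER ((?type = "Ki" || ?type = "IC50") && regex(?l6, "Sodium"))
}
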