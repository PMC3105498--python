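# Extraction query for a QSAR training set: collects seven related
# properties per activity — activity id (?act), assay id (?ass), molecule id
# (?mol), SMILES (?smiles), activity value (?val) and unit (?unit), and the
# assay confidence score (?conf) — for one activity type against one target.
# The target IRI and activity-type literal below are the defaults that the
# extraction API substitutes per request.
PREFIX chembl: <http://chemrdf.example.org/ont/chembl#>
SELECT ?act ?ass ?mol ?smiles ?val ?unit ?conf
WHERE {
  ?act a chembl:Activity ;
       chembl:activityType "IC50" ;
       chembl:onAssay ?ass ;
       chembl:forMolecule ?mol ;
       chembl:standardValue ?val ;
       chembl:standardUnits ?unit .
  ?ass chembl:hasTarget <http://chemrdf.example.org/data/target/10885> ;
       chembl:hasConfScore ?conf .
  ?mol chembl:smiles ?smiles .
}
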