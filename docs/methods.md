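# Methods

This note documents the models, conventions and design choices behind
`chemrdf`, in the order data flows through the package: RDF plumbing,
chemical graphs and descriptors, the synthetic bioactivity world, the two
statistical models, and NMR dereplication. Nothing here states a result
that the test suite or `scripts/acceptance.py` does not itself compute.

## RDF backbone

The `TripleStore` is a duplicate-free set of (subject, predicate, object)
triples plus a prefix map — the contract of an in-memory store; no on-disk
or remote backend is provided. Parsing and SPARQL evaluation are delegated
to rdflib behind the module's own types; the Turtle writer, however, is
native and deliberately deterministic (sorted prefixes, sorted statements,
one triple per line), because the synthetic generators promise byte-identical
output for identical seeds and a hash-order-dependent serializer would break
that promise across processes.

Only a declared subset of SPARQL SELECT is accepted: basic graph patterns,
joins, DISTINCT, FILTER with comparisons/boolean combinations/`regex`,
OPTIONAL, and LIMIT. The parsed query algebra is walked against a whitelist
and anything else — UNION, ORDER BY, aggregates, named graphs, property
paths, SELECT expressions — raises `UnsupportedSparqlError` before
evaluation. The rationale is that a silently wrong answer from a
half-supported feature is worse than a loud refusal. `SELECT *` is rejected
by `select_variables` because downstream dataset assembly depends on a
predictable column list.

Blank-node isomorphism (the round-trip oracle) is a backtracking bijection
search pruned by local signatures (the multiset of incident predicates with
ground neighbours). This is exponential in the worst case but instantaneous
for the graphs that occur here (fewer than ten blank nodes); the test suite
cross-checks it against a full-permutation search.

## Chemical graphs

Molecules are labelled graphs: atoms carry element (from
{H,B,C,N,O,F,P,S,Cl,Br,I}), formal charge, an implicit-hydrogen count and an
aromatic flag; bonds carry one of {single, double, triple, aromatic}.

The SMILES parser covers organic-subset atoms, bracket atoms with explicit H
count and charge, the four bond symbols, branches, ring closures (`1`–`9`,
`%nn`), dot disconnection and lowercase aromatic atoms. Stereochemistry,
isotopes and atom maps are rejected with a positioned error — they carry no
information any downstream consumer here uses, and silently dropping them
would misrepresent the structure. Implicit hydrogens follow standard SMILES
semantics: organic-subset atoms are filled to the default valence (B3 C4 N3
O2 P3 S2, halogens 1), with aromatic bonds counted 1.5 and the remainder
rounded down (so each benzene carbon gets one H); bracket atoms carry exactly
the written H count. Ring-closure bond orders may be written at either end;
a conflict is an error. These conventions were validated against rdkit on
hundreds of generator molecules (atom/bond counts, formulas, TPSA).

RDF serialization follows a CDK-style vocabulary (Molecule/Atom/Bond,
hasAtom/hasBond/bindsAtom/symbol/order), with the molecule name under Dublin
Core `title` and a known InChI expressed as an `owl:sameAs` link to the
resolver URI (`http://rdf.openmolecules.net/?InChI=<body>`; resolver base
configurable). Since RDF triples are unordered, atom indices are written
explicitly so that reading a graph back reproduces the original atom order —
without this annotation round-trip equality would only hold up to
permutation. The vocabulary IRIs are this package's own
(`http://chemrdf.example.org/ont/...`); the class and property names, not the
namespaces, are the meaningful part.

SD export writes V2000 molblocks with zero coordinates (no coordinate
generation is in scope), charges via `M  CHG`, aromatic bonds as type 4, and
per-molecule property blocks — enough for a molecules-table consumer, and
verified to read back with correct atom/bond counts in rdkit.

## Descriptors and provenance

The registry holds five descriptors: heavy-atom count, bond count, ring
count (cyclomatic number: bonds − atoms + connected components), molecular
weight (IUPAC standard atomic weights, implicit H included), and TPSA.

TPSA is the classic fragment-contribution sum over nitrogen and oxygen
environments (contributions in Å², e.g. hydroxyl 20.23, ether 9.23, carbonyl
17.07, pyridine-type aromatic N 12.89). The packaged table covers the
neutral and charged N/O environments that the synthetic chemistry can
produce; an environment outside the table raises an error rather than
contributing zero, because a silent zero would corrupt every model built on
top. The one parameter, `checkAromaticity` (default false), chooses whether
the lowercase-SMILES aromaticity marks are trusted or recomputed from the
bond graph; the default mirrors the provenance example, where aromaticity
was not re-detected before calculation.

Every result is a `DescriptorResult` recording the molecule, the dictionary
entry, the parameter values actually used and the software title/version.
Its RDF form classifies the result node against the descriptor dictionary
(`bodo:instanceOf`), attaches one parameter node per declared parameter and
a software node, and writes the value as a decimal literal using `repr` of
the float — so a parse-back recovers the value exactly, not merely to
printing precision. The dictionary and ontology terms ship as a small
OWL/Turtle document (`src/chemrdf/data/descriptor_dictionary.ttl`).

## The synthetic bioactivity world

`chembl_synth` stands in for a remote ChEMBL-like SPARQL endpoint. A seeded
configuration generates:

- **Molecules** (default 80): SMILES assembled from aliphatic/aromatic cores
  with functional groups (alcohols, ethers, amines, nitriles, ketones,
  acids, esters) hung as substituents off the core — a chemistry chosen to
  be parseable, kekulizable and fully covered by the TPSA table.
- **Targets** (default 7): one kinase (id 10885, the QSAR arm) and six
  voltage-gated ion channels (alternating sodium/calcium at classification
  level 6, the PCM arm), each with a seven-level classification and an
  aligned 30-residue sequence mutated from a common ancestor (30% per-site
  substitution), so protein similarity is structured, not random.
- **Assays**: one per activity, with integer confidence scores uniform on
  1..9. The score range is a free parameter of the generator (no canonical
  range is assumed).
- **Activities** (default 50 per target): mostly IC50/Ki with planted
  signal; a 15% admixture of "Ki app" / "Inhibition" / "Activity" rows with
  arbitrary values exercises type filtering.

The planted signal is linear-bilinear on the −log₁₀ molar scale:

    pact = 6.0 + x_L·β_L [+ x_P·β_P + x_Lᵀ B x_P] + ε,
    ε ~ N(0, σ₀/√conf),   σ₀ = 0.6 log units by default

where x_L are the standardized descriptors of the molecule, x_P the
standardized z-scale principal-component scores of the target sequence
(protein and cross terms only for the ion-channel arm), and the noise SD
decreases with assay confidence. The intercept 6.0 and noise scale put
values in the familiar 1 nM – 100 µM window. Crucially, σᵢ = σ₀/√confᵢ makes
confidence-proportional weights exactly inverse-variance weights, so the
weighted-versus-unweighted comparison tests a real phenomenon rather than an
artifact. Values are stored in nM, except that a configurable fraction
(default 30%) of the kinase-arm activities is reported in µM to exercise
unit conversion; ion-channel values are always nM because the
nine-column PCM extraction does not carry a unit column.

Extraction runs the two shipped SPARQL texts (`data/qsar_query.rq`,
`data/pcm_query.rq`) through `rdf_core.query`, substituting the target IRI /
activity type / level-6 regex into the shipped defaults. The QSAR query
projects seven variables (act, ass, mol, smiles, val, unit, conf); the PCM
query projects nine (target, type, pubmed, l4, l5, l6, smiles, val, seq) —
the SMILES doubles as the molecule reference, since the store has exactly
one molecule resource per SMILES. Extraction is verified against a direct
scan of the generator's record tables on every seeded store.

Dataset assembly (`qsar_matrix`) converts values to molar, takes −log₁₀,
and centers/scales the response and each descriptor column to unit variance;
constant columns are dropped with a warning. Weights are confidence
normalized to mean 1 (the mapping is injectable). `simulate_regression` is
the numeric arm of the same generator — standardized Gaussian design,
N(0,1) coefficients, the same confidence/noise law — used where a study
needs dimensions the descriptor set cannot supply (e.g. p = 10).

### What the generator does and does not emulate

It reproduces the *shape* of a bioactivity database (schema, types, units,
confidence semantics, classification filtering) and a recoverable
structure–activity signal. It does not reproduce real chemistry-activity
relationships, realistic descriptor correlation structure, assay batch
effects, censored values ("> 10000 nM"), or the scale of the real database;
passing tests therefore demonstrate the correctness of the machinery, not
predictive performance on real compounds. Published headline figures from
comparable real-data studies (PRESS 9.3 vs 11.2 on 449 kinase compounds;
PCM r = 0.79 on 1149 ion-channel pairs) depend on that real data and on
external descriptor software, and are deliberately not targets here; the
desk-scale stand-ins are the ≥90% weighted-win rate and the r > 0.9
recovery threshold.

## Bayesian weighted ridge regression

The model, for standardized y and X with weights w:

    y | β, σ²  ~ N(Xβ, σ² W⁻¹),  W = diag(w)
    β | τ²     ~ N(0, τ² I)
    σ², τ²     ~ Inverse-Gamma(0.001, 0.001)

The hyperpriors are weakly informative and configurable; the Gibbs sampler
cycles the conjugate full conditionals (β: multivariate normal with
precision XᵀWX/σ² + I/τ²; σ², τ²: inverse-gamma). The β draw factorizes the
precision matrix by Cholesky once per iteration; a non-positive-definite
precision raises a diagnostic error rather than limping on. Defaults are
12000 iterations / 2000 burn-in / thin 1; chains are exactly reproducible
from the seed. With `fix_variances` set, the β draws are iid from the exact
Gaussian posterior — the hook used to validate the sampler against the
closed-form ridge solution and the 1-D conjugate posterior.

Cross-validation draws folds by seeded permutation followed by contiguous
blocking (earlier folds absorb remainder rows), fits each training fold with
a fold-specific deterministic seed, and accumulates held-out predictions
Xβ⁽ˢ⁾ per retained draw. PRESS is reported as a posterior distribution —
PRESS_s = Σᵢ (yᵢ − ŷᵢ⁽ˢ⁾)² — summarized by its mean and central 95% interval
("9.3 (7.6; 12.8)"-style). The posterior-draw convention (rather than
resampling CV replicates) was chosen and is stated here because both
readings are defensible. A training fold with fewer rows than coefficients
triggers a warning and falls back to fixed unit variances for that fold.
`compare_weighted_unweighted` runs the weighted and unit-weight fits on
identical folds so the comparison is paired. The acceptance-scale study
(n = 300, p = 10, 20 seeds, 10-fold) uses 1500-iteration chains inside CV;
at that problem size the β conditional is tight and longer chains change
PRESS by far less than the fold-to-fold variation.

Predictive intervals add per-draw observation noise σ²⁽ˢ⁾/w_new (unit weight
by default) and take empirical quantiles over draws; their 95% coverage is
checked on simulated data.

## Proteochemometrics

Protein side: aligned sequences (alignment is an upstream input; no aligner
is included) are encoded position-major by the three-component z-scales of
each residue — the classic principal-property scales of the 20 amino acids,
shipped as `data/zscales.csv`. Gaps are imputed by the position-wise mean of
non-gap residues (an all-gap position encodes as zero and is dropped by
zero-variance filtering); the choice is stated because no convention is
canonical. The encoded block is autoscaled and compressed by PCA
(column-centered SVD). The component count defaults to 17, clamped to the
data's rank with a warning — with few distinct sequences the rank, not the
default, binds. Autoscaling before PCA (rather than centering only) was
chosen so that no single position dominates by variance alone.

Ligand side: the descriptor matrix, autoscaled. Cross-terms are all
elementwise products of ligand × protein columns (ligand-major order), each
autoscaled; the full product set is used rather than a subset. X is the
concatenation [ligand | protein PCs | cross-terms], y is −log₁₀ molar
activity (Ki and IC50 pooled — the pragmatic choice when both are present).

PLS1 is fitted by NIPALS: each component's weight vector is the normalized
covariance of the deflated X with the deflated y; X is deflated by the
loading, y by its regression on the score; extraction stops early with a
warning when covariance is exhausted. The coefficient vector is
W(PᵀW)⁻¹q. Score orthogonality, the OLS equivalence at one univariate
component, exact fit at full rank, and agreement with scikit-learn's
PLSRegression are all asserted in tests. The component count defaults to the
PRESS-minimizing value on the grid 1..10 under the same folds used for
reporting; this mildly optimistic shortcut is acceptable because the
reported statistic is the held-out Pearson r, not a generalization claim.
Variable importance is ranked by VIP (mean square 1 over columns by
construction), ties broken by column order.

## NMR dereplication

Spectra are RDF resources linking a molecule and one node per peak (shift in
ppm as a decimal literal; optional intensity). Matching a query peak list
against a reference spectrum is greedy one-to-one nearest-neighbour
assignment within a tolerance, processing query peaks in input order; the
score is the matched fraction of query peaks, so "all peaks must match" and
"any near-match" are both expressible as thresholds on the same score.
Results sort by score, then mean absolute deviation, then spectrum id. The
tolerance is an explicit parameter (default 0.5 ppm, a sensible 13C scale);
"near" has no universal definition, and the scoring rule itself is this
package's definition — chosen for transparency, not taken from elsewhere.

The synthetic reference database draws peak positions uniformly on 0–220 ppm
with a global minimum separation (default 0.2 ppm, rejection sampling,
rounded to 0.01 ppm) between all peaks in the database. The separation
guarantees that for any tolerance below half the separation each spectrum is
the unique perfect match for its own peak list, which is what makes the
rank-1 self-dereplication rate a sharp 100% criterion rather than a
probabilistic one.

## Numerical and interface conventions

- All randomness flows through `numpy.random.default_rng(seed)`; every
  stochastic API takes a seed or a seeded config, and CLI runs echo a
  provenance header (version, seed, config hash) to stderr and into text
  outputs.
- Decimal literals in RDF use `repr(float)` so value round-trips are exact.
- Standardization uses population SD (ddof 0); zero-variance columns are
  dropped, never divided by zero.
- Fold assignment, tie-breaks (VIP ties by column order; dereplication ties
  by deviation then id) and early-stop conditions are all deterministic.
- Errors name the offending token/position (SMILES), descriptor, sequence
  position, or SPARQL feature; empty-input cases (empty store, empty
  molecule, empty spectrum, unknown target) return well-defined empty
  results or documented warnings rather than crashing.

## Known limitations

- The SMILES subset excludes stereochemistry and isotopes; aromaticity is
  taken from lowercase notation, not perceived.
- TPSA covers N/O environments only (as the classic parameterization does)
  and within those, only the fragment classes the generator produces.
- The SPARQL subset is intentionally small; no remote endpoints, named
  graphs, or OWL reasoning.
- InChI strings are consumed, never computed from structures.
- PLS is single-response; the Gibbs model assumes standardized inputs and
  exchangeable coefficients (a single τ²).
- Synthetic-data caveats as above: correctness of machinery, not real-world
  predictive performance.
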