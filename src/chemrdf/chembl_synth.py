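"""Seeded synthetic ChEMBL-like triple store and dataset extraction.

This module stands in for a remote bioactivity SPARQL endpoint.  It generates
a deterministic RDF store of targets (with a seven-level classification and
an aligned protein sequence), assays (with integer confidence scores),
molecules (with SMILES from a restricted, descriptor-friendly chemistry) and
activities (IC50/Ki and friends, in nM or uM) — and then extracts QSAR and
proteochemometrics datasets from that store by running the two shipped SPARQL
query texts through :mod:`chemrdf.rdf_core`.

The planted signal makes the store useful for method validation: activity
values are a linear function of standardized ligand descriptors (plus, for
the ion-channel targets, protein principal-property scores and bilinear
ligand x protein cross-terms), with Gaussian noise whose standard deviation
decreases with assay confidence as sigma0/sqrt(conf).  Confidence-proportional
regression weights are therefore inverse-variance optimal, which is what
gives the weighted-versus-unweighted comparison its bite.  The generator
returns this ground truth alongside the store so that recovery can be tested.

Defaults emulate a desk-scale study: 7 targets (one kinase for the QSAR arm,
six voltage-gated ion channels for the PCM arm), 80 molecules, 50 activities
per target, confidence scores 1..9 and baseline noise SD 0.6 log units.
"""

from __future__ import annotations

import importlib.resources
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import vocabulary as voc
from .chemgraph import parse_smiles
from .descriptors import descriptor_matrix
from .rdf_core import IRI, Literal, ResultTable, TripleStore, query

__all__ = [
    "SyntheticConfig",
    "TargetRecord",
    "AssayRecord",
    "ActivityRecord",
    "ChemblRecords",
    "GroundTruth",
    "QSAR_COLUMNS",
    "PCM_COLUMNS",
    "DATA_BASE",
    "random_smiles",
    "generate_records",
    "records_to_store",
    "generate_chembl_store",
    "qsar_query_text",
    "pcm_query_text",
    "extract_qsar_dataset",
    "extract_pcm_dataset",
    "list_activity_types",
    "qsar_matrix",
    "simulate_regression",
]

DATA_BASE = "http://chemrdf.example.org/data/"
QSAR_COLUMNS = ["act", "ass", "mol", "smiles", "val", "unit", "conf"]
PCM_COLUMNS = ["target", "type", "pubmed", "l4", "l5", "l6", "smiles", "val", "seq"]
ACTIVITY_TYPES = ("IC50", "Ki", "Ki app", "Inhibition", "Activity")
DEFAULT_DESCRIPTORS = (
    "heavyAtomCount", "bondCount", "ringCount", "molecularWeight", "tpsa",
)
_UNIT_TO_MOLAR = {"nM": 1e-9, "uM": 1e-6}

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"


@dataclass
class SyntheticConfig:
    """Knobs of the synthetic study; the seed fixes every random draw."""

    seed: int = 0
    n_targets: int = 7           # first is the kinase QSAR target (id 10885)
    n_molecules: int = 80
    activities_per_target: int = 50
    sequence_length: int = 30
    confidence_range: tuple[int, int] = (1, 9)
    base_noise_sd: float = 0.6   # log-unit SD at confidence 1
    descriptor_ids: Sequence[str] = DEFAULT_DESCRIPTORS
    true_coefficients: Optional[np.ndarray] = None  # ligand betas, len p
    protein_components: int = 3
    protein_effect_sd: float = 0.5
    cross_effect_sd: float = 0.25
    intercept: float = 6.0       # mean -log10 molar activity
    first_target_id: int = 10885
    # fraction of kinase-arm activities reported in uM instead of nM
    um_fraction: float = 0.3
    extra_activity_types: bool = True

    def noise_sd(self, confidence: int) -> float:
        return self.base_noise_sd / np.sqrt(confidence)


@dataclass
class TargetRecord:
    id: int
    title: str
    target_type: str
    organism: str
    classification: tuple  # levels l1..l7
    sequence: str


@dataclass
class AssayRecord:
    id: int
    target: int
    confidence: int


@dataclass
class ActivityRecord:
    id: int
    assay: int
    molecule: int
    target: int
    type: str
    value: float  # > 0, in `unit`
    unit: str
    pubmed: int


@dataclass
class ChemblRecords:
    targets: list[TargetRecord]
    assays: list[AssayRecord]
    activities: list[ActivityRecord]
    molecule_smiles: list[str]


@dataclass
class GroundTruth:
    records: ChemblRecords
    ligand_beta: np.ndarray            # on standardized descriptor scale
    protein_beta: np.ndarray
    cross_beta: np.ndarray             # p x k bilinear coefficient matrix
    protein_scores: dict[int, np.ndarray]  # target id -> k-vector
    ligand_design: np.ndarray          # n_molecules x p standardized
    noise_sd_by_confidence: dict[int, float]
    intercept: float


# --- molecule generation -----------------------------------------------------

_CORES = (
    "CC", "CCC", "CCCC", "CCCCC", "CC(C)C", "CCC(C)C",
    "C1CCCC1", "C1CCCCC1", "CC1CCCCC1",
    "c1ccccc1", "Cc1ccccc1", "c1ccncc1", "c1ccoc1", "c1cc[nH]c1",
)
_GROUPS = (
    "O",          # hydroxyl
    "OC",         # methyl ether
    "N",          # primary amine
    "NC",         # secondary amine
    "N(C)C",      # tertiary amine
    "C#N",        # nitrile
    "C(C)=O",     # methyl ketone
    "C(=O)O",     # carboxylic acid
    "C(=O)OC",    # methyl ester
    "CO",         # hydroxymethyl
    "C", "CC",    # plain alkyl
)


def random_smiles(rng: np.random.Generator) -> str:
    """One random SMILES from the generator's restricted chemistry.

    Functional groups hang as substituents off the core's final atom (so a
    terminal heteroatom of one group is never extended into another).  Every
    emitted string parses under the package grammar, is kekulizable (plain
    benzene/pyridine/furan/pyrrole aromatics only) and contains only N/O
    environments covered by the packaged TPSA table.
    """
    core = _CORES[rng.integers(len(_CORES))]
    max_groups = 1 if "c1" in core else 2  # aromatic carbon holds one substituent
    n_groups = int(rng.integers(0, max_groups + 1))
    groups = [str(_GROUPS[rng.integers(len(_GROUPS))]) for _ in range(n_groups)]
    if not groups:
        return core
    branches = "".join(f"({g})" for g in groups[:-1])
    return core + branches + groups[-1]


def _random_sequences(
    rng: np.random.Generator, n: int, length: int
) -> list[str]:
    """Aligned (equal-length) sequences mutated from a common ancestor."""
    ancestor = [AMINO_ACIDS[i] for i in rng.integers(0, 20, size=length)]
    seqs = []
    for _ in range(n):
        seq = list(ancestor)
        for pos in range(length):
            if rng.random() < 0.3:
                seq[pos] = AMINO_ACIDS[int(rng.integers(0, 20))]
        seqs.append("".join(seq))
    return seqs


# --- record generation -------------------------------------------------------

_ION_L6 = ("Sodium channel", "Calcium channel")


def _standardize_columns(M: np.ndarray) -> np.ndarray:
    M = M - M.mean(axis=0)
    sd = M.std(axis=0)
    sd[sd == 0] = 1.0
    return M / sd


def generate_records(config: SyntheticConfig) -> tuple[ChemblRecords, GroundTruth]:
    """Draw the record tables and the planted structure-activity signal."""
    rng = np.random.default_rng(config.seed)
    smiles = [random_smiles(rng) for _ in range(config.n_molecules)]
    p = len(config.descriptor_ids)

    if config.n_molecules:
        mols = [parse_smiles(s) for s in smiles]
        X = _standardize_columns(
            descriptor_matrix(mols, config.descriptor_ids).values)
    else:
        X = np.zeros((0, p))

    beta = (
        np.asarray(config.true_coefficients, dtype=float)
        if config.true_coefficients is not None
        else rng.normal(0.0, 1.0, size=p)
    )
    if beta.shape != (p,):
        raise ValueError("true_coefficients length must match descriptor_ids")

    # targets: first is the kinase (QSAR arm), the rest ion channels (PCM arm)
    seqs = _random_sequences(rng, config.n_targets, config.sequence_length)
    targets = []
    for i in range(config.n_targets):
        tid = config.first_target_id + i
        if i == 0:
            classification = (
                "Protein", "Enzyme", "Kinase", "Protein Kinase",
                "CAMK protein kinase group", "CAMK protein kinase DAPK family",
                "Kinase domain")
            title = f"serine/threonine-protein kinase {tid}"
        else:
            l6 = _ION_L6[(i - 1) % 2]
            classification = (
                "Protein", "Membrane receptor", "Ion channel",
                "Ion channel", "Voltage-gated ion channel", l6,
                f"{l6} alpha subunit")
            title = f"voltage-gated {l6.lower()} subunit {tid}"
        targets.append(TargetRecord(
            id=tid, title=title, target_type="SINGLE PROTEIN",
            organism="Homo sapiens", classification=classification,
            sequence=seqs[i],
        ))

    # protein principal-property scores for the planted bilinear signal
    k = min(config.protein_components,
            max(1, config.n_targets - 1)) if config.n_targets else 1
    if config.n_targets > 1:
        from .pcm import encode_sequences, load_zscales, pca_reduce

        Z = encode_sequences(seqs, load_zscales())
        keep = Z.std(axis=0) > 0
        scores, _, _ = pca_reduce(Z[:, keep], min(k, int(np.linalg.matrix_rank(
            Z[:, keep] - Z[:, keep].mean(axis=0)))))
        scores = _standardize_columns(scores)
    else:
        scores = np.zeros((config.n_targets, k))
    k = scores.shape[1]
    protein_scores = {t.id: scores[i] for i, t in enumerate(targets)}
    beta_p = rng.normal(0.0, config.protein_effect_sd, size=k)
    B = rng.normal(0.0, config.cross_effect_sd, size=(p, k))

    lo, hi = config.confidence_range
    noise_map = {c: float(config.noise_sd(c)) for c in range(lo, hi + 1)}

    assays: list[AssayRecord] = []
    activities: list[ActivityRecord] = []
    for t_index, target in enumerate(targets):
        is_kinase = t_index == 0
        for _ in range(config.activities_per_target):
            if config.n_molecules == 0:
                break
            conf = int(rng.integers(lo, hi + 1))
            assay = AssayRecord(id=len(assays), target=target.id,
                                confidence=conf)
            assays.append(assay)
            mol_idx = int(rng.integers(config.n_molecules))
            if config.extra_activity_types and rng.random() < 0.15:
                atype = str(ACTIVITY_TYPES[2 + int(rng.integers(3))])
                value = float(10 ** rng.uniform(0, 4))
                unit = "uM" if rng.random() < 0.5 else "nM"
            else:
                atype = "IC50" if rng.random() < (0.85 if is_kinase else 0.7) \
                    else "Ki"
                pact = config.intercept + float(X[mol_idx] @ beta)
                if not is_kinase:
                    xp = protein_scores[target.id]
                    pact += float(xp @ beta_p + X[mol_idx] @ B @ xp)
                pact += rng.normal(0.0, noise_map[conf])
                value_nm = 10 ** (9.0 - pact)
                if is_kinase and rng.random() < config.um_fraction:
                    value, unit = value_nm / 1e3, "uM"
                else:
                    value, unit = value_nm, "nM"
            activities.append(ActivityRecord(
                id=len(activities), assay=assay.id, molecule=mol_idx,
                target=target.id, type=atype, value=value, unit=unit,
                pubmed=int(rng.integers(10_000_000, 30_000_000)),
            ))

    records = ChemblRecords(
        targets=targets, assays=assays, activities=activities,
        molecule_smiles=smiles,
    )
    truth = GroundTruth(
        records=records, ligand_beta=beta, protein_beta=beta_p, cross_beta=B,
        protein_scores=protein_scores, ligand_design=X,
        noise_sd_by_confidence=noise_map, intercept=config.intercept,
    )
    return records, truth


# --- RDF store ---------------------------------------------------------------


def _decimal(value: float) -> Literal:
    return Literal(repr(float(value)), datatype=voc.XSD_DECIMAL)


def _integer(value: int) -> Literal:
    return Literal(str(int(value)), datatype=voc.XSD_INTEGER)


def target_iri(target_id: int) -> IRI:
    return IRI(f"{DATA_BASE}target/{target_id}")


def records_to_store(records: ChemblRecords) -> TripleStore:
    """Serialize the record tables under the package's bioactivity vocabulary."""
    store = TripleStore(prefixes=dict(voc.PREFIXES))
    store.bind("data", DATA_BASE)
    mol_iris = []
    for i, smi in enumerate(records.molecule_smiles):
        m = IRI(f"{DATA_BASE}molecule/{i}")
        mol_iris.append(m)
        store.add(m, voc.RDF_TYPE, voc.CH_MOLECULE)
        store.add(m, voc.CH_SMILES, Literal(smi))
    for t in records.targets:
        ti = target_iri(t.id)
        store.add(ti, voc.RDF_TYPE, voc.CH_TARGET)
        store.add(ti, voc.CH_TITLE, Literal(t.title))
        store.add(ti, voc.CH_TARGET_TYPE, Literal(t.target_type))
        store.add(ti, voc.CH_ORGANISM, Literal(t.organism))
        store.add(ti, voc.CH_SEQUENCE, Literal(t.sequence))
        for level, text in enumerate(t.classification, start=1):
            store.add(ti, voc.CH_CLASS_LEVEL[level], Literal(text))
    for a in records.assays:
        ai = IRI(f"{DATA_BASE}assay/{a.id}")
        store.add(ai, voc.RDF_TYPE, voc.CH_ASSAY)
        store.add(ai, voc.CH_HAS_TARGET, target_iri(a.target))
        store.add(ai, voc.CH_CONF_SCORE, _integer(a.confidence))
    for act in records.activities:
        ci = IRI(f"{DATA_BASE}activity/{act.id}")
        store.add(ci, voc.RDF_TYPE, voc.CH_ACTIVITY)
        store.add(ci, voc.CH_ON_ASSAY, IRI(f"{DATA_BASE}assay/{act.assay}"))
        store.add(ci, voc.CH_FOR_MOLECULE, mol_iris[act.molecule])
        store.add(ci, voc.CH_ACTIVITY_TYPE, Literal(act.type))
        store.add(ci, voc.CH_STANDARD_VALUE, _decimal(act.value))
        store.add(ci, voc.CH_STANDARD_UNITS, Literal(act.unit))
        store.add(ci, voc.CH_PUBMED, _integer(act.pubmed))
    return store


def generate_chembl_store(
    config: Optional[SyntheticConfig] = None,
) -> tuple[TripleStore, GroundTruth]:
    """Generate the synthetic bioactivity store plus its ground truth."""
    config = config or SyntheticConfig()
    records, truth = generate_records(config)
    return records_to_store(records), truth


# --- extraction --------------------------------------------------------------


def _read_asset(name: str) -> str:
    return (
        importlib.resources.files("chemrdf") / "data" / name
    ).read_text(encoding="utf-8")


def qsar_query_text(
    target_id: int = 10885, activity_type: str = "IC50"
) -> str:
    """The QSAR extraction query, re-targeted from its shipped defaults."""
    text = _read_asset("qsar_query.rq")
    text = text.replace(
        f"<{DATA_BASE}target/10885>", f"<{DATA_BASE}target/{target_id}>")
    return text.replace('"IC50"', f'"{activity_type}"')


def pcm_query_text(level6_filter: str = "Sodium") -> str:
    """The PCM extraction query with the level-6 classification pattern."""
    text = _read_asset("pcm_query.rq")
    return text.replace('regex(?l6, "Sodium")',
                        f'regex(?l6, "{level6_filter}")')


def _table_to_frame(table: ResultTable, columns: list[str]) -> pd.DataFrame:
    rows = []
    for row in table.rows:
        rows.append({var: (None if row[var] is None else str(row[var]))
                     for var in table.variables})
    frame = pd.DataFrame(rows, columns=columns)
    return frame


def extract_qsar_dataset(
    store: TripleStore, target_id: int, activity_type: str = "IC50"
) -> pd.DataFrame:
    """One row per matching activity: the seven QSAR columns.

    An unknown target yields an empty dataset with a warning rather than an
    error (mirroring interactive wizard behaviour).
    """
    if not store.objects(target_iri(target_id), voc.RDF_TYPE):
        warnings.warn(f"target {target_id} not present in store; "
                      "returning empty dataset", stacklevel=2)
    table = query(store, qsar_query_text(target_id, activity_type))
    frame = _table_to_frame(table, QSAR_COLUMNS)
    if len(frame):
        frame["val"] = frame["val"].astype(float)
        frame["conf"] = frame["conf"].astype(int)
        frame = frame.sort_values("act", kind="stable").reset_index(drop=True)
    return frame


def extract_pcm_dataset(
    store: TripleStore, level6_filter: str = "Sodium"
) -> pd.DataFrame:
    """Ki/IC50 rows for targets whose level-6 class matches the filter."""
    table = query(store, pcm_query_text(level6_filter))
    frame = _table_to_frame(table, PCM_COLUMNS)
    if len(frame):
        frame["val"] = frame["val"].astype(float)
        frame["pubmed"] = frame["pubmed"].astype(int)
        frame = frame.sort_values(
            ["target", "pubmed", "smiles", "val"], kind="stable"
        ).reset_index(drop=True)
    return frame


def list_activity_types(store: TripleStore, target_id: int) -> list[str]:
    """Distinct activity types recorded against one target, sorted."""
    sparql = f"""
    PREFIX chembl: <{voc.CHEMBL}>
    SELECT DISTINCT ?type WHERE {{
        ?act chembl:onAssay ?ass ;
             chembl:activityType ?type .
        ?ass chembl:hasTarget <{DATA_BASE}target/{target_id}> .
    }}
    """
    table = query(store, sparql)
    return sorted(str(row["type"]) for row in table.rows)


# --- numeric dataset assembly ------------------------------------------------


def qsar_matrix(
    dataset: pd.DataFrame,
    descriptor_ids: Sequence[str] = DEFAULT_DESCRIPTORS,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Standardized design matrix, response and confidence weights.

    Activities are converted to molar, transformed as -log10, then centered
    and scaled to unit variance; descriptor columns likewise.  Weights are
    confidence scores normalized to mean 1 (proportionally higher weight for
    higher-confidence observations).  Constant descriptor columns are dropped
    with a warning.
    """
    if len(dataset) < 2:
        raise ValueError("need at least two activities")
    unknown = set(dataset["unit"]) - set(_UNIT_TO_MOLAR)
    if unknown:
        raise ValueError(f"unknown activity units: {sorted(unknown)}")
    molar = dataset["val"].to_numpy(float) * np.array(
        [_UNIT_TO_MOLAR[u] for u in dataset["unit"]])
    y = -np.log10(molar)
    if np.std(y) == 0:
        raise ValueError("response has zero variance")
    y = (y - y.mean()) / y.std()

    mols = [parse_smiles(s) for s in dataset["smiles"]]
    X = descriptor_matrix(mols, descriptor_ids).values
    keep = X.std(axis=0) > 0
    if not keep.all():
        dropped = [d for d, k in zip(descriptor_ids, keep) if not k]
        warnings.warn(f"dropping constant descriptor columns: {dropped}",
                      stacklevel=2)
    X = X[:, keep]
    X = (X - X.mean(axis=0)) / X.std(axis=0)

    conf = dataset["conf"].to_numpy(float)
    w = conf / conf.mean()
    return X, y, w


def simulate_regression(
    n: int = 300,
    p: int = 10,
    seed: int = 0,
    base_noise_sd: float = 0.6,
    confidence_range: tuple[int, int] = (1, 9),
    heteroscedastic: bool = True,
) -> dict:
    """Directly simulate the weighted-regression study conditions.

    The numeric arm of the generator: a standardized Gaussian design,
    coefficients drawn N(0,1), confidence scores uniform on the configured
    range, and noise SD ``base_noise_sd/sqrt(conf)`` (or constant at
    ``base_noise_sd`` for the homoscedastic control).  Returns the design,
    response, mean-1 confidence weights, and the ground truth.
    """
    rng = np.random.default_rng(seed)
    X = _standardize_columns(rng.normal(size=(n, p)))
    beta = rng.normal(size=p)
    conf = rng.integers(confidence_range[0], confidence_range[1] + 1, size=n)
    sd = (base_noise_sd / np.sqrt(conf)) if heteroscedastic \
        else np.full(n, float(base_noise_sd))
    y = X @ beta + rng.normal(0.0, sd)
    w = conf / conf.mean()
    return {
        "X": X, "y": y, "w": w.astype(float), "beta": beta,
        "confidence": conf, "noise_sd": sd,
    }
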