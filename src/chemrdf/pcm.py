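"""Proteochemometrics: z-scale encoding, PCA, cross-terms, PLS, VIP.

A proteochemometric model regresses interaction activity on ligand
descriptors, protein descriptors and ligand x protein cross-terms, so that
selectivity (which compound inhibits which protein) becomes learnable, not
just potency.  Here the protein side starts from an alignment of equal-length
sequences, encodes every position by the three principal physicochemical
property scales of its residue (z-scales), and compresses the resulting
3L-column block to a handful of orthogonal principal components (default 17,
clamped to the data's rank).  Ligand descriptors come from
:mod:`chemrdf.descriptors`; cross-terms are the elementwise products of the
two blocks.  The regression is PLS1 fitted by NIPALS, with variable
importance ranked by VIP scores and predictive ability estimated by k-fold
cross-validation (default 7-fold) as the Pearson correlation between held-out
predicted and observed activity.
"""

from __future__ import annotations

import csv
import importlib.resources
import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .chemgraph import parse_smiles
from .descriptors import descriptor_matrix
from .qsar_bayes import make_folds

__all__ = [
    "ZScaleTable",
    "load_zscales",
    "read_fasta_alignment",
    "encode_sequences",
    "pca_reduce",
    "cross_terms",
    "PLSModel",
    "pls_fit",
    "pls_predict",
    "importance_ranking",
    "PCMCVResult",
    "pcm_cross_validate",
    "DEFAULT_PROTEIN_COMPONENTS",
]

GAP = "-"
DEFAULT_PROTEIN_COMPONENTS = 17

ZScaleTable = dict  # residue letter -> (z1, z2, z3)


def load_zscales() -> ZScaleTable:
    """The packaged 3-component z-scale table for the 20 canonical residues."""
    path = importlib.resources.files("chemrdf") / "data" / "zscales.csv"
    table: ZScaleTable = {}
    with path.open() as fh:
        for row in csv.DictReader(fh):
            table[row["residue"]] = (
                float(row["z1"]), float(row["z2"]), float(row["z3"]))
    return table


def read_fasta_alignment(path_or_text: str) -> list[str]:
    """Read an aligned FASTA file (gaps allowed); returns the sequences.

    Accepts a path or the FASTA text itself; all sequences must be equal
    length (it is an alignment, produced upstream).
    """
    text = path_or_text
    if not path_or_text.lstrip().startswith(">"):
        with open(path_or_text) as fh:
            text = fh.read()
    seqs, current = [], []
    for line in text.splitlines():
        line = line.strip()
        if not line:
            continue
        if line.startswith(">"):
            if current:
                seqs.append("".join(current))
                current = []
        else:
            current.append(line)
    if current:
        seqs.append("".join(current))
    if seqs and len({len(s) for s in seqs}) != 1:
        raise ValueError("sequences are not aligned (unequal lengths)")
    return seqs


def encode_sequences(
    alignment: Sequence[str], table: Optional[ZScaleTable] = None
) -> np.ndarray:
    """Encode aligned sequences as an n x 3L z-scale matrix.

    Columns are position-major: position j contributes columns
    (3j, 3j+1, 3j+2) holding (z1, z2, z3) of the residue at j.  A gap is
    imputed by the position-wise mean of the non-gap residues' z values (an
    all-gap position encodes as zero and yields constant columns, dropped by
    downstream zero-variance filtering).
    """
    if table is None:
        table = load_zscales()
    if not alignment:
        return np.zeros((0, 0))
    length = len(alignment[0])
    for i, seq in enumerate(alignment):
        if len(seq) != length:
            raise ValueError(
                f"sequence {i} has length {len(seq)}, alignment is {length}")
        for j, letter in enumerate(seq):
            if letter != GAP and letter not in table:
                raise ValueError(
                    f"unknown residue {letter!r} in sequence {i} position {j}")
    n = len(alignment)
    out = np.zeros((n, 3 * length))
    for j in range(length):
        residues = [seq[j] for seq in alignment]
        known = [table[r] for r in residues if r != GAP]
        gap_value = (
            np.mean(known, axis=0) if known else np.zeros(3))
        for i, r in enumerate(residues):
            out[i, 3 * j:3 * j + 3] = table[r] if r != GAP else gap_value
    return out


def pca_reduce(
    M: np.ndarray, k: int
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Column-centered PCA via SVD.

    Returns (scores n x k, loadings q x k, explained variances).  Scores are
    mutually orthogonal and explained variances nonincreasing; at full rank
    ``scores @ loadings.T + column_means`` reconstructs M.
    """
    M = np.asarray(M, dtype=float)
    n, q = M.shape
    if k < 1 or k > min(n - 1, q):
        raise ValueError(
            f"k={k} out of range 1..min(n-1={n - 1}, q={q})")
    centered = M - M.mean(axis=0)
    U, s, Vt = np.linalg.svd(centered, full_matrices=False)
    scores = U[:, :k] * s[:k]
    loadings = Vt[:k].T
    explained = (s ** 2) / max(n - 1, 1)
    return scores, loadings, explained[:k]


def cross_terms(XL: np.ndarray, XP: np.ndarray) -> np.ndarray:
    """Ligand x protein interaction block: column (a, b) = XL[:,a] * XP[:,b],
    ordered ligand-major; always p*k columns."""
    XL = np.asarray(XL, dtype=float)
    XP = np.asarray(XP, dtype=float)
    if XL.shape[0] != XP.shape[0]:
        raise ValueError("row counts differ")
    n, p = XL.shape
    k = XP.shape[1]
    return (XL[:, :, None] * XP[:, None, :]).reshape(n, p * k)


# --- PLS (NIPALS, single response) ------------------------------------------


@dataclass
class PLSModel:
    n_components: int
    weights: np.ndarray      # m x A
    x_loadings: np.ndarray   # m x A
    scores: np.ndarray       # n x A (training scores)
    y_loadings: np.ndarray   # A
    coef: np.ndarray         # m, maps centered X to centered y
    x_mean: np.ndarray
    y_mean: float


def pls_fit(X: np.ndarray, y: np.ndarray, n_components: int) -> PLSModel:
    """Fit PLS1 by NIPALS: sequential covariance-maximizing components.

    Each component's weight vector is the (normalized) covariance of the
    deflated X with the deflated y; X is deflated by the component's loading
    and y by its regression on the score.  Extraction stops early, with a
    warning, if the remaining covariance vanishes.  Centering is handled
    internally; callers are expected to have scaled the columns.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n, m = X.shape
    if y.shape != (n,):
        raise ValueError("y length must match X rows")
    if n_components < 1:
        raise ValueError("n_components must be >= 1")
    x_mean = X.mean(axis=0)
    y_mean = float(y.mean())
    Xd = X - x_mean
    yd = y - y_mean

    W = np.zeros((m, n_components))
    P = np.zeros((m, n_components))
    T = np.zeros((n, n_components))
    q = np.zeros(n_components)
    extracted = 0
    for a in range(n_components):
        cov = Xd.T @ yd
        norm = np.linalg.norm(cov)
        if norm < 1e-12:
            warnings.warn(
                f"covariance exhausted after {extracted} components "
                f"(requested {n_components})", stacklevel=2)
            break
        w = cov / norm
        t = Xd @ w
        tt = float(t @ t)
        if tt < 1e-12:
            warnings.warn(
                f"degenerate score at component {a + 1}; stopping early",
                stacklevel=2)
            break
        p_load = Xd.T @ t / tt
        q_a = float(yd @ t) / tt
        Xd = Xd - np.outer(t, p_load)
        yd = yd - q_a * t
        W[:, a], P[:, a], T[:, a], q[a] = w, p_load, t, q_a
        extracted += 1
    if extracted == 0:
        raise ValueError("no PLS component could be extracted "
                         "(X carries no covariance with y)")
    W, P, T, q = W[:, :extracted], P[:, :extracted], T[:, :extracted], q[:extracted]
    # beta = W (P'W)^-1 q maps centered X to centered y
    coef = W @ np.linalg.solve(P.T @ W, q)
    return PLSModel(
        n_components=extracted, weights=W, x_loadings=P, scores=T,
        y_loadings=q, coef=coef, x_mean=x_mean, y_mean=y_mean,
    )


def pls_predict(model: PLSModel, X: np.ndarray) -> np.ndarray:
    X = np.atleast_2d(np.asarray(X, dtype=float))
    return (X - model.x_mean) @ model.coef + model.y_mean


def importance_ranking(
    model: PLSModel, column_names: Optional[Sequence[str]] = None
) -> list[tuple[str, float]]:
    """VIP scores per column, descending (ties broken by column order).

    VIP_j = sqrt( m * sum_a SS_a (w_ja / ||w_a||)^2 / sum_a SS_a ) with
    SS_a = q_a^2 t_a' t_a, the y-variance explained by component a; the
    mean square of the VIPs over columns is 1 by construction.
    """
    m = model.weights.shape[0]
    if column_names is None:
        column_names = [f"x{j}" for j in range(m)]
    if len(column_names) != m:
        raise ValueError("one name per column required")
    ss = model.y_loadings ** 2 * (model.scores ** 2).sum(axis=0)  # per comp
    wnorm2 = (model.weights ** 2).sum(axis=0)
    wnorm2[wnorm2 == 0] = 1.0
    contrib = (model.weights ** 2 / wnorm2) @ ss
    vip = np.sqrt(m * contrib / ss.sum())
    order = sorted(range(m), key=lambda j: (-vip[j], j))
    return [(str(column_names[j]), float(vip[j])) for j in order]


# --- full pipeline -----------------------------------------------------------


def _autoscale(M: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Center/unit-scale columns; returns (scaled, keep-mask). Zero-variance
    columns are dropped rather than scaled."""
    sd = M.std(axis=0)
    keep = sd > 0
    scaled = (M[:, keep] - M[:, keep].mean(axis=0)) / sd[keep]
    return scaled, keep


@dataclass
class PCMCVResult:
    predictions: np.ndarray
    observed: np.ndarray
    pearson_r: float
    n_components: int
    fold_assignment: np.ndarray
    column_names: list[str]
    model: PLSModel  # fitted on all rows with the chosen component count


def pcm_cross_validate(
    dataset: pd.DataFrame,
    descriptor_ids: Sequence[str] = (
        "heavyAtomCount", "bondCount", "ringCount", "molecularWeight", "tpsa"),
    k: int = 7,
    n_components: Optional[int] = None,
    seed: int = 0,
    protein_components: int = DEFAULT_PROTEIN_COMPONENTS,
) -> PCMCVResult:
    """Cross-validated proteochemometric model on an extracted dataset.

    Builds X = [ligand descriptors | protein PCA scores | cross-terms] with
    every block autoscaled, y = -log10 molar activity (values in nM), runs
    seeded k-fold cross-validation, and reports the Pearson correlation
    between held-out predictions and observations.  When ``n_components`` is
    None the component count minimizing cross-validated PRESS on the grid
    1..10 is used.  Protein components are clamped to the rank of the
    encoded-sequence block, with a warning when fewer than requested.
    """
    if dataset.empty:
        raise ValueError("dataset is empty")
    if dataset["seq"].isna().any():
        missing = dataset.index[dataset["seq"].isna()].tolist()
        raise ValueError(f"rows without protein sequence: {missing[:5]}")
    n = len(dataset)
    y = -np.log10(dataset["val"].to_numpy(float) * 1e-9)

    mols = [parse_smiles(s) for s in dataset["smiles"]]
    XL, keepL = _autoscale(descriptor_matrix(mols, descriptor_ids).values)
    ligand_names = [d for d, kf in zip(descriptor_ids, keepL) if kf]

    seqs = dataset["seq"].tolist()
    unique = sorted(set(seqs))
    Z = encode_sequences(unique)
    Zs, _ = _autoscale(Z)
    rank = int(np.linalg.matrix_rank(Zs - Zs.mean(axis=0)))
    kp = min(protein_components, rank, len(unique) - 1)
    if kp < 1:
        raise ValueError("protein block is degenerate (single sequence?)")
    if kp < protein_components:
        warnings.warn(
            f"protein components clamped to {kp} (requested "
            f"{protein_components}, data rank {rank})", stacklevel=2)
    scores, _, _ = pca_reduce(Zs, kp)
    seq_to_row = {s: scores[i] for i, s in enumerate(unique)}
    XPraw = np.vstack([seq_to_row[s] for s in seqs])
    XP, keepP = _autoscale(XPraw)
    protein_names = [f"PC{j + 1}" for j, kf in enumerate(keepP) if kf]

    XC, keepC = _autoscale(cross_terms(XL, XP))
    cross_names = [
        f"{a}*{b}" for a in ligand_names for b in protein_names]
    cross_names = [nm for nm, kf in zip(cross_names, keepC) if kf]

    X = np.hstack([XL, XP, XC])
    names = ligand_names + protein_names + list(cross_names)

    folds = make_folds(n, k, seed)

    def cv_predict(A: int) -> np.ndarray:
        preds = np.empty(n)
        for fold in range(k):
            test = folds == fold
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                model = pls_fit(X[~test], y[~test], A)
            preds[test] = pls_predict(model, X[test])
        return preds

    max_a = min(10, np.linalg.matrix_rank(X - X.mean(axis=0)))
    if n_components is None:
        press = {}
        for A in range(1, max_a + 1):
            press[A] = float(((y - cv_predict(A)) ** 2).sum())
        n_components = min(press, key=press.get)
    predictions = cv_predict(n_components)
    r = float(np.corrcoef(predictions, y)[0, 1])
    final_model = pls_fit(X, y, n_components)
    return PCMCVResult(
        predictions=predictions, observed=y, pearson_r=r,
        n_components=n_components, fold_assignment=folds,
        column_names=names, model=final_model,
    )
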