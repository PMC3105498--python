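"""NMR spectra as RDF and spectral dereplication by peak-shift matching.

A reference database is an RDF store of spectra, each linked to its molecule
and carrying one resource per peak with a chemical shift in ppm.  Two query
styles are supported, mirroring the classic knowledge-base formulation:
finding molecules with any peak near a given shift, and dereplicating a full
measured peak list against every reference spectrum.  Matching is greedy
one-to-one nearest-neighbour within a tolerance (the tolerance is an explicit
parameter — "near" has no universal definition — defaulting to 0.5 ppm,
appropriate for 13C shifts), and the similarity score is the matched fraction
of query peaks.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np

from . import vocabulary as voc
from .rdf_core import IRI, Literal, TripleStore

__all__ = [
    "Peak",
    "Spectrum",
    "MatchResult",
    "DEFAULT_TOLERANCE",
    "spectrum_to_rdf",
    "spectrum_from_rdf",
    "spectra_in_store",
    "find_molecules_with_peak_near",
    "match_spectrum",
    "generate_spectra_db",
    "results_to_csv",
]

DEFAULT_TOLERANCE = 0.5  # ppm, 13C-scale
NMR_DATA_BASE = "http://chemrdf.example.org/data/nmr/"


@dataclass(frozen=True)
class Peak:
    shift: float  # chemical shift, ppm
    intensity: Optional[float] = None

    def __post_init__(self):
        if not np.isfinite(self.shift):
            raise ValueError("peak shift must be finite")
        if self.intensity is not None and self.intensity < 0:
            raise ValueError("peak intensity must be nonnegative")


@dataclass
class Spectrum:
    id: str                       # IRI text
    molecule_ref: str             # IRI text
    peaks: list[Peak] = field(default_factory=list)
    nucleus: str = "13C"

    def __post_init__(self):
        self.peaks = sorted(self.peaks, key=lambda p: p.shift)

    @property
    def shifts(self) -> list[float]:
        return [p.shift for p in self.peaks]


@dataclass
class MatchResult:
    spectrum_id: str
    molecule_ref: str
    score: float                           # matched query peaks / total
    matched_pairs: list[tuple[float, float]]  # (query shift, db shift)

    @property
    def mean_abs_deviation(self) -> float:
        if not self.matched_pairs:
            return float("inf")
        return float(np.mean([abs(q - d) for q, d in self.matched_pairs]))


def _decimal(value: float) -> Literal:
    return Literal(repr(float(value)), datatype=voc.XSD_DECIMAL)


def spectrum_to_rdf(spectrum: Spectrum) -> TripleStore:
    """One spectrum resource linking its molecule and one node per peak."""
    store = TripleStore(prefixes=dict(voc.PREFIXES))
    s = IRI(spectrum.id)
    store.add(s, voc.RDF_TYPE, voc.NMR_SPECTRUM)
    store.add(s, voc.NMR_NUCLEUS, Literal(spectrum.nucleus))
    store.add(s, voc.NMR_OF_MOLECULE, IRI(spectrum.molecule_ref))
    for i, peak in enumerate(spectrum.peaks):
        node = IRI(f"{spectrum.id}/peak{i}")
        store.add(s, voc.NMR_HAS_PEAK, node)
        store.add(node, voc.RDF_TYPE, voc.NMR_PEAK)
        store.add(node, voc.NMR_SHIFT, _decimal(peak.shift))
        if peak.intensity is not None:
            store.add(node, voc.NMR_INTENSITY, _decimal(peak.intensity))
    return store


def spectrum_from_rdf(store: TripleStore, iri: str | IRI) -> Spectrum:
    """Read one spectrum back; a peak without a shift is a structural error."""
    s = IRI(iri) if isinstance(iri, str) else iri
    if (s, voc.RDF_TYPE, voc.NMR_SPECTRUM) not in store:
        raise ValueError(f"no spectrum resource at {s}")
    molecule = store.object(s, voc.NMR_OF_MOLECULE)
    nucleus = store.object(s, voc.NMR_NUCLEUS)
    peaks = []
    for node in store.objects(s, voc.NMR_HAS_PEAK):
        shift = store.object(node, voc.NMR_SHIFT)
        if shift is None:
            raise ValueError(f"peak {node} has no shift")
        intensity = store.object(node, voc.NMR_INTENSITY)
        peaks.append(Peak(
            shift=float(str(shift)),
            intensity=float(str(intensity)) if intensity is not None else None,
        ))
    return Spectrum(
        id=s.value,
        molecule_ref=str(molecule) if molecule is not None else "",
        peaks=peaks,
        nucleus=str(nucleus) if nucleus is not None else "13C",
    )


def spectra_in_store(store: TripleStore) -> list[Spectrum]:
    """All spectra in the store, sorted by IRI for reproducible iteration."""
    iris = sorted(
        s.value for s in store.subjects(voc.RDF_TYPE, voc.NMR_SPECTRUM)
        if isinstance(s, IRI)
    )
    return [spectrum_from_rdf(store, iri) for iri in iris]


def find_molecules_with_peak_near(
    store: TripleStore, shift: float, tol: float = DEFAULT_TOLERANCE
) -> list[str]:
    """Molecules with any spectrum peak within ``tol`` ppm of ``shift``,
    deduplicated and sorted by their best (smallest) deviation."""
    if tol < 0:
        raise ValueError("tolerance must be nonnegative")
    best: dict[str, float] = {}
    for spectrum in spectra_in_store(store):
        for peak in spectrum.peaks:
            dev = abs(peak.shift - shift)
            if dev <= tol:
                mol = spectrum.molecule_ref
                if mol not in best or dev < best[mol]:
                    best[mol] = dev
    return sorted(best, key=lambda m: (best[m], m))


def _greedy_match(
    query: Sequence[float], reference: Sequence[float], tol: float
) -> list[tuple[float, float]]:
    """Each query peak takes the nearest unused reference peak within tol;
    one-to-one, query peaks processed in input order."""
    used = [False] * len(reference)
    pairs = []
    for q in query:
        candidate, candidate_dev = None, None
        for j, r in enumerate(reference):
            if used[j]:
                continue
            dev = abs(q - r)
            if dev <= tol and (candidate_dev is None or dev < candidate_dev):
                candidate, candidate_dev = j, dev
        if candidate is not None:
            used[candidate] = True
            pairs.append((float(q), float(reference[candidate])))
    return pairs


def match_spectrum(
    query: Sequence[float],
    store: TripleStore,
    tol: float = DEFAULT_TOLERANCE,
) -> list[MatchResult]:
    """Dereplicate a query peak list against every spectrum in the store.

    Score = matched query peaks / total query peaks.  Results are sorted by
    score descending, then mean absolute deviation of matched pairs
    ascending, then spectrum id.
    """
    if not query:
        raise ValueError("query peak list is empty")
    if tol < 0:
        raise ValueError("tolerance must be nonnegative")
    results = []
    for spectrum in spectra_in_store(store):
        pairs = _greedy_match(list(query), spectrum.shifts, tol)
        results.append(MatchResult(
            spectrum_id=spectrum.id,
            molecule_ref=spectrum.molecule_ref,
            score=len(pairs) / len(query),
            matched_pairs=pairs,
        ))
    results.sort(key=lambda r: (-r.score, r.mean_abs_deviation, r.spectrum_id))
    return results


def generate_spectra_db(
    n_molecules: int,
    peaks_range: tuple[int, int] = (3, 8),
    seed: int = 0,
    shift_range: tuple[float, float] = (0.0, 220.0),
    min_separation: float = 0.2,
) -> tuple[TripleStore, dict[str, list[float]]]:
    """Seeded synthetic reference-spectra database plus its ground truth.

    Every peak shift keeps at least ``min_separation`` ppm from every other
    peak in the database (across spectra), so that for any matching tolerance
    below ``min_separation / 2`` each spectrum is the unique best match for
    its own peak list.  Shifts are rounded to 0.01 ppm.
    """
    rng = np.random.default_rng(seed)
    lo, hi = shift_range
    taken: list[float] = []
    store = TripleStore(prefixes=dict(voc.PREFIXES))
    truth: dict[str, list[float]] = {}
    for i in range(n_molecules):
        n_peaks = int(rng.integers(peaks_range[0], peaks_range[1] + 1))
        shifts = []
        attempts = 0
        while len(shifts) < n_peaks:
            candidate = round(float(rng.uniform(lo, hi)), 2)
            attempts += 1
            if attempts > 10000:
                raise RuntimeError(
                    "cannot place separated peaks; widen shift_range or "
                    "lower min_separation")
            if all(abs(candidate - t) >= min_separation for t in taken) and \
                    all(abs(candidate - s) >= min_separation for s in shifts):
                shifts.append(candidate)
        taken.extend(shifts)
        mol = f"{NMR_DATA_BASE}molecule/{i}"
        spectrum = Spectrum(
            id=f"{NMR_DATA_BASE}spectrum/{i}",
            molecule_ref=mol,
            peaks=[Peak(s) for s in shifts],
        )
        store.update(spectrum_to_rdf(spectrum))
        truth[mol] = sorted(shifts)
    return store, truth


def results_to_csv(results: Iterable[MatchResult], path_or_buf) -> None:
    """Ranked results as CSV: spectrum, molecule, score, deviations."""
    close = False
    if isinstance(path_or_buf, (str, bytes)):
        handle = open(path_or_buf, "w", newline="")
        close = True
    else:
        handle = path_or_buf
    try:
        writer = csv.writer(handle)
        writer.writerow(["spectrum", "molecule", "score", "mean_abs_deviation",
                         "matched_pairs"])
        for r in results:
            writer.writerow([
                r.spectrum_id, r.molecule_ref, f"{r.score:.6g}",
                "" if not r.matched_pairs else f"{r.mean_abs_deviation:.6g}",
                ";".join(f"{q}->{d}" for q, d in r.matched_pairs),
            ])
    finally:
        if close:
            handle.close()
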