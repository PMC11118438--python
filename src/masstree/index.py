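"""Reference database, binned fragment-ion inverted index, and search.

The reference side of a search is a set of LC-MS/MS files, each carrying
many MS/MS spectra and one metadata row (taxon, dataset, blank/QC flag).
Exact search gates candidates by precursor m/z within the precursor
tolerance, prefilters them through the fragment index, scores the survivors
with the direct cosine, and keeps hits passing the score/peak-count
thresholds. Analog search widens the precursor gate to ``analog_max_delta``
and scores with the modified cosine (no index prefilter by default, which
keeps candidate generation lossless for the shifted channel).

``brute_force_search`` is the index-free twin with the identical
filter/sort contract; the two must agree exactly, and the test suite and
acceptance checks enforce that equivalence.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import MasstreeError, ParameterError
from .scoring import (
    SearchParams,
    SimilarityResult,
    cosine_score,
    modified_cosine_score,
    passes_thresholds,
)
from .spectra import (
    MetadataEntry,
    Spectrum,
    preprocess_spectrum,
    read_metadata_table,
    read_mgf,
)

__all__ = [
    "ReferenceDB",
    "FragmentIndex",
    "MatchResult",
    "Annotation",
    "build_reference_db",
    "build_fragment_index",
    "search",
    "brute_force_search",
    "annotate_query",
    "matches_to_table",
    "file_level_matches",
    "save_db",
    "load_db",
]

INDEX_FORMAT_VERSION = 1


@dataclass
class ReferenceDB:
    """All reference spectra plus their file-level metadata.

    Spectra are preprocessed and ordered deterministically by
    (dataset_filename, scan order within the file). ``by_file`` maps each
    ``Dataset/Filename`` to the positions of its spectra. Blank/QC files may
    hold spectra (they are searchable) but are excluded from taxonomic
    sample totals downstream.
    """

    spectra: list[Spectrum]
    metadata: list[MetadataEntry]
    by_file: dict[str, list[int]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self._meta_by_file = {m.dataset_filename: m for m in self.metadata}
        if not self.by_file:
            for pos, s in enumerate(self.spectra):
                self.by_file.setdefault(s.source_file, []).append(pos)
        for s in self.spectra:
            if s.source_file not in self._meta_by_file:
                raise MasstreeError(
                    f"spectrum {s.spectrum_id!r} links to unknown file {s.source_file!r}"
                )

    @property
    def n_spectra(self) -> int:
        return len(self.spectra)

    @property
    def n_files(self) -> int:
        return len(self.by_file)

    def metadata_for_file(self, dataset_filename: str) -> MetadataEntry:
        return self._meta_by_file[dataset_filename]

    def spectrum_by_id(self, spectrum_id: str) -> Spectrum:
        for s in self.spectra:
            if s.spectrum_id == spectrum_id:
                return s
        raise KeyError(spectrum_id)


@dataclass
class FragmentIndex:
    """Binned fragment-m/z inverted index plus a sorted precursor index.

    Every reference peak lands in exactly one posting bin
    ``floor(mz / bin_width)``; probing a query peak's bin and both neighbors
    therefore covers every reference peak within one bin width, which makes
    the candidate prefilter lossless whenever ``bin_width >=
    fragment_tolerance``.
    """

    bin_width: float
    postings: dict[int, list[tuple[int, int]]]
    precursor_mz: np.ndarray  # sorted
    precursor_order: np.ndarray  # positions into db.spectra, parallel to precursor_mz
    bin_spectra: dict[int, np.ndarray] = field(default_factory=dict)

    def candidates_in_precursor_window(self, center: float, half_width: float) -> np.ndarray:
        lo = np.searchsorted(self.precursor_mz, center - half_width, side="left")
        hi = np.searchsorted(self.precursor_mz, center + half_width, side="right")
        return self.precursor_order[lo:hi]


def build_reference_db(
    mgf_paths: Iterable[str | Path],
    metadata_table_path: str | Path,
    precursor_exclusion_da: float | None = None,
    min_intensity_fraction: float = 0.0,
) -> ReferenceDB:
    """Load reference MGF files, link each to its metadata row, preprocess.

    Each MGF file maps to a metadata row whose ``dataset_filename`` basename
    equals the MGF file's name (the ``Dataset/`` prefix identifies the
    repository dataset, the basename the run). Orphan MGF files — no
    metadata row — are a hard error listing every orphan.
    """
    metadata = read_metadata_table(metadata_table_path)
    by_basename = {m.dataset_filename.split("/", 1)[1]: m for m in metadata}
    paths = sorted(Path(p) for p in mgf_paths)
    orphans = [p.name for p in paths if p.name not in by_basename]
    if orphans:
        raise MasstreeError(
            "MGF files with no metadata row: " + ", ".join(sorted(orphans))
        )
    # deterministic order: by dataset_filename, then scan order in file
    paths.sort(key=lambda p: by_basename[p.name].dataset_filename)
    spectra: list[Spectrum] = []
    for p in paths:
        entry = by_basename[p.name]
        for s in read_mgf(p):
            s = preprocess_spectrum(
                s,
                precursor_exclusion_da=precursor_exclusion_da,
                min_intensity_fraction=min_intensity_fraction,
            )
            s.source_file = entry.dataset_filename
            spectra.append(s)
    return ReferenceDB(spectra=spectra, metadata=metadata)


def build_fragment_index(db: ReferenceDB, bin_width: float = 0.05) -> FragmentIndex:
    """Index every reference peak into m/z bins of ``bin_width`` Da."""
    if bin_width <= 0:
        raise ParameterError("bin_width must be positive (Da)")
    if db.n_spectra == 0:
        raise MasstreeError("cannot index an empty reference database")
    postings: dict[int, list[tuple[int, int]]] = {}
    for pos, s in enumerate(db.spectra):
        bins = np.floor(s.mz / bin_width).astype(np.int64)
        for peak_pos, b in enumerate(bins):
            postings.setdefault(int(b), []).append((pos, peak_pos))
    bin_spectra = {
        b: np.unique(np.fromiter((sp for sp, _ in plist), dtype=np.int64, count=len(plist)))
        for b, plist in postings.items()
    }
    prec = np.array([s.precursor_mz for s in db.spectra])
    order = np.argsort(prec, kind="stable")
    return FragmentIndex(
        bin_width=float(bin_width),
        postings=postings,
        precursor_mz=prec[order],
        precursor_order=order.astype(np.int64),
        bin_spectra=bin_spectra,
    )


@dataclass(frozen=True)
class MatchResult:
    """One passing (query spectrum, reference spectrum) hit."""

    query_id: str
    ref_spectrum_id: str
    ref_file: str
    taxon_id: int | None
    score: float
    n_matched_peaks: int
    precursor_delta: float  # query - reference, Da
    analog: bool


def _sort_matches(matches: list[MatchResult]) -> list[MatchResult]:
    return sorted(
        matches, key=lambda m: (-m.score, abs(m.precursor_delta), m.ref_spectrum_id)
    )


def _score_candidates(
    db: ReferenceDB,
    query: Spectrum,
    candidate_positions: Iterable[int],
    params: SearchParams,
) -> list[MatchResult]:
    matches: list[MatchResult] = []
    for pos in candidate_positions:
        ref = db.spectra[pos]
        delta = query.precursor_mz - ref.precursor_mz
        if params.analog_search:
            if abs(delta) > params.analog_max_delta:
                continue
            result = modified_cosine_score(
                query, ref, params.fragment_tolerance, params.sqrt_intensity
            )
        else:
            if abs(delta) > params.precursor_tolerance:
                continue
            result = cosine_score(
                query, ref, params.fragment_tolerance, params.sqrt_intensity
            )
        if passes_thresholds(result, params):
            entry = db.metadata_for_file(ref.source_file)
            matches.append(
                MatchResult(
                    query_id=query.spectrum_id,
                    ref_spectrum_id=ref.spectrum_id,
                    ref_file=ref.source_file,
                    taxon_id=entry.ncbi_taxid,
                    score=result.score,
                    n_matched_peaks=result.n_matched_peaks,
                    precursor_delta=delta,
                    analog=params.analog_search,
                )
            )
    return _sort_matches(matches)


def _prefilter_positions(
    index: FragmentIndex, query: Spectrum, min_matched_peaks: int
) -> np.ndarray:
    """Reference spectra for which >= min_matched_peaks query peaks have at
    least one candidate reference peak in the probed bins (bin and both
    neighbors).

    Counting query peaks with candidates (rather than distinct shared bins)
    keeps the filter lossless: every true one-to-one pair consumes a
    distinct query peak, and that peak's partner always lies in a probed bin
    when bin_width >= fragment_tolerance.
    """
    counts: dict[int, int] = {}
    for mz in query.mz:
        b = int(np.floor(mz / index.bin_width))
        hit: set[int] = set()
        for probe in (b - 1, b, b + 1):
            arr = index.bin_spectra.get(probe)
            if arr is not None:
                hit.update(arr.tolist())
        for sp in hit:
            counts[sp] = counts.get(sp, 0) + 1
    return np.array(
        sorted(sp for sp, c in counts.items() if c >= min_matched_peaks), dtype=np.int64
    )


def search(
    db: ReferenceDB,
    index: FragmentIndex,
    query: Spectrum,
    params: SearchParams = SearchParams(),
) -> list[MatchResult]:
    """Index-accelerated search of one query spectrum.

    Exact mode: precursor gate at ``precursor_tolerance``, fragment-index
    prefilter, cosine scoring. Analog mode: precursor gate at
    ``analog_max_delta``, full modified-cosine scoring of the window (the
    unshifted-bin prefilter cannot see the shifted channel, so it is not
    applied). Results sorted by (score desc, |precursor delta| asc,
    reference spectrum id asc).
    """
    query = _require_searchable(query)
    if params.analog_search:
        cand = index.candidates_in_precursor_window(
            query.precursor_mz, params.analog_max_delta
        )
    else:
        gate = index.candidates_in_precursor_window(
            query.precursor_mz, params.precursor_tolerance
        )
        if gate.size == 0:
            return []
        passing = _prefilter_positions(index, query, params.min_matched_peaks)
        cand = np.intersect1d(gate, passing)
    return _score_candidates(db, query, cand.tolist(), params)


def brute_force_search(
    db: ReferenceDB,
    query: Spectrum,
    params: SearchParams = SearchParams(),
) -> list[MatchResult]:
    """Index-free twin of :func:`search`: scores every reference spectrum
    passing the precursor gate, same filtering and sort order."""
    query = _require_searchable(query)
    return _score_candidates(db, query, range(db.n_spectra), params)


def _require_searchable(query: Spectrum) -> Spectrum:
    if query.n_peaks == 0:
        from .errors import EmptySpectrumError

        raise EmptySpectrumError(f"query {query.spectrum_id!r} has no peaks")
    if not query.is_preprocessed:
        query = preprocess_spectrum(query)
    return query


@dataclass(frozen=True)
class Annotation:
    """A named spectral-library hit for a query spectrum."""

    compound_name: str
    score: float
    n_matched_peaks: int
    precursor_delta: float
    analog: bool


def annotate_query(
    query: Spectrum,
    annotated_library: Sequence[tuple[Spectrum, str]],
    params: SearchParams = SearchParams(),
) -> list[Annotation]:
    """Score a query against a compound-annotated spectral library.

    Same scoring and thresholds as :func:`search`, but hits carry compound
    names instead of file provenance.
    """
    query = _require_searchable(query)
    out: list[Annotation] = []
    for ref, name in annotated_library:
        ref = _require_searchable(ref)
        delta = query.precursor_mz - ref.precursor_mz
        if params.analog_search:
            if abs(delta) > params.analog_max_delta:
                continue
            result = modified_cosine_score(
                query, ref, params.fragment_tolerance, params.sqrt_intensity
            )
        else:
            if abs(delta) > params.precursor_tolerance:
                continue
            result = cosine_score(
                query, ref, params.fragment_tolerance, params.sqrt_intensity
            )
        if passes_thresholds(result, params):
            out.append(
                Annotation(name, result.score, result.n_matched_peaks, delta, params.analog_search)
            )
    return sorted(out, key=lambda a: (-a.score, abs(a.precursor_delta), a.compound_name))


# ---------------------------------------------------------------------------
# Tabular export and file-level deduplication
# ---------------------------------------------------------------------------

def matches_to_table(matches: Sequence[MatchResult], db: ReferenceDB) -> pd.DataFrame:
    """Spectrum-level match table with file metadata joined in."""
    rows = []
    for m in matches:
        entry = db.metadata_for_file(m.ref_file)
        rows.append(
            {
                "query_id": m.query_id,
                "ref_file": m.ref_file,
                "massive_id": entry.massive_id,
                "taxon_name": entry.taxon_name,
                "ncbi_taxid": m.taxon_id,
                "score": m.score,
                "n_matched_peaks": m.n_matched_peaks,
                "precursor_delta": m.precursor_delta,
                "analog_flag": m.analog,
                "usi": entry.file_usi,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "query_id",
            "ref_file",
            "massive_id",
            "taxon_name",
            "ncbi_taxid",
            "score",
            "n_matched_peaks",
            "precursor_delta",
            "analog_flag",
            "usi",
        ],
    )


def file_level_matches(matches: Sequence[MatchResult]) -> list[MatchResult]:
    """Deduplicate to one best hit per reference file.

    A file matches if at least one of its spectra matches; the retained
    representative is the file's best-scoring hit under the standard sort.
    """
    best: dict[str, MatchResult] = {}
    for m in _sort_matches(list(matches)):
        best.setdefault(m.ref_file, m)
    return _sort_matches(list(best.values()))


# ---------------------------------------------------------------------------
# On-disk serialized form (versioned)
# ---------------------------------------------------------------------------

def save_db(db: ReferenceDB, path: str | Path) -> None:
    """Serialize a reference DB to a single ``.npz`` container (versioned).

    Rebuild-from-MGF is always available; this is a cache, not the source
    of truth.
    """
    meta_json = json.dumps(
        {
            "format": "masstree-refdb",
            "version": INDEX_FORMAT_VERSION,
            "metadata": [
                {
                    "file_path": m.file_path,
                    "dataset_filename": m.dataset_filename,
                    "massive_id": m.massive_id,
                    "taxon_name": m.taxon_name,
                    "ncbi_taxid": m.ncbi_taxid,
                    "redu_available": m.redu_available,
                    "is_blank_or_qc": m.is_blank_or_qc,
                    "file_usi": m.file_usi,
                }
                for m in db.metadata
            ],
            "spectra": [
                {
                    "spectrum_id": s.spectrum_id,
                    "precursor_mz": s.precursor_mz,
                    "charge": s.charge,
                    "source_file": s.source_file,
                    "n_peaks": s.n_peaks,
                }
                for s in db.spectra
            ],
        }
    )
    mz = np.concatenate([s.mz for s in db.spectra]) if db.spectra else np.empty(0)
    inten = (
        np.concatenate([s.intensity for s in db.spectra]) if db.spectra else np.empty(0)
    )
    np.savez_compressed(path, header=np.array(meta_json), mz=mz, intensity=inten)


def load_db(path: str | Path) -> ReferenceDB:
    with np.load(path, allow_pickle=False) as z:
        header = json.loads(str(z["header"]))
        if header.get("format") != "masstree-refdb":
            raise MasstreeError(f"{path}: not a masstree reference DB container")
        if header.get("version") != INDEX_FORMAT_VERSION:
            raise MasstreeError(
                f"{path}: unsupported container version {header.get('version')}"
            )
        mz, inten = z["mz"], z["intensity"]
    spectra: list[Spectrum] = []
    offset = 0
    for rec in header["spectra"]:
        n = rec["n_peaks"]
        spectra.append(
            Spectrum(
                spectrum_id=rec["spectrum_id"],
                precursor_mz=rec["precursor_mz"],
                mz=mz[offset : offset + n],
                intensity=inten[offset : offset + n],
                charge=rec["charge"],
                source_file=rec["source_file"],
                is_preprocessed=True,
            )
        )
        offset += n
    metadata = [MetadataEntry(**rec) for rec in header["metadata"]]
    return ReferenceDB(spectra=spectra, metadata=metadata)
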