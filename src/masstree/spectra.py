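"""Spectrum and metadata I/O: MGF read/write, USI parsing, metadata tables,
and canonical spectrum preprocessing.

A :class:`Spectrum` stores its peak list as two parallel numpy arrays
(``mz``, ``intensity``), sorted ascending by m/z after preprocessing. The
``peaks`` property exposes the list-of-(mz, intensity) view used in examples
and exports.

m/z tolerances throughout the package are absolute Daltons, never ppm.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, NamedTuple, Sequence

import numpy as np
import pandas as pd
from pyteomics import mgf as _mgf
from pyteomics.auxiliary import PyteomicsError

from .errors import EmptySpectrumError, ParseError, ResolverUnavailableError, SchemaError

__all__ = [
    "Peak",
    "Spectrum",
    "UsiParts",
    "MetadataEntry",
    "read_mgf",
    "write_mgf",
    "parse_usi",
    "serialize_usi",
    "read_metadata_table",
    "write_metadata_table",
    "preprocess_spectrum",
    "OfflineUsiResolver",
    "METADATA_COLUMNS",
]


class Peak(NamedTuple):
    """One fragment ion: m/z in Da, intensity in arbitrary abundance units."""

    mz: float
    intensity: float


@dataclass
class Spectrum:
    """One MS/MS scan.

    Parameters
    ----------
    spectrum_id : str
        Opaque identifier (scan id, TITLE, or a USI).
    precursor_mz : float
        m/z of the selected precursor ion, in Da. Compared as-is during
        search: charge is *not* used to convert to neutral mass, so multiply
        charged ions are matched at their observed m/z.
    charge : int or None
        Optional signed charge state; informational only, never scored.
    mz, intensity : ndarray
        Parallel peak arrays. Not guaranteed sorted until
        :func:`preprocess_spectrum` has run.
    source_file : str or None
        ``Dataset/Filename`` of the reference file this spectrum came from.
    """

    spectrum_id: str
    precursor_mz: float
    mz: np.ndarray
    intensity: np.ndarray
    charge: int | None = None
    source_file: str | None = None
    is_preprocessed: bool = field(default=False, compare=False)

    def __post_init__(self) -> None:
        self.mz = np.asarray(self.mz, dtype=np.float64)
        self.intensity = np.asarray(self.intensity, dtype=np.float64)
        if self.mz.shape != self.intensity.shape:
            raise ValueError("mz and intensity arrays must have equal length")

    @classmethod
    def from_peaks(
        cls,
        spectrum_id: str,
        precursor_mz: float,
        peaks: Iterable[tuple[float, float]],
        charge: int | None = None,
        source_file: str | None = None,
    ) -> "Spectrum":
        pk = list(peaks)
        mz = np.array([p[0] for p in pk], dtype=np.float64)
        inten = np.array([p[1] for p in pk], dtype=np.float64)
        return cls(spectrum_id, float(precursor_mz), mz, inten, charge, source_file)

    @property
    def peaks(self) -> list[Peak]:
        return [Peak(float(m), float(i)) for m, i in zip(self.mz, self.intensity)]

    @property
    def n_peaks(self) -> int:
        return int(self.mz.size)

    def copy(self) -> "Spectrum":
        return replace(self, mz=self.mz.copy(), intensity=self.intensity.copy())


@dataclass(frozen=True)
class UsiParts:
    """Decomposed Universal Spectrum Identifier.

    ``serialize_usi(parse_usi(u)) == u`` byte-for-byte for well-formed USIs.
    """

    collection: str
    run: str
    index_type: str
    index_value: str
    interpretation: str | None = None

    PREFIX = "mzspec"
    INDEX_TYPES = frozenset({"scan", "index", "nativeId"})


def parse_usi(usi: str) -> UsiParts:
    """Split a USI string into its five (or six) colon-delimited segments.

    Raises
    ------
    ParseError
        If the string does not start with ``mzspec:`` or has fewer than five
        segments.
    """
    if not isinstance(usi, str) or not usi.startswith(UsiParts.PREFIX + ":"):
        raise ParseError(f"not a USI (must start with 'mzspec:'): {usi!r}")
    parts = usi.split(":")
    if len(parts) < 5:
        raise ParseError(
            f"USI needs at least 5 colon-delimited segments, got {len(parts)}: {usi!r}"
        )
    collection, run = parts[1], parts[2]
    index_type, index_value = parts[3], parts[4]
    interpretation = ":".join(parts[5:]) if len(parts) > 5 else None
    if index_type not in UsiParts.INDEX_TYPES:
        raise ParseError(
            f"USI index type must be one of {sorted(UsiParts.INDEX_TYPES)}, "
            f"got {index_type!r}"
        )
    return UsiParts(collection, run, index_type, index_value, interpretation)


def serialize_usi(parts: UsiParts) -> str:
    """Inverse of :func:`parse_usi`."""
    segs = [UsiParts.PREFIX, parts.collection, parts.run, parts.index_type, parts.index_value]
    if parts.interpretation is not None:
        segs.append(parts.interpretation)
    return ":".join(segs)


@dataclass(frozen=True)
class MetadataEntry:
    """One reference LC-MS/MS file in the library metadata table.

    ``dataset_filename`` is the ``Dataset/Filename`` key that links MGF files
    to metadata rows. ``ncbi_taxid`` may be None only for blank/QC files.
    """

    file_path: str
    dataset_filename: str
    massive_id: str
    taxon_name: str
    ncbi_taxid: int | None
    redu_available: bool
    is_blank_or_qc: bool
    file_usi: str

    def __post_init__(self) -> None:
        if self.dataset_filename.count("/") != 1:
            raise SchemaError(
                "dataset_filename must contain exactly one '/': "
                f"{self.dataset_filename!r}"
            )
        if self.ncbi_taxid is None and not self.is_blank_or_qc:
            raise SchemaError(
                f"non-blank file {self.dataset_filename!r} lacks an NCBI taxid"
            )


METADATA_COLUMNS = (
    "file_path",
    "dataset_filename",
    "massive_id",
    "taxon_name",
    "ncbi_taxid",
    "redu_available",
    "is_blank_or_qc",
    "file_usi",
)

_TRUTHY = {"yes", "true", "1"}


def _parse_flag(token: object) -> bool:
    return str(token).strip().lower() in _TRUTHY


# ---------------------------------------------------------------------------
# MGF I/O (pyteomics-backed)
# ---------------------------------------------------------------------------

def read_mgf(path: str | Path) -> list[Spectrum]:
    """Read an MGF file into a list of raw (unpreprocessed) spectra.

    One :class:`Spectrum` per ``BEGIN IONS`` block, in file order. The first
    PEPMASS value becomes ``precursor_mz``; a second value (precursor
    intensity) is discarded. TITLE, if present, becomes ``spectrum_id``,
    otherwise a positional id ``<filename>:block:<k>`` is assigned.

    Raises
    ------
    ParseError
        For a block lacking PEPMASS (naming the block index) or a malformed
        peak line (naming the line number).
    """
    path = Path(path)
    spectra: list[Spectrum] = []
    try:
        with _mgf.read(str(path), use_index=False, convert_arrays=1) as reader:
            for k, entry in enumerate(reader):
                params = entry.get("params", {})
                pepmass = params.get("pepmass")
                if pepmass is None or pepmass[0] is None:
                    raise ParseError(
                        f"{path.name}: block {k} has no PEPMASS line"
                    )
                charge = None
                ch = params.get("charge")
                if ch:
                    charge = int(ch[0])
                title = params.get("title") or f"{path.name}:block:{k}"
                spectra.append(
                    Spectrum(
                        spectrum_id=str(title),
                        precursor_mz=float(pepmass[0]),
                        mz=entry["m/z array"],
                        intensity=entry["intensity array"],
                        charge=charge,
                    )
                )
    except PyteomicsError as exc:
        raise ParseError(_locate_bad_line(path, str(exc))) from exc
    return spectra


def _locate_bad_line(path: Path, message: str) -> str:
    """Recover a 1-based line number for the peak line pyteomics rejected."""
    # pyteomics embeds the offending line after "Line:"; the newline may be
    # escaped depending on how the error message was formatted
    m = re.search(r"Line:(?:\\n|\n)(.*?)(?:\\n|\n|'|$)", message)
    if m:
        bad = m.group(1).strip()
        try:
            for lineno, line in enumerate(path.open(), start=1):
                if line.strip() == bad:
                    return f"{path.name}: malformed peak line {lineno}: {bad!r}"
        except OSError:
            pass
        return f"{path.name}: malformed peak line: {bad!r}"
    return f"{path.name}: MGF parse error: {message}"


def write_mgf(spectra: Sequence[Spectrum], path: str | Path) -> None:
    """Write spectra as MGF; TITLE carries ``spectrum_id``.

    Every spectrum must have at least one peak and a precursor m/z.
    """
    entries = []
    for s in spectra:
        if s.n_peaks < 1:
            raise EmptySpectrumError(f"spectrum {s.spectrum_id!r} has no peaks")
        params: dict = {"title": s.spectrum_id, "pepmass": s.precursor_mz}
        if s.charge is not None:
            params["charge"] = s.charge
        entries.append(
            {
                "params": params,
                "m/z array": s.mz,
                "intensity array": s.intensity,
            }
        )
    _mgf.write(entries, str(path), file_mode="w")


# ---------------------------------------------------------------------------
# Metadata table
# ---------------------------------------------------------------------------

def read_metadata_table(path: str | Path) -> list[MetadataEntry]:
    """Read the eight-column reference-file metadata table (CSV or TSV).

    Column matching is case-insensitive and order-insensitive. Flag columns
    (`redu_available`, `is_blank_or_qc`) are parsed from truthy tokens
    {"yes", "true", "1"} (case-insensitive); anything else is False. Rows
    with a missing taxid are admitted only when flagged blank/QC.
    """
    path = Path(path)
    sep = "\t" if path.suffix.lower() in {".tsv", ".tab", ".txt"} else ","
    df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    colmap = {c.strip().lower(): c for c in df.columns}
    missing = [c for c in METADATA_COLUMNS if c not in colmap]
    if missing:
        raise SchemaError(
            f"{path.name}: missing mandatory columns: {', '.join(missing)}"
        )
    entries: list[MetadataEntry] = []
    for i, row in df.iterrows():
        taxid_raw = row[colmap["ncbi_taxid"]].strip()
        is_blank = _parse_flag(row[colmap["is_blank_or_qc"]])
        if taxid_raw == "" and not is_blank:
            raise SchemaError(
                f"{path.name}: row {i}: non-blank file with empty ncbi_taxid"
            )
        taxid = int(float(taxid_raw)) if taxid_raw else None
        entries.append(
            MetadataEntry(
                file_path=row[colmap["file_path"]],
                dataset_filename=row[colmap["dataset_filename"]],
                massive_id=row[colmap["massive_id"]],
                taxon_name=row[colmap["taxon_name"]],
                ncbi_taxid=taxid,
                redu_available=_parse_flag(row[colmap["redu_available"]]),
                is_blank_or_qc=is_blank,
                file_usi=row[colmap["file_usi"]],
            )
        )
    return entries


def write_metadata_table(entries: Sequence[MetadataEntry], path: str | Path) -> None:
    """Write metadata entries back out as TSV (or CSV by extension)."""
    path = Path(path)
    sep = "\t" if path.suffix.lower() in {".tsv", ".tab", ".txt"} else ","
    rows = []
    for e in entries:
        rows.append(
            {
                "file_path": e.file_path,
                "dataset_filename": e.dataset_filename,
                "massive_id": e.massive_id,
                "taxon_name": e.taxon_name,
                "ncbi_taxid": "" if e.ncbi_taxid is None else e.ncbi_taxid,
                "redu_available": "yes" if e.redu_available else "no",
                "is_blank_or_qc": "yes" if e.is_blank_or_qc else "no",
                "file_usi": e.file_usi,
            }
        )
    pd.DataFrame(rows, columns=list(METADATA_COLUMNS)).to_csv(path, sep=sep, index=False)


# ---------------------------------------------------------------------------
# Preprocessing
# ---------------------------------------------------------------------------

def preprocess_spectrum(
    s: Spectrum,
    precursor_exclusion_da: float | None = None,
    min_intensity_fraction: float = 0.0,
) -> Spectrum:
    """Normalize a spectrum into canonical searchable form.

    Removes non-positive-intensity peaks, optionally removes peaks at
    ``mz >= precursor_mz - precursor_exclusion_da`` (off by default, so a
    user pasting raw peaks searches exactly what they pasted), drops peaks
    below ``min_intensity_fraction`` of the base peak, sorts ascending by
    m/z, and merges exact-duplicate m/z values by summing intensities.
    Idempotent.

    Raises
    ------
    EmptySpectrumError
        If no peaks survive.
    """
    if s.n_peaks < 1:
        raise EmptySpectrumError(f"spectrum {s.spectrum_id!r} has no raw peaks")
    mz, inten = s.mz, s.intensity
    keep = inten > 0
    if precursor_exclusion_da is not None:
        keep &= mz < s.precursor_mz - precursor_exclusion_da
    if min_intensity_fraction > 0 and keep.any():
        keep &= inten >= min_intensity_fraction * inten[keep].max()
    mz, inten = mz[keep], inten[keep]
    if mz.size == 0:
        raise EmptySpectrumError(
            f"spectrum {s.spectrum_id!r}: all peaks removed by preprocessing"
        )
    order = np.argsort(mz, kind="stable")
    mz, inten = mz[order], inten[order]
    # merge exact-duplicate m/z by intensity sum
    uniq, inverse = np.unique(mz, return_inverse=True)
    if uniq.size != mz.size:
        summed = np.zeros(uniq.size)
        np.add.at(summed, inverse, inten)
        mz, inten = uniq, summed
    return replace(s, mz=mz, intensity=inten, is_preprocessed=True)


# ---------------------------------------------------------------------------
# Offline USI resolution
# ---------------------------------------------------------------------------

class OfflineUsiResolver:
    """Resolve USIs to spectra from a local map; no network access ever.

    The map is built from MGF files whose TITLE fields are USI strings
    (the fixture generator writes queries this way), or from an explicit
    ``{usi: Spectrum}`` dict.
    """

    def __init__(self, mapping: dict[str, Spectrum] | None = None) -> None:
        self._map: dict[str, Spectrum] = dict(mapping or {})

    @classmethod
    def from_mgf(cls, path: str | Path) -> "OfflineUsiResolver":
        mapping = {}
        for s in read_mgf(path):
            try:
                parse_usi(s.spectrum_id)
            except ParseError:
                continue
            mapping[s.spectrum_id] = s
        return cls(mapping)

    def __len__(self) -> int:
        return len(self._map)

    def resolve(self, usi: str) -> Spectrum:
        parse_usi(usi)  # validate grammar first
        if usi not in self._map:
            raise ResolverUnavailableError(
                f"USI resolver unavailable for {usi!r}: no offline entry "
                "(network resolution is not performed)"
            )
        return self._map[usi]
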