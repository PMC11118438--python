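"""Deterministic synthetic taxonomies, reference libraries and query sets.

Every other module is testable offline against these fixtures, which
emulate the real inputs end to end: a rank-complete plant-like taxonomy, a
reference library of MGF files (one per "LC-MS/MS run") with the
eight-column metadata table, and query sets with known ground truth —
planted exact copies (m/z jitter + intensity-bounded peak dropout), planted
analogs (precursor and all fragments shifted by a hexose-like +162.053 Da),
and decoys whose fragments live in an m/z regime disjoint from every
reference fragment, so they can never share a fragment bin.

Determinism: one RNG stream per generation stage, spawned from the master
seed, so changing one stage's parameters does not perturb the others.

Reference peak lists enforce a minimum m/z spacing of 0.2 Da; with jitter
well below half the fragment tolerance this makes tolerance pairing of a
planted copy unambiguous, so planted recall is exact by construction rather
than statistical.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .spectra import MetadataEntry, Spectrum, write_metadata_table, write_mgf
from .taxonomy import LineageRecord, read_lineage_table, write_lineage_table

__all__ = ["FixtureSpec", "GroundTruth", "generate_taxonomy", "generate_reference_library", "generate_query_set", "generate_fixture_set"]

_MASSIVE_ID = "MSV_SYN000001"
_DATASET = "SyntheticPlants"

#: Fragments of decoy queries are drawn from this regime, strictly above
#: every reference fragment (reference peaks stay below precursor_range max),
#: so a decoy can never share a fragment bin with any reference spectrum.
DECOY_FRAGMENT_RANGE = (1200.0, 1900.0)

#: Minimum spacing between fragment m/z values within one spectrum (Da).
MIN_PEAK_SPACING = 0.2


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of one synthetic study.

    The defaults describe a small but fully structured library: 4 families
    x 3 genera x 3 species, two replicate files per species, ten spectra
    per file with 8-30 fragments each over a 200-1000 Da precursor range,
    exponential intensities, 0.01 Da fragment jitter and up to 20% peak
    dropout on planted exact queries (bounded so the planted spectrum stays
    recoverable at the default thresholds), unjittered +162.053 Da shifted
    copies as analogs, and bin-disjoint decoys. 5% of files are blanks.
    """

    seed: int = 0
    n_families: int = 4
    genera_per_family: int = 3
    species_per_genus: int = 3
    files_per_species: int = 2
    spectra_per_file: int = 10
    peaks_per_spectrum: tuple[int, int] = (8, 30)
    precursor_range: tuple[float, float] = (200.0, 1000.0)
    intensity_rate: float = 1.0  # exponential scale of raw intensities
    jitter_sd: float = 0.01  # Da, on exact-query fragments
    dropout_fraction: float = 0.2
    n_exact_queries: int = 10
    n_analog_queries: int = 5
    analog_shifts: tuple[float, ...] = (162.053,)
    analog_jitter_sd: float = 0.0  # analogs ship as exact shifted copies
    n_decoy_queries: int = 5
    blank_fraction: float = 0.05
    min_kept_peaks: int = 3
    min_kept_intensity_sq_fraction: float = 0.6  # bounds dropout: score >= sqrt(0.6)


@dataclass(frozen=True)
class GroundTruth:
    """What one synthetic query really is."""

    query_id: str
    kind: str  # "exact" | "analog" | "decoy"
    ref_spectrum_id: str | None
    ref_file: str | None
    taxid: int | None
    shift: float  # Da applied to precursor and fragments (0 unless analog)
    jitter_sd: float
    n_dropped_peaks: int


def _streams(seed: int, n: int) -> list[np.random.Generator]:
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


# ---------------------------------------------------------------------------
# Stage 1: taxonomy
# ---------------------------------------------------------------------------

def generate_taxonomy(spec: FixtureSpec) -> list[LineageRecord]:
    """Synthetic plant-like lineages: one kingdom/phylum/class/order chain
    over ``n_families`` families, each with its genera and species.

    Taxids are sequential from 1000 (never colliding with the synthetic
    root taxid 1). Deterministic for a fixed seed.
    """
    next_id = iter(range(1000, 10**6))
    kingdom = ("kingdom", "Synplantae", next(next_id))
    phylum = ("phylum", "Synstreptophyta", next(next_id))
    klass = ("class", "Synopsida", next(next_id))
    order = ("order", "Synales", next(next_id))
    trunk = (kingdom, phylum, klass, order)
    records = [LineageRecord(lv[2], trunk[: i + 1]) for i, lv in enumerate(trunk)]
    for f in range(spec.n_families):
        family = ("family", f"Famaceae{f:02d}", next(next_id))
        records.append(LineageRecord(family[2], trunk + (family,)))
        for g in range(spec.genera_per_family):
            genus = ("genus", f"Genus{f:02d}x{g:02d}", next(next_id))
            records.append(LineageRecord(genus[2], trunk + (family, genus)))
            for s in range(spec.species_per_genus):
                species = (
                    "species",
                    f"Genus{f:02d}x{g:02d} species{s:02d}",
                    next(next_id),
                )
                records.append(
                    LineageRecord(species[2], trunk + (family, genus, species))
                )
    return records


# ---------------------------------------------------------------------------
# Stage 2: reference library
# ---------------------------------------------------------------------------

def _draw_peaks(
    rng: np.random.Generator,
    n_peaks: int,
    mz_range: tuple[float, float],
    intensity_rate: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Fragment m/z values with enforced minimum spacing, exp intensities."""
    lo, hi = mz_range
    mz = np.sort(rng.uniform(lo, hi, n_peaks))
    for _ in range(100):
        close = np.diff(mz) < MIN_PEAK_SPACING
        if not close.any():
            break
        redraw = np.concatenate(([False], close))
        mz[redraw] = rng.uniform(lo, hi, int(redraw.sum()))
        mz.sort()
    inten = rng.exponential(intensity_rate, n_peaks) + 1e-6
    return mz, inten


def generate_reference_library(
    spec: FixtureSpec,
    lineages: Sequence[LineageRecord],
    out_dir: str | Path,
) -> tuple[list[Path], Path]:
    """Write per-file MGFs and the metadata table; return (mgf paths,
    metadata path).

    Every species leaf gets ``files_per_species`` replicate files; an
    additional ``round(blank_fraction * n_files)`` blank/QC files carry no
    taxid. Byte-identical output for a fixed seed.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = _streams(spec.seed, 3)[1]
    species = [r for r in lineages if r.lineage[-1][0] == "species"]
    mgf_paths: list[Path] = []
    entries: list[MetadataEntry] = []

    def make_file(filename: str, taxid: int | None, taxon_name: str, blank: bool) -> None:
        dataset_filename = f"{_DATASET}/{filename}"
        spectra = []
        for k in range(spec.spectra_per_file):
            n_peaks = int(rng.integers(*spec.peaks_per_spectrum, endpoint=True))
            precursor = float(rng.uniform(*spec.precursor_range))
            mz, inten = _draw_peaks(
                rng, n_peaks, (50.0, precursor - 10.0), spec.intensity_rate
            )
            spectra.append(
                Spectrum(
                    spectrum_id=f"{dataset_filename}:scan:{k + 1}",
                    precursor_mz=precursor,
                    mz=mz,
                    intensity=inten,
                )
            )
        path = out_dir / filename
        write_mgf(spectra, path)
        mgf_paths.append(path)
        entries.append(
            MetadataEntry(
                file_path=str(path),
                dataset_filename=dataset_filename,
                massive_id=_MASSIVE_ID,
                taxon_name=taxon_name,
                ncbi_taxid=taxid,
                redu_available=not blank,
                is_blank_or_qc=blank,
                file_usi=f"mzspec:{_MASSIVE_ID}:{filename}:scan:1",
            )
        )

    for rec in species:
        _, name, taxid = rec.lineage[-1]
        stem = name.replace(" ", "_")
        for rep in range(spec.files_per_species):
            make_file(f"{stem}_rep{rep + 1}.mgf", taxid, name, blank=False)
    n_blanks = int(round(spec.blank_fraction * len(mgf_paths)))
    for b in range(n_blanks):
        make_file(f"blank_{b + 1:02d}.mgf", None, "blank", blank=True)

    metadata_path = out_dir / "metadata.tsv"
    write_metadata_table(entries, metadata_path)
    return mgf_paths, metadata_path


# ---------------------------------------------------------------------------
# Stage 3: queries with ground truth
# ---------------------------------------------------------------------------

def _bounded_dropout(
    rng: np.random.Generator,
    mz: np.ndarray,
    inten: np.ndarray,
    spec: FixtureSpec,
) -> tuple[np.ndarray, np.ndarray, int]:
    """Drop up to ``dropout_fraction`` random peaks, but never so many that
    the kept intensity-squared share falls below
    ``min_kept_intensity_sq_fraction`` (which lower-bounds the planted
    cosine at its square root) or the peak count below ``min_kept_peaks``."""
    n = mz.size
    max_drop = int(np.floor(spec.dropout_fraction * n))
    order = rng.permutation(n)
    total_sq = float(np.sum(inten**2))
    dropped: list[int] = []
    kept_sq = total_sq
    for idx in order:
        if len(dropped) >= max_drop or n - len(dropped) <= spec.min_kept_peaks:
            break
        if (kept_sq - inten[idx] ** 2) / total_sq < spec.min_kept_intensity_sq_fraction:
            continue
        dropped.append(int(idx))
        kept_sq -= inten[idx] ** 2
    keep = np.setdiff1d(np.arange(n), np.array(dropped, dtype=int))
    return mz[keep], inten[keep], len(dropped)


def generate_query_set(
    spec: FixtureSpec,
    db,
    out_dir: str | Path | None = None,
) -> tuple[list[Spectrum], list[GroundTruth]]:
    """Planted exact / analog / decoy queries against a built reference DB.

    Planted queries are drawn only from non-blank files (blanks carry no
    taxon, so they cannot anchor ground truth). If ``out_dir`` is given,
    the queries are also written to ``queries.mgf`` and the ground truth
    to ``ground_truth.tsv`` there.
    """
    rng = _streams(spec.seed, 3)[2]
    taxid_by_file = {
        m.dataset_filename: m.ncbi_taxid
        for m in db.metadata
        if not m.is_blank_or_qc
    }
    pool = [s for s in db.spectra if s.source_file in taxid_by_file]
    if not pool:
        raise ValueError("reference library has no non-blank spectra")
    queries: list[Spectrum] = []
    truth: list[GroundTruth] = []

    n_planted = spec.n_exact_queries + spec.n_analog_queries
    picks = rng.choice(len(pool), size=n_planted, replace=n_planted > len(pool))

    for q in range(spec.n_exact_queries):
        ref = pool[int(picks[q])]
        mz, inten, n_dropped = _bounded_dropout(rng, ref.mz, ref.intensity, spec)
        mz = mz + rng.normal(0.0, spec.jitter_sd, mz.size)
        qid = f"exact_{q:04d}"
        queries.append(Spectrum(qid, ref.precursor_mz, np.sort(mz), inten))
        truth.append(
            GroundTruth(qid, "exact", ref.spectrum_id, ref.source_file,
                        _taxid_of(ref, taxid_by_file), 0.0, spec.jitter_sd, n_dropped)
        )

    for q in range(spec.n_analog_queries):
        ref = pool[int(picks[spec.n_exact_queries + q])]
        shift = float(spec.analog_shifts[q % len(spec.analog_shifts)])
        mz = ref.mz + shift
        if spec.analog_jitter_sd > 0:
            mz = np.sort(mz + rng.normal(0.0, spec.analog_jitter_sd, mz.size))
        qid = f"analog_{q:04d}"
        queries.append(Spectrum(qid, ref.precursor_mz + shift, mz, ref.intensity.copy()))
        truth.append(
            GroundTruth(qid, "analog", ref.spectrum_id, ref.source_file,
                        _taxid_of(ref, taxid_by_file), shift, spec.analog_jitter_sd, 0)
        )

    lo, hi = DECOY_FRAGMENT_RANGE
    for q in range(spec.n_decoy_queries):
        n_peaks = int(rng.integers(*spec.peaks_per_spectrum, endpoint=True))
        mz, inten = _draw_peaks(rng, n_peaks, (lo, hi), spec.intensity_rate)
        precursor = float(rng.uniform(*spec.precursor_range))
        qid = f"decoy_{q:04d}"
        queries.append(Spectrum(qid, precursor, mz, inten))
        truth.append(GroundTruth(qid, "decoy", None, None, None, 0.0, 0.0, 0))

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        write_mgf(queries, out_dir / "queries.mgf")
        pd.DataFrame([t.__dict__ for t in truth]).to_csv(
            out_dir / "ground_truth.tsv", sep="\t", index=False
        )
    return queries, truth


def _taxid_of(ref: Spectrum, taxid_by_file: dict[str, int] | None) -> int | None:
    if taxid_by_file is None:
        return None
    return taxid_by_file.get(ref.source_file)


# ---------------------------------------------------------------------------
# One-call convenience
# ---------------------------------------------------------------------------

def generate_fixture_set(spec: FixtureSpec, out_dir: str | Path):
    """Generate taxonomy + library + queries under ``out_dir``.

    Returns ``(lineage_path, mgf_paths, metadata_path)``; queries are
    written by :func:`generate_query_set` once the caller has built the
    reference DB (queries are planted from preprocessed spectra).
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    lineages = generate_taxonomy(spec)
    lineage_path = out_dir / "lineages.tsv"
    write_lineage_table(lineages, lineage_path)
    mgf_paths, metadata_path = generate_reference_library(spec, lineages, out_dir / "library")
    return lineage_path, mgf_paths, metadata_path
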