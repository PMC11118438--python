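"""Cosine and modified-cosine similarity between MS/MS spectra.

Both scores are normalized dot products over one-to-one, tolerance-matched
peak pairs. Intensities are scaled to unit Euclidean norm per spectrum (raw
intensities by default; an optional square-root transform is available as a
config switch), so a perfect match scores 1 and disjoint spectra score 0.

The modified cosine adds a second pairing channel shifted by the precursor
m/z difference between the two spectra, which is what lets structural
analogs, adducts, multimers and in-source fragments match: a fragment that
retains the modified substructure appears shifted by exactly the precursor
delta.

Pairing is greedy by descending intensity product with deterministic
tie-breaks — standard spectral-library-search practice. Greedy is not
guaranteed optimal for adversarial candidate graphs; the test suite bounds
it against an exhaustive assignment oracle on small spectra.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .errors import EmptySpectrumError, ParameterError
from .spectra import Spectrum

__all__ = [
    "PeakPair",
    "SimilarityResult",
    "SearchParams",
    "DEFAULT_PARAMS",
    "DIET_PARAMS",
    "match_peak_pairs",
    "cosine_score",
    "modified_cosine_score",
    "passes_thresholds",
]


@dataclass(frozen=True)
class PeakPair:
    """One matched fragment-ion pair between query (a) and reference (b).

    ``shift_used`` is 0 for a direct match and the precursor m/z delta for a
    shifted (analog-channel) match. ``product`` is the unit-norm intensity
    product this pair contributes to the score.
    """

    index_a: int
    index_b: int
    shift_used: float
    product: float


@dataclass(frozen=True)
class SimilarityResult:
    score: float
    n_matched_peaks: int
    pairs: tuple[PeakPair, ...] = ()


@dataclass(frozen=True)
class SearchParams:
    """Search thresholds and tolerances.

    Defaults are the standard single-query settings: cosine threshold 0.7,
    at least 3 matched fragment ions, 0.05 Da precursor and fragment
    tolerances, analog search off. All tolerances are absolute Da.
    Threshold comparisons are inclusive (>=).
    """

    cosine_threshold: float = 0.7
    min_matched_peaks: int = 3
    precursor_tolerance: float = 0.05
    fragment_tolerance: float = 0.05
    analog_search: bool = False
    analog_max_delta: float = 200.0
    sqrt_intensity: bool = False

    def __post_init__(self) -> None:
        if not (0.0 <= self.cosine_threshold <= 1.0):
            raise ParameterError("cosine_threshold must lie in [0, 1]")
        if self.min_matched_peaks < 1:
            raise ParameterError("min_matched_peaks must be >= 1")
        if self.precursor_tolerance <= 0 or self.fragment_tolerance <= 0:
            raise ParameterError("tolerances must be positive (Da)")
        if self.analog_max_delta <= 0:
            raise ParameterError("analog_max_delta must be positive (Da)")


DEFAULT_PARAMS = SearchParams()

#: Stricter batch settings used for re-analysis of dietary cohort data:
#: cosine 0.7, >=4 matched peaks, 0.02 Da tolerances, analog off.
DIET_PARAMS = SearchParams(
    cosine_threshold=0.7,
    min_matched_peaks=4,
    precursor_tolerance=0.02,
    fragment_tolerance=0.02,
    analog_search=False,
)


def _unit_norm(intensity: np.ndarray, sqrt_intensity: bool) -> np.ndarray:
    w = np.sqrt(intensity) if sqrt_intensity else intensity
    norm = np.linalg.norm(w)
    if norm == 0:
        raise EmptySpectrumError("spectrum has zero total intensity")
    return w / norm


def match_peak_pairs(
    a: Spectrum,
    b: Spectrum,
    fragment_tolerance: float,
    shifts: Sequence[float] = (0.0,),
    sqrt_intensity: bool = False,
) -> list[PeakPair]:
    """Greedy one-to-one peak pairing within an absolute m/z tolerance.

    Candidates are all ``(i, j, shift)`` with
    ``|mz_a[i] - (mz_b[j] + shift)| <= fragment_tolerance``. Final pairs are
    chosen greedily by descending unit-norm intensity product; each peak of
    each spectrum is used at most once across all shift channels. Ties break
    deterministically by (smaller |Δmz|, lower index_a, lower index_b).
    """
    if not shifts:
        raise ParameterError("shifts must be nonempty; use [0.0] for direct cosine")
    if a.n_peaks == 0 or b.n_peaks == 0:
        return []
    wa = _unit_norm(a.intensity, sqrt_intensity)
    wb = _unit_norm(b.intensity, sqrt_intensity)

    cand_i: list[np.ndarray] = []
    cand_j: list[np.ndarray] = []
    cand_shift: list[np.ndarray] = []
    for shift in shifts:
        shifted = b.mz + shift
        lo = np.searchsorted(shifted, a.mz - fragment_tolerance, side="left")
        hi = np.searchsorted(shifted, a.mz + fragment_tolerance, side="right")
        counts = hi - lo
        if counts.sum() == 0:
            continue
        ii = np.repeat(np.arange(a.n_peaks), counts)
        jj = np.concatenate([np.arange(l, h) for l, h in zip(lo, hi) if h > l])
        cand_i.append(ii)
        cand_j.append(jj)
        cand_shift.append(np.full(ii.size, shift))
    if not cand_i:
        return []
    ii = np.concatenate(cand_i)
    jj = np.concatenate(cand_j)
    sh = np.concatenate(cand_shift)
    prod = wa[ii] * wb[jj]
    dmz = np.abs(a.mz[ii] - (b.mz[jj] + sh))
    # lexsort: last key is primary
    order = np.lexsort((jj, ii, dmz, -prod))

    used_a = np.zeros(a.n_peaks, dtype=bool)
    used_b = np.zeros(b.n_peaks, dtype=bool)
    pairs: list[PeakPair] = []
    for k in order:
        i, j = int(ii[k]), int(jj[k])
        if used_a[i] or used_b[j]:
            continue
        used_a[i] = True
        used_b[j] = True
        pairs.append(PeakPair(i, j, float(sh[k]), float(prod[k])))
    return pairs


def _score_from_pairs(pairs: list[PeakPair]) -> SimilarityResult:
    score = float(np.clip(sum(p.product for p in pairs), 0.0, 1.0))
    return SimilarityResult(score=score, n_matched_peaks=len(pairs), pairs=tuple(pairs))


def cosine_score(
    a: Spectrum,
    b: Spectrum,
    fragment_tolerance: float = DEFAULT_PARAMS.fragment_tolerance,
    sqrt_intensity: bool = False,
) -> SimilarityResult:
    """Direct cosine: normalized dot product over unshifted peak pairs."""
    if a.n_peaks == 0 or b.n_peaks == 0:
        raise EmptySpectrumError("cannot score an empty spectrum")
    return _score_from_pairs(
        match_peak_pairs(a, b, fragment_tolerance, shifts=(0.0,), sqrt_intensity=sqrt_intensity)
    )


def modified_cosine_score(
    a: Spectrum,
    b: Spectrum,
    fragment_tolerance: float = DEFAULT_PARAMS.fragment_tolerance,
    sqrt_intensity: bool = False,
) -> SimilarityResult:
    """Modified cosine: adds a pairing channel shifted by the precursor delta.

    With zero precursor delta this reduces exactly to :func:`cosine_score`
    (the two shift channels coincide and duplicate candidates are pruned by
    the one-to-one constraint).
    """
    if a.n_peaks == 0 or b.n_peaks == 0:
        raise EmptySpectrumError("cannot score an empty spectrum")
    delta = a.precursor_mz - b.precursor_mz
    shifts = (0.0,) if delta == 0.0 else (0.0, delta)
    return _score_from_pairs(
        match_peak_pairs(a, b, fragment_tolerance, shifts=shifts, sqrt_intensity=sqrt_intensity)
    )


def passes_thresholds(r: SimilarityResult, p: SearchParams) -> bool:
    """Inclusive acceptance gate: score >= threshold and enough matched peaks."""
    return r.score >= p.cosine_threshold and r.n_matched_peaks >= p.min_matched_peaks
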