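"""Per-taxon, per-sample and per-compound aggregation of search matches.

The headline statistic is, for every node of the taxonomic tree, the
fraction of that node's reference samples (non-blank LC-MS/MS files in its
subtree) containing at least one passing match to the query — the quantity
the pie charts on the results tree display. A file counts as matched at a
node iff it lies in the node's subtree, regardless of how many of its
spectra matched. Blank/QC files never enter totals or matched counts.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import pandas as pd

from .errors import MasstreeError, ParameterError, UnknownTaxonError
from .index import FragmentIndex, MatchResult, ReferenceDB, search
from .scoring import SearchParams, cosine_score, modified_cosine_score
from .spectra import Spectrum
from .taxonomy import RANK_WHITELIST, TaxonNode, TaxonTree

__all__ = [
    "TaxonSummary",
    "SampleMatchRate",
    "summarize_by_taxon",
    "summaries_to_table",
    "presence_matrix",
    "per_sample_match_rate",
    "export_mirror_plot_data",
]


@dataclass(frozen=True)
class TaxonSummary:
    """Matched vs total reference samples for one taxonomic node."""

    taxid: int
    rank: str
    name: str
    n_total_samples: int
    n_matched_samples: int

    @property
    def fraction_matched(self) -> float:
        return self.n_matched_samples / self.n_total_samples

    def __post_init__(self) -> None:
        if not 0 <= self.n_matched_samples <= self.n_total_samples:
            raise MasstreeError(
                f"taxid {self.taxid}: matched {self.n_matched_samples} exceeds "
                f"total {self.n_total_samples}"
            )


@dataclass(frozen=True)
class SampleMatchRate:
    """Fraction of one query sample's spectra with >=1 reference match."""

    sample_id: str
    n_query_spectra: int
    n_matched_spectra: int

    @property
    def percent_matched(self) -> float:
        return 100.0 * self.n_matched_spectra / self.n_query_spectra


def summarize_by_taxon(
    matches: Sequence[MatchResult],
    metadata,
    tree: TaxonTree,
) -> list[TaxonSummary]:
    """Roll spectrum-level matches up to per-node sample fractions.

    Requires :func:`masstree.taxonomy.attach_sample_counts` to have run on
    the tree. Returns one summary per node with at least one sample, in
    preorder (tree traversal) order.
    """
    by_file = {m.dataset_filename: m for m in metadata}
    matched_files: set[str] = set()
    for m in matches:
        if m.ref_file not in by_file:
            raise MasstreeError(f"match references unknown file {m.ref_file!r}")
        if not by_file[m.ref_file].is_blank_or_qc:
            matched_files.add(m.ref_file)

    matched_direct: dict[int, int] = {}
    for f in matched_files:
        entry = by_file[f]
        if entry.ncbi_taxid not in tree:
            raise UnknownTaxonError(
                f"matched file {f!r} has taxid {entry.ncbi_taxid} absent from tree"
            )
        matched_direct[entry.ncbi_taxid] = matched_direct.get(entry.ncbi_taxid, 0) + 1

    matched_subtree: dict[int, int] = {}

    def accumulate(node: TaxonNode) -> int:
        total = matched_direct.get(node.taxid, 0) + sum(
            accumulate(c) for c in node.children
        )
        matched_subtree[node.taxid] = total
        return total

    accumulate(tree.root)

    out = []
    for node in tree.preorder():
        if node.n_samples > 0:
            out.append(
                TaxonSummary(
                    taxid=node.taxid,
                    rank=node.rank,
                    name=node.name,
                    n_total_samples=node.n_samples,
                    n_matched_samples=matched_subtree[node.taxid],
                )
            )
    return out


def summaries_to_table(summaries: Sequence[TaxonSummary]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "ncbi_taxid": s.taxid,
                "rank": s.rank,
                "name": s.name,
                "n_total_samples": s.n_total_samples,
                "n_matched_samples": s.n_matched_samples,
                "fraction_matched": s.fraction_matched,
            }
            for s in summaries
        ],
        columns=[
            "ncbi_taxid",
            "rank",
            "name",
            "n_total_samples",
            "n_matched_samples",
            "fraction_matched",
        ],
    )


def presence_matrix(
    summaries_by_query: Mapping[str, Sequence[TaxonSummary]],
    rank: str,
    tree: TaxonTree,
) -> pd.DataFrame:
    """Compounds x taxa matrix of matched-sample fractions at one rank.

    Rows are query compounds (mapping order), columns are the tree's taxa
    at ``rank`` in preorder traversal order; cells are ``fraction_matched``
    (0 where the compound was not detected in that taxon). All queries must
    have been summarized against the same tree.
    """
    if rank not in RANK_WHITELIST:
        raise ParameterError(f"rank {rank!r} not in {RANK_WHITELIST}")
    columns = [
        node.name for node in tree.preorder() if node.rank == rank and node.n_samples > 0
    ]
    col_taxids = [
        node.taxid for node in tree.preorder() if node.rank == rank and node.n_samples > 0
    ]
    data = {}
    for query, summaries in summaries_by_query.items():
        frac = {s.taxid: s.fraction_matched for s in summaries}
        data[query] = [frac.get(t, 0.0) for t in col_taxids]
    return pd.DataFrame.from_dict(data, orient="index", columns=columns)


def per_sample_match_rate(
    query_sets: Mapping[str, Sequence[Spectrum]],
    db: ReferenceDB,
    index: FragmentIndex,
    params: SearchParams,
) -> list[SampleMatchRate]:
    """Percentage of each sample's query spectra with >=1 library match.

    This is the per-sample statistic used to compare cohorts (e.g. dietary
    groups): each sample contributes one percentage, computed under the
    supplied thresholds. Samples with no query spectra are excluded with a
    warning.
    """
    out: list[SampleMatchRate] = []
    for sample_id, spectra in query_sets.items():
        spectra = list(spectra)
        if not spectra:
            warnings.warn(f"sample {sample_id!r} has no query spectra; excluded")
            continue
        n_matched = sum(1 for s in spectra if search(db, index, s, params))
        out.append(
            SampleMatchRate(
                sample_id=sample_id,
                n_query_spectra=len(spectra),
                n_matched_spectra=n_matched,
            )
        )
    return out


def export_mirror_plot_data(
    query: Spectrum, match: MatchResult, db: ReferenceDB
) -> str:
    """JSON for a mirror plot: both peak lists plus the matched-pair list.

    Shared peaks are flagged on both sides and each pair carries the m/z
    shift it used (0 for direct, precursor delta for the analog channel).
    """
    try:
        ref = db.spectrum_by_id(match.ref_spectrum_id)
    except KeyError:
        raise MasstreeError(
            f"match references unknown spectrum {match.ref_spectrum_id!r}"
        ) from None
    if match.analog:
        result = modified_cosine_score(query, ref)
    else:
        result = cosine_score(query, ref)
    shared_q = {p.index_a for p in result.pairs}
    shared_r = {p.index_b for p in result.pairs}
    doc = {
        "query_id": query.spectrum_id,
        "ref_spectrum_id": ref.spectrum_id,
        "score": result.score,
        "n_matched_peaks": result.n_matched_peaks,
        "query_peaks": [
            {"mz": float(m), "intensity": float(i), "shared": k in shared_q}
            for k, (m, i) in enumerate(zip(query.mz, query.intensity))
        ],
        "ref_peaks": [
            {"mz": float(m), "intensity": float(i), "shared": k in shared_r}
            for k, (m, i) in enumerate(zip(ref.mz, ref.intensity))
        ],
        "pairs": [
            {
                "query_index": p.index_a,
                "ref_index": p.index_b,
                "shift": p.shift_used,
                "product": p.product,
            }
            for p in result.pairs
        ],
    }
    return json.dumps(doc, indent=1)
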