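"""Per-taxon summaries, presence matrices, per-sample match rates and
mirror-plot export."""

from __future__ import annotations

import json

import numpy as np
import pytest

from masstree.aggregate import (
    export_mirror_plot_data,
    per_sample_match_rate,
    presence_matrix,
    summarize_by_taxon,
)
from masstree.errors import MasstreeError, ParameterError
from masstree.fixtures import FixtureSpec, generate_fixture_set, generate_query_set
from masstree.index import (
    MatchResult,
    build_fragment_index,
    build_reference_db,
    file_level_matches,
    search,
)
from masstree.scoring import SearchParams
from masstree.spectra import Spectrum, preprocess_spectrum
from masstree.taxonomy import attach_sample_counts, build_tree, read_lineage_table


def _match_for(entry, query_id="q"):
    return MatchResult(query_id, f"{entry.dataset_filename}:scan:1",
                       entry.dataset_filename, entry.ncbi_taxid, 0.9, 5, 0.0, False)


# ---------------------------------------------------------------------------
# summarize_by_taxon
# ---------------------------------------------------------------------------

def test_zero_matches_all_fractions_zero(ref_db, tree):
    summaries = summarize_by_taxon([], ref_db.metadata, tree)
    assert summaries, "every populated node should be summarized"
    assert all(s.fraction_matched == 0.0 for s in summaries)


def test_fully_matched_species_fraction_one(ref_db, tree):
    species_node = next(n for n in tree.preorder() if n.rank == "species" and n.n_samples > 0)
    entries = [
        m for m in ref_db.metadata
        if m.ncbi_taxid == species_node.taxid and not m.is_blank_or_qc
    ]
    matches = [_match_for(e) for e in entries]
    summaries = {s.taxid: s for s in summarize_by_taxon(matches, ref_db.metadata, tree)}
    assert summaries[species_node.taxid].fraction_matched == 1.0
    for anc in tree.ancestors(species_node.taxid):
        s = summaries[anc]
        assert s.n_matched_samples == len(entries)
        assert s.fraction_matched == pytest.approx(len(entries) / s.n_total_samples)


def test_partial_match_fraction_arithmetic(ref_db, tree):
    genus_node = next(n for n in tree.preorder() if n.rank == "genus" and n.n_samples >= 5)
    in_subtree_taxids = {n.taxid for n in genus_node.preorder()}
    entries = [
        m for m in ref_db.metadata
        if m.ncbi_taxid in in_subtree_taxids and not m.is_blank_or_qc
    ][:2]
    summaries = {
        s.taxid: s
        for s in summarize_by_taxon([_match_for(e) for e in entries], ref_db.metadata, tree)
    }
    s = summaries[genus_node.taxid]
    assert s.n_matched_samples == 2
    assert s.fraction_matched == pytest.approx(2 / s.n_total_samples)


def test_match_to_unknown_file_is_error(ref_db, tree):
    bogus = MatchResult("q", "x", "DS/nonexistent.mgf", 41, 0.9, 5, 0.0, False)
    with pytest.raises(MasstreeError, match="unknown file"):
        summarize_by_taxon([bogus], ref_db.metadata, tree)


def test_parent_matched_superset_of_children(ref_db, frag_index, tree, query_truth):
    queries, _ = query_truth
    all_matches = []
    for q in queries:
        all_matches.extend(file_level_matches(search(ref_db, frag_index, q)))
    summaries = {s.taxid: s for s in summarize_by_taxon(all_matches, ref_db.metadata, tree)}
    for node in tree.preorder():
        if node.taxid not in summaries:
            continue
        child_sum = sum(
            summaries[c.taxid].n_matched_samples
            for c in node.children
            if c.taxid in summaries
        )
        assert summaries[node.taxid].n_matched_samples >= child_sum


def test_root_fraction_is_distinct_matched_over_total(ref_db, frag_index, tree, query_truth):
    queries, _ = query_truth
    all_matches = []
    for q in queries:
        all_matches.extend(search(ref_db, frag_index, q))
    summaries = {s.taxid: s for s in summarize_by_taxon(all_matches, ref_db.metadata, tree)}
    by_file = {m.dataset_filename: m for m in ref_db.metadata}
    distinct = {
        m.ref_file for m in all_matches if not by_file[m.ref_file].is_blank_or_qc
    }
    nonblank_total = sum(1 for m in ref_db.metadata if not m.is_blank_or_qc)
    root = summaries[tree.root.taxid]
    assert root.n_matched_samples == len(distinct)
    assert root.n_total_samples == nonblank_total


# ---------------------------------------------------------------------------
# presence_matrix
# ---------------------------------------------------------------------------

def test_presence_matrix_single_hit(ref_db, tree):
    species_node = next(n for n in tree.preorder() if n.rank == "species" and n.n_samples > 0)
    entry = next(
        m for m in ref_db.metadata
        if m.ncbi_taxid == species_node.taxid and not m.is_blank_or_qc
    )
    summaries = summarize_by_taxon([_match_for(entry)], ref_db.metadata, tree)
    pm = presence_matrix({"compound": summaries}, "species", tree)
    assert pm.shape[0] == 1
    assert (pm.loc["compound"] > 0).sum() == 1


def test_presence_matrix_disjoint_queries_orthogonal(ref_db, tree):
    species = [n for n in tree.preorder() if n.rank == "species" and n.n_samples > 0]
    e1 = next(m for m in ref_db.metadata if m.ncbi_taxid == species[0].taxid)
    e2 = next(m for m in ref_db.metadata if m.ncbi_taxid == species[1].taxid)
    s1 = summarize_by_taxon([_match_for(e1)], ref_db.metadata, tree)
    s2 = summarize_by_taxon([_match_for(e2)], ref_db.metadata, tree)
    pm = presence_matrix({"c1": s1, "c2": s2}, "species", tree)
    assert float((pm.loc["c1"] * pm.loc["c2"]).sum()) == 0.0


def test_presence_matrix_row_marginals_recount(ref_db, frag_index, tree, query_truth):
    queries, truth = query_truth
    summaries_by_query = {}
    for q, t in zip(queries, truth):
        if t.kind != "exact":
            continue
        matches = file_level_matches(search(ref_db, frag_index, q))
        summaries_by_query[q.spectrum_id] = summarize_by_taxon(
            matches, ref_db.metadata, tree
        )
    pm = presence_matrix(summaries_by_query, "species", tree)
    for qid, summaries in summaries_by_query.items():
        n_matched_species = sum(
            1 for s in summaries if s.rank == "species" and s.n_matched_samples > 0
        )
        assert int((pm.loc[qid] > 0).sum()) == n_matched_species


def test_presence_matrix_cells_equal_summary_fractions(ref_db, frag_index, tree, query_truth):
    queries, _ = query_truth
    matches = file_level_matches(search(ref_db, frag_index, queries[0]))
    summaries = summarize_by_taxon(matches, ref_db.metadata, tree)
    pm = presence_matrix({"q": summaries}, "species", tree)
    by_name = {s.name: s for s in summaries if s.rank == "species"}
    for name in pm.columns:
        assert pm.loc["q", name] == pytest.approx(by_name[name].fraction_matched)


def test_presence_matrix_bad_rank_rejected(tree):
    with pytest.raises(ParameterError):
        presence_matrix({}, "tribe", tree)


# ---------------------------------------------------------------------------
# per_sample_match_rate
# ---------------------------------------------------------------------------

def test_all_reference_copies_sample_scores_100(ref_db, frag_index):
    sample = [
        preprocess_spectrum(Spectrum("c%d" % i, s.precursor_mz, s.mz.copy(), s.intensity.copy()))
        for i, s in enumerate(ref_db.spectra[:5])
    ]
    (rate,) = per_sample_match_rate({"s": sample}, ref_db, frag_index, SearchParams())
    assert rate.percent_matched == 100.0


def test_all_decoy_sample_scores_0(ref_db, frag_index, query_truth):
    queries, truth = query_truth
    decoys = [q for q, t in zip(queries, truth) if t.kind == "decoy"]
    (rate,) = per_sample_match_rate({"s": decoys}, ref_db, frag_index, SearchParams())
    assert rate.percent_matched == 0.0


def test_planted_mixture_rate_is_exact(ref_db, frag_index, query_truth):
    """A sample with 3 planted copies and 7 decoys scores exactly 30%."""
    queries, truth = query_truth
    exact = [q for q, t in zip(queries, truth) if t.kind == "exact"][:3]
    decoys = [q for q, t in zip(queries, truth) if t.kind == "decoy"][:5]
    rng = np.random.default_rng(3)
    extra_decoys = [
        preprocess_spectrum(
            Spectrum(f"xd{i}", float(rng.uniform(200, 1000)),
                     np.sort(rng.uniform(1200, 1900, 12)), rng.exponential(1, 12) + 0.01)
        )
        for i in range(7 - len(decoys))
    ]
    sample = exact + decoys + extra_decoys
    (rate,) = per_sample_match_rate({"s": sample}, ref_db, frag_index, SearchParams())
    assert rate.percent_matched == pytest.approx(30.0)


def test_empty_sample_excluded_with_warning(ref_db, frag_index):
    with pytest.warns(UserWarning, match="no query spectra"):
        rates = per_sample_match_rate({"empty": []}, ref_db, frag_index, SearchParams())
    assert rates == []


def test_cohort_with_more_planted_matches_has_higher_mean(tmp_path):
    """Parameter recovery: a cohort generated with a higher planted
    plant-match probability yields a strictly higher mean percent_matched."""
    spec = FixtureSpec(seed=11, n_exact_queries=40, n_decoy_queries=40,
                       n_analog_queries=0)
    lineage_path, mgf_paths, metadata_path = generate_fixture_set(spec, tmp_path)
    db = build_reference_db(mgf_paths, metadata_path)
    index = build_fragment_index(db)
    queries, truth = generate_query_set(spec, db)
    queries = [preprocess_spectrum(q) for q in queries]
    exact = [q for q, t in zip(queries, truth) if t.kind == "exact"]
    decoy = [q for q, t in zip(queries, truth) if t.kind == "decoy"]

    rng = np.random.default_rng(5)

    def cohort(p_plant, n_samples, tag):
        sets = {}
        for k in range(n_samples):
            picks = [
                (exact if rng.random() < p_plant else decoy)[
                    int(rng.integers(len(exact)))
                ]
                for _ in range(10)
            ]
            sets[f"{tag}{k}"] = picks
        return sets

    high = per_sample_match_rate(cohort(0.7, 6, "hi"), db, index, SearchParams())
    low = per_sample_match_rate(cohort(0.2, 6, "lo"), db, index, SearchParams())
    assert np.mean([r.percent_matched for r in high]) > np.mean(
        [r.percent_matched for r in low]
    )


# ---------------------------------------------------------------------------
# Mirror-plot export
# ---------------------------------------------------------------------------

def test_mirror_plot_self_match_all_shared(ref_db, frag_index):
    ref = ref_db.spectra[8]
    query = preprocess_spectrum(
        Spectrum("q", ref.precursor_mz, ref.mz.copy(), ref.intensity.copy())
    )
    (match,) = [
        m for m in search(ref_db, frag_index, query) if m.ref_spectrum_id == ref.spectrum_id
    ]
    doc = json.loads(export_mirror_plot_data(query, match, ref_db))
    assert all(p["shared"] for p in doc["query_peaks"])
    assert all(p["shared"] for p in doc["ref_peaks"])
    assert len(doc["pairs"]) == doc["n_matched_peaks"]


def test_mirror_plot_zero_pair_forced_export(ref_db):
    ref = ref_db.spectra[0]
    query = preprocess_spectrum(
        Spectrum("q", ref.precursor_mz, ref.mz + 500.0, ref.intensity.copy())
    )
    forced = MatchResult("q", ref.spectrum_id, ref.source_file, None, 0.0, 0, 0.0, False)
    doc = json.loads(export_mirror_plot_data(query, forced, ref_db))
    assert not any(p["shared"] for p in doc["query_peaks"])
    assert doc["pairs"] == []


def test_mirror_plot_dangling_reference_is_error(ref_db, query_truth):
    queries, _ = query_truth
    bogus = MatchResult("q", "no-such-spectrum", "DS/x.mgf", None, 0.9, 3, 0.0, False)
    with pytest.raises(MasstreeError, match="unknown spectrum"):
        export_mirror_plot_data(queries[0], bogus, ref_db)
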