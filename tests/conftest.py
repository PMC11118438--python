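"""Shared fixtures: one synthetic study generated once per session."""

from __future__ import annotations

import pytest

from masstree.fixtures import FixtureSpec, generate_fixture_set, generate_query_set
from masstree.index import build_fragment_index, build_reference_db
from masstree.spectra import preprocess_spectrum
from masstree.taxonomy import attach_sample_counts, build_tree, read_lineage_table


@pytest.fixture(scope="session")
def fixture_spec():
    return FixtureSpec(seed=0)


@pytest.fixture(scope="session")
def fixture_paths(fixture_spec, tmp_path_factory):
    out = tmp_path_factory.mktemp("fixture_set")
    lineage_path, mgf_paths, metadata_path = generate_fixture_set(fixture_spec, out)
    return {"lineages": lineage_path, "mgfs": mgf_paths, "metadata": metadata_path}


@pytest.fixture(scope="session")
def ref_db(fixture_paths):
    return build_reference_db(fixture_paths["mgfs"], fixture_paths["metadata"])


@pytest.fixture(scope="session")
def frag_index(ref_db):
    return build_fragment_index(ref_db, bin_width=0.05)


@pytest.fixture(scope="session")
def lineages(fixture_paths):
    return read_lineage_table(fixture_paths["lineages"])


@pytest.fixture(scope="session")
def tree(lineages, ref_db):
    return attach_sample_counts(build_tree(lineages), ref_db.metadata)


@pytest.fixture(scope="session")
def query_truth(fixture_spec, ref_db):
    queries, truth = generate_query_set(fixture_spec, ref_db)
    return [preprocess_spectrum(q) for q in queries], truth
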