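# masstree

Taxonomically-informed MS/MS spectral library search.

Untargeted metabolomics experiments identify molecules by their tandem mass
spectra (MS/MS): a precursor ion is selected and fragmented, and the
resulting fragment m/z–intensity pattern acts as a molecular fingerprint.
Given a curated reference library of LC-MS/MS runs of biological extracts —
each run tied to an organism via an NCBI taxonomy ID — a natural question
is: *in which taxa has this spectrum been observed?* `masstree` answers it:
it matches a query spectrum against every spectrum of every reference file,
rolls the hits up the taxonomic tree, and reports, for each node, the
fraction of that taxon's samples containing the queried molecule. This is
the chemotaxonomic view behind MASST-style repository-scale search tools,
reimplemented as an offline, fully testable library and CLI.

## The score

Two spectra are compared by the **cosine similarity over tolerance-matched
peak pairs**. With per-spectrum intensities scaled to unit Euclidean norm
(`ŵ = w / ‖w‖₂`), candidate pairs are all `(i, j)` with
`|mzₐ,ᵢ − mz_b,ⱼ| ≤ τ_frag`, and the score is

    S(a, b) = Σ_{(i,j) ∈ M} ŵₐ,ᵢ · ŵ_b,ⱼ

where `M` is a one-to-one pairing chosen greedily by descending intensity
product. The **modified cosine** adds a second pairing channel shifted by
the precursor m/z difference `Δ = mz_prec(a) − mz_prec(b)`, so fragments
that retain a modified substructure still pair; this is what lets *analog
search* find adducts, multimers, and structural analogs. A hit is accepted
when `S ≥ 0.7` and at least 3 peaks pair (defaults; all thresholds
adjustable). All tolerances are absolute Daltons (default 0.05 Da for both
precursor and fragments); analog mode widens the precursor gate to a
configurable ±200 Da.

Search is accelerated by a binned fragment-ion inverted index
(bin = `⌊mz / 0.05⌋`) with a losslessness guarantee: an index-free
brute-force twin is part of the package and the test suite asserts exact
equivalence.

## Worked example

Generate a synthetic study (taxonomy, reference library of MGF files +
metadata table, planted queries with ground truth), then search one
spectrum:

```sh
masstree make-fixtures --out fixtures --seed 0
# -> fixtures: 76 reference files, lineages lineages.tsv, queries.mgf + ground_truth.tsv

masstree search --peaks-file peaks.txt --precursor-mz 959.4698 \
  --ref-mgf-dir fixtures/library --metadata fixtures/library/metadata.tsv \
  --lineages fixtures/lineages.tsv --out results
# -> 1 spectrum-level matches -> results
```

`results/matches.tsv` (abridged):

```
query_id     ref_file                                       taxon_name            score               n_matched_peaks
peaks-query  SyntheticPlants/Genus03x02_species02_rep1.mgf  Genus03x02 species02  0.999999999825103   20
```

The query was a planted copy of a reference spectrum, so it comes back at
cosine ≈ 1.0 with all 20 peaks matched, pointing at the one reference file
(sample) it was planted from. `results/taxon_summary.tsv` shows the same
hit aggregated over the tree — one matched sample out of 72 at the root,
i.e. `fraction_matched = 0.0139` for the kingdom, rising to 1/2 at the
planted species:

```
rank     name             n_total_samples  n_matched_samples  fraction_matched
kingdom  Synplantae       72               1                  0.0138888…
…
species  Genus03x02 species02  2           1                  0.5
```

`results/tree.json` holds the result tree pruned to matched taxa and their
ancestors (the structure a pie-chart tree view renders), and
`manifest.json` records every effective parameter.

Batch mode (`masstree batch --query-mgf … | --usi-table …`) writes one
bundle per query plus a combined match table. USI inputs are resolved
strictly offline through `--usi-map`; there are no network calls anywhere.
An example config for the stricter per-sample dietary-cohort statistic
(cosine 0.7, ≥4 matched peaks, 0.02 Da) ships in
`examples/diet_params.yaml`, and the same parameter set is available in
code as `masstree.DIET_PARAMS` together with
`masstree.per_sample_match_rate`, which computes the percentage of a
sample's spectra matching the library — the per-sample statistic used to
compare cohorts.

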