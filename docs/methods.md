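# Methods

## The model

`masstree` implements repository-scale MS/MS spectral search with taxonomic
aggregation. The reference side is a set of LC-MS/MS files; each file holds
many MS/MS spectra and one metadata row: `Dataset/Filename`, repository
accession, taxon name, NCBI taxid, ReDU availability, a blank/QC flag, and
the file's USI. The query side is a single spectrum (precursor m/z + peak
list), a USI resolved through an injectable offline resolver, or a batch
(MGF or USI table). The output is (i) the list of reference files in which
the query was observed and (ii) per-node matched/total sample fractions on
a rank-filtered NCBI-style taxonomic tree.

### Similarity

Both scores are normalized dot products over one-to-one tolerance-matched
peak pairs; intensities are unit-L2-normalized per spectrum. We use raw
intensities by default; a square-root transform is available
(`SearchParams.sqrt_intensity`) but off, because the raw-intensity cosine
is the variant most repository search backends use and the choice only
matters for spectra with extreme dynamic range. The modified cosine adds a
pairing channel shifted by the precursor delta; with zero delta it
*is* the direct cosine. A peak can be consumed by at most one pair across
both channels.

### Pairing: greedy, and when it is exact

Candidate pairs are every `(i, j, shift)` within the fragment tolerance;
final pairs are selected greedily by descending intensity product with
deterministic tie-breaks (smaller |Δm/z|, then lower indices). Greedy
matches common practice and is O(C log C) in the candidate count, versus
exponential for exhaustive assignment. Because pair weights are the rank-1
products `ŵₐ,ᵢ·ŵ_b,ⱼ`, greedy is provably optimal whenever the candidate
graph decomposes into complete bipartite tolerance clusters (the
rearrangement inequality); it can be strictly suboptimal only on
*asymmetric adjacency chains* — peaks spaced so that one query peak sees
two reference peaks while its neighbor sees only one, which requires
several peaks within ~2 tolerance widths of each other. The test suite
verifies exact agreement with an exhaustive assignment oracle on ≤8-peak
spectra in the regimes searches actually encounter (well-separated peaks,
jittered partial copies, 2×2 ambiguity clusters) and we document, rather
than hide, that adversarial chains can open a gap; scores remain valid
lower bounds and never exceed 1.

### Thresholds

Defaults: cosine ≥ 0.7, ≥ 3 matched peaks, 0.05 Da precursor and fragment
tolerance, analog off. Comparisons are inclusive. The analog precursor
window defaults to ±200 Da — wide enough for common glycosylations,
adducts and small multimer offsets — and is configurable; no standard
value exists, so this is a deliberate package choice. Charge is stored but
never used for scoring: precursor m/z is compared as observed, so
multiply-charged species match at their m/z, not their neutral mass. All
tolerances are absolute Daltons; ppm tolerances are out of scope.

### Preprocessing

Reference and query spectra are canonicalized by removing non-positive
intensities, sorting by m/z and merging exact-duplicate m/z values by
intensity sum. Precursor-window exclusion and a relative intensity floor
exist but are **off by default**, so a user pasting raw peaks searches
exactly what they pasted. Preprocessing is idempotent; a spectrum with no
surviving peaks is an error, not an empty result.

### Index and losslessness

The fragment index bins every reference peak at `⌊mz/w⌋` with
`w = fragment tolerance` by default. Exact search gates candidates by
precursor window, then requires that at least `min_matched_peaks` *query
peaks* have ≥1 candidate reference peak in their bin or either neighbor.
We count qualifying query peaks rather than distinct shared bins: two true
pairs can fall in one bin, so a shared-bin count can undercount pairs and
drop true hits, while the per-query-peak count upper-bounds the achievable
pair count and is lossless whenever `w ≥ tolerance` (every in-tolerance
partner lies within one bin width, hence in a probed bin). Analog mode
scores the full precursor window without the bin prefilter — the unshifted
bins cannot see the shifted channel — keeping analog candidate generation
lossless too. `brute_force_search` shares the filtering/sorting contract
and none of the index code; equivalence between the two paths is asserted
on every fixture database and in the acceptance run (1,000 queries against
10,000 spectra).

File-level results deduplicate to the best-scoring hit per reference file
(a sample "contains" the molecule if any of its spectra matched); both
spectrum-level and file-level tables are written.

## Taxonomy

Lineage records (taxid + ordered rank path) are assembled into a tree
restricted to kingdom, phylum, class, order, family, genus, subgenus,
species, subspecies and varietas; other levels are dropped with children
re-attached to the nearest kept ancestor. We do not pad missing
intermediate ranks — a species whose lineage lacks a subgenus simply hangs
off its genus. Duplicate taxids collapse; conflicting parentage is a hard
error; multiple kingdoms join under a synthetic root (taxid 1, rank
"no rank"). Sample counts attach each non-blank file at its taxid's node —
possibly internal, when a sample is only identified to genus or family —
and propagate so that every node's total equals its direct attachments
plus its children's totals. Blank/QC files are searchable but never enter
totals or matched counts. Trees serialize to taxid-labelled Newick
(topology) and to a versioned JSON carrying name/rank/counts; pruning to a
match set keeps exactly the matched nodes and their ancestors with counts
untouched.

The per-node statistic is **fraction of samples matched**, computed over
files, not spectra (one file = one sample = one vote per node); per-spectrum
counts remain available in the match tables. `presence_matrix` pivots
per-query summaries into a compounds × taxa matrix at one rank (tree
traversal column order), and `per_sample_match_rate` computes, per query
sample, the percentage of its spectra with ≥1 library match — the
statistic used to compare cohorts. Cohort significance testing is left to
standard statistics libraries; the package's contract ends at the per-sample
percentages.

## Synthetic data

The fixture generator emulates the full input surface with three seeded
stages (taxonomy, library, queries), each on its own RNG stream spawned
from the master seed, so outputs are byte-identical across platforms for a
fixed seed and one stage's parameters never perturb another's draws.

* **Taxonomy**: one kingdom/phylum/class/order trunk over `n_families`
  families × `genera_per_family` × `species_per_genus` (defaults 4×3×3),
  taxids sequential from 1000.
* **Library**: `files_per_species` replicate files (default 2), 10 spectra
  per file, 8–30 fragments drawn uniformly in [50, precursor−10] Da with
  precursors in 200–1000 Da and exponential intensities; 5% additional
  blank/QC files without taxids. Fragment m/z values are redrawn until
  spaced ≥0.2 Da apart.
* **Queries**: planted exact copies with Gaussian fragment jitter
  (sd 0.01 Da) and random dropout of up to 20% of peaks — bounded so the
  kept intensity-squared share stays ≥0.6, which lower-bounds the planted
  cosine at √0.6 ≈ 0.775 > 0.7, and never below 3 peaks; analog queries as
  *unjittered* copies shifted by +162.053 Da (a hexose-like mass, the most
  common glycosylation offset) on precursor and all fragments, so the
  gating check is exact to 1e-9; decoys with fragments drawn from
  1200–1900 Da, strictly above every reference fragment, so they can never
  share a fragment bin with any reference spectrum.

The ≥0.2 Da spacing plus sd 0.01 jitter makes tolerance pairing of a
planted copy unambiguous, so planted recall = 100% and decoy false
positives = 0 are consequences of the construction, not statistical
accidents. That is deliberate — the fixtures certify the *machinery*
(pairing, scoring, indexing, aggregation), not detection power on real
data. Real spectra have correlated fragment ladders, isotope peaks,
chimeric co-isolation, collision-energy-dependent intensities and peaks
closer than 0.2 Da; passing these tests therefore says nothing about
recall/precision trade-offs on real libraries, only that the engine
computes the declared quantities exactly.

The acceptance run scales the same generator to 200 files × 50 spectra
(10,000 reference spectra) with 1,000 queries (600 exact / 200 analog /
200 decoy) — a size chosen so the full indexed-vs-brute-force comparison
completes in well under a minute while exercising thousands of candidate
evaluations per property.

## Numerical choices and degenerate inputs

Scores are clipped to [0, 1] (float noise can push a perfect self-match to
1 + 1e-16). Result ordering is fully deterministic: (score desc,
|precursor Δ| asc, reference spectrum id asc), with the same contract in
both search paths, so outputs are diffable. Ties in pairing break by
smaller |Δm/z|, then lower indices. Empty spectra raise
`EmptySpectrumError` everywhere rather than scoring 0. MGF round trips
preserve precursor, charge and sorted peak lists to 1e-6; the metadata
reader treats {"yes", "true", "1"} (case-insensitive) as truthy flags and
admits missing taxids only on blank/QC rows. A PEPMASS line with two
values keeps only the first (the second is precursor intensity).

## Known limitations

* Score parity with any hosted search backend is not promised: the exact
  intensity weighting and precursor-peak handling of production services
  are not public, and our cosine is the documented raw-intensity,
  unit-norm variant.
* Greedy pairing can under-score adversarially clustered spectra (see
  above); the gap never inflates a score.
* Analog search over a ±200 Da window scores every candidate in the window
  (no prefilter); on very large libraries this is the slow path by design,
  trading speed for guaranteed losslessness.
* The USI resolver is offline-only; resolving public USIs requires the
  caller to supply the spectra (`--usi-map`).
* No ppm tolerances, neutral-loss scoring, or spectral-entropy scores.
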