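# Batch search settings for per-sample dietary-cohort comparisons:
# stricter than the single-query defaults (more matched peaks, tighter
# tolerances) to suppress false positives when thousands of spectra per
# fecal sample are searched at once.
cosine: 0.7
min_peaks: 4
prec_tol: 0.02
frag_tol: 0.02
analog: false
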