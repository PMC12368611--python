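# Age-sampling weights for the synthetic cohort, by 5-year bin over the
# 5-74 year span.  These weights are an editable design fixture describing a
# plausible single-site lifespan recruitment (children and young adults
# over-represented, tapering toward the oldest bins); they are not measured
# from any published cohort.
bin_edges: [5, 10, 15, 20, 25, 30, 35, 40, 45, 50, 55, 60, 65, 70, 74]
weights:  [14, 18, 16, 15, 14, 13, 12, 12, 11, 11, 10,  9,  8,  7]
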