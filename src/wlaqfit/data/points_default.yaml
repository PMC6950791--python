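# Default m-WLAQ point weights per answer option (options 1-4).
# Intensity items (q6, q10, q15) are weighted most heavily; the per-question
# maxima sum to 44, the top of the PA-score scale.
q6: [0, 3, 5, 10]
q8: [0, 1, 2, 3]
q9: [1, 2, 3, 4]
q10: [0, 3, 5, 10]
q13: [0, 1, 2, 3]
q14: [1, 2, 3, 4]
q15: [0, 3, 5, 10]
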