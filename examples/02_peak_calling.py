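"""Call peaks on one track with the cutoff ladder and permutation FDR.

A per-track ceiling (mean + 6 SD) defines a ladder of cutoffs from 90%
down to 15%; windows of 500 bp need >=4 probes above the cutoff (3, then
2, when the window holds fewer).  Permuting the probe values 20 times
gives each cutoff level a false discovery rate.
"""

import tilemark as tm
from tilemark.peaks import cutoff_fdr_table

study = tm.simulate_study(tm.StudyDesign().scaled(400, 1), seed=7)
layout = study.layout
track = study.tracks[("BTSC1", "H3K27me3")]

print(f"theoretical maximum: {tm.theoretical_maximum(track):.3f} log2 units")

params = tm.PeakCallerParams(seed=7)
peaks = tm.estimate_fdr(track, layout, params)
stringent = tm.filter_stringent(peaks, params.fdr_threshold)
print(f"generous peaks: {len(peaks)}  (union over the whole ladder)")
print(f"stringent peaks (FDR < {params.fdr_threshold}): {len(stringent)}")

print("\nper-cutoff observed vs randomized peak counts:")
table = cutoff_fdr_table(track, layout, params)
print(table.to_string(index=False, float_format=lambda v: f"{v:.3f}"))
# FDR near 0 at high cutoffs means those peaks never arise from permuted
# data; levels with no observed peaks have an undefined (NaN) FDR.
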