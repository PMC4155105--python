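"""Simulate a small multi-cell-type epigenome survey with planted truth.

Builds a promoter-tile + long-region array layout, plants focal peaks,
bivalent promoters (both morphologies) and >50 kb broad domains, and
simulates log2(ChIP/input) probe tracks with Gaussian noise.
"""

import tilemark as tm

design = tm.StudyDesign().scaled(400, 2)  # 400 promoters, 2 x 500 kb regions
study = tm.simulate_study(design, seed=7)

print(f"layout: {study.layout.n_probes} probes, "
      f"{len(study.layout.promoter_tiles)} promoter tiles, "
      f"{len(study.layout.long_regions)} long regions")
print(f"truth table: {len(study.truth)} planted feature rows")

kinds = study.truth.features["feature_kind"].value_counts()
print("planted features by kind:")
print(kinds.to_string())

cell, mark = "fNSC", "H3K4me3"
n_pos = len(study.truth.positive_promoters(cell, mark))
print(f"\n{cell}/{mark}: {n_pos} promoters carry a planted focal peak")
# Each positive promoter has a ~600 bp amplitude-2.0 (log2, i.e. 4-fold)
# feature inside its 3.5 kb upstream / 750 bp downstream window; the rest
# of the track is baseline plus N(0, 0.3) probe noise.
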