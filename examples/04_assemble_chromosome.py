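"""Assemble a partial tumour chromosome from subclonal breakpoints.

After fitting, clonally divergent segments connected by subclonal
breakpoints are evidence of a whole derivative chromosome gained or lost in
one clone.  This walks the high-confidence subclonal breakpoints outward
from a divergent seed segment.
"""

import numpy as np

import clonebreak as cb

scenario = cb.Scenario(n_chromosomes=3, chromosome_length=10_000_000,
                       n_events=8, n_resample=20, descendant_fraction=0.3,
                       seed=5)
truth, segments, breakpoints = cb.simulate(scenario)
result = cb.fit(segments, breakpoints, cb.FitConfig(max_iter=25))

kept_bp, kept_seg = cb.select_confident_subclonal(result, breakpoints)
print(f"high-confidence subclonal breakpoints: {len(kept_bp)}")
print(f"merged divergent segments >= 1 Mb:      {len(kept_seg)}")

cn = result.cn_array()
divergent = np.flatnonzero(np.any(cn[:, 0, :] != cn[:, -1, :], axis=1))
if len(divergent):
    walk = cb.assemble_chromosome(result, breakpoints,
                                  seed_segment=int(divergent[0]))
    # each step is one reference segment traversed + (forward) or - (reverse)
    print("assembled walk:")
    for idx, orient in walk.steps:
        row = result.segment_cn.iloc[idx]
        strand = "+" if orient > 0 else "-"
        print(f"  chr{row['chromosome']}:{row['start']}-{row['end']} ({strand})")
    if walk.cycle:
        print("  (cycle detected; truncated at first revisit)")
else:
    print("no clonally divergent segments inferred in this simulation")
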