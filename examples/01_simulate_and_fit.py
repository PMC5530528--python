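"""Simulate a two-clone tumour mixture and infer its structure.

Generates a small genome (3 chromosomes, 60 x 500 kb segments) carrying a
known evolutionary history, simulates segment read counts, fits the joint
segment/breakpoint copy-number model and compares the result with truth.
"""

import numpy as np

import clonebreak as cb

scenario = cb.Scenario(
    n_chromosomes=3, chromosome_length=10_000_000, n_events=6,
    n_resample=20, normal_fraction=0.5, descendant_fraction=0.25, seed=7)
truth, segments, breakpoints = cb.simulate(scenario)
print(f"simulated {len(segments)} segments, {len(breakpoints)} breakpoints")
print(f"true clone fractions (normal, ancestral, descendant): "
      f"{np.round(truth.clone_fractions(), 3)}")

result = cb.fit(segments, breakpoints, cb.FitConfig(max_iter=25))
report = cb.score(result, truth)

# rho: inferred mixture proportions; segment accuracy: length-weighted
# fraction of the genome with both clones' allele copies exactly right
print(f"inferred fractions: {np.round(result.rho, 3)}  (ELBO {result.elbo:.1f})")
print(f"segment accuracy:   {report.segment_accuracy:.3f}")
print(f"breakpoint accuracy: {report.breakpoint_accuracy:.3f}")
print(f"normal fraction error (absolute): "
      f"{report.normal_fraction_abs_error:.3f}")
print(result.segment_cn.head(8).to_string(index=False))
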