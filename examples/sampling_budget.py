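"""Bookkeeping of adaptive-seeding MD campaigns.

An MSM is only as good as its aggregate sampling.  This example encodes
the two-batch conventional-MD campaign used per protein system (10 start
conformations x 3 replicas x 300 ns, then 20 x 2 x 300 ns) and the
accelerated-MD production campaign (5 replicas x 500 ns), and prints the
per-system totals in microseconds.
"""

from loopdyn.pipeline import (
    SamplingScheme,
    conventional_md_scheme,
    gamd_production_scheme,
    sampling_budget,
)

scheme = conventional_md_scheme()
for i, batch in enumerate(scheme.batches, 1):
    n, r, dur = batch
    us = sampling_budget(SamplingScheme([batch]))
    print(f"conventional batch {i}: {n} starts x {r} replicas x {dur:g} ns "
          f"= {us:g} us")
print(f"conventional total per system: {sampling_budget(scheme):g} us")
print(f"accelerated production per system: "
      f"{sampling_budget(gamd_production_scheme()):g} us")
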