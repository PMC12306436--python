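"""Simulate a labelled interval dataset and inspect its structure.

Builds 100 reference intervals with the default size ranges, derives the
ten truth-bearing queries per interval plus the multi-interval complex
queries, and writes everything to ./example_out/n100.
"""

from ivbench import SimConfig, simulate_reference, write_dataset

cfg = SimConfig(intvlnums=100, seed=1)
ref = simulate_reference(cfg)
manifest = write_dataset(ref, "example_out/n100")

print(f"intervals placed:   {manifest['intervals']}")
print(f"chromosomes used:   {manifest['chromosomes']}")
print(f"basic queries:      {manifest['basic_queries']}  (= 10 per interval)")
print(f"complex queries:    {manifest['complex_queries']}")
first = ref.intervals[ref.chrom_order[0]][0]
print(f"first interval:     {first.chrom}:{first.start}-{first.end} ({first.id})")
# The basic count is exactly 10x the interval count: five single-target
# overlap queries and five zero-target gap queries per reference interval.
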