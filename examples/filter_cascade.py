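"""Run the high-confidence/somatic filter cascade on a simulated sample.

The cascade keeps alterations with >= 2 discordant pairs and >= 2
soft-clipped reads, drops events larger than 10 Mb, subtracts alterations
matching the pooled normals within 100 bp, and removes breakpoints inside
blacklist intervals.
"""
from brehot import FilterConfig, SimulationConfig, filter_pipeline, simulate_germline_pair

cfg = SimulationConfig(n_samples=1, background_per_sample=40, support_range=(0, 6), seed=3)
pair = simulate_germline_pair(cfg, shared_fraction=0.3, jitter=50)
(sample_id, records), = pair.cancer_records.items()

blacklist = [("chr1", 0, 10_000_000)]  # e.g. a common-variant-dense region
stages = filter_pipeline(
    records,
    FilterConfig(),  # defaults: support 2/2, max size 10 Mb, tolerance 100 bp
    normal_records=pair.normal_records,
    blacklist=blacklist,
)
print(f"{sample_id}: {len(records)} raw alterations")
for stage, survivors in stages.items():
    print(f"  after {stage:9s}: {len(survivors)}")
# Support removes low-evidence calls, germline removes the ~30% of records
# shared with the pooled normals, blacklist removes chr1:0-10Mb breakpoints.
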