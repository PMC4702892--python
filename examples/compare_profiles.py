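"""Compare a query breakpoint profile against hotspots and other profiles.

Overlap counts are directional: they count QUERY breakpoints (each at most
once) that fall inside a hotspot interval, or within +/-window bases of a
target profile's breakpoint on the same chromosome.
"""
from brehot import SimulationConfig, compare_all, simulate_profiles

sim = simulate_profiles(
    SimulationConfig(n_samples=4, background_per_sample=60,
                     hotspot_loci=(("chr2", 15_000_000, 5_000, 1.0),), seed=5)
)
query, *targets = sim.profiles

hotspot_sets = {"chr2_hotspot": [("chr2", 14_990_000, 15_010_000)]}
profiles = {t.sample_id: t for t in targets}
report = compare_all(query, hotspot_sets, profiles, window=10_000)

print(f"query {report.query_id} ({len(query)} breakpoints), window {report.window} bp")
print(report.rows.to_string(index=False))
# Every sample hits the planted chr2 locus, so each target profile shares at
# least that breakpoint neighbourhood with the query; the hotspot-set row
# counts query breakpoints inside the interval itself.
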