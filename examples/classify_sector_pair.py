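"""Classify a red/white sector pair into recombination events.

Runs the full round trip for one colony: plant an event, render both
sectors, call segments, and classify.  The conversion tract's 3:1 / 4:0
sub-regions place the initiating DSB before or after replication.
"""

import oxloh as ox

genome = ox.build_genome("default", seed=1)
spec = ox.PlantedEvent("G1_DSB_CO", "chrIV", break_kb=1278.0,
                       tract_d1=13.0, tract_d2=15.0, donor="W")
d_red, d_white = ox.plant_event(genome, spec, seed=2)

segs_red = ox.call_pipeline(ox.render_profile(d_red, 0.1, seed=3), genome)[2]
segs_white = ox.call_pipeline(ox.render_profile(d_white, 0.1, seed=4), genome)[2]

events = ox.classify_sector_pair(ox.SectorPair(segs_red, segs_white, genome))
for ev in events:
    print(f"{ev.type} on {ev.chromosome}, donor {ev.donor}, phase {ev.phase}")
    for t in ev.tracts:
        print(f"  tract {t.start_kb:.1f}-{t.end_kb:.1f} kb  class {t.tract_class}")
    if ev.co_breakpoint:
        print(f"  crossover breakpoint between {ev.co_breakpoint[0]:.1f} and "
              f"{ev.co_breakpoint[1]:.1f} kb")

# Expected: one CO whose tract has a 3:1 region (one repaired chromatid)
# followed by a 4:0 region (both repaired chromatids), hence phase G1 -
# the DSB predated replication.
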