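"""Simulate a small variety panel with planted truth.

Builds the demo configuration (two 200 kb chromosomes, 24 varieties from a
3-way admixed background, one planted sweep, balancing region, CNV and PAV
dropout), generates the panel and prints what was planted where.
"""

from chickdiv import demo_config, simulate_genome, simulate_panel

cfg = demo_config(seed=3)
genome = simulate_genome(cfg)
panel, track, truth = simulate_panel(genome, cfg)

print(f"genome: {genome.chromosomes}, {len(genome.genes)} genes "
      f"({genome.cds_fraction():.0%} CDS)")
print(f"panel: {panel.n_sites} candidate variant sites x {panel.n_samples} varieties")
print(f"mean depth per variety: {track.genome_mean().mean():.1f}x")
print("\nplanted truth:")
print("  sweep:", truth.sweeps.to_dict(orient="records"))
print("  balancing:", truth.balancing.to_dict(orient="records"))
print("  CNV:", truth.cnv_events.to_dict(orient="records"))
print("  PAV regions:", truth.pav_regions.to_dict(orient="records"))
print("\ntrue ancestry of the first 3 varieties (rows sum to 1):")
print(truth.Q0[:3].round(3))
# Downstream stages are validated against exactly this ledger: every number
# the callers recover should trace back to one of the lines above.
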