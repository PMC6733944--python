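"""Metagene occupancy profile around tRNA gene TSSs.

Simulates a genome and a ChIP-exo-style tag track whose per-gene peaks
are planted 10 bp upstream of the TSS, then recovers the peak position
from the strand-aware average profile.
"""

from pol3prox import SimulationConfig, compute_profile, simulate_genome, simulate_tag_track

config = SimulationConfig(seed=42)
sim = simulate_genome(config)
track = simulate_tag_track(sim, config)

profile = compute_profile(track, sim.trnas, flank=300)

print(f"genes averaged:        {profile.n_regions}")
print(f"planted peak offset:   {config.peak_offset} bp")
print(f"recovered peak offset: {profile.peak_offset} bp")
print(f"mean occupancy at peak: {profile.values.max():.2f} tags/gene")
print(f"background level:       {profile.values[:200].mean():.3f} tags/gene")

# The recovered argmax matches the planted offset: the profiler reads
# minus-strand genes right-to-left, so upstream means upstream of
# transcription, not of the chromosome.
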