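"""Generate a synthetic terminator benchmark and look at its structure.

Positives are ~50 bp sequences carrying a GC-rich inverted repeat (the
hairpin stem), a short loop and a poly-T tail; negatives are 80 bp
i.i.d. background, mirroring the length asymmetry of curated benchmarks.
"""

from pseterm import SimulationConfig, generate_background, generate_terminators

config = SimulationConfig(n_pos=5, n_neg=3, seed=11)
positives = generate_terminators(config)
negatives = generate_background(3, config.neg_len, seed=12)

print("positives (50 bp, hairpin + poly-T):")
for record in positives:
    print(f"  {record.id}: {record.bases}")
print("negatives (80 bp background):")
for record in negatives:
    print(f"  {record.id}: {record.bases}")
print()
print("Every positive contains a TTTTTTT tract (the poly-T terminator tail);")
print("the 9 bp stem and its reverse complement flank a 5 bp loop just upstream.")
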