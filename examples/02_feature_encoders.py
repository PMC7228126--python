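"""Encode one DNA sequence with each of the five feature families.

Shows the numbers each encoder produces for a short terminator-like
sequence and what they mean.
"""

import numpy as np

from pseterm import (
    PseKNCConfig,
    base_content,
    build_pwm,
    load_property_table,
    nucleotidepro,
    pseknc,
    pwm_score,
)

table = load_property_table()
seq = "ACGCCGCGTTAACGCGGCGTTTTTTTA"  # stem, loop, reverse-complement stem, poly-T

bc = base_content(seq)
print("base content:", np.round(bc.values(), 3))
print("  (atContent, gcContent, atgcRatio, gcSkew, atSkew —")
print("   composition and strand-asymmetry of the sequence)")

pwm = build_pwm([seq, seq[2:], seq[:-2]], k=2, pseudocount=0.25)
print(f"2-pwm score of the sequence itself: {pwm_score(seq, pwm):.3f}")
print("  (mean per-site log-odds against a uniform background; positive")
print("   means the sequence matches the site-specific dinucleotide profile)")

vec = pseknc(seq, PseKNCConfig(K=4, lam=3, mode="parallel"), table)
print(f"Pse4NC-I: {vec.size} components summing to {vec.sum():.6f}")
print(f"  first 4^4 = 256 are weighted 4-mer frequencies, last 3 are the")
print(f"  pseudo-components (physicochemical correlation tiers): {np.round(vec[-3:], 4)}")

flat = nucleotidepro(seq, table, L_max=40)
print(f"Nucleotidepro: {flat.size} values = 47 properties x 40 positions,")
print(f"  zero-padded beyond position {len(seq) - 1}; first base row starts {flat[:3]}")
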