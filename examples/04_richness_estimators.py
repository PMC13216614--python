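"""The six per-cell richness measures on a toy abundance vector.

ES50 is the expected species count in a random draw of 50 individuals
(controls sampling effort); Chao2 and ACE extrapolate toward asymptotic
richness from rare species; Inverse Simpson is the evenness-weighted
effective species number.
"""
from oceangap import divstats

abund = [120, 40, 18, 9, 5, 3, 2, 1, 1, 1, 1]
print("abundances:", abund)
print(f"S_obs           = {len(abund)}")
print(f"ES50            = {divstats.es_n(abund, 50):.3f}")
print(f"ACE             = {divstats.ace(abund):.3f}")
print(f"Inverse Simpson = {divstats.inverse_simpson(abund):.3f}")
# Chao2 needs incidence across samples: 10 species seen, 4 in exactly one
# sample and 2 in exactly two samples, over 4 samples
print(f"Chao2(m=4, S=10, q1=4, q2=2) = {divstats.chao2_from_counts(10, 4, 2, 4)}")
# ES50 < S_obs because singletons are rarely captured in 50 draws, while
# ACE > S_obs because the many rare species imply more remain unseen.
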