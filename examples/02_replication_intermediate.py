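"""Decompose the linking-number difference of an early replication
intermediate into its five components.

The fixture reproduces the in-vivo state of a 2 kb plasmid 25%% through
replication: charge -12 in the unreplicated region (supercoiling) and
+2 in the replicated region (right-handed precatenanes), total
dLk = -10.  The decomposition reads the block sums of the parental
contribution matrix and splits each region charge geometrically.
"""
from ritopo import decompose_ri, early_invivo_config, make_ri

ri = make_ri(early_invivo_config(seed=1))
dec = decompose_ri(ri)
print(f"q_unrep = {dec.q_unrep:+.2f}   (prescribed -12: dTw + Wr of the "
      "unreplicated region)")
print(f"q_wrap  = {dec.q_wrap:+.2f}   (inter-region wrapping)")
print(f"q_rep   = {dec.q_rep:+.2f}   (precatenanes + their plectonemes)")
print("components c1..c5:",
      ", ".join(f"{c:+.2f}" for c in dec.components))
print(f"total dLk = {dec.delta_lk_total:+.3f} "
      f"(baseline Lk0 of the unreplicated region: {dec.baseline_unrep:.0f})")
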