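"""Detect juxtaposition (collision) events on early and late
replication intermediates and classify their geometry.

A collision is a pair of contour-distal duplex sites within 10 nm --
candidate substrate geometry for a type II topoisomerase.  Each event
gets a type (1: within the unreplicated region, 2: between regions,
3: within the precatenanes, 4: within plectonemes of precatenanes),
a chirality and a topological sign.
"""
from ritopo import (detect_collisions, early_invivo_config,
                    late_invivo_config, make_ri, tally)

for name, cfg in (("early", early_invivo_config(1)),
                  ("late", late_invivo_config(1))):
    events = detect_collisions(make_ri(cfg))
    print(f"{name} stage: {len(events)} events")
    print(tally(events))
    print()
print("Negative supercoiling gives right-handed negative crossings in the")
print("unreplicated region; positive precatenanes are right-handed too.")
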