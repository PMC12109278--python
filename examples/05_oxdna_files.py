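"""Write a conformation to oxDNA topology/configuration files and read
it back.  The files load in oxView; a JSON sidecar records which
nucleotide ranges form the unreplicated region and the two daughters.
"""
import tempfile
from pathlib import Path

import numpy as np

from ritopo import (TrajectoryFrame, early_invivo_config, make_ri,
                    read_oxdna, write_oxdna)

ri = make_ri(early_invivo_config(seed=1))
out = Path(tempfile.mkdtemp())
write_oxdna(TrajectoryFrame(0.0, ri), out / "ri.top", out / "ri.dat")
frames = read_oxdna(out / "ri.top", out / "ri.dat")
back = frames[0].conformation
err = np.abs(back.parentalA.points - ri.parentalA.points).max()
print(f"wrote {out/'ri.top'} (+ .dat, + region map)")
print(f"roundtrip: {len(frames)} frame, n_unrep = {back.n_unrep}, "
      f"max coordinate error = {err:.1e} nm")
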