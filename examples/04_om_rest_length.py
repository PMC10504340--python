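"""OM rest length from a turgid cell and its flattened spheroplast.

Renders a turgid cell to a mask, measures its surface of revolution
A_turgid, generates an amorphous spheroplast blob whose membrane area
A_OM = 2a + w*s matches a chosen target, and converts the area surplus into
a rest length l_OM = l_turgid + (A_OM - A_turgid)/(pi*w).
"""

import numpy as np

from envmorph import RodSpec
from envmorph.pipeline import rest_length_pipeline

rod = RodSpec(length=4.0, width=1.0, n_vertices=256)

matched = rest_length_pipeline(rod, target_A_OM=None, seed=3)
print("matched membrane areas (no stored stress):")
print(f"  A_turgid = {matched.A_turgid:.2f} um^2, A_OM = {matched.A_OM:.2f} um^2")
print(f"  l_OM = {matched.l_OM:.3f} um, l_OM/l_turgid = "
      f"{matched.ratio_rest_to_turgid:.3f}")

surplus = rest_length_pipeline(rod, target_A_OM=np.pi * 1.0 * 4.8, seed=4)
print("20 % membrane surplus:")
print(f"  l_OM = {surplus.l_OM:.3f} um (ground truth 4.800), "
      f"ratio = {surplus.ratio_rest_to_turgid:.3f}")
# A ratio near 1 means the membrane holds just enough material to sheathe
# the turgid cell at rest — no tension stored in the envelope.
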