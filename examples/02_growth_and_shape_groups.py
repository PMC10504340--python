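"""Instantaneous growth rates and shape-group comparison.

Simulates two cell populations: regular cells (low width CV) growing fast
and misshapen cells (high width CV) growing slower, then groups them by
shape defect and compares growth-rate distributions with a two-sample
Kolmogorov-Smirnov test — the analysis used to link envelope defects to a
metabolic burden.
"""

import numpy as np

from envmorph import GrowthTrackSpec, gen_growth_track, group_by_shape, instantaneous_growth_rate
from envmorph.morphometrics import WidthStats

rng = np.random.default_rng(0)
cells = []
for i in range(50):  # regular cells: CV ~0.03, rate ~0.022/min
    spec = GrowthTrackSpec(area0=2.0, rate_true=rng.normal(0.022, 0.002),
                           noise_cv=0.03, n_frames=40, seed=i)
    rates = instantaneous_growth_rate(gen_growth_track(spec))[:, 1]
    cells.append((WidthStats(1.0, rng.normal(0.03, 0.005), 36), rates.mean()))
for i in range(50):  # misshapen cells: CV ~0.15, rate ~0.012/min
    spec = GrowthTrackSpec(area0=2.0, rate_true=rng.normal(0.012, 0.002),
                           noise_cv=0.03, n_frames=40, seed=100 + i)
    rates = instantaneous_growth_rate(gen_growth_track(spec))[:, 1]
    cells.append((WidthStats(1.0, rng.normal(0.15, 0.01), 36), rates.mean()))

out = group_by_shape(cells, bin_edges=[0.08])
for g in out.groups:
    print(f"{g.label:22s} n={g.n:3d}  median rate {g.median_rate:.4f}/min "
          f"[{g.q25:.4f}, {g.q75:.4f}]")
(_, d, p), = out.ks_adjacent
print(f"KS between groups: D={d:.3f}, p={p:.2e}")
print("p << 0.001: misshapen cells grow significantly slower.")
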