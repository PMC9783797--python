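"""Static vs full-sequence normalization on published winter-wheat points.

Four winter-wheat sample points were observed on four 2018 dates; the table
lists the raw single-phase index plus its static (per-scene) and
full-sequence normalizations.  Fitting the affine min-max map from just two
printed pairs reproduces the remaining printed values, and the raw ordering
of p1@May-10 vs p4@Mar-23 survives the full-sequence map but flips under
the per-scene static maps - the failure mode that motivates normalizing
over the whole image sequence at once.
"""

import numpy as np

from ecoqi import apply_normalization, params_from_anchors
from ecoqi.data import WHEAT_POINT_SERIES
from ecoqi.raster import Raster

df = WHEAT_POINT_SERIES

a = df[(df.point == "p2") & (df.date == "2018-06-11")].iloc[0]
b = df[(df.point == "p3") & (df.date == "2018-04-08")].iloc[0]
params = params_from_anchors((a.original, a.full_sequence), (b.original, b.full_sequence))
print(f"global map recovered from two pairs: min={params.min:.4f}, max={params.max:.4f}")

out = apply_normalization(Raster.from_array([df.original.to_numpy()]), params).data[0]
err = np.abs(out - df.full_sequence.to_numpy())
print(f"reproduces all {len(df)} printed full-sequence cells, max error {err.max():.4f}")

p1 = df[(df.point == "p1") & (df.date == "2018-05-10")].iloc[0]
p4 = df[(df.point == "p4") & (df.date == "2018-03-23")].iloc[0]
print(f"\nraw:           p1@0510 = {p1.original:.3f}  >  p4@0323 = {p4.original:.3f}")
print(f"full-sequence: p1@0510 = {p1.full_sequence:.3f}  >  p4@0323 = {p4.full_sequence:.3f}  (order kept)")
print(f"static:        p1@0510 = {p1.static:.3f}  <  p4@0323 = {p4.static:.3f}  (order inverted!)")
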