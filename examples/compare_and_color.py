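"""Two-sample comparison statistics and the value -> color mapping.

Shows the three comparison modes on a toy matrix, then how the automatic
color scale bins the resulting values onto the YlOrRd ramp.
"""

import numpy as np

from omicsview import (ExpressionDataset, auto_scale, bin_index,
                       compare_samples, palette_color)

ds = ExpressionDataset(
    ["psbA", "rbcL", "cab1", "lhcb2"],
    ["embryo", "endosperm"],
    np.array([[120.0, 40.0], [90.0, 90.0], [15.0, 60.0], [33.0, 0.0]]),
)

for mode in ("difference", "fold", "difference_fold"):
    v = compare_samples(ds, "embryo", "endosperm", mode)
    pairs = ", ".join(f"{e}={x:g}" for e, x in zip(v.entity_ids, v.v))
    print(f"{mode:<16} {pairs}  (excluded zero-denominator: "
          f"{v.n_excluded_zero_denom})")
# fold = embryo/endosperm; difference_fold = fold - 1; lhcb2 has an
# endosperm value of 0 and is excluded from the two ratio modes

v = compare_samples(ds, "embryo", "endosperm", "fold")
scale = auto_scale(v, n_bins=9)
print(f"\nauto color range [{scale.vmin:g}, {scale.vmax:g}], 9 bins:")
for e, x in zip(v.entity_ids, v.v):
    b = bin_index(scale, x)
    print(f"  {e}: value {x:g} -> bin {b} -> {palette_color(scale, b)}")
# higher values land in darker bins; icons in a compartment are drawn in
# this ascending light-to-dark order
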