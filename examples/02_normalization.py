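"""The four per-sequence normalizations and the fixed global min-max map.

The pipeline uses the global map (x - 45) / 135 for both radial inputs and
aortic targets so they share one scale, and inverts it exactly to report
predictions in mmHg.  The per-sequence schemes are retained for comparison;
their statistics change from record to record, which is why they cannot be
inverted consistently across a dataset.
"""

import numpy as np

from capwave import NormalizationScheme, global_minmax_inverse, normalize

x = np.array([80.0, 95.0, 120.0, 150.0, 110.0])
print("raw pressures (mmHg):", x)
for method in ("minmax", "zscore", "mean", "unitnorm"):
    print(f"{method:>9}:", np.round(normalize(x, method), 4))

scheme = NormalizationScheme()  # global min-max, a=45, b=135
x_norm = scheme.apply(x)
print("   global:", np.round(x_norm, 4))
back = global_minmax_inverse(x_norm)
print("round-trip max abs error (mmHg):", np.abs(back - x).max())
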